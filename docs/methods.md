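# Methods

## Scope and data model

`cbscreen` models the discovery loop for colchicine-binding-site (CBS)
β-tubulin inhibitors as a pipeline of small, testable stages. The feature
vocabulary is fixed at four kinds — hydrogen-bond donor (HBD), acceptor
(HBA), hydrophobic contact (HC) and aromatic interaction (AI) — each a
tolerance sphere (anchor, radius) with an optional unit direction (D–H
vector for donors, lone-pair side for acceptors, ring normal for AI). A
pharmacophore model adds exclusion volumes (Xvols; forbidden spheres
standing in for protein bulk) and a `min_required` match count, which
defaults to *all* features: the reference campaign's models behave as
full-match queries, and partial matching is available but opt-in.

Positive/negative ionizable features are deliberately out of scope: they
appear in no final CBS model we emulate, and adding untested feature kinds
would dilute the matcher's test coverage.

## Feature perception

Typing is purely topological (SMARTS-driven), so counts are identical
across conformers and only anchors move with geometry:

* donors: `[#7,#8;!H0]`;
* acceptors: any O; N unless pyrrole-type aromatic (`nX3`) or amide
  (`NX3` bonded to `C=O`). Halogens are hydrophobic and never acceptors by
  default; `halogen_acceptors` turns fluorine into an acceptor surrogate
  for campaigns that treat CF₃ fluorine as one;
* AI: every fully aromatic ring (centroid + SVD normal);
* HC: the centroid of each maximal bond-connected group of ≥2 low-polarity
  heavy atoms (C, S, Cl, Br, I with no charged or polar neighbor).
  Group-level rather than per-atom HC features keep model feature counts in
  the 3–8 range typical of published CBS models.

Default tolerances are 1.5 Å radii for all kinds and a 30° direction cone.
Commercial modeling packages never publish their perception rules, so
these are explicit, conventional approximations and every rule is
configurable (YAML rule table).

## Conformers and properties

Conformer ensembles come from RDKit ETKDGv3 with an explicit seed, capped
at 25 conformers per record (the "FAST" regime of common conformer
generators), with duplicate pruning at 0.5 Å symmetry-aware heavy-atom
RMSD — a rigid ring collapses to one distinct geometry. The seven
descriptors used for decoy matching and triage (MW, #N, #O, rotatable
bonds, HBD, HBA, Crippen logP) delegate to RDKit's standard
implementations; the test suite cross-checks them against Open Babel on a
20-molecule panel where both toolkits implement the same conventions.

## Matching

Matching one conformer against a model:

1. **Correspondence graph.** Nodes are kind-compatible (model feature,
   ligand feature) pairs. An edge joins two nodes when the pairwise
   anchor-distance discrepancy is ≤ ε + r_i + r_k (ε = 0.5 Å; r are the
   two model radii). By the triangle inequality, any mapping that can pass
   the final tolerance test is a clique here, so nothing is lost before
   verification, and a self-match always survives.
2. **Clique enumeration** (networkx maximal cliques) plus all sub-mappings
   of admissible size, because a larger clique can fail verification while
   a subset passes.
3. **Rigid verification.** Least-squares (Kabsch) superposition of the
   mapped anchors; accept only if every ligand anchor lies in its model
   feature's tolerance sphere, directional features agree within the cone
   (ring normals compared up to sign), and no ligand heavy atom comes
   within r + 1.2 Å (van der Waals allowance) of an Xvol center.

The fit score is the transparent surrogate `|mapping| + (1 − rmsd/2 Å)`
clipped at zero: matched-feature count dominates, RMSD breaks ties.
Proprietary fit-score formulas are not reproducible and are never used as
acceptance surfaces. Best-conformer policy: highest score, then lowest
RMSD, then lowest conformer index — fully deterministic. The test suite
holds the matcher to exact agreement with an exhaustive
permutation-search oracle on hundreds of random instances.

## Model derivation

**Structure-based.** Ligand features are kept only where the protein
supports the interaction: donor–acceptor heavy-atom distance ≤ 3.5 Å with
D–H···A angle ≥ 130° (skipped when no explicit H is present); a ligand
acceptor requires a protein *nitrogen* partner, since with element-only
protein atoms N is the only reliably donor-capable choice; HC and AI
features need ≥3 apolar protein atoms (C/S) within a 4.5 Å shell. With
`include_waters`, a water bridging ligand and protein (both within 3.5 Å)
contributes the polar feature, aimed at the water — this reproduces the
water-mediated hydrogen-bond networks seen in CBS crystal structures
without modeling water energetics. Xvols are placed on every protein heavy
atom within 6.0 Å of the ligand (radius 1.0 Å). All cutoffs are standard
crystallographic-interaction values and configurable. Xvol counts depend
strongly on placement details and are not treated as a comparable quantity.

**Ligand-based.** The reference active is the one with the most perceived
features (ties by record id); every other active is aligned to the
reference features by the same correspondence matcher (best conformer,
best partial mapping, `min_required=1` during alignment). *Shared* mode
keeps reference features mapped in every active; *merged* mode keeps the
union of aligned features deduplicated by kind within 1.0 Å. Alignment
uses each ensemble's best-matching conformer; whether published campaigns
aligned single conformers or ensembles is unstated, and best-per-ensemble
is the choice that never discards an embeddable geometry.

**Optimization** is a greedy hill climb: candidate moves are single-feature
removal, per-feature radius ±0.25 Å (bounded to [0.5, 3.0] Å) and Xvol
growth (+0.25 Å radius). A move is accepted only if EF strictly increases
and sensitivity stays above a configurable floor; the climb stops at the
edit budget or a local optimum. Xvol *shell* growth from the source
complex is not available to a bare model (models do not carry their
protein), so radius growth is the steric-tightening analogue. Models
ending with EF < 4 carry a discard flag.

## Enrichment metrics

For A actives in a screened database of D = A + decoys records:
sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/D,
yield of actives (precision) YoA = TP/(TP+FP), and enrichment factor
EF = YoA/(A/D). EF conventions vary across the literature; the A/D
denominator is the one that exactly reproduces every printed value of the
packaged reference campaign table (95 actives, 4901 decoys), which the
test suite verifies cell by cell. Printed-style rounding is decimal
half-up (0.125 → 0.13), not banker's. YoA and EF are reported as missing —
never zero — when a model retrieves nothing, and such models are flagged
for discard.

## Decoy generation

The pipeline mirrors standard property-matched benchmark construction:
compute the actives' per-descriptor window; filter the candidate pool —
min–max by default (the literal "lowest to highest" reading), mean ± k·SD
as the alternative, exposed as a switch because published descriptions
support both; drop anything whose salt-stripped canonical SMILES matches a
known active; then sphere-exclusion (leader) clustering on 2048-bit
radius-2 Morgan fingerprints at Tanimoto 0.6, one representative per
cluster, deterministically subsampled to the target size (default 4901,
the reference campaign's decoy count). Output invariants — window
membership and actives exclusion — are re-asserted on every returned
record. The original campaign's exact decoy identities are unrecoverable
(they depend on a ~10⁶-compound commercial snapshot); only the procedure
is reproducible.

## Hit triage

Rule-of-five limits (MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10) with boundary
values passing ("no more than" semantics). PAINS and Brenk alerts use
RDKit's curated FilterCatalog; custom text catalogs (one
`SMARTS label` per line) cover reactive/unstable-group lists that
campaigns usually handle by visual inspection — an explicit approximation
of that step. Ranking is (models matched desc, fit score desc, record id
asc); failing records are excluded or, optionally, demoted.

## Assay analysis

Percent inhibition normalizes each kinetic trace to the blank at
t = 41.5 min (the evaluation timepoint of the emulated assay), with linear
interpolation between plate-reader samples and first-timepoint baseline
subtraction (a raw-endpoint switch exists because published normalizations
rarely state this). Activity bands default to <25 inactive, 25–50 weak,
50–75 moderate, ≥75 high — concentration-agnostic defaults, configurable,
since reported band labels drift with test concentration.

Dose–response fitting uses the variable-slope log-logistic model
`y = 100 / (1 + 10^((log10 c − log10 IC50)·h))` with y as % polymerization,
so h > 0 describes an inhibitor (the sign convention is stated here because
assay software writes the same equation with either sign). The 95% CI
comes from the asymptotic covariance of log10 IC50 with a t quantile at
n − 2 degrees of freedom — asymmetric on the concentration scale, like the
intervals assay software prints — with a pairs bootstrap fallback when the
covariance is unusable. Degenerate data (dynamic range < 10 percentage
points, or non-convergence) yields `converged=False` with a diagnostic
rather than an exception.

## Synthetic benchmarks

The feature-cloud benchmark is the workhorse: actives carry the model's
feature geometry jittered by N(0, σ) per coordinate plus 0–3 distractor
features, randomly rigid-transformed; decoys share the actives' kind-count
distribution with randomized geometry and are rejection-sampled against
the matcher so that, by construction, none embeds the model. Noise-free
actives are re-verified after generation by a direct known-correspondence
geometric check that is independent of the clique matcher. Benchmark
models default to 5 features scattered in an 8 Å cube with ≥2.5 Å
separation — enough geometric constraint that random decoy geometry
rarely embeds, keeping rejection sampling fast. Distractors force the
matcher to select sub-mappings rather than assume feature lists align.

Feature clouds deliberately bypass chemistry: they test the geometric
engine in isolation. The molecular benchmark (deterministic single-H
substituent decoration of template SMILES) covers the end-to-end path
through real molecules. What passing these benchmarks does *not* show:
robustness to conformer-generator undersampling of real flexible
molecules, tautomer/protonation ambiguity, or the property distributions
of commercial libraries.

The assay generator builds a logistic blank time course
(base 100 AU, amplitude 1000 AU, midpoint 15 min, width 5 min — shaped
like a typical fluorescence polymerization trace over 60 min) and scales
each dosed trace's amplitude-above-baseline by 1/(1 + (c/IC50)^h), so the
noise-free % inhibition is exact at every timepoint; Gaussian noise is
added per sample. A response-level generator (Gaussian noise in
percentage points) backs the IC50 recovery study: 100 replicates at
IC50 = 2.9 μM, h = 1, σ = 3 pp over an 8-point half-log dilution series —
the potency of the strongest inhibitor the emulated campaign reports, at
realistic duplicate-well noise.

## Workflow and determinism

Runs are driven by one YAML config with explicit seeds; validation reports
every offending field at once. Every stage output is a pure function of
(inputs, config, seeds): metric and consensus CSVs from identical configs
are byte-identical, and the manifest records config hash, package
versions, per-stage counts and per-model metrics.

## Not reproducible at desk scale

The identities of the emulated campaign's 11 experimentally confirmed
inhibitors and its printed IC50s (2.9/5.8/2.3 μM) rest on unpublished raw
fluorescence traces; its exact 4901-compound decoy set and full
commercial-library screens rest on proprietary database snapshots; and
proprietary software fit scores have no public formula. These quantities
are represented here by the packaged summary tables (as regression
fixtures for the arithmetic) and by the synthetic-benchmark and
simulation studies above, which test the same machinery under known
ground truth.
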