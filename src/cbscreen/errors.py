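"""Exception hierarchy shared across the toolkit."""


class CbscreenError(Exception):
    """Base class for all toolkit errors."""


class LibraryError(CbscreenError):
    """Problems reading or writing a compound library."""


class EmbeddingError(CbscreenError):
    """3D conformer embedding failed for a record."""


class EmptyModelError(CbscreenError):
    """Model derivation produced no pharmacophore features."""


class EditError(CbscreenError):
    """A model edit referenced a feature or exclusion volume that does not exist."""


class ConfigError(CbscreenError):
    """Invalid configuration value (unknown mode, bad rule table, ...)."""


class CatalogError(CbscreenError):
    """A structural-alert catalog failed to load or parse."""


class AssayError(CbscreenError):
    """Assay traces violate the analysis preconditions (e.g. dead blank)."""


class ValidationError(CbscreenError):
    """Workflow configuration failed validation.

    Carries the full list of offending fields so a run report can show
    every problem at once rather than the first.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
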