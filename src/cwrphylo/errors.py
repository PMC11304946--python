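"""Exception hierarchy shared across the package.

Each subclass maps onto one CLI exit code class: configuration errors exit 2,
data-validation errors 3, I/O errors 4 (see :mod:`cwrphylo.cli`).
"""


class CwrPhyloError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CwrPhyloError):
    """Bad option value, unknown method name, or invalid simulation config."""


class DataError(CwrPhyloError):
    """Invalid input data (trees or tables)."""


class MalformedInputError(DataError):
    """Unparseable Newick or table text; carries a character offset if known."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)
        self.offset = offset


class DuplicateTaxonError(DataError):
    """The same taxon name appears more than once where uniqueness is required."""


class DegenerateTreeError(DataError):
    """Tree has too few tips for the requested operation."""


class DegenerateHeightError(DataError):
    """Tree height is zero or numerically indistinguishable from zero."""


class NotUltrametricError(DataError):
    """Operation requires an ultrametric tree but the input is not."""


class InsufficientOverlapError(DataError):
    """Two trees share fewer than two tip labels."""


class MissingTaxonError(DataError):
    """A named taxon is absent from the distance matrix or knowledge base."""


class SchemaError(DataError):
    """A delimited-text input lacks a required column."""


class PackagingError(CwrPhyloError):
    """A packaged data file is missing or corrupt."""
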