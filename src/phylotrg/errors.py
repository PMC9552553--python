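"""Exception hierarchy for the phylotrg pipeline.

Every error raised by the package derives from :class:`PhyloTRGError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors.
"""


class PhyloTRGError(Exception):
    """Base class for all phylotrg errors."""


class NewickParseError(PhyloTRGError):
    """Malformed newick input; message carries the position when known."""


class SpeciesMapError(PhyloTRGError):
    """A gene-tree leaf could not be mapped to a species."""


class FormatError(PhyloTRGError):
    """A tabular file violates its declared column layout."""


class SchemaError(PhyloTRGError):
    """A typed table is missing a required column or carries illegal values."""


class DataError(PhyloTRGError):
    """Values are syntactically fine but semantically impossible
    (negative TPM, posterior outside [0, 1], ...)."""


class TreeStateError(PhyloTRGError):
    """An operation was applied to a tree in the wrong state
    (e.g. event annotation on an unrooted tree)."""


class ConfigError(PhyloTRGError):
    """Invalid run configuration (unknown key, threshold out of domain)."""
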