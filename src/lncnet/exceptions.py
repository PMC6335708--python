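"""Exception hierarchy for lncnet.

All lncnet-specific failures derive from :class:`LncnetError` so callers can
catch pipeline problems without masking programming errors.
"""


class LncnetError(Exception):
    """Base class for all lncnet errors."""


class ParseError(LncnetError):
    """A file could not be parsed; the message names the offending line."""


class ConfigError(LncnetError):
    """An invalid or internally inconsistent configuration."""


class ConstantVectorError(LncnetError):
    """Correlation requested for a constant expression vector (undefined)."""


class BipartiteError(LncnetError):
    """An id appears on both sides of the lncRNA-mRNA bipartition."""


class StructureError(LncnetError):
    """Invalid transcript structure input (e.g. mixed strands in one locus)."""
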