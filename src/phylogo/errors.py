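"""Exception hierarchy shared across the toolkit."""


class PhylogoError(Exception):
    """Base class for all toolkit errors."""


class StructureError(PhylogoError):
    """An input violates a structural invariant (cycle, dangling reference,
    cross-aspect edge, multiple roots per aspect, malformed tree)."""


class ParseError(PhylogoError):
    """A stream could not be parsed as the declared format."""


class TermLookupError(PhylogoError, KeyError):
    """A term accession is not present in the ontology graph."""


class InputError(PhylogoError, ValueError):
    """Numeric or set-valued inputs violate a documented precondition."""
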