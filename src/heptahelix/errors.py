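"""Exception hierarchy."""


class HeptahelixError(Exception):
    """Base class for all package errors."""


class ParseError(HeptahelixError):
    """A structure or config file could not be parsed."""


class EmptyStructureError(HeptahelixError):
    """A coordinate file contained no usable atoms."""


class ChainLookupError(HeptahelixError, KeyError):
    """Requested chain is absent from the structure."""


class AnchorInferenceError(HeptahelixError):
    """A required motif anchor could not be inferred for a helix."""


class LabelRangeError(HeptahelixError):
    """Arithmetic Ballesteros-Weinstein position fell outside 1..99."""


class InsufficientDataError(HeptahelixError):
    """Too few residues/atoms for the requested geometric analysis."""


class MeasurementError(HeptahelixError):
    """Atoms required for a distance mode are missing."""


class FeasibilityError(HeptahelixError):
    """A synthetic-structure request is geometrically impossible."""
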