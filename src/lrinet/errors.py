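"""Exception hierarchy for lri-net.

Validation problems (bad user input, malformed files, out-of-range
parameters) raise :class:`ValidationError`; the CLI maps these to exit
code 2 and everything else unexpected to exit code 1.
"""


class LriNetError(Exception):
    """Base class for all lri-net errors."""


class ValidationError(LriNetError):
    """Invalid user input: bad parameter, malformed file, inconsistent ids."""


class UnknownGeneError(ValidationError):
    """A gene identifier is not present in the network / matrix."""


class ParseError(ValidationError):
    """A file could not be parsed; message carries the offending location."""


class InsufficientDataError(ValidationError):
    """Too few samples (or genes) for the requested computation."""


class DegenerateGameError(LriNetError):
    """The network game has no active players (edgeless base network)."""


class CapacityError(LriNetError):
    """Problem size exceeds an enumeration cap (brute-force oracle)."""
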