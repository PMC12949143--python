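"""Exception hierarchy for rebreathe.

All domain errors derive from :class:`RebreatheError` so callers can catch
one base class at pipeline boundaries while the library raises precise
subclasses internally.
"""


class RebreatheError(Exception):
    """Base class for all rebreathe domain errors."""


class NoRespiratorySignalError(RebreatheError):
    """The trace carries no detectable breathing (running range below floor)."""


class InsufficientBreathsError(RebreatheError):
    """Fewer breaths were detected than the estimator requires (minimum 3)."""


class EndTidalError(RebreatheError):
    """An expiratory window is too short to resolve an end-tidal value."""


class NonRisingPetError(RebreatheError):
    """End-tidal CO2 failed to rise during rebreathing.

    Signals mouthpiece leakage or mis-segmentation: the weighted
    denominator of the ELV formula is non-positive.
    """


class KineticsFitError(RebreatheError):
    """The exponential wash-in fit did not converge or gave an unphysical rate."""


class TraceFormatError(RebreatheError):
    """A capnogram or pairs file could not be parsed."""
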