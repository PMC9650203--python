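"""Exception types raised across the pipeline."""


class ModwalkError(Exception):
    """Base class for all pipeline errors."""


class InsufficientDataError(ModwalkError):
    """Signal too short for the requested filtering or integration."""


class InsufficientCyclesError(ModwalkError):
    """Fewer than two paretic heel strikes: no gait cycle can be segmented."""


class NoEventsError(ModwalkError):
    """No threshold crossings found in the vertical ground reaction force."""


class MalformedEventsError(ModwalkError):
    """Gait events do not interleave validly (non-alternating contacts)."""


class ZeroChannelError(ModwalkError):
    """An EMG channel has no positive bin mean; amplitude normalization undefined."""


class UndefinedVAFError(ModwalkError):
    """A VAF partition has zero total sum of squares."""


class UndefinedMetricError(ModwalkError):
    """A ratio metric has a zero denominator (e.g. both anterior impulses zero)."""


class UndefinedRatioError(ModwalkError):
    """Interhemispheric ratio undefined: zero streamline weight in the denominator."""


class DegenerateBatchError(ModwalkError):
    """A scanner batch has fewer than two records; its variance cannot be estimated."""


class UndefinedCorrelationError(ModwalkError):
    """A correlation input is constant; the rank correlation is undefined."""
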