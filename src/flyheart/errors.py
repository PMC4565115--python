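"""Exception hierarchy for the flyheart pipeline."""


class FlyheartError(Exception):
    """Base class for all flyheart errors."""


class InputError(FlyheartError):
    """Invalid input data (bad array shape, empty table, out-of-range value)."""


class MetadataError(FlyheartError):
    """Missing or invalid acquisition metadata (e.g. no frame rate in sidecar)."""


class ParameterError(FlyheartError):
    """Invalid analysis or simulation parameter (Nyquist violation, bad window)."""


class VocabularyError(FlyheartError):
    """Stage label outside the controlled developmental-stage vocabulary."""


class RunawayFillError(FlyheartError):
    """Magic-wand fill flooded into the background (tolerance too high)."""


class SegmentationSeriesError(FlyheartError):
    """Too many frames failed to segment for the series to be usable."""
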