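class PeakDedupError(Exception):
    """Base class for all peakdedup errors."""


class UnsortedInputError(PeakDedupError):
    """Raised when a coordinate-sorted stream is required but violated."""


class MissingEvidenceError(PeakDedupError):
    """Raised when a record lacks the tags needed for a requested filter."""
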