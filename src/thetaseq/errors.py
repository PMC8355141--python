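"""Exception hierarchy for thetaseq."""


class ThetaseqError(Exception):
    """Base class for all thetaseq errors."""


class SchemaError(ThetaseqError):
    """An on-disk file does not conform to the expected schema."""


class SessionValidationError(ThetaseqError):
    """A session (or one of its components) violates a data-model invariant."""


class ChannelReferenceError(SessionValidationError):
    """A unit is mapped to an LFP channel that does not exist."""


class InsufficientDataError(ThetaseqError):
    """Not enough observations to compute the requested statistic."""


class NoPreferenceError(ThetaseqError):
    """A response table contains no spikes, so no preferred stimulus exists."""


class EmptyResultError(ThetaseqError):
    """An operation produced no usable output (e.g. all spikes excluded)."""
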