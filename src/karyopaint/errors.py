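"""Exception hierarchy shared across the pipeline stages."""


class KaryopaintError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(KaryopaintError, ValueError):
    """A numeric or categorical parameter is outside its valid range."""


class InvalidSequenceError(KaryopaintError, ValueError):
    """A sequence contains unexpected characters or has the wrong length."""


class CapacityError(KaryopaintError, ValueError):
    """A requested allocation exceeds what the pool or budget can provide."""


class InfeasibleDesignError(KaryopaintError, ValueError):
    """No placement/assignment satisfies the stated constraints."""


class ConsistencyError(KaryopaintError, ValueError):
    """Inputs contradict each other (e.g. a probe outside its scaffold)."""


class LookupError_(KaryopaintError, KeyError):
    """A referenced identifier does not exist."""


class ParseError(KaryopaintError, ValueError):
    """A standard-format record could not be parsed."""
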