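"""Exception hierarchy for erpstates."""


class ErpStatesError(Exception):
    """Base class for all erpstates errors."""


class InvalidInputError(ErpStatesError, ValueError):
    """An input violates a documented precondition."""


class NotReferencedError(InvalidInputError):
    """An operation that requires average-referenced (zero-mean) maps received data that is not."""


class UndefinedCorrelationError(InvalidInputError):
    """Spatial correlation requested for a zero-norm (flat) map."""


class MontageMismatchError(InvalidInputError):
    """Two objects indexed by different channel montages were combined."""


class ModelSelectionError(ErpStatesError):
    """The Krzanowski-Lai selection could not be carried out on the given k range."""


class IncompleteDesignError(ErpStatesError):
    """A repeated-measures analysis received an unbalanced/incomplete subject x cell table."""
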