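"""Exception types shared across the package."""


class TbnetError(Exception):
    """Base class for all package errors."""


class NotConnectedError(TbnetError):
    """Raised when an operation requires a connected graph."""


class PreconditionError(TbnetError):
    """An operation's stated precondition is violated."""


class CapExceeded(TbnetError):
    """A bounded exhaustive search ran out of budget.

    The result is *indeterminate*, not false; callers that aggregate
    results (e.g. the classifier) record the cap hit instead of guessing.
    """

    def __init__(self, what: str, cap: int):
        self.what = what
        self.cap = cap
        super().__init__(f"search cap exceeded in {what} (cap={cap})")
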