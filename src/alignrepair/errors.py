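"""Exception hierarchy shared by all modules."""

from __future__ import annotations


class AlignRepairError(Exception):
    """Base class for all errors raised by this package."""


class InputError(AlignRepairError):
    """A file could not be parsed, or refers to unknown entities."""


class PreconditionError(AlignRepairError):
    """An input violates a stated precondition of the method.

    The repair method assumes each input ontology is individually coherent
    and that its subsumption relation is acyclic; violations are reported
    through this error rather than silently repaired.
    """


class SearchCapExceeded(AlignRepairError):
    """The conflict search exceeded its state-space cap.

    Completeness of the enumeration can no longer be guaranteed, so the
    search aborts explicitly instead of silently truncating.  ``partial``
    holds the conflict sets discovered so far and ``witness`` the checkset
    class whose search overflowed.
    """

    def __init__(self, message: str, partial=None, witness=None):
        super().__init__(message)
        self.partial = partial
        self.witness = witness
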