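"""Exception hierarchy for the term-curation engine.

All engine-raised errors derive from :class:`TermOrgError` so callers (and
the CLI) can catch one type and map it to a non-zero exit code.
"""


class TermOrgError(Exception):
    """Base class for every error raised by the engine."""


class PermissionDenied(TermOrgError):
    """The acting user's role does not permit the requested action."""


class DuplicateName(TermOrgError):
    """A name that must be unique (dataset, category, order, user) already exists."""


class UnknownName(TermOrgError):
    """A referenced entity (term, category, dataset, user, action) does not exist."""


class FrozenTermSetError(TermOrgError):
    """A mutation was attempted on a finalized term set."""


class InvalidOperation(TermOrgError):
    """A precondition other than permission/uniqueness/frozen-state failed."""


class CycleError(InvalidOperation):
    """The operation would create a cycle in a synonym or part_of structure."""


class ValidationError(TermOrgError):
    """An input or output file violates the expected schema."""
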