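"""Exception hierarchy for sparsegmec."""


class SparseGmecError(Exception):
    """Base class for all package errors."""


class InvalidProblemError(SparseGmecError):
    """A design problem violates its invariants (see ``validate_problem``)."""


class InvalidConformationError(SparseGmecError):
    """A conformation indexes a rotamer that does not exist."""


class GraphMismatchError(SparseGmecError):
    """An interaction graph does not cover the problem's residue set."""


class DistanceUnavailableError(SparseGmecError):
    """No distance matrix and missing atom coordinates for a residue pair."""


class EmptySearchSpaceError(SparseGmecError):
    """Every conformation has been pruned; nothing to enumerate."""


class OracleTooLargeError(SparseGmecError):
    """Brute-force enumeration was asked to expand more conformations than its cap."""
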