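"""Exception hierarchy.

Every user-facing error carries a stable ``exit_code`` so the CLI can map
failure modes to distinct process exit statuses.
"""


class SpabbatsError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class MalformedModelError(SpabbatsError):
    """The network violates a structural invariant (bad coefficient, duplicate id, ...)."""

    exit_code = 3


class UnknownIdError(SpabbatsError):
    """A reaction or metabolite id was referenced that does not exist in the model."""

    exit_code = 4


class SolverUnknownError(SpabbatsError):
    """The backend hit a timeout or resource limit: neither SAT nor UNSAT.

    Never conflated with unsatisfiability — an UNSAT verdict is a proof,
    this is the absence of one.
    """

    exit_code = 5

    def __init__(self, message, partial_result=None):
        super().__init__(message)
        self.partial_result = partial_result


class VerificationError(SpabbatsError):
    """A solution surfaced by a backend failed independent re-verification."""

    exit_code = 6


class InstanceTooLargeError(SpabbatsError):
    """An exhaustive component was asked to handle an instance above its size guard."""

    exit_code = 7


class ModelIOError(SpabbatsError):
    """A model or report file could not be parsed or written."""

    exit_code = 3
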