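"""Exception hierarchy shared across the package."""


class ConvergeneError(Exception):
    """Base class for all package-specific errors."""


class ContractError(ConvergeneError, ValueError):
    """An argument violates an operation's stated precondition."""


class UndefinedRFError(ContractError):
    """A representation factor was requested for an empty gene set."""


class InfeasibleSpecError(ConvergeneError, ValueError):
    """A synthetic-data specification cannot be realised (e.g. jointly
    unsatisfiable planted overlaps)."""


class ConfigError(ConvergeneError, ValueError):
    """A run configuration failed validation.

    ``problems`` lists every violation found, so a user can fix the whole
    config in one pass.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems))
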