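"""Exception hierarchy shared across the package."""


class DietPAFError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(DietPAFError, ValueError):
    """A numeric input violates a precondition (e.g. non-positive intake mean)."""


class ContractError(DietPAFError, TypeError):
    """An operation was called with an object it is not defined for,
    e.g. routing an any-vs-none relative risk through the continuous
    dose-response path."""


class ConfigError(DietPAFError, ValueError):
    """An analysis configuration failed validation.

    ``problems`` collects every failing field so a user can fix the file
    in one pass.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__(
            "configuration invalid:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )
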