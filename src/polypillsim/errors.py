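"""Exception hierarchy.

All package errors derive from :class:`PolypillSimError` so callers can catch
one base class; subclasses distinguish bad configuration, bad data, broken
call contracts and model-fitting failures.
"""


class PolypillSimError(Exception):
    """Base class for all errors raised by polypillsim."""


class ConfigurationError(PolypillSimError):
    """A parameter, table or scenario setting is invalid or missing."""


class ValidationError(ConfigurationError):
    """Aggregated configuration problems, reported together.

    Carries the full list of messages so a user can fix every problem in
    one pass rather than playing whack-a-mole with first-failure errors.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "invalid configuration (%d problem%s):\n  - %s"
            % (len(self.problems), "s" if len(self.problems) != 1 else "",
               "\n  - ".join(self.problems))
        )


class DataError(PolypillSimError):
    """An input record is malformed or missing a required field."""


class ContractError(PolypillSimError):
    """A function was called outside its stated precondition."""


class FittingError(PolypillSimError):
    """A statistical model failed to fit (separation, non-convergence)."""
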