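"""Exception types shared across the package."""


class CascadeError(Exception):
    """Base class for package errors."""


class InputError(CascadeError, ValueError):
    """Invalid user-supplied input (unknown id, out-of-range value, ...)."""


class CaseValidationError(InputError):
    """A case file failed schema validation.

    Carries the complete list of violations, not just the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("case file invalid:\n" + "\n".join(f"  - {v}" for v in violations))
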