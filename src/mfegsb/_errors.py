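"""Exception hierarchy shared across the package.

CLI exit codes: InputError -> 2, FitDegeneracyError -> 3.
"""


class MfegsbError(Exception):
    """Base class for all package errors."""


class InputError(MfegsbError, ValueError):
    """Malformed or inconsistent user input (files, tables, parameters)."""


class FitError(MfegsbError, RuntimeError):
    """A model fit failed to converge; carries the best parameters seen."""

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class FitDegeneracyError(FitError):
    """The data admit no meaningful fit (e.g. constant aggregates)."""
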