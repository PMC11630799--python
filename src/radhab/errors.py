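"""Exception hierarchy shared across the package."""

from __future__ import annotations


class RadhabError(Exception):
    """Base class for all package errors."""


class ValidationError(RadhabError, ValueError):
    """An input value violates a documented invariant.

    The message names the offending field or key.
    """


class ConfigurationError(RadhabError):
    """A configuration file or coefficient table is incomplete or malformed."""


class DataError(RadhabError):
    """A data table cannot support the requested computation."""


class NonInactivatingCurveError(DataError):
    """Survival does not decrease with dose, so no decimal-reduction
    dose can be extracted."""


class MissingRecordError(RadhabError, KeyError):
    """A cross-referenced record is absent; carries the offending ids."""

    def __init__(self, message: str, missing_ids: list[str] | None = None):
        super().__init__(message)
        self.missing_ids = sorted(missing_ids or [])

    def __str__(self) -> str:  # KeyError quotes its arg; keep messages readable
        msg = self.args[0]
        if self.missing_ids:
            return f"{msg}: {', '.join(self.missing_ids)}"
        return msg
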