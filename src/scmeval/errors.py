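"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`ScmevalError` so the orchestrator
can report which stage and which practice failed.
"""


class ScmevalError(Exception):
    """Base class for all package errors."""


class ConfigError(ScmevalError):
    """Invalid simulation or pipeline configuration."""


class PanelSchemaError(ScmevalError):
    """A panel file violates the declared schema.

    Carries ``row`` (0-based data row, None when not row-specific) and
    ``column`` so callers can point at the offending cell.
    """

    def __init__(self, message: str, row=None, column=None):
        self.row = row
        self.column = column
        if row is not None or column is not None:
            message = f"{message} (row={row}, column={column})"
        super().__init__(message)


class DonorPoolError(ScmevalError):
    """Donor-pool construction failed (e.g. empty pool)."""


class FitError(ScmevalError):
    """Synthetic-control fit could not be computed."""


class PlaceboError(ScmevalError):
    """Placebo inference is unreliable (too few successful placebo fits)."""
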