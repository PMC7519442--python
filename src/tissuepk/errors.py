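"""Exception hierarchy for the pipeline."""


class TissuePKError(Exception):
    """Base class for all package errors."""


class SchemaError(TissuePKError):
    """A table is missing required columns or is otherwise malformed."""


class RecordError(TissuePKError):
    """One or more rows violate record invariants.

    ``problems`` holds ``(row_number, message)`` pairs; row numbers are
    1-based file line numbers (header is line 1).
    """

    def __init__(self, problems):
        self.problems = list(problems)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.problems)
        super().__init__(f"{len(self.problems)} invalid record(s): {lines}")


class DesignError(TissuePKError):
    """Study-design configuration is inconsistent or does not match the data."""


class FitError(TissuePKError):
    """Calibration fit preconditions violated."""


class DegenerateDesignError(FitError):
    """Zero variance in the calibration abscissa."""


class QuantifyError(TissuePKError):
    """Study records cannot be quantified (e.g. a calibration curve is missing)."""


class TargetingError(TissuePKError):
    """Targeting statistic is undefined for the given AUC maps."""


class StageError(TissuePKError):
    """A pipeline stage failed; carries the stage name for the manifest."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
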