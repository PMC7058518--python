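"""Exception hierarchy shared across the package."""


class PolyresError(Exception):
    """Base class for all package-specific errors."""


class PlinkFormatError(PolyresError):
    """Malformed or unsupported PLINK1 binary file."""


class SchemaError(PolyresError):
    """A text table is missing required columns."""


class GtfParseError(PolyresError):
    """Malformed GTF record; message carries the 1-based line number."""


class CalibrationError(PolyresError):
    """Intercept calibration of the simulator failed to hit the target rate."""


class CapacityError(PolyresError):
    """A defect-injection request exceeds the markers available."""


class HarmonizationError(PolyresError):
    """Alleles at a variant cannot be reconciled across studies."""


class StandardizationError(PolyresError):
    """Scores are degenerate (zero variance) and cannot be z-scaled."""


class StrataError(PolyresError):
    """Percentile stratification produced a degenerate partition."""


class CoverageError(PolyresError):
    """Too few score-model variants were found in the genotype panel."""


class AlignmentError(PolyresError):
    """Per-cohort results cannot be aligned (mismatched p-value bins)."""


class DesignError(PolyresError):
    """Regression design is unusable (single-class outcome, rank deficiency)."""
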