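"""Exception hierarchy shared across the package."""


class DDIError(Exception):
    """Base class for all package-specific errors."""


class FlatParseError(DDIError):
    """A 3did-style flat file violated the expected block structure.

    Carries the 1-based line number where parsing failed.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ChainMappingError(DDIError):
    """An interchain interface references a (pdb, chain) with no known protein."""

    def __init__(self, missing_keys):
        self.missing_keys = sorted(missing_keys)
        super().__init__(
            "no protein accession mapped for structure chains: "
            + ", ".join(f"{p}/{c}" for p, c in self.missing_keys)
        )


class StateError(DDIError):
    """An operation was called on objects not yet in the required state."""


class CoverageError(DDIError):
    """A per-residue profile does not cover a requested sequence position."""


class ConsistencyError(DDIError):
    """Cross-referenced inputs disagree (e.g. a label for an unknown DDI type)."""


class CollinearityError(DDIError):
    """The logistic design matrix is rank deficient."""

    def __init__(self, offending_columns):
        self.offending_columns = list(offending_columns)
        super().__init__(
            "design matrix is rank deficient; offending columns: "
            + ", ".join(self.offending_columns)
        )


class DegenerateDataError(DDIError):
    """Model fitting was requested on data that cannot identify the model."""


class FoldError(DDIError):
    """A cross-validation fold could not be fit."""

    def __init__(self, row_id, message: str):
        self.row_id = row_id
        super().__init__(f"LOOCV fold holding out row {row_id!r} failed: {message}")


class GenerationError(DDIError):
    """A synthetic-data generator received an infeasible configuration."""
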