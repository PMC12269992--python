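"""Exception hierarchy shared across the pipeline."""


class BrainArrowError(Exception):
    """Base class for all pipeline errors."""


class FormatError(BrainArrowError):
    """Malformed input file (ragged rows, non-numeric cells, duplicate ids)."""


class ParameterError(BrainArrowError):
    """Parameter outside its documented range."""


class ZeroVarianceError(BrainArrowError):
    """Columns with no variance after filtering; caller must exclude them.

    Carries ``region_ids``, the offending column identifiers.
    """

    def __init__(self, region_ids):
        self.region_ids = list(region_ids)
        super().__init__(
            "zero-variance columns after filtering; exclude explicitly: "
            + ", ".join(map(str, self.region_ids))
        )


class InstabilityError(BrainArrowError):
    """Linearized model has an eigenvalue with non-negative real part."""

    def __init__(self, max_real_part):
        self.max_real_part = float(max_real_part)
        super().__init__(
            f"unstable linearized system: largest eigenvalue real part "
            f"{self.max_real_part:.6g} >= 0"
        )


class NumericalError(BrainArrowError):
    """A numerical routine failed its residual check."""
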