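"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """Invalid parameter or malformed input (exit code 2 at the CLI)."""


class FitFailureError(RuntimeError):
    """Least-squares optimisation failed to converge (exit code 3)."""


class CalibrationError(FitFailureError):
    """Detection-volume calibration from a reference curve failed."""
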