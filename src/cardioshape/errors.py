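"""Exception hierarchy shared across the pipeline."""


class CardioshapeError(Exception):
    """Base class for all package errors."""


class FormatError(CardioshapeError):
    """A file could not be read or written in the expected format."""


class GridMismatchError(CardioshapeError):
    """Two grids that must share a lattice do not."""


class SpecError(CardioshapeError):
    """A parameter object violates its own invariants or the input contract."""


class DegenerateGeometryError(CardioshapeError):
    """A geometric problem (landmark correspondence, transform) is degenerate."""


class ValidationError(CardioshapeError):
    """An input collection fails a completeness/consistency check."""


class ConfigError(CardioshapeError):
    """A configuration is internally inconsistent."""


class TrainingError(CardioshapeError):
    """Optimisation diverged (non-finite loss)."""


class StageError(CardioshapeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
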