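"""Exception types shared across the package."""


class ViqaError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(ViqaError, ValueError):
    pass


class FormatError(ViqaError, ValueError):
    """Malformed keypoint record or file; carries the offending frame index."""

    def __init__(self, msg: str, frame_index: int | None = None):
        super().__init__(msg if frame_index is None else f"frame {frame_index}: {msg}")
        self.frame_index = frame_index


class OutOfRangeError(ViqaError, IndexError):
    pass


class InvalidDataError(ViqaError, ValueError):
    pass


class TooShortError(ViqaError, ValueError):
    pass


class InvalidViewError(ViqaError, ValueError):
    pass


class ConfigError(ViqaError, ValueError):
    pass


class SplitError(ViqaError, ValueError):
    pass


class EmptyDatasetError(ViqaError, ValueError):
    pass


class LabelError(ViqaError, ValueError):
    pass


class TrainingFailure(ViqaError, RuntimeError):
    def __init__(self, msg: str, step: int):
        super().__init__(f"step {step}: {msg}")
        self.step = step


class CheckpointError(ViqaError, ValueError):
    pass


class EmptyVideoError(ViqaError, ValueError):
    pass


class UndefinedCorrelationError(ViqaError, ValueError):
    pass

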