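"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument violates a documented precondition; names the offending field."""


class EstimationError(RuntimeError):
    """An estimator has no solution for the given data (e.g. rod-limit moment inversion)."""


class GenerationError(RuntimeError):
    """Synthetic-data rejection sampling exceeded its proposal cap."""


class FormatError(ValueError):
    """An input file does not conform to its documented schema."""


class MissingLandmarkError(ValueError):
    """A required landmark is absent from a frame; carries the frame id."""

    def __init__(self, frame_id, landmark: str):
        self.frame_id = frame_id
        self.landmark = landmark
        super().__init__(f"frame {frame_id}: missing landmark '{landmark}'")
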