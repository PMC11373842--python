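"""Exception hierarchy for the foodprint model."""


class FoodprintError(Exception):
    """Base class for all model errors."""


class ParameterError(FoodprintError):
    """A parameter table is missing, malformed, or violates an invariant."""


class SchemaError(FoodprintError):
    """A diet-survey file does not match the expected schema."""


class PipelineError(FoodprintError):
    """A simulation stage failed; the stage name is attached."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
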