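"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: InputError -> 2, ConfigError -> 3,
StageError -> 4.
"""


class ColocError(Exception):
    """Base class for all package errors."""


class InputError(ColocError):
    """Malformed or inconsistent input data (duplicate ids, unknown mark, ...)."""


class ConfigError(ColocError):
    """Invalid configuration (counts <= 0, rates exceeding genome size, ...)."""


class StageError(ColocError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


class UndefinedStatistic(ColocError):
    """A statistic could not be evaluated (zero variance, too few points)."""
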