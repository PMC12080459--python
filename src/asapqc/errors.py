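"""Exception types shared across the pipeline.

``ValidationError`` marks bad inputs or configuration (CLI exit code 2),
``ProcessingError`` marks failures while running a stage on valid inputs
(CLI exit code 3).
"""


class ValidationError(ValueError):
    """Raised when an input, parameter or configuration is invalid."""


class ProcessingError(RuntimeError):
    """Raised when a pipeline stage fails on otherwise valid inputs."""
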