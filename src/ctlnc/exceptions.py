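"""Exception hierarchy shared across the package."""


class CtlncError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CtlncError):
    """A configuration value is missing or outside its documented domain."""


class ConsistencyError(CtlncError):
    """Two inputs that must describe the same cohort disagree."""


class ParseError(CtlncError):
    """A file does not conform to its declared dialect."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        if loc:
            message = f"{loc}: {message}"
        super().__init__(message)
        self.path = path
        self.line = line


class PipelineError(CtlncError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
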