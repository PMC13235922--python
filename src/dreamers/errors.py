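"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class NumericError(ArithmeticError):
    """A computation produced non-finite values and cannot continue."""


class WriteError(OSError):
    """An output artefact could not be written; carries the offending path."""

    def __init__(self, path, message: str = ""):
        self.path = str(path)
        super().__init__(f"cannot write {self.path}" + (f": {message}" if message else ""))
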