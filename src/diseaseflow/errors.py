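"""Exception types shared across the package."""


class DiseaseFlowError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DiseaseFlowError, ValueError):
    """A TSV input line could not be parsed."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class ParameterError(DiseaseFlowError, ValueError):
    """A user-supplied parameter is out of its valid range."""


class UnknownIDError(DiseaseFlowError, KeyError):
    """A disease, protein, or cluster ID is not present in the model."""

    def __init__(self, kind, identifier):
        self.kind = kind
        self.identifier = identifier
        super().__init__(f"unknown {kind}: {identifier!r}")

    def __str__(self):  # KeyError quotes its arg; keep the plain message
        return f"unknown {self.kind}: {self.identifier!r}"
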