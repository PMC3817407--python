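"""Exception hierarchy shared across the package."""


class EcfError(Exception):
    """Base class for all ecfkit errors."""


class ParseError(EcfError):
    """A file could not be parsed (names the offending record where possible)."""


class ValidationError(EcfError):
    """Domain-object invariants were violated.

    ``problems`` carries one human-readable message per violation so a
    roster with several bad ids reports all of them at once.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
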