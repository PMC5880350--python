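"""Exception hierarchy shared across the package."""


class BibitError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(BibitError):
    """An input file could not be parsed (malformed ARFF/delimited content)."""


class ValidationError(BibitError):
    """Well-formed input violated a contract (dimensions, names, parameter ranges)."""
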