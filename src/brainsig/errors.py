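"""Exception hierarchy shared by all pipeline stages."""


class BrainsigError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BrainsigError, ValueError):
    """A file or table violates the expected format (duplicates, bad labels,
    non-numeric cells, empty input)."""


class DegenerateInputError(BrainsigError, ValueError):
    """Input is syntactically valid but admits no meaningful answer
    (constant expression, all-equal growth summaries, empty split)."""
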