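"""Exception hierarchy shared across the package."""


class RefstabError(Exception):
    """Base class for all refstab errors."""


class FormatError(RefstabError):
    """A file does not conform to the expected layout (missing column, bad cell)."""


class ValidationError(RefstabError):
    """Input data violates a structural invariant (duplicates, out-of-range Cq, ...)."""
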