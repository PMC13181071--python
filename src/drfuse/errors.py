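class InvalidInputError(ValueError):
    """Structurally invalid input to a fusion/evaluation operation."""


class DataError(InvalidInputError):
    """Malformed or inconsistent data read from disk."""
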