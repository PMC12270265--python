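class GrsimError(Exception):
    """Base class for all grsim errors."""


class ValidationError(GrsimError):
    """Invalid user input or data (maps to CLI exit code 2)."""
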