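"""Exception types distinguishing bad inputs from failed optimization."""


class InputError(ValueError):
    """Unreadable, malformed, or inconsistent input data."""


class ConvergenceError(RuntimeError):
    """An optimization or retention step failed to produce a usable result."""
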