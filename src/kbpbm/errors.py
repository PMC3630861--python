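"""Exception hierarchy shared across the package."""


class KbpbmError(Exception):
    """Base class for all package errors."""


class InputError(KbpbmError, ValueError):
    """A caller-supplied argument violates a precondition."""


class DesignError(KbpbmError, ValueError):
    """A probe design is physically impossible (e.g. exceeds array capacity)."""


class DataError(KbpbmError, ValueError):
    """An intensity or plate table is structurally inconsistent."""


class ParseError(KbpbmError, ValueError):
    """A file on disk could not be interpreted; carries location context."""


class PipelineError(KbpbmError, RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""
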