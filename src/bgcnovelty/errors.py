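"""Exception hierarchy shared across the pipeline."""


class BgcNoveltyError(Exception):
    """Base class for all package errors."""


class FormatError(BgcNoveltyError):
    """A file could not be parsed in the expected format."""


class ValidationError(BgcNoveltyError):
    """Parsed content violates a documented invariant."""


class UndefinedScoreError(BgcNoveltyError):
    """BiNI is undefined because a strain has zero in-scope clusters.

    Carries the strain id so callers can report per-strain failures
    instead of silently scoring zero (which would mis-rank).
    """

    def __init__(self, strain_id: str, message: str | None = None):
        self.strain_id = strain_id
        super().__init__(message or f"BiNI undefined for strain {strain_id!r}: no in-scope clusters")
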