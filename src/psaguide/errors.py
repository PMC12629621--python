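"""Exception hierarchy for psaguide.

Every error raised by the package derives from :class:`PsaGuideError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors with a single ``except`` clause.
"""


class PsaGuideError(Exception):
    """Base class for all psaguide errors."""


class CaseSchemaError(PsaGuideError, ValueError):
    """A case record violates the case schema (missing/ill-typed field)."""


class VocabularyError(CaseSchemaError):
    """A comorbidity code is not in the controlled vocabulary."""

    def __init__(self, unknown, accepted):
        self.unknown = sorted(unknown)
        self.accepted = sorted(accepted)
        super().__init__(
            f"unknown comorbidity code(s) {self.unknown}; "
            f"accepted codes: {self.accepted}"
        )


class ConfigurationError(PsaGuideError):
    """A config file (weights, rules, chunking, corpus tagging) is invalid."""


class TemplateError(PsaGuideError):
    """A prompt template is missing a required slot."""


class BackendError(PsaGuideError):
    """A generation backend failed (timeout, missing script, crash)."""


class ResponseParseError(PsaGuideError, ValueError):
    """A backend response could not be parsed into a Recommendation.

    Carries the raw response text on ``.raw`` for diagnosis.
    """

    def __init__(self, message: str, raw: str):
        self.raw = raw
        super().__init__(f"{message}; raw response: {raw!r}")


class PipelineStageError(PsaGuideError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


class DegenerateAgreementError(PsaGuideError):
    """Fleiss kappa is undefined: expected chance agreement equals 1."""


class GenerationError(PsaGuideError):
    """The synthetic-cohort generator could not satisfy its constraints."""


class ConsistencyError(PsaGuideError):
    """An evaluation report failed an internal consistency check."""
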