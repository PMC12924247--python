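"""Exception hierarchy for cmgym."""


class CmgymError(Exception):
    """Base class for all cmgym errors."""


class FormatError(CmgymError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(CmgymError):
    """A series or record violates a structural invariant."""


class GenerationError(CmgymError):
    """The synthetic-embryo generator could not satisfy its constraints."""


class EmptyWindowError(CmgymError):
    """Two cells share no frames, so no migration window exists."""


class ConfigurationError(CmgymError):
    """Mutually inconsistent configuration (e.g. both hypotheses active)."""


class EpisodeStateError(CmgymError):
    """An environment operation was called in an invalid episode state."""
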