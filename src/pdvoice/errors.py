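"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """An operation was called with an out-of-range or inconsistent parameter."""


class AudioFormatError(ValueError):
    """A WAV file could not be read as PCM audio."""


class ConfigurationError(ValueError):
    """A run or cohort configuration is invalid (missing pools, seeds, paths)."""
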