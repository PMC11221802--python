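"""Exception hierarchy for laflow.

Exit-code mapping used by the CLI: input/configuration problems are
``InputError`` subclasses (exit 1); internal bookkeeping violations are
``ConsistencyError`` (exit 2).
"""


class LaflowError(Exception):
    """Base class for all laflow errors."""


class InputError(LaflowError):
    """A problem with user-supplied files, configuration or parameters."""


class FormatError(InputError):
    """A file could not be parsed as the expected format."""


class TimingError(InputError):
    """Frame counts or times disagree with the cardiac timing definition."""


class LabelingError(InputError):
    """A mask contains labels not covered by the label map, or an empty LA."""


class SeedingError(InputError):
    """Seeding produced no particles or the patch misses the lumen."""


class ConfigError(InputError):
    """Invalid run configuration."""


class ConsistencyError(LaflowError):
    """An internal conservation or de-duplication check failed."""
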