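"""Exception hierarchy for minibarc.

All library errors derive from :class:`MinibarcError` so the CLI can map
them to exit code 1 while genuine usage errors keep click's exit code 2.
"""


class MinibarcError(Exception):
    """Base class for all minibarc errors."""


class FormatError(MinibarcError):
    """A file did not conform to its declared format."""


class AlignmentShapeError(MinibarcError):
    """Alignment rows have unequal lengths or too few sequences."""


class GeneLookupError(MinibarcError):
    """A requested gene feature was not found (or was ambiguous)."""


class ConfigError(MinibarcError):
    """Invalid simulation or run configuration."""


class AmplificationError(MinibarcError):
    """In-silico PCR produced zero or multiple products where exactly one
    was required."""
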