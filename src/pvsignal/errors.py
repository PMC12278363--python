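"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value violates its documented constraint."""


class ZeroCellError(ValueError):
    """A 2x2 contingency cell is zero and no continuity correction is enabled."""


class DegenerateTableError(ValueError):
    """A 2x2 table has an all-zero row or column margin."""


class InputFormatError(ValueError):
    """An input file is missing, empty, or lacks required columns."""
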