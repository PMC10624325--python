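"""Exception hierarchy for maitrep.

Every error raised by the package derives from :class:`MaitRepError` so
callers (and the CLI exit-code mapping) can distinguish configuration,
format and empty-result failures.
"""


class MaitRepError(Exception):
    """Base class for all maitrep errors."""


class ConfigError(MaitRepError):
    """Invalid or infeasible configuration (bad probability, weights, paths)."""


class FormatError(MaitRepError):
    """A table does not conform to the expected dialect (missing column,
    non-positive count, unparseable value)."""


class AmbiguityError(FormatError):
    """Conflicting rows that cannot be resolved deterministically, e.g. two
    differing chain rows for the same (cell_id, locus)."""


class EmptyRepertoireError(MaitRepError):
    """A repertoire is empty after productivity filtering."""


class EmptyResultError(MaitRepError):
    """An analysis step produced no usable records (e.g. no canonical cells)."""


class UndefinedDiversityError(MaitRepError):
    """Diversity statistic requested on a repertoire with fewer than two cells."""
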