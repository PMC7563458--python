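"""Exception hierarchy shared across the pipeline."""


class TipscanError(Exception):
    """Base class for all package errors."""


class ParseError(TipscanError):
    """A malformed record in an input file; message names the line."""


class PairingError(TipscanError):
    """Mate files disagree (record counts or pair identifiers)."""


class ValidationError(TipscanError):
    """A record violates a coordinate or value invariant."""


class ConfigurationError(TipscanError):
    """An invalid option value (unknown dialect, alpha outside (0,1), ...)."""


class IndexingError(TipscanError):
    """A subject sequence cannot be indexed (e.g. shorter than k)."""


class GenerationError(TipscanError):
    """The simulator could not satisfy its placement constraints."""


class LabelingError(TipscanError):
    """A sample lacks a condition label, or the cohort is single-class."""


class DegenerateTableError(TipscanError):
    """A contingency table with zero grand total."""


class MergeError(TipscanError):
    """A scatter/gather part output is missing at merge time."""
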