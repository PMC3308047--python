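"""Exception hierarchy.

Everything derives from :class:`ExonPopError` so callers can catch the
package's failures without also swallowing programming errors.
"""


class ExonPopError(Exception):
    """Base class for all errors raised by exonpop."""


class ConfigError(ExonPopError, ValueError):
    """An invalid configuration value; the message names the field."""


class PanelError(ExonPopError, ValueError):
    """Sample panel inconsistency (e.g. VCF sample absent from the panel)."""


class ParseError(ExonPopError, ValueError):
    """Malformed input record; the message carries the file line number."""


class AnnotationError(ExonPopError, ValueError):
    """A required per-site annotation (quality, depths, CDS overlap) is missing."""


class DomainError(ExonPopError, ValueError):
    """Arguments outside the mathematical domain of a statistic."""


class UnsupportedVariantError(ExonPopError, ValueError):
    """Variant type not handled by the requested operation (e.g. indel effect)."""


class NoPredictionError(ExonPopError, ValueError):
    """Neither functional predictor produced a call for the site."""


class UndefinedResultError(ExonPopError, ValueError):
    """The requested statistic is undefined on this input (empty denominator)."""
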