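"""Exception types raised across the tonescale modules.

Each error marks a *contract* violation or a statistically degenerate input
that callers must handle explicitly rather than receive a silent sentinel.
"""


class TonescaleError(Exception):
    """Base class for all tonescale errors."""


class DegenerateChromaticity(TonescaleError):
    """|b*| is below the configured floor, so ITA = arctan((L*-50)/b*) is undefined."""


class EmptyMask(TonescaleError):
    """An image patch whose inclusion mask selects no pixel."""


class DegenerateMarginals(TonescaleError):
    """Both raters used a single identical category; chance agreement is 1 and kappa undefined."""


class ZeroVariance(TonescaleError):
    """Between-subject mean square is zero; ICC undefined."""


class ZeroVarianceDifferences(TonescaleError):
    """Paired differences are a nonzero constant; the t statistic is undefined."""


class ZeroExpected(TonescaleError):
    """A contingency table cell has zero expected count under independence."""


class CoincidentCentroids(TonescaleError):
    """Two class centroids coincide, so the Davies-Bouldin ratio divides by zero."""


class ConfigError(TonescaleError):
    """A synthetic study configuration violates its invariants."""


class SchemaError(TonescaleError):
    """An input table is missing required columns or holds out-of-range codes."""
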