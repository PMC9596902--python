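"""Univariate quality control of the reference measurements.

Reference distributions (optical density and the three histologic
scores) are bounded and typically skewed, so normality is assessed first
(one-sample Kolmogorov–Smirnov on standardized values, with a Lilliefors
option) and outliers are then screened with a median ± k·MAD rule rather
than a mean/SD rule.

Exclusion is per reference property: a location excluded for one score
remains usable for the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .spectral_data import CartigradeError, LocationKey

logger = logging.getLogger(__name__)

ALPHA = 0.05  # significance level for the normality decision


class DegenerateValuesError(CartigradeError):
    """Input values carry no usable spread."""


@dataclass
class QcReport:
    """Normality assessment and MAD-outlier screen for one property."""

    property: str
    normality_p: float
    is_normal: bool
    outlier_locations: list[LocationKey] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.outlier_locations)

    def to_dict(self) -> dict:
        return {
            "property": self.property,
            "normality_p": self.normality_p,
            "is_normal": self.is_normal,
            "outlier_locations": [loc.label() for loc in self.outlier_locations],
            "n_excluded": self.n_excluded,
        }


def ks_normality(values, alpha: float = ALPHA, lilliefors_correction: bool = False) -> tuple[float, bool]:
    """One-sample KS test against the normal with estimated parameters.

    Values are standardized by their own sample mean/std and compared to
    the standard normal.  With ``lilliefors_correction=True`` the p-value
    accounts for the estimated parameters (the plain KS variant is
    anti-conservative).  Returns ``(p, is_normal)`` with
    ``is_normal = (p >= alpha)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("normality test requires n ≥ 4")
    sd = values.std(ddof=1)
    if sd == 0:
        raise DegenerateValuesError("constant values: normality test undefined")
    if lilliefors_correction:
        _, p = lilliefors(values, dist="norm")
    else:
        z = (values - values.mean()) / sd
        p = float(stats.kstest(z, "norm").pvalue)
    return float(p), bool(p >= alpha)


def mad_outlier_mask(values, k: float = 3.0, scaled: bool = True) -> np.ndarray:
    """Flag values farther than ``k`` MADs from the median.

    ``scaled=True`` uses the normal-consistent MAD (raw MAD × 1.4826);
    ``scaled=False`` uses the raw median absolute deviation.  At least
    one value (the median itself) is always unmasked.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("MAD screen requires n ≥ 3")
    scale = "normal" if scaled else 1.0
    mad = stats.median_abs_deviation(values, scale=scale)
    if mad == 0:
        raise DegenerateValuesError("MAD is zero: all deviations identical, screen undefined")
    return np.abs(values - np.median(values)) > k * mad


def qc_property(
    values, locations: list[LocationKey], property_name: str,
    k: float = 3.0, alpha: float = ALPHA, lilliefors_correction: bool = False,
) -> QcReport:
    """Full QC for one reference property: normality test + MAD screen."""
    values = np.asarray(values, dtype=float)
    if len(values) != len(locations):
        raise ValueError("values and locations must align")
    p, is_normal = ks_normality(values, alpha=alpha, lilliefors_correction=lilliefors_correction)
    mask = mad_outlier_mask(values, k=k)
    outliers = [loc for loc, m in zip(locations, mask) if m]
    if outliers:
        logger.info("%s: excluding %d reference outlier(s)", property_name, len(outliers))
    return QcReport(property=property_name, normality_p=p, is_normal=is_normal,
                    outlier_locations=outliers)
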