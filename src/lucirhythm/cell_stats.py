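"""Single-cell bioluminescence intensity statistics.

Cellular reporter intensities are well described by a log-normal law
(multiplicative variation in copy number, expression and optical path),
so the natural summaries are the geometric mean, fold differences of
geometric means, histograms on a log axis, and a normality test of the
log-intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellIntensitySet",
    "geometric_mean",
    "lognormality_ks",
    "fold_difference",
    "histogram_log",
]


@dataclass(frozen=True)
class CellIntensitySet:
    """Per-cell bioluminescence intensities (photons·min⁻¹) for one reporter."""

    label: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.intensities, dtype=float)
        if v.ndim != 1 or len(v) < 2:
            raise ValueError("need a 1-d array of at least two intensities")
        if not np.all(np.isfinite(v)):
            raise ValueError("intensities must be finite")
        if np.any(v <= 0):
            raise ValueError(
                f"{self.label}: {int(np.sum(v <= 0))} non-positive intensity "
                "value(s); background-subtracted or empty cells must be "
                "filtered upstream")
        object.__setattr__(self, "intensities", v)

    @property
    def n(self) -> int:
        return len(self.intensities)

    @classmethod
    def from_csv(cls, path, label: str | None = None) -> "CellIntensitySet":
        df = pd.read_csv(path, comment="#")
        if "intensity_photons_per_min" not in df.columns:
            raise ValueError("CSV needs an 'intensity_photons_per_min' column")
        return cls(label or str(path), df["intensity_photons_per_min"].to_numpy())


def geometric_mean(s: CellIntensitySet) -> float:
    """exp(mean(log intensities)) — the log-normal central tendency."""
    return float(stats.gmean(s.intensities))


def lognormality_ks(s: CellIntensitySet, method: str = "ks") -> tuple[float, float]:
    """Test log-normality of the intensities; returns (statistic, p-value).

    ``method='ks'`` is a one-sample Kolmogorov–Smirnov test of the
    log-intensities against a normal law with the sample mean and SD of
    the logs.  Because those parameters are estimated from the same
    sample, its p-value is conservative (true rejection rate well below
    the nominal level); ``method='lilliefors'`` applies the Lilliefors
    correction and is calibrated.
    """
    if s.n < 5:
        raise ValueError("need at least 5 cells for a distribution test")
    logs = np.log(s.intensities)
    sd = logs.std(ddof=1)
    if sd < 1e-12 * max(1.0, abs(logs.mean())):
        raise ValueError("degenerate sample: zero variance on the log scale")
    if method == "ks":
        res = stats.kstest(logs, "norm", args=(logs.mean(), sd))
        return float(res.statistic), float(res.pvalue)
    if method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors
        stat, pval = lilliefors(logs, dist="norm", pvalmethod="approx")
        return float(stat), float(pval)
    raise ValueError(f"method must be 'ks' or 'lilliefors', got {method!r}")


def fold_difference(a: CellIntensitySet, b: CellIntensitySet) -> float:
    """Ratio of geometric means a/b."""
    return geometric_mean(a) / geometric_mean(b)


def histogram_log(s: CellIntensitySet, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Histogram with equal-width bins in log10 space.

    Returns ``(edges, counts)`` where ``edges`` are bin edges in log10
    photons·min⁻¹ (length ``n_bins + 1``) and counts sum to n.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    counts, edges = np.histogram(np.log10(s.intensities), bins=n_bins)
    return edges, counts
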