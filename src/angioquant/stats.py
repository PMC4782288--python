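"""Nonparametric group comparison and assay calculations.

Implements the statistical layer used by every analysis stage: two-tailed
Mann-Whitney U tests (exact by enumeration for small tie-free samples,
normal approximation with tie and continuity correction otherwise),
median +/- median absolute deviation summaries, caliper tumor volumes,
and four-parameter-logistic immunoassay calibration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sps

__all__ = [
    "GroupComparison",
    "VolumeRecord",
    "FourPLModel",
    "Pge2Result",
    "mann_whitney_u",
    "median_mad",
    "tumor_volume",
    "normalize_series",
    "fit_4pl",
    "pge2_quantify",
]

log = logging.getLogger(__name__)

ALPHA = 0.05
EXACT_MAX_N = 12  # exact p by enumeration up to this combined sample size


@dataclass
class GroupComparison:
    """Result of a two-tailed Mann-Whitney U comparison of two groups."""

    group_a: np.ndarray
    group_b: np.ndarray
    u_statistic: float
    p_two_tailed: float
    median_a: float
    mad_a: float
    median_b: float
    mad_b: float
    alpha: float = ALPHA
    method: str = "exact"

    @property
    def significant(self) -> bool:
        return self.p_two_tailed < self.alpha

    @property
    def n_a(self) -> int:
        return len(self.group_a)

    @property
    def n_b(self) -> int:
        return len(self.group_b)

    def summary_row(self) -> dict:
        return {
            "n_a": self.n_a, "n_b": self.n_b,
            "median_a": self.median_a, "mad_a": self.mad_a,
            "median_b": self.median_b, "mad_b": self.mad_b,
            "U": self.u_statistic, "p": self.p_two_tailed,
            "alpha": self.alpha, "method": self.method,
        }


def median_mad(values) -> tuple[float, float]:
    """Median and (unscaled) median absolute deviation.

    No consistency factor is applied: MAD = median(|x - median(x)|).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("median_mad requires at least one value")
    med = float(np.median(x))
    return med, float(np.median(np.abs(x - med)))


def mann_whitney_u(a, b, alpha: float = ALPHA,
                   exact_max_n: int = EXACT_MAX_N) -> GroupComparison:
    """Two-tailed Mann-Whitney U test with median +/- MAD summaries.

    The p-value is exact (full enumeration of the rank distribution) when
    the combined sample size is at most ``exact_max_n`` and the data are
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (a.size + b.size) <= exact_max_n and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    med_a, mad_a = median_mad(a)
    med_b, mad_b = median_mad(b)
    return GroupComparison(a, b, float(res.statistic),
                           float(min(res.pvalue, 1.0)),
                           med_a, mad_a, med_b, mad_b, alpha, method)


# ---------------------------------------------------------------------------
# tumor volume from calipers

@dataclass
class VolumeRecord:
    """Caliper-derived tumor volume at one day: V = L * W^2 / 2 (mm^3)."""

    length: float
    width: float
    day: int
    volume: float = field(init=False)
    normalized_volume: float | None = None

    def __post_init__(self) -> None:
        if self.width > self.length:
            log.warning("width %.3g > length %.3g; swapping by convention",
                        self.width, self.length)
            self.length, self.width = self.width, self.length
        if self.width < 0:
            raise ValueError("caliper measurements must be non-negative")
        self.volume = tumor_volume(self.length, self.width)


def tumor_volume(length: float, width: float) -> float:
    """Ellipsoid-approximation tumor volume, 1/2 * length * width^2 (mm^3)."""
    if width > length:
        log.warning("width > length; swapping by convention")
        length, width = width, length
    if width < 0:
        raise ValueError("caliper measurements must be non-negative")
    return 0.5 * length * width ** 2


def normalize_series(records: list[VolumeRecord],
                     baseline_day: int) -> list[VolumeRecord]:
    """Attach volumes normalized to the baseline-day volume, in place."""
    baseline = [r for r in records if r.day == baseline_day]
    if not baseline:
        raise ValueError(f"no record at baseline day {baseline_day}")
    v0 = baseline[0].volume
    if v0 <= 0:
        raise ValueError("baseline volume must be positive for normalization")
    for r in records:
        r.normalized_volume = r.volume / v0
    return records


# ---------------------------------------------------------------------------
# four-parameter logistic immunoassay calibration

@dataclass
class FourPLModel:
    """4PL calibration curve y = d + (a - d) / (1 + (x/c)^b).

    ``a`` is the response at zero analyte, ``d`` the response at infinite
    analyte, ``c`` the inflection concentration (y = (a+d)/2 there) and
    ``b`` the slope.  For a competitive immunoassay a > d and b > 0.
    """

    a: float
    d: float
    c: float
    b: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.d + (self.a - self.d) / (1.0 + (x / self.c) ** self.b)

    def inverse(self, y) -> np.ndarray:
        """Concentration at response y (y strictly between the asymptotes)."""
        y = np.asarray(y, dtype=float)
        lo, hi = sorted((self.a, self.d))
        if np.any(y <= lo) or np.any(y >= hi):
            raise ValueError("response outside the open asymptote range")
        return self.c * ((self.a - self.d) / (y - self.d) - 1.0) ** (1.0 / self.b)

    def in_range(self, y: float, frac_lo: float = 0.2,
                 frac_hi: float = 0.8) -> bool:
        """Is y within the quantifiable 20-80% band of the response span?"""
        lo = self.d + frac_lo * (self.a - self.d)
        hi = self.d + frac_hi * (self.a - self.d)
        lo, hi = sorted((lo, hi))
        return lo <= y <= hi


def fit_4pl(concentrations, responses) -> FourPLModel:
    """Least-squares 4PL fit to standards; c constrained positive.

    Initial values come from the data: asymptotes from the extreme
    responses, inflection from the log-midpoint of the standard range.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 standards for a 4PL fit")
    if np.any(x <= 0):
        raise ValueError("standard concentrations must be positive")
    order = np.argsort(x)
    x, y = x[order], y[order]
    a0, d0 = y[0], y[-1]
    c0 = math.exp(0.5 * (math.log(x[0]) + math.log(x[-1])))

    def model(x, a, d, logc, b):
        return d + (a - d) / (1.0 + (x / np.exp(logc)) ** b)

    popt, _ = optimize.curve_fit(model, x, y,
                                 p0=[a0, d0, math.log(c0), 1.0],
                                 maxfev=20000)
    a, d, logc, b = popt
    return FourPLModel(a=float(a), d=float(d), c=float(math.exp(logc)),
                       b=float(b))


@dataclass
class Pge2Result:
    """PGE2 immunoassay readout for one sample, normalized per ng RNA."""

    pg_per_ng_rna: float | None
    concentration: float | None        # pg/ml after dilution scaling
    n_replicates_used: int
    n_replicates_total: int
    flagged: bool                      # fewer than 2 in-range replicates
    excluded: bool                     # no usable replicate at all


def pge2_quantify(absorbances, standards, dilution: float,
                  rna_ng: float, model: FourPLModel | None = None) -> Pge2Result:
    """Quantify PGE2 from replicate absorbances via a 4PL standard curve.

    ``standards`` is a sequence of (concentration, absorbance) pairs.
    Replicates outside the 20-80% response band are excluded, mirroring
    the out-of-range exclusion rule of plate-reader immunoassays.  The
    mean of the in-range replicates is inverted through the curve,
    scaled by the dilution factor, and normalized to ``rna_ng``.
    """
    if rna_ng <= 0:
        raise ValueError("rna_ng must be positive")
    if dilution <= 0:
        raise ValueError("dilution factor must be positive")
    reads = np.asarray(absorbances, dtype=float)
    if model is None:
        conc, resp = zip(*standards)
        model = fit_4pl(conc, resp)
    in_range = np.array([model.in_range(y) for y in reads])
    used = reads[in_range]
    if used.size == 0:
        log.warning("all %d replicates out of range; sample excluded",
                    reads.size)
        return Pge2Result(None, None, 0, reads.size, True, True)
    flagged = used.size < 2
    conc = float(model.inverse(used.mean())) * dilution
    return Pge2Result(conc / rna_ng, conc, int(used.size), reads.size,
                      flagged, False)
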