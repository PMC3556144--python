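"""Densitometry categorization, qPCR standard curves, and expression ratios.

Two layers of expression analysis for a paralog pair:

* semi-quantitative RT-PCR: band optical densities relative to a reference
  gene band, bucketed into high (>0.50), low (0.01-0.50) and absent
  (not detected or <0.01) categories for tissue surveys;
* quantitative RT-PCR: per-gene standard curves (Cq linear in log10
  concentration), absolute quantities from Cq inversion, dual-reference
  normalization by the geometric mean of the reference-gene quantities, the
  paralog expression ratio per sample, and an unpaired two-sample t test
  between groups (pooled Student by default, Welch optional).

The paralog ratio is invariant to any common rescaling of the reference
genes — the normalization factor cancels — which the result records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ND",
    "DensitometrySample",
    "StandardCurve",
    "GroupComparison",
    "categorize_expression",
    "fit_standard_curve",
    "quantify_sample",
    "normalize_and_ratio",
    "compare_groups",
    "compare_groups_from_summary",
]

#: Sentinel for "not detected" band densities.
ND = "nd"

#: Relative-OD category boundaries: > HIGH_CUT is high; [LOW_CUT, HIGH_CUT]
#: is low; below LOW_CUT or not detected is absent.
HIGH_CUT = 0.50
LOW_CUT = 0.01


@dataclass(frozen=True)
class DensitometrySample:
    tissue: str
    gene: str
    band_od: float | None  # None encodes ND
    reference_od: float
    relative_od: float | None
    category: str  # high | low | absent


def categorize_expression(
    band_od: float | str | None,
    reference_od: float,
    tissue: str = "",
    gene: str = "",
) -> DensitometrySample:
    """Relative OD and its expression category for one band.

    ``band_od`` may be a number, None, or the string ``"nd"`` for a band
    that was not detected.  The boundary value 0.50 itself is "low"
    (high is strictly greater).
    """
    if reference_od is None or reference_od <= 0:
        raise ValueError("reference_od must be positive")
    nd = band_od is None or (isinstance(band_od, str) and band_od.strip().lower() == ND)
    if nd:
        return DensitometrySample(tissue, gene, None, reference_od, None, "absent")
    value = float(band_od)
    if value < 0:
        raise ValueError("band_od must be nonnegative")
    rel = value / reference_od
    if rel > HIGH_CUT:
        cat = "high"
    elif rel >= LOW_CUT:
        cat = "low"
    else:
        cat = "absent"
    return DensitometrySample(tissue, gene, value, reference_od, rel, cat)


@dataclass(frozen=True)
class StandardCurve:
    gene: str
    slope: float  # Cq per log10 concentration; negative
    intercept: float  # Cq at 1 unit concentration
    r_squared: float

    @property
    def amplification_efficiency(self) -> float:
        """10^(-1/slope) - 1; 1.0 means perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(
    calibrators: Sequence[tuple[float, float]], gene: str = ""
) -> StandardCurve:
    """Ordinary least squares of Cq on log10(concentration).

    Needs >= 3 distinct positive concentrations and a negative fitted slope
    (Cq must fall as template rises); otherwise the dilution series is
    uninformative and the fit raises.
    """
    if any(c <= 0 for c, _ in calibrators):
        raise ValueError("calibrator concentrations must be positive")
    concs = sorted({c for c, _ in calibrators})
    if len(concs) < 3:
        raise ValueError("need at least 3 distinct calibrator concentrations")
    x = np.log10([c for c, _ in calibrators])
    y = np.array([cq for _, cq in calibrators], dtype=float)
    res = stats.linregress(x, y)
    if not res.slope < 0:
        raise ValueError(f"standard curve slope must be negative, got {res.slope:.4g}")
    return StandardCurve(
        gene=gene,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def quantify_sample(cq: float | Sequence[float], curve: StandardCurve) -> float:
    """Concentration from Cq by curve inversion: 10^((cq - b) / m).

    Replicate Cq values (e.g. triplicates) are averaged on the Cq scale
    before inversion, the same rule used for calibrator crossing points.
    """
    if not np.isscalar(cq):
        cq = float(np.mean(np.asarray(cq, dtype=float)))
    return 10.0 ** ((float(cq) - curve.intercept) / curve.slope)


def normalize_and_ratio(
    target_quantities: Mapping[str, float],
    reference_quantities: Mapping[str, float],
    numerator: str = "SCGB1A1A",
    denominator: str = "SCGB1A1",
) -> dict:
    """Reference-normalized quantities and the paralog ratio for one sample.

    The normalization factor is the geometric mean of the reference-gene
    quantities (the standard multi-reference convention); it cancels in the
    numerator/denominator ratio, which the output records explicitly.
    """
    for name, qty in {**target_quantities, **reference_quantities}.items():
        if qty is None or qty <= 0:
            raise ValueError(f"quantity for {name!r} must be positive")
    if not reference_quantities:
        raise ValueError("need at least one reference gene")
    for gene in (numerator, denominator):
        if gene not in target_quantities:
            raise ValueError(f"missing target gene {gene!r}")
    logs = [math.log(q) for q in reference_quantities.values()]
    factor = math.exp(sum(logs) / len(logs))
    normalized = {g: q / factor for g, q in target_quantities.items()}
    return {
        "normalization_factor": factor,
        "normalized": normalized,
        "ratio": normalized[numerator] / normalized[denominator],
        "ratio_reference_free": True,  # the factor cancels in the ratio
    }


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p_value: float
    method: str


def _welch_df(sd_a: float, n_a: int, sd_b: float, n_b: int) -> float:
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    return (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))


def compare_groups(
    ratios_a: Sequence[float],
    ratios_b: Sequence[float],
    method: str = "student",
) -> GroupComparison:
    """Unpaired two-sample t test between two groups of expression ratios.

    ``method='student'`` (default) pools variances; ``'welch'`` does not
    assume equal variances.  Two-sided p value; SDs are sample SDs (ddof 1).
    """
    if method not in ("student", "welch"):
        raise ValueError("method must be 'student' or 'welch'")
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    res = stats.ttest_ind(a, b, equal_var=(method == "student"))
    if method == "student":
        df = len(a) + len(b) - 2
    else:
        df = _welch_df(a.std(ddof=1), len(a), b.std(ddof=1), len(b))
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=len(a),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=len(b),
        t=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        method=method,
    )


def compare_groups_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    method: str = "student",
) -> GroupComparison:
    """Same t test computed from per-group summary statistics alone."""
    if method not in ("student", "welch"):
        raise ValueError("method must be 'student' or 'welch'")
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least two observations")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=(method == "student")
    )
    df = n_a + n_b - 2 if method == "student" else _welch_df(sd_a, n_a, sd_b, n_b)
    return GroupComparison(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b,
        t=float(res.statistic), df=float(df), p_value=float(res.pvalue),
        method=method,
    )
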