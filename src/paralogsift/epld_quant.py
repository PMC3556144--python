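"""End-point limiting-dilution (EPLD) PCR statistics.

Diluting a cDNA preparation until fewer than half of replicate PCR
reactions amplify drives the per-reaction template count into the Poisson
regime: with mean lambda templates per reaction, P(positive) = 1 - e^(-lambda),
so a positive fraction below 0.5 implies lambda < ln 2 and most positive
reactions contain a single template molecule.  Sequencing those amplicons
and reading their diagnostic signature then counts *molecules* per paralog,
turning a qualitative PCR into a digital quantification of transcript
proportions.

This module selects the limiting dilution (<50% positive rule, strict),
inverts the Poisson zero-class for lambda, computes the single-template
probability and assay efficiency, and estimates per-copy proportions with
Wilson score intervals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "EPLDExperiment",
    "EPLDEstimate",
    "select_limiting_dilution",
    "estimate_lambda",
    "epld_efficiency",
    "estimate_proportions",
    "analyze_experiment",
    "read_plate_csv",
    "write_plate_csv",
]


@dataclass
class EPLDExperiment:
    """Dilution-series outcomes plus classified amplicons.

    ``dilutions`` holds (concentration, n_positive, n_total) in strictly
    decreasing concentration order.  ``classified_counts`` are the sequenced
    amplicon counts per copy at the limiting dilution.  ``wells`` optionally
    retains per-well records (dilution concentration, positive flag,
    sequenced copy label or None).
    """

    dilutions: list[tuple[float, int, int]]
    classified_counts: dict[str, int] = field(default_factory=dict)
    wells: list[tuple[float, bool, str | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        concs = [c for c, _, _ in self.dilutions]
        if any(b >= a for a, b in zip(concs, concs[1:])):
            raise ValueError("concentrations must be strictly decreasing")
        for conc, pos, tot in self.dilutions:
            if not 0 <= pos <= tot:
                raise ValueError(f"dilution {conc}: need 0 <= positives <= total")


@dataclass
class EPLDEstimate:
    limiting_concentration: float
    p_hat: float
    lambda_hat: float
    p_single_given_positive: float
    efficiency_fraction: float
    efficiency_percent: int
    proportions: dict[str, tuple[float, float, float]]  # fraction, CI low, CI high
    n_classified: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "limiting_concentration": self.limiting_concentration,
            "p_hat": self.p_hat,
            "lambda_hat": self.lambda_hat,
            "p_single_given_positive": self.p_single_given_positive,
            "efficiency_fraction": self.efficiency_fraction,
            "efficiency_percent": self.efficiency_percent,
            "n_classified": self.n_classified,
            "proportions": {
                cid: {"fraction": f, "ci_low": lo, "ci_high": hi}
                for cid, (f, lo, hi) in self.proportions.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def select_limiting_dilution(experiment: EPLDExperiment) -> float:
    """Highest concentration with a positive fraction strictly below 50%.

    "Less than 50%" is strict: a dilution at exactly half positive does not
    qualify.  Raises when every dilution amplifies in >= 50% of reactions.
    """
    qualifying = [
        conc
        for conc, pos, tot in experiment.dilutions
        if tot > 0 and pos / tot < 0.5
    ]
    if not qualifying:
        raise ValueError("no dilution has a positive fraction below 50%")
    return max(qualifying)


def estimate_lambda(n_positive: int, n_total: int) -> tuple[float, float, float]:
    """Poisson template-number estimate from a positive/total count.

    Returns ``(p_hat, lambda_hat, p_single_given_positive)`` where
    lambda_hat = -ln(1 - p_hat) inverts the Poisson zero class and
    p_single|positive = lambda e^-lambda / (1 - e^-lambda) is the chance a
    positive reaction held exactly one template.  Saturated plates
    (all positive) leave lambda undefined and raise.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    if n_positive == n_total:
        raise ValueError("all reactions positive: lambda is unbounded (saturation)")
    p_hat = n_positive / n_total
    lam = -math.log1p(-p_hat)
    if lam == 0.0:
        p_single = 1.0  # lim_{lambda->0} lambda e^-lambda/(1-e^-lambda)
    else:
        p_single = lam * math.exp(-lam) / -math.expm1(-lam)
    return p_hat, lam, p_single


def epld_efficiency(n_positive: int, n_total: int) -> tuple[float, int]:
    """Assay efficiency: fraction of reactions yielding product, and the
    integer percent used for reporting."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    frac = n_positive / n_total
    return frac, round(frac * 100)


def estimate_proportions(
    classified_counts: Mapping[str, int],
    ci_level: float = 0.95,
    single_template_correction: float | None = None,
) -> dict[str, tuple[float, float, float]]:
    """Per-copy amplicon fractions with Wilson score intervals.

    Each copy is treated copy-vs-rest as a binomial count out of the total.
    ``single_template_correction`` optionally divides each count by the
    single-template probability before renormalizing; under the
    uniform-template-pick readout model this cancels and leaves the
    fractions unchanged, so it is off (None) by default and retained only
    for transparency.
    """
    total = sum(classified_counts.values())
    if total <= 0:
        raise ValueError("no classified amplicons")
    counts = dict(classified_counts)
    if single_template_correction is not None:
        if not 0 < single_template_correction <= 1:
            raise ValueError("correction must be in (0, 1]")
        counts = {k: v / single_template_correction for k, v in counts.items()}
    grand = sum(counts.values())
    out = {}
    for cid in classified_counts:
        frac = counts[cid] / grand
        lo, hi = proportion_confint(
            classified_counts[cid], total, alpha=1 - ci_level, method="wilson"
        )
        out[cid] = (frac, float(lo), float(hi))
    return out


def analyze_experiment(
    experiment: EPLDExperiment, ci_level: float = 0.95
) -> EPLDEstimate:
    """Full EPLD analysis: limiting dilution, Poisson estimate, efficiency,
    and classified-amplicon proportions."""
    limiting = select_limiting_dilution(experiment)
    pos, tot = next(
        (p, t) for c, p, t in experiment.dilutions if c == limiting
    )
    p_hat, lam, p_single = estimate_lambda(pos, tot)
    eff_frac, eff_pct = epld_efficiency(pos, tot)
    counts = experiment.classified_counts
    if not counts and experiment.wells:
        counts = {}
        for conc, positive, label in experiment.wells:
            if conc == limiting and positive and label is not None:
                counts[label] = counts.get(label, 0) + 1
    proportions = estimate_proportions(counts, ci_level) if counts else {}
    return EPLDEstimate(
        limiting_concentration=limiting,
        p_hat=p_hat,
        lambda_hat=lam,
        p_single_given_positive=p_single,
        efficiency_fraction=eff_frac,
        efficiency_percent=eff_pct,
        proportions=proportions,
        n_classified=sum(counts.values()) if counts else 0,
    )


# ---------------------------------------------------------------------------
# Plate CSV I/O (columns: well, dilution, positive, label)
# ---------------------------------------------------------------------------


def read_plate_csv(path: str | Path) -> EPLDExperiment:
    df = pd.read_csv(path)
    required = {"well", "dilution", "positive", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: plate file has no wells")
    dilutions = []
    wells: list[tuple[float, bool, str | None]] = []
    for conc, grp in df.groupby("dilution", sort=False):
        pos = int(grp["positive"].astype(bool).sum())
        dilutions.append((float(conc), pos, len(grp)))
    dilutions.sort(key=lambda d: -d[0])
    for _, row in df.iterrows():
        label = row["label"]
        label = None if pd.isna(label) or label == "" else str(label)
        wells.append((float(row["dilution"]), bool(row["positive"]), label))
    return EPLDExperiment(dilutions=dilutions, wells=wells)


def write_plate_csv(experiment: EPLDExperiment, path: str | Path) -> None:
    rows = [
        {
            "well": i + 1,
            "dilution": conc,
            "positive": int(positive),
            "label": label if label is not None else "",
        }
        for i, (conc, positive, label) in enumerate(experiment.wells)
    ]
    pd.DataFrame(rows, columns=["well", "dilution", "positive", "label"]).to_csv(
        path, index=False
    )
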