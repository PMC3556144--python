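"""Workflow orchestration: configuration, end-to-end EPLD and expression runs.

Workflows are pure functions of (inputs, config): given the same files and
seed they produce identical reports.  Each stage writes its intermediate
artifact into the output directory so a run can be inspected step by step.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import alignment_signature as sig
from . import epld_quant
from . import expression_quant as expr
from . import synthetic_data as synth

__all__ = ["PipelineConfig", "run_epld_workflow", "run_expression_workflow"]

logger = logging.getLogger("paralogsift")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the module defaults.

    Loadable from a YAML file; any simulation stage requires ``seed``.
    """

    # inputs (None -> simulate where supported)
    plates: str | None = None
    amplicons: str | None = None  # FASTA of reads to classify
    copy_cdnas: str | None = None  # FASTA of copy cDNA consensus sequences
    qpcr: str | None = None  # Cq table CSV
    samples: str | None = None  # sample -> group CSV
    # thresholds
    max_gap: int = 10_000
    ambiguity_threshold: float = 0.75
    tolerance: int = 0
    ci_level: float = 0.95
    t_method: str = "student"
    reference_genes: tuple[str, ...] = ("GAPDH", "18S")
    numerator: str = "SCGB1A1A"
    denominator: str = "SCGB1A1"
    # simulation
    seed: int | None = None
    sim_proportions: dict[str, float] = field(
        default_factory=lambda: {"SCGB1A1": 0.3, "SCGB1A1A": 0.7}
    )
    sim_lambdas: tuple[float, ...] = (2.0, 0.7, 0.4)
    sim_n_reactions: tuple[int, ...] = (8, 48, 96)
    sim_n_amplicons: int = 200
    sim_error_rate: float = 0.0
    sim_ratios: dict[str, float] = field(
        default_factory=lambda: {"control": 2.4, "rao": 5.1}
    )
    sim_n_by_group: dict[str, int] = field(
        default_factory=lambda: {"control": 9, "rao": 5}
    )
    sim_noise_sd: float = 0.2
    outdir: str = "paralogsift_out"

    def __post_init__(self) -> None:
        if not 0.5 < self.ambiguity_threshold <= 1.0:
            raise ValueError("ambiguity_threshold must be in (0.5, 1]")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")
        if self.t_method not in ("student", "welch"):
            raise ValueError("t_method must be 'student' or 'welch'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("a seed is required when any simulation stage runs")
        return self.seed


def _read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_epld_workflow(config: PipelineConfig) -> dict:
    """Signature discovery, amplicon classification and Poisson estimation.

    Inputs are a copy-cDNA FASTA plus either an amplicon FASTA and/or a
    plate CSV; with no inputs and a seed, the whole experiment is simulated
    at the configured proportions.  The report carries the signature scheme,
    the per-amplicon classification table and the EPLD estimate.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": {k: v for k, v in asdict(config).items()}}

    simulate = config.copy_cdnas is None
    if simulate:
        seed = config.require_seed()
        logger.info("epld: simulating paralog family (seed=%d)", seed)
        family = synth.simulate_paralog_family(seed=seed)
        cdnas = {
            cid: seq
            for cid, seq in family.cdnas.items()
            if cid in config.sim_proportions
        }
        family.write_fasta(outdir / "copy_cdnas.fasta", "cdna")
    else:
        cdnas = _read_fasta(config.copy_cdnas)
        if len(cdnas) < 2:
            raise ValueError("copy cDNA FASTA must hold at least two sequences")

    logger.info("epld: discovering signature over %d copies", len(cdnas))
    scheme = sig.discover_signature(sig.MultipleAlignment(dict(cdnas)))
    scheme.to_json(outdir / "signature.json")
    report["signature"] = {
        "columns": scheme.columns,
        "alleles": {
            cid: ["".join(sorted(s)) for s in sets]
            for cid, sets in scheme.alleles.items()
        },
    }

    if simulate:
        reads = synth.simulate_amplicon_reads(
            cdnas,
            config.sim_proportions,
            config.sim_n_amplicons,
            config.sim_error_rate,
            seed=config.require_seed() + 1,
        )
        read_seqs = [(f"amplicon_{i + 1}", r) for i, (r, _) in enumerate(reads)]
    elif config.amplicons:
        read_seqs = list(_read_fasta(config.amplicons).items())
    else:
        read_seqs = []

    classified_counts: dict[str, int] = {}
    table = []
    for name, read in read_seqs:
        res = sig.classify_by_signature(read, scheme, tolerance=config.tolerance)
        table.append(
            {
                "read": name,
                "copy_id": res.copy_id,
                "mismatches": res.mismatches,
                "observed": "".join(res.observed_alleles),
            }
        )
        if res.copy_id != sig.UNCLASSIFIED:
            classified_counts[res.copy_id] = classified_counts.get(res.copy_id, 0) + 1
    if table:
        pd.DataFrame(table).to_csv(outdir / "classification.csv", index=False)
        logger.info("epld: classified %d reads", len(table))
    report["classification_counts"] = classified_counts

    if simulate:
        experiment = synth.simulate_epld_plates(
            list(config.sim_lambdas),
            list(config.sim_n_reactions),
            config.sim_proportions,
            seed=config.require_seed() + 2,
        )
        epld_quant.write_plate_csv(experiment, outdir / "plates.csv")
    elif config.plates:
        experiment = epld_quant.read_plate_csv(config.plates)
    else:
        experiment = None

    if experiment is not None:
        if classified_counts:
            experiment.classified_counts = classified_counts
        estimate = epld_quant.analyze_experiment(experiment, config.ci_level)
        estimate.to_json(outdir / "epld_estimate.json")
        report["epld"] = json.loads((outdir / "epld_estimate.json").read_text())
    (outdir / "epld_report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report


def run_expression_workflow(config: PipelineConfig) -> dict:
    """Standard curves, per-sample paralog ratios, and group comparison.

    Input is a Cq table (sample, gene, cq, conc) whose calibrator rows carry
    a concentration, plus a sample->group table; with no input and a seed, a
    two-group cohort is simulated at the configured true ratios.  Every gene
    (targets and references) must have calibrator rows.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {}

    if config.qpcr is None:
        seed = config.require_seed()
        logger.info("expression: simulating qPCR cohorts (seed=%d)", seed)
        cq, samples = synth.simulate_expression_dataset(
            config.sim_ratios,
            config.sim_n_by_group,
            noise_sd=config.sim_noise_sd,
            seed=seed,
            reference_genes=config.reference_genes,
            numerator=config.numerator,
            denominator=config.denominator,
        )
        cq.to_csv(outdir / "qpcr.csv", index=False)
        samples.to_csv(outdir / "samples.csv", index=False)
    else:
        cq = pd.read_csv(config.qpcr)
        required = {"sample", "gene", "cq", "conc"}
        if missing := required - set(cq.columns):
            raise ValueError(f"qPCR table missing columns {sorted(missing)}")
        bad = cq[pd.to_numeric(cq["cq"], errors="coerce").isna()]
        if not bad.empty:
            raise ValueError(
                f"non-numeric Cq at rows {list(bad.index + 2)}"  # header is row 1
            )
        samples = (
            pd.read_csv(config.samples)
            if config.samples
            else pd.DataFrame(columns=["sample", "group"])
        )

    genes = sorted(set(config.reference_genes) | {config.numerator, config.denominator})
    calib = cq[cq["conc"].notna()]
    curves: dict[str, expr.StandardCurve] = {}
    for gene in genes:
        rows = calib[calib["gene"] == gene]
        if rows.empty:
            raise ValueError(f"no calibrator rows for gene {gene!r}")
        curves[gene] = expr.fit_standard_curve(
            list(zip(rows["conc"], rows["cq"])), gene=gene
        )
    report["standard_curves"] = {
        g: {
            "slope": c.slope,
            "intercept": c.intercept,
            "r_squared": c.r_squared,
            "amplification_efficiency": c.amplification_efficiency,
        }
        for g, c in curves.items()
    }
    logger.info("expression: fitted %d standard curves", len(curves))

    unknowns = cq[cq["conc"].isna()]
    per_sample: dict[str, dict] = {}
    for sample, grp in unknowns.groupby("sample"):
        quantities = {
            gene: expr.quantify_sample(g["cq"].tolist(), curves[gene])
            for gene, g in grp.groupby("gene")
            if gene in curves
        }
        targets = {
            g: q
            for g, q in quantities.items()
            if g in (config.numerator, config.denominator)
        }
        refs = {g: q for g, q in quantities.items() if g in config.reference_genes}
        per_sample[str(sample)] = expr.normalize_and_ratio(
            targets, refs, config.numerator, config.denominator
        )
    report["per_sample"] = per_sample
    pd.DataFrame(
        [
            {"sample": s, "ratio": d["ratio"], **d["normalized"]}
            for s, d in per_sample.items()
        ]
    ).to_csv(outdir / "ratios.csv", index=False)

    group_of = dict(zip(samples["sample"].astype(str), samples["group"].astype(str)))
    by_group: dict[str, list[float]] = {}
    for s, d in per_sample.items():
        g = group_of.get(s)
        if g is not None:
            by_group.setdefault(g, []).append(d["ratio"])
    report["groups"] = {
        g: {
            "n": len(v),
            "mean": float(pd.Series(v).mean()),
            "sd": float(pd.Series(v).std(ddof=1)) if len(v) > 1 else 0.0,
            "dispersion_is_sd": True,  # means +/- SD, not SEM
        }
        for g, v in by_group.items()
    }
    if len(by_group) == 2:
        (ga, va), (gb, vb) = sorted(by_group.items())
        cmp_res = expr.compare_groups(va, vb, method=config.t_method)
        report["comparison"] = {
            "group_a": ga,
            "group_b": gb,
            **{k: getattr(cmp_res, k) for k in ("t", "df", "p_value", "method")},
            "significant_at_0.05": cmp_res.p_value <= 0.05,
        }
        logger.info(
            "expression: %s vs %s: t=%.3f df=%.1f p=%.3g",
            ga, gb, cmp_res.t, cmp_res.df, cmp_res.p_value,
        )
    elif by_group:
        logger.warning("expression: only one group present; comparison skipped")
        report["comparison"] = None

    (outdir / "expression_report.json").write_text(
        json.dumps(report, indent=2, default=str) + "\n"
    )
    return report
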