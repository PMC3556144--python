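"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the pipeline consumes data this module can fabricate:

* a family of near-identical gene copies embedded on one chromosome axis —
  by default three copies of ~2,650 bp (three exons, two introns) spread
  over ~0.5 Mb, two in reverse orientation, whose cDNAs differ pairwise by
  9 nucleotides including diagnostic signature columns;
* amplicon reads drawn from the copy cDNAs at given proportions with i.i.d.
  per-base substitution error;
* limiting-dilution PCR plates with Poisson-distributed template counts per
  reaction and a single sequenced copy label per positive well;
* qPCR Cq tables on a log-linear standard curve (calibrator series
  100, 10, 1, 0.1, 0.01, 0.001 ng/uL) with Gaussian Cq noise.

Each operation takes a mandatory seed and draws from a single
``numpy.random.Generator`` stream, so identical seeds give byte-identical
outputs.  Substitutions are uniform over the three alternative bases; no
indels or chimeric molecules are generated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .epld_quant import EPLDExperiment, select_limiting_dilution

__all__ = [
    "CopyTruth",
    "ParalogFamilyTruth",
    "simulate_paralog_family",
    "simulate_amplicon_reads",
    "simulate_epld_plates",
    "simulate_qpcr",
    "simulate_expression_dataset",
    "DEFAULT_COPY_IDS",
    "DEFAULT_EXON_LENGTHS",
    "DEFAULT_INTRON_LENGTHS",
    "DEFAULT_INTERCOPY_GAPS",
    "DEFAULT_ORIENTATIONS",
    "CALIBRATOR_SERIES",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

# Study-scale defaults: three copies, exon/intron geometry summing to a
# 2,647 bp gene body, inter-copy gaps of ~19.7 kb and ~484 kb (a ~0.5 Mb
# region), two copies reversed; cDNAs differ pairwise by 9 nucleotides.
DEFAULT_COPY_IDS = ("SCGB1A1P", "SCGB1A1", "SCGB1A1A")
DEFAULT_EXON_LENGTHS = (55, 194, 34)  # mRNA order
DEFAULT_INTRON_LENGTHS = (2066, 298)
DEFAULT_INTERCOPY_GAPS = (19_703, 483_631)
DEFAULT_ORIENTATIONS = ("-", "-", "+")
DEFAULT_N_CDNA_DIFFS = 9

#: qPCR calibrator dilution series (ng/uL).
CALIBRATOR_SERIES = (100.0, 10.0, 1.0, 0.1, 0.01, 0.001)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    alternatives = [b for b in "ACGT" if b != base]
    return alternatives[rng.integers(3)]


@dataclass(frozen=True)
class CopyTruth:
    copy_id: str
    genomic: str  # chromosome-strand sequence of the gene body
    exons: tuple[tuple[int, int], ...]  # chromosome coords, 1-based inclusive
    orientation: str
    offset: int  # chromosome coordinate of the gene body's first base
    cdna: str

    @property
    def span_bp(self) -> int:
        return self.exons[-1][1] - self.exons[0][0] + 1


@dataclass
class ParalogFamilyTruth:
    """Ground truth for a simulated paralog family."""

    ancestor: str  # ancestral gene body (gene-forward)
    ancestor_cdna: str
    copies: list[CopyTruth]
    cdna_diffs: dict[tuple[str, str], int]
    signature_columns: list[int]  # 1-based cDNA positions
    per_copy_signature_alleles: dict[str, tuple[str, ...]]
    seed: int

    @property
    def cdnas(self) -> dict[str, str]:
        return {c.copy_id: c.cdna for c in self.copies}

    def write_fasta(self, path: str | Path, which: str = "cdna") -> None:
        """Write copy sequences ('cdna' or 'genomic') as FASTA."""
        with Path(path).open("w") as fh:
            for c in self.copies:
                seq = c.cdna if which == "cdna" else c.genomic
                fh.write(f">{c.copy_id}\n{seq}\n")


def _plan_differences(
    rng: np.random.Generator,
    copy_ids: Sequence[str],
    cdna_len: int,
    n_diffs: int,
) -> tuple[dict[str, dict[int, str]], list[int], str]:
    """Choose mutated cDNA columns so every copy pair differs at exactly
    ``n_diffs`` positions; returns per-copy {position: base} overrides,
    the chosen signature columns, and the ancestor cDNA placeholder bases.

    Construction: ``a`` columns where all copies carry pairwise-distinct
    bases plus ``b`` private columns per copy where only that copy deviates
    gives every pair a distance of a + 2b.  Odd distances need a = 1
    (feasible for <= 4 copies); even distances use a = 0.
    """
    n = len(copy_ids)
    if n_diffs <= 0:
        raise ValueError("n_cdna_diffs must be >= 1: identical copies carry no signature")
    if n == 2:
        a, b = 0, 0
        positions = rng.choice(cdna_len, size=n_diffs, replace=False) + 1
        positions = sorted(int(p) for p in positions)
        overrides: dict[str, dict[int, str]] = {cid: {} for cid in copy_ids}
        sig_cols = [positions[0]]
        return overrides, sig_cols, _n2_fill(rng, copy_ids, positions, overrides)
    if n_diffs % 2 == 1:
        if n > 4:
            raise ValueError(
                "odd pairwise distances need an all-distinct column, "
                "impossible for more than 4 copies over a 4-letter alphabet"
            )
        a, b = 1, (n_diffs - 1) // 2
    else:
        a, b = 0, n_diffs // 2
    if b == 0 and a == 0:
        raise ValueError("n_cdna_diffs too small for this copy number")
    needed = a + n * b
    if needed > cdna_len:
        raise ValueError(
            f"requested divergence needs {needed} columns but the cDNA has {cdna_len}"
        )
    cols = rng.choice(cdna_len, size=needed, replace=False) + 1
    cols = [int(c) for c in cols]
    shared = cols[:a]
    private = {
        cid: sorted(cols[a + i * b : a + (i + 1) * b]) for i, cid in enumerate(copy_ids)
    }
    overrides = {cid: {} for cid in copy_ids}
    for col in shared:
        bases = rng.permutation(_BASES)[:n]
        for cid, base in zip(copy_ids, bases):
            overrides[cid][col] = str(base)
    for cid in copy_ids:
        for col in private[cid]:
            overrides[cid][col] = None  # filled once the ancestor base is known
    if b >= 1:
        sig_cols = sorted(private[cid][0] for cid in copy_ids)
    else:
        sig_cols = sorted(shared)
    return overrides, sig_cols, ""


def _n2_fill(rng, copy_ids, positions, overrides) -> str:
    for p in positions:
        overrides[copy_ids[1]][p] = None
    return ""


def simulate_paralog_family(
    n_copies: int = 3,
    exon_lengths: Sequence[int] = DEFAULT_EXON_LENGTHS,
    intron_lengths: Sequence[int] = DEFAULT_INTRON_LENGTHS,
    intercopy_gaps: Sequence[int] = DEFAULT_INTERCOPY_GAPS,
    n_cdna_diffs: int = DEFAULT_N_CDNA_DIFFS,
    orientations: Sequence[str] = DEFAULT_ORIENTATIONS,
    seed: int = 0,
    copy_ids: Sequence[str] | None = None,
    ancestor_length: int | None = None,
) -> ParalogFamilyTruth:
    """Simulate a family of gene copies on one chromosome axis.

    Exon and intron lengths are in mRNA order; a copy's gene body is
    exon1-intron1-exon2-...-exonK, reverse-complemented onto the chromosome
    for '-' orientation.  Copies are placed left to right separated by
    ``intercopy_gaps``.  Every copy pair's cDNA Hamming distance equals
    ``n_cdna_diffs`` exactly, and the planted signature columns carry
    pairwise-distinct allele tuples.

    ``ancestor_length``, when given, must equal the gene-body length implied
    by the exon/intron geometry (it is redundant and only validated).
    """
    if n_copies < 2:
        raise ValueError("n_copies must be >= 2")
    if len(exon_lengths) < 1 or any(l <= 0 for l in exon_lengths):
        raise ValueError("exon lengths must be positive")
    if len(intron_lengths) != len(exon_lengths) - 1 or any(
        l <= 0 for l in intron_lengths
    ):
        raise ValueError("need len(exons) - 1 positive intron lengths")
    if len(intercopy_gaps) != n_copies - 1 or any(g < 0 for g in intercopy_gaps):
        raise ValueError("need n_copies - 1 nonnegative intercopy gaps")
    if len(orientations) != n_copies or any(o not in "+-" for o in orientations):
        raise ValueError("orientations must be '+'/'-' strings, one per copy")
    copy_ids = list(copy_ids) if copy_ids else (
        list(DEFAULT_COPY_IDS[:n_copies])
        if n_copies <= len(DEFAULT_COPY_IDS)
        else [f"copy{i + 1}" for i in range(n_copies)]
    )
    gene_len = sum(exon_lengths) + sum(intron_lengths)
    if ancestor_length is not None and ancestor_length != gene_len:
        raise ValueError(
            f"ancestor_length {ancestor_length} contradicts exon/intron geometry ({gene_len})"
        )
    cdna_len = sum(exon_lengths)
    rng = np.random.default_rng(seed)
    ancestor_cdna = _random_dna(rng, cdna_len)
    introns = [_random_dna(rng, l) for l in intron_lengths]

    overrides, sig_cols, _ = _plan_differences(rng, copy_ids, cdna_len, n_cdna_diffs)
    # fill private (odd-one-out) columns: mutate away from the ancestor base
    for cid in copy_ids:
        for col, base in list(overrides[cid].items()):
            if base is None:
                overrides[cid][col] = _mutate_base(rng, ancestor_cdna[col - 1])

    # assemble per-copy cDNA and gene body
    exon_bounds = []
    pos = 0
    for l in exon_lengths:
        exon_bounds.append((pos, pos + l))
        pos += l

    def gene_forward(cdna: str) -> tuple[str, list[tuple[int, int]]]:
        parts, coords = [], []
        cursor = 0
        for i, (s, e) in enumerate(exon_bounds):
            parts.append(cdna[s:e])
            coords.append((cursor + 1, cursor + (e - s)))
            cursor += e - s
            if i < len(introns):
                parts.append(introns[i])
                cursor += len(introns[i])
        return "".join(parts), coords

    copies: list[CopyTruth] = []
    offset = 1
    for k, cid in enumerate(copy_ids):
        cdna = list(ancestor_cdna)
        for col, base in overrides[cid].items():
            cdna[col - 1] = base
        cdna = "".join(cdna)
        body, exon_local = gene_forward(cdna)
        if orientations[k] == "+":
            chrom_seq = body
            exons = tuple((offset + s - 1, offset + e - 1) for s, e in exon_local)
        else:
            chrom_seq = str(Seq(body).reverse_complement())
            exons = tuple(
                sorted(
                    (offset + gene_len - e, offset + gene_len - s)
                    for s, e in exon_local
                )
            )
        copies.append(
            CopyTruth(
                copy_id=cid,
                genomic=chrom_seq,
                exons=exons,
                orientation=orientations[k],
                offset=offset,
                cdna=cdna,
            )
        )
        if k < n_copies - 1:
            offset += gene_len + intercopy_gaps[k]

    ancestor_body, _ = gene_forward(ancestor_cdna)
    diffs = {
        (a, b): sum(
            x != y
            for x, y in zip(
                next(c.cdna for c in copies if c.copy_id == a),
                next(c.cdna for c in copies if c.copy_id == b),
            )
        )
        for a, b in itertools.combinations(copy_ids, 2)
    }
    alleles = {
        c.copy_id: tuple(c.cdna[col - 1] for col in sig_cols) for c in copies
    }
    return ParalogFamilyTruth(
        ancestor=ancestor_body,
        ancestor_cdna=ancestor_cdna,
        copies=copies,
        cdna_diffs=diffs,
        signature_columns=sig_cols,
        per_copy_signature_alleles=alleles,
        seed=seed,
    )


def simulate_amplicon_reads(
    copy_cdnas: Mapping[str, str],
    proportions: Mapping[str, float],
    n_reads: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Draw reads from copy cDNAs with i.i.d. substitution errors.

    Each read is its source cDNA with every base independently substituted
    with probability ``error_rate`` (uniform over the three alternatives);
    the true source label is retained.  Stands in for Sanger-sequenced
    single-molecule amplicons.
    """
    if not copy_cdnas:
        raise ValueError("empty copy set")
    if set(proportions) != set(copy_cdnas):
        raise ValueError("proportions must cover exactly the copy ids")
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    if not 0.0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    if n_reads < 0:
        raise ValueError("n_reads must be nonnegative")
    rng = np.random.default_rng(seed)
    ids = sorted(copy_cdnas)
    probs = np.array([proportions[c] for c in ids])
    encoded = {
        c: np.array([_BASE_INDEX[b] for b in copy_cdnas[c].upper()], dtype=np.int8)
        for c in ids
    }
    sources = rng.choice(len(ids), size=n_reads, p=probs)
    reads: list[tuple[str, str]] = []
    for src in sources:
        cid = ids[src]
        arr = encoded[cid].copy()
        if error_rate > 0:
            mask = rng.random(arr.shape) < error_rate
            if mask.any():
                # shift by 1-3 positions in base space: never the original base
                shifts = rng.integers(1, 4, size=int(mask.sum()))
                arr[mask] = (arr[mask] + shifts) % 4
        reads.append(("".join(_BASES[arr]), cid))
    return reads


def simulate_epld_plates(
    lambda_per_dilution: Sequence[float],
    n_reactions: Sequence[int],
    proportions: Mapping[str, float],
    seed: int = 0,
    concentrations: Sequence[float] | None = None,
) -> EPLDExperiment:
    """Simulate a limiting-dilution series of PCR plates.

    Per reaction the template count is Poisson(lambda); a reaction is
    positive iff it holds >= 1 template, and its sequenced label is one of
    its templates picked uniformly (single Sanger trace, no chimeras).
    Concentrations default to the lambda values themselves (arbitrary units)
    and must be strictly decreasing.
    """
    if len(lambda_per_dilution) != len(n_reactions):
        raise ValueError("lambda_per_dilution and n_reactions must align")
    if any(l < 0 for l in lambda_per_dilution):
        raise ValueError("lambda values must be nonnegative")
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    concs = list(concentrations) if concentrations is not None else list(lambda_per_dilution)
    if len(concs) != len(lambda_per_dilution):
        raise ValueError("concentrations must align with dilutions")
    rng = np.random.default_rng(seed)
    ids = sorted(proportions)
    probs = np.array([proportions[c] for c in ids])
    dilutions = []
    wells: list[tuple[float, bool, str | None]] = []
    for conc, lam, n in zip(concs, lambda_per_dilution, n_reactions):
        counts = rng.poisson(lam, size=n)
        n_pos = int((counts >= 1).sum())
        dilutions.append((float(conc), n_pos, int(n)))
        for c in counts:
            if c == 0:
                wells.append((float(conc), False, None))
            else:
                templates = rng.choice(len(ids), size=int(c), p=probs)
                label = ids[int(templates[rng.integers(len(templates))])]
                wells.append((float(conc), True, label))
    experiment = EPLDExperiment(
        dilutions=sorted(dilutions, key=lambda d: -d[0]),
        wells=wells,
    )
    try:
        limiting = select_limiting_dilution(experiment)
    except ValueError:
        return experiment
    counts_at_limit: dict[str, int] = {}
    for conc, positive, label in wells:
        if conc == limiting and positive and label is not None:
            counts_at_limit[label] = counts_at_limit.get(label, 0) + 1
    experiment.classified_counts = counts_at_limit
    return experiment


#: Slope of an ideal standard curve: one cycle per doubling,
#: i.e. -1/log10(2) Cq per decade of template.
IDEAL_SLOPE = -1.0 / math.log10(2.0)


def simulate_qpcr(
    true_conc: Mapping[tuple[str, str], float],
    slope: float = IDEAL_SLOPE,
    intercept: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    calibrator_series: Sequence[float] = CALIBRATOR_SERIES,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate a Cq table with per-gene calibrator dilution series.

    Cq = intercept + slope * log10(concentration) + N(0, noise_sd), with
    ``n_replicates`` wells per (sample, gene).  Calibrator rows carry their
    known concentration in the ``conc`` column (sample = 'calibrator');
    unknowns have an empty ``conc``.
    """
    if slope >= 0:
        raise ValueError("slope must be negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    for (sample, gene), conc in true_conc.items():
        if conc <= 0:
            raise ValueError(f"nonpositive concentration for ({sample}, {gene})")
    rng = np.random.default_rng(seed)
    rows = []

    def cq_of(conc: float) -> float:
        cq = intercept + slope * math.log10(conc)
        if noise_sd > 0:
            cq += rng.normal(0.0, noise_sd)
        return cq

    genes = sorted({gene for _, gene in true_conc})
    for gene in genes:
        for conc in calibrator_series:
            for _ in range(n_replicates):
                rows.append(
                    {"sample": "calibrator", "gene": gene, "cq": cq_of(conc), "conc": conc}
                )
    for (sample, gene), conc in sorted(true_conc.items()):
        for _ in range(n_replicates):
            rows.append({"sample": sample, "gene": gene, "cq": cq_of(conc), "conc": np.nan})
    return pd.DataFrame(rows, columns=["sample", "gene", "cq", "conc"])


def simulate_expression_dataset(
    ratio_by_group: Mapping[str, float],
    n_by_group: Mapping[str, int],
    noise_sd: float = 0.2,
    seed: int = 0,
    base_conc: float = 1.0,
    reference_genes: Sequence[str] = ("GAPDH", "18S"),
    reference_conc: float = 10.0,
    numerator: str = "SCGB1A1A",
    denominator: str = "SCGB1A1",
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-paralog qPCR cohort study.

    Each sample in group g has denominator-gene concentration ``base_conc``
    and numerator-gene concentration ``ratio_by_group[g] * base_conc``, plus
    constant reference-gene concentrations; measurement noise enters only
    through Cq (``noise_sd``).  Returns ``(cq_table, sample_table)`` where
    the sample table maps sample id to group (CSV-ready sidecars).
    """
    true_conc: dict[tuple[str, str], float] = {}
    groups = []
    for group in sorted(ratio_by_group):
        ratio = ratio_by_group[group]
        if ratio <= 0:
            raise ValueError("ratios must be positive")
        for i in range(n_by_group[group]):
            sample = f"{group}_{i + 1}"
            groups.append({"sample": sample, "group": group})
            true_conc[(sample, denominator)] = base_conc
            true_conc[(sample, numerator)] = ratio * base_conc
            for ref in reference_genes:
                true_conc[(sample, ref)] = reference_conc
    cq = simulate_qpcr(
        true_conc, noise_sd=noise_sd, seed=seed, n_replicates=n_replicates
    )
    return cq, pd.DataFrame(groups, columns=["sample", "group"])
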