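"""Alignment statistics, consensus calling, and diagnostic-signature analysis.

Near-identical gene paralogs (>97% cDNA identity) cannot be told apart by
overall similarity; they can be told apart by a small set of alignment
columns — a "signature" — at which their alleles differ.  This module
discovers the minimal such column set from aligned copy sequences, classifies
amplicon reads by their bases at those columns, and provides the supporting
utilities the workflow needs: pairwise identity statistics, IUPAC-aware
consensus calling from replicate sequences, codon-consequence annotation
(e.g. a premature stop gained in a pseudogene candidate), protein comparison
and isoelectric-point prediction.

Coordinates for signature columns are 1-based on the cDNA, counted from the
first base of the start codon.  Genomic positions, where carried, are a
parallel list with a fixed per-copy offset; the mapping is explicit input
and never inferred.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

from Bio import Align
from Bio.Seq import Seq

__all__ = [
    "IUPAC_SETS",
    "MultipleAlignment",
    "SignatureScheme",
    "ClassificationResult",
    "UNCLASSIFIED",
    "align_pair",
    "pairwise_identity",
    "call_consensus",
    "discover_signature",
    "classify_by_signature",
    "detect_premature_stop",
    "CodonConsequence",
    "translate_cdna",
    "compare_proteins",
    "variant_prevalence",
    "isoelectric_point",
    "net_charge",
    "PKA_SETS",
]

# ---------------------------------------------------------------------------
# IUPAC nucleotide ambiguity codes
# ---------------------------------------------------------------------------

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "M": frozenset("AC"),
    "K": frozenset("GT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_SET_TO_CODE = {bases: code for code, bases in IUPAC_SETS.items()}


def iupac_code(bases: set[str] | frozenset[str]) -> str:
    """Minimal IUPAC code covering a non-empty set of concrete bases."""
    key = frozenset(bases)
    try:
        return _SET_TO_CODE[key]
    except KeyError:
        raise ValueError(f"not a valid base set: {sorted(bases)}") from None


def expand_iupac(code: str) -> frozenset[str]:
    try:
        return IUPAC_SETS[code.upper()]
    except KeyError:
        raise ValueError(f"unknown IUPAC code {code!r}") from None


# ---------------------------------------------------------------------------
# Alignment container and primitive
# ---------------------------------------------------------------------------


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows keyed by sequence id (IUPAC DNA + '-')."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        allowed = set(IUPAC_SETS) | {"-"}
        for sid, seq in self.rows.items():
            self.rows[sid] = seq = seq.upper()
            bad = set(seq) - allowed
            if bad:
                raise ValueError(f"row {sid!r} has non-IUPAC characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def column(self, pos: int) -> dict[str, str]:
        """Bases of a 1-based column, keyed by row id."""
        return {sid: seq[pos - 1] for sid, seq in self.rows.items()}


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Global Needleman-Wunsch alignment (match 1, mismatch -2, gap -2).

    Intended for the small inputs this workflow sees (primer sites, short
    cDNAs); returns the two gapped rows of the best alignment.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def pairwise_identity(aln: MultipleAlignment) -> dict:
    """Pairwise and column-wise identity statistics of an alignment.

    Per-pair identity is matching columns over columns where neither row is
    gapped, as a percentage.  An identical site is a column at which every
    row carries the same non-gap base.  Percentages are rounded to one
    decimal for reporting; full precision is retained under ``*_raw`` keys.
    """
    ids = list(aln.rows)
    if len(ids) < 2:
        raise ValueError("pairwise identity needs at least two rows")
    per_pair: dict[tuple[str, str], float] = {}
    for x, y in itertools.combinations(ids, 2):
        rx, ry = aln.rows[x], aln.rows[y]
        both = [(a, b) for a, b in zip(rx, ry) if a != "-" and b != "-"]
        if not both:
            per_pair[(x, y)] = float("nan")
            continue
        match = sum(a == b for a, b in both)
        per_pair[(x, y)] = 100.0 * match / len(both)
    n_cols = aln.length
    identical = 0
    for i in range(n_cols):
        col = {seq[i] for seq in aln.rows.values()}
        if len(col) == 1 and "-" not in col:
            identical += 1
    mean_raw = sum(per_pair.values()) / len(per_pair)
    return {
        "per_pair": {k: round(v, 1) for k, v in per_pair.items()},
        "per_pair_raw": per_pair,
        "mean_identity": round(mean_raw, 1),
        "identical_sites": identical,
        "identical_sites_pct": round(100.0 * identical / n_cols, 1) if n_cols else 0.0,
        "n_columns": n_cols,
    }


# ---------------------------------------------------------------------------
# Consensus calling
# ---------------------------------------------------------------------------

DEFAULT_AMBIGUITY_THRESHOLD = 0.75


def call_consensus(
    replicates: Sequence[str],
    ambiguity_threshold: float = DEFAULT_AMBIGUITY_THRESHOLD,
) -> str:
    """Column-wise consensus of aligned replicate sequences.

    Per column: if the majority base reaches ``ambiguity_threshold`` of the
    non-gap observations it is called outright; otherwise the minimal IUPAC
    code covering every base whose frequency exceeds ``1 - threshold`` is
    emitted, so a genuine polymorphism (e.g. a C/A site split 50/50 across
    replicates) surfaces as an ambiguity code rather than an arbitrary pick.
    Gap-only columns yield '-'.
    """
    if len(replicates) < 2:
        raise ValueError("consensus needs at least two replicates")
    if not 0.5 < ambiguity_threshold <= 1.0:
        raise ValueError("ambiguity_threshold must be in (0.5, 1]")
    lengths = {len(r) for r in replicates}
    if len(lengths) != 1:
        raise ValueError(f"replicates have conflicting lengths: {sorted(lengths)}")
    reps = [r.upper() for r in replicates]
    out = []
    for col in zip(*reps):
        bases = [b for b in col if b != "-"]
        if not bases:
            out.append("-")
            continue
        counts: dict[str, int] = {}
        for b in bases:
            counts[b] = counts.get(b, 0) + 1
        n = len(bases)
        # ties break deterministically by base order
        top, top_n = max(sorted(counts.items()), key=lambda kv: kv[1])
        if top_n / n >= ambiguity_threshold:
            out.append(top)
        else:
            keep = {b for b, c in counts.items() if c / n > 1.0 - ambiguity_threshold}
            out.append(iupac_code(keep or set(counts)))
    return "".join(out)


# ---------------------------------------------------------------------------
# Signature discovery and classification
# ---------------------------------------------------------------------------

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class SignatureScheme:
    """Ordered diagnostic columns plus per-copy allele sets.

    ``columns`` are 1-based cDNA positions; ``alleles`` maps each copy id to
    one allele *set* per column (a set, so a copy with a polymorphic
    signature base — like a C/A site — is representable).  Validity requires
    that every pair of copies has disjoint allele sets in at least one
    column; otherwise the scheme cannot discriminate that pair.
    """

    columns: list[int]
    alleles: dict[str, tuple[frozenset[str], ...]]
    genomic_columns: list[int] | None = None

    def __post_init__(self) -> None:
        if list(self.columns) != sorted(set(self.columns)):
            raise ValueError("columns must be strictly increasing")
        k = len(self.columns)
        self.alleles = {
            cid: tuple(frozenset(s) for s in sets) for cid, sets in self.alleles.items()
        }
        for cid, sets in self.alleles.items():
            if len(sets) != k:
                raise ValueError(f"copy {cid!r}: expected {k} allele sets")
        for a, b in itertools.combinations(self.alleles, 2):
            if not any(
                sa.isdisjoint(sb)
                for sa, sb in zip(self.alleles[a], self.alleles[b])
            ):
                raise ValueError(
                    f"copies {a!r} and {b!r} share alleles in every column; "
                    "scheme cannot discriminate them"
                )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "columns": self.columns,
            "genomic_columns": self.genomic_columns,
            "alleles": {
                cid: ["".join(sorted(s)) for s in sets]
                for cid, sets in self.alleles.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureScheme":
        payload = json.loads(Path(path).read_text())
        return cls(
            columns=payload["columns"],
            alleles={
                cid: tuple(frozenset(s) for s in sets)
                for cid, sets in payload["alleles"].items()
            },
            genomic_columns=payload.get("genomic_columns"),
        )


@dataclass(frozen=True)
class ClassificationResult:
    copy_id: str  # a copy id or UNCLASSIFIED
    mismatches: int
    observed_alleles: tuple[str, ...]


def _pairs_separated(
    alleles: Mapping[str, Sequence[frozenset[str]]], cols_idx: tuple[int, ...]
) -> bool:
    for a, b in itertools.combinations(alleles, 2):
        if not any(alleles[a][i].isdisjoint(alleles[b][i]) for i in cols_idx):
            return False
    return True


def discover_signature(
    copy_sequences: MultipleAlignment,
    max_columns: int = 5,
) -> SignatureScheme:
    """Find the smallest diagnostic column set over aligned copy sequences.

    Exhaustive search over subsets of the variable columns in increasing
    size; among minimal sets, the lexicographically smallest position tuple
    wins.  Ambiguity codes in the input expand to allele sets, so a
    consensus carrying e.g. ``M`` contributes {A, C} at that column.
    Raises ``ValueError`` when no set of size <= ``max_columns`` separates
    every pair (indistinguishable copies).
    """
    ids = list(copy_sequences.rows)
    if len(ids) < 2:
        raise ValueError("signature discovery needs at least two copies")
    n_cols = copy_sequences.length
    # Allele sets per copy per column; gaps get an empty set (never matches).
    allele_table: dict[str, list[frozenset[str]]] = {
        cid: [
            frozenset() if ch == "-" else expand_iupac(ch)
            for ch in copy_sequences.rows[cid]
        ]
        for cid in ids
    }
    # Only columns where some pair is separable can help.
    candidate_cols = [
        j
        for j in range(n_cols)
        if any(
            allele_table[a][j].isdisjoint(allele_table[b][j])
            and (allele_table[a][j] or allele_table[b][j])
            for a, b in itertools.combinations(ids, 2)
        )
    ]
    for size in range(1, max_columns + 1):
        best: tuple[int, ...] | None = None
        for combo in itertools.combinations(candidate_cols, size):
            if _pairs_separated(allele_table, combo):
                best = combo
                break  # combinations() is lexicographic, first hit is smallest
        if best is not None:
            columns = [j + 1 for j in best]
            return SignatureScheme(
                columns=columns,
                alleles={
                    cid: tuple(allele_table[cid][j] for j in best) for cid in ids
                },
            )
    raise ValueError(
        f"no diagnostic column set of size <= {max_columns} separates all copies"
    )


def classify_by_signature(
    read: str,
    scheme: SignatureScheme,
    offset: int | Callable[[int], int] = 0,
    tolerance: int = 0,
) -> ClassificationResult:
    """Assign a read to a copy by its bases at the signature columns.

    ``offset`` maps cDNA coordinates onto the read: an integer ``k`` means
    cDNA position ``p`` is read position ``p - k`` (both 1-based); a callable
    receives the cDNA position and returns the read position.  A read is
    assigned to the unique copy with mismatches <= ``tolerance`` and strictly
    fewer mismatches than every other copy; on a tie or when no copy
    qualifies the result is UNCLASSIFIED.  The default tolerance of 0
    demands an exact signature match.
    """
    read = read.upper()
    mapper = offset if callable(offset) else (lambda p, k=offset: p - k)
    observed: list[str] = []
    for col in scheme.columns:
        pos = mapper(col)
        if not 1 <= pos <= len(read):
            raise ValueError(
                f"signature column {col} maps to read position {pos}, "
                f"outside read of length {len(read)}"
            )
        observed.append(read[pos - 1])
    scores = {
        cid: sum(base not in sets[i] for i, base in enumerate(observed))
        for cid, sets in scheme.alleles.items()
    }
    ranked = sorted(scores.items(), key=lambda kv: kv[1])
    best_id, best = ranked[0]
    runner_up = ranked[1][1] if len(ranked) > 1 else best + 1
    obs = tuple(observed)
    if best <= tolerance and best < runner_up:
        return ClassificationResult(best_id, best, obs)
    return ClassificationResult(UNCLASSIFIED, best, obs)


# ---------------------------------------------------------------------------
# Coding consequences and protein utilities
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class CodonConsequence:
    codon_number: int  # 1-based codon index from the start codon
    cdna_position: int  # 1-based position of the codon's first base
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    kind: str  # synonymous | missense | stop_gained | stop_lost


def translate_cdna(cdna: str) -> str:
    """Translate from the first base; trailing partial codon ignored."""
    usable = len(cdna) - len(cdna) % 3
    return str(Seq(cdna[:usable].upper()).translate())


def detect_premature_stop(reference_cdna: str, variant_cdna: str) -> list[CodonConsequence]:
    """Annotate codon-level consequences of a variant against a reference.

    Both sequences must share the reading frame from the annotated start
    codon (position 1) and be equal length — substitution-only variants.
    A codon is reported once however many of its bases differ; a stop gained
    upstream of the natural stop is what demotes a gene copy to pseudogene
    status.
    """
    ref, alt = reference_cdna.upper(), variant_cdna.upper()
    if len(ref) != len(alt):
        raise ValueError("reference and variant cDNA must be equal length")
    out: list[CodonConsequence] = []
    for i in range(0, len(ref) - len(ref) % 3, 3):
        rc, ac = ref[i : i + 3], alt[i : i + 3]
        if rc == ac:
            continue
        ra = str(Seq(rc).translate())
        aa = str(Seq(ac).translate())
        if ac in _STOPS and rc not in _STOPS:
            kind = "stop_gained"
        elif rc in _STOPS and ac not in _STOPS:
            kind = "stop_lost"
        elif ra == aa:
            kind = "synonymous"
        else:
            kind = "missense"
        out.append(
            CodonConsequence(
                codon_number=i // 3 + 1,
                cdna_position=i + 1,
                ref_codon=rc,
                alt_codon=ac,
                ref_aa=ra,
                alt_aa=aa,
                kind=kind,
            )
        )
    return out


def compare_proteins(prot_a: str, prot_b: str) -> tuple[int, list[tuple[int, str, str]]]:
    """Positional substitutions between two equal-length protein sequences."""
    a, b = prot_a.upper(), prot_b.upper()
    if len(a) != len(b):
        raise ValueError("protein sequences must be equal length")
    subs = [(i + 1, x, y) for i, (x, y) in enumerate(zip(a, b)) if x != y]
    return len(subs), subs


def variant_prevalence(n_variant: int, n_total: int) -> tuple[float, int]:
    """Fraction and rounded integer percent of individuals carrying a variant."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_variant <= n_total:
        raise ValueError("n_variant must be in [0, n_total]")
    frac = n_variant / n_total
    return frac, round(frac * 100)


# ---------------------------------------------------------------------------
# Isoelectric point
# ---------------------------------------------------------------------------

#: pKa tables by name: N-terminus, C-terminus, and ionizable side chains.
PKA_SETS: dict[str, dict[str, float]] = {
    # EMBOSS iep defaults
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
    },
    # Sillero & Ribeiro (1989)
    "sillero": {
        "Nterm": 8.2, "Cterm": 3.2,
        "C": 9.0, "D": 4.0, "E": 4.5, "H": 6.4, "K": 10.4, "R": 12.0, "Y": 10.0,
    },
}

_POSITIVE = ("Nterm", "H", "K", "R")
_NEGATIVE = ("Cterm", "C", "D", "E", "Y")
_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


def net_charge(prot: str, ph: float, pka_set: str = "emboss") -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH."""
    prot = prot.upper()
    bad = set(prot) - _AA20
    if bad:
        raise ValueError(f"unknown residues: {sorted(bad)}")
    pka = PKA_SETS[pka_set]
    counts = {aa: prot.count(aa) for aa in "CDEHKRY"}
    charge = 0.0
    for group in _POSITIVE:
        n = 1 if group == "Nterm" else counts.get(group, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka[group]))
    for group in _NEGATIVE:
        n = 1 if group == "Cterm" else counts.get(group, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[group] - ph))
    return charge


def isoelectric_point(
    prot: str, pka_set: str = "emboss", tol: float = 0.01
) -> float:
    """pH at which the peptide's net charge crosses zero, by bisection.

    The charge function is strictly decreasing in pH, so bisection on
    [0, 14] converges to the unique root; ``tol`` is the pH resolution.
    """
    if pka_set not in PKA_SETS:
        raise ValueError(f"unknown pKa set {pka_set!r}; have {sorted(PKA_SETS)}")
    lo, hi = 0.0, 14.0
    # bisect an order of magnitude past tol so rounding stays within it
    while hi - lo > tol / 10.0:
        mid = 0.5 * (lo + hi)
        if net_charge(prot, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return round(0.5 * (lo + hi), 2)
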