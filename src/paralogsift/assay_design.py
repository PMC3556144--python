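"""In-silico validation of copy-specific PCR assays.

For paralogs this similar, assay specificity has to be engineered: primers
anchored on copy-unique bases, product identity confirmed by size and by a
restriction-digest fingerprint.  This module predicts primer binding sites
(IUPAC-degenerate primers against concrete templates), PCR products, the
copy-specificity of a primer (>= 3 target-unique bases under its footprint),
and restriction fragments, and decides whether two fragment fingerprints are
distinguishable on a gel of given relative resolution.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .alignment_signature import IUPAC_SETS, MultipleAlignment, expand_iupac

__all__ = [
    "PrimerRecord",
    "PrimerSite",
    "AmpliconPrediction",
    "DigestResult",
    "load_enzymes",
    "find_primer_sites",
    "in_silico_pcr",
    "check_copy_specificity",
    "digest",
    "digest_discrimination",
    "DEFAULT_THREE_PRIME_EXACT",
    "DEFAULT_GEL_RESOLUTION",
]

#: 3'-terminal bases of a primer that must match with zero mismatches
#: (a 3' mismatch abolishes polymerase extension).
DEFAULT_THREE_PRIME_EXACT = 3

#: Default gel resolution as a relative fragment-length difference;
#: ~5% is typical for agarose electrophoresis.
DEFAULT_GEL_RESOLUTION = 0.05


@dataclass(frozen=True)
class PrimerRecord:
    name: str
    sequence: str  # IUPAC DNA, 5'->3'
    intended_target: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.replace(" ", "").upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 10:
            raise ValueError(f"primer {self.name!r}: length must be >= 10")
        bad = set(seq) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"primer {self.name!r}: non-IUPAC characters {sorted(bad)}")


@dataclass(frozen=True)
class PrimerSite:
    position: int  # 1-based, 5'-most template coordinate of the site
    strand: str
    mismatches: int


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    start: int  # 1-based inclusive on template
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DigestResult:
    enzyme: str
    recognition: str
    cut_offset: int  # cut after this many bases of the site, top strand
    site_starts: list[int]  # 1-based
    fragment_lengths: list[int] = field(init=False)
    template_length: int = 0

    def __post_init__(self) -> None:
        cuts = [s + self.cut_offset - 1 for s in sorted(self.site_starts)]
        bounds = [0, *cuts, self.template_length]
        self.fragment_lengths = sorted(
            b - a for a, b in zip(bounds, bounds[1:]) if b > a
        )


def load_enzymes() -> dict[str, tuple[str, int]]:
    """Bundled restriction enzymes: name -> (recognition site, cut offset)."""
    text = resources.files("paralogsift.data").joinpath("enzymes.json").read_text()
    return {name: (e["site"], e["cut_offset"]) for name, e in json.loads(text).items()}


def _matches(primer: str, window: str, three_prime_exact: int, max_mismatch: int) -> int | None:
    """Mismatch count of a primer against an equal-length template window,
    or None if the 3' anchor or the mismatch budget is violated."""
    n = len(primer)
    mism = 0
    for i, (p, t) in enumerate(zip(primer, window)):
        if t in expand_iupac(p):
            continue
        if i >= n - three_prime_exact:
            return None
        mism += 1
        if mism > max_mismatch:
            return None
    return mism


def find_primer_sites(
    template: str,
    primer: PrimerRecord | str,
    max_mismatch: int = 0,
    three_prime_exact: int = DEFAULT_THREE_PRIME_EXACT,
) -> list[PrimerSite]:
    """Scan both template strands for primer annealing sites.

    Degenerate primer bases match any template base in their IUPAC set
    (templates are concrete ACGT).  Site positions are the 5'-most template
    coordinate (the leftmost base of the footprint, 1-based) regardless of
    strand.  The final ``three_prime_exact`` primer bases must match exactly.
    """
    seq = primer.sequence if isinstance(primer, PrimerRecord) else primer.upper()
    template = template.upper()
    n, m = len(template), len(seq)
    if m >= n:
        raise ValueError("primer must be shorter than template")
    rc = str(Seq(seq).reverse_complement())
    sites: list[PrimerSite] = []
    for i in range(n - m + 1):
        window = template[i : i + m]
        mism = _matches(seq, window, three_prime_exact, max_mismatch)
        if mism is not None:
            sites.append(PrimerSite(i + 1, "+", mism))
        # minus-strand annealing: the primer's reverse complement lies on the
        # top strand; its 3' anchor maps to the *left* end of the footprint.
        mism = _matches(rc[::-1], window[::-1], three_prime_exact, max_mismatch)
        if mism is not None:
            sites.append(PrimerSite(i + 1, "-", mism))
    return sites


def in_silico_pcr(
    template: str,
    fwd: PrimerRecord | str,
    rev: PrimerRecord | str,
    size_range: tuple[int, int] | None = None,
    template_id: str = "template",
    max_mismatch: int = 0,
    three_prime_exact: int = DEFAULT_THREE_PRIME_EXACT,
) -> list[AmpliconPrediction]:
    """Predict PCR products: every plus-strand forward site paired with
    every downstream minus-strand reverse site, optionally size-filtered.

    The amplicon spans the forward primer's 5' end through the reverse
    primer's 5' end, inclusive.
    """
    template = template.upper()
    fwd_sites = [s for s in find_primer_sites(template, fwd, max_mismatch, three_prime_exact) if s.strand == "+"]
    rev_sites = [s for s in find_primer_sites(template, rev, max_mismatch, three_prime_exact) if s.strand == "-"]
    rev_len = len(rev.sequence if isinstance(rev, PrimerRecord) else rev)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r.position + rev_len - 1  # reverse primer's 5' end
            if end <= f.position:
                continue
            length = end - f.position + 1
            if size_range and not size_range[0] <= length <= size_range[1]:
                continue
            products.append(
                AmpliconPrediction(
                    template_id=template_id,
                    start=f.position,
                    end=end,
                    sequence=template[f.position - 1 : end],
                )
            )
    products.sort(key=lambda p: (p.start, p.end))
    return products


def check_copy_specificity(
    primer: PrimerRecord | str,
    copy_alignment: MultipleAlignment,
    target: str,
    min_unique: int = 3,
) -> tuple[int, bool, list[int]]:
    """Count target-unique bases under a primer's footprint in a copy alignment.

    The primer is located on the degapped target row (either strand, exact
    IUPAC match); its footprint is mapped back to alignment columns.  A
    column counts as unique when the target base differs from EVERY other
    copy's character at that column.  The assay passes with >= ``min_unique``
    unique bases (default 3), the anchoring rule for copy-specific primers.

    Returns ``(unique_base_count, passed, alignment_columns)``.
    """
    if target not in copy_alignment.rows:
        raise ValueError(f"target {target!r} not in alignment")
    row = copy_alignment.rows[target]
    degapped = row.replace("-", "")
    sites = find_primer_sites(degapped, primer, max_mismatch=0, three_prime_exact=0)
    if not sites:
        raise ValueError("primer site not found on target copy")
    site = sites[0]
    m = len(primer.sequence if isinstance(primer, PrimerRecord) else primer)
    # map degapped target positions -> alignment columns (1-based)
    col_of: list[int] = [i + 1 for i, ch in enumerate(row) if ch != "-"]
    footprint = [col_of[p - 1] for p in range(site.position, site.position + m)]
    unique_cols = []
    for col in footprint:
        bases = copy_alignment.column(col)
        t = bases[target]
        if all(b != t for cid, b in bases.items() if cid != target):
            unique_cols.append(col)
    return len(unique_cols), len(unique_cols) >= min_unique, unique_cols


def digest(template: str, enzyme: str | tuple[str, int]) -> DigestResult:
    """Cut a linear template at every top-strand recognition-site occurrence.

    ``enzyme`` is a name from the bundled table or an explicit
    ``(recognition, cut_offset)`` pair; the cut falls after ``cut_offset``
    bases of the site.  Only palindromic recognition sequences are bundled,
    so top-strand scanning finds every site.
    """
    template = template.upper()
    if isinstance(enzyme, str):
        table = load_enzymes()
        if enzyme not in table:
            raise KeyError(f"unknown enzyme {enzyme!r}; bundled: {sorted(table)}")
        site, offset = table[enzyme]
        name = enzyme
    else:
        site, offset = enzyme
        site = site.upper()
        name = site
    if set(site) - set("ACGT"):
        raise ValueError("degenerate recognition sequences are not supported")
    if not 0 < offset <= len(site):
        raise ValueError("cut_offset must be within the recognition site")
    starts = []
    pos = template.find(site)
    while pos != -1:
        starts.append(pos + 1)
        pos = template.find(site, pos + 1)
    return DigestResult(
        enzyme=name,
        recognition=site,
        cut_offset=offset,
        site_starts=starts,
        template_length=len(template),
    )


def digest_discrimination(
    fingerprints: Mapping[str, DigestResult | Sequence[int]],
    gel_resolution: float = DEFAULT_GEL_RESOLUTION,
) -> dict[tuple[str, str], bool]:
    """Decide per pair whether two digest fingerprints separate on a gel.

    Two fragment sets are discriminable iff at least one fragment of either
    has no counterpart in the other within ``gel_resolution`` relative
    length (|a-b| <= resolution * a counts as co-migrating).
    """
    if len(fingerprints) < 2:
        raise ValueError("need at least two fingerprints")
    frag = {
        cid: sorted(fp.fragment_lengths if isinstance(fp, DigestResult) else fp)
        for cid, fp in fingerprints.items()
    }

    def co_migrates(a: int, others: Sequence[int]) -> bool:
        return any(abs(a - b) <= gel_resolution * a for b in others)

    out = {}
    for x, y in itertools.combinations(frag, 2):
        distinct = any(not co_migrates(a, frag[y]) for a in frag[x]) or any(
            not co_migrates(b, frag[x]) for b in frag[y]
        )
        out[(x, y)] = distinct
    return out
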