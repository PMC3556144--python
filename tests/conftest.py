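import pytest

from paralogsift.alignment_signature import SignatureScheme
from paralogsift.locus_mapping import HitRecord
from paralogsift.synthetic_data import simulate_paralog_family

# The nine published hit intervals on the chromosome-12 contig (subject
# start, end, % identity, e-value): three exon-sized hits per gene copy.
STUDY_HITS = [
    (2788223, 2788256, 100.0, 2e-10),
    (2788555, 2788748, 99.0, 2e-95),
    (2790815, 2790869, 96.0, 9e-19),
    (2810573, 2810606, 100.0, 2e-10),
    (2810905, 2811098, 99.0, 4e-97),
    (2813166, 2813220, 98.0, 2e-20),
    (3296852, 3296906, 98.0, 2e-20),
    (3298978, 3299171, 97.0, 8e-89),
    (3299470, 3299503, 94.0, 4e-07),
]


@pytest.fixture
def study_hits() -> list[HitRecord]:
    return [
        HitRecord(
            query_id="SCGB1A1_mRNA",
            subject_id="chr12_contig",
            subject_start=s,
            subject_end=e,
            percent_identity=pid,
            e_value=ev,
            strand="+",
        )
        for s, e, pid, ev in STUDY_HITS
    ]


@pytest.fixture
def study_scheme() -> SignatureScheme:
    """The three-copy diagnostic signature at cDNA positions 150/175/217:
    pseudogene candidate C/A--G--A, SCGB1A1 A--A--A, SCGB1A1A A--G--G."""
    return SignatureScheme(
        columns=[150, 175, 217],
        genomic_columns=[2217, 2242, 2284],
        alleles={
            "SCGB1A1P": (frozenset("CA"), frozenset("G"), frozenset("A")),
            "SCGB1A1": (frozenset("A"), frozenset("A"), frozenset("A")),
            "SCGB1A1A": (frozenset("A"), frozenset("G"), frozenset("G")),
        },
    )


@pytest.fixture(scope="session")
def family():
    return simulate_paralog_family(seed=1)


def read_with_signature(alleles: str, columns=(150, 175, 217), length=300) -> str:
    """A synthetic cDNA-coordinate read carrying given bases at the
    signature columns and 'A' elsewhere."""
    read = ["A"] * length
    for col, base in zip(columns, alleles):
        read[col - 1] = base
    return "".join(read)
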