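import itertools

import pytest

from pedvar.genes import GeneModel
from pedvar.reference import WindowReference, revcomp
from pedvar.simulate import SimConfig, simulate_cohort
from pedvar import studycase

# toy transcript: 6 residues + stop spread over three exons
TOY_CDS = "ATGGATTACAAAGATGACTAA"  # M D Y K D D *
_SEG_LENS = (9, 6, 6)
_INTRONS = (7, 5)
_FLANK = 10


def make_toy_gene(strand: str) -> tuple[GeneModel, WindowReference]:
    """A 3-exon toy gene whose CDS is TOY_CDS on the chosen strand.

    The same genomic segment layout is used for both strands, so the
    forward/reverse pair shares coordinates and differs only in sequence
    content and orientation.
    """
    gen_lens = _SEG_LENS if strand == "+" else _SEG_LENS[::-1]
    exons = []
    cur = _FLANK + 1
    for i, ln in enumerate(gen_lens):
        exons.append((cur, cur + ln - 1))
        cur += ln + (_INTRONS[i] if i < len(_INTRONS) else 0)
    total = exons[-1][1] + _FLANK
    background = list(itertools.islice(itertools.cycle("TGCA"), total))
    chunks = []
    off = 0
    for ln in _SEG_LENS:
        chunks.append(TOY_CDS[off : off + ln])
        off += ln
    if strand == "-":
        # transcript order is genomically descending: first chunk goes to
        # the genomically last exon, reverse-complemented
        targets = list(zip(exons[::-1], chunks))
    else:
        targets = list(zip(exons, chunks))
    for (s, e), chunk in targets:
        piece = chunk if strand == "+" else revcomp(chunk)
        background[s - 1 : e] = list(piece)
    model = GeneModel(
        gene_id="toy",
        transcript_id="toy-t1",
        chrom="t",
        strand=strand,
        exons=exons,
        cds_segments=exons,
    )
    return model, WindowReference("t", "".join(background), offset=0)


@pytest.fixture(scope="session")
def toy_forward():
    return make_toy_gene("+")


@pytest.fixture(scope="session")
def toy_reverse():
    return make_toy_gene("-")


@pytest.fixture(scope="session")
def study_gene():
    return studycase.synthetic_study_gene()


@pytest.fixture(scope="session")
def study_ped():
    return studycase.study_pedigree()


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SimConfig(seed=11))
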