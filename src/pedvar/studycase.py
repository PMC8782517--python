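"""The packaged study cohort: pedigree, candidate variants and a SYNTHETIC
stand-in for the canine *HACE1* gene model.

What is real here, taken from the published study of cerebellar ataxia in
the Norwegian elkhound black: the pedigree structure (five litters, 18
offspring of which 8 affected, 10 parent roles, with the dam of litter 5
being an unaffected offspring of litter 1), the sequencing design (both
parents, one affected puppy and one healthy littermate from litters 1-3
plus three saluki controls), the four candidate variant sites on CFA12 with
their forward-strand alleles, the gene span (12:62,227,078-62,337,183,
reverse strand), the exon count (24) and the protein length (877 residues).

What is SYNTHETIC: the exon coordinates, the reference sequence and hence
the exact coding sequence.  The public transcript annotation is not bundled
with this package, so :func:`synthetic_study_gene` engineers a reverse-strand
24-exon gene at the real genomic span whose coding sequence reproduces the
reported molecular arithmetic exactly: the 1-bp deletion at 62,282,766
(AC>A) hits codon 333 in exon 11, shifts the frame, and runs into a
premature stop in exon 12 that truncates the 877-residue protein to 366
residues; the nearby SNV at 62,282,727 is the synonymous AAC>AAT change in
the same exon.  The two remaining candidate sites fall in non-coding gene
sequence (the 3' UTR in this synthetic geometry).
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .consequence import DomainAnnotation
from .genes import GeneModel, CodingMap
from .pedigree import (
    Affection,
    Pedigree,
    RoleAssignment,
    assign_roles,
    read_ped,
    read_roles_tsv,
)
from .reference import WindowReference
from .variants import Genotype, VariantRecord

CHROM = "12"
GENE_START = 62_227_078
GENE_END = 62_337_183
WINDOW_OFFSET = 62_220_000
WINDOW_LENGTH = 120_000

#: forward-strand VCF representations of the four candidate sites
DELETION_SITE = (62_282_766, "AC", "A")
SYNONYMOUS_SITE = (62_282_727, "G", "A")
NONCODING_SITES = ((62_229_840, "G", "A"), (62_230_974, "A", "T"))

_N_CODONS = 877  # translated residues; the stop codon is codon 878
_TARGET_CODON = 333
_DEL_CDS_POS = 998  # CDS position of the deleted coding base (codon 333, base 2)
_DEL_GENOMIC = 62_282_767  # forward-strand position of the deleted base
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP = [
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_SEED = 424243  # fixed: the fixture is one deterministic object, not a simulation


def study_pedigree() -> Pedigree:
    """The study pedigree (27 individuals: 9 founder parents, 18 offspring)."""
    with resources.as_file(
        resources.files("pedvar.data") / "study_pedigree.ped"
    ) as p:
        return read_ped(p)


def study_roles() -> tuple[list[str], list[str]]:
    """(sequenced_ids, control_ids) of the whole-genome sequencing design."""
    with resources.as_file(resources.files("pedvar.data") / "study_roles.tsv") as p:
        return read_roles_tsv(p)


def study_role_assignment(pedigree: Pedigree | None = None) -> RoleAssignment:
    sequenced, controls = study_roles()
    return assign_roles(pedigree or study_pedigree(), sequenced, controls)


def _exon_layout() -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Exon and CDS segments (genomically ascending) of the synthetic gene.

    Transcript-order CDS chunk lengths are chosen so that CDS position 998
    (codon 333, base 2) sits in exon 11 at forward position 62,282,767, the
    synonymous site 40 bp downstream (genomically) is also in exon 11, the
    frameshift-induced stop lands in exon 12, and the 3' UTR of exon 24
    covers both non-coding candidate sites.
    """
    chunks = (
        [60] + [100] * 8 + [119]      # exons 1-10   (CDS 1-979)
        + [81]                        # exon 11      (CDS 980-1060)
        + [110]                       # exon 12      (CDS 1061-1170)
        + [100] * 11                  # exons 13-23  (CDS 1171-2270)
        + [364]                       # exon 24      (CDS 2271-2634)
    )
    assert sum(chunks) == 3 * (_N_CODONS + 1)
    utr5, utr3 = 200, 3900

    # exon 11 is anchored by the deleted base: CDS 980 maps to the genomic
    # top of the exon on this reverse-strand gene
    e11_top = _DEL_GENOMIC + (_DEL_CDS_POS - 980)
    e11_bot = e11_top - chunks[10] + 1
    tops = {11: e11_top}
    bots = {11: e11_bot}

    # exons 10..1 walk genomically upward to end exactly at GENE_END
    up_exonic = [chunks[i] for i in range(9, -1, -1)]
    up_exonic[-1] += utr5  # exon 1 carries the 5' UTR at its genomic top
    up_intron_total = (GENE_END - e11_top) - sum(up_exonic)
    q, r = divmod(up_intron_total, 10)
    up_introns = [q + 1] * r + [q] * (10 - r)
    cur = e11_top
    for j, k in enumerate(range(10, 0, -1)):
        bot = cur + up_introns[j] + 1
        top = bot + up_exonic[j] - 1
        bots[k], tops[k] = bot, top
        cur = top
    assert tops[1] == GENE_END

    # exons 12..24 walk genomically downward to end exactly at GENE_START
    down_exonic = chunks[11:]
    down_exonic[-1] += utr3  # exon 24 carries the 3' UTR at its genomic bottom
    down_intron_total = (e11_bot - GENE_START) - sum(down_exonic)
    q, r = divmod(down_intron_total, 13)
    down_introns = [q + 1] * r + [q] * (13 - r)
    cur = e11_bot
    for j, k in enumerate(range(12, 25)):
        top = cur - down_introns[j] - 1
        bot = top - down_exonic[j] + 1
        bots[k], tops[k] = bot, top
        cur = bot
    assert bots[24] == GENE_START

    exons = sorted((bots[k], tops[k]) for k in range(1, 25))
    cds = []
    for k in range(1, 25):
        if k == 1:
            cds.append((bots[1], tops[1] - utr5))
        elif k == 24:
            cds.append((bots[24] + utr3, tops[24]))
        else:
            cds.append((bots[k], tops[k]))
    return exons, sorted(cds)


def _design_cds(rng: np.random.Generator) -> str:
    """Engineer the 2634-bp coding sequence (877 codons + stop).

    Constraints: ATG start, TAA stop, internally stop-free in frame; codon
    333 is x-G-T with x != G (so the forward-strand VCF record AC>A at
    62,282,766 is already normalized and unambiguous); codon 346 is AAC
    (third base at the synonymous site); after deleting CDS base 998 the
    shifted frame is stop-free through mutant codon 366 and terminates at
    mutant codon 367 (TAA), whose first base lies in exon 12.
    """
    L = [str(rng.choice(_NONSTOP)) for _ in range(_N_CODONS)]
    L[0] = "ATG"
    L[332] = str(rng.choice(["A", "C", "T"])) + "GT"    # codon 333
    L[345] = "AAC"                                       # codon 346
    L[366] = str(rng.choice(list("ACGT"))) + "TA"        # codon 367: ?TA
    L[367] = "A" + str(rng.choice(_NONSTOP))[:2]         # codon 368: A??
    # after deleting CDS 998, mutant codon m (m>=334) reads the last two
    # bases of codon m and the first base of codon m+1
    for _ in range(10_000):
        clean = True
        for m in range(334, 367):
            mc = L[m - 1][1:] + L[m][0]
            if mc in _STOPS:
                clean = False
                if m == 345:  # L[345] is the fixed AAC codon; vary its left
                    L[m - 1] = str(rng.choice(_NONSTOP))
                elif m == 366:
                    L[m] = str(rng.choice(list("CT"))) + "TA"
                else:
                    L[m] = str(rng.choice(_NONSTOP))
        if clean:
            break
    else:  # pragma: no cover - rejection loop converges in a few passes
        raise RuntimeError("could not satisfy shifted-frame constraints")
    cds = "".join(L) + "TAA"
    assert len(cds) == 3 * (_N_CODONS + 1)
    return cds


def synthetic_study_gene() -> tuple[GeneModel, WindowReference]:
    """Deterministically build the synthetic study gene and its reference window."""
    exons, cds_segments = _exon_layout()
    model = GeneModel(
        gene_id="HACE1",
        transcript_id="HACE1-tx1",
        chrom=CHROM,
        strand="-",
        exons=exons,
        cds_segments=cds_segments,
        gene_start=GENE_START,
        gene_end=GENE_END,
    )
    rng = np.random.default_rng(_SEED)
    seq = list("".join(rng.choice(np.array(list("ACGT")), size=WINDOW_LENGTH)))
    cds = _design_cds(rng)
    cmap = CodingMap(model)
    assert len(cmap) == len(cds)
    for cds_pos in range(1, len(cds) + 1):
        g = cmap.genomic_pos(cds_pos)
        seq[g - WINDOW_OFFSET - 1] = _COMP[cds[cds_pos - 1]]
    for pos, ref, _alt in NONCODING_SITES:
        seq[pos - WINDOW_OFFSET - 1] = ref
    reference = WindowReference(CHROM, "".join(seq), offset=WINDOW_OFFSET)
    return model, reference


_HOM_REF = Genotype((0, 0))
_HET = Genotype((0, 1))
_HOM_ALT = Genotype((1, 1))


def _wgs_genotypes() -> dict[str, Genotype]:
    """Causal-pattern genotypes of the 15 whole-genome-sequenced samples."""
    ped = study_pedigree()
    roles = study_role_assignment(ped)
    from .pedigree import Role

    gts: dict[str, Genotype] = {}
    for s in roles.constrained_samples():
        role = roles[s]
        gts[s] = {
            Role.OBLIGATE_CARRIER_PARENT: _HET,
            Role.AFFECTED_CASE: _HOM_ALT,
            Role.UNAFFECTED_SIBLING: _HET,
            Role.UNRELATED_CONTROL: _HOM_REF,
        }[role]
    return gts


def study_variant_records() -> list[VariantRecord]:
    """The four candidate sites with causal-pattern genotypes, sorted by position.

    All four sit on the same private haplotype, so every sample carries the
    same genotype at each site.
    """
    gts = _wgs_genotypes()
    sites = sorted([DELETION_SITE, SYNONYMOUS_SITE, *NONCODING_SITES])
    return [
        VariantRecord(chrom=CHROM, pos=p, ref=r, alts=(a,), genotypes=dict(gts))
        for p, r, a in sites
    ]


def study_cohort_genotypes() -> dict[str, Genotype]:
    """Causal-site genotypes of every pedigree member plus the controls,
    derived from the recessive model: affected dogs are homozygous for the
    deletion, parents of affected dogs are carriers, all other relatives and
    the controls are homozygous reference."""
    ped = study_pedigree()
    _, controls = study_roles()
    carrier_ids = {i.id for i in ped.parents_of_affected()}
    gts: dict[str, Genotype] = {}
    for ind in ped:
        if ind.affection is Affection.AFFECTED:
            gts[ind.id] = _HOM_ALT
        elif ind.id in carrier_ids:
            gts[ind.id] = _HET
        else:
            gts[ind.id] = _HOM_REF
    for c in controls:
        gts[c] = _HOM_REF
    return gts


def study_domains() -> DomainAnnotation:
    """Synthetic approximation of the protein's domain architecture: six
    N-terminal ankyrin repeats and the catalytic C-terminal HECT domain.
    Boundaries are round numbers consistent with the 877-residue protein,
    not curated database coordinates."""
    return DomainAnnotation(
        protein_id="HACE1-tx1",
        domains=[("ankyrin_repeats", 64, 264), ("HECT", 574, 877)],
    )
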