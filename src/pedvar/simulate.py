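"""Synthetic cohort generation for end-to-end pipeline testing.

The generator emulates the sequencing design of a small recessive-disease
mapping study: a handful of nuclear families (two parents, one affected and
one unaffected offspring each) plus unrelated controls, genotyped at one
planted causal variant inside a multi-exon gene, a private block of variants
fully linked to the causal haplotype, and unlinked background variants at a
configurable allele frequency.  Everything is driven by a single seed;
identical configurations produce byte-identical output bundles.

Simulation operates at the genotype level — read alignment and variant
calling are upstream of this tool, which consumes genotype calls.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .genes import GeneModel, CodingMap, build_cds, write_gff3
from .pedigree import (
    Affection,
    Individual,
    Pedigree,
    Sex,
    assign_roles,
    read_ped,
    write_ped,
)
from .reference import WindowReference, write_fasta
from .variants import Genotype, VariantRecord, read_vcf, write_vcf

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

HOM_REF = Genotype((0, 0))
HET = Genotype((0, 1))
HOM_ALT = Genotype((1, 1))


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the sequencing design the filter is built for: three
    families of two parents plus one affected and one unaffected offspring,
    and three unrelated controls (15 samples), a 24-exon reverse-strand gene
    encoding an 877-residue protein, and a 1-bp coding deletion planted at
    codon 333 with three fully linked private variants nearby.
    """

    seed: int = 0
    n_families: int = 3
    n_controls: int = 3
    chrom: str = "1"
    ref_length: int = 100_000
    n_exons: int = 24
    gene_strand: str = "-"
    cds_codons: int = 877
    utr5: int = 150
    utr3: int = 200
    causal_edit: str = "deletion"  # or "snv_stop"
    target_codon: int = 333
    n_background: int = 80
    background_af: float = 0.2
    n_linked: int = 3
    linked_max_span: int = 50_000
    genotype_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.background_af < 1):
            raise ValueError("background_af must be in (0, 1)")
        if not (0 <= self.genotype_error_rate < 1):
            raise ValueError("genotype_error_rate must be in [0, 1)")
        if self.target_codon > self.cds_codons:
            raise ValueError("target_codon beyond the coding sequence")


@dataclass
class SimulatedCohort:
    """In-memory result of a full cohort simulation."""

    config: SimConfig
    reference: WindowReference
    gene: GeneModel
    pedigree: Pedigree
    sequenced_ids: list[str]
    control_ids: list[str]
    records: list[VariantRecord]  # sorted by position, possibly with errors
    truth: dict  # causal site, linked block, true genotypes

    @property
    def samples(self) -> list[str]:
        return self.sequenced_ids + self.control_ids

    @property
    def roles(self):
        return assign_roles(self.pedigree, self.sequenced_ids, self.control_ids)


@dataclass
class CohortBundle:
    """Paths of an emitted cohort plus its truth record."""

    fasta: Path
    gff3: Path
    ped: Path
    roles_tsv: Path
    vcf: Path
    truth_json: Path
    truth: dict


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random internal-stop-free codons + one stop codon."""
    body = [str(rng.choice(_NONSTOP_CODONS)) for _ in range(n_codons - 1)]
    stop = str(rng.choice(_STOPS))
    return "ATG" + "".join(body) + stop


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def simulate_reference_and_gene(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[WindowReference, GeneModel]:
    """Simulate a reference window containing one multi-exon gene.

    The gene has ``config.n_exons`` exons on ``config.gene_strand`` and a
    CDS of ``3 * (cds_codons + 1)`` bases (coding codons plus stop) that
    begins with ATG, ends with a stop codon and is internally stop-free.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_exons
    cds_len = 3 * (config.cds_codons + 1)
    base, rem = divmod(cds_len, n)
    chunks = [base + (1 if i < rem else 0) for i in range(n)]  # transcript order
    if min(chunks) < 10:
        raise ValueError("infeasible geometry: exons too short for the CDS")
    introns = rng.integers(200, 2001, size=n - 1).tolist()  # transcript order
    exon_lens_tx = list(chunks)
    exon_lens_tx[0] += config.utr5
    exon_lens_tx[-1] += config.utr3
    gene_len = sum(exon_lens_tx) + sum(introns)
    margin = 5_000
    if gene_len + 2 * margin > config.ref_length:
        raise ValueError(
            f"infeasible geometry: gene ({gene_len} bp) plus flanks exceeds "
            f"ref_length {config.ref_length}"
        )
    gene_start = int(rng.integers(margin, config.ref_length - gene_len - margin))

    # genomic order: transcript order for '+', reversed for '-'
    lens_gen = exon_lens_tx if config.gene_strand == "+" else exon_lens_tx[::-1]
    intr_gen = introns if config.gene_strand == "+" else introns[::-1]
    exons: list[tuple[int, int]] = []
    cur = gene_start
    for i, length in enumerate(lens_gen):
        exons.append((cur, cur + length - 1))
        if i < len(intr_gen):
            cur += length + intr_gen[i]

    # carve CDS segments out of the exons: UTRs sit at the transcript ends
    # trim the UTRs off the transcript-terminal exons (a single-exon gene
    # carries both): 5' UTR sits at the genomic start for '+', at the
    # genomic end for '-', and vice versa for the 3' UTR
    first_idx = 0 if config.gene_strand == "+" else len(exons) - 1
    last_idx = len(exons) - 1 if config.gene_strand == "+" else 0
    cds_segments = []
    for i, (s, e) in enumerate(exons):
        if i == first_idx:
            if config.gene_strand == "+":
                s += config.utr5
            else:
                e -= config.utr5
        if i == last_idx:
            if config.gene_strand == "+":
                e -= config.utr3
            else:
                s += config.utr3
        cds_segments.append((s, e))

    model = GeneModel(
        gene_id="simgene",
        transcript_id="simgene-t1",
        chrom=config.chrom,
        strand=config.gene_strand,
        exons=exons,
        cds_segments=cds_segments,
    )
    seq = list(_random_sequence(rng, config.ref_length))
    cds = _random_cds(rng, config.cds_codons)
    # keep the causal target codon non-homopolymeric so a 1-bp deletion in it
    # always has a normalized placement inside the codon (left-alignment
    # cannot slide the whole edit across the codon boundary)
    t = config.target_codon
    if 1 < t <= config.cds_codons:
        codon = cds[3 * t - 3 : 3 * t]
        if len(set(codon)) == 1:
            choices = [c for c in _NONSTOP_CODONS if len(set(c)) > 1]
            cds = cds[: 3 * t - 3] + str(rng.choice(choices)) + cds[3 * t :]
    cmap = CodingMap(model)
    assert len(cmap) == len(cds)
    for cds_pos in range(1, len(cds) + 1):
        g = cmap.genomic_pos(cds_pos)
        b = cds[cds_pos - 1]
        seq[g - 1] = b if config.gene_strand == "+" else _COMP[b]
    reference = WindowReference(config.chrom, "".join(seq), offset=0)
    return reference, model


def plant_causal_variant(
    model: GeneModel,
    reference: WindowReference,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> VariantRecord:
    """Plant the causal edit inside the target codon.

    For ``deletion`` a 1-bp coding deletion is chosen among the codon's
    bases such that the VCF representation (anchor base included) stays
    within the CDS and its normalized projection still lands in the target
    codon; for ``snv_stop`` a substitution converting the codon to a stop is
    used.  The returned record carries no genotypes.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    from .consequence import project_variant  # local import to avoid a cycle
    from .variants import normalize_variant

    cds, cmap = build_cds(model, reference)
    t = config.target_codon
    if config.causal_edit == "snv_stop":
        # not every codon is one substitution away from a stop; re-site to
        # the nearest convertible codon (the target itself is tried first)
        n_codons = len(cds) // 3 - 1
        for delta in range(n_codons):
            for t_try in dict.fromkeys((t + delta, t - delta)):
                if not (1 < t_try <= n_codons):
                    continue
                codon = cds[3 * t_try - 3 : 3 * t_try]
                for stop in _STOPS:
                    diff = [i for i in range(3) if codon[i] != stop[i]]
                    if len(diff) != 1:
                        continue
                    cds_pos = 3 * t_try - 2 + diff[0]
                    g = cmap.genomic_pos(cds_pos)
                    ref_b = reference.fetch(model.chrom, g, g)
                    alt_b = (
                        stop[diff[0]]
                        if model.strand == "+"
                        else _COMP[stop[diff[0]]]
                    )
                    return VariantRecord(
                        chrom=model.chrom, pos=g, ref=ref_b, alts=(alt_b,)
                    )
        raise ValueError("no codon can be converted to a stop by one substitution")

    offsets = list(rng.permutation(3))
    for off in offsets:
        cds_pos = 3 * t - 2 + int(off)
        g = cmap.genomic_pos(cds_pos)
        if cmap.cds_pos(model.chrom, g - 1) is None:
            continue  # anchor base would fall outside the CDS
        anchor = reference.fetch(model.chrom, g - 1, g - 1)
        deleted = reference.fetch(model.chrom, g, g)
        rec = VariantRecord(
            chrom=model.chrom, pos=g - 1, ref=anchor + deleted, alts=(anchor,)
        )
        norm = normalize_variant(rec, reference)
        proj = project_variant(norm, cmap)
        if proj.region == "cds" and proj.codon_index == t:
            return norm
    raise ValueError(
        f"no 1-bp deletion in codon {t} has a CDS-internal normalized placement"
    )


def draw_offspring(
    rng: np.random.Generator, sire: Genotype, dam: Genotype
) -> Genotype:
    """Mendelian gene drop: one uniformly chosen allele from each parent."""
    a = sire.alleles[int(rng.integers(2))]
    b = dam.alleles[int(rng.integers(2))]
    return Genotype((a, b))


def simulate_pedigree(config: SimConfig) -> tuple[Pedigree, list[str], list[str]]:
    """Build the cohort pedigree: per family two founder parents, one
    affected and one unaffected offspring; controls as singleton families."""
    ped = Pedigree()
    sequenced: list[str] = []
    for f in range(1, config.n_families + 1):
        fam = f"F{f}"
        sire, dam = f"{fam}_sire", f"{fam}_dam"
        ped.add(Individual(sire, fam, sex=Sex.MALE, affection=Affection.UNAFFECTED))
        ped.add(Individual(dam, fam, sex=Sex.FEMALE, affection=Affection.UNAFFECTED))
        ped.add(
            Individual(f"{fam}_case", fam, sire, dam, Sex.MALE, Affection.AFFECTED)
        )
        ped.add(
            Individual(f"{fam}_sib", fam, sire, dam, Sex.FEMALE, Affection.UNAFFECTED)
        )
        sequenced += [sire, dam, f"{fam}_case", f"{fam}_sib"]
    controls = []
    for c in range(1, config.n_controls + 1):
        cid = f"CTRL{c}"
        ped.add(Individual(cid, f"CF{c}", affection=Affection.UNAFFECTED))
        controls.append(cid)
    return ped, sequenced, controls


def gene_drop(
    pedigree: Pedigree,
    config: SimConfig,
    rng: np.random.Generator,
    founder_genotypes: dict[str, Genotype] | None = None,
    max_attempts: int = 10_000,
) -> dict[str, Genotype]:
    """Drop the causal alleles through each family.

    Founder parents are heterozygous (unless overridden), offspring draw one
    allele per parent, and each family is resampled until its genotypes are
    consistent with the recorded affection status under full penetrance
    (affected <=> homozygous alternate).  Controls and other founders are
    homozygous reference.
    """
    founder_genotypes = founder_genotypes or {}
    genotypes: dict[str, Genotype] = {}
    litters = pedigree.litters()
    parents_in_litters = {p for pair in litters for p in pair if p is not None}
    for ind in pedigree:
        if ind.is_founder:
            if ind.id in parents_in_litters:
                genotypes[ind.id] = founder_genotypes.get(ind.id, HET)
            else:
                genotypes[ind.id] = founder_genotypes.get(ind.id, HOM_REF)
    for (sire_id, dam_id), offspring in litters.items():
        gs, gd = genotypes[sire_id], genotypes[dam_id]
        for _ in range(max_attempts):
            draws = {o.id: draw_offspring(rng, gs, gd) for o in offspring}
            ok = all(
                (draws[o.id] == HOM_ALT) == (o.affection is Affection.AFFECTED)
                for o in offspring
            )
            if ok:
                genotypes.update(draws)
                break
        else:
            raise RuntimeError(
                f"gene drop for litter ({sire_id}, {dam_id}) found no genotype "
                f"configuration matching the affection pattern in {max_attempts} "
                "attempts (impossible founder genotypes?)"
            )
    return genotypes


def _sample_positions(
    rng: np.random.Generator,
    n: int,
    lo: int,
    hi: int,
    taken: set[int],
    max_attempts: int = 100_000,
) -> list[int]:
    out: list[int] = []
    for _ in range(max_attempts):
        if len(out) == n:
            break
        p = int(rng.integers(lo, hi + 1))
        if p not in taken:
            taken.add(p)
            out.append(p)
    if len(out) != n:
        raise RuntimeError("could not place variant positions without collision")
    return out


def _snv_at(reference: WindowReference, chrom: str, pos: int,
            rng: np.random.Generator) -> tuple[str, str]:
    ref_b = reference.fetch(chrom, pos, pos)
    alts = [b for b in "ACGT" if b != ref_b]
    return ref_b, alts[int(rng.integers(3))]


def add_background_and_block(
    cohort_genotypes: dict[str, Genotype],
    pedigree: Pedigree,
    causal: VariantRecord,
    gene: GeneModel,
    reference: WindowReference,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Assemble the full record set: causal + linked private block + background.

    Linked variants are placed within ``linked_max_span`` of the causal site
    (inside the gene span) and inherit the causal haplotype exactly, i.e.
    every sample shows the same genotype as at the causal site.  Background
    variants are unlinked: founder alleles are independent Bernoulli draws
    at ``background_af`` and offspring receive one allele per parent.
    """
    samples = list(cohort_genotypes)
    taken = set(range(causal.pos, causal.end + 1))
    records = [
        VariantRecord(
            chrom=causal.chrom,
            pos=causal.pos,
            ref=causal.ref,
            alts=causal.alts,
            genotypes=dict(cohort_genotypes),
        )
    ]
    lo = max(gene.gene_start, causal.pos - config.linked_max_span)
    hi = min(gene.gene_end, causal.pos + config.linked_max_span)
    for pos in sorted(_sample_positions(rng, config.n_linked, lo, hi, taken)):
        ref_b, alt_b = _snv_at(reference, causal.chrom, pos, rng)
        records.append(
            VariantRecord(
                chrom=causal.chrom,
                pos=pos,
                ref=ref_b,
                alts=(alt_b,),
                genotypes=dict(cohort_genotypes),
            )
        )
    litters = pedigree.litters()
    founders = [i.id for i in pedigree if i.is_founder]
    for pos in sorted(
        _sample_positions(rng, config.n_background, 1, len(reference.seq), taken)
    ):
        ref_b, alt_b = _snv_at(reference, causal.chrom, pos, rng)
        gts: dict[str, Genotype] = {}
        for fid in founders:
            alleles = tuple(int(rng.random() < config.background_af) for _ in range(2))
            gts[fid] = Genotype(alleles)  # type: ignore[arg-type]
        for (sire_id, dam_id), offspring in litters.items():
            for o in offspring:
                gts[o.id] = draw_offspring(rng, gts[sire_id], gts[dam_id])
        records.append(
            VariantRecord(
                chrom=causal.chrom, pos=pos, ref=ref_b, alts=(alt_b,),
                genotypes={s: gts[s] for s in samples},
            )
        )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


_STATES = (HOM_REF, HET, HOM_ALT)


def add_genotype_errors(
    records: list[VariantRecord],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Independently replace each genotype, with probability
    ``genotype_error_rate``, by a uniformly chosen *different* state among
    hom_ref / het / hom_alt.  Missing genotypes are left untouched.  Returns
    new records; the input (the truth) is not modified."""
    rate = config.genotype_error_rate
    out = []
    for rec in records:
        gts = {}
        for s, g in rec.genotypes.items():
            if rate > 0 and not g.is_missing and rng.random() < rate:
                others = [st for st in _STATES if st != g]
                g = others[int(rng.integers(len(others)))]
            gts[s] = g
        out.append(
            VariantRecord(
                chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alts=rec.alts,
                genotypes=gts, id=rec.id,
            )
        )
    return out


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Run the full generator: reference + gene, pedigree, causal variant,
    gene drop, linked block, background, optional genotyping error."""
    rng = np.random.default_rng(config.seed)
    reference, gene = simulate_reference_and_gene(config, rng)
    pedigree, sequenced, controls = simulate_pedigree(config)
    causal = plant_causal_variant(gene, reference, config, rng)
    genotypes = gene_drop(pedigree, config, rng)
    records = add_background_and_block(
        genotypes, pedigree, causal, gene, reference, config, rng
    )
    truth = {
        "causal": {
            "chrom": causal.chrom, "pos": causal.pos,
            "ref": causal.ref, "alt": causal.alt,
        },
        # linked variants carry the causal haplotype: identical genotype map
        "linked_positions": [
            r.pos
            for r in records
            if r.pos != causal.pos
            and all(r.genotypes[s] == genotypes[s] for s in genotypes)
        ],
        "genotypes": {s: list(g.alleles) for s, g in genotypes.items()},
    }
    observed = add_genotype_errors(records, config, rng)
    return SimulatedCohort(
        config=config,
        reference=reference,
        gene=gene,
        pedigree=pedigree,
        sequenced_ids=sequenced,
        control_ids=controls,
        records=observed,
        truth=truth,
    )


def emit_bundle(cohort: SimulatedCohort, out_dir: str | Path) -> CohortBundle:
    """Write the cohort as FASTA/GFF3/PED/roles-TSV/VCF plus a truth JSON.

    Every file parses with this package's own readers; a fixed seed yields a
    byte-identical bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    fasta = write_fasta({cfg.chrom: cohort.reference.seq}, out / "reference.fa")
    gff3 = write_gff3(
        [cohort.gene], out / "genes.gff3",
        sequence_regions={cfg.chrom: (1, len(cohort.reference.seq))},
    )
    ped = write_ped(cohort.pedigree, out / "cohort.ped")
    roles_tsv = out / "roles.tsv"
    lines = ["id\tsequenced\tcontrol"]
    for ind in cohort.pedigree:
        seq_flag = int(ind.id in cohort.sequenced_ids)
        ctl_flag = int(ind.id in cohort.control_ids)
        lines.append(f"{ind.id}\t{seq_flag}\t{ctl_flag}")
    roles_tsv.write_text("\n".join(lines) + "\n")
    vcf = write_vcf(
        cohort.records, cohort.samples, out / "cohort.vcf",
        contig_lengths={cfg.chrom: len(cohort.reference.seq)},
    )
    truth_json = out / "truth.json"
    truth = dict(cohort.truth, config=asdict(cfg))
    truth_json.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return CohortBundle(
        fasta=fasta, gff3=gff3, ped=ped, roles_tsv=roles_tsv, vcf=vcf,
        truth_json=truth_json, truth=truth,
    )
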