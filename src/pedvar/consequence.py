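"""Coding-consequence classification and protein-domain impact.

Given a gene model, a reference and a normalized biallelic variant, the
classifier rebuilds the transcript's coding sequence, applies the edit in
coding-strand orientation, translates both haplotypes with the standard
genetic code and compares them.

Conventions (chosen to match how truncating frameshifts are reported in the
clinical/veterinary genetics literature):

* the *first affected codon* of an indel is the codon containing the first
  coding base that differs between the reference and alternate alleles in
  coding-strand orientation, after normalization;
* *protein lengths* count translated residues only — the stop codon is not a
  residue, so a protein "reduced to N amino acids" has its premature stop at
  codon index N + 1;
* *novel residues* of a frameshift are the aberrant residues carboxy-terminal
  of the frameshift codon, i.e. ``mut_protein_length - first_affected_codon``
  when a premature stop is reached.  The frameshift codon itself is usually
  altered too but is reported separately as ``first_affected_codon``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .genes import CodingMap, GeneModel, build_cds
from .reference import SequenceAccessor, revcomp
from .variants import UnsupportedVariantError, VariantRecord


class ConsequenceClass(enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    STOP_GAIN = "stop_gain"
    INFRAME_INDEL = "inframe_indel"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"


_REGION_TO_CLASS = {
    "intronic": ConsequenceClass.INTRONIC,
    "intergenic": ConsequenceClass.INTERGENIC,
    "five_prime": ConsequenceClass.FIVE_PRIME,
    "three_prime": ConsequenceClass.THREE_PRIME,
}


@dataclass
class Projection:
    """Where a variant lands on a transcript."""

    region: str  # "cds", "intronic", "five_prime", "three_prime", "intergenic"
    cds_pos: int | None = None
    codon_index: int | None = None
    exon_index: int | None = None


@dataclass
class ConsequenceRecord:
    variant: VariantRecord
    transcript_id: str
    consequence_class: ConsequenceClass
    wt_protein_length: int
    mut_protein_length: int
    first_affected_codon: int | None = None
    novel_residue_count: int | None = None
    stop_codon_index: int | None = None
    stop_exon_index: int | None = None


@dataclass
class DomainAnnotation:
    protein_id: str
    domains: list[tuple[str, int, int]]  # (name, aa_start, aa_end), 1-based inclusive


def translate(coding_sequence: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    Translation stops at the first stop codon, which is not counted as a
    residue.  A trailing partial codon is ignored.
    """
    seq = coding_sequence.upper()
    seq = seq[: len(seq) - len(seq) % 3]
    if not seq:
        return ""
    protein = str(Seq(seq).translate())
    stop = protein.find("*")
    return protein if stop < 0 else protein[:stop]


def _has_stop(coding_sequence: str) -> bool:
    seq = coding_sequence.upper()
    seq = seq[: len(seq) - len(seq) % 3]
    return "*" in str(Seq(seq).translate()) if seq else False


def project_variant(record: VariantRecord, cmap: CodingMap) -> Projection:
    """Project a normalized variant onto CDS/codon coordinates.

    For indels the projected base is the first reference base that actually
    changes (the VCF anchor base is skipped).  Positions outside the CDS
    return the region tag from the gene geometry; a chromosome mismatch is
    tagged intergenic.
    """
    model = cmap.model
    if record.chrom != model.chrom:
        return Projection(region="intergenic")
    ref, alt = record.ref, record.alt
    prefix = 0
    while prefix < min(len(ref), len(alt)) and ref[prefix] == alt[prefix]:
        prefix += 1
    if prefix == len(ref):  # pure insertion: first novel base sits after the anchor
        changed = range(record.pos + prefix - 1, record.end + 1)
    else:
        changed = range(record.pos + prefix, record.end + 1)
    cds_hits = [
        cmap.cds_pos(record.chrom, p)
        for p in changed
        if cmap.cds_pos(record.chrom, p) is not None
    ]
    if not cds_hits:
        probe = record.pos + min(prefix, len(ref) - 1)
        return Projection(region=model.region_at(record.chrom, probe))
    cds_pos = min(cds_hits)  # 5'-most affected coding base
    return Projection(
        region="cds",
        cds_pos=cds_pos,
        codon_index=cmap.codon_index(cds_pos),
        exon_index=cmap.exon_of_cds(cds_pos),
    )


def _coding_edit(
    cds: str, cmap: CodingMap, record: VariantRecord
) -> tuple[int, str, str] | None:
    """Locate the edit on the coding strand.

    Returns (cds_start, coding_ref, coding_alt) with cds_start the 1-based
    CDS position of the first REF base in coding orientation, or None when
    the edit lies entirely outside the CDS.  An edit partially overlapping
    the CDS (spanning a splice/CDS junction) is unsupported.
    """
    model = cmap.model
    if record.chrom != model.chrom:
        return None
    positions = list(range(record.pos, record.end + 1))
    hits = [cmap.cds_pos(record.chrom, p) for p in positions]
    if all(h is None for h in hits):
        return None
    if any(h is None for h in hits):
        raise UnsupportedVariantError(
            f"edit at {record.chrom}:{record.pos} spans a CDS/exon junction"
        )
    if model.strand == "+":
        cds_start = hits[0]
        coding_ref, coding_alt = record.ref, record.alt
        expect_contiguous = list(range(cds_start, cds_start + len(hits)))
    else:
        cds_start = hits[-1]
        coding_ref, coding_alt = revcomp(record.ref), revcomp(record.alt)
        expect_contiguous = list(range(cds_start + len(hits) - 1, cds_start - 1, -1))
    if hits != (expect_contiguous if model.strand == "+" else
                list(range(cds_start, cds_start + len(hits)))[::-1]):
        raise UnsupportedVariantError(
            f"edit at {record.chrom}:{record.pos} maps to non-contiguous CDS positions"
        )
    if cds[cds_start - 1 : cds_start - 1 + len(coding_ref)] != coding_ref:
        raise ValueError(
            f"CDS/REF disagreement for {record.chrom}:{record.pos} "
            f"on {model.transcript_id}"
        )
    return cds_start, coding_ref, coding_alt


def apply_variant_to_cds(cds: str, cmap: CodingMap, record: VariantRecord) -> str:
    """Apply a normalized biallelic edit to a coding sequence.

    Forward-strand alleles are reverse-complemented for reverse-strand
    transcripts.  Edits entirely outside the CDS return ``cds`` unchanged;
    edits spanning a CDS junction raise :class:`UnsupportedVariantError`.
    """
    edit = _coding_edit(cds, cmap, record)
    if edit is None:
        return cds
    cds_start, coding_ref, coding_alt = edit
    i = cds_start - 1
    return cds[:i] + coding_alt + cds[i + len(coding_ref):]


def classify_consequence(
    model: GeneModel,
    reference: SequenceAccessor,
    record: VariantRecord,
) -> ConsequenceRecord:
    """Classify a normalized biallelic variant against one transcript.

    The class is decided by comparing the wild-type and mutant translations;
    an indel whose length difference is not a multiple of three inside the
    CDS is a frameshift.  For premature stops the stop codon index, the
    transcript-order exon containing the stop's first base, and (for
    frameshifts) the count of novel residues downstream of the frameshift
    codon are reported.
    """
    cds, cmap = build_cds(model, reference)
    wt_protein = translate(cds)
    wt_len = len(wt_protein)

    edit = _coding_edit(cds, cmap, record)
    if edit is None:
        proj = project_variant(record, cmap)
        return ConsequenceRecord(
            variant=record,
            transcript_id=model.transcript_id,
            consequence_class=_REGION_TO_CLASS.get(
                proj.region, ConsequenceClass.INTERGENIC
            ),
            wt_protein_length=wt_len,
            mut_protein_length=wt_len,
        )

    cds_start, coding_ref, coding_alt = edit
    mutant = cds[: cds_start - 1] + coding_alt + cds[cds_start - 1 + len(coding_ref):]
    mut_protein = translate(mutant)
    mut_len = len(mut_protein)
    delta = len(coding_alt) - len(coding_ref)

    # first coding base that differs, in coding orientation
    prefix = 0
    while (
        prefix < min(len(coding_ref), len(coding_alt))
        and coding_ref[prefix] == coding_alt[prefix]
    ):
        prefix += 1
    first_cds = cds_start + prefix
    first_codon = CodingMap.codon_index(min(first_cds, len(cds)))

    if delta % 3 != 0:
        cls = ConsequenceClass.FRAMESHIFT
    elif mut_protein == wt_protein:
        cls = ConsequenceClass.SYNONYMOUS
    elif delta != 0:
        cls = ConsequenceClass.INFRAME_INDEL
    elif mut_len < wt_len and mut_protein == wt_protein[:mut_len]:
        cls = ConsequenceClass.STOP_GAIN
    else:
        cls = ConsequenceClass.MISSENSE

    stop_codon_index = None
    stop_exon_index = None
    novel = None
    premature = cls in (ConsequenceClass.FRAMESHIFT, ConsequenceClass.STOP_GAIN)
    if premature and _has_stop(mutant):
        stop_codon_index = mut_len + 1
        # map the stop's first base back to wild-type CDS coordinates to
        # find its exon: positions past the edited block shift by -delta
        stop_start_mut = 3 * mut_len + 1
        if stop_start_mut >= cds_start + len(coding_alt):
            stop_start_wt = stop_start_mut - delta
        else:
            stop_start_wt = cds_start
        stop_start_wt = min(stop_start_wt, len(cds))
        stop_exon_index = cmap.exon_of_cds(stop_start_wt)
        if cls is ConsequenceClass.FRAMESHIFT:
            novel = max(0, mut_len - first_codon)

    return ConsequenceRecord(
        variant=record,
        transcript_id=model.transcript_id,
        consequence_class=cls,
        wt_protein_length=wt_len,
        mut_protein_length=mut_len,
        first_affected_codon=first_codon,
        novel_residue_count=novel,
        stop_codon_index=stop_codon_index,
        stop_exon_index=stop_exon_index,
    )


def domain_impact(
    consequence: ConsequenceRecord, domains: DomainAnnotation
) -> dict[str, str]:
    """Status of each protein domain after truncation.

    ``lost`` when the truncated protein ends before the domain starts,
    ``truncated_partial`` when it ends inside the domain, ``retained``
    otherwise.  Domain bounds must fit the wild-type protein.
    """
    wt = consequence.wt_protein_length
    mut = consequence.mut_protein_length
    out: dict[str, str] = {}
    for name, aa_start, aa_end in domains.domains:
        if not (1 <= aa_start <= aa_end <= wt):
            raise ValueError(
                f"domain {name!r} bounds {aa_start}-{aa_end} exceed "
                f"wild-type protein length {wt}"
            )
        if aa_start > mut:
            out[name] = "lost"
        elif mut < aa_end:
            out[name] = "truncated_partial"
        else:
            out[name] = "retained"
    return out


def read_domain_tsv(path: str | Path) -> list[DomainAnnotation]:
    """Read a protein-domain table (protein_id, name, aa_start, aa_end)."""
    df = pd.read_csv(path, sep="\t", comment=None)
    required = {"protein_id", "name", "aa_start", "aa_end"}
    if not required <= set(df.columns):
        raise ValueError(f"domain TSV must have columns {sorted(required)}")
    out = []
    for pid, grp in df.groupby("protein_id", sort=False):
        out.append(
            DomainAnnotation(
                protein_id=str(pid),
                domains=[
                    (str(r["name"]), int(r.aa_start), int(r.aa_end))
                    for _, r in grp.iterrows()
                ],
            )
        )
    return out


def write_domain_tsv(annotations: list[DomainAnnotation], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"protein_id": a.protein_id, "name": n, "aa_start": s, "aa_end": e}
        for a in annotations
        for n, s, e in a.domains
    ]
    pd.DataFrame(rows, columns=["protein_id", "name", "aa_start", "aa_end"]).to_csv(
        path, sep="\t", index=False
    )
    return path
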