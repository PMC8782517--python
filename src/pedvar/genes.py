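"""Gene models: GFF3 loading, CDS assembly and genomic<->CDS projection.

A :class:`GeneModel` stores exon and CDS segments as 1-based inclusive
genomic intervals sorted by genomic position.  Transcript-order indexing
(exon 1 = 5'-most exon on the coding strand) is used everywhere a biologist
would say "exon N": for a reverse-strand gene exon 1 is the genomically
*last* exon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gffutils

from .reference import FastaReference, SequenceAccessor, revcomp

Interval = tuple[int, int]


@dataclass
class GeneModel:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[Interval]  # sorted by genomic position
    cds_segments: list[Interval]
    gene_start: int | None = None
    gene_end: int | None = None
    flagged: bool = False  # CDS length not divisible by 3, or missing start/stop

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds_segments = sorted(self.cds_segments)
        for segs in (self.exons, self.cds_segments):
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"overlapping segments in {self.transcript_id}: "
                        f"({s1},{e1}) and ({s2},{e2})"
                    )
        if self.gene_start is None:
            self.gene_start = self.exons[0][0]
        if self.gene_end is None:
            self.gene_end = self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    def exons_transcript_order(self) -> list[Interval]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def exon_index_at(self, pos: int) -> int | None:
        """1-based transcript-order exon index containing ``pos``, else None."""
        for i, (s, e) in enumerate(self.exons_transcript_order(), 1):
            if s <= pos <= e:
                return i
        return None

    def region_at(self, chrom: str, pos: int) -> str:
        """Region tag of a genomic position relative to this transcript.

        One of ``exon <N>``, ``intronic``, ``five_prime``, ``three_prime``
        or ``intergenic``.  Exonic positions outside the CDS are classified
        as UTR (five_prime/three_prime) by their side of the CDS on the
        coding strand; positions inside the gene/transcript span but outside
        every exon are intronic; positions outside the span are upstream
        (five_prime) or downstream (three_prime) of the gene on the coding
        strand.
        """
        if chrom != self.chrom:
            return "intergenic"
        tx_start, tx_end = self.exons[0][0], self.exons[-1][1]
        lo = min(tx_start, self.gene_start or tx_start)
        hi = max(tx_end, self.gene_end or tx_end)
        exon_idx = self.exon_index_at(pos)
        if exon_idx is not None:
            if self.cds_segments:
                cds_lo, cds_hi = self.cds_segments[0][0], self.cds_segments[-1][1]
                if cds_lo <= pos <= cds_hi:
                    return f"exon {exon_idx}"
                before_cds = pos < cds_lo  # genomically 5' on the forward strand
                if (self.strand == "+") == before_cds:
                    return "five_prime"
                return "three_prime"
            return f"exon {exon_idx}"
        if lo <= pos <= hi:
            return "intronic"
        upstream = pos < lo  # genomically before the gene
        if (self.strand == "+") == upstream:
            return "five_prime"
        return "three_prime"


class CodingMap:
    """Bijective genomic<->CDS coordinate projection for one transcript.

    CDS positions are 1-based, 5'->3' on the coding strand: for a
    reverse-strand transcript CDS position 1 maps to the genomically
    greatest CDS base.
    """

    def __init__(self, model: GeneModel) -> None:
        self.model = model
        self.transcript_id = model.transcript_id
        positions: list[int] = []
        segs = model.cds_segments if model.strand == "+" else model.cds_segments[::-1]
        for s, e in segs:
            rng = range(s, e + 1) if model.strand == "+" else range(e, s - 1, -1)
            positions.extend(rng)
        self._genomic = positions  # index i -> genomic position of CDS i+1
        self._cds = {g: i + 1 for i, g in enumerate(positions)}

    def __len__(self) -> int:
        return len(self._genomic)

    def cds_pos(self, chrom: str, pos: int) -> int | None:
        if chrom != self.model.chrom:
            return None
        return self._cds.get(pos)

    def genomic_pos(self, cds_pos: int) -> int:
        return self._genomic[cds_pos - 1]

    @staticmethod
    def codon_index(cds_pos: int) -> int:
        return (cds_pos + 2) // 3

    def exon_of_cds(self, cds_pos: int) -> int:
        """Transcript-order exon index containing a CDS position."""
        idx = self.model.exon_index_at(self.genomic_pos(cds_pos))
        assert idx is not None, "CDS position outside every exon"
        return idx


def build_cds(model: GeneModel, reference: SequenceAccessor) -> tuple[str, CodingMap]:
    """Assemble the coding sequence of ``model`` on its coding strand.

    For strand '-' the result equals the reverse complement of the
    concatenated segments in ascending genomic order, i.e. the segments in
    descending order each reverse-complemented.  The sequence is expected to
    begin with ATG and end with a stop codon; deviations flag the model and
    emit a warning rather than failing.
    """
    if not model.cds_segments:
        raise ValueError(f"{model.transcript_id}: no CDS segments")
    parts = [reference.fetch(model.chrom, s, e).upper() for s, e in model.cds_segments]
    seq = "".join(parts)
    if model.strand == "-":
        seq = revcomp(seq)
    issues = []
    if len(seq) % 3 != 0:
        issues.append(f"CDS length {len(seq)} not divisible by 3")
    else:
        if not seq.startswith("ATG"):
            issues.append("CDS does not start with ATG")
        if seq[-3:] not in ("TAA", "TAG", "TGA"):
            issues.append("CDS does not end with a stop codon")
    if issues:
        model.flagged = True
        warnings.warn(f"{model.transcript_id}: " + "; ".join(issues))
    return seq, CodingMap(model)


def load_gene_models(
    gff3_path: str | Path, fasta_path: str | Path
) -> tuple[list[GeneModel], FastaReference]:
    """Load Ensembl-dialect GFF3 gene models plus an indexed FASTA accessor.

    Expects gene -> mRNA -> exon/CDS features linked by Parent attributes.
    One GeneModel is produced per mRNA.  Models whose CDS length is not a
    multiple of 3 are flagged with a warning.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [
                (f.start, f.end) for f in db.children(mrna, featuretype="exon")
            ]
            cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
            model = GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.attributes.get("ID", [mrna.id])[0],
                chrom=gene.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_segments=cds,
                gene_start=gene.start,
                gene_end=gene.end,
            )
            if cds and model.cds_length % 3 != 0:
                model.flagged = True
                warnings.warn(
                    f"{model.transcript_id}: CDS length {model.cds_length} "
                    "not divisible by 3"
                )
            models.append(model)
    return models, FastaReference(fasta_path)


def write_gff3(
    models: Sequence[GeneModel],
    path: str | Path,
    sequence_regions: dict[str, tuple[int, int]] | None = None,
) -> Path:
    """Write gene models as Ensembl-dialect GFF3 (gene/mRNA/exon/CDS)."""
    path = Path(path)
    lines = ["##gff-version 3"]
    for chrom, (start, end) in (sequence_regions or {}).items():
        lines.append(f"##sequence-region {chrom} {start} {end}")
    for m in models:
        lines.append(
            "\t".join(
                [m.chrom, "pedvar", "gene", str(m.gene_start), str(m.gene_end),
                 ".", m.strand, ".", f"ID={m.gene_id}"]
            )
        )
        tx_start, tx_end = m.exons[0][0], m.exons[-1][1]
        lines.append(
            "\t".join(
                [m.chrom, "pedvar", "mRNA", str(tx_start), str(tx_end), ".",
                 m.strand, ".", f"ID={m.transcript_id};Parent={m.gene_id}"]
            )
        )
        for i, (s, e) in enumerate(m.exons_transcript_order(), 1):
            lines.append(
                "\t".join(
                    [m.chrom, "pedvar", "exon", str(s), str(e), ".", m.strand,
                     ".", f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}"]
                )
            )
        cds_tx = m.cds_segments if m.strand == "+" else m.cds_segments[::-1]
        cum = 0
        for i, (s, e) in enumerate(cds_tx, 1):
            phase = (3 - cum % 3) % 3
            lines.append(
                "\t".join(
                    [m.chrom, "pedvar", "CDS", str(s), str(e), ".", m.strand,
                     str(phase),
                     f"ID={m.transcript_id}.cds{i};Parent={m.transcript_id}"]
                )
            )
            cum += e - s + 1
    path.write_text("\n".join(lines) + "\n")
    return path
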