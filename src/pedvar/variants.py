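"""Multi-sample VCF IO, indel normalization and HGVS-style display names.

Coordinates are 1-based inclusive throughout, matching VCF.  Genotype phase
is ignored (``|`` is treated as ``/``): the segregation model is phase-free.

The display-name convention deliberately mirrors how candidate deletions in
reverse-strand genes are commonly reported in the canine genetics literature:
the position is the 3'-most placement of the deleted base on the *forward*
strand, while the base letter itself is given on the gene's *coding* strand
(e.g. a forward-strand ``C`` deletion in a reverse-strand gene is rendered
``<pos>delG``).  This hybrid differs from strict HGVS, which shifts 3' on the
coding strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .reference import SequenceAccessor, revcomp


class VariantError(ValueError):
    """Raised for malformed or unsupported variant input."""


class UnsupportedVariantError(VariantError):
    """Raised for allele classes outside the supported small-variant set."""


MISSING_ALLELE = None


@dataclass(frozen=True)
class Genotype:
    """A diploid genotype as a pair of allele indices (0=ref, >=1 alt, None=missing)."""

    alleles: tuple[int | None, int | None]

    @classmethod
    def missing(cls) -> "Genotype":
        return cls((None, None))

    @property
    def is_missing(self) -> bool:
        return any(a is None for a in self.alleles)

    def non_missing(self) -> tuple[int, ...]:
        return tuple(a for a in self.alleles if a is not None)


@dataclass
class VariantRecord:
    """One VCF site with per-sample diploid genotypes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    id: str | None = None

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alts = tuple(a.upper() for a in self.alts)
        if self.pos < 1:
            raise VariantError(f"position must be >= 1, got {self.pos}")
        if not self.ref:
            raise VariantError("empty REF allele")
        for alt in self.alts:
            if not alt:
                raise VariantError("empty ALT allele")
            if alt == self.ref:
                raise VariantError(f"ALT equals REF at {self.chrom}:{self.pos}")

    @property
    def alt(self) -> str:
        if len(self.alts) != 1:
            raise VariantError(
                f"record at {self.chrom}:{self.pos} is not biallelic"
            )
        return self.alts[0]

    @property
    def end(self) -> int:
        """Last reference base covered by REF, 1-based inclusive."""
        return self.pos + len(self.ref) - 1

    def is_snv(self) -> bool:
        return len(self.alts) == 1 and len(self.ref) == 1 and len(self.alts[0]) == 1

    def is_symbolic(self) -> bool:
        return any(("<" in a) or ("[" in a) or ("]" in a) or ("*" in a) for a in self.alts)


@dataclass(frozen=True)
class HgvsName:
    chrom: str
    description: str
    reported_base_strand: str  # "forward" or "gene_coding"

    def __str__(self) -> str:
        return f"{self.chrom}:{self.description}"


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF 4.x file (plain or bgzipped) into records plus sample roster.

    Multiallelic sites are preserved as single records.  A missing GT FORMAT
    declaration is a hard error.
    """
    path = str(path)
    with pysam.VariantFile(path) as vcf:
        if "GT" not in vcf.header.formats:
            raise VariantError(f"{path}: VCF has no GT FORMAT field")
        samples = list(vcf.header.samples)
        records: list[VariantRecord] = []
        for i, rec in enumerate(vcf, 1):
            if rec.alts is None:
                continue  # no ALT: places no genotype pattern, skip
            try:
                genotypes = {}
                for s in samples:
                    gt = rec.samples[s].get("GT", (None, None))
                    if gt is None or len(gt) == 0:
                        gt = (None, None)
                    elif len(gt) == 1:
                        gt = (gt[0], gt[0])
                    genotypes[s] = Genotype((gt[0], gt[1]))
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alts=tuple(rec.alts),
                        genotypes=genotypes,
                        id=rec.id,
                    )
                )
            except (VariantError, TypeError) as exc:
                raise VariantError(f"{path}: record {i} ({rec.chrom}:{rec.pos}): {exc}")
    return records, samples


def write_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> Path:
    """Write records to a VCF readable by :func:`read_vcf`.

    Every record must carry a genotype for every sample in ``samples``.
    """
    path = Path(path)
    header = pysam.VariantHeader()
    header.formats.add("GT", 1, "String", "Genotype")
    contigs: dict[str, int | None] = dict(contig_lengths or {})
    for rec in records:
        contigs.setdefault(rec.chrom, None)
    for name, length in contigs.items():
        if length is None:
            length = max((r.end for r in records if r.chrom == name), default=1) + 1
        header.contigs.add(name, length=length)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            missing = set(samples) - set(rec.genotypes)
            extra = set(rec.genotypes) - set(samples)
            if missing or extra:
                raise VariantError(
                    f"sample roster mismatch at {rec.chrom}:{rec.pos}: "
                    f"missing={sorted(missing)} extra={sorted(extra)}"
                )
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, *rec.alts),
                id=rec.id,
            )
            for s in samples:
                vrec.samples[s]["GT"] = rec.genotypes[s].alleles
                vrec.samples[s].phased = False
            out.write(vrec)
    return path


def split_multiallelic(record: VariantRecord) -> list[VariantRecord]:
    """Split a multiallelic record into one biallelic record per ALT.

    In each output, allele indices are remapped so the retained ALT is 1;
    calls to any *other* ALT allele become missing, so a foreign-allele call
    never masquerades as reference.
    """
    if len(record.alts) == 1:
        return [record]
    out = []
    for k in range(1, len(record.alts) + 1):
        def remap(a: int | None, k: int = k) -> int | None:
            if a is None:
                return None
            if a == 0:
                return 0
            return 1 if a == k else None

        genotypes = {
            s: Genotype(tuple(remap(a) for a in g.alleles))  # type: ignore[arg-type]
            for s, g in record.genotypes.items()
        }
        out.append(
            VariantRecord(
                chrom=record.chrom,
                pos=record.pos,
                ref=record.ref,
                alts=(record.alts[k - 1],),
                genotypes=genotypes,
                id=record.id,
            )
        )
    return out


def _check_ref(record: VariantRecord, reference: SequenceAccessor) -> None:
    seen = reference.fetch(record.chrom, record.pos, record.end).upper()
    if seen != record.ref:
        raise VariantError(
            f"REF mismatch at {record.chrom}:{record.pos}: "
            f"record has {record.ref!r}, reference has {seen!r}"
        )


def normalize_variant(
    record: VariantRecord, reference: SequenceAccessor
) -> VariantRecord:
    """Left-align and trim a biallelic record to its minimal representation.

    Implements the standard parsimony/left-alignment algorithm: shared
    trailing bases are trimmed (extending left into the reference when an
    allele would empty), then shared leading bases beyond the single VCF
    anchor base are trimmed.  Idempotent.
    """
    _check_ref(record, reference)
    if record.is_symbolic():
        raise UnsupportedVariantError("cannot normalize symbolic alleles")
    ref, alt, pos = record.ref, record.alt, record.pos
    while True:
        if len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (
            len(ref) > 1 or len(alt) > 1
        ):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    raise VariantError(
                        f"cannot left-extend past contig start at {record.chrom}:1"
                    )
                base = reference.fetch(record.chrom, pos - 1, pos - 1).upper()
                ref, alt, pos = base + ref, base + alt, pos - 1
        elif len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt, pos = ref[1:], alt[1:], pos + 1
        else:
            break
    return replace(record, pos=pos, ref=ref, alts=(alt,))


def _shift_3prime(
    chrom: str, start: int, seq: str, reference: SequenceAccessor, limit: int = 10000
) -> tuple[int, str]:
    """Shift a deleted/inserted block 3' (rightward on the forward strand).

    ``start`` is the first affected base (deletion) or the first base after
    the insertion point.  Returns the right-most equivalent placement.
    """
    for _ in range(limit):
        try:
            nxt = reference.fetch(chrom, start + len(seq), start + len(seq)).upper()
        except (ValueError, KeyError):
            break
        if nxt != seq[0]:
            break
        seq = seq[1:] + nxt
        start += 1
    return start, seq


def to_hgvs(
    record: VariantRecord,
    reference: SequenceAccessor,
    gene_strand: str = "+",
) -> HgvsName:
    """Render a normalized biallelic record as an HGVS-style genomic name.

    Deletions are positioned at the deleted bases (anchor excluded) after
    shifting to the 3'-most placement on the forward strand; the base letters
    are reported on ``gene_strand``.  Substitutions are ``<pos><ref>><alt>``
    on the chosen strand.
    """
    if gene_strand not in "+-":
        raise ValueError(f"gene_strand must be '+' or '-', got {gene_strand!r}")
    if record.is_symbolic():
        raise UnsupportedVariantError(
            f"symbolic/SV alleles are not supported: {record.alts}"
        )
    _check_ref(record, reference)
    ref, alt, pos = record.ref, record.alt, record.pos
    on_strand = (lambda s: s) if gene_strand == "+" else revcomp

    if len(ref) == 1 and len(alt) == 1:
        return HgvsName(
            record.chrom,
            f"{pos}{on_strand(ref)}>{on_strand(alt)}",
            "forward" if gene_strand == "+" else "gene_coding",
        )
    if len(alt) < len(ref) and ref.startswith(alt):
        # deletion with leading anchor
        deleted = ref[len(alt):]
        start = pos + len(alt)
        start, deleted = _shift_3prime(record.chrom, start, deleted, reference)
        end = start + len(deleted) - 1
        span = f"{start}" if start == end else f"{start}_{end}"
        desc = f"{span}del{on_strand(deleted)}"
    elif len(ref) < len(alt) and alt.startswith(ref):
        inserted = alt[len(ref):]
        after = pos + len(ref) - 1  # insertion sits after this base
        start, inserted = _shift_3prime(record.chrom, after + 1, inserted, reference)
        after = start - 1
        desc = f"{after}_{after + 1}ins{on_strand(inserted)}"
    else:
        end = record.end
        span = f"{pos}" if pos == end else f"{pos}_{end}"
        desc = f"{span}delins{on_strand(alt)}"
    return HgvsName(
        record.chrom, desc, "forward" if gene_strand == "+" else "gene_coding"
    )
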