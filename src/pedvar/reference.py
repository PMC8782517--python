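"""Reference sequence access.

Two accessors implement the same 1-based inclusive ``fetch`` interface:
:class:`FastaReference` for an indexed FASTA on disk and
:class:`WindowReference` for an in-memory slice of a chromosome placed at an
arbitrary genomic offset.  The window form lets fixtures and simulations use
realistic multi-megabase coordinates without materialising the full
chromosome.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Protocol

import pyfaidx

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


class SequenceAccessor(Protocol):
    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence of ``chrom`` from ``start`` to ``end``, 1-based inclusive."""
        ...


class FastaReference:
    """Random access to an (indexed) FASTA file via pyfaidx."""

    def __init__(self, path: str | Path) -> None:
        self._fasta = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 1 or end < start:
            raise ValueError(f"bad range {start}-{end}")
        return str(self._fasta[chrom][start - 1 : end])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta


class WindowReference:
    """An in-memory sequence window ``chrom:offset+1..offset+len(seq)``.

    ``offset`` is the number of bases preceding the window, so the first base
    of ``seq`` sits at 1-based genomic position ``offset + 1``.
    """

    def __init__(self, chrom: str, seq: str, offset: int = 0) -> None:
        self.chrom = chrom
        self.seq = seq.upper()
        self.offset = offset

    @property
    def start(self) -> int:
        return self.offset + 1

    @property
    def end(self) -> int:
        return self.offset + len(self.seq)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom != self.chrom:
            raise KeyError(f"unknown contig {chrom!r}")
        if start < self.start or end > self.end or end < start:
            raise ValueError(
                f"range {chrom}:{start}-{end} outside window "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        return self.seq[start - self.offset - 1 : end - self.offset]

    def with_edit(self, pos: int, ref: str, alt: str) -> "WindowReference":
        """Return a copy with ``ref`` at 1-based ``pos`` replaced by ``alt``."""
        i = pos - self.offset - 1
        if self.seq[i : i + len(ref)] != ref.upper():
            raise ValueError(f"ref mismatch at {self.chrom}:{pos}")
        return WindowReference(
            self.chrom, self.seq[:i] + alt.upper() + self.seq[i + len(ref):], self.offset
        )


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> Path:
    """Write sequences to a FASTA file with fixed line width."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path
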