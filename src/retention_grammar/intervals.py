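"""Core genomic coordinate types.

All coordinates in this package are 0-based half-open (`[start, end)`),
the BED convention. File-format dialects (GTF's 1-based closed
coordinates, rmsk tables) are converted at the IO boundary and never
leak past it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located, stranded span on a chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name, verbatim from the annotation source.
    start, end : int
        0-based half-open bounds; ``start < end`` is required so every
        interval has positive length.
    strand : str
        ``"+"`` or ``"-"``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def sequence(self, genome: dict[str, str], stranded: bool = True) -> str:
        """Extract the sequence, reverse-complemented for '-' when *stranded*."""
        chrom_seq = genome[self.chrom]
        if self.end > len(chrom_seq):
            raise ValueError(
                f"interval [{self.start}, {self.end}) exceeds {self.chrom} "
                f"length {len(chrom_seq)}"
            )
        seq = chrom_seq[self.start : self.end]
        if stranded and self.strand == "-":
            seq = reverse_complement(seq)
        return seq


@dataclass
class TranscriptModel:
    """A transcript as an ordered chain of exons.

    Exons are stored sorted in transcription direction: ascending genomic
    start for '+' transcripts, descending for '-'. All exons share the
    transcript's chromosome and strand and must not overlap each other.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.strand != self.strand:
                raise ValueError(
                    f"exon {ex} of {self.transcript_id} disagrees with "
                    f"transcript chrom/strand {self.chrom}{self.strand}"
                )
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        self.exons = genomic if self.strand == "+" else genomic[::-1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[GenomicInterval]:
        """Intervals between consecutive exons, in transcription order."""
        out = []
        for up, down in zip(self.exons, self.exons[1:]):
            lo, hi = (up.end, down.start) if self.strand == "+" else (down.end, up.start)
            out.append(GenomicInterval(self.chrom, lo, hi, self.strand))
        return out

    def span(self) -> GenomicInterval:
        starts = [e.start for e in self.exons]
        ends = [e.end for e in self.exons]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)


@dataclass(frozen=True)
class RepeatElement:
    """One RepeatMasker annotation: an interval plus its three-level taxonomy.

    Class/family/subfamily strings are preserved verbatim from the source
    table; confidence filtering happens downstream.
    """

    interval: GenomicInterval
    rep_class: str
    rep_family: str
    rep_subfamily: str


@dataclass
class PWMRecord:
    """A position probability matrix for one RNA-binding protein motif.

    ``matrix`` has shape (4, k) with rows in A, C, G, T order (U inputs
    are remapped to T at parse time) and each column summing to 1.
    """

    rbp_name: str
    matrix: "object"  # numpy (4, k) float array
    k: int = 0

    def __post_init__(self) -> None:
        import numpy as np

        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError(
                f"PWM {self.rbp_name}: expected shape (4, k), got {self.matrix.shape}"
            )
        self.k = self.matrix.shape[1]
        if (self.matrix < 0).any():
            raise ValueError(f"PWM {self.rbp_name}: negative probability entry")
        colsums = self.matrix.sum(axis=0)
        bad = abs(colsums - 1.0) > 1e-3
        if bad.any():
            j = int(bad.argmax())
            raise ValueError(
                f"PWM {self.rbp_name}: column {j} sums to {colsums[j]:.6f}, not 1"
            )
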