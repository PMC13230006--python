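"""Exon-intron-exon unit cataloguing and CI/RI classification.

A transcriptome is decomposed into its atomic splicing events: triples
of (upstream exon, intron, downstream exon), deduplicated within each
gene. A unit is a retained intron (RI) when, among the gene's
transcripts, the intron is excised in some isoforms while others carry
one exon spanning the unit's outer boundaries *exactly* — the flanking
5'/3' splice sites must be identical and invariant across spliced and
retained isoforms. Units whose intron or flanking exons are touched by
any alternative splice-site usage are excluded rather than guessed at,
so the catalog contains only unambiguous splicing contexts. Units that
never show retention and never show conflicting usage are constitutive
introns (CIs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .intervals import GenomicInterval, TranscriptModel

CI = "CI"
RI = "RI"
EXCLUDED = "EXCLUDED"

# Filters: exons <= 6 nt, introns <= 26 nt, any N in the unit sequence.
MIN_EXON_LEN = 7
MIN_INTRON_LEN = 27


@dataclass
class EIEUnit:
    """One exon-intron-exon splicing event.

    ``upstream``/``downstream`` refer to transcription direction; on the
    '-' strand the upstream exon is genomically rightmost. The three
    intervals are genomically adjacent:
    ``left_exon.end == intron.start`` and ``intron.end == right_exon.start``.
    """

    upstream_exon: GenomicInterval
    intron: GenomicInterval
    downstream_exon: GenomicInterval
    strand: str
    gene_id: str
    supporting_spliced: set[str] = field(default_factory=set)
    supporting_retained: set[str] = field(default_factory=set)
    label: str | None = None
    consistent: bool = True

    def __post_init__(self) -> None:
        left, right = self.flanks_genomic()
        if left.end != self.intron.start or self.intron.end != right.start:
            raise ValueError(
                f"unit {self.unit_id()} exons are not adjacent to the intron"
            )

    def flanks_genomic(self) -> tuple[GenomicInterval, GenomicInterval]:
        """(genomically left exon, genomically right exon)."""
        if self.strand == "+":
            return self.upstream_exon, self.downstream_exon
        return self.downstream_exon, self.upstream_exon

    def span(self) -> GenomicInterval:
        left, right = self.flanks_genomic()
        return GenomicInterval(self.intron.chrom, left.start, right.end, self.strand)

    def unit_id(self) -> str:
        sp_start = min(self.upstream_exon.start, self.downstream_exon.start)
        sp_end = max(self.upstream_exon.end, self.downstream_exon.end)
        return (
            f"{self.gene_id}:{self.intron.chrom}:{sp_start}-"
            f"{self.intron.start}-{self.intron.end}-{sp_end}:{self.strand}"
        )

    def sequence(self, genome: dict[str, str]) -> str:
        """Full E-I-E sequence, 5'->3' on the transcribed strand."""
        return self.span().sequence(genome, stranded=True)


def enumerate_units(transcripts: list[TranscriptModel]) -> list[EIEUnit]:
    """Decompose transcripts into deduplicated E-I-E units per gene.

    Each consecutive exon pair of every multi-exon transcript yields one
    unit; identical triples within a gene are merged, accumulating the
    supporting (spliced) transcript ids. Single-exon transcripts
    contribute no units. Output order is deterministic: sorted by
    gene, chromosome and coordinates, independent of input order.
    """
    merged: dict[tuple, EIEUnit] = {}
    for tx in transcripts:
        for i, intron in enumerate(tx.introns()):
            up, down = tx.exons[i], tx.exons[i + 1]
            key = (tx.gene_id, tx.chrom, tx.strand, up.start, up.end,
                   intron.start, intron.end, down.start, down.end)
            if key not in merged:
                merged[key] = EIEUnit(
                    upstream_exon=up, intron=intron, downstream_exon=down,
                    strand=tx.strand, gene_id=tx.gene_id,
                )
            merged[key].supporting_spliced.add(tx.transcript_id)
    return [merged[k] for k in sorted(merged)]


def detect_retention(units: list[EIEUnit], transcripts: list[TranscriptModel]) -> list[EIEUnit]:
    """Populate retention evidence: transcripts with one exon spanning the unit.

    A transcript of the same gene supports retention iff it contains an
    exon whose interval equals the unit's outer span exactly; any
    boundary shift disqualifies it (and will typically also flag the
    unit inconsistent).
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    for unit in units:
        span = unit.span()
        for tx in by_gene.get(unit.gene_id, []):
            if tx.chrom != span.chrom or tx.strand != unit.strand:
                continue
            for ex in tx.exons:
                if ex.start == span.start and ex.end == span.end:
                    unit.supporting_retained.add(tx.transcript_id)
                    break
    return units


def check_consistency(units: list[EIEUnit], transcripts: list[TranscriptModel]) -> list[EIEUnit]:
    """Flag units touched by alternative splice-site usage.

    A unit is inconsistent when any transcript of its gene overlapping
    the unit's span places an exon boundary strictly inside the unit's
    intron (a splice site within the intron) or strictly inside either
    flanking exon (an alternative 5'/3' boundary splitting the exon).
    Retention isoforms — one exon covering the span exactly — have their
    boundaries on the span's edges and therefore never trigger this.
    Distal alternative splicing elsewhere in the gene is ignored.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    for unit in units:
        span = unit.span()
        left, right = unit.flanks_genomic()
        inconsistent = False
        for tx in by_gene.get(unit.gene_id, []):
            if tx.chrom != span.chrom:
                continue
            tx_span = tx.span()
            if not tx_span.overlaps(span):
                continue
            for ex in tx.exons:
                for boundary in (ex.start, ex.end):
                    if unit.intron.start < boundary < unit.intron.end:
                        inconsistent = True
                    for flank in (left, right):
                        if flank.start < boundary < flank.end:
                            inconsistent = True
            if inconsistent:
                break
        unit.consistent = not inconsistent
    return units


def assign_labels(units: list[EIEUnit]) -> list[EIEUnit]:
    """Assign CI/RI/EXCLUDED from consistency and retention evidence."""
    for unit in units:
        if not unit.consistent:
            unit.label = EXCLUDED
        elif unit.supporting_retained:
            unit.label = RI
        else:
            unit.label = CI
    return units


def apply_filters(units: list[EIEUnit], genome: dict[str, str]) -> list[EIEUnit]:
    """Drop units failing the sequence-quality filters.

    Kept iff both flanking exons are longer than 6 nt, the intron is
    longer than 26 nt, and the full E-I-E genomic sequence is free of
    ambiguous nucleotides (N). Coordinates beyond the chromosome end
    raise.
    """
    kept = []
    for unit in units:
        if unit.upstream_exon.length() < MIN_EXON_LEN:
            continue
        if unit.downstream_exon.length() < MIN_EXON_LEN:
            continue
        if unit.intron.length() < MIN_INTRON_LEN:
            continue
        seq = unit.span().sequence(genome, stranded=False)  # raises if out of range
        if "N" in seq:
            continue
        kept.append(unit)
    return kept


def build_catalog(
    transcripts: list[TranscriptModel], genome: dict[str, str]
) -> list[EIEUnit]:
    """Full catalog pipeline: enumerate, classify, filter.

    Returns labeled units that pass the filters; EXCLUDED units are
    dropped. Counts of each label pre-filter are available via
    :func:`label_counts` on the intermediate list if needed.
    """
    units = enumerate_units(transcripts)
    units = detect_retention(units, transcripts)
    units = check_consistency(units, transcripts)
    units = assign_labels(units)
    labeled = [u for u in units if u.label != EXCLUDED]
    return apply_filters(labeled, genome)


def label_counts(units: list[EIEUnit]) -> dict[str, int]:
    counts = {CI: 0, RI: 0, EXCLUDED: 0}
    for u in units:
        counts[u.label] = counts.get(u.label, 0) + 1
    return counts


def write_catalog(units: list[EIEUnit], path: str | Path) -> None:
    """Write the catalog as a BED12-like TSV plus supporting transcript ids."""
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tunit_id\tlabel\tstrand\tblock_starts\tblock_sizes"
            "\tsupporting_spliced\tsupporting_retained\n"
        )
        for u in units:
            span = u.span()
            left, right = u.flanks_genomic()
            blocks = [left, u.intron, right]
            starts = ",".join(str(b.start - span.start) for b in blocks)
            sizes = ",".join(str(b.length()) for b in blocks)
            fh.write(
                f"{span.chrom}\t{span.start}\t{span.end}\t{u.unit_id()}\t{u.label}"
                f"\t{u.strand}\t{starts}\t{sizes}"
                f"\t{','.join(sorted(u.supporting_spliced))}"
                f"\t{','.join(sorted(u.supporting_retained))}\n"
            )


def read_catalog(path: str | Path) -> list[EIEUnit]:
    """Re-load a catalog written by :func:`write_catalog`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    units = []
    for _, row in df.iterrows():
        starts = [int(x) for x in str(row["block_starts"]).split(",")]
        sizes = [int(x) for x in str(row["block_sizes"]).split(",")]
        chrom, strand = row["chrom"], row["strand"]
        abs_start = int(row["start"])
        ivs = [
            GenomicInterval(chrom, abs_start + s, abs_start + s + z, strand)
            for s, z in zip(starts, sizes)
        ]
        left, intron, right = ivs
        up, down = (left, right) if strand == "+" else (right, left)
        gene_id = str(row["unit_id"]).split(":")[0]
        unit = EIEUnit(
            upstream_exon=up, intron=intron, downstream_exon=down,
            strand=strand, gene_id=gene_id,
            supporting_spliced=set(filter(None, str(row["supporting_spliced"]).split(","))),
            supporting_retained=set(filter(None, str(row["supporting_retained"]).split(","))),
            label=row["label"],
        )
        units.append(unit)
    return units
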