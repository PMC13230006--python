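"""Readers and writers for the external formats the pipeline touches.

Every reader normalizes to the package's internal conventions: 0-based
half-open coordinates, uppercase DNA (U mapped to T), PWM rows in
A/C/G/T order. Supported inputs: FASTA genomes, GTF transcript
annotations, UCSC rmsk tables or BED repeat files, and plain-text PWM
blocks (oRNAment-style probability matrices).
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Iterable
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .intervals import GenomicInterval, PWMRecord, RepeatElement, TranscriptModel

logger = logging.getLogger(__name__)

_NUC_ORDER = "ACGT"


def read_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome as ``{chromosome: uppercase sequence}``.

    U is converted to T so RNA-space references work transparently; Ns
    are retained verbatim (ambiguity filtering happens in the catalog
    stage). Record order is preserved (Python dicts are ordered).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not genome:
        raise ValueError(f"no FASTA records parsed from {path}")
    return genome


def read_transcripts(
    path: str | Path,
    allow_chroms: set[str] | None = None,
    id_filter: Callable[[str], bool] | None = None,
) -> list[TranscriptModel]:
    """Parse transcript models from a GTF file.

    Only ``exon`` features are used; they must carry ``transcript_id``
    and ``gene_id`` attributes. GTF 1-based closed coordinates are
    converted to 0-based half-open. Transcripts on chromosomes outside
    *allow_chroms* are dropped, as are transcripts whose id fails
    *id_filter* (e.g. ``lambda t: t.startswith("NM_")`` to restrict to a
    curated RefSeq-style subset). Transcripts with exons on mixed
    strands are skipped with a warning.
    """
    import pyranges as pr

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        return []
    df = pr.read_gtf(str(path), as_df=True)
    if df.empty:
        return []
    exons = df[df["Feature"] == "exon"]
    if exons.empty:
        return []
    for col in ("transcript_id", "gene_id"):
        if col not in exons.columns or exons[col].isna().any() or (exons[col] == "").any():
            raise ValueError(f"GTF {path}: exon feature missing {col} attribute")

    transcripts: list[TranscriptModel] = []
    for tid, grp in exons.groupby("transcript_id", sort=True):
        chroms = grp["Chromosome"].unique()
        strands = grp["Strand"].unique()
        if len(strands) != 1 or len(chroms) != 1:
            logger.warning("transcript %s has mixed strand/chromosome; skipped", tid)
            continue
        chrom, strand = str(chroms[0]), str(strands[0])
        if allow_chroms is not None and chrom not in allow_chroms:
            continue
        if id_filter is not None and not id_filter(str(tid)):
            continue
        ivs = [
            GenomicInterval(chrom, int(s), int(e), strand)
            for s, e in zip(grp["Start"], grp["End"])
        ]
        transcripts.append(
            TranscriptModel(
                transcript_id=str(tid),
                gene_id=str(grp["gene_id"].iloc[0]),
                chrom=chrom,
                strand=strand,
                exons=ivs,
            )
        )
    return transcripts


def write_transcripts_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF (1-based closed exon features)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            span = tx.span()
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            fh.write(
                f"{tx.chrom}\tretention_grammar\ttranscript\t{span.start + 1}\t"
                f"{span.end}\t.\t{tx.strand}\t.\t{attrs}\n"
            )
            for ex in sorted(tx.exons, key=lambda e: e.start):
                fh.write(
                    f"{tx.chrom}\tretention_grammar\texon\t{ex.start + 1}\t{ex.end}"
                    f"\t.\t{tx.strand}\t.\t{attrs}\n"
                )


_RMSK_COLS = ["genoName", "genoStart", "genoEnd", "repName", "repClass", "repFamily"]


def read_repeats(path: str | Path) -> list[RepeatElement]:
    """Load repetitive elements from a UCSC rmsk-style TSV or a BED6+3 file.

    Both dialects are 0-based half-open already. The rmsk dialect is
    recognized by a header naming ``genoName``; otherwise the file is
    read as headerless BED with columns
    chrom/start/end/name/score/strand/repName/repClass/repFamily, where
    short BED files may omit name/score/strand and carry the three
    repeat columns directly after the coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        return []
    first = open(path).readline()
    elements: list[RepeatElement] = []
    if "genoName" in first:
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in _RMSK_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"rmsk table {path} missing columns {missing}")
        rows = zip(
            df["genoName"], df["genoStart"], df["genoEnd"],
            df["repName"], df["repClass"], df["repFamily"],
        )
        strands = df["strand"] if "strand" in df.columns else ["+"] * len(df)
        for (chrom, s, e, name, cls, fam), strand in zip(rows, strands):
            elements.append(
                RepeatElement(
                    GenomicInterval(str(chrom), int(s), int(e), str(strand)),
                    rep_class=str(cls), rep_family=str(fam), rep_subfamily=str(name),
                )
            )
        return elements
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 9:
        chrom_c, s_c, e_c, strand_c, name_c, cls_c, fam_c = 0, 1, 2, 5, 6, 7, 8
    elif df.shape[1] == 6:
        chrom_c, s_c, e_c, strand_c, name_c, cls_c, fam_c = 0, 1, 2, None, 3, 4, 5
    else:
        raise ValueError(
            f"repeat file {path}: need rmsk header or >=6 BED columns with "
            f"subfamily/class/family, got {df.shape[1]} columns"
        )
    for _, row in df.iterrows():
        strand = str(row[strand_c]) if strand_c is not None else "+"
        if strand not in ("+", "-"):
            strand = "+"
        elements.append(
            RepeatElement(
                GenomicInterval(str(row[chrom_c]), int(row[s_c]), int(row[e_c]), strand),
                rep_class=str(row[cls_c]),
                rep_family=str(row[fam_c]),
                rep_subfamily=str(row[name_c]),
            )
        )
    return elements


def write_repeats_bed(repeats: Iterable[RepeatElement], path: str | Path) -> None:
    """Write repeats as BED6+3 (chrom start end name score strand name class family)."""
    with open(path, "w") as fh:
        for rep in repeats:
            iv = rep.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rep.rep_subfamily}\t0\t"
                f"{iv.strand}\t{rep.rep_subfamily}\t{rep.rep_class}\t{rep.rep_family}\n"
            )


def _parse_pwm_block(name: str, rows: list[list[float]], source: str) -> PWMRecord:
    mat = np.array(rows, dtype=float)
    # Orientation auto-detect: the nucleotide axis is the one of size 4
    # whose opposite axis sums to ~1 per position.
    if mat.shape[0] == 4 and mat.shape[1] == 4:
        if np.allclose(mat.sum(axis=0), 1.0, atol=1e-3):
            pass
        elif np.allclose(mat.sum(axis=1), 1.0, atol=1e-3):
            mat = mat.T
    elif mat.shape[0] == 4:
        pass
    elif mat.shape[1] == 4:
        mat = mat.T
    else:
        raise ValueError(f"PWM block {name!r} in {source}: no axis of size 4")
    return PWMRecord(rbp_name=name, matrix=mat)


def read_pwms(path: str | Path) -> dict[str, list[PWMRecord]]:
    """Read plain-text PWM files, grouping matrices by RBP name.

    Format: one matrix per block; a header line starting with ``>``
    carrying the RBP name, followed by 4 x k (rows A, C, G, T/U) or
    k x 4 floats. A directory is read file by file in sorted order.
    Multiple blocks may share one name: those RBPs are characterized by
    several motifs and their binding signals are OR-merged downstream.
    """
    path = Path(path)
    files = sorted(path.glob("*")) if path.is_dir() else [path]
    groups: dict[str, list[PWMRecord]] = {}
    for fp in files:
        if fp.is_dir():
            continue
        name: str | None = None
        rows: list[list[float]] = []
        with open(fp) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if name is not None and rows:
                        rec = _parse_pwm_block(name, rows, str(fp))
                        groups.setdefault(rec.rbp_name, []).append(rec)
                    name = line[1:].strip().split()[0]
                    rows = []
                else:
                    rows.append([float(tok) for tok in line.replace(",", " ").split()])
        if name is not None and rows:
            rec = _parse_pwm_block(name, rows, str(fp))
            groups.setdefault(rec.rbp_name, []).append(rec)
    return groups


def write_pwms(groups: dict[str, list[PWMRecord]], path: str | Path) -> None:
    """Write PWM groups to one plain-text file (4 x k blocks, rows A/C/G/T)."""
    with open(path, "w") as fh:
        for name in groups:
            for rec in groups[name]:
                fh.write(f">{name}\n")
                for row in rec.matrix:
                    fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
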