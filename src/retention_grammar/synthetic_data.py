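"""Self-contained synthetic study generator.

Emits a miniature genome, transcript annotation (with retention
isoforms), repeat annotation, PWM set and a truth table, with planted
class contrasts mirroring the statistical structure the analysis
expects of real catalogs:

* retained introns (RIs) are a small minority, shorter and more
  GC-rich than constitutive introns (CIs), with weaker
  (degraded-consensus) splice sites;
* RI introns are depleted of the planted repeat subfamilies;
* RBP motif placements are denser and clustered into loose bursts in
  CIs versus sparser and uniformly scattered in RIs, so CI binding
  signals carry more multiscale wavelet energy and structure.

Every contrast is individually switchable, magnitudes are config
fields, and everything is a deterministic function of (config, seed).
Retention isoforms are written as single-exon transcripts spanning the
unit exactly, the minimal structure satisfying the catalog's
exact-boundary retention rule. The generator also plants
filter-violating units (short intron/exon, ambiguous N) to exercise the
catalog filters; their truth label is FILTERED.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import write_pwms, write_repeats_bed, write_transcripts_gtf
from .intervals import GenomicInterval, PWMRecord, RepeatElement, TranscriptModel, reverse_complement

BASES = np.array(list("ACGT"))

DONOR_CONSENSUS = "CAGGTAAGT"  # 3 exonic + 6 intronic
ACCEPTOR_INTRON_CONSENSUS = "TTTTTTTTTTTTTTTTTCAG"  # last 20 intronic nt
ACCEPTOR_EXON_CONSENSUS = "GTC"  # first 3 exonic nt

DEFAULT_REPEAT_TAXA = (
    ("AluY", "SINE", "Alu"),
    ("L1M5", "LINE", "L1"),
)


@dataclass(frozen=True)
class EffectConfig:
    """Planted study conditions; defaults define the package's default catalog."""

    n_ci: int = 3000
    n_ri: int = 25
    # filter-violating plants (truth label FILTERED)
    n_short_intron: int = 3
    n_short_exon: int = 3
    n_ambiguous: int = 3
    # exon/intron length distributions (log-normal, natural-log scale)
    exon_logmean: float = math.log(120.0)
    exon_logsd: float = 0.3
    ci_intron_logmean: float = math.log(420.0)
    ri_intron_logmean: float = math.log(150.0)
    intron_logsd: float = 0.4
    min_intron_len: int = 40
    min_exon_len: int = 12
    ri_down_exon_shift: float = 0.0  # optional shift for RI downstream exon length
    # fraction of CIs whose length triple is drawn from the RI length
    # distribution: real catalogs contain many short constitutive
    # introns, and the overlap makes 20:1 length matching meaningful
    ci_short_len_frac: float = 0.4
    # GC content of generated sequence
    ci_gc: float = 0.45
    ri_gc: float = 0.55
    # per-position probability of degrading a splice-site consensus base
    ci_splice_degrade: float = 0.05
    ri_splice_degrade: float = 0.40
    # repeat planting: per-intron, per-taxon planting probability
    repeat_taxa: tuple = DEFAULT_REPEAT_TAXA
    ci_repeat_prob: float = 0.75
    ri_repeat_prob: float = 0.03
    repeat_len_frac: float = 0.25
    # RBP motifs
    n_rbps: int = 3
    pwm_k: int = 7
    pwm_info: float = 0.85
    multi_pwm_fraction: float = 0.34
    # planted motif copies per 100 nt of intron interior; constitutive
    # introns carry both a denser and a more clustered binding signal,
    # the joint contrast the wavelet descriptors are built to resolve
    ci_motif_density: float = 0.4
    ri_motif_density: float = 0.3
    # effect switches
    length_effect: bool = True
    gc_effect: bool = True
    splice_effect: bool = True
    repeat_effect: bool = True
    motif_effect: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ci, self.n_ri) < 0:
            raise ValueError("counts must be >= 0")
        for p in (self.ci_gc, self.ri_gc, self.ci_splice_degrade,
                  self.ri_splice_degrade, self.ci_repeat_prob, self.ri_repeat_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.min_intron_len <= 26:
            raise ValueError(
                "min_intron_len <= 26 would make every planted unit filterable"
            )

    def informative_features(self) -> list[str]:
        """Named feature columns carrying a planted class contrast.

        The motif-organization contrast is spread across the wavelet
        descriptor block and is deliberately not listed here.
        """
        out: list[str] = []
        if self.length_effect:
            out += ["len_intron"]
            if self.ri_down_exon_shift > 0:
                out += ["len_down"]
        if self.gc_effect:
            out += ["gc_intron"]
        if self.splice_effect:
            out += ["donor_score", "acceptor_score"]
        if self.repeat_effect:
            out += [f"repeat|{cls} {fam}" for _, cls, fam in self.repeat_taxa]
        return out


def length_only_config(seed: int = 0, n_ci: int = 5950, n_ri: int = 40) -> EffectConfig:
    """Confounder-study conditions: only the length contrast is planted.

    Intron lengths are strongly bimodal between classes (with a short
    constitutive subpopulation supplying matching controls) and exon
    lengths are kept nearly constant so the planted contrast is purely
    a length contrast; every compositional effect is switched off.
    """
    return EffectConfig(
        n_ci=n_ci, n_ri=n_ri,
        n_short_intron=0, n_short_exon=0, n_ambiguous=0,
        ci_short_len_frac=0.2,
        ci_intron_logmean=math.log(800.0),
        ri_intron_logmean=math.log(120.0),
        intron_logsd=0.25,
        exon_logsd=0.05,
        ri_down_exon_shift=0.0,
        gc_effect=False, splice_effect=False,
        repeat_effect=False, motif_effect=False,
        seed=seed,
    )


def generate_pwms(
    n_rbps: int,
    k: int = 7,
    seed: int = 0,
    multi_fraction: float = 0.2,
    info: float = 0.85,
) -> dict[str, list[PWMRecord]]:
    """Information-content-controlled random PWMs, grouped by RBP name.

    Each matrix has one consensus base per column at probability *info*
    and the rest uniform. The first ``round(multi_fraction * n_rbps)``
    RBPs receive a second, independent matrix to exercise OR-merging.
    """
    if n_rbps < 1:
        raise ValueError("n_rbps must be >= 1")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[PWMRecord]] = {}
    n_multi = int(round(multi_fraction * n_rbps))
    for i in range(n_rbps):
        name = f"RBP{i + 1:03d}"
        n_mats = 2 if i < n_multi else 1
        groups[name] = [_random_pwm(name, k, info, rng) for _ in range(n_mats)]
    return groups


def _random_pwm(name: str, k: int, info: float, rng: np.random.Generator) -> PWMRecord:
    consensus = rng.integers(0, 4, size=k)
    mat = np.full((4, k), (1 - info) / 3)
    mat[consensus, np.arange(k)] = info
    return PWMRecord(rbp_name=name, matrix=mat)


def pwm_consensus(pwm: PWMRecord) -> str:
    return "".join(BASES[np.asarray(pwm.matrix).argmax(axis=0)])


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.arange(4), size=n, p=probs)


def _degrade(consensus: str, prob: float, rng: np.random.Generator,
             protected: tuple[int, ...] = ()) -> str:
    out = list(consensus)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < prob:
            out[i] = str(rng.choice(BASES))
    return "".join(out)


def plant_motifs(
    seq: str,
    pwm: PWMRecord,
    mode: str,
    density: float,
    rng: np.random.Generator,
    burst_size: int = 5,
) -> str:
    """Embed high-scoring motif copies into *seq*.

    ``copies = round(density * len(seq) / 100)`` consensus copies are
    written either scattered uniformly or concentrated into bursts of
    ~*burst_size* adjacent placements; the total copy count is
    identical across modes at equal density.
    """
    k = pwm.k
    copies = int(round(density * len(seq) / 100))
    if copies == 0:
        return seq
    if copies * k >= len(seq):
        raise ValueError(f"cannot plant {copies} x {k}-mers into {len(seq)} nt")
    if mode not in ("clustered", "uniform"):
        raise ValueError("mode must be 'clustered' or 'uniform'")
    consensus = pwm_consensus(pwm)
    max_start = len(seq) - k
    if mode == "uniform":
        starts = rng.integers(0, max_start + 1, size=copies)
    else:
        # regulatory-hub geometry: a few bursts of copies spaced ~3k
        # apart, so a burst spans a localized window rather than one
        # contiguous run
        n_bursts = max(1, int(round(copies / burst_size)))
        centers = rng.integers(0, max_start + 1, size=n_bursts)
        starts = []
        for c in range(copies):
            center = centers[c % n_bursts]
            offset = (c // n_bursts) * 3 * k + int(rng.integers(0, k))
            starts.append(min(max_start, center + offset))
        starts = np.array(starts)
    arr = list(seq)
    for s in starts:
        arr[s : s + k] = consensus
    return "".join(arr)


@dataclass
class SimulatedStudy:
    """In-memory synthetic study: inputs for every pipeline stage plus truth."""

    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    repeats: list[RepeatElement]
    pwm_groups: dict[str, list[PWMRecord]]
    truth: pd.DataFrame
    config: EffectConfig


def simulate_study(cfg: EffectConfig) -> SimulatedStudy:
    """Generate the full synthetic study deterministically from (cfg, seed)."""
    rng = np.random.default_rng(cfg.seed)
    pwm_groups = generate_pwms(
        cfg.n_rbps, cfg.pwm_k, seed=cfg.seed + 1,
        multi_fraction=cfg.multi_pwm_fraction, info=cfg.pwm_info,
    )
    chrom = "chrS"
    spacer = 50
    cursor = 0
    chrom_parts: list[str] = []
    transcripts: list[TranscriptModel] = []
    repeats: list[RepeatElement] = []
    truth_rows: list[dict] = []

    plan = (
        [("CI", None)] * cfg.n_ci
        + [("RI", None)] * cfg.n_ri
        + [("FILTERED", "short_intron")] * cfg.n_short_intron
        + [("FILTERED", "short_exon")] * cfg.n_short_exon
        + [("FILTERED", "ambiguous")] * cfg.n_ambiguous
    )
    for gi, (label, defect) in enumerate(plan):
        gene_id = f"G{gi + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        is_ri = label == "RI"

        # RI units always use the RI length distribution; a configured
        # fraction of CIs draws the same length triple (short introns
        # are common among constitutive introns too).
        ri_like_lengths = cfg.length_effect and (
            is_ri or rng.random() < cfg.ci_short_len_frac
        )
        up_len = _draw_len(cfg.exon_logmean, cfg.exon_logsd, cfg.min_exon_len, rng)
        down_mu = cfg.exon_logmean + (
            cfg.ri_down_exon_shift if ri_like_lengths else 0.0
        )
        down_len = _draw_len(down_mu, cfg.exon_logsd, cfg.min_exon_len, rng)
        intron_mu = (
            cfg.ri_intron_logmean if ri_like_lengths else cfg.ci_intron_logmean
        )
        intron_len = _draw_len(intron_mu, cfg.intron_logsd, cfg.min_intron_len, rng)
        if defect == "short_intron":
            intron_len = 26
        elif defect == "short_exon":
            up_len = 6

        # GC contrast is planted in the intron; flanking exons stay at
        # the baseline composition for both classes
        gc = cfg.ri_gc if (is_ri and cfg.gc_effect) else cfg.ci_gc
        up_seq = "".join(BASES[_random_seq(up_len, cfg.ci_gc, rng)])
        in_seq = "".join(BASES[_random_seq(intron_len, gc, rng)])
        down_seq = "".join(BASES[_random_seq(down_len, cfg.ci_gc, rng)])

        degrade = (
            cfg.ri_splice_degrade if (is_ri and cfg.splice_effect) else cfg.ci_splice_degrade
        )
        donor = _degrade(DONOR_CONSENSUS, degrade, rng, protected=(3, 4))
        acc_in = _degrade(ACCEPTOR_INTRON_CONSENSUS, degrade, rng, protected=(18, 19))
        acc_ex = _degrade(ACCEPTOR_EXON_CONSENSUS, degrade, rng)
        if up_len >= 3:
            up_seq = up_seq[:-3] + donor[:3]
        if intron_len >= 26:
            in_seq = donor[3:9] + in_seq[6 : intron_len - 20] + acc_in
            down_seq = acc_ex + down_seq[3:]
        if defect == "ambiguous":
            mid = intron_len // 2
            in_seq = in_seq[:mid] + "N" + in_seq[mid + 1 :]

        # plant RBP motifs into the intron interior (splice windows untouched)
        if cfg.motif_effect and label != "FILTERED" and intron_len > 60:
            interior = in_seq[6 : intron_len - 20]
            mode = "uniform" if is_ri else "clustered"
            density = cfg.ri_motif_density if is_ri else cfg.ci_motif_density
            for group in pwm_groups.values():
                interior = plant_motifs(interior, group[0], mode, density, rng)
            in_seq = in_seq[:6] + interior + in_seq[intron_len - 20 :]

        unit_seq = up_seq + in_seq + down_seq  # transcribed orientation
        L = len(unit_seq)
        g0 = cursor
        genomic_seq = unit_seq if strand == "+" else reverse_complement(unit_seq)
        chrom_parts.append(genomic_seq)
        chrom_parts.append("".join(BASES[_random_seq(spacer, 0.5, rng)]))
        cursor += L + spacer

        if strand == "+":
            up_iv = GenomicInterval(chrom, g0, g0 + up_len, strand)
            in_iv = GenomicInterval(chrom, g0 + up_len, g0 + up_len + intron_len, strand)
            down_iv = GenomicInterval(chrom, g0 + up_len + intron_len, g0 + L, strand)
        else:
            up_iv = GenomicInterval(chrom, g0 + L - up_len, g0 + L, strand)
            in_iv = GenomicInterval(chrom, g0 + down_len, g0 + L - up_len, strand)
            down_iv = GenomicInterval(chrom, g0, g0 + down_len, strand)

        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene_id}.sp", gene_id=gene_id,
                chrom=chrom, strand=strand, exons=[up_iv, down_iv],
            )
        )
        if is_ri:
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.ret", gene_id=gene_id,
                    chrom=chrom, strand=strand,
                    exons=[GenomicInterval(chrom, g0, g0 + L, strand)],
                )
            )

        planted_taxa = []
        if label != "FILTERED":
            prob = cfg.ri_repeat_prob if (is_ri and cfg.repeat_effect) else cfg.ci_repeat_prob
            for subfam, cls, fam in cfg.repeat_taxa:
                if rng.random() < prob:
                    rep_len = max(10, int(intron_len * cfg.repeat_len_frac))
                    rep_len = min(rep_len, in_iv.length() - 2)
                    start = in_iv.start + int(
                        rng.integers(0, in_iv.length() - rep_len)
                    )
                    repeats.append(
                        RepeatElement(
                            GenomicInterval(chrom, start, start + rep_len, strand),
                            rep_class=cls, rep_family=fam, rep_subfamily=subfam,
                        )
                    )
                    planted_taxa.append(f"{cls} {fam}")

        span_start, span_end = g0, g0 + L
        unit_id = (
            f"{gene_id}:{chrom}:{span_start}-{in_iv.start}-{in_iv.end}-{span_end}:{strand}"
        )
        truth_rows.append(
            {
                "unit_id": unit_id, "gene_id": gene_id, "chrom": chrom,
                "span_start": span_start, "span_end": span_end, "strand": strand,
                "intron_start": in_iv.start, "intron_end": in_iv.end,
                "label": label, "defect": defect or "",
                "up_len": up_len, "intron_len": intron_len, "down_len": down_len,
                "gc": gc, "splice_degrade": degrade,
                "planted_repeats": ",".join(planted_taxa),
            }
        )

    genome = {chrom: "".join(chrom_parts)}
    truth = pd.DataFrame(truth_rows)
    return SimulatedStudy(
        genome=genome, transcripts=transcripts, repeats=repeats,
        pwm_groups=pwm_groups, truth=truth, config=cfg,
    )


def _draw_len(logmean: float, logsd: float, minimum: int, rng: np.random.Generator) -> int:
    return max(minimum, int(round(rng.lognormal(logmean, logsd))))


def generate_catalog(cfg: EffectConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the synthetic study to disk as standard-format files.

    Emits genome.fa, annotation.gtf, repeats.bed, pwms.txt and
    truth.tsv under *outdir*; the files are valid inputs for the
    genome_io readers with no special-casing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(cfg)
    paths = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "repeats": outdir / "repeats.bed",
        "pwms": outdir / "pwms.txt",
        "truth": outdir / "truth.tsv",
    }
    with open(paths["genome"], "w") as fh:
        for chrom, seq in study.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_transcripts_gtf(study.transcripts, paths["gtf"])
    write_repeats_bed(study.repeats, paths["repeats"])
    write_pwms(study.pwm_groups, paths["pwms"])
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def with_seed(cfg: EffectConfig, seed: int) -> EffectConfig:
    """Copy a config with a different seed (configs are frozen)."""
    return replace(cfg, seed=seed)
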