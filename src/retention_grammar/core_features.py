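"""Length, GC-content and splice-site-strength features per E-I-E unit.

Splice-site strength follows the MaxEntScan window geometry: the donor
context is a 9-mer (last 3 exonic nt of the upstream exon + first 6
intronic nt) and the acceptor context a 23-mer (last 20 intronic nt +
first 3 exonic nt of the downstream exon), both read 5'->3' on the
transcribed strand. Scoring is pluggable: a table-consumer scorer for
externally supplied maximum-entropy score tables, and a self-contained
fallback that trains first-order log2-odds PWMs on the catalog's CI
splice sites against a uniform background.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .eie_catalog import CI, EIEUnit

DONOR_EXON_NT, DONOR_INTRON_NT = 3, 6
ACCEPTOR_INTRON_NT, ACCEPTOR_EXON_NT = 20, 3
DONOR_LEN = DONOR_EXON_NT + DONOR_INTRON_NT
ACCEPTOR_LEN = ACCEPTOR_INTRON_NT + ACCEPTOR_EXON_NT

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}

CORE_FEATURE_NAMES = [
    "len_up", "len_intron", "len_down",
    "gc_up", "gc_intron", "gc_down",
    "donor_score", "acceptor_score",
]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C in an unambiguous DNA string."""
    if not seq:
        raise ValueError("empty sequence")
    if "N" in seq:
        raise ValueError("ambiguous nucleotide in sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def splice_contexts(unit: EIEUnit, genome: dict[str, str]) -> tuple[str, str]:
    """(donor 9-mer, acceptor 23-mer) for a unit, on the transcribed strand.

    The windows are carved out of the unit's transcribed-orientation
    sequence, so '-' strand units are handled by the same arithmetic.
    """
    seq = unit.sequence(genome)
    up_len = unit.upstream_exon.length()
    intron_len = unit.intron.length()
    if up_len < DONOR_EXON_NT or unit.downstream_exon.length() < ACCEPTOR_EXON_NT:
        raise ValueError(f"unit {unit.unit_id()}: flanking exon too short for context")
    if intron_len < DONOR_INTRON_NT + ACCEPTOR_INTRON_NT:
        raise ValueError(f"unit {unit.unit_id()}: intron too short for contexts")
    donor = seq[up_len - DONOR_EXON_NT : up_len + DONOR_INTRON_NT]
    intron_end = up_len + intron_len
    acceptor = seq[intron_end - ACCEPTOR_INTRON_NT : intron_end + ACCEPTOR_EXON_NT]
    return donor, acceptor


def _encode(context: str) -> np.ndarray:
    try:
        return np.array([_IDX[b] for b in context], dtype=int)
    except KeyError as exc:
        raise ValueError(f"ambiguous/invalid base in context {context!r}") from exc


class PWMSpliceScorer:
    """First-order log2-odds scorer trained on observed splice contexts.

    ``fit`` estimates per-position base frequencies (with a pseudocount)
    from training contexts; ``score`` returns
    ``sum_j log2(p_j(base_j) / 0.25)``. A scorer fit on no data uses the
    uniform PWM and scores every context 0.
    """

    def __init__(self, length: int, pseudocount: float = 0.5):
        self.length = length
        self.pseudocount = pseudocount
        self.logodds_ = np.zeros((4, length))  # uniform until fit

    def fit(self, contexts: list[str]) -> "PWMSpliceScorer":
        counts = np.full((4, self.length), self.pseudocount)
        for ctx in contexts:
            if len(ctx) != self.length:
                raise ValueError(f"context length {len(ctx)} != {self.length}")
            counts[_encode(ctx), np.arange(self.length)] += 1
        probs = counts / counts.sum(axis=0, keepdims=True)
        self.logodds_ = np.log2(probs / 0.25)
        return self

    def score(self, context: str) -> float:
        if len(context) != self.length:
            raise ValueError(f"context length {len(context)} != {self.length}")
        idx = _encode(context)
        return float(self.logodds_[idx, np.arange(self.length)].sum())

    def max_score(self) -> float:
        return float(self.logodds_.max(axis=0).sum())


class TableSpliceScorer:
    """Scorer backed by an externally supplied context -> score table.

    The table is a two-column TSV (context, score), one row per scored
    k-mer, as produced by exporting a maximum-entropy splice model's
    score tables. Contexts absent from the table raise.
    """

    def __init__(self, table: dict[str, float], length: int):
        self.table = table
        self.length = length

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TableSpliceScorer":
        df = pd.read_csv(path, sep="\t", header=None, names=["context", "score"])
        table = dict(zip(df["context"].str.upper(), df["score"].astype(float)))
        lengths = {len(c) for c in table}
        if len(lengths) != 1:
            raise ValueError(f"score table {path} mixes context lengths {lengths}")
        return cls(table, lengths.pop())

    def score(self, context: str) -> float:
        if len(context) != self.length:
            raise ValueError(f"context length {len(context)} != {self.length}")
        if "N" in context:
            raise ValueError(f"ambiguous base in context {context!r}")
        try:
            return self.table[context.upper()]
        except KeyError as exc:
            raise KeyError(f"context {context!r} not in score table") from exc


class CoreFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer: list of EIEUnits -> core feature frame (8 columns).

    Parameters
    ----------
    genome : dict
        Chromosome -> sequence map the units refer to.
    donor_scorer, acceptor_scorer : optional
        Objects with a ``score(context) -> float`` method (e.g.
        :class:`TableSpliceScorer`). When omitted, ``fit`` trains
        :class:`PWMSpliceScorer` fallbacks on the CI units' contexts.
    """

    def __init__(self, genome=None, donor_scorer=None, acceptor_scorer=None):
        self.genome = genome
        self.donor_scorer = donor_scorer
        self.acceptor_scorer = acceptor_scorer

    def fit(self, X: list[EIEUnit], y=None):
        if self.genome is None:
            raise ValueError("genome is required")
        self.donor_scorer_ = self.donor_scorer
        self.acceptor_scorer_ = self.acceptor_scorer
        if self.donor_scorer_ is None or self.acceptor_scorer_ is None:
            ci_units = [u for u in X if u.label == CI] or list(X)
            donors, acceptors = [], []
            for u in ci_units:
                d, a = splice_contexts(u, self.genome)
                donors.append(d)
                acceptors.append(a)
            if self.donor_scorer_ is None:
                self.donor_scorer_ = PWMSpliceScorer(DONOR_LEN).fit(donors)
            if self.acceptor_scorer_ is None:
                self.acceptor_scorer_ = PWMSpliceScorer(ACCEPTOR_LEN).fit(acceptors)
        self.feature_names_out_ = list(CORE_FEATURE_NAMES)
        return self

    def transform(self, X: list[EIEUnit]) -> pd.DataFrame:
        rows = []
        for u in X:
            seq = u.sequence(self.genome)
            up_len, in_len = u.upstream_exon.length(), u.intron.length()
            up_seq = seq[:up_len]
            in_seq = seq[up_len : up_len + in_len]
            down_seq = seq[up_len + in_len :]
            donor, acceptor = splice_contexts(u, self.genome)
            rows.append(
                {
                    "len_up": up_len,
                    "len_intron": in_len,
                    "len_down": u.downstream_exon.length(),
                    "gc_up": gc_fraction(up_seq),
                    "gc_intron": gc_fraction(in_seq),
                    "gc_down": gc_fraction(down_seq),
                    "donor_score": self.donor_scorer_.score(donor),
                    "acceptor_score": self.acceptor_scorer_.score(acceptor),
                }
            )
        return pd.DataFrame(rows, index=[u.unit_id() for u in X], dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)
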