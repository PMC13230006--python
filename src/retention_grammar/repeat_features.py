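"""Fractional repeat coverage of introns.

Each intron gets, per repeat taxon, the proportion of its length covered
by elements of that taxon (same-taxon overlaps union-merged first), a
normalized fraction independent of intron length. Elements with
uncertain classification ('?' anywhere in class/family, or
'unknown') are discarded before measuring. Columns can be defined at
subfamily (repName) or family granularity ("<class> <family>", the
rollup used for modeling defaults).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.base import BaseEstimator, TransformerMixin

from .eie_catalog import EIEUnit
from .intervals import GenomicInterval, RepeatElement


def filter_repeats(repeats: list[RepeatElement]) -> list[RepeatElement]:
    """Drop elements whose class or family is uncertain.

    An element is removed iff its rep_class or rep_family contains '?'
    or equals 'unknown' (case-insensitive).
    """
    out = []
    for rep in repeats:
        bad = False
        for tag in (rep.rep_class, rep.rep_family):
            if "?" in tag or tag.lower() == "unknown":
                bad = True
        if not bad:
            out.append(rep)
    return out


def _taxon(rep: RepeatElement, granularity: str) -> str:
    if granularity == "subfamily":
        return rep.rep_subfamily
    if granularity == "family":
        return f"{rep.rep_class} {rep.rep_family}"
    raise ValueError(f"granularity must be 'subfamily' or 'family', got {granularity!r}")


class _RepeatIndex:
    """Per-chromosome interval trees keyed for overlap queries."""

    def __init__(self, repeats: list[RepeatElement], granularity: str):
        self.trees: dict[str, IntervalTree] = {}
        self.granularity = granularity
        for rep in repeats:
            iv = rep.interval
            tree = self.trees.setdefault(iv.chrom, IntervalTree())
            tree.addi(iv.start, iv.end, _taxon(rep, granularity))

    def query(self, interval: GenomicInterval):
        tree = self.trees.get(interval.chrom)
        if tree is None:
            return []
        return tree.overlap(interval.start, interval.end)


def subfamily_coverage(
    intron: GenomicInterval,
    repeats: list[RepeatElement],
    granularity: str = "subfamily",
    index: _RepeatIndex | None = None,
) -> dict[str, float]:
    """Per-taxon fraction of the intron covered by elements of that taxon.

    Overlaps within a taxon are merged before measuring so no fraction
    can exceed 1; across taxa the fractions may sum above 1 when
    elements of different taxa overlap.
    """
    if index is None:
        index = _RepeatIndex(repeats, granularity)
    hits: dict[str, list[tuple[int, int]]] = {}
    for hit in index.query(intron):
        lo = max(hit.begin, intron.start)
        hi = min(hit.end, intron.end)
        if lo < hi:
            hits.setdefault(hit.data, []).append((lo, hi))
    coverage: dict[str, float] = {}
    for taxon, segs in hits.items():
        segs.sort()
        covered, cur_lo, cur_hi = 0, *segs[0]
        for lo, hi in segs[1:]:
            if lo > cur_hi:
                covered += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        covered += cur_hi - cur_lo
        coverage[taxon] = covered / intron.length()
    return coverage


class RepeatCoverageExtractor(BaseEstimator, TransformerMixin):
    """Transformer: list of EIEUnits -> repeat-coverage feature frame.

    The feature vocabulary (column set) is either supplied explicitly or
    learned in ``fit`` as the sorted taxa present after confidence
    filtering; units lacking a taxon get 0, keeping the matrix dense and
    identically shaped across catalogs.

    Parameters
    ----------
    repeats : list of RepeatElement
    granularity : {'family', 'subfamily'}
        'family' (default) emits "<class> <family>" rollup columns, the
        level at which the informative repeat taxa are reported;
        'subfamily' emits repName-level columns.
    vocabulary : list of str, optional
        Fixed column order; overrides learning from the data.
    """

    def __init__(self, repeats=None, granularity: str = "family", vocabulary=None):
        self.repeats = repeats
        self.granularity = granularity
        self.vocabulary = vocabulary

    def fit(self, X: list[EIEUnit], y=None):
        confident = filter_repeats(self.repeats or [])
        self.index_ = _RepeatIndex(confident, self.granularity)
        if self.vocabulary is not None:
            self.vocabulary_ = list(self.vocabulary)
        else:
            self.vocabulary_ = sorted({_taxon(r, self.granularity) for r in confident})
        self.feature_names_out_ = [f"repeat|{t}" for t in self.vocabulary_]
        return self

    def transform(self, X: list[EIEUnit]) -> pd.DataFrame:
        mat = np.zeros((len(X), len(self.vocabulary_)))
        col = {t: j for j, t in enumerate(self.vocabulary_)}
        for i, unit in enumerate(X):
            cov = subfamily_coverage(unit.intron, [], self.granularity, index=self.index_)
            for taxon, frac in cov.items():
                if taxon in col:
                    mat[i, col[taxon]] = frac
        return pd.DataFrame(
            mat, index=[u.unit_id() for u in X], columns=self.feature_names_out_
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_out_, dtype=object)
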