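"""Assembly of the per-unit feature matrix.

Joins the three feature blocks — core architecture (8 columns), repeat
coverage (one per taxon in the vocabulary), and wavelet RBP descriptors
(3*L per RBP group) — into one dense named table with binary labels
(RI = 1, CI = 0). At the published configuration (130 RBP groups,
L = 6, 49 repeat taxa) the matrix is 2,397 columns wide.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_features import CoreFeatureExtractor
from .eie_catalog import RI, EIEUnit
from .repeat_features import RepeatCoverageExtractor
from .rbp_wavelet import DEFAULT_LEVELS, RBPWaveletExtractor

CORE_GROUP = "core"
REPEAT_GROUP = "repeat"
RBP_GROUP = "rbp"


@dataclass
class FeatureMatrix:
    """Named feature table plus labels and column-group bookkeeping."""

    X: pd.DataFrame
    y: pd.Series  # 1 = RI, 0 = CI
    groups: dict[str, list[str]]  # group name -> column names

    @property
    def width(self) -> int:
        return self.X.shape[1]

    def columns_for(self, *group_names: str) -> list[str]:
        cols: list[str] = []
        for g in group_names:
            cols.extend(self.groups[g])
        return cols

    def to_tsv(self, path) -> None:
        out = self.X.copy()
        out.insert(0, "label", self.y)
        out.to_csv(path, sep="\t", index_label="unit_id")


def build_feature_matrix(
    units: list[EIEUnit],
    genome: dict[str, str],
    repeats=None,
    pwm_groups=None,
    levels: int = DEFAULT_LEVELS,
    repeat_granularity: str = "family",
    repeat_vocabulary=None,
    donor_scorer=None,
    acceptor_scorer=None,
) -> FeatureMatrix:
    """Compute all feature groups for a labeled catalog.

    Repeat and RBP blocks are optional (pass None to omit), supporting
    the feature-subset model variants. Raises on duplicate column names
    or missing values, which would silently corrupt modeling.
    """
    if not units:
        raise ValueError("empty unit catalog")
    blocks: list[pd.DataFrame] = []
    groups: dict[str, list[str]] = {}

    core = CoreFeatureExtractor(
        genome=genome, donor_scorer=donor_scorer, acceptor_scorer=acceptor_scorer
    ).fit(units)
    core_df = core.transform(units)
    blocks.append(core_df)
    groups[CORE_GROUP] = list(core_df.columns)

    if repeats is not None:
        rep = RepeatCoverageExtractor(
            repeats=repeats, granularity=repeat_granularity,
            vocabulary=repeat_vocabulary,
        ).fit(units)
        rep_df = rep.transform(units)
        blocks.append(rep_df)
        groups[REPEAT_GROUP] = list(rep_df.columns)

    if pwm_groups is not None:
        rbp = RBPWaveletExtractor(
            genome=genome, pwm_groups=pwm_groups, levels=levels
        ).fit(units)
        rbp_df = rbp.transform(units)
        blocks.append(rbp_df)
        groups[RBP_GROUP] = list(rbp_df.columns)

    X = pd.concat(blocks, axis=1)
    if X.columns.duplicated().any():
        dup = X.columns[X.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature columns: {dup}")
    if X.isna().any().any():
        raise ValueError("missing values in feature matrix")
    y = pd.Series(
        [1 if u.label == RI else 0 for u in units],
        index=X.index, name="label", dtype=int,
    )
    return FeatureMatrix(X=X, y=y, groups=groups)
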