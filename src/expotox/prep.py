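"""Preprocessing for health-examination records.

Covers row cleaning by missingness, min-max feature normalization
(x' = (x - min x) / (max x - min x), fitted on the training split only),
train/test splitting, the Binary-Relevance (BR) and Label-Powerset (LP)
multi-label reductions, and the Pearson-weighted association loss
CL = loss_anchor + sum_i alpha_i * loss_i used to couple the otherwise
independent BR heads during training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from .synthio import HealthTable


class EmptyDatasetError(ValueError):
    pass


def clean_records(table: HealthTable, max_missing_fraction: float = 0.2
                  ) -> HealthTable:
    """Drop rows whose missing-feature fraction exceeds the threshold;
    impute remaining missing values with the per-feature median of the
    retained rows.  The returned table carries ``n_dropped``.
    """
    feats = table.features
    frac = feats.isna().mean(axis=1)
    keep = frac <= max_missing_fraction
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise EmptyDatasetError("all rows exceed the missingness threshold")
    kept = feats.loc[keep]
    imputed = kept.fillna(kept.median())
    return HealthTable(
        features=imputed.reset_index(drop=True),
        labels=table.labels.loc[keep].reset_index(drop=True),
        timestamps=table.timestamps.loc[keep].reset_index(drop=True),
        exposure=None if table.exposure is None
        else table.exposure.loc[keep].reset_index(drop=True),
        n_dropped=n_dropped,
    )


@dataclass
class NormalizationParams:
    """Per-feature minima and maxima fitted on the training split."""

    minimum: pd.Series
    maximum: pd.Series

    def to_yaml(self, path) -> None:
        payload = {
            "minimum": {k: float(v) for k, v in self.minimum.items()},
            "maximum": {k: float(v) for k, v in self.maximum.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "NormalizationParams":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(minimum=pd.Series(payload["minimum"]),
                   maximum=pd.Series(payload["maximum"]))


def minmax_fit(features: pd.DataFrame) -> NormalizationParams:
    if features.shape[0] == 0 or features.shape[1] == 0:
        raise EmptyDatasetError("cannot fit normalization on empty features")
    return NormalizationParams(minimum=features.min(), maximum=features.max())


def minmax_apply(features: pd.DataFrame, params: NormalizationParams
                 ) -> pd.DataFrame:
    """Apply x' = (x - min)/(max - min).  Constant features (max == min)
    map to 0 by convention; values outside the fitted range extrapolate
    linearly (so test-split outputs may leave [0, 1])."""
    rng = (params.maximum - params.minimum).replace(0.0, np.nan)
    out = (features - params.minimum) / rng
    return out.fillna(0.0)


def split_train_test(table: HealthTable, fraction: float = 0.8,
                     seed: int = 0, stratify_lp: bool = False
                     ) -> tuple[HealthTable, HealthTable]:
    """Random split into train/test with ``fraction`` of rows in train.

    With ``stratify_lp`` the split is stratified on the Label-Powerset class
    of each record so per-class proportions track the global fraction.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    idx = np.arange(len(table))
    strat = None
    if stratify_lp:
        strat = lp_transform(MultiLabelSet.from_table(table)).classes
    train_idx, test_idx = train_test_split(
        idx, train_size=fraction, random_state=seed, stratify=strat)

    def take(sel: np.ndarray) -> HealthTable:
        return HealthTable(
            features=table.features.iloc[sel].reset_index(drop=True),
            labels=table.labels.iloc[sel].reset_index(drop=True),
            timestamps=table.timestamps.iloc[sel].reset_index(drop=True),
            exposure=None if table.exposure is None
            else table.exposure.iloc[sel].reset_index(drop=True),
        )

    return take(np.sort(train_idx)), take(np.sort(test_idx))


@dataclass
class MultiLabelSet:
    """Binary multi-label block: names plus an n x l {0,1} matrix."""

    names: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise ValueError("label matrix must be n x l with l >= 1")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("label matrix entries must be binary")
        if len(self.names) != self.matrix.shape[1]:
            raise ValueError("names/matrix width mismatch")

    @classmethod
    def from_table(cls, table: HealthTable) -> "MultiLabelSet":
        return cls(names=table.label_names,
                   matrix=table.labels.to_numpy(int))


@dataclass
class BRDataset:
    """Binary-Relevance reduction: one single-label dataset per label,
    all sharing the same feature matrix."""

    names: list[str]
    targets: dict[str, np.ndarray]


@dataclass
class LPDataset:
    """Label-Powerset reduction: one categorical target over the observed
    label combinations, classes ordered by first occurrence."""

    classes: np.ndarray            # class id per record
    combinations: np.ndarray       # class id -> original label row
    names: list[str]

    @property
    def n_classes(self) -> int:
        return len(self.combinations)

    def inverse(self) -> np.ndarray:
        """Reconstruct the original binary label matrix."""
        return self.combinations[self.classes]


def br_transform(labels: MultiLabelSet) -> BRDataset:
    return BRDataset(names=list(labels.names),
                     targets={n: labels.matrix[:, i].copy()
                              for i, n in enumerate(labels.names)})


def lp_transform(labels: MultiLabelSet) -> LPDataset:
    combos, classes = np.unique(labels.matrix, axis=0, return_inverse=True)
    # np.unique sorts; reorder classes by first occurrence for stability
    remap = np.full(len(combos), -1, dtype=int)
    nxt = 0
    for cid in classes:
        if remap[cid] < 0:
            remap[cid] = nxt
            nxt += 1
    new_classes = remap[classes]
    new_combos = np.empty_like(combos)
    new_combos[remap] = combos
    return LPDataset(classes=new_classes, combinations=new_combos,
                     names=list(labels.names))


@dataclass
class AssociationLossSpec:
    """Coefficients of the association loss for one anchor label.

    ``alpha[i]`` is the training-set Pearson correlation between the anchor
    label vector and label i's vector; the anchor's own coefficient is fixed
    at 1 and excluded from ``alpha``.
    """

    anchor: int
    alpha: np.ndarray           # length l, anchor position holds 0
    names: list[str] = field(default_factory=list)

    def coefficients(self) -> np.ndarray:
        """Full per-label loss weights (1 at the anchor, alpha elsewhere)."""
        c = np.array(self.alpha, dtype=float)
        c[self.anchor] = 1.0
        return c


def pearson_alpha(labels: MultiLabelSet, anchor: int) -> AssociationLossSpec:
    """Sample Pearson correlation of the anchor label with every other label.

    Zero-variance labels get alpha = 0 with a warning; the anchor itself must
    have nonzero variance.
    """
    mat = labels.matrix.astype(float)
    l = mat.shape[1]
    if not 0 <= anchor < l:
        raise IndexError("anchor out of range")
    av = mat[:, anchor]
    if av.std() == 0:
        raise ValueError("anchor label has zero variance")
    alpha = np.zeros(l)
    for i in range(l):
        if i == anchor:
            continue
        if mat[:, i].std() == 0:
            warnings.warn(
                f"label {labels.names[i]!r} has zero variance; alpha set to 0",
                RuntimeWarning, stacklevel=2)
            continue
        alpha[i] = np.corrcoef(av, mat[:, i])[0, 1]
    return AssociationLossSpec(anchor=anchor, alpha=alpha,
                               names=list(labels.names))


def association_loss(per_label_losses: np.ndarray,
                     spec: AssociationLossSpec) -> float:
    """CL = loss_anchor + sum_{i != anchor} alpha_i * loss_i."""
    losses = np.asarray(per_label_losses, dtype=float)
    if losses.shape[0] != spec.alpha.shape[0]:
        raise ValueError("length mismatch between alpha and losses")
    return float(losses @ spec.coefficients())
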