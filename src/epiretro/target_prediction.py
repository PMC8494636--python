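"""Pairwise prediction of projection groups by regularized logistic models.

The separability of two (source, target) cell groups in posterior mCH
feature space is quantified by the cross-validated AUROC of an
L2-regularized logistic regression.  Splits are either computational
replicates (repeated stratified 50/50 splits) or biological replicates
(train on one sex, test on the other; both directions, averaged).  When
groups span several subclasses the training set is upsampled so both
groups contribute equal numbers per subclass, preventing the model from
learning subclass composition instead of the projection difference.
Transfer variants train on one source's target pair and test on another
source's (cross-source), or train on all but one layer and test on the
held-out layer (cross-layer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler

__all__ = [
    "PredictionResult",
    "split_cells",
    "balance_upsample",
    "fit_auroc",
    "cross_source_auroc",
    "cross_layer_auroc",
]


@dataclass
class PredictionResult:
    auroc: float
    fold_aurocs: list[float]
    n_train: dict[str, int]
    n_test: dict[str, int]


def split_cells(
    table: pd.DataFrame,
    mode: str = "computational",
    seed: int = 0,
    group_col: str = "group",
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Train/test index splits: stratified 50/50, or by sex (both directions).

    Computational mode returns one split; biological mode returns the two
    directed splits (M trains / F tests and the reverse).  Indices are
    positions into ``table``.
    """
    groups = table[group_col].to_numpy()
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, found {list(uniq)}")
    if mode == "computational":
        rng = np.random.default_rng(seed)
        train_idx, test_idx = [], []
        for g in uniq:
            members = np.flatnonzero(groups == g)
            rng.shuffle(members)
            half = len(members) // 2
            train_idx.append(members[:half])
            test_idx.append(members[half:])
        splits = [(np.concatenate(train_idx), np.concatenate(test_idx))]
    elif mode == "biological":
        sex = table["sex"].to_numpy()
        males = np.flatnonzero(sex == "M")
        females = np.flatnonzero(sex == "F")
        splits = [(males, females), (females, males)]
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    for train, test in splits:
        for g in uniq:
            if not (groups[train] == g).any():
                raise ValueError(f"group {g!r} absent from a training split")
            if not (groups[test] == g).any():
                raise ValueError(f"group {g!r} absent from a test split")
    return splits


def balance_upsample(
    table: pd.DataFrame,
    train_idx: np.ndarray,
    seed: int = 0,
    group_col: str = "group",
    subclass_col: str = "subclass",
) -> np.ndarray:
    """Equalize the two groups' training counts within every subclass.

    The minority group of each subclass is resampled with replacement.
    Subclasses with cells from only one group are dropped (with a warning).
    Returns an augmented multiset of training positions.
    """
    rng = np.random.default_rng(seed)
    sub = table.iloc[train_idx]
    groups = np.unique(sub[group_col])
    out: list[np.ndarray] = []
    for subclass, grp in sub.groupby(subclass_col, sort=True):
        present = grp[group_col].unique()
        if len(present) < 2:
            warnings.warn(
                f"subclass {subclass!r} has cells from one group only in training; dropped"
            )
            continue
        counts = grp[group_col].value_counts()
        n_max = counts.max()
        for g in groups:
            members = train_idx[
                (sub[subclass_col].to_numpy() == subclass) & (sub[group_col].to_numpy() == g)
            ]
            out.append(members)
            deficit = n_max - len(members)
            if deficit > 0:
                out.append(rng.choice(members, size=deficit, replace=True))
    if not out:
        raise ValueError("no subclass retained both groups; cannot balance")
    return np.concatenate(out)


def _fit_one(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    C: float,
    seed: int,
) -> float:
    scaler = StandardScaler().fit(X_train)
    # sklearn's default penalty is L2; C controls its strength
    model = LogisticRegression(C=C, max_iter=2000, random_state=seed % (2**31))
    model.fit(scaler.transform(X_train), y_train)
    scores = model.decision_function(scaler.transform(X_test))
    if len(np.unique(y_test)) < 2:
        raise ValueError("test set contains a single class")
    return float(roc_auc_score(y_test, scores))


def fit_auroc(
    M: np.ndarray,
    table: pd.DataFrame,
    mode: str = "computational",
    n_repeats: int = 10,
    balance: bool = False,
    C: float = 1.0,
    seed: int = 0,
    group_col: str = "group",
) -> PredictionResult:
    """Cross-validated AUROC for separating two groups in feature space.

    Computational mode averages ``n_repeats`` stratified 50/50 splits;
    biological mode averages the two sex directions.  Features are
    standardized on training statistics; the test set is never upsampled.
    """
    M = np.asarray(M, dtype=float)
    groups = table[group_col].to_numpy()
    uniq = np.unique(groups)
    y = (groups == uniq[1]).astype(int)

    fold_aurocs: list[float] = []
    n_train_last: dict[str, int] = {}
    n_test_last: dict[str, int] = {}
    repeats = range(n_repeats) if mode == "computational" else [0]
    for rep in repeats:
        splits = split_cells(table, mode=mode, seed=seed + rep, group_col=group_col)
        for direction, (train, test) in enumerate(splits):
            fit_train = train
            if balance:
                fit_train = balance_upsample(
                    table, train, seed=seed + rep * 7 + direction, group_col=group_col
                )
            fold_aurocs.append(
                _fit_one(M[fit_train], y[fit_train], M[test], y[test], C, seed)
            )
            n_train_last = {str(g): int((groups[fit_train] == g).sum()) for g in uniq}
            n_test_last = {str(g): int((groups[test] == g).sum()) for g in uniq}
    return PredictionResult(
        auroc=float(np.mean(fold_aurocs)),
        fold_aurocs=fold_aurocs,
        n_train=n_train_last,
        n_test=n_test_last,
    )


def cross_source_auroc(
    M: np.ndarray,
    table: pd.DataFrame,
    train_source: str,
    test_source: str,
    mode: str = "computational",
    balance: bool = False,
    C: float = 1.0,
    seed: int = 0,
    group_col: str = "group",
    source_col: str = "source",
) -> PredictionResult:
    """Train on one source's target pair, test on another source's same pair.

    Biological mode averages the two sex directions (train male in the
    training source / test female in the test source, and the reverse);
    computational mode trains on all training-source cells and tests on
    all test-source cells.
    """
    src = table[source_col].to_numpy()
    groups = table[group_col].to_numpy()
    uniq = np.unique(groups)
    y = (groups == uniq[1]).astype(int)
    train_all = np.flatnonzero(src == train_source)
    test_all = np.flatnonzero(src == test_source)
    if len(train_all) == 0 or len(test_all) == 0:
        raise ValueError("empty source partition")

    if mode == "biological":
        sex = table["sex"].to_numpy()
        pairs = [
            (train_all[sex[train_all] == "M"], test_all[sex[test_all] == "F"]),
            (train_all[sex[train_all] == "F"], test_all[sex[test_all] == "M"]),
        ]
    else:
        pairs = [(train_all, test_all)]

    fold_aurocs = []
    for direction, (train, test) in enumerate(pairs):
        fit_train = train
        if balance:
            fit_train = balance_upsample(table, train, seed=seed + direction, group_col=group_col)
        fold_aurocs.append(_fit_one(M[fit_train], y[fit_train], M[test], y[test], C, seed))
    return PredictionResult(
        auroc=float(np.mean(fold_aurocs)),
        fold_aurocs=fold_aurocs,
        n_train={str(g): int((groups[train_all] == g).sum()) for g in uniq},
        n_test={str(g): int((groups[test_all] == g).sum()) for g in uniq},
    )


def cross_layer_auroc(
    M: np.ndarray,
    table: pd.DataFrame,
    held_out_layer: str,
    balance: bool = False,
    C: float = 1.0,
    seed: int = 0,
    group_col: str = "group",
    layer_col: str = "subclass",
) -> PredictionResult:
    """Train on all but one layer and test on the held-out layer."""
    layers = table[layer_col].to_numpy()
    groups = table[group_col].to_numpy()
    uniq = np.unique(groups)
    y = (groups == uniq[1]).astype(int)
    test = np.flatnonzero(layers == held_out_layer)
    train = np.flatnonzero(layers != held_out_layer)
    if len(test) == 0:
        raise ValueError(f"held-out layer {held_out_layer!r} has no cells")
    fit_train = train
    if balance:
        fit_train = balance_upsample(table, train, seed=seed, group_col=group_col)
    auroc = _fit_one(M[fit_train], y[fit_train], M[test], y[test], C, seed)
    return PredictionResult(
        auroc=auroc,
        fold_aurocs=[auroc],
        n_train={str(g): int((groups[train] == g).sum()) for g in uniq},
        n_test={str(g): int((groups[test] == g).sum()) for g in uniq},
    )
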