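"""Conditional-inference random-forest screening of fatigue-change predictors.

The screening step grows many small forests of conditional-inference
trees (split variables chosen by association-test p-values, which avoids
the selection bias of exhaustive-search trees toward many-valued
predictors), aggregates out-of-bag permutation importances across
forests, and flags as *potential predictors* every variable whose mean
importance exceeds a data-driven threshold: the magnitude of the most
negative mean importance, i.e. the largest excursion a no-signal variable
produced (an all-noise calibration of the cut line).

The published analysis ran 1000 forests of 500 trees; the default here is
a 50-forest x 100-tree desk scale with identical aggregation semantics,
and the full scale is one parameter away (``ForestSpec(n_forests=1000,
n_trees=500)``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._forest_kernels import (
    _fit_forest,
    _fit_single_tree,
    _permutation_importance,
    _predict_rows,
)

__all__ = [
    "ForestSpec",
    "ConditionalTree",
    "ConditionalForest",
    "ImportanceTable",
    "fit_conditional_tree",
    "fit_forest",
    "permutation_importance",
    "aggregate_and_select",
    "screen_predictors",
]


@dataclass(frozen=True)
class ForestSpec:
    """Forest-screening configuration.

    ``split_alpha`` is the per-node level of the Bonferroni-adjusted
    association test; ``mtry=None`` uses ``ceil(sqrt(p))``;
    ``response_mode`` is ``"continuous"`` (squared-error importance, the
    default: screening regresses the continuous FACIT-FS change) or
    ``"binary"`` (misclassification importance).
    """

    n_forests: int = 50
    n_trees: int = 100
    split_alpha: float = 0.05
    min_node: int = 20
    mtry: int | None = None
    response_mode: str = "continuous"
    seed: int = 0

    def validate(self) -> None:
        if self.n_forests < 1 or self.n_trees < 1:
            raise ValueError("n_forests and n_trees must be >= 1")
        if not 0.0 < self.split_alpha < 1.0:
            raise ValueError("split_alpha must be in (0, 1)")
        if self.min_node < 1:
            raise ValueError("min_node must be >= 1")
        if self.response_mode not in ("continuous", "binary"):
            raise ValueError(f"unknown response_mode {self.response_mode!r}")

    def resolved_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else int(np.ceil(np.sqrt(p)))
        return max(1, min(m, p))


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return np.ascontiguousarray(X.to_numpy(dtype=float)), list(X.columns)
    arr = np.ascontiguousarray(np.asarray(X, dtype=float))
    if arr.ndim != 2:
        raise ValueError("predictor matrix must be 2-dimensional")
    return arr, [f"x{i}" for i in range(arr.shape[1])]


class ConditionalTree:
    """One fitted conditional-inference tree (array-backed)."""

    def __init__(self, feat, thr, left, right, value, n_nodes: int):
        self.feat = feat[:n_nodes].copy()
        self.thr = thr[:n_nodes].copy()
        self.left = left[:n_nodes].copy()
        self.right = right[:n_nodes].copy()
        self.value = value[:n_nodes].copy()

    @property
    def n_nodes(self) -> int:
        return len(self.feat)

    @property
    def is_leaf_only(self) -> bool:
        return self.n_nodes == 1

    @property
    def features_used(self) -> list[int]:
        return sorted(set(int(f) for f in self.feat if f >= 0))

    @property
    def depth(self) -> int:
        def walk(node: int) -> int:
            if self.feat[node] < 0:
                return 0
            return 1 + max(walk(self.left[node]), walk(self.right[node]))
        return walk(0)

    def predict(self, X) -> np.ndarray:
        arr, _ = _as_matrix(X)
        rows = np.arange(arr.shape[0], dtype=np.int64)
        out = np.empty(arr.shape[0])
        _predict_rows(self.feat, self.thr, self.left, self.right, self.value,
                      arr, rows, out)
        return out


def fit_conditional_tree(X, y, spec: ForestSpec | None = None,
                         seed: int | None = None) -> ConditionalTree:
    """Fit a single conditional-inference tree on all rows (no bootstrap).

    Unlike forest trees, a standalone tree tests *all* predictors at each
    node when ``spec.mtry`` is unset (the conditional-inference
    convention; subsampling is for ensemble decorrelation only).  A
    constant response yields a single-leaf tree with a warning.
    """
    spec = spec or ForestSpec()
    spec.validate()
    arr, _ = _as_matrix(X)
    if spec.mtry is None:
        spec = replace(spec, mtry=arr.shape[1])
    yv = np.ascontiguousarray(np.asarray(y, dtype=float))
    if arr.shape[0] != yv.shape[0]:
        raise ValueError("X and y must have the same number of rows")
    if arr.shape[0] < 1:
        raise ValueError("need at least one row")
    max_nodes = _max_nodes(arr.shape[0], spec.min_node)
    feat = np.full(max_nodes, -1, np.int64)
    thr = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    value = np.zeros(max_nodes)
    n_nodes = _fit_single_tree(arr, yv, spec.resolved_mtry(arr.shape[1]),
                               spec.split_alpha, spec.min_node,
                               spec.seed if seed is None else seed,
                               feat, thr, left, right, value)
    if np.ptp(yv) == 0:
        warnings.warn("constant response: tree is a single leaf", stacklevel=2)
    return ConditionalTree(feat, thr, left, right, value, n_nodes)


def _max_nodes(n: int, min_node: int) -> int:
    return 4 * max(n // max(min_node, 1), 1) + 8


class ConditionalForest:
    """A bootstrap ensemble of conditional-inference trees with OOB records."""

    def __init__(self, feats, thrs, lefts, rights, values, n_nodes, inbag,
                 spec: ForestSpec):
        self._feats = feats
        self._thrs = thrs
        self._lefts = lefts
        self._rights = rights
        self._values = values
        self._n_nodes = n_nodes
        self.inbag = inbag            # (n_trees, n_train) uint8
        self.spec = spec

    @property
    def n_trees(self) -> int:
        return self._feats.shape[0]

    @property
    def oob_mask(self) -> np.ndarray:
        return self.inbag == 0

    def tree(self, t: int) -> ConditionalTree:
        return ConditionalTree(self._feats[t], self._thrs[t], self._lefts[t],
                               self._rights[t], self._values[t],
                               int(self._n_nodes[t]))

    def predict(self, X) -> np.ndarray:
        arr, _ = _as_matrix(X)
        rows = np.arange(arr.shape[0], dtype=np.int64)
        out = np.empty(arr.shape[0])
        total = np.zeros(arr.shape[0])
        for t in range(self.n_trees):
            _predict_rows(self._feats[t], self._thrs[t], self._lefts[t],
                          self._rights[t], self._values[t], arr, rows, out)
            total += out
        return total / self.n_trees

    def oob_predict(self, X) -> np.ndarray:
        """Per-row mean over the trees for which the row was out of bag
        (NaN where a row was in every bag)."""
        arr, _ = _as_matrix(X)
        n = arr.shape[0]
        if self.inbag.shape[1] != n:
            raise ValueError("X must be the training matrix for OOB prediction")
        total = np.zeros(n)
        count = np.zeros(n)
        out = np.empty(n)
        for t in range(self.n_trees):
            oob_rows = np.flatnonzero(self.inbag[t] == 0).astype(np.int64)
            if oob_rows.size == 0:
                continue
            _predict_rows(self._feats[t], self._thrs[t], self._lefts[t],
                          self._rights[t], self._values[t], arr, oob_rows,
                          out)
            total[oob_rows] += out[:oob_rows.size]
            count[oob_rows] += 1
        with np.errstate(invalid="ignore"):
            return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def fit_forest(X, y, spec: ForestSpec | None = None) -> ConditionalForest:
    """Fit one forest; each tree grows on a bootstrap sample and records
    its out-of-bag rows.  Deterministic given ``spec.seed`` (per-tree
    seeds are derived arithmetically, so any tree-level parallelism of a
    caller cannot change results)."""
    spec = spec or ForestSpec()
    spec.validate()
    arr, _ = _as_matrix(X)
    yv = np.ascontiguousarray(np.asarray(y, dtype=float))
    if arr.shape[0] != yv.shape[0]:
        raise ValueError("X and y must have the same number of rows")
    max_nodes = _max_nodes(arr.shape[0], spec.min_node)
    feats, thrs, lefts, rights, values, n_nodes, inbag = _fit_forest(
        arr, yv, spec.n_trees, spec.resolved_mtry(arr.shape[1]),
        spec.split_alpha, spec.min_node, spec.seed % 2147483647, max_nodes)
    return ConditionalForest(feats, thrs, lefts, rights, values, n_nodes,
                             inbag, spec)


def permutation_importance(forest: ConditionalForest, X, y,
                           seed: int = 0) -> np.ndarray:
    """Out-of-bag permutation importance per predictor.

    Per tree: OOB loss (squared error, or misclassification in binary
    response mode) after permuting a predictor among the OOB rows, minus
    the baseline OOB loss; averaged over all trees.  Predictors a tree
    never split on contribute exactly zero for that tree.
    """
    arr, _ = _as_matrix(X)
    yv = np.ascontiguousarray(np.asarray(y, dtype=float))
    if forest.inbag.shape[1] != arr.shape[0]:
        raise ValueError("X must be the training matrix of this forest")
    binary = 1 if forest.spec.response_mode == "binary" else 0
    return _permutation_importance(
        forest._feats, forest._thrs, forest._lefts, forest._rights,
        forest._values, forest._n_nodes, forest.inbag, arr.copy(), yv,
        seed % 2147483647, binary)


@dataclass
class ImportanceTable:
    """Aggregated importances with the selection threshold applied."""

    frame: pd.DataFrame          # importance, dispersion, rank, selected
    threshold: float
    rule: str

    @property
    def selected(self) -> list[str]:
        return list(self.frame.index[self.frame["selected"]])

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["threshold"] = self.threshold
        return out


def aggregate_and_select(importances, names: list[str],
                         rule: str = "most-negative-mean",
                         margin: float = 1.5) -> ImportanceTable:
    """Aggregate per-forest importances and apply the selection rule.

    ``importances`` is (n_forests, p).  The threshold is ``margin *
    |min(mean importance)|``: the most negative mean importance is the
    largest excursion a no-signal variable produced, and the safety
    margin compensates for the sign-asymmetry of permutation importance
    -- a variable spuriously associated with the response in the sample
    at hand earns a *positive* importance whichever the association's
    sign, so the negative excursions alone understate the spurious
    positive tail.  Predictors whose mean importance strictly exceeds
    the threshold are flagged selected.
    """
    imp = np.atleast_2d(np.asarray(importances, dtype=float))
    if imp.shape[1] != len(names):
        raise ValueError("importance matrix width != number of predictor names")
    if rule != "most-negative-mean":
        raise ValueError(f"unknown selection rule {rule!r}")
    if margin <= 0:
        raise ValueError("margin must be positive")
    mean = imp.mean(axis=0)
    disp = imp.std(axis=0, ddof=1) if imp.shape[0] > 1 else np.zeros_like(mean)
    threshold = float(margin * abs(mean.min()))
    order = np.argsort(-mean, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(names) + 1)
    frame = pd.DataFrame({
        "importance": mean,
        "dispersion": disp,
        "rank": rank,
        "selected": mean > threshold,
    }, index=pd.Index(names, name="predictor"))
    return ImportanceTable(frame.sort_values("rank"), threshold, rule)


def screen_predictors(X, y, spec: ForestSpec | None = None) -> ImportanceTable:
    """Grow ``n_forests`` forests, aggregate their permutation importances
    and flag the potential predictors.  Forest seeds derive from
    ``spec.seed`` through a SeedSequence, one stream per forest."""
    spec = spec or ForestSpec()
    spec.validate()
    arr, names = _as_matrix(X)
    seeds = np.random.SeedSequence(spec.seed & 0x7FFFFFFF).generate_state(
        2 * spec.n_forests) % 2147483647
    rows = []
    for f in range(spec.n_forests):
        forest = fit_forest(arr, y, replace(spec, seed=int(seeds[2 * f])))
        rows.append(permutation_importance(forest, arr, y,
                                           seed=int(seeds[2 * f + 1])))
    return aggregate_and_select(np.vstack(rows), names)
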