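"""Random survival forest with log-rank splitting and ensemble mortality.

Each tree is grown on a bootstrap sample (with replacement, same n).  At every
node, ``max_features`` candidate features are drawn without replacement and
every midpoint between consecutive distinct observed values is scored by the
standardised two-sample log-rank statistic (hypergeometric variance); the
split with the largest statistic wins, ties broken by feature draw order and
then by the lower threshold.  Splitting stops at ``max_depth``, when a child
would fall below ``min_node_size`` in-bag samples, or when a node carries no
events (the log-rank statistic is then undefined and the node is pure).  Terminal nodes store the Nelson-Aalen cumulative hazard of their
in-bag members over the forest's event-time grid.

The prognostic score of a subject is the *ensemble mortality*: the sum over
the event-time grid of the forest-averaged cumulative hazard.  Higher
mortality means higher predicted risk.

Randomness discipline: the master seed spawns independent per-tree bootstrap
streams and per-node feature-draw streams keyed by (tree id, node id), with
features addressed by sorted name — so neither tree order nor the column
order of the input changes any result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sksurv.metrics import concordance_index_censored

from .screen import _as_frame, _unpack_survival


@dataclass
class TreeNode:
    node_id: int
    depth: int
    n_samples: int          # in-bag, counted with bootstrap multiplicity
    n_events: int
    feature: int | None = None      # index into sorted feature names
    threshold: float | None = None
    left: int | None = None
    right: int | None = None
    chf: np.ndarray | None = None   # terminal Nelson-Aalen over the grid

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class SurvivalTree:
    nodes: list[TreeNode]
    inbag_counts: np.ndarray   # per training sample bootstrap multiplicity

    def leaf_for(self, X: np.ndarray) -> np.ndarray:
        """Route rows of X to terminal node ids (no surrogate splits)."""
        out = np.zeros(X.shape[0], dtype=int)
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            nid, rows = stack.pop()
            node = self.nodes[nid]
            if node.is_leaf:
                out[rows] = nid
                continue
            go_left = X[rows, node.feature] <= node.threshold
            stack.append((node.left, rows[go_left]))
            stack.append((node.right, rows[~go_left]))
        return out

    def chf_for(self, X: np.ndarray) -> np.ndarray:
        leaves = self.leaf_for(X)
        return np.stack([self.nodes[l].chf for l in leaves])

    def mortality_for(self, X: np.ndarray) -> np.ndarray:
        return self.chf_for(X).sum(axis=1)

    @property
    def max_node_depth(self) -> int:
        return max(n.depth for n in self.nodes)


def _node_logrank_scan(xv, time, event, min_child: int):
    """Best split of one feature in one node.

    Scores every admissible prefix of the value-sorted samples with the
    standardised log-rank statistic.  Admissible: both children hold at least
    ``min_child`` samples and at least one event.  Returns
    (stat, threshold) or None.
    """
    order = np.argsort(xv, kind="stable")
    xs, ts, es = xv[order], time[order], event[order]
    m = xs.size
    tau = np.unique(ts[es == 1])
    if tau.size == 0:
        return None

    at_risk = ts[:, None] >= tau[None, :]
    ev_here = (ts[:, None] == tau[None, :]) & (es[:, None] == 1)
    N1 = np.cumsum(at_risk, axis=0)       # at-risk in left child per prefix
    D1 = np.cumsum(ev_here, axis=0)       # events in left child per prefix
    n_k = N1[-1]
    d_k = D1[-1].astype(float)

    q = np.arange(1, m)                   # prefix sizes
    ok = (xs[:-1] < xs[1:]) & (q >= min_child) & ((m - q) >= min_child)
    if not ok.any():
        return None

    qi = np.flatnonzero(ok)               # candidate prefix ends (index q-1)
    N1c = N1[qi].astype(float)
    D1c = D1[qi].astype(float)
    frac = N1c / n_k
    num = (D1c - d_k * frac).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_terms = d_k * frac * (1.0 - frac) * np.where(n_k > 1, (n_k - d_k) / np.maximum(n_k - 1, 1), 0.0)
    var = var_terms.sum(axis=1)
    valid = var > 0
    if not valid.any():
        return None
    stat = np.full(qi.size, -np.inf)
    stat[valid] = np.abs(num[valid]) / np.sqrt(var[valid])
    best = int(np.argmax(stat))           # first max -> lowest threshold
    if not np.isfinite(stat[best]):
        return None
    qbest = qi[best]
    threshold = 0.5 * (xs[qbest] + xs[qbest + 1])
    return float(stat[best]), float(threshold)


class RandomSurvivalForest(BaseEstimator):
    """Bootstrap ensemble of log-rank-split survival trees.

    Parameters follow the conventions of the survival-forest literature:
    ``n_estimators`` trees, depth limit ``max_depth`` (root at depth 0; with
    ``max_depth=0`` every tree is a single root node), ``min_node_size``
    in-bag samples per terminal node, and ``max_features`` candidate features
    per split.  Defaults are the configuration the signature model is trained
    with: 200 trees, depth 3, node size 15, mtry 6.

    Attributes (after fit)
    ----------------------
    event_times_ : ascending grid of unique training event times
    feature_names_ : sorted feature names
    trees_ : list of SurvivalTree
    oob_mortality_ : per-training-sample out-of-bag mortality (NaN if never OOB)
    oob_score_ : Harrell concordance of OOB mortality (when ``oob_score=True``)
    """

    def __init__(
        self,
        n_estimators: int = 200,
        max_depth: int = 3,
        min_node_size: int = 15,
        max_features: int = 6,
        random_state: int | None = None,
        oob_score: bool = False,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_node_size = min_node_size
        self.max_features = max_features
        self.random_state = random_state
        self.oob_score = oob_score

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        X = _as_frame(X)
        time, event = _unpack_survival(y)
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        n, p = X.shape
        if self.max_features > p:
            raise ValueError(f"max_features={self.max_features} > number of features ({p})")
        if not (1 <= self.max_features):
            raise ValueError("max_features must be >= 1")
        if int((event == 1).sum()) < 1:
            raise ValueError("all-censored data: no events to model")
        if n < 2 * self.min_node_size:
            raise ValueError("need at least 2 * min_node_size samples")

        self.feature_names_ = sorted(map(str, X.columns))
        self._X = X[self.feature_names_].to_numpy(dtype=float)
        self._time = time
        self._event = event
        self.event_times_ = np.unique(time[event == 1])
        seed = 0 if self.random_state is None else int(self.random_state)

        self.trees_ = [self._grow_tree(seed, t) for t in range(self.n_estimators)]

        self.oob_mortality_ = self._compute_oob_mortality()
        if self.oob_score:
            mask = ~np.isnan(self.oob_mortality_)
            self.oob_score_ = float(
                concordance_index_censored(
                    event[mask].astype(bool), time[mask], self.oob_mortality_[mask]
                )[0]
            )
        return self

    def _grow_tree(self, seed: int, tree_id: int) -> SurvivalTree:
        n = self._X.shape[0]
        rng_boot = np.random.default_rng(np.random.SeedSequence([seed, 1, tree_id]))
        idx = rng_boot.integers(0, n, size=n)
        inbag_counts = np.bincount(idx, minlength=n)

        nodes: list[TreeNode] = []

        def build(sample_idx: np.ndarray, depth: int) -> int:
            node_id = len(nodes)
            node = TreeNode(
                node_id=node_id,
                depth=depth,
                n_samples=sample_idx.size,
                n_events=int((self._event[sample_idx] == 1).sum()),
            )
            nodes.append(node)

            split = None
            if depth < self.max_depth and sample_idx.size >= 2 * self.min_node_size:
                split = self._find_split(seed, tree_id, node_id, sample_idx)
            if split is None:
                node.chf = self._nelson_aalen(sample_idx)
                return node_id
            feat, thr = split
            node.feature = feat
            node.threshold = thr
            xv = self._X[sample_idx, feat]
            node.left = build(sample_idx[xv <= thr], depth + 1)
            node.right = build(sample_idx[xv > thr], depth + 1)
            return node_id

        build(idx, 0)
        return SurvivalTree(nodes=nodes, inbag_counts=inbag_counts)

    def _find_split(self, seed, tree_id, node_id, sample_idx):
        p = len(self.feature_names_)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2, tree_id, node_id]))
        feats = rng.choice(p, size=min(self.max_features, p), replace=False)
        time = self._time[sample_idx]
        event = self._event[sample_idx]
        best = None
        for f in feats:  # draw order breaks ties
            res = _node_logrank_scan(self._X[sample_idx, f], time, event, self.min_node_size)
            if res is None:
                continue
            stat, thr = res
            if best is None or stat > best[0] + 1e-12:
                best = (stat, int(f), thr)
        if best is None:
            return None
        return best[1], best[2]

    def _nelson_aalen(self, sample_idx: np.ndarray) -> np.ndarray:
        """Nelson-Aalen cumulative hazard of in-bag members on the forest grid."""
        time = self._time[sample_idx]
        event = self._event[sample_idx]
        etimes = np.unique(time[event == 1])
        if etimes.size == 0:
            return np.zeros(self.event_times_.size)
        order = np.sort(time)
        n_at_risk = time.size - np.searchsorted(order, etimes, side="left")
        d = np.array([np.sum((time == t) & (event == 1)) for t in etimes], dtype=float)
        increments = d / n_at_risk
        cumhaz = np.cumsum(increments)
        # step-evaluate on the global event-time grid
        pos = np.searchsorted(etimes, self.event_times_, side="right")
        return np.concatenate([[0.0], cumhaz])[pos]

    # -- prediction --------------------------------------------------------

    def _check_features(self, X) -> np.ndarray:
        X = _as_frame(X)
        missing = [f for f in self.feature_names_ if f not in map(str, X.columns)]
        if missing:
            raise ValueError(f"missing features at prediction time: {missing}")
        return X[self.feature_names_].to_numpy(dtype=float)

    def predict_cumulative_hazard(self, X) -> np.ndarray:
        """Ensemble cumulative hazard, shape (n_samples, len(event_times_))."""
        arr = self._check_features(X)
        chf = np.zeros((arr.shape[0], self.event_times_.size))
        for tree in self.trees_:
            chf += tree.chf_for(arr)
        return chf / len(self.trees_)

    def predict(self, X) -> np.ndarray:
        """Ensemble mortality (prognostic score): higher = higher risk."""
        return self.predict_cumulative_hazard(X).sum(axis=1)

    def _compute_oob_mortality(self) -> np.ndarray:
        n = self._X.shape[0]
        total = np.zeros(n)
        count = np.zeros(n)
        for tree in self.trees_:
            oob = np.flatnonzero(tree.inbag_counts == 0)
            if oob.size == 0:
                continue
            total[oob] += tree.mortality_for(self._X[oob])
            count[oob] += 1
        with np.errstate(invalid="ignore"):
            out = total / count
        out[count == 0] = np.nan
        return out

    # -- serialisation -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "params": self.get_params(),
            "feature_names": self.feature_names_,
            "event_times": self.event_times_.tolist(),
            "trees": [
                {
                    "inbag_counts": tree.inbag_counts.tolist(),
                    "nodes": [
                        {
                            "node_id": nd.node_id,
                            "depth": nd.depth,
                            "n_samples": nd.n_samples,
                            "n_events": nd.n_events,
                            "feature": nd.feature,
                            "threshold": nd.threshold,
                            "left": nd.left,
                            "right": nd.right,
                            "chf": None if nd.chf is None else nd.chf.tolist(),
                        }
                        for nd in tree.nodes
                    ],
                }
                for tree in self.trees_
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, payload: str) -> "RandomSurvivalForest":
        data = json.loads(payload)
        forest = cls(**data["params"])
        forest.feature_names_ = data["feature_names"]
        forest.event_times_ = np.asarray(data["event_times"])
        forest.trees_ = [
            SurvivalTree(
                nodes=[
                    TreeNode(
                        node_id=nd["node_id"],
                        depth=nd["depth"],
                        n_samples=nd["n_samples"],
                        n_events=nd["n_events"],
                        feature=nd["feature"],
                        threshold=nd["threshold"],
                        left=nd["left"],
                        right=nd["right"],
                        chf=None if nd["chf"] is None else np.asarray(nd["chf"]),
                    )
                    for nd in tr["nodes"]
                ],
                inbag_counts=np.asarray(tr["inbag_counts"]),
            )
            for tr in data["trees"]
        ]
        return forest


def fit_rsf(features: pd.DataFrame, time, event, **params) -> RandomSurvivalForest:
    """Functional wrapper over :class:`RandomSurvivalForest`."""
    return RandomSurvivalForest(**params).fit(features, (time, event))


def predict_mortality(forest: RandomSurvivalForest, features) -> pd.Series:
    """Per-sample ensemble mortality as a Series indexed by sample id."""
    features = _as_frame(features)
    return pd.Series(forest.predict(features), index=features.index, name="mortality")


def permutation_importance(
    forest: RandomSurvivalForest,
    X,
    y,
    seed: int = 0,
    n_repeats: int = 1,
    shuffle_fn=None,
) -> pd.Series:
    """Out-of-bag permutation importance per feature.

    For every tree, the OOB prediction error (1 - Harrell concordance of the
    tree's mortality) is measured before and after permuting one feature's
    values among the OOB samples; the importance is the mean error increase
    over trees and repeats.  ``shuffle_fn(values, rng) -> values`` is a test
    hook (an identity shuffle yields importance exactly 0).
    """
    X = _as_frame(X)
    arr = X[forest.feature_names_].to_numpy(dtype=float)
    time, event = _unpack_survival(y)
    p = len(forest.feature_names_)
    totals = np.zeros(p)
    counts = np.zeros(p)

    def error(mort, t, e):
        try:
            c = concordance_index_censored(e.astype(bool), t, mort)[0]
        except Exception:
            return None
        return 1.0 - c

    for tree_id, tree in enumerate(forest.trees_):
        oob = np.flatnonzero(tree.inbag_counts == 0)
        if oob.size < 2:
            continue
        t_oob, e_oob = time[oob], event[oob]
        if (e_oob == 1).sum() == 0:
            continue
        base = error(tree.mortality_for(arr[oob]), t_oob, e_oob)
        if base is None:
            continue
        for f in range(p):
            for rep in range(n_repeats):
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(seed), 3, tree_id, f, rep])
                )
                perm = arr[oob].copy()
                if shuffle_fn is None:
                    perm[:, f] = rng.permutation(perm[:, f])
                else:
                    perm[:, f] = shuffle_fn(perm[:, f], rng)
                err = error(tree.mortality_for(perm), t_oob, e_oob)
                if err is None:
                    continue
                totals[f] += err - base
                counts[f] += 1

    with np.errstate(invalid="ignore"):
        imp = totals / counts
    imp[counts == 0] = 0.0
    return pd.Series(imp, index=forest.feature_names_, name="importance")
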