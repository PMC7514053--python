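"""Edge splitting, negative sampling, AUPR / precision@k and experiment drivers.

Known interactions are randomly partitioned 80/10/10 into train, validation
and test positives; negatives are non-edges of the *full* graph sampled per
scenario:

* ``matched``    — as many negatives as positives in each held-out set
  (the standard, optimistic protocol),
* ``ratio_1_10`` — ten test negatives per test positive (moderately
  imbalanced),
* ``all_unknown``— every unconnected pair not already used as a validation
  negative becomes a test negative (the realistic, extremely imbalanced
  protocol under which AUPR drops sharply for all methods).

Ranking quality is summarized by AUPR (step-wise average precision, ties
grouped per threshold) and precision@k with k = number of test positives.
Robustness runs rerun the standard protocol on graphs with a fraction of
edges deleted; the grid search selects hyper-parameters by validation AUPR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .graph import Graph

__all__ = [
    "EdgeSplit",
    "MetricReport",
    "split_edges",
    "aupr",
    "precision_at_k",
    "evaluate_method",
    "aggregate_reports",
    "robustness_sweep",
    "grid_search",
    "SCENARIOS",
]

SCENARIOS = ("matched", "ratio_1_10", "all_unknown")


@dataclass
class EdgeSplit:
    """Train/val/test positive edges plus per-scenario negative pairs.

    Positives partition the full edge set; negatives are non-edges of the
    full graph, with validation and test negatives disjoint.
    """

    train_edges: list[tuple[int, int]]
    val_pos: list[tuple[int, int]]
    val_neg: list[tuple[int, int]]
    test_pos: list[tuple[int, int]]
    test_neg: list[tuple[int, int]]
    scenario: str
    seed: int
    node_ids: list[str] = field(default_factory=list)

    def train_graph(self) -> Graph:
        """Graph over all nodes containing only training edges."""
        return Graph.from_edges(self.node_ids, self.train_edges)


@dataclass
class MetricReport:
    aupr: float
    precision_at_k: float
    k: int
    method: str
    seed: int
    scenario: str = ""


def _non_edges(g: Graph) -> list[tuple[int, int]]:
    edges = g.edge_set()
    return [(i, j) for i in range(g.n) for j in range(i + 1, g.n) if (i, j) not in edges]


def split_edges(
    g: Graph,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    scenario: str = "matched",
    seed: int = 0,
) -> EdgeSplit:
    """Random 80/10/10 edge partition plus scenario-specific negatives.

    Held-out set sizes are round(fraction * |E|) with the remainder going
    to train.  Negatives are drawn uniformly without replacement from the
    non-edges of the full graph; validation negatives are always matched
    in count to validation positives and excluded from the test negatives.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    edges = sorted(g.edge_set())
    m = len(edges)
    if m < 10:
        raise ValueError(f"need at least 10 edges to split, got {m}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    n_val = int(round(fractions[1] * m))
    n_test = int(round(fractions[2] * m))
    val_pos = [edges[i] for i in perm[:n_val]]
    test_pos = [edges[i] for i in perm[n_val : n_val + n_test]]
    train = [edges[i] for i in perm[n_val + n_test :]]

    non_edges = _non_edges(g)
    if scenario == "matched":
        n_test_neg = n_test
    elif scenario == "ratio_1_10":
        n_test_neg = 10 * n_test
    else:
        n_test_neg = len(non_edges) - n_val
    if n_val + n_test_neg > len(non_edges):
        raise ValueError(
            f"scenario {scenario!r} needs {n_val + n_test_neg} negatives "
            f"but only {len(non_edges)} non-edges exist"
        )
    neg_perm = rng.permutation(len(non_edges))
    val_neg = [non_edges[i] for i in neg_perm[:n_val]]
    if scenario == "all_unknown":
        used = set(val_neg)
        test_neg = [p for p in non_edges if p not in used]
    else:
        test_neg = [non_edges[i] for i in neg_perm[n_val : n_val + n_test_neg]]
    return EdgeSplit(
        train_edges=train,
        val_pos=val_pos,
        val_neg=val_neg,
        test_pos=test_pos,
        test_neg=test_neg,
        scenario=scenario,
        seed=seed,
        node_ids=list(g.node_ids),
    )


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise average precision).

    Equal scores are grouped into a single threshold, so the value is
    invariant to the input order of tied pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("AUPR undefined: need at least one positive and one negative")
    return float(average_precision_score(labels, scores))


def precision_at_k(scores, labels, k: int) -> float:
    """Fraction of positives among the k top-scoring pairs.

    The sort is stable on the caller's order, so supplying pairs in
    lexicographic order gives the documented deterministic tie-break.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not (1 <= k <= len(scores)):
        raise ValueError(f"k must be in [1, {len(scores)}], got {k}")
    order = np.argsort(-scores, kind="stable")
    return float(np.mean(labels[order[:k]]))


def _check_no_leakage(train_graph: Graph, split: EdgeSplit) -> None:
    train_edges = train_graph.edge_set()
    held_out = set(split.val_pos) | set(split.test_pos)
    leaked = train_edges & held_out
    if leaked:
        raise RuntimeError(f"leakage: held-out edges visible to scorer: {sorted(leaked)[:5]}")


def evaluate_split(method_factory, split: EdgeSplit) -> MetricReport:
    """Fit a scorer on the training graph of one split and score its test set.

    ``method_factory(seed)`` must return an object with ``fit(graph)`` and
    ``score_pairs(pairs) -> array``.  The adjacency passed to ``fit`` is
    checked to contain no held-out positive (leakage guard).
    """
    tg = split.train_graph()
    _check_no_leakage(tg, split)
    method = method_factory(split.seed)
    method.fit(tg, val_pos=split.val_pos, val_neg=split.val_neg)
    pairs = sorted(split.test_pos) + sorted(split.test_neg)
    labels = np.array([1] * len(split.test_pos) + [0] * len(split.test_neg))
    # re-sort lexicographically so tied scores break deterministically by pair
    order = np.lexsort((np.array([p[1] for p in pairs]), np.array([p[0] for p in pairs])))
    pairs = [pairs[i] for i in order]
    labels = labels[order]
    scores = np.asarray(method.score_pairs(pairs), dtype=float)
    k = len(split.test_pos)
    return MetricReport(
        aupr=aupr(scores, labels),
        precision_at_k=precision_at_k(scores, labels, k),
        k=k,
        method=getattr(method, "name", type(method).__name__),
        seed=split.seed,
        scenario=split.scenario,
    )


def evaluate_method(
    method_factory,
    g: Graph,
    scenario: str = "matched",
    seeds=(0,),
    fractions=(0.8, 0.1, 0.1),
) -> tuple[list[MetricReport], dict]:
    """Run the full protocol over several random splits and aggregate.

    Returns the per-seed reports plus a mean +/- sd summary dict.
    """
    reports = [
        evaluate_split(method_factory, split_edges(g, fractions, scenario, seed))
        for seed in seeds
    ]
    return reports, aggregate_reports(reports)


def aggregate_reports(reports: list[MetricReport]) -> dict:
    auprs = np.array([r.aupr for r in reports])
    precs = np.array([r.precision_at_k for r in reports])
    return {
        "method": reports[0].method,
        "scenario": reports[0].scenario,
        "n_seeds": len(reports),
        "aupr_mean": float(auprs.mean()),
        "aupr_sd": float(auprs.std(ddof=1)) if len(reports) > 1 else 0.0,
        "precision_at_k_mean": float(precs.mean()),
        "precision_at_k_sd": float(precs.std(ddof=1)) if len(reports) > 1 else 0.0,
    }


def remove_edges(g: Graph, fraction: float, seed: int) -> Graph:
    """Delete round(fraction * |E|) uniformly random edges (nodes kept)."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    edges = sorted(g.edge_set())
    rng = np.random.default_rng(seed)
    n_remove = int(round(fraction * len(edges)))
    keep_idx = rng.permutation(len(edges))[n_remove:]
    return Graph.from_edges(g.node_ids, [edges[i] for i in sorted(keep_idx)])


def robustness_sweep(
    g: Graph,
    removal_fractions,
    methods: dict,
    seeds=(0,),
    scenario: str = "all_unknown",
) -> pd.DataFrame:
    """Edge-removal robustness protocol.

    For each removal fraction and seed, delete that share of edges, rerun
    the standard split on the reduced graph and evaluate every method with
    all unknown pairs as negatives (co-training should be disabled in the
    supplied factories).  Empty or disconnected remainders are tolerated:
    a split that cannot be formed yields NaN metrics for that cell.
    """
    rows = []
    for frac in removal_fractions:
        for seed in seeds:
            reduced = remove_edges(g, frac, seed=seed + 1_000_003) if frac > 0 else g
            for name, factory in methods.items():
                try:
                    split = split_edges(reduced, scenario=scenario, seed=seed)
                    rep = evaluate_split(factory, split)
                    a, p = rep.aupr, rep.precision_at_k
                except (ValueError, RuntimeError):
                    a = p = float("nan")
                rows.append(
                    {"fraction": frac, "seed": seed, "method": name,
                     "aupr": a, "precision_at_k": p}
                )
    return pd.DataFrame(rows)


def grid_search(g: Graph, split: EdgeSplit, grid: dict, factory) -> tuple[dict, pd.DataFrame]:
    """Validation-AUPR grid search over a parameter lattice.

    ``grid`` maps parameter names to candidate lists; ``factory(seed,
    **point)`` builds a fit/score method.  One model is trained per lattice
    point on the split's training graph; the point with the highest
    validation AUPR wins, ties broken by lattice order.
    """
    if not grid:
        raise ValueError("empty grid")
    tg = split.train_graph()
    _check_no_leakage(tg, split)
    val_pairs = sorted(split.val_pos) + sorted(split.val_neg)
    val_labels = np.array([1] * len(split.val_pos) + [0] * len(split.val_neg))
    keys = list(grid)
    best, best_aupr, rows = None, -np.inf, []
    for values in product(*(grid[k] for k in keys)):
        point = dict(zip(keys, values))
        method = factory(split.seed, **point)
        method.fit(tg, val_pos=split.val_pos, val_neg=split.val_neg)
        scores = np.asarray(method.score_pairs(val_pairs), dtype=float)
        a = aupr(scores, val_labels)
        rows.append({**point, "val_aupr": a})
        if a > best_aupr:
            best, best_aupr = point, a
    return best, pd.DataFrame(rows)
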