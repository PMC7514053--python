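"""Uniform fit/score adapters over heuristics and the embedding models.

Every scorer exposes ``fit(graph, val_pos=None, val_neg=None)`` and
``score_pairs(pairs) -> array`` so the evaluation drivers can treat
path-count heuristics and trained auto-encoders interchangeably.  The
registry names match the method tags used in reports: ``hovgae``,
``vgae_1hop``, ``cn``, ``pa``, ``aa``, ``l3``, ``ch2_l3``.
"""

from __future__ import annotations

import numpy as np

from . import heuristics
from .graph import Graph
from .model import HOVGAEModel, TrainConfig
from .propagation import PropagationConfig

__all__ = ["HeuristicScorer", "make_method", "METHOD_NAMES"]

_HEURISTICS = {
    "cn": heuristics.common_neighbors,
    "pa": heuristics.preferential_attachment,
    "aa": heuristics.adamic_adar,
    "l3": heuristics.l3_score,
    "ch2_l3": heuristics.ch2_l3_score,
}

METHOD_NAMES = ("hovgae", "vgae_1hop", *_HEURISTICS)


class HeuristicScorer:
    """Topology heuristic behind the common fit/score interface."""

    def __init__(self, name: str):
        if name not in _HEURISTICS:
            raise ValueError(f"unknown heuristic {name!r}; valid: {sorted(_HEURISTICS)}")
        self.name = name
        self._graph: Graph | None = None

    def fit(self, g: Graph, val_pos=None, val_neg=None) -> "HeuristicScorer":
        self._graph = g
        return self

    def score_pairs(self, pairs) -> np.ndarray:
        if self._graph is None:
            raise RuntimeError("scorer not fitted")
        return _HEURISTICS[self.name](self._graph, pairs).scores()


class _NamedModel(HOVGAEModel):
    def __init__(self, cfg: TrainConfig, name: str):
        super().__init__(cfg)
        self.name = name


def make_method(name: str, seed: int = 0, **overrides):
    """Build a scorer by registry name.

    ``hovgae`` uses personalized-PageRank power propagation (alpha=0.1,
    K=10) with the default 256-128-64 encoder.  ``vgae_1hop`` is the
    plain-GCN ablation: one shared hidden layer plus the Gaussian heads,
    single-hop aggregation — the reference two-layer VGAE.  Keyword
    overrides are applied to the training config of either model.
    """
    if name in _HEURISTICS:
        return HeuristicScorer(name)
    if name == "hovgae":
        cfg = TrainConfig(seed=seed, **overrides)
        return _NamedModel(cfg, "hovgae")
    if name == "vgae_1hop":
        overrides.setdefault("layer_widths", (256, 64))
        prop = overrides.pop("propagation", PropagationConfig(mode="standard_1hop"))
        cfg = TrainConfig(seed=seed, propagation=prop, **overrides)
        return _NamedModel(cfg, "vgae_1hop")
    raise ValueError(f"unknown method {name!r}; valid: {METHOD_NAMES}")
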