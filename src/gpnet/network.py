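"""Weighted PPI network construction and descriptive statistics.

Edges come from STRING-style exports (``protein1 protein2 combined_score``,
scores in 0--1000). The adjacency is aligned to the protein order of the
expression matrix so that propagation operates on consistent indices, and the
graph Laplacian is the standard unnormalized ``L = D - W`` with ``D`` the
diagonal matrix of weighted row sums.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Edge = tuple[str, str, float]


@dataclass
class PPINetwork:
    """Symmetric weighted protein interaction network.

    Attributes
    ----------
    proteins : list of str
        Node order; identical to the paired expression matrix after alignment.
    W : ndarray of shape (p, p)
        Symmetric nonnegative edge weights in [0, 1], zero diagonal.
    """

    proteins: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        p = len(self.proteins)
        if p < 2:
            raise ValueError("network needs at least 2 proteins")
        if len(set(self.proteins)) != p:
            raise ValueError("protein symbols must be unique")
        if self.W.shape != (p, p):
            raise ValueError(f"W shape {self.W.shape} does not match {p} proteins")
        if not np.array_equal(self.W, self.W.T):
            raise ValueError("W must be exactly symmetric")
        if np.any(self.W < 0):
            raise ValueError("edge weights must be nonnegative")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W must have zero diagonal (no self-loops)")

    @property
    def n_nodes(self) -> int:
        return len(self.proteins)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.W, k=1)))

    def degree(self) -> np.ndarray:
        """Number of nonzero-weight incident edges per node."""
        return (self.W > 0).sum(axis=1)


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    density: float
    degree_by_node: dict[str, int]
    group_stats: Optional[dict] = None

    def to_json(self) -> str:
        payload = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "degrees": self.degree_by_node,
        }
        if self.group_stats is not None:
            payload["intra"] = self.group_stats["intra"]
            payload["inter"] = self.group_stats["inter"]
        return json.dumps(payload, indent=2)


def load_ppi_edges(path, score_scale: str = "raw_0_1000") -> list[Edge]:
    """Read a STRING-style TSV edge list.

    Columns are ``protein1 protein2 score`` (header optional, ``#`` comments
    skipped). Undirected duplicates keep the maximum weight; self-loops are
    dropped. ``score_scale='raw_0_1000'`` divides combined scores by 1000 so
    weights land in [0, 1]; ``'unit'`` takes scores as already in [0, 1].
    """
    if score_scale not in ("raw_0_1000", "unit"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    best: dict[tuple[str, str], float] = {}
    first_data_row = True
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 columns, got {len(fields)}")
            a, b, raw = fields[0], fields[1], fields[2]
            try:
                score = float(raw)
            except ValueError:
                if first_data_row:  # optional header row
                    first_data_row = False
                    continue
                raise ValueError(f"{path}: line {lineno}: non-numeric score {raw!r}") from None
            first_data_row = False
            if score < 0:
                raise ValueError(f"{path}: line {lineno}: negative score {score}")
            if a == b:
                continue
            w = score / 1000.0 if score_scale == "raw_0_1000" else score
            key = (a, b) if a < b else (b, a)
            if w > best.get(key, -1.0):
                best[key] = w
    return [(a, b, w) for (a, b), w in best.items()]


def build_network(
    edges: Iterable[Edge],
    protein_order: Sequence[str],
    missing_policy: str = "zero_row",
) -> PPINetwork:
    """Restrict an edge list to ``protein_order`` and build the adjacency.

    Edges with an endpoint outside the order are discarded (logged). Under
    ``zero_row`` proteins without any surviving edge keep an all-zero
    row/column, so their propagated values degenerate to the raw expression;
    under ``error`` any edgeless protein raises.
    """
    order = list(protein_order)
    index = {s: i for i, s in enumerate(order)}
    p = len(order)
    W = np.zeros((p, p))
    for a, b, w in edges:
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            logger.debug("dropping edge (%s, %s): endpoint not in protein order", a, b)
            continue
        w = max(W[ia, ib], w)
        W[ia, ib] = W[ib, ia] = w
    net = PPINetwork(order, W)
    if missing_policy == "error":
        isolated = [order[i] for i in np.flatnonzero(net.degree() == 0)]
        if isolated:
            raise ValueError(f"proteins without any PPI edge: {isolated}")
    elif missing_policy != "zero_row":
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    return net


def laplacian(net: PPINetwork) -> np.ndarray:
    """Unnormalized graph Laplacian ``L = D - W`` (D = weighted degrees)."""
    return np.diag(net.W.sum(axis=1)) - net.W


def network_stats(
    net: PPINetwork, group_of: Optional[Mapping[str, str]] = None
) -> NetworkStats:
    """Node/edge counts, density, degrees, and optional two-group edge split.

    ``group_of`` partitions nodes into two groups (e.g. up/down regulated);
    intra edges join same-group endpoints, inter edges cross groups, and the
    mean edge weight is reported for each.
    """
    p = net.n_nodes
    n_edges = net.n_edges
    density = n_edges / (p * (p - 1) / 2)
    degrees = dict(zip(net.proteins, (int(d) for d in net.degree())))
    group_stats = None
    if group_of is not None:
        missing = [s for s in net.proteins if s not in group_of]
        if missing:
            raise ValueError(f"group_of does not cover all nodes: {missing}")
        intra_w, inter_w = [], []
        iu, ju = np.triu_indices(p, k=1)
        for i, j in zip(iu, ju):
            w = net.W[i, j]
            if w > 0:
                same = group_of[net.proteins[i]] == group_of[net.proteins[j]]
                (intra_w if same else inter_w).append(w)
        group_stats = {
            "intra": {
                "count": len(intra_w),
                "mean_weight": float(np.mean(intra_w)) if intra_w else float("nan"),
            },
            "inter": {
                "count": len(inter_w),
                "mean_weight": float(np.mean(inter_w)) if inter_w else float("nan"),
            },
        }
    return NetworkStats(p, n_edges, density, degrees, group_stats)
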