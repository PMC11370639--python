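"""Synthetic cohort generator.

Emulates the statistical shape of a plasma-proteomics dementia cohort: a small
biomarker panel (default 26 proteins split into an "up" and a "down" group), a
STRING-like weighted interaction network with denser, heavier intra-group
connectivity and hub nodes, and a 3-class sample set with strongly imbalanced
class proportions (default 70/21/8% over discovery n=271 and validation n=121).

Class signal is injected through the same diffusion family the classifier
assumes: each class k shifts a small set of seed proteins by ``effect_size``
and the shift is spread over the network by the propagation operator,
``m_k = (I + mu_true L)^{-1} s_k``; samples are ``m_k + N(0, noise_sd^2)``
columns. Setting ``mu_true = 0`` gives the mismatched mode (pure mean shift,
no diffusion) used for robustness checks; ``effect_size = 0`` gives the null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .network import PPINetwork
from .propagation import PropagationOperator


@dataclass
class SimConfig:
    p: int = 26
    n_discovery: int = 271
    n_validation: int = 121
    class_names: tuple[str, ...] = ("MCI", "AD", "VD")
    # ~70/21/8% imbalance (191/58/22 of a 271-sample discovery cohort)
    class_props: tuple[float, ...] = (191 / 271, 58 / 271, 22 / 271)
    n_up: int = 9  # size of the "upregulated" block; rest are "down"
    intra_rate: float = 0.25  # within-block edge probability
    inter_rate: float = 0.235  # between-block edge probability
    target_density: float = 0.2431
    intra_weight_mean: float = 0.33
    inter_weight_mean: float = 0.25
    weight_concentration: float = 10.0  # Beta concentration for edge weights
    hub_per_block: int = 1
    hub_boost: float = 3.0  # multiplier on hub edge probabilities
    seed_proteins_per_class: int = 4
    cluster_seeds: bool = True  # seed sets are connected neighborhoods (pathway-like)
    effect_size: float = 1.0
    mu_true: float = 1.0
    noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_props) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.mu_true < 0:
            raise ValueError("mu_true must be >= 0")
        if min(self.p, self.n_discovery, self.n_validation) <= 0:
            raise ValueError("all counts must be positive")


def largest_remainder_counts(n: int, props: tuple[float, ...]) -> np.ndarray:
    """Integer class counts summing exactly to n, largest-remainder rounding."""
    raw = np.asarray(props) * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for idx in np.argsort(-remainder)[: n - counts.sum()]:
        counts[idx] += 1
    return counts


def simulate_network(cfg: SimConfig, rng: Optional[np.random.Generator] = None):
    """Two-block weighted network with hubs.

    Returns the network and a node->{'up','down'} group annotation. Edge
    probabilities follow a two-block pattern (denser within blocks), hub nodes
    get boosted connectivity, and the whole probability matrix is rescaled so
    the expected density matches ``cfg.target_density``. Edge weights are Beta
    draws with block-dependent means (heavier within blocks).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p, n_up = cfg.p, cfg.n_up
    proteins = [f"P{i+1:02d}" for i in range(p)]
    group = {s: ("up" if i < n_up else "down") for i, s in enumerate(proteins)}
    same_block = np.zeros((p, p), dtype=bool)
    same_block[:n_up, :n_up] = True
    same_block[n_up:, n_up:] = True
    prob = np.where(same_block, cfg.intra_rate, cfg.inter_rate).astype(float)
    hubs = list(range(cfg.hub_per_block)) + list(range(n_up, n_up + cfg.hub_per_block))
    for h in hubs:
        prob[h, :] *= cfg.hub_boost
        prob[:, h] *= cfg.hub_boost
    iu, ju = np.triu_indices(p, k=1)
    prob_u = np.minimum(prob[iu, ju], 1.0)
    prob_u *= cfg.target_density / prob_u.mean()
    prob_u = np.minimum(prob_u, 1.0)
    present = rng.random(prob_u.shape) < prob_u
    nu = cfg.weight_concentration
    means = np.where(same_block[iu, ju], cfg.intra_weight_mean, cfg.inter_weight_mean)
    # quantize to integer 0-1000 combined scores (STRING-style), floor at 1
    weights = rng.beta(means * nu, (1 - means) * nu)
    weights = np.maximum(np.round(weights * 1000.0), 1.0) / 1000.0
    W = np.zeros((p, p))
    W[iu[present], ju[present]] = weights[present]
    W = W + W.T
    return PPINetwork(proteins, W), group


def _bfs_module(W: np.ndarray, start: int, k: int, taken: set[int], rng) -> list[int]:
    """Breadth-first connected module of size k avoiding already-taken nodes."""
    if start in taken:
        free = [i for i in range(W.shape[0]) if i not in taken]
        start = int(rng.choice(free))
    module = [start]
    seen = set(taken) | {start}
    frontier = [start]
    while len(module) < k and frontier:
        nxt = []
        for u in frontier:
            for v in np.flatnonzero(W[u] > 0):
                v = int(v)
                if v not in seen:
                    seen.add(v)
                    module.append(v)
                    nxt.append(v)
                    if len(module) >= k:
                        return module
        frontier = nxt
    while len(module) < k:  # disconnected remainder: fill randomly
        free = [i for i in range(W.shape[0]) if i not in seen]
        v = int(rng.choice(free))
        seen.add(v)
        module.append(v)
    return module


def simulate_expression(
    net: PPINetwork, cfg: SimConfig, rng: Optional[np.random.Generator] = None
):
    """Discovery and validation expression + labels from the diffusion model.

    Returns ``(X_disc, y_disc, X_val, y_val, truth)`` where the X's are
    proteins x samples arrays, the y's are per-sample class-name lists, and
    ``truth`` records seed proteins, class mean vectors and mu_true for
    parameter-recovery tests.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    from .network import laplacian

    p = net.n_nodes
    c = len(cfg.class_names)
    if cfg.seed_proteins_per_class * c > p:
        raise ValueError("not enough proteins for disjoint per-class seed sets")
    if cfg.cluster_seeds:
        # each class perturbs a connected neighborhood (a pathway module),
        # so its shift is smooth on the graph and spreads to network neighbors
        starts = rng.choice(p, size=c, replace=False)
        taken: set[int] = set()
        seed_sets = {}
        for k in range(c):
            module = _bfs_module(net.W, int(starts[k]), cfg.seed_proteins_per_class, taken, rng)
            taken.update(module)
            seed_sets[cfg.class_names[k]] = sorted(module)
    else:
        perm = rng.permutation(p)
        seed_sets = {
            cfg.class_names[k]: sorted(
                perm[k * cfg.seed_proteins_per_class : (k + 1) * cfg.seed_proteins_per_class]
            )
            for k in range(c)
        }
    op = PropagationOperator(laplacian(net), cfg.mu_true) if cfg.mu_true > 0 else None
    means = np.zeros((p, c))
    for k, name in enumerate(cfg.class_names):
        s = np.zeros(p)
        s[seed_sets[name]] = cfg.effect_size
        means[:, k] = op.solve(s) if op is not None else s

    def draw(n_samples):
        counts = largest_remainder_counts(n_samples, cfg.class_props)
        labels = np.repeat(np.arange(c), counts)
        rng.shuffle(labels)
        X = means[:, labels] + rng.normal(0.0, cfg.noise_sd, size=(p, n_samples))
        return X, [cfg.class_names[k] for k in labels]

    X_disc, y_disc = draw(cfg.n_discovery)
    X_val, y_val = draw(cfg.n_validation)
    truth = {
        "seed_proteins": {k: [net.proteins[i] for i in v] for k, v in seed_sets.items()},
        "class_means": means,
        "mu_true": cfg.mu_true,
        "effect_size": cfg.effect_size,
        "noise_sd": cfg.noise_sd,
    }
    return X_disc, y_disc, X_val, y_val, truth


def simulate_dataset(cfg: SimConfig):
    """One-call generator: network, group annotation, both splits, truth."""
    rng = np.random.default_rng(cfg.seed)
    net, group = simulate_network(cfg, rng)
    X_disc, y_disc, X_val, y_val, truth = simulate_expression(net, cfg, rng)
    truth["groups"] = group
    return net, X_disc, y_disc, X_val, y_val, truth


def one_hot(labels: list[str], class_names) -> np.ndarray:
    Y = np.zeros((len(class_names), len(labels)))
    order = {c: k for k, c in enumerate(class_names)}
    for j, lab in enumerate(labels):
        Y[order[lab], j] = 1.0
    return Y


def write_fixture(dirpath, cfg: SimConfig) -> dict[str, Path]:
    """Write a full synthetic cohort to disk in the package's TSV formats.

    Emits expression and label TSVs for both splits, the edge list on the
    STRING 0-1000 score scale, and a truth JSON (seed proteins, mu_true).
    Byte-deterministic given ``cfg.seed``.
    """
    import pandas as pd

    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    net, X_disc, y_disc, X_val, y_val, truth = simulate_dataset(cfg)
    paths = {}

    def write_split(tag, X, y):
        samples = [f"S{tag[0].upper()}{j+1:03d}" for j in range(X.shape[1])]
        expr = pd.DataFrame(X, index=net.proteins, columns=samples)
        paths[f"expression_{tag}"] = dirpath / f"expression_{tag}.tsv"
        expr.to_csv(paths[f"expression_{tag}"], sep="\t", index_label="protein",
                    lineterminator="\n")
        lab = pd.DataFrame({"sample": samples, "class": y})
        paths[f"labels_{tag}"] = dirpath / f"labels_{tag}.tsv"
        lab.to_csv(paths[f"labels_{tag}"], sep="\t", index=False, lineterminator="\n")

    write_split("discovery", X_disc, y_disc)
    write_split("validation", X_val, y_val)

    iu, ju = np.triu_indices(net.n_nodes, k=1)
    rows = [
        (net.proteins[i], net.proteins[j], int(round(net.W[i, j] * 1000.0)))
        for i, j in zip(iu, ju)
        if net.W[i, j] > 0
    ]
    paths["edges"] = dirpath / "ppi_edges.tsv"
    with open(paths["edges"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, s in rows:
            fh.write(f"{a}\t{b}\t{s}\n")

    paths["truth"] = dirpath / "truth.json"
    with open(paths["truth"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(
            {
                "seed_proteins": truth["seed_proteins"],
                "mu_true": truth["mu_true"],
                "effect_size": truth["effect_size"],
                "noise_sd": truth["noise_sd"],
                "class_means": truth["class_means"].tolist(),
                "groups": truth["groups"],
                "class_names": list(cfg.class_names),
                "seed": cfg.seed,
            },
            fh,
            indent=2,
        )
    return paths
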