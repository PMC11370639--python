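"""Multi-class evaluation: one-vs-rest AUROC/AUPRC, per-group mean predicted
probabilities, and the (mu, theta) parameter-sweep surface.

AUROC uses the midrank (Mann-Whitney) convention, so it equals the fraction of
positive-negative pairs ranked correctly with ties counted half. AUPRC is the
step-wise (non-interpolated) precision-recall area. Both are macro-averaged
over classes; per-class values are always reported so any other average can be
recomputed downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import GPNParams, train
from .propagation import PropagationOperator


@dataclass
class MetricReport:
    auroc_per_class: dict[str, Optional[float]]
    auroc_macro: Optional[float]
    auprc_per_class: dict[str, Optional[float]]
    auprc_macro: Optional[float]
    n_per_class: dict[str, int]
    mean_prob_matrix: np.ndarray
    class_names: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "auroc_per_class": self.auroc_per_class,
                "auroc_macro": self.auroc_macro,
                "auprc_per_class": self.auprc_per_class,
                "auprc_macro": self.auprc_macro,
                "n_per_class": self.n_per_class,
                "mean_prob_matrix": self.mean_prob_matrix.tolist(),
                "class_names": self.class_names,
            },
            indent=2,
        )


def _per_class(P: np.ndarray, Y: np.ndarray, scorer) -> list[Optional[float]]:
    vals: list[Optional[float]] = []
    for k in range(Y.shape[0]):
        y = Y[k]
        if y.sum() == 0 or y.sum() == len(y):
            vals.append(None)
        else:
            vals.append(float(scorer(y, P[k])))
    return vals


def _macro(vals: Sequence[Optional[float]]) -> Optional[float]:
    defined = [v for v in vals if v is not None]
    if len(defined) < len(vals):
        warnings.warn("degenerate class without positives and negatives; macro average over defined classes only")
    return float(np.mean(defined)) if defined else None


def auroc_ovr(P: np.ndarray, Y: np.ndarray) -> tuple[list[Optional[float]], Optional[float]]:
    """One-vs-rest AUROC per class (None when degenerate) and macro average."""
    vals = _per_class(P, Y, roc_auc_score)
    return vals, _macro(vals)


def auprc_ovr(P: np.ndarray, Y: np.ndarray) -> tuple[list[Optional[float]], Optional[float]]:
    """One-vs-rest step-wise precision-recall area per class and macro average."""
    vals = _per_class(P, Y, average_precision_score)
    return vals, _macro(vals)


def mean_probability_by_group(P: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """c x c matrix: entry (i, j) is the mean predicted probability of class j
    among samples whose true class is i."""
    c = Y.shape[0]
    M = np.full((c, c), np.nan)
    for i in range(c):
        mask = Y[i] == 1
        if mask.any():
            M[i] = P[:, mask].mean(axis=1)
    return M


def metric_report(
    P: np.ndarray, Y: np.ndarray, class_names: Optional[Sequence[str]] = None
) -> MetricReport:
    names = list(class_names) if class_names is not None else [
        f"class{i}" for i in range(Y.shape[0])
    ]
    roc, roc_m = auroc_ovr(P, Y)
    prc, prc_m = auprc_ovr(P, Y)
    return MetricReport(
        auroc_per_class=dict(zip(names, roc)),
        auroc_macro=roc_m,
        auprc_per_class=dict(zip(names, prc)),
        auprc_macro=prc_m,
        n_per_class={nm: int(Y[k].sum()) for k, nm in enumerate(names)},
        mean_prob_matrix=mean_probability_by_group(P, Y),
        class_names=names,
    )


@dataclass
class SweepResult:
    """Macro-AUROC surface over the (mu, theta) grid plus marginal averages."""

    mu_grid: list[float]
    theta_grid: list[float]
    auroc_surface: np.ndarray  # len(mu) x len(theta)
    records: pd.DataFrame  # long format: mu, theta, class, auroc, auprc

    def row_averages(self) -> np.ndarray:
        """Average AUROC at each mu level (across theta)."""
        return np.nanmean(self.auroc_surface, axis=1)

    def col_averages(self) -> np.ndarray:
        """Average AUROC at each theta level (across mu)."""
        return np.nanmean(self.auroc_surface, axis=0)

    def argmax_cell(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.nanargmax(self.auroc_surface), self.auroc_surface.shape)
        return self.mu_grid[i], self.theta_grid[j]

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def parameter_sweep(
    X: np.ndarray,
    L: np.ndarray,
    Y_train: np.ndarray,
    eval_set: tuple[np.ndarray, np.ndarray],
    mu_grid: Sequence[float],
    theta_grid: Sequence[float],
    class_names: Optional[Sequence[str]] = None,
    delta: float = 1e-3,
    lr: float = 0.001,
    epochs: int = 500,
    seed: int = 0,
    tol: float = 1e-7,
) -> SweepResult:
    """Grid evaluation with mu and theta frozen per cell; only beta is trained.

    theta is realized by freezing alpha at logit(theta), with theta in {0, 1}
    handled as exact endpoints (Z = X and Z = F respectively, no logit). Each
    cell trains the classifier on the discovery split and reports one-vs-rest
    AUROC/AUPRC on the held-out split.
    """
    X_val, Y_val = eval_set
    c = Y_train.shape[0]
    p = X.shape[0]
    names = list(class_names) if class_names is not None else [f"class{i}" for i in range(c)]
    surface = np.full((len(mu_grid), len(theta_grid)), np.nan)
    rows = []
    for i, mu in enumerate(mu_grid):
        op = PropagationOperator(L, mu)
        F_tr, F_val = op.solve(X), op.solve(X_val)
        for j, theta in enumerate(theta_grid):
            Z_tr = theta * F_tr + (1 - theta) * X
            Z_val = theta * F_val + (1 - theta) * X_val
            beta = _train_beta_only(Z_tr, Y_train, delta, lr, epochs, seed, tol)
            P_val = _softmax_probs(beta, Z_val)
            roc, roc_m = auroc_ovr(P_val, Y_val)
            prc, prc_m = auprc_ovr(P_val, Y_val)
            surface[i, j] = np.nan if roc_m is None else roc_m
            for k, nm in enumerate(names):
                rows.append(
                    {"mu": mu, "theta": theta, "class": nm, "auroc": roc[k], "auprc": prc[k]}
                )
            rows.append(
                {"mu": mu, "theta": theta, "class": "macro", "auroc": roc_m, "auprc": prc_m}
            )
    return SweepResult(list(mu_grid), list(theta_grid), surface, pd.DataFrame(rows))


def _train_beta_only(Z, Y, delta, lr, epochs, seed, tol):
    """Multinomial softmax regression on a fixed combined effect Z.

    Reuses the ADAM loop with alpha and mu frozen; mu = 0 and alpha irrelevant
    because Z enters directly (identity graph would reproduce Z = X = Z here).
    """
    p, c = Z.shape[0], Y.shape[0]
    init = GPNParams(alpha=0.0, mu=0.0, beta=np.zeros((p, c)), delta=delta)
    # with mu=0 and theta fixed the forward pass reduces to softmax(beta^T Z)
    # as long as Z is handed in as the "expression"; combine(Z, Z, 0) = Z.
    state = train(
        Z, np.zeros((p, p)), Y, init, lr=lr, epochs=epochs, seed=seed, tol=tol,
        train_alpha=False, train_mu=False,
    )
    return state.params.beta


def _softmax_probs(beta, Z):
    from .model import softmax_columns

    return softmax_columns(beta.T @ Z)


def export_combined_effect(
    Z: np.ndarray, proteins: Sequence[str], samples: Sequence[str], path
) -> None:
    """Write Z as a TSV (rows = proteins, columns = sample ids) at full
    precision so external classifiers can reuse the combined effect."""
    df = pd.DataFrame(np.asarray(Z, dtype=float), index=list(proteins), columns=list(samples))
    df.to_csv(path, sep="\t", index_label="protein")
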