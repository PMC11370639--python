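"""Readers, writers, and run configuration.

All tabular files are TSV (UTF-8, Unix newlines on write, tolerant on read).
Expression files are proteins x samples with a header row of sample ids and
the protein symbol in the first column; label files map sample id to class.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Expression values, proteins x samples (the independent effect)."""

    proteins: list[str]
    samples: list[str]
    X: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.proteins, columns=self.samples)


@dataclass
class LabelMatrix:
    """One-hot class labels (c x n) with a fixed class order."""

    Y: np.ndarray
    class_names: list[str]
    samples: list[str]

    def __post_init__(self) -> None:
        if not np.all(self.Y.sum(axis=0) == 1):
            raise ValueError("every sample must belong to exactly one class")

    @property
    def labels(self) -> list[str]:
        return [self.class_names[k] for k in np.argmax(self.Y, axis=0)]


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    proteins = [str(s) for s in df.index]
    dup = pd.Index(proteins)[pd.Index(proteins).duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated protein symbols: {sorted(set(dup))}")
    values = np.empty(df.shape)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                raise ValueError(
                    f"{path}: missing value at protein {proteins[i]!r}, sample {col!r}"
                )
            try:
                values[i, j] = float(raw)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {raw!r} at protein {proteins[i]!r}, "
                    f"sample {col!r}"
                ) from None
    return ExpressionMatrix(proteins, [str(c) for c in df.columns], values)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="protein",
                           lineterminator="\n")


def read_labels(
    path, samples: Sequence[str], class_order: Optional[Sequence[str]] = None
) -> LabelMatrix:
    """One-hot labels aligned to the expression sample order.

    Class order is first appearance in the file unless ``class_order`` pins
    it. Samples missing from the label file raise; extra labeled samples are
    ignored with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns 'sample' and 'class'")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    missing = [s for s in samples if s not in mapping]
    if missing:
        raise ValueError(f"{path}: samples missing from label file: {missing}")
    extra = sorted(set(mapping) - set(samples))
    if extra:
        warnings.warn(f"{path}: ignoring {len(extra)} labeled samples absent from expression")
    ordered = [mapping[s] for s in samples]
    if class_order is None:
        classes = list(dict.fromkeys(df.iloc[:, 1]))
        classes = [c for c in classes if c in set(ordered)] or classes
    else:
        classes = list(class_order)
        unknown = sorted(set(ordered) - set(classes))
        if unknown:
            raise ValueError(f"{path}: classes outside fixed class order: {unknown}")
    Y = np.zeros((len(classes), len(samples)))
    for j, cl in enumerate(ordered):
        Y[classes.index(cl), j] = 1.0
    return LabelMatrix(Y, classes, list(samples))


def write_labels(labels: LabelMatrix, path) -> None:
    pd.DataFrame({"sample": labels.samples, "class": labels.labels}).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_probabilities(P: np.ndarray, class_names, samples, predicted, path) -> None:
    """Per-sample class probabilities (6 decimals) plus the argmax label."""
    df = pd.DataFrame(np.asarray(P).T, index=list(samples), columns=list(class_names))
    df["predicted"] = list(predicted)
    df.to_csv(path, sep="\t", index_label="sample", float_format="%.6f",
              lineterminator="\n")


@dataclass
class RunConfig:
    """Configuration for the CLI pipeline; YAML-loadable, flag-overridable."""

    expression: Optional[str] = None
    labels: Optional[str] = None
    ppi: Optional[str] = None
    outdir: str = "gpnet_out"
    delta: float = 1e-3
    lr: float = 0.001
    epochs: int = 2000
    tol: float = 1e-7
    mu_grid: tuple[float, ...] = (1e-2, 1e-1, 1.0, 1e1, 1e2)
    alpha_init: float = 0.0
    standardize: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if any(g <= 0 for g in cfg.mu_grid):
            raise ValueError("mu grid values must be > 0")
        return cfg

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def log_run(cfg: RunConfig) -> None:
    """Reproducibility log line: seed, config hash, package version."""
    from . import __version__

    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    logger.info("gpnet %s | seed=%d | config=%s", __version__, cfg.seed, cfg.digest())
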