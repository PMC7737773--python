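"""Metric suite and stratified performance analyses.

The headline metric pair is Pearson's r with RMSE in kcal/mol; rank
coefficients (Spearman, Kendall) and a sign-classification AUC complete the
panel. AUC here is the probability that a randomly chosen stabilizing record
receives a higher predicted ddG than a randomly chosen destabilizing one
(ties count half), with class labels taken from the *observed* values.

Outlier handling follows the residual definition: ``remove_outliers`` drops
the ceil(fraction * n) records with the largest absolute prediction error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import classify_sign
from .interactions import volume_class  # noqa: F401  (re-export convenience)
from .structure_io import rsa_class

__all__ = ["Metrics", "score", "remove_outliers", "stratified_report",
           "fisher_r_to_z"]

MIN_STRATUM = 5


@dataclass
class Metrics:
    pearson_r: float
    spearman_rho: float
    kendall_tau: float
    rmse: float
    mae: float
    auc: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


def _auc_rank(pred: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC via midranks; nan when a class is empty."""
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(pred)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def score(pred: Sequence[float], obs: Sequence[float]) -> Metrics:
    """Full metric panel for predicted vs observed ddG."""
    p = np.asarray(pred, float)
    o = np.asarray(obs, float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("pred and obs must be equal-length 1-D arrays")
    if len(p) < 2:
        raise ValueError("need at least 2 records")
    if np.std(p) == 0.0 or np.std(o) == 0.0:
        raise ValueError("correlation undefined: zero variance input")
    err = p - o
    positive = np.array([classify_sign(v) == "stabilizing" for v in o])
    return Metrics(
        pearson_r=float(stats.pearsonr(p, o).statistic),
        spearman_rho=float(stats.spearmanr(p, o).statistic),
        kendall_tau=float(stats.kendalltau(p, o).statistic),
        rmse=float(np.sqrt(np.mean(err ** 2))),
        mae=float(np.mean(np.abs(err))),
        auc=_auc_rank(p, positive),
        n=len(p),
    )


def remove_outliers(pred: Sequence[float], obs: Sequence[float],
                    fraction: float = 0.10) -> np.ndarray:
    """Indices retained after dropping the ceil(fraction*n) largest absolute
    residuals (ties resolved by input order: earlier records dropped first)."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    p = np.asarray(pred, float)
    o = np.asarray(obs, float)
    n = len(p)
    n_drop = math.ceil(fraction * n)
    if n_drop == 0:
        return np.arange(n)
    resid = np.abs(p - o)
    order = sorted(range(n), key=lambda i: (-resid[i], i))
    dropped = set(order[:n_drop])
    return np.array([i for i in range(n) if i not in dropped])


def stratified_report(df: pd.DataFrame) -> dict:
    """Metrics per stratum family.

    ``df`` needs columns ``pred`` and ``obs``; optional columns ``rsa``
    (fraction), ``n_residues`` (protein size) and ``volume_class`` switch on
    the corresponding stratifications. Families: sign class of the observed
    ddG; buried (RSA <= 0.30) vs exposed; small (<= 150 residues) vs large;
    volume class. Strata with fewer than 5 records are flagged insufficient.
    Within each family the strata partition the record set.
    """
    out: dict[str, dict] = {}

    def family(name: str, labels: pd.Series):
        rep = {}
        for label in sorted(labels.unique()):
            sub = df[labels == label]
            if len(sub) < MIN_STRATUM:
                rep[label] = {"n": len(sub), "status": "insufficient"}
            else:
                try:
                    rep[label] = score(sub["pred"].to_numpy(),
                                       sub["obs"].to_numpy()).as_dict()
                except ValueError as exc:
                    rep[label] = {"n": len(sub), "status": f"undefined: {exc}"}
        out[name] = rep

    family("sign", df["obs"].map(classify_sign))
    if "rsa" in df.columns:
        family("burial", df["rsa"].map(rsa_class))
    if "n_residues" in df.columns:
        family("size", df["n_residues"].map(
            lambda n: "small" if n <= 150 else "large"))
    if "volume_class" in df.columns:
        family("volume", df["volume_class"])
    return out


def fisher_r_to_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sided z test for the difference of two independent correlations."""
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))
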