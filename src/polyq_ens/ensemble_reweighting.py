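"""Ensemble reweighting: fit conformer weights to experimental shifts.

The central computation: given a pool of K conformers with predicted shift
matrix M (K x J) and J experimental shifts y, find non-negative weights w on
the probability simplex minimising

    || M^T w - y ||^2  +  l2 * ||w||^2

with sequential least squares programming (SLSQP). The weighted ensemble
then yields per-residue secondary-structure probabilities
p_S(i) = sum_k w_k * 1[ss_k(i) = S] and fit diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .conformer_model import Conformer
from .forward_shift_model import ShiftMatrix
from .shift_data import ShiftTable

__all__ = [
    "WeightVector",
    "EnsembleSummary",
    "FitError",
    "fit_weights",
    "ensemble_summary",
    "compare_variants",
]


class FitError(RuntimeError):
    """Weight fitting failed; carries the last iterate and objective."""

    def __init__(self, message: str, weights=None, objective=None):
        super().__init__(message)
        self.weights = weights
        self.objective = objective


@dataclass
class WeightVector:
    """Simplex weights over pool conformers plus solver metadata."""

    w: np.ndarray
    objective: float
    rank_deficient: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if (self.w < -1e-10).any():
            raise ValueError("weights must be non-negative")
        if abs(self.w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")

    def __len__(self) -> int:
        return len(self.w)

    @property
    def effective_size(self) -> float:
        """1 / sum(w^2): conformers meaningfully contributing."""
        return 1.0 / float(np.sum(self.w**2))


@dataclass
class EnsembleSummary:
    """Per-residue secondary-structure probabilities and fit diagnostics."""

    sequence: str
    p_h: np.ndarray
    p_e: np.ndarray
    p_c: np.ndarray
    effective_size: float
    rmsd_by_nucleus: dict[str, float] = field(default_factory=dict)
    correlation_by_nucleus: dict[str, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        total = self.p_h + self.p_e + self.p_c
        if np.abs(total - 1.0).max() > 1e-9:
            raise ValueError("per-residue probabilities must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        n = len(self.sequence)
        return pd.DataFrame(
            {
                "index": np.arange(1, n + 1),
                "aa": list(self.sequence),
                "p_H": self.p_h,
                "p_E": self.p_e,
                "p_C": self.p_c,
            }
        )


def _match(
    matrix: ShiftMatrix, exp: ShiftTable
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, str, str]]]:
    columns = matrix.column_index()
    keys = [k for k in exp.observables() if k in columns]
    if not keys:
        raise ValueError("no overlap between experimental observables and matrix")
    cols = [columns[k] for k in keys]
    sub = matrix.values[:, cols]
    y = np.array([exp.shifts[k] for k in keys])
    obs = [matrix.observables[c] for c in cols]
    return sub, y, obs


def fit_weights(
    matrix: ShiftMatrix,
    exp: ShiftTable,
    l2: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 1000,
    nucleus_variance: dict[str, float] | None = None,
) -> WeightVector:
    """SLSQP fit of simplex-constrained weights to experimental shifts.

    Observables present in both the matrix and the experimental table are
    used; ``nucleus_variance`` optionally applies per-nucleus
    inverse-variance scaling to the residuals. Deterministic for fixed
    inputs and solver settings (initialisation at uniform weights).
    """
    sub, y, obs = _match(matrix, exp)
    k, j = sub.shape
    if k < 1:
        raise ValueError("pool must contain at least one conformer")

    scale = np.ones(j)
    if nucleus_variance:
        scale = np.array(
            [1.0 / np.sqrt(nucleus_variance.get(nuc, 1.0)) for _i, _aa, nuc in obs]
        )
    a = sub * scale  # K x J
    b = y * scale

    if k == 1:
        w = np.array([1.0])
        resid = a[0] - b
        return WeightVector(
            w=w,
            objective=float(resid @ resid) + l2,
            meta={"solver": "trivial", "n_observables": j},
        )

    gram = a @ a.T + l2 * np.eye(k)
    lin = a @ b
    const = float(b @ b)

    def objective(w: np.ndarray) -> float:
        return float(w @ gram @ w - 2.0 * (lin @ w) + const)

    def gradient(w: np.ndarray) -> np.ndarray:
        return 2.0 * (gram @ w - lin)

    centered = a - a.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(a).max()))
    rank_deficient = rank < k - 1

    x0 = np.full(k, 1.0 / k)
    result = minimize(
        objective,
        x0,
        jac=gradient,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones_like(w)}],
        options={"ftol": tol, "maxiter": max_iter},
    )
    w = np.clip(result.x, 0.0, None)
    w = w / w.sum()
    obj = objective(w)
    uniform_obj = objective(x0)
    if obj > uniform_obj + 1e-9 * max(1.0, uniform_obj):
        raise FitError(
            f"SLSQP did not improve on uniform weights ({result.message})",
            weights=w,
            objective=obj,
        )
    if not result.success and result.status != 0:
        # iteration-limit exits still return the best iterate; only hard
        # failures (infeasible, bad directional derivative w/o progress) raise
        if obj > uniform_obj:
            raise FitError(
                f"SLSQP failed: {result.message}", weights=w, objective=obj
            )
    return WeightVector(
        w=w,
        objective=obj,
        rank_deficient=bool(rank_deficient),
        meta={
            "solver": "SLSQP",
            "ftol": tol,
            "maxiter": max_iter,
            "n_iter": int(result.nit),
            "n_observables": j,
            "l2": l2,
            "message": str(result.message),
        },
    )


def ensemble_summary(
    pool: list[Conformer],
    weights: WeightVector,
    exp: ShiftTable | None = None,
    matrix: ShiftMatrix | None = None,
    label: str = "",
) -> EnsembleSummary:
    """Weighted per-residue p_H/p_E/p_C plus optional fit diagnostics."""
    if len(pool) != len(weights):
        raise ValueError("pool size and weight vector length differ")
    sequence = pool[0].sequence
    n = len(sequence)
    p = {s: np.zeros(n) for s in "HEC"}
    for w_k, conf in zip(weights.w, pool):
        ss = conf.ss
        for i, state in enumerate(ss):
            p[state][i] += w_k

    rmsd: dict[str, float] = {}
    corr: dict[str, float] = {}
    if exp is not None and matrix is not None:
        sub, y, obs = _match(matrix, exp)
        fitted = weights.w @ sub
        for nucleus in sorted({nuc for _i, _aa, nuc in obs}):
            mask = np.array([nuc == nucleus for _i, _aa, nuc in obs])
            d = fitted[mask] - y[mask]
            rmsd[nucleus] = float(np.sqrt(np.mean(d**2)))
            if mask.sum() >= 2 and np.std(y[mask]) > 0 and np.std(fitted[mask]) > 0:
                corr[nucleus] = float(np.corrcoef(fitted[mask], y[mask])[0, 1])

    return EnsembleSummary(
        sequence=sequence,
        p_h=p["H"],
        p_e=p["E"],
        p_c=p["C"],
        effective_size=weights.effective_size,
        rmsd_by_nucleus=rmsd,
        correlation_by_nucleus=corr,
        label=label,
    )


def compare_variants(
    a: EnsembleSummary,
    b: EnsembleSummary,
    region: tuple[int, int],
    a_frame: np.ndarray | None = None,
    b_frame: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Signed helix-probability differences (b - a) over a shared region.

    ``a_frame``/``b_frame`` optionally give each summary's residue labels in
    the normal-polyQ (10Q) numbering; insertions (fractional labels) are
    dropped and integers aligned. Without frames the summaries must have
    equal length.
    """
    start, end = region
    if a_frame is None and b_frame is None:
        if len(a.sequence) != len(b.sequence):
            raise ValueError(
                "summaries of different lengths need explicit residue frames"
            )
        a_frame = b_frame = np.arange(1, len(a.sequence) + 1, dtype=float)
    a_frame = np.asarray(a_frame, dtype=float)
    b_frame = np.asarray(b_frame, dtype=float)

    a_map = {int(f): a.p_h[i] for i, f in enumerate(a_frame) if f == int(f)}
    b_map = {int(f): b.p_h[i] for i, f in enumerate(b_frame) if f == int(f)}
    shared = [i for i in range(start, end + 1) if i in a_map and i in b_map]
    if not shared:
        raise ValueError(f"no shared residues in region {region}")
    delta = np.array([b_map[i] - a_map[i] for i in shared])
    return delta, float(delta.mean())
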