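"""Linear network control metrics on structural connectomes.

The brain is modelled as a noise-free discrete-time linear time-invariant
system x(t+1) = A x(t) + B_k u_k(t), where A is the (normalised) structural
connectivity matrix and B_k selects the control parcel k (canonical vector).

Two per-parcel controllability statistics are computed:

* **Average controllability** — trace of the infinite-horizon controllability
  Gramian W_k = sum_t A^t B_k B_k' A'^t.  High values mark densely connected
  parcels that can steer the system to nearby, easy-to-reach states.  For a
  symmetric stable A the trace has the closed form
  ``trace(W_k) = [(I - A^2)^{-1}]_{kk}``, which is what the fast path uses.
* **Modal controllability** — phi_i = sum_j (1 - lambda_j^2) v_ij^2 from the
  eigendecomposition A = V diag(lambda) V'.  High values mark weakly
  connected parcels able to push the system into difficult-to-reach states.

Normalisation ("stabilisation") of the raw streamline matrix supports two
conventions: dividing by the mean nonzero edge weight, and dividing by
(1 + |lambda_max|).  On dense high-weight connectomes the mean-edge-weight
convention generally leaves the spectral radius far above one, in which case
infinite-horizon quantities are undefined and requesting them raises
:class:`UnstableSystemError`; the spectral convention guarantees stability
and is the default used by the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov
from scipy.stats import rankdata

from .core import Connectome, validate_connectome

STABILIZATION_MODES = ("mean_edge_weight", "spectral")


class NoEdgesError(ValueError):
    """The connectome has no edges; dynamics are undefined."""


class UnstableSystemError(ValueError):
    """Infinite-horizon quantity requested for a system with rho >= 1."""


@dataclass
class StabilizedSystem:
    """Normalised dynamics matrix A_stab = A / scale plus bookkeeping."""

    A_stab: np.ndarray
    scale: float
    spectral_radius: float
    mode: str

    @property
    def n(self) -> int:
        return self.A_stab.shape[0]

    @property
    def stable(self) -> bool:
        return self.spectral_radius < 1.0

    def _require_stable(self) -> None:
        if not self.stable:
            raise UnstableSystemError(
                f"unstable system: spectral radius {self.spectral_radius:.4g} >= 1 "
                f"under mode={self.mode!r}; use mode='spectral'")


@dataclass
class EigenSystem:
    """Eigendecomposition of a symmetric A_stab (ascending eigenvalues)."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns are orthonormal eigenvectors


@dataclass
class Gramian:
    W: np.ndarray
    control_node: int
    horizon: int | None  # None means infinite


def stabilize(C: Connectome, mode: str = "mean_edge_weight") -> StabilizedSystem:
    """Normalise the raw streamline matrix into a dynamics matrix.

    mode='mean_edge_weight' divides by the mean of the nonzero upper-triangle
    weights; mode='spectral' divides by (1 + |lambda_max|), guaranteeing a
    spectral radius below one.
    """
    if mode not in STABILIZATION_MODES:
        raise ValueError(f"unknown stabilization mode {mode!r}")
    W = C.weights
    iu = np.triu_indices(W.shape[0], k=1)
    upper = W[iu]
    nz = upper[upper > 0]
    if nz.size == 0:
        raise NoEdgesError("no edges: all-zero connectome")
    lam_abs_max = float(np.max(np.abs(np.linalg.eigvalsh(W))))
    if mode == "mean_edge_weight":
        scale = float(nz.mean())
    else:
        scale = 1.0 + lam_abs_max
    A_stab = W / scale
    rho = lam_abs_max / scale
    if mode == "mean_edge_weight" and rho >= 1.0:
        warnings.warn(
            f"mean-edge-weight stabilization leaves spectral radius "
            f"{rho:.3g} >= 1; infinite-horizon metrics will refuse to run",
            RuntimeWarning, stacklevel=2)
    return StabilizedSystem(A_stab, scale, rho, mode)


def weighted_degree(C: Connectome) -> np.ndarray:
    """Per-parcel sum of incident edge weights, on the raw matrix."""
    return C.weights.sum(axis=1)


def eigensystem(S: StabilizedSystem) -> EigenSystem:
    lam, V = np.linalg.eigh(S.A_stab)
    return EigenSystem(lam, V)


def controllability_gramian(S: StabilizedSystem, node: int,
                            horizon: int | None = None) -> Gramian:
    """Controllability Gramian for a single control parcel.

    Finite horizon T computes the exact partial sum over t = 0..T; infinite
    horizon (``horizon=None``) solves the discrete Lyapunov fixed point
    W = A W A' + B B'.
    """
    n = S.n
    if not 0 <= node < n:
        raise IndexError(f"control node {node} out of range 0..{n - 1}")
    B = np.zeros((n, 1))
    B[node, 0] = 1.0
    BBt = B @ B.T
    if horizon is None:
        S._require_stable()
        W = solve_discrete_lyapunov(S.A_stab, BBt)
    else:
        W = BBt.copy()
        M = BBt
        for _ in range(horizon):
            M = S.A_stab @ M @ S.A_stab.T
            W += M
    W = (W + W.T) / 2.0
    return Gramian(W, node, horizon)


def average_controllability(S: StabilizedSystem,
                            statistic: str = "trace") -> np.ndarray:
    """Infinite-horizon average controllability of every parcel.

    statistic='trace' (default) returns trace(W_k), computed in closed form
    as the diagonal of (I - A^2)^{-1}; statistic='trace_inverse' returns
    trace(pinv(W_k)) per node, which is much slower and numerically delicate
    for near-singular Gramians.
    """
    S._require_stable()
    A = S.A_stab
    n = S.n
    if statistic == "trace":
        return np.diag(np.linalg.inv(np.eye(n) - A @ A)).copy()
    if statistic != "trace_inverse":
        raise ValueError(f"unknown ac statistic {statistic!r}")
    warnings.warn(
        "trace_inverse average controllability uses per-node Gramian "
        "pseudo-inverses; results are sensitive to Gramian conditioning",
        RuntimeWarning, stacklevel=2)
    lam, V = np.linalg.eigh(A)
    denom = 1.0 - np.outer(lam, lam)
    out = np.empty(n)
    for k in range(n):
        c = V[k, :]
        W = V @ (np.outer(c, c) / denom) @ V.T
        out[k] = np.trace(np.linalg.pinv(W, hermitian=True))
    return out


def modal_controllability(S: StabilizedSystem) -> np.ndarray:
    """phi_i = sum_j (1 - lambda_j^2) v_ij^2 over all eigenmodes."""
    eig = eigensystem(S)
    return ((1.0 - eig.eigenvalues**2)[None, :] * eig.eigenvectors**2).sum(axis=1)


def node_metrics(C: Connectome, mode: str = "spectral",
                 ac_statistic: str = "trace") -> pd.DataFrame:
    """Per-parcel weighted degree, average and modal controllability + ranks.

    Ranks are within-subject, ascending (rank 1 = smallest), ties averaged.
    Returns a DataFrame with one row per parcel.
    """
    report = validate_connectome(C)
    if not report.passed:
        raise ValueError(f"invalid connectome: {report.failures}")
    S = stabilize(C, mode)
    wd = weighted_degree(C)
    ac = average_controllability(S, ac_statistic)
    mc = modal_controllability(S)
    df = pd.DataFrame({
        "parcel_id": np.arange(C.n),
        "label": C.parcellation.labels,
        "weighted_degree": wd,
        "average_controllability": ac,
        "modal_controllability": mc,
    })
    for col, rank_col in [("weighted_degree", "wd_rank"),
                          ("average_controllability", "ac_rank"),
                          ("modal_controllability", "mc_rank")]:
        df[rank_col] = rankdata(df[col].to_numpy(), method="average")
    return df
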