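"""Alternating heuristic baselines for multilinear discriminant analysis.

CMDA, DATER and DATEReig alternate over modes: the scatter matrices are
projected onto all modes but the one being updated (via per-observation
matricised projections), and the mode factor is replaced by the leading
singular vectors of W^{-1}B (CMDA), the leading generalised eigenvectors of
(B, W) (DATER, giving W-orthogonal factors), or the leading eigenvectors of
W^{-1}B (DATEReig).  These updates do not monotonically improve the scatter
ratio, so each fit records the scatter-ratio objective after every single-mode
update and returns the factors at the best recorded value.  DGTDA is a
deterministic single pass that maximises the scatter *difference* B - zeta*W
per mode with zeta the largest singular value of W^{-1}B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .core import (
    ProjectionModel,
    ScatterPair,
    Structure,
    TensorDataset,
    centered_decomposition,
    matricize,
    project_scatter,
    random_orthonormal,
)
from .manifold import ObjectiveSpec, _Problem

__all__ = ["HeuristicConfig", "fit_alternating", "fit_dgtda", "fit_heuristic"]

HEURISTIC_METHODS = ("cmda", "dater", "datereig", "dgtda")


@dataclass
class HeuristicConfig:
    method: str  # cmda | dater | datereig | dgtda
    K: tuple[int, int]
    max_iters: int = 5000
    tol: float = 1e-6
    seed: int = 0
    restarts: int = 3

    def __post_init__(self) -> None:
        self.method = self.method.lower()
        if self.method not in HEURISTIC_METHODS:
            raise ValueError(f"unknown heuristic {self.method!r}")
        if isinstance(self.K, int):
            self.K = (self.K, self.K)
        self.K = tuple(self.K)


#: eigenvalues of a within-scatter below ``max_eig * _EIG_FLOOR`` are lifted to
#: that floor before inversion (ridge for the rank-deficient regime)
_EIG_FLOOR = 1e-10


def _floored_eig(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, V = np.linalg.eigh((W + W.T) / 2.0)
    top = max(float(vals.max()), np.finfo(float).tiny)
    return np.maximum(vals, top * _EIG_FLOOR), V


def _ridge_solve(W: np.ndarray, B: np.ndarray) -> np.ndarray:
    """W^{-1} B for symmetric PSD W, with a spectral floor on singular W."""
    vals, V = _floored_eig(W)
    return V @ ((V.T @ B) / vals[:, None])


def _regularised(W: np.ndarray) -> np.ndarray:
    vals, V = _floored_eig(W)
    return (V * vals) @ V.T


def _update_factor(method: str, pair: ScatterPair, k: int) -> np.ndarray:
    """One mode update for cmda / dater / datereig."""
    W, B = pair.W, pair.B
    if method == "cmda":
        M = _ridge_solve(W, B)
        u, _, _ = np.linalg.svd(M)
        return u[:, :k]
    if method == "dater":
        # generalised eigenproblem B u = lambda W u; eigh returns ascending.
        # Columns are rescaled to unit Euclidean norm: W-orthogonality
        # (diagonal U'WU) is preserved while the wild per-column scaling of
        # W-orthonormal eigenvectors (v'Wv = 1) is removed, keeping later
        # mode projections well conditioned.
        _, V = scipy.linalg.eigh((B + B.T) / 2.0, _regularised(W))
        U = V[:, ::-1][:, :k]
        return U / np.linalg.norm(U, axis=0)
    # datereig: standard eigenproblem of the (nonsymmetric) W^{-1}B
    M = _ridge_solve(W, B)
    vals, V = np.linalg.eig(M)
    if np.max(np.abs(vals.imag)) > 1e-8 * max(np.max(np.abs(vals)), 1e-300):
        warnings.warn(
            "complex eigenpairs in DATEReig update; taking real parts",
            RuntimeWarning,
        )
    order = np.argsort(-np.abs(vals.real))
    U = V[:, order[:k]].real
    Q, R = np.linalg.qr(U)  # re-orthonormalise
    return Q * np.sign(np.where(np.diag(R) == 0, 1.0, np.diag(R)))


def fit_alternating(data: TensorDataset, cfg: HeuristicConfig) -> ProjectionModel:
    """Alternating CMDA / DATER / DATEReig fit, best-recorded-iterate policy.

    One trace entry = one single-mode update.  Convergence: Frobenius change
    of every mode's subspace projector below ``tol * sqrt(Jp*Kp)``, or
    ``max_iters`` updates.
    """
    if cfg.method == "dgtda":
        raise ValueError("use fit_dgtda for the single-pass method")
    j = data.dims
    k1, k2 = cfg.K
    sr_spec = ObjectiveSpec(structure=Structure.TUCKER, criterion="scatter_ratio", K=cfg.K)
    problem = _Problem(data, sr_spec)

    best_obj, best_factors, best_trace = -np.inf, None, None
    for r in range(cfg.restarts):
        rng = np.random.default_rng(cfg.seed + 104729 * r)
        U = [random_orthonormal(rng, j[0], k1), random_orthonormal(rng, j[1], k2)]
        trace: list[float] = []
        run_best_obj, run_best_U = -np.inf, [u.copy() for u in U]
        n_updates = 0
        while n_updates < cfg.max_iters:
            converged = True
            for p in (1, 2):
                model = ProjectionModel(
                    factors=U, structure=Structure.TUCKER, orthonormal=False
                )
                pair = project_scatter(data, model, exclude_mode=p)
                U_new = _update_factor(cfg.method, pair, cfg.K[p - 1])
                # subspace (projector) change: invariant to the sign/rotation
                # indeterminacy of eigen/singular-vector updates
                drift = np.linalg.norm(
                    U_new @ U_new.T - U[p - 1] @ U[p - 1].T
                )
                if drift >= cfg.tol * np.sqrt(U_new.size):
                    converged = False
                U[p - 1] = U_new
                obj = problem.value(*U, floored=True)
                trace.append(obj)
                if obj > run_best_obj:
                    run_best_obj, run_best_U = obj, [u.copy() for u in U]
                n_updates += 1
                if n_updates >= cfg.max_iters:
                    break
            if converged:
                break
        if run_best_obj > best_obj:
            best_obj, best_factors, best_trace = run_best_obj, run_best_U, trace
    assert best_factors is not None
    return ProjectionModel(
        factors=best_factors,
        structure=Structure.TUCKER,
        orthonormal=(cfg.method != "dater"),
        objective_trace=np.asarray(best_trace),
        method_tag=cfg.method.upper() if cfg.method != "datereig" else "DATEReig",
    )


def fit_dgtda(data: TensorDataset, cfg: HeuristicConfig) -> ProjectionModel:
    """Single-pass DGTDA: per mode, leading directions of B - zeta*W.

    W_(p), B_(p) are the mode-p scatter matrices of the matricised centred
    observations (no projection); zeta is the largest singular value of
    W_(p)^{-1} B_(p), which makes B - zeta*W negative semidefinite.  U^(p) is
    the top-K_p eigenbasis of that symmetric difference in descending
    algebraic eigenvalue order — the maximiser of Tr(U'(B - zeta W)U) over
    orthonormal U (magnitude-ordered singular vectors of a NSD matrix would
    select the *least* discriminative directions).  Deterministic — no
    initialisation.
    """
    within, between = centered_decomposition(data)
    factors = []
    for p in (1, 2):
        Wp = sum(matricize(D, p) @ matricize(D, p).T for D in within)
        Bp = sum(matricize(M, p) @ matricize(M, p).T for M in between)
        zeta = np.linalg.svd(_ridge_solve(Wp, Bp), compute_uv=False)[0]
        diff = Bp - zeta * Wp
        _, V = np.linalg.eigh((diff + diff.T) / 2.0)
        U = V[:, ::-1][:, : cfg.K[p - 1]]
        factors.append(U * np.sign(np.sum(U, axis=0) + (np.sum(U, axis=0) == 0)))
    sr_spec = ObjectiveSpec(structure=Structure.TUCKER, criterion="scatter_ratio", K=cfg.K)
    obj = _Problem(data, sr_spec).value(*factors, floored=True)
    return ProjectionModel(
        factors=factors,
        structure=Structure.TUCKER,
        orthonormal=True,
        objective_trace=np.asarray([obj]),
        method_tag="DGTDA",
    )


def fit_heuristic(data: TensorDataset, cfg: HeuristicConfig) -> ProjectionModel:
    """Dispatch to fit_alternating or fit_dgtda based on cfg.method."""
    if cfg.method == "dgtda":
        return fit_dgtda(data, cfg)
    return fit_alternating(data, cfg)
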