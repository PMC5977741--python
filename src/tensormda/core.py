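"""Tensor/matrix algebra primitives shared by all discriminant methods.

Observations are matrix-variate trials (e.g. EEG channels x time samples).
A single vectorisation/matricisation convention is used throughout:
``vec`` is column-major, and mode-p matricisation orders the remaining modes
ascending with the lowest mode varying fastest.  Under this convention the
Tucker-structured joint projection is ``U2 kron U1`` and
``(U2 kron U1).T @ vec(X) == vec(U1.T @ X @ U2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Structure",
    "TensorDataset",
    "ScatterPair",
    "ProjectionModel",
    "FeatureBlock",
    "DegenerateScatterError",
    "vec",
    "unvec",
    "matricize",
    "kronecker",
    "khatri_rao",
    "compute_scatter",
    "project_scatter",
    "build_structured_projection",
    "extract_features",
    "centered_decomposition",
]

#: Largest vectorised dimension J1*J2 for which the full (J1*J2)^2 scatter
#: matrices may be materialised; above this only projected forms are offered.
DENSE_SCATTER_CAP = 4096


class Structure(str, Enum):
    """Interaction structure of the joint multilinear projection."""

    TUCKER = "tucker"
    PARAFAC = "parafac"


class DegenerateScatterError(ValueError):
    """Raised when a discriminant ratio is undefined (e.g. zero within-scatter)."""


# ---------------------------------------------------------------------------
# datasets


@dataclass
class TensorDataset:
    """N labelled matrix observations sharing dimensions J1 x J2.

    Parameters
    ----------
    X : ndarray, shape (N, J1, J2)
        Trials, e.g. channels x time samples.
    y : ndarray, shape (N,)
        Integer class labels in {0, ..., C-1}.
    """

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 3:
            raise ValueError(f"X must be (N, J1, J2); got shape {self.X.shape}")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError(
                f"labels must have shape ({self.X.shape[0]},); got {self.y.shape}"
            )
        if self.X.shape[0] == 0:
            raise ValueError("dataset must contain at least one trial")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def dims(self) -> tuple[int, int]:
        return self.X.shape[1], self.X.shape[2]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    @property
    def n_classes(self) -> int:
        return self.classes.size

    @property
    def class_counts(self) -> np.ndarray:
        return np.array([np.sum(self.y == c) for c in self.classes])

    def class_means(self) -> np.ndarray:
        """Per-class mean trials, shape (C, J1, J2), ordered as ``classes``."""
        return np.stack([self.X[self.y == c].mean(axis=0) for c in self.classes])

    def global_mean(self) -> np.ndarray:
        return self.X.mean(axis=0)

    def subset(self, idx: np.ndarray) -> "TensorDataset":
        return TensorDataset(self.X[idx], self.y[idx])


@dataclass
class ScatterPair:
    """Within-class (W) and between-class (B) scatter matrices.

    ``space`` is "vectorised" (J1J2 x J1J2) or "mode_projected" (Jp x Jp, with
    ``excluded_mode`` recording the mode p that was *not* projected away).
    """

    W: np.ndarray
    B: np.ndarray
    space: str
    excluded_mode: Optional[int] = None

    def __post_init__(self) -> None:
        if self.W.shape != self.B.shape or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W and B must be square and of equal shape")


@dataclass
class ProjectionModel:
    """Per-mode factor matrices U^(p) (Jp x Kp) plus structure metadata."""

    factors: list[np.ndarray]
    structure: Structure
    orthonormal: bool = True
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    method_tag: str = ""

    def __post_init__(self) -> None:
        self.structure = Structure(self.structure)
        self.factors = [np.asarray(U, dtype=float) for U in self.factors]
        ks = [U.shape[1] for U in self.factors]
        if self.structure is Structure.PARAFAC and len(set(ks)) > 1:
            raise ValueError("parafac structure requires equal Kp in every mode")
        if self.orthonormal:
            for p, U in enumerate(self.factors):
                dev = np.max(np.abs(U.T @ U - np.eye(U.shape[1])))
                if dev > 1e-8:
                    raise ValueError(
                        f"factor {p} not orthonormal (max deviation {dev:.2e})"
                    )

    @property
    def ranks(self) -> tuple[int, ...]:
        return tuple(U.shape[1] for U in self.factors)


@dataclass
class FeatureBlock:
    """N x F feature matrix extracted from projected trials."""

    features: np.ndarray
    layout: str  # "tucker_full" (F = K1*K2) or "parafac_diag" (F = K)

    def __post_init__(self) -> None:
        if self.layout not in ("tucker_full", "parafac_diag"):
            raise ValueError(f"unknown layout {self.layout!r}")


# ---------------------------------------------------------------------------
# algebra primitives


def vec(X: np.ndarray) -> np.ndarray:
    """Column-major vectorisation."""
    return np.asarray(X).reshape(-1, order="F")


def unvec(v: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return np.asarray(v).reshape(shape, order="F")


def matricize(X: np.ndarray, mode: int) -> np.ndarray:
    """Mode-p matricisation: rows index mode ``mode`` (1-based).

    The remaining modes index columns in ascending mode order with the lowest
    mode varying fastest (consistent with column-major ``vec``).  For a matrix
    this gives ``matricize(X, 1) == X`` and ``matricize(X, 2) == X.T``.
    """
    X = np.asarray(X)
    if not 1 <= mode <= X.ndim:
        raise ValueError(f"mode must be in 1..{X.ndim}; got {mode}")
    return np.moveaxis(X, mode - 1, 0).reshape(X.shape[mode - 1], -1, order="F")


def kronecker(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Kronecker product (thin wrapper, kept for a uniform surface)."""
    return np.kron(np.asarray(A), np.asarray(B))


def khatri_rao(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product of A (m x K) and B (r x K) -> (mr x K)."""
    A = np.asarray(A)
    B = np.asarray(B)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError(
            f"khatri_rao requires equal column counts; got {A.shape} and {B.shape}"
        )
    # column k = kron(A[:, k], B[:, k])
    return (A[:, None, :] * B[None, :, :]).reshape(A.shape[0] * B.shape[0], A.shape[1])


# ---------------------------------------------------------------------------
# scatter computation


def _require_multiclass(data: TensorDataset) -> None:
    if data.n_classes < 2:
        raise DegenerateScatterError(
            "between-class scatter undefined: dataset contains a single class"
        )


def centered_decomposition(data: TensorDataset) -> tuple[np.ndarray, np.ndarray]:
    """Within/between deviation stacks used by every scatter-based objective.

    Returns
    -------
    within : ndarray, shape (N, J1, J2)
        ``X_n - Xbar_c`` for each trial.
    between : ndarray, shape (C, J1, J2)
        ``sqrt(N_c) * (Xbar_c - Xbar)`` per class, so that both scatter
        matrices are plain sums of outer products of the stacks.
    """
    _require_multiclass(data)
    gmean = data.global_mean()
    cmeans = data.class_means()
    within = np.empty_like(data.X)
    for i, c in enumerate(data.classes):
        mask = data.y == c
        within[mask] = data.X[mask] - cmeans[i]
    counts = data.class_counts.astype(float)
    between = np.sqrt(counts)[:, None, None] * (cmeans - gmean)
    return within, between


def compute_scatter(
    data: TensorDataset, dense_cap: int = DENSE_SCATTER_CAP
) -> ScatterPair:
    """Within- and between-class scatter of the vectorised trials.

    W = sum_c sum_{n in c} vec(X_n - Xbar_c) vec(.)'
    B = sum_c N_c vec(Xbar_c - Xbar) vec(.)'

    Accumulated streaming (rank-1 per trial); refuses to materialise the
    (J1*J2)^2 matrices above ``dense_cap``.
    """
    j1, j2 = data.dims
    d = j1 * j2
    if d > dense_cap:
        raise ValueError(
            f"vectorised scatter would be {d}x{d} (> cap {dense_cap}); "
            "use project_scatter instead"
        )
    within, between = centered_decomposition(data)
    W = np.zeros((d, d))
    for Dn in within:
        v = vec(Dn)
        W += np.outer(v, v)
    B = np.zeros((d, d))
    for Mc in between:
        v = vec(Mc)
        B += np.outer(v, v)
    return ScatterPair(W=W, B=B, space="vectorised")


def _mode_project(stack: np.ndarray, other_factor: np.ndarray, mode: int) -> np.ndarray:
    """sum_m A_m U U' A_m' where A_m is the mode-``mode`` matricisation."""
    if mode == 1:
        T = stack @ other_factor  # (M, J1, K)
        return np.einsum("mik,mjk->ij", T, T)
    T = np.einsum("mij,ik->mjk", stack, other_factor)  # (M, J2, K)
    return np.einsum("mik,mjk->ij", T, T)


def project_scatter(
    data: TensorDataset, model: ProjectionModel, exclude_mode: int
) -> ScatterPair:
    """Mode-projected scatter pair (W_proj, B_proj) of size Jp x Jp.

    Projects the scatter onto all modes except ``exclude_mode`` using the
    current factors, working per observation so the full vectorised scatter is
    never formed.
    """
    if exclude_mode not in (1, 2):
        raise ValueError("exclude_mode must be 1 or 2 for matrix observations")
    other = model.factors[1] if exclude_mode == 1 else model.factors[0]
    if other is None:
        raise ValueError(f"factor for mode {3 - exclude_mode} is missing")
    within, between = centered_decomposition(data)
    W = _mode_project(within, other, exclude_mode)
    B = _mode_project(between, other, exclude_mode)
    return ScatterPair(W=W, B=B, space="mode_projected", excluded_mode=exclude_mode)


# ---------------------------------------------------------------------------
# structured projections and features


def build_structured_projection(model: ProjectionModel) -> np.ndarray:
    """Joint projection matrix U_s on the vectorised space.

    Tucker: U2 kron U1 (J1J2 x K1K2); PARAFAC: U2 khatri-rao U1 (J1J2 x K).
    Consistent with column-major ``vec`` so that ``U_s.T @ vec(X)`` equals
    ``vec(U1.T X U2)`` (Tucker) or ``diag(U1.T X U2)`` (PARAFAC).
    """
    U1, U2 = model.factors
    if model.structure is Structure.TUCKER:
        return kronecker(U2, U1)
    if U1.shape[1] != U2.shape[1]:
        raise ValueError("parafac projection requires K1 == K2")
    return khatri_rao(U2, U1)


def project_trials(stack: np.ndarray, U1: np.ndarray, U2: np.ndarray) -> np.ndarray:
    """Batch core projection: (M, J1, J2) -> (M, K1, K2) via U1' X U2."""
    return np.einsum("ik,mij,jl->mkl", U1, stack, U2, optimize=True)


def extract_features(data: TensorDataset, model: ProjectionModel) -> FeatureBlock:
    """Project every trial; Tucker keeps the full core, PARAFAC its diagonal.

    Tucker row n = vec(U1' X_n U2) (column-major); PARAFAC row n =
    diag(U1' X_n U2).
    """
    U1, U2 = model.factors
    j1, j2 = data.dims
    if U1.shape[0] != j1 or U2.shape[0] != j2:
        raise ValueError(
            f"factor shapes {U1.shape}, {U2.shape} do not match trial dims {(j1, j2)}"
        )
    cores = project_trials(data.X, U1, U2)
    if model.structure is Structure.TUCKER:
        feats = vec_batch(cores)
        return FeatureBlock(features=feats, layout="tucker_full")
    diag = np.einsum("mkk->mk", cores)
    return FeatureBlock(features=np.ascontiguousarray(diag), layout="parafac_diag")


def vec_batch(cores: np.ndarray) -> np.ndarray:
    """Column-major vec applied to each matrix in an (M, K1, K2) stack."""
    m = cores.shape[0]
    return cores.transpose(0, 2, 1).reshape(m, -1)


def random_orthonormal(
    rng: np.random.Generator, rows: int, cols: int
) -> np.ndarray:
    """Haar-ish random Stiefel point via QR with positive R diagonal."""
    if cols > rows:
        raise ValueError(f"cannot build {rows}x{cols} orthonormal matrix")
    Q, R = np.linalg.qr(rng.standard_normal((rows, cols)))
    return Q * np.sign(np.where(np.diag(R) == 0, 1.0, np.diag(R)))


def check_binary_labels(y: np.ndarray) -> None:
    labels = np.unique(y)
    if not np.array_equal(labels, [0, 1]):
        raise ValueError(f"binary labels coded {{0,1}} required; found {labels}")
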