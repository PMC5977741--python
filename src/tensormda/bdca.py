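"""Bilinear discriminant component analysis: logistic regression whose linear
predictor acts directly on matrix-variate trials.

BDCA (PARAFAC form) scores a trial X by w0 + Tr(U1' X U2); the Tucker variant
scores by w0 + sum_{k1,k2} [U1' X U2]_{k1,k2} V_{k1,k2} with the diagonal of
the interaction matrix V pinned to 1 to remove scaling ambiguity between V and
the factors.  There are no orthogonality constraints on U1, U2.  Maximum
likelihood is found by BFGS with analytic gradients, multiple random-normal
restarts, best final log-likelihood kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.optimize
from scipy.special import expit

from .core import Structure, TensorDataset, check_binary_labels
from .manifold import OptimizerConfig

__all__ = ["BdcaModel", "bdca_linear_predictor", "bdca_loglik", "bdca_gradient", "fit_bdca"]


@dataclass
class BdcaModel:
    U1: np.ndarray  # J1 x K1
    U2: np.ndarray  # J2 x K2
    w0: float
    structure: Structure
    V: Optional[np.ndarray] = None  # K1 x K2, tucker only; unit diagonal

    def __post_init__(self) -> None:
        self.structure = Structure(self.structure)
        self.U1 = np.asarray(self.U1, dtype=float)
        self.U2 = np.asarray(self.U2, dtype=float)
        if self.structure is Structure.PARAFAC:
            if self.U1.shape[1] != self.U2.shape[1]:
                raise ValueError("parafac BDCA requires K1 == K2")
            self.V = None
        else:
            k1, k2 = self.U1.shape[1], self.U2.shape[1]
            if self.V is None:
                self.V = np.eye(k1, k2)
            self.V = np.asarray(self.V, dtype=float)
            if self.V.shape != (k1, k2):
                raise ValueError(f"V must be {k1}x{k2}; got {self.V.shape}")
            d = np.diagonal(self.V)
            if not np.allclose(d, 1.0):
                raise ValueError("tucker BDCA requires unit diagonal of V")

    @property
    def K(self) -> tuple[int, int]:
        return self.U1.shape[1], self.U2.shape[1]


def _cores(model: BdcaModel, X: np.ndarray) -> np.ndarray:
    """U1' X U2 for a batch (N, J1, J2) -> (N, K1, K2)."""
    return np.einsum("ik,nij,jl->nkl", model.U1, X, model.U2, optimize=True)


def bdca_linear_predictor(model: BdcaModel, X: np.ndarray) -> np.ndarray:
    """w0 + psi(X) for one trial (J1 x J2) or a batch (N, J1, J2).

    The class-1 probability is the logistic transform of this value.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    j1, j2 = model.U1.shape[0], model.U2.shape[0]
    if X.shape[1:] != (j1, j2):
        raise ValueError(f"trial shape {X.shape[1:]} does not match model {(j1, j2)}")
    cores = _cores(model, X)
    if model.structure is Structure.PARAFAC:
        psi = np.einsum("nkk->n", cores)
    else:
        psi = np.einsum("nkl,kl->n", cores, model.V)
    eta = model.w0 + psi
    return float(eta[0]) if single else eta


def predict_proba(model: BdcaModel, X: np.ndarray) -> np.ndarray:
    """Class-1 probabilities for one trial or a batch."""
    return expit(np.atleast_1d(bdca_linear_predictor(model, X)))


def bdca_loglik(model: BdcaModel, data: TensorDataset) -> float:
    """Bernoulli log-likelihood sum_n [y_n eta_n - log(1 + exp(eta_n))]."""
    check_binary_labels(data.y)
    eta = bdca_linear_predictor(model, data.X)
    return float(np.sum(data.y * eta - np.logaddexp(0.0, eta)))


def bdca_gradient(
    model: BdcaModel, data: TensorDataset
) -> dict[str, np.ndarray | float]:
    """Gradients of the log-likelihood over U1, U2, w0 and off-diagonal V."""
    check_binary_labels(data.y)
    eta = bdca_linear_predictor(model, data.X)
    r = data.y - expit(eta)  # residuals y - p, shape (N,)
    X = data.X
    if model.structure is Structure.PARAFAC:
        gU1 = np.einsum("n,nij,jk->ik", r, X, model.U2, optimize=True)
        gU2 = np.einsum("n,nij,ik->jk", r, X, model.U1, optimize=True)
        gV = None
    else:
        # d eta / d U1 = X U2 V', d eta / d U2 = X' U1 V
        gU1 = np.einsum("n,nij,jl,kl->ik", r, X, model.U2, model.V, optimize=True)
        gU2 = np.einsum("n,nij,ik,kl->jl", r, X, model.U1, model.V, optimize=True)
        cores = _cores(model, X)
        gV = np.einsum("n,nkl->kl", r, cores)
        np.fill_diagonal(gV, 0.0)  # diagonal pinned at 1
    out: dict[str, np.ndarray | float] = {"U1": gU1, "U2": gU2, "w0": float(r.sum())}
    if gV is not None:
        out["V"] = gV
    return out


# ---------------------------------------------------------------------------
# fitting


def _pack(model: BdcaModel) -> np.ndarray:
    parts = [model.U1.ravel(), model.U2.ravel(), [model.w0]]
    if model.structure is Structure.TUCKER:
        k1, k2 = model.K
        mask = ~np.eye(k1, k2, dtype=bool)
        parts.append(model.V[mask])
    return np.concatenate([np.asarray(p, dtype=float).ravel() for p in parts])


def _unpack(
    theta: np.ndarray, dims: tuple[int, int], K: tuple[int, int], structure: Structure
) -> BdcaModel:
    j1, j2 = dims
    k1, k2 = K
    i = 0
    U1 = theta[i : i + j1 * k1].reshape(j1, k1); i += j1 * k1
    U2 = theta[i : i + j2 * k2].reshape(j2, k2); i += j2 * k2
    w0 = float(theta[i]); i += 1
    V = None
    if structure is Structure.TUCKER:
        V = np.eye(k1, k2)
        mask = ~np.eye(k1, k2, dtype=bool)
        V[mask] = theta[i:]
    return BdcaModel(U1=U1, U2=U2, w0=w0, structure=structure, V=V)


def fit_bdca(
    data: TensorDataset,
    K: int | tuple[int, int],
    structure: Structure | str = Structure.PARAFAC,
    init_std: float = 0.01,
    cfg: OptimizerConfig | None = None,
) -> BdcaModel:
    """Maximum-likelihood BDCA / BDCA_Tucker fit by BFGS.

    Factors and bias start at i.i.d. N(0, init_std^2) (off-diagonal V at 0);
    ``cfg.restarts`` runs are performed and the best log-likelihood kept.  If
    the likelihood is non-finite at initialisation the fit aborts advising a
    smaller ``init_std``.
    """
    check_binary_labels(data.y)
    structure = Structure(structure)
    if isinstance(K, int):
        K = (K, K)
    if structure is Structure.PARAFAC and K[0] != K[1]:
        raise ValueError("parafac BDCA requires equal K")
    cfg = cfg or OptimizerConfig()
    j1, j2 = data.dims

    def negll_and_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        model = _unpack(theta, (j1, j2), K, structure)
        ll = bdca_loglik(model, data)
        g = bdca_gradient(model, data)
        grads = [np.asarray(g["U1"]).ravel(), np.asarray(g["U2"]).ravel(), [g["w0"]]]
        if structure is Structure.TUCKER:
            mask = ~np.eye(K[0], K[1], dtype=bool)
            grads.append(np.asarray(g["V"])[mask])
        grad = np.concatenate([np.asarray(p, dtype=float).ravel() for p in grads])
        return -ll, -grad

    best_ll, best_model = -np.inf, None
    for r in range(cfg.restarts):
        rng = np.random.default_rng(cfg.seed + 15485863 * r)
        U1 = init_std * rng.standard_normal((j1, K[0]))
        U2 = init_std * rng.standard_normal((j2, K[1]))
        w0 = init_std * rng.standard_normal()
        model0 = BdcaModel(U1=U1, U2=U2, w0=w0, structure=structure)
        theta0 = _pack(model0)
        f0, _ = negll_and_grad(theta0)
        if not np.isfinite(f0):
            raise FloatingPointError(
                "log-likelihood non-finite at initialisation; reduce init_std"
            )
        res = scipy.optimize.minimize(
            negll_and_grad,
            theta0,
            jac=True,
            method="BFGS",
            options={"maxiter": cfg.max_iters, "gtol": 1e-8},
        )
        if -res.fun > best_ll:
            best_ll = -res.fun
            best_model = _unpack(res.x, (j1, j2), K, structure)
    assert best_model is not None
    return best_model
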