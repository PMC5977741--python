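"""Classification and evaluation harness.

Features extracted by any of the discriminant methods are scored with plain
(unregularised) maximum-likelihood logistic regression, and classification
quality is summarised by the AUC — the probability that a random class-1 trial
is ranked above a random class-0 trial, with ties counted one half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .bdca import fit_bdca, predict_proba
from .core import (
    ProjectionModel,
    Structure,
    TensorDataset,
    check_binary_labels,
    compute_scatter,
    extract_features,
    random_orthonormal,
    vec,
)
from .heuristics import HeuristicConfig, fit_heuristic
from .manifold import MANIFOLD_METHODS, OptimizerConfig, fit_manifold_mda, spec_for_method

__all__ = [
    "EvalResult",
    "LogisticModel",
    "fit_logreg",
    "auc",
    "cross_validate",
    "fit_lda_baseline",
    "make_method",
    "METHOD_NAMES",
]


# ---------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticModel:
    weights: np.ndarray  # (F,)
    bias: float

    def decision(self, features: np.ndarray) -> np.ndarray:
        return features @ self.weights + self.bias

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return expit(self.decision(features))


def fit_logreg(
    features: np.ndarray,
    labels: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-12,
    norm_cap: float = 1e4,
) -> LogisticModel:
    """Unregularised maximum-likelihood logistic fit by Newton/IRLS.

    Deterministic.  Under perfect separation the ML optimum is at infinity;
    iteration stops with a warning once every trial is scored past saturation
    (|eta| > 30, probabilities within 1e-13 of 0/1) or the coefficient norm
    exceeds ``norm_cap`` — the ranking, hence AUC, is unaffected.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    check_binary_labels(labels)
    n, f = X.shape
    if n <= f:
        warnings.warn(
            f"N={n} <= F={f}: logistic fit is under-determined", RuntimeWarning
        )
    Xb = np.column_stack([X, np.ones(n)])
    w = np.zeros(f + 1)
    ll = -n * np.log(2.0)
    for _ in range(max_iter):
        eta = Xb @ w
        p = expit(eta)
        g = Xb.T @ (y - p)
        s = np.maximum(p * (1 - p), 1e-12)
        H = (Xb * s[:, None]).T @ Xb
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, g, rcond=None)[0]
        if not np.all(np.isfinite(delta)):
            delta = np.linalg.lstsq(H, g, rcond=None)[0]
        # step-halving to guarantee likelihood ascent
        step = 1.0
        for _h in range(40):
            w_new = w + step * delta
            eta_new = Xb @ w_new
            ll_new = float(np.sum(y * eta_new - np.logaddexp(0.0, eta_new)))
            if ll_new >= ll - 1e-14:
                break
            step *= 0.5
        moved = np.linalg.norm(w_new - w)
        w, ll = w_new, ll_new
        eta = Xb @ w
        separated = eta[y == 1].min() > eta[y == 0].max()
        if (separated and np.abs(eta).min() > 30.0) or np.linalg.norm(w) > norm_cap:
            warnings.warn(
                "perfect separation suspected: stopping at capped-norm solution",
                RuntimeWarning,
            )
            break
        if moved < tol * max(1.0, np.linalg.norm(w)):
            break
    return LogisticModel(weights=w[:-1], bias=float(w[-1]))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney), ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    r = rankdata(scores)
    return float((r[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# LDA baseline on vectorised trials


def fit_lda_baseline(data: TensorDataset) -> np.ndarray:
    """Fisher direction w ~ W^+ (vec(Xbar_1) - vec(Xbar_0)) on vectorised trials.

    Uses the pseudo-inverse (minimum-norm solve), so the N < J1*J2 singular
    regime runs without error.
    """
    check_binary_labels(data.y)
    pair = compute_scatter(data, dense_cap=10**9)
    means = data.class_means()
    d = vec(means[1]) - vec(means[0])
    if np.linalg.norm(d) == 0:
        raise ValueError("class means coincide: LDA direction undefined")
    w, *_ = np.linalg.lstsq(pair.W, d, rcond=None)
    return w


# ---------------------------------------------------------------------------
# method registry: name -> fit(train) -> score(test trials)


@dataclass
class FittedMethod:
    score: Callable[[TensorDataset], np.ndarray]
    train_scores: np.ndarray
    tag: str


MethodFactory = Callable[[TensorDataset, int], FittedMethod]

METHOD_NAMES = (
    list(MANIFOLD_METHODS)
    + ["CMDA", "DATER", "DATEReig", "DGTDA", "LDA", "BDCA", "BDCA_Tucker", "RandomProj"]
)


def _projection_scorer(
    model: ProjectionModel, train: TensorDataset, tag: str
) -> FittedMethod:
    feats = extract_features(train, model).features
    clf = fit_logreg(feats, train.y)
    train_scores = clf.predict_proba(feats)

    def score(test: TensorDataset) -> np.ndarray:
        return clf.predict_proba(extract_features(test, model).features)

    return FittedMethod(score=score, train_scores=train_scores, tag=tag)


def make_method(
    name: str,
    K: int | tuple[int, int] = 3,
    max_iters: int | None = None,
    restarts: int | None = None,
    init_std: float = 0.01,
) -> MethodFactory:
    """Build a fit(train_data, seed) -> FittedMethod callable for ``name``.

    Supported names: ManTDA, ManPDA, ManTDA_sr, ManPDA_sr, CMDA, DATER,
    DATEReig, DGTDA, LDA, BDCA, BDCA_Tucker, RandomProj (an unsupervised-style
    random orthonormal Tucker projection used as a floor reference).
    """

    def fit(train: TensorDataset, seed: int) -> FittedMethod:
        if name in MANIFOLD_METHODS:
            cfg = OptimizerConfig(seed=seed)
            if max_iters is not None:
                cfg.max_iters = max_iters
            if restarts is not None:
                cfg.restarts = restarts
            model = fit_manifold_mda(train, spec_for_method(name, K), cfg)
            return _projection_scorer(model, train, name)
        if name in ("CMDA", "DATER", "DATEReig", "DGTDA"):
            hcfg = HeuristicConfig(method=name.lower(), K=K, seed=seed)
            if max_iters is not None:
                hcfg.max_iters = max_iters
            if restarts is not None:
                hcfg.restarts = restarts
            model = fit_heuristic(train, hcfg)
            return _projection_scorer(model, train, name)
        if name == "RandomProj":
            rng = np.random.default_rng(seed)
            k = (K, K) if isinstance(K, int) else tuple(K)
            model = ProjectionModel(
                factors=[
                    random_orthonormal(rng, train.dims[0], k[0]),
                    random_orthonormal(rng, train.dims[1], k[1]),
                ],
                structure=Structure.TUCKER,
                method_tag="RandomProj",
            )
            return _projection_scorer(model, train, name)
        if name == "LDA":
            w = fit_lda_baseline(train)
            feats = np.array([vec(x) @ w for x in train.X])[:, None]
            clf = fit_logreg(feats, train.y)

            def score(test: TensorDataset) -> np.ndarray:
                f = np.array([vec(x) @ w for x in test.X])[:, None]
                return clf.predict_proba(f)

            return FittedMethod(
                score=score, train_scores=clf.predict_proba(feats), tag=name
            )
        if name in ("BDCA", "BDCA_Tucker"):
            structure = Structure.PARAFAC if name == "BDCA" else Structure.TUCKER
            cfg = OptimizerConfig(seed=seed)
            if max_iters is not None:
                cfg.max_iters = max_iters
            if restarts is not None:
                cfg.restarts = restarts
            model = fit_bdca(train, K=K, structure=structure, init_std=init_std, cfg=cfg)
            return FittedMethod(
                score=lambda test: predict_proba(model, test.X),
                train_scores=predict_proba(model, train.X),
                tag=name,
            )
        raise ValueError(f"unknown method {name!r}")

    return fit


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class EvalResult:
    per_fold_auc: list[float]
    mean_auc: float
    train_auc: float
    method_tag: str
    K: tuple[int, int]
    seed: int


def cross_validate(
    data: TensorDataset,
    method: MethodFactory,
    folds: int = 5,
    seed: int = 0,
    groups: Optional[np.ndarray] = None,
    K: int | tuple[int, int] = 3,
    tag: str = "",
) -> EvalResult:
    """Per-fold fit-on-train / score-on-held-out AUC.

    ``folds`` stratified folds (seeded shuffle), or leave-one-group-out when
    ``groups`` is given.  The extractor and classifier only ever see training
    folds; the train AUC is also reported for overfitting inspection.
    """
    check_binary_labels(data.y)
    idx_all = np.arange(data.n_trials)
    if groups is not None:
        groups = np.asarray(groups)
        splits = [
            (idx_all[groups != g], idx_all[groups == g]) for g in np.unique(groups)
        ]
    else:
        if folds < 2:
            raise ValueError("need at least 2 folds")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(idx_all, data.y))

    per_fold, train_aucs = [], []
    for i, (tr, te) in enumerate(splits):
        tr_y, te_y = data.y[tr], data.y[te]
        if np.unique(tr_y).size < 2 or np.unique(te_y).size < 2:
            raise ValueError(f"fold {i} is missing a class")
        fitted = method(data.subset(tr), seed + 1000 * i)
        per_fold.append(auc(fitted.score(data.subset(te)), te_y))
        train_aucs.append(auc(fitted.train_scores, tr_y))
    k = (K, K) if isinstance(K, int) else tuple(K)
    return EvalResult(
        per_fold_auc=per_fold,
        mean_auc=float(np.mean(per_fold)),
        train_auc=float(np.mean(train_aucs)),
        method_tag=tag or getattr(method, "__name__", "method"),
        K=k,
        seed=seed,
    )
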