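"""Filter-to-pattern transform and pattern bundling for model interpretation.

Discriminant projections are *filters*: they extract a source from the trials
but do not show how that source is expressed in the measurements.  Assuming
uncorrelated sources, the interpretable *pattern* is obtained by
pre-multiplying the mode covariance of the (centred) data onto the filter —
the spatial-domain convention extended here to the temporal mode as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ProjectionModel, Structure, TensorDataset, matricize

__all__ = ["PatternSet", "filter_to_pattern", "mode_covariance", "build_pattern_set"]


@dataclass
class PatternSet:
    spatial_patterns: np.ndarray  # J1 x K
    temporal_patterns: np.ndarray  # J2 x K
    logreg_coefs: Optional[np.ndarray]
    method_tag: str

    def __post_init__(self) -> None:
        if not (
            np.all(np.isfinite(self.spatial_patterns))
            and np.all(np.isfinite(self.temporal_patterns))
        ):
            raise ValueError("patterns must be finite")


def mode_covariance(data: TensorDataset, mode: int) -> np.ndarray:
    """Mode-p sample covariance of the trial-mean-centred matricised trials."""
    if mode not in (1, 2):
        raise ValueError("mode must be 1 or 2")
    centred = data.X - data.global_mean()
    d = data.dims[mode - 1]
    cov = np.zeros((d, d))
    for Xc in centred:
        M = matricize(Xc, mode)
        cov += M @ M.T
    return cov / data.n_trials


def filter_to_pattern(U: np.ndarray, data: TensorDataset, mode: int) -> np.ndarray:
    """Pattern = Sigma_p @ U, Sigma_p the mode-p data covariance.

    Raw (unnormalised): scaling the data by c scales the pattern by c^2.
    """
    U = np.asarray(U, dtype=float)
    if U.shape[0] != data.dims[mode - 1]:
        raise ValueError(
            f"filter has {U.shape[0]} rows; mode {mode} has dim {data.dims[mode - 1]}"
        )
    return mode_covariance(data, mode) @ U


def _normalise_columns(P: np.ndarray) -> np.ndarray:
    out = P.copy()
    for k in range(out.shape[1]):
        nrm = np.linalg.norm(out[:, k])
        if nrm > 0:
            out[:, k] /= nrm
        j = np.argmax(np.abs(out[:, k]))
        if out[j, k] < 0:
            out[:, k] *= -1
    return out


def build_pattern_set(
    model: ProjectionModel,
    data: TensorDataset,
    logreg_coefs: Optional[np.ndarray] = None,
) -> PatternSet:
    """Patterns for a fitted model, columns unit-normalised with fixed sign.

    Restricted to PARAFAC-structure models and one-component Tucker models:
    multi-component Tucker projections are rotationally invariant, so their
    individual columns carry no interpretable identity.
    """
    if model.structure is Structure.TUCKER and max(model.ranks) > 1:
        raise ValueError(
            "patterns are only defined for parafac models and K=1 tucker models "
            "(multi-component tucker factors are rotationally ambiguous)"
        )
    sp = _normalise_columns(filter_to_pattern(model.factors[0], data, 1))
    tp = _normalise_columns(filter_to_pattern(model.factors[1], data, 2))
    return PatternSet(
        spatial_patterns=sp,
        temporal_patterns=tp,
        logreg_coefs=None if logreg_coefs is None else np.asarray(logreg_coefs),
        method_tag=model.method_tag,
    )


def plot_pattern_set(ps: PatternSet, path: str) -> None:
    """Write a simple patterns figure (spatial bars, temporal curves) to path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = ps.spatial_patterns.shape[1]
    fig, axes = plt.subplots(2, k, figsize=(3.2 * k, 5), squeeze=False)
    for i in range(k):
        axes[0][i].bar(
            np.arange(ps.spatial_patterns.shape[0]), ps.spatial_patterns[:, i]
        )
        title = f"component {i + 1}"
        if ps.logreg_coefs is not None and i < len(ps.logreg_coefs):
            title += f"  (coef {ps.logreg_coefs[i]:+.3f})"
        axes[0][i].set_title(title, fontsize=9)
        axes[1][i].plot(ps.temporal_patterns[:, i])
    axes[0][0].set_ylabel("spatial pattern")
    axes[1][0].set_ylabel("temporal pattern")
    fig.suptitle(ps.method_tag)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
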