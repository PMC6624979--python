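"""Empirical-Bayes Gamma priors on the precision of each observed LFC.

Each observation (construct, sample) gets its own precision tau with a
Gamma(alpha, beta) prior estimated from across-replicate variability.  The
prior mean is matched to 1/var with a fixed pseudo-observation weight ``w``
(replicate-equivalents): alpha = w/2, beta = (w/2) * var.  Highly correlated
replicates produce near-zero variance estimates, so a variance floor keeps
the implied precision finite; a shrinkage mode pools each observation's
variance toward the sample-wide mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .screen_data import LFCTensor, ScreenError

__all__ = ["TauPrior", "estimate_tau_empirical", "estimate_tau_smoothed"]

DEFAULT_FLOOR_VAR = 1e-3
DEFAULT_WEIGHT = 2.0


@dataclass(frozen=True)
class TauPrior:
    """Per-(construct, sample) Gamma(shape=alpha, rate=beta) precision prior."""

    alpha: np.ndarray  # (n_constructs, n_samples)
    beta: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        if np.any(self.alpha <= 0) or np.any(self.beta <= 0):
            raise ValueError("Gamma prior parameters must be positive")

    @property
    def mean(self) -> np.ndarray:
        """Prior mean precision E[tau] = alpha / beta."""
        return self.alpha / self.beta


def _fill_missing_variances(rep_var: np.ndarray) -> np.ndarray:
    """Observations without >=2 replicates inherit the sample-wide median variance."""
    filled = rep_var.copy()
    for li in range(rep_var.shape[1]):
        col = rep_var[:, li]
        missing = np.isnan(col)
        if missing.all():
            continue
        filled[missing, li] = np.median(col[~missing])
    return filled


def _prior_from_variance(var: np.ndarray, w: float, mode: str) -> TauPrior:
    alpha = np.full_like(var, w / 2.0)
    beta = (w / 2.0) * var
    return TauPrior(alpha=alpha, beta=beta, mode=mode)


def estimate_tau_empirical(
    lfc: LFCTensor, floor_var: float = DEFAULT_FLOOR_VAR, w: float = DEFAULT_WEIGHT
) -> TauPrior:
    """Direct empirical estimate: prior mean precision 1/max(rep_var, floor_var).

    ``w`` is the pseudo-observation weight in replicate-equivalents
    (alpha = w/2, beta = w/2 * var), controlling how strongly the prior
    resists the single observed residual during inference.
    """
    rep_var = lfc.rep_var.to_numpy(dtype=float)
    if np.isnan(rep_var).all():
        if floor_var is None or floor_var <= 0:
            raise ScreenError(
                "no observation has >=2 replicates; use estimate_tau_smoothed with an "
                "explicit prior variance, or supply floor_var > 0"
            )
        warnings.warn(
            "no replicate variance available anywhere; tau prior falls back to the "
            "variance floor for every observation",
            stacklevel=2,
        )
        var = np.full_like(rep_var, floor_var)
        return _prior_from_variance(var, w, "empirical")
    var = _fill_missing_variances(rep_var)
    var = np.maximum(var, floor_var)
    return _prior_from_variance(var, w, "empirical")


def estimate_tau_smoothed(
    lfc: LFCTensor,
    shrink: float = 0.5,
    floor_var: float = DEFAULT_FLOOR_VAR,
    w: float = DEFAULT_WEIGHT,
) -> TauPrior:
    """Shrink per-observation variances toward the sample-wide mean before mapping.

    ``var* = (1 - shrink) * rep_var + shrink * mean_sample(rep_var)``; shrink=0
    reproduces the empirical estimate, shrink=1 gives every observation in a
    sample the same prior.
    """
    if not 0.0 <= shrink <= 1.0:
        raise ValueError(f"shrink must be in [0, 1], got {shrink}")
    rep_var = lfc.rep_var.to_numpy(dtype=float)
    if np.isnan(rep_var).all():
        raise ScreenError("smoothed tau estimation requires replicate variances")
    var = _fill_missing_variances(rep_var)
    sample_mean = var.mean(axis=0, keepdims=True)
    var = (1.0 - shrink) * var + shrink * sample_mean
    var = np.maximum(var, floor_var)
    return _prior_from_variance(var, w, "smoothed")
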