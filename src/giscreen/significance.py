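"""Empirical-null p-values, Benjamini-Hochberg FDR and z-scores for interaction scores.

Gene pairs involving a declared negative control (or an explicit list of known
non-interacting pairs) define the null score distribution per sample.  Tested
pairs — those with no control gene — get a right-tail p-value against that
null, BH-corrected within each (sample, score type) family; significance is
called at FDR < 0.01 by default.

Two p-value constructions are available.  The default is the Gaussian tail of
the null distribution, p = P(N(mean_null, sd_null) >= score): null sets in
these libraries hold on the order of a hundred pairs, so a counting estimate
cannot resolve p below ~1/#null, far above the FDR < 0.01 regime interaction
calls operate in.  The add-one empirical estimator
p = (1 + #{null >= score}) / (1 + #null) is exact and assumption-free and can
be selected instead when the null is large.  A z-score transform against the
same null supports rank-based cross-method comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .screen_data import ScreenDesign, pair_key

__all__ = [
    "NullSet",
    "build_null_sets",
    "empirical_pvalues",
    "gaussian_pvalues",
    "bh_fdr",
    "zscore_transform",
    "annotate_significance",
    "recurrent_hits",
]

MIN_NULL_RECOMMENDED = 20

# score_type -> (score column, eligibility column or None, direction filter on s)
_SCORE_TYPES = {
    "strong_lethality": ("strong_score", None, "neg"),
    "strong_recovery": ("strong_score", None, "pos"),
    "sensitive_lethality": ("sens_lethality", "sens_lethality_eligible", None),
    "sensitive_recovery": ("sens_recovery", "sens_recovery_eligible", None),
}


@dataclass(frozen=True)
class NullSet:
    """Null score pool for one (sample, score type)."""

    sample: str
    score_type: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.scores.size == 0:
            raise ValueError(
                f"empty null set for {self.score_type} in sample {self.sample}"
            )
        if self.scores.size < MIN_NULL_RECOMMENDED:
            warnings.warn(
                f"only {self.scores.size} null scores for {self.score_type} in "
                f"sample {self.sample}; p-values will be coarse",
                stacklevel=2,
            )


def _null_mask(table: pd.DataFrame, design: ScreenDesign) -> pd.Series:
    """Rows whose gene pair belongs to the declared null."""
    mask = table["involves_control"].copy()
    if design.nonint_pairs:
        keys = [pair_key(g, h) for g, h in zip(table["gene_g"], table["gene_h"])]
        mask |= pd.Series([k in design.nonint_pairs for k in keys], index=table.index)
    return mask


def build_null_sets(table: pd.DataFrame, design: ScreenDesign) -> dict[tuple[str, str], NullSet]:
    """Null pools per (sample, score type) from control-involving / declared pairs.

    Strong-score pools are direction-matched (null pairs with s < 0 feed the
    lethality null, s > 0 the recovery null); sensitive pools use eligible
    null pairs only.
    """
    nulls: dict[tuple[str, str], NullSet] = {}
    null_rows = table[_null_mask(table, design)]
    for sample, sub in null_rows.groupby("sample", sort=True):
        for score_type, (col, elig, direction) in _SCORE_TYPES.items():
            pool = sub
            if direction == "neg":
                pool = pool[pool["s"] < 0]
            elif direction == "pos":
                pool = pool[pool["s"] > 0]
            if elig is not None:
                pool = pool[pool[elig]]
            scores = pool[col].to_numpy(dtype=float)
            scores = scores[np.isfinite(scores)]
            if scores.size:
                nulls[(str(sample), score_type)] = NullSet(str(sample), score_type, scores)
    return nulls


def empirical_pvalues(observed: np.ndarray, null: NullSet) -> np.ndarray:
    """Add-one right-tail empirical p: (1 + #{null >= obs}) / (1 + #null).

    NaN observations (ineligible pairs) propagate as NaN.
    """
    obs = np.asarray(observed, dtype=float)
    sorted_null = np.sort(null.scores)
    n = sorted_null.size
    # count of null >= obs via position of obs in the sorted null
    ge = n - np.searchsorted(sorted_null, obs, side="left")
    p = (1.0 + ge) / (1.0 + n)
    return np.where(np.isnan(obs), np.nan, p)


def gaussian_pvalues(observed: np.ndarray, null: NullSet) -> np.ndarray:
    """Right-tail p under a normal fit to the null scores (resolves p << 1/#null).

    NaN observations (ineligible pairs) propagate as NaN.
    """
    return stats.norm.sf(zscore_transform(observed, null))


def bh_fdr(pvalues: np.ndarray, alpha: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and a significance flag at ``alpha``.

    NaN entries are excluded from the family and returned as NaN/False.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if (p[ok] < 0).any() or (p[ok] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        rej, qv, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        q[ok] = qv
        sig[ok] = qv < alpha
    return q, sig


def zscore_transform(scores: np.ndarray, null: NullSet) -> np.ndarray:
    """Standardize scores against the null pool: z = (score - mean) / sd (ddof=1)."""
    mu = float(np.mean(null.scores))
    sd = float(np.std(null.scores, ddof=1))
    if sd == 0 or null.scores.size < 2:
        raise ValueError("null set needs >=2 distinct values for a z-score")
    return (np.asarray(scores, dtype=float) - mu) / sd


def annotate_significance(
    table: pd.DataFrame,
    design: ScreenDesign,
    fdr_threshold: float = 0.01,
    p_method: str = "gaussian",
) -> pd.DataFrame:
    """Long-format results: per (gene pair, sample, score type) score, z, p, fdr.

    Null pairs (involving controls or declared non-interacting) form the null
    pools and are excluded from the tested set.  BH correction is applied
    within each (sample, score type) family.  ``p_method`` selects the null
    tail model: "gaussian" (default) or "empirical" (add-one counting).
    """
    if p_method not in ("gaussian", "empirical"):
        raise ValueError(f"p_method must be 'gaussian' or 'empirical', got {p_method!r}")
    nulls = build_null_sets(table, design)
    tested = table[~_null_mask(table, design)]
    out = []
    for (sample, score_type), null in sorted(nulls.items()):
        col, elig, direction = _SCORE_TYPES[score_type]
        sub = tested[tested["sample"] == sample]
        scores = sub[col].to_numpy(dtype=float)
        if direction == "neg":
            scores = np.where(sub["s"] < 0, scores, np.nan)
        elif direction == "pos":
            scores = np.where(sub["s"] > 0, scores, np.nan)
        try:
            z = zscore_transform(scores, null)
        except ValueError:
            z = np.full_like(scores, np.nan)
        if p_method == "gaussian" and np.isfinite(z).any():
            p = stats.norm.sf(z)
        else:
            p = empirical_pvalues(scores, null)
        q, sig = bh_fdr(p, alpha=fdr_threshold)
        out.append(
            pd.DataFrame(
                {
                    "gene_g": sub["gene_g"].to_numpy(),
                    "gene_h": sub["gene_h"].to_numpy(),
                    "sample": sample,
                    "score_type": score_type,
                    "score": scores,
                    "z": z,
                    "p": p,
                    "fdr": q,
                    "significant": sig,
                }
            )
        )
    if not out:
        raise ValueError("no null pools could be built; declare negative controls or nonint pairs")
    return pd.concat(out, ignore_index=True)


def recurrent_hits(
    results: pd.DataFrame,
    min_samples: int,
    q_thresh: float = 0.01,
    score_type: str = "sensitive_lethality",
) -> pd.DataFrame:
    """Gene pairs significant (FDR < q_thresh) in at least ``min_samples`` samples."""
    sub = results[(results["score_type"] == score_type) & (results["fdr"] < q_thresh)]
    counts = (
        sub.groupby(["gene_g", "gene_h"])["sample"].nunique().rename("n_significant_samples")
    )
    hits = counts[counts >= min_samples].reset_index()
    return hits.sort_values("n_significant_samples", ascending=False).reset_index(drop=True)
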