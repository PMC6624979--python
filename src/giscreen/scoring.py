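"""Interaction scores from posterior means of gene (y) and combination (s) effects.

Two complementary scoring systems per (gene pair, sample):

* **strong**: ``|s| - max(|y_g|, |y_h|)`` — the combination effect must dwarf
  both single-gene effects ("much more than additive").  The sign of s
  distinguishes lethality (s < 0) from recovery (s > 0).
* **sensitive lethality**: ``min(y_g, y_h) - (y_g + y_h + s)`` subject to
  ``y_g and y_h > c*lambda`` — extra dropout of the pair beyond the stronger
  single knockout, restricted to pairs where neither gene is strongly
  depleting on its own.
* **sensitive recovery**: ``(y_g + y_h + s) - min(y_g, y_h)`` subject to
  ``y_g or y_h < c*lambda`` — viability restored relative to the more lethal
  single knockout.

``c`` is the 0.01-quantile of the y values in the sample (a negative number in
any screen with depleting genes) and ``lambda = 0.5``, so the lethality
constraint drops pairs in which a gene is more than 50% as depleted as the
most depleted genes in the screen.  ``c`` may instead be anchored to positive
controls (median y of known essential genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .cavi import VariationalPosterior
from .screen_data import ScreenDesign

__all__ = [
    "ScoreConfig",
    "strong_score",
    "sensitive_lethality",
    "sensitive_recovery",
    "compute_c",
    "score_interactions",
]


@dataclass(frozen=True)
class ScoreConfig:
    lam: float = 0.5
    quantile_for_c: float = 0.01
    use_positive_controls_for_c: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile_for_c < 1.0:
            raise ValueError("quantile_for_c must be in (0, 1)")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


def strong_score(y_g, y_h, s_gh):
    """``|s| - max(|y_g|, |y_h|)``; elementwise on arrays."""
    return np.abs(s_gh) - np.maximum(np.abs(y_g), np.abs(y_h))


def sensitive_lethality(y_g, y_h, s_gh, c: float, lam: float = 0.5):
    """(score, eligible): extra pair dropout where neither gene alone is strongly depleting.

    Eligibility is the strict constraint ``y_g > c*lam and y_h > c*lam``;
    ineligible entries get a NaN score.
    """
    y_g, y_h, s_gh = np.asarray(y_g, float), np.asarray(y_h, float), np.asarray(s_gh, float)
    eligible = (y_g > c * lam) & (y_h > c * lam)
    score = np.minimum(y_g, y_h) - (y_g + y_h + s_gh)
    return np.where(eligible, score, np.nan), eligible


def sensitive_recovery(y_g, y_h, s_gh, c: float, lam: float = 0.5):
    """(score, eligible): viability restored relative to the more lethal single knockout.

    Eligibility requires at least one gene strongly depleting alone:
    ``y_g < c*lam or y_h < c*lam`` (strict).
    """
    y_g, y_h, s_gh = np.asarray(y_g, float), np.asarray(y_h, float), np.asarray(s_gh, float)
    eligible = (y_g < c * lam) | (y_h < c * lam)
    score = (y_g + y_h + s_gh) - np.minimum(y_g, y_h)
    return np.where(eligible, score, np.nan), eligible


def compute_c(
    y_means: Iterable[float],
    config: ScoreConfig = ScoreConfig(),
    positive_control_y: Iterable[float] | None = None,
) -> float:
    """Depletion anchor c for one sample.

    Default: the ``quantile_for_c`` empirical quantile (linear interpolation)
    of all fitted y means in the sample.  With
    ``use_positive_controls_for_c``, the median y of the supplied positive
    control (known essential) genes instead.
    """
    if config.use_positive_controls_for_c:
        pc = np.asarray(list(positive_control_y or []), dtype=float)
        if pc.size == 0:
            raise ValueError("positive-control mode requires a nonempty set of control y values")
        return float(np.median(pc))
    y = np.asarray(list(y_means), dtype=float)
    if y.size == 0:
        raise ValueError("no fitted y values in sample")
    return float(np.quantile(y, config.quantile_for_c))


def score_interactions(
    posterior: VariationalPosterior,
    design: ScreenDesign,
    config: ScoreConfig = ScoreConfig(),
    positive_control_genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Interaction table: one row per (gene pair, sample).

    Columns: gene_g, gene_h, sample, y_g, y_h, s, c, strong_score, direction
    (lethality/recovery by the sign of s), sens_lethality(+eligible),
    sens_recovery(+eligible), same_gene, involves_control.
    """
    genes = posterior.idx.genes
    pairs = posterior.idx.pairs
    gene_pos = {g: i for i, g in enumerate(genes)}
    gi = np.array([gene_pos[p[0]] for p in pairs])
    hi = np.array([gene_pos[p[1]] for p in pairs])
    controls = design.negative_control_genes

    frames = []
    for li, sample in enumerate(posterior.sample_ids):
        y = posterior.y_mean[:, li]
        if config.use_positive_controls_for_c:
            pc_y = [y[gene_pos[g]] for g in (positive_control_genes or []) if g in gene_pos]
            c = compute_c(y, config, positive_control_y=pc_y)
        else:
            c = compute_c(y, config)
        y_g, y_h = y[gi], y[hi]
        s = posterior.s_mean[:, li]
        strong = strong_score(y_g, y_h, s)
        leth, leth_ok = sensitive_lethality(y_g, y_h, s, c, config.lam)
        rec, rec_ok = sensitive_recovery(y_g, y_h, s, c, config.lam)
        frames.append(
            pd.DataFrame(
                {
                    "gene_g": [p[0] for p in pairs],
                    "gene_h": [p[1] for p in pairs],
                    "sample": sample,
                    "y_g": y_g,
                    "y_h": y_h,
                    "s": s,
                    "c": c,
                    "strong_score": strong,
                    "direction": np.where(s < 0, "lethality", np.where(s > 0, "recovery", "none")),
                    "sens_lethality": leth,
                    "sens_lethality_eligible": leth_ok,
                    "sens_recovery": rec,
                    "sens_recovery_eligible": rec_ok,
                    "same_gene": [p[0] == p[1] for p in pairs],
                    "involves_control": [
                        p[0] in controls or p[1] in controls for p in pairs
                    ],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
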