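"""Forward simulation of combinatorial knockout screens with known ground truth.

Screens are generated straight from the observation model: per-guide and
per-construct sample-independent effects x, per-(gene, sample) single-gene
effects y with a spike-and-slab essentiality structure, sparse planted
combination effects s, and Gaussian replicate noise on the LFCs,

    D_rep[p, l, r] = x[gi] y[g, l] + x[hj] y[h, l] + xp[p] s[(g,h), l] + eps,
    eps ~ N(0, noise_sd^2).

Two library layouts are supported: ``all_by_all`` (every gene pair, including
gene x control and control x control) and ``set_by_set_with_controls`` (two
disjoint gene sets crossed, each gene also paired with every control).  The
default geometry — 25 genes x 3 guides, 4 negative controls, 6 samples,
2 replicates — is a desk-scale screen of the kind used to hunt synthetic
lethality in cancer cell lines, small enough that a full fit takes seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .screen_data import (
    CountMatrix,
    LFCTensor,
    ReplicateBinding,
    SampleLayout,
    ScreenDesign,
    ScreenError,
    _tensor_from_reps,
    pair_key,
)

__all__ = ["SimConfig", "SimulatedScreen", "simulate_screen", "downsample_guides", "write_screen"]


@dataclass(frozen=True)
class SimConfig:
    """Generative settings; the seed fully determines the output."""

    n_genes: int = 25
    guides_per_gene: int = 3
    n_controls: int = 4
    layout: str = "all_by_all"  # or "set_by_set_with_controls"
    n_samples: int = 6
    n_replicates: int = 2

    # sample-independent effects: x ~ N(x_mean, x_sd^2), optional truncation at 0
    x_mean: float = 1.0
    x_sd: float = 0.2
    truncate_x: bool = False

    # single-gene effects: an essential gene depletes in every sample;
    # everything else (and every control) hovers near zero
    essential_fraction: float = 0.2
    essential_effect_mean: float = -1.5
    essential_effect_sd: float = 0.5
    background_y_sd: float = 0.05

    # planted combination effects on pairs of non-essential, non-control genes
    n_lethal: int = 5
    lethal_effect: float = -3.0
    n_recovery: int = 0
    recovery_effect: float = 3.0

    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layout not in ("all_by_all", "set_by_set_with_controls"):
            raise ScreenError(f"unknown layout {self.layout!r}")
        if self.n_genes < 2 or self.guides_per_gene < 1 or self.n_samples < 1:
            raise ScreenError("degenerate screen geometry")
        if self.layout == "set_by_set_with_controls" and self.n_genes < 4:
            raise ScreenError("set-by-set layout needs at least 4 genes")


@dataclass
class SimulatedScreen:
    design: ScreenDesign
    lfc: LFCTensor
    truth_x_guides: pd.Series
    truth_x_pairs: pd.Series
    truth_y: pd.DataFrame  # genes x samples
    truth_s: pd.DataFrame  # pairs x samples
    lethal_pairs: list[tuple[str, str]]
    recovery_pairs: list[tuple[str, str]]

    def counts(self, depth: int = 10_000_000, early_reads: int = 1000) -> tuple[CountMatrix, pd.DataFrame]:
        """Invert the LFCs into a count table exercising the normalization path.

        Early counts are uniform (``early_reads`` per construct); each late
        column carries frequencies proportional to ``f_early * 2**D_rep``
        scaled to ``depth`` reads.  Because depth normalization recentres
        log-frequencies, recomputed LFCs match ``D_rep`` only up to one
        additive constant per (sample, replicate) column.  Returns the counts
        and the matching sample-sheet records.
        """
        n = len(self.design.construct_ids)
        cols = {"early_ref": np.full(n, early_reads, dtype=np.int64)}
        records = [{"column": "early_ref", "sample": "shared", "replicate": "1", "timepoint": "early"}]
        for li, sample in enumerate(self.lfc.sample_ids):
            for r in range(self.lfc.D_rep.shape[2]):
                d = self.lfc.D_rep[:, li, r]
                if np.isnan(d).all():
                    continue
                freq = np.exp2(d)
                freq = freq / freq.sum()
                name = f"{sample}_rep{r + 1}"
                cols[name] = np.maximum(1, np.round(freq * depth)).astype(np.int64)
                records.append(
                    {"column": name, "sample": sample, "replicate": str(r + 1), "timepoint": "late"}
                )
        counts = pd.DataFrame(cols, index=self.design.construct_ids)
        counts.index.name = "construct_id"
        return CountMatrix(values=counts), pd.DataFrame(records)


def _gene_labels(cfg: SimConfig) -> tuple[list[str], list[str]]:
    genes = [f"GENE{i:03d}" for i in range(1, cfg.n_genes + 1)]
    controls = [f"CTRL{i:02d}" for i in range(1, cfg.n_controls + 1)]
    return genes, controls


def _layout_pairs(cfg: SimConfig, genes: list[str], controls: list[str]) -> list[tuple[str, str]]:
    if cfg.layout == "all_by_all":
        everything = genes + controls
        return [
            pair_key(everything[a], everything[b])
            for a in range(len(everything))
            for b in range(a + 1, len(everything))
        ]
    half = len(genes) // 2
    set_a, set_b = genes[:half], genes[half:]
    pairs = [pair_key(a, b) for a in set_a for b in set_b]
    pairs += [pair_key(g, c) for g in genes for c in controls]
    pairs += [
        pair_key(controls[a], controls[b])
        for a in range(len(controls))
        for b in range(a + 1, len(controls))
    ]
    return sorted(set(pairs))


def simulate_screen(cfg: SimConfig) -> SimulatedScreen:
    """Draw a screen from the generative model; returns data plus truth tables."""
    rng = np.random.default_rng(cfg.seed)
    genes, controls = _gene_labels(cfg)
    all_genes = genes + controls
    samples = [f"S{i + 1}" for i in range(cfg.n_samples)]

    guides = {g: [f"{g}_sg{k + 1}" for k in range(cfg.guides_per_gene)] for g in all_genes}
    pairs = _layout_pairs(cfg, genes, controls)

    rows = []
    for g, h in pairs:
        for u in guides[g]:
            for v in guides[h]:
                rows.append((f"{u}~{v}", u, v, g, h))
    constructs = pd.DataFrame(
        rows, columns=["construct_id", "guide_i", "guide_j", "gene_g", "gene_h"]
    ).set_index("construct_id")

    # --- effects -----------------------------------------------------------
    def draw_x(size: int) -> np.ndarray:
        x = rng.normal(cfg.x_mean, cfg.x_sd, size=size)
        if cfg.truncate_x:
            while (x < 0).any():  # resample the truncated tail
                bad = x < 0
                x[bad] = rng.normal(cfg.x_mean, cfg.x_sd, size=bad.sum())
        return x

    guide_list = sorted(u for us in guides.values() for u in us)
    x_guides = pd.Series(draw_x(len(guide_list)), index=guide_list)
    x_pairs = pd.Series(draw_x(len(constructs)), index=constructs.index)

    essential = rng.random(len(genes)) < cfg.essential_fraction
    y = np.zeros((len(all_genes), cfg.n_samples))
    for i, g in enumerate(genes):
        if essential[i]:
            y[i] = rng.normal(cfg.essential_effect_mean, cfg.essential_effect_sd, cfg.n_samples)
        else:
            y[i] = rng.normal(0.0, cfg.background_y_sd, cfg.n_samples)
    # controls stay exactly at zero effect
    truth_y = pd.DataFrame(y, index=all_genes, columns=samples)

    nonessential = [g for i, g in enumerate(genes) if not essential[i]]
    essential_genes = [g for i, g in enumerate(genes) if essential[i]]
    candidate_lethal = [
        p for p in pairs if p[0] in nonessential and p[1] in nonessential
    ]
    if len(candidate_lethal) < cfg.n_lethal:
        raise ScreenError(
            f"layout offers only {len(candidate_lethal)} eligible pairs for "
            f"{cfg.n_lethal} planted lethal interactions"
        )
    chosen = rng.choice(len(candidate_lethal), size=cfg.n_lethal, replace=False)
    lethal_pairs = [candidate_lethal[i] for i in sorted(chosen)]

    recovery_pairs: list[tuple[str, str]] = []
    if cfg.n_recovery:
        candidates = [
            p for p in pairs
            if (p[0] in essential_genes) != (p[1] in essential_genes) and p not in lethal_pairs
        ]
        if len(candidates) < cfg.n_recovery:
            raise ScreenError("not enough essential/non-essential pairs for planted recovery")
        chosen = rng.choice(len(candidates), size=cfg.n_recovery, replace=False)
        recovery_pairs = [candidates[i] for i in sorted(chosen)]

    s = np.zeros((len(pairs), cfg.n_samples))
    pair_pos = {p: i for i, p in enumerate(pairs)}
    for p in lethal_pairs:
        s[pair_pos[p]] = cfg.lethal_effect
    for p in recovery_pairs:
        s[pair_pos[p]] = cfg.recovery_effect
    truth_s = pd.DataFrame(
        s, index=pd.MultiIndex.from_tuples(pairs, names=["gene_g", "gene_h"]), columns=samples
    )

    # --- observations ------------------------------------------------------
    gene_pos = {g: i for i, g in enumerate(all_genes)}
    gi = constructs["guide_i"].map(x_guides).to_numpy()
    hj = constructs["guide_j"].map(x_guides).to_numpy()
    g_idx = np.array([gene_pos[g] for g in constructs["gene_g"]])
    h_idx = np.array([gene_pos[g] for g in constructs["gene_h"]])
    p_idx = np.array([pair_pos[pair_key(g, h)] for g, h in zip(constructs["gene_g"], constructs["gene_h"])])

    mu = gi[:, None] * y[g_idx] + hj[:, None] * y[h_idx] + x_pairs.to_numpy()[:, None] * s[p_idx]
    noise = rng.normal(0.0, cfg.noise_sd, size=(len(constructs), cfg.n_samples, cfg.n_replicates))
    D_rep = mu[:, :, None] + noise

    layout_samples = tuple(
        SampleLayout(
            sample_id=sid,
            replicates=tuple(
                ReplicateBinding(str(r + 1), f"{sid}_rep{r + 1}", ("early_ref",))
                for r in range(cfg.n_replicates)
            ),
        )
        for sid in samples
    )
    design = ScreenDesign(
        constructs=constructs,
        samples=layout_samples,
        negative_control_genes=frozenset(controls),
    )
    lfc = _tensor_from_reps(D_rep, design)

    return SimulatedScreen(
        design=design,
        lfc=lfc,
        truth_x_guides=x_guides,
        truth_x_pairs=x_pairs,
        truth_y=truth_y,
        truth_s=truth_s,
        lethal_pairs=lethal_pairs,
        recovery_pairs=recovery_pairs,
    )


def downsample_guides(
    design: ScreenDesign,
    lfc: LFCTensor,
    k_pairs_per_genepair: int,
    seed: int = 0,
) -> tuple[ScreenDesign, LFCTensor]:
    """Keep a seeded uniform subset of k constructs per gene pair."""
    rng = np.random.default_rng(seed)
    keys = design.pair_keys()
    keep: list[str] = []
    for _, group in design.constructs.groupby(keys, sort=True):
        ids = list(group.index)
        if k_pairs_per_genepair > len(ids):
            raise ScreenError(
                f"cannot keep {k_pairs_per_genepair} constructs: gene pair has only {len(ids)}"
            )
        chosen = rng.choice(len(ids), size=k_pairs_per_genepair, replace=False)
        keep.extend(ids[i] for i in sorted(chosen))
    keep_idx = design.construct_ids.get_indexer(keep)

    new_design = ScreenDesign(
        constructs=design.constructs.loc[keep],
        samples=design.samples,
        negative_control_genes=design.negative_control_genes,
        nonint_pairs=design.nonint_pairs,
    )
    new_lfc = _tensor_from_reps(lfc.D_rep[keep_idx], new_design)
    return new_design, new_lfc


def write_screen(sim: SimulatedScreen, out_dir: str | Path, counts_mode: bool = False) -> dict[str, Path]:
    """Write the simulated screen in the TSV/YAML formats the loaders read.

    Emits annotation, controls, LFCs (or counts + sample sheet when
    ``counts_mode``), and the ground-truth tables.  Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ann = sim.design.constructs[["guide_i", "guide_j", "gene_g", "gene_h"]].copy()
    ann.index.name = "construct_id"
    paths["annotation"] = out / "annotation.tsv"
    ann.to_csv(paths["annotation"], sep="\t")

    paths["controls"] = out / "negative_controls.txt"
    paths["controls"].write_text(
        "".join(f"{g}\n" for g in sorted(sim.design.negative_control_genes))
    )

    if counts_mode:
        counts, sheet = sim.counts()
        paths["counts"] = out / "counts.tsv"
        counts.values.to_csv(paths["counts"], sep="\t")
        paths["sample_sheet"] = out / "samples.yaml"
        with open(paths["sample_sheet"], "w") as fh:
            yaml.safe_dump({"columns": sheet.to_dict("records")}, fh, sort_keys=False)
    else:
        paths["lfc"] = out / "lfc.tsv"
        sim.lfc.to_tsv(paths["lfc"])
        sheet = pd.DataFrame(
            [
                {"column": f"{s}.{r + 1}", "sample": s, "replicate": str(r + 1), "timepoint": "late"}
                for s in sim.lfc.sample_ids
                for r in range(sim.lfc.D_rep.shape[2])
            ]
        )
        paths["sample_sheet"] = out / "samples.tsv"
        sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)

    paths["truth_y"] = out / "truth_y.tsv"
    sim.truth_y.rename_axis("gene").to_csv(paths["truth_y"], sep="\t")
    paths["truth_s"] = out / "truth_s.tsv"
    sim.truth_s.to_csv(paths["truth_s"], sep="\t")
    paths["truth_x_guides"] = out / "truth_x_guides.tsv"
    sim.truth_x_guides.rename_axis("guide").rename("x").to_csv(paths["truth_x_guides"], sep="\t")
    paths["planted"] = out / "planted_interactions.tsv"
    pd.DataFrame(
        [{"gene_g": g, "gene_h": h, "kind": "lethal"} for g, h in sim.lethal_pairs]
        + [{"gene_g": g, "gene_h": h, "kind": "recovery"} for g, h in sim.recovery_pairs]
    ).to_csv(paths["planted"], sep="\t", index=False)
    return paths
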