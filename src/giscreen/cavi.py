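"""Mean-field coordinate-ascent variational inference for the screen model.

The observed replicate-mean LFC of construct p = (guide gi, guide hj) targeting
genes (g, h) in sample l is modelled as

    D[p, l] ~ Normal( x[gi] * y[g, l]  +  x[hj] * y[h, l]  +  xp[p] * s[(g,h), l],
                      1 / tau[p, l] )

with Normal priors on the sample-independent guide and guide-pair effects
(x, xp), on the sample-dependent single-gene effects (y) and combination
effects (s), and a Gamma prior on each observation's precision tau.  The
variational posterior factorizes over every latent variable; each factor then
has a closed-form conjugate update, and a fit is a fixed deterministic
schedule of block updates (x-guides, x-pairs, y, s, tau) iterated until the
mean absolute change of the posterior means falls below a tolerance.

For a Gaussian latent v entering one observation's mean linearly as v*c + m,
the update is the textbook conjugate one:

    precision = 1/sigma_v^2 + sum_obs E[tau] <c^2>
    mean      = (mu_v/sigma_v^2 + sum_obs E[tau] (<c> D - <c m>)) / precision

summing over every observation containing v.  Two moment conventions are
offered for the coefficient c (a product/sum of other latents):

* ``moment_mode="plugin"`` (default): <c^2> = E[c]^2 and <c m> = E[c] E[m] —
  other factors enter at their posterior means.  The target factor's update
  is still the exact Bayesian conjugate posterior given those plug-in values.
* ``moment_mode="full"``: <c^2> = E[c]^2 + Var[c] under the factorized q
  (fully-factorized mean-field), with the exact cross moment for constructs
  whose two guides target one gene (their two products share y).

The full variant is the textbook mean-field ascent, but on this bilinear
model it zero-forces weak effects: a guide of a no-phenotype gene accumulates
variance pseudo-evidence (sum E[tau] Var[y]) with no signal, its x collapses
toward 0 and the scale of the whole decomposition drifts — the analogue of
the well-known exact-sparsity behaviour of fully-factorized VB matrix
factorization.  The plug-in variant has the correct decomposition as a stable
fixed point and is the default.  The tau updates use the full uncertainty-
aware expected squared residual in both modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen_data import LFCTensor, ScreenDesign, ScreenError, pair_key
from .tau_prior import TauPrior

__all__ = [
    "Priors",
    "VariationalPosterior",
    "FitDiagnostics",
    "initialize",
    "update_gaussian_factor",
    "update_tau_factor",
    "fit",
]


@dataclass(frozen=True)
class Priors:
    """Hyperparameters of the Normal priors on x, y and s.

    Defaults: x ~ N(1, 1) — a moderate prior centred on "fully active guide";
    y, s ~ N(0, 10) — diffuse, reflecting limited prior knowledge of
    sample-dependent effects.  With fewer than 3 samples a stronger x prior
    (e.g. sigma_x = 0.1) is advisable; :func:`fit` warns but never silently
    changes it.
    """

    mu_x: float = 1.0
    sigma_x2: float = 1.0
    mu_y: float = 0.0
    sigma_y2: float = 10.0
    mu_s: float = 0.0
    sigma_s2: float = 10.0

    def __post_init__(self) -> None:
        if min(self.sigma_x2, self.sigma_y2, self.sigma_s2) <= 0:
            raise ValueError("prior variances must be positive")


@dataclass
class _Indices:
    """Integer index arrays tying constructs to guides, genes and gene pairs."""

    guides: list[str]
    genes: list[str]
    pairs: list[tuple[str, str]]
    gi: np.ndarray  # (P,) guide index, slot i
    hj: np.ndarray  # (P,) guide index, slot j
    g: np.ndarray  # (P,) gene index, slot i
    h: np.ndarray  # (P,) gene index, slot j
    pair: np.ndarray  # (P,) gene-pair index
    same_gene: np.ndarray  # (P,) bool

    @classmethod
    def from_design(cls, design: ScreenDesign) -> "_Indices":
        guides = design.guides
        genes = design.genes
        gidx = {g: i for i, g in enumerate(guides)}
        nidx = {g: i for i, g in enumerate(genes)}
        tab = design.constructs
        pairs_per_row = [pair_key(a, b) for a, b in zip(tab["gene_g"], tab["gene_h"])]
        pairs = sorted(set(pairs_per_row))
        pidx = {p: i for i, p in enumerate(pairs)}
        return cls(
            guides=guides,
            genes=genes,
            pairs=pairs,
            gi=np.array([gidx[u] for u in tab["guide_i"]]),
            hj=np.array([gidx[u] for u in tab["guide_j"]]),
            g=np.array([nidx[u] for u in tab["gene_g"]]),
            h=np.array([nidx[u] for u in tab["gene_h"]]),
            pair=np.array([pidx[p] for p in pairs_per_row]),
            same_gene=(tab["gene_g"] == tab["gene_h"]).to_numpy(),
        )


@dataclass
class VariationalPosterior:
    """Factorized posterior: Gaussian factors for x, xp, y, s; Gamma for tau.

    Arrays are indexed by the label lists in ``idx`` (guides, genes, pairs)
    and by construct row / sample column for xp and tau.
    """

    idx: _Indices
    sample_ids: list[str]
    construct_ids: pd.Index
    x_mean: np.ndarray  # (n_guides,)
    x_var: np.ndarray
    xp_mean: np.ndarray  # (n_constructs,)
    xp_var: np.ndarray
    y_mean: np.ndarray  # (n_genes, n_samples)
    y_var: np.ndarray
    s_mean: np.ndarray  # (n_pairs, n_samples)
    s_var: np.ndarray
    tau_shape: np.ndarray  # (n_constructs, n_samples)
    tau_rate: np.ndarray

    @property
    def tau_mean(self) -> np.ndarray:
        return self.tau_shape / self.tau_rate

    def means_vector(self) -> np.ndarray:
        """All Gaussian posterior means, concatenated (convergence metric)."""
        return np.concatenate(
            [self.x_mean, self.xp_mean, self.y_mean.ravel(), self.s_mean.ravel()]
        )

    def check_finite(self) -> None:
        for name in ("x_mean", "x_var", "xp_mean", "xp_var", "y_mean", "y_var",
                     "s_mean", "s_var", "tau_shape", "tau_rate"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"non-finite values in posterior factor {name}")

    # -- tabular exports ----------------------------------------------------
    def y_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.y_mean, index=self.idx.genes, columns=self.sample_ids)

    def y_var_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.y_var, index=self.idx.genes, columns=self.sample_ids)

    def s_table(self) -> pd.DataFrame:
        index = pd.MultiIndex.from_tuples(self.idx.pairs, names=["gene_g", "gene_h"])
        return pd.DataFrame(self.s_mean, index=index, columns=self.sample_ids)

    def s_var_table(self) -> pd.DataFrame:
        index = pd.MultiIndex.from_tuples(self.idx.pairs, names=["gene_g", "gene_h"])
        return pd.DataFrame(self.s_var, index=index, columns=self.sample_ids)

    def x_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.x_mean, "var": self.x_var}, index=pd.Index(self.idx.guides, name="guide")
        )

    def xp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.xp_mean, "var": self.xp_var},
            index=pd.Index(self.construct_ids, name="construct_id"),
        )


@dataclass
class FitDiagnostics:
    """Convergence trace: mean absolute change of posterior means per sweep."""

    mae_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    def largest_drop_sweep(self) -> int:
        """1-based sweep index with the largest decrease of the MAE trace."""
        t = np.asarray(self.mae_trace)
        if len(t) < 2:
            return 1
        return int(np.argmax(t[:-1] - t[1:])) + 2


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize(
    lfc: LFCTensor,
    design: ScreenDesign,
    priors: Priors,
    tau_prior: TauPrior,
) -> VariationalPosterior:
    """Initial variational state.

    Single-gene effects y are initialized per (gene, sample) to the median LFC
    of the constructs pairing that gene with a negative control; genes with no
    control-paired construct (or screens without declared controls) fall back
    to the median over all of the gene's constructs.  Guide and pair effects
    start at the prior means, all variances at the prior variances, and tau
    factors at the prior (alpha, beta).
    """
    idx = _Indices.from_design(design)
    D = lfc.D.to_numpy(dtype=float)
    n_genes, n_samples = len(idx.genes), len(lfc.sample_ids)
    controls = design.negative_control_genes

    y0 = np.zeros((n_genes, n_samples))
    gene_names = idx.genes
    for ui, gene in enumerate(gene_names):
        in_g = idx.g == ui
        in_h = idx.h == ui
        rows_any = in_g | in_h
        if not rows_any.any():
            raise ScreenError(f"gene {gene!r} has zero constructs")
        partner_is_control = np.zeros(len(idx.g), dtype=bool)
        if controls:
            partner_gene = np.where(in_g, idx.h, idx.g)
            partner_is_control = rows_any & np.isin(
                partner_gene, [gene_names.index(c) for c in controls if c in gene_names]
            )
            # for a control gene, require the *partner* to be a control too
        rows = partner_is_control if partner_is_control.any() else rows_any
        y0[ui] = np.median(D[rows], axis=0)

    n_guides, n_constructs = len(idx.guides), len(lfc.construct_ids)
    return VariationalPosterior(
        idx=idx,
        sample_ids=list(lfc.sample_ids),
        construct_ids=lfc.construct_ids,
        x_mean=np.full(n_guides, priors.mu_x, dtype=float),
        x_var=np.full(n_guides, priors.sigma_x2, dtype=float),
        xp_mean=np.full(n_constructs, priors.mu_x, dtype=float),
        xp_var=np.full(n_constructs, priors.sigma_x2, dtype=float),
        y_mean=y0,
        y_var=np.full((n_genes, n_samples), priors.sigma_y2, dtype=float),
        s_mean=np.full((len(idx.pairs), n_samples), priors.mu_s, dtype=float),
        s_var=np.full((len(idx.pairs), n_samples), priors.sigma_s2, dtype=float),
        tau_shape=tau_prior.alpha.copy(),
        tau_rate=tau_prior.beta.copy(),
    )


# ---------------------------------------------------------------------------
# block updates (exact coordinate ascent; see module docstring)
# ---------------------------------------------------------------------------

def _update_one_guide(
    state: VariationalPosterior, u: int, D: np.ndarray, priors: Priors, full: bool = False
) -> None:
    """Conjugate update of q(x[u]) over every observation containing guide u."""
    idx = state.idx
    Etau = state.tau_mean
    prec = 1.0 / priors.sigma_x2
    num = priors.mu_x / priors.sigma_x2
    for slot_guides, own_gene, other_guides, other_gene in (
        (idx.gi, idx.g, idx.hj, idx.h),
        (idx.hj, idx.h, idx.gi, idx.g),
    ):
        rows = np.flatnonzero(slot_guides == u)
        if rows.size == 0:
            continue
        gg = own_gene[rows]
        c_mean = state.y_mean[gg]  # (rows, L)
        c_sq = c_mean**2 + state.y_var[gg] if full else c_mean**2
        m = (
            state.x_mean[other_guides[rows], None] * state.y_mean[other_gene[rows]]
            + state.xp_mean[rows, None] * state.s_mean[idx.pair[rows]]
        )
        resid = D[rows] - m
        term = c_mean * resid
        same = idx.same_gene[rows]
        if full and same.any():
            # both guides hit one gene: the remainder shares y with c, so
            # E[c m] = E[c] E[m] + E[x_other] Var[y]
            term[same] -= state.x_mean[other_guides[rows][same], None] * state.y_var[gg[same]]
        tau_rows = Etau[rows]
        prec += np.sum(tau_rows * c_sq)
        num += np.sum(tau_rows * term)
    var = 1.0 / prec
    state.x_var[u] = var
    state.x_mean[u] = var * num


def _update_x_guides(
    state: VariationalPosterior, D: np.ndarray, priors: Priors, full: bool = False
) -> None:
    for u in range(len(state.idx.guides)):
        _update_one_guide(state, u, D, priors, full)


def _update_x_pairs(
    state: VariationalPosterior, D: np.ndarray, priors: Priors, full: bool = False
) -> None:
    # xp[p] appears only in construct p's observations; parallel update is exact.
    idx = state.idx
    Etau = state.tau_mean
    s_mean = state.s_mean[idx.pair]  # (P, L)
    s_sq = s_mean**2 + state.s_var[idx.pair] if full else s_mean**2
    m = (
        state.x_mean[idx.gi, None] * state.y_mean[idx.g]
        + state.x_mean[idx.hj, None] * state.y_mean[idx.h]
    )
    prec = 1.0 / priors.sigma_x2 + np.sum(Etau * s_sq, axis=1)
    num = priors.mu_x / priors.sigma_x2 + np.sum(Etau * s_mean * (D - m), axis=1)
    state.xp_var = 1.0 / prec
    state.xp_mean = state.xp_var * num


def _update_one_gene(
    state: VariationalPosterior, ui: int, D: np.ndarray, priors: Priors, full: bool = False
) -> None:
    """Conjugate update of q(y[ui, l]) for all samples l at once."""
    idx = state.idx
    Etau = state.tau_mean
    L = D.shape[1]
    prec = np.full(L, 1.0 / priors.sigma_y2)
    num = np.full(L, priors.mu_y / priors.sigma_y2)

    same_rows = np.flatnonzero(idx.same_gene & (idx.g == ui))
    if same_rows.size:
        # coefficient is x[gi] + x[hj]; remainder only the pair term
        c_mean = state.x_mean[idx.gi[same_rows]] + state.x_mean[idx.hj[same_rows]]
        c_sq = c_mean**2
        if full:
            c_sq = c_sq + state.x_var[idx.gi[same_rows]] + state.x_var[idx.hj[same_rows]]
        m = state.xp_mean[same_rows, None] * state.s_mean[idx.pair[same_rows]]
        tau_rows = Etau[same_rows]
        prec += np.sum(tau_rows * c_sq[:, None], axis=0)
        num += np.sum(tau_rows * c_mean[:, None] * (D[same_rows] - m), axis=0)

    for own_gene, own_guides, other_gene, other_guides in (
        (idx.g, idx.gi, idx.h, idx.hj),
        (idx.h, idx.hj, idx.g, idx.gi),
    ):
        rows = np.flatnonzero((own_gene == ui) & ~idx.same_gene)
        if rows.size == 0:
            continue
        c_mean = state.x_mean[own_guides[rows]]
        c_sq = c_mean**2 + state.x_var[own_guides[rows]] if full else c_mean**2
        m = (
            state.x_mean[other_guides[rows], None] * state.y_mean[other_gene[rows]]
            + state.xp_mean[rows, None] * state.s_mean[idx.pair[rows]]
        )
        tau_rows = Etau[rows]
        prec += np.sum(tau_rows * c_sq[:, None], axis=0)
        num += np.sum(tau_rows * c_mean[:, None] * (D[rows] - m), axis=0)

    state.y_var[ui] = 1.0 / prec
    state.y_mean[ui] = state.y_var[ui] * num


def _update_y(
    state: VariationalPosterior, D: np.ndarray, priors: Priors, full: bool = False
) -> None:
    for ui in range(len(state.idx.genes)):
        _update_one_gene(state, ui, D, priors, full)


def _update_s(
    state: VariationalPosterior, D: np.ndarray, priors: Priors, full: bool = False
) -> None:
    # each observation contains exactly one s factor; parallel update is exact.
    idx = state.idx
    Etau = state.tau_mean
    L = D.shape[1]
    nQ = len(idx.pairs)
    c_mean = state.xp_mean  # (P,)
    c_sq = c_mean**2 + state.xp_var if full else c_mean**2
    m = (
        state.x_mean[idx.gi, None] * state.y_mean[idx.g]
        + state.x_mean[idx.hj, None] * state.y_mean[idx.h]
    )
    resid = D - m
    prec = np.full((nQ, L), 1.0 / priors.sigma_s2)
    num = np.full((nQ, L), priors.mu_s / priors.sigma_s2)
    for l in range(L):
        prec[:, l] += np.bincount(idx.pair, weights=Etau[:, l] * c_sq, minlength=nQ)
        num[:, l] += np.bincount(idx.pair, weights=Etau[:, l] * c_mean * resid[:, l], minlength=nQ)
    state.s_var = 1.0 / prec
    state.s_mean = state.s_var * num


def _expected_mu_and_var(state: VariationalPosterior) -> tuple[np.ndarray, np.ndarray]:
    """E[mu] and Var[mu] of the model mean for every observation, under q."""
    idx = state.idx
    ax, vx = state.x_mean[idx.gi], state.x_var[idx.gi]
    bx, vb = state.x_mean[idx.hj], state.x_var[idx.hj]
    yg, vyg = state.y_mean[idx.g], state.y_var[idx.g]
    yh, vyh = state.y_mean[idx.h], state.y_var[idx.h]
    sp, vsp = state.s_mean[idx.pair], state.s_var[idx.pair]
    xp, vxp = state.xp_mean, state.xp_var

    mu = ax[:, None] * yg + bx[:, None] * yh + xp[:, None] * sp

    def prod_var(ma, va, mb, vb_):
        return (ma**2 + va) * (mb**2 + vb_) - (ma * mb) ** 2

    var = (
        prod_var(ax[:, None], vx[:, None], yg, vyg)
        + prod_var(bx[:, None], vb[:, None], yh, vyh)
        + prod_var(xp[:, None], vxp[:, None], sp, vsp)
    )
    same = idx.same_gene
    if same.any():
        # the two single-gene products share y: add 2 Cov = 2 E[x_gi]E[x_hj]Var[y]
        var[same] += 2.0 * (ax[same] * bx[same])[:, None] * vyg[same]
    return mu, var


def _update_tau(state: VariationalPosterior, D: np.ndarray, tau_prior: TauPrior) -> None:
    mu, var = _expected_mu_and_var(state)
    state.tau_shape = tau_prior.alpha + 0.5
    state.tau_rate = tau_prior.beta + 0.5 * ((D - mu) ** 2 + var)


# ---------------------------------------------------------------------------
# single-factor interface (mirrors the block math; used by callers and tests)
# ---------------------------------------------------------------------------

def update_gaussian_factor(
    target: tuple[str, object],
    state: VariationalPosterior,
    lfc: LFCTensor,
    priors: Priors,
    moment_mode: str = "plugin",
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Update one Gaussian factor in place and return its new (mean, var).

    ``target`` is ``("x_guide", guide_id)``, ``("x_pair", construct_id)``,
    ``("y", gene)`` or ``("s", (gene_g, gene_h))``.  A latent referenced by no
    observation keeps its prior (empty-sum case).  See the module docstring
    for the two ``moment_mode`` conventions; with all other factors at point
    values (zero variance) they coincide with the closed-form Bayesian
    posterior of a Gaussian mean under known noise.
    """
    full = _full_moments(moment_mode)
    D = lfc.D.to_numpy(dtype=float)
    kind, label = target
    idx = state.idx
    if kind == "x_guide":
        u = idx.guides.index(label)
        _update_one_guide(state, u, D, priors, full)
        return state.x_mean[u], state.x_var[u]
    if kind == "x_pair":
        p = state.construct_ids.get_loc(label)
        old_mean, old_var = state.xp_mean.copy(), state.xp_var.copy()
        _update_x_pairs(state, D, priors, full)
        keep = np.arange(len(old_mean)) != p
        state.xp_mean[keep], state.xp_var[keep] = old_mean[keep], old_var[keep]
        return state.xp_mean[p], state.xp_var[p]
    if kind == "y":
        ui = idx.genes.index(label)
        _update_one_gene(state, ui, D, priors, full)
        return state.y_mean[ui].copy(), state.y_var[ui].copy()
    if kind == "s":
        q = idx.pairs.index(pair_key(*label))
        old_mean, old_var = state.s_mean.copy(), state.s_var.copy()
        _update_s(state, D, priors, full)
        keep = np.arange(old_mean.shape[0]) != q
        state.s_mean[keep], state.s_var[keep] = old_mean[keep], old_var[keep]
        return state.s_mean[q].copy(), state.s_var[q].copy()
    raise ValueError(f"unknown factor kind {kind!r}")


def _full_moments(moment_mode: str) -> bool:
    if moment_mode not in ("plugin", "full"):
        raise ValueError(f"moment_mode must be 'plugin' or 'full', got {moment_mode!r}")
    return moment_mode == "full"


def update_tau_factor(
    construct_id: object,
    sample_id: str,
    state: VariationalPosterior,
    lfc: LFCTensor,
    tau_prior: TauPrior,
) -> tuple[float, float]:
    """Update q(tau) for one observation; returns the new (shape, rate).

    shape' = alpha + 1/2;  rate' = beta + 1/2 * E[(D - mu)^2], with the
    expectation of the squared residual taken under the current q.
    """
    p = state.construct_ids.get_loc(construct_id)
    l = state.sample_ids.index(sample_id)
    D = lfc.D.to_numpy(dtype=float)
    mu, var = _expected_mu_and_var(state)
    shape = float(tau_prior.alpha[p, l] + 0.5)
    rate = float(tau_prior.beta[p, l] + 0.5 * ((D[p, l] - mu[p, l]) ** 2 + var[p, l]))
    state.tau_shape[p, l] = shape
    state.tau_rate[p, l] = rate
    return shape, rate


# ---------------------------------------------------------------------------
# fit loop
# ---------------------------------------------------------------------------

def fit(
    lfc: LFCTensor,
    design: ScreenDesign,
    priors: Priors | None = None,
    tau_prior: TauPrior | None = None,
    max_iter: int = 50,
    tol: float = 1e-3,
    moment_mode: str = "plugin",
) -> tuple[VariationalPosterior, FitDiagnostics]:
    """Run coordinate-ascent sweeps until the posterior means stabilize.

    One sweep updates, in order: every (gene, sample) y factor, every
    (gene pair, sample) s factor, every per-guide x factor, every
    per-construct pair factor, and every tau factor.  Convergence is declared
    when the mean absolute change of all Gaussian posterior means between
    consecutive sweeps drops below ``tol``.  The run is fully deterministic.
    """
    from .tau_prior import estimate_tau_empirical

    full = _full_moments(moment_mode)
    priors = priors or Priors()
    if tau_prior is None:
        tau_prior = estimate_tau_empirical(lfc)
    if len(design.samples) < 3:
        warnings.warn(
            "fewer than 3 samples: sample-independent effects are weakly identified; "
            "consider a stronger guide prior (e.g. sigma_x = 0.1)",
            stacklevel=2,
        )

    state = initialize(lfc, design, priors, tau_prior)
    D = lfc.D.to_numpy(dtype=float)
    diag = FitDiagnostics()
    prev = state.means_vector()
    for it in range(1, max_iter + 1):
        # sample-dependent blocks first: at initialization y and s carry the
        # diffuse prior variance, and an x-update at that point would see
        # E[y^2] inflated by it and collapse the x scale (x -> 0, y -> huge,
        # a spurious mean-field optimum of the bilinear model)
        _update_y(state, D, priors, full)
        _update_s(state, D, priors, full)
        _update_x_guides(state, D, priors, full)
        _update_x_pairs(state, D, priors, full)
        _update_tau(state, D, tau_prior)
        try:
            state.check_finite()
        except FloatingPointError as err:
            raise FloatingPointError(
                f"inference diverged at sweep {it}: {err}; MAE trace so far: {diag.mae_trace}"
            ) from err
        cur = state.means_vector()
        mae = float(np.mean(np.abs(cur - prev)))
        diag.mae_trace.append(mae)
        diag.n_iter = it
        prev = cur
        if mae < tol:
            diag.converged = True
            break
    return state, diag
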