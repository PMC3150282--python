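"""Bayesian MCMC estimation of the fluorescence model on a single synapse.

Each synapse is fitted separately.  Global observation parameters
(free-surface means, complex amplitude A_B, barrier factor Gamma, and --
for Gaussian/Gamma noise -- the overdispersion/shape) and per-pixel SQREs
are sampled jointly by an adaptive random-walk Metropolis-within-Gibbs
scheme: globals are updated one at a time, then all per-pixel locals are
updated in a single vectorised block (pixels are conditionally
independent given the globals, so per-pixel accept/reject within one
block is a valid Gibbs step).  Proposals reflect at the uniform prior
bounds (symmetric), scales adapt toward target acceptance during the
first half of the run (burn-in) and are frozen afterwards to preserve
detailed balance.

Two fits mirror the two analysis stages:

* ``fit_unconstrained`` -- independent (e_C, e_I) per contact-interface
  pixel; the SQRE linearity is *not* imposed, so a straight line in the
  posterior-mean scatter is evidence for the size-exclusion model.  A
  weighted total-least-squares line (both coordinates are uncertain) is
  fitted through the posterior means.
* ``fit_constrained`` -- the line e_I = max(0, alpha - beta e_C) is
  imposed; (alpha, beta) become global parameters and each pixel keeps a
  single latent e_C (equivalently the hidden separation).  Energies are
  clamped at zero beyond the line's zero crossing.

Convergence is monitored with the Gelman--Rubin potential scale
reduction over >= 2 independently seeded chains (house threshold
R-hat < 1.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .energy_model import SpringParams, separation_from_sqre
from .fluorescence_model import FluorModelSpec
from .pattern_dynamics import sqre_margin

__all__ = [
    "PriorSpec",
    "ChainSet",
    "PosteriorSummary",
    "run_mcmc",
    "fit_unconstrained",
    "fit_constrained",
    "gelman_rubin",
    "slope_unity_test",
    "patternation_posterior",
    "reconstruct_separation",
]

RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior bounds.

    ``bounds`` maps global parameter names to (lo, hi); ``e_max`` is the
    upper bound of the SQRE uniform prior [0, e_max] (kT^1/2).  The
    default e_max = 2.5 allows exclusion energies to 6.25 kT -- generous
    against the few-kT range membrane proteins actually show, while
    avoiding the long zero-signal prior tail (exp(-E) < 1e-3) that a
    much larger ceiling would add; with flat priors that tail is not
    harmless, it feeds a marginal-likelihood (Occam) bias into the
    global barrier/amplitude parameters.  ``z_hat_bounds`` is the
    uniform support of the constrained fit's normalised separation, an
    interval containing [0, 1]; the padding 0.06 was calibrated on
    known-truth simulations of the default generator so that boundary
    folding at the two pure phases leaves the (alpha, beta) posterior
    centred (larger padding biases beta low, smaller biases it high).
    """

    bounds: dict = field(default_factory=dict)
    e_max: float = 2.5
    z_hat_bounds: tuple = (-0.06, 1.06)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not np.isfinite([lo, hi]).all() or not lo < hi:
                raise ValueError(f"bad bounds for {name}: ({lo}, {hi})")
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")
        lo, hi = self.z_hat_bounds
        if not (lo < 0 < 1 < hi):
            raise ValueError("z_hat prior support must contain [0, 1]")


def _default_prior(constrained: bool, family: str) -> PriorSpec:
    b = {
        "mu_fs_small": (1e-2, 1e4),
        "mu_fs_long": (1e-2, 1e4),
        "A_B": (1e-2, 1e4),
        "Gamma_barrier": (1e-3, 1.0),
    }
    if family in ("gaussian", "gamma"):
        b["overdispersion"] = (0.05, 100.0)
    if constrained:
        b["alpha"] = (1e-2, 10.0)
        b["beta"] = (1e-2, 10.0)
    return PriorSpec(bounds=b)


@dataclass
class ChainSet:
    """Post-warm-up MCMC draws of the global parameters.

    ``draws`` maps parameter name -> array (n_chains, n_kept).  Local
    (per-pixel) parameters are summarised by running per-chain moments
    in ``local_moments`` (name -> dict of mean/var arrays, (n_chains, n_px))
    rather than stored densely.
    """

    draws: dict
    seeds: tuple
    acceptance: dict = field(default_factory=dict)
    local_moments: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]


@dataclass
class PosteriorSummary:
    """Posterior summaries of one fit."""

    mode: str                     # "unconstrained" | "constrained"
    params: dict                  # name -> {mean, sd, ci_low, ci_high, rhat}
    chains: ChainSet
    pixel: dict                   # e_C_mean, e_C_sd, (e_I_mean, e_I_sd), rhat
    line: dict | None = None      # TLS fit (unconstrained) or (alpha, beta)
    spec_template: FluorModelSpec | None = None
    n_ci: int = 0
    n_fs: int = 0
    seed: int | None = None

    @property
    def max_rhat(self) -> float:
        r = [v["rhat"] for v in self.params.values() if np.isfinite(v["rhat"])]
        return float(max(r)) if r else np.nan

    @property
    def converged(self) -> bool:
        return self.max_rhat < RHAT_THRESHOLD


# ---------------------------------------------------------------------------
# Generic Metropolis engine (scalar parameters)
# ---------------------------------------------------------------------------

def _reflect(x, lo, hi):
    """Fold a proposal back into [lo, hi] (symmetric reflection)."""
    w = hi - lo
    y = np.mod(np.asarray(x, float) - lo, 2 * w)
    return lo + np.minimum(y, 2 * w - y)


def run_mcmc(
    loglik,
    priors: PriorSpec | dict,
    n_chains: int = 4,
    n_iter: int = 2000,
    seed: int | None = None,
    target_accept: float = 0.3,
    init: dict | None = None,
    max_init_tries: int = 200,
) -> ChainSet:
    """Adaptive random-walk Metropolis over scalar parameters.

    ``loglik`` maps a dict of parameter values to a float (``None`` for a
    prior-only run).  Uniform priors per :class:`PriorSpec`; proposals
    reflect at the bounds.  Scales adapt during the first half (burn-in,
    discarded) and are frozen after.  Fully reproducible: chain c uses
    ``np.random.default_rng`` seeded from SeedSequence(seed).spawn.
    """
    if isinstance(priors, dict):
        priors = PriorSpec(bounds=priors)
    names = list(priors.bounds)
    if n_chains < 2:
        raise ValueError("need at least 2 chains for convergence checking")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_chains)
    n_burn = n_iter // 2
    draws = {n: np.empty((n_chains, n_iter - n_burn)) for n in names}
    acc_out = {}
    for c, child in enumerate(children):
        rng = np.random.default_rng(child)
        x = {}
        ll = -np.inf
        for _ in range(max_init_tries):
            for n in names:
                lo, hi = priors.bounds[n]
                x[n] = init[n] if (init and n in init) else rng.uniform(lo, hi)
            ll = 0.0 if loglik is None else float(loglik(x))
            if np.isfinite(ll):
                break
            init = None  # fall back to prior draws
        else:
            raise RuntimeError("could not find a finite-likelihood initial state")
        scales = {n: 0.1 * (priors.bounds[n][1] - priors.bounds[n][0]) for n in names}
        n_acc = {n: 0 for n in names}
        for t in range(n_iter):
            for n in names:
                lo, hi = priors.bounds[n]
                prop = dict(x)
                prop[n] = float(_reflect(x[n] + scales[n] * rng.standard_normal(), lo, hi))
                ll_p = 0.0 if loglik is None else float(loglik(prop))
                if np.log(rng.uniform()) < ll_p - ll:
                    x, ll = prop, ll_p
                    n_acc[n] += 1
                    acc = 1.0
                else:
                    acc = 0.0
                if t < n_burn:
                    scales[n] *= np.exp((acc - target_accept) / (1 + t) ** 0.6)
            if t >= n_burn:
                for n in names:
                    draws[n][c, t - n_burn] = x[n]
        acc_out[f"chain{c}"] = {n: n_acc[n] / n_iter for n in names}
    return ChainSet(
        draws=draws,
        seeds=tuple(int(ch.generate_state(1)[0] % 2**31) for ch in children),
        acceptance=acc_out,
    )


# ---------------------------------------------------------------------------
# Fast likelihood pieces for the image fits
# ---------------------------------------------------------------------------

class _FsStats:
    """Sufficient statistics of one channel's free-surface pixels."""

    def __init__(self, counts: np.ndarray, family: str):
        self.n = counts.size
        self.family = family
        self.sum = float(counts.sum())
        if family == "poisson":
            self.lgam = float(gammaln(counts + 1.0).sum())
        elif family == "gaussian":
            self.sum2 = float((counts**2).sum())
        else:  # gamma
            if np.any(counts <= 0):
                raise ValueError("gamma likelihood requires positive counts")
            self.sumlog = float(np.log(counts).sum())

    def loglik(self, mu: float, disp: float) -> float:
        if mu <= 0:
            return -np.inf
        if self.family == "poisson":
            return self.sum * np.log(mu) - self.n * mu - self.lgam
        if self.family == "gaussian":
            var = disp * mu
            return -0.5 * (
                self.n * np.log(2 * np.pi * var)
                + (self.sum2 - 2 * mu * self.sum + self.n * mu * mu) / var
            )
        a = disp
        return (
            (a - 1) * self.sumlog
            - (a / mu) * self.sum
            - self.n * (a * np.log(mu / a) + gammaln(a))
        )


def _ci_loglik_vec(counts, mean, family: str, disp: float):
    """Per-pixel log-likelihood vector (constants in counts retained)."""
    if family == "poisson":
        return counts * np.log(mean) - mean - gammaln(counts + 1.0)
    if family == "gaussian":
        var = disp * mean
        return -0.5 * (np.log(2 * np.pi * var) + (counts - mean) ** 2 / var)
    a = disp
    with np.errstate(divide="ignore"):
        return (a - 1) * np.log(counts) - (a / mean) * counts - a * np.log(mean / a) - gammaln(a)


def _validate_regions(fs_mask, ci_mask):
    fs_mask = np.asarray(fs_mask, bool)
    ci_mask = np.asarray(ci_mask, bool)
    if np.any(fs_mask & ci_mask):
        raise ValueError("region masks must be disjoint")
    deficient = []
    if ci_mask.sum() < 50:
        deficient.append(f"contact_interface ({int(ci_mask.sum())} px)")
    if fs_mask.sum() < 50:
        deficient.append(f"free_surface ({int(fs_mask.sum())} px)")
    if deficient:
        raise ValueError(
            "under-identified fit; regions with fewer than 50 pixels: "
            + ", ".join(deficient)
        )
    return fs_mask, ci_mask


class _RunningMoments:
    def __init__(self, n_chains, n_px):
        self.counts = np.zeros(n_chains, dtype=int)
        self.mean = np.zeros((n_chains, n_px))
        self.m2 = np.zeros((n_chains, n_px))

    def update(self, c, x):
        self.counts[c] += 1
        d = x - self.mean[c]
        self.mean[c] += d / self.counts[c]
        self.m2[c] += d * (x - self.mean[c])

    @property
    def count(self):
        return int(self.counts.max())

    def var(self):
        return self.m2 / np.maximum(self.counts - 1, 1)[:, None]


def _summarise_global(draws: np.ndarray) -> dict:
    pooled = draws.ravel()
    lo, hi = np.percentile(pooled, [2.5, 97.5])
    return {
        "mean": float(pooled.mean()),
        "sd": float(pooled.std(ddof=1)),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "rhat": _rhat_array(draws),
    }


def _fit_mcmc(
    counts_small,
    counts_long,
    fs_mask,
    ci_mask,
    spec: FluorModelSpec,
    priors: PriorSpec,
    constrained: bool,
    n_chains: int,
    n_iter: int,
    seed: int | None,
):
    """Shared Metropolis-within-Gibbs core of both fits."""
    fs_mask, ci_mask = _validate_regions(fs_mask, ci_mask)
    counts_small = np.asarray(counts_small, float)
    counts_long = np.asarray(counts_long, float)
    fam = spec.noise_family
    fixed_disp = fam == "poisson"
    S_fs = _FsStats(counts_small[fs_mask], fam)
    L_fs = _FsStats(counts_long[fs_mask], fam)
    S = counts_small[ci_mask]
    L = counts_long[ci_mask]
    n_px = S.size
    bgs, bgl = spec.bg_small, spec.bg_long

    gnames = list(priors.bounds)
    n_burn = n_iter // 2
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_chains)
    draws = {n: np.empty((n_chains, n_iter - n_burn)) for n in gnames}
    mom_eC = _RunningMoments(n_chains, n_px)
    mom_eI = _RunningMoments(n_chains, n_px)
    acc_out = {}

    # moment-based initial guesses (jittered per chain below); Gamma is
    # started at the excluded-pixel floor estimate because the joint
    # posterior has a long (Gamma, {e_C}) ridge that random-walk updates
    # traverse slowly
    mu_s0 = max(S_fs.sum / S_fs.n - bgs, 1e-2)
    floor0 = float(np.percentile(S, 3)) - bgs
    init0 = {
        "mu_fs_small": mu_s0,
        "mu_fs_long": max(L_fs.sum / L_fs.n - bgl, 1e-2),
        "A_B": max(float(np.percentile(S, 98)) - 0.7 * (S_fs.sum / S_fs.n), 1.0),
        "Gamma_barrier": float(np.clip(floor0 / mu_s0, 0.05, 0.99)),
        "overdispersion": spec.overdispersion,
        "alpha": 1.5,
        "beta": 1.0,
    }

    def mean_small(g, eC):
        return g["Gamma_barrier"] * g["mu_fs_small"] + g["A_B"] * np.exp(-(eC**2)) + bgs

    def mean_long(g, eI):
        return g["mu_fs_long"] * np.exp(-(eI**2)) + bgl

    for c, child in enumerate(children):
        rng = np.random.default_rng(child)
        g = {}
        for n in gnames:
            lo, hi = priors.bounds[n]
            v = init0.get(n, 0.5 * (lo + hi))
            v = v * np.exp(0.05 * rng.standard_normal()) if n != "Gamma_barrier" else v
            g[n] = float(np.clip(v, lo + 1e-9, hi - 1e-9))
        disp = g.get("overdispersion", spec.overdispersion)
        # local inits: invert the mean relations at the initial globals
        floor = g["Gamma_barrier"] * g["mu_fs_small"] + bgs
        ratio = np.clip((S - floor) / g["A_B"], 1e-4, 1.0)
        eC = np.sqrt(-np.log(ratio))
        ratio_l = np.clip((L - bgl) / g["mu_fs_long"], 1e-4, 1.0)
        eI = np.sqrt(-np.log(ratio_l))
        eC = _reflect(eC + 0.05 * rng.standard_normal(n_px), 0, priors.e_max)
        eI = _reflect(eI + 0.05 * rng.standard_normal(n_px), 0, priors.e_max)
        if constrained:
            # the constrained local is the normalised hidden separation
            # z_hat, uniform on a bounded interval containing [0, 1]; the
            # quadratic spring model gives e_C = (alpha/beta)|z_hat| and
            # e_I = alpha|1 - z_hat| (energies fold back up outside the
            # natural lengths, so no boundary clamp is needed)
            zh = np.clip(eC * g["beta"] / g["alpha"], *priors.z_hat_bounds)
            eC = (g["alpha"] / g["beta"]) * np.abs(zh)
            eI = g["alpha"] * np.abs(1.0 - zh)

        ll_s = _ci_loglik_vec(S, mean_small(g, eC), fam, disp)
        ll_l = _ci_loglik_vec(L, mean_long(g, eI), fam, disp)
        ll_fs = S_fs.loglik(g["mu_fs_small"] + bgs, disp) + L_fs.loglik(
            g["mu_fs_long"] + bgl, disp)

        gscales = {n: 0.05 * max(abs(g[n]), 0.1) for n in gnames}
        lscale_C = np.full(n_px, 0.2)
        lscale_I = np.full(n_px, 0.2)
        n_acc = {n: 0 for n in gnames}
        n_acc_loc = {"e_C": 0.0, "e_I": 0.0}

        for t in range(n_iter):
            adapt = t < n_burn
            # --- global parameters, one at a time ---
            for n in gnames:
                lo, hi = priors.bounds[n]
                gp = dict(g)
                gp[n] = float(_reflect(g[n] + gscales[n] * rng.standard_normal(), lo, hi))
                disp_p = gp.get("overdispersion", spec.overdispersion)
                if constrained and n in ("alpha", "beta"):
                    eC_p = (gp["alpha"] / gp["beta"]) * np.abs(zh)
                    eI_p = gp["alpha"] * np.abs(1.0 - zh)
                else:
                    eC_p, eI_p = eC, eI
                touch_s = n in ("mu_fs_small", "A_B", "Gamma_barrier",
                                "overdispersion", "alpha", "beta")
                touch_l = n in ("mu_fs_long", "overdispersion", "alpha", "beta")
                ll_s_p = (_ci_loglik_vec(S, mean_small(gp, eC_p), fam, disp_p)
                          if touch_s else ll_s)
                ll_l_p = (_ci_loglik_vec(L, mean_long(gp, eI_p), fam, disp_p)
                          if touch_l else ll_l)
                ll_fs_p = (S_fs.loglik(gp["mu_fs_small"] + bgs, disp_p)
                           + L_fs.loglik(gp["mu_fs_long"] + bgl, disp_p))
                d = (ll_fs_p - ll_fs) + (ll_s_p.sum() - ll_s.sum()) + (ll_l_p.sum() - ll_l.sum())
                if np.log(rng.uniform()) < d:
                    g, ll_s, ll_l, ll_fs = gp, ll_s_p, ll_l_p, ll_fs_p
                    eC, eI = eC_p, eI_p
                    disp = disp_p
                    n_acc[n] += 1
                    a = 1.0
                else:
                    a = 0.0
                if adapt:
                    gscales[n] *= np.exp((a - 0.3) / (1 + t) ** 0.6)

            # --- per-pixel block: z_hat (constrained) or e_C ---
            if constrained:
                zh_p = _reflect(zh + lscale_C * rng.standard_normal(n_px),
                                *priors.z_hat_bounds)
                eC_p = (g["alpha"] / g["beta"]) * np.abs(zh_p)
                eI_p = g["alpha"] * np.abs(1.0 - zh_p)
                ll_s_p = _ci_loglik_vec(S, mean_small(g, eC_p), fam, disp)
                ll_l_p = _ci_loglik_vec(L, mean_long(g, eI_p), fam, disp)
                d = (ll_s_p - ll_s) + (ll_l_p - ll_l)
            else:
                eC_p = _reflect(eC + lscale_C * rng.standard_normal(n_px),
                                0, priors.e_max)
                ll_s_p = _ci_loglik_vec(S, mean_small(g, eC_p), fam, disp)
                d = ll_s_p - ll_s
            acc = np.log(rng.uniform(size=n_px)) < d
            eC = np.where(acc, eC_p, eC)
            ll_s = np.where(acc, ll_s_p, ll_s)
            if constrained:
                zh = np.where(acc, zh_p, zh)
                eI = np.where(acc, eI_p, eI)
                ll_l = np.where(acc, ll_l_p, ll_l)
            n_acc_loc["e_C"] += acc.mean()
            if adapt:
                lscale_C *= np.exp((acc - 0.44) / (1 + t) ** 0.6)

            # --- per-pixel block: e_I (unconstrained only) ---
            if not constrained:
                eI_p = _reflect(eI + lscale_I * rng.standard_normal(n_px), 0, priors.e_max)
                ll_l_p = _ci_loglik_vec(L, mean_long(g, eI_p), fam, disp)
                acc = np.log(rng.uniform(size=n_px)) < ll_l_p - ll_l
                eI = np.where(acc, eI_p, eI)
                ll_l = np.where(acc, ll_l_p, ll_l)
                n_acc_loc["e_I"] += acc.mean()
                if adapt:
                    lscale_I *= np.exp((acc - 0.44) / (1 + t) ** 0.6)

            if t >= n_burn:
                for n in gnames:
                    draws[n][c, t - n_burn] = g[n]
                mom_eC.update(c, eC)
                mom_eI.update(c, eI)

        acc_out[f"chain{c}"] = {
            **{n: n_acc[n] / n_iter for n in gnames},
            "e_C": n_acc_loc["e_C"] / n_iter,
            "e_I": n_acc_loc["e_I"] / n_iter,
        }

    chains = ChainSet(
        draws=draws,
        seeds=tuple(int(ch.generate_state(1)[0] % 2**31) for ch in children),
        acceptance=acc_out,
        local_moments={
            "e_C": {"mean": mom_eC.mean, "var": mom_eC.var(), "n": mom_eC.count},
            "e_I": {"mean": mom_eI.mean, "var": mom_eI.var(), "n": mom_eI.count},
        },
    )
    return chains, int(fs_mask.sum()), n_px


def _pixel_summary(chains: ChainSet) -> dict:
    out = {}
    for name, m in chains.local_moments.items():
        mu = m["mean"]          # (n_chains, n_px)
        var = m["var"]
        n = m["n"]
        pooled_mean = mu.mean(axis=0)
        # law of total variance across chains
        pooled_var = var.mean(axis=0) + mu.var(axis=0)
        W = var.mean(axis=0)
        B_over_n = mu.var(axis=0, ddof=1) if mu.shape[0] > 1 else np.zeros_like(pooled_mean)
        with np.errstate(divide="ignore", invalid="ignore"):
            rhat = np.sqrt((n - 1) / n + B_over_n / np.where(W > 0, W, np.nan))
        rhat = np.where(np.isfinite(rhat), rhat, 1.0)
        out[f"{name}_mean"] = pooled_mean
        out[f"{name}_sd"] = np.sqrt(np.maximum(pooled_var, 0.0))
        out[f"{name}_rhat_max"] = float(np.nanmax(rhat))
    return out


def _tls_line(e_C_mean, e_C_sd, e_I_mean, e_I_sd, sd_max: float | None = None) -> dict:
    """Weighted total-least-squares line through posterior-mean SQREs.

    With ``sd_max`` set, the fit uses only pixels whose posterior sds are
    below it in both coordinates: at the signal-to-noise edges (complex
    fully excluded, or long ligand fully excluded) the energies are
    prior-dominated and their posterior means are boundary-biased, which
    would attenuate the slope; identified pixels carry the line.  Falls
    back to all pixels when fewer than 50 qualify.
    """
    from scipy import odr

    n_total = e_C_mean.size
    if sd_max is not None:
        # identified in both coordinates, and detected (a posterior piled
        # against the e >= 0 boundary has a folded, upward-biased mean)
        keep = ((e_C_sd < sd_max) & (e_I_sd < sd_max)
                & (e_C_mean > 2 * e_C_sd) & (e_I_mean > 2 * e_I_sd))
        if keep.sum() >= 50:
            e_C_mean, e_C_sd = e_C_mean[keep], e_C_sd[keep]
            e_I_mean, e_I_sd = e_I_mean[keep], e_I_sd[keep]
    sx = np.maximum(e_C_sd, 0.02)
    sy = np.maximum(e_I_sd, 0.02)
    data = odr.RealData(e_C_mean, e_I_mean, sx=sx, sy=sy)
    # seed with weighted OLS
    w = 1.0 / (sy**2)
    X = np.vstack([np.ones_like(e_C_mean), e_C_mean]).T
    b0, b1 = np.linalg.lstsq(X * w[:, None] ** 0.5, e_I_mean * w**0.5, rcond=None)[0]
    out = odr.ODR(data, odr.unilinear, beta0=[b1, b0]).run()
    slope, intercept = float(out.beta[0]), float(out.beta[1])
    return {
        "slope": slope,
        "intercept": intercept,
        "slope_magnitude": abs(slope),
        "slope_sd": float(out.sd_beta[0]),
        "intercept_sd": float(out.sd_beta[1]),
        "n_used": int(e_C_mean.size),
        "n_total": int(n_total),
        "sd_max": sd_max,
    }


def fit_unconstrained(
    counts_small,
    counts_long,
    fs_mask,
    ci_mask,
    spec: FluorModelSpec | None = None,
    priors: PriorSpec | None = None,
    n_chains: int = 4,
    n_iter: int = 4000,
    seed: int | None = None,
) -> PosteriorSummary:
    """Joint fit of globals and independent per-pixel (e_C, e_I).

    The returned summary includes the weighted TLS regression line
    through the posterior-mean SQRE scatter -- the measured counterpart
    of the predicted line e_I = alpha - beta e_C.
    """
    spec = spec or FluorModelSpec()
    priors = priors or _default_prior(False, spec.noise_family)
    chains, n_fs, n_ci = _fit_mcmc(
        counts_small, counts_long, fs_mask, ci_mask, spec, priors,
        constrained=False, n_chains=n_chains, n_iter=n_iter, seed=seed,
    )
    params = {n: _summarise_global(d) for n, d in chains.draws.items()}
    pixel = _pixel_summary(chains)
    line = _tls_line(pixel["e_C_mean"], pixel["e_C_sd"],
                     pixel["e_I_mean"], pixel["e_I_sd"], sd_max=0.35)
    return PosteriorSummary(
        mode="unconstrained", params=params, chains=chains, pixel=pixel,
        line=line, spec_template=spec, n_ci=n_ci, n_fs=n_fs, seed=seed,
    )


def fit_constrained(
    counts_small,
    counts_long,
    fs_mask,
    ci_mask,
    spec: FluorModelSpec | None = None,
    priors: PriorSpec | None = None,
    n_chains: int = 4,
    n_iter: int = 4000,
    seed: int | None = None,
) -> PosteriorSummary:
    """Fit with the SQRE line imposed: globals + (alpha, beta) + one
    latent e_C per pixel, e_I = max(0, alpha - beta e_C)."""
    spec = spec or FluorModelSpec()
    priors = priors or _default_prior(True, spec.noise_family)
    if "alpha" not in priors.bounds or "beta" not in priors.bounds:
        raise ValueError("constrained fit requires alpha and beta priors")
    chains, n_fs, n_ci = _fit_mcmc(
        counts_small, counts_long, fs_mask, ci_mask, spec, priors,
        constrained=True, n_chains=n_chains, n_iter=n_iter, seed=seed,
    )
    params = {n: _summarise_global(d) for n, d in chains.draws.items()}
    pixel = _pixel_summary(chains)
    line = {"alpha": params["alpha"]["mean"], "beta": params["beta"]["mean"]}
    return PosteriorSummary(
        mode="constrained", params=params, chains=chains, pixel=pixel,
        line=line, spec_template=spec, n_ci=n_ci, n_fs=n_fs, seed=seed,
    )


# ---------------------------------------------------------------------------
# Diagnostics and posterior functionals
# ---------------------------------------------------------------------------

def _rhat_array(draws: np.ndarray) -> float:
    """Classic Gelman--Rubin potential scale reduction for (m, n) draws."""
    draws = np.asarray(draws, float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need draws shaped (n_chains >= 2, n_iter)")
    m, n = draws.shape
    W = draws.var(axis=1, ddof=1).mean()
    B_over_n = draws.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0 if B_over_n == 0 else np.inf
    var_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_hat / W))


def gelman_rubin(chains: ChainSet | np.ndarray) -> dict | float:
    """Potential scale reduction R-hat.

    Accepts a :class:`ChainSet` (returns name -> R-hat) or a raw (m, n)
    array (returns a float).  Identical duplicated chains give R-hat
    slightly below 1 (the classic (n-1)/n factor); a degenerate-variance
    chain set (all draws equal) is reported as exactly 1.
    """
    if isinstance(chains, np.ndarray):
        return _rhat_array(chains)
    return {n: _rhat_array(d) for n, d in chains.draws.items()}


def slope_unity_test(summary: PosteriorSummary) -> dict:
    """Posterior evidence on whether the SQRE slope magnitude equals 1.

    A unit slope means equal spring constants for the complex and the
    long ligand; the measured asymmetry (beta != 1) is the signature
    that accommodating the unbound long protein is energetically cheaper
    than stretching the bond.
    """
    if "beta" not in summary.chains.draws:
        raise ValueError("summary has no beta draws (run fit_constrained)")
    b = summary.chains.draws["beta"].ravel()
    lo, hi = np.percentile(b, [2.5, 97.5])
    return {
        "p_beta_gt_1": float((b > 1).mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "one_in_ci": bool(lo <= 1.0 <= hi),
        "mean": float(b.mean()),
    }


def patternation_posterior(summary: PosteriorSummary, p=None, n_grid: int = 400) -> dict:
    """Posterior probability that the SQRE line crosses the instability region.

    Evaluates, for every posterior draw of (alpha, beta), whether the
    k = 0 margin is positive anywhere along the line (the patternation
    test); returns the fraction of intersecting draws and the per-draw
    mask.  Elastic parameters drop out at k = 0, so no dynamics
    parameters are needed beyond the line itself.
    """
    if "alpha" not in summary.chains.draws:
        raise ValueError("summary has no (alpha, beta) draws")
    a = summary.chains.draws["alpha"].ravel()
    b = summary.chains.draws["beta"].ravel()
    t = np.linspace(1e-4, 1 - 1e-4, n_grid)
    # parametrise the line by t: e_C = t*alpha/beta, e_I = alpha*(1-t)
    eC = t[None, :] * (a / b)[:, None]
    eI = a[:, None] * (1 - t)[None, :]
    g = sqre_margin(eC, eI, b[:, None])
    intersects = (g > 0).any(axis=1)
    return {
        "p_intersect": float(intersects.mean()),
        "per_draw": intersects,
        "n_draws": int(a.size),
    }


def reconstruct_separation(
    summary: PosteriorSummary,
    springs: SpringParams,
    bins: int = 60,
) -> dict:
    """Per-pixel posterior-mean hidden separation z_hat and its histogram.

    z_hat = 0 at the complex bond length, 1 at the long-ligand length.
    Modes of the histogram are located by kernel density estimation; a
    two-phase interface shows one mode near 0 (enriched small-ligand
    phase) and one near 1 (complex-excluded phase).
    """
    e_C = summary.pixel["e_C_mean"]
    z_hat = separation_from_sqre(e_C, springs).z_hat
    hist, edges = np.histogram(z_hat, bins=bins, range=(-0.1, 1.4), density=True)
    from scipy.stats import gaussian_kde

    grid = np.linspace(-0.1, 1.4, 400)
    if np.ptp(z_hat) < 1e-12:  # degenerate: all pixels at one separation
        kde = np.zeros_like(grid)
        peaks = [float(z_hat.ravel()[0])]
    else:
        kde = gaussian_kde(z_hat, bw_method=0.15)(grid)
        peaks = [
            float(grid[i])
            for i in range(1, len(grid) - 1)
            if kde[i] > kde[i - 1] and kde[i] >= kde[i + 1] and kde[i] > 0.1 * kde.max()
        ]
    return {
        "z_hat": z_hat,
        "hist": hist,
        "bin_edges": edges,
        "modes": peaks,
        "kde_grid": grid,
        "kde": kde,
    }
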