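"""Maximum-likelihood merging of partiality-corrected integrated intensities.

Given integrated intensity observations from many still patterns, the
merger jointly estimates one merged intensity per symmetry-unique
reflection and, per crystal, the parameters of the Gaussian diffraction
kernel (reciprocal cell, peak-shape covariance, mosaicity, strain, linear
scale and B factor), plus a global two-parameter error model.  Each
observation is compared with ``coef * I_merged`` where ``coef`` carries
the closed-form partiality correction; the likelihood is a Gaussian mixed
with a fixed-weight Cauchy outlier component whose slow tail keeps wild
observations from dominating.

Optimization alternates closed-ish blocks -- per-reflection intensities by
bounded 1-D search, per-crystal parameters by quasi-Newton with exact
forward-mode gradients, error model globally -- accepting a block update
only when it improves the total likelihood, so the likelihood trace is
non-decreasing by construction.  The overall scale gauge (intensities up,
crystal scales down) is fixed by normalizing the mean crystal scale to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from . import chain
from .beam import BeamModel
from .crystal import CrystalModel

__all__ = [
    "ReflectionObservation",
    "MergeConfig",
    "MergeState",
    "asu_index",
    "observation_loglikelihood",
    "merge",
    "measured_partiality",
    "monte_carlo_merge",
    "fit_cauchy_gamma",
]

_LOG_2PI = math.log(2.0 * math.pi)

OBSERVATION_COLUMNS = ["crystal_id", "h", "k", "l", "I", "sigma", "panel", "fs", "ss"]


@dataclass(frozen=True)
class ReflectionObservation:
    """One integrated intensity observation on one still pattern."""

    crystal_id: int
    hkl: tuple
    intensity: float
    sigma_counting: float
    panel: str = "panel0"
    fs: float = 0.0
    ss: float = 0.0

    def __post_init__(self):
        if self.sigma_counting <= 0:
            raise ValueError("sigma_counting must be positive")


@dataclass
class MergeConfig:
    """Knobs of the merging optimizer.

    ``laue``: symmetry used for the unique-reflection reduction; ``"-1"``
    merges Friedel pairs (default, matching triclinic data without
    anomalous signal), ``"1"`` keeps h and -h separate.
    ``epsilon``: outlier mixture weight (default 1/16).
    ``gamma``: Cauchy outlier scale; fitted from the global intensity
    histogram when None (the value is data-set specific).
    """

    laue: str = "-1"
    epsilon: float = 1.0 / 16.0
    gamma: float | None = None
    alpha0: float = 1.0
    beta0: float = 1e-4
    max_outer: int = 8
    tol: float = 1e-6
    min_obs_per_crystal: int = 5
    intensity_floor: float = 1e-10
    crystal_maxiter: int = 60
    warmup_passes: int = 2
    gain: float = 1.0
    fit_crystals: bool = True
    fit_error_model: bool = True


@dataclass
class MergeState:
    """Current parameter set of a merging run."""

    crystals: dict
    beam: BeamModel
    merged: dict  # asu hkl tuple -> intensity
    alpha: float
    beta: float
    epsilon: float
    gamma: float
    cauchy_x0: float = 0.0
    loglik_trace: list = field(default_factory=list)
    #: Gaussian-information standard error of each merged intensity; a
    #: reflection observed only deep in the overprediction tail has a huge
    #: sigma here and its merged value is essentially unconstrained.
    merged_sigma: dict = field(default_factory=dict)
    n_obs: dict = field(default_factory=dict)


def asu_index(hkl: np.ndarray, laue: str = "-1") -> np.ndarray:
    """Map Miller indices to their symmetry-unique representative.

    For Laue class ``-1`` the representative of {h, -h} is the
    lexicographically larger triple; class ``1`` is the identity.
    """
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    if laue == "1":
        return hkl.copy()
    if laue != "-1":
        raise ValueError(f"unsupported Laue class {laue!r} (use '1' or '-1')")
    neg = -hkl
    keys = hkl[:, 0] * 4_000_000 + hkl[:, 1] * 2_000 + hkl[:, 2]
    nkeys = neg[:, 0] * 4_000_000 + neg[:, 1] * 2_000 + neg[:, 2]
    take_neg = nkeys > keys
    out = hkl.copy()
    out[take_neg] = neg[take_neg]
    return out


def fit_cauchy_gamma(intensities: np.ndarray) -> float:
    """ML scale of a zero-centred Cauchy fitted to all intensities.

    Used as the default outlier scale; the outlier distribution should
    describe the measured intensities in general, without prediction or
    scaling.
    """
    I = np.asarray(intensities, dtype=float)
    I = I[np.isfinite(I)]

    def neg(log_g):
        g = math.exp(log_g)
        return -np.sum(np.log(g / (math.pi * (I**2 + g**2))))

    res = minimize_scalar(neg, bounds=(math.log(1e-6 + np.abs(I).mean() * 1e-3),
                                       math.log(np.abs(I).max() + 1.0)),
                          method="bounded")
    return float(math.exp(res.x))


def _cauchy_logpdf(x, gamma, x0=0.0):
    return np.log(gamma / math.pi) - np.log((np.asarray(x, float) - x0) ** 2 + gamma**2)


def _mixture_loglik(I_obs, pred, var, eps, gamma, x0=0.0):
    """Vectorized log[(1-eps) N(I; pred, var) + eps Cauchy(I; x0, gamma)]."""
    lg = -0.5 * ((I_obs - pred) ** 2 / var + np.log(var) + _LOG_2PI)
    if eps == 0:
        return lg
    lo = _cauchy_logpdf(I_obs, gamma, x0)
    return np.logaddexp(lg + math.log1p(-eps), lo + math.log(eps))


def _coef_partiality(crystal: CrystalModel, beam: BeamModel, hkl: np.ndarray, gain: float):
    t = chain.reflection_terms(
        crystal.R,
        crystal.shape_cov,
        crystal.mosaicity,
        crystal.strain,
        crystal.scale_a,
        crystal.b_factor,
        hkl,
        beam,
        gain=gain,
    )
    return t.coef, t.partiality


def observation_loglikelihood(obs: ReflectionObservation, state: MergeState) -> float:
    """Mixture log-likelihood of a single observation under a merge state."""
    crystal = state.crystals[obs.crystal_id]
    hkl = np.asarray(obs.hkl, dtype=float).reshape(1, 3)
    coef, _ = _coef_partiality(crystal, state.beam, hkl, gain=1.0)
    asu = tuple(asu_index(np.asarray(obs.hkl).reshape(1, 3))[0])
    I_m = state.merged.get(asu, 0.0)
    pred = float(coef[0]) * I_m
    var = state.alpha * obs.sigma_counting**2 + state.beta * pred**2
    return float(
        _mixture_loglik(
            np.array([obs.intensity]), np.array([pred]), np.array([var]),
            state.epsilon, state.gamma, state.cauchy_x0,
        )[0]
    )


# ---------------------------------------------------------------------------
# the merging engine
# ---------------------------------------------------------------------------

class _Problem:
    """Flat arrays + bookkeeping shared by all optimization blocks."""

    def __init__(self, observations: pd.DataFrame, crystals: dict, beam: BeamModel,
                 cfg: MergeConfig):
        df = observations
        missing = [c for c in ("crystal_id", "h", "k", "l", "I", "sigma") if c not in df]
        if missing:
            raise ValueError(f"observation table lacks columns {missing}")
        counts = df.groupby("crystal_id").size()
        bad = counts[counts < cfg.min_obs_per_crystal]
        if len(bad):
            raise ValueError(
                f"crystals with fewer than {cfg.min_obs_per_crystal} observations: "
                f"{list(bad.index)[:10]}"
            )
        for cid in counts.index:
            if cid not in crystals:
                raise KeyError(f"no initial crystal model for crystal_id {cid}")
        self.cfg = cfg
        self.beam = beam
        self.I_obs = df["I"].to_numpy(dtype=float)
        self.sigma2 = df["sigma"].to_numpy(dtype=float) ** 2
        self.hkl = df[["h", "k", "l"]].to_numpy(dtype=int)
        asu = asu_index(self.hkl, cfg.laue)
        uniq, self.asu_of = np.unique(asu, axis=0, return_inverse=True)
        self.asu_hkl = [tuple(int(i) for i in row) for row in uniq]
        self.n_asu = len(self.asu_hkl)
        cids = df["crystal_id"].to_numpy()
        self.crystal_ids = list(dict.fromkeys(cids.tolist()))
        self.slices = {cid: np.flatnonzero(cids == cid) for cid in self.crystal_ids}
        self.theta = {cid: chain.crystal_to_theta(crystals[cid]) for cid in self.crystal_ids}
        self.coef = np.empty(len(df))
        self.part = np.empty(len(df))
        for cid in self.crystal_ids:
            self._refresh_coef(cid)
        # observations grouped per unique reflection
        order = np.argsort(self.asu_of, kind="stable")
        bounds = np.searchsorted(self.asu_of[order], np.arange(self.n_asu + 1))
        self.groups = [order[bounds[j]: bounds[j + 1]] for j in range(self.n_asu)]

    def _refresh_coef(self, cid):
        idx = self.slices[cid]
        c = chain.theta_to_crystal(self.theta[cid])
        coef, part = _coef_partiality(c, self.beam, self.hkl[idx].astype(float), self.cfg.gain)
        self.coef[idx] = coef
        self.part[idx] = part

    def crystal(self, cid) -> CrystalModel:
        return chain.theta_to_crystal(self.theta[cid])


def _total_loglik(prob: _Problem, I_asu, alpha, beta, eps, gamma):
    pred = prob.coef * I_asu[prob.asu_of]
    var = alpha * prob.sigma2 + beta * pred**2
    return float(_mixture_loglik(prob.I_obs, pred, var, eps, gamma).sum())


def _init_intensities(prob: _Problem, alpha) -> np.ndarray:
    w = prob.coef / (alpha * prob.sigma2)
    num = np.bincount(prob.asu_of, weights=w * prob.I_obs, minlength=prob.n_asu)
    den = np.bincount(prob.asu_of, weights=w * prob.coef, minlength=prob.n_asu)
    I = np.divide(num, den, out=np.zeros(prob.n_asu), where=den > 0)
    return np.clip(I, prob.cfg.intensity_floor, None)


def _update_intensities(prob: _Problem, I_asu, alpha, beta, eps, gamma):
    """Per-reflection 1-D ML update (multi-start, accept if improved).

    The Gaussian + Cauchy mixture is multimodal in the intensity (a bad
    start can park every observation in the outlier component), so the
    bounded search is restarted from robust candidates: the current value,
    the precision-weighted least-squares solution, and the median of the
    per-observation estimates with non-negligible partiality coefficient.
    """
    floor = prob.cfg.intensity_floor
    for j, idx in enumerate(prob.groups):
        if idx.size == 0:
            continue
        Io = prob.I_obs[idx]
        k = prob.coef[idx]
        s2 = alpha * prob.sigma2[idx]

        def neg(I):
            pred = k * I
            var = s2 + beta * pred**2
            return -float(_mixture_loglik(Io, pred, var, eps, gamma).sum())

        cur = float(I_asu[j])
        kmax = float(np.max(k))
        if kmax <= 0:
            continue
        wls_num = float(np.sum(k * Io / s2))
        wls_den = float(np.sum(k * k / s2))
        wls = max(wls_num / wls_den, floor) if wls_den > 0 else cur
        strong = k > 0.1 * kmax
        med = max(float(np.median(Io[strong] / k[strong])), floor) if strong.any() else cur
        hi = max(floor * 10.0, 4.0 * float(np.max(np.abs(Io))) / kmax, 2.0 * cur)
        # coarse log-grid scan first: the mixture profile can have a narrow
        # Gaussian dip inside a flat outlier-dominated plateau, which a
        # bare bracketing search walks straight past
        cand = np.unique(np.concatenate([
            np.geomspace(max(floor, hi * 1e-8), hi, 48),
            [c for c in (cur, wls, med) if c > 0],
        ]))
        vals = np.array([neg(c) for c in cand])
        b = int(np.argmin(vals))
        best_I, best_f = float(cand[b]), float(vals[b])
        res = minimize_scalar(neg, bounds=(max(floor, best_I / 4.0), best_I * 4.0),
                              method="bounded", options={"xatol": 1e-8 * best_I})
        if res.fun < best_f:
            best_I, best_f = float(res.x), float(res.fun)
        if best_f < neg(cur):
            I_asu[j] = best_I
    return I_asu


def _crystal_objective(theta, prob: _Problem, cid, I_obs_c, I_pred_target, sigma2_c,
                       hkl_c, alpha, beta, eps, gamma):
    """Negative log-likelihood and exact gradient for one crystal block.

    Steps that wander into numerical overflow return a large finite value
    so the line search backtracks instead of propagating NaNs.
    """
    P = chain.N_CRYSTAL_PARAMS
    try:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            R, shape_cov, sigm, sigs, a, B = chain.theta_to_duals(theta, nparams=P)
            t = chain.reflection_terms(R, shape_cov, sigm, sigs, a, B, hkl_c,
                                       prob.beam, gain=prob.cfg.gain)
            pred = t.coef * I_pred_target  # Dual (N,)
            var = alpha * sigma2_c + (pred**2) * beta
            resid = pred - I_obs_c
            lg = (resid**2 / var + var.log() + _LOG_2PI) * (-0.5)
            if eps == 0:
                total = lg.sum()
            else:
                lo = _cauchy_logpdf(I_obs_c, gamma)
                shift = np.maximum(lg.val + math.log1p(-eps), lo + math.log(eps))
                mix = (lg + (math.log1p(-eps) - shift)).exp() + np.exp(
                    lo + math.log(eps) - shift
                )
                total = (mix.log() + shift).sum()
            f, g = -float(total.val), -total.grad
    except (np.linalg.LinAlgError, FloatingPointError):
        return 1e30, np.zeros(P)
    if not (np.isfinite(f) and np.all(np.isfinite(g))):
        return 1e30, np.zeros(P)
    return f, g


def _crystal_bounds(theta0: np.ndarray) -> list:
    """Generous box bounds that keep log-parameters in sane territory."""
    b = []
    rmax = 2.0 * float(np.abs(theta0[:9]).max()) + 0.05
    for i in range(9):
        b.append((-rmax, rmax))
    for k in range(6):
        if k in (0, 2, 5):  # log-diagonal Cholesky entries
            b.append((math.log(1e-6), math.log(0.5)))
        else:
            b.append((-0.5, 0.5))
    b.append((math.log(1e-7), math.log(0.3)))  # log mosaicity (rad)
    b.append((math.log(1e-7), math.log(0.3)))  # log strain
    b.append((-6.0, 6.0))  # log scale
    b.append((-2.0, 20.0))  # B (nm^2)
    return b


def _crystal_scales(theta0: np.ndarray) -> np.ndarray:
    """Diagonal preconditioner: typical per-parameter variation.

    The likelihood is orders of magnitude more sensitive to reciprocal-cell
    entries (a 1e-3 relative cell change moves peaks by a full excitation
    width) than to the log-parameterized disorder terms; without rescaling
    a quasi-Newton method crawls.
    """
    s = np.empty(chain.N_CRYSTAL_PARAMS)
    s[:9] = 1e-3 * max(float(np.abs(theta0[:9]).max()), 1e-6)
    s[9:15] = [0.3 if k in (0, 2, 5) else 1e-3 for k in range(6)]
    s[15] = 0.3  # log mosaicity
    s[16] = 0.3  # log strain
    s[17] = 0.2  # log scale
    s[18] = 0.02  # B
    return s


#: step limit for reciprocal-cell entries within one quasi-Newton stage, in
#: units of the cell preconditioner (1e-3 of the largest entry): peaks may
#: move by at most a few excitation widths per stage, which keeps the
#: refinement inside the local basin the indexing solution defines.
_CELL_STEP_UNITS = 4.0


def _update_crystals(prob: _Problem, I_asu, alpha, beta, eps, gamma):
    """Per-crystal staged quasi-Newton refinement (accept if improved).

    The likelihood is locally crinkly in the reciprocal cell (moving a peak
    by more than its excitation width swaps which observations it explains),
    so each pass first refines the smooth parameters (shape, mosaicity,
    strain, scale, B) with the cell frozen, then refines everything with
    the cell step-limited to a few excitation widths.
    """
    P = chain.N_CRYSTAL_PARAMS
    mask_nocell = np.ones(P)
    mask_nocell[:9] = 0.0
    mask_all = np.ones(P)
    for cid in prob.crystal_ids:
        idx = prob.slices[cid]
        hkl_c = prob.hkl[idx].astype(float)
        I_t = I_asu[prob.asu_of[idx]]
        args = (prob, cid, prob.I_obs[idx], I_t, prob.sigma2[idx], hkl_c,
                alpha, beta, eps, gamma)
        th0 = prob.theta[cid].copy()
        scale = _crystal_scales(th0)
        f0, _ = _crystal_objective(th0, *args)

        def stage(th_start, mask, maxiter, cell_limit=None):
            def scaled(z):
                f, g = _crystal_objective(th_start + scale * (z * mask), *args)
                return f, (g * scale) * mask

            zb = []
            for i, (lo, hi) in enumerate(_crystal_bounds(th_start)):
                if not mask[i]:
                    zb.append((0.0, 0.0))
                    continue
                zlo = (lo - th_start[i]) / scale[i]
                zhi = (hi - th_start[i]) / scale[i]
                if cell_limit is not None and i < 9:
                    zlo, zhi = max(zlo, -cell_limit), min(zhi, cell_limit)
                zb.append((zlo, zhi))
            res = minimize(scaled, np.zeros(P), jac=True, method="L-BFGS-B",
                           bounds=zb,
                           options={"maxiter": maxiter, "ftol": 1e-13})
            return th_start + scale * (res.x * mask), float(res.fun)

        it = prob.cfg.crystal_maxiter
        th_a, f_a = stage(th0, mask_nocell, it)
        th_b, f_b = stage(th_a, mask_all, 2 * it, cell_limit=_CELL_STEP_UNITS)
        best_th, best_f = min([(th0, f0), (th_a, f_a), (th_b, f_b)],
                              key=lambda p: p[1] if np.isfinite(p[1]) else np.inf)
        if best_f < f0:
            prob.theta[cid] = best_th
            prob._refresh_coef(cid)


def _update_error_model(prob: _Problem, I_asu, alpha, beta, eps, gamma):
    pred = prob.coef * I_asu[prob.asu_of]

    def neg(logab):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            a, b = np.exp(np.clip(logab, -700, 700))
            var = a * prob.sigma2 + b * pred**2
            if not np.all(var > 0):
                return 1e30
            f = -float(_mixture_loglik(prob.I_obs, pred, var, eps, gamma).sum())
        return f if np.isfinite(f) else 1e30

    x0 = np.log([alpha, max(beta, 1e-12)])
    f0 = neg(x0)
    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 200})
    if np.isfinite(res.fun) and res.fun < f0:
        x = np.clip(res.x, -700, 700)  # same clamp the objective applied
        return float(np.exp(x[0])), float(np.exp(x[1]))
    return alpha, beta


def merge(
    observations: pd.DataFrame,
    crystals: dict,
    beam: BeamModel,
    config: MergeConfig | None = None,
):
    """Joint maximum-likelihood merge of integrated still intensities.

    Parameters
    ----------
    observations : DataFrame
        Columns ``crystal_id h k l I sigma`` (detector columns optional).
    crystals : dict
        Initial :class:`CrystalModel` per crystal id (cells from indexing).
    beam : BeamModel
        Shared source description; held fixed.
    config : MergeConfig

    Returns
    -------
    (MergeState, DataFrame)
        Final state and a per-observation diagnostics table with predicted
        intensities, predicted and measured partialities and Gaussian
        responsibilities.
    """
    cfg = config or MergeConfig()
    prob = _Problem(observations, crystals, beam, cfg)
    alpha, beta, eps = cfg.alpha0, cfg.beta0, cfg.epsilon
    gamma = cfg.gamma if cfg.gamma is not None else fit_cauchy_gamma(prob.I_obs)

    I_asu = _init_intensities(prob, alpha)
    ll = _total_loglik(prob, I_asu, alpha, beta, eps, gamma)
    trace = [ll]
    for outer in range(cfg.max_outer):
        I_asu = _update_intensities(prob, I_asu, alpha, beta, eps, gamma)
        if cfg.fit_error_model:
            alpha, beta = _update_error_model(prob, I_asu, alpha, beta, eps, gamma)
        # crystal refinement only after the intensities and error model have
        # settled against the initial (indexing) models: fitting geometry
        # against raw least-squares intensities drags the disorder
        # parameters into a collapsed local optimum
        if cfg.fit_crystals and outer >= cfg.warmup_passes:
            _update_crystals(prob, I_asu, alpha, beta, eps, gamma)
            I_asu = _update_intensities(prob, I_asu, alpha, beta, eps, gamma)
        # gauge: mean crystal scale = 1 (exactly likelihood-neutral); only
        # meaningful while the scales are free parameters
        if cfg.fit_crystals:
            scales = np.array([math.exp(prob.theta[cid][17]) for cid in prob.crystal_ids])
            c = float(scales.mean())
            if c > 0 and abs(math.log(c)) > 1e-12:
                for cid in prob.crystal_ids:
                    prob.theta[cid][17] -= math.log(c)
                    prob._refresh_coef(cid)
                I_asu = I_asu * c
        ll_new = _total_loglik(prob, I_asu, alpha, beta, eps, gamma)
        trace.append(ll_new)
        if not np.isfinite(ll_new):
            raise FloatingPointError("merging likelihood became non-finite")
        if abs(ll_new - ll) <= cfg.tol * abs(ll):
            ll = ll_new
            break
        ll = ll_new

    state = MergeState(
        crystals={cid: prob.crystal(cid) for cid in prob.crystal_ids},
        beam=beam,
        merged={prob.asu_hkl[j]: float(I_asu[j]) for j in range(prob.n_asu)},
        alpha=alpha,
        beta=beta,
        epsilon=eps,
        gamma=gamma,
        loglik_trace=trace,
    )

    pred = prob.coef * I_asu[prob.asu_of]
    var = alpha * prob.sigma2 + beta * pred**2
    fisher = np.bincount(prob.asu_of, weights=prob.coef**2 / var,
                         minlength=prob.n_asu)
    sig_m = 1.0 / np.sqrt(np.maximum(fisher, 1e-300))
    counts = np.bincount(prob.asu_of, minlength=prob.n_asu)
    state.merged_sigma = {prob.asu_hkl[j]: float(sig_m[j]) for j in range(prob.n_asu)}
    state.n_obs = {prob.asu_hkl[j]: int(counts[j]) for j in range(prob.n_asu)}
    lg = math.log1p(-eps) - 0.5 * ((prob.I_obs - pred) ** 2 / var + np.log(var) + _LOG_2PI)
    lo = math.log(max(eps, 1e-300)) + _cauchy_logpdf(prob.I_obs, gamma)
    resp = 1.0 / (1.0 + np.exp(np.clip(lo - lg, -700, 700)))
    full = np.divide(pred, prob.part, out=np.zeros_like(pred), where=prob.part > 1e-300)
    measured_part = np.divide(
        prob.I_obs * prob.part, pred, out=np.zeros_like(pred), where=pred != 0
    )
    diag = pd.DataFrame(
        {
            "crystal_id": observations["crystal_id"].to_numpy(),
            "h": prob.hkl[:, 0],
            "k": prob.hkl[:, 1],
            "l": prob.hkl[:, 2],
            "I": prob.I_obs,
            "sigma": np.sqrt(prob.sigma2),
            "I_pred": pred,
            "partiality_pred": prob.part,
            "partiality_meas": measured_part,
            "I_full_pred": full,
            "responsibility": resp,
        }
    )
    return state, diag


def measured_partiality(obs: ReflectionObservation, state: MergeState) -> float:
    """Observed intensity over the predicted full (partiality-1) intensity."""
    crystal = state.crystals[obs.crystal_id]
    hkl = np.asarray(obs.hkl, dtype=float).reshape(1, 3)
    coef, part = _coef_partiality(crystal, state.beam, hkl, gain=1.0)
    asu = tuple(asu_index(np.asarray(obs.hkl).reshape(1, 3))[0])
    I_m = state.merged.get(asu)
    if I_m is None or I_m <= 0 or part[0] <= 0:
        return 0.0
    full = float(coef[0]) / float(part[0]) * I_m
    if full == 0:
        return 0.0
    return obs.intensity / full


def monte_carlo_merge(observations: pd.DataFrame, laue: str = "-1") -> pd.DataFrame:
    """Plain per-reflection averaging (the Monte Carlo integration baseline).

    Returns columns ``h k l I_merged sigma_merged n_obs`` where the sigma
    is the standard error of the mean.
    """
    hkl = observations[["h", "k", "l"]].to_numpy(dtype=int)
    asu = asu_index(hkl, laue)
    df = observations.assign(_h=asu[:, 0], _k=asu[:, 1], _l=asu[:, 2])
    g = df.groupby(["_h", "_k", "_l"])["I"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out.columns = ["h", "k", "l", "I_merged", "sigma_merged", "n_obs"]
    out["sigma_merged"] = out["sigma_merged"].fillna(0.0) / np.sqrt(out["n_obs"])
    return out
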