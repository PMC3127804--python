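"""Metropolis-Hastings inference over observer-model parameters.

Parameters are sampled with component-wise Gaussian random-walk proposals in
a transformed space (log for SDs and for the sample count ``K``, raw for the
prior means). The prior is uniform on the *original* scale over a very large
bounded range, so the transformed-space density carries the corresponding
Jacobian term. All chains are advanced together as one vectorized batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from .observer import SAMPLE_AVERAGE, response_loglik

# ---------------------------------------------------------------------------
# Parameter vectors
# ---------------------------------------------------------------------------

#: uniform prior bounds on the original scale ("very large range")
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "sigma_phi_true": (1e-4, 10.0),
    "sigma_phi": (1e-4, 10.0),
    "sigma_h_true": (1e-4, 10.0),
    "sigma_h": (1e-4, 10.0),
    "mu_d": (0.0, 12.0),
    "sigma_d": (1e-4, 10.0),
    "mu_s": (0.0, 12.0),
    "sigma_s": (1e-4, 10.0),
    "sigma_m": (1e-4, 10.0),
    "K": (1.0, 1000.0),
}

#: parameters sampled on a log scale
POSITIVE_PARAMS = frozenset(
    ["sigma_phi_true", "sigma_phi", "sigma_h_true", "sigma_h",
     "sigma_d", "sigma_s", "sigma_m", "K"]
)


def active_parameters(model) -> tuple[str, ...]:
    """Canonical ordered name tuple of a model's free parameters.

    Knowledge-accurate couplings collapse a true/assumed SD pair into one
    shared entry; no-haptic models expose no haptic SDs; only
    sample-averaging models expose ``K``.
    """
    names: list[str] = []
    if model.image_knowledge_accurate:
        names.append("sigma_phi")
    else:
        names.extend(["sigma_phi_true", "sigma_phi"])
    if model.use_haptic:
        if model.haptic_knowledge_accurate:
            names.append("sigma_h")
        else:
            names.extend(["sigma_h_true", "sigma_h"])
    names.extend(["mu_d", "sigma_d", "mu_s", "sigma_s", "sigma_m"])
    if model.decision_rule == SAMPLE_AVERAGE:
        names.append("K")
    return tuple(names)


def theta_in_bounds(theta: Mapping[str, float]) -> bool:
    return all(PARAM_BOUNDS[k][0] <= v <= PARAM_BOUNDS[k][1] for k, v in theta.items())


def log_prior(theta: Mapping[str, float]) -> float:
    """Log-density of the bounded uniform prior (original scale)."""
    total = 0.0
    for name, value in theta.items():
        lo, hi = PARAM_BOUNDS[name]
        if not (lo <= value <= hi):
            return -math.inf
        total -= math.log(hi - lo)
    return total


def log_posterior(theta: Mapping[str, float], records, model) -> float:
    """Unnormalized log posterior: trial-wise log-likelihood sum + log prior.

    ``records`` is the arrays tuple ``(d_true, s_true, is_haptic, r)`` or a
    sequence of :class:`~sizedist.observer.ResponseRecord`.
    """
    d, s, hap, r = _as_arrays(records)
    if d.size == 0:
        raise ValueError("records must be non-empty")
    lp = log_prior(theta)
    if not math.isfinite(lp):
        return -math.inf
    return float(response_loglik(model, theta, d, s, hap, r)) + lp


def _as_arrays(records):
    if isinstance(records, tuple) and len(records) == 4:
        return tuple(np.asarray(a) for a in records)
    d = np.array([rec.stimulus.d_true for rec in records])
    s = np.array([rec.stimulus.s_true for rec in records])
    hap = np.array([rec.stimulus.condition == "haptic" for rec in records])
    r = np.array([rec.r for rec in records])
    return d, s, hap, r


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


class SamplerConfig(BaseModel):
    """Desk-scale defaults; the original study's scale is available too."""

    model_config = ConfigDict(frozen=True)

    chains: int = Field(default=8, ge=1)
    burnin: int = Field(default=2000, ge=0)
    samples: int = Field(default=1500, ge=1)
    init_scale: float = 0.2
    target_accept: float = 0.3


#: sampler scale used in the original analysis (360 chains, 15k burn-in, 6k kept)
PAPER_SCALE = SamplerConfig(chains=360, burnin=15000, samples=6000)


@dataclass
class MCMCResult:
    """Posterior samples plus bookkeeping.

    ``samples`` has shape (chains, draws, params) on the ORIGINAL parameter
    scale, in ``param_names`` order.
    """

    param_names: tuple[str, ...]
    samples: np.ndarray
    log_post: np.ndarray
    accept_rate: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def pooled(self) -> np.ndarray:
        """All post-burn-in draws stacked: shape (chains*draws, params)."""
        return self.samples.reshape(-1, self.samples.shape[-1])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.pooled, columns=list(self.param_names))
        n_chains, n_draws, _ = self.samples.shape
        df.insert(0, "chain", np.repeat(np.arange(n_chains), n_draws))
        df.insert(1, "draw", np.tile(np.arange(n_draws), n_chains))
        return df


def metropolis_hastings(
    log_post: Callable[[np.ndarray], np.ndarray],
    init: np.ndarray,
    config: SamplerConfig,
    rng: np.random.Generator,
    extra_directions: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized component-wise random-walk Metropolis-Hastings.

    ``log_post`` maps a state matrix of shape (chains, params) to a vector
    of log-densities; ``init`` is the (chains, params) starting state.
    Proposal scales adapt per chain and component during burn-in only,
    steered toward ``target_accept``, then freeze.

    ``extra_directions`` (k, params) adds symmetric joint moves along fixed
    direction vectors to each sweep — used to traverse the likelihood ridges
    that component-wise moves cross only diffusively.

    Returns ``(samples, log_post_trace, accept_rate)`` where samples has
    shape (chains, config.samples, params) and accept_rate one entry per
    component followed by one per extra direction.
    """
    state = np.array(init, dtype=float)
    if state.ndim != 2:
        raise ValueError("init must have shape (chains, params)")
    n_chains, n_params = state.shape
    lp = np.asarray(log_post(state), dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("log_post must be finite at every chain's init")

    directions = list(np.eye(n_params))
    if extra_directions is not None:
        directions += [np.asarray(d, dtype=float) for d in np.atleast_2d(extra_directions)]
    n_moves = len(directions)

    log_scales = np.full((n_chains, n_moves), math.log(config.init_scale))
    stored = np.empty((n_chains, config.samples, n_params))
    lp_trace = np.empty((n_chains, config.samples))
    accepted = np.zeros(n_moves)
    total = config.burnin + config.samples
    for it in range(total):
        adapting = it < config.burnin
        for j, direction in enumerate(directions):
            step_sizes = np.exp(log_scales[:, j]) * rng.standard_normal(n_chains)
            prop = state + step_sizes[:, None] * direction[None, :]
            lp_new = np.asarray(log_post(prop), dtype=float)
            acc = np.log(rng.random(n_chains)) < lp_new - lp
            state[acc] = prop[acc]
            lp[acc] = lp_new[acc]
            if adapting:
                # Robbins-Monro step on the log proposal scale
                step = 1.0 / math.sqrt(it + 1.0)
                log_scales[:, j] += step * (acc.astype(float) - config.target_accept)
            else:
                accepted[j] += acc.mean()
        if not adapting:
            k = it - config.burnin
            stored[:, k, :] = state
            lp_trace[:, k] = lp
    accept_rate = accepted / config.samples
    return stored, lp_trace, accept_rate


def _transform(theta_row: np.ndarray, names: Sequence[str]) -> np.ndarray:
    z = theta_row.copy()
    for j, name in enumerate(names):
        if name in POSITIVE_PARAMS:
            z[..., j] = np.log(z[..., j])
    return z


def _untransform(z: np.ndarray, names: Sequence[str]) -> np.ndarray:
    x = z.copy()
    for j, name in enumerate(names):
        if name in POSITIVE_PARAMS:
            x[..., j] = np.exp(x[..., j])
    return x


def _bounds_arrays(names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([PARAM_BOUNDS[n][0] for n in names])
    hi = np.array([PARAM_BOUNDS[n][1] for n in names])
    return lo, hi


def make_transformed_logpost(records, model, names: Sequence[str]):
    """Batched log-posterior over the transformed space (with Jacobian).

    Returns a callable mapping (chains, params) transformed states to
    (chains,) log-densities, suitable for :func:`metropolis_hastings`.
    """
    d, s, hap, r = _as_arrays(records)
    lo, hi = _bounds_arrays(names)
    pos = np.array([n in POSITIVE_PARAMS for n in names])
    prior_const = -float(np.sum(np.log(hi - lo)))

    def logpost(z: np.ndarray) -> np.ndarray:
        x = _untransform(z, names)
        ok = np.all((x >= lo) & (x <= hi), axis=1)
        out = np.full(z.shape[0], -np.inf)
        if np.any(ok):
            xs = x[ok]
            theta = {n: xs[:, j:j + 1] for j, n in enumerate(names)}
            ll = response_loglik(model, theta, d, s, hap, r)
            jac = z[ok][:, pos].sum(axis=1)  # d(exp z)/dz for log-scale params
            out[ok] = ll + prior_const + jac
        return out

    return logpost


def initial_theta(records, model, names: Sequence[str]) -> dict[str, float]:
    """Data-driven starting point: regression of responses on log-distance.

    The fitted means seed the prior-mean parameters; the residual SD is
    split heuristically across the noise sources.
    """
    d, s, hap, r = _as_arrays(records)
    slope, intercept = np.polyfit(d, r, 1)
    resid_sd = float(np.std(r - (slope * d + intercept)))
    resid_sd = max(resid_sd, 0.02)
    init = {
        "sigma_phi_true": resid_sd / 2,
        "sigma_phi": resid_sd / 2,
        "sigma_h_true": resid_sd / 2,
        "sigma_h": resid_sd / 2,
        "mu_d": float(np.clip(np.mean(d), *PARAM_BOUNDS["mu_d"])),
        "sigma_d": max(float(np.std(d)), 0.05),
        "mu_s": float(np.clip(np.mean(s), *PARAM_BOUNDS["mu_s"])),
        "sigma_s": max(float(np.std(s)), 0.05),
        "sigma_m": resid_sd / 4,
        "K": 4.0,
    }
    return {n: init[n] for n in names}


def fit_model(
    records,
    model,
    config: Optional[SamplerConfig] = None,
    rng: Optional[np.random.Generator] = None,
    compute_diagnostics: bool = True,
) -> MCMCResult:
    """Fit one observer model to trial records by Metropolis-Hastings.

    Chains start from a jittered data-driven initialization; samples are
    returned on the original parameter scale together with acceptance rates
    and (optionally) split-Rhat / effective-sample-size diagnostics.
    """
    config = config or SamplerConfig()
    rng = rng or np.random.default_rng()
    names = active_parameters(model)
    logpost = make_transformed_logpost(records, model, names)

    base = np.array([initial_theta(records, model, names)[n] for n in names])
    z0 = _transform(base, names)
    init = np.empty((config.chains, len(names)))
    for c in range(config.chains):
        for attempt in range(100):
            cand = z0 + 0.15 * rng.standard_normal(len(names))
            if np.isfinite(logpost(cand[None, :])[0]):
                init[c] = cand
                break
        else:
            raise RuntimeError("could not find a finite-posterior initialization")

    # joint move along all log-scale components: slides chains along the
    # scale ridge the likelihood leaves unconstrained
    scale_dir = np.array([1.0 if n in POSITIVE_PARAMS else 0.0 for n in names])
    z_samples, lp_trace, acc = metropolis_hastings(
        logpost, init, config, rng, extra_directions=scale_dir[None, :]
    )
    samples = _untransform(z_samples, names)
    result = MCMCResult(
        param_names=names, samples=samples, log_post=lp_trace, accept_rate=acc
    )
    if compute_diagnostics:
        result.diagnostics = {
            "rhat": {n: split_rhat(samples[:, :, j]) for j, n in enumerate(names)},
            "ess": {n: effective_sample_size(samples[:, :, j]) for j, n in enumerate(names)},
        }
    return result


def save_result(result: MCMCResult, path) -> None:
    """Persist samples as CSV (chain, draw, one column per parameter)."""
    result.to_frame().to_csv(path, index=False)


def load_result(path) -> MCMCResult:
    """Load samples saved by :func:`save_result` (no diagnostics attached)."""
    import pandas as pd

    df = pd.read_csv(path)
    names = tuple(c for c in df.columns if c not in ("chain", "draw"))
    n_chains = int(df["chain"].max()) + 1
    n_draws = int(df["draw"].max()) + 1
    samples = (
        df.sort_values(["chain", "draw"])[list(names)]
        .to_numpy()
        .reshape(n_chains, n_draws, len(names))
    )
    return MCMCResult(
        param_names=names,
        samples=samples,
        log_post=np.full((n_chains, n_draws), np.nan),
        accept_rate=np.full(len(names), np.nan),
    )


# ---------------------------------------------------------------------------
# Summaries and diagnostics
# ---------------------------------------------------------------------------


def robust_mean(result: MCMCResult, trim: float = 0.1, snap_to_sample: bool = True) -> dict[str, float]:
    """Outlier-resistant central point estimate of the pooled draws.

    Computes the per-parameter ``trim``-trimmed mean (on the log scale for
    scale parameters, i.e. a trimmed geometric mean), then — by default —
    snaps it to the nearest pooled draw (standardized distance in the
    sampling space). The snap matters because these posteriors can be
    curved ridges: a componentwise center may lie far off the
    high-likelihood manifold, whereas the nearest actual draw is both
    central and on it, which keeps deviance-at-the-point-estimate (and
    hence DIC) stable.
    """
    pooled = result.pooled
    if pooled.size == 0:
        raise ValueError("no samples")
    pos = np.array([n in POSITIVE_PARAMS for n in result.param_names])
    z = pooled.copy()
    z[:, pos] = np.log(z[:, pos])
    center = stats.trim_mean(z, proportiontocut=trim, axis=0)
    if snap_to_sample:
        scale = z.std(axis=0)
        scale[scale == 0] = 1.0
        idx = int(np.argmin((((z - center) / scale) ** 2).sum(axis=1)))
        center = z[idx]
    theta = center.copy()
    theta[pos] = np.exp(theta[pos])
    return {name: float(theta[j]) for j, name in enumerate(result.param_names)}


def credible_interval(result: MCMCResult, prob: float = 0.95) -> dict[str, tuple[float, float]]:
    """Central credible interval per parameter from the pooled draws."""
    alpha = (1.0 - prob) / 2.0
    pooled = result.pooled
    out = {}
    for j, name in enumerate(result.param_names):
        lo, hi = np.quantile(pooled[:, j], [alpha, 1.0 - alpha])
        out[name] = (float(lo), float(hi))
    return out


def split_rhat(chain_draws: np.ndarray) -> float:
    """Split-Rhat convergence statistic for one parameter (chains, draws)."""
    x = np.asarray(chain_draws, dtype=float)
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    within = halves.var(axis=1, ddof=1).mean()
    between = n * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    var_hat = (n - 1) / n * within + between / n
    return float(math.sqrt(var_hat / within))


def effective_sample_size(chain_draws: np.ndarray) -> float:
    """Bulk ESS for one parameter, shaped (chains, draws); delegated to arviz."""
    import arviz as az

    return float(az.ess(np.asarray(chain_draws, dtype=float)))
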