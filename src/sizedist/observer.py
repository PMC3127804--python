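"""Generative observer models: sensation, explaining-away perception, decision.

All quantities live in natural-log coordinates: log-distance, log-size and
judged log-distance in log-mm; log visual angle in log-radians via the exact
small-angle identity angle = size / distance, i.e.
``log-angle = log-size - log-distance``.

The observer is a linear-Gaussian Bayes net over (distance, size) with two
sensory children: the visual angle ``phi`` (informative about size/distance)
and, on haptic trials, the felt size ``h`` (informative about size alone).
Because ``h`` pins down size, it *explains away* the size/distance ambiguity
in ``phi`` — the mechanism every function in this module implements.

Tilde-free parameters (``sigma_phi``, ``sigma_h``) are the observer's
*assumed* noise magnitudes; ``*_true`` parameters are the magnitudes that
actually corrupt the sensations. Models in which the observer's knowledge is
accurate couple the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np

Condition = Literal["haptic", "no_haptic"]
HAPTIC: Condition = "haptic"
NO_HAPTIC: Condition = "no_haptic"

MAP: str = "MAP"
SAMPLE_AVERAGE: str = "sample_average"


class ValidationError(ValueError):
    """Malformed data: non-finite stimulus or response values."""


class ParameterError(ValueError):
    """A parameter lies outside its mathematical domain."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneStimulus:
    """True world state of one trial.

    ``d_true`` and ``s_true`` are natural logs of the crossing distance and
    ball diameter in mm. ``speed_mm_s`` and ``angle_deg`` are schedule
    metadata never consumed by any observer model.
    """

    d_true: float
    s_true: float
    condition: Condition
    day: int = 1
    block: int = 1
    trial_index: int = 0
    speed_mm_s: Optional[float] = None
    angle_deg: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d_true) and math.isfinite(self.s_true)):
            raise ValidationError(
                f"non-finite stimulus: d_true={self.d_true}, s_true={self.s_true}"
            )
        if self.condition not in (HAPTIC, NO_HAPTIC):
            raise ValidationError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class Sensations:
    """Proximal stimulus: log visual angle, and log haptic size when touched."""

    phi: float
    h: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.phi):
            raise ValidationError(f"non-finite phi={self.phi}")
        if self.h is not None and not math.isfinite(self.h):
            raise ValidationError(f"non-finite h={self.h}")


@dataclass(frozen=True)
class NoiseModel:
    """SDs of the noise that actually corrupts sensation and action."""

    sigma_phi_true: float
    sigma_h_true: float
    sigma_m: float

    def __post_init__(self) -> None:
        for name in ("sigma_phi_true", "sigma_h_true", "sigma_m"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ObserverKnowledge:
    """The observer's assumed noise SDs and Gaussian priors (log-mm)."""

    sigma_phi: float
    sigma_h: float
    mu_d: float
    sigma_d: float
    mu_s: float
    sigma_s: float

    def __post_init__(self) -> None:
        for name in ("sigma_phi", "sigma_h", "sigma_d", "sigma_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")


@dataclass(frozen=True)
class DecisionPolicy:
    """How a posterior belief becomes a response.

    ``rule`` is either ``"MAP"`` (respond with the posterior mean, which is
    also the mode for Gaussians) or ``"sample_average"`` (respond with the
    mean of ``K`` independent posterior draws). ``K`` is ignored under MAP.
    """

    rule: str
    K: float = 1.0

    def __post_init__(self) -> None:
        if self.rule not in (MAP, SAMPLE_AVERAGE):
            raise ParameterError(f"unknown decision rule {self.rule!r}")
        if self.K < 1:
            raise ParameterError("K must be >= 1")


@dataclass(frozen=True)
class PosteriorBelief:
    """Gaussian posterior over log-distance with its cue weights.

    ``weights`` is ``(w_phi, w_h, w_s, w_d)`` such that
    ``mu_post = -w_phi*phi + w_h*h + w_s*mu_s + w_d*mu_d``. In the
    no-haptic form ``w_h = 0`` and ``w_s = w_phi`` (the size-prior mean
    substitutes for the missing haptic measurement).
    """

    mu_post: float
    var_post: float
    weights: tuple[float, float, float, float]


@dataclass(frozen=True)
class ResponseRecord:
    """A stimulus together with the judged log-distance ``r`` (log-mm)."""

    stimulus: SceneStimulus
    r: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.r):
            raise ValidationError(f"non-finite response r={self.r}")


# ---------------------------------------------------------------------------
# Posterior weights (closed form, certified against grid integration)
# ---------------------------------------------------------------------------


def haptic_weights(v_phi, v_h, v_s, v_d):
    """Cue weights of the explaining-away posterior when touch is used.

    Accepts scalars or broadcasting arrays of *variances*. Returns
    ``(w_phi, w_h, w_s, w_d)`` with ``w_h + w_s + w_d = 1`` and
    ``w_phi = w_h + w_s``; the posterior variance is ``v_d * w_d``.
    """
    den = v_d * v_s + v_d * v_h + v_phi * v_s + v_phi * v_h + v_s * v_h
    w_phi = (v_d * v_s + v_d * v_h) / den
    w_h = v_d * v_s / den
    w_s = v_d * v_h / den
    w_d = (v_phi * v_s + v_phi * v_h + v_s * v_h) / den
    return w_phi, w_h, w_s, w_d


def no_haptic_weights(v_phi, v_s, v_d):
    """Weights of the vision-only posterior: ``(w_phi, w_d)``.

    ``w_phi`` multiplies ``(mu_s - phi)``: absent a size measurement the
    observer substitutes its size-prior mean, so visual angle and size prior
    share one weight. ``w_phi + w_d = 1``; posterior variance is
    ``v_d * (v_phi + v_s) / (v_d + v_phi + v_s)``.
    """
    den = v_d + v_phi + v_s
    return v_d / den, (v_phi + v_s) / den


def sense(stimulus: SceneStimulus, noise: NoiseModel, rng: np.random.Generator) -> Sensations:
    """Generate noisy sensations for one trial.

    ``phi = s_true - d_true + eps_phi``; on haptic trials additionally
    ``h = s_true + eps_h``; both noises zero-mean Gaussian with the *true*
    SDs. No-haptic trials carry no ``h`` regardless of the noise model.
    """
    phi = stimulus.s_true - stimulus.d_true
    if noise.sigma_phi_true > 0:
        phi += rng.normal(0.0, noise.sigma_phi_true)
    h: Optional[float] = None
    if stimulus.condition == HAPTIC:
        h = stimulus.s_true
        if noise.sigma_h_true > 0:
            h += rng.normal(0.0, noise.sigma_h_true)
    return Sensations(phi=phi, h=h)


def compute_posterior(
    sens: Sensations, knowledge: ObserverKnowledge, use_haptic: bool
) -> PosteriorBelief:
    """Explaining-away posterior over log-distance given the sensations.

    With ``use_haptic`` the haptic measurement disambiguates the visual
    angle; without it the size-prior mean plays that role and the posterior
    is wider. Requires ``sens.h`` when ``use_haptic`` is set.
    """
    v_phi = knowledge.sigma_phi**2
    v_s = knowledge.sigma_s**2
    v_d = knowledge.sigma_d**2
    if use_haptic:
        if sens.h is None:
            raise ValidationError("use_haptic requires a haptic sensation h")
        v_h = knowledge.sigma_h**2
        w_phi, w_h, w_s, w_d = haptic_weights(v_phi, v_h, v_s, v_d)
        mu = -w_phi * sens.phi + w_h * sens.h + w_s * knowledge.mu_s + w_d * knowledge.mu_d
        var = v_d * w_d
        return PosteriorBelief(mu, var, (w_phi, w_h, w_s, w_d))
    w_phi, w_d = no_haptic_weights(v_phi, v_s, v_d)
    mu = w_phi * (knowledge.mu_s - sens.phi) + w_d * knowledge.mu_d
    var = v_d * (v_phi + v_s) / (v_d + v_phi + v_s)
    return PosteriorBelief(mu, var, (w_phi, 0.0, w_phi, w_d))


def decide(
    belief: PosteriorBelief,
    policy: DecisionPolicy,
    sigma_m: float,
    rng: np.random.Generator,
) -> float:
    """Turn a posterior belief into a judged log-distance.

    MAP responds with the posterior mean; sample-averaging with the mean of
    ``K`` posterior draws (``K`` rounded to the nearest integer >= 1 for
    simulation). Motor noise ``N(0, sigma_m^2)`` is always added.
    """
    if sigma_m < 0:
        raise ParameterError("sigma_m must be >= 0")
    if policy.rule == MAP:
        r = belief.mu_post
    else:
        k = max(1, int(round(policy.K)))
        draws = rng.normal(belief.mu_post, math.sqrt(belief.var_post), size=k)
        r = float(np.mean(draws))
    if sigma_m > 0:
        r += rng.normal(0.0, sigma_m)
    return float(r)


# ---------------------------------------------------------------------------
# Closed-form response likelihood
# ---------------------------------------------------------------------------

#: every parameter a model may expose; couplings collapse true/assumed pairs
ALL_PARAMETERS = (
    "sigma_phi_true",
    "sigma_phi",
    "sigma_h_true",
    "sigma_h",
    "mu_d",
    "sigma_d",
    "mu_s",
    "sigma_s",
    "sigma_m",
    "K",
)


def expand_theta(theta: Mapping[str, float], model) -> dict:
    """Resolve a model's active parameter set into the full parameter table.

    Knowledge-accurate models carry one entry per coupled pair; this copies
    it into both the assumed and true slot. No-haptic models carry no haptic
    entries; MAP models no ``K``.
    """
    p: dict = {}
    if model.image_knowledge_accurate:
        p["sigma_phi_true"] = p["sigma_phi"] = theta["sigma_phi"]
    else:
        p["sigma_phi_true"] = theta["sigma_phi_true"]
        p["sigma_phi"] = theta["sigma_phi"]
    if model.use_haptic:
        if model.haptic_knowledge_accurate:
            p["sigma_h_true"] = p["sigma_h"] = theta["sigma_h"]
        else:
            p["sigma_h_true"] = theta["sigma_h_true"]
            p["sigma_h"] = theta["sigma_h"]
    else:
        p["sigma_h_true"] = p["sigma_h"] = None
    for name in ("mu_d", "sigma_d", "mu_s", "sigma_s", "sigma_m"):
        p[name] = theta[name]
    p["K"] = theta["K"] if model.decision_rule == SAMPLE_AVERAGE else None
    return p


def response_moments(model, theta: Mapping[str, float], d_true, s_true, is_haptic):
    """Per-trial mean and variance of the judged log-distance.

    Marginalizes the whole sensation -> posterior -> decision chain in
    closed form. ``d_true``, ``s_true``, ``is_haptic`` may be arrays of
    trials; theta entries may themselves broadcast (e.g. one MCMC draw per
    row), so the result follows numpy broadcasting rules.

    Haptic models apply the explaining-away form on haptic trials and the
    vision-only form otherwise; no-haptic models ignore touch everywhere.
    ``K`` enters as a continuous positive parameter.
    """
    p = expand_theta(theta, model)
    d_true = np.asarray(d_true, dtype=float)
    s_true = np.asarray(s_true, dtype=float)
    is_haptic = np.asarray(is_haptic, dtype=bool)

    v_phi = np.asarray(p["sigma_phi"]) ** 2
    v_s = np.asarray(p["sigma_s"]) ** 2
    v_d = np.asarray(p["sigma_d"]) ** 2
    vt_phi = np.asarray(p["sigma_phi_true"]) ** 2
    v_m = np.asarray(p["sigma_m"]) ** 2
    mu_d, mu_s = p["mu_d"], p["mu_s"]

    w0, wd0 = no_haptic_weights(v_phi, v_s, v_d)
    m0 = w0 * (d_true - s_true + mu_s) + wd0 * mu_d
    var0 = v_d * (v_phi + v_s) / (v_d + v_phi + v_s)
    v0 = w0**2 * vt_phi + v_m
    if p["K"] is not None:
        v0 = v0 + var0 / np.asarray(p["K"])

    if not model.use_haptic:
        m, v = np.broadcast_arrays(m0, v0)
        return m, v

    v_h = np.asarray(p["sigma_h"]) ** 2
    vt_h = np.asarray(p["sigma_h_true"]) ** 2
    w_phi, w_h, w_s, w_d = haptic_weights(v_phi, v_h, v_s, v_d)
    m1 = w_phi * d_true - w_s * s_true + w_s * mu_s + w_d * mu_d
    var1 = v_d * w_d
    v1 = w_phi**2 * vt_phi + w_h**2 * vt_h + v_m
    if p["K"] is not None:
        v1 = v1 + var1 / np.asarray(p["K"])

    m = np.where(is_haptic, m1, m0)
    v = np.where(is_haptic, v1, v0)
    return m, v


def response_loglik(model, theta: Mapping[str, float], d_true, s_true, is_haptic, r):
    """Summed log-likelihood of responses ``r`` over the trial axis.

    The workhorse behind MCMC fitting and deviance: fully vectorized, and
    broadcasts theta entries shaped ``(n, 1)`` against trial vectors to
    score many parameter draws in one call (returning shape ``(n,)``).
    """
    m, v = response_moments(model, theta, d_true, s_true, is_haptic)
    r = np.asarray(r, dtype=float)
    ll = -0.5 * (np.log(2.0 * np.pi * v) + (r - m) ** 2 / v)
    return ll.sum(axis=-1)


def response_likelihood(record: ResponseRecord, theta: Mapping[str, float], model) -> float:
    """Log-density of one record's response under the closed-form Normal."""
    st = record.stimulus
    m, v = response_moments(
        model, theta, st.d_true, st.s_true, st.condition == HAPTIC
    )
    m, v = float(m), float(v)
    if v <= 0:
        # only reachable with degenerate (all-zero) test noise
        return math.inf if record.r == m else -math.inf
    return -0.5 * (math.log(2.0 * math.pi * v) + (record.r - m) ** 2 / v)


def simulate_responses(
    stimuli: Sequence[SceneStimulus],
    theta: Mapping[str, float],
    model,
    rng: np.random.Generator,
) -> list[ResponseRecord]:
    """Simulate one response per stimulus through the full generative chain.

    Runs sense -> compute_posterior -> decide trial by trial; haptic
    sensations are integrated only when the model uses them AND the trial is
    haptic. Deterministic under a fixed rng state.
    """
    if len(stimuli) == 0:
        raise ValidationError("stimuli must be non-empty")
    p = expand_theta(theta, model)
    noise = NoiseModel(
        sigma_phi_true=p["sigma_phi_true"],
        sigma_h_true=p["sigma_h_true"] if p["sigma_h_true"] is not None else 0.0,
        sigma_m=p["sigma_m"],
    )
    knowledge = ObserverKnowledge(
        sigma_phi=p["sigma_phi"],
        sigma_h=p["sigma_h"] if p["sigma_h"] is not None else 1.0,
        mu_d=p["mu_d"],
        sigma_d=p["sigma_d"],
        mu_s=p["mu_s"],
        sigma_s=p["sigma_s"],
    )
    policy = DecisionPolicy(
        rule=model.decision_rule,
        K=p["K"] if p["K"] is not None else 1.0,
    )
    out = []
    for st in stimuli:
        sens = sense(st, noise, rng)
        use_h = model.use_haptic and st.condition == HAPTIC
        belief = compute_posterior(sens, knowledge, use_haptic=use_h)
        r = decide(belief, policy, p["sigma_m"], rng)
        out.append(ResponseRecord(stimulus=st, r=r))
    return out
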