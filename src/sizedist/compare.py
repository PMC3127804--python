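"""Candidate model family, DIC scoring, ranking, and parameter reporting.

The family crosses four binary questions — does the observer use the haptic
cue; is its haptic-noise knowledge accurate; is its image-noise knowledge
accurate; does it answer with posterior-sample averages or MAP estimates —
and merges the haptic-knowledge question away for observers that never use
touch, leaving 12 distinct models.

Canonical numbering (odd ids are sample-averaging, even their MAP twins)::

    id  haptic  haptic-knowledge  image-knowledge  decision
     1    no          n/a           inaccurate     sample_average
     2    no          n/a           inaccurate     MAP
     3    no          n/a           accurate       sample_average
     4    no          n/a           accurate       MAP
     5    yes      inaccurate       inaccurate     sample_average
     6    yes      inaccurate       inaccurate     MAP
     7    yes      inaccurate       accurate       sample_average
     8    yes      inaccurate       accurate       MAP
     9    yes       accurate        inaccurate     sample_average
    10    yes       accurate        inaccurate     MAP
    11    yes       accurate        accurate       sample_average
    12    yes       accurate        accurate       MAP

Reference relations under this scheme: 7 = haptic observer with
misestimated haptic noise, accurate image noise, sampling decisions;
11 = its accurate-haptic-knowledge twin; 5 = 7 with inaccurate image
knowledge; 3 = 7 without touch. Ids are labels only — semantics live in
the flags, and reports always print both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .mcmc import MCMCResult, _as_arrays, active_parameters, robust_mean
from .observer import MAP, SAMPLE_AVERAGE, response_loglik


@dataclass(frozen=True)
class ModelSpec:
    """One candidate observer structure."""

    id: int
    use_haptic: bool
    haptic_knowledge_accurate: Optional[bool]
    image_knowledge_accurate: bool
    decision_rule: str

    def __post_init__(self) -> None:
        if self.use_haptic == (self.haptic_knowledge_accurate is None):
            raise ValueError(
                "haptic_knowledge_accurate must be None iff use_haptic is False"
            )
        if self.decision_rule not in (MAP, SAMPLE_AVERAGE):
            raise ValueError(f"unknown decision rule {self.decision_rule!r}")

    @property
    def label(self) -> str:
        parts = [
            "haptic" if self.use_haptic else "no-haptic",
        ]
        if self.use_haptic:
            parts.append(
                "hk-acc" if self.haptic_knowledge_accurate else "hk-inacc"
            )
        parts.append("ik-acc" if self.image_knowledge_accurate else "ik-inacc")
        parts.append("sampling" if self.decision_rule == SAMPLE_AVERAGE else "MAP")
        return "/".join(parts)


def enumerate_models() -> list[ModelSpec]:
    """All 12 distinct candidates in canonical order."""
    models: list[ModelSpec] = []
    mid = 1
    for image_acc in (False, True):
        for rule in (SAMPLE_AVERAGE, MAP):
            models.append(
                ModelSpec(
                    id=mid,
                    use_haptic=False,
                    haptic_knowledge_accurate=None,
                    image_knowledge_accurate=image_acc,
                    decision_rule=rule,
                )
            )
            mid += 1
    for haptic_acc in (False, True):
        for image_acc in (False, True):
            for rule in (SAMPLE_AVERAGE, MAP):
                models.append(
                    ModelSpec(
                        id=mid,
                        use_haptic=True,
                        haptic_knowledge_accurate=haptic_acc,
                        image_knowledge_accurate=image_acc,
                        decision_rule=rule,
                    )
                )
                mid += 1
    return models


def get_model(model_id: int) -> ModelSpec:
    for m in enumerate_models():
        if m.id == model_id:
            return m
    raise KeyError(f"no model with id {model_id} (valid ids: 1-12)")


def count_free_parameters(model: ModelSpec) -> int:
    """Active theta entries under the knowledge-coupling rules (6 to 10)."""
    return len(active_parameters(model))


def deviance(theta: Mapping[str, float], records, model: ModelSpec) -> float:
    """D(theta) = -2 * total log-likelihood (prior excluded)."""
    d, s, hap, r = _as_arrays(records)
    return float(-2.0 * response_loglik(model, theta, d, s, hap, r))


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------


@dataclass
class DICEntry:
    """Deviance summaries for one fitted model."""

    model: ModelSpec
    d_bar: float
    d_at_theta_bar: float
    theta_bar: dict[str, float]
    delta_vs_best: float = math.nan
    significance: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def p_d(self) -> float:
        return self.d_bar - self.d_at_theta_bar

    @property
    def dic(self) -> float:
        return self.d_bar + self.p_d


def dic_from_deviances(deviances: np.ndarray, deviance_at_point: float) -> tuple[float, float, float]:
    """Core DIC arithmetic: returns (d_bar, p_d, dic)."""
    d_bar = float(np.mean(deviances))
    p_d = d_bar - deviance_at_point
    return d_bar, p_d, d_bar + p_d


def dic(samples: MCMCResult, records, model: ModelSpec, max_draws: int = 20000) -> DICEntry:
    """Score one fitted model: expected deviance plus effective complexity.

    ``d_bar`` averages the deviance over (at most ``max_draws`` evenly
    thinned) posterior draws; the point estimate is the robust (trimmed)
    mean of the pooled draws. A negative ``p_d`` or a split-Rhat above 1.05
    is flagged in ``warnings`` rather than raised.
    """
    d, s, hap, r = _as_arrays(records)
    pooled = samples.pooled
    if pooled.shape[0] > max_draws:
        idx = np.linspace(0, pooled.shape[0] - 1, max_draws).astype(int)
        pooled = pooled[idx]
    theta_arrays = {
        name: pooled[:, j : j + 1] for j, name in enumerate(samples.param_names)
    }
    ll = response_loglik(model, theta_arrays, d, s, hap, r)
    deviances = -2.0 * ll
    theta_bar = robust_mean(samples)
    d_hat = deviance(theta_bar, (d, s, hap, r), model)
    d_bar, p_d, _ = dic_from_deviances(deviances, d_hat)

    warnings = []
    rhats = samples.diagnostics.get("rhat", {})
    bad = {n: v for n, v in rhats.items() if v > 1.05}
    if bad:
        warnings.append(f"split-Rhat above 1.05: {bad}")
    if p_d < 0:
        warnings.append(f"negative p_D = {p_d:.3f} (non-convergence or multimodality?)")
    return DICEntry(
        model=model,
        d_bar=d_bar,
        d_at_theta_bar=d_hat,
        theta_bar=theta_bar,
        warnings=warnings,
    )


#: DIC-difference thresholds for the two significance labels
SIGNIFICANT_DELTA = 10.0
HIGHLY_SIGNIFICANT_DELTA = 15.0


def rank_models(reports: Sequence[DICEntry]) -> list[DICEntry]:
    """Ascending-DIC ranking with deltas and significance labels.

    Deltas above 10 are "significant", above 15 "highly significant",
    otherwise "n.s."; ties break on model id.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 models to rank")
    ranked = sorted(reports, key=lambda e: (e.dic, e.model.id))
    best = ranked[0].dic
    for i, entry in enumerate(ranked):
        entry.delta_vs_best = entry.dic - best
        if i == 0:
            entry.significance = "best"
        elif entry.delta_vs_best > HIGHLY_SIGNIFICANT_DELTA:
            entry.significance = "highly significant"
        elif entry.delta_vs_best > SIGNIFICANT_DELTA:
            entry.significance = "significant"
        else:
            entry.significance = "n.s."
    return ranked


def weber_fraction(sigma: float) -> float:
    """Convert a log-domain noise SD to a Weber fraction: exp(sigma) - 1.

    Uses a 1-SD discrimination criterion; for small sigma this is ~sigma.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return math.expm1(sigma)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def report_to_dict(ranked: Sequence[DICEntry]) -> dict:
    """JSON-ready DIC report (includes the id -> structure map)."""
    return {
        "id_map": {str(e.model.id): e.model.label for e in ranked},
        "models": [
            {
                "id": e.model.id,
                "label": e.model.label,
                "n_free_parameters": count_free_parameters(e.model),
                "D_bar": e.d_bar,
                "D_at_theta_bar": e.d_at_theta_bar,
                "p_D": e.p_d,
                "DIC": e.dic,
                "delta_vs_best": e.delta_vs_best,
                "significance": e.significance,
                "theta_bar": e.theta_bar,
                "warnings": e.warnings,
            }
            for e in ranked
        ],
    }


def format_report(ranked: Sequence[DICEntry]) -> str:
    """Human-readable DIC table."""
    lines = [
        f"{'id':>3} {'model':<38} {'k':>2} {'D_bar':>10} {'p_D':>8} "
        f"{'DIC':>10} {'dDIC':>8}  significance",
    ]
    for e in ranked:
        lines.append(
            f"{e.model.id:>3} {e.model.label:<38} {count_free_parameters(e.model):>2} "
            f"{e.d_bar:>10.2f} {e.p_d:>8.2f} {e.dic:>10.2f} "
            f"{e.delta_vs_best:>8.2f}  {e.significance}"
        )
    return "\n".join(lines)


def parameter_summary(
    entry: DICEntry,
    intervals: Mapping[str, tuple[float, float]],
    stimulus_stats: Optional[Mapping[str, float]] = None,
) -> dict:
    """Interpretable per-model summary: point estimates, 95% CIs, Weber
    fractions for the sensory SDs, and (optionally) the stimulus log-domain
    statistics the fitted priors should resemble."""
    out: dict = {"model_id": entry.model.id, "label": entry.model.label, "parameters": {}}
    for name, value in entry.theta_bar.items():
        row = {"estimate": value, "ci95": list(intervals.get(name, (math.nan, math.nan)))}
        if name.startswith("sigma_phi") or name.startswith("sigma_h"):
            row["weber_fraction"] = weber_fraction(value)
        out["parameters"][name] = row
    if stimulus_stats is not None:
        out["stimulus_log_stats"] = dict(stimulus_stats)
    return out
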