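"""Per-participant maximum-likelihood fitting of the arbitration models.

Parameters are optimized in an unconstrained space via transforms
(beta = exp(x), theta0 = sigmoid(x), eta0 = exp(x), w = sigmoid(x)) with
seeded multistart quasi-Newton, and hard guard rails applied after the
transform for numerical stability. Model evidence is a BIC-based
approximation (AIC selectable) used downstream for random-effects model
selection.

Recovery bounds (verified by simulation, see the test suite): on synthetic
cohorts the median fitted inverse temperature lands within +/-50% of the
generating value; the fixed weight exceeds 0.5 in >=90% of replicates from a
w=0.9 generator at 480-trial sessions. At the task's native 240 trials the
fixed weight shrinks toward 0.5 in a minority of replicates via a beta-w
likelihood degeneracy (the fitted likelihood exceeds the generating one, so
this is an identifiability limit, not an optimizer failure). Prior-parameter
(theta0, eta0) recovery is weaker and only sanity-bounded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from pavarb._rng import substream
from pavarb.models import (
    ModelSpec,
    PriorParams,
    Variant,
    _loglik_compiled,
    compile_session,
)
from pavarb.task import TrialRecord

logger = logging.getLogger(__name__)

# Guard rails applied after the unconstrained transform.
BETA_MAX = 50.0
ETA0_MIN, ETA0_MAX = 0.1, 100.0
THETA0_MIN, THETA0_MAX = 0.01, 0.99

PARAM_NAMES = {
    Variant.ADAPTIVE: ("beta", "theta0_u", "eta0_u", "theta0_c", "eta0_c"),
    Variant.FIXED: ("beta", "theta0_u", "eta0_u", "theta0_c", "eta0_c", "w_fixed"),
}


@dataclass(frozen=True)
class FitSettings:
    """Multistart MLE settings."""

    n_restarts: int = 10
    seed: int = 0
    maxiter: int = 500
    evidence: str = "bic"  # or "aic"
    L0: float = 0.5

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.evidence not in ("bic", "aic"):
            raise ValueError(f"unknown evidence approximation {self.evidence!r}")


@dataclass(frozen=True)
class FitResult:
    participant_id: str
    variant: Variant
    params: dict[str, float]
    loglik: float
    n_params: int
    n_trials: int
    evidence: float
    converged: bool
    n_restarts_used: int

    def model_spec(self, L0: float = 0.5) -> ModelSpec:
        """The fitted parameters as a runnable model specification."""
        p = self.params
        return ModelSpec(
            variant=self.variant,
            beta=p["beta"],
            prior_uncontrollable=PriorParams(p["theta0_u"], p["eta0_u"]),
            prior_controllable=PriorParams(p["theta0_c"], p["eta0_c"]),
            w_fixed=p.get("w_fixed"),
            L0=L0,
        )


def _clip(x: float, lo: float, hi: float) -> float:
    return lo if x < lo else (hi if x > hi else x)


def _transform(x: np.ndarray, variant: Variant) -> dict[str, float]:
    """Unconstrained vector -> natural parameters, with guard rails."""
    sig = lambda v: 1.0 / (1.0 + math.exp(-_clip(v, -35.0, 35.0)))
    params = {
        "beta": _clip(math.exp(_clip(x[0], -30.0, 30.0)), 1e-3, BETA_MAX),
        "theta0_u": _clip(sig(x[1]), THETA0_MIN, THETA0_MAX),
        "eta0_u": _clip(math.exp(_clip(x[2], -30.0, 30.0)), ETA0_MIN, ETA0_MAX),
        "theta0_c": _clip(sig(x[3]), THETA0_MIN, THETA0_MAX),
        "eta0_c": _clip(math.exp(_clip(x[4], -30.0, 30.0)), ETA0_MIN, ETA0_MAX),
    }
    if variant is Variant.FIXED:
        params["w_fixed"] = sig(x[5])
    return params


def _draw_start(rng: np.random.Generator, variant: Variant) -> np.ndarray:
    """Random start in the unconstrained space, centered on mild defaults."""
    x = [
        rng.normal(math.log(3.0), 1.0),  # beta
        rng.normal(0.0, 1.0),  # logit theta0_u
        rng.normal(math.log(2.0), 1.0),  # log eta0_u
        rng.normal(0.0, 1.0),  # logit theta0_c
        rng.normal(math.log(2.0), 1.0),  # log eta0_c
    ]
    if variant is Variant.FIXED:
        x.append(rng.normal(0.0, 1.0))  # logit w
    return np.array(x)


def _neg_loglik(x: np.ndarray, blocks, variant: Variant, L0: float) -> float:
    p = _transform(x, variant)
    return -_loglik_compiled(
        blocks,
        beta=p["beta"],
        theta0_u=p["theta0_u"],
        eta0_u=p["eta0_u"],
        theta0_c=p["theta0_c"],
        eta0_c=p["eta0_c"],
        w_fixed=p.get("w_fixed"),
        L0=L0,
    )


def log_evidence(loglik: float, n_params: int, n_trials: int, kind: str = "bic") -> float:
    """Approximate log model evidence from an MLE fit.

    ``bic``: loglik - (k/2) log(n); ``aic``: loglik - k.
    """
    if n_trials < 2:
        raise ValueError("evidence approximation requires n_trials >= 2")
    if kind == "bic":
        return loglik - 0.5 * n_params * math.log(n_trials)
    if kind == "aic":
        return loglik - n_params
    raise ValueError(f"unknown evidence approximation {kind!r}")


def fit_participant(
    trials: Sequence[TrialRecord],
    variant: Variant | str,
    settings: FitSettings = FitSettings(),
) -> FitResult:
    """Multistart MLE for one participant's session.

    Deterministic given ``settings.seed`` and the participant id; the best
    restart is retained. ``converged`` is False only if every restart failed.
    """
    variant = Variant(variant)
    if not trials:
        raise ValueError("cannot fit a participant with zero trials")
    pid = trials[0].participant_id
    blocks = compile_session(trials)
    n_trials = sum(len(b[0]) for b in blocks)
    rng = substream(settings.seed, "fit", pid, variant.value)

    best_x: np.ndarray | None = None
    best_nll = math.inf
    any_success = False
    for _ in range(settings.n_restarts):
        x0 = _draw_start(rng, variant)
        res = minimize(
            _neg_loglik,
            x0,
            args=(blocks, variant, settings.L0),
            method="L-BFGS-B",
            options={"maxiter": settings.maxiter},
        )
        any_success = any_success or bool(res.success)
        if res.fun < best_nll:
            best_nll = float(res.fun)
            best_x = res.x
    if best_x is None or not math.isfinite(best_nll):
        logger.warning("all restarts failed for participant %s (%s)", pid, variant.value)
        params = _transform(_draw_start(rng, variant), variant)
        return FitResult(
            participant_id=pid,
            variant=variant,
            params=params,
            loglik=-math.inf,
            n_params=len(PARAM_NAMES[variant]),
            n_trials=n_trials,
            evidence=-math.inf,
            converged=False,
            n_restarts_used=settings.n_restarts,
        )

    params = _transform(best_x, variant)
    loglik = -best_nll
    n_params = len(PARAM_NAMES[variant])
    if n_trials >= 2:
        evidence = log_evidence(loglik, n_params, n_trials, settings.evidence)
    else:
        evidence = loglik  # single-trial session: no penalty defined
    return FitResult(
        participant_id=pid,
        variant=variant,
        params=params,
        loglik=loglik,
        n_params=n_params,
        n_trials=n_trials,
        evidence=evidence,
        converged=any_success,
        n_restarts_used=settings.n_restarts,
    )


def fit_cohort(
    all_trials: Sequence[TrialRecord],
    variants: Sequence[Variant | str] = (Variant.ADAPTIVE, Variant.FIXED),
    settings: FitSettings = FitSettings(),
) -> list[FitResult]:
    """Fit every (participant, variant) pair. Results are independent of the
    input ordering: participants are processed in sorted id order and each
    fit draws from its own named RNG substream."""
    by_pid: dict[str, list[TrialRecord]] = {}
    for t in all_trials:
        by_pid.setdefault(t.participant_id, []).append(t)
    results: list[FitResult] = []
    for pid in sorted(by_pid):
        trials = sorted(by_pid[pid], key=lambda t: t.trial_index)
        if not trials:
            logger.warning("skipping participant %s with zero trials", pid)
            continue
        for variant in variants:
            results.append(fit_participant(trials, variant, settings))
    return results


FIT_CSV_HEADER = [
    "participant_id",
    "variant",
    "beta",
    "theta0_u",
    "eta0_u",
    "theta0_c",
    "eta0_c",
    "w_fixed",
    "loglik",
    "evidence",
    "converged",
]


def fits_to_frame(results: Sequence[FitResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "participant_id": r.participant_id,
                "variant": r.variant.value,
                "beta": r.params["beta"],
                "theta0_u": r.params["theta0_u"],
                "eta0_u": r.params["eta0_u"],
                "theta0_c": r.params["theta0_c"],
                "eta0_c": r.params["eta0_c"],
                "w_fixed": r.params.get("w_fixed", ""),
                "loglik": r.loglik,
                "evidence": r.evidence,
                "converged": r.converged,
            }
        )
    return pd.DataFrame(rows, columns=FIT_CSV_HEADER)


def write_fits(results: Sequence[FitResult], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fits_to_frame(results).to_csv(path, index=False)


def evidence_matrix(results: Sequence[FitResult]) -> tuple[np.ndarray, list[str], list[str]]:
    """Pivot fit results into a (participants x models) log-evidence matrix."""
    df = fits_to_frame(results)
    pivot = df.pivot(index="participant_id", columns="variant", values="evidence")
    pivot = pivot.sort_index().sort_index(axis=1)
    return pivot.to_numpy(dtype=float), list(pivot.index), list(pivot.columns)
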