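"""Random-effects Bayesian model selection across participants.

Given a (participants x models) matrix of approximate log evidences, a
variational Dirichlet-multinomial scheme estimates the population frequency
of each model. From the Dirichlet posterior we compute the exceedance
probability (EP) of each model, the Bayes omnibus risk (BOR) — the posterior
probability that observed evidence differences arose by chance under an
equal-frequency null — and the protected exceedance probability

    PXP_k = EP_k * (1 - BOR) + BOR / K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import digamma, gammaln, logsumexp
from scipy.stats import beta as beta_dist

from pavarb._rng import substream


@dataclass(frozen=True)
class BMSResult:
    models: tuple[str, ...]
    alpha: np.ndarray
    expected_freq: np.ndarray
    ep: np.ndarray
    bor: float
    pxp: np.ndarray

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "alpha": self.alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "ep": self.ep.tolist(),
            "bor": float(self.bor),
            "pxp": self.pxp.tolist(),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def exceedance_from_dirichlet(
    alpha: np.ndarray, n_samples: int = 1_000_000, seed: int = 0
) -> np.ndarray:
    """P(r_k > r_j for all j != k) under Dirichlet(alpha).

    K=2 is computed analytically via the regularized incomplete beta
    function; K>2 by seeded Monte-Carlo sampling.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet concentrations must be positive")
    K = alpha.shape[0]
    if K < 2:
        raise ValueError("need at least two models")
    if K == 2:
        # r0 ~ Beta(a0, a1); EP_0 = P(r0 > 1/2)
        ep0 = float(beta_dist.sf(0.5, alpha[0], alpha[1]))
        return np.array([ep0, 1.0 - ep0])
    rng = substream(seed, "exceedance")
    samples = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(samples, axis=1)
    return np.bincount(winners, minlength=K) / n_samples


def _variational_posterior(
    lme: np.ndarray, alpha0: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the Dirichlet-multinomial variational updates to convergence.

    Returns (alpha posterior, per-participant model responsibilities g)."""
    alpha = alpha0.copy()
    g = np.full_like(lme, 1.0 / lme.shape[1])
    for _ in range(max_iter):
        elog_r = digamma(alpha) - digamma(alpha.sum())
        log_u = lme + elog_r
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, g


def _free_energy(
    lme: np.ndarray, alpha0: np.ndarray, alpha: np.ndarray, g: np.ndarray
) -> float:
    """Variational free energy of the random-effects (alternative) model."""
    elog_r = digamma(alpha) - digamma(alpha.sum())
    elj = (
        gammaln(alpha0.sum())
        - gammaln(alpha0).sum()
        + ((alpha0 - 1.0) * elog_r).sum()
        + (g * (lme + elog_r)).sum()
    )
    sqf = gammaln(alpha).sum() - gammaln(alpha.sum()) - ((alpha - 1.0) * elog_r).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        glogg = np.where(g > 0, g * np.log(g), 0.0)
    sqm = -glogg.sum()
    return float(elj + sqf + sqm)


def _free_energy_null(lme: np.ndarray) -> float:
    """Free energy (exact log evidence) of the equal-frequency null model."""
    K = lme.shape[1]
    return float((logsumexp(lme, axis=1) - np.log(K)).sum())


def bms(
    evidence: np.ndarray,
    models: Sequence[str] | None = None,
    alpha0: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Random-effects model selection on a (participants x models) matrix of
    log evidences. Returns frequencies, EP, BOR and PXP."""
    lme = np.asarray(evidence, dtype=float)
    if lme.ndim != 2:
        raise ValueError("evidence must be a 2-D (participants x models) array")
    n, K = lme.shape
    if K < 2:
        raise ValueError("need at least two models")
    if n < 2:
        raise ValueError("need at least two participants")
    bad = np.argwhere(~np.isfinite(lme))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"non-finite evidence at participant row {i}, model column {j}")
    if models is None:
        models = tuple(f"model{k}" for k in range(K))
    models = tuple(models)
    if len(models) != K:
        raise ValueError("model names do not match evidence columns")

    alpha0_vec = np.full(K, float(alpha0))
    alpha, g = _variational_posterior(lme, alpha0_vec, tol, max_iter)
    expected_freq = alpha / alpha.sum()
    ep = exceedance_from_dirichlet(alpha, n_samples=n_samples, seed=seed)

    f1 = _free_energy(lme, alpha0_vec, alpha, g)
    f0 = _free_energy_null(lme)
    # BOR = posterior probability of the null given equal prior odds.
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = ep * (1.0 - bor) + bor / K
    return BMSResult(
        models=models,
        alpha=alpha,
        expected_freq=expected_freq,
        ep=ep,
        bor=bor,
        pxp=pxp,
    )
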