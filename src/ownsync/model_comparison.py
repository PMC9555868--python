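"""Model comparison: information criteria, bootstrap CIs, pseudo-R²,
and group-level random-effects Bayesian model selection (RFX-BMS).

Per participant, competing fits are scored by AIC/BIC; group evidence is
summarised three ways:

* the sum of per-participant AIC (or BIC) differences between two models,
  with a percentile-bootstrap 95% CI over participants;
* a max-corrected Nagelkerke pseudo-R² against a fair-coin null responder;
* random-effects BMS: model frequencies in the population get a Dirichlet
  posterior (variational scheme), from which expected frequencies,
  exceedance probabilities (EP), the Bayes omnibus risk (BOR — the
  posterior probability that all models are equally frequent) and
  protected EPs ``pEP = EP (1 - BOR) + BOR / K`` are derived.  Model
  families are compared by summing Dirichlet weights within families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

__all__ = [
    "ComparisonTable",
    "BMSResult",
    "information_criteria",
    "bootstrap_summed_diff_ci",
    "pseudo_r2",
    "rfx_bms",
]


def information_criteria(
    log_likelihood: float, n_par: int, n_trials: int
) -> tuple[float, float]:
    """AIC and BIC of a fit: ``(2 n_par - 2 logL*, n_par ln(n_trials) - 2 logL*)``."""
    if n_par < 0:
        raise ValueError("n_par must be >= 0")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    aic = 2.0 * n_par - 2.0 * log_likelihood
    bic = n_par * math.log(n_trials) - 2.0 * log_likelihood
    return aic, bic


@dataclass(frozen=True)
class ComparisonTable:
    """Summed criterion difference between two named fits, with bootstrap CI."""

    label: str  # e.g. "BCI - FC"
    criterion: str  # "AIC" or "BIC"
    per_participant: tuple[float, ...]
    lower: float
    raw_sum: float
    upper: float


def bootstrap_summed_diff_ci(
    per_participant_diffs: Sequence[float],
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile-bootstrap CI of the summed per-participant difference.

    Draws ``len(diffs)`` differences with replacement, sums them, repeats
    ``n_boot`` times, and returns ``(lower, raw_sum, upper)`` where the
    bounds are the (1-level)/2 and 1-(1-level)/2 percentiles of the
    resampled sums and ``raw_sum`` is the observed sum.
    """
    diffs = np.asarray(list(per_participant_diffs), dtype=float)
    if diffs.size == 0:
        raise ValueError("need at least one difference")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, diffs.size, size=(n_boot, diffs.size))
    sums = diffs[idx].sum(axis=1)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.percentile(sums, [100 * alpha, 100 * (1 - alpha)])
    return float(lower), float(diffs.sum()), float(upper)


def pseudo_r2(log_l_model: float, n_trials: int) -> float:
    """Max-corrected Nagelkerke pseudo-R² against a fair-coin responder.

    ``R² = 1 - exp(-2/n (logL(M) - logL(M0)))`` with the null
    ``logL(M0) = n ln 0.5``, divided by ``max(R²) = 1 - exp(2/n logL(M0))``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    log_l0 = n_trials * math.log(0.5)
    r2 = 1.0 - math.exp(-2.0 / n_trials * (log_l_model - log_l0))
    r2_max = 1.0 - math.exp(2.0 / n_trials * log_l0)
    return r2 / r2_max


@dataclass(frozen=True)
class BMSResult:
    """Group-level random-effects model-selection output."""

    models: tuple[str, ...]
    dirichlet_alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance_probabilities: np.ndarray
    bor: float
    protected_exceedance_probabilities: np.ndarray
    family_exceedance: dict[str, float] | None = None


def _dirichlet_ep(alpha: np.ndarray, n_samples: int, rng) -> np.ndarray:
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=alpha.size) / n_samples


def rfx_bms(
    log_evidence: np.ndarray,
    model_names: Sequence[str] | None = None,
    families: Mapping[str, Sequence[str]] | None = None,
    alpha0: float = 1.0,
    n_samples: int = 100_000,
    max_iter: int = 10_000,
    tol: float = 1e-6,
    seed: int = 0,
) -> BMSResult:
    """Random-effects Bayesian model selection over a participants x models
    log-evidence matrix (e.g. -AIC/2 or -BIC/2 per fit).

    Variational scheme: iterate participant-wise model responsibilities and
    Dirichlet updates ``alpha_k = alpha0 + sum_n g_nk`` until the largest
    change in alpha falls below ``tol``.  EPs are estimated from Dirichlet
    samples; the BOR compares the free energy of the random-effects model
    with a null in which every model is equally frequent, and protected EPs
    blend the two: ``pEP = EP (1 - BOR) + BOR / K``.
    """
    ev = np.asarray(log_evidence, dtype=float)
    if ev.ndim != 2 or ev.shape[1] < 2:
        raise ValueError("log_evidence must be (participants x >=2 models)")
    if not np.all(np.isfinite(ev)):
        raise ValueError("log_evidence contains non-finite values")
    n_sub, n_mod = ev.shape
    if model_names is None:
        model_names = tuple(f"M{i + 1}" for i in range(n_mod))
    model_names = tuple(model_names)
    if len(model_names) != n_mod:
        raise ValueError("model_names length mismatch")

    alpha = np.full(n_mod, alpha0, dtype=float)
    g = np.full((n_sub, n_mod), 1.0 / n_mod)
    for _ in range(max_iter):
        log_u = ev + digamma(alpha) - digamma(alpha.sum())
        log_g = log_u - logsumexp(log_u, axis=1, keepdims=True)
        g = np.exp(log_g)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    expected = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    ep = _dirichlet_ep(alpha, n_samples, rng)

    # free energy of the random-effects model
    e_logr = digamma(alpha) - digamma(alpha.sum())
    elj = (
        gammaln(n_mod * alpha0)
        - n_mod * gammaln(alpha0)
        + float(np.sum((alpha0 - 1.0) * e_logr))
        + float(np.sum(g * (e_logr[None, :] + ev)))
    )
    sqf = (
        float(np.sum(gammaln(alpha)))
        - gammaln(alpha.sum())
        - float(np.sum((alpha - 1.0) * e_logr))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        sqm = -float(np.nansum(g * np.log(np.where(g > 0, g, 1.0))))
    f_rfx = elj + sqf + sqm
    # null: all models equally frequent
    f_null = float(np.sum(logsumexp(ev, axis=1) - math.log(n_mod)))
    bor = 1.0 / (1.0 + math.exp(min(700.0, f_rfx - f_null)))
    pep = ep * (1.0 - bor) + bor / n_mod

    family_ep = None
    if families is not None:
        members: dict[str, list[int]] = {}
        for fam, mods in families.items():
            members[fam] = [model_names.index(m) for m in mods]
        covered = sorted(i for idxs in members.values() for i in idxs)
        if covered != list(range(n_mod)):
            raise ValueError("families must partition the model set")
        fam_names = list(members)
        fam_alpha = np.array([alpha[members[f]].sum() for f in fam_names])
        fam_ep_vec = _dirichlet_ep(fam_alpha, n_samples, rng)
        family_ep = dict(zip(fam_names, fam_ep_vec.tolist()))

    return BMSResult(
        models=model_names,
        dirichlet_alpha=alpha,
        expected_frequencies=expected,
        exceedance_probabilities=ep,
        bor=bor,
        protected_exceedance_probabilities=pep,
        family_exceedance=family_ep,
    )
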