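"""Forward observer models for yes/no common-cause detection.

Three observers map a visuotactile asynchrony ``s`` (ms) to the probability
of reporting a common cause ("the rubber hand felt like my own" /
"the touches were synchronous"):

* ``BCI`` — Bayesian causal inference.  The observer holds a prior
  ``p_same`` on the common-cause hypothesis, measures the asynchrony with
  Gaussian noise of SD ``sigma`` (which depends on the visual-noise
  condition), and reports "yes" when the posterior favours a common cause,
  i.e. when ``|x| < k`` with the criterion ``k`` derived from
  ``p_same``, ``sigma`` and the assumed distinct-cause SD ``sigma_s``.
* ``BCI_STAR`` — identical, but ``sigma_s`` is a free parameter rather than
  a constant fixed to the true stimulus SD.
* ``FC`` — fixed criterion.  The observer uses a constant threshold ``k0``
  that ignores trial-to-trial sensory uncertainty (the encoding stage is
  still noisy).

All observers lapse with probability ``lapse``, guessing "yes" half the
time, so response probabilities live in ``[lapse/2, 1 - lapse/2]``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "Model",
    "ObserverParams",
    "decision_criterion",
    "posterior_log_odds",
    "p_report_common",
    "predicted_curve",
    "mc_decision_oracle",
]

#: Default visual-noise levels, percent of white-noise pixels per frame.
NOISE_LEVELS: tuple[int, ...] = (0, 30, 50)

#: Default assumed SD of the distinct-cause asynchrony distribution (ms):
#: the RMS of the six nonzero asynchronies of the ownership design
#: ({±150, ±300, ±500} ms → 347.6), conventionally rounded to 348.
SIGMA_S_DEFAULT: float = 348.0


class Model(str, enum.Enum):
    """Observer-model family."""

    BCI = "BCI"
    BCI_STAR = "BCI_STAR"
    FC = "FC"


@dataclass(frozen=True)
class ObserverParams:
    """Parameter vector of one observer model.

    Parameters
    ----------
    model
        Which observer family the vector parameterises.
    sigma_by_noise
        Measurement-noise SD sigma (ms) per visual-noise level, e.g.
        ``{0: 116, 30: 141, 50: 178}``.
    p_same
        Prior probability of a common cause, in (0, 1).  BCI/BCI* only.
    k0
        Fixed decision criterion (ms), > 0.  FC only.
    sigma_s
        Assumed SD of the distinct-cause asynchrony distribution (ms).
        A fixed design constant for BCI and FC, a free parameter for BCI*.
    lapse
        Lapse rate lambda in [0, 1]: probability of a random 50/50 guess.
        Fitting constrains it to [0, 0.5]; the forward model admits the
        full range (a pure-lapse observer is a useful degenerate case).
    """

    model: Model
    sigma_by_noise: Mapping[int, float]
    p_same: float | None = None
    k0: float | None = None
    sigma_s: float = SIGMA_S_DEFAULT
    lapse: float = 0.0

    def __post_init__(self) -> None:
        model = Model(self.model)
        object.__setattr__(self, "model", model)
        object.__setattr__(self, "sigma_by_noise", dict(self.sigma_by_noise))
        if model is Model.FC:
            if self.k0 is None or self.p_same is not None:
                raise ValueError("FC requires k0 and forbids p_same")
            if not self.k0 > 0:
                raise ValueError(f"k0 must be > 0, got {self.k0}")
        else:
            if self.p_same is None or self.k0 is not None:
                raise ValueError(f"{model.value} requires p_same and forbids k0")
            if not 0.0 < self.p_same < 1.0:
                raise ValueError(f"p_same must be in (0, 1), got {self.p_same}")
        for noise, sigma in self.sigma_by_noise.items():
            if not sigma > 0:
                raise ValueError(f"sigma for noise {noise} must be > 0, got {sigma}")
        if not self.sigma_s > 0:
            raise ValueError(f"sigma_s must be > 0, got {self.sigma_s}")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError(f"lapse must be in [0, 1], got {self.lapse}")

    def sigma(self, noise: int) -> float:
        """Measurement-noise SD (ms) for a visual-noise level."""
        try:
            return float(self.sigma_by_noise[noise])
        except KeyError:
            raise KeyError(
                f"noise level {noise!r} not in sigma_by_noise "
                f"{sorted(self.sigma_by_noise)}"
            ) from None

    def criterion(self, noise: int) -> float | None:
        """Decision criterion (ms) in effect at a noise level.

        ``k0`` for the fixed-criterion observer, the Bayesian criterion
        otherwise; ``None`` when the Bayesian criterion is undefined.
        """
        if self.model is Model.FC:
            return self.k0
        return decision_criterion(self.p_same, self.sigma(noise), self.sigma_s)


def _check_domain(p_same: float, sigma: float, sigma_s: float) -> None:
    if not 0.0 < p_same < 1.0:
        raise ValueError(f"p_same must be in (0, 1), got {p_same}")
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if not sigma_s > 0:
        raise ValueError(f"sigma_s must be > 0, got {sigma_s}")


def decision_criterion(p_same: float, sigma: float, sigma_s: float) -> float | None:
    """Bayesian decision criterion k (ms) on the measured asynchrony.

    The posterior favours a common cause exactly when ``|x| < k`` with

        K = [sigma^2 (sigma_s^2 + sigma^2) / sigma_s^2]
            * [2 ln(p_same / (1 - p_same)) + ln((sigma_s^2 + sigma^2) / sigma^2)]

    and ``k = sqrt(K)``.  Returns ``None`` when ``K <= 0``, i.e. when the
    prior is so low that no measurement yields a common-cause verdict.
    """
    _check_domain(p_same, sigma, sigma_s)
    v = sigma * sigma
    vs = sigma_s * sigma_s
    bracket = 2.0 * math.log(p_same / (1.0 - p_same)) + math.log((vs + v) / v)
    big_k = v * (vs + v) / vs * bracket
    if big_k <= 0.0:
        return None
    return math.sqrt(big_k)


def posterior_log_odds(
    x: float, p_same: float, sigma: float, sigma_s: float
) -> float:
    """Posterior log-odds d of a common cause given a measurement x (ms).

    d = ln(p_same/(1-p_same)) + ln[ N(x; 0, sigma^2) / N(x; 0, sigma_s^2+sigma^2) ].
    Positive d means the posterior favours the common cause; d crosses zero
    at |x| = k whenever the criterion is defined.
    """
    _check_domain(p_same, sigma, sigma_s)
    v = sigma * sigma
    vs = sigma_s * sigma_s
    prior = math.log(p_same / (1.0 - p_same))
    # log N(x;0,v) - log N(x;0,vs+v), expanded to avoid density underflow
    llr = 0.5 * math.log((vs + v) / v) - 0.5 * x * x * (1.0 / v - 1.0 / (vs + v))
    return prior + llr


def p_report_common(s, params: ObserverParams, noise: int):
    """Probability of a "yes, common cause" report at true asynchrony s (ms).

    With criterion c (Bayesian k or fixed k0) and measurement SD sigma for
    the given noise level:

        p(yes | s) = lapse/2 + (1 - lapse) * [Phi((c-s)/sigma) - Phi((-c-s)/sigma)]

    i.e. the probability that the noisy measurement lands inside (-c, c),
    mixed with a 50/50 lapse.  When the Bayesian criterion is undefined
    (K <= 0) only lapses produce "yes", so the probability is lapse/2.
    Accepts scalar or array ``s``; even in s; bounded by
    [lapse/2, 1 - lapse/2].
    """
    s = np.asarray(s, dtype=float)
    lam = params.lapse
    c = params.criterion(noise)
    if c is None:
        out = np.full(s.shape, lam / 2.0)
        return float(out) if out.ndim == 0 else out
    sigma = params.sigma(noise)
    inside = stats.norm.cdf((c - s) / sigma) - stats.norm.cdf((-c - s) / sigma)
    out = lam / 2.0 + (1.0 - lam) * inside
    return float(out) if out.ndim == 0 else out


def predicted_curve(design, params: ObserverParams):
    """Predicted response probability for every cell of a stimulus design.

    Returns a DataFrame with columns (noise, asynchrony_ms, p_yes), one row
    per (noise level, asynchrony) cell of ``design`` (a
    :class:`~ownsync.synthetic_data.StimulusDesign`).
    """
    import pandas as pd

    design_noises = set(design.noise_levels)
    param_noises = set(params.sigma_by_noise)
    if not design_noises <= param_noises:
        raise ValueError(
            f"design noise levels {sorted(design_noises)} not covered by "
            f"sigma_by_noise {sorted(param_noises)}"
        )
    rows = []
    for noise in design.noise_levels:
        p = p_report_common(np.array(design.asynchronies, dtype=float), params, noise)
        for s, pi in zip(design.asynchronies, np.atleast_1d(p)):
            rows.append({"noise": noise, "asynchrony_ms": s, "p_yes": float(pi)})
    return pd.DataFrame(rows)


def mc_decision_oracle(
    s: float,
    params: ObserverParams,
    noise: int,
    n_samples: int,
    seed: int,
) -> float:
    """Monte-Carlo fraction of common-cause reports at asynchrony s.

    Independent check of :func:`p_report_common` for the Bayesian family:
    draws measurements x ~ N(s, sigma^2), evaluates the posterior log-odds
    on each, reports "yes" when d > 0, then overrides each trial by a lapse
    coin (probability ``lapse``) followed by a fair guess.
    """
    if params.model is Model.FC:
        raise ValueError("oracle is defined for the Bayesian family (BCI/BCI*)")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = params.sigma(noise)
    x = rng.normal(loc=s, scale=sigma, size=n_samples)
    v = sigma * sigma
    vs = params.sigma_s * params.sigma_s
    prior = math.log(params.p_same / (1.0 - params.p_same))
    d = prior + 0.5 * math.log((vs + v) / v) - 0.5 * x * x * (1.0 / v - 1.0 / (vs + v))
    say_yes = d > 0.0
    lapses = rng.random(n_samples) < params.lapse
    guesses = rng.random(n_samples) < 0.5
    say_yes = np.where(lapses, guesses, say_yes)
    return float(np.mean(say_yes))
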