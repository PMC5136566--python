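"""Logistic baseline, model comparison, and goodness of fit.

The conventional psychometric analysis fits, per temporal combination
``j``, a two-coefficient logistic regression of the detection report on
the amplitude, ``logit Pr(R=1|A) = beta0_j + beta1_j * A``.  With four
combinations that is 8 free coefficients against the hazard model's 6
parameters; the Bayesian Information Criterion
``BIC = -2 log L_hat + n_P log n_D`` weighs fit against complexity, and a
one-tailed sign (binomial) test over many datasets asks whether the
mechanistic model wins more often than chance.  Absolute goodness of fit
uses the likelihood-ratio statistic G^2 against the saturated model whose
fitted probabilities are the observed per-cell detection fractions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data import Dataset
from .model import HazardParams, ModelConstants

__all__ = [
    "Cell",
    "GroupedCells",
    "LogisticCoefficients",
    "ComparisonResult",
    "group_trials",
    "clopper_pearson",
    "fit_logistic",
    "bic",
    "bic_sign_test",
    "goodness_of_fit",
    "compare_models",
]

#: Cap on |beta1| (logit per mA) used when complete separation is detected.
SLOPE_CAP = 1e3


@dataclass(frozen=True)
class Cell:
    """Trials grouped at one (combination, amplitude) level."""

    combo_label: str
    amplitude: float
    n: int
    k: int

    @property
    def fraction(self) -> float:
        return self.k / self.n


@dataclass(frozen=True)
class GroupedCells:
    cells: tuple[Cell, ...]

    @property
    def n_total(self) -> int:
        return sum(c.n for c in self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)


def group_trials(dataset: Dataset, amp_round: float = 0.01) -> GroupedCells:
    """Group trials into (combination, amplitude) cells.

    Amplitudes are rounded to ``amp_round`` mA first, since adaptive
    amplitude selection can emit near-duplicate levels.  Counts are
    conserved: the cell sizes sum to the trial count.
    """
    counts: dict[tuple[str, float], list[int]] = {}
    for trial in dataset:
        amp = round(trial.stimulus.A / amp_round) * amp_round
        key = (trial.stimulus.combo_label, round(amp, 10))
        cell = counts.setdefault(key, [0, 0])
        cell[0] += 1
        cell[1] += trial.response
    cells = tuple(
        Cell(label, amp, n, k) for (label, amp), (n, k) in sorted(counts.items())
    )
    return GroupedCells(cells)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval via beta quantiles.

    Returns ``(lower, upper)`` with ``lower = 0`` when ``k = 0`` and
    ``upper = 1`` when ``k = n``.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    tail = (1.0 - level) / 2.0
    lower = 0.0 if k == 0 else float(stats.beta.ppf(tail, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1.0 - tail, k + 1, n - k))
    return lower, upper


@dataclass(frozen=True)
class LogisticCoefficients:
    """Per-combination intercepts and slopes of the logistic baseline."""

    beta0: dict[str, float]
    beta1: dict[str, float]
    separated: tuple[str, ...] = ()

    @property
    def n_params(self) -> int:
        return 2 * len(self.beta0)


def _logistic_nll(beta0: float, beta1: float, amps: np.ndarray, resp: np.ndarray) -> float:
    eta = beta0 + beta1 * amps
    # -log L = sum log(1 + exp(eta)) - sum_{R=1} eta, in stable form
    return float(np.sum(np.logaddexp(0.0, eta)) - resp @ eta)


def _is_separated(amps: np.ndarray, resp: np.ndarray) -> bool:
    """Complete (or one-class) separation: the ML slope or intercept is
    unbounded because an amplitude cut classifies every response."""
    detected = amps[resp == 1]
    missed = amps[resp == 0]
    if detected.size == 0 or missed.size == 0:
        return True
    return missed.max() < detected.min() or detected.max() < missed.min()


def fit_logistic(dataset: Dataset) -> tuple[LogisticCoefficients, float]:
    """Per-combination Bernoulli ML fit of the logit-linear model.

    Fitting uses iteratively reweighted least squares (statsmodels GLM).
    Complete separation (a perfectly classifying amplitude cut) makes the
    ML slope diverge; such combinations are flagged and refit with the
    slope capped at ``|beta1| <= 1000`` per mA so the total NLL and BIC
    remain finite.  Returns the coefficients and the summed NLL.
    """
    beta0: dict[str, float] = {}
    beta1: dict[str, float] = {}
    separated: list[str] = []
    total_nll = 0.0
    for label in dataset.combos:
        sub = dataset.subset(label)
        amps = sub.amplitudes
        resp = sub.responses.astype(float)
        if np.unique(amps).size < 2:
            raise ValueError(
                f"combination {label!r} has a single amplitude level; "
                "the logistic slope is not estimable"
            )
        X = sm.add_constant(amps)
        b0 = b1 = None
        if not _is_separated(amps, resp):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = sm.GLM(resp, X, family=sm.families.Binomial()).fit(maxiter=200)
                    b0, b1 = float(res.params[0]), float(res.params[1])
                except Exception:
                    pass
        if b0 is None or not np.isfinite([b0, b1]).all() or abs(b1) > SLOPE_CAP:
            # separation: bounded refit with the slope capped
            separated.append(label)
            from scipy.optimize import minimize

            def nll_fn(b, amps=amps, resp=resp):
                return _logistic_nll(b[0], b[1], amps, resp)

            start = [0.0, 0.0]
            res = minimize(
                nll_fn, start, method="L-BFGS-B",
                bounds=[(-1e4, 1e4), (-SLOPE_CAP, SLOPE_CAP)],
            )
            b0, b1 = float(res.x[0]), float(res.x[1])
        beta0[label] = b0
        beta1[label] = b1
        total_nll += _logistic_nll(b0, b1, amps, resp)
    return (
        LogisticCoefficients(beta0=beta0, beta1=beta1, separated=tuple(separated)),
        total_nll,
    )


def bic(nll: float, n_params: int, n_obs: int) -> float:
    """Bayesian Information Criterion ``2 * nll + n_params * ln(n_obs)``."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return 2.0 * nll + n_params * math.log(n_obs)


def bic_sign_test(deltas) -> tuple[int, float]:
    """One-tailed sign test on per-dataset BIC differences.

    ``deltas`` are ``BIC_hazard - BIC_logistic``; a negative delta favours
    the hazard model.  Returns the number of datasets favouring it and
    the exact upper-tail binomial probability
    ``P(X >= n_favor | n, 1/2)``.  Exact zeros are dropped with a warning.
    """
    deltas = np.asarray(list(deltas), dtype=float)
    if deltas.size == 0:
        raise ValueError("need at least one BIC difference")
    zeros = deltas == 0.0
    if zeros.any():
        warnings.warn(f"dropping {int(zeros.sum())} exact BIC ties", stacklevel=2)
        deltas = deltas[~zeros]
    n = deltas.size
    n_favor = int(np.sum(deltas < 0))
    p = float(stats.binom.sf(n_favor - 1, n, 0.5))
    return n_favor, p


def goodness_of_fit(
    dataset: Dataset,
    theta_hat: HazardParams,
    constants: ModelConstants | None = None,
    amp_round: float = 0.01,
) -> tuple[float, int, float]:
    """Likelihood-ratio goodness of fit against the saturated model.

    The saturated model's fitted probability in each (combination,
    amplitude) cell is the observed detection fraction ``k/n``;
    ``G^2 = 2 (log L_saturated - log L_hazard) >= 0`` is referred to a
    chi-squared distribution with ``(number of cells) - 6`` degrees of
    freedom.  Returns ``(G2, df, p)``.
    """
    from .inference import LikelihoodEvaluator

    cells = group_trials(dataset, amp_round=amp_round)
    df = len(cells) - 6
    if df < 1:
        raise ValueError(
            f"{len(cells)} cells give {df} degrees of freedom; "
            "the model is not testable on this grouping"
        )
    # saturated log-likelihood with 0*log(0) := 0
    ll_sat = 0.0
    for c in cells:
        if 0 < c.k:
            ll_sat += c.k * math.log(c.k / c.n)
        if c.k < c.n:
            ll_sat += (c.n - c.k) * math.log(1.0 - c.k / c.n)
    # hazard-model log-likelihood on the *rounded* grouping, so the two
    # likelihoods are computed on identical cells
    rounded = _rounded_dataset(dataset, amp_round)
    nll_hm = LikelihoodEvaluator(rounded, constants).nll(theta_hat)
    g2 = max(2.0 * (ll_sat + nll_hm), 0.0)
    p = float(stats.chi2.sf(g2, df))
    return g2, df, p


def _rounded_dataset(dataset: Dataset, amp_round: float) -> Dataset:
    from .data import Trial
    from dataclasses import replace as dc_replace

    trials = []
    for t in dataset:
        amp = round(round(t.stimulus.A / amp_round) * amp_round, 10)
        trials.append(Trial(dc_replace(t.stimulus, A=amp), t.response, t.index))
    return Dataset(tuple(trials), dataset.design_label, dict(dataset.meta))


@dataclass(frozen=True)
class ComparisonResult:
    """BIC comparison of the hazard model against the logistic baseline."""

    nll_hm: float
    nll_logistic: float
    n_obs: int
    n_params_hm: int
    n_params_logistic: int
    bic_hm: float
    bic_logistic: float

    @property
    def delta(self) -> float:
        """``BIC_hazard - BIC_logistic``; negative favours the hazard model."""
        return self.bic_hm - self.bic_logistic


def compare_models(
    dataset: Dataset,
    theta_hat: HazardParams,
    constants: ModelConstants | None = None,
) -> ComparisonResult:
    """Fit the logistic baseline and assemble the BIC comparison."""
    from .inference import LikelihoodEvaluator

    nll_hm = LikelihoodEvaluator(dataset, constants).nll(theta_hat)
    coeffs, nll_logistic = fit_logistic(dataset)
    n_obs = dataset.n
    return ComparisonResult(
        nll_hm=nll_hm,
        nll_logistic=nll_logistic,
        n_obs=n_obs,
        n_params_hm=6,
        n_params_logistic=coeffs.n_params,
        bic_hm=bic(nll_hm, 6, n_obs),
        bic_logistic=bic(nll_logistic, coeffs.n_params, n_obs),
    )
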