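"""Maximum-likelihood estimation of the hazard-model parameters.

The likelihood of a dataset is the product of independent Bernoulli terms,
one per trial, with success probability given by the model psychometric
function.  The negative log-likelihood is minimised over the hypercubic
feasible space by multi-start bounded local optimisation: Latin-hypercube
starting points (log10-uniform per parameter, because the bounds span 2-6
decades) followed by a trust-region-reflective least-squares descent on
residuals ``r = sqrt(-log Psi)`` / ``sqrt(-log(1 - Psi))`` whose squared
sum is exactly the negative log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .data import Dataset, Trial
from .model import (
    PARAM_NAMES,
    HazardParams,
    ModelConstants,
    ParameterSpace,
    default_parameter_space,
    effective_activation,
    initial_panels,
    membrane_response_kernel,
    peripheral_drive,
    _gl_rule,
    _panel_nodes,
)
from scipy.special import expit

__all__ = [
    "LikelihoodEvaluator",
    "LocalFit",
    "FitResult",
    "CombineReport",
    "negative_log_likelihood",
    "latin_hypercube_starts",
    "local_optimize",
    "fit_hazard_model",
    "boundary_flags",
    "combine_datasets",
]

#: Probabilities are clamped into [PSI_EPS, 1 - PSI_EPS] inside logs.
PSI_EPS = 1e-12

# Initial tail splits (ms after the last pulse onset) for the adaptive
# quadrature in the likelihood hot path; bisection refines from here.
_TAIL_LADDER = (2.0, 10.0, 50.0, 200.0)
_HOT_ORDER = 16
_HOT_RTOL = 1e-7
_HOT_MAX_DEPTH = 14


class LikelihoodEvaluator:
    """Precomputed fast Bernoulli likelihood for one dataset.

    Trials are grouped into (temporal combination, amplitude) cells; the
    membrane-response kernel, which is shared by all amplitudes of one
    combination, is evaluated once per parameter vector on a fixed
    composite Gauss-Legendre grid.  The grid (one panel per inter-pulse
    segment plus a graded tail ladder) is dense enough that the result
    matches the adaptive quadrature of
    :func:`nocifit.model.detection_probability` to ~1e-9 at data-relevant
    parameter values.
    """

    def __init__(self, dataset: Dataset, constants: ModelConstants | None = None):
        if constants is None:
            constants = ModelConstants()
        self.dataset = dataset
        self.constants = constants
        self.n_trials = dataset.n

        # group trials into (combo, amplitude) cells
        self._groups = []  # per combo: dict of precomputed arrays
        by_combo: dict[str, list[Trial]] = {}
        for trial in dataset:
            by_combo.setdefault(trial.stimulus.combo_label, []).append(trial)

        for label, trials in by_combo.items():
            stim0 = trials[0].stimulus
            nop = stim0.NoP
            ipi = 0.0 if stim0.IPI is None else stim0.IPI
            onsets = np.arange(nop, dtype=float) * ipi

            # initial quadrature panels; adaptive bisection refines per theta
            edges = [t for t in onsets if t < constants.T]
            t_last = edges[-1] if edges else 0.0
            for step in _TAIL_LADDER:
                t = t_last + step
                if t < constants.T:
                    edges.append(t)
            edges.append(constants.T)
            edges = sorted(set(edges))
            panels = list(zip(edges[:-1], edges[1:]))

            amps = np.array([t.stimulus.A for t in trials])
            unique_amps = np.unique(amps)
            k = np.zeros(unique_amps.size)
            n = np.zeros(unique_amps.size)
            for trial in trials:
                i = int(np.searchsorted(unique_amps, trial.stimulus.A))
                n[i] += 1
                k[i] += trial.response

            self._groups.append(
                dict(
                    label=label,
                    PW=stim0.PW,
                    onsets=onsets,
                    panels=panels,
                    amps=unique_amps,
                    k=k,
                    n=n,
                )
            )

    # -- core evaluations ---------------------------------------------------

    def _cell_psi(self, theta: np.ndarray) -> list[np.ndarray]:
        """Detection probability per (combo, amplitude) cell.

        The rate integral is computed by composite Gauss-Legendre
        quadrature with adaptive panel bisection, vectorised over the
        amplitudes of one combination (the membrane kernel is shared).
        A panel is accepted once the coarse/bisected discrepancy is below
        tolerance for every amplitude; adaptivity matters when a small
        slope parameter makes the rate nearly a step function in time.
        """
        alpha1, tau1, tau2, alphaL, sigmaL, lambdaL = theta
        tau_s = self.constants.tau_s
        nodes_ref, weights_ref = _gl_rule(_HOT_ORDER)
        out = []
        for grp in self._groups:
            onsets = grp["onsets"]
            fA = grp["amps"] * -np.expm1(-grp["PW"] / tau1)
            c = np.maximum(fA - alpha1, 0.0)

            def seg_batch(edges: np.ndarray) -> np.ndarray:
                """Panel integrals for rows (a, b) of ``edges``, batched."""
                half = 0.5 * (edges[:, 1] - edges[:, 0])  # (P,)
                t = edges[:, 0, None] + half[:, None] * (nodes_ref + 1.0)  # (P, m)
                g = membrane_response_kernel(t.ravel(), onsets, tau2, tau_s)
                z = (c[:, None] * g[None, :] - alphaL) / sigmaL
                lam = lambdaL * expit(z).reshape(c.size, t.shape[0], t.shape[1])
                return np.einsum("apm,pm->ap", lam, half[:, None] * weights_ref)

            panels = np.asarray(grp["panels"], dtype=float)
            coarse = None  # parent integrals, carried over from the last round
            scale = None
            lam_T = np.zeros_like(c)
            depth = 0
            while panels.size:
                mids = 0.5 * (panels[:, 0] + panels[:, 1])
                halves = np.empty((2 * panels.shape[0], 2))
                halves[0::2, 0], halves[0::2, 1] = panels[:, 0], mids
                halves[1::2, 0], halves[1::2, 1] = mids, panels[:, 1]
                if coarse is None:
                    # first round: parents and children in one batched call
                    batch = seg_batch(np.vstack([panels, halves]))
                    coarse = batch[:, : panels.shape[0]]
                    children = batch[:, panels.shape[0]:]
                    scale = np.maximum(np.abs(coarse.sum(axis=1)), 1e-2)
                else:
                    children = seg_batch(halves)
                fine = children[:, 0::2] + children[:, 1::2]
                ok = np.all(
                    np.abs(fine - coarse) <= _HOT_RTOL * scale[:, None], axis=0
                )
                if depth >= _HOT_MAX_DEPTH:
                    ok[:] = True
                ok |= (panels[:, 1] - panels[:, 0]) < 1e-9
                lam_T += fine[:, ok].sum(axis=1)
                keep = ~ok
                panels = halves[np.repeat(keep, 2)]
                coarse = children[:, np.repeat(keep, 2)]
                depth += 1
            out.append(-np.expm1(-lam_T))
        return out

    def psi(self, params: HazardParams | np.ndarray) -> dict[tuple, float]:
        """Mapping (combo_label, amplitude) -> Psi."""
        theta = (
            params.to_array() if isinstance(params, HazardParams) else np.asarray(params)
        )
        result: dict[tuple, float] = {}
        for grp, psi in zip(self._groups, self._cell_psi(theta)):
            for a, p in zip(grp["amps"], psi):
                result[(grp["label"], float(a))] = float(p)
        return result

    def nll(self, params: HazardParams | np.ndarray) -> float:
        theta = (
            params.to_array() if isinstance(params, HazardParams) else np.asarray(params)
        )
        total = 0.0
        for grp, psi in zip(self._groups, self._cell_psi(theta)):
            psi = np.clip(psi, PSI_EPS, 1.0 - PSI_EPS)
            total -= float(
                grp["k"] @ np.log(psi) + (grp["n"] - grp["k"]) @ np.log1p(-psi)
            )
        return total

    def residuals(self, params: HazardParams | np.ndarray) -> np.ndarray:
        """Least-squares residuals with ``sum(r**2) == nll`` exactly.

        Two residuals per cell: ``sqrt(k * -log Psi)`` for the detections
        and ``sqrt((n - k) * -log(1 - Psi))`` for the misses; algebraically
        identical to one ``sqrt(-log .)`` residual per trial.
        """
        theta = (
            params.to_array() if isinstance(params, HazardParams) else np.asarray(params)
        )
        parts = []
        for grp, psi in zip(self._groups, self._cell_psi(theta)):
            psi = np.clip(psi, PSI_EPS, 1.0 - PSI_EPS)
            parts.append(np.sqrt(grp["k"] * -np.log(psi)))
            parts.append(np.sqrt((grp["n"] - grp["k"]) * -np.log1p(-psi)))
        return np.concatenate(parts)


def negative_log_likelihood(
    dataset: Dataset,
    params: HazardParams,
    constants: ModelConstants | None = None,
) -> float:
    """Negative log-likelihood ``-sum_k [R_k log Psi_k + (1-R_k) log(1-Psi_k)]``.

    Probabilities are clamped into ``[1e-12, 1 - 1e-12]`` so the value is
    always finite and non-negative.
    """
    return LikelihoodEvaluator(dataset, constants).nll(params)


# ---------------------------------------------------------------------------
# Multi-start bounded optimisation
# ---------------------------------------------------------------------------

def latin_hypercube_starts(
    space: ParameterSpace, n_starts: int, seed: int
) -> list[HazardParams]:
    """Latin-hypercube starting points, uniform in log10 of each parameter.

    Each marginal has exactly one point per equal-probability stratum;
    identical seeds give identical samples.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    sampler = qmc.LatinHypercube(d=6, seed=seed)
    u = sampler.random(n_starts)
    log_theta = space.log_lower + u * (space.log_upper - space.log_lower)
    return [HazardParams.from_array(10.0**row) for row in log_theta]


@dataclass(frozen=True)
class LocalFit:
    """Outcome of one bounded local optimisation run."""

    params: HazardParams
    nll: float
    converged: bool
    n_evaluations: int = 0


def _minimize_from(
    evaluator: LikelihoodEvaluator,
    start_log: np.ndarray,
    log_lower: np.ndarray,
    log_upper: np.ndarray,
    free: np.ndarray,
    fixed_log: np.ndarray,
    tol: float = 1e-10,
    max_nfev: int = 3500,
) -> LocalFit:
    """Trust-region-reflective descent in log10 space.

    ``free`` is a boolean mask of optimised coordinates; the rest are held
    at ``fixed_log`` (used by the profile-likelihood machinery).
    """
    full = fixed_log.copy()

    def resid(u_free: np.ndarray) -> np.ndarray:
        full[free] = u_free
        return evaluator.residuals(10.0**full)

    eps = 1e-12 * (log_upper - log_lower)
    x0 = np.clip(start_log[free], (log_lower + eps)[free], (log_upper - eps)[free])
    result = least_squares(
        resid,
        x0,
        bounds=(log_lower[free], log_upper[free]),
        method="trf",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_nfev,
    )
    full[free] = result.x
    theta = HazardParams.from_array(10.0**full)
    return LocalFit(
        params=theta,
        nll=float(np.dot(result.fun, result.fun)),
        converged=bool(result.status > 0),
        n_evaluations=int(result.nfev),
    )


def local_optimize(
    dataset: Dataset,
    start: HazardParams,
    space: ParameterSpace | None = None,
    constants: ModelConstants | None = None,
    tol: float = 1e-10,
    max_nfev: int = 3500,
) -> LocalFit:
    """Bounded local minimisation of the NLL from one starting point.

    The NLL is cast as a nonlinear least-squares problem (see
    :meth:`LikelihoodEvaluator.residuals`) and minimised with the
    trust-region-reflective method on log10-transformed parameters.
    Non-convergence returns the best iterate flagged, never raises.
    """
    if space is None:
        space = default_parameter_space()
    evaluator = LikelihoodEvaluator(dataset, constants)
    start_log = np.log10(start.to_array())
    free = np.ones(6, dtype=bool)
    return _minimize_from(
        evaluator, start_log, space.log_lower, space.log_upper, free,
        start_log.copy(), tol=tol, max_nfev=max_nfev,
    )


@dataclass(frozen=True)
class FitResult:
    """Multi-start maximum-likelihood estimate.

    ``per_start`` keeps one (start, final, final NLL, converged) record per
    Latin-hypercube start, sorted by final NLL; a step-like pattern in the
    sorted NLLs (a plateau at the global value) indicates that local
    optimisation was effective.
    """

    theta_hat: HazardParams
    nll_hat: float
    start_count: int
    per_start: tuple
    boundary: tuple
    converged: bool

    @property
    def sorted_nlls(self) -> np.ndarray:
        return np.array([rec[2] for rec in self.per_start])

    @property
    def any_boundary(self) -> bool:
        return any(self.boundary)


def fit_hazard_model(
    dataset: Dataset,
    space: ParameterSpace | None = None,
    constants: ModelConstants | None = None,
    n_starts: int = 100,
    seed: int = 0,
    tol: float = 1e-10,
) -> FitResult:
    """Maximum-likelihood fit by Latin-hypercube multi-start optimisation.

    Runs :func:`local_optimize` from every start and takes the argmin of
    the final NLLs.  Deterministic given ``seed``.
    """
    if space is None:
        space = default_parameter_space()
    evaluator = LikelihoodEvaluator(dataset, constants)
    starts = latin_hypercube_starts(space, n_starts, seed)

    records = []
    for start in starts:
        start_log = np.log10(start.to_array())
        fit = _minimize_from(
            evaluator, start_log, space.log_lower, space.log_upper,
            np.ones(6, dtype=bool), start_log.copy(), tol=tol,
        )
        records.append((start, fit.params, fit.nll, fit.converged))
    if not records:
        raise RuntimeError("all optimisation starts failed")
    records.sort(key=lambda rec: rec[2])
    best = records[0]
    flags = boundary_flags(best[1], space)
    return FitResult(
        theta_hat=best[1],
        nll_hat=best[2],
        start_count=n_starts,
        per_start=tuple(records),
        boundary=flags,
        converged=best[3],
    )


def boundary_flags(
    theta_hat: HazardParams,
    space: ParameterSpace | None = None,
    rel_tol: float = 1e-3,
) -> tuple[bool, ...]:
    """Flag parameters whose estimate sits on the feasible-space boundary.

    Parameter ``i`` is flagged when ``log10(theta_i)`` is within
    ``rel_tol`` of the log10-range of either bound.  Boundary estimates
    signal that the model (or the dataset) cannot support an interior
    optimum and downstream identifiability analysis is unreliable.
    """
    if space is None:
        space = default_parameter_space()
    log_theta = np.log10(theta_hat.to_array())
    span = space.log_upper - space.log_lower
    near_low = (log_theta - space.log_lower) < rel_tol * span
    near_high = (space.log_upper - log_theta) < rel_tol * span
    return tuple(bool(b) for b in (near_low | near_high))


# ---------------------------------------------------------------------------
# Combining repeated sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CombineReport:
    """Outcome of the day-1 / day-2 combination screen.

    ``failures`` lists (combo_label, criterion, detail) tuples where
    criterion is ``"amplitude_shift"`` (ranges barely overlap) or
    ``"probability_mismatch"`` (non-overlapping exact binomial intervals
    at a shared amplitude).
    """

    accepted: bool
    failures: tuple = ()
    dataset: Dataset | None = None


def _amp_range_overlap(a: np.ndarray, b: np.ndarray) -> float:
    lo = max(a.min(), b.min())
    hi = min(a.max(), b.max())
    shorter = min(a.max() - a.min(), b.max() - b.min())
    if shorter <= 0:  # degenerate range: a single amplitude level
        return 1.0 if lo <= hi else 0.0
    return max(0.0, hi - lo) / shorter


def combine_datasets(
    day1: Dataset,
    day2: Dataset,
    amp_overlap_min: float = 0.5,
    alpha: float = 0.95,
    amp_round: float = 0.01,
) -> CombineReport:
    """Screen two same-design sessions for similarity, then concatenate.

    Per temporal combination, the sessions must (a) probe overlapping
    amplitude ranges (overlap fraction of the shorter range >=
    ``amp_overlap_min``) and (b) show compatible detection probabilities:
    at every amplitude level present on both days, the exact
    (Clopper-Pearson) binomial intervals at level ``alpha`` must overlap.
    Any failure yields a structured rejection instead of a combined
    dataset.
    """
    from .baseline import clopper_pearson, group_trials

    if day1.combos != day2.combos:
        raise ValueError(
            f"designs differ: {day1.combos} vs {day2.combos}"
        )

    failures = []
    cells1 = group_trials(day1, amp_round=amp_round)
    cells2 = group_trials(day2, amp_round=amp_round)
    for label in day1.combos:
        a1 = day1.subset(label).amplitudes
        a2 = day2.subset(label).amplitudes
        frac = _amp_range_overlap(a1, a2)
        if frac < amp_overlap_min:
            failures.append(
                (label, "amplitude_shift",
                 f"amplitude-range overlap fraction {frac:.3f} < {amp_overlap_min}")
            )
        d1 = {c.amplitude: c for c in cells1.cells if c.combo_label == label}
        d2 = {c.amplitude: c for c in cells2.cells if c.combo_label == label}
        for amp in sorted(set(d1) & set(d2)):
            c1, c2 = d1[amp], d2[amp]
            l1, u1 = clopper_pearson(c1.k, c1.n, alpha)
            l2, u2 = clopper_pearson(c2.k, c2.n, alpha)
            if l1 > u2 or l2 > u1:
                failures.append(
                    (label, "probability_mismatch",
                     f"at A={amp} mA: {c1.k}/{c1.n} vs {c2.k}/{c2.n} "
                     f"(CIs [{l1:.3f},{u1:.3f}] and [{l2:.3f},{u2:.3f}] disjoint)")
                )
    if failures:
        return CombineReport(accepted=False, failures=tuple(failures))
    return CombineReport(accepted=True, dataset=day1.concat(day2))
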