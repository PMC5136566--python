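"""Profile-likelihood identifiability analysis of the hazard model.

For each parameter ``theta_i`` the profile likelihood is the maximal
likelihood with ``theta_i`` frozen on a grid and the other five
parameters re-optimised; ``LPL = -2 log PL`` is compared with the global
optimum ``-2 log L_hat``.  A bounded likelihood-based confidence interval
(threshold = optimum + chi-squared 0.95 quantile with one degree of
freedom, 3.84) marks an identifiable parameter; an interval running into
a feasible-space bound marks practical non-identifiability; a flat LPL
marks structural non-identifiability.

The structural case has an analytic origin here: when every stimulus in a
design shares one pulse width, scaling ``alpha1``, ``alphaL`` and
``sigmaL`` by a common factor and re-solving ``tau1`` so that the
peripheral charging factor ``1 - exp(-PW/tau1)`` scales by the same
factor leaves the firing rate, and hence the likelihood, exactly
invariant.  The scale factor is confined to a finite window by the
``tau1`` bounds, so those three parameters are *set*-identifiable with
interval-endpoint ratio

    r = (1 - exp(-PW / tau1_lower)) / (1 - exp(-PW / tau1_upper)),

while ``tau1`` itself is non-identifiable over its whole range.  Varying
the pulse width across stimuli is therefore necessary for structural
identifiability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .data import Dataset
from .inference import FitResult, LikelihoodEvaluator, _minimize_from
from .model import (
    PARAM_NAMES,
    HazardParams,
    ModelConstants,
    ParameterSpace,
    default_parameter_space,
    peripheral_drive,
)

__all__ = [
    "ProfileCurve",
    "ProfileCI",
    "Classification",
    "Profiler",
    "profile_likelihood",
    "profile_confidence_interval",
    "classify_identifiability",
    "symmetry_transform",
    "admissible_scale_range",
    "set_identifiability_ratio",
    "check_design_pw_variation",
    "DesignReport",
]

LABEL_IDENTIFIABLE = "identifiable"
LABEL_PRACTICAL = "practically_non_identifiable"
LABEL_STRUCTURAL = "structurally_non_identifiable"


@dataclass
class ProfileCurve:
    """Profile of ``-2 log PL`` for one parameter on a log-spaced grid."""

    param_index: int
    param_name: str
    grid: np.ndarray
    lpl: np.ndarray
    nll_hat: float
    theta_hat_value: float
    idx_hat: int
    solutions: tuple = ()
    failed: tuple = ()
    improved: bool = False
    ci: "ProfileCI | None" = None
    label: str | None = None
    flat_ratio: float | None = None


@dataclass(frozen=True)
class ProfileCI:
    """Likelihood-based confidence interval from a profile curve."""

    lower: float
    upper: float
    open_low: bool
    open_high: bool
    level: float
    multimodal: bool = False

    @property
    def bounded(self) -> bool:
        return not (self.open_low or self.open_high)


@dataclass(frozen=True)
class Classification:
    label: str
    flat_interval: tuple[float, float] | None = None

    @property
    def flat_ratio(self) -> float | None:
        if self.flat_interval is None:
            return None
        lo, hi = self.flat_interval
        return hi / lo


# ---------------------------------------------------------------------------
# Closed-form symmetry of the single-pulse-width design
# ---------------------------------------------------------------------------

def set_identifiability_ratio(PW: float, tau1_lower: float, tau1_upper: float) -> float:
    """Endpoint ratio of the set-identifiability interval.

    ``r = (1 - exp(-PW/tau1_lower)) / (1 - exp(-PW/tau1_upper))``; always
    > 1, decreasing in ``PW``, with limits ``tau1_upper/tau1_lower`` as
    ``PW -> 0`` and 1 as ``PW -> inf``.
    """
    if not 0 < tau1_lower < tau1_upper:
        raise ValueError(
            f"need 0 < tau1_lower < tau1_upper, got {tau1_lower}, {tau1_upper}"
        )
    if PW <= 0:
        raise ValueError(f"PW must be positive, got {PW}")
    return -math.expm1(-PW / tau1_lower) / -math.expm1(-PW / tau1_upper)


def admissible_scale_range(
    theta: HazardParams, PW: float, space: ParameterSpace | None = None
) -> tuple[float, float]:
    """Admissible window ``(r_l, r_u)`` for the symmetry scale factor.

    The spurious ``tau1*`` must stay within its feasible bounds, which
    confines the ratio ``r* = (1 - exp(-PW/tau1*)) / (1 - exp(-PW/tau1))``
    to a finite window.
    """
    if space is None:
        space = default_parameter_space()
    denom = -math.expm1(-PW / theta.tau1)
    r_l = -math.expm1(-PW / space.upper[1]) / denom
    r_u = -math.expm1(-PW / space.lower[1]) / denom
    return r_l, r_u


def symmetry_transform(
    theta: HazardParams,
    r_star: float,
    PW: float,
    space: ParameterSpace | None = None,
) -> HazardParams:
    """Spurious parameter vector with an identical likelihood at fixed PW.

    ``alpha1``, ``alphaL`` and ``sigmaL`` are scaled by ``r_star``;
    ``tau1`` is re-solved so the peripheral charging factor scales by the
    same ``r_star``; ``tau2`` and ``lambdaL`` are copied.  On any stimulus
    set sharing the single pulse width ``PW`` the transformed vector
    produces the identical firing rate, hence an identical likelihood.
    """
    if space is None:
        space = default_parameter_space()
    r_l, r_u = admissible_scale_range(theta, PW, space)
    # the window endpoints map tau1* onto its bounds, which are feasible
    if not r_l * (1 - 1e-12) <= r_star <= r_u * (1 + 1e-12):
        raise ValueError(
            f"scale factor {r_star} outside the admissible range "
            f"({r_l:.6g}, {r_u:.6g}) set by the tau1 bounds"
        )
    scaled_charge = r_star * -math.expm1(-PW / theta.tau1)
    if scaled_charge >= 1.0:
        raise ValueError(
            f"scale factor {r_star} would require a charging fraction >= 1"
        )
    tau1_star = -PW / math.log1p(-scaled_charge)
    return HazardParams(
        alpha1=r_star * theta.alpha1,
        tau1=tau1_star,
        tau2=theta.tau2,
        alphaL=r_star * theta.alphaL,
        sigmaL=r_star * theta.sigmaL,
        lambdaL=theta.lambdaL,
    )


# ---------------------------------------------------------------------------
# Profile-likelihood computation
# ---------------------------------------------------------------------------

class Profiler:
    """Warm-started profile-likelihood sweeps for one fitted dataset.

    Each grid point solves a 5-parameter bounded re-optimisation, warm
    started from the neighbouring grid point's solution (sweeping outward
    from the estimate in both directions), from the global estimate, and
    -- on single-pulse-width designs -- from the closed-form symmetry
    transform, which makes the structurally flat directions exact.
    """

    def __init__(
        self,
        dataset: Dataset,
        fit: FitResult,
        space: ParameterSpace | None = None,
        constants: ModelConstants | None = None,
        tol: float = 1e-8,
        max_nfev: int = 400,
    ):
        self.space = space if space is not None else default_parameter_space()
        self.evaluator = LikelihoodEvaluator(dataset, constants)
        self.fit = fit
        self.theta_hat = fit.theta_hat
        self.nll_hat = fit.nll_hat
        self.tol = tol
        self.max_nfev = max_nfev
        pws = dataset.pulse_widths()
        self.single_pw = float(pws[0]) if pws.size == 1 else None
        counts = {}
        for trial in dataset:
            counts[trial.stimulus.PW] = counts.get(trial.stimulus.PW, 0) + 1
        self.modal_pw = float(max(counts, key=counts.get))
        if self.single_pw is not None:
            self._canonicalise_on_manifold()

    def _canonicalise_on_manifold(self) -> None:
        """Move the estimate along the exact symmetry manifold so that the
        scaled trio (alpha1, alphaL, sigmaL) keeps margin from its bounds.

        On single-pulse-width data the likelihood is invariant along the
        manifold, so this is a representative choice, not a refit; it
        keeps the symmetry warm starts admissible over the whole tau1
        range (the scale factor can drop to ~1/7.65 of the estimate).
        Applied only when the likelihood is verified unchanged.
        """
        PW = self.single_pw
        r_l, r_u = admissible_scale_range(self.theta_hat, PW, self.space)
        trio = np.array(
            [self.theta_hat.alpha1, self.theta_hat.alphaL, self.theta_hat.sigmaL]
        )
        lo = np.array([self.space.lower[0], self.space.lower[3], self.space.lower[4]])
        hi = np.array([self.space.upper[0], self.space.upper[3], self.space.upper[4]])
        headroom = 1.0 / r_l  # lowest scale the tau1 sweep will request
        r_min = max(np.max(headroom * lo / trio), r_l * 1.001)
        r_max = min(np.min(hi / trio), r_u * 0.999)
        if not r_min < r_max:
            return
        r0 = math.sqrt(r_min * r_max)
        if abs(math.log(r0)) < 1e-3:
            return
        try:
            candidate = symmetry_transform(self.theta_hat, r0, PW, self.space)
        except ValueError:
            return
        arr = candidate.to_array()
        if np.any(arr < self.space.lower) or np.any(arr > self.space.upper):
            return
        nll = self.evaluator.nll(candidate)
        if abs(nll - self.nll_hat) <= 1e-6 * max(self.nll_hat, 1.0):
            self.theta_hat = candidate
            self.nll_hat = min(nll, self.nll_hat)

    # -- symmetry-informed warm start ---------------------------------------

    def _symmetry_start(self, i: int, value: float) -> np.ndarray | None:
        """Warm start on (or nearest to) the symmetry manifold.

        The requested scale factor is clamped into the admissible window
        and the resulting vector clipped into the feasible space: when the
        manifold itself leaves the space (e.g. the scaled slope parameter
        would drop below its bound) this still lands the optimiser next
        to the constrained optimum instead of abandoning the start.  The
        profiled coordinate is overwritten with the grid value afterwards.
        """
        if self.single_pw is None or i in (2, 5):
            return None
        theta = self.theta_hat
        PW = self.single_pw
        if i == 1:  # profiled parameter is tau1 itself
            r = -math.expm1(-PW / value) / -math.expm1(-PW / theta.tau1)
        else:
            r = value / getattr(theta, PARAM_NAMES[i])
        r_l, r_u = admissible_scale_range(theta, PW, self.space)
        r = min(max(r, r_l), r_u)
        try:
            candidate = symmetry_transform(theta, r, PW, self.space)
        except ValueError:
            return None
        return np.log10(self.space.clip(candidate.to_array()))

    # -- single profile point ------------------------------------------------

    def lpl_point(
        self, i: int, value: float, warm: list[np.ndarray] | None = None
    ) -> tuple[float, np.ndarray]:
        """Profile ``-2 log PL`` at ``theta_i = value``.

        Returns ``(lpl, solution)`` with the solution as a full linear
        6-vector (coordinate ``i`` equal to ``value``).
        """
        log_value = math.log10(value)
        free = np.ones(6, dtype=bool)
        free[i] = False
        starts = [np.log10(self.theta_hat.to_array())]
        if warm:
            starts = [np.asarray(w, dtype=float) for w in warm] + starts
        sym = self._symmetry_start(i, value)
        if sym is not None:
            starts.insert(0, sym)

        best_nll = np.inf
        best_log = None
        seen = set()
        for start_log in starts:
            key = tuple(np.round(start_log, 9))
            if key in seen:
                continue
            seen.add(key)
            start_log = start_log.copy()
            start_log[i] = log_value
            fixed = start_log.copy()
            local = _minimize_from(
                self.evaluator, start_log, self.space.log_lower,
                self.space.log_upper, free, fixed,
                tol=self.tol, max_nfev=self.max_nfev,
            )
            if local.nll < best_nll:
                best_nll = local.nll
                best_log = np.log10(local.params.to_array())
            if best_nll <= self.nll_hat + 1e-6:
                # profile dominance: no start can do better than the
                # global optimum, so stop once it is attained
                break
        return 2.0 * best_nll, 10.0**best_log

    # -- full curve ----------------------------------------------------------

    def curve(
        self, i: int, n_grid: int = 41, span: tuple[float, float] | None = None
    ) -> ProfileCurve:
        """Profile curve on a log-spaced grid including the estimate.

        If a sweep finds a better optimum than the fit being profiled,
        the fit is re-opened: the profiler adopts the improved estimate
        and the curve is recomputed around it (so warm and symmetry
        starts stay consistent with the new reference).
        """
        if n_grid < 11:
            raise ValueError("n_grid must be >= 11")
        if self.single_pw is not None:
            # start every sweep from an admissible manifold representative
            # (the working estimate may have drifted during earlier curves)
            self._canonicalise_on_manifold()
        improved = False
        for attempt in range(3):
            grid, lpl, solutions, failed, idx_hat, hat = self._sweep(i, n_grid, span)
            best = np.nanmin(lpl) / 2.0
            if best < self.nll_hat - 1e-9:
                improved = True
                j = int(np.nanargmin(lpl))
                material = self.nll_hat - best > 2.5e-3  # ~ flat_tol / 4 in LPL
                self.nll_hat = best
                self.theta_hat = HazardParams.from_array(solutions[j])
                # re-sweep only for a material improvement (keeps warm and
                # symmetry starts consistent); plain optimiser jitter just
                # updates the reference optimum
                if material and attempt < 2:
                    if self.single_pw is not None:
                        # keep symmetry starts admissible around the new
                        # estimate before recomputing the curve
                        self._canonicalise_on_manifold()
                    continue
            break
        return ProfileCurve(
            param_index=i,
            param_name=PARAM_NAMES[i],
            grid=grid,
            lpl=lpl,
            nll_hat=self.nll_hat,
            theta_hat_value=hat,
            idx_hat=idx_hat,
            solutions=tuple(solutions),
            failed=tuple(failed),
            improved=improved,
        )

    def _sweep(self, i: int, n_grid: int, span):
        lo, hi = (self.space.lower[i], self.space.upper[i]) if span is None else span
        grid = np.geomspace(lo, hi, n_grid)
        hat = getattr(self.theta_hat, PARAM_NAMES[i])
        if not np.any(np.isclose(grid, hat, rtol=1e-12)):
            grid = np.sort(np.append(grid, hat))
        idx_hat = int(np.argmin(np.abs(np.log(grid) - math.log(hat))))

        lpl = np.full(grid.size, np.nan)
        solutions: list[np.ndarray | None] = [None] * grid.size
        failed = []
        for direction in (1, -1):
            prev = np.log10(self.theta_hat.to_array())
            rng = (
                range(idx_hat, grid.size) if direction == 1 else range(idx_hat - 1, -1, -1)
            )
            for j in rng:
                if solutions[j] is not None:
                    prev = np.log10(solutions[j])
                    continue
                warm = [prev]
                carried = self._continuation_start(i, 10.0**prev, float(grid[j]))
                if carried is not None:
                    warm.insert(0, carried)
                try:
                    val, sol = self.lpl_point(i, float(grid[j]), warm=warm)
                except Exception:
                    failed.append(j)
                    continue
                lpl[j] = val
                solutions[j] = sol
                prev = np.log10(sol)
        return grid, lpl, solutions, failed, idx_hat, hat

    def _continuation_start(
        self, i: int, prev_sol: np.ndarray, value: float
    ) -> np.ndarray | None:
        """Carry the neighbouring solution along the parameter-scaling
        symmetry (exact at a single pulse width, a good approximation
        otherwise) to the next grid value.

        The coupled trio (alpha1, alphaL, sigmaL) moves together along a
        sloppy likelihood valley; rescaling the previous solution instead
        of reusing it verbatim keeps the warm start inside the valley.
        """
        if i in (2, 5):
            return None
        PW = self.modal_pw
        theta_prev = HazardParams.from_array(prev_sol)
        if i == 1:
            r = -math.expm1(-PW / value) / -math.expm1(-PW / theta_prev.tau1)
        else:
            r = value / prev_sol[i]
        try:
            candidate = symmetry_transform(theta_prev, r, PW, self.space)
        except ValueError:
            return None
        arr = candidate.to_array()
        if np.any(arr < self.space.lower * (1 - 1e-9)) or np.any(
            arr > self.space.upper * (1 + 1e-9)
        ):
            return None
        return np.log10(self.space.clip(arr))

    def confidence_interval(
        self, curve: ProfileCurve, level: float = 0.95, log_xtol: float = 5e-3
    ) -> ProfileCI:
        """Confidence interval with bisection-refined endpoints.

        Starts from the grid interval of :func:`profile_confidence_interval`
        and relocates each closed endpoint by Brent's method on the
        profile objective itself (warm-started from the stored grid
        solutions), removing the coarse-grid interpolation error.
        """
        ci = profile_confidence_interval(curve, level)
        threshold = 2.0 * curve.nll_hat + float(stats.chi2.ppf(level, 1))
        i = curve.param_index
        logg = np.log10(curve.grid)

        def refine(endpoint: float, side: int) -> float:
            j_in = int(np.argmin(np.abs(logg - math.log10(endpoint))))
            while curve.lpl[j_in] > threshold and 0 < j_in < curve.grid.size - 1:
                j_in -= side
            j_out = j_in + side
            if not 0 <= j_out < curve.grid.size:
                return endpoint
            if not (np.isfinite(curve.lpl[j_in]) and np.isfinite(curve.lpl[j_out])):
                return endpoint
            sol = curve.solutions[j_in]
            if sol is None:
                return endpoint
            warm = [np.log10(sol)]

            def f(logv: float) -> float:
                val, s = self.lpl_point(i, 10.0**logv, warm=warm)
                warm[0] = np.log10(s)
                return val - threshold

            a, b = logg[j_in], logg[j_out]
            fa, fb = curve.lpl[j_in] - threshold, curve.lpl[j_out] - threshold
            if fa * fb > 0:
                return endpoint
            try:
                return 10.0 ** brentq(f, a, b, xtol=log_xtol)
            except ValueError:
                return endpoint

        lower = ci.lower if ci.open_low else refine(ci.lower, -1)
        upper = ci.upper if ci.open_high else refine(ci.upper, +1)
        return ProfileCI(lower, upper, ci.open_low, ci.open_high, level, ci.multimodal)

    # -- refined flat-interval measurement ------------------------------------

    def flat_interval(
        self, curve: ProfileCurve, flat_tol: float = 0.01, log_xtol: float = 5e-3
    ) -> tuple[float, float]:
        """Locate the flat interval's endpoints by bisection on the profile.

        The edges are the crossings of ``lpl = 2 * nll_hat + flat_tol``
        nearest to the estimate, refined with Brent's method in log10 of
        the parameter; warm starts come from the stored grid solutions.
        """
        i = curve.param_index
        base = 2.0 * self.nll_hat
        excess = curve.lpl - base
        flat = excess < flat_tol
        if not flat[curve.idx_hat]:
            raise ValueError("profile is not flat at the estimate")

        def refine(j_in: int, j_out: int) -> float:
            warm = [np.log10(curve.solutions[j_in])]

            def f(logv: float) -> float:
                val, sol = self.lpl_point(i, 10.0**logv, warm=warm)
                warm[0] = np.log10(sol)
                return val - base - flat_tol

            a, b = math.log10(curve.grid[j_in]), math.log10(curve.grid[j_out])
            return 10.0 ** brentq(f, a, b, xtol=log_xtol)

        j = curve.idx_hat
        while j + 1 < curve.grid.size and flat[j + 1]:
            j += 1
        hi = curve.grid[-1] if j == curve.grid.size - 1 else refine(j, j + 1)
        j = curve.idx_hat
        while j - 1 >= 0 and flat[j - 1]:
            j -= 1
        lo = curve.grid[0] if j == 0 else refine(j, j - 1)
        return float(lo), float(hi)


def profile_likelihood(
    dataset: Dataset,
    fit: FitResult,
    param_index: int,
    space: ParameterSpace | None = None,
    constants: ModelConstants | None = None,
    n_grid: int = 41,
    span: tuple[float, float] | None = None,
) -> ProfileCurve:
    """Profile ``-2 log PL`` of one parameter over its feasible range."""
    profiler = Profiler(dataset, fit, space=space, constants=constants)
    return profiler.curve(param_index, n_grid=n_grid, span=span)


def profile_confidence_interval(curve: ProfileCurve, level: float = 0.95) -> ProfileCI:
    """Likelihood-based confidence interval from a profile curve.

    Grid points with ``lpl <= 2 nll_hat + chi2_ppf(level, 1)`` are inside;
    endpoints are located by linear interpolation of ``lpl`` against
    log10 of the parameter.  If the sub-threshold region is disconnected,
    the component containing the estimate defines the interval and the
    result is flagged multimodal.  An endpoint is open when the curve
    never rises through the threshold before the feasible-space bound.
    """
    threshold = 2.0 * curve.nll_hat + float(stats.chi2.ppf(level, 1))
    ok = np.isfinite(curve.lpl)
    below = (curve.lpl <= threshold) & ok
    if not below[curve.idx_hat]:
        # the nearest valid grid point to the estimate
        candidates = np.where(below)[0]
        if candidates.size == 0:
            hat = curve.theta_hat_value
            return ProfileCI(hat, hat, False, False, level)
        idx = int(candidates[np.argmin(np.abs(candidates - curve.idx_hat))])
    else:
        idx = curve.idx_hat

    logg = np.log10(curve.grid)
    j_hi = idx
    while j_hi + 1 < curve.grid.size and below[j_hi + 1]:
        j_hi += 1
    j_lo = idx
    while j_lo - 1 >= 0 and below[j_lo - 1]:
        j_lo -= 1

    open_high = j_hi == curve.grid.size - 1
    open_low = j_lo == 0
    if open_high:
        upper = float(curve.grid[-1])
    else:
        frac = (threshold - curve.lpl[j_hi]) / (curve.lpl[j_hi + 1] - curve.lpl[j_hi])
        upper = float(10.0 ** (logg[j_hi] + frac * (logg[j_hi + 1] - logg[j_hi])))
    if open_low:
        lower = float(curve.grid[0])
    else:
        frac = (threshold - curve.lpl[j_lo]) / (curve.lpl[j_lo - 1] - curve.lpl[j_lo])
        lower = float(10.0 ** (logg[j_lo] + frac * (logg[j_lo - 1] - logg[j_lo])))

    # disconnected sub-threshold regions signal multiple local minima
    runs = np.flatnonzero(np.diff(below.astype(int)) != 0).size
    multimodal = below.sum() > (j_hi - j_lo + 1)
    del runs
    return ProfileCI(lower, upper, open_low, open_high, level, multimodal)


def classify_identifiability(
    curve: ProfileCurve,
    flat_tol: float = 0.01,
    level: float = 0.95,
    flat_span_min: float = 0.10,
) -> Classification:
    """Label a profile curve by the identifiability taxonomy.

    Structural non-identifiability: a contiguous flat run (``lpl`` within
    ``flat_tol`` of its minimum) around the estimate spanning at least
    ``flat_span_min`` of the log10-range; the flat interval's endpoint
    ratio is reported.  Practical non-identifiability: a confidence
    interval open at either feasible-space bound without such flatness.
    Otherwise the parameter is identifiable.
    """
    ci = curve.ci if curve.ci is not None else profile_confidence_interval(curve, level)
    ok = np.isfinite(curve.lpl)
    lpl_min = np.nanmin(curve.lpl)
    flat = (curve.lpl - lpl_min < flat_tol) & ok
    logg = np.log10(curve.grid)
    log_range = logg[-1] - logg[0]

    j_hi = curve.idx_hat
    while j_hi + 1 < curve.grid.size and flat[j_hi + 1]:
        j_hi += 1
    j_lo = curve.idx_hat
    while j_lo - 1 >= 0 and flat[j_lo - 1]:
        j_lo -= 1
    flat_span = logg[j_hi] - logg[j_lo]

    if flat[curve.idx_hat] and flat_span >= flat_span_min * log_range:
        # interpolate the flat edges at lpl = min + flat_tol
        target = lpl_min + flat_tol
        if j_hi == curve.grid.size - 1:
            hi = float(curve.grid[-1])
        else:
            frac = (target - curve.lpl[j_hi]) / (curve.lpl[j_hi + 1] - curve.lpl[j_hi])
            hi = float(10.0 ** (logg[j_hi] + frac * (logg[j_hi + 1] - logg[j_hi])))
        if j_lo == 0:
            lo = float(curve.grid[0])
        else:
            frac = (target - curve.lpl[j_lo]) / (curve.lpl[j_lo - 1] - curve.lpl[j_lo])
            lo = float(10.0 ** (logg[j_lo] + frac * (logg[j_lo - 1] - logg[j_lo])))
        return Classification(LABEL_STRUCTURAL, flat_interval=(lo, hi))
    if ci.open_low or ci.open_high:
        return Classification(LABEL_PRACTICAL)
    return Classification(LABEL_IDENTIFIABLE)


# ---------------------------------------------------------------------------
# Design checks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignReport:
    """Outcome of the a-priori structural-identifiability design screen."""

    structural_warning: bool
    subthreshold_warning: bool
    pulse_widths: tuple[float, ...]
    affected: tuple[str, ...] = ()
    set_ratio: float | None = None
    messages: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not (self.structural_warning or self.subthreshold_warning)


def check_design_pw_variation(
    design_or_dataset,
    space: ParameterSpace | None = None,
    theta: HazardParams | None = None,
) -> DesignReport:
    """Screen a stimulus design for structural-identifiability hazards.

    Warns STRUCTURAL when all stimuli share a single pulse width: the
    peripheral threshold, peripheral time constant and the central
    threshold and slope (``alpha1``, ``tau1``, ``alphaL``, ``sigmaL``)
    then become structurally non-identifiable, with the finite
    set-identifiability ratio reported for the configured ``tau1``
    bounds.  If ``theta`` is supplied and the design carries amplitudes,
    additionally warns when every stimulus stays below the peripheral
    threshold (no effective activation at all).
    """
    if space is None:
        space = default_parameter_space()

    if hasattr(design_or_dataset, "trials"):
        dataset: Dataset = design_or_dataset
        pws = tuple(float(p) for p in dataset.pulse_widths())
        stimuli = [t.stimulus for t in dataset]
    else:
        design = design_or_dataset
        pws = tuple(sorted({float(c[3]) for c in design.combinations}))
        stimuli = []

    messages = []
    structural = len(pws) == 1
    affected: tuple[str, ...] = ()
    ratio = None
    if structural:
        ratio = set_identifiability_ratio(pws[0], space.lower[1], space.upper[1])
        affected = ("alpha1", "tau1", "alphaL", "sigmaL")
        messages.append(
            "STRUCTURAL: all stimuli share PW = "
            f"{pws[0]} ms; alpha1, tau1, alphaL and sigmaL are structurally "
            f"non-identifiable (set-identifiability endpoint ratio "
            f"{ratio:.4f} for the configured tau1 bounds; tau1 flat over "
            "its entire range). Vary the pulse width across stimuli."
        )

    subthreshold = False
    if theta is not None and stimuli:
        drives = [
            peripheral_drive(s.A, s.PW, theta.tau1) for s in stimuli
        ]
        if all(d < theta.alpha1 for d in drives):
            subthreshold = True
            messages.append(
                "SUBTHRESHOLD: every stimulus has a peripheral drive below "
                f"alpha1 = {theta.alpha1}; no stimulus produces effective "
                "activation and alpha1 is trivially non-identifiable."
            )
    return DesignReport(
        structural_warning=structural,
        subthreshold_warning=subthreshold,
        pulse_widths=pws,
        affected=affected,
        set_ratio=ratio,
        messages=tuple(messages),
    )
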