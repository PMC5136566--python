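"""Forward hazard model of nociceptive detection.

The model maps an electrocutaneous pulse-train stimulus to a detection
probability through a cascade of mechanisms:

1. Peripheral activation of A-delta fibres.  A rectangular pulse of
   amplitude ``A`` (mA) and width ``PW`` (ms) charges the fibre membrane
   with time constant ``tau1``; the effective drive is
   ``fA = A * (1 - exp(-PW/tau1))``.  Activation above the peripheral
   threshold ``alpha1`` is passed on threshold-linearly,
   ``c = max(fA - alpha1, 0)``.
2. Synaptic transmission.  Each pulse in the train injects an excitatory
   post-synaptic current decaying with the synaptic time constant
   ``tau_s`` (fixed at 1.5 ms).
3. Central integration.  A secondary dorsal-horn neuron integrates the
   current as a leaky integrator with membrane time constant ``tau2``,
   giving the noise-free post-synaptic potential ``x(t)`` (A/s; the unit
   convention mA / ms == A/s keeps the cascade dimensionally closed).
4. Spike generation.  ``x(t)`` drives an inhomogeneous Poisson process
   with sigmoidal rate ``lambda(t) = lambdaL / (1 + exp((alphaL - x)/sigmaL))``
   (kHz).  The stimulus is detected if at least one spike occurs in the
   trial interval ``[0, T]``, so the psychometric function is
   ``Psi = 1 - exp(-integral_0^T lambda(t) dt)``.

Because the integrator is linear, ``x(t)`` has an exact closed form (a
sum of two exponentials per pulse); only the final rate integral needs
quadrature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import expit

__all__ = [
    "PARAM_NAMES",
    "Stimulus",
    "HazardParams",
    "ModelConstants",
    "ParameterSpace",
    "default_parameter_space",
    "QuadratureError",
    "peripheral_drive",
    "effective_activation",
    "pulse_onsets",
    "membrane_potential",
    "firing_rate",
    "expected_spike_count",
    "detection_probability",
]

#: Canonical ordering of the six lumped parameters.
PARAM_NAMES = ("alpha1", "tau1", "tau2", "alphaL", "sigmaL", "lambdaL")

# Relative |tau2 - tau_s| gap below which the removable singularity of the
# double-exponential kernel is replaced by its analytic limit.
_TAU_DEGENERACY_RTOL = 1e-6


@dataclass(frozen=True)
class Stimulus:
    """One pulse-train stimulus.

    Parameters
    ----------
    A : float
        Current amplitude in mA (>= 0).
    NoP : int
        Number of pulses (>= 1).
    IPI : float or None
        Inter-pulse interval in ms; must be ``None`` for single-pulse
        stimuli and positive otherwise.
    PW : float
        Pulse width in ms (> 0).
    combo_label : str
        Identifier of the temporal combination this stimulus belongs to
        (conventionally "A".."D").
    """

    A: float
    NoP: int = 1
    IPI: float | None = None
    PW: float = 0.42
    combo_label: str = "A"

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError(f"amplitude must be non-negative, got {self.A}")
        if int(self.NoP) != self.NoP or self.NoP < 1:
            raise ValueError(f"NoP must be a positive integer, got {self.NoP}")
        if self.PW <= 0:
            raise ValueError(f"pulse width must be positive, got {self.PW}")
        if self.NoP == 1:
            if self.IPI is not None:
                raise ValueError("IPI must be absent for a single-pulse stimulus")
        else:
            if self.IPI is None or self.IPI <= 0:
                raise ValueError(
                    f"NoP={self.NoP} requires a positive IPI, got {self.IPI}"
                )

    @property
    def span(self) -> float:
        """Temporal footprint of the train, ``(NoP - 1) * IPI + PW`` (ms)."""
        ipi = 0.0 if self.IPI is None else self.IPI
        return (self.NoP - 1) * ipi + self.PW

    def temporal_key(self) -> tuple:
        """Hashable key of the temporal properties (NoP, IPI, PW)."""
        return (self.NoP, self.IPI, self.PW)


@dataclass(frozen=True)
class HazardParams:
    """The six lumped parameters ``theta`` of the hazard model.

    alpha1 : peripheral activation threshold (mA)
    tau1   : peripheral (fibre) time constant (ms)
    tau2   : central membrane time constant (ms)
    alphaL : central firing threshold (A/s)
    sigmaL : slope of the rate sigmoid (A/s)
    lambdaL: maximal firing rate (kHz)
    """

    alpha1: float
    tau1: float
    tau2: float
    alphaL: float
    sigmaL: float
    lambdaL: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and positive, got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "HazardParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (6,):
            raise ValueError(f"expected a 6-vector, got shape {theta.shape}")
        return cls(*theta)

    def replace(self, **kwargs) -> "HazardParams":
        values = {n: getattr(self, n) for n in PARAM_NAMES}
        values.update(kwargs)
        return HazardParams(**values)


@dataclass(frozen=True)
class ModelConstants:
    """Fixed quantities of the forward model.

    tau_s : synaptic time constant, 1.5 ms.
    T     : trial-interval duration (ms).  The default of 1000 ms
            comfortably contains the response to any design stimulus;
            ``T`` also sets the spontaneous (A = 0) detection
            probability ``1 - exp(-T * lambdaL * expit(-alphaL/sigmaL))``.
    """

    tau_s: float = 1.5
    T: float = 1000.0

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.T <= 0:
            raise ValueError("T must be positive")

    def validate_for(self, stimulus: Stimulus, params: "HazardParams") -> None:
        """Warn when the trial window cuts off the central response."""
        if self.T < stimulus.span + 5.0 * params.tau2:
            warnings.warn(
                f"trial interval T={self.T} ms is shorter than the stimulus "
                f"span plus 5*tau2 ({stimulus.span + 5 * params.tau2:.1f} ms); "
                "the rate integral may be truncated",
                stacklevel=2,
            )


# Feasible parameter space: physiologically motivated bounds per parameter,
# in the canonical ordering (alpha1, tau1, tau2, alphaL, sigmaL, lambdaL).
_DEFAULT_LOWER = (1e-6, 1e-2, 2.0, 1e-5, 1e-8, 1e-3)
_DEFAULT_UPPER = (1.0, 3.0, 1e3, 1.0, 0.1, 1e2)


@dataclass(frozen=True)
class ParameterSpace:
    """Hypercubic feasible space for the six parameters."""

    lower: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_LOWER))
    upper: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_UPPER))

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != (6,) or upper.shape != (6,):
            raise ValueError("bounds must be 6-vectors")
        if not np.all((lower > 0) & (lower < upper)):
            raise ValueError("bounds must satisfy 0 < lower < upper elementwise")

    @property
    def log_lower(self) -> np.ndarray:
        return np.log10(self.lower)

    @property
    def log_upper(self) -> np.ndarray:
        return np.log10(self.upper)

    def contains(self, params: HazardParams, atol: float = 0.0) -> bool:
        theta = params.to_array()
        return bool(
            np.all(theta >= self.lower - atol) and np.all(theta <= self.upper + atol)
        )

    def clip(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(theta, dtype=float), self.lower, self.upper)


def default_parameter_space() -> ParameterSpace:
    """The default feasible space used throughout the package."""
    return ParameterSpace()


class QuadratureError(RuntimeError):
    """Raised when the rate integral fails to converge."""


# ---------------------------------------------------------------------------
# Cascade stages
# ---------------------------------------------------------------------------

def peripheral_drive(A: float, PW: float, tau1: float) -> float:
    """Effective peripheral drive ``fA = A * (1 - exp(-PW / tau1))`` (mA).

    The membrane of the afferent fibre charges exponentially during the
    pulse, so a finite pulse width delivers only a fraction of the
    amplitude; ``fA -> A`` as ``PW/tau1 -> inf``.
    """
    if PW <= 0:
        raise ValueError(f"pulse width must be positive, got {PW}")
    if tau1 <= 0:
        raise ValueError(f"tau1 must be positive, got {tau1}")
    if A < 0:
        raise ValueError(f"amplitude must be non-negative, got {A}")
    return A * -math.expm1(-PW / tau1)


def effective_activation(fA: float, alpha1: float) -> float:
    """Threshold-linear activation ``[fA - alpha1]_+`` (mA)."""
    if fA < 0:
        raise ValueError(f"peripheral drive must be non-negative, got {fA}")
    if alpha1 <= 0:
        raise ValueError(f"alpha1 must be positive, got {alpha1}")
    return max(fA - alpha1, 0.0)


def pulse_onsets(stimulus: Stimulus) -> np.ndarray:
    """Pulse onset times ``k * IPI`` for ``k = 0..NoP-1`` (ms)."""
    ipi = 0.0 if stimulus.IPI is None else stimulus.IPI
    return np.arange(stimulus.NoP, dtype=float) * ipi


def _impulse_response(s: np.ndarray, tau2: float, tau_s: float) -> np.ndarray:
    """Unit-activation membrane response at lags ``s`` (>= 0 assumed masked).

    Exact solution of ``tau2 * x' = -x + (1/tau_s) * exp(-s/tau_s)`` with
    x(0) = 0:

        g(s) = (exp(-s/tau2) - exp(-s/tau_s)) / (tau2 - tau_s)

    with the removable singularity at ``tau2 == tau_s`` replaced by the
    limit ``s * exp(-s/tau_s) / tau_s**2``.
    """
    s = np.asarray(s, dtype=float)
    if abs(tau2 - tau_s) < _TAU_DEGENERACY_RTOL * tau_s:
        return s * np.exp(-s / tau_s) / tau_s**2
    return (np.exp(-s / tau2) - np.exp(-s / tau_s)) / (tau2 - tau_s)


def membrane_response_kernel(
    t: np.ndarray, onsets: np.ndarray, tau2: float, tau_s: float
) -> np.ndarray:
    """Summed unit-activation response ``g(t) = sum_k g(t - t_k) H(t - t_k)``.

    The post-synaptic potential is ``x(t) = c * g(t)`` with ``c`` the
    effective activation; ``g`` carries all dependence on the temporal
    stimulus properties, ``tau2`` and ``tau_s``.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    s = t[..., None] - onsets  # (..., NoP) lags
    s_pos = np.where(s > 0, s, 0.0)
    g = _impulse_response(s_pos, tau2, tau_s)
    g = np.where(s > 0, g, 0.0)
    return g.sum(axis=-1)


def membrane_potential(
    t, stimulus: Stimulus, params: HazardParams, constants: ModelConstants
) -> np.ndarray | float:
    """Post-synaptic potential ``x(t)`` (A/s); exact, vectorised over ``t``.

    ``x(t) = 0`` for ``t <= 0`` (causality) and each pulse contributes
    only after its onset ``k * IPI``.
    """
    c = effective_activation(
        peripheral_drive(stimulus.A, stimulus.PW, params.tau1), params.alpha1
    )
    out = c * membrane_response_kernel(
        t, pulse_onsets(stimulus), params.tau2, constants.tau_s
    )
    if np.isscalar(t):
        return float(out[0])
    return out


def firing_rate(x, params: HazardParams) -> np.ndarray | float:
    """Instantaneous Poisson rate ``lambdaL * expit((x - alphaL)/sigmaL)`` (kHz).

    Uses the logistic sigmoid in its numerically safe form, saturating to
    0 or ``lambdaL`` without overflow.
    """
    if params.sigmaL <= 0 or params.lambdaL <= 0:
        raise ValueError("sigmaL and lambdaL must be positive")
    z = (np.asarray(x, dtype=float) - params.alphaL) / params.sigmaL
    out = params.lambdaL * expit(z)
    if np.isscalar(x):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Rate integral by adaptive composite Gauss-Legendre quadrature
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _gl_rule(order: int) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.legendre.leggauss(order)
    return nodes, weights


def _panel_nodes(a: float, b: float, order: int) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = _gl_rule(order)
    half = 0.5 * (b - a)
    return a + half * (nodes + 1.0), half * weights


def initial_panels(stimulus: Stimulus, constants: ModelConstants) -> list[tuple[float, float]]:
    """Quadrature panels: one per inter-pulse segment plus a graded tail.

    The integrand is smooth within each segment; the tail after the last
    pulse is split on a graded ladder so that both fast (tau_s) and slow
    (tau2 up to 1000 ms) decay, and any sharp sigmoid crossing, are
    resolved before adaptive refinement starts.
    """
    onsets = pulse_onsets(stimulus)
    T = constants.T
    edges = [t for t in onsets if t < T]
    t_last = edges[-1] if edges else 0.0
    ladder = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 400.0, 700.0)
    for step in ladder:
        t = t_last + step
        if t < T:
            edges.append(t)
    edges.append(T)
    edges = sorted(set(edges))
    return list(zip(edges[:-1], edges[1:]))


def _integrate_adaptive(
    rate_fn, panels: list[tuple[float, float]], rtol: float, order: int, max_depth: int
) -> float:
    """Adaptively bisect panels until coarse/fine Gauss-Legendre agree."""
    total = 0.0
    # first pass: coarse estimate for the relative-tolerance scale
    scale = 0.0
    for a, b in panels:
        t, w = _panel_nodes(a, b, order)
        scale += float(np.dot(w, rate_fn(t)))
    scale = max(abs(scale), 1e-300)

    stack = [(a, b, 0) for a, b in panels]
    while stack:
        a, b, depth = stack.pop()
        t, w = _panel_nodes(a, b, order)
        coarse = float(np.dot(w, rate_fn(t)))
        mid = 0.5 * (a + b)
        fine = 0.0
        for lo, hi in ((a, mid), (mid, b)):
            t, w = _panel_nodes(lo, hi, order)
            fine += float(np.dot(w, rate_fn(t)))
        if abs(fine - coarse) <= rtol * scale or (b - a) < 1e-12:
            total += fine
        elif depth >= max_depth:
            raise QuadratureError(
                f"rate integral did not converge on panel [{a:.6g}, {b:.6g}] "
                f"after {max_depth} bisections (|coarse-fine| = {abs(fine - coarse):.3g}, "
                f"tolerance = {rtol * scale:.3g})"
            )
        else:
            stack.append((a, mid, depth + 1))
            stack.append((mid, b, depth + 1))
    return total


def expected_spike_count(
    stimulus: Stimulus,
    params: HazardParams,
    constants: ModelConstants,
    rtol: float = 1e-8,
    order: int = 40,
    max_depth: int = 30,
) -> float:
    """Expected number of central spikes ``int_0^T lambda(t) dt``.

    Computed by adaptive composite Gauss-Legendre quadrature over one
    smooth panel per inter-pulse segment plus a graded tail, refined until
    the Richardson (coarse vs bisected) discrepancy falls below ``rtol``
    relative to the integral.
    """
    c = effective_activation(
        peripheral_drive(stimulus.A, stimulus.PW, params.tau1), params.alpha1
    )
    onsets = pulse_onsets(stimulus)

    def rate_fn(t: np.ndarray) -> np.ndarray:
        x = c * membrane_response_kernel(t, onsets, params.tau2, constants.tau_s)
        return firing_rate(x, params)

    panels = initial_panels(stimulus, constants)
    return _integrate_adaptive(rate_fn, panels, rtol, order, max_depth)


def detection_probability(
    stimulus: Stimulus,
    params: HazardParams,
    constants: ModelConstants | None = None,
    rtol: float = 1e-8,
) -> float:
    """Psychometric function ``Psi = 1 - exp(-lambda_T)`` in [0, 1).

    Non-decreasing in the amplitude and non-increasing in the thresholds
    ``alpha1`` and ``alphaL`` with everything else fixed.
    """
    if constants is None:
        constants = ModelConstants()
    lam_T = expected_spike_count(stimulus, params, constants, rtol=rtol)
    return float(-math.expm1(-lam_T))
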