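"""Synthetic yes-no detection sessions.

Emulates a ~10-minute electrocutaneous detection experiment: around 200
trials split equally over four temporal combinations of a pulse-train
design, amplitudes concentrated near the detection threshold by an
adaptive 1-up/1-down staircase, and responses drawn as Bernoulli variates
from the hazard-model psychometric function (``R = 1`` when a standard
uniform draw falls below ``Psi``).

Two preset designs are provided.  ``TS1`` varies all three temporal
properties including the pulse width; ``TS2`` keeps a single pulse width
(0.42 ms) across all four combinations and therefore carries the
structural non-identifiability signature analysed in
:mod:`nocifit.identifiability`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Dataset, Trial
from .model import (
    HazardParams,
    ModelConstants,
    Stimulus,
    default_parameter_space,
    detection_probability,
)

__all__ = [
    "Design",
    "design_ts1",
    "design_ts2",
    "SimulationConfig",
    "reference_parameters",
    "staircase_amplitudes",
    "simulate_dataset",
]


@dataclass(frozen=True)
class Design:
    """Stimulus design: temporal combinations ``(label, NoP, IPI, PW)``."""

    combinations: tuple[tuple[str, int, float | None, float], ...]
    name: str = "custom"

    def pulse_widths(self) -> tuple[float, ...]:
        return tuple(sorted({c[3] for c in self.combinations}))

    def stimulus(self, label: str, amplitude: float) -> Stimulus:
        for lab, nop, ipi, pw in self.combinations:
            if lab == label:
                return Stimulus(A=amplitude, NoP=nop, IPI=ipi, PW=pw, combo_label=lab)
        raise KeyError(f"no combination {label!r} in design {self.name}")


def design_ts1() -> Design:
    """Design with varied pulse width: two single-pulse widths plus two
    double-pulse trains (IPI 10 and 50 ms) at the short width."""
    return Design(
        combinations=(
            ("A", 1, None, 0.42),
            ("B", 1, None, 0.84),
            ("C", 2, 10.0, 0.42),
            ("D", 2, 50.0, 0.42),
        ),
        name="TS1",
    )


def design_ts2() -> Design:
    """Single-pulse-width design: one single pulse and three double-pulse
    trains (IPI 10, 50, 100 ms), all at 0.42 ms width."""
    return Design(
        combinations=(
            ("A", 1, None, 0.42),
            ("B", 2, 10.0, 0.42),
            ("C", 2, 50.0, 0.42),
            ("D", 2, 100.0, 0.42),
        ),
        name="TS2",
    )


def reference_parameters() -> HazardParams:
    """Reference parameter vector used for forward simulation.

    Strictly interior to the default feasible space.
    """
    return HazardParams(
        alpha1=0.1, tau1=0.1, tau2=50.0, alphaL=0.022, sigmaL=0.0021, lambdaL=0.4020
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of one synthetic session.

    Defaults emulate the experimental protocol: 200 trials split equally
    over the design's four combinations, a 1-up/1-down staircase with
    0.1 mA steps over 0-3 mA (the reference-parameter detection threshold
    lies inside this range for every preset combination).
    """

    theta_true: HazardParams = field(default_factory=reference_parameters)
    design: Design = field(default_factory=design_ts1)
    n_total: int = 200
    seed: int = 0
    amplitude_policy: str = "staircase"
    step: float = 0.1
    amp_bounds: tuple[float, float] = (0.0, 3.0)

    def __post_init__(self) -> None:
        k = len(self.design.combinations)
        if self.n_total % k != 0:
            raise ValueError(
                f"n_total={self.n_total} is not divisible by the "
                f"{k} combinations"
            )
        if self.amplitude_policy not in ("staircase", "uniform_grid"):
            raise ValueError(f"unknown amplitude policy {self.amplitude_policy!r}")
        if self.step <= 0:
            raise ValueError("staircase step must be positive")


def staircase_amplitudes(
    psi_fn,
    n_trials: int,
    step: float,
    bounds: tuple[float, float],
    rng: np.random.Generator,
    start: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive 1-up/1-down amplitude track for one combination.

    Starts at the midpoint of ``bounds``; after a detection the amplitude
    decreases by ``step``, after a miss it increases, clipped to
    ``bounds``.  The track equilibrates around the 50%-detection
    amplitude.  Returns ``(amplitudes, responses)`` — the responses drawn
    to drive the staircase are part of the simulated session.
    """
    lo, hi = bounds
    if step <= 0:
        raise ValueError("step must be positive")
    amp = 0.5 * (lo + hi) if start is None else start
    amps = np.empty(n_trials)
    resps = np.empty(n_trials, dtype=int)
    for i in range(n_trials):
        amps[i] = amp
        r = int(rng.uniform() < psi_fn(amp))
        resps[i] = r
        amp = amp - step if r else amp + step
        amp = min(max(amp, lo), hi)
    return amps, resps


def simulate_dataset(
    config: SimulationConfig, constants: ModelConstants | None = None
) -> Dataset:
    """Simulate one session from the hazard model.

    Trials are interleaved across combinations in round-robin order with
    equal counts per combination; each response is Bernoulli with success
    probability ``Psi(S; theta_true)``.  Bit-for-bit reproducible given
    the seed.
    """
    if constants is None:
        constants = ModelConstants()
    rng = np.random.default_rng(config.seed)
    design = config.design
    labels = [c[0] for c in design.combinations]
    n_per = config.n_total // len(labels)
    lo, hi = config.amp_bounds

    psi_cache: dict[tuple, float] = {}

    def psi(label: str, amplitude: float) -> float:
        key = (label, round(amplitude, 10))
        if key not in psi_cache:
            stim = design.stimulus(label, amplitude)
            psi_cache[key] = detection_probability(stim, config.theta_true, constants)
        return psi_cache[key]

    if config.amplitude_policy == "uniform_grid":
        per_combo_amps = {
            lab: rng.permutation(np.linspace(lo if lo > 0 else lo + config.step, hi, n_per))
            for lab in labels
        }
        state = {lab: 0 for lab in labels}
    else:
        per_combo_amps = None
        state = {lab: 0.5 * (lo + hi) for lab in labels}

    trials = []
    for t in range(config.n_total):
        lab = labels[t % len(labels)]
        if config.amplitude_policy == "uniform_grid":
            amp = float(per_combo_amps[lab][state[lab]])
            state[lab] += 1
            r = int(rng.uniform() < psi(lab, amp))
        else:
            amp = round(float(state[lab]), 10)
            r = int(rng.uniform() < psi(lab, amp))
            nxt = amp - config.step if r else amp + config.step
            state[lab] = min(max(nxt, lo), hi)
        trials.append(Trial(design.stimulus(lab, amp), r, index=t))
    return Dataset(
        tuple(trials),
        design_label=design.name,
        meta={"seed": config.seed, "policy": config.amplitude_policy},
    )
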