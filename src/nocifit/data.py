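"""Trial-level containers for yes-no detection data.

An *elementary dataset* is the ordered set of roughly 200 stimulus-response
pairs collected in one 10-minute detection session: per trial a pulse-train
stimulus (amplitude plus temporal properties) and a binary detected /
not-detected report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Stimulus

__all__ = ["Trial", "Dataset"]


@dataclass(frozen=True)
class Trial:
    """A single stimulus-response pair; ``response`` is 0 or 1."""

    stimulus: Stimulus
    response: int
    index: int = 0

    def __post_init__(self) -> None:
        if self.response not in (0, 1):
            raise ValueError(f"response must be 0 or 1, got {self.response}")


@dataclass(frozen=True)
class Dataset:
    """Ordered collection of trials with design metadata.

    Every ``combo_label`` must map to a single temporal combination
    (NoP, IPI, PW); the amplitude is the only within-combination variable.
    """

    trials: tuple[Trial, ...]
    design_label: str = "custom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        trials = tuple(self.trials)
        object.__setattr__(self, "trials", trials)
        if len(trials) == 0:
            raise ValueError("a dataset must contain at least one trial")
        combos: dict[str, tuple] = {}
        for trial in trials:
            label = trial.stimulus.combo_label
            key = trial.stimulus.temporal_key()
            if combos.setdefault(label, key) != key:
                raise ValueError(
                    f"combination {label!r} maps to multiple temporal "
                    f"property triples: {combos[label]} and {key}"
                )

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def n(self) -> int:
        return len(self.trials)

    @property
    def combos(self) -> dict[str, tuple]:
        """Mapping combo_label -> (NoP, IPI, PW), in first-seen order."""
        out: dict[str, tuple] = {}
        for trial in self.trials:
            out.setdefault(trial.stimulus.combo_label, trial.stimulus.temporal_key())
        return out

    @property
    def responses(self) -> np.ndarray:
        return np.array([t.response for t in self.trials], dtype=int)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([t.stimulus.A for t in self.trials], dtype=float)

    def pulse_widths(self) -> np.ndarray:
        """Distinct PW values in the design (sorted)."""
        return np.unique([t.stimulus.PW for t in self.trials])

    def subset(self, combo_label: str) -> "Dataset":
        trials = tuple(
            t for t in self.trials if t.stimulus.combo_label == combo_label
        )
        if not trials:
            raise KeyError(f"no trials with combination {combo_label!r}")
        return Dataset(trials, self.design_label, dict(self.meta))

    def concat(self, other: "Dataset") -> "Dataset":
        """Concatenate, reindexing the second dataset's trials."""
        offset = self.n
        merged = self.trials + tuple(
            Trial(t.stimulus, t.response, offset + i)
            for i, t in enumerate(other.trials)
        )
        meta = {**self.meta, "combined_with": other.meta or other.design_label}
        return Dataset(merged, self.design_label, meta)
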