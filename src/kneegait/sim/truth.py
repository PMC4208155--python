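"""Ground-truth containers emitted alongside simulated sessions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ActivityTruth:
    """True events and parameter values for one annotated activity."""

    label: str
    repetition: int = 1
    heel_strikes: np.ndarray | None = None   # ipsilateral, seconds
    toe_offs: np.ndarray | None = None
    contacts: np.ndarray | None = None       # stair contacts, both feet
    transitions: list[tuple[float, float]] = field(default_factory=list)
    params: dict = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover.

    ``orientations`` hold true *sensor* orientations (sensor -> world,
    scalar-last quaternions) on the session time base; ``knee_flexion`` is
    the true joint angle in degrees.
    """

    orientations: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    knee_flexion: tuple[np.ndarray, np.ndarray] | None = None
    activities: list[ActivityTruth] = field(default_factory=list)

    def activity(self, label: str, repetition: int = 1) -> ActivityTruth:
        for a in self.activities:
            if a.label == label and a.repetition == repetition:
                return a
        raise KeyError(f"no ground truth for {label} rep {repetition}")

    def all(self, label: str) -> list[ActivityTruth]:
        return [a for a in self.activities if a.label == label]
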