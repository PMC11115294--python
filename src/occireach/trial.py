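"""Core container for one motion-capture trial.

A trial is a dictionary of named 3-D marker trajectories sampled at a fixed
rate (100 Hz by default), in a lab frame with X anterior, Y left, Z up, in
millimetres, together with the side label (paralyzed / non-paralyzed limb),
the instrumented limb (R or L) and participant metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, MissingMarkerError

PARALYZED = "paralyzed"
NON_PARALYZED = "non_paralyzed"
SIDES = (PARALYZED, NON_PARALYZED)

#: markers every analysis-ready trial must carry, given the instrumented limb
def required_markers(limb: str) -> tuple[str, ...]:
    if limb not in ("R", "L"):
        raise InvalidArgumentError(f"limb must be 'R' or 'L', got {limb!r}")
    other = "L" if limb == "R" else "R"
    return (
        f"{limb}SHO",  # acromion of the moving arm
        f"{limb}ELB",  # lateral olecranon
        f"{limb}WRA",  # radial wrist eminence
        f"{limb}WRB",  # ulnar wrist eminence
        f"{limb}FIN",  # head of the second metacarpal (index marker)
        "CLAV",        # manubrium / upper sternal body
        "C7",          # seventh cervical vertebra
        f"{limb}BHD",  # posterior head, same side as the moving arm
        f"{other}SHO",  # contralateral acromion (trunk mediolateral axis)
    )


@dataclass
class TrialRecording:
    """One trial's marker trajectories plus labels and metadata.

    ``markers`` maps marker name to an (n_frames, 3) float array in mm.
    ``metadata`` carries participant covariates (sex, age, bmi,
    months_post_onset) and is passed through untouched.
    """

    participant_id: str
    side: str
    markers: dict[str, np.ndarray]
    sampling_rate: float = 100.0
    limb: str = "R"
    trial_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.side not in SIDES:
            raise InvalidArgumentError(
                f"side must be one of {SIDES}, got {self.side!r}")
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be positive")
        lengths = {name: np.asarray(xyz).shape for name, xyz in self.markers.items()}
        n = None
        for name, shape in lengths.items():
            if len(shape) != 2 or shape[1] != 3:
                raise InvalidArgumentError(
                    f"marker {name!r} must be an (n, 3) array, got shape {shape}")
            if n is None:
                n = shape[0]
            elif shape[0] != n:
                raise InvalidArgumentError(
                    f"marker {name!r} has {shape[0]} frames, expected {n}")
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) / self.sampling_rate

    def marker(self, name: str) -> np.ndarray:
        try:
            return self.markers[name]
        except KeyError:
            raise MissingMarkerError(name, self.trial_id or self.participant_id)

    def check_required_markers(self) -> None:
        for name in required_markers(self.limb):
            if name not in self.markers:
                raise MissingMarkerError(name, self.trial_id or self.participant_id)

    def map_markers(self, fn) -> "TrialRecording":
        """Return a copy with ``fn`` applied to every marker trajectory."""
        return TrialRecording(
            participant_id=self.participant_id,
            side=self.side,
            markers={k: fn(v) for k, v in self.markers.items()},
            sampling_rate=self.sampling_rate,
            limb=self.limb,
            trial_id=self.trial_id,
            metadata=dict(self.metadata),
        )
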