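"""Synthetic occiput-reaching trials.

Generates marker trajectories for a seated reach to the back of the head,
standing in for raw optical motion-capture data.  Each trial is a rest
period, an outward movement whose three joint angles (shoulder flexion,
shoulder abduction, elbow flexion) follow minimum-jerk profiles toward a
sampled end pose, a short hold at the occiput, a return movement back to the
hanging-arm start pose, and a final rest.  Trunk (CLAV) and head (BHD)
markers sway with a low-frequency sinusoid, and white noise of configurable
standard deviation is added to every marker.

Side-dependent defaults encode a mildly hemiplegic cohort: the paralyzed
limb moves slowly (outward motor time 2.3 +/- 0.7 s versus 1.3 +/- 0.3 s)
with a larger shoulder-flexion and smaller elbow-flexion end pose.  All
per-trial quantities are drawn from truncated normal distributions so that
anatomically bounded ranges are respected.

The end pose is realized purely in joint space (no hand-occiput contact
model): only joint-space features are analyzed downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as _sps

from .errors import InvalidArgumentError
from .kinematics import trunk_axes
from .trial import NON_PARALYZED, PARALYZED, TrialRecording

SWAY_FREQ_HZ = 0.3
WRIST_HALF_WIDTH_MM = 25.0


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruncNormal:
    """Normal distribution truncated to [lo, hi]; sd = 0 degenerates to mean."""

    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self):
        if self.sd < 0:
            raise InvalidArgumentError("sd must be non-negative")
        if not self.lo <= self.mean <= self.hi:
            raise InvalidArgumentError("mean must lie within [lo, hi]")

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return self.mean
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return float(_sps.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                        random_state=rng))


@dataclass
class ArmGeometry:
    """Body-segment dimensions (mm) carrying the upper-body marker subset.

    Defaults are scaled from a 169 cm participant (the cohort's median
    height) with conventional anthropometric segment ratios.
    """

    upper_arm_length: float = 314.0
    forearm_length: float = 247.0
    hand_length: float = 91.0
    shoulder_offset_from_c7: tuple[float, float, float] = (20.0, -175.0, -25.0)
    trunk_height: float = 450.0

    def __post_init__(self):
        for name in ("upper_arm_length", "forearm_length", "hand_length"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")

    @classmethod
    def from_height(cls, height_cm: float) -> "ArmGeometry":
        h = height_cm * 10.0  # mm
        return cls(upper_arm_length=0.186 * h,
                   forearm_length=0.146 * h,
                   hand_length=0.054 * h,
                   shoulder_offset_from_c7=(20.0, -0.104 * h, -25.0),
                   trunk_height=0.266 * h)


@dataclass
class SidedMotionParams:
    """Per-side kinematic distributions (times in s, angles deg, sway mm)."""

    motor_time: TruncNormal
    return_motor_time: TruncNormal
    peak_shoulder_flex: TruncNormal
    peak_shoulder_abd: TruncNormal
    peak_elbow_flex: TruncNormal
    trunk_sway_amp: float = 2.0
    head_sway_amp: float = 5.0
    marker_noise_sd: float = 0.2
    rest_pre_s: float = 1.0
    rest_post_s: float = 1.0
    hold_s: float = 0.5

    def __post_init__(self):
        if self.motor_time.mean <= 0 or self.return_motor_time.mean <= 0:
            raise InvalidArgumentError("motor time means must be positive")
        if self.peak_elbow_flex.hi >= 150.0:
            raise InvalidArgumentError(
                "peak elbow flexion must stay below the 150 deg anatomical bound")
        for name in ("trunk_sway_amp", "head_sway_amp", "marker_noise_sd",
                     "rest_pre_s", "rest_post_s", "hold_s"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be non-negative")


def paralyzed_defaults() -> SidedMotionParams:
    """Paralyzed-side distributions: slow, flexed-shoulder, reduced elbow."""
    return SidedMotionParams(
        motor_time=TruncNormal(2.3, 0.7, 1.5, 4.4),
        return_motor_time=TruncNormal(2.3, 0.7, 1.5, 4.2),
        peak_shoulder_flex=TruncNormal(48.9, 15.4, 24.4, 75.1),
        peak_shoulder_abd=TruncNormal(117.5, 16.7, 88.8, 156.8),
        peak_elbow_flex=TruncNormal(134.2, 8.0, 113.0, 145.0),
        trunk_sway_amp=3.5,
        head_sway_amp=6.0,
    )


def nonparalyzed_defaults() -> SidedMotionParams:
    """Non-paralyzed-side distributions: fast, consistent, full elbow flexion."""
    return SidedMotionParams(
        motor_time=TruncNormal(1.3, 0.3, 0.9, 1.9),
        return_motor_time=TruncNormal(1.5, 0.3, 1.0, 2.2),
        peak_shoulder_flex=TruncNormal(42.3, 11.2, 23.2, 59.5),
        peak_shoulder_abd=TruncNormal(118.9, 6.2, 102.7, 129.2),
        peak_elbow_flex=TruncNormal(140.0, 6.1, 120.6, 145.6),
        trunk_sway_amp=2.0,
        head_sway_amp=5.0,
    )


@dataclass(frozen=True)
class PhaseTargets:
    """Explicit per-trial values overriding the sampled distributions."""

    outward_duration_s: float
    return_duration_s: float
    peak_shoulder_flex: float
    peak_shoulder_abd: float
    peak_elbow_flex: float


# ---------------------------------------------------------------------------
# minimum-jerk profile
# ---------------------------------------------------------------------------

def minimum_jerk_profile(theta_start: float, theta_end: float,
                         duration: float, fs: float) -> np.ndarray:
    """Point-to-point minimum-jerk angle profile (deg).

    The classic quintic 10 tau^3 - 15 tau^4 + 6 tau^5 blend: boundary values
    are exact and the first and second derivatives vanish at both ends; the
    peak velocity is 1.875 * amplitude / duration at the midpoint.
    """
    if duration <= 0 or fs <= 0:
        raise InvalidArgumentError("duration and fs must be positive")
    n = int(round(duration * fs)) + 1
    tau = np.linspace(0.0, 1.0, n)
    blend = tau ** 3 * (10.0 - 15.0 * tau + 6.0 * tau ** 2)
    return theta_start + (theta_end - theta_start) * blend


def _mj_unit(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return tau ** 3 * (10.0 - 15.0 * tau + 6.0 * tau ** 2)


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

def _base_markers(geometry: ArmGeometry) -> dict[str, np.ndarray]:
    """Static trunk/head marker layout in the lab frame (upright sitting)."""
    z = geometry.trunk_height
    dx, dy, dz = geometry.shoulder_offset_from_c7
    c7 = np.array([-55.0, 0.0, z])
    return {
        "C7": c7,
        "CLAV": np.array([85.0, 0.0, z]),
        "RSHO": c7 + np.array([dx, -abs(dy), dz]),
        "LSHO": c7 + np.array([dx, abs(dy), dz]),
        "RBHD": np.array([-135.0, -35.0, z + 240.0]),
        "LBHD": np.array([-135.0, 35.0, z + 240.0]),
    }


def _arm_rotations(flex_deg: np.ndarray, abd_deg: np.ndarray,
                   limb: str) -> np.ndarray:
    """Per-frame rotation of the upper-arm frame relative to the trunk.

    Composition R = Rx(-s*abd) @ Ry(-flex) with s = +1 for the right limb:
    the zero pose (arm hanging, body z up) maps to flexion rotating the arm
    anteriorly about the trunk mediolateral axis and abduction carrying it
    away from the trunk, which for the right arm is the -Y (rightward)
    direction.  This is the exact inverse of the decomposition used by
    :func:`occireach.kinematics.shoulder_angles`.
    """
    phi = np.radians(np.asarray(flex_deg, dtype=float))
    alpha = np.radians(np.asarray(abd_deg, dtype=float))
    if limb == "L":
        alpha = -alpha
    cf, sf = np.cos(phi), np.sin(phi)
    ca, sa = np.cos(alpha), np.sin(alpha)
    n = phi.shape[0]
    R = np.empty((n, 3, 3))
    # columns are the arm body axes expressed in trunk coordinates
    R[:, 0, 0], R[:, 1, 0], R[:, 2, 0] = cf, sa * sf, ca * sf
    R[:, 0, 1], R[:, 1, 1], R[:, 2, 1] = 0.0, ca, -sa
    R[:, 0, 2], R[:, 1, 2], R[:, 2, 2] = -sf, sa * cf, ca * cf
    return R


def _arm_markers(geometry: ArmGeometry, flex, abd, elbow, limb: str,
                 trunk_basis: np.ndarray, shoulder_center: np.ndarray,
                 ) -> dict[str, np.ndarray]:
    """Arm marker trajectories for angle series; shapes (n, 3)."""
    beta = np.radians(np.asarray(elbow, dtype=float))
    R = _arm_rotations(flex, abd, limb)
    # trunk coords -> lab coords
    R_lab = np.einsum("ij,njk->nik", trunk_basis, R)
    u = -R_lab[:, :, 2]                                # upper-arm distal dir
    f = (np.sin(beta)[:, None] * R_lab[:, :, 0]
         - np.cos(beta)[:, None] * R_lab[:, :, 2])     # forearm distal dir
    w = R_lab[:, :, 1]                                 # wrist-pair axis

    elb = shoulder_center + geometry.upper_arm_length * u
    wrist = elb + geometry.forearm_length * f
    return {
        f"{limb}SHO": np.broadcast_to(shoulder_center, u.shape).copy(),
        f"{limb}ELB": elb,
        f"{limb}WRA": wrist + WRIST_HALF_WIDTH_MM * w,
        f"{limb}WRB": wrist - WRIST_HALF_WIDTH_MM * w,
        f"{limb}FIN": wrist + geometry.hand_length * f,
    }


def forward_kinematics(geometry: ArmGeometry, shoulder_flex: float,
                       shoulder_abd: float, elbow_flex: float,
                       limb: str = "R") -> dict[str, np.ndarray]:
    """Marker positions for a single posture (angles in deg).

    Returns the full upper-body marker dictionary (one (3,) vector each),
    consistent with the angle-extraction conventions: at the zero pose the
    arm hangs along the trunk with the elbow extended.
    """
    for name, val in (("shoulder_flex", shoulder_flex),
                      ("shoulder_abd", shoulder_abd),
                      ("elbow_flex", elbow_flex)):
        if not -180.0 < val < 180.0:
            raise InvalidArgumentError(f"{name} must lie in (-180, 180) deg")
    base = _base_markers(geometry)
    basis = trunk_axes(base["CLAV"][None], base["C7"][None],
                       base["LSHO"][None], base["RSHO"][None])[0]
    shoulder = base[f"{limb}SHO"]
    arm = _arm_markers(geometry,
                       np.array([shoulder_flex]), np.array([shoulder_abd]),
                       np.array([elbow_flex]), limb, basis, shoulder)
    out = {k: v.copy() for k, v in base.items()}
    out.update({k: v[0] for k, v in arm.items()})
    return out


# ---------------------------------------------------------------------------
# trial and cohort generation
# ---------------------------------------------------------------------------

def simulate_trial(geometry: ArmGeometry, params: SidedMotionParams,
                   phase_targets: PhaseTargets | None = None,
                   seed: int | np.random.SeedSequence = 0,
                   side: str = PARALYZED, limb: str = "R",
                   participant_id: str = "P01", trial_id: str = "",
                   fs: float = 100.0,
                   metadata: dict | None = None) -> TrialRecording:
    """Simulate one seated occiput reach; deterministic under ``seed``."""
    rng = np.random.default_rng(seed)

    if phase_targets is None:
        for _ in range(1000):
            t_out = params.motor_time.sample(rng)
            t_ret = params.return_motor_time.sample(rng)
            if t_out > 0 and t_ret > 0:
                break
        else:  # pragma: no cover - requires pathological parameters
            raise InvalidArgumentError("could not sample positive motor times")
        targets = PhaseTargets(
            outward_duration_s=t_out,
            return_duration_s=t_ret,
            peak_shoulder_flex=params.peak_shoulder_flex.sample(rng),
            peak_shoulder_abd=params.peak_shoulder_abd.sample(rng),
            peak_elbow_flex=params.peak_elbow_flex.sample(rng),
        )
    else:
        targets = phase_targets
        if targets.outward_duration_s <= 0 or targets.return_duration_s <= 0:
            raise InvalidArgumentError("phase durations must be positive")

    t0 = params.rest_pre_s
    t1 = t0 + targets.outward_duration_s
    t2 = t1 + params.hold_s
    t3 = t2 + targets.return_duration_s
    total = t3 + params.rest_post_s
    n = int(round(total * fs)) + 1
    t = np.arange(n) / fs

    out_tau = _mj_unit((t - t0) / targets.outward_duration_s)
    ret_tau = _mj_unit((t - t2) / targets.return_duration_s)
    blend = np.where(t < t1, out_tau, 1.0 - ret_tau)
    blend[t < t0] = 0.0
    blend[(t >= t1) & (t < t2)] = 1.0
    blend[t >= t3] = 0.0

    flex = targets.peak_shoulder_flex * blend
    abd = targets.peak_shoulder_abd * blend
    elbow = targets.peak_elbow_flex * blend

    base = _base_markers(geometry)
    basis = trunk_axes(base["CLAV"][None], base["C7"][None],
                       base["LSHO"][None], base["RSHO"][None])[0]
    markers = {k: np.tile(v, (n, 1)) for k, v in base.items()}
    markers.update(_arm_markers(geometry, flex, abd, elbow, limb, basis,
                                base[f"{limb}SHO"]))

    # low-frequency postural sway on the trunk and head markers; the
    # amplitude varies trial to trial (lognormal, ~50% CV) so the maximum
    # displacement reflects sway magnitude rather than phase duration
    for names, amp in ((("CLAV",), params.trunk_sway_amp),
                       (("RBHD", "LBHD"), params.head_sway_amp)):
        theta = rng.uniform(0, 2 * math.pi)       # horizontal direction
        phase0 = rng.uniform(0, 2 * math.pi)
        trial_amp = amp * rng.lognormal(mean=-0.125, sigma=0.5)
        direction = np.array([math.cos(theta), math.sin(theta), 0.0])
        wave = trial_amp * np.sin(2 * math.pi * SWAY_FREQ_HZ * t + phase0)
        for name in names:
            markers[name] = markers[name] + wave[:, None] * direction

    if params.marker_noise_sd > 0:
        for name in sorted(markers):
            markers[name] = markers[name] + rng.normal(
                0.0, params.marker_noise_sd, size=markers[name].shape)

    keep = [f"{limb}{m}" for m in ("SHO", "ELB", "WRA", "WRB", "FIN", "BHD")]
    other = "L" if limb == "R" else "R"
    keep += ["CLAV", "C7", f"{other}SHO", f"{other}BHD"]
    return TrialRecording(
        participant_id=participant_id,
        side=side,
        markers={k: markers[k] for k in keep},
        sampling_rate=fs,
        limb=limb,
        trial_id=trial_id or f"{participant_id}_{side}",
        metadata=metadata or {},
    )


@dataclass
class CohortSpec:
    """Study-design description: participants x sides x repeated trials."""

    n_participants: int = 10
    trials_per_side: int = 5
    paralyzed_params: SidedMotionParams = field(default_factory=paralyzed_defaults)
    nonparalyzed_params: SidedMotionParams = field(default_factory=nonparalyzed_defaults)
    geometry: ArmGeometry | None = None  # None: per-participant, height-scaled
    seed: int = 0
    fs: float = 100.0
    paralyzed_limb: str = "R"

    def __post_init__(self):
        if self.n_participants < 1 or self.trials_per_side < 1:
            raise InvalidArgumentError(
                "n_participants and trials_per_side must be at least 1")


def generate_cohort(spec: CohortSpec) -> list[TrialRecording]:
    """All trials of a cohort: participants x 2 sides x trials_per_side.

    Participant covariates (sex, age, BMI, months post onset, height) are
    sampled once per participant and shared across that participant's
    trials; arm geometry is scaled from the sampled height unless a fixed
    geometry is supplied.  Fully deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    other = "L" if spec.paralyzed_limb == "R" else "R"
    trials = []
    for i in range(spec.n_participants):
        pid = f"P{i + 1:02d}"
        meta = {
            "sex": "F" if rng.random() < 0.3 else "M",
            "age": float(np.round(TruncNormal(48, 8, 25, 80).sample(rng))),
            "bmi": float(np.round(TruncNormal(24, 3, 17, 35).sample(rng), 1)),
            "months_post_onset": float(np.round(
                rng.lognormal(mean=math.log(54.0), sigma=0.55))),
        }
        height = TruncNormal(169, 8, 150, 195).sample(rng)
        meta["height_cm"] = float(np.round(height, 1))
        geometry = spec.geometry or ArmGeometry.from_height(height)
        for side, limb, params in (
                (PARALYZED, spec.paralyzed_limb, spec.paralyzed_params),
                (NON_PARALYZED, other, spec.nonparalyzed_params)):
            for j in range(spec.trials_per_side):
                trial_seed = int(rng.integers(2 ** 31))
                trials.append(simulate_trial(
                    geometry, params, seed=trial_seed, side=side, limb=limb,
                    participant_id=pid,
                    trial_id=f"{pid}_{side}_{j + 1}",
                    fs=spec.fs, metadata=dict(meta)))
    return trials


def noiseless(params: SidedMotionParams) -> SidedMotionParams:
    """Copy of ``params`` with all stochastic components switched off."""
    def frozen(tn: TruncNormal) -> TruncNormal:
        return TruncNormal(tn.mean, 0.0, tn.mean, tn.mean)

    return replace(params,
                   motor_time=frozen(params.motor_time),
                   return_motor_time=frozen(params.return_motor_time),
                   peak_shoulder_flex=frozen(params.peak_shoulder_flex),
                   peak_shoulder_abd=frozen(params.peak_shoulder_abd),
                   peak_elbow_flex=frozen(params.peak_elbow_flex),
                   trunk_sway_amp=0.0, head_sway_amp=0.0,
                   marker_noise_sd=0.0)
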