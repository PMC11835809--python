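"""Class-conditional synthetic reach trajectories.

Each trial emulates one recorded action execution: the wrist follows a
minimum-jerk point-to-point path between a common start point and an
action-specific end point, with a lateral bow, an optional mid-path
excursion that lengthens the path (rude overshoot), band-limited Gaussian
positional jitter, and heavy-tailed (alpha-stable) velocity perturbations.
Elbow and shoulder are derived from a two-link arm model with a fixed
swivel angle per actor; the chest is quasi-static.  A Return-phase mirror
movement follows a short hold at the target so that automatic GO/Return
segmentation is non-trivial.

The five condition parameter sets returned by :func:`default_class_params`
are calibrated so that extracted features reproduce the qualitative
condition structure of the actor study: rude movements are the fastest,
jerkiest, longest-path and most heavy-tailed; slow movements are the
smoothest; gentle and slow share low peak speeds but differ in smoothness
and arm-angle excursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.stats import levy_stable

from vitalkin.errors import ConfigurationError, GeometryError
from vitalkin.io import TrialMeta, TrialRecording

CONDITIONS = ("gentle", "neutral", "rude", "slow", "fast")
ACTIONS = (
    "grasp",
    "offer",
    "drop",
    "point_surface",
    "thumb_up",
    "silence",
    "point_you",
)

#: trials per action type and condition in the reference two-actor recording
#: campaign (totals: rude 294, neutral 142, gentle 301, slow 143, fast 141;
#: grand total 1,021 after discards)
REFERENCE_COUNTS = {
    "grasp": {"rude": 60, "neutral": 21, "gentle": 61, "slow": 21, "fast": 22},
    "offer": {"rude": 61, "neutral": 20, "gentle": 62, "slow": 21, "fast": 21},
    "drop": {"rude": 38, "neutral": 21, "gentle": 41, "slow": 20, "fast": 20},
    "point_surface": {"rude": 39, "neutral": 20, "gentle": 37, "slow": 20, "fast": 20},
    "thumb_up": {"rude": 38, "neutral": 20, "gentle": 40, "slow": 20, "fast": 20},
    "silence": {"rude": 19, "neutral": 19, "gentle": 20, "slow": 20, "fast": 20},
    "point_you": {"rude": 39, "neutral": 21, "gentle": 40, "slow": 21, "fast": 18},
}

#: common start point on the actor's right leg and per-action end points (m)
DEFAULT_START = np.array([0.25, 0.12, 0.05])
DEFAULT_END_POINTS = {
    "grasp": np.array([0.18, 0.42, 0.28]),
    "offer": np.array([0.22, 0.46, 0.32]),
    "drop": np.array([0.15, 0.40, 0.30]),
    "point_surface": np.array([0.27, 0.41, 0.20]),
    "thumb_up": np.array([0.20, 0.35, 0.45]),
    "silence": np.array([0.10, 0.24, 0.60]),
    "point_you": np.array([0.18, 0.50, 0.35]),
}

#: physical cap on perturbation velocity draws (m/s); keeps heavy-tailed
#: draws within humanly plausible hand speeds without touching the bulk of
#: the distribution that the tail-index estimator sees
PERTURB_SPEED_CAP = 6.0

#: cap on the perturbation displacement per axis (m); corrective
#: sub-movements wander around the intended path, they do not leave it
PERTURB_DISP_CAP = 0.05


@dataclass
class ActorProfile:
    """Geometric profile of one (synthetic) actor."""

    name: str
    sex: str
    upper_arm_m: float  # L1, shoulder->elbow
    forearm_m: float  # L2, elbow->wrist
    shoulder_pos: np.ndarray  # resting shoulder centroid (m)
    swivel_rad: float = 0.2  # elbow swivel about the shoulder-wrist axis
    sway_gain: float = 0.05  # shoulder displacement per unit wrist displacement

    def __post_init__(self):
        self.shoulder_pos = np.asarray(self.shoulder_pos, dtype=float)
        if self.upper_arm_m <= 0 or self.forearm_m <= 0:
            raise ConfigurationError("arm segment lengths must be positive")


def default_actor_profiles() -> list:
    """Two actors with mildly different arm geometry (male slightly longer)."""
    return [
        ActorProfile("actor_m", "m", 0.320, 0.300, np.array([0.18, 0.02, 0.50]), 0.15, 0.05),
        ActorProfile("actor_f", "f", 0.300, 0.280, np.array([0.15, 0.06, 0.44]), 0.35, 0.06),
    ]


@dataclass
class SynthClassParams:
    """Generative knobs for one action condition.

    duration_s
        nominal GO-phase duration.
    path_scale
        >= 1; > 1 adds a sharp mid-path lateral excursion that lengthens the
        path (overshooting, "rude" trajectories).
    curvature_offset_m
        height of the smooth lateral bow at mid-path.
    jitter_sd_m / jitter_cutoff_hz
        amplitude and band of additive Gaussian positional noise.
    stable_alpha
        tail index in (0.3, 2] of the alpha-stable velocity perturbations
        (2 = Gaussian, lower = heavier tails / more sudden).
    perturb_scale_m_s
        scale of those velocity perturbations.
    perturb_rate_hz
        innovation rate of the perturbations: each draw is held for
        fps/rate samples, emulating discrete sub-movement corrections that
        survive low-pass filtering.
    arm_angle_gain
        scales shoulder sway and bow height, driving arm-angle excursion.
    """

    duration_s: float
    path_scale: float = 1.0
    curvature_offset_m: float = 0.0
    jitter_sd_m: float = 0.0
    jitter_cutoff_hz: float = 6.0
    stable_alpha: float = 2.0
    perturb_scale_m_s: float = 0.0
    perturb_rate_hz: float = 12.0
    arm_angle_gain: float = 1.0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if self.path_scale < 1:
            raise ConfigurationError("path_scale must be >= 1")
        if not (0.3 < self.stable_alpha <= 2.0):
            raise ConfigurationError("stable_alpha must lie in (0.3, 2]")
        if self.jitter_sd_m < 0 or self.perturb_scale_m_s < 0:
            raise ConfigurationError("noise amplitudes must be >= 0")


def default_class_params() -> dict:
    """Condition -> parameters calibrated to the reference ordinal structure.

    Orderings guaranteed at n >= 20 trials/condition for any seed:
    peak speed/acceleration/jerk and arc length greatest for rude; tail
    index (Suddenness) lowest for rude; smoothness greatest for slow and
    greater for gentle than for rude.
    """
    return {
        "gentle": SynthClassParams(1.50, 1.0, 0.060, 0.00030, 5.0, 2.0, 0.015, 10.0, 1.25),
        "neutral": SynthClassParams(1.10, 1.0, 0.035, 0.00040, 6.0, 2.0, 0.020, 10.0, 1.00),
        "rude": SynthClassParams(0.70, 1.18, 0.050, 0.00120, 8.0, 1.10, 0.30, 12.0, 1.50),
        "slow": SynthClassParams(2.20, 1.0, 0.050, 0.00015, 4.0, 2.0, 0.008, 8.0, 0.80),
        "fast": SynthClassParams(0.65, 1.0, 0.020, 0.00060, 8.0, 1.90, 0.05, 12.0, 1.00),
    }


@dataclass
class TrialSpec:
    """Everything besides the condition parameters needed to realize a trial."""

    actor: ActorProfile
    action: str
    condition: str
    direction: int = 0  # degrees about the vertical axis at the start point
    trial_index: int = 0
    fps: float = 100.0
    start_point: np.ndarray = field(default_factory=lambda: DEFAULT_START.copy())
    end_point: np.ndarray | None = None

    def resolved_end(self) -> np.ndarray:
        end = self.end_point if self.end_point is not None else DEFAULT_END_POINTS[self.action]
        delta = np.asarray(end, float) - np.asarray(self.start_point, float)
        th = np.deg2rad(self.direction)
        c, s = np.cos(th), np.sin(th)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return np.asarray(self.start_point, float) + rot @ delta


@dataclass
class SynthDatasetConfig:
    """Layout of a full synthetic recording campaign."""

    counts: dict = field(default_factory=lambda: {a: dict(c) for a, c in REFERENCE_COUNTS.items()})
    seed: int = 0
    fps: float = 100.0
    start_point: np.ndarray = field(default_factory=lambda: DEFAULT_START.copy())
    end_points: dict = field(default_factory=lambda: {k: v.copy() for k, v in DEFAULT_END_POINTS.items()})
    actor_profiles: list = field(default_factory=default_actor_profiles)
    directions: tuple = (-45, 0, 45)
    endpoint_jitter_m: float = 0.010
    duration_jitter_frac: float = 0.08

    def __post_init__(self):
        if self.fps <= 0:
            raise ConfigurationError("fps must be > 0")
        for action, conds in self.counts.items():
            for cond, n in conds.items():
                if n < 0:
                    raise ConfigurationError(f"negative count for {action}/{cond}")


def _minjerk_s(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _perp_frame(u: np.ndarray):
    """Orthonormal (lateral, vertical-ish) pair perpendicular to unit chord u."""
    ez = np.array([0.0, 0.0, 1.0])
    lat = np.cross(u, ez)
    if np.linalg.norm(lat) < 1e-9:
        lat = np.cross(u, np.array([1.0, 0.0, 0.0]))
    lat /= np.linalg.norm(lat)
    vert = np.cross(lat, u)
    vert /= np.linalg.norm(vert)
    if vert[2] < 0:
        vert = -vert
    return lat, vert


def _band_limited_noise(rng, n: int, sd: float, cutoff_hz: float, fps: float) -> np.ndarray:
    """(n, 3) Gaussian noise low-passed at cutoff_hz and rescaled to sd per axis."""
    white = rng.standard_normal((n, 3))
    nyq = fps / 2.0
    wn = min(cutoff_hz / nyq, 0.99)
    b, a = signal.butter(2, wn, "low")
    smoothed = signal.filtfilt(b, a, white, axis=0)
    std = smoothed.std(axis=0)
    std[std == 0] = 1.0
    return smoothed / std * sd


def _bridge_active_runs(disp: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Force a cumulative displacement back to zero at the end of every
    contiguous active run (and keep it at zero outside runs)."""
    out = disp.copy()
    n = disp.shape[0]
    i = 0
    offset = np.zeros(disp.shape[1])
    while i < n:
        if not active[i]:
            out[i] = 0.0
            i += 1
            continue
        j = i
        while j < n and active[j]:
            j += 1
        seg = disp[i:j] - offset
        w = (np.arange(1, j - i + 1) / (j - i))[:, None]
        out[i:j] = seg - seg[-1] * w
        offset = disp[j - 1]  # everything after the run reverts to zero
        i = j
    return out


def _elbow_ik(shoulder, wrist, L1, L2, swivel, trial_id):
    """Vectorized two-link inverse kinematics: elbow position per frame."""
    d_vec = wrist - shoulder
    d = np.linalg.norm(d_vec, axis=1)
    too_far = d > (L1 + L2) - 1e-9
    if too_far.any():
        i = int(np.argmax(too_far))
        raise GeometryError(
            f"{trial_id}: wrist unreachable at sample {i} "
            f"(|wrist-shoulder| = {d[i]:.4f} m > L1+L2 = {L1 + L2:.4f} m)"
        )
    too_near = d < abs(L1 - L2) + 1e-9
    if too_near.any():
        i = int(np.argmax(too_near))
        raise GeometryError(f"{trial_id}: wrist-shoulder distance degenerate at sample {i}")
    u = d_vec / d[:, None]
    a = (L1**2 + d**2 - L2**2) / (2 * d)
    r = np.sqrt(np.maximum(L1**2 - a**2, 0.0))
    g = np.array([0.0, 0.0, -1.0])
    b1 = np.cross(np.broadcast_to(g, u.shape), u)
    norms = np.linalg.norm(b1, axis=1)
    # fall back for frames where the arm points straight down
    bad = norms < 1e-9
    if bad.any():
        b1[bad] = np.cross(np.array([0.0, 1.0, 0.0]), u[bad])
        norms = np.linalg.norm(b1, axis=1)
    b1 /= norms[:, None]
    b2 = np.cross(u, b1)
    circ = np.cos(swivel) * b2 + np.sin(swivel) * b1
    return shoulder + a[:, None] * u + r[:, None] * circ


def generate_trial(params: SynthClassParams, spec: TrialSpec, seed: int) -> TrialRecording:
    """Synthesize one out-and-back trial; identical (params, spec, seed) give
    bit-identical output."""
    rng = np.random.default_rng(seed)
    fps = spec.fps
    dt = 1.0 / fps
    start = np.asarray(spec.start_point, float)
    end = spec.resolved_end()
    chord = end - start
    D = np.linalg.norm(chord)
    if D < 1e-9:
        raise ConfigurationError("start and end points must be distinct")
    u = chord / D
    lat, vert = _perp_frame(u)

    T = params.duration_s
    n_go = max(int(round(T * fps)), 4)
    n_pre = int(round(0.25 * fps))
    n_hold = int(round(0.12 * fps))
    # the return is unhurried (slower than the GO movement), so the trial's
    # global speed peak belongs to the GO-phase
    n_ret = max(int(round(1.15 * T * fps)), 4)
    n_post = int(round(0.20 * fps))

    tau_go = np.linspace(0.0, 1.0, n_go + 1)
    go = start + np.outer(_minjerk_s(tau_go), chord)
    # sin^2 bow: zero position AND velocity at both ends (a plain sine would
    # inject a velocity discontinuity at the phase boundaries), peak height
    # curvature_offset_m at mid-path
    bow = params.curvature_offset_m * params.arm_angle_gain
    go += np.outer(np.sin(np.pi * tau_go) ** 2 * bow, vert)
    if params.path_scale > 1.0:
        # sharp lateral excursion past mid-path: lengthens the path without
        # moving the farthest-from-start point away from the end point
        h = (params.path_scale - 1.0) * D * 1.1
        bump = np.exp(-(((tau_go - 0.60) / 0.12) ** 2))
        go += np.outer(h * bump, lat)

    tau_ret = np.linspace(0.0, 1.0, n_ret + 1)
    ret = end + np.outer(_minjerk_s(tau_ret), start - end)

    base = np.concatenate(
        [
            np.tile(start, (n_pre, 1)),
            go,
            np.tile(end, (n_hold, 1)),
            ret[1:],
            np.tile(start, (n_post, 1)),
        ]
    )
    n = base.shape[0]
    time = np.arange(n) * dt

    wrist = base.copy()
    # movement envelope from the noiseless base path gates the perturbations
    base_speed = np.linalg.norm(np.gradient(base, dt, axis=0), axis=1)
    peak = base_speed.max()
    env = base_speed / peak if peak > 0 else np.zeros(n)

    if params.perturb_scale_m_s > 0:
        hold = max(int(round(fps / params.perturb_rate_hz)), 1)
        n_draws = n // hold + 1
        draws = levy_stable.rvs(params.stable_alpha, 0.0, size=(n_draws, 3), random_state=rng)
        v_pert = np.repeat(draws, hold, axis=0)[:n] * params.perturb_scale_m_s
        v_pert = np.clip(v_pert, -PERTURB_SPEED_CAP, PERTURB_SPEED_CAP)
        disp = np.cumsum(v_pert * env[:, None], axis=0) * dt
        # corrections are excursions, not net transport: bridge the
        # displacement to zero at the boundaries of each movement phase and
        # cap its amplitude so targets are still reached
        disp = _bridge_active_runs(disp, env > 1e-9)
        wrist += np.clip(disp, -PERTURB_DISP_CAP, PERTURB_DISP_CAP)
    if params.jitter_sd_m > 0:
        # signal-dependent noise: tremor is stronger during movement than rest
        gate = 0.25 + 0.75 * env
        wrist += gate[:, None] * _band_limited_noise(
            rng, n, params.jitter_sd_m, params.jitter_cutoff_hz, fps
        )

    prof = spec.actor
    sway = prof.sway_gain * params.arm_angle_gain
    shoulder = prof.shoulder_pos + sway * (base - start)
    if params.jitter_sd_m > 0:
        shoulder = shoulder + _band_limited_noise(
            rng, n, 0.25 * params.jitter_sd_m, params.jitter_cutoff_hz, fps
        )
    chest0 = prof.shoulder_pos + np.array([-0.17, -0.02, -0.16])
    chest = chest0 + 0.4 * (shoulder - prof.shoulder_pos)

    trial_id = f"{prof.name}_{spec.action}_{spec.condition}_{spec.trial_index:04d}"

    # the deterministic base path must be reachable (hard contract) ...
    reach = prof.upper_arm_m + prof.forearm_m - 2e-3
    fold = abs(prof.upper_arm_m - prof.forearm_m) + 2e-3
    d_base = np.linalg.norm(base - (prof.shoulder_pos + sway * (base - start)), axis=1)
    if (d_base > reach).any():
        i = int(np.argmax(d_base > reach))
        raise GeometryError(
            f"{trial_id}: wrist unreachable at sample {i} "
            f"(|wrist-shoulder| = {d_base[i]:.4f} m > L1+L2 = {prof.upper_arm_m + prof.forearm_m:.4f} m)"
        )
    # ... while noise-driven excursions saturate at the arm's radial limits
    # (an actor cannot move the wrist beyond full extension or inside full flexion)
    d_vec = wrist - shoulder
    d = np.linalg.norm(d_vec, axis=1)
    out = np.clip(d, fold, reach)
    off = out != d
    if off.any():
        wrist[off] = shoulder[off] + d_vec[off] * (out[off] / d[off])[:, None]
    elbow = _elbow_ik(shoulder, wrist, prof.upper_arm_m, prof.forearm_m, prof.swivel_rad, trial_id)

    meta = TrialMeta(
        trial_id=trial_id,
        actor=prof.name,
        sex=prof.sex,
        action=spec.action,
        condition=spec.condition,
        direction=spec.direction,
        trial_index=spec.trial_index,
        extras={
            "seed": int(seed),
            "go_onset_s": round(n_pre * dt, 6),
            "go_end_s": round((n_pre + n_go) * dt, 6),
            "nominal_duration_s": round(T, 6),
        },
    )
    return TrialRecording(
        time=time,
        points={"C1": wrist, "C2": elbow, "C3": shoulder, "C4": chest},
        meta=meta,
    )


def _trial_seed(base_seed: int, index: int) -> int:
    """Deterministic per-trial seed below 2**31."""
    return (base_seed * 1_000_003 + 7919 * index + 1) % (2**31 - 1)


def plan_trials(cfg: SynthDatasetConfig) -> list:
    """Expand the per-cell counts into an ordered list of (spec, seed) pairs.

    Trials in each action x condition cell alternate between the two actors
    and cycle through the three directions, mirroring a balanced session.
    """
    plans = []
    idx = 0
    profiles = cfg.actor_profiles
    for action in sorted(cfg.counts):
        if action not in cfg.end_points:
            raise ConfigurationError(f"no end point defined for action {action!r}")
        for cond in CONDITIONS:
            if cond not in cfg.counts[action]:
                continue
            for rep in range(cfg.counts[action][cond]):
                spec = TrialSpec(
                    actor=profiles[rep % len(profiles)],
                    action=action,
                    condition=cond,
                    direction=cfg.directions[rep % len(cfg.directions)],
                    trial_index=idx,
                    fps=cfg.fps,
                    start_point=np.asarray(cfg.start_point, float),
                    end_point=np.asarray(cfg.end_points[action], float),
                )
                plans.append((spec, _trial_seed(cfg.seed, idx)))
                idx += 1
    return plans


def generate_dataset(cfg: SynthDatasetConfig, class_param_map: dict | None = None) -> list:
    """Realize the full campaign; returns a list of :class:`TrialRecording`.

    Per-trial seeds are derived deterministically from ``cfg.seed``; each
    trial additionally receives small random variations of its duration and
    end point so that within-cell variance is realistic.
    """
    if class_param_map is None:
        class_param_map = default_class_params()
    missing = [c for c in CONDITIONS if c not in class_param_map]
    present = {c for a in cfg.counts.values() for c, n in a.items() if n > 0}
    missing = [c for c in missing if c in present]
    if missing:
        raise ConfigurationError(f"class_param_map missing conditions {missing}")
    trials = []
    for spec, seed in plan_trials(cfg):
        vary = np.random.default_rng(seed ^ 0x5A5A5A)
        params = class_param_map[spec.condition]
        params = replace(
            params,
            duration_s=params.duration_s
            * (1.0 + cfg.duration_jitter_frac * vary.uniform(-1, 1)),
        )
        spec = replace(
            spec,
            end_point=spec.end_point + vary.normal(0.0, cfg.endpoint_jitter_m, 3),
        )
        trials.append(generate_trial(params, spec, seed))
    return trials


def write_dataset(trials, outdir, metadata_name: str = "metadata.csv"):
    """Write one CSV per trial plus a dataset-level metadata table."""
    import pandas as pd

    from vitalkin.io import write_trial

    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in trials:
        fname = f"{rec.meta.trial_id}.csv"
        write_trial(rec, outdir / fname)
        rows.append(
            {
                "trial_id": rec.meta.trial_id,
                "actor": rec.meta.actor,
                "action": rec.meta.action,
                "condition": rec.meta.condition,
                "direction": rec.meta.direction,
                "seed": rec.meta.extras.get("seed", ""),
                "file": fname,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / metadata_name, index=False)
    return outdir
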