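"""Differentiation and automatic GO/Return segmentation.

Positions are zero-phase low-pass filtered before successive central
differencing (jerk via triple differencing is otherwise noise-dominated);
segmentation uses a speed threshold relative to the trial's peak speed so
that slow and fast trials segment comparably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from vitalkin.errors import SegmentationError, FormatError
from vitalkin.io import TrialRecording

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Zero-phase Butterworth pre-filter for position signals."""

    cutoff_hz: float | None = 10.0  # None disables filtering
    order: int = 2


@dataclass
class SegmentationConfig:
    """Thresholds for movement-phase detection.

    v_thr_rel
        onset/offset speed threshold as a fraction of the trial's peak speed.
    sustain_s
        how long the speed must stay above threshold to count as movement onset.
    split_window_s
        width of the speed-minimum search window centered on the frame of
        maximum distance from the start position; the minimum inside this
        window is the GO/Return split.
    min_go_s
        shortest admissible GO-phase.
    """

    v_thr_rel: float = 0.05
    sustain_s: float = 0.05
    split_window_s: float = 0.30
    min_go_s: float = 0.10
    far_plateau_tol: float = 0.002  # relative; defines the max-distance plateau


@dataclass
class KinematicSignals:
    """Filtered position and its first three derivatives on the trial time base."""

    pos: np.ndarray  # (n, 3) filtered wrist position
    vel: np.ndarray  # (n, 3)
    acc: np.ndarray  # (n, 3)
    jerk: np.ndarray  # (n, 3)
    speed: np.ndarray  # (n,)
    accel_mag: np.ndarray  # (n,)
    jerk_mag: np.ndarray  # (n,)
    dt: float

    @property
    def n_samples(self) -> int:
        return self.speed.shape[0]


@dataclass
class SegmentedTrial:
    """Half-open frame intervals of the two movement phases."""

    go_range: tuple  # [start, end)
    return_range: tuple  # [start, end); empty as (i, i)
    n_samples: int

    def __post_init__(self):
        g0, g1 = self.go_range
        r0, r1 = self.return_range
        if not (0 <= g0 < g1 <= self.n_samples):
            raise SegmentationError(f"invalid go_range {self.go_range}")
        if not (g1 <= r0 <= r1 <= self.n_samples):
            raise SegmentationError(f"return_range {self.return_range} precedes go_range end")

    @property
    def go_slice(self) -> slice:
        return slice(*self.go_range)

    @property
    def has_return(self) -> bool:
        return self.return_range[1] > self.return_range[0]


def lowpass(x: np.ndarray, cutoff_hz: float, fps: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0."""
    nyq = fps / 2.0
    wn = min(cutoff_hz / nyq, 0.99)
    b, a = signal.butter(order, wn, "low")
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.shape[0] <= padlen:
        raise FormatError(
            f"signal of {x.shape[0]} samples shorter than filter warm-up ({padlen + 1})"
        )
    return signal.filtfilt(b, a, x, axis=0)


def differentiate(
    rec: TrialRecording, filter_cfg: FilterConfig | None = None, point: str = "C1"
) -> KinematicSignals:
    """Filter the wrist position and differentiate it three times.

    Velocity, acceleration and jerk are obtained by successive central
    differences (``np.gradient``) of the zero-phase-filtered position.
    """
    if filter_cfg is None:
        filter_cfg = FilterConfig()
    pos = rec.points[point]
    dt = rec.dt
    if filter_cfg.cutoff_hz is not None:
        pos = lowpass(pos, filter_cfg.cutoff_hz, rec.fps, filter_cfg.order)
    vel = np.gradient(pos, dt, axis=0)
    acc = np.gradient(vel, dt, axis=0)
    jerk = np.gradient(acc, dt, axis=0)
    return KinematicSignals(
        pos=pos,
        vel=vel,
        acc=acc,
        jerk=jerk,
        speed=np.linalg.norm(vel, axis=1),
        accel_mag=np.linalg.norm(acc, axis=1),
        jerk_mag=np.linalg.norm(jerk, axis=1),
        dt=dt,
    )


def segment_go_phase(
    sig: KinematicSignals,
    rec: TrialRecording,
    cfg: SegmentationConfig | None = None,
) -> SegmentedTrial:
    """Split a trial into GO-phase and Return-phase.

    Onset is the first frame where speed exceeds the (relative) threshold
    for a sustained window; the GO/Return split is the frame of minimum
    speed within a window centered on the frame of maximum distance from
    the start position; the Return-phase ends at the last above-threshold
    frame.  A trial with no secondary movement gets an empty return range.
    """
    if cfg is None:
        cfg = SegmentationConfig()
    speed = sig.speed
    n = speed.shape[0]
    fps = 1.0 / sig.dt
    v_peak = float(speed.max())
    v_thr = cfg.v_thr_rel * v_peak
    if v_peak <= 0 or not np.any(speed > v_thr) or v_peak < 1e-9:
        raise SegmentationError("no movement detected: speed never exceeds threshold")
    sustain = max(int(round(cfg.sustain_s * fps)), 1)
    above = speed > v_thr
    onset = None
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= sustain:
            onset = i - sustain + 1
            break
    if onset is None:
        raise SegmentationError("no movement detected: threshold never sustained")
    # refine: walk back down the rising flank toward the actual movement
    # start (a relative threshold alone clips the slow head of the speed
    # profile); stop at the quiescent floor
    floor = 0.25 * v_thr
    while onset > 0 and floor < speed[onset - 1] < speed[onset]:
        onset -= 1

    last_above = int(np.nonzero(above)[0][-1])
    # bound the outbound search at the first sustained quiescent interval
    # after onset (the hold at the target); otherwise excursions during the
    # return can masquerade as the farthest point
    below = ~above
    start_pos = sig.pos[onset]
    dist_all = np.linalg.norm(sig.pos - start_pos, axis=1)
    far_ref = dist_all[onset : last_above + 1].max()
    # the hold at the target is the first sustained quiescent (below
    # threshold) interval that occurs far from the start position; speed
    # dips mid-movement and quiescence back at the start do not qualify
    search_end = last_above + 1
    hold_found = False
    half_peak = onset + int(np.argmax(speed[onset:] >= 0.5 * v_peak))
    run = 0
    for i in range(half_peak, n):
        run = run + 1 if below[i] else 0
        if run >= sustain:
            if dist_all[i - run + 1] >= 0.75 * far_ref:
                search_end = min(search_end, i + 1)
                hold_found = True
                break
            run = 0
    if hold_found:
        # walk back from the hold to where the distance leaves the arrival
        # plateau: anchors at the arrival even if a mid-path excursion
        # briefly strayed farther from the start
        j = search_end - 1
        ref = dist_all[j]
        lo = (1.0 - cfg.far_plateau_tol) * ref
        hi = (1.0 + cfg.far_plateau_tol) * ref
        i_far = j
        while i_far > onset and lo <= dist_all[i_far - 1] <= hi:
            i_far -= 1
    else:
        # no quiescent hold: center on the first frame entering the
        # maximum-distance plateau
        dist = dist_all[onset:search_end]
        near_max = dist >= (1.0 - cfg.far_plateau_tol) * dist.max()
        i_far = onset + int(np.argmax(near_max))

    half = max(int(round(cfg.split_window_s * fps / 2)), 1)
    w0 = max(i_far - half, onset + 1)
    w1 = min(i_far + half + 1, n)
    w = speed[w0:w1]
    # first frame entering the minimum-speed plateau (the argmin itself
    # wanders over the quiescent noise floor); when the window reaches
    # quiescence the movement threshold defines the plateau level
    level = max(1.2 * w.min() + 1e-6, v_thr if w.min() < v_thr else 0.0)
    split = w0 + int(np.argmax(w <= level))
    # refine: follow the falling flank toward the arrival, mirroring the
    # onset refinement; stop at the quiescent floor
    while split + 1 < w1 and 0.25 * v_thr < speed[split + 1] < speed[split]:
        split += 1

    min_go = max(int(round(cfg.min_go_s * fps)), 2)
    if split - onset < min_go:
        raise SegmentationError(
            f"GO-phase of {split - onset} frames shorter than minimum {min_go}"
        )

    # return movement: any sustained above-threshold activity after the split
    ret_above = np.nonzero(above[split:])[0]
    if ret_above.size >= sustain:
        ret_end = split + int(ret_above[-1]) + 1
        return_range = (split, ret_end)
    else:
        log.warning("no return movement detected; empty return range")
        return_range = (split, split)
    return SegmentedTrial(go_range=(onset, split), return_range=return_range, n_samples=n)
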