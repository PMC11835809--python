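"""The 22 kinematic features computed on the GO-phase of each trial.

Feature groups
--------------
* peak kinematics: Vmx, Amx, Jmx (m/s, m/s^2, m/s^3)
* Suddenness S: tail index of the alpha-stable law fitted to the GO-phase
  speed samples by a quantile-spread estimator (lower = heavier tails =
  more abrupt movement)
* path geometry: POWmx/POSmx maximum perpendicular deviation of the
  wrist/shoulder path from the start-end chord (m), with %POWmx/%POSmx the
  percentage of GO duration at which the maximum occurs; AL arc length (m);
  CWmx maximum trajectory curvature (1/m)
* smoothness: per-frame s(t) = 1 / (1 + jerk(t)^2), max/mean/sd (higher =
  smoother)
* variability: absolute residual between speed and its 2 Hz low-passed
  version, max/mean/sd (m/s)
* posture: arm-chest angle AAC and elbow angle AE, max/mean/sd (degrees)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from vitalkin.errors import DegenerateInputError, GeometryError, SegmentationError
from vitalkin.io import TrialRecording
from vitalkin.kinematics import (
    FilterConfig,
    KinematicSignals,
    SegmentationConfig,
    SegmentedTrial,
    differentiate,
    lowpass,
    segment_go_phase,
)

log = logging.getLogger(__name__)

#: canonical column order of the feature table
FEATURE_NAMES = (
    "Vmx", "Amx", "Jmx", "S",
    "POWmx", "POSmx", "%POWmx", "%POSmx",
    "AL", "CWmx",
    "SMmx", "SMa", "SMsd",
    "VWmx", "VWa", "VWsd",
    "AACmx", "AACa", "AACsd",
    "AEmx", "AEa", "AEsd",
)

META_COLUMNS = ("trial_id", "actor", "action", "condition", "direction")

# ---------------------------------------------------------------------------
# Suddenness: quantile-spread estimator of the stable-law tail index.
# The table maps alpha -> nu(alpha) = (q95 - q05) / (q75 - q25) for the
# symmetric stable law (computed from its quantile function; nu(2) = 2.4387
# is the Gaussian value, nu(1) = 6.3138 the Cauchy value) and is inverted by
# monotone interpolation in log(nu).
# ---------------------------------------------------------------------------
_STABLE_ALPHAS = np.array([
    0.40, 0.45, 0.50, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95,
    1.00, 1.05, 1.10, 1.15, 1.20, 1.25, 1.30, 1.35, 1.40, 1.45, 1.50, 1.55,
    1.60, 1.65, 1.70, 1.75, 1.80, 1.85, 1.90, 1.95, 2.00,
])
_STABLE_NUS = np.array([
    115.036596, 68.039584, 44.635118, 31.565569, 23.612189, 18.439617,
    14.893767, 12.357522, 10.479083, 9.047016, 7.928492, 7.036866,
    6.313752, 5.718676, 5.222869, 4.805423, 4.450851, 4.147494,
    3.886470, 3.660946, 3.465625, 3.296352, 3.149795, 3.023170,
    2.914029, 2.820128, 2.739382, 2.669882, 2.609914, 2.557985,
    2.512818, 2.473342, 2.438664,
])

ALPHA_MIN, ALPHA_MAX = 0.35, 2.0
SUDDENNESS_MIN_SAMPLES = 50


def stable_alpha_quantile(x: np.ndarray) -> float:
    """Estimate the stable-law tail index alpha from samples ``x``.

    Uses the ratio of the 5-95% spread to the interquartile range, inverted
    against the symmetric stable law; the result is clamped to
    [0.35, 2] (a spread ratio below the Gaussian value maps to 2).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise DegenerateInputError(f"need >= 4 samples to estimate alpha, got {x.size}")
    q05, q25, q75, q95 = np.quantile(x, [0.05, 0.25, 0.75, 0.95])
    iqr = q75 - q25
    if iqr <= 1e-12 or (q95 - q05) <= 1e-12:
        raise DegenerateInputError("constant signal: stable-law fit is undefined")
    nu = (q95 - q05) / iqr
    if nu <= _STABLE_NUS[-1]:
        return ALPHA_MAX
    if nu >= _STABLE_NUS[0]:
        log.warning("spread ratio %.3g beyond table; alpha clamped to %.2f", nu, ALPHA_MIN)
        return ALPHA_MIN
    # table is decreasing in alpha -> interpolate on reversed axis
    alpha = float(np.interp(np.log(nu), np.log(_STABLE_NUS[::-1]), _STABLE_ALPHAS[::-1]))
    return float(np.clip(alpha, ALPHA_MIN, ALPHA_MAX))


# ---------------------------------------------------------------------------
# individual feature groups
# ---------------------------------------------------------------------------

def peak_kinematics(seg: SegmentedTrial, sig: KinematicSignals):
    """(Vmx, Amx, Jmx): maxima of speed/acceleration/jerk over the GO-phase."""
    sl = seg.go_slice
    if sl.stop - sl.start < 1:
        raise SegmentationError("empty GO range")
    return (
        float(sig.speed[sl].max()),
        float(sig.accel_mag[sl].max()),
        float(sig.jerk_mag[sl].max()),
    )


def suddenness(sig: KinematicSignals, seg: SegmentedTrial) -> float:
    """S: stable-law tail index of the GO-phase speed samples."""
    sl = seg.go_slice
    x = sig.speed[sl]
    if x.size < SUDDENNESS_MIN_SAMPLES:
        raise SegmentationError(
            f"GO-phase of {x.size} samples too short for the tail-index "
            f"estimator (needs >= {SUDDENNESS_MIN_SAMPLES})"
        )
    return stable_alpha_quantile(x)


def _chord_offsets(path: np.ndarray):
    """Per-frame perpendicular distance of a 3D path from its start-end chord."""
    a, b = path[0], path[-1]
    chord = b - a
    L = np.linalg.norm(chord)
    if L <= 1e-6:
        raise DegenerateInputError("zero-length chord: path offset undefined")
    u = chord / L
    rel = path - a
    return np.linalg.norm(np.cross(rel, u), axis=1)


def path_offsets(seg: SegmentedTrial, rec: TrialRecording, sig: KinematicSignals | None = None):
    """(POWmx, %POWmx, POSmx, %POSmx): max chord deviation and its timing.

    Wrist offsets use the filtered wrist path when signals are supplied;
    shoulder offsets use the raw C3 centroid path.
    """
    sl = seg.go_slice
    wrist = sig.pos[sl] if sig is not None else rec.points["C1"][sl]
    shoulder = rec.points["C3"][sl]
    n = sl.stop - sl.start
    out = []
    for path in (wrist, shoulder):
        d = _chord_offsets(path)
        i = int(np.argmax(d))
        out.append(float(d[i]))
        out.append(100.0 * i / max(n - 1, 1))
    return out[0], out[1], out[2], out[3]


def arc_length(seg: SegmentedTrial, rec: TrialRecording, sig: KinematicSignals | None = None) -> float:
    """AL: cumulative sum of inter-sample distances of the GO-phase wrist path."""
    sl = seg.go_slice
    path = sig.pos[sl] if sig is not None else rec.points["C1"][sl]
    if path.shape[0] < 2:
        raise SegmentationError("GO-phase needs >= 2 samples for arc length")
    return float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())


CURVATURE_SPEED_EPS = 1e-3


def curvature_max(seg: SegmentedTrial, sig: KinematicSignals) -> float:
    """CWmx: max of kappa = |v x a| / |v|^3 over GO frames with speed > eps."""
    sl = seg.go_slice
    v, a, s = sig.vel[sl], sig.acc[sl], sig.speed[sl]
    ok = s > CURVATURE_SPEED_EPS
    if not ok.any():
        raise DegenerateInputError("no frames above the curvature speed floor")
    kappa = np.linalg.norm(np.cross(v[ok], a[ok]), axis=1) / s[ok] ** 3
    return float(kappa.max())


def smoothness(seg: SegmentedTrial, sig: KinematicSignals):
    """(SMmx, SMa, SMsd) of the per-frame score s(t) = 1 / (1 + jerk(t)^2)."""
    j = sig.jerk_mag[seg.go_slice]
    s = 1.0 / (1.0 + j**2)
    return float(s.max()), float(s.mean()), float(s.std(ddof=0))


VARIABILITY_CUTOFF_HZ = 2.0


def variability(seg: SegmentedTrial, sig: KinematicSignals, cutoff_hz: float = VARIABILITY_CUTOFF_HZ):
    """(VWmx, VWa, VWsd) of |speed - lowpass(speed)| over the GO-phase.

    The residual is taken against a zero-phase 2nd-order low-pass of the
    whole-trial speed signal (cutting at ``cutoff_hz``), then restricted to
    the GO-phase.
    """
    fps = 1.0 / sig.dt
    smooth = lowpass(sig.speed[:, None], cutoff_hz, fps).ravel()
    r = np.abs(sig.speed - smooth)[seg.go_slice]
    return float(r.max()), float(r.mean()), float(r.std(ddof=0))


def _angle_deg(v1: np.ndarray, v2: np.ndarray, label: str) -> np.ndarray:
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if (n1 < 1e-9).any() or (n2 < 1e-9).any():
        raise GeometryError(f"coincident centroids produce a zero-length {label} vector")
    cosang = np.einsum("ij,ij->i", v1, v2) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def angle_features(seg: SegmentedTrial, rec: TrialRecording):
    """(AACmx, AACa, AACsd, AEmx, AEa, AEsd) in degrees over the GO-phase.

    AAC is the angle at the shoulder between the upper arm (C2 - C3) and the
    chest direction (C4 - C3); AE the elbow angle between (C3 - C2) and
    (C1 - C2).
    """
    sl = seg.go_slice
    c1, c2, c3, c4 = (rec.points[k][sl] for k in ("C1", "C2", "C3", "C4"))
    aac = _angle_deg(c2 - c3, c4 - c3, "arm/chest")
    ae = _angle_deg(c3 - c2, c1 - c2, "elbow")
    return (
        float(aac.max()), float(aac.mean()), float(aac.std(ddof=0)),
        float(ae.max()), float(ae.mean()), float(ae.std(ddof=0)),
    )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass
class ExtractionConfig:
    filter: FilterConfig = None
    segmentation: SegmentationConfig = None
    variability_cutoff_hz: float = VARIABILITY_CUTOFF_HZ

    def __post_init__(self):
        if self.filter is None:
            self.filter = FilterConfig()
        if self.segmentation is None:
            self.segmentation = SegmentationConfig()


def extract_all(rec: TrialRecording, cfg: ExtractionConfig | None = None) -> dict:
    """Compute all 22 features (plus metadata) for one trial."""
    if cfg is None:
        cfg = ExtractionConfig()
    sig = differentiate(rec, cfg.filter)
    seg = segment_go_phase(sig, rec, cfg.segmentation)
    vmx, amx, jmx = peak_kinematics(seg, sig)
    s_alpha = suddenness(sig, seg)
    powmx, ppowmx, posmx, pposmx = path_offsets(seg, rec, sig)
    al = arc_length(seg, rec, sig)
    cwmx = curvature_max(seg, sig)
    smmx, sma, smsd = smoothness(seg, sig)
    vwmx, vwa, vwsd = variability(seg, sig, cfg.variability_cutoff_hz)
    aacmx, aaca, aacsd, aemx, aea, aesd = angle_features(seg, rec)
    feats = {
        "Vmx": vmx, "Amx": amx, "Jmx": jmx, "S": s_alpha,
        "POWmx": powmx, "POSmx": posmx, "%POWmx": ppowmx, "%POSmx": pposmx,
        "AL": al, "CWmx": cwmx,
        "SMmx": smmx, "SMa": sma, "SMsd": smsd,
        "VWmx": vwmx, "VWa": vwa, "VWsd": vwsd,
        "AACmx": aacmx, "AACa": aaca, "AACsd": aacsd,
        "AEmx": aemx, "AEa": aea, "AEsd": aesd,
    }
    feats.update(
        trial_id=rec.meta.trial_id,
        actor=rec.meta.actor,
        action=rec.meta.action,
        condition=rec.meta.condition,
        direction=rec.meta.direction,
    )
    return feats


def build_table(trials, cfg: ExtractionConfig | None = None):
    """Extract features for every trial; failing trials are excluded and logged.

    Returns ``(table, discard_report)`` where the table has one row per
    retained trial (columns: the 22 features then metadata) and the report
    lists each excluded trial with the reason.
    """
    rows, discards = [], []
    for rec in trials:
        try:
            rows.append(extract_all(rec, cfg))
        except Exception as exc:
            log.warning("trial %s excluded: %s", rec.meta.trial_id, exc)
            discards.append({"trial_id": rec.meta.trial_id, "reason": str(exc)})
    table = pd.DataFrame(rows, columns=list(FEATURE_NAMES) + list(META_COLUMNS))
    return table, pd.DataFrame(discards, columns=["trial_id", "reason"])
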