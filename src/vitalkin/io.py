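"""Trial I/O and rigid-body centroid reduction.

A trial is stored as one CSV file: commented ``# key=value`` header lines
carry the metadata, followed by a ``t,<point>_x,<point>_y,<point>_z,...``
table with time in seconds and coordinates in meters.  A recording holds
either the 16 raw markers (grouped into four rigid bodies) or the four
derived centroids C1 (wrist), C2 (elbow), C3 (shoulder), C4 (chest).
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from vitalkin.errors import DataError, FormatError

log = logging.getLogger(__name__)

#: canonical centroid names, proximal ordering follows the body layout
CENTROID_NAMES = ("C1", "C2", "C3", "C4")

#: maximum timestamp jitter tolerated before the time base is rejected (s)
TIME_JITTER_TOL = 1e-6

#: longest gap (in frames at 100 fps this is 100 ms) filled by interpolation
DEFAULT_MAX_GAP = 10


@dataclass
class TrialMeta:
    """Identity of one recorded action execution."""

    trial_id: str
    actor: str
    action: str
    condition: str
    direction: int = 0  # degrees: -45, 0 or 45
    sex: str = ""
    trial_index: int = 0
    extras: dict = field(default_factory=dict)

    def to_header(self) -> list[str]:
        items = {
            "trial_id": self.trial_id,
            "actor": self.actor,
            "sex": self.sex,
            "action": self.action,
            "condition": self.condition,
            "direction": self.direction,
            "trial_index": self.trial_index,
        }
        lines = [f"# {k}={v}" for k, v in items.items()]
        for k in sorted(self.extras):
            lines.append(f"# x_{k}={self.extras[k]!r}")
        return lines

    @classmethod
    def from_header(cls, pairs: dict) -> "TrialMeta":
        extras = {}
        for k in list(pairs):
            if k.startswith("x_"):
                import ast

                extras[k[2:]] = ast.literal_eval(pairs.pop(k))
        required = ("trial_id", "actor", "action", "condition")
        missing = [k for k in required if not pairs.get(k)]
        if missing:
            raise FormatError(f"trial metadata incomplete, missing {missing}")
        return cls(
            trial_id=pairs["trial_id"],
            actor=pairs["actor"],
            sex=pairs.get("sex", ""),
            action=pairs["action"],
            condition=pairs["condition"],
            direction=int(pairs.get("direction", 0)),
            trial_index=int(pairs.get("trial_index", 0)),
            extras=extras,
        )


@dataclass
class TrialRecording:
    """Uniformly sampled 3D point trajectories for one action execution.

    Parameters
    ----------
    time : (n,) array of seconds, uniform.
    points : mapping of point name to (n, 3) array of meters; insertion
        order defines the on-disk column order.
    meta : trial identity.
    """

    time: np.ndarray
    points: dict
    meta: TrialMeta

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    @property
    def fps(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.time)))

    def validate(self):
        n = self.time.shape[0]
        if n < 2:
            raise FormatError(f"recording needs >= 2 samples, got {n}")
        dts = np.diff(self.time)
        if dts.min() <= 0:
            raise FormatError("time base is not strictly increasing")
        if np.ptp(dts) > TIME_JITTER_TOL:
            raise FormatError(
                f"non-uniform sampling: timestamp jitter {np.ptp(dts):.3g} s "
                f"exceeds {TIME_JITTER_TOL:.0e} s"
            )
        for name, arr in self.points.items():
            if arr.shape != (n, 3):
                raise FormatError(f"point {name!r} has shape {arr.shape}, expected {(n, 3)}")
            if not np.isfinite(arr).all():
                raise DataError(f"point {name!r} contains NaN/inf after gap filling")

    def translated(self, offset) -> "TrialRecording":
        """Return a copy rigidly translated by ``offset`` (3-vector, meters)."""
        off = np.asarray(offset, dtype=float)
        return TrialRecording(
            time=self.time.copy(),
            points={k: v + off for k, v in self.points.items()},
            meta=replace(self.meta),
        )


def _fill_gaps(df: pd.DataFrame, max_gap: int, origin: str) -> pd.DataFrame:
    """Linearly interpolate interior NaN runs no longer than ``max_gap`` frames."""
    if not df.isna().any().any():
        return df
    for col in df.columns:
        na = df[col].isna()
        if not na.any():
            continue
        # length of the longest interior NaN run
        runs = (na != na.shift()).cumsum()[na]
        longest = runs.value_counts().max()
        if longest > max_gap:
            raise DataError(
                f"{origin}: column {col!r} has a gap of {longest} frames "
                f"(> max_gap={max_gap}); trial rejected"
            )
        log.info("%s: interpolated %d missing samples in %s", origin, int(na.sum()), col)
    out = df.interpolate(method="linear", limit_area="inside")
    if out.isna().any().any():
        raise DataError(f"{origin}: leading/trailing missing samples cannot be interpolated")
    return out


def read_trial(path, max_gap: int = DEFAULT_MAX_GAP) -> TrialRecording:
    """Read one trial CSV written by :func:`write_trial`.

    Interior gaps of at most ``max_gap`` frames are linearly interpolated
    (and logged); longer gaps reject the trial.
    """
    path = Path(path)
    header = {}
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                header[k.strip()] = v.strip()
    try:
        df = pd.read_csv(_io.StringIO(text), comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if "t" not in df.columns:
        raise FormatError(f"{path}: missing time column 't'")
    if len(df) < 2:
        raise FormatError(f"{path}: {len(df)} sample(s), need >= 2")
    bad = df["t"].isna()
    if bad.any():
        raise FormatError(f"{path}: missing timestamp at data row {int(bad.idxmax()) + 1}")
    coord_cols = [c for c in df.columns if c != "t"]
    names = []
    for c in coord_cols:
        if "_" not in c or c.rsplit("_", 1)[1] not in ("x", "y", "z"):
            raise FormatError(f"{path}: unrecognized column {c!r}")
        base = c.rsplit("_", 1)[0]
        if base not in names:
            names.append(base)
    for name in names:
        for ax in ("x", "y", "z"):
            if f"{name}_{ax}" not in df.columns:
                raise FormatError(f"{path}: point {name!r} missing axis {ax}")
    filled = _fill_gaps(df[coord_cols].astype(float), max_gap, str(path))
    points = {
        name: np.column_stack([filled[f"{name}_{ax}"].to_numpy() for ax in ("x", "y", "z")])
        for name in names
    }
    meta = TrialMeta.from_header(header)
    return TrialRecording(time=df["t"].to_numpy(float), points=points, meta=meta)


def write_trial(rec: TrialRecording, path) -> Path:
    """Write a trial to CSV; round-trips through :func:`read_trial` to 1e-9 m."""
    path = Path(path)
    missing = [
        k
        for k in ("trial_id", "actor", "action", "condition")
        if not getattr(rec.meta, k)
    ]
    if missing:
        raise DataError(f"cannot write trial: metadata fields {missing} are empty")
    cols = {"t": rec.time}
    for name, arr in rec.points.items():
        for i, ax in enumerate(("x", "y", "z")):
            cols[f"{name}_{ax}"] = arr[:, i]
    df = pd.DataFrame(cols)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(rec.meta.to_header()) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")
    return path


def compute_centroids(rec: TrialRecording, grouping: dict, max_gap: int = DEFAULT_MAX_GAP) -> TrialRecording:
    """Reduce a 16-marker recording to the four rigid-body centroids C1-C4.

    ``grouping`` maps each centroid name (C1..C4) to the list of marker
    names belonging to that rigid body; the centroid is the per-frame
    arithmetic mean of those markers.
    """
    missing = [c for c in CENTROID_NAMES if c not in grouping]
    if missing:
        raise DataError(f"grouping missing rigid bodies {missing}")
    out = {}
    for cname in CENTROID_NAMES:
        markers = grouping[cname]
        if not markers:
            raise DataError(f"rigid body {cname} has no markers assigned")
        absent = [m for m in markers if m not in rec.points]
        if absent:
            raise DataError(f"rigid body {cname}: markers {absent} not in recording")
        stack = np.stack([rec.points[m] for m in markers])  # (m, n, 3)
        out[cname] = stack.mean(axis=0)
    return TrialRecording(time=rec.time.copy(), points=out, meta=replace(rec.meta))
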