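"""Session-bundle I/O.

A session bundle is a directory with a ``manifest.json`` naming one file per
data stream.  Tracking, accelerometer, spikes and clicks are stored as
comma-separated UTF-8 text with a header row; the LFP is stored as a flat
little-endian float32 binary (sample-major) whose shape and rate live in the
manifest.  All timestamps are seconds on one session clock with t=0 at
session start; intervals are half-open ``[start, stop)``.

The accelerometer is stored in units of g (gravity = 1.0), so the movement
level of :func:`flightreplay.behavior.movement_level` is a subtraction of 1.
Channel index 0 of the LFP is the most superficial contact; depth increases
with index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SessionBundle",
    "ResultTable",
    "SessionValidationError",
    "read_session",
    "write_session",
    "write_table",
    "read_table",
]

_FLOAT_FMT = "%.10g"  # >= 9 significant digits for round-trip identity


class SessionValidationError(ValueError):
    """Raised when a stream violates the bundle invariants."""


@dataclass
class SessionBundle:
    """All raw streams of one recording session.

    Attributes
    ----------
    tracking : DataFrame with columns ``t, x, y, z`` (s, m), nominally 120 Hz.
    accel : DataFrame with columns ``t, ax, ay, az`` (s, g), nominally 500 Hz.
    lfp : float32 array ``[n_samples, n_channels]`` in microvolt at ``lfp_rate``.
    spikes : DataFrame with columns ``unit_id, t`` sorted by (t, unit_id).
    clicks : float array of echolocation click times (s); may be empty.
    meta : free-form metadata; must contain the sampling rates.
    """

    tracking: pd.DataFrame
    accel: pd.DataFrame
    lfp: np.ndarray
    lfp_rate: float
    spikes: pd.DataFrame
    clicks: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        if len(self.spikes) == 0:
            return 0
        return int(self.spikes["unit_id"].max()) + 1

    def spike_trains(self) -> dict[int, np.ndarray]:
        """Spike times per unit as a dict ``unit_id -> sorted array``."""
        out = {u: np.empty(0) for u in range(self.n_units)}
        for u, grp in self.spikes.groupby("unit_id"):
            out[int(u)] = np.sort(grp["t"].to_numpy())
        return out

    def duration(self) -> float:
        ends = [self.tracking["t"].iloc[-1] if len(self.tracking) else 0.0,
                self.accel["t"].iloc[-1] if len(self.accel) else 0.0,
                self.lfp.shape[0] / self.lfp_rate if self.lfp.size else 0.0]
        return float(max(ends))

    def validate(self) -> None:
        """Check timestamp monotonicity and declared-rate consistency."""
        for name, df in (("tracking", self.tracking), ("accel", self.accel)):
            t = df["t"].to_numpy()
            bad = np.nonzero(np.diff(t) <= 0)[0]
            if bad.size:
                raise SessionValidationError(
                    f"{name}: non-monotonic timestamp at index {int(bad[0]) + 1}")
        if len(self.spikes):
            t = self.spikes["t"].to_numpy()
            if np.any(np.diff(t) < 0):
                raise SessionValidationError("spikes: times not sorted")
            units = np.unique(self.spikes["unit_id"].to_numpy())
            if units.min() < 0:
                raise SessionValidationError("spikes: negative unit id")
        for name, df, key in (("tracking", self.tracking, "tracking_rate_hz"),
                              ("accel", self.accel, "accel_rate_hz")):
            rate = self.meta.get(key)
            if rate and len(df) > 2:
                med = float(np.median(np.diff(df["t"].to_numpy())))
                if abs(med - 1.0 / rate) > 0.01 / rate:
                    raise SessionValidationError(
                        f"{name}: declared rate {rate} Hz disagrees with "
                        f"median interval {med:.6f} s by more than 1%")


@dataclass
class ResultTable:
    """A named table of analysis results with provenance."""

    name: str
    rows: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def write_session(bundle: SessionBundle, path: str | Path) -> dict:
    """Write a bundle to ``path`` and return the manifest written."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bundle.tracking.to_csv(path / "tracking.csv", index=False,
                           float_format=_FLOAT_FMT)
    bundle.accel.to_csv(path / "accel.csv", index=False,
                        float_format=_FLOAT_FMT)
    bundle.spikes.to_csv(path / "spikes.csv", index=False,
                         float_format=_FLOAT_FMT)
    pd.DataFrame({"t": bundle.clicks}).to_csv(
        path / "clicks.csv", index=False, float_format=_FLOAT_FMT)
    lfp = np.ascontiguousarray(bundle.lfp, dtype="<f4")
    lfp.tofile(path / "lfp.f32")
    manifest = {
        "tracking": "tracking.csv",
        "accel": "accel.csv",
        "lfp": {"file": "lfp.f32",
                "n_channels": int(lfp.shape[1]) if lfp.ndim == 2 else 1,
                "n_samples": int(lfp.shape[0]),
                "rate_hz": float(bundle.lfp_rate)},
        "spikes": "spikes.csv",
        "clicks": "clicks.csv",
        "meta": bundle.meta,
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_session(path: str | Path) -> SessionBundle:
    """Read and validate a session bundle from a directory."""
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"missing mandatory file: {mpath}")
    with open(mpath) as fh:
        manifest = json.load(fh)
    for key in ("tracking", "accel", "lfp", "spikes"):
        if key not in manifest:
            raise SessionValidationError(f"manifest lacks mandatory entry '{key}'")

    def _csv(key: str, optional: bool = False) -> pd.DataFrame:
        f = path / manifest[key]
        if not f.exists():
            if optional:
                return pd.DataFrame()
            raise FileNotFoundError(f"missing mandatory file: {f}")
        return pd.read_csv(f)

    tracking = _csv("tracking")
    accel = _csv("accel")
    spikes = _csv("spikes")
    if len(spikes) == 0:
        spikes = pd.DataFrame({"unit_id": pd.Series(dtype=int),
                               "t": pd.Series(dtype=float)})
    lfp_info = manifest["lfp"]
    lfp_file = path / lfp_info["file"]
    if not lfp_file.exists():
        raise FileNotFoundError(f"missing mandatory file: {lfp_file}")
    lfp = np.fromfile(lfp_file, dtype="<f4")
    n_ch = int(lfp_info["n_channels"])
    lfp = lfp.reshape(-1, n_ch)
    clicks = np.empty(0)
    if "clicks" in manifest and (path / manifest["clicks"]).exists():
        cdf = pd.read_csv(path / manifest["clicks"])
        if len(cdf):
            clicks = cdf["t"].to_numpy(dtype=float)
    bundle = SessionBundle(tracking=tracking, accel=accel, lfp=lfp,
                           lfp_rate=float(lfp_info["rate_hz"]),
                           spikes=spikes, clicks=clicks,
                           meta=manifest.get("meta", {}))
    bundle.validate()
    return bundle


def write_table(table: ResultTable, path: str | Path) -> None:
    """Write a result table as CSV with a provenance side-car comment file."""
    path = Path(path)
    table.rows.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if table.provenance:
        with open(path.with_suffix(path.suffix + ".prov.json"), "w") as fh:
            json.dump(table.provenance, fh, indent=1, sort_keys=True)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
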