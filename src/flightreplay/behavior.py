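"""Behavioural segmentation: flights, trajectory clusters, turns, clicks.

Flights are segmented from 3D tracking with a 0.5 m/s speed threshold after
smoothing; trajectories are spatially downsampled to seven points, compared
with the discrete Fréchet distance and grouped by agglomerative hierarchical
clustering with a metric linkage cut (0.6-1.5 m); clusters with fewer than
five member flights are discarded.  Turns are classified from the maximum
smoothed 3D curvature with flight tails (outside 25-75% of trajectory
length) forced to zero curvature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal import find_peaks
from scipy.spatial.distance import squareform

__all__ = [
    "FlightSegment", "FlightCluster", "segment_flights", "downsample_path",
    "frechet_distance", "frechet_matrix", "cluster_flights", "detect_turns",
    "linearize_flight", "movement_level", "detect_clicks",
]


@dataclass
class FlightSegment:
    start: float
    stop: float
    path: np.ndarray                 # samples x 3, metres
    t: np.ndarray                    # sample times
    arc_length: np.ndarray = field(default=None)  # cumulative, metres

    def __post_init__(self):
        if self.arc_length is None:
            seg = np.linalg.norm(np.diff(self.path, axis=0), axis=1)
            self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def duration(self) -> float:
        return self.stop - self.start

    @property
    def length_m(self) -> float:
        return float(self.arc_length[-1])

    @property
    def takeoff(self) -> np.ndarray:
        return self.path[0]

    @property
    def landing(self) -> np.ndarray:
        return self.path[-1]


@dataclass
class FlightCluster:
    cluster_id: int
    members: list                    # indices into the flight list
    mean_path: np.ndarray            # 7 x 3
    mean_length_m: float
    mean_duration_s: float
    shape_class: str = "straight"


def segment_flights(tracking: pd.DataFrame, v_thresh: float = 0.5,
                    smooth_s: float = 0.1, merge_gap_s: float = 0.3,
                    min_duration_s: float = 0.5
                    ) -> tuple[list[FlightSegment], pd.DataFrame]:
    """Split a session into flight segments and complementary rest intervals.

    Speed comes from centred finite differences of the tracking positions,
    smoothed with a moving average (``smooth_s``) before thresholding at
    ``v_thresh``; sub-threshold dips shorter than ``merge_gap_s`` are merged
    (hysteresis) and flights shorter than ``min_duration_s`` dropped.
    """
    t = tracking["t"].to_numpy()
    xyz = tracking[["x", "y", "z"]].to_numpy()
    if len(t) < 2:
        return [], pd.DataFrame({"start": [t[0] if len(t) else 0.0],
                                 "stop": [t[-1] if len(t) else 0.0]})
    dt = float(np.median(np.diff(t)))
    vel = np.gradient(xyz, t, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    w = max(1, int(round(smooth_s / dt)))
    speed = uniform_filter1d(speed, w, mode="nearest")
    above = speed > v_thresh
    # runs of above-threshold samples
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(above))
    runs = list(zip(starts, stops))
    # hysteresis: merge runs separated by a short sub-threshold dip
    merged = []
    for s, e in runs:
        if merged and (t[s] - t[merged[-1][1] - 1]) < merge_gap_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    flights = []
    for s, e in merged:
        if t[e - 1] - t[s] < min_duration_s:
            continue
        flights.append(FlightSegment(start=float(t[s]), stop=float(t[e - 1]),
                                     path=xyz[s:e].copy(), t=t[s:e].copy()))
    rest_rows = []
    prev = float(t[0])
    for fl in flights:
        if fl.start > prev:
            rest_rows.append({"start": prev, "stop": fl.start})
        prev = fl.stop
    if float(t[-1]) > prev:
        rest_rows.append({"start": prev, "stop": float(t[-1])})
    if not flights:
        rest_rows = [{"start": float(t[0]), "stop": float(t[-1])}]
    return flights, pd.DataFrame(rest_rows, columns=["start", "stop"])


def downsample_path(path: np.ndarray, n_points: int = 7) -> np.ndarray:
    """Spatially downsample a path to ``n_points`` equally spaced in arc
    length; first and last points are take-off and landing."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] == 0:
        return np.repeat(path[:1], n_points, axis=0)
    targets = np.linspace(0, arc[-1], n_points)
    out = np.empty((n_points, path.shape[1]))
    for k in range(path.shape[1]):
        out[:, k] = np.interp(targets, arc, path[:, k])
    return out


def frechet_distance(path_a: np.ndarray, path_b: np.ndarray) -> float:
    """Discrete Fréchet distance between two point sequences.

    Dynamic program over the pairwise distance matrix:
    ``F[i,j] = max(d(i,j), min(F[i-1,j], F[i,j-1], F[i-1,j-1]))``.
    """
    a = np.asarray(path_a, dtype=float)
    b = np.asarray(path_b, dtype=float)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    n, m = d.shape
    F = np.empty((n, m))
    F[0, 0] = d[0, 0]
    for j in range(1, m):
        F[0, j] = max(F[0, j - 1], d[0, j])
    for i in range(1, n):
        F[i, 0] = max(F[i - 1, 0], d[i, 0])
        for j in range(1, m):
            F[i, j] = max(d[i, j], min(F[i - 1, j], F[i, j - 1],
                                       F[i - 1, j - 1]))
    return float(F[-1, -1])


def frechet_matrix(paths: list[np.ndarray]) -> np.ndarray:
    n = len(paths)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = frechet_distance(paths[i], paths[j])
    return D


def cluster_flights(flights: list[FlightSegment], linkage_m: float = 1.0,
                    method: str = "single", min_members: int = 5
                    ) -> tuple[list[FlightCluster], np.ndarray]:
    """Agglomerative clustering of 7-point downsampled flight paths.

    Returns retained clusters (>= ``min_members`` flights) and a per-flight
    label array (-1 for flights in discarded clusters).
    """
    if not flights:
        return [], np.empty(0, dtype=int)
    paths = [downsample_path(f.path) for f in flights]
    if len(flights) == 1:
        labels = np.array([-1])
        return [], labels
    D = frechet_matrix(paths)
    Z = linkage(squareform(D, checks=False), method=method)
    raw = fcluster(Z, t=linkage_m, criterion="distance")
    labels = np.full(len(flights), -1, dtype=int)
    clusters = []
    next_id = 0
    for lab in np.unique(raw):
        members = np.nonzero(raw == lab)[0]
        if len(members) < min_members:
            continue
        mean_path = np.mean([paths[i] for i in members], axis=0)
        clusters.append(FlightCluster(
            cluster_id=next_id, members=list(members), mean_path=mean_path,
            mean_length_m=float(np.mean([flights[i].length_m for i in members])),
            mean_duration_s=float(np.mean([flights[i].duration for i in members]))))
        labels[members] = next_id
        next_id += 1
    return clusters, labels


def detect_turns(flight: FlightSegment, kernel_s: float = 0.12,
                 curv_thresh: float = 1.0) -> tuple[str, float]:
    """Classify a flight as straight or loop by maximum smoothed curvature.

    Curvature kappa = |v x a| / |v|^3 from Gaussian-smoothed derivatives;
    the first and last quarters of the trajectory (by arc length) are forced
    to zero curvature to avoid take-off/landing edge effects.
    """
    t, path = flight.t, flight.path
    if len(t) < 5:
        return "straight", 0.0
    dt = float(np.median(np.diff(t)))
    sigma = max(kernel_s / dt, 1e-6)
    sm = gaussian_filter1d(path, sigma, axis=0, mode="nearest")
    v = np.gradient(sm, t, axis=0)
    a = np.gradient(v, t, axis=0)
    cross = np.cross(v, a)
    speed = np.linalg.norm(v, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        curv = np.linalg.norm(cross, axis=1) / np.maximum(speed, 1e-9) ** 3
    frac = flight.arc_length / max(flight.arc_length[-1], 1e-9)
    curv[(frac < 0.25) | (frac > 0.75)] = 0.0
    mx = float(np.nanmax(curv))
    return ("loop" if mx > curv_thresh else "straight"), mx


def linearize_flight(flight: FlightSegment) -> pd.DataFrame:
    """Per-sample absolute and normalized distance along the flight path."""
    arc = flight.arc_length
    norm = arc / max(arc[-1], 1e-12)
    return pd.DataFrame({"t": flight.t, "d_m": arc, "d_norm": norm})


def movement_level(accel: pd.DataFrame, gravity_g: float = 1.0) -> pd.DataFrame:
    """|‖a‖ - g| at the accelerometer rate."""
    mag = np.linalg.norm(accel[["ax", "ay", "az"]].to_numpy(), axis=1)
    return pd.DataFrame({"t": accel["t"].to_numpy(),
                         "level": np.abs(mag - gravity_g)})


def detect_clicks(signal: np.ndarray, rate_hz: float, z_thresh: float = 10.0,
                  min_sep_s: float = 0.01) -> np.ndarray:
    """Threshold click detector on a band-limited (or envelope) signal.

    The signal is z-scored; peaks above ``z_thresh`` standard deviations
    separated by at least ``min_sep_s`` are click times.
    """
    x = np.asarray(signal, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.empty(0)
    z = (x - x.mean()) / sd
    peaks, _ = find_peaks(z, height=z_thresh,
                          distance=max(1, int(round(min_sep_s * rate_hz))))
    return peaks / rate_hz
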