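"""Synthetic session generator with full ground truth.

Emulates the statistical structure of a bat foraging session: repeated
smooth 3D flight trajectories separated by rest epochs, 1D place-tuned
Poisson spiking, time-compressed forward/reverse replay insertions during
rest, ripple-band LFP transients, theta bouts, an ~8 Hz wing-beat rhythm on
the accelerometer with von Mises spike-phase modulation and optional phase
precession, wing-beat-locked representational sweeps, and echolocation
click trains.

Every embedded event is recorded in a :class:`GroundTruth` object so each
downstream detector has a recoverable target.  All randomness flows from a
single ``numpy.random.default_rng`` (PCG64) seed: identical seeds give
bit-identical bundles.

Modelling choices
-----------------
* Spiking is conditionally Poisson given position and wing-beat phase with
  a multiplicative phase factor ``exp(kappa*cos(phi-mu))/I0(kappa)``, which
  keeps the mean rate invariant to ``kappa``.
* Phase precession advances the preferred phase ``mu`` linearly with
  within-field distance.
* Replays are scaled, field-ordered first-spike templates with Gaussian
  jitter (default SD 5 ms).
* Flight paths are cubic splines through a handful of control points flown
  at constant cruise speed with short sinusoidal speed ramps at take-off
  and landing.
* Background LFP is 1/f (pink) noise, giving realistic delta power for
  theta/delta ratios.
* Representational sweeps displace the position that drives place-tuned
  firing by a transient Gaussian bump locked to a fixed wing-beat phase, so
  a decoder sees the represented position sweep away from the true one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.special import i0

from flightreplay.session_io import SessionBundle

__all__ = [
    "ReplaySpec", "SwrSpec", "ThetaSpec", "ClickSpec", "SweepSpec",
    "SynthConfig", "GroundTruth", "generate_session", "embed_replay",
    "synth_wingbeat_accel", "synth_lfp", "pink_noise",
]


@dataclass
class ReplaySpec:
    """Embedded-replay parameters."""
    n_forward: int = 10
    n_reverse: int = 5
    duration_s: float = 0.3
    jitter_sd_s: float = 0.005
    spikes_per_unit: int = 2
    burst_gap_s: float = 0.006
    remote_fraction: float = 0.5


@dataclass
class SwrSpec:
    """Sharp-wave-ripple insertion parameters (rest epochs only)."""
    rate_hz: float = 0.05
    ripple_hz: float = 150.0
    envelope_sd_s: float = 0.02
    amplitude_uv: float = 200.0
    couple_to_replays: bool = True
    depth_profile: tuple = (0.5, 0.75, 1.0, 0.9, 0.75, 0.6, 0.5, 0.4)


@dataclass
class ThetaSpec:
    """Rest-epoch theta-bout insertion parameters."""
    n_bouts: int = 4
    duration_s: float = 3.0
    freq_hz: float = 8.0
    amplitude_uv: float = 150.0


@dataclass
class ClickSpec:
    """Echolocation-click generation (one candidate click per wing-beat)."""
    enabled: bool = True
    per_cycle_prob: float = 0.8
    phase_deg: float = 0.0
    jitter_s: float = 0.005
    suppress_near_sweeps_s: float = 0.0


@dataclass
class SweepSpec:
    """Wing-beat-locked representational-sweep embedding."""
    enabled: bool = False
    amplitude_m: float = 0.9
    width_s: float = 0.06          # FWHM of the Gaussian displacement bump
    phase_deg: float = 116.0
    per_cycle_prob: float = 1.0


@dataclass
class SynthConfig:
    """Full specification of a synthetic session.

    Trajectories come in reciprocal pairs (A->B then B->A) so that the
    simulated bat moves continuously; ``n_trajectories`` is rounded up to
    the next even number.
    """
    seed: int = 0
    n_trajectories: int = 2
    trajectory_length_m: float = 10.0
    path_bow_m: float = 0.8          # lateral bow of the spline paths
    flight_speed_mps: float = 3.0
    ramp_s: float = 0.3              # take-off / landing speed-ramp duration
    n_flights: int = 10              # per trajectory
    rest_gap_s: float = 12.0
    rest_gap_jitter_s: float = 2.0
    initial_rest_s: float = 10.0
    final_rest_s: float = 10.0
    n_units: int = 20                # per trajectory
    field_sd_m: float = 0.5          # Gaussian tuning-curve SD
    peak_rate_hz: float = 8.0
    baseline_rate_hz: float = 0.2
    tracking_rate_hz: float = 120.0
    accel_rate_hz: float = 500.0
    lfp_rate_hz: float = 500.0
    n_lfp_channels: int = 8
    lfp_noise_uv: float = 50.0
    wingbeat_hz: float = 8.0
    wingbeat_amp_g: float = 0.4
    accel_noise_g: float = 0.02
    tracking_noise_m: float = 0.002
    kappa: float = 0.0               # wing-beat phase-locking concentration
    mu_deg: float = 71.0
    precession_slope_deg_per_m: float = 0.0
    replay: ReplaySpec = field(default_factory=ReplaySpec)
    swr: SwrSpec = field(default_factory=SwrSpec)
    theta: ThetaSpec = field(default_factory=ThetaSpec)
    clicks: ClickSpec = field(default_factory=ClickSpec)
    sweeps: SweepSpec = field(default_factory=SweepSpec)

    def validate(self) -> None:
        if self.replay.duration_s <= 0:
            raise ValueError("replay duration must be positive")
        for name, v in (("peak_rate_hz", self.peak_rate_hz),
                        ("baseline_rate_hz", self.baseline_rate_hz),
                        ("kappa", self.kappa),
                        ("swr rate", self.swr.rate_hz)):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        min_rest = min(self.initial_rest_s, self.rest_gap_s - 3 * self.rest_gap_jitter_s)
        if self.replay.duration_s + 1.0 > max(min_rest, self.final_rest_s):
            raise ValueError("replay duration does not fit in the rest gaps")
        if self.trajectory_length_m <= self.flight_speed_mps * self.ramp_s:
            raise ValueError("trajectory shorter than the speed ramps")


@dataclass
class GroundTruth:
    """Everything the generator embedded, for recovery scoring."""
    flights: pd.DataFrame            # start, stop, t_takeoff, t_land, trajectory_id
    rests: pd.DataFrame              # start, stop
    units: pd.DataFrame              # unit_id, trajectory_id, centre_m, sd_m
    replays: pd.DataFrame            # t_start, duration_s, trajectory_id, direction,
                                     # start_dist_to_bat_m
    swr_times: np.ndarray
    theta_bouts: pd.DataFrame        # start, stop
    sweeps: pd.DataFrame             # t, phase_rad, amplitude_m, flight_idx
    clicks: np.ndarray
    trajectories: list               # per-trajectory dict: points Nx3, length_m
    wingbeat_hz: float


# ---------------------------------------------------------------------------
# geometry helpers

def _make_trajectories(cfg: SynthConfig, rng: np.random.Generator) -> list:
    """Reciprocal spline paths between perch points around a circle."""
    n = cfg.n_trajectories + (cfg.n_trajectories % 2)
    n_pairs = n // 2
    L = cfg.trajectory_length_m
    # perch points: pairs of endpoints separated by the chord length of L
    trajs = []
    for p in range(n_pairs):
        ang = 2 * np.pi * p / max(n_pairs, 1)
        a = np.array([0.0, 0.0, 1.5])
        b = a + L * 0.92 * np.array([np.cos(ang), np.sin(ang), 0.0])
        perp = np.array([-np.sin(ang), np.cos(ang), 0.0])
        for direction, bow in ((+1, cfg.path_bow_m), (-1, cfg.path_bow_m)):
            p0, p1 = (a, b) if direction > 0 else (b, a)
            u = np.linspace(0, 1, 5)
            pts = p0[None, :] + u[:, None] * (p1 - p0)[None, :]
            pts = pts + (np.sin(np.pi * u)[:, None]
                         * (direction * bow * perp + np.array([0, 0, 0.4]))[None, :])
            trajs.append(_spline_path(pts, L))
    return trajs[:n]


def _spline_path(control_points: np.ndarray, target_length_m: float) -> dict:
    """Cubic-spline path through control points, rescaled to target length."""
    u = np.linspace(0, 1, len(control_points))
    cs = CubicSpline(u, control_points, axis=0)
    uu = np.linspace(0, 1, 2000)
    xyz = cs(uu)
    seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    scale = target_length_m / arc[-1]
    xyz = xyz * scale
    arc = arc * scale
    return {"xyz": xyz, "arc": arc, "length_m": float(arc[-1]),
            "takeoff": xyz[0].copy(), "landing": xyz[-1].copy()}


def _position_at(traj: dict, dist: np.ndarray) -> np.ndarray:
    d = np.clip(dist, 0.0, traj["length_m"])
    out = np.empty((len(d), 3))
    for k in range(3):
        out[:, k] = np.interp(d, traj["arc"], traj["xyz"][:, k])
    return out


def _distance_profile(t_rel: np.ndarray, speed: float, ramp: float,
                      length: float) -> np.ndarray:
    """Distance travelled since take-off under sin^2 speed ramps."""
    cruise_len = length - speed * ramp      # ramps cover speed*ramp/2 each
    t_cruise = cruise_len / speed
    t_total = t_cruise + 2 * ramp
    d = np.empty_like(t_rel, dtype=float)
    t = np.clip(t_rel, 0.0, t_total)
    # integral of speed*sin^2(pi*t/(2*ramp)) = speed*(t/2 - ramp*sin(pi t/ramp)/(2 pi))
    in_up = t < ramp
    d[in_up] = speed * (t[in_up] / 2
                        - ramp * np.sin(np.pi * t[in_up] / ramp) / (2 * np.pi))
    mid = (~in_up) & (t < ramp + t_cruise)
    d_ramp = speed * ramp / 2
    d[mid] = d_ramp + speed * (t[mid] - ramp)
    down = t >= ramp + t_cruise
    td = t[down] - (ramp + t_cruise)
    d[down] = d_ramp + cruise_len + speed * (
        td / 2 + ramp * np.sin(np.pi * td / ramp) / (2 * np.pi))
    # symmetric decel ramp: speed*cos^2 -> integral t/2 + ramp*sin(pi t/ramp)/(2 pi)
    return d


def flight_total_duration(cfg: SynthConfig) -> float:
    cruise = (cfg.trajectory_length_m
              - cfg.flight_speed_mps * cfg.ramp_s) / cfg.flight_speed_mps
    return cruise + 2 * cfg.ramp_s


def _threshold_crossings(t_rel: np.ndarray, speed_profile: np.ndarray,
                         thresh: float) -> tuple[float, float]:
    above = speed_profile > thresh
    idx = np.nonzero(above)[0]
    return float(t_rel[idx[0]]), float(t_rel[idx[-1]])


# ---------------------------------------------------------------------------
# stream synthesis

def pink_noise(n: int, rng: np.random.Generator, exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec = spec / f ** (exponent / 2.0)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def synth_wingbeat_accel(t: np.ndarray, flights: pd.DataFrame,
                         cfg: SynthConfig, rng: np.random.Generator
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Accelerometer stream plus the true wing-beat phase per sample.

    During flight ``|a|`` oscillates at the wing-beat frequency with the
    trough at phase 0; at rest ``|a|`` is 1 g plus noise.  Phase is NaN
    outside flight.
    """
    az = np.ones_like(t)
    phase = np.full_like(t, np.nan)
    for _, fl in flights.iterrows():
        m = (t >= fl["t_takeoff"]) & (t < fl["t_land"])
        ph = 2 * np.pi * cfg.wingbeat_hz * (t[m] - fl["t_takeoff"])
        phase[m] = np.mod(ph + np.pi, 2 * np.pi) - np.pi
        az[m] = 1.0 - cfg.wingbeat_amp_g * np.cos(ph)
    noise = cfg.accel_noise_g * rng.standard_normal((len(t), 3))
    accel = pd.DataFrame({"t": t, "ax": noise[:, 0], "ay": noise[:, 1],
                          "az": az + noise[:, 2]})
    return accel, phase


def synth_lfp(t: np.ndarray, rests: pd.DataFrame, cfg: SynthConfig,
              rng: np.random.Generator
              ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """LFP matrix with pink-noise background, SWR bursts and theta bouts.

    Returns (lfp [n x n_ch] in microvolt, swr_times, theta_bouts).
    """
    n = len(t)
    lfp = np.empty((n, cfg.n_lfp_channels), dtype=float)
    for ch in range(cfg.n_lfp_channels):
        lfp[:, ch] = cfg.lfp_noise_uv * pink_noise(n, rng)

    # --- SWR times: Poisson in rest epochs, away from the edges
    swr_times = []
    for _, r in rests.iterrows():
        lo, hi = r["start"] + 0.5, r["stop"] - 0.5
        if hi <= lo:
            continue
        n_ev = rng.poisson(cfg.swr.rate_hz * (hi - lo))
        swr_times.extend(np.sort(rng.uniform(lo, hi, n_ev)))
    swr_times = np.sort(np.asarray(swr_times))
    # enforce 150 ms separation
    if swr_times.size:
        keep = np.concatenate([[True], np.diff(swr_times) > 0.15])
        swr_times = swr_times[keep]
    prof = np.asarray(cfg.swr.depth_profile[:cfg.n_lfp_channels])
    for tc in swr_times:
        w = 4 * cfg.swr.envelope_sd_s
        m = (t >= tc - w) & (t <= tc + w)
        env = np.exp(-0.5 * ((t[m] - tc) / cfg.swr.envelope_sd_s) ** 2)
        burst = cfg.swr.amplitude_uv * env * np.sin(
            2 * np.pi * cfg.swr.ripple_hz * (t[m] - tc))
        lfp[m, :] += burst[:, None] * prof[None, :]

    # --- theta bouts: fixed count spread over the longest rests
    bouts = []
    order = rests.assign(dur=rests["stop"] - rests["start"]).sort_values(
        "dur", ascending=False)
    for _, r in order.head(cfg.theta.n_bouts).iterrows():
        dur = min(cfg.theta.duration_s, (r["stop"] - r["start"]) - 1.0)
        if dur < 1.2:
            continue
        b0 = r["start"] + 0.5
        m = (t >= b0) & (t <= b0 + dur)
        ramp = np.minimum(1.0, np.minimum(t[m] - b0, b0 + dur - t[m]) / 0.25)
        wave = cfg.theta.amplitude_uv * ramp * np.sin(
            2 * np.pi * cfg.theta.freq_hz * (t[m] - b0))
        lfp[m, :] += wave[:, None]
        bouts.append({"start": b0, "stop": b0 + dur})
    theta_bouts = pd.DataFrame(bouts, columns=["start", "stop"])
    return lfp, swr_times, theta_bouts


def embed_replay(rng: np.random.Generator, ordered_unit_ids: np.ndarray,
                 t_start: float, duration_s: float, direction: str,
                 jitter_sd_s: float = 0.005, spikes_per_unit: int = 2,
                 burst_gap_s: float = 0.006) -> pd.DataFrame:
    """Insert one compressed replay as a field-ordered first-spike template.

    ``ordered_unit_ids`` lists the participating units in field order
    (take-off to landing).  Forward replays fire them in that order across
    ``duration_s``; reverse replays in the opposite order.  Each unit emits
    ``spikes_per_unit`` spikes (a short burst) and every spike gets
    independent Gaussian jitter.
    """
    n = len(ordered_unit_ids)
    if n < 2:
        raise ValueError("a replay needs at least two units")
    frac = np.arange(n) / (n - 1)
    if direction == "reverse":
        frac = frac[::-1]
    elif direction != "forward":
        raise ValueError(f"unknown direction {direction!r}")
    rows = []
    for uid, f in zip(ordered_unit_ids, frac):
        base = t_start + f * duration_s
        for k in range(spikes_per_unit):
            rows.append((int(uid),
                         base + k * burst_gap_s + rng.normal(0, jitter_sd_s)))
    return pd.DataFrame(rows, columns=["unit_id", "t"])


# ---------------------------------------------------------------------------
# main generator

def generate_session(cfg: SynthConfig) -> tuple[SessionBundle, GroundTruth]:
    """Generate a session bundle and its ground truth from ``cfg``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    trajs = _make_trajectories(cfg, rng)
    n_traj = len(trajs)
    fdur = flight_total_duration(cfg)

    # --- timeline: reciprocal pairs flown alternately, pairs round-robin
    flight_rows = []
    t_cursor = cfg.initial_rest_s
    order = []
    for rep in range(cfg.n_flights):
        for pair in range(n_traj // 2):
            order.extend([2 * pair, 2 * pair + 1])
    for traj_id in order:
        gap = max(3.0, cfg.rest_gap_s + cfg.rest_gap_jitter_s * rng.standard_normal())
        flight_rows.append({"t_takeoff": t_cursor, "t_land": t_cursor + fdur,
                            "trajectory_id": traj_id})
        t_cursor += fdur + gap
    T = flight_rows[-1]["t_land"] + cfg.final_rest_s if flight_rows \
        else cfg.initial_rest_s + cfg.final_rest_s
    flights = pd.DataFrame(flight_rows, columns=["t_takeoff", "t_land",
                                                 "trajectory_id"])

    # threshold-crossing boundaries of the true speed profile
    tt = np.arange(0, fdur, 1e-3)
    dd = _distance_profile(tt, cfg.flight_speed_mps, cfg.ramp_s,
                           cfg.trajectory_length_m)
    sp = np.gradient(dd, tt)
    c0, c1 = _threshold_crossings(tt, sp, 0.5)
    flights["start"] = flights["t_takeoff"] + c0
    flights["stop"] = flights["t_takeoff"] + c1

    rest_rows = []
    prev = 0.0
    for _, fl in flights.iterrows():
        if fl["t_takeoff"] > prev:
            rest_rows.append({"start": prev, "stop": fl["t_takeoff"]})
        prev = fl["t_land"]
    if T > prev:
        rest_rows.append({"start": prev, "stop": T})
    rests = pd.DataFrame(rest_rows, columns=["start", "stop"])

    # --- tracking (120 Hz)
    t_track = np.arange(0, T, 1.0 / cfg.tracking_rate_hz)
    pos = np.empty((len(t_track), 3))
    # rest position = last landing point (initial rest at first take-off perch)
    if len(flights):
        pos[:] = trajs[int(flights.iloc[0]["trajectory_id"])]["takeoff"]
    else:
        pos[:] = trajs[0]["takeoff"]
    for _, fl in flights.iterrows():
        traj = trajs[int(fl["trajectory_id"])]
        m = (t_track >= fl["t_takeoff"]) & (t_track < fl["t_land"])
        d = _distance_profile(t_track[m] - fl["t_takeoff"], cfg.flight_speed_mps,
                              cfg.ramp_s, cfg.trajectory_length_m)
        pos[m] = _position_at(traj, d)
        pos[t_track >= fl["t_land"]] = traj["landing"]
    pos = pos + cfg.tracking_noise_m * rng.standard_normal(pos.shape)
    tracking = pd.DataFrame({"t": t_track, "x": pos[:, 0], "y": pos[:, 1],
                             "z": pos[:, 2]})

    # --- accel + wing-beat phase (500 Hz)
    t_acc = np.arange(0, T, 1.0 / cfg.accel_rate_hz)
    accel, wb_phase = synth_wingbeat_accel(t_acc, flights, cfg, rng)

    # --- units
    unit_rows = []
    uid = 0
    for k in range(n_traj):
        L = trajs[k]["length_m"]
        centres = np.linspace(0.06 * L, 0.94 * L, cfg.n_units)
        centres = centres + rng.normal(0, 0.02, cfg.n_units)
        for c in centres:
            unit_rows.append({"unit_id": uid, "trajectory_id": k,
                              "centre_m": float(c), "sd_m": cfg.field_sd_m})
            uid += 1
    units = pd.DataFrame(unit_rows)

    # --- sweeps: per flight, bumps locked to a wing-beat phase
    sweep_rows = []
    sweep_offset = np.zeros_like(t_acc)
    if cfg.sweeps.enabled:
        ph0 = np.deg2rad(cfg.sweeps.phase_deg)
        sd = cfg.sweeps.width_s / 2.3548
        for fi, fl in flights.iterrows():
            n_cycles = int(np.floor(fdur * cfg.wingbeat_hz))
            for k in range(n_cycles):
                tk = fl["t_takeoff"] + (ph0 / (2 * np.pi) + k) / cfg.wingbeat_hz
                frac = _distance_profile(np.array([tk - fl["t_takeoff"]]),
                                         cfg.flight_speed_mps, cfg.ramp_s,
                                         cfg.trajectory_length_m)[0] \
                    / cfg.trajectory_length_m
                if frac < 0.17 or frac > 0.83:
                    continue
                if rng.uniform() > cfg.sweeps.per_cycle_prob:
                    continue
                m = (t_acc >= tk - 4 * sd) & (t_acc <= tk + 4 * sd)
                sweep_offset[m] += cfg.sweeps.amplitude_m * np.exp(
                    -0.5 * ((t_acc[m] - tk) / sd) ** 2)
                sweep_rows.append({"t": tk, "phase_rad": float(
                    np.mod(ph0 + np.pi, 2 * np.pi) - np.pi),
                    "amplitude_m": cfg.sweeps.amplitude_m, "flight_idx": fi})
    sweeps_gt = pd.DataFrame(
        sweep_rows, columns=["t", "phase_rad", "amplitude_m", "flight_idx"])

    # --- spikes: baseline Poisson + in-flight place/phase-modulated Poisson
    mu0 = np.deg2rad(cfg.mu_deg)
    slope = np.deg2rad(cfg.precession_slope_deg_per_m)
    spike_frames = []
    dt = 1.0 / cfg.accel_rate_hz
    # precompute per-flight distance along path on the accel grid
    flight_masks = []
    for _, fl in flights.iterrows():
        m = (t_acc >= fl["t_takeoff"]) & (t_acc < fl["t_land"])
        d = _distance_profile(t_acc[m] - fl["t_takeoff"], cfg.flight_speed_mps,
                              cfg.ramp_s, cfg.trajectory_length_m)
        flight_masks.append((int(fl["trajectory_id"]), m, d))
    for _, u in units.iterrows():
        times = []
        # baseline over whole session
        n_b = rng.poisson(cfg.baseline_rate_hz * T)
        times.append(rng.uniform(0, T, n_b))
        for traj_id, m, d in flight_masks:
            if traj_id != int(u["trajectory_id"]):
                continue
            d_eff = d + sweep_offset[m]
            lam = cfg.peak_rate_hz * np.exp(
                -0.5 * ((d_eff - u["centre_m"]) / u["sd_m"]) ** 2)
            if cfg.kappa > 0:
                mu = mu0 + slope * (d - u["centre_m"])
                lam = lam * np.exp(
                    cfg.kappa * np.cos(wb_phase[m] - mu)) / i0(cfg.kappa)
            counts = rng.poisson(lam * dt)
            idx = np.repeat(np.nonzero(counts)[0], counts[counts > 0])
            times.append(t_acc[m][idx] + rng.uniform(0, dt, idx.size))
        tt_u = np.sort(np.concatenate(times))
        spike_frames.append(pd.DataFrame({"unit_id": int(u["unit_id"]),
                                          "t": tt_u}))

    # --- replays during rest
    rp = cfg.replay
    replay_rows = []
    n_total = rp.n_forward + rp.n_reverse
    directions = np.array(["forward"] * rp.n_forward + ["reverse"] * rp.n_reverse)
    rng.shuffle(directions)
    usable = rests[(rests["stop"] - rests["start"]) > rp.duration_s + 2.0]
    usable = usable.reset_index(drop=True)
    if n_total > 0 and len(usable) == 0:
        raise ValueError("no rest interval long enough for the requested replays")
    placed: list[float] = []
    for i in range(n_total):
        r = usable.iloc[i % len(usable)]
        lo = r["start"] + 1.0
        hi = r["stop"] - 1.0 - rp.duration_s
        t0 = rng.uniform(lo, max(lo + 1e-6, hi))
        for _ in range(50):   # keep embedded events well separated
            if not placed or min(abs(t0 - p) for p in placed) > 1.5:
                break
            t0 = rng.uniform(lo, max(lo + 1e-6, hi))
        placed.append(t0)
        # bat position during this rest = perch point at that time
        bat_xyz = pos[np.searchsorted(t_track, t0) - 1]
        # choose local vs remote trajectory
        remote = rng.uniform() < rp.remote_fraction
        direction = directions[i]
        dists = []
        for k in range(n_traj):
            start_pt = (trajs[k]["takeoff"] if direction == "forward"
                        else trajs[k]["landing"])
            dists.append(np.linalg.norm(bat_xyz - start_pt))
        dists = np.asarray(dists)
        traj_id = int(np.argmax(dists) if remote else np.argmin(dists))
        uu = units[units["trajectory_id"] == traj_id].sort_values("centre_m")
        ev = embed_replay(rng, uu["unit_id"].to_numpy(), t0, rp.duration_s,
                          direction, rp.jitter_sd_s, rp.spikes_per_unit,
                          rp.burst_gap_s)
        spike_frames.append(ev)
        replay_rows.append({"t_start": t0, "duration_s": rp.duration_s,
                            "trajectory_id": traj_id, "direction": direction,
                            "start_dist_to_bat_m": float(dists[traj_id])})
    replays = pd.DataFrame(replay_rows, columns=[
        "t_start", "duration_s", "trajectory_id", "direction",
        "start_dist_to_bat_m"])

    if not spike_frames:
        spike_frames = [pd.DataFrame({"unit_id": pd.Series(dtype=int),
                                      "t": pd.Series(dtype=float)})]
    spikes = pd.concat(spike_frames, ignore_index=True)
    spikes = spikes.sort_values(["t", "unit_id"], kind="mergesort"
                                ).reset_index(drop=True)
    spikes = spikes[(spikes["t"] >= 0) & (spikes["t"] < T)]

    # --- LFP
    t_lfp = np.arange(0, T, 1.0 / cfg.lfp_rate_hz)
    lfp, swr_times, theta_bouts = synth_lfp(t_lfp, rests, cfg, rng)
    if cfg.swr.couple_to_replays and len(replays):
        prof = np.asarray(cfg.swr.depth_profile[:cfg.n_lfp_channels])
        extra = replays["t_start"].to_numpy() + cfg.replay.duration_s / 2
        for tc in extra:
            w = 4 * cfg.swr.envelope_sd_s
            m = (t_lfp >= tc - w) & (t_lfp <= tc + w)
            env = np.exp(-0.5 * ((t_lfp[m] - tc) / cfg.swr.envelope_sd_s) ** 2)
            burst = cfg.swr.amplitude_uv * env * np.sin(
                2 * np.pi * cfg.swr.ripple_hz * (t_lfp[m] - tc))
            lfp[m, :] += burst[:, None] * prof[None, :]
        swr_times = np.sort(np.concatenate([swr_times, extra]))

    # --- clicks
    click_times = np.empty(0)
    if cfg.clicks.enabled:
        ck = []
        ph0 = np.deg2rad(cfg.clicks.phase_deg)
        for _, fl in flights.iterrows():
            n_cycles = int(np.floor(fdur * cfg.wingbeat_hz))
            for k in range(n_cycles):
                if rng.uniform() > cfg.clicks.per_cycle_prob:
                    continue
                tk = (fl["t_takeoff"] + (np.mod(ph0, 2 * np.pi) / (2 * np.pi) + k)
                      / cfg.wingbeat_hz + rng.normal(0, cfg.clicks.jitter_s))
                ck.append(tk)
        click_times = np.sort(np.asarray(ck))
        if cfg.clicks.suppress_near_sweeps_s > 0 and len(sweeps_gt):
            st = sweeps_gt["t"].to_numpy()
            keep = np.array([np.min(np.abs(st - c)) >
                             cfg.clicks.suppress_near_sweeps_s
                             for c in click_times])
            click_times = click_times[keep]

    meta = {"tracking_rate_hz": cfg.tracking_rate_hz,
            "accel_rate_hz": cfg.accel_rate_hz,
            "lfp_rate_hz": cfg.lfp_rate_hz,
            "gravity_g": 1.0,
            "rng": "PCG64", "seed": cfg.seed}
    bundle = SessionBundle(tracking=tracking, accel=accel,
                           lfp=lfp.astype(np.float32), lfp_rate=cfg.lfp_rate_hz,
                           spikes=spikes, clicks=click_times, meta=meta)
    truth = GroundTruth(flights=flights, rests=rests, units=units,
                        replays=replays, swr_times=swr_times,
                        theta_bouts=theta_bouts, sweeps=sweeps_gt,
                        clicks=click_times, trajectories=trajs,
                        wingbeat_hz=cfg.wingbeat_hz)
    return bundle, truth


def generate_rest_replay_trains(rng: np.random.Generator, n_units: int = 15,
                                length_m: float = 10.0, n_replays: int = 10,
                                duration_s: float = 0.3,
                                direction: str = "forward",
                                baseline_rate_hz: float = 0.2,
                                jitter_sd_s: float = 0.005,
                                spacing_s: float = 3.0):
    """Rest-only spike trains with embedded replays for one trajectory.

    A lightweight fixture for replay-dynamics analyses that do not need
    tracking/LFP streams: ``n_units`` place cells with centres evenly
    spaced along a ``length_m`` track fire at ``baseline_rate_hz`` during
    one long rest, with ``n_replays`` compressed templates embedded
    ``spacing_s`` apart.

    Returns (spike_trains dict, rests DataFrame, centres array,
    replay start times array).
    """
    T = (n_replays + 1) * spacing_s
    centres = np.linspace(0.06 * length_m, 0.94 * length_m, n_units)
    frames = []
    for uid in range(n_units):
        n_b = rng.poisson(baseline_rate_hz * T)
        frames.append(pd.DataFrame({"unit_id": uid,
                                    "t": rng.uniform(0, T, n_b)}))
    t_starts = spacing_s * (0.5 + np.arange(n_replays))
    for t0 in t_starts:
        frames.append(embed_replay(rng, np.arange(n_units), t0, duration_s,
                                   direction, jitter_sd_s))
    spikes = pd.concat(frames, ignore_index=True)
    trains = {uid: np.sort(spikes[spikes["unit_id"] == uid]["t"].to_numpy())
              for uid in range(n_units)}
    rests = pd.DataFrame({"start": [0.0], "stop": [T]})
    return trains, rests, centres, t_starts


def default_config(**overrides) -> SynthConfig:
    """A 10-minute-scale demo configuration; keyword overrides applied."""
    cfg = SynthConfig()
    return replace(cfg, **overrides) if overrides else cfg
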