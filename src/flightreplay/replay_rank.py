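"""Spike-sequence replay detection and replay-dynamics analyses.

Candidate replays are excursions of the pooled place-cell spike density
(Gaussian kernel, SD 100 ms) above two standard deviations during rest,
50 ms to 1 s long, with events closer than 200 ms joined.  Each candidate
gets a rank-order score: the Spearman correlation between the field-centre
order of the participating cells and their first-spike times, with a
permutation p value from 100 random reassignments of cell identities
(p = fraction of shuffles whose |rho| exceeds the observed, strictly
greater, no +1 correction).

Retained replays satisfy |rho| > 0.2, more than 5 active cells, at least
30% of the trajectory's place cells active, and p < 0.05; direction is
forward when rho > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, ranksums, spearmanr, wilcoxon

__all__ = [
    "CandidateEvent", "RankReplay", "spike_density_candidates",
    "rank_order_test", "replay_speed_rank", "score_candidates",
    "replay_rate_analysis", "classify_locality", "categorize_vs_behaviour",
    "duration_length_scaling",
]


@dataclass
class CandidateEvent:
    start: float
    stop: float
    peak_density: float
    unit_ids: np.ndarray             # active units
    first_spike_t: np.ndarray        # first spike per active unit
    trajectory_id: int = -1

    @property
    def duration(self) -> float:
        return self.stop - self.start

    @property
    def n_active(self) -> int:
        return len(self.unit_ids)


@dataclass
class RankReplay:
    event: CandidateEvent
    rho: float
    p: float
    active_fraction: float
    direction: str                   # forward | reverse
    speed_mps: float = np.nan
    bat_xyz: np.ndarray = field(default=None)
    delta_s_m: float = np.nan
    delta_t_s: float = np.nan
    locality: str = ""
    behaviour_category: str = ""

    @property
    def t_centre(self) -> float:
        return 0.5 * (self.event.start + self.event.stop)


def spike_density_candidates(spike_trains: dict[int, np.ndarray],
                             rests: pd.DataFrame, session_T: float,
                             kernel_sd_s: float = 0.1, z_thresh: float = 2.0,
                             min_dur_s: float = 0.05, max_dur_s: float = 1.0,
                             join_s: float = 0.2, grid_dt: float = 0.005
                             ) -> list[CandidateEvent]:
    """Candidate replay events from the pooled spike density during rest.

    The density z-score baseline (mean and SD) is computed over rest
    samples only, so in-flight firing cannot inflate the threshold.
    """
    all_spikes = np.sort(np.concatenate(
        [v for v in spike_trains.values()] or [np.empty(0)]))
    if all_spikes.size == 0:
        return []
    t_grid = np.arange(0.0, session_T, grid_dt)
    counts = np.histogram(all_spikes, bins=np.append(t_grid, session_T))[0]
    sd_bins = kernel_sd_s / grid_dt
    k = np.arange(-int(4 * sd_bins), int(4 * sd_bins) + 1)
    kern = np.exp(-0.5 * (k / sd_bins) ** 2)
    kern /= kern.sum() * grid_dt
    density = np.convolve(counts.astype(float), kern, mode="same")
    rest_mask = np.zeros(len(t_grid), dtype=bool)
    for _, r in rests.iterrows():
        rest_mask |= (t_grid >= r["start"]) & (t_grid < r["stop"])
    if not rest_mask.any():
        return []
    mu = density[rest_mask].mean()
    sd = density[rest_mask].std()
    if sd == 0:
        return []
    z = (density - mu) / sd
    above = (z > z_thresh) & rest_mask
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(above))
    runs = [(s, e) for s, e in zip(starts, stops)
            if min_dur_s <= (e - s) * grid_dt <= max_dur_s]
    joined = []
    for s, e in runs:
        if joined and (s - joined[-1][1]) * grid_dt < join_s:
            joined[-1] = (joined[-1][0], e)
        else:
            joined.append((s, e))
    events = []
    for s, e in joined:
        t0, t1 = t_grid[s], t_grid[min(e, len(t_grid) - 1)]
        uids, firsts = [], []
        for uid, st in spike_trains.items():
            m = st[(st >= t0) & (st < t1)]
            if m.size:
                uids.append(uid)
                firsts.append(m[0])
        if not uids:
            continue
        events.append(CandidateEvent(
            start=float(t0), stop=float(t1),
            peak_density=float(z[s:e].max()),
            unit_ids=np.asarray(uids), first_spike_t=np.asarray(firsts)))
    return events


def rank_order_test(event: CandidateEvent, field_order: dict[int, int],
                    n_shuffle: int = 100,
                    rng: np.random.Generator | None = None
                    ) -> tuple[float, float]:
    """Spearman rho between field-centre rank and first-spike time, with a
    cell-identity permutation p value.

    ``field_order`` maps unit_id -> rank of the unit's field centre along
    the trajectory (take-off = 0).  Returns (rho, p); rho is NaN when the
    correlation is undefined (all ranks tie).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ranks = np.asarray([field_order[u] for u in event.unit_ids], dtype=float)
    times = np.asarray(event.first_spike_t, dtype=float)
    if len(ranks) < 2 or np.all(ranks == ranks[0]):
        return np.nan, 1.0
    rho = spearmanr(ranks, times)[0]
    if not np.isfinite(rho):
        return np.nan, 1.0
    count = 0
    for _ in range(n_shuffle):
        perm = rng.permutation(ranks)
        rs = spearmanr(perm, times)[0]
        if np.isfinite(rs) and abs(rs) > abs(rho):
            count += 1
    return float(rho), count / n_shuffle


def replay_speed_rank(event: CandidateEvent, field_order: dict[int, int],
                      trajectory_span_m: float, n_place_cells: int) -> float:
    """Replay speed = (neurons per second) x (metres per neuron).

    Neurons/s is the inverse slope of a least-squares line through the
    first-spike times ordered by activation index; metres/neuron is the
    distance between the outermost place cells divided by the number of
    place cells on the trajectory.
    """
    times = np.sort(np.asarray(event.first_spike_t, dtype=float))
    if len(times) < 3 or n_place_cells == 0:
        return np.nan
    idx = np.arange(len(times), dtype=float)
    slope = np.polyfit(idx, times, 1)[0]     # s per neuron
    if slope <= 0:
        return np.nan
    neurons_per_s = 1.0 / slope
    metres_per_neuron = trajectory_span_m / n_place_cells
    return float(neurons_per_s * metres_per_neuron)


def score_candidates(events: list[CandidateEvent],
                     field_order: dict[int, int], n_place_cells: int,
                     trajectory_span_m: float, n_shuffle: int = 100,
                     rho_min: float = 0.2, min_active: int = 5,
                     active_frac_min: float = 0.3, p_max: float = 0.05,
                     rng: np.random.Generator | None = None
                     ) -> list[RankReplay]:
    """Run the rank-order test on every candidate and keep good replays."""
    if rng is None:
        rng = np.random.default_rng(0)
    out = []
    for ev in events:
        known = np.isin(ev.unit_ids, list(field_order.keys()))
        sub = CandidateEvent(ev.start, ev.stop, ev.peak_density,
                             ev.unit_ids[known], ev.first_spike_t[known],
                             ev.trajectory_id)
        rho, p = rank_order_test(sub, field_order, n_shuffle, rng)
        if not np.isfinite(rho):
            continue
        frac = sub.n_active / max(n_place_cells, 1)
        if (abs(rho) > rho_min and sub.n_active > min_active
                and frac >= active_frac_min and p < p_max):
            speed = replay_speed_rank(sub, field_order, trajectory_span_m,
                                      n_place_cells)
            out.append(RankReplay(event=sub, rho=rho, p=p,
                                  active_fraction=frac,
                                  direction="forward" if rho > 0 else "reverse",
                                  speed_mps=speed))
    return out


# ---------------------------------------------------------------------------
# replay-dynamics analyses

def replay_rate_analysis(replay_times: dict[int, np.ndarray],
                         flights: pd.DataFrame, rests: pd.DataFrame,
                         window_s: float = 30.0) -> pd.DataFrame:
    """Replay rate per minute in peri-flight rest (within ``window_s`` of a
    flight) versus remaining rest, per trajectory, plus a Wilcoxon
    signed-rank test across trajectories.

    Returns a DataFrame with one row per trajectory and attrs
    ``{'wilcoxon_p': ...}``.
    """
    peri = []
    for _, fl in flights.iterrows():
        peri.append((fl["start"] - window_s, fl["start"]))
        peri.append((fl["stop"], fl["stop"] + window_s))

    def _class_time() -> tuple[float, float]:
        dt = 0.25
        grid = []
        for _, r in rests.iterrows():
            grid.append(np.arange(r["start"], r["stop"], dt))
        grid = np.concatenate(grid) if grid else np.empty(0)
        isperi = np.zeros(len(grid), dtype=bool)
        for a, b in peri:
            isperi |= (grid >= a) & (grid < b)
        return isperi.sum() * dt, (~isperi).sum() * dt

    t_peri, t_rest = _class_time()
    rows = []
    for traj, times in replay_times.items():
        times = np.asarray(times)
        n_peri = 0
        for a, b in peri:
            n_peri += int(np.sum((times >= a) & (times < b)))
        n_rest = len(times) - n_peri
        rows.append({"trajectory_id": traj,
                     "rate_peri_per_min": 60.0 * n_peri / max(t_peri, 1e-9),
                     "rate_rest_per_min": 60.0 * n_rest / max(t_rest, 1e-9)})
    df = pd.DataFrame(rows)
    if len(df) >= 2 and not np.allclose(df["rate_peri_per_min"],
                                        df["rate_rest_per_min"]):
        df.attrs["wilcoxon_p"] = float(wilcoxon(
            df["rate_peri_per_min"], df["rate_rest_per_min"])[1])
    else:
        df.attrs["wilcoxon_p"] = np.nan
    return df


def classify_locality(replay: RankReplay, takeoff_xyz: np.ndarray,
                      landing_xyz: np.ndarray, flights: pd.DataFrame,
                      trajectory_id: int, ds_thresh_m: float,
                      dt_thresh_s: float) -> RankReplay:
    """Classify a replay as local or remote.

    delta-s is the distance between the bat at replay time and the start
    location of the replayed motion: the take-off point for forward events,
    the landing point for reverse events.  delta-t is the interval to the
    nearest same-trajectory take-off (forward) or landing (reverse).  The
    event is local when both are below threshold.
    """
    ref = takeoff_xyz if replay.direction == "forward" else landing_xyz
    ds = float(np.linalg.norm(np.asarray(replay.bat_xyz) - np.asarray(ref)))
    same = flights[flights["trajectory_id"] == trajectory_id]
    col = "start" if replay.direction == "forward" else "stop"
    if len(same):
        dtv = float(np.min(np.abs(same[col].to_numpy() - replay.t_centre)))
    else:
        dtv = np.inf
    replay.delta_s_m = ds
    replay.delta_t_s = dtv
    replay.locality = ("local" if ds <= ds_thresh_m and dtv <= dt_thresh_s
                       else "remote")
    return replay


def categorize_vs_behaviour(replays: list[tuple[float, int]],
                            flights: pd.DataFrame, min_replays_per_traj: int = 0
                            ) -> tuple[pd.DataFrame, float]:
    """Categorize each replay as previous / next / other relative to the
    flight sequence.

    ``replays`` is a list of (time, trajectory_id).  Events replaying both
    the previous and the next flight's trajectory (loops) are excluded, as
    are events before the first or after the last flight.  Returns the
    per-replay table and the session chance level (1 / number of distinct
    flight paths).
    """
    fl = flights.sort_values("start").reset_index(drop=True)
    n_types = fl["trajectory_id"].nunique()
    chance = 1.0 / n_types if n_types else np.nan
    if min_replays_per_traj > 0:
        counts = pd.Series([tr for _, tr in replays]).value_counts()
        ok_traj = set(counts[counts > min_replays_per_traj].index)
    else:
        ok_traj = None
    rows = []
    for t, traj in replays:
        if ok_traj is not None and traj not in ok_traj:
            continue
        if t < fl["start"].iloc[0] or t > fl["stop"].iloc[-1]:
            continue
        prev_fl = fl[fl["stop"] <= t]
        next_fl = fl[fl["start"] >= t]
        if len(prev_fl) == 0 or len(next_fl) == 0:
            continue
        prev_traj = int(prev_fl.iloc[-1]["trajectory_id"])
        next_traj = int(next_fl.iloc[0]["trajectory_id"])
        if traj == prev_traj and traj == next_traj:
            continue                 # overlapping-loop case, excluded
        if traj == prev_traj:
            cat = "previous"
        elif traj == next_traj:
            cat = "next"
        else:
            cat = "other"
        rows.append({"t": t, "trajectory_id": traj, "category": cat})
    return pd.DataFrame(rows, columns=["t", "trajectory_id", "category"]), chance


def duration_length_scaling(per_cluster: pd.DataFrame
                            ) -> tuple[pd.DataFrame, dict]:
    """Replay duration and speed versus trajectory length across clusters.

    ``per_cluster`` needs columns ``cluster_id, length_m, mean_duration_s,
    mean_speed_mps, group`` (group in {'short','long'}).  Returns group
    summary plus rank-sum tests and the Pearson correlation of duration
    with length.
    """
    stats: dict = {}
    groups = per_cluster["group"].unique()
    summary = per_cluster.groupby("group").agg(
        mean_duration_s=("mean_duration_s", "mean"),
        mean_speed_mps=("mean_speed_mps", "mean"),
        n=("cluster_id", "count")).reset_index()
    if len(groups) < 2:
        stats["warning"] = "single group; tests skipped"
        return summary, stats
    a = per_cluster[per_cluster["group"] == "short"]
    b = per_cluster[per_cluster["group"] == "long"]
    stats["duration_ranksum_p"] = float(
        ranksums(a["mean_duration_s"], b["mean_duration_s"])[1])
    stats["speed_ranksum_p"] = float(
        ranksums(a["mean_speed_mps"], b["mean_speed_mps"])[1])
    r, p = pearsonr(per_cluster["length_m"], per_cluster["mean_duration_s"])
    stats["duration_length_pearson_r"] = float(r)
    stats["duration_length_pearson_p"] = float(p)
    return summary, stats
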