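"""End-to-end orchestration: behaviour -> LFP / place fields ->
replay detectors / wing-beat -> sweeps, with result tables and a
ground-truth recovery report.

Every stage is a plain function on in-memory objects so the stages are
individually usable; :func:`run_pipeline` wires them together, writes CSV
tables and a run log, and is fully deterministic given (config, seed).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from flightreplay import behavior, lfp as lfpmod, place_fields as pf
from flightreplay import replay_bayes as rb, replay_rank as rr
from flightreplay import sweeps as sw, wingbeat as wb
from flightreplay.session_io import SessionBundle, read_session

__all__ = ["PipelineResults", "analyze_behavior", "analyze_place_fields",
           "analyze_replays_rank", "analyze_replays_bayes",
           "analyze_wingbeat", "analyze_sweeps", "run_pipeline",
           "recovery_report", "match_events"]


@dataclass
class PipelineResults:
    behavior: dict = field(default_factory=dict)
    lfp: dict = field(default_factory=dict)
    fields: dict = field(default_factory=dict)
    rank: dict = field(default_factory=dict)
    bayes: dict = field(default_factory=dict)
    wingbeat: dict = field(default_factory=dict)
    sweeps: dict = field(default_factory=dict)


def _flight_df(flights: list[behavior.FlightSegment]) -> pd.DataFrame:
    return pd.DataFrame([{"start": f.start, "stop": f.stop,
                          "duration_s": f.duration, "length_m": f.length_m}
                         for f in flights],
                        columns=["start", "stop", "duration_s", "length_m"])


def analyze_behavior(bundle: SessionBundle, linkage_m: float = 1.0) -> dict:
    flights, rests = behavior.segment_flights(bundle.tracking)
    clusters, labels = behavior.cluster_flights(flights, linkage_m)
    turns = [behavior.detect_turns(f) for f in flights]
    lin = [behavior.linearize_flight(f) for f in flights]
    return {"flights": flights, "rests": rests, "clusters": clusters,
            "labels": labels, "turns": turns, "lin": lin,
            "flight_df": _flight_df(flights)}


def analyze_lfp(bundle: SessionBundle, behav: dict) -> dict:
    fdf = behav["flight_df"]
    swr = lfpmod.detect_swr(bundle.lfp, bundle.lfp_rate, fdf)
    ch = lfpmod.select_theta_channel(bundle.lfp, bundle.lfp_rate)
    x = np.asarray(bundle.lfp[:, ch], dtype=float)
    bouts = lfpmod.detect_theta_bouts(x, bundle.lfp_rate)
    flight_theta = []
    for _, fl in fdf.iterrows():
        flight_theta.append(lfpmod.classify_flight_theta(
            x, bundle.lfp_rate, fl["start"], fl["stop"]))
    return {"swr": swr, "theta_bouts": bouts, "theta_channel": ch,
            "flight_theta": flight_theta}


def analyze_place_fields(bundle: SessionBundle, behav: dict) -> dict:
    """Per-cluster 1D fields and place-cell classification for all units."""
    trains = bundle.spike_trains()
    out = {}
    for cl in behav["clusters"]:
        lin = [behav["lin"][i] for i in cl.members]
        L = cl.mean_length_m
        fields, cells = {}, []
        for uid, st in trains.items():
            try:
                f = pf.compute_field(st, lin, L)
            except ValueError:
                continue
            f.is_place_cell = pf.classify_place_cell(f)
            fields[uid] = f
            if f.is_place_cell:
                cells.append(uid)
        out[cl.cluster_id] = {"fields": fields, "place_cells": cells,
                              "length_m": L}
    return out


def analyze_replays_rank(bundle: SessionBundle, behav: dict, fields: dict,
                         seed: int = 0, n_shuffle: int = 100) -> dict:
    """Rank-order replay detection per trajectory cluster.

    When a session has several clusters, events overlapping in time are
    assigned to the cluster giving the highest |rho|.
    """
    trains = bundle.spike_trains()
    rests = behav["rests"]
    T = bundle.duration()
    per_cluster: dict[int, list[rr.RankReplay]] = {}
    for cid, info in fields.items():
        cells = info["place_cells"]
        if len(cells) < 2:
            per_cluster[cid] = []
            continue
        rng = np.random.default_rng((seed, cid))
        centres = {u: info["fields"][u].centre_m for u in cells}
        order = {u: int(i) for i, u in
                 enumerate(sorted(cells, key=lambda u: centres[u]))}
        span = max(centres.values()) - min(centres.values())
        cand = rr.spike_density_candidates(
            {u: trains[u] for u in cells}, rests, T)
        reps = rr.score_candidates(cand, order, len(cells), span,
                                   n_shuffle=n_shuffle, rng=rng)
        for r in reps:
            r.event.trajectory_id = cid
        per_cluster[cid] = reps
    # cross-cluster assignment by |rho| for overlapping events
    allreps = [r for reps in per_cluster.values() for r in reps]
    allreps.sort(key=lambda r: r.t_centre)
    kept = []
    for r in allreps:
        if kept and abs(r.t_centre - kept[-1].t_centre) < 0.1:
            if abs(r.rho) > abs(kept[-1].rho):
                kept[-1] = r
        else:
            kept.append(r)
    return {"per_cluster": per_cluster, "replays": kept}


def analyze_replays_bayes(bundle: SessionBundle, behav: dict, fields: dict,
                          seed: int = 0, n_shuffle: int = 100) -> dict:
    trains = bundle.spike_trains()
    rests = behav["rests"]
    out = {}
    events = []
    for cid, info in fields.items():
        cells = info["place_cells"]
        if len(cells) < 5:
            out[cid] = []
            continue
        cl = next(c for c in behav["clusters"] if c.cluster_id == cid)
        lin = [behav["lin"][i] for i in cl.members]
        resp = rb.compute_responses({u: trains[u] for u in cells}, lin,
                                    info["length_m"], cid, n_bins=30)
        post = rb.decode_session({u: trains[u] for u in cells}, resp, rests)
        rng = np.random.default_rng((seed, 1000 + cid))
        evs = rb.detect_decoded_replays(post, rng, n_shuffle=n_shuffle)
        out[cid] = evs
        events.extend((cid, e) for e in evs)
    return {"per_cluster": out, "replays": events}


def analyze_wingbeat(bundle: SessionBundle, behav: dict, fields: dict,
                     seed: int = 0) -> dict:
    phases = wb.wingbeat_phase(bundle.accel)
    fdf = behav["flight_df"]
    t_acc = bundle.accel["t"].to_numpy()
    fmask = np.zeros(len(t_acc), dtype=bool)
    for _, fl in fdf.iterrows():
        fmask |= (t_acc >= fl["start"]) & (t_acc < fl["stop"])
    pool = phases.phase[fmask]
    trains = bundle.spike_trains()
    rng = np.random.default_rng((seed, 7))
    results = []
    for uid, st in trains.items():
        m = np.zeros(len(st), dtype=bool)
        for _, fl in fdf.iterrows():
            m |= (st >= fl["start"]) & (st < fl["stop"])
        ph = phases.phase_at(st[m])
        res = wb.spike_phase_stats(ph, uid)
        if len(ph) >= 30:
            r, z, p = wb.resultant_and_rayleigh(ph, pool, rng=rng)
            res.shuffle_p = p
        results.append(res)
    locked = [r for r in results if r.is_phase_locked]
    pop = None
    if len(locked) >= 2:
        pop = wb.population_phase_profile(locked, pool, rng=rng)
    return {"phases": phases, "units": results, "locked": locked,
            "population": pop}


def analyze_sweeps(bundle: SessionBundle, behav: dict, fields: dict,
                   phases: wb.WingbeatPhaseSeries, seed: int = 0) -> dict:
    trains = bundle.spike_trains()
    rng = np.random.default_rng((seed, 13))
    all_results, all_sweeps = [], []
    for cid, info in fields.items():
        stable = [u for u, f in info["fields"].items()
                  if np.isfinite(f.stability) and f.stability > 0.6]
        if len(stable) < 5:
            continue
        cl = next(c for c in behav["clusters"] if c.cluster_id == cid)
        lin = [behav["lin"][i] for i in cl.members]
        n_bins = max(2, int(round(info["length_m"] / 0.15)))
        resp = rb.compute_responses({u: trains[u] for u in stable}, lin,
                                    info["length_m"], cid, n_bins=n_bins)
        for i in cl.members:
            try:
                res = sw.decode_flight({u: trains[u] for u in stable}, resp,
                                       behav["lin"][i], flight_idx=i)
            except ValueError:
                continue
            all_results.append(res)
            all_sweeps.extend(sw.detect_sweeps(res, phases))
    cyc = None
    qc = [r for r in all_results if r.qc_pass]
    if qc:
        try:
            cyc = sw.cycle_average_error(qc, phases, rng)
        except ValueError:
            cyc = None
    return {"flights": all_results, "sweeps": all_sweeps, "cycle_error": cyc}


# ---------------------------------------------------------------------------

def run_pipeline(session_dir: str | Path, out_dir: str | Path, seed: int = 0,
                 linkage_m: float = 1.0, n_shuffle: int = 100,
                 stages: set | None = None) -> PipelineResults:
    """Run all stages on a session directory and write result tables."""
    if stages is None:
        stages = {"behavior", "lfp", "place_fields", "replay_rank",
                  "replay_bayes", "wingbeat", "sweeps"}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = []
    t0 = time.time()

    def _log(msg):
        log.append(f"[{time.time() - t0:8.1f}s] {msg}")

    bundle = read_session(session_dir)
    results = PipelineResults()
    _log(f"loaded session: {bundle.duration():.0f} s, "
         f"{bundle.n_units} units")

    results.behavior = analyze_behavior(bundle, linkage_m)
    behav = results.behavior
    fdf = behav["flight_df"].copy()
    fdf["cluster_id"] = behav["labels"]
    fdf["shape"] = [t[0] for t in behav["turns"]]
    fdf["max_curvature"] = [t[1] for t in behav["turns"]]
    fdf.to_csv(out / "flights.csv", index=False)
    _log(f"behavior: {len(behav['flights'])} flights, "
         f"{len(behav['clusters'])} clusters")

    if "lfp" in stages:
        results.lfp = analyze_lfp(bundle, behav)
        pd.DataFrame([{"t": e.t, "peak_z": e.peak_z, "channel": e.channel,
                       "duration_s": e.duration_s,
                       "template_corr": e.template_corr}
                      for e in results.lfp["swr"]],
                     columns=["t", "peak_z", "channel", "duration_s",
                              "template_corr"]).to_csv(
            out / "swr.csv", index=False)
        pd.DataFrame([{"start": b.start, "stop": b.stop,
                       "mean_ratio": b.mean_ratio}
                      for b in results.lfp["theta_bouts"]],
                     columns=["start", "stop", "mean_ratio"]).to_csv(
            out / "theta_bouts.csv", index=False)
        _log(f"lfp: {len(results.lfp['swr'])} SWRs, "
             f"{len(results.lfp['theta_bouts'])} theta bouts")

    results.fields = analyze_place_fields(bundle, behav)
    rows = []
    for cid, info in results.fields.items():
        for uid, f in info["fields"].items():
            rows.append({"unit_id": uid, "trajectory_id": cid,
                         "SI": f.si_bits, "stability": f.stability,
                         "pks": f.pks, "peak_hz": f.peak_rate_hz,
                         "centre_m": f.centre_m, "width_m": f.width_m,
                         "is_place_cell": f.is_place_cell})
    pd.DataFrame(rows).to_csv(out / "place_cells.csv", index=False)
    _log(f"place fields: {sum(len(i['place_cells']) for i in results.fields.values())} place cells")

    if "replay_rank" in stages:
        results.rank = analyze_replays_rank(bundle, behav, results.fields,
                                            seed, n_shuffle)
        pd.DataFrame([{"start_s": r.event.start, "stop_s": r.event.stop,
                       "trajectory_id": r.event.trajectory_id,
                       "rho": r.rho, "p_value": r.p,
                       "n_active": r.event.n_active,
                       "direction": r.direction, "speed_mps": r.speed_mps}
                      for r in results.rank["replays"]],
                     columns=["start_s", "stop_s", "trajectory_id", "rho",
                              "p_value", "n_active", "direction",
                              "speed_mps"]).to_csv(
            out / "replays_rank.csv", index=False)
        _log(f"rank replays: {len(results.rank['replays'])}")

    if "replay_bayes" in stages:
        results.bayes = analyze_replays_bayes(bundle, behav, results.fields,
                                              seed, n_shuffle)
        pd.DataFrame([{"start_s": e.start, "stop_s": e.stop,
                       "trajectory_id": cid, "wcorr": e.wcorr,
                       "replay_score": e.replay_score,
                       "coverage": e.coverage, "direction": e.direction,
                       "p_colshuffle": e.p_colshuffle,
                       "p_timeshuffle": e.p_timeshuffle,
                       "speed_mps": e.speed_mps}
                      for cid, e in results.bayes["replays"]],
                     columns=["start_s", "stop_s", "trajectory_id", "wcorr",
                              "replay_score", "coverage", "direction",
                              "p_colshuffle", "p_timeshuffle",
                              "speed_mps"]).to_csv(
            out / "replays_bayes.csv", index=False)
        _log(f"bayes replays: {len(results.bayes['replays'])}")

    if "wingbeat" in stages or "sweeps" in stages:
        results.wingbeat = analyze_wingbeat(bundle, behav, results.fields,
                                            seed)
        pd.DataFrame([{"unit_id": u.unit_id, "n_spikes": u.n_spikes,
                       "r": u.r, "z": u.z, "r_squared": u.r_squared,
                       "preferred_phase_deg": u.preferred_phase_deg,
                       "shuffle_p": u.shuffle_p,
                       "is_phase_locked": u.is_phase_locked}
                      for u in results.wingbeat["units"]],
                     columns=["unit_id", "n_spikes", "r", "z", "r_squared",
                              "preferred_phase_deg", "shuffle_p",
                              "is_phase_locked"]).to_csv(
            out / "phase_locking.csv", index=False)
        _log(f"wingbeat: {len(results.wingbeat['locked'])} locked units")

    if "sweeps" in stages:
        results.sweeps = analyze_sweeps(bundle, behav, results.fields,
                                        results.wingbeat["phases"], seed)
        pd.DataFrame([{"t": s.t, "phase_rad": s.phase_rad,
                       "match_score": s.match_score,
                       "flight_idx": s.flight_idx}
                      for s in results.sweeps["sweeps"]],
                     columns=["t", "phase_rad", "match_score",
                              "flight_idx"]).to_csv(
            out / "sweeps.csv", index=False)
        _log(f"sweeps: {len(results.sweeps['sweeps'])} events")

    with open(out / "run_log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")
    with open(out / "run_config.json", "w") as fh:
        json.dump({"seed": seed, "linkage_m": linkage_m,
                   "n_shuffle": n_shuffle,
                   "stages": sorted(stages)}, fh, indent=1)
    return results


# ---------------------------------------------------------------------------
# recovery metrics

def match_events(detected_t: np.ndarray, truth_t: np.ndarray,
                 tol_s: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Greedy one-to-one matching of detected to true event times.

    Returns (indices into detected, indices into truth) of matched pairs.
    """
    detected_t = np.asarray(detected_t)
    truth_t = np.asarray(truth_t)
    used = np.zeros(len(detected_t), dtype=bool)
    di, ti = [], []
    for j, tt in enumerate(truth_t):
        if len(detected_t) == 0:
            break
        d = np.abs(detected_t - tt)
        d[used] = np.inf
        i = int(np.argmin(d))
        if d[i] <= tol_s:
            used[i] = True
            di.append(i)
            ti.append(j)
    return np.asarray(di, dtype=int), np.asarray(ti, dtype=int)


def recovery_report(detected: pd.DataFrame, truth: pd.DataFrame,
                    tol_s: float = 0.1) -> dict:
    """Sensitivity, false-discovery rate and direction accuracy of detected
    events against ground truth.

    Both frames need a ``t`` column (event centre); a ``direction`` column
    is compared when present in both.
    """
    di, ti = match_events(detected["t"].to_numpy() if len(detected) else
                          np.empty(0), truth["t"].to_numpy(), tol_s)
    n_match = len(di)
    sens = n_match / len(truth) if len(truth) else np.nan
    fdr = 1.0 - n_match / len(detected) if len(detected) else 0.0
    out = {"n_true": int(len(truth)), "n_detected": int(len(detected)),
           "n_matched": int(n_match), "sensitivity": float(sens),
           "fdr": float(fdr)}
    if n_match and "direction" in detected and "direction" in truth:
        acc = np.mean(detected["direction"].to_numpy()[di]
                      == truth["direction"].to_numpy()[ti])
        out["direction_accuracy"] = float(acc)
    if n_match:
        dt = (detected["t"].to_numpy()[di] - truth["t"].to_numpy()[ti])
        out["median_abs_time_error_s"] = float(np.median(np.abs(dt)))
    return out
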