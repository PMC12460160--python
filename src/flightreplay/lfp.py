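"""LFP event detection: sharp-wave ripples, theta bouts, flight theta,
and non-oscillatory cycle phase.

All filters are 4th-order Butterworth applied forward-backward
(zero-phase), so detected event centres are unbiased in time.  SWR
z-scoring uses rest-epoch statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, filtfilt, find_peaks, hilbert
from scipy.stats import pearsonr, ranksums

__all__ = [
    "SwrEvent", "ThetaBout", "bandpass", "detect_swr", "detect_theta_bouts",
    "classify_flight_theta", "nonosc_phase", "select_theta_channel",
]


@dataclass
class SwrEvent:
    t: float                     # centre (peak of ripple power), s
    peak_z: float
    channel: int
    duration_s: float
    template_corr: float


@dataclass
class ThetaBout:
    start: float
    stop: float
    mean_ratio: float
    mean_theta_power: float


def bandpass(x: np.ndarray, rate_hz: float, lo: float, hi: float,
             order: int = 4) -> np.ndarray:
    nyq = rate_hz / 2.0
    b, a = butter(order, [lo / nyq, hi / nyq], btype="band")
    return filtfilt(b, a, x, axis=0)


def _interval_mask(t: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    m = np.zeros(len(t), dtype=bool)
    for _, r in intervals.iterrows():
        m |= (t >= r["start"]) & (t < r["stop"])
    return m


def detect_swr(lfp: np.ndarray, rate_hz: float, flights: pd.DataFrame,
               z_thresh: float = 3.0, min_peak_dist_s: float = 0.05,
               min_width_s: float = 0.01, merge_s: float = 0.05,
               template_corr_min: float = 0.2, smooth_s: float = 0.05,
               template_win_s: float = 0.1) -> list[SwrEvent]:
    """Detect sharp-wave ripples across channels.

    Per channel: bandpass 100-200 Hz -> |Hilbert| envelope -> 50 ms Gaussian
    smooth -> z-score on rest samples -> peaks above ``z_thresh`` with
    minimum width and separation.  Near-coincident events on different
    channels (< ``merge_s``) are merged keeping the largest power; retained
    events must correlate at least ``template_corr_min`` with the mean event
    waveform across the channel-depth profile (leave-one-out Pearson over a
    +/- ``template_win_s`` window).
    """
    n, n_ch = lfp.shape
    t = np.arange(n) / rate_hz
    flight_mask = _interval_mask(t, flights) if len(flights) else \
        np.zeros(n, dtype=bool)
    rest_mask = ~flight_mask
    if not rest_mask.any():
        return []
    bp = bandpass(np.asarray(lfp, dtype=float), rate_hz, 100.0,
                  min(200.0, rate_hz / 2 - 1))
    env = np.abs(hilbert(bp, axis=0))
    env = gaussian_filter1d(env, smooth_s * rate_hz, axis=0)
    mu = env[rest_mask].mean(axis=0)
    sd = env[rest_mask].std(axis=0)
    z = (env - mu) / np.maximum(sd, 1e-12)

    cands = []  # (time_idx, z, channel, width_s)
    for ch in range(n_ch):
        peaks, props = find_peaks(z[:, ch], height=z_thresh,
                                  distance=max(1, int(min_peak_dist_s * rate_hz)),
                                  width=min_width_s * rate_hz)
        for p, w in zip(peaks, props["widths"]):
            if flight_mask[p]:
                continue
            cands.append((p, float(z[p, ch]), ch, float(w / rate_hz)))
    if not cands:
        return []
    cands.sort(key=lambda c: c[0])
    merged = []
    for c in cands:
        if merged and (c[0] - merged[-1][0]) / rate_hz < merge_s:
            if c[1] > merged[-1][1]:
                merged[-1] = c
        else:
            merged.append(c)

    # template filter on the multichannel bandpassed waveform; windows are
    # aligned to the ripple trough nearest each power peak so that
    # carrier-phase jitter between events cannot destroy the correlation
    half = int(template_win_s * rate_hz)
    align = int(0.005 * rate_hz)
    # the central +/-10 ms is excluded from the correlation: any aligned
    # noise excursion is locally self-similar there, whereas a genuine
    # ripple stays coherent across the full burst
    row_keep = np.abs(np.arange(-half, half + 1)) > int(0.01 * rate_hz)
    wins = []
    kept = []
    for p, zz, ch, w in merged:
        lo, hi = max(0, p - align), min(n, p + align + 1)
        c = lo + int(np.argmin(bp[lo:hi, ch]))
        if c - half < 0 or c + half >= n:
            continue
        wins.append(bp[c - half:c + half + 1, :][row_keep].ravel())
        kept.append((p, zz, ch, w))
    if not wins:
        return []
    wins = np.asarray(wins)
    events = []
    for i, (p, zz, ch, w) in enumerate(kept):
        if len(kept) > 1:
            template = (wins.sum(axis=0) - wins[i]) / (len(kept) - 1)
            corr = float(pearsonr(wins[i], template)[0])
        else:
            corr = 1.0
        if corr >= template_corr_min:
            events.append(SwrEvent(t=float(p / rate_hz), peak_z=zz,
                                   channel=ch, duration_s=w,
                                   template_corr=corr))
    return events


def detect_theta_bouts(x: np.ndarray, rate_hz: float, ratio_thresh: float = 3.0,
                       min_dur_s: float = 1.0, join_s: float = 0.1
                       ) -> list[ThetaBout]:
    """Theta bouts: epochs where theta (4-11 Hz) to delta (1-4 Hz) Hilbert
    power ratio exceeds ``ratio_thresh`` for at least ``min_dur_s``, after
    joining supra-threshold intervals closer than ``join_s``."""
    x = np.asarray(x, dtype=float)
    theta = np.abs(hilbert(bandpass(x, rate_hz, 4.0, 11.0)))
    delta = np.abs(hilbert(bandpass(x, rate_hz, 1.0, 4.0)))
    ratio = theta / np.maximum(delta, 1e-12)
    above = ratio > ratio_thresh
    edges = np.diff(above.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(above))
    runs = []
    for s, e in zip(starts, stops):
        if runs and (s - runs[-1][1]) / rate_hz < join_s:
            runs[-1] = (runs[-1][0], e)
        else:
            runs.append((s, e))
    bouts = []
    for s, e in runs:
        if (e - s) / rate_hz < min_dur_s:
            continue
        bouts.append(ThetaBout(start=s / rate_hz, stop=e / rate_hz,
                               mean_ratio=float(ratio[s:e].mean()),
                               mean_theta_power=float((theta[s:e] ** 2).mean())))
    return bouts


def classify_flight_theta(x: np.ndarray, rate_hz: float, flight_start: float,
                          flight_stop: float, ratio_thresh: float = 2.0,
                          window_s: float = 3.0
                          ) -> tuple[bool, float, float]:
    """Is a flight accompanied by theta?  Requires BOTH a median
    theta/delta ratio above ``ratio_thresh`` during flight AND a significant
    increase (rank-sum) in theta power in the first ``window_s`` of flight
    versus the ``window_s`` before it.

    Flights shorter than ``window_s`` use their full duration for the onset
    comparison.  Returns (flag, median ratio, p value).
    """
    x = np.asarray(x, dtype=float)
    t = np.arange(len(x)) / rate_hz
    theta = np.abs(hilbert(bandpass(x, rate_hz, 4.0, 11.0)))
    delta = np.abs(hilbert(bandpass(x, rate_hz, 1.0, 4.0)))
    ratio = theta / np.maximum(delta, 1e-12)
    in_flight = (t >= flight_start) & (t < flight_stop)
    if not in_flight.any():
        return False, np.nan, np.nan
    med = float(np.median(ratio[in_flight]))
    w = min(window_s, flight_stop - flight_start)
    pre = (t >= flight_start - w) & (t < flight_start)
    post = (t >= flight_start) & (t < flight_start + w)
    power = theta ** 2
    if pre.sum() < 10 or post.sum() < 10:
        return False, med, np.nan
    stat, p = ranksums(power[post], power[pre])
    increased = stat > 0 and p < 0.05
    return bool(med > ratio_thresh and increased), med, float(p)


def select_theta_channel(lfp: np.ndarray, rate_hz: float) -> int:
    """Channel with maximal relative 4-11 Hz power (automated proxy for
    visual channel selection)."""
    best, best_ch = -np.inf, 0
    for ch in range(lfp.shape[1]):
        x = np.asarray(lfp[:, ch], dtype=float)
        th = np.abs(hilbert(bandpass(x, rate_hz, 4.0, 11.0))) ** 2
        rel = th.mean() / max(np.var(x), 1e-12)
        if rel > best:
            best, best_ch = rel, ch
    return best_ch


def nonosc_phase(x: np.ndarray, rate_hz: float, flights: pd.DataFrame,
                 lo: float = 1.0, hi: float = 10.0,
                 power_pct: float = 25.0) -> pd.DataFrame:
    """Non-oscillatory cycle phase: linear 0-360 degrees between consecutive
    troughs of the 1-10 Hz filtered LFP, with per-cycle mean power and a
    mask for cycles below the ``power_pct`` percentile of the in-flight
    cycle-power distribution.

    Returns a per-sample DataFrame (t, phase_deg, power, cycle, masked);
    samples outside any trough-to-trough cycle have NaN phase.
    """
    x = np.asarray(x, dtype=float)
    filt = bandpass(x, rate_hz, lo, hi)
    power = np.abs(hilbert(filt)) ** 2
    troughs, _ = find_peaks(-filt, distance=max(1, int(rate_hz / (2 * hi))))
    n = len(x)
    t = np.arange(n) / rate_hz
    phase = np.full(n, np.nan)
    cycle = np.full(n, -1, dtype=int)
    if len(troughs) < 2:
        return pd.DataFrame({"t": t, "phase_deg": phase, "power": power,
                             "cycle": cycle, "masked": np.zeros(n, bool)})
    cyc_power = []
    cyc_mid_inflight = []
    fmask = _interval_mask(t, flights) if len(flights) else np.zeros(n, bool)
    for c, (a, b) in enumerate(zip(troughs[:-1], troughs[1:])):
        phase[a:b] = 360.0 * (np.arange(b - a)) / (b - a)
        cycle[a:b] = c
        cyc_power.append(power[a:b].mean())
        cyc_mid_inflight.append(bool(fmask[(a + b) // 2]))
    cyc_power = np.asarray(cyc_power)
    in_flight = np.asarray(cyc_mid_inflight)
    ref = cyc_power[in_flight] if in_flight.any() else cyc_power
    thresh = np.percentile(ref, power_pct)
    masked_cycles = np.nonzero(cyc_power < thresh)[0]
    masked = np.isin(cycle, masked_cycles)
    return pd.DataFrame({"t": t, "phase_deg": phase, "power": power,
                         "cycle": cycle, "masked": masked})
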