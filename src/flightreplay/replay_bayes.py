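"""Uniform-prior Bayesian decoding and continuous replay detection.

The decoder assigns each time window a posterior over position bins

    P(x | n) = C * (prod_i f_i(x)^{n_i}) * exp(-tau * sum_i f_i(x))

with f_i(x) the spatial response of cell i (spikes per second per bin),
n_i the window's spike count for cell i, tau the window length and C a
normalization making each column sum to one.  Spikes are mirrored by
+/-5 ms before counting, and the decoder runs in a 20-ms window stepped by
5 ms over the whole session excluding flight.  Computation is in log space;
a small rate floor inside f_i(x)^{n_i} avoids zero posteriors.

Candidate events are runs of high-confidence time bins (posterior spread
<= 0.3 in normalized track units and peak probability at least three times
the average), at least 25 ms long, merged across gaps under 75 ms, and not
more than 70% low-confidence after merging.  Events are refined by random
trimming, scored (weighted correlation, replay score, spread, coverage) and
gated by two shuffles (per-column circular position shift; time-bin
permutation) on both metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SpatialResponseSet", "PosteriorMatrix", "DecodedReplay",
    "compute_responses", "bayes_posterior", "decode_windows",
    "decode_session", "event_scores", "posterior_spread",
    "segment_candidates", "refine_event", "shuffle_significance",
    "decoded_replay_speed", "detect_decoded_replays",
]

RATE_FLOOR_HZ = 0.01


@dataclass
class SpatialResponseSet:
    """Per-unit spatial responses f_i(x) on one trajectory."""
    unit_ids: np.ndarray
    rates_hz: np.ndarray             # n_units x n_bins
    trajectory_id: int
    length_m: float

    @property
    def n_bins(self) -> int:
        return self.rates_hz.shape[1]


@dataclass
class PosteriorMatrix:
    times: np.ndarray                # window-centre times, s
    P: np.ndarray                    # n_t x n_bins, rows sum to 1
    n_spikes: np.ndarray             # real (unmirrored) spikes per window
    length_m: float

    @property
    def argmax(self) -> np.ndarray:
        return self.P.argmax(axis=1)

    @property
    def spread(self) -> np.ndarray:
        return posterior_spread(self.P)

    @property
    def step_s(self) -> float:
        return float(np.median(np.diff(self.times))) if len(self.times) > 1 \
            else 0.005


@dataclass
class DecodedReplay:
    start: float
    stop: float
    wcorr: float
    replay_score: float
    spread: float
    coverage: float
    p_colshuffle: float
    p_timeshuffle: float
    direction: str
    speed_mps: float = np.nan

    @property
    def duration(self) -> float:
        return self.stop - self.start

    @property
    def t_centre(self) -> float:
        return 0.5 * (self.start + self.stop)


def _smooth_gauss(x: np.ndarray, sd_bins: float,
                  valid: np.ndarray | None = None) -> np.ndarray:
    half = int(np.ceil(4 * sd_bins))
    k = np.arange(-half, half + 1)
    w = np.exp(-0.5 * (k / sd_bins) ** 2)
    if valid is None:
        valid = np.ones_like(x, dtype=bool)
    num = np.convolve(np.where(valid, x, 0.0), w, mode="same")
    den = np.convolve(valid.astype(float), w, mode="same")
    out = np.zeros_like(x, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def compute_responses(spike_trains: dict[int, np.ndarray],
                      lin_flights: list[pd.DataFrame], length_m: float,
                      trajectory_id: int = -1, n_bins: int = 30,
                      smooth_sd_bins: float = 2.0,
                      unit_ids: list | None = None) -> SpatialResponseSet:
    """Spatial responses: spikes per bin / occupancy, Gaussian smoothed."""
    if unit_ids is None:
        unit_ids = sorted(spike_trains.keys())
    edges = np.linspace(0.0, length_m, n_bins + 1)
    occ = np.zeros(n_bins)
    cnt = np.zeros((len(unit_ids), n_bins))
    for lf in lin_flights:
        t = lf["t"].to_numpy()
        d = lf["d_norm"].to_numpy() * length_m
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
        occ += np.histogram(d, bins=edges)[0] * dt
        for ui, uid in enumerate(unit_ids):
            st = spike_trains[uid]
            m = (st >= t[0]) & (st <= t[-1])
            if m.any():
                ds = np.interp(st[m], t, d)
                cnt[ui] += np.histogram(ds, bins=edges)[0]
    valid = occ > 0
    rates = np.zeros_like(cnt)
    rates[:, valid] = cnt[:, valid] / occ[valid]
    for ui in range(len(unit_ids)):
        rates[ui] = _smooth_gauss(rates[ui], smooth_sd_bins, valid)
    return SpatialResponseSet(unit_ids=np.asarray(unit_ids), rates_hz=rates,
                              trajectory_id=trajectory_id, length_m=length_m)


def bayes_posterior(counts: np.ndarray, rates_hz: np.ndarray,
                    tau_s: float) -> np.ndarray:
    """Posterior over position bins for one window (log-space)."""
    f = np.maximum(np.asarray(rates_hz, dtype=float), RATE_FLOOR_HZ)
    logp = counts @ np.log(f) - tau_s * rates_hz.sum(axis=0)
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def _mirror(spikes: np.ndarray, offsets_s: tuple) -> np.ndarray:
    parts = [spikes] + [spikes + o for o in offsets_s]
    return np.sort(np.concatenate(parts))


def decode_windows(spike_trains: dict[int, np.ndarray],
                   responses: SpatialResponseSet, window_starts: np.ndarray,
                   window_s: float,
                   mirror_s: tuple = (-0.005, 0.005)) -> PosteriorMatrix:
    """Decode a set of windows; spikes are mirrored by ``mirror_s`` first."""
    f = responses.rates_hz
    n_u, n_bins = f.shape
    n_t = len(window_starts)
    counts = np.zeros((n_t, n_u), dtype=np.float64)
    real = np.zeros(n_t, dtype=np.int64)
    ends = window_starts + window_s
    for ui, uid in enumerate(responses.unit_ids):
        st = spike_trains.get(int(uid), np.empty(0))
        if st.size == 0:
            continue
        real += (np.searchsorted(st, ends) - np.searchsorted(st, window_starts))
        mt = _mirror(st, mirror_s)
        counts[:, ui] = (np.searchsorted(mt, ends)
                         - np.searchsorted(mt, window_starts))
    fl = np.maximum(f, RATE_FLOOR_HZ)
    logf = np.log(fl)
    logp = counts @ logf - window_s * f.sum(axis=0)[None, :]
    logp -= logp.max(axis=1, keepdims=True)
    P = np.exp(logp)
    P /= P.sum(axis=1, keepdims=True)
    return PosteriorMatrix(times=window_starts + window_s / 2, P=P,
                           n_spikes=real, length_m=responses.length_m)


def decode_session(spike_trains: dict[int, np.ndarray],
                   responses: SpatialResponseSet, rests: pd.DataFrame,
                   window_s: float = 0.02, step_s: float = 0.005,
                   mirror_s: tuple = (-0.005, 0.005)) -> PosteriorMatrix:
    """Sliding-window decoding over all rest epochs."""
    starts = []
    for _, r in rests.iterrows():
        if r["stop"] - r["start"] >= window_s:
            starts.append(np.arange(r["start"], r["stop"] - window_s, step_s))
    starts = np.concatenate(starts) if starts else np.empty(0)
    return decode_windows(spike_trains, responses, starts, window_s, mirror_s)


# ---------------------------------------------------------------------------
# event scores

def posterior_spread(P: np.ndarray) -> np.ndarray:
    """Per-time-bin sqrt of the second central moment of the posterior, in
    normalized track units (track length = 1)."""
    n_bins = P.shape[1]
    x = (np.arange(n_bins) + 0.5) / n_bins
    mean = P @ x
    var = P @ (x ** 2) - mean ** 2
    return np.sqrt(np.maximum(var, 0.0))


def weighted_correlation(P: np.ndarray) -> float:
    """Pearson correlation of time vs position weighted by the posterior."""
    n_t, n_bins = P.shape
    t = np.arange(n_t, dtype=float)
    x = np.arange(n_bins, dtype=float)
    w = P / P.sum()
    wt = w.sum(axis=1)
    wx = w.sum(axis=0)
    mt = float(wt @ t)
    mx = float(wx @ x)
    cov = float(((t - mt)[:, None] * (x - mx)[None, :] * w).sum())
    vt = float(wt @ (t - mt) ** 2)
    vx = float(wx @ (x - mx) ** 2)
    if vt <= 0 or vx <= 0:
        return 0.0
    return cov / np.sqrt(vt * vx)


def event_scores(P: np.ndarray, band_bins: float = 1.0,
                 good: np.ndarray | None = None
                 ) -> tuple[float, float, float, float]:
    """(weighted correlation, replay score, mean spread, coverage).

    The replay score is the mean posterior mass within ``band_bins`` of the
    least-squares line through the per-bin maximum-probability positions;
    coverage is the fraction of the track spanned by that line between the
    first and last time bins, clamped to [0, 1].

    The line fit weights each bin's predicted position by its peak
    posterior probability (a bin's argmax is only as reliable as the mass
    behind it); with a high-confidence mask ``good``, low-confidence bins
    retained inside merged events are excluded from the fit entirely.
    Mass and coverage are evaluated over the whole event.
    """
    n_t, n_bins = P.shape
    wcorr = weighted_correlation(P)
    spread = float(posterior_spread(P).mean())
    amax = P.argmax(axis=1).astype(float)
    t = np.arange(n_t, dtype=float)
    wfit = P.max(axis=1)
    if good is not None and good.sum() >= 2:
        wfit = wfit * good
    if n_t >= 2 and np.count_nonzero(wfit) >= 2:
        slope, icpt = np.polyfit(t, amax, 1, w=np.sqrt(wfit))
        # one robust refit: drop bins far off the line (stray-spike bins
        # have high leverage at event edges)
        dev = np.abs(amax - (slope * t + icpt))
        inlier = wfit * (dev <= 0.25 * n_bins)
        if np.count_nonzero(inlier) >= 2:
            slope, icpt = np.polyfit(t, amax, 1, w=np.sqrt(inlier))
    else:
        slope, icpt = 0.0, amax[0]
    line = slope * t + icpt
    dist = np.abs(np.arange(n_bins)[None, :] - line[:, None])
    mass = np.where(dist <= band_bins, P, 0.0).sum(axis=1)
    replay_score = float(mass.mean())
    coverage = float(np.clip(abs(line[-1] - line[0]) / n_bins, 0.0, 1.0))
    return wcorr, replay_score, spread, coverage


# ---------------------------------------------------------------------------
# continuous detection

def confidence_mask(post: PosteriorMatrix, spread_max: float = 0.3,
                    peak_factor: float = 3.0) -> np.ndarray:
    """True for high-confidence time bins."""
    n_bins = post.P.shape[1]
    peak = post.P.max(axis=1)
    avg = 1.0 / n_bins
    return (post.spread <= spread_max) & (peak >= peak_factor * avg)


def segment_candidates(post: PosteriorMatrix, spread_max: float = 0.3,
                       peak_factor: float = 3.0, min_sub_s: float = 0.025,
                       merge_gap_s: float = 0.075,
                       max_lowconf_frac: float = 0.7
                       ) -> list[tuple[int, int]]:
    """Raw candidate segments as half-open index ranges into the posterior.

    Discontinuities in the window-centre times (rest-epoch boundaries)
    break segments.
    """
    good = confidence_mask(post, spread_max, peak_factor)
    step = post.step_s
    tgap = np.diff(post.times) > 1.5 * step
    # subsequences: runs of good bins not crossing a time discontinuity
    subs = []
    i = 0
    n = len(good)
    while i < n:
        if not good[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and good[j + 1] and not tgap[j]:
            j += 1
        subs.append((i, j + 1))
        i = j + 1
    subs = [(a, b) for a, b in subs if (b - a) * step >= min_sub_s]
    merged = []
    for a, b in subs:
        if merged and (a - merged[-1][1]) * step < merge_gap_s \
                and not tgap[merged[-1][1] - 1:a].any():
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    out = []
    for a, b in merged:
        frac_low = 1.0 - good[a:b].mean()
        if frac_low <= max_lowconf_frac:
            out.append((a, b))
    return out


def refine_event(post: PosteriorMatrix, seg: tuple[int, int],
                 rng: np.random.Generator, n_trims: int = 1000,
                 min_keep_frac: float = 0.5, min_centre_s: float = 0.05,
                 low_conf_stop_s: float = 0.05, band_bins: float = 1.0
                 ) -> tuple[int, int] | None:
    """Find the event centre by random trimming, then extend its borders.

    The candidate is trimmed on both ends ``n_trims`` times keeping at
    least ``min_keep_frac`` of its duration; each trim is scored by
    weighted correlation plus trajectory coverage and one of the top 5% is
    picked at random.  Centres shorter than ``min_centre_s`` are rejected.
    The final event extends the centre through high-confidence bins until a
    low-confidence region of at least ``low_conf_stop_s`` is met.
    """
    a, b = seg
    n = b - a
    step = post.step_s
    min_len = max(int(np.ceil(min_keep_frac * n)), 2)
    lo = rng.integers(0, n - min_len + 1, size=n_trims)
    hi = np.minimum(lo + min_len + rng.integers(
        0, n, size=n_trims) % (n - min_len + 1), n)
    hi = np.maximum(hi, lo + min_len)
    # O(1) per-trim |wcorr| + coverage via prefix sums over the segment
    P = post.P[a:b]
    n_bins = P.shape[1]
    x = np.arange(n_bins, dtype=float)
    t = np.arange(n, dtype=float)
    px = P @ x
    pxx = P @ (x ** 2)
    amax = P.argmax(axis=1).astype(float)
    g = confidence_mask(post)[a:b].astype(float) * P.max(axis=1)

    def _csum(v):
        return np.concatenate([[0.0], np.cumsum(v)])

    Ct, Ctt = _csum(t), _csum(t * t)
    Cx, Cxx, Ctx = _csum(px), _csum(pxx), _csum(t * px)
    Cg, Cgt, Cgtt = _csum(g), _csum(g * t), _csum(g * t * t)
    Ca, Cta = _csum(g * amax), _csum(g * t * amax)
    N = (hi - lo).astype(float)
    St = Ct[hi] - Ct[lo]
    Stt = Ctt[hi] - Ctt[lo]
    Sx = Cx[hi] - Cx[lo]
    Sxx = Cxx[hi] - Cxx[lo]
    Stx = Ctx[hi] - Ctx[lo]
    Ng = np.maximum(Cg[hi] - Cg[lo], 1e-12)
    Sgt = Cgt[hi] - Cgt[lo]
    Sgtt = Cgtt[hi] - Cgtt[lo]
    Sa = Ca[hi] - Ca[lo]
    Sta = Cta[hi] - Cta[lo]
    mt, mx = St / N, Sx / N
    cov_tx = Stx / N - mt * mx
    vt = Stt / N - mt ** 2
    vx = Sxx / N - mx ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        wcorr = cov_tx / np.sqrt(vt * vx)
        # line through high-confidence bins only
        slope = (Sta - Sgt * Sa / Ng) / np.maximum(
            Sgtt - Sgt ** 2 / Ng, 1e-12)
    coverage = np.clip(np.abs(slope) * (N - 1) / n_bins, 0.0, 1.0)
    scores = np.where(N * step >= min_centre_s,
                      np.abs(np.nan_to_num(wcorr)) + coverage, -np.inf)
    ok = np.isfinite(scores)
    if not ok.any():
        return None
    thresh = np.quantile(scores[ok], 0.95)
    top = np.nonzero(scores >= thresh)[0]
    pick = top[rng.integers(0, len(top))]
    c0, c1 = a + lo[pick], a + hi[pick]
    # extension through high-confidence bins
    good = confidence_mask(post)
    stop_bins = max(1, int(round(low_conf_stop_s / step)))
    tgap = np.diff(post.times) > 1.5 * step

    def _extend(idx: int, direction: int) -> int:
        run_low = 0
        pos = idx
        while True:
            nxt = pos + direction
            if nxt < 0 or nxt >= len(good):
                break
            edge = min(pos, nxt)
            if tgap[edge] if edge < len(tgap) else False:
                break
            if good[nxt]:
                run_low = 0
            else:
                run_low += 1
                if run_low >= stop_bins:
                    pos = nxt - direction * run_low
                    break
            pos = nxt
        return pos

    e0 = _extend(c0, -1)
    e1 = _extend(c1 - 1, +1) + 1
    # trim leading/trailing low-confidence bins
    while e0 < e1 - 1 and not good[e0]:
        e0 += 1
    while e1 - 1 > e0 and not good[e1 - 1]:
        e1 -= 1
    return (e0, e1)


def shuffle_significance(P: np.ndarray, rng: np.random.Generator,
                         n_shuffle: int = 100, band_bins: float = 1.0,
                         good: np.ndarray | None = None,
                         per_metric: bool = False):
    """p values under the column circular-position shuffle and the time-bin
    shuffle, each taken as the worse of the two replay metrics.

    For each shuffle the weighted correlation (absolute value) and replay
    score are recomputed; p is the fraction of shuffles reaching the
    observed value.
    """
    n_t, n_bins = P.shape
    w_obs, s_obs, _, _ = event_scores(P, band_bins, good)
    cnt_w_col = cnt_s_col = cnt_w_time = cnt_s_time = 0
    for _ in range(n_shuffle):
        shifts = rng.integers(0, n_bins, size=n_t)
        rows, cols = np.ogrid[:n_t, :n_bins]
        Pc = P[rows, (cols - shifts[:, None]) % n_bins]
        w, s, _, _ = event_scores(Pc, band_bins, good)
        cnt_w_col += abs(w) >= abs(w_obs)
        cnt_s_col += s >= s_obs
        perm = rng.permutation(n_t)
        Pt = P[perm]
        w, s, _, _ = event_scores(Pt, band_bins,
                                  good[perm] if good is not None else None)
        cnt_w_time += abs(w) >= abs(w_obs)
        cnt_s_time += s >= s_obs
    if per_metric:
        return {"wcorr_col": cnt_w_col / n_shuffle,
                "score_col": cnt_s_col / n_shuffle,
                "wcorr_time": cnt_w_time / n_shuffle,
                "score_time": cnt_s_time / n_shuffle}
    p_col = max(cnt_w_col, cnt_s_col) / n_shuffle
    p_time = max(cnt_w_time, cnt_s_time) / n_shuffle
    return float(p_col), float(p_time)


def decoded_replay_speed(length_m: float, duration_s: float) -> float:
    """Replayed flight length divided by replay duration."""
    return length_m / duration_s


def detect_decoded_replays(post: PosteriorMatrix,
                           rng: np.random.Generator, n_shuffle: int = 100,
                           wcorr_min: float = 0.4, score_min: float = 0.4,
                           coverage_min: float = 0.5, p_max: float = 0.05,
                           band_bins: float = 1.0) -> list[DecodedReplay]:
    """Full continuous-detection pipeline on a decoded session."""
    out = []
    step = post.step_s
    for seg in segment_candidates(post):
        if (seg[1] - seg[0]) * step < 0.05:
            continue
        ref = refine_event(post, seg, rng, band_bins=band_bins)
        if ref is None:
            continue
        i0, i1 = ref
        if i1 - i0 < 2:
            continue
        Pseg = post.P[i0:i1]
        good = confidence_mask(post)[i0:i1]
        w, s, spread, cov = event_scores(Pseg, band_bins, good)
        p_col, p_time = shuffle_significance(Pseg, rng, n_shuffle, band_bins,
                                             good)
        if (abs(w) > wcorr_min and s > score_min and cov > coverage_min
                and p_col < p_max and p_time < p_max):
            start = float(post.times[i0] - step / 2)
            stop = float(post.times[i1 - 1] + step / 2)
            out.append(DecodedReplay(
                start=start, stop=stop, wcorr=w, replay_score=s,
                spread=spread, coverage=cov, p_colshuffle=p_col,
                p_timeshuffle=p_time,
                direction="forward" if w > 0 else "reverse",
                speed_mps=decoded_replay_speed(post.length_m, stop - start)))
    return out
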