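"""Wing-beat phase extraction and spike-phase statistics.

The wing-beat phase is the Hilbert phase of the absolute acceleration
band-passed between 7 and 9 Hz, shifted so that phase 0 falls at the trough
of |a|; the downstroke corresponds to the half-cycle from 0 to -pi.
Phase locking is quantified two ways: a cosine fit to the
20-bin spike-phase histogram (locked iff R^2 > 0 with at least 50 in-flight
spikes), and circular statistics -- the mean resultant length

    r = | (1/n) * sum_j exp(i * theta_j) |

with Rayleigh statistic z = r^2 * n and a phase-reassignment shuffle p.
Phase precession is the Spearman correlation between within-field distance
and spike phase after scanning the phase shift that maximizes |rho|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, hilbert
from scipy.stats import spearmanr

from flightreplay.lfp import bandpass

__all__ = [
    "WingbeatPhaseSeries", "PhaseLockResult", "wingbeat_frequency",
    "wingbeat_phase", "spike_phase_stats", "resultant_and_rayleigh",
    "population_phase_profile", "autocorr_rhythm", "phase_precession",
    "resultant_length",
]

N_PHASE_BINS = 20


@dataclass
class WingbeatPhaseSeries:
    t: np.ndarray
    phase: np.ndarray                # rad in [-pi, pi), 0 at |a| trough
    inst_freq_hz: np.ndarray
    rate_hz: float

    def phase_at(self, times: np.ndarray) -> np.ndarray:
        """Phase of the nearest accelerometer sample for each time."""
        idx = np.clip(np.round((np.asarray(times) - self.t[0]) * self.rate_hz
                               ).astype(int), 0, len(self.t) - 1)
        return self.phase[idx]


@dataclass
class PhaseLockResult:
    unit_id: int
    n_spikes: int
    hist: np.ndarray                 # spike-fraction histogram, 20 bins
    cos_a: float
    cos_b: float
    r_squared: float
    preferred_phase_deg: float
    circ_mean_deg: float
    r: float
    z: float
    shuffle_p: float
    is_phase_locked: bool
    precession_rho: float = np.nan
    precession_p: float = np.nan
    precession_shift_deg: float = np.nan


def _abs_accel(accel: pd.DataFrame) -> np.ndarray:
    return np.linalg.norm(accel[["ax", "ay", "az"]].to_numpy(), axis=1)


def wingbeat_frequency(accel: pd.DataFrame, flight_start: float,
                       flight_stop: float, band: tuple = (6.0, 10.0)
                       ) -> tuple[float, np.ndarray, bool]:
    """Wing-beat frequency of one flight.

    Returns (FFT peak in ``band``, instantaneous-frequency series from the
    Hilbert transform of the 7-9 Hz band-passed |a|, significance flag).
    The flag is False when the in-band FFT peak does not rise above twice
    the median in-band power (no rhythmic modulation).
    """
    t = accel["t"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t)))
    m = (t >= flight_start) & (t < flight_stop)
    if m.sum() < rate:
        raise ValueError("flight too short for a frequency estimate")
    x = _abs_accel(accel)[m]
    x = x - x.mean()
    n_fft = max(4096, len(x))
    spec = np.abs(np.fft.rfft(x, n_fft)) ** 2
    freqs = np.fft.rfftfreq(n_fft, 1.0 / rate)
    inband = (freqs >= band[0]) & (freqs <= band[1])
    peak_hz = float(freqs[inband][np.argmax(spec[inband])])
    significant = bool(spec[inband].max() > 10.0 * np.median(spec[inband]))
    bp = bandpass(x, rate, 7.0, 9.0)
    phase = np.unwrap(np.angle(hilbert(bp)))
    inst = np.gradient(phase) * rate / (2 * np.pi)
    return peak_hz, inst, significant


def wingbeat_phase(accel: pd.DataFrame) -> WingbeatPhaseSeries:
    """Instantaneous wing-beat phase with troughs of |a| mapped to 0."""
    t = accel["t"].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t)))
    x = _abs_accel(accel)
    bp = bandpass(x - x.mean(), rate, 7.0, 9.0)
    analytic = hilbert(bp)
    # at a trough the band-passed signal is minimal: analytic angle +/-pi;
    # shifting by pi maps troughs to phase 0
    phase = np.angle(-analytic)
    inst = np.gradient(np.unwrap(np.angle(analytic))) * rate / (2 * np.pi)
    return WingbeatPhaseSeries(t=t, phase=phase, inst_freq_hz=inst, rate_hz=rate)


def _phase_hist(phases: np.ndarray, n_bins: int = N_PHASE_BINS) -> np.ndarray:
    h, _ = np.histogram(phases, bins=np.linspace(-np.pi, np.pi, n_bins + 1))
    return h / max(h.sum(), 1)


def resultant_length(phases: np.ndarray) -> float:
    return float(np.abs(np.mean(np.exp(1j * np.asarray(phases)))))


def spike_phase_stats(spike_phases: np.ndarray, unit_id: int = -1,
                      min_spikes: int = 50) -> PhaseLockResult:
    """Cosine-fit phase locking for one unit.

    The 20-bin spike-phase histogram is cloned over two cycles, normalized
    to [-1, 1], and fitted with cos(a*x - b), b > 0.  The unit is locked iff
    the fit beats the constant model (R^2 > 0) and it has at least
    ``min_spikes`` in-flight spikes.  The preferred phase is the argmax of
    the fitted cosine within [-pi, pi).
    """
    phases = np.asarray(spike_phases, dtype=float)
    n = len(phases)
    hist = _phase_hist(phases)
    centres = (np.arange(N_PHASE_BINS) + 0.5) / N_PHASE_BINS * 2 * np.pi - np.pi
    x2 = np.concatenate([centres, centres + 2 * np.pi])
    y2 = np.tile(hist, 2)
    span = y2.max() - y2.min()
    y2n = (2 * (y2 - y2.min()) / span - 1.0) if span > 0 else np.zeros_like(y2)

    def model(x, a, b):
        return np.cos(a * x - b)

    best = (np.nan, np.nan, -np.inf)
    ss_tot = float(np.sum((y2n - y2n.mean()) ** 2))
    for b0 in np.arange(np.pi / 4, 2 * np.pi + 1e-9, np.pi / 4):
        try:
            # a is kept near 1: the histogram is 2*pi-periodic by
            # construction, so sub/super-harmonic fits are spurious
            popt, _ = curve_fit(model, x2, y2n, p0=[1.0, b0],
                                bounds=([0.5, 1e-6], [2.0, 4 * np.pi]),
                                maxfev=2000)
        except RuntimeError:
            continue
        resid = y2n - model(x2, *popt)
        r2 = 1.0 - float(np.sum(resid ** 2)) / max(ss_tot, 1e-12)
        if r2 > best[2]:
            best = (popt[0], popt[1], r2)
    a, b, r2 = best
    circ_mean = float(np.rad2deg(np.angle(np.mean(np.exp(1j * phases))))) \
        if n else np.nan
    if np.isfinite(a) and r2 > 0:
        # argmax of cos(a*x - b): x = b/a modulo the cycle, folded to [-pi,pi)
        xpk = b / a
        xpk = np.mod(xpk + np.pi, 2 * np.pi) - np.pi
        pref = float(np.rad2deg(xpk))
    else:
        # the cosine model does not beat the constant model (degenerate or
        # unstructured histogram): report the circular mean instead
        pref = circ_mean
        r2 = r2 if np.isfinite(a) else -np.inf
    r = resultant_length(phases) if n else 0.0
    locked = bool(r2 > 0 and n >= min_spikes)
    return PhaseLockResult(unit_id=unit_id, n_spikes=n, hist=hist,
                           cos_a=float(a), cos_b=float(b), r_squared=float(r2),
                           preferred_phase_deg=pref, circ_mean_deg=circ_mean,
                           r=r, z=r ** 2 * n,
                           shuffle_p=np.nan, is_phase_locked=locked)


def resultant_and_rayleigh(spike_phases: np.ndarray,
                           flight_phase_pool: np.ndarray | None = None,
                           n_shuffle: int = 100, min_spikes: int = 30,
                           rng: np.random.Generator | None = None
                           ) -> tuple[float, float, float]:
    """Mean resultant length r, Rayleigh statistic z = r^2 * n, and a
    shuffle p (phases randomly reassigned from the flight-epoch pool).

    Raises ``ValueError`` below ``min_spikes`` spikes (excluded units).
    """
    phases = np.asarray(spike_phases, dtype=float)
    n = len(phases)
    if n < min_spikes:
        raise ValueError(f"needs at least {min_spikes} spikes, got {n}")
    r = resultant_length(phases)
    z = r ** 2 * n
    if flight_phase_pool is None or rng is None:
        return r, z, np.nan
    pool = np.asarray(flight_phase_pool)
    count = 0
    for _ in range(n_shuffle):
        rs = resultant_length(rng.choice(pool, size=n, replace=True))
        if rs >= r:
            count += 1
    return r, z, count / n_shuffle


def population_phase_profile(locked: list[PhaseLockResult],
                             occupancy_phases: np.ndarray,
                             n_boot: int = 200,
                             rng: np.random.Generator | None = None
                             ) -> tuple[np.ndarray, float, tuple]:
    """Occupancy-corrected mean spike-phase histogram across locked units.

    The mean spike-fraction histogram minus the wing-beat phase occupancy
    histogram; returns (corrected histogram, peak phase in degrees,
    bootstrap 95% CI of the peak over unit resampling).
    """
    if len(locked) < 2:
        raise ValueError("needs at least two locked units")
    if rng is None:
        rng = np.random.default_rng(0)
    H = np.vstack([u.hist for u in locked])
    occ = _phase_hist(np.asarray(occupancy_phases))
    corrected = H.mean(axis=0) - occ
    centres_deg = ((np.arange(N_PHASE_BINS) + 0.5) / N_PHASE_BINS * 360.0
                   - 180.0)
    peak = float(centres_deg[int(np.argmax(corrected))])
    peaks = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(locked), len(locked))
        c = H[idx].mean(axis=0) - occ
        peaks.append(centres_deg[int(np.argmax(c))])
    lo, hi = np.percentile(peaks, [2.5, 97.5])
    return corrected, peak, (float(lo), float(hi))


def autocorr_rhythm(spike_trains: list[np.ndarray], max_lag_s: float = 0.5,
                    bin_s: float = 0.01, fit_lo_s: float = 0.1
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """Mean spike autocorrelogram and the intrinsic-rhythm frequency.

    Per-unit autocorrelograms within +/-``max_lag_s`` (10 ms bins,
    normalized by total counts) are averaged; a mono-exponential is fitted
    to the average between ``fit_lo_s`` and ``max_lag_s`` of positive lag
    and subtracted; the residual's zero-padded FFT peak is the rhythm
    frequency in Hz.
    """
    n_bins = int(round(2 * max_lag_s / bin_s))
    edges = np.linspace(-max_lag_s, max_lag_s, n_bins + 1)
    acc = np.zeros(n_bins)
    total = 0
    for st in spike_trains:
        st = np.sort(np.asarray(st))
        if len(st) < 2:
            continue
        for i, s in enumerate(st):
            lo = np.searchsorted(st, s - max_lag_s)
            hi = np.searchsorted(st, s + max_lag_s)
            lags = st[lo:hi] - s
            lags = lags[lags != 0]
            acc += np.histogram(lags, bins=edges)[0]
            total += len(lags)
    if total < 100:
        raise ValueError("too few spikes for an autocorrelogram")
    acf = acc / total
    lag_centres = (edges[:-1] + edges[1:]) / 2
    m = (lag_centres >= fit_lo_s) & (lag_centres <= max_lag_s)
    x, y = lag_centres[m], acf[m]
    try:
        popt, _ = curve_fit(lambda tt, A, lam, c: A * np.exp(-lam * tt) + c,
                            x, y, p0=[max(y.max(), 1e-6), 5.0, float(y.min())],
                            maxfev=5000)
        resid = y - (popt[0] * np.exp(-popt[1] * x) + popt[2])
    except RuntimeError:
        resid = y - y.mean()
    n_fft = 4096
    spec = np.abs(np.fft.rfft(resid - resid.mean(), n_fft))
    freqs = np.fft.rfftfreq(n_fft, bin_s)
    inband = (freqs >= 4.0) & (freqs <= 16.0)
    peak_hz = float(freqs[inband][np.argmax(spec[inband])])
    return lag_centres, acf, peak_hz


def phase_precession(distances_m: np.ndarray, spike_phases: np.ndarray,
                     n_shifts: int = 20) -> tuple[float, float, float]:
    """Spearman correlation of within-field distance vs spike phase after
    scanning ``n_shifts`` phase shifts (18 degree steps) for the one that
    maximizes |rho|.  Precession = rho < 0 with p < 0.05.

    Returns (rho, p, best shift in degrees).
    """
    d = np.asarray(distances_m, dtype=float)
    ph = np.asarray(spike_phases, dtype=float)
    best = (0.0, 1.0, 0.0)
    for k in range(n_shifts):
        shift = k * 2 * np.pi / n_shifts
        shifted = np.mod(ph + shift + np.pi, 2 * np.pi) - np.pi
        rho, p = spearmanr(d, shifted)
        if np.isfinite(rho) and abs(rho) > abs(best[0]):
            best = (float(rho), float(p), float(np.rad2deg(shift)))
    return best
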