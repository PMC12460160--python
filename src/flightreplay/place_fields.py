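"""Linearized 1D place fields and place-cell selection statistics.

A unit's field is the average firing rate per 0.15 m bin along the
linearized flight path (spike count / occupancy), smoothed with a Gaussian
window spanning seven bins.  Selection uses four criteria: peak rate above
3 Hz, half-session stability (Spearman) of at least 0.4, a second-to-first
peak ratio (pks) of at most 0.5, and more than one spike per flight.

Spatial information per spike is

    SI = sum_i (p_i * lambda_i / lambda) * log2(lambda_i / lambda)

with p_i the occupancy probability of bin i, lambda_i the rate in bin i and
lambda the occupancy-weighted mean rate; 0*log(0) counts as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import spearmanr

__all__ = [
    "SpatialField1D", "compute_field", "spatial_information",
    "field_stability", "classify_place_cell", "field_geometry",
    "gaussian_window_smooth", "field_from_counts",
]


@dataclass
class SpatialField1D:
    bin_edges_m: np.ndarray
    occupancy_s: np.ndarray
    rate_hz: np.ndarray              # smoothed rate per bin
    mean_rate_hz: float
    si_bits: float
    stability: float
    pks: float
    peak_rate_hz: float
    centre_m: float
    width_m: float                   # width at half prominence
    n_spikes: int
    n_flights: int
    is_place_cell: bool = False

    @property
    def occupancy_p(self) -> np.ndarray:
        tot = self.occupancy_s.sum()
        return self.occupancy_s / tot if tot > 0 else self.occupancy_s


def gaussian_window_smooth(x: np.ndarray, window_bins: int = 7,
                           valid: np.ndarray | None = None) -> np.ndarray:
    """Smooth with a Gaussian window of total width ``window_bins`` bins
    (SD = window/6, truncated at the window edge), renormalized at edges
    and at unoccupied bins so the occupancy-weighted mean rate is conserved.
    """
    half = window_bins // 2
    k = np.arange(-half, half + 1)
    sd = window_bins / 6.0
    w = np.exp(-0.5 * (k / sd) ** 2)
    if valid is None:
        valid = np.ones_like(x, dtype=bool)
    num = np.convolve(np.where(valid, x, 0.0), w, mode="same")
    den = np.convolve(valid.astype(float), w, mode="same")
    out = np.zeros_like(x, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    out[~valid] = 0.0
    return out


def _bin_spikes_occupancy(spikes: np.ndarray, lin_flights: list[pd.DataFrame],
                          length_m: float, bin_m: float
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spike counts and occupancy (s) per spatial bin across flights.

    ``lin_flights`` hold per-sample (t, d_norm); positions are normalized
    per flight then mapped to the cluster mean length for metric units.
    """
    n_bins = max(2, int(np.ceil(length_m / bin_m)))
    edges = np.linspace(0.0, length_m, n_bins + 1)
    occ = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    for lf in lin_flights:
        t = lf["t"].to_numpy()
        d = lf["d_norm"].to_numpy() * length_m
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
        occ += np.histogram(d, bins=edges)[0] * dt
        m = (spikes >= t[0]) & (spikes <= t[-1])
        if m.any():
            ds = np.interp(spikes[m], t, d)
            cnt += np.histogram(ds, bins=edges)[0]
    return edges, cnt, occ


def field_from_counts(edges: np.ndarray, counts: np.ndarray,
                      occupancy: np.ndarray, smooth_bins: int = 7
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Raw and smoothed rate maps from spike counts and occupancy."""
    valid = occupancy > 0
    raw = np.zeros_like(counts, dtype=float)
    raw[valid] = counts[valid] / occupancy[valid]
    sm = gaussian_window_smooth(raw, smooth_bins, valid)
    return raw, sm


def spatial_information(occupancy_p: np.ndarray, rate_hz: np.ndarray) -> float:
    """Spatial information in bits per spike over occupied bins."""
    p = np.asarray(occupancy_p, dtype=float)
    lam = np.asarray(rate_hz, dtype=float)
    ok = p > 0
    p, lam = p[ok], lam[ok]
    mean = float(np.sum(p * lam))
    if mean <= 0:
        return 0.0
    ratio = lam / mean
    terms = np.zeros_like(ratio)
    pos = ratio > 0
    terms[pos] = p[pos] * ratio[pos] * np.log2(ratio[pos])
    return float(terms.sum())


def _pks(rate: np.ndarray) -> float:
    """Second/first peak ratio; 0 when the map has a single prominent field.

    Peaks are local maxima whose prominence reaches half the global
    maximum, so ripples on the main field's shoulder do not count as a
    second place field.
    """
    peak = rate.max()
    if peak <= 0:
        return 0.0
    idx, _props = find_peaks(rate, prominence=peak / 2.0)
    heights = sorted(rate[idx], reverse=True)
    if len(heights) < 2:
        return 0.0
    return float(heights[1] / heights[0])


def _width_at_half_prominence(rate: np.ndarray, bin_m: float) -> float:
    """Width of the main field where the rate crosses half its prominence
    (peak minus map minimum), interpolated between bins."""
    peak = rate.max()
    if peak <= 0:
        return 0.0
    i = int(np.argmax(rate))
    level = peak - 0.5 * (peak - rate.min())

    def _cross(side: int) -> float:
        j = i
        while 0 <= j + side < len(rate) and rate[j + side] >= level:
            j += side
        if j + side < 0 or j + side >= len(rate):
            return float(j)
        lo, hi = rate[j + side], rate[j]
        frac = (hi - level) / max(hi - lo, 1e-12)
        return j + side * frac

    return float((_cross(+1) - _cross(-1)) * bin_m)


def field_stability(spikes: np.ndarray, lin_flights: list[pd.DataFrame],
                    length_m: float, bin_m: float = 0.15,
                    smooth_bins: int = 7) -> float:
    """Spearman correlation between smoothed fields of the first versus the
    second half of the flights.  NaN when a half has no spikes."""
    if len(lin_flights) < 2:
        return np.nan
    half = len(lin_flights) // 2
    maps = []
    for part in (lin_flights[:half], lin_flights[half:]):
        edges, cnt, occ = _bin_spikes_occupancy(spikes, part, length_m, bin_m)
        if cnt.sum() == 0:
            return np.nan
        _, sm = field_from_counts(edges, cnt, occ, smooth_bins)
        maps.append(sm)
    rho = spearmanr(maps[0], maps[1])[0]
    return float(rho)


def compute_field(spikes: np.ndarray, lin_flights: list[pd.DataFrame],
                  length_m: float, bin_m: float = 0.15,
                  smooth_bins: int = 7) -> SpatialField1D:
    """Compute a unit's linearized tuning curve and selection statistics."""
    if not lin_flights:
        raise ValueError("at least one traversal required")
    edges, cnt, occ = _bin_spikes_occupancy(spikes, lin_flights, length_m, bin_m)
    if occ.sum() <= 0:
        raise ValueError("zero total occupancy")
    raw, sm = field_from_counts(edges, cnt, occ, smooth_bins)
    p = occ / occ.sum()
    si = spatial_information(p, sm)
    stab = field_stability(spikes, lin_flights, length_m, bin_m, smooth_bins)
    centres = (edges[:-1] + edges[1:]) / 2
    peak = float(sm.max())
    centre = float(centres[int(np.argmax(sm))]) if peak > 0 else np.nan
    mean_rate = float(np.sum(p * sm))
    return SpatialField1D(
        bin_edges_m=edges, occupancy_s=occ, rate_hz=sm,
        mean_rate_hz=mean_rate, si_bits=si, stability=stab,
        pks=_pks(sm), peak_rate_hz=peak, centre_m=centre,
        width_m=_width_at_half_prominence(sm, bin_m),
        n_spikes=int(cnt.sum()), n_flights=len(lin_flights))


def classify_place_cell(field: SpatialField1D, peak_min_hz: float = 3.0,
                        stability_min: float = 0.4, pks_max: float = 0.5,
                        spikes_per_flight_min: float = 1.0) -> bool:
    """Conjunction of the four place-cell criteria."""
    if field.n_flights == 0:
        return False
    spf = field.n_spikes / field.n_flights
    ok = (field.peak_rate_hz > peak_min_hz
          and np.isfinite(field.stability)
          and field.stability >= stability_min
          and field.pks <= pks_max
          and spf > spikes_per_flight_min)
    return bool(ok)


def field_geometry(fields: list[SpatialField1D]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell half-prominence widths and sorted neighbouring field-centre
    distances for the place cells of one trajectory."""
    widths = np.asarray([f.width_m for f in fields])
    centres = np.sort([f.centre_m for f in fields])
    dists = np.diff(centres) if len(centres) > 1 else np.empty(0)
    return widths, dists
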