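"""ECG delineation, feature extraction and distribution summaries.

A derivative-energy delineator detects R peaks and then searches
slope/threshold windows around each beat for wave onsets and offsets:
P_on, P_off, QRS_on, QRS_off, T_off plus the P/Q/R/S/T peak times and
amplitudes.  Undetected fiducials are reported absent rather than
fabricated.  From the fiducials, the eleven features of the validation
layout are computed per lead (six timing: Pdur, QRSdur, Tdur, PQint,
QTint, RRint; five amplitude: Pamp, Qamp, Ramp, Samp, Tamp), and
cohorts are summarized by per-feature mean, standard deviation and a
Gaussian kernel density estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import gaussian_kde

from .forward import LEADS

TIMING_FEATURES = ("Pdur", "QRSdur", "Tdur", "PQint", "QTint", "RRint")
AMPLITUDE_FEATURES = ("Pamp", "Qamp", "Ramp", "Samp", "Tamp")
ALL_FEATURES = TIMING_FEATURES + AMPLITUDE_FEATURES


@dataclass
class BeatFiducials:
    """Fiducials of one beat (ms; NaN = not detected)."""

    r_peak: float
    qrs_on: float = math.nan
    qrs_off: float = math.nan
    p_on: float = math.nan
    p_peak: float = math.nan
    p_off: float = math.nan
    t_peak: float = math.nan
    t_off: float = math.nan
    q_peak: float = math.nan
    s_peak: float = math.nan
    amplitudes: dict[str, float] = field(default_factory=dict)


@dataclass
class FiducialSet:
    """Delineation result for one channel."""

    beats: list[BeatFiducials]
    fs: float

    def __len__(self) -> int:
        return len(self.beats)

    def series(self, name: str) -> np.ndarray:
        return np.array([getattr(b, name) for b in self.beats])


def _moving_avg(x: np.ndarray, n: int) -> np.ndarray:
    n = max(n, 1)
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def _first_below(x: np.ndarray, thr: float, start: int, step: int,
                 sustain: int) -> int | None:
    """First index from ``start`` (moving by ``step``) where x stays
    below thr for ``sustain`` consecutive samples."""
    i = start
    run = 0
    while 0 <= i < len(x):
        if x[i] < thr:
            run += 1
            if run >= sustain:
                return i - step * (sustain - 1)
        else:
            run = 0
        i += step
    return None


def delineate(x: np.ndarray, fs: float) -> FiducialSet:
    """Delineate one ECG channel.

    R peaks come from a smoothed squared-derivative energy signal;
    QRS bounds from sustained energy-threshold crossings; T and P waves
    from peak search and threshold decay inside physiological windows.
    A flat or beat-free channel yields an empty set.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < int(2 * fs):
        raise ValueError("need at least 2 s of signal")
    if np.ptp(x) < 1e-6:
        return FiducialSet(beats=[], fs=fs)
    dt_ms = 1000.0 / fs
    d = np.gradient(x)
    energy = _moving_avg(d * d, int(0.040 * fs))
    energy_narrow = _moving_avg(d * d, max(int(0.008 * fs), 1))
    # isoelectric baseline from quiet (low slope-energy) samples
    quiet = energy < np.percentile(energy, 40)
    base = np.median(x[quiet]) if quiet.any() else np.median(x)
    xc = x - base
    thr = 0.15 * np.percentile(energy, 99.5)
    if thr <= 0:
        return FiducialSet(beats=[], fs=fs)
    peaks, _ = sps.find_peaks(energy, height=thr, distance=int(0.25 * fs))
    if len(peaks) == 0:
        return FiducialSet(beats=[], fs=fs)

    # smoothed copies for low-frequency wave search
    sos_t = sps.butter(2, 12.0, btype="lowpass", fs=fs, output="sos")
    xs = sps.sosfiltfilt(sos_t, xc)
    xp = _moving_avg(xc, int(0.010 * fs))

    beats: list[BeatFiducials] = []
    for k, pk in enumerate(peaks):
        w0 = max(pk - int(0.06 * fs), 0)
        w1 = min(pk + int(0.06 * fs), n)
        r_idx = w0 + int(np.argmax(np.abs(xc[w0:w1])))
        b = BeatFiducials(r_peak=r_idx * dt_ms)
        e_local = energy_narrow[max(pk - int(0.08 * fs), 0):
                                min(pk + int(0.08 * fs), n)].max()
        lo_thr = 0.012 * e_local
        sustain = max(int(0.010 * fs), 1)
        on = _first_below(energy_narrow, lo_thr, r_idx, -1, sustain)
        off = _first_below(energy_narrow, lo_thr, r_idx, +1, sustain)
        prev_pk = peaks[k - 1] if k > 0 else None
        next_pk = peaks[k + 1] if k + 1 < len(peaks) else None
        if on is not None and (prev_pk is None or on > prev_pk):
            b.qrs_on = on * dt_ms
        if off is not None and (next_pk is None or off < next_pk):
            b.qrs_off = off * dt_ms

        # T wave: search after QRS_off
        if off is not None:
            t0 = off + int(0.02 * fs)
            t1 = min(off + int(0.45 * fs), n)
            if next_pk is not None:
                t1 = min(t1, next_pk - int(0.08 * fs))
            if t1 - t0 > int(0.04 * fs):
                seg = xs[t0:t1]
                tp = t0 + int(np.argmax(np.abs(seg)))
                t_amp = xs[tp]
                b.t_peak = tp * dt_ms
                b.amplitudes["T"] = float(xc[tp])
                dec = np.abs(xs[tp:t1])
                below = np.flatnonzero(dec < 0.03 * abs(t_amp))
                if len(below):
                    b.t_off = (tp + below[0]) * dt_ms

        # P wave: search before QRS_on on a lightly smoothed copy (the
        # heavier T-wave smoothing would smear the R peak into the window)
        if on is not None:
            p1 = on - int(0.030 * fs)
            p0 = max(on - int(0.28 * fs), 0)
            if prev_pk is not None:
                p0 = max(p0, prev_pk + int(0.20 * fs))
            if p1 - p0 > int(0.03 * fs):
                seg = xp[p0:p1]
                pp = p0 + int(np.argmax(np.abs(seg)))
                p_amp = xp[pp]
                if abs(p_amp) > 0.015:
                    b.p_peak = pp * dt_ms
                    b.amplitudes["P"] = float(xc[pp])
                    dec_l = np.abs(xp[p0:pp + 1][::-1])
                    dec_r = np.abs(xp[pp:p1 + int(0.02 * fs)])
                    bl = np.flatnonzero(dec_l < 0.08 * abs(p_amp))
                    br = np.flatnonzero(dec_r < 0.08 * abs(p_amp))
                    if len(bl):
                        b.p_on = (pp - bl[0]) * dt_ms
                    if len(br):
                        b.p_off = (pp + br[0]) * dt_ms

        # Q/R/S peaks within the QRS window
        if on is not None and off is not None and off > on:
            seg = xc[on:off]
            rrel = r_idx - on
            b.amplitudes["R"] = float(xc[r_idx])
            if rrel > 1:
                qi = on + int(np.argmin(seg[:rrel] * np.sign(xc[r_idx])))
                b.q_peak = qi * dt_ms
                b.amplitudes["Q"] = float(xc[qi])
            if rrel < len(seg) - 1:
                si = on + rrel + 1 + int(np.argmin(
                    seg[rrel + 1:] * np.sign(xc[r_idx])))
                b.s_peak = si * dt_ms
                b.amplitudes["S"] = float(xc[si])
        beats.append(b)
    return FiducialSet(beats=beats, fs=fs)


def extract_features(record_data: np.ndarray, fs: float,
                     fiducials: dict[str, FiducialSet] | None = None
                     ) -> pd.DataFrame:
    """Beat-averaged 11-feature x 12-lead table from one record.

    Each channel is delineated independently (or supplied fiducial
    sets are used); intervals are fiducial differences, amplitudes are
    peak values relative to the channel median baseline.  Missing
    fiducials yield NaN features.
    """
    rows = {}
    for li, lead in enumerate(LEADS):
        fs_set = (fiducials or {}).get(lead) \
            or delineate(record_data[li], fs)
        feat = {f: math.nan for f in ALL_FEATURES}
        if len(fs_set):
            warn_ctx = warnings.catch_warnings()
            warn_ctx.__enter__()
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN beats
            p_on = fs_set.series("p_on")
            p_off = fs_set.series("p_off")
            q_on = fs_set.series("qrs_on")
            q_off = fs_set.series("qrs_off")
            t_off = fs_set.series("t_off")
            t_peak = fs_set.series("t_peak")
            r = fs_set.series("r_peak")
            feat["Pdur"] = np.nanmean(p_off - p_on)
            feat["QRSdur"] = np.nanmean(q_off - q_on)
            feat["Tdur"] = np.nanmean(t_off - q_off)
            feat["PQint"] = np.nanmean(q_on - p_on)
            feat["QTint"] = np.nanmean(t_off - q_on)
            if len(r) > 1:
                feat["RRint"] = float(np.nanmean(np.diff(r)))
            for key, col in (("P", "Pamp"), ("Q", "Qamp"), ("R", "Ramp"),
                             ("S", "Samp"), ("T", "Tamp")):
                vals = [b.amplitudes.get(key, math.nan)
                        for b in fs_set.beats]
                feat[col] = float(np.nanmean(vals)) \
                    if np.isfinite(vals).any() else math.nan
            warn_ctx.__exit__(None, None, None)
        rows[lead] = feat
    df = pd.DataFrame(rows).T
    df.index.name = "lead"
    return df[list(ALL_FEATURES)]


@dataclass
class DistributionSummary:
    """Per-feature/lead mean, standard deviation and density estimate."""

    mean: pd.DataFrame                    # leads x features
    std: pd.DataFrame
    densities: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]

    def to_csv(self) -> str:
        """Validation-table layout: one row per (lead, statistic)."""
        out = []
        for lead in self.mean.index:
            m = self.mean.loc[lead]
            s = self.std.loc[lead]
            out.append(pd.DataFrame(
                {"lead": lead, "stat": ["mu", "sigma"],
                 **{f: [m[f], s[f]] for f in self.mean.columns}}))
        return pd.concat(out, ignore_index=True).to_csv(
            index=False, float_format="%.4f")


def summarize(tables: list[pd.DataFrame],
              density_points: int = 128) -> DistributionSummary:
    """Cohort summary over per-record feature tables.

    Requires at least two records; degenerate (zero-variance) features
    get a bandwidth floor so the density stays proper.
    """
    if len(tables) < 2:
        raise ValueError("need at least two records to summarize")
    stacked = pd.concat(tables, keys=range(len(tables)))
    mean = stacked.groupby(level=1).mean().loc[list(LEADS)]
    std = stacked.groupby(level=1).std(ddof=1).loc[list(LEADS)]
    densities = {}
    for lead in LEADS:
        for feat in ALL_FEATURES:
            vals = stacked.xs(lead, level=1)[feat].dropna().to_numpy()
            if len(vals) < 2:
                continue
            spread = vals.std()
            bw_floor = max(spread, 1e-3 * max(abs(vals).max(), 1.0), 1e-6)
            grid = np.linspace(vals.min() - 3 * bw_floor,
                               vals.max() + 3 * bw_floor, density_points)
            if spread < 1e-12:
                dens = np.exp(-0.5 * ((grid - vals.mean()) / bw_floor)**2)
                dens /= np.trapezoid(dens, grid)
            else:
                dens = gaussian_kde(vals)(grid)
            densities[(lead, feat)] = (grid, dens)
    return DistributionSummary(mean=mean, std=std, densities=densities)
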