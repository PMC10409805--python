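"""Assembly of single-beat P waves and QRST complexes into 10 s records.

Atrial and ventricular beats are simulated by different forward setups,
so their amplitudes are made mutually consistent by Gaussian
conditioning on clinical lead-II statistics: the QRST complex is
rescaled so its R peak matches a draw from R | P, the PQ interval is
drawn from PQ | P_dur (from > 200 ms for 1st-degree AV block), and the
segments are joined with endpoint-exact sigmoid connectors.  Heart rate
variability enters through a power-law-correlated RR series; every beat
is individually warped in its [QRS_off, T_off] interval to a QT drawn
from QT | (QRS_dur, RR).  Records are finished with a composite noise
model (baseline wander, electrode movement transients, motion
artifacts, mixed in electrode space and scaled to a target SNR) and a
zero-phase 3rd-order Butterworth 0.5-150 Hz bandpass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import config
from .config import SynthesisConfig
from .forward import LEADS, BeatECG12, derive_leads


# ---------------------------------------------------------------------------
# Multivariate-normal feature coupling


@dataclass
class MVNSpec:
    """Correlated clinical feature blocks (lead II statistics).

    Three independent blocks: amplitudes (P_amp, R_amp) in mV,
    conduction (P_dur, PQ_int) in ms, and rate (QRS_dur, QT_int,
    RR_int) in ms.  Means and standard deviations default to published
    clinical values; the correlations are calibration knobs.
    """

    blocks: dict[str, tuple[tuple[str, ...], np.ndarray, np.ndarray]]

    @classmethod
    def default(cls, cfg: SynthesisConfig | None = None) -> "MVNSpec":
        cfg = cfg or SynthesisConfig()
        stats = config.CLINICAL_LEAD_II

        def block(names, corr):
            mu = np.array([stats[n][0] for n in names])
            sd = np.array([stats[n][1] for n in names])
            cov = np.outer(sd, sd) * np.asarray(corr)
            return tuple(names), mu, cov

        c = cfg
        blocks = {
            "amplitude": block(("P_amp", "R_amp"),
                               [[1, c.corr_amp], [c.corr_amp, 1]]),
            "conduction": block(("P_dur", "PQ_int"),
                                [[1, c.corr_pdur_pq], [c.corr_pdur_pq, 1]]),
            "rate": block(("QRS_dur", "QT_int", "RR_int"),
                          [[1, c.corr_qrs_qt, c.corr_qrs_rr],
                           [c.corr_qrs_qt, 1, c.corr_qt_rr],
                           [c.corr_qrs_rr, c.corr_qt_rr, 1]]),
        }
        spec = cls(blocks=blocks)
        spec.validate()
        return spec

    @classmethod
    def from_feature_table(cls, table, cfg: SynthesisConfig | None = None
                           ) -> "MVNSpec":
        """Fit block means/covariances from a per-record feature table
        (pandas DataFrame with the seven lead-II feature columns)."""
        spec = cls.default(cfg)
        for key, (names, _, _) in list(spec.blocks.items()):
            sub = table[list(names)].dropna().to_numpy(dtype=float)
            if len(sub) < 3:
                raise ValueError(f"too few rows to fit block {key!r}")
            mu = sub.mean(axis=0)
            cov = np.cov(sub.T)
            spec.blocks[key] = (names, mu, np.atleast_2d(cov))
        spec.validate()
        return spec

    def validate(self) -> None:
        for key, (_, _, cov) in self.blocks.items():
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(f"block {key!r} covariance not positive "
                                 "definite")

    def conditional(self, block: str, given: dict[str, float]):
        """Closed-form Gaussian conditioning within one block.

        Returns ``(names, mu_cond, cov_cond)`` of the remaining
        variables given the fixed ones.
        """
        names, mu, cov = self.blocks[block]
        gi = [i for i, n in enumerate(names) if n in given]
        ri = [i for i, n in enumerate(names) if n not in given]
        if not gi:
            return tuple(names[i] for i in ri), mu[ri], cov[np.ix_(ri, ri)]
        x = np.array([given[names[i]] for i in gi])
        c_rr = cov[np.ix_(ri, ri)]
        c_rg = cov[np.ix_(ri, gi)]
        c_gg = cov[np.ix_(gi, gi)]
        sol = np.linalg.solve(c_gg, x - mu[gi])
        mu_c = mu[ri] + c_rg @ sol
        cov_c = c_rr - c_rg @ np.linalg.solve(c_gg, c_rg.T)
        return tuple(names[i] for i in ri), mu_c, cov_c

    def draw_conditional(self, block: str, given: dict[str, float],
                         rng: np.random.Generator, size: int = 1):
        names, mu_c, cov_c = self.conditional(block, given)
        draws = rng.multivariate_normal(mu_c, cov_c, size=size,
                                        method="cholesky")
        return names, draws


@dataclass
class HRVParams:
    """Heart-rate-variability model: power-law-correlated RR series."""

    mean_hr: float = 70.0            # bpm
    spectral_exponent: float = 1.0   # beta of the 1/f^beta spectrum
    sdnn: float = 40.0               # ms
    n_beats: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = config.HR_RANGE_BPM
        if not lo <= self.mean_hr <= hi:
            raise ValueError(f"mean heart rate outside [{lo}, {hi}] bpm")
        if self.sdnn < 0:
            raise ValueError("sdnn must be non-negative")


@dataclass
class NoiseModel:
    """Composite ECG noise description.

    Components: slow baseline wander (< 0.5 Hz), sparse electrode
    movement transients, and band-limited motion artifact; mixed in
    electrode space so the lead identities also hold for the noise, and
    scaled so the total 12-lead SNR equals ``snr_db``.
    """

    snr_db: float = 17.5
    weights: dict[str, float] = field(default_factory=lambda: {
        "baseline_wander": 1.0, "electrode_movement": 0.6,
        "motion_artifact": 0.8})
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("component weights must be non-negative")


# ---------------------------------------------------------------------------
# Beat-level operations


def _lead_ii_peak(beat: BeatECG12, t0: float, t1: float) -> float:
    """Largest absolute lead-II excursion in [t0, t1] ms."""
    x = beat.lead("II")
    i0 = max(int(t0 / beat.dt), 0)
    i1 = min(int(math.ceil(t1 / beat.dt)) + 1, len(x))
    seg = x[i0:i1]
    return float(np.abs(seg).max())


def scale_qrst(qrst: BeatECG12, pwave: BeatECG12, mvn: MVNSpec,
               rng: np.random.Generator) -> BeatECG12:
    """Rescale the QRST complex to an R amplitude drawn from R | P.

    The measured lead-II P amplitude conditions the clinical
    amplitude block; one global factor is applied to all 12 leads so
    the lead-II R peak matches the draw (truncated at a small positive
    floor).
    """
    p_amp = _lead_ii_peak(pwave, 0.0, pwave.fiducials["P_off"])
    if p_amp <= 0:
        raise ValueError("P amplitude not measurable")
    names, mu_c, cov_c = mvn.conditional("amplitude", {"P_amp": p_amp})
    sd = math.sqrt(max(cov_c[0, 0], 0.0))
    floor = 0.15 * mvn.blocks["amplitude"][1][1]
    target = -np.inf
    for _ in range(100):
        target = mu_c[0] + sd * rng.standard_normal()
        if target >= floor:
            break
    target = max(target, floor)
    r_meas = _lead_ii_peak(qrst, qrst.fiducials["QRS_on"],
                           qrst.fiducials["QRS_off"])
    factor = target / max(r_meas, 1e-9)
    return BeatECG12(data=qrst.data * factor, fs=qrst.fs,
                     fiducials=dict(qrst.fiducials), label=qrst.label)


def sample_pq(p_dur: float, mvn: MVNSpec, avb: bool,
              rng: np.random.Generator) -> float:
    """PQ interval from PQ | P_dur, restricted to PQ >= P_dur
    (and PQ > 200 ms under 1st-degree AV block).

    The restriction is applied by sampling the conditional Gaussian
    truncated at the lower bound (equivalent to rejection, but exact
    even when the bound sits far in the tail).
    """
    if p_dur <= 0:
        raise ValueError("P duration must be positive")
    from scipy.stats import truncnorm

    names, mu_c, cov_c = mvn.conditional("conduction", {"P_dur": p_dur})
    sd = math.sqrt(max(cov_c[0, 0], 1e-12))
    lower = max(p_dur, config.AVB_PQ_MIN if avb else 0.0)
    a = (lower - mu_c[0]) / sd
    if a > 8.0:
        raise ValueError(
            f"PQ lower bound {lower} ms unreachable from the conditional "
            f"distribution (mean {mu_c[0]:.1f}, sd {sd:.1f})")
    u = rng.random()
    return float(truncnorm.ppf(u, a, np.inf, loc=mu_c[0], scale=sd))


def _sigmoid_connector(y0: np.ndarray, y1: np.ndarray, n: int) -> np.ndarray:
    """Endpoint-exact logistic transition of n samples between two
    per-lead amplitude vectors (n x leads orientation: returns (L, n))."""
    if n == 0:
        return np.zeros((len(y0), 0))
    t = np.linspace(0.0, 1.0, n + 2)[1:-1]
    s = 1.0 / (1.0 + np.exp(-9.19 * (t - 0.5)))   # 1%..99% over the span
    s = (s - s[0]) / (s[-1] - s[0]) if n > 1 else np.array([0.5])
    return y0[:, None] + (y1 - y0)[:, None] * s[None, :]


def concat_beat(pwave: BeatECG12, qrst: BeatECG12, pq: float) -> BeatECG12:
    """One full heart beat: P wave, sigmoid PQ connector, QRST complex.

    The connector spans pq - P_dur per lead from the P_off amplitude to
    the QRS_on amplitude; ground-truth fiducials are propagated into
    beat time (P_on at 0 ms).
    """
    if pq < pwave.fiducials["P_off"] - 1e-9:
        raise ValueError("PQ interval shorter than the P wave")
    dt = pwave.dt
    p_dur = pwave.fiducials["P_off"]
    n_p = int(round(p_dur / dt))
    pseg = pwave.data[:, :n_p]
    q_on = qrst.fiducials["QRS_on"]
    i_q = int(round(q_on / dt))
    t_end = min(qrst.fiducials["T_off"] + 60.0,
                qrst.data.shape[1] * dt)
    qseg = qrst.data[:, i_q:int(round(t_end / dt))]
    n_c = int(round(pq / dt)) - n_p
    conn = _sigmoid_connector(pseg[:, -1] if n_p else np.zeros(12),
                              qseg[:, 0], n_c)
    data = np.concatenate([pseg, conn, qseg], axis=1)
    fid = {
        "P_on": 0.0,
        "P_off": p_dur,
        "QRS_on": pq,
        "QRS_off": pq + (qrst.fiducials["QRS_off"] - q_on),
        "T_off": pq + (qrst.fiducials["T_off"] - q_on),
    }
    return BeatECG12(data=data, fs=pwave.fs, fiducials=fid,
                     label=qrst.label)


def generate_rr_series(hrv: HRVParams) -> np.ndarray:
    """RR intervals (ms) with a 1/f^beta long-range-correlated spectrum.

    Spectral synthesis: Gaussian spectral amplitudes shaped by
    f^(-beta/2), inverse transformed, rescaled to the requested SDNN
    and shifted to the mean RR of the configured heart rate.
    """
    rng = np.random.default_rng(hrv.seed)
    n = max(hrv.n_beats, 4)
    nfft = 1 << max(int(math.ceil(math.log2(n))), 4)
    freqs = np.fft.rfftfreq(nfft, d=1.0)
    amp = np.zeros(len(freqs))
    amp[1:] = freqs[1:] ** (-hrv.spectral_exponent / 2.0)
    phase = rng.uniform(0, 2 * np.pi, len(freqs))
    spec = amp * np.exp(1j * phase)
    series = np.fft.irfft(spec, n=nfft)[:n]
    sd = series.std()
    if sd > 0 and hrv.sdnn > 0:
        series = series / sd * hrv.sdnn
    else:
        series = np.zeros(n)
    return 60000.0 / hrv.mean_hr + series


def stretch_beat(beat: BeatECG12, rr_target: float, mvn: MVNSpec,
                 rng: np.random.Generator) -> BeatECG12:
    """Warp the [QRS_off, T_off] interval to a QT drawn from
    QT | (QRS_dur, RR = rr_target); P and QRS segments are untouched."""
    fid = beat.fiducials
    for k in ("QRS_on", "QRS_off", "T_off"):
        if k not in fid:
            raise ValueError("beat lacks fiducials")
    dt = beat.dt
    qrs_dur = fid["QRS_off"] - fid["QRS_on"]
    names, mu_c, cov_c = mvn.conditional(
        "rate", {"QRS_dur": qrs_dur, "RR_int": rr_target})
    sd = math.sqrt(max(cov_c[0, 0], 0.0))
    qt = -np.inf
    for _ in range(100):
        qt = mu_c[0] + sd * rng.standard_normal()
        if qt > qrs_dur + 20.0:
            break
    qt = max(qt, qrs_dur + 20.0)
    i_off = int(round(fid["QRS_off"] / dt))
    i_t = int(round(fid["T_off"] / dt))
    n_new = int(round((qt - qrs_dur) / dt))
    seg = beat.data[:, i_off:i_t]
    if seg.shape[1] < 2 or n_new < 2:
        return beat
    x_old = np.linspace(0.0, 1.0, seg.shape[1])
    x_new = np.linspace(0.0, 1.0, n_new)
    warped = np.vstack([np.interp(x_new, x_old, seg[i]) for i in range(12)])
    data = np.concatenate([beat.data[:, :i_off], warped,
                           beat.data[:, i_t:]], axis=1)
    new_fid = dict(fid)
    new_fid["T_off"] = fid["QRS_off"] + n_new * dt
    return BeatECG12(data=data, fs=beat.fs, fiducials=new_fid,
                     label=beat.label)


def assemble_record(beats: list[BeatECG12], rr: np.ndarray,
                    n_samples: int = config.RECORD_SAMPLES) -> tuple:
    """Place beats at cumulative RR onsets with sigmoid TP segments.

    Returns ``(data, fiducials)`` where data is (12, n_samples) and
    fiducials is the list of per-beat ground-truth dictionaries in
    record time (ms).  Raises when a beat does not fit its RR slot.
    """
    fs = beats[0].fs
    dt = 1000.0 / fs
    onsets_ms = np.concatenate([[0.0], np.cumsum(rr)])[:len(beats)]
    total = onsets_ms[-1] + beats[-1].data.shape[1] * dt
    if total < n_samples * dt:
        raise ValueError("beats do not cover the record duration")
    n_total = int(math.ceil(total / dt)) + 1
    data = np.zeros((12, n_total))
    fiducials = []
    cursor = 0
    for k, beat in enumerate(beats):
        i0 = int(round(onsets_ms[k] / dt))
        nb = beat.data.shape[1]
        if k + 1 < len(beats):
            slot = int(round(onsets_ms[k + 1] / dt)) - i0
            if nb > slot:
                raise ValueError(
                    f"beat {k} ({nb * dt:.0f} ms) exceeds its RR slot "
                    f"({slot * dt:.0f} ms)")
        if i0 > cursor:   # TP segment from previous beat end
            y0 = data[:, cursor - 1] if cursor else np.zeros(12)
            data[:, cursor:i0] = _sigmoid_connector(y0, beat.data[:, 0],
                                                    i0 - cursor)
        data[:, i0:i0 + nb] = beat.data
        cursor = i0 + nb
        fiducials.append({k2: v + onsets_ms[k]
                          for k2, v in beat.fiducials.items()})
    out = data[:, :n_samples]
    fiducials = [f for f in fiducials if f["P_on"] < n_samples * dt]
    return out, fiducials


# ---------------------------------------------------------------------------
# Noise and filtering


def _electrode_noise(n: int, fs: float, rng: np.random.Generator,
                     weights: dict[str, float]) -> np.ndarray:
    """One electrode's composite noise trace (unit-power components)."""
    t = np.arange(n) / fs
    parts = []
    # baseline wander: sum of slow sinusoids below 0.5 Hz
    bw = np.zeros(n)
    for _ in range(4):
        f = rng.uniform(0.05, 0.45)
        bw += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * f * t
                                             + rng.uniform(0, 2 * np.pi))
    parts.append(("baseline_wander", bw))
    # electrode movement: sparse smoothed step transients
    em = np.zeros(n)
    n_events = rng.poisson(2.0)
    for _ in range(n_events):
        t0 = rng.integers(0, n)
        amp = rng.normal(0, 1.0)
        tau = rng.uniform(0.1, 0.5) * fs
        k = np.arange(n - t0)
        em[t0:] += amp * np.exp(-k / tau)
    parts.append(("electrode_movement", em))
    # motion artifact: band-limited stochastic component
    white = rng.standard_normal(n)
    sos = sps.butter(2, [1.0, 12.0], btype="bandpass", fs=fs, output="sos")
    ma = sps.sosfiltfilt(sos, white)
    env = 1.0 + 0.8 * np.sin(2 * np.pi * rng.uniform(0.05, 0.2) * t
                             + rng.uniform(0, 2 * np.pi))
    parts.append(("motion_artifact", ma * env))
    out = np.zeros(n)
    for name, sig in parts:
        p = np.sqrt(np.mean(sig**2))
        if p > 0:
            out += weights.get(name, 0.0) * sig / p
    return out


def add_noise(raw: np.ndarray, noise: NoiseModel,
              fs: float = config.FS_OUT) -> np.ndarray:
    """Superimpose composite ECG noise at the requested SNR.

    Noise is generated per electrode and combined into the 12 leads so
    Einthoven/Goldberger/Wilson identities also hold for the noisy
    signal; one global factor enforces
    10 log10(P_signal / P_noise) = snr_db exactly.
    """
    p_sig = float(np.mean(raw**2))
    if p_sig <= 0:
        raise ValueError("zero-power signal")
    if not np.isfinite(noise.snr_db):
        return raw.copy()
    rng = np.random.default_rng(noise.seed)
    n = raw.shape[1]
    elec = {name: _electrode_noise(n, fs, rng, noise.weights)
            for name in ("RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5",
                         "V6")}
    lead_noise = derive_leads(elec, fs=fs).data
    p_noise = float(np.mean(lead_noise**2))
    target_p = p_sig / 10.0 ** (noise.snr_db / 10.0)
    lead_noise *= math.sqrt(target_p / p_noise)
    return raw + lead_noise


def butterworth_sos(fs: float = config.FS_OUT):
    """The single-pass high-pass / low-pass filter prototypes."""
    hp = sps.butter(config.FILTER_ORDER, config.FILTER_HP_HZ,
                    btype="highpass", fs=fs, output="sos")
    lp = sps.butter(config.FILTER_ORDER, config.FILTER_LP_HZ,
                    btype="lowpass", fs=fs, output="sos")
    return hp, lp


def bandpass_filter(noisy: np.ndarray,
                    fs: float = config.FS_OUT) -> np.ndarray:
    """Zero-phase 3rd-order Butterworth band-pass (0.5 / 150 Hz)."""
    hp, lp = butterworth_sos(fs)
    out = sps.sosfiltfilt(hp, noisy, axis=-1)
    return sps.sosfiltfilt(lp, out, axis=-1)


# ---------------------------------------------------------------------------
# Record orchestration


@dataclass
class ECGRecord:
    """A complete 10 s record with its ground truth and provenance."""

    raw: np.ndarray
    noisy: np.ndarray
    filtered: np.ndarray
    fs: float
    label: str
    anatomy_id: str
    fiducials: list[dict[str, float]]
    snr_db: float
    seeds: dict[str, int] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for arr in (self.raw, self.noisy, self.filtered):
            if arr.shape != (12, config.RECORD_SAMPLES):
                raise ValueError("records must be 12 x 5000 samples")


def synthesize_record(pwave: BeatECG12, qrst: BeatECG12, label: str,
                      seed: int, cfg: SynthesisConfig | None = None,
                      mvn: MVNSpec | None = None, avb: bool = False,
                      anatomy_id: str = "a0",
                      provenance: dict | None = None) -> ECGRecord:
    """Full synthesis chain from two single beats to a labeled record."""
    cfg = cfg or SynthesisConfig()
    mvn = mvn or MVNSpec.default(cfg)
    rng = np.random.default_rng(seed)

    qrst_s = scale_qrst(qrst, pwave, mvn, rng)
    p_dur = pwave.fiducials["P_off"] - pwave.fiducials["P_on"]
    pq = sample_pq(p_dur, mvn, avb, rng)
    beat = concat_beat(pwave, qrst_s, pq)

    qt = beat.fiducials["T_off"] - beat.fiducials["QRS_on"]
    rr_names, mu_rr, cov_rr = mvn.conditional("rate", {"QT_int": qt})
    i_rr = rr_names.index("RR_int")
    rr_mean = float(mu_rr[i_rr]
                    + math.sqrt(max(cov_rr[i_rr, i_rr], 0))
                    * rng.standard_normal())
    lo, hi = cfg.hr_range_bpm
    beat_ms = beat.data.shape[1] * beat.dt
    hr = float(np.clip(60000.0 / rr_mean, lo,
                       min(hi, 60000.0 / (beat_ms + 40.0))))
    n_beats = int(math.ceil(config.RECORD_SECONDS * 1000.0
                            / (60000.0 / hi))) + 4

    record_data = None
    for attempt in range(5):
        hrv = HRVParams(mean_hr=hr, spectral_exponent=cfg.spectral_exponent,
                        sdnn=cfg.sdnn_ms, n_beats=n_beats,
                        seed=int(rng.integers(0, 2**31 - 1)))
        rr = generate_rr_series(hrv)
        rr = np.clip(rr, beat_ms + 20.0, None)
        beats = [stretch_beat(beat, r, mvn, rng) for r in rr]
        # a QT warp can lengthen a beat beyond its drawn slot; widen the
        # affected RR intervals minimally so every beat fits
        rr_eff = np.array([max(r, b.data.shape[1] * b.dt + 20.0)
                           for r, b in zip(rr, beats)])
        try:
            record_data, fiducials = assemble_record(beats, rr_eff)
            break
        except ValueError:
            continue
    if record_data is None:
        raise ValueError("could not assemble record within RR constraints")

    snr = float(rng.uniform(*cfg.snr_range_db))
    noise = NoiseModel(snr_db=snr, seed=int(rng.integers(0, 2**31 - 1)))
    noisy = add_noise(record_data, noise)
    filtered = bandpass_filter(noisy)
    return ECGRecord(raw=record_data, noisy=noisy, filtered=filtered,
                     fs=config.FS_OUT, label=label, anatomy_id=anatomy_id,
                     fiducials=fiducials, snr_db=snr,
                     seeds={"record": seed, "noise": noise.seed,
                            "hrv": hrv.seed},
                     provenance=dict(provenance or {}))
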