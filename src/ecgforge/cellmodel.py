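"""Mitchell-Schaeffer action potentials, APD calibration and APD fields.

The two-current Mitchell-Schaeffer model drives all cellular dynamics:

    dv/dt = h * v^2 * (1 - v) / tau_in  -  v / tau_out  +  J_stim
    dh/dt = (1 - h) / tau_open   if v <  V_gate
          = -h / tau_close       if v >= V_gate

with normalized voltage v in [0, 1] mapped affinely onto physical
membrane voltage  V_m = V_min + v * (V_max - V_min).  The action
potential duration is controlled almost entirely by tau_close, which is
calibrated numerically against a target APD.  Template banks (one trace
per 1 ms of APD) feed the reaction-Eikonal voltage construction, and the
UVC-weighted APD field creates the repolarization gradients that shape
the T wave.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from . import config
from .geometry import CardiacMesh


@dataclass(frozen=True)
class MSParams:
    """Mitchell-Schaeffer parameters plus the physical voltage mapping."""

    v_gate: float = 0.13
    v_min: float = -86.2     # mV, resting membrane voltage
    v_max: float = 40.0      # mV, action potential peak
    tau_in: float = 0.3
    tau_out: float = 5.4
    tau_open: float = 80.0
    tau_close: float = 150.0

    def __post_init__(self) -> None:
        if min(self.tau_in, self.tau_out, self.tau_open, self.tau_close) <= 0:
            raise ValueError("all time constants must be positive")
        if not 0 < self.v_gate < 1:
            raise ValueError("V_gate must lie in (0, 1)")
        if self.v_min >= self.v_max:
            raise ValueError("V_min must be below V_max")
        if self.tau_in >= self.tau_out:
            raise ValueError("excitability requires tau_in < tau_out")


#: Ventricular sinus-rhythm cell (fixed across all healthy simulations).
SINUS_PARAMS = MSParams()

#: Infarct border-zone variant: depolarized rest, reduced peak, slower
#: inward and faster outward kinetics.
BZ_PARAMS = MSParams(v_gate=0.13, v_min=-73.1, v_max=12.5,
                     tau_in=0.45, tau_out=3.6, tau_open=44.0)

#: Atrial surrogate cell with atrial resting/peak voltages.
ATRIAL_PARAMS = MSParams(v_min=-80.0, v_max=20.0)

#: Fibrotic atrial remodeling expressed at template level.
FIBROTIC_AMPLITUDE_FACTOR = 0.7
FIBROTIC_APD_FACTOR = 0.85


@dataclass
class APTemplate:
    """A physical-voltage action potential trace sampled at fixed dt."""

    trace: np.ndarray        # mV
    dt: float                # ms
    apd: float               # ms, upstroke to V_gate downcrossing
    apd90: float             # ms, upstroke to 90% repolarization
    upstroke_offset: float   # ms from trace start to max dV/dt
    params: MSParams

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.trace)) * self.dt


@dataclass
class TWaveParams:
    """Repolarization-gradient parameterization of the T wave."""

    i_sinus: MSParams = SINUS_PARAMS
    apd_min: float = 162.5
    apd_max: float = 237.5
    q_w: tuple[float, float, float, float] = (-0.3, 0.125, 0.0, 0.95)

    def __post_init__(self) -> None:
        if self.apd_min >= self.apd_max:
            raise ValueError("apd_min must be below apd_max")


def ms_simulate(params: MSParams, duration: float, dt: float,
                stim_time: float | None = 5.0,
                stim_duration: float = 1.0,
                stim_amplitude: float = 0.6):
    """Integrate the two-current model; returns (t, v, h).

    Explicit Euler at time step ``dt`` (must satisfy dt <= 0.1 * tau_in
    for stability of the fast inward current).  ``stim_time=None`` leaves
    the cell unstimulated.
    """
    if dt > 0.1 * params.tau_in + 1e-12:
        raise ValueError(
            f"dt={dt} unstable; need dt <= 0.1*tau_in = {0.1 * params.tau_in}")
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    v = np.zeros(n)
    h = np.ones(n)
    vi, hi = 0.0, 1.0
    s0 = -1.0 if stim_time is None else stim_time
    s1 = s0 + stim_duration
    for k in range(1, n):
        tk = t[k - 1]
        stim = stim_amplitude if (s0 <= tk < s1) else 0.0
        dv = hi * vi * vi * (1 - vi) / params.tau_in - vi / params.tau_out \
            + stim
        dh = (1 - hi) / params.tau_open if vi < params.v_gate \
            else -hi / params.tau_close
        vi = min(max(vi + dt * dv, 0.0), 1.0)
        hi = min(max(hi + dt * dh, 0.0), 1.0)
        v[k] = vi
        h[k] = hi
    return t, v, h


def _simulate_batch(params: MSParams, tau_close: np.ndarray, duration: float,
                    dt: float, stim_time: float = 5.0,
                    stim_duration: float = 1.0,
                    stim_amplitude: float = 0.6) -> np.ndarray:
    """Vectorized integration over a batch of tau_close values.

    Returns the normalized voltage array of shape (len(tau_close), nt).
    """
    tau_close = np.asarray(tau_close, dtype=float)
    n = int(round(duration / dt)) + 1
    m = len(tau_close)
    v = np.zeros((m, n))
    vi = np.zeros(m)
    hi = np.ones(m)
    s0, s1 = stim_time, stim_time + stim_duration
    for k in range(1, n):
        tk = (k - 1) * dt
        stim = stim_amplitude if (s0 <= tk < s1) else 0.0
        dv = hi * vi * vi * (1 - vi) / params.tau_in - vi / params.tau_out \
            + stim
        gate = vi < params.v_gate
        dh = np.where(gate, (1 - hi) / params.tau_open, -hi / tau_close)
        vi = np.clip(vi + dt * dv, 0.0, 1.0)
        hi = np.clip(hi + dt * dh, 0.0, 1.0)
        v[:, k] = vi
    return v


def measure_apd(t: np.ndarray, v: np.ndarray,
                v_gate: float = 0.13) -> tuple[float, float, float]:
    """(apd, apd90, upstroke time) from a normalized single-AP trace.

    APD runs from the instant of maximum dv/dt to the downstroke
    crossing of ``v_gate``; APD90 to the downstroke crossing of 10% of
    the peak.  Returns NaNs when no action potential was elicited.
    """
    if v.max() < v_gate:
        return float("nan"), float("nan"), float("nan")
    dv = np.diff(v)
    k_up = int(np.argmax(dv))
    t_up = t[k_up]
    k_peak = int(np.argmax(v))

    def _downcross(level: float) -> float:
        below = np.flatnonzero(v[k_peak:] < level)
        if len(below) == 0:
            return float("nan")
        k = k_peak + below[0]
        # linear interpolation between samples k-1 and k
        v0, v1 = v[k - 1], v[k]
        frac = (v0 - level) / max(v0 - v1, 1e-12)
        return t[k - 1] + frac * (t[k] - t[k - 1])

    apd = _downcross(v_gate) - t_up
    apd90 = _downcross(0.1 * v.max()) - t_up
    return float(apd), float(apd90), float(t_up)


_CAL_DT = 0.025   # ms, template integration step (<= 0.1 * tau_in)


@functools.lru_cache(maxsize=8)
def _apd_curve(params: MSParams):
    """Monotone APD(tau_close) relationship sampled on a tau grid."""
    taus = np.geomspace(20.0, 500.0, 40)
    duration = 700.0
    v = _simulate_batch(params, taus, duration, _CAL_DT)
    t = np.arange(v.shape[1]) * _CAL_DT
    apds = np.array([measure_apd(t, v[i], params.v_gate)[0]
                     for i in range(len(taus))])
    ok = np.isfinite(apds)
    taus, apds = taus[ok], apds[ok]
    keep = np.concatenate([[True], np.diff(apds) > 0])
    return taus[keep], apds[keep]


def calibrate_tau_close_batch(params: MSParams,
                              apd_targets: np.ndarray) -> np.ndarray:
    """Vectorized tau_close calibration for a batch of APD targets.

    Inverts the cached monotone APD(tau_close) curve with a shape
    preserving interpolant and refines with Newton steps on batched
    simulations until every measured APD is within 0.25 ms of its
    target.  Raises ``ValueError`` naming the achievable APD interval
    when any target lies outside it.
    """
    targets = np.atleast_1d(np.asarray(apd_targets, dtype=float))
    taus_grid, apds_grid = _apd_curve(params)
    if targets.min() < apds_grid[0] or targets.max() > apds_grid[-1]:
        raise ValueError(
            f"APD target outside achievable range "
            f"[{apds_grid[0]:.1f}, {apds_grid[-1]:.1f}] ms")
    inv = PchipInterpolator(apds_grid, taus_grid)
    dtau_dapd = inv.derivative()
    taus = inv(targets)
    t = None
    for _ in range(5):
        v = _simulate_batch(params, taus, 700.0, _CAL_DT)
        if t is None:
            t = np.arange(v.shape[1]) * _CAL_DT
        apds = np.array([measure_apd(t, v[i], params.v_gate)[0]
                         for i in range(len(taus))])
        err = apds - targets
        if np.nanmax(np.abs(err)) < 0.25:
            break
        slope = dtau_dapd(np.clip(apds, apds_grid[0], apds_grid[-1]))
        taus = np.clip(taus - err * slope, taus_grid[0], taus_grid[-1])
    return taus


def calibrate_tau_close(params: MSParams, apd_target: float) -> float:
    """tau_close whose simulated APD matches ``apd_target`` within 1 ms."""
    return float(calibrate_tau_close_batch(params, [apd_target])[0])


def make_template(params: MSParams, apd_target: float,
                  dt: float = 0.5) -> APTemplate:
    """Physical-voltage AP template with the requested APD.

    The normalized trace is integrated at the calibration step and
    resampled to ``dt`` for storage; the resting value equals ``V_min``
    exactly and the trace is trimmed so that t=0 is 2 ms before the
    upstroke.
    """
    tau = calibrate_tau_close(params, apd_target)
    p = replace(params, tau_close=tau)
    v = _simulate_batch(p, [tau], 700.0, _CAL_DT)[0]
    t = np.arange(len(v)) * _CAL_DT
    apd, apd90, t_up = measure_apd(t, v, p.v_gate)
    t_out = np.arange(0.0, 700.0, dt)
    lead_in = 2.0
    v_out = np.interp(t_out + (t_up - lead_in), t, v, left=0.0, right=v[-1])
    trace = params.v_min + v_out * (params.v_max - params.v_min)
    trace[0] = params.v_min
    return APTemplate(trace=trace, dt=dt, apd=apd, apd90=apd90,
                      upstroke_offset=lead_in, params=p)


class TemplateBank:
    """Templates on a 1 ms APD grid, evaluated by linear interpolation.

    All traces share the storage dt and length; ``voltage_matrix`` is a
    (n_apd, n_samples) array of physical voltages used for vectorized
    reaction-Eikonal evaluation.
    """

    def __init__(self, params: MSParams, apd_grid: np.ndarray,
                 dt: float = 0.5):
        self.params = params
        self.apd_grid = np.asarray(apd_grid, dtype=float)
        self.dt = dt
        taus = calibrate_tau_close_batch(params, self.apd_grid)
        v = _simulate_batch(params, taus, 700.0, _CAL_DT)
        t = np.arange(v.shape[1]) * _CAL_DT
        self.apd = np.empty(len(taus))
        self.apd90 = np.empty(len(taus))
        ups = np.empty(len(taus))
        for i in range(len(taus)):
            self.apd[i], self.apd90[i], ups[i] = measure_apd(
                t, v[i], params.v_gate)
        t_out = np.arange(0.0, 700.0, dt)
        lead_in = 2.0
        mat = np.empty((len(taus), len(t_out)))
        for i in range(len(taus)):
            mat[i] = np.interp(t_out + (ups[i] - lead_in), t, v[i],
                               left=0.0, right=v[i, -1])
        self.voltage_matrix = params.v_min + mat * (params.v_max - params.v_min)
        self.upstroke_offset = lead_in
        self.rest = params.v_min

    def interp_weights(self, apd: np.ndarray):
        """(lower index, upper index, upper weight) for APD interpolation."""
        a = np.asarray(apd, dtype=float)
        lo, hi = self.apd_grid[0], self.apd_grid[-1]
        if np.any(a < lo - 0.5) or np.any(a > hi + 0.5):
            raise ValueError(
                f"APD outside bank range [{lo}, {hi}] ms")
        a = np.clip(a, lo, hi)
        i1 = np.clip(np.searchsorted(self.apd_grid, a), 1,
                     len(self.apd_grid) - 1)
        i0 = i1 - 1
        w = (a - self.apd_grid[i0]) / (self.apd_grid[i1] - self.apd_grid[i0])
        return i0, i1, w

    def to_text(self) -> str:
        """Columnar (time ms, voltage mV per APD) serialization."""
        t = np.arange(self.voltage_matrix.shape[1]) * self.dt
        header = "time_ms," + ",".join(f"apd_{a:.0f}" for a in self.apd_grid)
        body = np.column_stack([t, self.voltage_matrix.T])
        lines = [header] + [",".join(f"{x:.4f}" for x in row) for row in body]
        return "\n".join(lines) + "\n"


@functools.lru_cache(maxsize=8)
def get_bank(params: MSParams, apd_lo: float = 140.0, apd_hi: float = 260.0,
             spacing: float = 1.0) -> TemplateBank:
    """Process-wide cached template bank for a fixed cell parameterization."""
    grid = np.arange(apd_lo, apd_hi + spacing / 2, spacing)
    return TemplateBank(params, grid)


def make_atrial_template(region_kind: str = "healthy",
                         apd_target: float = 250.0) -> APTemplate:
    """Atrial AP surrogate; the fibrotic variant has a reduced upstroke
    amplitude and a shortened APD relative to the healthy target."""
    if region_kind not in ("healthy", "fibrotic"):
        raise ValueError(f"unknown region kind {region_kind!r}")
    if region_kind == "fibrotic":
        apd_target = apd_target * FIBROTIC_APD_FACTOR
        p = ATRIAL_PARAMS
        vmax = p.v_min + FIBROTIC_AMPLITUDE_FACTOR * (p.v_max - p.v_min)
        params = replace(p, v_max=vmax)
    else:
        params = ATRIAL_PARAMS
    return make_template(params, apd_target)


# ---------------------------------------------------------------------------
# APD field


def compute_apd_field(mesh: CardiacMesh, tw: TWaveParams) -> np.ndarray:
    """Per-node APD map from a weighted linear combination of UVCs.

    s(x) = q_rho * rho + q_v * v~ + q_phi * (phi/pi) + q_z * z, with the
    chamber encoded as v~ = -1 (lv) / +1 (rv), min-max normalized onto
    [apd_min, apd_max] over the myocardium.  A spatially constant s maps
    every node to the interval midpoint.
    """
    if "rho" not in mesh.uvc or mesh.n_nodes == 0:
        raise ValueError("mesh has no universal coordinates")
    q_rho, q_v, q_phi, q_z = tw.q_w
    vtilde = np.where(mesh.uvc["v"] == "rv", 1.0, -1.0)
    s = (q_rho * mesh.uvc["rho"] + q_v * vtilde
         + q_phi * (mesh.uvc["phi"] / np.pi) + q_z * mesh.uvc["z"])
    lo, hi = s.min(), s.max()
    if hi - lo < 1e-12:
        return np.full(mesh.n_nodes, 0.5 * (tw.apd_min + tw.apd_max))
    return tw.apd_min + (s - lo) / (hi - lo) * (tw.apd_max - tw.apd_min)
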