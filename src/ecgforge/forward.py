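"""Reaction-Eikonal voltage fields and the infinite-volume-conductor ECG.

Transmembrane voltage is constructed without diffusion by shifting
action-potential templates in time according to the activation map:
V_m(x, t) = template(t - LAT(x); APD(x)), with inert or unreached tissue
resting permanently.  Electrode potentials follow from the elemental
dipole sum in an unbounded homogeneous medium,

    phi(y, t) = 1 / (4 pi sigma_m) * sum_e  sigma_i grad V_m(x_e, t)
                 . (y - x_e) / |y - x_e|^3 * Vol_e,

with per-element gradients from vertex finite differences and inert
elements excluded.  The operator is linear in V_m and is precomputed as
a lead-field matrix, so a beat simulation reduces to one matrix product.
The 12 standard leads are derived from the 9 measurement electrodes
with the Einthoven / Goldberger / Wilson combinations in the published
channel order I, II, III, aVR, aVL, aVF, V1-V6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix

from . import config
from .cellmodel import TemplateBank
from .geometry import CardiacMesh

LEADS = ("I", "II", "III", "aVR", "aVL", "aVF",
         "V1", "V2", "V3", "V4", "V5", "V6")
MEASUREMENT_ELECTRODES = ("RA", "LA", "LL",
                          "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass
class ConductivitySet:
    """Tissue and volume-conductor conductivities (S/m).

    The full anisotropic bidomain values and the torso-compartment
    conductivities are recorded; the dipole operator itself uses the
    scalar ``sigma_i_bulk`` for the sources and ``sigma_medium`` for the
    unbounded medium.
    """

    sigma_il: float = config.CONDUCTIVITIES["sigma_il"]
    sigma_in: float = config.CONDUCTIVITIES["sigma_in"]
    sigma_it: float = config.CONDUCTIVITIES["sigma_it"]
    sigma_el: float = config.CONDUCTIVITIES["sigma_el"]
    sigma_en: float = config.CONDUCTIVITIES["sigma_en"]
    sigma_et: float = config.CONDUCTIVITIES["sigma_et"]
    sigma_torso: float = config.CONDUCTIVITIES["sigma_torso"]
    sigma_atria: float = config.CONDUCTIVITIES["sigma_atria"]
    sigma_lungs: float = config.CONDUCTIVITIES["sigma_lungs"]
    sigma_blood: float = config.CONDUCTIVITIES["sigma_blood"]
    sigma_i_bulk: float = config.CONDUCTIVITIES["sigma_il"]
    sigma_medium: float = config.CONDUCTIVITIES["sigma_torso"]

    def __post_init__(self) -> None:
        for name, val in vars(self).items():
            if val <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BeatECG12:
    """Single-beat 12-lead signal (mV) with ground-truth fiducials (ms)."""

    data: np.ndarray                  # (12, T)
    fs: float                         # Hz
    fiducials: dict[str, float] = field(default_factory=dict)
    label: str = ""

    @property
    def dt(self) -> float:
        return 1000.0 / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) * self.dt

    def lead(self, name: str) -> np.ndarray:
        return self.data[LEADS.index(name)]


# ---------------------------------------------------------------------------
# Lead-field construction


# vertex groups of the hexahedron on the +side / -side of each local axis
_PLUS = ([1, 2, 5, 6], [2, 3, 6, 7], [4, 5, 6, 7])
_MINUS = ([0, 3, 4, 7], [0, 1, 4, 5], [0, 1, 2, 3])


def _gradient_operators(mesh: CardiacMesh):
    """Sparse per-element finite-difference operators along local axes."""
    ne, nv = mesh.n_elements, mesh.n_nodes
    h = mesh.resolution
    ops = []
    rows = np.repeat(np.arange(ne), 8)
    for plus, minus in zip(_PLUS, _MINUS):
        cols = mesh.elements[:, plus + minus].ravel()
        vals = np.tile(np.array([1.0] * 4 + [-1.0] * 4) / (4 * h), ne)
        ops.append(csr_matrix((vals, (rows, cols)), shape=(ne, nv)))
    return ops


def lead_field(mesh: CardiacMesh, electrodes: dict[str, np.ndarray],
               sigma: ConductivitySet,
               active: np.ndarray | None = None,
               names: tuple[str, ...] = MEASUREMENT_ELECTRODES) -> np.ndarray:
    """Matrix B (n_electrodes, n_nodes) with phi = B @ V_m.

    ``active`` masks the contributing elements (inert infarct core or
    removed fibrotic elements are excluded).  Raises ``ValueError`` when
    an electrode lies inside the myocardium.
    """
    ne = mesh.n_elements
    if active is None:
        active = np.ones(ne, dtype=bool)
    centers = mesh.element_centers
    vol = mesh.element_volume
    h = mesh.resolution
    pts = mesh.node_positions[mesh.elements]
    # actual local axis vectors (unit-cell edges; rotation-aware)
    axes = np.stack([pts[:, 1] - pts[:, 0],
                     pts[:, 3] - pts[:, 0],
                     pts[:, 4] - pts[:, 0]], axis=1)      # (Ne, 3ax, 3)
    gops = _gradient_operators(mesh)
    scale = sigma.sigma_i_bulk / (4 * np.pi * sigma.sigma_medium)
    b = np.zeros((len(names), mesh.n_nodes))
    for k, name in enumerate(names):
        y = np.asarray(electrodes[name], dtype=float)
        r = y[None, :] - centers
        dist = np.linalg.norm(r, axis=1)
        if dist.min() < h:
            raise ValueError(f"electrode {name} lies inside the myocardium")
        a = scale * vol * r / dist[:, None]**3            # (Ne, 3)
        a[~active] = 0.0
        for i in range(3):
            coeff = (a * axes[:, i, :]).sum(axis=1) / h   # (Ne,)
            b[k] += coeff @ gops[i]
    return b


# ---------------------------------------------------------------------------
# Transmembrane voltage evaluation


def evaluate_tmv(lat: np.ndarray, apd: np.ndarray, banks: list[TemplateBank],
                 bank_id: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """V_m samples (n_nodes, n_times) by template shift and interpolation.

    ``bank_id`` selects the template bank per node (e.g. sinus cell vs
    border-zone cell); nodes with non-finite activation time rest at
    their bank's V_min throughout.
    """
    lat = np.asarray(lat, dtype=float)
    nv, nt = len(lat), len(t_grid)
    vm = np.empty((nv, nt), dtype=np.float32)
    inert = ~np.isfinite(lat)
    lat_safe = np.where(inert, 1e9, lat)
    t32 = t_grid.astype(np.float32)
    for bid, bank in enumerate(banks):
        m = bank_id == bid
        if not m.any():
            continue
        i0, i1, w = bank.interp_weights(apd[m])
        lat32 = (lat_safe[m] - bank.upstroke_offset).astype(np.float32)
        tau = t32[None, :] - lat32[:, None]
        np.multiply(tau, np.float32(1.0 / bank.dt), out=tau)
        np.clip(tau, 0.0, bank.voltage_matrix.shape[1] - 1, out=tau)
        idx = (tau + np.float32(0.5)).astype(np.int32)
        np.clip(idx, 0, bank.voltage_matrix.shape[1] - 1, out=idx)
        mat = bank.voltage_matrix.astype(np.float32)
        v0 = mat[i0[:, None], idx]
        v1 = mat[i1[:, None], idx]
        v1 -= v0
        v1 *= w[:, None].astype(np.float32)
        v0 += v1
        vm[m] = v0
    return vm


def forward_ecg(b: np.ndarray, vm: np.ndarray) -> dict[str, np.ndarray]:
    """Electrode potentials (mV) from the lead-field matrix and V_m."""
    phi = b @ vm
    return {name: phi[k] for k, name in enumerate(MEASUREMENT_ELECTRODES)}


def derive_leads(potentials: dict[str, np.ndarray], fs: float,
                 fiducials: dict[str, float] | None = None,
                 label: str = "") -> BeatECG12:
    """12 standard leads from the 9 electrode potentials.

    Einthoven limb leads, Goldberger augmented leads and Wilson
    precordial leads referenced to the central terminal.
    """
    missing = set(MEASUREMENT_ELECTRODES) - set(potentials)
    if missing:
        raise ValueError(f"missing electrodes: {sorted(missing)}")
    ra, la, ll = (np.asarray(potentials[k], dtype=float)
                  for k in ("RA", "LA", "LL"))
    wct = (ra + la + ll) / 3.0
    chans = [
        la - ra, ll - ra, ll - la,
        ra - (la + ll) / 2.0, la - (ra + ll) / 2.0, ll - (ra + la) / 2.0,
    ]
    chans += [np.asarray(potentials[f"V{i}"], dtype=float) - wct
              for i in range(1, 7)]
    return BeatECG12(data=np.vstack(chans), fs=fs,
                     fiducials=dict(fiducials or {}), label=label)


# ---------------------------------------------------------------------------
# Beat simulations


def _interp_apd90(bank: TemplateBank, apd: np.ndarray) -> np.ndarray:
    i0, i1, w = bank.interp_weights(apd)
    return bank.apd90[i0] + w * (bank.apd90[i1] - bank.apd90[i0])


def simulate_qrst(case, duration: float = config.QRST_BEAT_MS,
                  dt_sim: float = 1.0,
                  fs_out: float = config.FS_OUT) -> BeatECG12:
    """Simulate one ventricular beat (QRST complex).

    ``case`` is a ventricular case configuration (see
    ``pathology.make_case_config``) carrying the placed mesh, conduction
    field, fascicular sources, T-wave parameterization, template banks
    and electrodes.  Ground-truth QRS_on / QRS_off / T_off fiducials are
    taken from the activation and repolarization fields.
    """
    from .cellmodel import compute_apd_field

    v = case.ventricular
    lat = v["solver"].solve(v["sources"])
    apd = compute_apd_field(v["mesh"], v["tw"])
    banks = v["banks"]
    vm = evaluate_tmv(lat, apd, banks, v["bank_id"],
                      np.arange(0.0, duration, dt_sim))
    phi = forward_ecg(v["lead_field"], vm)
    finite = np.isfinite(lat)
    if not finite.any():
        raise ValueError("no tissue activated")
    t90 = np.empty_like(apd)
    for bid, bank in enumerate(banks):
        m = v["bank_id"] == bid
        if m.any():
            t90[m] = _interp_apd90(bank, apd[m])
    fiducials = {
        "QRS_on": float(lat[finite].min()),
        "QRS_off": float(lat[finite].max()) + banks[0].upstroke_offset,
        "T_off": float((lat[finite] + t90[finite]).max()),
    }
    beat = derive_leads(phi, fs=1000.0 / dt_sim, fiducials=fiducials,
                        label=case.label.name)
    step = int(round(1000.0 / fs_out / dt_sim))
    return BeatECG12(data=beat.data[:, ::step], fs=fs_out,
                     fiducials=fiducials, label=beat.label)


def simulate_pwave(case, dt_sim: float = 1.0,
                   fs_out: float = config.FS_OUT) -> BeatECG12:
    """Simulate one atrial beat (P wave).

    The window is auto-sized to the end of atrial depolarization plus a
    margin and clamped to the configured 150-200 ms range; ground-truth
    P_on / P_off fiducials come from the activation map.
    """
    a = case.atrial
    lat = a["solver"].solve(a["sources"])
    finite = np.isfinite(lat)
    if not finite.any():
        raise ValueError("no atrial tissue activated")
    max_lat = float(lat[finite].max())
    lo, hi = config.PWAVE_WINDOW_MS
    window = float(np.clip(np.ceil(max_lat + 40.0), lo, hi))
    apd = np.full(len(lat), a["apd"])
    vm = evaluate_tmv(lat, apd, a["banks"], a["bank_id"],
                      np.arange(0.0, window, dt_sim))
    phi = forward_ecg(a["lead_field"], vm)
    fiducials = {
        "P_on": float(lat[finite].min()),
        "P_off": max_lat + a["banks"][0].upstroke_offset,
    }
    beat = derive_leads(phi, fs=1000.0 / dt_sim, fiducials=fiducials,
                        label=case.label.name)
    step = int(round(1000.0 / fs_out / dt_sim))
    return BeatECG12(data=beat.data[:, ::step], fs=fs_out,
                     fiducials=fiducials, label=beat.label)
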