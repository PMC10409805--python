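"""Central parameter tables and run configuration.

All electrophysiological constants and sampling ranges used by the
simulation pipeline live here, grouped the way they enter the model:
fascicular-site geometry and conduction settings for the QRS complex,
action-potential / repolarization-gradient settings for the T wave,
infarct construction parameters, and the atrial (P-wave) parameter set.

Units follow the conventions used throughout the package: lengths in mm,
times in ms, conduction velocities in m/s (1 m/s == 1 mm/ms), voltages
in mV, conductivities in S/m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


# ---------------------------------------------------------------------------
# QRS complex: fascicular breakthrough sites of the His-Purkinje surrogate.
# Each site is given in universal ventricular coordinates (rho, phi, z)
# with a chamber label, an endocardial-extent radius r (fraction of the
# apico-basal arc length) and an activation delay t (ms).  Scalars are
# fixed values; 2-tuples are uniform sampling ranges.
FASCICULAR_SITE_RANGES: dict[str, dict] = {
    "rv_mod": {
        "v": "rv", "rho": 0.2,
        "phi": (0.0, 1.0), "z": (0.1, 0.6),
        "r": (0.2, 0.8), "t": (0.0, 10.0),
    },
    "rv_sept": {
        "v": "rv", "rho": 0.8,
        "phi": (-1.5, 1.5), "z": (0.2, 0.4),
        "r": 0.4, "t": 10.0,
    },
    "lv_sept": {
        "v": "lv", "rho": 0.2,
        "phi": (-1.5, 1.5), "z": (0.3, 0.7),
        "r": (0.05, 0.4), "t": 10.0,
    },
    "lv_ant": {
        "v": "lv", "rho": 0.2,
        "phi": (1.0, math.pi), "z": (0.2, 0.8),
        "r": (0.05, 0.4), "t": 10.0,
    },
    "lv_post": {
        "v": "lv", "rho": 0.2,
        "phi": (-math.pi, -1.0), "z": (0.2, 0.7),
        "r": (0.05, 0.4), "t": 10.0,
    },
}

# Ventricular conduction settings.
CV_ENDO = 2.0           # m/s, isotropic within the fast-conducting endocardium
CV_MYO = 0.6            # m/s along the principal fiber direction
CV_MYO_RATIO = (4.0, 2.0, 1.0)   # fiber : sheet : sheet-normal
ENDO_BAND_Z = (0.1, 0.9)         # apico-basal extent of the fast endocardium
ENDO_RHO = 0.15                  # transmural extent of the fast endocardium

# Fiber rule: helix angle alpha and sheet angle beta, endo -> epi (degrees).
ALPHA_ENDO, ALPHA_EPI = 60.0, -60.0
BETA_ENDO, BETA_EPI = -65.0, 25.0

# Conductivities (S/m), recorded as metadata; the forward operator uses
# sigma_i_bulk (intracellular longitudinal) and sigma_torso as the medium.
CONDUCTIVITIES = {
    "sigma_il": 0.34, "sigma_in": 0.06, "sigma_it": 0.06,
    "sigma_el": 0.12, "sigma_en": 0.08, "sigma_et": 0.08,
    "sigma_torso": 0.22, "sigma_atria": 0.0537,
    "sigma_lungs": 0.0389, "sigma_blood": 0.7,
}

# ---------------------------------------------------------------------------
# T wave: repolarization gradient sampling ranges.
APD_MIN_RANGE = (150.0, 175.0)   # ms
APD_MAX_RANGE = (225.0, 250.0)   # ms
QW_RANGES = {                    # UVC weights of the APD gradient
    "q_rho": (-0.6, 0.0),
    "q_v": (0.1, 0.15),
    "q_phi": (0.0, 0.0),
    "q_z": (0.9, 1.0),
}

# ---------------------------------------------------------------------------
# Myocardial infarction construction.
MI_CENTER_RANGES = {
    # artery -> UVC bounds of the infarct core center (phi may be a union
    # of two intervals for the lateral LCX territory)
    "LAD": {"phi": [(0.0, 2.0)], "z": (0.1, 1.0)},
    "RCA": {"phi": [(-2.0, 0.0)], "z": (0.2, 1.0)},
    "LCX": {"phi": [(2.0, math.pi), (-math.pi, -2.0)], "z": (0.2, 1.0)},
}
MI_DCO_RANGE = (0.15, 1.0)   # dimensionless radius fraction of the LV long axis
MI_RHO_N = (0.3, 1.0)        # transmural extents modeled
MI_BZ_FRACTION = 0.05        # outer fraction of the infarct area -> border zone
CV_BZ = 0.15                 # m/s, isotropic in the border zone

# ---------------------------------------------------------------------------
# Atrial (P wave) parameter set: transversal conduction velocities (m/s)
# and fixed anisotropy ratios per anatomical region.
ATRIAL_CV_RANGES = {
    "bulk_tissue": (0.57, 0.85),
    "interatrial_connections": (0.46, 0.70),
    "crista_terminalis": (0.57, 0.85),
    "pectinate_muscles": (0.62, 0.92),
    "inferior_isthmus": (0.57, 0.85),
}
ATRIAL_AR = {
    "bulk_tissue": 1.94,
    "interatrial_connections": 3.0,
    "crista_terminalis": 2.56,
    "pectinate_muscles": 3.24,
    "inferior_isthmus": 1.0,
}
ROTATION_RANGE = (-20.0, 20.0)     # degrees, each axis
TRANSLATION_RANGE = (-10.0, 10.0)  # mm, each axis
SHAPE_COEFF_BOUNDS_ATRIA = (-3.0, 3.0)
SHAPE_COEFF_BOUNDS_TORSO = (-2.0, 2.0)

# Fibrotic atrial cardiomyopathy.
FIBROSIS_FRACTIONS = tuple(round(0.05 * k, 2) for k in range(1, 10))  # 5%..45%
FIBROSIS_REMOVAL_FRACTION = 0.5
FIBROSIS_CV_FACTOR_LONG = 0.5
FIBROSIS_CV_FACTOR_TRANS = 0.2

# Left atrial enlargement: sampled LA volume scale relative to healthy.
LAE_SCALE_RANGE = (1.1, 1.6)

# ---------------------------------------------------------------------------
# Synthesis-stage clinical feature statistics (lead II, healthy cohort):
# means and standard deviations used to parameterize the multivariate
# normal coupling blocks.  Correlations are not published; the defaults
# below are declared calibration knobs, re-fittable from a user-supplied
# feature table.
CLINICAL_LEAD_II = {
    "P_amp": (0.05, 0.06),      # mV
    "R_amp": (0.79, 0.38),      # mV
    "P_dur": (136.44, 11.51),   # ms
    "PQ_int": (158.80, 24.16),  # ms
    "QRS_dur": (122.15, 16.04), # ms
    "QT_int": (420.29, 62.68),  # ms
    "RR_int": (879.82, 143.73), # ms
}
DEFAULT_CORR_AMP = 0.5      # P_amp -- R_amp
DEFAULT_CORR_PDUR_PQ = 0.4  # P_dur -- PQ_int
DEFAULT_CORR_QRS_QT = 0.4   # QRS_dur -- QT_int
DEFAULT_CORR_QT_RR = 0.6    # QT_int -- RR_int
DEFAULT_CORR_QRS_RR = 0.2   # QRS_dur -- RR_int

AVB_PQ_MIN = 200.0          # ms, 1st-degree AV block lower bound
HR_RANGE_BPM = (50.0, 90.0)
SNR_RANGE_DB = (15.0, 20.0)

FS_OUT = 500.0              # Hz, output sampling rate
RECORD_SECONDS = 10.0
RECORD_SAMPLES = 5000
QRST_BEAT_MS = 450.0
PWAVE_WINDOW_MS = (150.0, 200.0)

# Bandpass filter applied to the noisy variant.
FILTER_ORDER = 3
FILTER_HP_HZ = 0.5
FILTER_LP_HZ = 150.0


@dataclass
class SynthesisConfig:
    """Tunable knobs of the record-synthesis stage."""

    corr_amp: float = DEFAULT_CORR_AMP
    corr_pdur_pq: float = DEFAULT_CORR_PDUR_PQ
    corr_qrs_qt: float = DEFAULT_CORR_QRS_QT
    corr_qt_rr: float = DEFAULT_CORR_QT_RR
    corr_qrs_rr: float = DEFAULT_CORR_QRS_RR
    snr_range_db: tuple[float, float] = SNR_RANGE_DB
    hr_range_bpm: tuple[float, float] = HR_RANGE_BPM
    sdnn_ms: float = 40.0
    spectral_exponent: float = 1.0
    avb_pq_min: float = AVB_PQ_MIN
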