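"""Mechanistic pathology modifiers and case configuration.

Seven disease classes are produced as transformations of the healthy
simulation configuration, each with an exact mechanistic ground-truth
label:

* LBBB / RBBB — all fascicular breakthrough sites of one ventricle are
  removed, forcing trans-septal activation of the blocked chamber.
* MI (6 sub-classes) — an infarct grown geodesically around an
  artery-specific center: electrically inert core, slow isotropic
  border zone with its own cell parameterization, two transmural
  extents (30% / transmural) for each of LAD, RCA and LCX.
* FAM — fibrotic atrial cardiomyopathy: seeded patches covering a
  prescribed volume fraction in which half the elements become passive
  barriers and the rest conduct slowly with increased anisotropy.
* IAB — interatrial conduction block: Bachmann's bundle is inert, the
  left atrium activates via the posterior connection.
* LAE — left atrial enlargement, encoded geometrically by scaling the
  LA volume above the healthy range.
* AVB — 1st-degree AV block, flagged for the synthesis stage which
  samples the PQ interval from > 200 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from . import config
from .activation import (ConductionField, EikonalSolver, FascicularSource,
                         build_conduction_field_atrial,
                         build_conduction_field_ventricular,
                         fascicular_sources, geodesic_region)
from .cellmodel import (ATRIAL_PARAMS, BZ_PARAMS, FIBROTIC_AMPLITUDE_FACTOR,
                        SINUS_PARAMS, TWaveParams, get_bank)
from .forward import ConductivitySet, lead_field
from .geometry import (AnatomyParams, CardiacMesh, ParameterSample, TorsoPose,
                       build_atrial_mesh, build_ventricular_mesh, lhs_sample,
                       place_and_project)


@dataclass(frozen=True)
class PathologyLabel:
    """Pathology class with the MI sub-class when applicable."""

    name: str                      # sinus, avblock, lbbb, rbbb, lae, fam, iab, mi
    mi_artery: str | None = None   # LAD, RCA, LCX
    mi_rho_n: float | None = None  # 0.3 or 1.0

    def __post_init__(self) -> None:
        if self.name == "mi":
            if self.mi_artery not in ("LAD", "RCA", "LCX") \
                    or self.mi_rho_n not in (0.3, 1.0):
                raise ValueError("mi label needs artery and transmurality")
        elif self.mi_artery is not None or self.mi_rho_n is not None:
            raise ValueError("mi sub-class only valid for class 'mi'")

    @property
    def case_key(self) -> str:
        if self.name == "mi":
            return f"mi/{self.mi_artery}_{self.mi_rho_n}"
        return self.name


def all_cases() -> list[PathologyLabel]:
    """The 13 labeled cases: 7 non-MI classes + 6 MI sub-classes."""
    cases = [PathologyLabel(n) for n in
             ("sinus", "avblock", "lbbb", "rbbb", "lae", "fam", "iab")]
    for artery in ("LAD", "RCA", "LCX"):
        for rho_n in (0.3, 1.0):
            cases.append(PathologyLabel("mi", artery, rho_n))
    return cases


def parse_label(text: str) -> PathologyLabel:
    """Parse 'sinus', 'mi/LAD_0.3', 'mi/RAD_1.0' (RAD aliases RCA)."""
    if "/" in text:
        name, sub = text.split("/", 1)
        artery, rho = sub.rsplit("_", 1)
        artery = {"RAD": "RCA"}.get(artery, artery)
        return PathologyLabel(name, artery, float(rho))
    return PathologyLabel(text)


@dataclass
class InfarctSpec:
    """Infarct construction parameters for one artery territory."""

    artery: str
    phi: float
    z: float
    rho_n: float
    d_co: float
    bz_fraction: float = config.MI_BZ_FRACTION
    bz_cv: float = config.CV_BZ

    def __post_init__(self) -> None:
        if self.artery not in config.MI_CENTER_RANGES:
            raise ValueError(f"unknown artery {self.artery!r}")
        bounds = config.MI_CENTER_RANGES[self.artery]
        if not any(lo <= self.phi <= hi for lo, hi in bounds["phi"]):
            raise ValueError(f"{self.artery} center phi={self.phi} outside "
                             f"{bounds['phi']}")
        lo, hi = bounds["z"]
        if not lo <= self.z <= hi:
            raise ValueError(f"{self.artery} center z={self.z} outside range")
        if self.rho_n not in config.MI_RHO_N:
            raise ValueError("rho_n must be 0.3 or 1.0")
        if self.d_co < 0:
            raise ValueError("d_co must be non-negative")


@dataclass
class FibrosisSpec:
    """Fibrotic atrial cardiomyopathy remodeling parameters."""

    volume_fraction: float
    removal_fraction: float = config.FIBROSIS_REMOVAL_FRACTION
    cv_factor_long: float = config.FIBROSIS_CV_FACTOR_LONG
    cv_factor_trans: float = config.FIBROSIS_CV_FACTOR_TRANS
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(config.FIBROSIS_FRACTIONS)
        if not np.isclose(grid, self.volume_fraction).any():
            raise ValueError(
                f"volume fraction must be one of {list(grid)}")
        for f in (self.removal_fraction, self.cv_factor_long,
                  self.cv_factor_trans):
            if not 0 < f <= 1:
                raise ValueError("fractions/factors must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Modifiers


def apply_bbb(sources: list[FascicularSource],
              side: str) -> list[FascicularSource]:
    """Remove all fascicular sites of the blocked ventricle."""
    kept = [s for s in sources if s.v != side]
    if not kept:
        raise ValueError("bundle branch block removed every source")
    return kept


def apply_mi(mesh: CardiacMesh, cond: ConductionField, spec: InfarctSpec):
    """Insert an infarct: inert core, slow isotropic border zone.

    The infarct region is grown geodesically (healthy myocardial CVs,
    left ventricle only) to radius ``d_co`` times the LV long axis and
    intersected with the transmural extent rho <= rho_n.  The outermost
    geodesic shell holding ``bz_fraction`` of the region's elements is
    the border zone; the remainder is the electrically inert core.

    Returns ``(new_cond, info)`` with ``info['core']`` / ``info['bz']``
    element indices and ``info['bz_nodes']`` the nodes carrying the
    border-zone cell parameterization.  A zero radius removes the
    infarct entirely, recovering the healthy configuration.
    """
    if spec.d_co == 0:
        empty = np.array([], dtype=int)
        return (ConductionField(cv=cond.cv.copy(), region=cond.region.copy()),
                {"region": empty, "core": empty, "bz": empty,
                 "bz_nodes": empty})
    ratio = np.asarray(config.CV_MYO_RATIO) / config.CV_MYO_RATIO[0]
    healthy = ConductionField(
        cv=np.tile(config.CV_MYO * ratio, (mesh.n_elements, 1)),
        region=mesh.element_region.copy())
    center = {"rho": 0.3, "phi": spec.phi, "z": spec.z, "v": "lv"}
    region, elat = geodesic_region(mesh, center, spec.d_co, healthy,
                                   return_times=True)
    el_rho = mesh.element_uvc("rho")
    el_ch = mesh.element_chamber()
    region = region[(el_rho[region] <= spec.rho_n + 1e-9)
                    & (el_ch[region] == "lv")]
    if len(region) == 0:
        raise ValueError("infarct region is empty")
    n_bz = max(1, int(round(spec.bz_fraction * len(region))))
    order = np.argsort(elat[region])
    core = region[order[:len(region) - n_bz]]
    bz = region[order[len(region) - n_bz:]]
    new = ConductionField(cv=cond.cv.copy(), region=cond.region.copy())
    new.cv[core] = 0.0
    new.cv[bz] = spec.bz_cv
    new.region[core] = "infarct_core"
    new.region[bz] = "infarct_bz"
    bz_nodes = np.unique(mesh.elements[bz])
    return new, {"region": region, "core": core, "bz": bz,
                 "bz_nodes": bz_nodes}


def _element_adjacency(mesh: CardiacMesh, mask: np.ndarray) -> csr_matrix:
    """Face adjacency of the masked elements (graph over all elements)."""
    ijk = mesh.metadata["element_ijk"]
    gs = ijk.max(axis=0) + 1
    grid = np.full(tuple(gs), -1, dtype=np.int64)
    sel = np.flatnonzero(mask)
    grid[tuple(ijk[sel].T)] = sel
    rows, cols = [], []
    for ax in range(3):
        off = np.zeros(3, dtype=np.int64)
        off[ax] = 1
        nb = ijk[sel] + off
        ok = (nb < gs).all(axis=1)
        j = grid[tuple(nb[ok].T)]
        valid = j >= 0
        rows.append(sel[ok][valid])
        cols.append(j[valid])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    n = mesh.n_elements
    return csr_matrix((np.ones(len(r)), (r, c)), shape=(n, n))


def apply_fibrosis(mesh: CardiacMesh, cond: ConductionField,
                   spec: FibrosisSpec):
    """Fibrotic patches on the atrial shells.

    Patches are Voronoi-like blobs grown from random seed elements with
    randomized edge weights until they cover ``volume_fraction`` of the
    shell elements (the interatrial bridges are spared so the atria
    stay connected).  Within the patches, ``removal_fraction`` of the
    elements become passive barriers (cv = 0); survivors conduct at
    0.5x longitudinally and 0.2x transversally, raising the anisotropy
    ratio by exactly 2.5.

    Returns ``(new_cond, info)`` with patch / removed / surviving
    element indices and the fibrotic node set.
    """
    shell = ~np.isin(mesh.element_region,
                     ("bachmanns_bundle", "posterior_connection"))
    candidates = np.flatnonzero(shell)
    target = int(round(spec.volume_fraction * len(candidates)))
    if target > len(candidates):
        raise ValueError("requested fibrotic fraction exceeds the shell")
    rng = np.random.default_rng(spec.seed)
    new = ConductionField(cv=cond.cv.copy(), region=cond.region.copy())
    info = {"patch": np.array([], dtype=int),
            "removed": np.array([], dtype=int),
            "surviving": np.array([], dtype=int)}
    if target == 0:
        return new, info
    n_patches = max(1, int(round(target / 150)))
    seeds = rng.choice(candidates, size=min(n_patches, len(candidates)),
                       replace=False)
    adj = _element_adjacency(mesh, shell).tocoo()
    w = rng.uniform(0.5, 1.5, size=len(adj.data))
    g = csr_matrix((w, (adj.row, adj.col)), shape=adj.shape)
    dist = dijkstra(g, directed=False, indices=seeds, min_only=True)
    order = np.argsort(dist[candidates])
    patch = candidates[order[:target]]
    patch = patch[np.isfinite(dist[patch])]
    n_rm = int(round(spec.removal_fraction * len(patch)))
    rm_idx = rng.choice(len(patch), size=n_rm, replace=False)
    removed = patch[rm_idx]
    surviving = np.setdiff1d(patch, removed)
    new.cv[removed] = 0.0
    new.cv[surviving, 0] *= spec.cv_factor_long
    new.cv[surviving, 1] *= spec.cv_factor_trans
    new.cv[surviving, 2] *= spec.cv_factor_trans
    new.region[surviving] = "fibrotic"
    new.region[removed] = "fibrotic"
    fib_nodes = np.unique(mesh.elements[surviving]) if len(surviving) \
        else np.array([], dtype=int)
    info.update(patch=patch, removed=removed, surviving=surviving,
                fibrotic_nodes=fib_nodes)
    return new, info


def apply_iab(mesh: CardiacMesh, cond: ConductionField) -> ConductionField:
    """Block conduction through Bachmann's bundle.

    The posterior interatrial connection remains, so the LA activates
    late and retrogradely.  Raises when the block would disconnect the
    LA from the RA entirely.
    """
    bb = mesh.element_region == "bachmanns_bundle"
    if not bb.any():
        raise ValueError("mesh has no Bachmann's bundle elements")
    new = ConductionField(cv=cond.cv.copy(), region=cond.region.copy())
    new.cv[bb] = 0.0
    active = new.active
    adj = _element_adjacency(mesh, active)
    _, comp = connected_components(adj, directed=False)
    el_ch = mesh.uvc["v"][mesh.elements[:, 0]]
    ra_comp = np.unique(comp[active & (el_ch == "ra")])
    la_active = active & (el_ch == "la")
    if not np.isin(comp[la_active], ra_comp).any():
        raise ValueError("interatrial block would disconnect the left atrium")
    return new


# ---------------------------------------------------------------------------
# Parameter sampling


def _derive_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0]
               % (2**31 - 1))


def draw_parameter_samples(label: PathologyLabel, n: int,
                           seed: int) -> list[ParameterSample]:
    """Latin-hypercube draws of the full parameter vector for one case.

    The healthy QRST variability is controlled by the 20 variable
    parameters of the fascicular-site and repolarization tables; the
    atrial parameter vector adds regional conduction velocities, pose
    and shape coefficients.  Disease-specific parameters (infarct
    center and radius, fibrosis fraction, LA scaling) are appended
    according to the label.
    """
    ranges: dict[str, tuple[float, float]] = {}
    for site, fields_ in config.FASCICULAR_SITE_RANGES.items():
        for key in ("phi", "z", "r", "t"):
            val = fields_[key]
            if isinstance(val, tuple):
                ranges[f"{site}.{key}"] = val
    ranges["apd_min"] = config.APD_MIN_RANGE
    ranges["apd_max"] = config.APD_MAX_RANGE
    for k, v in config.QW_RANGES.items():
        if v[0] != v[1]:
            ranges[k] = v
    for region, rng_ in config.ATRIAL_CV_RANGES.items():
        ranges[f"cv.{region}"] = rng_
    for ax in "xyz":
        ranges[f"alpha_{ax}"] = config.ROTATION_RANGE
        ranges[f"t_{ax}"] = config.TRANSLATION_RANGE
    for i in range(4):
        ranges[f"lam_a{i}"] = config.SHAPE_COEFF_BOUNDS_ATRIA
    for i in range(2):
        ranges[f"lam_t{i}"] = config.SHAPE_COEFF_BOUNDS_TORSO
    if label.name == "mi":
        bounds = config.MI_CENTER_RANGES[label.mi_artery]
        total = sum(hi - lo for lo, hi in bounds["phi"])
        ranges["mi.phi_u"] = (0.0, total)
        ranges["mi.z"] = bounds["z"]
        ranges["mi.d_co"] = config.MI_DCO_RANGE
    if label.name == "lae":
        ranges["la_volume_scale"] = config.LAE_SCALE_RANGE
    if label.name == "fam":
        ranges["fam.level"] = (0.0, float(len(config.FIBROSIS_FRACTIONS)))

    rows = lhs_sample(ranges, n, seed)
    samples = []
    for i, row in enumerate(rows):
        omega_qrs = {}
        for site, fields_ in config.FASCICULAR_SITE_RANGES.items():
            omega_qrs[site] = {
                "v": fields_["v"], "rho": fields_["rho"],
                **{key: (row[f"{site}.{key}"]
                         if isinstance(fields_[key], tuple)
                         else fields_[key])
                   for key in ("phi", "z", "r", "t")},
            }
        omega_t = {
            "apd_min": row["apd_min"], "apd_max": row["apd_max"],
            "q_rho": row.get("q_rho", 0.0), "q_v": row.get("q_v", 0.0),
            "q_phi": row.get("q_phi", 0.0), "q_z": row.get("q_z", 0.0),
        }
        omega_p = {
            "cv": {r: row[f"cv.{r}"] for r in config.ATRIAL_CV_RANGES},
            **{f"alpha_{ax}": row[f"alpha_{ax}"] for ax in "xyz"},
            **{f"t_{ax}": row[f"t_{ax}"] for ax in "xyz"},
            "shape_coeffs": tuple(row[f"lam_a{i}"] for i in range(4))
            + tuple(row[f"lam_t{i}"] for i in range(2)),
            "la_volume_scale": row.get("la_volume_scale", 1.0),
            "atrial_apd": 250.0,
        }
        omega_mi = None
        if label.name == "mi":
            bounds = config.MI_CENTER_RANGES[label.mi_artery]
            u = row["mi.phi_u"]
            phi = None
            for lo, hi in bounds["phi"]:
                if u <= hi - lo:
                    phi = lo + u
                    break
                u -= hi - lo
            if phi is None:  # numerical edge of the union
                phi = bounds["phi"][-1][1]
            omega_mi = {"artery": label.mi_artery, "phi": phi,
                        "z": row["mi.z"], "rho_n": label.mi_rho_n,
                        "d_co": row["mi.d_co"]}
        if label.name == "fam":
            level = min(int(row["fam.level"]),
                        len(config.FIBROSIS_FRACTIONS) - 1)
            omega_p["fibrosis_fraction"] = config.FIBROSIS_FRACTIONS[level]
        samples.append(ParameterSample(
            omega_qrs=omega_qrs, omega_t=omega_t, omega_p=omega_p,
            omega_mi=omega_mi, seed=_derive_seed(seed, i),
            label=label.case_key))
    return samples


# ---------------------------------------------------------------------------
# Case configuration


@dataclass
class CaseConfig:
    """Complete, solver-ready configuration of one simulation run."""

    label: PathologyLabel
    sample: ParameterSample
    ventricular: dict
    atrial: dict
    electrodes: dict
    avb: bool = False


class AnatomyCache:
    """Reuses meshes, Eikonal graphs and template banks across runs."""

    def __init__(self) -> None:
        self._store: dict = {}

    def get(self, key, builder):
        if key not in self._store:
            self._store[key] = builder()
        return self._store[key]


#: Fixed anatomical orientation of the heart inside the torso frame:
#: tips the long axis so the apex points left, inferior and anterior.
BASE_ORIENTATION = {"alpha_x": 165.0, "alpha_y": -40.0, "alpha_z": 0.0}


def make_case_config(label: PathologyLabel, sample: ParameterSample,
                     anatomy: AnatomyParams | None = None,
                     cache: AnatomyCache | None = None,
                     sigma: ConductivitySet | None = None) -> CaseConfig:
    """Build the complete simulation configuration for one run.

    Dispatches the pathology modifiers, constructs (or fetches from the
    cache) meshes and Eikonal graphs, places the heart with the sampled
    pose composed onto the fixed anatomical orientation, and assembles
    lead-field matrices for the dipole forward operator.
    """
    cache = cache or AnatomyCache()
    sigma = sigma or ConductivitySet()
    anatomy = anatomy or AnatomyParams()
    op = sample.omega_p

    # --- ventricles -------------------------------------------------------
    vmesh = cache.get(("vmesh", id(anatomy)),
                      lambda: build_ventricular_mesh(anatomy))
    vcond = build_conduction_field_ventricular(vmesh)
    sources = fascicular_sources(vmesh, sample.omega_qrs)
    if label.name == "lbbb":
        sources = apply_bbb(sources, "lv")
    elif label.name == "rbbb":
        sources = apply_bbb(sources, "rv")

    bank_sinus = get_bank(SINUS_PARAMS)
    bank_bz = get_bank(BZ_PARAMS)
    bank_id_v = np.zeros(vmesh.n_nodes, dtype=np.int64)
    if label.name == "mi":
        if sample.omega_mi is None:
            raise ValueError("sample carries no infarct parameters; draw "
                             "it with the matching MI label")
        spec = InfarctSpec(**sample.omega_mi)
        vcond, mi_info = apply_mi(vmesh, vcond, spec)
        bank_id_v[mi_info["bz_nodes"]] = 1
        vsolver = EikonalSolver(vmesh, vcond)
        # drop source nodes swallowed by the inert core (border-zone
        # nodes remain excitable)
        core_nodes = np.setdiff1d(np.unique(vmesh.elements[mi_info["core"]]),
                                  mi_info["bz_nodes"])
        pruned = []
        for s in sources:
            nodes = s.nodes[~np.isin(s.nodes, core_nodes)]
            if len(nodes):
                pruned.append(replace(s, nodes=nodes))
        if not pruned:
            raise ValueError("infarct removed every fascicular source")
        sources = pruned
    else:
        mi_info = None
        vsolver = cache.get(("vsolver", id(anatomy)),
                            lambda: EikonalSolver(vmesh, vcond))

    tw = TWaveParams(apd_min=sample.omega_t["apd_min"],
                     apd_max=sample.omega_t["apd_max"],
                     q_w=(sample.omega_t["q_rho"], sample.omega_t["q_v"],
                          sample.omega_t["q_phi"], sample.omega_t["q_z"]))

    base = TorsoPose(**BASE_ORIENTATION)
    pose = TorsoPose(alpha_x=op["alpha_x"], alpha_y=op["alpha_y"],
                     alpha_z=op["alpha_z"], t_x=op["t_x"], t_y=op["t_y"],
                     t_z=op["t_z"])
    vplaced, electrodes = place_and_project(vmesh, base)
    vplaced, electrodes = place_and_project(vplaced, pose)
    v_active = vcond.active
    v_lf = lead_field(vplaced, electrodes, sigma, active=v_active)

    ventricular = {"mesh": vmesh, "cond": vcond, "solver": vsolver,
                   "sources": sources, "tw": tw,
                   "banks": [bank_sinus, bank_bz], "bank_id": bank_id_v,
                   "lead_field": v_lf, "mi_info": mi_info}

    # --- atria ------------------------------------------------------------
    la_scale = float(op.get("la_volume_scale", 1.0))
    if label.name != "lae":
        la_scale = 1.0
    a_anatomy = replace(anatomy, la_volume_scale=la_scale,
                        shape_coeffs=op.get("shape_coeffs",
                                            anatomy.shape_coeffs))
    akey = ("amesh", id(anatomy), round(la_scale, 3),
            tuple(round(c, 3) for c in a_anatomy.shape_coeffs))
    amesh = cache.get(akey, lambda: build_atrial_mesh(a_anatomy))
    acond = build_conduction_field_atrial(amesh, op["cv"])

    bank_healthy = get_bank(ATRIAL_PARAMS, 170.0, 300.0)
    fib_params = replace(
        ATRIAL_PARAMS,
        v_max=ATRIAL_PARAMS.v_min + FIBROTIC_AMPLITUDE_FACTOR
        * (ATRIAL_PARAMS.v_max - ATRIAL_PARAMS.v_min))
    bank_fibrotic = get_bank(fib_params, 170.0, 300.0)
    bank_id_a = np.zeros(amesh.n_nodes, dtype=np.int64)

    if label.name == "fam":
        if "fibrosis_fraction" not in op:
            raise ValueError("sample carries no fibrosis fraction; draw "
                             "it with the fam label")
        fspec = FibrosisSpec(volume_fraction=op["fibrosis_fraction"],
                             seed=sample.seed)
        acond, fib_info = apply_fibrosis(amesh, acond, fspec)
        bank_id_a[fib_info["fibrotic_nodes"]] = 1
    elif label.name == "iab":
        acond = apply_iab(amesh, acond)

    asolver = EikonalSolver(amesh, acond)
    sa_nodes = amesh.metadata["sa_node_nodes"]
    a_sources = [FascicularSource(name="sa_node", v="ra",
                                  nodes=np.asarray(sa_nodes), delay=0.0)]
    aplaced, _ = place_and_project(amesh, base)
    aplaced, _ = place_and_project(aplaced, pose)
    a_lf = lead_field(aplaced, electrodes, sigma, active=acond.active)

    atrial = {"mesh": amesh, "cond": acond, "solver": asolver,
              "sources": a_sources, "banks": [bank_healthy, bank_fibrotic],
              "bank_id": bank_id_a, "lead_field": a_lf,
              "apd": op.get("atrial_apd", 250.0)}

    return CaseConfig(label=label, sample=sample, ventricular=ventricular,
                      atrial=atrial, electrodes=electrodes,
                      avb=label.name == "avblock")
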