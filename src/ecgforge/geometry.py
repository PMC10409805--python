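"""Parametric idealized cardiac and torso geometry.

The anatomies used by the simulation pipeline are generated here rather
than derived from imaging: the ventricles are two truncated prolate
ellipsoids (a thick-walled LV and a thin crescent-shaped RV wrapped
around it) voxelized on a regular grid, and the atria are two spheroidal
shells bridged by a cylindrical Bachmann's-bundle surrogate and a
posterior interatrial connection, with great-circle bands standing in
for the crista terminalis, the pectinate muscles and the inferior
isthmus.  Every ventricular node carries analytic universal ventricular
coordinates (UVCs): transmural rho in [0, 1] (0 = endocardium),
rotational phi in [-pi, pi] (0 = mid-septum, positive toward anterior),
apico-basal z in [0, 1] (0 = apex) and a chamber label v.

The module also provides the Latin-hypercube sampler used to draw
electrophysiological parameter vectors, rigid placement of the heart
inside the torso frame, and a small VTK-legacy exporter for inspection.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import qmc

from . import config


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class AnatomyParams:
    """Dimensions of the idealized anatomy (mm unless noted).

    ``shape_coeffs`` are bounded surrogate eigen-coefficients: the first
    entries (bounds [-3, 3]) perturb the atrial shell radii, the last two
    (bounds [-2, 2]) perturb the torso electrode cage scale.  Each unit of
    coefficient maps to a 5% axis change, so the extreme +/-3 maps to
    +/-15%.
    """

    # ventricles
    lv_outer: tuple[float, float, float] = (34.0, 34.0, 48.0)
    lv_wall: float = 10.0
    rv_outer: tuple[float, float, float] = (40.0, 30.0, 44.0)
    rv_wall: float = 6.0
    rv_center: tuple[float, float, float] = (-18.0, 0.0, 2.0)
    base_truncation: float = 0.35   # base plane at z = frac * lv long semi-axis
    # atria
    ra_radius: float = 24.0
    la_radius: float = 21.0
    atrial_wall: float = 3.0
    atrial_separation: float = 52.0   # center-to-center distance
    la_volume_scale: float = 1.0      # >= 1; > 1 encodes left atrial enlargement
    shape_coeffs: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    resolution: float = 2.0           # voxel edge, mm

    def __post_init__(self) -> None:
        dims = (*self.lv_outer, self.lv_wall, *self.rv_outer, self.rv_wall,
                self.ra_radius, self.la_radius, self.atrial_wall,
                self.resolution)
        if any(d <= 0 for d in dims):
            raise ValueError("all anatomy dimensions must be positive")
        if self.la_volume_scale < 1.0:
            raise ValueError("la_volume_scale must be >= 1")
        n_atrial = len(self.shape_coeffs) - 2
        for i, c in enumerate(self.shape_coeffs):
            lo, hi = (config.SHAPE_COEFF_BOUNDS_ATRIA if i < n_atrial
                      else config.SHAPE_COEFF_BOUNDS_TORSO)
            if not lo <= c <= hi:
                raise ValueError(
                    f"shape coefficient {i} = {c} outside bounds [{lo}, {hi}]")


def standard_electrodes(scale: float = 1.0) -> dict[str, np.ndarray]:
    """Ten standard electrode positions (mm) in the torso frame.

    Frame: x toward the patient's left, y anterior, z superior, heart
    near the origin.  ``scale`` uniformly scales the cage to emulate
    torso size variation.
    """
    pos = {
        "RA": (-150.0, 50.0, 220.0),
        "LA": (150.0, 50.0, 220.0),
        "LL": (60.0, 40.0, -350.0),
        "RL": (-60.0, 40.0, -350.0),
        "V1": (-25.0, 95.0, 10.0),
        "V2": (25.0, 95.0, 10.0),
        "V3": (50.0, 95.0, -25.0),
        "V4": (75.0, 90.0, -55.0),
        "V5": (105.0, 70.0, -60.0),
        "V6": (125.0, 40.0, -60.0),
    }
    return {k: scale * np.asarray(v, dtype=float) for k, v in pos.items()}


@dataclass
class TorsoPose:
    """Rigid placement of the heart inside the torso frame.

    Rotations are applied in x -> y -> z order (degrees), then the
    translation (mm).  Electrode positions stay fixed in the torso frame.
    """

    alpha_x: float = 0.0
    alpha_y: float = 0.0
    alpha_z: float = 0.0
    t_x: float = 0.0
    t_y: float = 0.0
    t_z: float = 0.0
    electrode_positions: dict[str, np.ndarray] = field(
        default_factory=standard_electrodes)

    def __post_init__(self) -> None:
        missing = {"RA", "LA", "LL", "RL", "V1", "V2", "V3", "V4", "V5",
                   "V6"} - set(self.electrode_positions)
        if missing:
            raise ValueError(f"missing electrodes: {sorted(missing)}")

    def rotation_matrix(self) -> np.ndarray:
        ax, ay, az = (math.radians(a) for a in
                      (self.alpha_x, self.alpha_y, self.alpha_z))
        rx = np.array([[1, 0, 0],
                       [0, math.cos(ax), -math.sin(ax)],
                       [0, math.sin(ax), math.cos(ax)]])
        ry = np.array([[math.cos(ay), 0, math.sin(ay)],
                       [0, 1, 0],
                       [-math.sin(ay), 0, math.cos(ay)]])
        rz = np.array([[math.cos(az), -math.sin(az), 0],
                       [math.sin(az), math.cos(az), 0],
                       [0, 0, 1]])
        return rz @ ry @ rx

    def translation(self) -> np.ndarray:
        return np.array([self.t_x, self.t_y, self.t_z], dtype=float)


@dataclass
class ParameterSample:
    """One drawn electrophysiological parameter vector with its label."""

    omega_qrs: dict        # per-site {rho, phi, z, r, t, v}
    omega_t: dict          # {apd_min, apd_max, q_rho, q_v, q_phi, q_z}
    omega_p: dict          # atrial CVs + pose + shape coefficients
    omega_mi: dict | None  # {artery, phi, z, rho_n, d_co} or None
    seed: int
    label: str


# ---------------------------------------------------------------------------
# Mesh container


VENTRICULAR_REGIONS = ("lv_myo", "rv_myo")
ATRIAL_REGIONS = ("bulk_tissue", "bachmanns_bundle", "posterior_connection",
                  "crista_terminalis", "pectinate_muscles", "inferior_isthmus")


@dataclass
class CardiacMesh:
    """Voxelized cardiac mesh with region tags, fibers and coordinates.

    ``node_positions`` are the voxel vertices (mm); ``elements`` index
    eight vertices per hexahedron in VTK ordering.  Universal coordinates
    and the chamber label are per node; region tags and fiber triads
    (rows f, s, n) are per element.
    """

    node_positions: np.ndarray          # (Nv, 3) float, mm
    elements: np.ndarray                # (Ne, 8) int
    element_region: np.ndarray          # (Ne,) str
    fiber_frames: np.ndarray | None     # (Ne, 3, 3) float or None
    uvc: dict[str, np.ndarray]          # per-node rho, phi, z; 'v' per node
    chamber: np.ndarray                 # (Nv,) str
    resolution: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.node_positions) == 0 or len(self.elements) == 0:
            raise ValueError("mesh must contain nodes and elements")

    @property
    def n_nodes(self) -> int:
        return len(self.node_positions)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def element_centers(self) -> np.ndarray:
        return self.node_positions[self.elements].mean(axis=1)

    @property
    def element_volume(self) -> float:
        return float(self.resolution**3)

    def element_uvc(self, key: str) -> np.ndarray:
        """Element-averaged universal coordinate (phi via circular mean)."""
        vals = self.uvc[key][self.elements]
        if key == "phi":
            return np.arctan2(np.sin(vals).mean(axis=1),
                              np.cos(vals).mean(axis=1))
        return vals.mean(axis=1)

    def element_chamber(self) -> np.ndarray:
        """Majority chamber label per element."""
        ch = self.uvc["v"][self.elements]
        out = np.empty(self.n_elements, dtype=ch.dtype)
        for i in range(self.n_elements):
            labels, counts = np.unique(ch[i], return_counts=True)
            out[i] = labels[np.argmax(counts)]
        return out


# ---------------------------------------------------------------------------
# Voxelization helpers


# VTK hexahedron vertex ordering relative to the voxel's lower corner.
_HEX_OFFSETS = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
], dtype=np.int64)


def _voxels_to_mesh(ijk: np.ndarray, origin: np.ndarray, h: float):
    """Build (vertices, hexes, vertex_ijk) from voxel integer coordinates."""
    corners = ijk[:, None, :] + _HEX_OFFSETS[None, :, :]     # (Ne, 8, 3)
    flat = corners.reshape(-1, 3)
    uniq, inv = np.unique(flat, axis=0, return_inverse=True)
    elements = inv.reshape(-1, 8)
    vertices = origin[None, :] + uniq * h
    return vertices, elements, uniq


def _ellipsoid_radius(u: np.ndarray, axes: tuple[float, float, float]):
    """Distance from the center to the ellipsoid surface along unit rays."""
    a, b, c = axes
    denom = np.sqrt((u[:, 0] / a)**2 + (u[:, 1] / b)**2 + (u[:, 2] / c)**2)
    return 1.0 / np.maximum(denom, 1e-12)


def _inside_ellipsoid(p: np.ndarray, center, axes) -> np.ndarray:
    d = (p - np.asarray(center)) / np.asarray(axes)
    return (d**2).sum(axis=1) < 1.0


def _radial_rho(p: np.ndarray, center, inner_axes, outer_axes) -> np.ndarray:
    """Transmural coordinate along rays from the chamber center."""
    x = p - np.asarray(center)
    r = np.linalg.norm(x, axis=1)
    u = x / np.maximum(r, 1e-12)[:, None]
    r_in = _ellipsoid_radius(u, inner_axes)
    r_out = _ellipsoid_radius(u, outer_axes)
    return np.clip((r - r_in) / np.maximum(r_out - r_in, 1e-9), 0.0, 1.0)


def meridian_arc_length(axes_xy: float, axis_z: float,
                        z_lo: float, z_hi: float, n: int = 400) -> float:
    """Arc length of an ellipse meridian (semi-axes axes_xy, axis_z)
    between heights z_lo and z_hi, by polyline quadrature."""
    t_lo = math.asin(np.clip(z_lo / axis_z, -1, 1))
    t_hi = math.asin(np.clip(z_hi / axis_z, -1, 1))
    t = np.linspace(t_lo, t_hi, n)
    pts = np.stack([axes_xy * np.cos(t), axis_z * np.sin(t)], axis=1)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# Ventricular mesh


def build_ventricular_mesh(params: AnatomyParams | None = None) -> CardiacMesh:
    """Voxelized two-chamber truncated-ellipsoid ventricular mesh.

    The LV is a thick-walled prolate ellipsoid centered at the origin
    with its long axis along z (apex at -z); the RV is a thinner shell
    wrapped around the LV's septal side, truncated at the same base
    plane.  Analytic UVCs are assigned to every node.

    Raises ``ValueError`` when the voxel resolution cannot resolve at
    least three elements across the thinner wall.
    """
    p = params or AnatomyParams()
    h = p.resolution
    if h < 0.5:
        raise ValueError("resolution below 0.5 mm is not supported")
    min_wall = min(p.lv_wall, p.rv_wall)
    if min_wall / h < 3.0:
        raise ValueError(
            f"resolution {h} mm too coarse: only {min_wall / h:.1f} elements "
            f"across the {min_wall} mm wall (need >= 3)")

    lv_out = np.asarray(p.lv_outer, dtype=float)
    lv_in = lv_out - p.lv_wall
    rv_out = np.asarray(p.rv_outer, dtype=float)
    rv_in = rv_out - p.rv_wall
    rv_c = np.asarray(p.rv_center, dtype=float)
    z_base = p.base_truncation * lv_out[2]

    lo = np.minimum(-lv_out, rv_c - rv_out) - h
    hi = np.maximum(lv_out, rv_c + rv_out) + h
    hi[2] = z_base + h
    ni = np.ceil((hi - lo) / h).astype(int)
    origin = lo

    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in ni), indexing="ij")
    ijk = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = origin + (ijk + 0.5) * h

    below_base = centers[:, 2] <= z_base
    in_lv_out = _inside_ellipsoid(centers, (0, 0, 0), lv_out)
    in_lv_in = _inside_ellipsoid(centers, (0, 0, 0), lv_in)
    lv_mask = in_lv_out & ~in_lv_in & below_base

    in_rv_out = _inside_ellipsoid(centers, rv_c, rv_out)
    in_rv_in = _inside_ellipsoid(centers, rv_c, rv_in)
    rv_mask = in_rv_out & ~in_rv_in & ~in_lv_out & below_base & ~lv_mask

    keep = lv_mask | rv_mask
    region = np.where(lv_mask[keep], "lv_myo", "rv_myo")
    vertices, elements, vertex_ijk = _voxels_to_mesh(ijk[keep], origin, h)

    # Per-node chamber label and UVCs.  Nodes shared at the LV/RV junction
    # are labeled lv (the septum belongs to the left ventricle).
    chamber = np.full(len(vertices), "rv", dtype="<U2")
    lv_nodes = np.unique(elements[region == "lv_myo"])
    chamber[lv_nodes] = "lv"

    rho = np.empty(len(vertices))
    phi = np.empty(len(vertices))
    zuvc = np.empty(len(vertices))

    is_lv = chamber == "lv"
    pl = vertices[is_lv]
    rho[is_lv] = _radial_rho(pl, (0, 0, 0), tuple(lv_in), tuple(lv_out))
    phi[is_lv] = np.arctan2(pl[:, 1], -pl[:, 0])
    zuvc[is_lv] = np.clip((pl[:, 2] + lv_out[2]) / (z_base + lv_out[2]), 0, 1)

    is_rv = ~is_lv
    pr = vertices[is_rv] - rv_c
    rho[is_rv] = _radial_rho(vertices[is_rv], tuple(rv_c), tuple(rv_in),
                             tuple(rv_out))
    phi[is_rv] = np.arctan2(pr[:, 1], pr[:, 0])
    z_apex_rv = -rv_out[2]
    zuvc[is_rv] = np.clip((pr[:, 2] - z_apex_rv) / (z_base - rv_c[2] - z_apex_rv),
                          0, 1)

    # Apico-basal arc lengths of the mid-wall meridians, used to convert
    # fractional fascicular-site radii into physical distances.
    lv_mid = 0.5 * (lv_in + lv_out)
    arc_lv = meridian_arc_length(lv_mid[0], lv_mid[2], -lv_mid[2] * 0.999,
                                 min(z_base, lv_mid[2] * 0.999))
    rv_mid = 0.5 * (rv_in + rv_out)
    arc_rv = meridian_arc_length(rv_mid[0], rv_mid[2], -rv_mid[2] * 0.999,
                                 min(z_base - rv_c[2], rv_mid[2] * 0.999))

    mesh = CardiacMesh(
        node_positions=vertices,
        elements=elements,
        element_region=region,
        fiber_frames=None,
        uvc={"rho": rho, "phi": phi, "z": zuvc, "v": chamber},
        chamber=chamber,
        resolution=h,
        metadata={
            "kind": "ventricles",
            "lv_long_axis": float(z_base + lv_out[2]),
            "arc_length": {"lv": arc_lv, "rv": arc_rv},
            "z_base": float(z_base),
            "anatomy": p,
            "element_ijk": ijk[keep],
            "vertex_ijk": vertex_ijk,
            "origin": origin,
        },
    )
    return assign_ventricular_fibers(mesh)


def helix_angle(rho: np.ndarray, alpha_endo: float, alpha_epi: float):
    """Linear transmural interpolation of the fiber angle (degrees)."""
    return alpha_endo + np.asarray(rho) * (alpha_epi - alpha_endo)


def fiber_triad(e_c: np.ndarray, e_l: np.ndarray, e_t: np.ndarray,
                alpha_deg: np.ndarray, beta_deg: np.ndarray) -> np.ndarray:
    """Orthonormal (f, s, n) triads from local wall directions and angles.

    ``e_c`` circumferential, ``e_l`` apico-basal (in-wall), ``e_t``
    transmural; the helix angle alpha rotates the fiber from e_c toward
    e_l, the sheet angle beta rotates the sheet away from the transmural
    direction about the fiber axis.
    """
    a = np.radians(alpha_deg)[:, None]
    b = np.radians(beta_deg)[:, None]
    f = np.cos(a) * e_c + np.sin(a) * e_l
    s = np.cos(b) * e_t + np.sin(b) * np.cross(f, e_t)
    n = np.cross(f, s)
    return np.stack([f, s, n], axis=1)


def _wall_directions(centers: np.ndarray, chamber_centers: np.ndarray):
    """Local (circumferential, apico-basal, transmural) unit vectors."""
    x = centers - chamber_centers
    r = np.linalg.norm(x, axis=1)
    e_t = x / np.maximum(r, 1e-12)[:, None]
    zhat = np.array([0.0, 0.0, 1.0])
    e_c = np.cross(np.broadcast_to(zhat, e_t.shape), e_t)
    nc = np.linalg.norm(e_c, axis=1)
    degen = nc < 1e-8
    e_c[degen] = np.array([0.0, 1.0, 0.0])
    e_c /= np.linalg.norm(e_c, axis=1)[:, None]
    # re-orthogonalize against e_t (degenerate apex rays)
    e_c -= (e_c * e_t).sum(axis=1)[:, None] * e_t
    e_c /= np.linalg.norm(e_c, axis=1)[:, None]
    e_l = np.cross(e_t, e_c)
    flip = e_l[:, 2] < 0
    e_l[flip] *= -1
    e_c[flip] *= -1
    return e_c, e_l, e_t


def assign_ventricular_fibers(mesh: CardiacMesh,
                              alpha_endo: float = config.ALPHA_ENDO,
                              alpha_epi: float = config.ALPHA_EPI,
                              beta_endo: float = config.BETA_ENDO,
                              beta_epi: float = config.BETA_EPI) -> CardiacMesh:
    """Rule-based fibers: helix angle rotating linearly across the wall."""
    if "rho" not in mesh.uvc:
        raise ValueError("mesh has no universal coordinates")
    centers = mesh.element_centers
    el_ch = mesh.element_chamber()
    rho = mesh.element_uvc("rho")
    anatomy: AnatomyParams = mesh.metadata["anatomy"]
    ccenters = np.where((el_ch == "rv")[:, None],
                        np.asarray(anatomy.rv_center), 0.0)
    e_c, e_l, e_t = _wall_directions(centers, ccenters)
    alpha = helix_angle(rho, alpha_endo, alpha_epi)
    beta = helix_angle(rho, beta_endo, beta_epi)
    mesh.fiber_frames = fiber_triad(e_c, e_l, e_t, alpha, beta)
    return mesh


# ---------------------------------------------------------------------------
# Atrial mesh


def _band_az(w: np.ndarray, center: float, half_width: float) -> np.ndarray:
    az = np.arctan2(w[:, 1], w[:, 0])
    d = np.angle(np.exp(1j * (az - center)))
    return np.abs(d) <= half_width


def build_atrial_mesh(params: AnatomyParams | None = None) -> CardiacMesh:
    """Two spheroidal atrial shells with interatrial bridges and bands.

    The RA sits at -x, the LA at +x; both are spherical shells of the
    configured wall thickness.  A cylindrical anterior bridge stands in
    for Bachmann's bundle and a thinner posterior bridge provides the
    secondary interatrial pathway.  Great-circle bands on the RA are
    tagged crista terminalis, pectinate muscles and inferior isthmus;
    the sinoatrial exit site is the set of nodes at the superior end of
    the crista terminalis (the SVC junction surrogate).
    """
    p = params or AnatomyParams()
    if p.la_volume_scale < 1.0:
        raise ValueError("la_volume_scale must be >= 1")
    h = p.resolution
    c_shape = 1.0 + 0.05 * p.shape_coeffs[0] if p.shape_coeffs else 1.0
    r_ra = p.ra_radius * c_shape
    r_la = p.la_radius * c_shape * p.la_volume_scale ** (1.0 / 3.0)
    wall = p.atrial_wall
    d = p.atrial_separation / 2.0
    ra_c = np.array([-d, 0.0, 0.0])
    la_c = np.array([+d, 0.0, 0.0])

    lo = np.array([-d - r_ra, -max(r_ra, r_la), -max(r_ra, r_la)]) - h
    hi = np.array([d + r_la, max(r_ra, r_la), max(r_ra, r_la)]) + h
    ni = np.ceil((hi - lo) / h).astype(int)
    origin = lo
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in ni), indexing="ij")
    ijk = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = origin + (ijk + 0.5) * h

    dist_ra = np.linalg.norm(centers - ra_c, axis=1)
    dist_la = np.linalg.norm(centers - la_c, axis=1)
    ra_shell = (dist_ra <= r_ra) & (dist_ra > r_ra - wall)
    la_shell = (dist_la <= r_la) & (dist_la > r_la - wall)

    def _cylinder(p0, p1, radius):
        seg = p1 - p0
        L2 = seg @ seg
        t = np.clip(((centers - p0) @ seg) / L2, 0.0, 1.0)
        proj = p0 + t[:, None] * seg
        return np.linalg.norm(centers - proj, axis=1) <= radius

    u_bb_ra = np.array([0.50, 0.40, 0.80]); u_bb_ra /= np.linalg.norm(u_bb_ra)
    u_bb_la = np.array([-0.50, 0.40, 0.80]); u_bb_la /= np.linalg.norm(u_bb_la)
    bb = _cylinder(ra_c + (r_ra - 1.5) * u_bb_ra,
                   la_c + (r_la - 1.5) * u_bb_la, 3.5)
    bb &= (dist_ra > r_ra - wall) & (dist_la > r_la - wall)

    u_po_ra = np.array([0.35, -0.55, -0.75]); u_po_ra /= np.linalg.norm(u_po_ra)
    u_po_la = np.array([-0.35, -0.55, -0.75]); u_po_la /= np.linalg.norm(u_po_la)
    post = _cylinder(ra_c + (r_ra - 1.5) * u_po_ra,
                     la_c + (r_la - 1.5) * u_po_la, 2.5)
    post &= (dist_ra > r_ra - wall) & (dist_la > r_la - wall) & ~bb

    keep = ra_shell | la_shell | bb | post
    region = np.full(keep.sum(), "bulk_tissue", dtype="<U24")
    c_kept = centers[keep]
    ra_k = ra_shell[keep]
    w_ra = (c_kept - ra_c) / np.maximum(
        np.linalg.norm(c_kept - ra_c, axis=1), 1e-12)[:, None]

    # crista terminalis: posterior-lateral meridian band of the RA
    az_ct = -2.2
    ct = ra_k & _band_az(w_ra, az_ct, 0.35) & (w_ra[:, 2] > -0.6) \
        & (w_ra[:, 2] < 0.85)
    # pectinate muscles: band anterior of the crista
    pm = ra_k & _band_az(w_ra, az_ct + 0.9, 0.5) & (np.abs(w_ra[:, 2]) < 0.55)
    # inferior isthmus: inferior cap of the RA
    isth = ra_k & (w_ra[:, 2] <= -0.7)

    region[isth] = "inferior_isthmus"
    region[pm & ~isth] = "pectinate_muscles"
    region[ct & ~isth] = "crista_terminalis"
    region[bb[keep]] = "bachmanns_bundle"
    region[post[keep]] = "posterior_connection"

    vertices, elements, vertex_ijk = _voxels_to_mesh(ijk[keep], origin, h)

    vdist_ra = np.linalg.norm(vertices - ra_c, axis=1)
    vdist_la = np.linalg.norm(vertices - la_c, axis=1)
    chamber = np.where(vdist_ra / r_ra <= vdist_la / r_la, "ra", "la")
    is_ra = chamber == "ra"
    cc = np.where(is_ra[:, None], ra_c, la_c)
    rr = np.where(is_ra, r_ra, r_la)
    w = (vertices - cc) / np.maximum(
        np.linalg.norm(vertices - cc, axis=1), 1e-12)[:, None]
    vdist = np.where(is_ra, vdist_ra, vdist_la)
    rho = np.clip((vdist - (rr - wall)) / wall, 0.0, 1.0)
    phi = np.arctan2(w[:, 1], w[:, 0])
    zc = np.clip((w[:, 2] + 1.0) / 2.0, 0.0, 1.0)

    # sinoatrial exit: superior end of the crista terminalis
    ct_elems = np.flatnonzero(region == "crista_terminalis")
    ct_nodes = np.unique(elements[ct_elems])
    sa_nodes = ct_nodes[vertices[ct_nodes, 2] - ra_c[2]
                        >= 0.7 * r_ra]
    if len(sa_nodes) == 0 and len(ct_nodes):
        top = np.argsort(vertices[ct_nodes, 2])[::-1][:4]
        sa_nodes = ct_nodes[top]

    # fibers: bands along their axis, bulk circumferential, radial sheets
    el_center = vertices[elements].mean(axis=1)
    el_ra = np.linalg.norm(el_center - ra_c, axis=1) / r_ra <= \
        np.linalg.norm(el_center - la_c, axis=1) / r_la
    el_cc = np.where(el_ra[:, None], ra_c, la_c)
    ex = el_center - el_cc
    e_t = ex / np.maximum(np.linalg.norm(ex, axis=1), 1e-12)[:, None]
    zhat = np.array([0.0, 0.0, 1.0])
    f = np.cross(np.broadcast_to(zhat, e_t.shape), e_t)
    bad = np.linalg.norm(f, axis=1) < 1e-8
    f[bad] = np.array([0.0, 1.0, 0.0])
    f /= np.linalg.norm(f, axis=1)[:, None]
    merid = np.cross(e_t, f)
    for tag, axis in (("crista_terminalis", None), ("pectinate_muscles", None)):
        m = region == tag
        f[m] = merid[m]
    for tag, p0, p1 in (("bachmanns_bundle", ra_c + r_ra * u_bb_ra,
                         la_c + r_la * u_bb_la),
                        ("posterior_connection", ra_c + r_ra * u_po_ra,
                         la_c + r_la * u_po_la)):
        m = region == tag
        ax = (p1 - p0) / np.linalg.norm(p1 - p0)
        f[m] = ax
    s = e_t - (e_t * f).sum(axis=1)[:, None] * f
    ns = np.linalg.norm(s, axis=1)
    bad = ns < 1e-8
    s[bad] = np.cross(f[bad], np.array([1.0, 0.0, 0.0]))
    s /= np.linalg.norm(s, axis=1)[:, None]
    n = np.cross(f, s)
    frames = np.stack([f, s, n], axis=1)

    return CardiacMesh(
        node_positions=vertices,
        elements=elements,
        element_region=region,
        fiber_frames=frames,
        uvc={"rho": rho, "phi": phi, "z": zc, "v": chamber},
        chamber=chamber,
        resolution=h,
        metadata={
            "kind": "atria",
            "sa_node_nodes": sa_nodes,
            "la_enclosed_volume_mm3": 4.0 / 3.0 * math.pi * r_la**3,
            "ra_radius": float(r_ra), "la_radius": float(r_la),
            "ra_center": ra_c, "la_center": la_c,
            "anatomy": p,
            "element_ijk": ijk[keep],
            "vertex_ijk": vertex_ijk,
            "origin": origin,
        },
    )


# ---------------------------------------------------------------------------
# Placement and sampling


def place_and_project(mesh: CardiacMesh, pose: TorsoPose):
    """Apply the rigid pose to the heart; electrodes stay in the torso frame.

    Returns ``(placed_mesh, electrodes)`` where ``electrodes`` maps the
    ten electrode names to positions (mm).
    """
    R = pose.rotation_matrix()
    t = pose.translation()
    frames = (None if mesh.fiber_frames is None
              else mesh.fiber_frames @ R.T)
    moved = replace(mesh, node_positions=mesh.node_positions @ R.T + t,
                    fiber_frames=frames)
    md = dict(mesh.metadata)
    for key in ("ra_center", "la_center"):
        if key in md:
            md[key] = R @ md[key] + t
    moved.metadata = md
    return moved, dict(pose.electrode_positions)


def lhs_sample(ranges: dict[str, tuple[float, float]], n: int,
               seed: int) -> list[dict[str, float]]:
    """Latin-hypercube design over named ranges.

    For every symbol the ``n`` samples occupy each of the ``n``
    equal-width strata of its ``[lo, hi]`` range exactly once; the
    design is deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = list(ranges)
    for k in names:
        lo, hi = ranges[k]
        if lo > hi:
            raise ValueError(f"inverted range for {k}: [{lo}, {hi}]")
    if not names:
        return [{} for _ in range(n)]
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    lows = np.array([ranges[k][0] for k in names])
    highs = np.array([ranges[k][1] for k in names])
    scaled = lows + unit * (highs - lows)
    return [dict(zip(names, row)) for row in scaled]


# ---------------------------------------------------------------------------
# VTK-legacy export (inspection aid)


def write_vtk(mesh: CardiacMesh, path: str,
              point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh (and optional per-node scalars) as legacy ASCII VTK."""
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\necgforge mesh\nASCII\n")
    buf.write("DATASET UNSTRUCTURED_GRID\n")
    buf.write(f"POINTS {mesh.n_nodes} float\n")
    np.savetxt(buf, mesh.node_positions, fmt="%.4f")
    ne = mesh.n_elements
    buf.write(f"CELLS {ne} {ne * 9}\n")
    cells = np.hstack([np.full((ne, 1), 8), mesh.elements])
    np.savetxt(buf, cells, fmt="%d")
    buf.write(f"CELL_TYPES {ne}\n")
    np.savetxt(buf, np.full(ne, 12), fmt="%d")
    regions = {r: i for i, r in enumerate(np.unique(mesh.element_region))}
    buf.write(f"CELL_DATA {ne}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
    np.savetxt(buf, [regions[r] for r in mesh.element_region], fmt="%d")
    if point_data:
        buf.write(f"POINT_DATA {mesh.n_nodes}\n")
        for name, vals in point_data.items():
            buf.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(buf, np.asarray(vals, dtype=float), fmt="%.6g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def build_slab_mesh(size: tuple[float, float, float], resolution: float,
                    fiber_axis: int = 0) -> CardiacMesh:
    """Homogeneous rectangular slab with axis-aligned fibers.

    A verification fixture: uniform region tag, fibers along the given
    lattice axis, UVCs set to normalized box coordinates.
    """
    h = resolution
    ni = np.maximum(np.round(np.asarray(size) / h).astype(int), 1)
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in ni), indexing="ij")
    ijk = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    origin = np.zeros(3)
    vertices, elements, vertex_ijk = _voxels_to_mesh(ijk, origin, h)
    ne = len(elements)
    frames = np.zeros((ne, 3, 3))
    axes = [fiber_axis, (fiber_axis + 1) % 3, (fiber_axis + 2) % 3]
    for row, ax in enumerate(axes):
        frames[:, row, ax] = 1.0
    ext = np.maximum(vertices.max(axis=0), 1e-9)
    uvc = {
        "rho": vertices[:, 0] / ext[0],
        "phi": vertices[:, 1] / ext[1] * 2 * math.pi - math.pi,
        "z": vertices[:, 2] / ext[2],
        "v": np.full(len(vertices), "lv", dtype="<U2"),
    }
    return CardiacMesh(
        node_positions=vertices,
        elements=elements,
        element_region=np.full(ne, "lv_myo", dtype="<U24"),
        fiber_frames=frames,
        uvc=uvc,
        chamber=uvc["v"].copy(),
        resolution=h,
        metadata={"kind": "slab", "lv_long_axis": float(size[2]),
                  "anatomy": None, "element_ijk": ijk,
                  "vertex_ijk": vertex_ijk, "origin": origin},
    )
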