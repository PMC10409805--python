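"""Anisotropic Eikonal activation on voxel meshes.

Local activation times are computed as shortest travel times on a graph
whose vertices are the mesh nodes and whose edges connect lattice
neighbors up to second order (all integer offsets in {-2..2}^3 with
coprime components, 98 neighbors).  Each edge is weighted with the
anisotropic travel-time metric

    w(e) = || e ||_M,   M = R diag(cv_f^-2, cv_s^-2, cv_n^-2) R^T,

evaluated in the fiber frame of the voxels the edge traverses; edges
whose path crosses inert tissue (cv = 0) are removed.  A single
label-correcting shortest-path pass (scipy's Dijkstra) from a
super-source node carrying the per-site delays yields the activation
map; unreachable nodes keep +inf.

The same machinery provides geodesic region growing used by the infarct
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from . import config
from .geometry import CardiacMesh, meridian_arc_length

@dataclass
class FascicularSource:
    """A named source node set with its activation delay (ms)."""

    name: str
    v: str                # chamber the site belongs to
    nodes: np.ndarray
    delay: float


#: Source description: FascicularSource records or (nodes, delay) pairs.
SourceSet = list


def _as_pairs(sources: SourceSet) -> list[tuple[np.ndarray, float]]:
    pairs = []
    for s in sources:
        if isinstance(s, FascicularSource):
            pairs.append((np.asarray(s.nodes), float(s.delay)))
        else:
            nodes, delay = s
            pairs.append((np.asarray(nodes), float(delay)))
    return pairs


@dataclass
class ConductionField:
    """Per-element principal conduction velocities (m/s) and region labels."""

    cv: np.ndarray        # (Ne, 3): along fiber, sheet, sheet-normal
    region: np.ndarray    # (Ne,) str

    def __post_init__(self) -> None:
        if np.any(self.cv < 0):
            raise ValueError("conduction velocities must be non-negative")

    @property
    def active(self) -> np.ndarray:
        """Elements with non-zero conduction on all axes."""
        return (self.cv > 0).all(axis=1)


@dataclass
class FascicularSite:
    """Disc-shaped fascicular breakthrough region in UVCs."""

    name: str
    v: str
    rho: float
    phi: float
    z: float
    r: float          # endocardial extent, fraction of the apico-basal arc
    t: float          # activation delay, ms
    thickness: float = 0.005   # transmural, fraction of the wall

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("site delay must be non-negative")
        if not 0.0 <= self.r <= 0.8:
            raise ValueError("site radius outside [0, 0.8]")


# ---------------------------------------------------------------------------
# Conduction fields


def build_conduction_field_ventricular(
        mesh: CardiacMesh,
        cv_myo: float = config.CV_MYO,
        ratio: tuple[float, float, float] = config.CV_MYO_RATIO,
        cv_endo: float = config.CV_ENDO,
        endo_band_z: tuple[float, float] = config.ENDO_BAND_Z,
        endo_rho: float = config.ENDO_RHO) -> ConductionField:
    """Myocardial anisotropic CVs plus the isotropic fast endocardium.

    The fast-conducting endocardial layer covers elements with
    transmural coordinate rho <= ``endo_rho`` whose apico-basal
    coordinate lies inside ``endo_band_z``.
    """
    if mesh.fiber_frames is None:
        raise ValueError("mesh needs fiber frames")
    ne = mesh.n_elements
    r = np.asarray(ratio, dtype=float) / ratio[0]
    cv = np.tile(cv_myo * r, (ne, 1))
    rho = mesh.element_uvc("rho")
    z = mesh.element_uvc("z")
    endo = (rho <= endo_rho) & (z >= endo_band_z[0]) & (z <= endo_band_z[1])
    cv[endo] = cv_endo
    region = mesh.element_region.copy().astype("<U24")
    region[endo] = "fast_endo"
    return ConductionField(cv=cv, region=region)


def build_conduction_field_atrial(
        mesh: CardiacMesh,
        cv_trans: dict[str, float]) -> ConductionField:
    """Regional atrial CVs: transversal values per region, longitudinal
    obtained by multiplying with the fixed anisotropy ratio.

    ``cv_trans`` maps every region of ``config.ATRIAL_CV_RANGES`` to its
    transversal conduction velocity (m/s); the posterior interatrial
    connection shares the interatrial-connection values.
    """
    missing = set(config.ATRIAL_CV_RANGES) - set(cv_trans)
    if missing:
        raise ValueError(f"missing region CVs: {sorted(missing)}")
    alias = {"posterior_connection": "interatrial_connections",
             "bachmanns_bundle": "interatrial_connections"}
    ne = mesh.n_elements
    cv = np.zeros((ne, 3))
    for tag in np.unique(mesh.element_region):
        key = alias.get(tag, tag)
        if key not in cv_trans:
            raise ValueError(f"region {tag!r} has no conduction velocity")
        trans = cv_trans[key]
        ar = config.ATRIAL_AR[key]
        if tag == "posterior_connection":
            # secondary pathway: interatrial CV but without the fast
            # longitudinal anisotropy, so Bachmann's bundle dominates
            ar = 1.0
        m = mesh.element_region == tag
        cv[m] = (ar * trans, trans, trans)
    return ConductionField(cv=cv, region=mesh.element_region.copy())


# ---------------------------------------------------------------------------
# Fascicular sources


def _wrap(a: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * a))


def make_fascicular_sites(omega_qrs: dict) -> list[FascicularSite]:
    return [FascicularSite(name=name, v=s["v"], rho=s["rho"], phi=s["phi"],
                           z=s["z"], r=s["r"], t=s["t"])
            for name, s in omega_qrs.items()]


def fascicular_sources(mesh: CardiacMesh, omega_qrs: dict) -> SourceSet:
    """Five disc-shaped node sets with their activation delays.

    Each site is grown on its rho shell: nodes of the site's chamber
    within one transmural node layer (the configured 0.5%-of-wall disc
    thickness is below mesh resolution, so at least one full layer is
    seeded) and within geodesic radius ``r`` times the chamber's
    apico-basal arc length of the site center.  A site degenerates to
    its single nearest node when the radius resolves no neighbors.
    """
    sites = make_fascicular_sites(omega_qrs)
    arcs = mesh.metadata.get("arc_length", {})
    rho = mesh.uvc["rho"]
    phi = mesh.uvc["phi"]
    zc = mesh.uvc["z"]
    vlab = mesh.uvc["v"]
    anatomy = mesh.metadata.get("anatomy")
    sources: SourceSet = []
    for s in sites:
        if not (0 <= s.rho <= 1 and -np.pi <= s.phi <= np.pi and
                0 <= s.z <= 1):
            raise ValueError(f"site {s.name} center outside UVC ranges")
        side = vlab == s.v
        if not side.any():
            raise ValueError(f"no nodes in chamber {s.v!r}")
        idx = np.flatnonzero(side)
        d2 = ((rho[idx] - s.rho)**2 + (_wrap(phi[idx] - s.phi) / np.pi)**2
              + (zc[idx] - s.z)**2)
        center = idx[np.argmin(d2)]
        wall = (anatomy.lv_wall if s.v == "lv" else anatomy.rv_wall) \
            if anatomy is not None else 10.0
        rho_tol = max(s.thickness / 2, 0.6 * mesh.resolution / wall)
        shell = idx[np.abs(rho[idx] - s.rho) <= rho_tol]
        arc = arcs.get(s.v, mesh.metadata.get("lv_long_axis", 60.0))
        radius = s.r * arc
        dist = np.linalg.norm(mesh.node_positions[shell]
                              - mesh.node_positions[center], axis=1)
        nodes = shell[dist <= radius]
        if len(nodes) == 0:
            nodes = np.array([center])
        sources.append(FascicularSource(name=s.name, v=s.v, nodes=nodes,
                                        delay=float(s.t)))
    return sources


# ---------------------------------------------------------------------------
# Eikonal solver


def _neighbor_offsets(order: int = 2) -> np.ndarray:
    """Canonical half-space lattice offsets with coprime components."""
    offs = []
    for o in product(range(-order, order + 1), repeat=3):
        if o == (0, 0, 0):
            continue
        g = np.gcd.reduce([abs(c) for c in o])
        if g != 1:
            continue
        # keep one representative per +/- pair
        if o > (0, 0, 0):
            offs.append(o)
    return np.array(offs, dtype=np.int64)


class EikonalSolver:
    """Shortest-travel-time solver bound to one (mesh, conduction) pair.

    Building the anisotropic edge graph is the expensive part; the
    instance can then solve for many source configurations.
    """

    def __init__(self, mesh: CardiacMesh, cond: ConductionField,
                 order: int = 2):
        if "element_ijk" not in mesh.metadata:
            raise ValueError("mesh lacks lattice metadata")
        self.mesh = mesh
        self.n = mesh.n_nodes
        active = cond.active
        eijk = mesh.metadata["element_ijk"]
        vijk = mesh.metadata["vertex_ijk"]
        gs = eijk.max(axis=0) + 1
        vgs = vijk.max(axis=0) + 1

        vid = np.full(tuple(vgs), -1, dtype=np.int64)
        vid[tuple(vijk.T)] = np.arange(self.n)

        act = np.zeros(tuple(gs), dtype=bool)
        act[tuple(eijk.T)] = active
        cv_grid = np.zeros((*gs, 3))
        cv_grid[tuple(eijk.T)] = np.where(active[:, None], cond.cv, 0.0)
        fr_grid = np.zeros((*gs, 3, 3))
        fr_grid[tuple(eijk.T)] = mesh.fiber_frames

        pos = mesh.node_positions
        rows, cols, weights = [], [], []
        n_samp = 4
        ts = (2 * np.arange(n_samp) + 1) / (2 * n_samp)
        for off in _neighbor_offsets(order):
            a = vijk
            b = vijk + off
            ok = ((b >= 0) & (b < vgs)).all(axis=1)
            ia = np.flatnonzero(ok)
            jb = vid[tuple(b[ok].T)]
            ok2 = jb >= 0
            ia, jb = ia[ok2], jb[ok2]
            if len(ia) == 0:
                continue
            # voxel-candidate combinations: along dimensions where the
            # offset is zero the sample point lies on a lattice plane and
            # either adjacent voxel counts
            zero_dims = np.flatnonzero(off == 0)
            combos = list(product(*[( -1, 0) if d in zero_dims else (0,)
                                    for d in range(3)]))
            d_phys = pos[jb] - pos[ia]
            time = np.zeros(len(ia))
            valid = np.ones(len(ia), dtype=bool)
            base = vijk[ia].astype(float)
            for t in ts:
                p = base + t * off        # lattice coords of the sample
                # sample coords are integers exactly on zero-offset dims
                # (handled by the candidate combos) and never otherwise
                cell = np.floor(p).astype(np.int64)
                found = np.zeros(len(ia), dtype=bool)
                tt_best = np.full(len(ia), np.inf)
                for combo in combos:
                    c = cell + np.asarray(combo, dtype=np.int64)
                    inb = ((c >= 0) & (c < gs)).all(axis=1)
                    cc = np.clip(c, 0, gs - 1)
                    hit = inb & act[tuple(cc.T)]
                    if not hit.any():
                        continue
                    cv_s = cv_grid[tuple(cc[hit].T)]
                    fr_s = fr_grid[tuple(cc[hit].T)]
                    comp = np.einsum("ei,eri->er", d_phys[hit], fr_s)
                    tt = np.sqrt(((comp / cv_s)**2).sum(axis=1))
                    # fastest active candidate: blocking tissue can then
                    # only remove options, keeping LAT maps monotone
                    tt_best[hit] = np.minimum(tt_best[hit], tt)
                    found |= hit
                valid &= found
                time += np.where(found, tt_best, 0.0) / n_samp
            rows.append(ia[valid])
            cols.append(jb[valid])
            weights.append(time[valid])
        self._rows = np.concatenate(rows)
        self._cols = np.concatenate(cols)
        self._weights = np.concatenate(weights)
        # nodes touching at least one conducting element; source nodes
        # outside this set (e.g. swallowed by an inert infarct core) are
        # ignored, keeping source sets disjoint from inert tissue
        self._active_nodes = np.zeros(self.n, dtype=bool)
        self._active_nodes[np.unique(mesh.elements[active])] = True

    def solve(self, sources: SourceSet) -> np.ndarray:
        """Per-node activation time (ms); +inf on unreachable nodes."""
        pairs = _as_pairs(sources) if sources else []
        if not pairs or all(len(nodes) == 0 for nodes, _ in pairs):
            raise ValueError("empty source set")
        src_rows, src_cols, src_w = [], [], []
        super_src = self.n
        pairs = [(nodes[self._active_nodes[np.asarray(nodes,
                                                      dtype=np.int64)]],
                  delay) for nodes, delay in pairs]
        if all(len(nodes) == 0 for nodes, _ in pairs):
            raise ValueError("every source node lies in inert tissue")
        for nodes, delay in pairs:
            nodes = np.asarray(nodes, dtype=np.int64)
            src_rows.append(np.full(len(nodes), super_src))
            src_cols.append(nodes)
            src_w.append(np.full(len(nodes), float(delay)))
        rows = np.concatenate([self._rows, *src_rows])
        cols = np.concatenate([self._cols, *src_cols])
        w = np.concatenate([self._weights, *src_w])
        g = csr_matrix((w, (rows, cols)), shape=(self.n + 1, self.n + 1))
        dist = dijkstra(g, directed=False, indices=super_src)
        return dist[:self.n]


def solve_eikonal(mesh: CardiacMesh, cond: ConductionField,
                  sources: SourceSet, order: int = 2) -> np.ndarray:
    """One-shot activation map: LAT(x) = min over sources of
    (delay + anisotropic travel time)."""
    return EikonalSolver(mesh, cond, order=order).solve(sources)


# ---------------------------------------------------------------------------
# Geodesic region growing


def geodesic_region(mesh: CardiacMesh, center: dict, d_co: float,
                    cond: ConductionField,
                    solver: EikonalSolver | None = None,
                    return_times: bool = False):
    """Element indices within geodesic radius ``d_co * L`` of a UVC center.

    ``center`` holds UVC keys (rho, phi, z, v); ``L`` is the LV
    long-axis length, so ``d_co`` is a dimensionless radius fraction.
    The region is grown by thresholding an Eikonal solve from the
    center node at the time whose isochrone reaches the prescribed
    radius at the fastest principal speed of the field.  The element
    closest to the center is always included.
    """
    if d_co < 0:
        raise ValueError("d_co must be non-negative")
    rho = mesh.uvc["rho"]
    phi = mesh.uvc["phi"]
    zc = mesh.uvc["z"]
    side = mesh.uvc["v"] == center.get("v", "lv")
    idx = np.flatnonzero(side)
    d2 = ((rho[idx] - center.get("rho", 0.3))**2
          + (_wrap(phi[idx] - center["phi"]) / np.pi)**2
          + (zc[idx] - center["z"])**2)
    cnode = idx[np.argmin(d2)]
    if solver is None:
        solver = EikonalSolver(mesh, cond)
    lat = solver.solve([(np.array([cnode]), 0.0)])
    L = mesh.metadata["lv_long_axis"]
    cv_ref = float(cond.cv.max())
    t_star = d_co * L / cv_ref
    elat = lat[mesh.elements].mean(axis=1)
    region = np.flatnonzero(elat <= t_star)
    if len(region) == 0:
        region = np.array([int(np.argmin(elat))])
    if return_times:
        return region, elat
    return region
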