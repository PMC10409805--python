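"""Disease modifiers: BBB, MI, fibrosis, IAB, case configuration."""

import numpy as np
import pytest

from ecgforge import (FibrosisSpec, InfarctSpec, PathologyLabel, all_cases,
                      apply_bbb, apply_fibrosis, apply_iab, apply_mi,
                      build_conduction_field_atrial,
                      build_conduction_field_ventricular, fascicular_sources,
                      parse_label, solve_eikonal)
from ecgforge.activation import EikonalSolver
from ecgforge.config import ATRIAL_CV_RANGES
from ecgforge.pathology import draw_parameter_samples

from test_activation import mid_range_sites


@pytest.fixture(scope="module")
def vent_sources(vent_mesh):
    return fascicular_sources(vent_mesh, mid_range_sites())


@pytest.fixture(scope="module")
def atrial_cond(atrial_mesh):
    cvs = {r: np.mean(v) for r, v in ATRIAL_CV_RANGES.items()}
    return build_conduction_field_atrial(atrial_mesh, cvs)


class TestBBB:
    def test_lbbb_leaves_rv_sites(self, vent_sources):
        kept = apply_bbb(vent_sources, "lv")
        assert {s.name for s in kept} == {"rv_mod", "rv_sept"}

    def test_rbbb_leaves_lv_sites(self, vent_sources):
        kept = apply_bbb(vent_sources, "rv")
        assert {s.name for s in kept} == {"lv_ant", "lv_post", "lv_sept"}

    def test_block_with_no_sites_is_noop(self, vent_sources):
        rv_only = [s for s in vent_sources if s.v == "rv"]
        assert apply_bbb(rv_only, "lv") == rv_only

    def test_blocking_everything_rejected(self, vent_sources):
        lv_only = [s for s in vent_sources if s.v == "lv"]
        with pytest.raises(ValueError):
            apply_bbb(lv_only, "lv")

    def test_transseptal_spread_reaches_blocked_ventricle(self, vent_mesh,
                                                          vent_sources):
        """The blocked LV still activates (slower) through the septum."""
        cond = build_conduction_field_ventricular(vent_mesh)
        lat0 = solve_eikonal(vent_mesh, cond, vent_sources)
        lat1 = solve_eikonal(vent_mesh, cond, apply_bbb(vent_sources, "lv"))
        fin0, fin1 = np.isfinite(lat0), np.isfinite(lat1)
        assert fin1.all() == fin0.all()
        assert lat1[fin1].max() > lat0[fin0].max()


@pytest.fixture(scope="module")
def lad_mi(vent_mesh):
    cond = build_conduction_field_ventricular(vent_mesh)
    spec = InfarctSpec(artery="LAD", phi=1.0, z=0.5, rho_n=1.0, d_co=0.5)
    return apply_mi(vent_mesh, cond, spec)


class TestMI:
    def test_bz_area_fraction(self, lad_mi):
        cond, info = lad_mi
        frac = len(info["bz"]) / len(info["region"])
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_core_bz_partition(self, lad_mi):
        _, info = lad_mi
        assert set(info["core"]) | set(info["bz"]) == set(info["region"])
        assert not set(info["core"]) & set(info["bz"])

    def test_core_unreachable(self, vent_mesh, lad_mi, vent_sources):
        cond, info = lad_mi
        lat = solve_eikonal(vent_mesh, cond, vent_sources)
        core_nodes = np.setdiff1d(
            np.unique(vent_mesh.elements[info["core"]]), info["bz_nodes"])
        # interior core nodes (untouched by any conducting element)
        active_nodes = np.unique(
            vent_mesh.elements[(cond.cv > 0).all(axis=1)])
        interior = np.setdiff1d(core_nodes, active_nodes)
        assert len(interior) > 0
        assert np.isinf(lat[interior]).all()

    def test_subendocardial_extent(self, vent_mesh):
        cond = build_conduction_field_ventricular(vent_mesh)
        spec = InfarctSpec(artery="LAD", phi=1.0, z=0.5, rho_n=0.3, d_co=0.5)
        _, info = apply_mi(vent_mesh, cond, spec)
        rho = vent_mesh.element_uvc("rho")
        assert rho[info["region"]].max() <= 0.3 + 1e-9

    def test_bz_conduction_slowed_isotropic(self, lad_mi):
        cond, info = lad_mi
        assert np.allclose(cond.cv[info["bz"]], 0.15)
        assert np.allclose(cond.cv[info["core"]], 0.0)

    def test_zero_radius_recovers_healthy_map(self, vent_mesh, vent_sources):
        cond = build_conduction_field_ventricular(vent_mesh)
        spec = InfarctSpec(artery="LAD", phi=1.0, z=0.5, rho_n=1.0, d_co=0.0)
        cond2, info = apply_mi(vent_mesh, cond, spec)
        assert len(info["region"]) == 0
        lat0 = solve_eikonal(vent_mesh, cond, vent_sources)
        lat1 = solve_eikonal(vent_mesh, cond2, vent_sources)
        assert np.array_equal(lat0, lat1)

    def test_center_bounds_enforced(self):
        with pytest.raises(ValueError):
            InfarctSpec(artery="LAD", phi=3.0, z=0.5, rho_n=1.0, d_co=0.3)
        with pytest.raises(ValueError):
            InfarctSpec(artery="LCX", phi=0.5, z=0.5, rho_n=1.0, d_co=0.3)
        # LCX union accepts both lobes
        InfarctSpec(artery="LCX", phi=2.5, z=0.5, rho_n=1.0, d_co=0.3)
        InfarctSpec(artery="LCX", phi=-2.5, z=0.5, rho_n=1.0, d_co=0.3)


class TestFibrosis:
    def test_zero_fraction_is_noop(self, atrial_mesh, atrial_cond):
        spec = FibrosisSpec(volume_fraction=0.05, seed=1)
        spec.volume_fraction = 0.0  # bypass the 9-level grid for the no-op
        cond, info = apply_fibrosis(atrial_mesh, atrial_cond, spec)
        assert np.array_equal(cond.cv, atrial_cond.cv)
        assert len(info["patch"]) == 0

    def test_removed_fraction_within_patches(self, atrial_mesh, atrial_cond):
        spec = FibrosisSpec(volume_fraction=0.30, seed=7)
        cond, info = apply_fibrosis(atrial_mesh, atrial_cond, spec)
        frac = len(info["removed"]) / len(info["patch"])
        assert frac == pytest.approx(0.50, abs=0.03)
        assert np.all(cond.cv[info["removed"]] == 0.0)

    def test_anisotropy_ratio_increased_by_2_5(self, atrial_mesh,
                                               atrial_cond):
        spec = FibrosisSpec(volume_fraction=0.25, seed=3)
        cond, info = apply_fibrosis(atrial_mesh, atrial_cond, spec)
        surv = info["surviving"]
        ar_new = cond.cv[surv, 0] / cond.cv[surv, 1]
        ar_old = atrial_cond.cv[surv, 0] / atrial_cond.cv[surv, 1]
        assert np.allclose(ar_new / ar_old, 2.5)

    def test_expected_removed_volume_over_seeds(self, atrial_mesh,
                                                atrial_cond):
        """Removed volume matches fraction x removal x shell volume."""
        shell = ~np.isin(atrial_mesh.element_region,
                         ("bachmanns_bundle", "posterior_connection"))
        n_shell = shell.sum()
        for seed in (0, 1, 2):
            spec = FibrosisSpec(volume_fraction=0.20, seed=seed)
            _, info = apply_fibrosis(atrial_mesh, atrial_cond, spec)
            expected = 0.20 * 0.5 * n_shell
            assert len(info["removed"]) == pytest.approx(expected, rel=0.02)

    def test_determinism(self, atrial_mesh, atrial_cond):
        spec = FibrosisSpec(volume_fraction=0.15, seed=11)
        c1, i1 = apply_fibrosis(atrial_mesh, atrial_cond, spec)
        c2, i2 = apply_fibrosis(atrial_mesh, atrial_cond, spec)
        assert np.array_equal(c1.cv, c2.cv)
        assert np.array_equal(i1["removed"], i2["removed"])

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            FibrosisSpec(volume_fraction=0.17)


class TestIAB:
    def test_ra_unchanged_la_delayed(self, atrial_mesh, atrial_cond):
        sa = atrial_mesh.metadata["sa_node_nodes"]
        sources = [(np.asarray(sa), 0.0)]
        lat0 = solve_eikonal(atrial_mesh, atrial_cond, sources)
        cond_iab = apply_iab(atrial_mesh, atrial_cond)
        lat1 = solve_eikonal(atrial_mesh, cond_iab, sources)
        ra = atrial_mesh.uvc["v"] == "ra"
        la = ~ra
        # propagation is SA-outward: RA activation is unaffected except
        # immediately at the (now inert) Bachmann's-bundle junction
        bb_nodes = np.unique(atrial_mesh.elements[
            atrial_mesh.element_region == "bachmanns_bundle"])
        d = np.linalg.norm(
            atrial_mesh.node_positions[:, None, :]
            - atrial_mesh.node_positions[None, bb_nodes, :],
            axis=2).min(axis=1)
        near_bb = d < 8.0
        ra_interior = ra & ~near_bb & np.isfinite(lat0) & np.isfinite(lat1)
        assert np.allclose(lat0[ra_interior], lat1[ra_interior], atol=1e-6)
        assert np.all(lat1[ra] >= lat0[ra] - 1e-9)
        fin = la & np.isfinite(lat0) & np.isfinite(lat1)
        assert lat1[fin].min() > lat0[fin].min()

    def test_la_stays_reachable(self, atrial_mesh, atrial_cond):
        cond_iab = apply_iab(atrial_mesh, atrial_cond)
        sa = atrial_mesh.metadata["sa_node_nodes"]
        lat = solve_eikonal(atrial_mesh, cond_iab, [(np.asarray(sa), 0.0)])
        la = atrial_mesh.uvc["v"] == "la"
        assert np.isfinite(lat[la]).mean() > 0.9


class TestCasesAndSampling:
    def test_thirteen_distinct_cases(self):
        cases = all_cases()
        assert len(cases) == 13
        assert len({c.case_key for c in cases}) == 13

    def test_label_parsing_accepts_rad_alias(self):
        assert parse_label("mi/RAD_1.0") == PathologyLabel("mi", "RCA", 1.0)
        with pytest.raises(ValueError):
            PathologyLabel("sinus", mi_artery="LAD")

    def test_sampled_values_inside_table_ranges(self):
        samples = draw_parameter_samples(PathologyLabel("mi", "LCX", 0.3),
                                         8, seed=4)
        from ecgforge.config import FASCICULAR_SITE_RANGES, MI_CENTER_RANGES
        for s in samples:
            for site, fields_ in s.omega_qrs.items():
                for key, bound in FASCICULAR_SITE_RANGES[site].items():
                    if isinstance(bound, tuple):
                        assert bound[0] <= fields_[key] <= bound[1]
            phi = s.omega_mi["phi"]
            assert any(lo <= phi <= hi
                       for lo, hi in MI_CENTER_RANGES["LCX"]["phi"])
            assert s.omega_mi["rho_n"] == 0.3

    def test_twenty_variable_healthy_parameters(self):
        """The healthy QRST variability is spanned by 20 sampled values."""
        s = draw_parameter_samples(PathologyLabel("sinus"), 1, seed=0)[0]
        n_qrs = sum(1 for site, f in s.omega_qrs.items()
                    for k in ("phi", "z", "r", "t")
                    if isinstance(__import__("ecgforge.config",
                                             fromlist=["c"])
                                  .FASCICULAR_SITE_RANGES[site][k], tuple))
        n_t = 5  # apd_min, apd_max, q_rho, q_v, q_z
        assert n_qrs + n_t == 20

    def test_sampling_deterministic(self):
        a = draw_parameter_samples(PathologyLabel("fam"), 3, seed=9)
        b = draw_parameter_samples(PathologyLabel("fam"), 3, seed=9)
        assert all(x.omega_p == y.omega_p and x.seed == y.seed
                   for x, y in zip(a, b))
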