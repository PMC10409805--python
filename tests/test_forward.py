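"""Reaction-Eikonal voltages, dipole forward operator, lead derivation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgforge import (ConductivitySet, LEADS, build_slab_mesh, derive_leads,
                      evaluate_tmv, forward_ecg, lead_field)
from ecgforge.cellmodel import SINUS_PARAMS, get_bank
from ecgforge.forward import MEASUREMENT_ELECTRODES
from ecgforge.geometry import TorsoPose, place_and_project


@pytest.fixture(scope="module")
def bank():
    return get_bank(SINUS_PARAMS)


@pytest.fixture(scope="module")
def small_slab():
    return build_slab_mesh((10.0, 10.0, 10.0), 1.0)


def far_electrodes(scale=1.0):
    base = {
        "RA": (-150.0, 40.0, 200.0), "LA": (150.0, 40.0, 200.0),
        "LL": (60.0, 30.0, -300.0), "RL": (-60.0, 30.0, -300.0),
        "V1": (-30.0, 90.0, 10.0), "V2": (30.0, 90.0, 10.0),
        "V3": (55.0, 95.0, -20.0), "V4": (80.0, 95.0, -50.0),
        "V5": (110.0, 80.0, -55.0), "V6": (130.0, 50.0, -55.0),
    }
    return {k: scale * np.asarray(v) for k, v in base.items()}


class TestTMV:
    def test_rest_before_activation(self, bank):
        lat = np.array([50.0, 80.0, np.inf])
        apd = np.full(3, 200.0)
        vm = evaluate_tmv(lat, apd, [bank], np.zeros(3, dtype=int),
                          np.arange(0.0, 40.0, 1.0))
        assert np.allclose(vm, -86.2, atol=1e-4)

    def test_uniform_lat_gives_uniform_field(self, bank):
        lat = np.zeros(5)
        apd = np.full(5, 210.0)
        vm = evaluate_tmv(lat, apd, [bank], np.zeros(5, dtype=int),
                          np.arange(0.0, 300.0, 1.0))
        assert np.abs(vm - vm[0]).max() < 1e-5

    def test_shifted_node_reproduces_trace(self, bank):
        lat = np.array([0.0, 5.0])
        apd = np.full(2, 200.0)
        t = np.arange(0.0, 300.0, 1.0)
        vm = evaluate_tmv(lat, apd, [bank], np.zeros(2, dtype=int), t)
        assert np.allclose(vm[1, 5:], vm[0, :-5], atol=1e-4)

    def test_apd_outside_bank_rejected(self, bank):
        with pytest.raises(ValueError, match="bank range"):
            evaluate_tmv(np.zeros(2), np.array([200.0, 500.0]), [bank],
                         np.zeros(2, dtype=int), np.arange(10.0))


class TestForwardOperator:
    def test_uniform_vm_gives_zero_potentials(self, small_slab):
        b = lead_field(small_slab, far_electrodes(), ConductivitySet())
        vm = np.full((small_slab.n_nodes, 5), -86.2, dtype=np.float32)
        phi = forward_ecg(b, vm)
        assert max(np.abs(v).max() for v in phi.values()) < 1e-9

    def test_point_dipole_closed_form(self, small_slab):
        """A single active element matches p / (4 pi sigma r^2) on the
        dipole axis in the far field within 1%."""
        sigma = ConductivitySet()
        active = np.zeros(small_slab.n_elements, dtype=bool)
        # central element, x-oriented voltage step across it
        centers = small_slab.element_centers
        ce = np.argmin(np.linalg.norm(centers - 5.0, axis=1))
        active[ce] = True
        b = lead_field(small_slab, {"V1": np.array([5.0, 5.0, 5.0])
                                    + np.array([400.0, 0.0, 0.0]),
                                    **{k: v for k, v in
                                       far_electrodes(10).items()
                                       if k != "V1"}},
                       sigma, active=active)
        vm = (small_slab.node_positions[:, 0:1]
              * np.ones((1, 1))).astype(np.float32)   # dV/dx = 1 mV/mm
        phi = forward_ecg(b, vm)
        r = 400.0 - (centers[ce, 0] - 5.0)
        vol = small_slab.element_volume
        p = sigma.sigma_i_bulk * 1.0 * vol          # dipole moment density
        expected = p / (4 * np.pi * sigma.sigma_medium * r**2)
        assert phi["V1"][0] == pytest.approx(expected, rel=0.01)

    def test_medium_conductivity_scaling(self, small_slab):
        rng = np.random.default_rng(0)
        vm = rng.normal(size=(small_slab.n_nodes, 3)).astype(np.float32)
        b1 = lead_field(small_slab, far_electrodes(), ConductivitySet())
        s2 = ConductivitySet(sigma_medium=2 * 0.22)
        b2 = lead_field(small_slab, far_electrodes(), s2)
        assert np.allclose(b2 @ vm, 0.5 * (b1 @ vm))

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000), a=st.floats(-2, 2), b_=st.floats(-2, 2))
    def test_linearity(self, small_slab, seed, a, b_):
        rng = np.random.default_rng(seed)
        v1 = rng.normal(size=(small_slab.n_nodes, 4))
        v2 = rng.normal(size=(small_slab.n_nodes, 4))
        bmat = lead_field(small_slab, far_electrodes(), ConductivitySet())
        lhs = bmat @ (a * v1 + b_ * v2)
        rhs = a * (bmat @ v1) + b_ * (bmat @ v2)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_far_field_decay_slope(self, small_slab):
        """log-log slope of |phi| vs distance is -2 +/- 0.05."""
        sigma = ConductivitySet()
        rng = np.random.default_rng(1)
        vm = (small_slab.node_positions[:, 0:1]).astype(np.float32)
        dists = np.geomspace(200.0, 2000.0, 8)
        vals = []
        for r in dists:
            elec = far_electrodes(50)
            elec["V1"] = np.array([5.0 + r, 5.0, 5.0])
            b = lead_field(small_slab, elec, sigma)
            vals.append(abs((b @ vm)[MEASUREMENT_ELECTRODES.index("V1"), 0]))
        slope = np.polyfit(np.log(dists), np.log(vals), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.05)

    def test_rigid_cotransform_invariance(self, small_slab):
        """Rotating heart and electrodes together leaves potentials
        unchanged."""
        sigma = ConductivitySet()
        vm = (small_slab.node_positions @ np.array([0.3, -0.2, 0.5])
              )[:, None].astype(np.float32)
        elec = far_electrodes()
        b0 = lead_field(small_slab, elec, sigma)
        phi0 = b0 @ vm
        pose = TorsoPose(alpha_x=25.0, alpha_y=-10.0, alpha_z=40.0,
                         t_x=30.0, t_y=-12.0, t_z=8.0)
        moved, _ = place_and_project(small_slab, pose)
        r, t = pose.rotation_matrix(), pose.translation()
        elec_m = {k: r @ v + t for k, v in elec.items()}
        b1 = lead_field(moved, elec_m, sigma)
        assert np.allclose(b1 @ vm, phi0, rtol=1e-9, atol=1e-12)

    def test_electrode_inside_mesh_rejected(self, small_slab):
        elec = far_electrodes()
        elec["V1"] = np.array([5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="inside"):
            lead_field(small_slab, elec, ConductivitySet())


class TestLeads:
    def test_identities_and_order(self):
        rng = np.random.default_rng(2)
        pots = {k: rng.normal(size=30) for k in MEASUREMENT_ELECTRODES}
        beat = derive_leads(pots, fs=500.0)
        assert LEADS[0] == "I" and LEADS[6] == "V1"
        i, ii, iii = beat.data[0], beat.data[1], beat.data[2]
        assert np.abs(i - ii + iii).max() < 1e-12
        avr, avl, avf = beat.data[3], beat.data[4], beat.data[5]
        assert np.abs(avr + avl + avf).max() < 1e-12
        assert np.allclose(beat.data[6],
                           pots["V1"] - (pots["RA"] + pots["LA"]
                                         + pots["LL"]) / 3)

    def test_missing_electrode_rejected(self):
        pots = {k: np.zeros(10) for k in MEASUREMENT_ELECTRODES[:-1]}
        with pytest.raises(ValueError, match="missing"):
            derive_leads(pots, fs=500.0)


class TestBeatSimulations:
    def test_qrst_sample_count(self, anatomies, shared_cache):
        from ecgforge import simulate_qrst
        from ecgforge.pathology import (PathologyLabel,
                                        draw_parameter_samples,
                                        make_case_config)
        label = PathologyLabel("sinus")
        sample = draw_parameter_samples(label, 1, seed=6)[0]
        case = make_case_config(label, sample, anatomy=anatomies[0],
                                cache=shared_cache)
        beat = simulate_qrst(case)
        assert beat.data.shape == (12, 225)    # 450 ms at 500 Hz
        f = beat.fiducials
        assert f["QRS_on"] < f["QRS_off"] < f["T_off"]
        # single dominant R deflection in lead II
        from scipy.signal import find_peaks
        ii = beat.lead("II")
        peaks, _ = find_peaks(np.abs(ii), height=0.5 * np.abs(ii).max(),
                              distance=25)
        assert len(peaks) <= 2

    def test_pwave_window_within_range(self, anatomies, shared_cache):
        from ecgforge import simulate_pwave
        from ecgforge.pathology import (PathologyLabel,
                                        draw_parameter_samples,
                                        make_case_config)
        label = PathologyLabel("sinus")
        sample = draw_parameter_samples(label, 1, seed=8)[0]
        case = make_case_config(label, sample, anatomy=anatomies[0],
                                cache=shared_cache)
        beat = simulate_pwave(case)
        dur = beat.data.shape[1] * beat.dt
        assert 150.0 <= dur <= 200.0
        assert beat.fiducials["P_on"] < beat.fiducials["P_off"] < dur
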