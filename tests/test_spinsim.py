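"""Density-matrix simulator: product operators, pulses, coherence pathways."""

import math

import numpy as np
import pytest

from lacdqf import spinsim as sp
from lacdqf.seqmodel import CH3_PPM, CH_PPM, ppm_to_hz, selective_carrier_offset


@pytest.fixture(scope="module")
def sys_is():
    return sp.SpinSystem(topology="IS", j_hz=16.6)


@pytest.fixture(scope="module")
def sys_is3():
    return sp.SpinSystem(topology="IS3", j_hz=16.6)


@pytest.fixture(scope="module")
def dqf_pulse():
    off = selective_carrier_offset(4.0)
    return sp.make_sinc_pulse(duration_ms=4.0, n_lobes=5, carrier_offset_hz=off.hz)


class TestStatesAndEvolution:
    def test_equilibrium_is_pure_z(self, sys_is, sys_is3):
        for system in (sys_is, sys_is3):
            proj = sp.equilibrium(system).projections()
            coeffs = []
            for label, coeff in proj.items():
                assert set(label) & {"x", "y"} == set()
                coeffs.append(coeff)
            assert len(proj) == system.n_spins
            # one z term per spin, all with equal weight
            assert np.allclose(coeffs, coeffs[0])
            assert coeffs[0].real > 0

    def test_projection_reconstructs_state(self, sys_is3):
        st = sp.equilibrium(sys_is3)
        st = sp.apply_ideal_pulse(st, 37.0, 20.0)
        st = sp.evolve(st, 13.0)
        resid = np.max(np.abs(st.reconstruct_from_projections() - st.matrix))
        assert resid < 1e-12

    def test_ix_evolves_to_antiphase_at_half_j_period(self, sys_is):
        """On-resonance, Ix becomes pure two-spin antiphase at t = 1/(2J)."""
        onres = sp.SpinSystem(topology="IS", shift_i_ppm=4.7, shift_s_ppm=4.7, j_hz=16.6)
        st = sp.DensityState(onres.operator(0, "x"), onres)
        st = sp.evolve(st, 1000.0 / (2 * 16.6))
        proj = st.projections(tol=1e-9)
        assert set(proj) == {"IySz"}
        assert abs(proj["IySz"]) == pytest.approx(1.0)

    def test_is3_preparation_terms_at_half_j(self):
        """At 0.5/J the IS3 state holds only IzSx-type and IxSzSzSz terms."""
        onres = sp.SpinSystem(topology="IS3", shift_i_ppm=4.7, shift_s_ppm=4.7, j_hz=16.6)
        st = sp.equilibrium(onres)
        st = sp.apply_ideal_pulse(st, 90.0, 0.0)
        st = sp.evolve(st, 1000.0 / (2 * 16.6))
        labels = set(st.projections(tol=1e-9))
        expected = {
            "IzSxS0S0", "IzS0SxS0", "IzS0S0Sx",  # from the S spins
            "IxSzSzSz",  # from the I spin
        }
        assert labels == expected

    def test_zero_j_is_pure_precession(self):
        system = sp.SpinSystem(topology="IS", j_hz=0.0)
        st = sp.DensityState(system.operator(0, "x"), system)
        st2 = sp.evolve(st, 10.0)
        proj = st2.projections(tol=1e-9)
        # stays single-spin transverse: no antiphase terms appear
        assert set(proj) <= {"IxS0", "IyS0"}

    def test_unitarity_of_evolution_and_pulses(self, sys_is3):
        st = sp.equilibrium(sys_is3)
        norm0 = st.frobenius_norm
        st = sp.apply_ideal_pulse(st, 73.0, 31.0)
        st = sp.evolve(st, 17.3)
        st = sp.apply_ideal_pulse(st, 180.0, 90.0, spins=[0])
        assert st.frobenius_norm == pytest.approx(norm0, abs=1e-10)
        assert st.is_hermitian()


class TestIdealPulses:
    def test_360_degree_pulse_is_identity(self, sys_is3):
        st = sp.equilibrium(sys_is3)
        st = sp.apply_ideal_pulse(st, 45.0, 10.0)
        st2 = sp.apply_ideal_pulse(st, 360.0, 55.0)
        assert np.allclose(st2.matrix, st.matrix, atol=1e-12)

    def test_two_90s_compose_to_180(self, sys_is):
        st = sp.equilibrium(sys_is)
        once = sp.apply_ideal_pulse(sp.apply_ideal_pulse(st, 90.0, 0.0), 90.0, 0.0)
        twice = sp.apply_ideal_pulse(st, 180.0, 0.0)
        assert np.allclose(once.matrix, twice.matrix, atol=1e-12)

    def test_selective_entry_converts_antiphase_to_multiquantum(self, sys_is):
        """A 90 on I turns the IzSx antiphase term into IySx-type DQ+ZQ."""
        st = sp.DensityState(
            2.0 * sys_is.operator(0, "z") @ sys_is.operator(1, "x"), sys_is
        )
        out = sp.apply_ideal_pulse(st, 90.0, 0.0, spins=[0])
        proj = out.projections(tol=1e-9)
        assert set(proj) == {"IySx"}
        dq = sp.coherence_select(out, +2)
        assert dq.frobenius_norm > 0.1

    def test_empty_target_rejected(self, sys_is):
        with pytest.raises(ValueError):
            sp.apply_ideal_pulse(sp.equilibrium(sys_is), 90.0, 0.0, spins=[])


class TestCoherenceSelect:
    def test_idempotent(self, sys_is3):
        st = sp.apply_ideal_pulse(sp.equilibrium(sys_is3), 77.0, 13.0)
        once = sp.coherence_select(st, 1)
        twice = sp.coherence_select(once, 1)
        assert np.allclose(once.matrix, twice.matrix, atol=1e-14)

    def test_order_zero_on_equilibrium_is_identity(self, sys_is):
        st = sp.equilibrium(sys_is)
        assert np.allclose(sp.coherence_select(st, 0).matrix, st.matrix)

    def test_orders_partition_the_state(self, sys_is3):
        st = sp.apply_ideal_pulse(sp.equilibrium(sys_is3), 60.0, 45.0)
        st = sp.evolve(st, 7.0)
        total = sum(
            sp.coherence_select(st, p).matrix
            for p in range(-sys_is3.n_spins, sys_is3.n_spins + 1)
        )
        assert np.allclose(total, st.matrix, atol=1e-13)

    def test_order_beyond_spin_count_rejected(self, sys_is):
        with pytest.raises(ValueError):
            sp.coherence_select(sp.equilibrium(sys_is), 3)


class TestDetect:
    def test_pure_z_state_is_silent(self, sys_is):
        fid = sp.detect(sp.equilibrium(sys_is))
        assert np.max(np.abs(fid)) < 1e-14

    def test_single_spin_transverse_gives_offset_exponential(self):
        system = sp.SpinSystem(topology="IS", shift_i_ppm=5.0, shift_s_ppm=4.7, j_hz=0.0)
        st = sp.DensityState(system.operator(0, "x"), system)
        fid = sp.detect(st, n_points=256, lb_hz=0.0)
        delta = ppm_to_hz(5.0 - 4.7, system.larmor_mhz)
        t = np.arange(256) * 2.5e-4
        expected = np.exp(2j * math.pi * delta * t)  # Tr(Ix F+) = 1
        assert np.allclose(fid, expected, atol=1e-10)

    def test_antiphase_state_transforms_to_antiphase_doublet(self, sys_is):
        st = sp.DensityState(
            2.0 * sys_is.operator(1, "x") @ sys_is.operator(0, "z"), sys_is
        )
        spec = np.fft.fftshift(np.fft.fft(sp.detect(st, lb_hz=2.0)))
        freqs = np.fft.fftshift(np.fft.fftfreq(1024, d=2.5e-4))
        center = ppm_to_hz(CH3_PPM - 4.7, sys_is.larmor_mhz)
        lo = (freqs > center - 16.6) & (freqs < center)
        hi = (freqs >= center) & (freqs < center + 16.6)
        # the two doublet components have opposite sign
        assert np.sign(spec.real[lo][np.argmax(np.abs(spec.real[lo]))]) != np.sign(
            spec.real[hi][np.argmax(np.abs(spec.real[hi]))]
        )


class TestShapedPulses:
    def test_on_resonance_flip_calibrated(self, dqf_pulse):
        flips, _ = sp.pulse_profile(dqf_pulse, np.array([dqf_pulse.carrier_offset_hz]))
        assert flips[0] == pytest.approx(90.0, abs=0.1)

    def test_small_tip_profile_matches_fourier_transform(self):
        pulse = sp.make_sinc_pulse(nominal_flip_deg=5.0)
        grid = np.linspace(-2500.0, 2500.0, 201)
        flips, _ = sp.pulse_profile(pulse, grid)
        t = pulse.times_s
        ft = np.abs(
            np.array([np.sum(pulse.amplitude * np.exp(-2j * math.pi * f * t)) for f in grid])
        ) * pulse.dt_s
        ft *= 5.0 / ft[np.argmin(np.abs(grid))]
        assert np.max(np.abs(flips - ft)) / 5.0 < 0.02

    def test_doubling_discretization_changes_flips_under_0p1_percent(self, dqf_pulse):
        ch3 = -ppm_to_hz(CH_PPM - CH3_PPM)
        flips1, _ = sp.pulse_profile(dqf_pulse, np.array([0.0, ch3]))
        pulse2 = sp.make_sinc_pulse(
            duration_ms=4.0, n_lobes=5,
            carrier_offset_hz=dqf_pulse.carrier_offset_hz, n_samples=1024,
        )
        flips2, _ = sp.pulse_profile(pulse2, np.array([0.0, ch3]))
        assert np.all(np.abs(flips2 - flips1) / flips1 < 1e-3)

    def test_profile_symmetric_for_symmetric_envelope(self):
        pulse = sp.make_sinc_pulse(carrier_offset_hz=0.0)
        offs = np.linspace(100.0, 2000.0, 40)
        up, _ = sp.pulse_profile(pulse, offs)
        dn, _ = sp.pulse_profile(pulse, -offs)
        assert np.allclose(up, dn, rtol=1e-8)

    def test_sinc_transition_sharper_than_matched_gaussian(self, dqf_pulse):
        """At matched FWHM, the sinc's pass-to-stop transition is narrower."""
        fwhm = sp.profile_fwhm(dqf_pulse)
        gauss = sp.make_gaussian_pulse(bandwidth_hz=fwhm)
        sinc0 = sp.make_sinc_pulse(carrier_offset_hz=0.0)

        def transition_width(pulse):
            grid = np.linspace(0.0, 3000.0, 1500)
            flips, _ = sp.pulse_profile(pulse, grid)
            mxy = np.abs(np.sin(np.radians(flips)))
            i95 = np.nonzero(mxy < 0.95)[0][0]
            i05 = np.nonzero(mxy < 0.05)[0][0]
            return grid[i05] - grid[i95]

        assert transition_width(sinc0) < transition_width(gauss)

    def test_uncalibrated_pulse_rejected(self, sys_is):
        raw = sp.ShapedPulse(
            amplitude=np.ones(256), phase_rad=np.zeros(256),
            duration_ms=4.0, nominal_flip_deg=90.0,
        )
        with pytest.raises(ValueError):
            sp.apply_shaped_pulse(sp.equilibrium(sys_is), raw)
        with pytest.raises(ValueError):
            sp.pulse_profile(raw, np.array([0.0]))

    def test_shaped_pulse_on_system_reaches_nominal_flip(self, sys_is):
        """Full-system propagation on resonance tips I like the ideal pulse."""
        onres = sp.SpinSystem(topology="IS", shift_i_ppm=4.7, shift_s_ppm=0.0, j_hz=0.0)
        pulse = sp.make_sinc_pulse(carrier_offset_hz=0.0, target="CH_selective")
        st = sp.apply_shaped_pulse(sp.equilibrium(onres), pulse)
        proj = st.projections(tol=1e-3)
        # I magnetization fully transverse, S (far off-resonance) mostly intact
        assert abs(proj.get("IzS0", 0.0)) < 0.05
        assert abs(proj.get("I0Sz", 0.0)) > 0.9


class TestDqfSequence:
    def test_uncoupled_spins_are_fully_suppressed(self):
        lipid = sp.SpinSystem(topology="IS", shift_i_ppm=4.1, shift_s_ppm=1.5, j_hz=0.0)
        spec, _ = sp.simulate_dqf(lipid)
        assert np.max(np.abs(spec)) < 1e-12

    @pytest.mark.parametrize("topology", ["IS", "IS3"])
    def test_filtered_yield_at_most_half_of_spin_echo(self, topology):
        """DQF passes at most half the signal of the matched unfiltered echo."""
        system = sp.SpinSystem(topology=topology, j_hz=16.6)
        spec_f, fr = sp.simulate_dqf(system)
        spec_u, _ = sp.simulate_dqf(system, filtered=False)
        center = ppm_to_hz(CH3_PPM - 4.7, system.larmor_mhz)
        half = ppm_to_hz(0.2, system.larmor_mhz)
        mask = (fr >= center - half) & (fr <= center + half)
        ratio = np.abs(spec_f[mask]).sum() / np.abs(spec_u[mask]).sum()
        assert ratio <= 0.5 + 1e-9

    @pytest.mark.parametrize("topology", ["IS", "IS3"])
    def test_amplitude_follows_sin_pi_j_tau1(self, topology):
        system = sp.SpinSystem(topology=topology, j_hz=16.6)
        taus = np.linspace(25.0, 115.0, 7)
        amps = np.array(
            [sp.ch3_amplitude(*sp.simulate_dqf(system, tau1_ms=t), system) for t in taus]
        )
        target = np.sin(np.pi * 16.6 * taus / 1000.0)
        scale = (amps @ target) / (target @ target)
        resid = np.abs(amps - scale * target).max() / np.abs(amps).max()
        assert resid < 1e-10

    def test_inconsistent_pulse_target_rejected(self, sys_is):
        hard = sp.make_sinc_pulse(target="hard")
        with pytest.raises(ValueError):
            sp.simulate_dqf(sys_is, mode="CH_selective", entry_pulse=hard)


class TestPhaseSweep:
    def test_selective_entry_is_phase_invariant(self, sys_is3):
        amps = sp.phase_sweep(sys_is3, np.arange(0.0, 360.0, 45.0))
        assert np.std(amps) / np.mean(amps) < 0.01

    def test_hard_entry_modulates_sinusoidally(self, sys_is3):
        phases = np.arange(0.0, 360.0, 30.0)
        amps = sp.phase_sweep(sys_is3, phases, mode="hard_entry")
        # magnitude follows |cos(phi)|: full sinusoidal modulation with nulls
        x = np.radians(phases)
        expected = amps[0] * np.abs(np.cos(x))
        assert np.allclose(amps, expected, atol=1e-6 * amps[0])
        assert amps.min() < 1e-6 * amps.max()

    def test_zero_amplitude_entry_gives_zero_signal(self, sys_is):
        amps = sp.phase_sweep(sys_is, np.arange(0.0, 360.0, 45.0), entry_flip_deg=0.0)
        assert np.max(amps) < 1e-12

    def test_requires_at_least_8_phases(self, sys_is):
        with pytest.raises(ValueError):
            sp.phase_sweep(sys_is, [0.0, 90.0])


class TestPaperPulseNumbers:
    def test_ch3_flip_and_selectivity_of_shifted_sinc(self, dqf_pulse):
        """The shifted 5-lobe sinc leaves ~1.4 deg on CH3, ~63x less than CH."""
        ch3 = -ppm_to_hz(CH_PPM - CH3_PPM)
        flips, stop = sp.pulse_profile(dqf_pulse, np.array([0.0, ch3]))
        assert flips[1] == pytest.approx(1.4, rel=0.2)
        assert flips[0] / flips[1] == pytest.approx(63.0, rel=0.2)
        assert not stop[0] and stop[1]
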