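"""Hydrodynamic radii, diffusion fitting, CD and mass calculations."""

import numpy as np
import pytest

from bexfes.biophys import (
    CDRecord,
    DiffusionDecay,
    MET_AB40_SEQUENCE,
    compaction_index,
    fit_diffusion,
    internal_standard_rh,
    mean_residue_ellipticity,
    percent_change,
    reversibility_check,
    rh_empirical,
    sec_rh_from_mmapp,
    sequence_mass,
    stokes_einstein_rh,
)
from bexfes.synthetic import make_diffusion_decay


class TestSequenceMass:
    def test_single_glycine(self):
        assert sequence_mass("G") == pytest.approx(75.07, abs=0.01)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sequence_mass("")

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="residue"):
            sequence_mass("AXA")

    def test_construct_mass_matches_biopython(self):
        from Bio.SeqUtils import molecular_weight

        ours = sequence_mass(MET_AB40_SEQUENCE)
        ref = molecular_weight(MET_AB40_SEQUENCE, seq_type="protein")
        assert ours == pytest.approx(ref, abs=0.5)


class TestRhEmpirical:
    @pytest.mark.parametrize("state,basis,kwargs,expected,digits", [
        ("F", "length", {"N": 41}, 13.9, 1),
        ("U", "length", {"N": 41}, 18.4, 1),
        ("PMG", "mass", {"M": 4461.0}, 17.0, 0),
        ("F", "mass", {"M": 4461.0}, 12.6, 1),
        ("U", "mass", {"M": 4461.0}, 17.9, 1),
    ])
    def test_reference_state_predictions(self, state, basis, kwargs, expected, digits):
        assert round(rh_empirical(state=state, basis=basis, **kwargs), digits) \
            == pytest.approx(expected)

    def test_monotone_in_size_and_state_ordering(self):
        masses = np.linspace(3000, 100000, 40)
        prev = {s: 0.0 for s in ("F", "U", "PMG")}
        for m in masses:
            vals = {s: rh_empirical(M=m, state=s) for s in ("F", "U", "PMG")}
            for s, v in vals.items():
                assert v > prev[s]
            assert vals["U"] > vals["PMG"] > vals["F"]
            prev = vals

    def test_pmg_has_no_length_relation(self):
        with pytest.raises(ValueError):
            rh_empirical(N=41, state="PMG", basis="length")


class TestSecConversion:
    def test_apparent_mass_of_construct(self):
        assert round(sec_rh_from_mmapp(8800.0)) == 16

    def test_true_mass_falls_in_folded_range(self):
        rh = sec_rh_from_mmapp(4400.0)
        assert 12.4 <= rh <= 13.9

    def test_power_law_scaling(self):
        assert sec_rh_from_mmapp(2000.0) * 2 ** 0.357 \
            == pytest.approx(sec_rh_from_mmapp(4000.0))


class TestCompactionIndex:
    def test_affine_endpoints(self):
        assert compaction_index(18.0, 18.0, 12.4) == pytest.approx(0.0)
        assert compaction_index(12.4, 18.0, 12.4) == pytest.approx(1.0)

    def test_forty_degree_value(self):
        assert round(compaction_index(15.5, 18.0, 12.4), 2) == 0.45

    def test_linearity_in_rh(self):
        rhs = np.linspace(12.4, 18.0, 10)
        cis = [compaction_index(r, 18.0, 12.4) for r in rhs]
        assert np.allclose(np.diff(cis), np.diff(cis)[0])

    def test_outside_range_warned_not_clamped(self):
        with pytest.warns(UserWarning):
            ci = compaction_index(20.0, 18.0, 12.4)
        assert ci < 0

    def test_bad_references_rejected(self):
        with pytest.raises(ValueError):
            compaction_index(15.0, 12.4, 18.0)


class TestFitDiffusion:
    def test_noiseless_roundtrip_is_exact(self):
        g = np.linspace(0.025, 0.475, 16)
        decay = make_diffusion_decay(1.5e-10, 100.0, 4e-3, 0.1, g)
        D, I0, diag = fit_diffusion(decay)
        assert D == pytest.approx(1.5e-10, rel=1e-6)
        assert I0 == pytest.approx(100.0, rel=1e-6)

    def test_noisy_roundtrip_within_two_percent(self):
        g = np.linspace(0.05, 0.95, 16) * 0.5
        errs = []
        for seed in range(100):
            decay = make_diffusion_decay(1.5e-10, 100.0, 4e-3, 0.1, g,
                                         noise_sd=0.01, seed=seed)
            D, _, _ = fit_diffusion(decay)
            errs.append(abs(D - 1.5e-10) / 1.5e-10)
        assert np.max(errs) < 0.02

    def test_too_few_points_rejected(self):
        decay = DiffusionDecay([0.1, 0.2], [10.0, 8.0], 4e-3, 0.1)
        with pytest.raises(ValueError, match="4"):
            fit_diffusion(decay)

    def test_nondecreasing_intensities_warn(self):
        decay = DiffusionDecay([0.1, 0.2, 0.3, 0.4], [8.0, 9.0, 7.0, 6.0], 4e-3, 0.1)
        with pytest.warns(UserWarning):
            fit_diffusion(decay)


class TestStokesEinstein:
    def test_water_at_25C(self):
        # D chosen to invert the measured 25 °C radius
        assert stokes_einstein_rh(1.545e-10, 298.15, 8.902e-4) \
            == pytest.approx(15.9, abs=0.05)

    def test_inverse_in_d(self):
        assert stokes_einstein_rh(2e-10, 298.0, 1e-3) * 2 \
            == pytest.approx(stokes_einstein_rh(1e-10, 298.0, 1e-3))

    def test_t_over_eta_invariance(self):
        a = stokes_einstein_rh(1e-10, 300.0, 1e-3)
        b = stokes_einstein_rh(1e-10, 600.0, 2e-3)
        assert a == pytest.approx(b)


class TestInternalStandard:
    def test_equal_diffusion_returns_reference(self):
        assert internal_standard_rh(1e-10, 1e-10, 2.0) == pytest.approx(2.0)

    def test_ratio_scaling(self):
        assert internal_standard_rh(2e-10, 1e-10, 2.0) == pytest.approx(4.0)

    def test_closure_with_fitted_decays(self):
        # fitting the sample and reference decays and taking the D ratio
        # must agree with the ground-truth Rh ratio
        g = np.linspace(0.05, 0.95, 16) * 0.5
        d_ref, d_samp = 6.0e-10, 1.5e-10
        ref = make_diffusion_decay(d_ref, 50.0, 4e-3, 0.1, g, 0.005, seed=1)
        samp = make_diffusion_decay(d_samp, 80.0, 4e-3, 0.1, g, 0.005, seed=2)
        Dr, _, _ = fit_diffusion(ref)
        Ds, _, _ = fit_diffusion(samp)
        rh = internal_standard_rh(Dr, Ds, 4.0)
        assert rh == pytest.approx(4.0 * d_ref / d_samp, rel=0.02)


class TestMre:
    def _record(self, theta):
        n = len(np.atleast_1d(theta))
        return CDRecord(np.linspace(190, 250, n), np.atleast_1d(theta),
                        path_length=0.1, concentration=0.0892,
                        molecular_mass=4461.0, n_res=41)

    def test_zero_ellipticity_gives_zero(self):
        assert np.allclose(mean_residue_ellipticity(self._record([0.0, 0.0])), 0.0)

    def test_doubling_concentration_halves_mre(self):
        rec = self._record([-10.0])
        rec2 = CDRecord(rec.wavelengths, rec.ellipticities, 0.1, 2 * 0.0892,
                        4461.0, 41)
        assert mean_residue_ellipticity(rec)[0] \
            == pytest.approx(2 * mean_residue_ellipticity(rec2)[0])

    def test_magnitude_at_20uM(self):
        # θ = −10 mdeg at 20 µM (0.0892 mg/mL), MRW = 4461/40 = 111.5
        mre = mean_residue_ellipticity(self._record([-10.0]))[0]
        assert mre == pytest.approx(-10.0 * 111.525 / (10 * 0.1 * 0.0892), rel=1e-9)
        assert mre == pytest.approx(-1.25e4, rel=0.01)


class TestPercentChangeAndReversibility:
    def test_rh_decrease_between_5_and_40C(self):
        assert round(percent_change([15.5], 16.9)[0]) == -8

    def test_reference_itself_is_zero(self):
        assert percent_change([100.0], 100.0)[0] == 0.0

    def test_signed_decrease(self):
        assert percent_change([65.0], 100.0)[0] == pytest.approx(-35.0)

    def test_identical_curves_reversible(self):
        t = np.arange(5, 100, 10.0)
        i = np.linspace(100, 40, len(t))
        ok, dev = reversibility_check(t, i, t, i)
        assert ok and np.allclose(dev, 0.0)

    def test_half_intensity_not_reversible(self):
        t = np.arange(5, 100, 10.0)
        i = np.linspace(100, 40, len(t))
        ok, _ = reversibility_check(t, i, t, 0.5 * i)
        assert not ok

    def test_small_noise_within_tolerance(self, rng):
        t = np.arange(5, 100, 10.0)
        i = np.linspace(100, 40, len(t))
        ok, _ = reversibility_check(t, i, t, i * (1 + 0.03 * rng.standard_normal(len(t))))
        assert ok

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            reversibility_check([5.0, 15.0], [1.0, 2.0], [5.0, 25.0], [1.0, 2.0])
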