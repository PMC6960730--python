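"""Mueller-matrix reconstruction from simulated intensity stacks."""

import numpy as np
import pytest

import fiberpol as fp
from fiberpol.acquisition import FULL_PAIRS, MINIMAL_PAIRS
from fiberpol.synthetic import simulate_intensities
from conftest import random_physical_matrix


def stack_from_matrix(m, instrument=None, pairs=FULL_PAIRS, shape=(3, 4)):
    """Noiseless stack whose every pixel carries the same sample matrix."""
    instrument = instrument or fp.InstrumentModel.ideal()
    field = np.broadcast_to(m.m, shape + (4, 4))
    images = simulate_intensities(field, instrument, pairs)
    return fp.PolarizationImageStack(images)


class TestSchemes:
    def test_full_scheme_has_36_pairs_and_minimal_16(self):
        assert len(FULL_PAIRS) == 36
        assert len(set(FULL_PAIRS)) == 36
        assert len(MINIMAL_PAIRS) == 16
        assert set(MINIMAL_PAIRS) == {
            (g, a) for g in "HVPR" for a in "HVPR"
        }

    def test_incomplete_stack_rejected_naming_missing_pair(self):
        images = {p: np.ones((2, 2)) for p in FULL_PAIRS if p != ("L", "L")}
        with pytest.raises(ValueError, match="LL"):
            fp.PolarizationImageStack(images)


class TestReconstructTable3:
    def test_diffuser_round_trip(self):
        mm = fp.reconstruct_table3(stack_from_matrix(fp.ideal_diffuser()))
        assert np.allclose(mm.m, np.diag([1.0, 0, 0, 0]), atol=1e-12)

    def test_identity_round_trip(self):
        mm = fp.reconstruct_table3(stack_from_matrix(fp.MuellerMatrix(np.eye(4))))
        assert np.allclose(mm.m, np.eye(4), atol=1e-12)

    def test_random_matrix_round_trip(self, rng):
        for _ in range(25):
            m = random_physical_matrix(rng)
            mm = fp.reconstruct_table3(stack_from_matrix(m))
            assert np.abs(mm.m - m.m / m.m[0, 0]).max() < 1e-10

    def test_gain_cancels(self, rng):
        m = random_physical_matrix(rng)
        stack = stack_from_matrix(m)
        a = fp.reconstruct_table3(stack)
        b = fp.reconstruct_table3(stack.scaled(7.3))
        assert np.allclose(a.m, b.m, atol=1e-12)

    def test_16_mode_stack_rejected(self, rng):
        stack = stack_from_matrix(random_physical_matrix(rng), pairs=MINIMAL_PAIRS)
        with pytest.raises(ValueError, match="36-pair"):
            fp.reconstruct_table3(stack)


class TestReconstructLsq:
    def test_matches_direct_route_on_36_images(self, rng):
        m = random_physical_matrix(rng)
        stack = stack_from_matrix(m)
        direct = fp.reconstruct_table3(stack)
        lsq = fp.reconstruct_lsq(stack, fp.InstrumentModel.ideal())
        assert np.abs(direct.m - lsq.m).max() < 1e-9

    def test_exactly_determined_16_image_solve(self, rng):
        for _ in range(10):
            m = random_physical_matrix(rng)
            stack = stack_from_matrix(m, pairs=MINIMAL_PAIRS)
            mm = fp.reconstruct_lsq(stack, fp.InstrumentModel.ideal())
            assert np.abs(mm.m - m.m / m.m[0, 0]).max() < 1e-9

    def test_degenerate_instrument_rejected(self):
        instrument = fp.InstrumentModel.ideal()
        gens = {k: instrument.generator_states["H"] for k in "HVPMRL"}
        broken = fp.InstrumentModel(gens, instrument.analyzer_vectors)
        stack = stack_from_matrix(fp.ideal_diffuser())
        with pytest.raises(ValueError, match="rank"):
            fp.reconstruct_lsq(stack, broken)

    def test_overdetermination_compensates_calibration_error(self, rng):
        """36-image least squares beats the 16-image solve in median entry
        error when the true instrument states are perturbed."""
        nominal = fp.InstrumentModel.ideal()
        err36, err16 = [], []
        for _ in range(50):
            m = random_physical_matrix(rng)
            true_m = m.m / m.m[0, 0]
            perturbed = nominal.perturbed(0.02, rng)
            s36 = stack_from_matrix(m, instrument=perturbed, shape=(1, 1))
            s16 = stack_from_matrix(
                m, instrument=perturbed, pairs=MINIMAL_PAIRS, shape=(1, 1)
            )
            r36 = fp.reconstruct_lsq(s36, nominal)
            r16 = fp.reconstruct_lsq(s16, nominal)
            err36.append(np.median(np.abs(r36.m[0, 0] - true_m)))
            err16.append(np.median(np.abs(r16.m[0, 0] - true_m)))
        assert np.median(err36) <= np.median(err16)


class TestNormalizeM11:
    def test_scaled_identity_normalizes(self):
        m = np.broadcast_to(2 * np.eye(4), (2, 2, 4, 4)).copy()
        mm = fp.normalize_m11(fp.MMImage(m, np.ones((2, 2), bool)))
        assert np.allclose(mm.m, np.eye(4))

    def test_dark_pixel_masked_not_infinite(self):
        m = np.broadcast_to(np.eye(4), (1, 2, 4, 4)).copy()
        m[0, 1] = 0.0
        mm = fp.normalize_m11(fp.MMImage(m, np.ones((1, 2), bool)))
        assert mm.mask[0, 0] and not mm.mask[0, 1]
        assert np.all(np.isnan(mm.m[0, 1]))

    def test_all_dark_rejected(self):
        m = np.zeros((2, 2, 4, 4))
        with pytest.raises(ValueError, match="no signal"):
            fp.normalize_m11(fp.MMImage(m, np.ones((2, 2), bool)))


class TestRoiAverage:
    def test_constant_field_has_zero_std(self):
        m = np.broadcast_to(np.eye(4), (3, 3, 4, 4)).copy()
        mm = fp.MMImage(m, np.ones((3, 3), bool), normalized=True)
        mean, std = fp.roi_average(mm, fp.Roi(0, 0, 3, 3))
        assert np.allclose(mean.m, np.eye(4))
        assert np.allclose(std, 0.0)

    def test_two_pixel_sample_std(self):
        m = np.zeros((1, 2, 4, 4))
        m[:, :, 0, 0] = 1.0
        m[0, 1, 1, 0] = 1.0  # entry M21: values 0 and 1
        mm = fp.MMImage(m, np.ones((1, 2), bool), normalized=True)
        mean, std = fp.roi_average(mm, fp.Roi(0, 0, 2, 1))
        assert mean.m[1, 0] == pytest.approx(0.5)
        assert std[1, 0] == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_homogeneous_synthetic_scaffold_recovers_truth(self):
        model = fp.ScaffoldModel(q=0.7, phi_deg=40.0)
        noise = fp.NoiseModel(read_noise=0.002, seed=7)
        stack, truth = fp.generate_stack(model, noise=noise, width=24, height=24)
        mm = fp.reconstruct_table3(stack)
        mean, _ = fp.roi_average(mm, fp.Roi(0, 0, 24, 24))
        expected = truth[0, 0] / truth[0, 0, 0, 0]
        assert np.abs(mean.m - expected).max() < 0.02

    def test_too_few_valid_pixels_rejected(self):
        m = np.broadcast_to(np.eye(4), (2, 2, 4, 4)).copy()
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        mm = fp.MMImage(m, mask, normalized=True)
        with pytest.raises(ValueError, match="at least 2"):
            fp.roi_average(mm, fp.Roi(0, 0, 2, 2))

    def test_roi_outside_bounds_rejected(self):
        m = np.broadcast_to(np.eye(4), (2, 2, 4, 4)).copy()
        mm = fp.MMImage(m, np.ones((2, 2), bool))
        with pytest.raises(ValueError, match="bounds"):
            fp.roi_average(mm, fp.Roi(1, 1, 3, 3))
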