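import numpy as np
import pytest

import pairscreen as ps


class TestSurvivalIndex:
    def test_control_signal_gives_one(self):
        assert ps.survival_index(1000.0, 100.0, 1000.0) == 1.0

    def test_blank_signal_gives_zero(self):
        assert ps.survival_index(100.0, 100.0, 1000.0) == 0.0

    def test_midpoint_gives_half(self):
        assert ps.survival_index(550.0, 100.0, 1000.0) == pytest.approx(0.5)

    def test_degenerate_assay_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            ps.survival_index(5.0, 100.0, 100.0)


class TestBlissIndex:
    @pytest.mark.parametrize(
        "s1,s2,s12,expected",
        [(0.5, 0.5, 0.25, 0.0), (0.5, 0.5, 0.15, 10.0), (1.0, 1.0, 1.0, 0.0)],
    )
    def test_known_values(self, s1, s2, s12, expected):
        assert ps.bliss_index(s1, s2, s12) == pytest.approx(expected)

    def test_zero_on_independent_surface(self):
        grid = np.linspace(0, 1, 11)
        for s1 in grid:
            for s2 in grid:
                assert ps.bliss_index(s1, s2, s1 * s2) == pytest.approx(0.0, abs=1e-12)


class TestTherapeuticIndex:
    @pytest.mark.parametrize(
        "st_,sr,expected", [(0.7, 0.7, 0.0), (0.0, 1.0, 100.0), (1.0, 0.0, -100.0)]
    )
    def test_known_values(self, st_, sr, expected):
        assert ps.therapeutic_index(st_, sr) == expected

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(0)
        for st_, sr in rng.random((20, 2)):
            assert ps.therapeutic_index(st_, sr) == -ps.therapeutic_index(sr, st_)


class TestRefineIndex:
    @pytest.mark.parametrize(
        "index,weight,expected", [(80, 1.0, 80), (80, 0.0, 0), (-50, 0.5, -25)]
    )
    def test_known_values(self, index, weight, expected):
        assert ps.refine_index(index, weight) == expected

    def test_weight_outside_unit_interval_raises(self):
        with pytest.raises(ValueError):
            ps.refine_index(10, 1.5)

    def test_positive_weight_preserves_sign(self):
        for x in (-73.0, -0.1, 0.2, 99.0):
            for w in (0.1, 0.5, 1.0):
                assert np.sign(ps.refine_index(x, w)) == np.sign(x)


@pytest.fixture(scope="module")
def layout():
    return ps.demo_layout(n_pairs=2, n_conc=4, n_replicates=2, plate_format=384, n_blanks=4)


@pytest.fixture(scope="module")
def truth_surfaces(layout):
    truth = {}
    for k, pair in enumerate(layout.drug_pairs):
        c1, c2 = layout.conc_grid(pair)
        s1 = np.linspace(1.0, 0.3 - 0.05 * k, len(c1))
        s2 = np.linspace(1.0, 0.6, len(c2))
        truth[pair] = np.outer(s1, s2)
    return truth


class TestViabilityWorkflow:
    def test_noise_free_round_trip_is_exact(self, layout, truth_surfaces):
        """Zero-noise reader plates reproduce the generating survival surface."""
        fluor = ps.synth_reader_plate(layout, truth_surfaces, noise_sd=0.0)
        result = ps.run_viability(fluor, layout)
        for pair, truth in truth_surfaces.items():
            surv = result.survival[pair]
            np.testing.assert_allclose(surv.values, truth, atol=1e-12)
            assert not surv.excluded.any()
            # the truth surfaces are Bliss-independent products
            np.testing.assert_allclose(result.bliss[pair], 0.0, atol=1e-9)

    def test_therapeutic_indices_need_reference(self, layout, truth_surfaces):
        fluor = ps.synth_reader_plate(layout, truth_surfaces, noise_sd=0.0)
        alone = ps.run_viability(fluor, layout)
        assert alone.therapeutic == {}
        with_ref = ps.run_viability(fluor, layout, reference_fluorescence=fluor)
        for pair in layout.drug_pairs:
            np.testing.assert_allclose(with_ref.therapeutic[pair], 0.0, atol=1e-9)
            np.testing.assert_allclose(with_ref.therapeutic_rw[pair], 0.0, atol=1e-9)

    def test_therapeutic_window_sign(self, layout, truth_surfaces):
        """Reference cells surviving better than target cells give positive T."""
        fluor_t = ps.synth_reader_plate(layout, truth_surfaces, noise_sd=0.0)
        ref_truth = {p: np.minimum(1.0, s + 0.2) for p, s in truth_surfaces.items()}
        fluor_r = ps.synth_reader_plate(layout, ref_truth, noise_sd=0.0)
        res = ps.run_viability(fluor_t, layout, reference_fluorescence=fluor_r)
        for pair in layout.drug_pairs:
            t = res.therapeutic[pair]
            assert np.nanmin(t) >= -1e-9  # reference never survives less here
            expected = 100.0 * (ref_truth[pair] - truth_surfaces[pair])
            np.testing.assert_allclose(t, expected, atol=1e-9)
            np.testing.assert_allclose(
                res.therapeutic_rw[pair], t * ref_truth[pair], atol=1e-9
            )

    def test_overdispersed_patch_excluded_everywhere(self, layout, truth_surfaces):
        """A patch failing the 30%-SD rule is masked in survival and synergy."""
        fluor = dict(ps.synth_reader_plate(layout, truth_surfaces, noise_sd=0.0))
        pair = layout.drug_pairs[0]
        groups = layout.replicate_groups()
        patch = next(
            k for k in groups if k[0] == pair and k[1] > 0 and k[2] > 0 and len(groups[k]) == 2
        )
        w1, w2 = groups[patch]
        # push the two replicates far apart: SI difference > 60 points
        fluor[w1] = fluor[w1] + 0.8 * (20000.0 - 200.0)
        result = ps.run_viability(fluor, layout)
        surv = result.survival[pair]
        i = surv.conc1.index(patch[1])
        j = surv.conc2.index(patch[2])
        assert surv.excluded[i, j]
        assert np.isnan(surv.values[i, j])
        assert np.isnan(result.bliss[pair][i, j])
        assert np.isnan(result.bliss_scaled[pair][i, j])

    def test_mismatched_reference_grid_raises(self, layout, truth_surfaces):
        fluor = ps.synth_reader_plate(layout, truth_surfaces, noise_sd=0.0)
        other = ps.demo_layout(n_pairs=2, n_conc=3, n_replicates=2, plate_format=384)
        other_truth = {
            p: np.ones((len(other.conc_grid(p)[0]), len(other.conc_grid(p)[1])))
            for p in other.drug_pairs
        }
        ref = ps.synth_reader_plate(other, other_truth)
        with pytest.raises(ps.LayoutError):
            ps.run_viability(
                fluor, layout, reference_fluorescence=ref, reference_layout=other
            )
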