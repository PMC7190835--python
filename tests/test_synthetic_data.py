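"""Synthetic dataset generator: oracles, determinism, model consistency."""

import numpy as np
import pytest

from tunedev.synthetic_data import (
    NOR_TUNER_GRID_RPU,
    SyntheticDatasetSpec,
    generate_device_dataset,
    generate_events,
    generate_nor_dataset,
)


class TestGenerateEvents:
    def test_zero_log_sd_collapses_all_events_onto_the_median(self):
        sample, _ = generate_events(42.0, 0.0, 500, seed=1)
        np.testing.assert_array_equal(sample.yfp, np.full(500, 42.0))

    def test_large_sample_median_matches_the_requested_median(self):
        sample, _ = generate_events(500.0, 0.45, 10**6, seed=8)
        assert np.median(sample.yfp) == pytest.approx(500.0, rel=0.005)

    def test_same_seed_reproduces_the_sample_bit_identically(self):
        a, la = generate_events(100.0, 0.4, 2000, seed=13)
        b, lb = generate_events(100.0, 0.4, 2000, seed=13)
        np.testing.assert_array_equal(a.yfp, b.yfp)
        np.testing.assert_array_equal(a.fsc, b.fsc)
        np.testing.assert_array_equal(la, lb)

    def test_rejects_empty_or_degenerate_requests(self):
        with pytest.raises(ValueError):
            generate_events(10.0, 0.3, 0, seed=1)
        with pytest.raises(ValueError):
            generate_events(0.0, 0.3, 10, seed=1)
        with pytest.raises(ValueError):
            generate_events(10.0, -0.1, 10, seed=1)

    def test_scatter_mixture_has_both_clusters(self):
        _, labels = generate_events(10.0, 0.3, 20_000, seed=3)
        frac = labels.mean()
        assert 0.8 < frac < 0.9  # dominant cluster at its design fraction


@pytest.fixture(scope="module")
def small_spec():
    return SyntheticDatasetSpec(n_events=2000, seed=21, include_scatter=False)


class TestDeviceDataset:

    def test_same_spec_and_seed_reproduce_the_dataset(self, small_spec):
        a = generate_device_dataset(small_spec)
        b = generate_device_dataset(small_spec)
        assert a.manifest.conditions == b.manifest.conditions
        for key in a.samples:
            np.testing.assert_array_equal(a.samples[key].yfp, b.samples[key].yfp)

    def test_noise_free_medians_equal_model_outputs(self):
        spec = SyntheticDatasetSpec(n_events=50, replicate_cv=0.0, log_sd=0.0,
                                    seed=2, include_scatter=False)
        ds = generate_device_dataset(spec)
        for rec in ds.manifest.conditions:
            observed = ds.samples[rec.key].median()
            assert observed == pytest.approx(
                rec.true_signal_median + spec.autofluorescence_median, rel=1e-12
            )

    def test_every_condition_and_control_is_present(self, small_spec):
        ds = generate_device_dataset(small_spec)
        expected = (len(small_spec.input_grid) * len(small_spec.tuner_grid)
                    * small_spec.replicates)
        assert len(ds.manifest.conditions) == expected
        assert len(ds.autofluorescence_controls) == small_spec.replicates
        assert len(ds.rpu_standards) == small_spec.replicates

    def test_replicate_factor_is_a_shared_batch_effect(self, small_spec):
        ds = generate_device_dataset(small_spec)
        by_rep = {}
        for rec in ds.manifest.conditions:
            by_rep.setdefault(rec.replicate, set()).add(rec.replicate_factor)
        for factors in by_rep.values():
            assert len(factors) == 1

    def test_booster_design_raises_every_on_state_median(self):
        kw = dict(n_events=50, replicate_cv=0.0, log_sd=0.0, seed=5, include_scatter=False)
        orig = generate_device_dataset(SyntheticDatasetSpec(design="original", **kw))
        boost = generate_device_dataset(SyntheticDatasetSpec(design="booster", **kw))
        t_orig = {(r.input_rpu, r.tuner_rpu): r.true_signal_median
                  for r in orig.manifest.conditions}
        t_boost = {(r.input_rpu, r.tuner_rpu): r.true_signal_median
                   for r in boost.manifest.conditions}
        assert all(t_boost[k] >= t_orig[k] for k in t_orig)

    def test_hill_truth_recovered_from_a_seeded_dataset(self):
        spec = SyntheticDatasetSpec(n_events=10_000, replicate_cv=0.05, seed=11,
                                    include_scatter=False)
        ds = generate_device_dataset(spec)
        from tunedev.response_fitting import ResponseCurve, fit_hill_activation

        af = np.mean([c.median() for c in ds.autofluorescence_controls])
        for tuner, truth in ds.manifest.hill_truth.items():
            if not truth.reliable:
                continue
            xs, ys = [], []
            for rec in ds.manifest.conditions:
                if rec.tuner_rpu == tuner:
                    xs.append(rec.input_rpu)
                    ys.append(max(ds.samples[rec.key].median() - af, 1e-3))
            fit = fit_hill_activation(ResponseCurve(np.array(xs), np.array(ys)))
            assert fit.K == pytest.approx(truth.K, rel=0.10)

    def test_long_format_frame_carries_all_events(self, small_spec):
        ds = generate_device_dataset(small_spec)
        frame = ds.to_frame()
        n_samples = len(ds.samples) + 2 * small_spec.replicates
        assert len(frame) == n_samples * small_spec.n_events
        assert set(frame["sample"].unique()) == {
            "device", "autofluorescence_control", "rpu_standard"
        }


@pytest.fixture(scope="module")
def nor_ds():
    spec = SyntheticDatasetSpec(
        device="nor", tuner_grid=NOR_TUNER_GRID_RPU, n_events=200,
        replicate_cv=0.0, log_sd=0.0, replicates=1, seed=6, include_scatter=False,
    )
    return generate_nor_dataset(spec)


class TestNorDataset:

    def test_output_grid_reproduces_nor_truth_table_corners(self, nor_ds):
        spec = nor_ds.spec
        truth = {(r.input_a_rpu, r.input_b_rpu, r.tuner_rpu): r.true_output_rpu
                 for r in nor_ds.manifest.conditions}
        a_lo, a_hi = min(spec.input_grid), max(spec.input_grid)
        b_lo, b_hi = min(spec.input_grid_b), max(spec.input_grid_b)
        # low-tuner operating point: raising the tuner shifts the gate
        # threshold below the B input's nonzero floor and saturates repression
        ut = min(spec.tuner_grid)
        high = truth[(a_lo, b_lo, ut)]
        assert high > 5 * truth[(a_lo, b_hi, ut)]
        assert high > 5 * truth[(a_hi, b_lo, ut)]
        assert high > 5 * truth[(a_hi, b_hi, ut)]

    def test_swapping_symmetric_inputs_transposes_the_output_grid(self):
        grid = (0.01, 0.1, 1.0, 5.0)
        kw = dict(device="nor", tuner_grid=(2.6,), n_events=50, replicates=1,
                  replicate_cv=0.0, log_sd=0.0, seed=9, include_scatter=False)
        ab = generate_nor_dataset(SyntheticDatasetSpec(input_grid=grid, input_grid_b=grid, **kw))
        truth = {(r.input_a_rpu, r.input_b_rpu): r.true_output_rpu
                 for r in ab.manifest.conditions}
        for a in grid:
            for b in grid:
                assert truth[(a, b)] == pytest.approx(truth[(b, a)], rel=1e-12)

    def test_device_field_is_enforced(self):
        with pytest.raises(ValueError, match="nor"):
            generate_nor_dataset(SyntheticDatasetSpec(device="tes"))
        with pytest.raises(ValueError, match="tes/not"):
            generate_device_dataset(SyntheticDatasetSpec(
                device="nor", tuner_grid=NOR_TUNER_GRID_RPU))


class TestSpecValidation:
    def test_rejects_unknown_device_and_design(self):
        with pytest.raises(ValueError, match="device"):
            SyntheticDatasetSpec(device="and")
        with pytest.raises(ValueError, match="design"):
            SyntheticDatasetSpec(design="turbo")

    def test_rejects_non_positive_grid_values(self):
        with pytest.raises(ValueError, match="tuner_grid"):
            SyntheticDatasetSpec(tuner_grid=(0.0, 1.0))

    def test_rejects_negative_noise(self):
        with pytest.raises(ValueError, match="noise"):
            SyntheticDatasetSpec(replicate_cv=-0.1)
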