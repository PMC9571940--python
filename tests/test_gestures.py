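"""Synthetic-gesture generator: class models, study designs, interference
conditions, sample/dataset determinism and the difference preprocessing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eitgesture import synthetic_gestures as sg


class TestClassModels:
    def test_five_distinct_models_with_engineered_confusability(self):
        models = sg.make_class_models(0)
        assert len(models) == 5
        assert [m.class_id for m in models] == list(range(5))
        regions = [set((r.cx, r.cy, r.radius) for r in m.active_regions)
                   for m in models]
        # pistol (2) and six (4) share a region; fist (0) and palm (1) do not
        assert regions[2] & regions[4]
        assert not (regions[0] & regions[1])
        assert models[4].similarity_link == 2

    def test_models_deterministic(self):
        assert sg.make_class_models(7) == sg.make_class_models(7)

    def test_activation_curve_bounds(self):
        m = sg.make_class_models(0)[2]
        act = m.activation(np.arange(40))
        assert act.min() >= 0.0 and act.max() <= 1.0
        assert np.all(np.diff(act) >= 0)

    def test_zero_delta_sigma_collapses_all_classes(self, coarse_phantom):
        """With every region's conductivity change zeroed, all classes
        produce the identical baseline measurement."""
        eff = sg.ParticipantEffect()
        outs = []
        for m in sg.make_class_models(0)[:3]:
            flat = sg.GestureClassModel(
                m.class_id, m.name,
                tuple(sg.Region(r.cx, r.cy, r.radius, 0.0, r.ramp)
                      for r in m.active_regions),
                ramp=m.ramp,
            )
            outs.append(sg.trajectory_voltages(coarse_phantom, flat,
                                               "fixed_opposite", effect=eff))
        np.testing.assert_allclose(outs[0], outs[1])
        np.testing.assert_allclose(outs[0], outs[2])


class TestStudyDesign:
    def test_default_counts(self):
        assert sg.default_design("normal").n_samples == 4000
        assert sg.default_design("shake").n_samples == 4000
        assert sg.default_design("electrode_move").n_samples == 6000
        assert sg.default_design("cross_day").n_samples == 3250

    def test_single_cell_design(self):
        d = sg.StudyDesign(1, 1, 1, 1)
        assert d.n_samples == 1

    @pytest.mark.parametrize("bad", [
        dict(n_participants=0), dict(condition="windy"),
        dict(sets_per_iteration=(10, 20)),
    ])
    def test_invalid_designs_rejected(self, bad):
        with pytest.raises(ValueError):
            sg.StudyDesign(**bad)


class TestInterference:
    def test_normal_is_identity(self):
        ctx = sg.apply_interference("normal", 0, 0, 0)
        assert ctx == sg.InterferenceContext(condition="normal")

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            sg.apply_interference("gusty", 0, 0, 0)

    def test_electrode_move_rotation_within_half_spacing(self):
        for it in range(6):
            ctx = sg.apply_interference("electrode_move", 5, 0, it)
            assert abs(ctx.ring_rotation) <= np.pi / 8

    def test_contexts_session_deterministic(self):
        a = sg.apply_interference("cross_day", 3, 1, 2)
        b = sg.apply_interference("cross_day", 3, 1, 2)
        assert a == b and a.day_factor > 0

    def test_shake_changes_measurements(self, coarse_phantom):
        """A nonzero swing produces measurably different trajectories
        than the normal condition for the same class and phantom."""
        m = sg.make_class_models(0)[0]
        eff = sg.ParticipantEffect()
        normal = sg.trajectory_voltages(coarse_phantom, m, "fixed_opposite",
                                        effect=eff)
        ctx = sg.apply_interference("shake", 1, 0, 0)
        shaken = sg.trajectory_voltages(coarse_phantom, m, "fixed_opposite",
                                        effect=eff, context=ctx)
        assert np.linalg.norm(normal - shaken) > 0


class TestSamplesAndDatasets:
    def test_sample_seeded_determinism(self, coarse_phantom):
        m = sg.make_class_models(0)[1]
        kw = dict(phantom=coarse_phantom, seed=11)
        a = sg.generate_sample(m, "fixed_opposite", **kw)
        b = sg.generate_sample(m, "fixed_opposite", **kw)
        np.testing.assert_array_equal(a.voltages, b.voltages)
        assert a.label == 1

    def test_noise_free_sample_equals_clean_trajectory(self, coarse_phantom):
        m = sg.make_class_models(0)[2]
        eff = sg.ParticipantEffect()
        s = sg.generate_sample(m, "fixed_opposite", participant_effect=eff,
                               noise=sg.NoiseParams(0.0, 0.0, 0.0),
                               timing=None, phantom=coarse_phantom)
        clean = sg.trajectory_voltages(coarse_phantom, m, "fixed_opposite",
                                       effect=eff)
        np.testing.assert_allclose(s.voltages, clean)

    def test_fixed_pattern_tracks_evolve_smoothly(self, coarse_phantom):
        """Noise-free fixed-excitation measurements change gradually: on
        each measurement-pair track the largest single step is a modest
        fraction of the track's total range."""
        m = sg.make_class_models(0)[0]
        v = sg.trajectory_voltages(coarse_phantom, m, "fixed_opposite",
                                   effect=sg.ParticipantEffect())
        for i in range(4):
            track = v[i::4]
            rng_ = track.max() - track.min()
            if rng_ > 0:
                assert np.abs(np.diff(track)).max() <= 0.5 * rng_

    def test_small_dataset_counts_and_determinism(self):
        design = sg.StudyDesign(2, 2, 3, 2, seed=5)
        a = sg.generate_dataset(design, "fixed_opposite")
        b = sg.generate_dataset(design, "fixed_opposite")
        assert len(a) == design.n_samples == 24
        np.testing.assert_array_equal(a.X(), b.X())
        np.testing.assert_array_equal(a.y(), b.y())

    def test_split_by_last_iteration(self):
        design = sg.StudyDesign(1, 2, 3, 3, seed=2)
        ds = sg.generate_dataset(design, "fixed_opposite")
        sp = sg.split_dataset(ds)
        assert len(sp.train) == 12 and len(sp.test) == 6
        assert set(sp.train.iterations()) == {0, 1}
        assert set(sp.test.iterations()) == {2}

    def test_split_requires_multiple_iterations(self):
        ds = sg.generate_dataset(sg.StudyDesign(1, 2, 2, 1), "fixed_opposite")
        with pytest.raises(ValueError):
            sg.split_dataset(ds)

    def test_csv_roundtrip(self):
        ds = sg.generate_dataset(sg.StudyDesign(1, 2, 2, 2, seed=1),
                                 "fixed_adjacent")
        back = sg.dataset_from_frame(sg.dataset_to_frame(ds))
        np.testing.assert_allclose(back.X(), ds.X())
        np.testing.assert_array_equal(back.y(), ds.y())
        assert back.pattern_name == "fixed_adjacent"


class TestFirstOrderDifference:
    def test_stated_examples(self):
        np.testing.assert_allclose(
            sg.first_order_difference([1, 3, 6, 10]), [0, 2, 3, 4]
        )
        np.testing.assert_allclose(
            sg.first_order_difference(np.full(40, 2.5)), np.zeros(40)
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sg.first_order_difference([1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=60))
    def test_matches_elementwise_oracle(self, seq):
        got = sg.first_order_difference(seq)
        assert got[0] == 0.0
        for t in range(1, len(seq)):
            assert got[t] == seq[t] - seq[t - 1]
        assert len(got) == len(seq)
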