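"""Generator correctness: sampling oracles, containment, determinism."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import synaptostats3d as s3d
from synaptostats3d import synthgen


class TestCsrPoints:
    def test_zero_intensity_gives_empty(self, box10):
        assert len(s3d.generate_csr_points(box10, 0.0, seed=0)) == 0

    def test_negative_intensity_rejected(self, box10):
        with pytest.raises(ValueError, match="intensity"):
            s3d.generate_csr_points(box10, -0.1, seed=0)

    def test_points_inside_box(self, box10):
        pts = s3d.generate_csr_points(box10, 0.67, seed=3)
        assert np.all((pts >= 0.0) & (pts < box10.extents))

    def test_poisson_count_oracle(self, box10):
        # mean count over 200 seeds vs Poisson(0.67 * 1000 um^3) = 670
        counts = [len(s3d.generate_csr_points(box10, 0.67, seed=i))
                  for i in range(200)]
        se = math.sqrt(670.0 / 200)
        assert abs(np.mean(counts) - 670.0) < 3 * se

    def test_deterministic(self, box10):
        a = s3d.generate_csr_points(box10, 0.5, seed=11)
        b = s3d.generate_csr_points(box10, 0.5, seed=11)
        np.testing.assert_array_equal(a, b)


class TestPopulation:
    def test_as_fraction_binomial_oracle(self, profiles):
        # SO AS share 94.10%; check the empirical share at n ~ 10,000
        big = s3d.StackGeometry(30_000, 30_000, 25_000)  # 22,500 um^3
        df = s3d.generate_population(big, profiles["SO"], seed=7)
        n = len(df)
        assert n > 8_000
        frac = (df["polarity"] == "AS").mean()
        se = math.sqrt(0.9410 * 0.0590 / n)
        assert abs(frac - 0.9410) < 3 * se

    def test_zero_intensity_empty_table(self, box10, profiles):
        import dataclasses
        prof = dataclasses.replace(profiles["SO"], intensity=0.0)
        df = s3d.generate_population(box10, prof, seed=0)
        assert len(df) == 0
        assert list(df.columns) == list(synthgen.SYNAPSE_COLUMNS)

    def test_lognormal_mean_calibration(self, profiles):
        # pooled-CA1-like AS model: mean 89,727.65 nm^2 recovered at n=10,000
        model = s3d.SizeModel.lognormal_from_moments(89_727.65, 70_000.0)
        rng = np.random.default_rng(5)
        x = model.sample(rng, 10_000)
        se = 70_000.0 / math.sqrt(10_000)
        assert abs(x.mean() - 89_727.65) < 3 * se

    def test_categorical_proportions_chi2_gof(self, profiles):
        # sampled shape classes converge to the profile multinomial
        big = s3d.StackGeometry(42_000, 42_000, 30_000)  # ~50,000 synapses in SR
        prof = profiles["SR"]
        df = s3d.generate_population(big, prof, seed=21)
        sub = df[df["polarity"] == "AS"]
        obs = sub["shape_class"].value_counts()
        exp_p = np.array([prof.shape_probs["AS"][c] for c in synthgen.SHAPE_CLASSES])
        obs_v = np.array([obs.get(c, 0) for c in synthgen.SHAPE_CLASSES])
        stat, p = sps.chisquare(obs_v, exp_p * obs_v.sum())
        assert p > 0.001

    def test_bad_probability_vector_rejected(self, profiles):
        import dataclasses
        bad_shapes = {p: dict(profiles["SO"].shape_probs[p])
                      for p in synthgen.POLARITIES}
        bad_shapes["AS"]["macular"] += 0.2
        with pytest.raises(ValueError, match="sum"):
            dataclasses.replace(profiles["SO"], shape_probs=bad_shapes)

    def test_serialized_determinism(self, box10, profiles, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        s3d.synthgen.write_synapse_table(
            s3d.generate_population(box10, profiles["SLM"], seed=9), p1)
        s3d.synthgen.write_synapse_table(
            s3d.generate_population(box10, profiles["SLM"], seed=9), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestSasMeshes:
    def test_disk_ground_truth(self):
        spec = s3d.SasShapeSpec("disk", {"radius": 500.0})
        mesh, truth = s3d.generate_sas_mesh(spec, seed=0)
        assert truth["area"] == pytest.approx(math.pi * 500.0 ** 2)
        assert truth["n_components"] == 1 and truth["n_holes"] == 0

    def test_hemisphere_curvature_half(self):
        spec = s3d.SasShapeSpec("spherical_cap", {"radius": 600.0, "height": 600.0})
        _, truth = s3d.generate_sas_mesh(spec, seed=0)
        assert truth["curvature"] == pytest.approx(0.5)

    def test_fragment_set_components(self):
        spec = s3d.SasShapeSpec("fragment_set", {"radii": [300.0, 400.0]})
        _, truth = s3d.generate_sas_mesh(spec, seed=0)
        assert truth["n_components"] == 2
        assert truth["shape_class"] == "fragmented"

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            s3d.SasShapeSpec("disk", {"radius": 0.0})
        with pytest.raises(ValueError):
            s3d.SasShapeSpec("spherical_cap", {"radius": 100.0, "height": 150.0})


class TestArtifactMask:
    def test_zero_fraction_all_zero(self):
        g = s3d.StackGeometry(2_000, 2_000, 2_000, voxel_xy=20, voxel_z=20)
        assert s3d.generate_artifact_mask(g, 0.0, seed=0).sum() == 0

    def test_fraction_hit_within_tolerance(self):
        g = s3d.StackGeometry(4_000, 4_000, 2_000, voxel_xy=20, voxel_z=20)
        mask = s3d.generate_artifact_mask(g, 0.12, seed=4)
        assert 0.11 <= mask.mean() <= 0.13

    def test_mask_shape_matches_voxel_grid(self):
        g = s3d.StackGeometry(4_000, 2_000, 1_000, voxel_xy=20, voxel_z=20)
        mask = s3d.generate_artifact_mask(g, 0.05, seed=1)
        assert mask.shape == g.grid_shape == (50, 100, 200)

    def test_out_of_range_rejected(self):
        g = s3d.StackGeometry(1_000, 1_000, 1_000, voxel_xy=20, voxel_z=20)
        with pytest.raises(ValueError):
            s3d.generate_artifact_mask(g, 0.7, seed=0)


class TestSemithinLabels:
    def test_two_class_even_split(self):
        img, truth = s3d.generate_semithin_labels(
            [("a", 50.0), ("b", 50.0)], (128, 128), seed=0)
        assert truth["actual_vv_percent"]["a"] == pytest.approx(50.0, abs=0.1)

    def test_sp_like_neuron_share(self):
        classes = [("vessels", 5.0), ("glia", 0.66), ("neurons", 4.23),
                   ("neuropil", 90.11)]
        img, truth = s3d.generate_semithin_labels(classes, (512, 512), seed=2)
        assert 3.7 <= truth["actual_vv_percent"]["neurons"] <= 4.7
        assert truth["target_sum"] == pytest.approx(100.0)

    def test_shares_not_summing_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            s3d.generate_semithin_labels([("a", 60.0), ("b", 50.0)], seed=0)
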