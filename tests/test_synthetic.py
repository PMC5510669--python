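import numpy as np
import pytest

from mwtriage import (
    Cohort,
    CohortParseError,
    SyntheticConfig,
    generate_cohort,
    read_cohort,
    write_cohort,
)


class TestConfigValidation:
    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(freq_start=1.0, freq_stop=0.5)

    def test_step_must_divide_span(self):
        with pytest.raises(ValueError):
            SyntheticConfig(freq_start=0.1, freq_stop=1.0, freq_step=0.07)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(noise_sd=-0.1)

    def test_default_grid_has_38_points(self):
        assert len(SyntheticConfig().freq_grid) == 38

    def test_yaml_round_trip(self, tmp_path):
        cfg = SyntheticConfig(seed=5, lesion_band=(0.75, 1.95))
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert SyntheticConfig.from_yaml(p) == cfg


class TestGenerateCohort:
    def test_determinism_same_seed_identical(self, tiny_config):
        c1 = generate_cohort(tiny_config)
        c2 = generate_cohort(tiny_config)
        for s1, s2 in zip(c1.subjects, c2.subjects):
            assert s1.subject_id == s2.subject_id
            for r1, r2 in zip(s1.repetitions, s2.repetitions):
                np.testing.assert_array_equal(r1, r2)

    def test_different_seeds_differ(self, tiny_config):
        import dataclasses

        c1 = generate_cohort(tiny_config)
        c2 = generate_cohort(dataclasses.replace(tiny_config, seed=tiny_config.seed + 1))
        assert not np.array_equal(c1.subjects[0].repetitions[0], c2.subjects[0].repetitions[0])

    def test_shapes_and_labels(self, tiny_cohort, tiny_config):
        assert len(tiny_cohort) == 12
        n_chan = 36
        n_freq = len(tiny_config.freq_grid)
        for s in tiny_cohort.subjects:
            assert len(s.repetitions) == 3
            assert s.repetitions[0].shape == (n_chan, n_freq)
        assert sum(tiny_cohort.labels == "cSDH") == 6

    def test_zero_noise_makes_repetitions_identical(self):
        cfg = SyntheticConfig(
            n_patients=2, n_controls=2, noise_sd=0.0, repositioning_sd=0.0, seed=3
        )
        c = generate_cohort(cfg)
        for s in c.subjects:
            np.testing.assert_array_equal(s.repetitions[0], s.repetitions[1])
            np.testing.assert_array_equal(s.repetitions[0], s.repetitions[2])

    def test_no_gain_means_no_class_contrast(self):
        # with kappa=0 and all nuisances off, patient and control baselines
        # follow the identical deterministic model
        cfg = SyntheticConfig(
            n_patients=2,
            n_controls=2,
            hematoma_gain=0.0,
            noise_sd=0.0,
            repositioning_sd=0.0,
            head_scale_sd=0.0,
            contact_sd=0.0,
            seed=3,
        )
        c = generate_cohort(cfg)
        np.testing.assert_allclose(
            c.subjects[0].repetitions[0], c.subjects[2].repetitions[0], rtol=1e-12
        )

    def test_patients_carry_volume_metadata(self, tiny_cohort):
        for s in tiny_cohort.subjects:
            if s.label == "cSDH":
                assert s.total_volume > 0
                assert s.lesion_azimuth is not None
            else:
                assert s.total_volume == 0
                assert s.lesion_azimuth is None

    def test_degenerate_frequency_band_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(freq_start=0.5, freq_stop=0.5)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(SyntheticConfig(n_patients=0))

    def test_lesion_band_confines_perturbation(self):
        base = dict(
            n_patients=2, n_controls=2, noise_sd=0.0, repositioning_sd=0.0,
            head_scale_sd=0.0, contact_sd=0.0, seed=3,
        )
        with_lesion = generate_cohort(SyntheticConfig(**base, lesion_band=(1.0, 1.95)))
        without = generate_cohort(SyntheticConfig(**base, hematoma_gain=0.0))
        patient = with_lesion.subjects[0].repetitions[0]
        control = without.subjects[0].repetitions[0]
        low = with_lesion.freq_grid < 1.0
        np.testing.assert_allclose(patient[:, low], control[:, low], rtol=1e-12)
        assert not np.allclose(patient[:, ~low], control[:, ~low])


class TestVolumeEffect:
    def test_decision_values_track_lesion_size(self):
        # larger lesions should, on average, push patients' LOO decision
        # values up: Spearman rho(volume^(1/3), score) > 0 in >= 80% of
        # seeded replicates
        from scipy.stats import spearmanr

        from mwtriage import loo_cross_validate

        hits = 0
        n_rep = 20
        for seed in range(1, n_rep + 1):
            cohort = generate_cohort(SyntheticConfig(seed=seed))
            result = loo_cross_validate(cohort)
            pos = result.labels == "cSDH"
            volumes = np.array([s.total_volume for s in cohort.subjects])[pos]
            rho = spearmanr(volumes ** (1 / 3), result.scores[pos]).statistic
            hits += rho > 0
        assert hits >= 0.8 * n_rep


class TestCohortCSV:
    def test_round_trip_preserves_values(self, tmp_path):
        cfg = SyntheticConfig(
            n_patients=2, n_controls=2, freq_start=0.1, freq_stop=0.7, freq_step=0.2, seed=9
        )
        cohort = generate_cohort(cfg)
        p = tmp_path / "cohort.csv"
        write_cohort(cohort, p)
        loaded = read_cohort(p)
        assert len(loaded) == len(cohort)
        assert loaded.channels == cohort.channels
        np.testing.assert_allclose(loaded.freq_grid, cohort.freq_grid)
        by_id = {s.subject_id: s for s in cohort.subjects}
        for s in loaded.subjects:
            orig = by_id[s.subject_id]
            assert s.label == orig.label
            for r1, r2 in zip(s.repetitions, orig.repetitions):
                np.testing.assert_allclose(r1, r2, rtol=1e-12)

    def test_missing_frequency_row_names_subject_and_channel(self, tmp_path):
        cfg = SyntheticConfig(
            n_patients=1, n_controls=1, freq_start=0.1, freq_stop=0.7, freq_step=0.2, seed=9
        )
        write_cohort(generate_cohort(cfg), tmp_path / "c.csv")
        lines = (tmp_path / "c.csv").read_text().splitlines()
        # drop one data row belonging to subject C01
        drop = next(i for i, l in enumerate(lines) if l.startswith("C01"))
        (tmp_path / "bad.csv").write_text("\n".join(lines[:drop] + lines[drop + 1 :]) + "\n")
        with pytest.raises(CohortParseError, match="C01.*1-1"):
            read_cohort(tmp_path / "bad.csv")

    def test_empty_file_rejected(self, tmp_path):
        (tmp_path / "empty.csv").write_text("")
        with pytest.raises(CohortParseError, match="no records"):
            read_cohort(tmp_path / "empty.csv")

    def test_duplicate_key_rejected(self, tmp_path):
        cfg = SyntheticConfig(
            n_patients=1, n_controls=1, freq_start=0.1, freq_stop=0.7, freq_step=0.2, seed=9
        )
        write_cohort(generate_cohort(cfg), tmp_path / "c.csv")
        lines = (tmp_path / "c.csv").read_text().splitlines()
        (tmp_path / "dup.csv").write_text("\n".join(lines + [lines[1]]) + "\n")
        with pytest.raises(CohortParseError, match="duplicate"):
            read_cohort(tmp_path / "dup.csv")


class TestCohortContainer:
    def test_duplicate_subject_ids_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            Cohort(
                subjects=[tiny_cohort.subjects[0], tiny_cohort.subjects[0]],
                channels=tiny_cohort.channels,
                freq_grid=tiny_cohort.freq_grid,
            )

    def test_with_labels_reassigns(self, tiny_cohort):
        new = ["HC"] * 6 + ["cSDH"] * 6
        relabeled = tiny_cohort.with_labels(new)
        assert list(relabeled.labels) == new
        # measurements are untouched
        np.testing.assert_array_equal(
            relabeled.subjects[0].repetitions[0], tiny_cohort.subjects[0].repetitions[0]
        )
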