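"""Domain types, the study-design manifest, spectrum I/O and split rules."""

import numpy as np
import pytest

from sersquant.spectra import (
    CROP_HI,
    CROP_LO,
    LabelledDataset,
    Medium,
    SampleManifest,
    Spectrum,
    SpectrumState,
    SplitAssignment,
    SplitRole,
    crop_range,
    default_grid,
    read_spectra,
    split_dataset,
    study_manifest,
    write_spectra,
)

from conftest import make_uniform_spectrum


class TestSpectrum:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            Spectrum(np.arange(5.0), np.arange(4.0))

    def test_non_monotonic_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Spectrum(np.array([1.0, 3.0, 2.0]), np.zeros(3))

    def test_non_uniform_spacing_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            Spectrum(np.array([0.0, 1.0, 3.0]), np.zeros(3))

    def test_normalized_state_enforces_bounds(self):
        with pytest.raises(ValueError, match="normalized"):
            Spectrum(np.arange(3.0), np.array([0.0, 0.5, 1.5]),
                     SpectrumState.NORMALIZED)


class TestStudyManifest:
    def test_medium_totals(self):
        rows = study_manifest()
        urine = sum(r.n_spectra for r in rows if r.medium is Medium.URINE)
        water = sum(r.n_spectra for r in rows if r.medium is Medium.WATER)
        assert urine == 318
        assert water == 364
        assert urine + water == 682

    def test_held_out_roles(self):
        roles = {r.sample_id: r.split_role for r in study_manifest("urine")}
        assert roles["D"] is SplitRole.HELD_OUT_TEST
        assert roles["E"] is SplitRole.HELD_OUT_TEST
        assert roles["F"] is SplitRole.HELD_OUT_VALIDATION
        others = {k: v for k, v in roles.items() if k not in "DEF"}
        assert all(v is SplitRole.REPEAT for v in others.values())

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            SampleManifest("X", -1.0, 0, 0, Medium.WATER, 5)


class TestIO:
    def test_delimited_roundtrip(self, tmp_path, rng):
        w = 100.0 + 2.0 * np.arange(50)
        spectra = [Spectrum(w, rng.uniform(0, 7, 50)) for _ in range(3)]
        path = tmp_path / "spec.csv"
        write_spectra(path, spectra)
        back = read_spectra(path)
        assert len(back) == 3
        for a, b in zip(spectra, back):
            np.testing.assert_allclose(a.wavenumbers, b.wavenumbers, rtol=1e-10)
            np.testing.assert_allclose(a.intensities, b.intensities, rtol=1e-10)

    def test_matrix_container_roundtrip(self, tmp_path, rng):
        w = 100.0 + 2.0 * np.arange(20)
        spectra = [Spectrum(w, rng.uniform(0, 7, 20)) for _ in range(2)]
        path = tmp_path / "spec.npz"
        write_spectra(path, spectra, format="matrix_container")
        back = read_spectra(path, format="matrix_container")
        np.testing.assert_allclose(back[1].intensities, spectra[1].intensities)

    def test_three_column_table(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "wavenumber,s1,s2\n100,1,2\n102,3,4\n104,5,6\n106,7,8\n108,9,0\n"
        )
        spectra = read_spectra(path)
        assert len(spectra) == 2
        assert len(spectra[0]) == 5

    def test_non_numeric_cell_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wavenumber,s1\n100,1\n102,oops\n104,3\n")
        with pytest.raises(ValueError, match=r"row 1.*'s1'"):
            read_spectra(path)

    def test_unsorted_grid_sorted_on_read(self, tmp_path):
        path = tmp_path / "u.csv"
        path.write_text("wavenumber,s1\n104,3\n100,1\n102,2\n")
        (s,) = read_spectra(path)
        np.testing.assert_array_equal(s.wavenumbers, [100, 102, 104])
        np.testing.assert_array_equal(s.intensities, [1, 2, 3])

    def test_duplicate_wavenumbers_rejected(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("wavenumber,s1\n100,1\n100,2\n102,3\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_spectra(path)


class TestCropRange:
    def test_fixture_grid_crops_to_842_points(self):
        s = Spectrum(default_grid(), np.zeros(937))
        c = crop_range(s, CROP_LO, CROP_HI)
        assert len(c) == 842
        assert c.wavenumbers[0] == pytest.approx(300.0, abs=1e-9)
        assert c.wavenumbers[-1] == pytest.approx(2000.0, abs=1e-6)

    def test_full_range_is_identity(self, random_spectrum):
        c = crop_range(random_spectrum, random_spectrum.wavenumbers[0],
                       random_spectrum.wavenumbers[-1])
        np.testing.assert_array_equal(c.intensities, random_spectrum.intensities)

    def test_idempotent(self, random_spectrum):
        once = crop_range(random_spectrum, 500, 1500)
        twice = crop_range(once, 500, 1500)
        np.testing.assert_array_equal(once.intensities, twice.intensities)

    def test_single_point(self):
        s = make_uniform_spectrum(np.arange(10.0))
        c = crop_range(s, 103.9, 104.1)
        assert len(c) == 1

    def test_empty_range_rejected(self):
        s = make_uniform_spectrum(np.arange(10.0))
        with pytest.raises(ValueError, match="no grid points"):
            crop_range(s, 104.3, 105.1)


def _dataset_for(manifest, grid_n=16):
    spectra, targets, ids = [], [], []
    for row in manifest:
        for _ in range(row.n_spectra):
            spectra.append(make_uniform_spectrum(np.zeros(grid_n)))
            targets.append(row.conc_5ht)
            ids.append(row.sample_id)
    return LabelledDataset(spectra, np.array(targets), np.array(ids, object))


class TestSplitDataset:
    def test_study_urine_split_counts(self):
        manifest = study_manifest("urine")
        ds = split_dataset(_dataset_for(manifest), manifest, 0.1, seed=0)
        counts = {
            k: len(ds.split(k)) for k in ("train", "validation", "test")
        }
        assert counts == {"train": 218, "validation": 46, "test": 54}

    def test_single_repeat_sample(self):
        manifest = [SampleManifest("A", 1, 0, 0, Medium.URINE, 10)]
        ds = split_dataset(_dataset_for(manifest), manifest, 0.1, seed=1)
        assert len(ds.split("train")) == 9
        assert len(ds.split("validation")) == 1
        assert len(ds.split("test")) == 0

    def test_same_seed_reproduces_assignment(self):
        manifest = study_manifest("urine")
        base = _dataset_for(manifest)
        a = split_dataset(base, manifest, 0.1, seed=5).split_assignment
        b = split_dataset(base, manifest, 0.1, seed=5).split_assignment
        assert list(a) == list(b)

    def test_unknown_sample_id_rejected(self):
        manifest = [SampleManifest("A", 1, 0, 0, Medium.URINE, 2)]
        ds = _dataset_for(manifest + [SampleManifest("Z", 0, 0, 0, Medium.URINE, 1)])
        with pytest.raises(ValueError, match="not in manifest"):
            split_dataset(ds, manifest, 0.1, seed=0)

    @pytest.mark.parametrize("seed", range(4))
    def test_partition_conserves_counts_random_manifests(self, seed):
        rng = np.random.default_rng(seed)
        roles = [SplitRole.REPEAT, SplitRole.HELD_OUT_VALIDATION,
                 SplitRole.HELD_OUT_TEST]
        manifest = [
            SampleManifest(
                f"S{i}", 0, 0, float(i), Medium.URINE,
                int(rng.integers(1, 20)),
                roles[int(rng.integers(0, 3))] if i else SplitRole.REPEAT,
            )
            for i in range(int(rng.integers(2, 8)))
        ]
        ds = split_dataset(_dataset_for(manifest), manifest, 0.1, seed=seed)
        total = sum(len(ds.split(k)) for k in ("train", "validation", "test"))
        assert total == len(ds)
        # test split only ever holds held-out-test samples
        test_ids = set(ds.split("test").sample_ids)
        held_test = {r.sample_id for r in manifest
                     if r.split_role is SplitRole.HELD_OUT_TEST}
        assert test_ids <= held_test
        # validation holds every held-out-validation spectrum
        val_ids = list(ds.split("validation").sample_ids)
        for r in manifest:
            if r.split_role is SplitRole.HELD_OUT_VALIDATION:
                assert val_ids.count(r.sample_id) == r.n_spectra
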