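import numpy as np
import pytest
from scipy import stats

from neurofuse.cohort import (
    CohortConfig,
    default_domain_map,
    group_difference_scan,
    read_cohort,
    simulate_cohort,
    simulate_fnc,
    simulate_snps,
    simulate_volumes,
    write_cohort,
)


class TestFNC:
    def test_symmetry_unit_diagonal_and_range(self, small_cohort):
        for m in small_cohort.fnc:
            assert np.array_equal(m, m.T)
            assert np.array_equal(np.diag(m), np.ones(len(m)))
            off = m[~np.eye(len(m), dtype=bool)]
            assert ((off > -1) & (off < 1)).all()

    def test_53_components_give_1378_lower_triangle_entries(self):
        cfg = CohortConfig(n_subjects=4, n_components=53, n_snps=10)
        assert cfg.n_connections == 1378
        fnc, _ = simulate_fnc(cfg, np.array([0, 1, 0, 1]))
        assert fnc.shape == (4, 53, 53)
        rows, cols = np.tril_indices(53, k=-1)
        assert len(fnc[0][rows, cols]) == 1378

    def test_planted_shift_recovered_monte_carlo(self):
        # one planted connection, shift 0.5 in Fisher-z space, n=2000
        cfg = CohortConfig(
            n_subjects=2000, n_components=10, n_snps=5,
            fnc_effect=[(7, 0.5)], noise_sd=0.2, seed=5,
        )
        labels = (np.arange(2000) % 2).astype(np.int8)
        fnc, _ = simulate_fnc(cfg, labels)
        rows, cols = np.tril_indices(10, k=-1)
        z = np.arctanh(fnc[:, rows, cols])
        diff = z[labels == 1].mean(axis=0) - z[labels == 0].mean(axis=0)
        assert abs(diff[7] - 0.5) < 0.05
        assert np.abs(np.delete(diff, 7)).max() < 0.05

    def test_no_planted_signal_means_no_group_difference(self):
        cfg = CohortConfig(n_subjects=1000, n_components=8, n_snps=5, seed=3)
        labels = (np.arange(1000) % 2).astype(np.int8)
        fnc, _ = simulate_fnc(cfg, labels)
        rows, cols = np.tril_indices(8, k=-1)
        flat = fnc[:, rows, cols]
        diff = np.abs(flat[labels == 1].mean(axis=0) - flat[labels == 0].mean(axis=0))
        assert diff.max() < 0.06

    def test_planted_index_out_of_range_rejected(self):
        cfg = CohortConfig(n_subjects=10, n_components=5, n_snps=5,
                           fnc_effect=[(10, 0.5)])
        with pytest.raises(ValueError, match="planted FNC"):
            simulate_fnc(cfg, np.zeros(10, dtype=int))


class TestSNPs:
    def test_dosage_codomain(self, small_cohort):
        assert set(np.unique(small_cohort.snps)) <= {0, 1, 2}

    def test_hardy_weinberg_allele_frequency(self):
        cfg = CohortConfig(n_subjects=5000, n_components=5, n_snps=200,
                           maf_range=(0.3, 0.3), seed=2)
        dosages, _, _ = simulate_snps(cfg)
        freq = dosages.mean(axis=0) / 2.0
        assert np.abs(freq - 0.3).max() < 0.02

    def test_null_model_gives_calibrated_association_scan(self):
        # with no planted SNPs a per-feature two-sample test rejects at
        # roughly the nominal rate
        cfg = CohortConfig(n_subjects=600, n_components=5, n_snps=600, seed=9)
        dosages, labels, _ = simulate_snps(cfg)
        _, p = stats.ttest_ind(dosages[labels == 1], dosages[labels == 0], axis=0)
        rate = (p < 0.05).mean()
        assert 0.02 < rate < 0.08

    def test_planted_snps_shift_case_dosage(self):
        cfg = CohortConfig(n_subjects=3000, n_components=5, n_snps=50,
                           snp_effect=[(4, 1.5)], seed=4)
        dosages, labels, truth = simulate_snps(cfg)
        assert truth["snp"] == [(4, 1.5)]
        diff = group_difference_scan(dosages, labels)
        assert diff[4] == diff.max()

    def test_bad_maf_range_rejected(self):
        with pytest.raises(ValueError, match="maf_range"):
            CohortConfig(n_subjects=10, n_snps=5, maf_range=(0.0, 0.6)).validate()


class TestVolumes:
    def test_shape_and_range(self, small_cohort):
        assert small_cohort.volumes.shape == (40, 16, 16, 16)
        assert small_cohort.volumes.min() >= 0.0
        assert small_cohort.volumes.max() <= 1.0

    def test_planted_density_shift_recovered(self):
        box = ((3, 13), (3, 13), (3, 13))
        cfg = CohortConfig(n_subjects=200, volume_shape=(20, 20, 20),
                           n_components=5, n_snps=5,
                           volume_effect=[(box, -0.2)], seed=6)
        labels = (np.arange(200) % 2).astype(np.int8)
        vols = simulate_volumes(cfg, labels)
        sl = (slice(None),) + tuple(slice(lo, hi) for lo, hi in box)
        diff = vols[labels == 1][sl].mean() - vols[labels == 0][sl].mean()
        assert abs(diff - (-0.2)) < 0.03

    def test_region_box_outside_volume_rejected(self):
        cfg = CohortConfig(n_subjects=10, volume_shape=(16, 16, 16), n_snps=5,
                           volume_effect=[(((0, 20), (0, 8), (0, 8)), 0.1)])
        with pytest.raises(ValueError, match="region box"):
            cfg.validate()


class TestCohort:
    def test_same_seed_bit_identical(self):
        cfg = dict(n_subjects=12, volume_shape=(8, 8, 8), n_components=6,
                   n_snps=20, seed=42)
        a = simulate_cohort(CohortConfig(**cfg))
        b = simulate_cohort(CohortConfig(**cfg))
        assert np.array_equal(a.volumes, b.volumes)
        assert np.array_equal(a.fnc, b.fnc)
        assert np.array_equal(a.snps, b.snps)
        assert np.array_equal(a.labels, b.labels)

    def test_labels_binary_and_both_classes(self, small_cohort):
        assert set(np.unique(small_cohort.labels)) == {0, 1}

    def test_default_domain_map_partition(self):
        dm = default_domain_map(53)
        assert len(dm) == 53
        assert set(dm) == {"SC", "AUD", "SM", "VIS", "CC", "DM", "CB"}
        dm10 = default_domain_map(10)
        assert len(dm10) == 10

    def test_group_difference_scan_finds_planted_connection(self, small_cohort):
        rows, cols = np.tril_indices(10, k=-1)
        flat = small_cohort.fnc[:, rows, cols]
        diff = group_difference_scan(flat, small_cohort.labels)
        planted = [i for i, _ in small_cohort.truth["fnc"]]
        # both planted connections rank inside the top 5 of 45
        top5 = np.argsort(-diff)[:5]
        assert set(planted) <= set(top5.tolist())


class TestRoundTrip:
    def test_write_read_reproduces_cohort(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path / "c")
        back = read_cohort(tmp_path / "c")
        assert back.subject_ids == small_cohort.subject_ids
        assert np.array_equal(back.snps, small_cohort.snps)  # lossless ints
        assert np.array_equal(back.labels, small_cohort.labels)
        assert np.allclose(back.fnc, small_cohort.fnc, atol=1e-9)
        assert np.allclose(back.volumes, small_cohort.volumes, atol=1e-7)
        assert back.domain_map == small_cohort.domain_map
        assert back.snp_ids == small_cohort.snp_ids

    def test_phenotype_recode_1_2_to_0_1(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path / "c")
        with open(tmp_path / "c" / "snps.raw") as fh:
            fh.readline()
            phen = [int(line.split()[5]) for line in fh]
        assert set(phen) <= {1, 2}
        assert np.array_equal(np.array(phen) - 1, small_cohort.labels)

    def test_missing_fnc_file_raises(self, small_cohort, tmp_path):
        d = write_cohort(small_cohort, tmp_path / "c")
        (d / "fnc" / "sub-0000.csv").unlink()
        with pytest.raises(FileNotFoundError, match="manifest entry"):
            read_cohort(d)

    def test_malformed_raw_header_raises(self, small_cohort, tmp_path):
        d = write_cohort(small_cohort, tmp_path / "c")
        raw = (d / "snps.raw").read_text().splitlines()
        raw[0] = raw[0].replace("PHENOTYPE", "PHENO")
        (d / "snps.raw").write_text("\n".join(raw) + "\n")
        with pytest.raises(ValueError, match="malformed"):
            read_cohort(d)
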