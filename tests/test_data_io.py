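import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import permlmm as pl
from permlmm.data_io import (DataError, write_genotype_csv, write_genotype_hdf5,
                             write_genotype_plink)
from permlmm.kinship import KinshipMatrix


@pytest.fixture
def tiny_genotype():
    return pl.GenotypeMatrix(
        sample_ids=np.array(["A", "B", "C"]),
        dosages=np.array([[0.0, 1.0], [2.0, 1.0], [0.0, 0.0]]),
        marker_ids=np.array(["1:100", "1:200"]),
        chromosomes=np.array(["1", "1"]),
        positions=np.array([100, 200]),
    )


class TestGenotypeFormats:
    def test_csv_read_back(self, tiny_genotype, tmp_path):
        path = tmp_path / "geno.csv"
        write_genotype_csv(tiny_genotype, path)
        geno = pl.read_genotype(path)
        np.testing.assert_array_equal(geno.dosages, tiny_genotype.dosages)
        np.testing.assert_array_equal(geno.sample_ids, tiny_genotype.sample_ids)
        np.testing.assert_array_equal(geno.marker_ids, tiny_genotype.marker_ids)
        np.testing.assert_array_equal(geno.positions, [100, 200])

    @pytest.mark.parametrize("fmt,writer", [
        ("hdf5", write_genotype_hdf5),
        ("plink", write_genotype_plink),
    ])
    def test_format_round_trip_matches_csv(self, tiny_genotype, tmp_path, fmt, writer):
        """The same data through bed/bim/fam or HDF5 equals the CSV read."""
        csv_path = tmp_path / "geno.csv"
        write_genotype_csv(tiny_genotype, csv_path)
        from_csv = pl.read_genotype(csv_path)
        other = tmp_path / ("geno.h5" if fmt == "hdf5" else "geno.bed")
        writer(tiny_genotype, other if fmt == "hdf5" else tmp_path / "geno")
        loaded = pl.read_genotype(other, fmt)
        np.testing.assert_array_equal(loaded.dosages, from_csv.dosages)
        np.testing.assert_array_equal(loaded.sample_ids, from_csv.sample_ids)

    def test_plink_round_trip_larger_panel(self, tmp_path):
        geno = pl.simulate_genotypes(n=37, m=23, seed=5)   # n not divisible by 4
        # orient columns to the minor allele first: that is the only
        # orientation the PLINK reader preserves by design
        flip = geno.allele_frequencies() > 0.5
        dosages = geno.dosages.copy()
        dosages[:, flip] = 2.0 - dosages[:, flip]
        geno = pl.GenotypeMatrix(geno.sample_ids, dosages, geno.marker_ids,
                                 geno.chromosomes, geno.positions)
        write_genotype_plink(geno, tmp_path / "panel")
        loaded = pl.read_genotype(tmp_path / "panel.bed", "plink")
        np.testing.assert_array_equal(loaded.dosages, geno.dosages)

    def test_plink_flips_to_minor_allele(self, tmp_path):
        """A marker whose A1 is the major allele is flipped on load."""
        geno = pl.GenotypeMatrix(
            np.array(["A", "B", "C", "D"]),
            np.array([[2.0], [2.0], [2.0], [1.0]]),    # A1 frequency 7/8
            np.array(["m1"]), np.array(["1"]), np.array([10]))
        write_genotype_plink(geno, tmp_path / "flip")
        loaded = pl.read_genotype(tmp_path / "flip.bed", "plink")
        np.testing.assert_array_equal(loaded.dosages[:, 0], [0.0, 0.0, 0.0, 1.0])
        assert loaded.maf()[0] == pytest.approx(1 / 8)

    def test_bed_with_zero_markers_errors(self, tmp_path):
        (tmp_path / "bad.fam").write_text("A A 0 0 0 -9\nB B 0 0 0 -9\nC C 0 0 0 -9\n")
        (tmp_path / "bad.bim").write_text("")
        (tmp_path / "bad.bed").write_bytes(bytes([0x6C, 0x1B, 0x01]))
        with pytest.raises(DataError, match="no markers"):
            pl.read_genotype(tmp_path / "bad.bed", "plink")

    def test_dosage_out_of_range_rejected(self, tmp_path):
        pd.DataFrame({"m1": [0.0, 3.0]}, index=["A", "B"]).to_csv(tmp_path / "bad.csv")
        with pytest.raises(DataError, match=r"\[0, 2\]"):
            pl.read_genotype(tmp_path / "bad.csv")

    def test_missing_calls_mean_imputed(self, tmp_path):
        pd.DataFrame({"m1": [0.0, np.nan, 2.0, 2.0]},
                     index=["A", "B", "C", "D"]).to_csv(tmp_path / "na.csv")
        geno = pl.read_genotype(tmp_path / "na.csv")
        assert geno.dosages[1, 0] == pytest.approx(4 / 3)

    def test_markers_sorted_by_position(self, tmp_path):
        df = pd.DataFrame(np.zeros((3, 2)) + [[0, 1], [1, 0], [2, 2]],
                          index=["A", "B", "C"], columns=["1:500", "1:100"])
        df.to_csv(tmp_path / "unsorted.csv")
        geno = pl.read_genotype(tmp_path / "unsorted.csv")
        assert list(geno.positions) == [100, 500]
        np.testing.assert_array_equal(geno.dosages[:, 1], [0, 1, 2])


class TestPhenotype:
    def test_missing_value_retained_as_nan(self, tmp_path):
        (tmp_path / "p.csv").write_text("accession,FT16\nA,1.0\nB,2.0\nC,NA\n")
        pheno = pl.read_phenotype(tmp_path / "p.csv", "FT16")
        np.testing.assert_array_equal(pheno.sample_ids, ["A", "B", "C"])
        assert pheno.values[0] == 1.0 and pheno.values[1] == 2.0
        assert np.isnan(pheno.values[2])

    def test_replicates_averaged(self, tmp_path, caplog):
        (tmp_path / "p.csv").write_text("accession,FT16\nA,1.0\nA,3.0\nB,5.0\n")
        with caplog.at_level("INFO"):
            pheno = pl.read_phenotype(tmp_path / "p.csv", "FT16")
        assert dict(zip(pheno.sample_ids, pheno.values)) == {"A": 2.0, "B": 5.0}
        assert any("replicate" in r.message for r in caplog.records)

    def test_unknown_trait_names_available(self, tmp_path):
        (tmp_path / "p.csv").write_text("accession,FT16\nA,1.0\n")
        with pytest.raises(DataError, match="FT16"):
            pl.read_phenotype(tmp_path / "p.csv", "FT10")


class TestAlignment:
    def _kin(self, ids):
        return KinshipMatrix(np.asarray(ids, dtype=str), np.eye(len(ids)))

    def test_intersection(self):
        geno = pl.GenotypeMatrix(
            np.array(["A", "B", "C", "D", "E", "F"]),
            np.tile([[0.0, 1.0]], (6, 1)) + np.arange(6)[:, None] % 2,
            np.array(["m1", "m2"]), np.array(["1", "1"]), np.array([1, 2]))
        pheno = pl.PhenotypeVector(np.array(["B", "C", "D", "E", "F", "G"]),
                                   np.arange(6, dtype=float))
        ds = pl.align_samples(geno, pheno, self._kin(list("ABCDEFG")))
        assert list(ds.genotype.sample_ids) == ["B", "C", "D", "E", "F"]

    def test_missing_phenotype_dropped(self, panel, panel_kinship):
        values = np.arange(panel.n_samples, dtype=float)
        values[3] = np.nan
        pheno = pl.PhenotypeVector(panel.sample_ids, values)
        ds = pl.align_samples(panel, pheno, panel_kinship)
        assert panel.sample_ids[3] not in set(ds.genotype.sample_ids)
        assert ds.n_samples == panel.n_samples - 1

    def test_sample_absent_from_kinship_dropped(self, panel, panel_kinship, caplog):
        from permlmm.kinship import KinshipMatrix
        pheno = pl.PhenotypeVector(panel.sample_ids,
                                   np.arange(panel.n_samples, dtype=float))
        kin = KinshipMatrix(panel_kinship.sample_ids[:-1],
                            panel_kinship.values[:-1, :-1])
        with caplog.at_level("INFO"):
            ds = pl.align_samples(panel, pheno, kin)
        assert panel.sample_ids[-1] not in set(ds.genotype.sample_ids)
        assert ds.n_samples == panel.n_samples - 1
        assert any("dropped" in r.message for r in caplog.records)

    def test_order_independent_of_input_ordering(self, panel, panel_kinship, rng_seed=7):
        rng = np.random.default_rng(rng_seed)
        values = rng.normal(size=panel.n_samples)
        pheno = pl.PhenotypeVector(panel.sample_ids, values)
        ds1 = pl.align_samples(panel, pheno, panel_kinship)
        shuffle = rng.permutation(panel.n_samples)
        pheno2 = pl.PhenotypeVector(panel.sample_ids[shuffle], values[shuffle])
        kshuffle = rng.permutation(panel.n_samples)
        kin2 = KinshipMatrix(panel_kinship.sample_ids[kshuffle],
                             panel_kinship.values[np.ix_(kshuffle, kshuffle)])
        ds2 = pl.align_samples(panel, pheno2, kin2)
        np.testing.assert_array_equal(ds1.genotype.sample_ids, ds2.genotype.sample_ids)
        np.testing.assert_allclose(ds1.phenotype.values, ds2.phenotype.values)
        np.testing.assert_allclose(ds1.kinship, ds2.kinship)

    def test_empty_intersection_errors(self, tiny_genotype):
        pheno = pl.PhenotypeVector(np.array(["X", "Y"]), np.array([1.0, 2.0]))
        with pytest.raises(DataError):
            pl.align_samples(tiny_genotype, pheno, self._kin(["X", "Y"]))


class TestMafFilter:
    def test_counting(self):
        geno = pl.GenotypeMatrix(np.array(["a", "b", "c", "d"]),
                                 np.array([[0.0], [0.0], [1.0], [2.0]]),
                                 np.array(["m"]), np.array(["1"]), np.array([1]))
        assert geno.maf()[0] == pytest.approx(3 / 8)
        assert pl.filter_maf(geno, maf_min=0.05).n_markers == 1

    def test_monomorphic_removed_and_boundary(self, panel):
        n = 50
        dosages = np.zeros((n, 3))
        dosages[:2, 1] = [1.0, 1.0]      # MAF 0.02
        dosages[:10, 2] = 1.0            # MAF 0.10
        geno = pl.GenotypeMatrix(np.array([f"s{i}" for i in range(n)]), dosages,
                                 np.array(["mono", "rare", "common"]),
                                 np.array(["1"] * 3), np.array([1, 2, 3]))
        kept = pl.filter_maf(geno, maf_min=0.05)
        assert list(kept.marker_ids) == ["common"]

    def test_mac_threshold(self):
        geno = pl.simulate_genotypes(n=100, m=50, maf_low=0.01, maf_high=0.5, seed=3)
        kept = pl.filter_maf(geno, mac_min=10)
        assert np.all(kept.mac() >= 10)
        assert kept.n_markers < 50 or np.all(geno.mac() >= 10)

    def test_all_removed_errors(self):
        geno = pl.GenotypeMatrix(np.array(["a", "b"]), np.array([[0.0], [0.0]]),
                                 np.array(["m"]), np.array(["1"]), np.array([1]))
        with pytest.raises(DataError):
            pl.filter_maf(geno, maf_min=0.05)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), maf_min=st.floats(0.0, 0.5))
    def test_idempotent(self, seed, maf_min):
        geno = pl.simulate_genotypes(n=30, m=40, maf_low=0.01, maf_high=0.5, seed=seed)
        try:
            once = pl.filter_maf(geno, maf_min=maf_min)
        except DataError:
            return
        twice = pl.filter_maf(once, maf_min=maf_min)
        np.testing.assert_array_equal(once.dosages, twice.dosages)
        np.testing.assert_array_equal(once.marker_ids, twice.marker_ids)


class TestResults:
    def test_write_and_round_trip(self, panel, panel_kinship, tmp_path):
        rng = np.random.default_rng(0)
        from conftest import draw_null_phenotype, make_dataset
        y = draw_null_phenotype(rng, panel_kinship.values)
        ds = make_dataset(panel, panel_kinship, y)
        scan = pl.gwas_scan(ds)
        perms = pl.generate_permutations(ds.n_samples, 10, 1)
        pscan = pl.permutation_scan(ds, perms)
        thr = pl.compute_thresholds(scan, perm_scan=pscan)
        out = tmp_path / "results.csv"
        pl.write_results(scan, out, thresholds=thr, seed=1)
        df = pl.read_results(out)
        assert len(df) == panel.n_markers
        np.testing.assert_allclose(df["pvalue"].to_numpy(), scan.pvalues, rtol=1e-10)
        import json
        summary = json.loads((tmp_path / "results.summary.json").read_text())
        assert summary["permutation_threshold"] == thr.maxt
        assert len(summary["p_min_per_permutation"]) == 10
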