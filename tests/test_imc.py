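"""Single-cell gating, clustering, phenotype assignment and ratios."""
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from vaximg import imc, synth


@pytest.fixture(scope="module")
def sim_table():
    table, truth = synth.make_cell_table(n_cells=6000, seed=17)
    return table, truth


class TestZNormalize:
    def test_mean_zero_sd_one_within_scope(self, sim_table):
        table, _ = sim_table
        out = imc.znormalize(table, synth.DEFAULT_CHANNELS)
        for ch in synth.DEFAULT_CHANNELS:
            z = out[f"z_{ch}"]
            assert abs(z.mean()) < 1e-9
            assert abs(z.std(ddof=0) - 1.0) < 1e-9

    def test_two_point_channel_population_sd(self):
        t = pd.DataFrame({"sample_id": "S1", "cell_id": [1, 2], "CD20": [0.0, 2.0]})
        out = imc.znormalize(t, ["CD20"])
        np.testing.assert_allclose(sorted(out["z_CD20"]), [-1.0, 1.0])

    def test_outlier_has_largest_abs_z(self, rng):
        vals = np.r_[rng.normal(0, 1, 99), 50.0]
        t = pd.DataFrame({"sample_id": "S1", "cell_id": range(100), "CD3": vals})
        out = imc.znormalize(t, ["CD3"])
        assert out["z_CD3"].abs().idxmax() == 99

    def test_zero_variance_names_channel(self):
        t = pd.DataFrame({"sample_id": "S1", "cell_id": [1, 2], "CD68": [3.0, 3.0]})
        with pytest.raises(ValueError, match="CD68"):
            imc.znormalize(t, ["CD68"])

    def test_raw_intensities_retained(self, sim_table):
        table, _ = sim_table
        out = imc.znormalize(table, ["CD20"])
        pd.testing.assert_series_equal(out["CD20"], table["CD20"])


class TestGateChannel:
    def test_well_separated_mixture_recovers_positive_fraction(self):
        rng = np.random.default_rng(4)
        n = 5000
        truth = rng.random(n) < 0.3
        z = np.where(truth, rng.normal(3.0, 0.5, n), rng.normal(-0.5, 0.5, n))
        res = imc.gate_channel(z, seed=0)
        sd = np.sqrt(0.3 * 0.7 / n)
        assert abs(res.positive_fraction - 0.3) <= 3 * sd
        assert (res.positive == truth).mean() > 0.99
        assert res.means[1] > res.means[0]

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            imc.gate_channel(np.ones(100))

    def test_mirrored_data_labels_same_cells(self):
        rng = np.random.default_rng(8)
        z = np.r_[rng.normal(-1, 0.4, 700), rng.normal(2, 0.4, 300)]
        a = imc.gate_channel(z, seed=1)
        b = imc.gate_channel(-z, seed=1)
        # negation flips which component is "positive"; the positive cells
        # of the original are the negative cells of the mirror
        np.testing.assert_array_equal(a.positive, ~b.positive)

    def test_minimum_cell_count_enforced(self):
        with pytest.raises(ValueError, match="at least"):
            imc.gate_channel(np.random.default_rng(0).normal(size=10))


class TestClusterCells:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(3)
        n = 400
        labels = np.r_[np.zeros(n), np.ones(n)]
        x = np.r_[rng.normal(-3, 0.3, n), rng.normal(3, 0.3, n)]
        y = np.r_[rng.normal(-3, 0.3, n), rng.normal(3, 0.3, n)]
        t = pd.DataFrame({"sample_id": "S1", "cell_id": range(2 * n),
                          "chA": x, "chB": y})
        t = imc.znormalize(t, ["chA", "chB"])
        out = imc.cluster_cells(t, ["chA", "chB"], k=2, seed=0)
        assert adjusted_rand_score(labels, out["cluster_id"]) > 0.99

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame({"sample_id": "S1", "cell_id": range(8),
                          "chA": rng.normal(0, 1, 8)})
        t = imc.znormalize(t, ["chA"])
        out = imc.cluster_cells(t, ["chA"], k=8, seed=0)
        assert out["cluster_id"].nunique() == 8

    def test_seed_reproducibility(self, sim_table):
        table, _ = sim_table
        t = imc.znormalize(table.head(1000), synth.DEFAULT_CHANNELS)
        a = imc.cluster_cells(t, synth.DEFAULT_CHANNELS, k=10, seed=5)
        b = imc.cluster_cells(t, synth.DEFAULT_CHANNELS, k=10, seed=5)
        np.testing.assert_array_equal(a["cluster_id"], b["cluster_id"])

    def test_k_above_n_rejected(self):
        t = pd.DataFrame({"sample_id": "S1", "cell_id": [1, 2], "z_chA": [0.0, 1.0],
                          "chA": [0.0, 1.0]})
        with pytest.raises(ValueError, match="exceeds"):
            imc.cluster_cells(t, ["chA"], k=5)


def _cluster_table(pos_frac_by_channel, n=100, cluster=0):
    """Single-cluster table with given per-channel positive fractions."""
    rng = np.random.default_rng(0)
    t = pd.DataFrame({"sample_id": "S1", "cell_id": range(n), "cluster_id": cluster})
    for ch, frac in pos_frac_by_channel.items():
        t[f"pos_{ch}"] = rng.random(n) < frac
    return t


class TestAssignPhenotypes:
    def test_cd21_pos_cd20_neg_is_fdc(self):
        t = _cluster_table({"CD21": 1.0, "CD20": 0.0, "CD3": 0.0, "Bcl6": 0.0,
                            "CD4": 0.0, "CD8": 0.0, "FoxP3": 0.0, "CD68": 0.0,
                            "MHCII": 0.0})
        out = imc.assign_phenotypes(t)
        assert (out["phenotype"] == "follicular dendritic cell").all()

    def test_all_negative_cluster_unassigned(self):
        t = _cluster_table({ch: 0.0 for ch in synth.DEFAULT_CHANNELS})
        out = imc.assign_phenotypes(t)
        assert (out["phenotype"] == imc.UNASSIGNED).all()

    def test_cd21_with_cd20_is_not_fdc(self):
        # CD20 co-expression violates the FDC rule's required negative
        t = _cluster_table({"CD21": 1.0, "CD20": 1.0, "CD3": 0.0, "Bcl6": 0.0,
                            "CD4": 0.0, "CD8": 0.0, "FoxP3": 0.0, "CD68": 0.0,
                            "MHCII": 0.0})
        out = imc.assign_phenotypes(t)
        assert (out["phenotype"] == "B cell").all()

    def test_equal_priority_conflict_raises(self):
        t = _cluster_table({"CD21": 1.0, "CD68": 1.0})
        defs = [
            imc.PhenotypeDefinition("x", ("CD21",), priority=1),
            imc.PhenotypeDefinition("y", ("CD68",), priority=1),
        ]
        with pytest.raises(ValueError, match="priority"):
            imc.assign_phenotypes(t, defs, channels=["CD21", "CD68"])


class TestCellTypeRatio:
    def test_single_phenotype_sample(self):
        t = pd.DataFrame({"sample_id": "S1", "cell_id": range(5),
                          "phenotype": "B cell"})
        r = imc.cell_type_ratio(t)
        assert r.loc[0, "ratio"] == 1.0

    def test_ratios_sum_to_one_per_sample(self, sim_table):
        table, _ = sim_table
        labelled, ratios, _ = imc.run_imc_pipeline(
            table, synth.DEFAULT_CHANNELS, k=15, seed=2, n_init=3)
        sums = ratios.groupby("sample_id")["ratio"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_ratio_invariant_to_roi_splitting(self):
        table, _ = synth.make_cell_table(n_cells=2000, n_rois=1, seed=9)
        split, _ = synth.make_cell_table(n_cells=2000, n_rois=4, seed=9)
        table = table.rename(columns={"true_phenotype": "phenotype"})
        split = split.rename(columns={"true_phenotype": "phenotype"})
        r1 = imc.cell_type_ratio(table).set_index("phenotype")["ratio"]
        r2 = imc.cell_type_ratio(split).set_index("phenotype")["ratio"]
        pd.testing.assert_series_equal(r1.sort_index(), r2.sort_index())


class TestEndToEnd:
    def test_phenotype_recovery_and_ratio_error(self, sim_table):
        table, truth = sim_table
        labelled, ratios, gates = imc.run_imc_pipeline(
            table, synth.DEFAULT_CHANNELS, k=15, seed=0, n_init=5)
        accuracy = (labelled["phenotype"] == labelled["true_phenotype"]).mean()
        assert accuracy >= 0.95
        est = ratios.set_index("phenotype")["ratio"]
        for name, frac in truth.phenotype_fractions.items():
            assert abs(est.get(name, 0.0) - frac) < 0.03

    def test_pipeline_deterministic_under_seed(self, sim_table):
        table, _ = sim_table
        sub = table.head(2000)
        a, ra, _ = imc.run_imc_pipeline(sub, synth.DEFAULT_CHANNELS, k=10,
                                        seed=33, n_init=3)
        b, rb, _ = imc.run_imc_pipeline(sub, synth.DEFAULT_CHANNELS, k=10,
                                        seed=33, n_init=3)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ra, rb)
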