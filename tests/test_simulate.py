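import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mdgpipe import io as mio
from mdgpipe.simulate import (SimulationConfig, simulate_block_cohort,
                              simulate_cohort, simulate_survival, write_fixtures)
from mdgpipe.survival import logrank_test


class TestCohortGeneration:
    def test_same_seed_identical(self):
        cfg = SimulationConfig(group_sizes={"NT": 4, "I": 4}, n_genes=20,
                               n_hypo_planted=2, n_hyper_planted=2, seed=5)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_no_planted_signal_truth_all_null(self, null_cohort):
        truth = null_cohort["truth"]
        assert (truth["planted_class"] == "null").all()
        assert (truth["planted_direction"] == "none").all()

    def test_no_planted_signal_groups_exchangeable(self, null_cohort):
        # group beta means should differ only by sampling noise
        beta, samples = null_cohort["beta"], null_cohort["samples"]
        nt = samples.loc[samples["phenotype"] == "NT", "sample_id"]
        tm = samples.loc[samples["phenotype"] == "I", "sample_id"]
        diff = beta[tm].mean(axis=1) - beta[nt].mean(axis=1)
        assert abs(diff.mean()) < 0.01
        assert (diff.abs() > 0.15).mean() < 0.01

    def test_truth_counts_and_anticorrelation_by_construction(self, two_group_cohort):
        truth = two_group_cohort["truth"]
        cfg = two_group_cohort["config"]
        planted = truth[truth["planted_class"] != "null"]
        assert len(planted) == cfg.n_hypo_planted + cfg.n_hyper_planted
        assert (planted.loc[planted["planted_class"] == "hypo",
                            "planted_direction"] == "up").all()
        assert (planted.loc[planted["planted_class"] == "hyper",
                            "planted_direction"] == "down").all()
        # sign of methylation change opposite to expression direction, every row
        beta, counts = two_group_cohort["beta"], two_group_cohort["counts"]
        samples, cmap = two_group_cohort["samples"], two_group_cohort["cpg_map"]
        nt = samples.loc[samples["phenotype"] == "NT", "sample_id"].tolist()
        tm = samples.loc[samples["phenotype"] == "I", "sample_id"].tolist()
        for _, row in planted.iterrows():
            cpgs = cmap.loc[cmap["gene_id"] == row["gene_id"], "cpg_id"]
            dmeth = (np.median(beta.loc[cpgs, tm].to_numpy())
                     - np.median(beta.loc[cpgs, nt].to_numpy()))
            dexpr = (counts.loc[row["gene_id"], tm].mean()
                     - counts.loc[row["gene_id"], nt].mean())
            assert np.sign(dmeth) == -np.sign(dexpr)

    def test_planted_medians_cross_thresholds(self):
        """Planted tumor medians cross 0.4/0.6 in >=99% of seeded replicates."""
        hits = 0
        reps = 300
        for seed in range(reps):
            cfg = SimulationConfig(group_sizes={"NT": 24, "I": 24}, n_genes=2,
                                   cpgs_per_gene=5, n_hypo_planted=1,
                                   n_hyper_planted=0, seed=seed)
            beta, _, cmap, samples, truth = simulate_cohort(cfg)
            gene = truth.loc[truth["planted_class"] == "hypo", "gene_id"].item()
            cpgs = cmap.loc[cmap["gene_id"] == gene, "cpg_id"]
            nt = samples.loc[samples["phenotype"] == "NT", "sample_id"].tolist()
            tm = samples.loc[samples["phenotype"] == "I", "sample_id"].tolist()
            ok = (np.median(beta.loc[cpgs, tm].to_numpy()) < 0.4
                  and np.median(beta.loc[cpgs, nt].to_numpy()) > 0.6)
            hits += ok
        assert hits / reps >= 0.99

    def test_counts_nonnegative_integers_beta_in_unit_interval(self, two_group_cohort):
        counts = two_group_cohort["counts"]
        beta = two_group_cohort["beta"]
        assert (counts.to_numpy() >= 0).all()
        assert np.issubdtype(counts.to_numpy().dtype, np.integer)
        vals = beta.to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_missing_rate_injects_nans(self):
        cfg = SimulationConfig(group_sizes={"NT": 4, "I": 4}, n_genes=50,
                               n_hypo_planted=5, n_hyper_planted=5,
                               missing_rate=0.1, seed=2)
        beta, *_ = simulate_cohort(cfg)
        frac = beta.isna().to_numpy().mean()
        assert 0.05 < frac < 0.15

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(group_sizes={"NT": 1, "I": 4}).validate()
        with pytest.raises(ValueError):
            SimulationConfig(baseline_beta_low=0.2, beta_shift=0.9).validate()

    def test_stage_exclusive_planting(self):
        cfg = SimulationConfig(group_sizes={"NT": 10, "I": 10, "II": 10},
                               n_genes=30, n_hypo_planted=5, n_hyper_planted=0,
                               planted_stages=["I"], seed=3)
        beta, _, cmap, samples, truth = simulate_cohort(cfg)
        gene = truth.loc[truth["planted_class"] == "hypo", "gene_id"].iloc[0]
        cpgs = cmap.loc[cmap["gene_id"] == gene, "cpg_id"]
        med = {p: np.median(beta.loc[cpgs, samples.loc[samples["phenotype"] == p,
                                                       "sample_id"]].to_numpy())
               for p in ("NT", "I", "II")}
        assert med["I"] < 0.4 < 0.6 < med["NT"]
        assert med["II"] > 0.6  # unaffected stage stays at the NT level


class TestSurvivalSimulation:
    def _cohort(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                                "phenotype": ["I"] * n})
        expr = pd.DataFrame(rng.lognormal(5, 1, size=(1, n)),
                            index=["G1"], columns=samples["sample_id"]).round()
        return samples, expr.astype(int)

    def test_null_hazard_logrank_p_uniform(self):
        """Under hazard_ratio=1 the log-rank p-value is uniform (KS check)."""
        samples, expr = self._cohort(n=60)
        pvals = []
        for seed in range(300):
            tab = simulate_survival(samples, expr, link_gene="G1", hazard_ratio=1.0,
                                    censor_rate=0.2, seed=seed)
            labels = np.where(
                expr.loc["G1"].to_numpy() > np.median(expr.loc["G1"]), "high", "low")
            _, p = logrank_test(tab["time"], tab["event"], labels)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_hazard_ratio_three_power(self):
        """hazard_ratio=3, n=200, 20% censoring: log-rank rejects >=90%."""
        samples, expr = self._cohort(n=200)
        labels = np.where(expr.loc["G1"].to_numpy() > np.median(expr.loc["G1"]),
                          "high", "low")
        rejections = 0
        reps = 200
        for seed in range(reps):
            tab = simulate_survival(samples, expr, link_gene="G1", hazard_ratio=3.0,
                                    censor_rate=0.2, seed=seed)
            _, p = logrank_test(tab["time"], tab["event"], labels)
            rejections += p < 0.05
        assert rejections / reps >= 0.90

    def test_zero_censoring_all_events(self):
        samples, expr = self._cohort(n=50)
        tab = simulate_survival(samples, expr, link_gene=None, hazard_ratio=2.0,
                                censor_rate=0.0, seed=1)
        assert (tab["event"] == 1).all()

    def test_invalid_hazard_ratio(self):
        samples, expr = self._cohort(n=10)
        with pytest.raises(ValueError):
            simulate_survival(samples, expr, None, hazard_ratio=0.0,
                              censor_rate=0.1, seed=0)


class TestFixtures:
    def test_write_read_round_trip(self, tmp_path, null_cohort):
        paths = write_fixtures(null_cohort["beta"], null_cohort["counts"],
                               null_cohort["cpg_map"], null_cohort["samples"],
                               null_cohort["truth"], tmp_path)
        pd.testing.assert_frame_equal(mio.read_beta(paths["beta"]),
                                      null_cohort["beta"])
        pd.testing.assert_frame_equal(mio.read_counts(paths["counts"]),
                                      null_cohort["counts"])
        pd.testing.assert_frame_equal(mio.read_cpg_map(paths["cpg_map"]),
                                      null_cohort["cpg_map"])
        back = pd.read_csv(paths["truth"], sep="\t")
        assert list(back.columns) == ["gene_id", "planted_class", "planted_direction"]

    def test_gmt_of_planted_sets(self, tmp_path, two_group_cohort):
        paths = write_fixtures(two_group_cohort["beta"], two_group_cohort["counts"],
                               two_group_cohort["cpg_map"], two_group_cohort["samples"],
                               two_group_cohort["truth"], tmp_path)
        with open(paths["sets"]) as fh:
            lines = [ln.rstrip("\n").split("\t") for ln in fh if ln.strip()]
        assert len(lines) == 2
        for fields in lines:
            assert len(fields) >= 3  # name, description, >=1 member

    def test_empty_truth_still_valid_files(self, tmp_path, null_cohort):
        paths = write_fixtures(null_cohort["beta"], null_cohort["counts"],
                               null_cohort["cpg_map"], null_cohort["samples"],
                               null_cohort["truth"], tmp_path)
        assert mio.read_gmt(paths["sets"]) == {}

    def test_byte_identical_fixtures_for_same_seed(self, tmp_path):
        cfg = SimulationConfig(group_sizes={"NT": 3, "I": 3}, n_genes=10,
                               n_hypo_planted=1, n_hyper_planted=1, seed=9)
        pa = write_fixtures(*simulate_cohort(cfg), tmp_path / "a")
        pb = write_fixtures(*simulate_cohort(cfg), tmp_path / "b")
        for key in pa:
            assert pa[key].read_bytes() == pb[key].read_bytes()


class TestBlockCohort:
    def test_block_genes_mutually_correlated(self):
        counts, samples, block = simulate_block_cohort(seed=4)
        sub = np.log1p(counts.loc[block, samples["sample_id"][:25]])
        corr = np.corrcoef(sub)
        off_diag = corr[np.triu_indices_from(corr, k=1)]
        assert off_diag.mean() > 0.5
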