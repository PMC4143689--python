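import numpy as np
import pytest

import puregxe as pgx
from puregxe.genio import MISSING
from puregxe.scan import ScanConfig, scan_g_only, scan_pure_gxe, \
    tally_significance


@pytest.fixture(scope="module")
def interaction_cohort():
    cfg = pgx.SimConfig(
        seed=1, n_samples=130, n_snps=60,
        causal=[pgx.CausalSNP(7, "pure-interaction", 18.0)],
    )
    return pgx.simulate_cohort(cfg)


def test_pure_gxe_scan_ranks_interaction_snp_highly(interaction_cohort):
    g, c, truth = interaction_cohort
    t = scan_pure_gxe(g, c, "SBP", "age", ScanConfig(n_perm=0))
    assert t.mode == "pure-GxE" and t.env_name == "age"
    assert len(t.rows) == 60
    assert truth["causal_ids"][0] in t.top(5)


def test_rows_keep_input_snp_order_with_rank_annotation(
    interaction_cohort,
):
    g, c, _ = interaction_cohort
    t = scan_pure_gxe(g, c, "SBP", "age", ScanConfig(n_perm=0))
    assert t.rows["snp_id"].tolist() == g.snp_ids
    ranks = t.rows["rank"].to_numpy()
    assert sorted(ranks.tolist()) == list(range(1, 61))
    best = t.rows.loc[t.rows["rank"] == 1, "i_score"].item()
    assert best == t.rows["i_score"].max()


def test_monomorphic_and_sparse_snps_are_skipped_not_raised():
    cfg = pgx.SimConfig(seed=2, n_samples=60, n_snps=6)
    g, c, _ = pgx.simulate_cohort(cfg)
    g.codes[:, 0] = 1                      # monomorphic
    g.codes[:45, 1] = MISSING              # too few usable samples
    t = scan_pure_gxe(g, c, "SBP", "age", ScanConfig(n_perm=0))
    flags = t.rows["flags"].tolist()
    assert flags[0] == "skipped:monomorphic"
    assert flags[1] == "skipped:too-few-samples"
    assert np.isnan(t.rows["i_score"][0])
    assert t.rows["flags"][2:].eq("").all()


def test_main_effect_snp_not_elevated_after_residualization():
    """A strong additive SNP should look null in the pure-GxE scan."""
    scores = []
    null_scores = []
    for seed in range(8):
        cfg = pgx.SimConfig(
            seed=seed, n_samples=130, n_snps=40,
            causal=[pgx.CausalSNP(3, "main", 15.0)],
        )
        g, c, _ = pgx.simulate_cohort(cfg)
        t = scan_pure_gxe(g, c, "SBP", "age", ScanConfig(n_perm=0))
        s = t.rows.set_index("snp_id")["i_score"]
        scores.append(s["snp00003"])
        null_scores.extend(s.drop("snp00003").dropna().tolist())
    lo, hi = np.percentile(null_scores, [2.5, 97.5])
    assert lo < np.mean(scores) < hi


def test_pairwise_deletion_changes_only_affected_snp():
    cfg = pgx.SimConfig(seed=3, n_samples=80, n_snps=5)
    g, c, _ = pgx.simulate_cohort(cfg)
    t_full = scan_pure_gxe(g, c, "SBP", "age", ScanConfig(n_perm=0))
    g.codes[:10, 2] = MISSING
    t_miss = scan_pure_gxe(g, c, "SBP", "age", ScanConfig(n_perm=0))
    same = [0, 1, 3, 4]
    np.testing.assert_allclose(
        t_full.rows["i_score"][same], t_miss.rows["i_score"][same]
    )
    assert t_miss.rows["n_used"][2] == 70


class TestScanGOnly:
    def test_whole_cohort_subgroup_equals_overall_column(self):
        cfg = pgx.SimConfig(seed=4, n_samples=100, n_snps=10)
        g, c, _ = pgx.simulate_cohort(cfg)
        t = scan_g_only(g, c, "SBP", cfg=ScanConfig(n_perm=0))
        ok = t.rows.dropna(subset=["i_score"])
        np.testing.assert_allclose(
            ok["i_score"], ok["overall_i_score"], rtol=1e-9
        )

    def test_shuffled_trait_scores_sit_at_null_scale(self):
        cfg = pgx.SimConfig(seed=5, n_samples=300, n_snps=50)
        g, c, _ = pgx.simulate_cohort(cfg)
        rngl = np.random.default_rng(0)
        # average over several shuffles: one shared trait draw makes all
        # per-SNP scores move together
        score_sets = []
        for _ in range(10):
            c.traits["SBP"] = rngl.permutation(c.traits["SBP"])
            t = scan_g_only(g, c, "SBP", cfg=ScanConfig(n_perm=0))
            score_sets.append(t.rows["i_score"].to_numpy())
        ok = ~np.isnan(score_sets[0])
        scores = np.nanmean(score_sets, axis=0)[ok]
        # null scale for unbalanced cells is 1 - sum (n_i/n)^2 per SNP
        expected = []
        for j in np.flatnonzero(ok):
            counts = np.bincount(g.codes[:, j], minlength=3)
            expected.append(1 - np.sum((counts / counts.sum()) ** 2))
        assert scores.mean() == pytest.approx(np.mean(expected), rel=0.25)
        assert scores.max() < 3.0

    def test_too_small_subgroup_rejected(self):
        cfg = pgx.SimConfig(seed=6, n_samples=50, n_snps=4)
        g, c, _ = pgx.simulate_cohort(cfg)
        mask = np.zeros(50, dtype=bool)
        mask[:5] = True
        with pytest.raises(ValueError, match="subgroup"):
            scan_g_only(g, c, "SBP", subgroup_mask=mask)


class TestTallySignificance:
    def _table(self, pvals):
        import pandas as pd

        from puregxe.scan import ScanTable

        rows = pd.DataFrame(
            {
                "rank": range(1, len(pvals) + 1),
                "snp_id": [f"s{i}" for i in range(len(pvals))],
                "chrom": "3", "pos": 0, "n_used": 100,
                "i_score": 1.0, "p_perm": pvals,
                "n_perm": 1000, "flags": "",
            }
        )
        return ScanTable(rows=rows, mode="pure-GxE")

    def test_strict_threshold_counting(self):
        t = self._table([1e-4, 5e-4, 2e-3])
        tally = tally_significance(t, [1e-3, 1e-4, 1e-5])
        assert tally.counts == [2, 0, 0]
        assert tally.fractions == [2 / 3, 0.0, 0.0]

    def test_empty_and_all_one_tables(self):
        assert tally_significance(
            self._table([]), [1e-3]
        ).counts == [0]
        assert tally_significance(
            self._table([1.0, 1.0]), [1e-3, 1e-4]
        ).counts == [0, 0]

    def test_counts_monotone_over_nested_thresholds(self):
        rngl = np.random.default_rng(1)
        t = self._table(rngl.uniform(0, 1, 200).tolist())
        tally = tally_significance(t, [0.1, 0.05, 0.01, 0.001])
        assert all(
            a >= b for a, b in zip(tally.counts, tally.counts[1:])
        )


def test_scan_table_tsv_round_trip(tmp_path, interaction_cohort):
    from puregxe.scan import ScanTable

    g, c, _ = interaction_cohort
    t = scan_pure_gxe(g, c, "SBP", "age", ScanConfig(n_perm=0))
    path = tmp_path / "scan.tsv"
    t.to_tsv(path, meta={"seed": 1})
    back = ScanTable.from_tsv(path)
    assert back.mode == t.mode and back.env_name == t.env_name
    np.testing.assert_allclose(
        back.rows["i_score"], t.rows["i_score"], rtol=1e-6
    )


def test_score_and_pvalue_rankings_agree_in_top_tail():
    """On a signal-rich top tail the I-score ordering and the permutation
    p-value ordering coincide (ties in discrete null p-values make the
    comparison meaningless for pure-noise SNPs)."""
    from scipy.stats import spearmanr

    causal = [
        pgx.CausalSNP(j, "pure-interaction", beta)
        for j, beta in enumerate(np.linspace(8, 26, 12))
    ]
    cfg = pgx.SimConfig(seed=9, n_samples=130, n_snps=60, causal=causal)
    g, c, _ = pgx.simulate_cohort(cfg)
    t = scan_pure_gxe(g, c, "SBP", "age",
                      ScanConfig(n_perm=20000, seed=0))
    top = t.ranked().head(20)
    rho = spearmanr(top["i_score"], -np.log(top["p_perm"])).statistic
    assert rho > 0.9
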