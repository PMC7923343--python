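import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixpanel.freqs import AlleleFrequencyTable, minor_allele_frequency
from admixpanel.io import make_variant_table
from admixpanel.panels import (
    BREED_PROPORTION_SCHEDULE,
    PARENTAGE_SCHEDULE,
    PanelShortfallWarning,
    PruningSchedule,
    rank_by_score,
    select_panel_maf,
    select_panel_split,
    select_panel_weighted,
    stepwise_prune,
)


# --- independent oracles -------------------------------------------------

def greedy_prune_oracle(ranked, variants, stages):
    """Quadratic brute-force reimplementation of stage-wise greedy pruning."""
    vmap = {
        r.snp_id: (r.chromosome, int(r.position_bp))
        for r in variants.itertuples()
    }
    accepted = []

    def stage_distance(k):
        for cum, dist in stages:
            if cum is None or k < cum:
                return dist
        raise AssertionError

    for snp in ranked:
        c, p = vmap[snp]
        d = stage_distance(len(accepted))
        if all(cc != c or abs(p - pp) >= d for s in accepted
               for cc, pp in [vmap[s]]):
            accepted.append(snp)
    return accepted


def check_distances(snp_ids, variants, stages):
    """Independent stage-wise scan of every accepted same-chromosome pair."""
    vmap = {
        r.snp_id: (r.chromosome, int(r.position_bp))
        for r in variants.itertuples()
    }

    def stage_distance(k):
        for cum, dist in stages:
            if cum is None or k < cum:
                return dist
        raise AssertionError

    for k, snp in enumerate(snp_ids):
        d = stage_distance(k)
        c, p = vmap[snp]
        for prev in snp_ids[:k]:
            cc, pp = vmap[prev]
            if cc == c and abs(p - pp) < d:
                return False
    return True


def random_universe(rng, n_snps=200, n_chrom=5, span=50_000_000):
    chroms = []
    positions = []
    per = n_snps // n_chrom
    for c in range(n_chrom):
        pos = np.sort(rng.choice(span, size=per, replace=False) + 1)
        chroms += [str(c + 1)] * per
        positions += pos.tolist()
    n = len(chroms)
    variants = make_variant_table([f"s{j}" for j in range(n)], chroms, positions)
    freq = pd.DataFrame(
        {
            "EUT": rng.uniform(0.01, 0.99, n),
            "AFT": rng.uniform(0.01, 0.99, n),
            "BI": rng.uniform(0.01, 0.99, n),
            "crossbred": rng.uniform(0.01, 0.99, n),
        },
        index=variants["snp_id"].tolist(),
    )
    return AlleleFrequencyTable(freq=freq, variants=variants)


# --- schedule ------------------------------------------------------------

class TestPruningSchedule:
    def test_stage_lookup(self):
        s = BREED_PROPORTION_SCHEDULE
        assert s.distance_for(0) == 3_500_000
        assert s.distance_for(99) == 3_500_000
        assert s.distance_for(100) == 3_000_000
        assert s.distance_for(299) == 3_000_000
        assert s.distance_for(300) == 1_250_000
        assert s.distance_for(10_000) == 1_250_000

    def test_validation(self):
        with pytest.raises(ValueError, match="unbounded"):
            PruningSchedule(((100, 1_000_000),))
        with pytest.raises(ValueError, match="strictly increasing"):
            PruningSchedule(((100, 2), (50, 2), (None, 1)))
        with pytest.raises(ValueError, match="positive"):
            PruningSchedule(((None, 0),))


# --- ranking -------------------------------------------------------------

class TestRankByScore:
    def _variants(self):
        return make_variant_table(
            ["a", "b", "c"], ["1", "1", "2"], [100, 200, 50]
        )

    def test_descending_order(self):
        scores = pd.Series({"a": 0.9, "b": 0.5, "c": 0.7})
        assert rank_by_score(scores, self._variants()) == ["a", "c", "b"]

    def test_ties_broken_positionally(self):
        scores = pd.Series({"a": 0.5, "b": 0.5, "c": 0.5})
        assert rank_by_score(scores, self._variants()) == ["a", "b", "c"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        t = random_universe(rng, n_snps=50)
        scores = t.freq["EUT"]
        base = rank_by_score(scores, t.variants)
        shuffled = scores.sample(frac=1.0, random_state=1)
        assert rank_by_score(shuffled, t.variants) == base

    def test_nan_scores_dropped(self):
        scores = pd.Series({"a": np.nan, "b": 0.5, "c": 0.7})
        assert rank_by_score(scores, self._variants()) == ["c", "b"]


# --- pruning -------------------------------------------------------------

class TestStepwisePrune:
    def test_close_pair_rejected_in_first_stage(self):
        variants = make_variant_table(
            ["a", "b"], ["1", "1"], [1_000_000, 2_000_000]
        )
        out = stepwise_prune(["a", "b"], variants, BREED_PROPORTION_SCHEDULE)
        assert out == ["a"]

    def test_distinct_chromosomes_never_conflict(self):
        variants = make_variant_table(
            ["a", "b", "c"], ["1", "2", "3"], [100, 100, 100]
        )
        out = stepwise_prune(["a", "b", "c"], variants, BREED_PROPORTION_SCHEDULE)
        assert out == ["a", "b", "c"]

    def test_matches_oracle_on_toy_map(self):
        rng = np.random.default_rng(4)
        t = random_universe(rng, n_snps=30, n_chrom=2, span=20_000_000)
        ranked = rank_by_score(t.freq["EUT"], t.variants)
        stages = ((3, 4_000_000), (None, 1_000_000))
        schedule = PruningSchedule(stages)
        assert stepwise_prune(ranked, t.variants, schedule) == greedy_prune_oracle(
            ranked, t.variants, stages
        )

    def test_unknown_snp_rejected(self):
        variants = make_variant_table(["a"], ["1"], [100])
        with pytest.raises(KeyError, match="ghost"):
            stepwise_prune(["ghost"], variants, PARENTAGE_SCHEDULE)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_oracle_property_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        t = random_universe(rng, n_snps=100, n_chrom=3, span=30_000_000)
        ranked = rank_by_score(t.freq["AFT"], t.variants)
        stages = ((10, 3_500_000), (30, 3_000_000), (None, 1_250_000))
        schedule = PruningSchedule(stages)
        got = stepwise_prune(ranked, t.variants, schedule)
        assert got == greedy_prune_oracle(ranked, t.variants, stages)
        assert check_distances(got, t.variants, stages)


# --- weighted-pool panels ------------------------------------------------

class TestWeightedPanel:
    def test_half_weight_equals_plain_average_ranking(self):
        rng = np.random.default_rng(7)
        t = random_universe(rng, n_snps=100)
        panel = select_panel_weighted(t, w=0.5, sizes=(20,), schedule=None)
        scores = (t.freq["EUT"] - (t.freq["AFT"] + t.freq["BI"]) / 2).abs()
        assert panel.ids(20) == rank_by_score(scores, t.variants)[:20]

    def test_fixed_difference_snp_ranks_first(self):
        rng = np.random.default_rng(8)
        for w in (0.1, 0.5, 0.9):
            t = random_universe(rng, n_snps=50)
            t.freq.loc["s0", ["EUT", "AFT", "BI"]] = [1.0, 0.0, 0.0]
            panel = select_panel_weighted(t, w=w, sizes=(10,), schedule=None)
            assert panel.ids(1) == ["s0"]

    def test_matches_brute_force_score_and_prune(self):
        rng = np.random.default_rng(9)
        t = random_universe(rng, n_snps=200)
        sizes = (20, 50)
        panel = select_panel_weighted(t, w=0.7, sizes=sizes)
        pooled = 0.7 * t.freq["AFT"] + 0.3 * t.freq["BI"]
        scores = (t.freq["EUT"] - pooled).abs()
        ranked = rank_by_score(scores, t.variants)
        stages = BREED_PROPORTION_SCHEDULE.stages
        expected = greedy_prune_oracle(ranked, t.variants, stages)[:50]
        assert panel.ids() == expected

    def test_invalid_weight_rejected(self):
        rng = np.random.default_rng(10)
        t = random_universe(rng, n_snps=20)
        with pytest.raises(ValueError, match="w must be"):
            select_panel_weighted(t, w=1.0, sizes=(5,))


# --- MAF panels ----------------------------------------------------------

class TestMafPanel:
    def test_order_by_descending_maf(self):
        rng = np.random.default_rng(11)
        t = random_universe(rng, n_snps=50)
        panel = select_panel_maf(t, "crossbred", sizes=(10,), pruned=False)
        maf = minor_allele_frequency(t, "crossbred")
        got = [maf[s] for s in panel.ids(10)]
        assert got == sorted(got, reverse=True)

    def test_unpruned_prefix_is_top_k_maf(self):
        rng = np.random.default_rng(12)
        t = random_universe(rng, n_snps=80)
        panel = select_panel_maf(t, "crossbred", sizes=(15,), pruned=False)
        maf = minor_allele_frequency(t, "crossbred")
        top = set(maf.sort_values(ascending=False).index[:15])
        assert set(panel.ids(15)) == top

    def test_pruned_respects_one_mb(self):
        rng = np.random.default_rng(13)
        t = random_universe(rng, n_snps=200, span=30_000_000)
        panel = select_panel_maf(t, "crossbred", sizes=(30,), pruned=True)
        assert check_distances(panel.ids(), t.variants, PARENTAGE_SCHEDULE.stages)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(14)
        t = random_universe(rng, n_snps=200)
        panel = select_panel_maf(t, "crossbred", sizes=(40,), pruned=True)
        ranked = rank_by_score(minor_allele_frequency(t, "crossbred"), t.variants)
        expected = greedy_prune_oracle(ranked, t.variants, PARENTAGE_SCHEDULE.stages)[:40]
        assert panel.ids() == expected


# --- split panels --------------------------------------------------------

class TestSplitPanel:
    def test_rounding_rule_7_3(self):
        rng = np.random.default_rng(15)
        t = random_universe(rng, n_snps=200)
        panel = select_panel_split(t, f=0.7, sizes=(10,))
        sources = panel.table["source"].tolist()
        assert sources.count("AFTvsEUT") == math.ceil(0.7 * 10)
        assert sources.count("BIvsEUT") == 10 - math.ceil(0.7 * 10)

    def test_quota_holds_at_every_size(self):
        rng = np.random.default_rng(16)
        t = random_universe(rng, n_snps=300)
        sizes = (10, 20, 40)
        panel = select_panel_split(t, f=0.6, sizes=sizes)
        for n in sizes:
            sources = panel.table["source"].tolist()[:n]
            assert sources.count("AFTvsEUT") == math.ceil(0.6 * n)

    def test_high_fraction_approaches_pure_aft_ranking(self):
        rng = np.random.default_rng(17)
        t = random_universe(rng, n_snps=200)
        panel = select_panel_split(t, f=0.9, sizes=(10,))
        assert panel.table["source"].tolist().count("AFTvsEUT") == 9

    def test_snp_in_both_rankings_appears_once(self):
        rng = np.random.default_rng(18)
        t = random_universe(rng, n_snps=100)
        # make s0 the top SNP of both rankings
        t.freq.loc["s0", ["EUT", "AFT", "BI"]] = [1.0, 0.0, 0.0]
        panel = select_panel_split(t, f=0.5, sizes=(10,))
        assert panel.ids().count("s0") == 1
        assert len(set(panel.ids())) == len(panel.ids())

    def test_combined_panel_passes_schedule(self):
        rng = np.random.default_rng(19)
        t = random_universe(rng, n_snps=300, span=40_000_000)
        panel = select_panel_split(t, f=0.5, sizes=(30,))
        assert check_distances(
            panel.ids(), t.variants, BREED_PROPORTION_SCHEDULE.stages
        )


# --- panel invariants ----------------------------------------------------

class TestPanelInvariants:
    @pytest.mark.parametrize("mode", ["weighted", "split", "maf"])
    def test_nesting_exact(self, mode):
        rng = np.random.default_rng(20)
        t = random_universe(rng, n_snps=400, span=80_000_000)
        sizes = (10, 25, 50)
        if mode == "weighted":
            panel = select_panel_weighted(t, w=0.7, sizes=sizes)
        elif mode == "split":
            panel = select_panel_split(t, f=0.7, sizes=sizes)
        else:
            panel = select_panel_maf(t, "crossbred", sizes=sizes)
        ids = panel.ids()
        for n1, n2 in zip(sizes, sizes[1:]):
            assert ids[:n1] == panel.ids(n2)[:n1]

    def test_shortfall_warns(self):
        rng = np.random.default_rng(21)
        t = random_universe(rng, n_snps=20, n_chrom=1, span=5_000_000)
        with pytest.warns(PanelShortfallWarning):
            select_panel_weighted(t, w=0.5, sizes=(15,))

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(22)
        t = random_universe(rng, n_snps=100)
        panel = select_panel_weighted(t, w=0.3, sizes=(20,))
        path = tmp_path / "panel.tsv"
        panel.to_tsv(path)
        from admixpanel.panels import SnpPanel

        back = SnpPanel.from_tsv(path)
        assert back.ids() == panel.ids()
        np.testing.assert_allclose(back.table["score"], panel.table["score"])
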