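"""PSI computation, filters, DSI calling, and the A3SS analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import shortsplice as ss
from shortsplice.splicing import (
    binomial_lrt,
    frameshift_fraction,
    sample_id,
)


def _counts(rows):
    return pd.DataFrame(rows, columns=["intron_id", "sample_id", "inclusion_reads", "spliced_reads"])


class TestComputePsi:
    @pytest.mark.parametrize("inc,spl,expected", [(0, 40, 0.0), (10, 0, 1.0), (20, 10, 0.5)])
    def test_formula(self, inc, spl, expected):
        assert ss.compute_psi(inc, spl) == pytest.approx(expected)

    def test_no_reads_is_missing_not_zero(self):
        assert np.isnan(ss.compute_psi(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ss.compute_psi(-1, 5)

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_monotonicity(self, inc, spl):
        if inc + spl == 0:
            return
        psi = ss.compute_psi(inc, spl)
        assert 0.0 <= psi <= 1.0
        assert ss.compute_psi(inc + 1, spl) >= psi
        if spl + inc > 0:
            assert ss.compute_psi(inc, spl + 1) <= psi


class TestFilterPsi:
    def _table(self, psis, total=100):
        rows = []
        for r, p in enumerate(psis, 1):
            inc = round(total * 2 * p / (1 + p))
            rows.append(("i1", sample_id("symbiotic", 1, r), inc, total - inc))
        return ss.psi_table(_counts(rows))

    def test_low_junction_support_dropped(self):
        tab = ss.psi_table(_counts([("i1", sample_id("symbiotic", 1, r), 4, 5) for r in (1, 2, 3)]))
        assert (tab["junction_total"] == 9).all()
        assert ss.filter_psi(tab).empty

    def test_noisy_replicates_dropped(self):
        # replicate PSIs {0, 0, 0.5}: SD ~0.289 > 0.1
        rows = [
            ("i1", sample_id("symbiotic", 1, 1), 0, 100),
            ("i1", sample_id("symbiotic", 1, 2), 0, 100),
            ("i1", sample_id("symbiotic", 1, 3), 67, 33),  # psi ~0.5
        ]
        assert ss.filter_psi(ss.psi_table(_counts(rows))).empty

    def test_tight_replicates_retained(self):
        tab = self._table([0.05, 0.06, 0.07], total=1000)
        out = ss.filter_psi(tab)
        assert len(out) == 3
        assert (out["replicate_sd"] < 0.1).all()

    def test_incomplete_triples_dropped(self):
        rows = [("i1", sample_id("symbiotic", 1, r), 50, 50) for r in (1, 2)]
        assert ss.filter_psi(ss.psi_table(_counts(rows))).empty


class TestBinomialLrt:
    def test_matches_g_test(self, rng):
        # independent oracle: scipy's log-likelihood-ratio contingency test
        for _ in range(20):
            x1, n1 = rng.integers(1, 50), 60
            x2, n2 = rng.integers(1, 50), 80
            ours = float(binomial_lrt(x1, n1, x2, n2))
            table = [[x1, n1 - x1], [x2, n2 - x2]]
            g, p, _, _ = stats.chi2_contingency(table, correction=False, lambda_="log-likelihood")
            assert ours == pytest.approx(p, rel=1e-9)

    def test_zero_trials_gives_nan(self):
        assert np.isnan(binomial_lrt(0, 0, 5, 10))


class TestCallDsis:
    def _cohort_counts(self, inc_a, spl_a, inc_b, spl_b, n_introns=1):
        rows = []
        for i in range(n_introns):
            for r in (1, 2, 3):
                rows.append((f"i{i}", sample_id("symbiotic", 1, r), inc_a, spl_a))
                rows.append((f"i{i}", sample_id("aposymbiotic", 1, r), inc_b, spl_b))
        return _counts(rows)

    def test_identical_conditions_not_dsi(self):
        res = ss.call_dsis(self._cohort_counts(20, 80, 20, 80), "symbiotic", "aposymbiotic", 1)
        assert len(res) == 1
        assert res.loc[0, "delta_psi"] == 0.0
        assert not res.loc[0, "is_dsi"]

    def test_effect_size_gate_blocks_tiny_deltas(self):
        # ~0.05 PSI difference with overwhelming depth: p tiny, effect too small
        res = ss.call_dsis(
            self._cohort_counts(2000, 8000, 1530, 8470), "symbiotic", "aposymbiotic", 1
        )
        assert res.loc[0, "p_value"] < 1e-10
        assert abs(res.loc[0, "delta_psi"]) < 0.1
        assert not res.loc[0, "is_dsi"]

    def test_unsupported_introns_absent_not_p1(self):
        rows = [
            ("weak", sample_id("symbiotic", 1, 1), 1, 2),
            ("weak", sample_id("aposymbiotic", 1, 1), 1, 2),
            ("ok", sample_id("symbiotic", 1, 1), 30, 70),
            ("ok", sample_id("aposymbiotic", 1, 1), 30, 70),
        ]
        res = ss.call_dsis(_counts(rows), "symbiotic", "aposymbiotic", 1)
        assert res["intron_id"].tolist() == ["ok"]

    def test_direction_sign_convention(self):
        res = ss.call_dsis(
            self._cohort_counts(200, 100, 20, 280), "symbiotic", "aposymbiotic", 1
        )
        assert res.loc[0, "delta_psi"] > 0
        assert res.loc[0, "direction"] == "higher_symbiotic"


class TestPoolDsis:
    def _res(self, intron, tp, dpsi, is_dsi=True):
        return pd.DataFrame(
            {
                "intron_id": [intron], "timepoint": [tp], "delta_psi": [dpsi],
                "p_value": [1e-6], "fdr": [1e-5], "is_dsi": [is_dsi],
                "direction": ["higher_symbiotic" if dpsi > 0 else "higher_aposymbiotic"],
            }
        )

    def test_repeated_intron_counted_once(self):
        pooled, n_genes = ss.pool_dsis(
            [self._res("g1.i1", 1, 0.2), self._res("g1.i1", 2, 0.4)], {"g1.i1": "g1"}
        )
        assert len(pooled) == 1
        assert pooled.loc[0, "n_timepoints"] == 2
        assert pooled.loc[0, "delta_psi"] == 0.4  # strongest timepoint wins
        assert n_genes == 1

    def test_empty_inputs(self):
        pooled, n_genes = ss.pool_dsis([])
        assert pooled.empty and n_genes == 0

    def test_size_bound(self):
        frames = [self._res("a.i1", 1, 0.2), self._res("b.i1", 1, 0.3), self._res("a.i1", 2, 0.1)]
        pooled, _ = ss.pool_dsis(frames)
        assert len(pooled) == 2 <= sum(len(f) for f in frames)


class TestA3ss:
    def test_frame_classification(self):
        events = pd.DataFrame(
            {"intron_id": ["a", "b"], "canonical_3ss": [100, 100], "alternative_3ss": [103, 104]}
        )
        out, frac = ss.a3ss_frame_analysis(events)
        assert out.loc[0, "frameshift"] == False  # distance 3, in frame
        assert out.loc[1, "frameshift"] == True  # distance 4
        assert frac == 0.5

    def test_zero_distance_invalid(self):
        events = pd.DataFrame({"intron_id": ["a"], "canonical_3ss": [5], "alternative_3ss": [5]})
        with pytest.raises(ValueError):
            ss.a3ss_frame_analysis(events)

    def test_frameshift_share_from_event_counts(self):
        assert frameshift_fraction(479, 512) == pytest.approx(0.93555, abs=1e-4)


class TestDownstreamJunctionEnrichment:
    def _flags(self, yes, no, prefix):
        return pd.DataFrame(
            {
                "intron_id": [f"{prefix}{k}" for k in range(yes + no)],
                "has_downstream_junction": [True] * yes + [False] * no,
            }
        )

    def test_balanced_table_odds_ratio_one(self):
        a3 = self._flags(10, 10, "a")
        # background pool exactly the sample size: the draw is the whole pool
        bg = self._flags(10, 10, "b")
        odds, p, table = ss.downstream_junction_enrichment(a3, bg, seed=0)
        assert odds == pytest.approx(1.0)
        assert table.tolist() == [[10, 10], [10, 10]]

    def test_odds_ratio_arithmetic(self):
        a3 = self._flags(30, 10, "a")
        bg = self._flags(15, 25, "b")
        odds, p, _ = ss.downstream_junction_enrichment(a3, bg, seed=0)
        assert odds == pytest.approx(5.0)
        assert p < 0.01

    def test_depletion_direction(self):
        a3 = self._flags(0, 20, "a")  # e.g. all A3SS introns in terminal exons
        bg = self._flags(15, 5, "b")
        odds, _, _ = ss.downstream_junction_enrichment(a3, bg, seed=0)
        assert odds < 1.0

    def test_small_background_rejected(self):
        with pytest.raises(ValueError):
            ss.downstream_junction_enrichment(self._flags(5, 5, "a"), self._flags(2, 2, "b"), seed=0)


class TestRetentionSummary:
    def _retained(self, psis_by_intron):
        rows = []
        for intron, psis in psis_by_intron.items():
            for r, p in enumerate(psis, 1):
                inc = round(1000 * 2 * p / (1 + p))
                rows.append((intron, sample_id("symbiotic", 1, r), inc, 1000 - inc))
        return ss.filter_psi(ss.psi_table(_counts(rows)))

    def _features(self, introns):
        return pd.DataFrame(
            {
                "intron_id": introns,
                "gc": [0.15] * len(introns),
                "length": [24] * len(introns),
                "length_group": ["23-26"] * len(introns),
            }
        )

    def test_all_low_retention(self):
        tab = self._retained({"i1": [0.0, 0.0, 0.0], "i2": [0.01, 0.02, 0.01]})
        out = ss.retention_summary(tab, self._features(["i1", "i2"]))
        assert out["fraction_max_psi_below_threshold"] == 1.0

    def test_half_low_retention(self):
        tab = self._retained({"i1": [0.05, 0.05, 0.05], "i2": [0.5, 0.5, 0.5]})
        out = ss.retention_summary(tab, self._features(["i1", "i2"]))
        assert out["fraction_max_psi_below_threshold"] == 0.5

    def test_planted_gc_trend_is_monotone(self):
        # a cohort with no condition or factor effects isolates the planted
        # positive GC -> retention slope
        cohort = ss.generate_cohort(
            ss.CohortConfig(n_genes=150, n_factors=0, frac_dsi=0.0, seed=5)
        )
        retained = ss.filter_psi(ss.psi_table(cohort.counts))
        ref = cohort.config.reference
        genome = cohort.genome(ref)
        feats = []
        for g in cohort.genes[ref].values():
            gene = ss.GeneModel(g.gene_id, g.contig, g.strand, list(g.exons))
            feats.extend(ss.extract_introns(gene, genome))
        out = ss.retention_summary(retained, ss.feature_table(feats))
        bins = out["psi_by_gc_bin"]
        big = bins[bins["size"] >= 10]
        rho = stats.spearmanr(big.index.to_numpy(), big["mean"]).statistic
        assert len(big) >= 5
        assert rho > 0.5
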