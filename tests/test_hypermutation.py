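import math

import numpy as np
import pytest
from scipy import stats

from clonalpair.datasets import (
    HYPERMUTATED_PATIENTS,
    reference_loh_counts,
    reference_mutation_counts,
    reference_pair_table,
)
from clonalpair.hypermutation import (
    annotate_panel_hits,
    call_hypermutated,
    loh_association,
    paired_t,
    repair_gene_hits,
    two_sample_t,
)
from clonalpair.io_formats import MutationRecord
from clonalpair.scna import ScnaSummary

from oracles import paired_reference, pooled_reference, welch_reference


class TestCallHypermutated:
    @pytest.mark.parametrize("strategy", ["absolute", "fold_over_median"])
    def test_reference_metastases_flag_exactly_four(self, strategy):
        counts = reference_mutation_counts("CLM")
        calls = call_hypermutated(counts, strategy=strategy)
        flagged = {c.sample_id for c in calls if c.flagged}
        assert flagged == set(HYPERMUTATED_PATIENTS)

    def test_equal_counts_never_flag_under_fold_strategy(self):
        calls = call_hypermutated({f"S{i}": 50 for i in range(10)},
                                  strategy="fold_over_median")
        assert not any(c.flagged for c in calls)

    def test_flags_match_direct_comparison(self, rng):
        counts = {f"S{i}": int(rng.integers(0, 1200)) for i in range(50)}
        for strategy, param in [("absolute", 500.0),
                                ("fold_over_median", 5.0)]:
            threshold = (
                param if strategy == "absolute"
                else param * float(np.median(list(counts.values())))
            )
            calls = call_hypermutated(counts, strategy=strategy, param=param)
            for c in calls:
                assert c.flagged == (counts[c.sample_id] > threshold)

    def test_monotone_in_threshold(self, rng):
        counts = {f"S{i}": int(rng.integers(0, 1000)) for i in range(30)}
        flags = [
            {c.sample_id for c in call_hypermutated(counts, param=p) if c.flagged}
            for p in (100, 300, 500, 700)
        ]
        for lower, higher in zip(flags, flags[1:]):
            assert higher <= lower

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            call_hypermutated({})


class TestRepairGeneHits:
    def test_missense_mlh1_hits_repair_panel(self):
        muts = [MutationRecord("S", "chr3", 100, "A", "G", "MLH1", "nonsynonymous")]
        repair, polymerase = repair_gene_hits(muts)
        assert repair == {"MLH1"} and polymerase == set()

    def test_synonymous_msh2_does_not_count(self):
        muts = [MutationRecord("S", "chr2", 100, "A", "G", "MSH2", "synonymous")]
        assert repair_gene_hits(muts) == (frozenset(), frozenset())

    def test_polymerase_hit_and_annotation(self):
        muts = [
            MutationRecord("S1", "chr12", 100, "A", "G", "POLE", "nonsynonymous"),
            MutationRecord("S2", "chr1", 100, "A", "G", "G001", "nonsynonymous"),
        ]
        calls = call_hypermutated({"S1": 900, "S2": 30})
        annotated = annotate_panel_hits(calls, muts)
        by_id = {c.sample_id: c for c in annotated}
        assert by_id["S1"].polymerase_genes_hit == {"POLE"}
        assert by_id["S2"].polymerase_genes_hit == frozenset()


class TestTwoSampleT:
    def test_identical_groups_give_null_result(self):
        res = two_sample_t([1, 2, 3], [1, 2, 3], variant="welch")
        assert res.t_statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_reference_loh_split_reproduces_published_association(self):
        loh = reference_loh_counts("CLM")
        hyper = [loh[p] for p in HYPERMUTATED_PATIENTS]
        other = [v for p, v in loh.items() if p not in HYPERMUTATED_PATIENTS]
        assert sorted(hyper) == [145, 146, 160, 164]
        res = two_sample_t(hyper, other, variant="welch")
        assert f"{res.p_value:.1e}" == "2.8e-09"
        assert res.p_value == pytest.approx(2.782e-09, rel=0.01)

    def test_pooled_variant_matches_textbook_df(self):
        res = two_sample_t([1.0, 2.0, 4.0], [2.0, 5.0, 9.0, 1.0], variant="pooled")
        assert res.degrees_of_freedom == 5.0
        t_sp, p_sp = stats.ttest_ind([1.0, 2.0, 4.0], [2.0, 5.0, 9.0, 1.0],
                                     equal_var=True)
        assert res.t_statistic == pytest.approx(t_sp)
        assert res.p_value == pytest.approx(p_sp)

    def test_symmetric_under_group_exchange(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=5)
        r1 = two_sample_t(a, b)
        r2 = two_sample_t(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_zero_variance_limits(self):
        equal = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert equal.p_value == 1.0 and equal.degenerate
        unequal = two_sample_t([2.0, 2.0], [3.0, 3.0])
        assert unequal.p_value == 0.0 and unequal.degenerate

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])

    @pytest.mark.parametrize("variant,reference", [
        ("welch", welch_reference), ("pooled", pooled_reference),
    ])
    def test_against_high_precision_oracle(self, rng, variant, reference):
        for _ in range(60):
            na, nb = int(rng.integers(2, 15)), int(rng.integers(2, 15))
            a = rng.normal(rng.normal(), 1 + rng.random(), size=na)
            b = rng.normal(rng.normal(), 1 + rng.random(), size=nb)
            res = two_sample_t(a, b, variant=variant)
            t_ref, df_ref, p_ref = reference(a, b)
            assert res.t_statistic == pytest.approx(t_ref, rel=1e-10)
            assert res.degrees_of_freedom == pytest.approx(df_ref, rel=1e-10)
            assert abs(res.p_value - p_ref) / p_ref < 1e-8


class TestPairedT:
    def test_identical_lists_null(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0 and res.p_value == 1.0

    def test_grouped_reference_pairs_burden_comparison(self):
        """The grouped pairs' burden difference is non-significant (reported,
        not pinned to the published rounded figure)."""
        table = reference_pair_table()
        grouped = table[table.grouped]
        res = paired_t(grouped.crc_mutations.tolist(), grouped.clm_mutations.tolist())
        assert res.degrees_of_freedom == 7
        assert 0.0 < res.p_value < 1.0
        assert res.p_value > 0.05  # no significant difference within grouped pairs

    def test_ungrouped_reference_pairs_differ_significantly(self):
        table = reference_pair_table()
        ungrouped = table[~table.grouped]
        res = paired_t(ungrouped.crc_mutations.tolist(),
                       ungrouped.clm_mutations.tolist())
        assert res.p_value < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0])

    def test_against_high_precision_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 20))
            a = rng.normal(size=n)
            b = a + rng.normal(0.3, 1.0, size=n)
            res = paired_t(a, b)
            t_ref, df_ref, p_ref = paired_reference(a, b)
            assert res.t_statistic == pytest.approx(t_ref, rel=1e-10)
            assert abs(res.p_value - p_ref) / p_ref < 1e-8


def _summary(sample_id, n_loh):
    return ScnaSummary(sample_id, 0, 0, 0, 0, n_loh)


class TestLohAssociation:
    def test_reference_cohort_association(self):
        loh = reference_loh_counts("CLM")
        counts = reference_mutation_counts("CLM")
        calls = call_hypermutated(counts, strategy="absolute")
        summaries = [_summary(p, v) for p, v in loh.items()]
        res = loh_association(summaries, calls, variant="welch")
        assert res.p_value == pytest.approx(2.782e-09, rel=0.01)

    def test_equal_loh_counts_give_p_one(self):
        calls = call_hypermutated({"A": 900, "B": 800, "C": 10, "D": 20})
        summaries = [_summary(s, 50) for s in "ABCD"]
        res = loh_association(summaries, calls)
        assert res.p_value == 1.0

    def test_coupling_strength_lowers_p(self):
        """Stronger LOH-hypermutator coupling should shrink the p-value."""
        rng = np.random.default_rng(7)
        calls = call_hypermutated(
            {f"H{i}": 900 for i in range(5)} | {f"L{i}": 50 for i in range(10)}
        )
        p_values = []
        for shift in (0.0, 30.0, 120.0):
            summaries = [
                _summary(f"H{i}", int(20 + shift + rng.normal(0, 5))) for i in range(5)
            ] + [_summary(f"L{i}", int(20 + rng.normal(0, 5))) for i in range(10)]
            p_values.append(loh_association(summaries, calls).p_value)
        assert p_values[2] < p_values[1] < p_values[0]

    def test_small_group_rejected(self):
        calls = call_hypermutated({"A": 900, "B": 10, "C": 20})
        summaries = [_summary(s, 10) for s in "ABC"]
        with pytest.raises(ValueError):
            loh_association(summaries, calls)

    def test_missing_call_rejected(self):
        calls = call_hypermutated({"A": 900})
        with pytest.raises(ValueError):
            loh_association([_summary("B", 5)], calls)
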