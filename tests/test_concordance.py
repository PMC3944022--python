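import numpy as np
import pytest

from clonalpair.concordance import (
    driver_concordance,
    gene_discordance_rate,
    gene_mutation_frequency,
    mutation_spectrum,
    pair_concordance,
    shared_mutations,
    shared_percentage,
)
from clonalpair.datasets import reference_pair_table
from clonalpair.io_formats import CohortManifest, MutationRecord, PatientPair
from clonalpair.panels import DRIVER_PANEL, GenePanel

from conftest import random_mutation


def _mut(sample, chrom, pos, ref="A", alt="G", gene="GX", effect="nonsynonymous"):
    return MutationRecord(sample, chrom, pos, ref, alt, gene, effect)


class TestSharedMutations:
    def test_disjoint_lists_share_nothing(self):
        a = [_mut("A", "chr1", 10)]
        b = [_mut("B", "chr1", 20)]
        assert shared_mutations(a, b) == set()

    def test_identical_lists_share_everything(self):
        a = [_mut("A", "chr1", i) for i in range(1, 6)]
        b = [_mut("B", "chr1", i) for i in range(1, 6)]
        assert len(shared_mutations(a, b)) == 5

    def test_within_sample_duplicates_collapse(self):
        a = [_mut("A", "chr1", 10), _mut("A", "chr1", 10)]
        b = [_mut("B", "chr1", 10)]
        assert len(shared_mutations(a, b)) == 1

    def test_planted_overlap_matches_double_loop_oracle(self, rng):
        a = [random_mutation(rng, "A") for _ in range(60)]
        b = [random_mutation(rng, "B") for _ in range(60)]
        k = 17
        for i in range(k):  # plant exact key overlap
            src = a[i]
            b[i] = MutationRecord("B", src.chromosome, src.position,
                                  src.ref_allele, src.alt_allele, src.gene,
                                  src.effect)
        brute = {
            (x.chromosome, x.position, x.ref_allele, x.alt_allele)
            for x in a
            for y in b
            if (x.chromosome, x.position, x.ref_allele, x.alt_allele)
            == (y.chromosome, y.position, y.ref_allele, y.alt_allele)
        }
        assert shared_mutations(a, b) == brute
        assert len(brute) >= k


class TestSharedPercentage:
    @pytest.mark.parametrize(
        "n_a,n_b,s,expected",
        [(72, 65, 48, 53.9), (55, 63, 36, 43.9), (66, 77, 49, 52.1)],
    )
    def test_reference_pairs_reproduce_printed_values(self, n_a, n_b, s, expected):
        assert shared_percentage(n_a, n_b, s) == pytest.approx(expected, abs=0.05)

    def test_zero_shared_and_empty_inputs(self):
        assert shared_percentage(10, 10, 0) == 0.0
        assert shared_percentage(0, 0, 0) == 0.0

    def test_symmetric_and_bounded(self, rng):
        for _ in range(200):
            n_a, n_b = int(rng.integers(0, 100)), int(rng.integers(0, 100))
            s = int(rng.integers(0, min(n_a, n_b) + 1))
            p = shared_percentage(n_a, n_b, s)
            assert p == shared_percentage(n_b, n_a, s)
            assert 0.0 <= p <= 100.0
            if p == 100.0:
                assert n_a == n_b == s > 0

    def test_jaccard_backsolves_every_reference_pair(self):
        """An integer shared count reproduces each printed percentage."""
        for row in reference_pair_table().itertuples():
            n_a, n_b = row.crc_mutations, row.clm_mutations
            candidates = [
                s
                for s in range(min(n_a, n_b) + 1)
                if abs(shared_percentage(n_a, n_b, s) - row.shared_pct) <= 0.05
            ]
            assert candidates, f"no integer S for pair {row.patient}"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            shared_percentage(-1, 5, 0)
        with pytest.raises(ValueError):
            shared_percentage(5, 5, 6)


class TestDriverConcordance:
    def test_same_key_is_shared(self):
        a = [_mut("A", "chr12", 100, gene="KRAS")]
        b = [_mut("B", "chr12", 100, gene="KRAS")]
        shared, discordant = driver_concordance(a, b)
        assert shared == {"KRAS"} and discordant == set()

    def test_different_positions_are_discordant(self):
        a = [_mut("A", "chr12", 100, gene="KRAS")]
        b = [_mut("B", "chr12", 200, gene="KRAS")]
        shared, discordant = driver_concordance(a, b)
        assert shared == set() and discordant == {"KRAS"}

    def test_synonymous_calls_do_not_count(self):
        a = [_mut("A", "chr12", 100, gene="KRAS", effect="synonymous")]
        b = [_mut("B", "chr12", 100, gene="KRAS", effect="synonymous")]
        assert driver_concordance(a, b) == (set(), set())

    def test_random_planting_matches_exhaustive_oracle(self, rng):
        genes = sorted(DRIVER_PANEL.genes)
        for _ in range(30):
            a, b = [], []
            for sample, muts in (("A", a), ("B", b)):
                for _ in range(rng.integers(0, 10)):
                    muts.append(
                        _mut(sample, "chr1", int(rng.integers(1, 30)),
                             gene=genes[rng.integers(len(genes))])
                    )
            shared, discordant = driver_concordance(a, b)
            for gene in genes:
                keys_a = {m.key for m in a if m.gene == gene}
                keys_b = {m.key for m in b if m.gene == gene}
                if keys_a & keys_b:
                    assert gene in shared
                elif keys_a or keys_b:
                    assert gene in discordant
                else:
                    assert gene not in shared and gene not in discordant
            assert shared & discordant == set()


def _cohort(pair_muts):
    """pair_muts: list of (primary mutation list, metastasis mutation list)."""
    patients, mutations = [], []
    for i, (pri, met) in enumerate(pair_muts):
        pid = f"P{i}"
        patients.append(PatientPair(pid, f"{pid}-PRI", f"{pid}-MET"))
        for m in pri:
            mutations.append(MutationRecord(f"{pid}-PRI", m.chromosome, m.position,
                                            m.ref_allele, m.alt_allele, m.gene, m.effect))
        for m in met:
            mutations.append(MutationRecord(f"{pid}-MET", m.chromosome, m.position,
                                            m.ref_allele, m.alt_allele, m.gene, m.effect))
    return mutations, CohortManifest(patients=patients)


class TestGeneDiscordance:
    def test_three_of_six_informative_pairs_discordant(self):
        # 3 concordant KRAS pairs, 3 discordant, 2 uninformative
        pairs = []
        for i in range(3):
            m = _mut("x", "chr12", 100 + i, gene="KRAS")
            pairs.append(([m], [m]))
        for i in range(3):
            pairs.append(
                ([_mut("x", "chr12", 200 + i, gene="KRAS")],
                 [_mut("x", "chr12", 300 + i, gene="KRAS")])
            )
        pairs.extend([([], []), ([_mut("x", "chr1", 5, gene="APC")], [])])
        mutations, manifest = _cohort(pairs)
        n_disc, n_inf, rate = gene_discordance_rate(mutations, manifest, "KRAS")
        assert (n_disc, n_inf, rate) == (3, 6, 0.5)

    def test_all_concordant_gives_zero_rate(self):
        m = _mut("x", "chr12", 100, gene="KRAS")
        mutations, manifest = _cohort([([m], [m])] * 4)
        assert gene_discordance_rate(mutations, manifest, "KRAS")[2] == 0.0

    def test_zero_informative_pairs_flagged_undefined(self):
        mutations, manifest = _cohort([([], [])])
        n_disc, n_inf, rate = gene_discordance_rate(mutations, manifest, "KRAS")
        assert n_inf == 0 and rate is None


class TestGeneFrequency:
    def test_eleven_of_fifteen_is_seventy_three_percent(self):
        pairs = []
        for i in range(15):
            pri = [_mut("x", "chr5", 1000 + i, gene="APC")] if i < 11 else []
            pairs.append((pri, []))
        mutations, manifest = _cohort(pairs)
        freq = gene_mutation_frequency(mutations, manifest, "APC", "primary")
        assert round(freq) == 73
        assert gene_mutation_frequency(mutations, manifest, "APC", "metastasis") == 0.0

    def test_synonymous_only_does_not_count(self):
        pairs = [([_mut("x", "chr5", 1, gene="APC", effect="synonymous")], [])]
        mutations, manifest = _cohort(pairs)
        assert gene_mutation_frequency(mutations, manifest, "APC", "primary") == 0.0

    def test_unknown_role_rejected(self):
        mutations, manifest = _cohort([([], [])])
        with pytest.raises(ValueError):
            gene_mutation_frequency(mutations, manifest, "APC", "tumour")


class TestSpectrum:
    def test_purine_reference_collapses_to_complement(self):
        spec = mutation_spectrum([_mut("A", "chr1", 1, ref="G", alt="T")])
        assert spec["C>A"] == 1.0

    def test_uniform_over_all_twelve_raw_changes(self):
        muts = []
        pos = 1
        for ref in "ACGT":
            for alt in "ACGT":
                if ref != alt:
                    muts.append(_mut("A", "chr1", pos, ref=ref, alt=alt))
                    pos += 1
        spec = mutation_spectrum(muts)
        for v in spec.values():
            assert v == pytest.approx(1 / 6)

    def test_indels_excluded_and_empty_input_zero(self):
        spec = mutation_spectrum(
            [_mut("A", "chr1", 1, ref="-", alt="T", effect="frameshift_indel")]
        )
        assert all(v == 0.0 for v in spec.values())

    def test_random_substitutions_match_direct_tally(self, rng):
        complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
        muts = [random_mutation(rng, "A") for _ in range(1000)]
        spec = mutation_spectrum(muts)
        tally = {}
        total = 0
        for m in muts:
            if not m.is_substitution:
                continue
            ref, alt = m.ref_allele, m.alt_allele
            if ref in "AG":
                ref, alt = complement[ref], complement[alt]
            tally[f"{ref}>{alt}"] = tally.get(f"{ref}>{alt}", 0) + 1
            total += 1
        for cls, prop in spec.items():
            assert prop == pytest.approx(tally.get(cls, 0) / total)

    def test_proportions_sum_to_one(self, rng):
        muts = [random_mutation(rng, "A") for _ in range(200)]
        if any(m.is_substitution for m in muts):
            assert sum(mutation_spectrum(muts).values()) == pytest.approx(1.0)


class TestPairConcordance:
    def test_counts_and_invariant(self, rng):
        trunk = [random_mutation(rng, "x") for _ in range(10)]
        pri = trunk + [random_mutation(rng, "x") for _ in range(5)]
        met = trunk + [random_mutation(rng, "x") for _ in range(8)]
        c = pair_concordance("P1", pri, met)
        assert c.n_shared >= 10
        assert c.n_shared <= min(c.n_primary, c.n_metastasis)
        expected = 100 * c.n_shared / (c.n_primary + c.n_metastasis - c.n_shared)
        assert c.shared_pct == pytest.approx(expected)
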