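import math

import pytest

from kmerbg import (
    BackgroundSpec,
    MarkovBackground,
    SequenceRecord,
    SequenceSet,
    ak1_expected,
    ak1_score,
    ak1_scores,
    build_count_table,
    c0c1_score,
    markov_expected,
    markov_score,
    mismatch_neighbors,
    mono_frequencies,
    reverse_complement,
    score_sequences,
)

from .conftest import make_set


def _ak1_inputs(seqs, k, strand="forward"):
    return (
        build_count_table(seqs, k, strand),
        build_count_table(seqs, k - 1, strand),
        mono_frequencies(seqs, strand),
    )


class TestAk1:
    def test_homopolymer_closed_form_forward(self):
        """On A^6 (forward strand) the model is exact: E1=E2=O, F=1, Z=0."""
        seqs = make_set("AAAAAA")
        table_k, table_km1, mono = _ak1_inputs(seqs, 3, "forward")
        e1, e2 = ak1_expected("AAA", table_k, table_km1, mono)
        assert e1 == e2 == 2.0 == table_k.get("AAA")
        rec = ak1_score("AAA", table_k, table_km1, mono)
        assert rec.fold_1 == rec.fold_2 == rec.fold == 1.0
        assert rec.zscore == 0.0
        assert rec.pvalue == pytest.approx(0.5)

    def test_homopolymer_both_strands_fold_two(self):
        """Strand aggregation halves both subword and base frequencies for a
        pure homopolymer, so the expected count is O/2 and F = 2 exactly."""
        seqs = make_set("A" * 50)
        table_k, table_km1, mono = _ak1_inputs(seqs, 3, "both")
        rec = ak1_score("AAA", table_k, table_km1, mono)
        assert rec.fold == pytest.approx(2.0)

    def test_unseen_prefix_gives_zero_expectation(self):
        seqs = make_set("ACGTACGT")
        table_k, table_km1, mono = _ak1_inputs(seqs, 3, "forward")
        e1, e2 = ak1_expected("TTT", table_k, table_km1, mono)
        assert e1 == 0.0

    def test_fold_consistency_invariants(self, random_10kb):
        table_k, table_km1, mono = _ak1_inputs(random_10kb, 4, "both")
        for rec in ak1_scores(table_k, table_km1, mono):
            assert rec.defined
            assert rec.fold_1 == pytest.approx(rec.observed / rec.expected_1)
            assert rec.fold_2 == pytest.approx(rec.observed / rec.expected_2)
            assert rec.fold == pytest.approx((rec.fold_1 + rec.fold_2) / 2)
            assert rec.expected_mean == pytest.approx(
                (rec.expected_1 + rec.expected_2) / 2
            )

    def test_law_of_large_numbers_on_uniform_1mb(self, uniform_1mb):
        """For iid uniform input, observed/expected is near 1 for any word."""
        table_k, table_km1, mono = _ak1_inputs(uniform_1mb, 4, "both")
        rec = ak1_score("ATCG", table_k, table_km1, mono)
        assert 0.8 <= rec.observed / rec.expected_mean <= 1.2

    def test_z_increasing_in_observed(self):
        """At fixed expectations, Z grows with the observed count."""
        seqs = make_set("AAAAAA")
        table_k, table_km1, mono = _ak1_inputs(seqs, 3, "forward")
        from kmerbg.backgrounds import _ak1_record

        z_values = [
            _ak1_record("AAA", o, 2.0, 2.0, 10, "poisson").zscore for o in (1, 2, 5)
        ]
        assert z_values == sorted(z_values)
        assert _ak1_record("AAA", 2, 2.0, 2.0, 10, "poisson").zscore == 0.0

    def test_binomial_variance_option(self):
        seqs = make_set("AAAAAA")
        table_k, table_km1, mono = _ak1_inputs(seqs, 3, "forward")
        rec = ak1_score("AAA", table_k, table_km1, mono, variance="binomial")
        assert rec.zscore == 0.0  # O == E regardless of variance model

    def test_reverse_complement_invariance(self, random_10kb):
        rc_set = SequenceSet(
            records=[
                SequenceRecord(id=r.id, residues=reverse_complement(r.residues))
                for r in random_10kb
            ],
            label="rc",
        )
        fwd = {r.kmer: r for r in score_sequences(random_10kb, 3)}
        rev = {r.kmer: r for r in score_sequences(rc_set, 3)}
        assert set(fwd) == set(rev)
        for w in fwd:
            assert fwd[w].fold == pytest.approx(rev[w].fold)
            assert fwd[w].zscore == pytest.approx(rev[w].zscore)


class TestC0C1:
    def test_neighborhood_size_and_content(self):
        nbrs = mismatch_neighbors("ATGCCGTA")
        assert len(nbrs) == 24  # 3k with k=8
        assert len(set(nbrs)) == 24
        assert "ATGCCGTA" not in nbrs
        assert all(sum(a != b for a, b in zip(n, "ATGCCGTA")) == 1 for n in nbrs)

    def test_degenerate_neighborhood_undefined(self):
        table = build_count_table(make_set("ACGT" * 20), 4, "both")
        rec = c0c1_score("ACGT", table)
        assert not rec.defined
        assert not rec.significant

    def test_single_expectation_invariant(self, random_10kb):
        table = build_count_table(random_10kb, 3, "both")
        rec = c0c1_score("ACG", table)
        assert rec.expected_1 == rec.expected_2 == rec.expected_mean
        assert rec.fold_1 == rec.fold_2 == rec.fold

    def test_fold_near_one_on_uniform_1mb(self, uniform_1mb):
        table = build_count_table(uniform_1mb, 4, "both")
        rec = c0c1_score("ATCG", table)
        assert 0.8 <= rec.fold <= 1.2

    def test_pseudocount_defines_empty_neighborhood(self):
        table = build_count_table(make_set("ACGT" * 20), 4, "both")
        rec = c0c1_score("ACGT", table, pseudocount=0.5)
        assert rec.defined and rec.fold > 1


class TestMarkov:
    def test_order0_is_bernoulli_composition(self, random_10kb):
        """m=0 reduces to M_k times the product of base frequencies."""
        mono = mono_frequencies(random_10kb, "both")
        table_k = build_count_table(random_10kb, 4, "both")
        e = markov_expected("ACGT", random_10kb, 0)
        product = 1.0
        for b in "ACGT":
            product *= mono[b]
        assert e == pytest.approx(table_k.total_occurrences * product, rel=1e-9)

    def test_order0_expectations_sum_to_total(self, random_10kb):
        """Expectations over all 16 dimers sum to M_2 (normalization)."""
        bg = MarkovBackground(random_10kb, 2, 0)
        total = sum(
            bg.expected(a + b) for a in "ACGT" for b in "ACGT"
        )
        assert total == pytest.approx(bg.table_k.total_occurrences, abs=1e-9)

    def test_maximal_order_self_consistent_on_homopolymer(self):
        """m = k-2 on A^6: the chain reproduces the observed count exactly."""
        seqs = make_set("AAAAAA")
        e = markov_expected("AAA", seqs, 1)
        table = build_count_table(seqs, 3, "both")
        assert e == pytest.approx(table.get("AAA"))
        rec = markov_score("AAA", seqs, 1)
        assert rec.zscore == pytest.approx(0.0, abs=1e-9)

    def test_order_too_high_rejected(self):
        with pytest.raises(ValueError, match="order too high"):
            markov_expected("ACGT", make_set("ACGTACGT"), 3)

    def test_binomial_tail_matches_direct_summation(self):
        """The record's p-value equals a hand-summed binomial upper tail."""
        seqs = make_set("ACGTAGGATCGCA")
        rec = markov_score("ACG", seqs, 0)
        table = build_count_table(seqs, 3, "both")
        m = table.total_occurrences
        pr = rec.expected_mean / m
        # direct summation of the lower tail, complemented
        lower = sum(
            math.comb(m, i) * pr**i * (1 - pr) ** (m - i) for i in range(rec.observed)
        )
        assert rec.pvalue == pytest.approx(1.0 - lower, abs=1e-9)

    def test_certain_event_tail_is_one(self):
        """If every trial is a success the upper tail at O = M is 1."""
        seqs = make_set("AAAAAA")
        rec = markov_score("AAA", seqs, 0)
        # not the degenerate case, but tail is bounded
        assert 0.0 <= rec.pvalue <= 1.0
        import scipy.stats as sps

        assert sps.binom.sf(9, 10, 1.0) == pytest.approx(1.0)


class TestBackgroundSpec:
    def test_markov_requires_order(self):
        with pytest.raises(ValueError):
            BackgroundSpec(model="markov")

    def test_order_only_for_markov(self):
        with pytest.raises(ValueError):
            BackgroundSpec(model="ak1", markov_order=2)

    def test_binomial_only_for_markov(self):
        with pytest.raises(ValueError):
            BackgroundSpec(model="ak1", rank_statistic="binomial")

    def test_dispatcher_routes_models(self, random_10kb):
        for spec in (
            BackgroundSpec("ak1"),
            BackgroundSpec("c0c1"),
            BackgroundSpec("markov", markov_order=1, rank_statistic="zscore"),
        ):
            records = score_sequences(random_10kb, 3, spec)
            assert len(records) == 64  # all 3-mers observed in 10 kb
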