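"""Domain-pair association scoring against an independent brute force."""

import math
import random

import pytest

from mechnet.annotations_io import DomainHit, Evidence, PPIRecord
from mechnet.ddi_stats import (UNOBSERVED_SCORE, association_score,
                               call_enrichment, count_pairs, pair_pvalue,
                               score_all_pairs, score_pair,
                               select_nonredundant, DomainPairStats,
                               PairCounts)


def ppi(a, b, n_sources=2):
    return PPIRecord(pair=(a, b),
                     evidence=[Evidence(f"s{i}", "m", "low")
                               for i in range(n_sources)])


def hit(protein, domain_id):
    return DomainHit(protein=protein, domain_id=domain_id,
                     domain_name=domain_id, start=1, end=10, evalue=1e-6)


def brute_force_counts(ppis, domains):
    """Independent double-loop oracle for co-occurrence counting."""
    doms = {}
    for d in domains:
        doms.setdefault(d.protein, set()).add(d.domain_id)
    pairs = sorted({rec.pair for rec in ppis})
    universe = sorted({p for pr in pairs for p in pr})
    vocabulary = sorted({d.domain_id for d in domains})
    n_by_dom = {a: sum(1 for p in universe if a in doms.get(p, set()))
                for a in vocabulary}
    observed = {}
    for ai, a in enumerate(vocabulary):
        for b in vocabulary[ai:]:
            n = 0
            for (p, q) in pairs:
                dp, dq = doms.get(p, set()), doms.get(q, set())
                if (a in dp and b in dq) or (a in dq and b in dp):
                    n += 1
            if n:
                observed[(a, b)] = n
    return universe, pairs, n_by_dom, observed


class TestSelectNonredundant:
    def test_two_source_threshold(self):
        kept = select_nonredundant([ppi("A", "B", 1), ppi("C", "D", 2)])
        assert [r.pair for r in kept] == [("C", "D")]

    def test_duplicate_evidence_counts_once(self):
        rec = PPIRecord(pair=("A", "B"),
                        evidence=[Evidence("s1", "m", "low"),
                                  Evidence("s1", "m", "high")])
        assert select_nonredundant([rec]) == []

    def test_six_pair_fixture(self):
        records = [ppi("A", "B", 2), ppi("A", "C", 1), ppi("B", "C", 3),
                   ppi("A", "D", 2), ppi("C", "D", 1), ppi("B", "D", 4)]
        assert len(select_nonredundant(records)) == 4


class TestCountPairs:
    def test_single_interaction(self):
        counts = count_pairs([ppi("P", "Q")], [hit("P", "a"), hit("Q", "b")])
        assert counts.observed_by_pair == {("a", "b"): 1}
        assert counts.n_proteins == 2 and counts.n_pairs == 1

    def test_presence_not_multiplicity(self):
        domains = [hit("P", "a"),
                   DomainHit("P", "a", "a", 20, 30, 1e-6),  # second copy
                   hit("Q", "b")]
        counts = count_pairs([ppi("P", "Q")], domains)
        assert counts.observed_by_pair[("a", "b")] == 1

    def test_homodimer_counts_own_architecture(self):
        counts = count_pairs([ppi("P", "P")], [hit("P", "a"),
                                               DomainHit("P", "b", "b", 20, 30, 1e-6)])
        assert counts.observed_by_pair[("a", "b")] == 1
        assert counts.observed_by_pair[("a", "a")] == 1

    def test_mixed_fixture_equals_brute_force(self):
        domains = [hit("P1", "a"), hit("P1", "b"), hit("P2", "a"),
                   hit("P3", "b"), hit("P4", "c"), hit("P5", "a"),
                   DomainHit("P5", "c", "c", 30, 40, 1e-6)]
        ppis = [ppi("P1", "P2"), ppi("P1", "P3"), ppi("P2", "P4"),
                ppi("P3", "P5"), ppi("P4", "P5")]
        counts = count_pairs(ppis, domains)
        universe, pairs, n_by_dom, observed = brute_force_counts(ppis, domains)
        assert counts.n_proteins == len(universe)
        assert counts.n_pairs == len(pairs)
        assert counts.observed_by_pair == observed
        for dom, n in n_by_dom.items():
            assert counts.protein_count_by_domain.get(dom, 0) == n


class TestAssociationScore:
    def _counts(self):
        return PairCounts(
            n_proteins=10, n_pairs=12,
            protein_count_by_domain={"a": 4, "b": 5},
            observed_by_pair={("a", "b"): 6})

    def test_hand_computed_value(self):
        # ln((6/12) / (2 * 0.4 * 0.5)) = ln(1.25)
        score = association_score(self._counts(), ("a", "b"))
        assert score == pytest.approx(math.log(1.25), abs=1e-12)

    def test_unobserved_sentinel(self):
        counts = self._counts()
        counts.observed_by_pair = {}
        assert association_score(counts, ("a", "b")) == UNOBSERVED_SCORE

    def test_symmetry(self):
        counts = self._counts()
        assert association_score(counts, ("a", "b")) == \
            association_score(counts, ("b", "a"))

    def test_unknown_domain_raises(self):
        with pytest.raises(KeyError, match="zz"):
            association_score(self._counts(), ("a", "zz"))

    def test_log_base_configurable(self):
        nat = association_score(self._counts(), ("a", "b"))
        base2 = association_score(self._counts(), ("a", "b"), log_base=2)
        assert base2 == pytest.approx(nat / math.log(2))


class TestEnrichment:
    def _stats(self, score, observed=6):
        return DomainPairStats(pair=("a", "b"), observed=observed,
                               expected=1.0, score=score, enriched=False,
                               p_value=0.1)

    def _counts(self, n_a=4, n_b=4):
        return PairCounts(n_proteins=20, n_pairs=12,
                          protein_count_by_domain={"a": n_a, "b": n_b},
                          observed_by_pair={("a", "b"): 6})

    def test_score_boundary(self):
        assert not call_enrichment(self._stats(1.99), self._counts())
        assert call_enrichment(self._stats(2.0), self._counts())

    def test_observed_minimum(self):
        assert not call_enrichment(self._stats(5.0, observed=3), self._counts())
        assert call_enrichment(self._stats(5.0, observed=4), self._counts())

    def test_per_domain_minimum(self):
        assert not call_enrichment(self._stats(5.0), self._counts(n_b=3))
        assert call_enrichment(self._stats(5.0), self._counts(n_a=4, n_b=4))


class TestPairPvalue:
    def test_values(self):
        assert pair_pvalue(12, 12) == 1.0
        assert pair_pvalue(3, 12) == 0.25
        assert pair_pvalue(0, 12) == 0.0

    def test_zero_universe_is_error(self):
        with pytest.raises(ValueError):
            pair_pvalue(0, 0)

    def test_monotone_in_observed(self):
        values = [pair_pvalue(k, 30) for k in range(31)]
        assert values == sorted(values)
        assert all(0.0 <= v <= 1.0 for v in values)


class TestScoreAllPairs:
    def test_empty_input(self):
        assert score_all_pairs([], []) == []

    def test_random_instances_match_brute_force(self):
        """Counts, scores and P-values agree with the independent oracle
        on many random small instances."""
        rng = random.Random(42)
        for trial in range(60):
            n_prot = rng.randint(2, 15)
            prots = [f"P{i}" for i in range(n_prot)]
            vocab = ["a", "b", "c", "d", "e"][:rng.randint(1, 5)]
            domains = []
            for p in prots:
                for d in rng.sample(vocab, rng.randint(0, len(vocab))):
                    domains.append(hit(p, d))
            ppis = []
            seen = set()
            for _ in range(rng.randint(0, 30)):
                a, b = rng.choice(prots), rng.choice(prots)
                pair = tuple(sorted((a, b)))
                if pair in seen:
                    continue
                seen.add(pair)
                ppis.append(ppi(*pair))
            result = score_all_pairs(ppis, domains)
            universe, pairs, n_by_dom, observed = brute_force_counts(ppis, domains)
            assert {s.pair for s in result} == set(observed)
            for s in result:
                a, b = s.pair
                exp = len(pairs) * (1 if a == b else 2) * \
                    (n_by_dom[a] / len(universe)) * (n_by_dom[b] / len(universe))
                assert s.observed == observed[s.pair]
                assert s.expected == pytest.approx(exp)
                assert s.score == pytest.approx(math.log(s.observed / exp))
                assert s.p_value == pytest.approx(s.observed / len(pairs))
                assert 0.0 <= s.p_value <= 1.0
                if s.enriched:
                    assert s.score >= 2 and s.observed >= 4
                    assert n_by_dom[a] >= 4 and n_by_dom[b] >= 4

    def test_unobserved_query_scores_sentinel(self):
        domains = [hit("P", "a"), hit("Q", "b"), hit("R", "c")]
        ppis = [ppi("P", "Q"), ppi("Q", "R")]
        counts = count_pairs(ppis, domains)
        stats = score_pair(counts, ("a", "c"))
        assert stats.score == UNOBSERVED_SCORE
        assert stats.observed == 0 and not stats.enriched
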