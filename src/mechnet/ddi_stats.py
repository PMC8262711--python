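"""Domain-domain association inference from protein interaction data.

Over-represented domain pairs in interacting proteins (the
Sprinzak-Margalit co-occurrence approach): for every domain pair (a, b),
the number of non-redundant interacting protein pairs in which one partner
contains *a* and the other contains *b* (presence, not copy number) is
compared with the count expected if domains decorated interactions
independently. The association score is the log-odds

    score(a, b) = log( I_ab / E_ab ),
    E_ab = I * (2 - delta_ab) * (n_a / N) * (n_b / N)

where I is the number of non-redundant interacting pairs, N the number of
distinct proteins in that interaction universe, n_x the number of proteins
containing domain x, and delta_ab = 1 for homotypic pairs. The (2 -
delta_ab) factor counts the two ways a heterotypic pair can decorate an
unordered interaction. Pairs never observed together get the sentinel
score -5, below any computed log-odds of interest.

A pair is called *enriched* when score >= 2 and, to screen out fragile
associations, the observed count and both per-domain protein counts are
all >= 4. The observed frequency I_ab / I doubles as an empirical P-value:
the probability of drawing the pair when sampling an interaction uniformly
from the universe.

Scoring is per organism; inputs are assumed to come from one organism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .annotations_io import DomainHit, PPIRecord, canonical_pair

#: Sentinel association score for pairs with zero observed co-occurrence.
UNOBSERVED_SCORE = -5.0

#: Enrichment thresholds: minimum score, observed pair count and
#: per-domain protein counts.
MIN_ENRICH_SCORE = 2.0
MIN_OBSERVED = 4
MIN_DOMAIN_PROTEINS = 4


@dataclass
class PairCounts:
    """Co-occurrence counts underlying the association scores."""

    n_proteins: int
    n_pairs: int
    protein_count_by_domain: dict[str, int]
    observed_by_pair: dict[tuple[str, str], int]

    def validate(self) -> None:
        for dom, n in self.protein_count_by_domain.items():
            if not 0 <= n <= self.n_proteins:
                raise ValueError(f"count for {dom} outside 0..{self.n_proteins}")
        for pair, obs in self.observed_by_pair.items():
            if not 0 <= obs <= self.n_pairs:
                raise ValueError(f"observed for {pair} outside 0..{self.n_pairs}")
            if pair != canonical_pair(*pair):
                raise ValueError(f"pair {pair} not canonical")


@dataclass(frozen=True)
class DomainPairStats:
    """Association statistics for one canonical domain pair."""

    pair: tuple[str, str]
    observed: int
    expected: float
    score: float
    enriched: bool
    p_value: float


def select_nonredundant(ppis: Sequence[PPIRecord],
                        min_sources: int = 2) -> list[PPIRecord]:
    """Keep unique interacting pairs supported by at least *min_sources*
    distinct experimental evidence records (identity = source + method;
    identical records count once)."""
    seen: set[tuple[str, str]] = set()
    out: list[PPIRecord] = []
    for rec in ppis:
        if rec.pair in seen:
            continue
        seen.add(rec.pair)
        if rec.n_distinct_sources >= min_sources:
            out.append(rec)
    return out


def count_pairs(ppis: Sequence[PPIRecord],
                domains: Sequence[DomainHit]) -> PairCounts:
    """Count domain-pair co-occurrence over a non-redundant interaction set.

    An interacting pair (P, Q) exhibits the heterotypic domain pair (a, b)
    if a is in P and b in Q, or a in Q and b in P; it exhibits the
    homotypic pair (a, a) if both partners contain a. Each interaction
    counts each domain pair at most once (presence, not multiplicity);
    homodimers (P, P) count pairs formed by P's own domain set.
    """
    domains_by_protein: dict[str, set[str]] = {}
    for hit in domains:
        domains_by_protein.setdefault(hit.protein, set()).add(hit.domain_id)

    universe: set[str] = set()
    for rec in ppis:
        universe.update(rec.pair)

    protein_count_by_domain: dict[str, int] = {}
    for prot in universe:
        for dom in domains_by_protein.get(prot, ()):
            protein_count_by_domain[dom] = protein_count_by_domain.get(dom, 0) + 1

    observed: dict[tuple[str, str], int] = {}
    for rec in ppis:
        p, q = rec.pair
        doms_p = domains_by_protein.get(p, set())
        doms_q = domains_by_protein.get(q, set())
        pairs_here = {canonical_pair(a, b) for a in doms_p for b in doms_q}
        for pair in pairs_here:
            observed[pair] = observed.get(pair, 0) + 1

    counts = PairCounts(
        n_proteins=len(universe),
        n_pairs=len({rec.pair for rec in ppis}),
        protein_count_by_domain=protein_count_by_domain,
        observed_by_pair=observed,
    )
    counts.validate()
    return counts


def association_score(counts: PairCounts, pair: tuple[str, str],
                      log_base: float = math.e) -> float:
    """Log-odds association score for a domain pair.

    Returns :data:`UNOBSERVED_SCORE` (-5) when the pair was never observed.
    The score is symmetric in the pair. *log_base* defaults to the natural
    logarithm.
    """
    a, b = canonical_pair(*pair)
    for dom in (a, b):
        if dom not in counts.protein_count_by_domain:
            raise KeyError(f"domain {dom!r} not in the interaction universe")
    observed = counts.observed_by_pair.get((a, b), 0)
    if observed == 0:
        return UNOBSERVED_SCORE
    expected = expected_count(counts, (a, b))
    return math.log(observed / expected) / math.log(log_base)


def expected_count(counts: PairCounts, pair: tuple[str, str]) -> float:
    """Expected number of interacting pairs exhibiting the domain pair
    under independent decoration: I * (2 - delta_ab) * p_a * p_b."""
    a, b = canonical_pair(*pair)
    n_a = counts.protein_count_by_domain[a]
    n_b = counts.protein_count_by_domain[b]
    ways = 1 if a == b else 2
    return counts.n_pairs * ways * (n_a / counts.n_proteins) * (n_b / counts.n_proteins)


def call_enrichment(stats: DomainPairStats, counts: PairCounts) -> bool:
    """Enrichment call: score >= 2 AND observed >= 4 AND both per-domain
    protein counts >= 4."""
    a, b = stats.pair
    n_a = counts.protein_count_by_domain.get(a, 0)
    n_b = counts.protein_count_by_domain.get(b, 0)
    return (stats.score >= MIN_ENRICH_SCORE
            and stats.observed >= MIN_OBSERVED
            and n_a >= MIN_DOMAIN_PROTEINS
            and n_b >= MIN_DOMAIN_PROTEINS)


def pair_pvalue(observed: int, n_pairs: int) -> float:
    """Empirical P-value of a pair: its observed frequency among the
    non-redundant interacting pairs, observed / n_pairs."""
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if not 0 <= observed <= n_pairs:
        raise ValueError(f"observed {observed} outside 0..{n_pairs}")
    return observed / n_pairs


def score_pair(counts: PairCounts, pair: tuple[str, str],
               log_base: float = math.e) -> DomainPairStats:
    """Full statistics record for one domain pair (observed or not)."""
    pair = canonical_pair(*pair)
    observed = counts.observed_by_pair.get(pair, 0)
    score = association_score(counts, pair, log_base=log_base)
    stats = DomainPairStats(
        pair=pair,
        observed=observed,
        expected=expected_count(counts, pair),
        score=score,
        enriched=False,
        p_value=pair_pvalue(observed, counts.n_pairs) if counts.n_pairs else 0.0,
    )
    return DomainPairStats(
        pair=stats.pair, observed=stats.observed, expected=stats.expected,
        score=stats.score, enriched=call_enrichment(stats, counts),
        p_value=stats.p_value,
    )


def score_all_pairs(ppis: Sequence[PPIRecord],
                    domains: Sequence[DomainHit],
                    min_sources: int = 2,
                    log_base: float = math.e,
                    assume_nonredundant: bool = False,
                    ) -> list[DomainPairStats]:
    """Score every domain pair observed at least once in the interaction
    set (one organism at a time).

    The input is reduced to the non-redundant subset (>= *min_sources*
    distinct evidence records) unless *assume_nonredundant*. Unobserved
    pairs are not materialized; query them with :func:`score_pair`.
    """
    subset = list(ppis) if assume_nonredundant else \
        select_nonredundant(ppis, min_sources=min_sources)
    if not subset:
        return []
    counts = count_pairs(subset, domains)
    return [score_pair(counts, pair, log_base=log_base)
            for pair in sorted(counts.observed_by_pair)]
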