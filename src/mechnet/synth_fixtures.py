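"""Seeded synthetic proteomes, annotations and interaction sets.

Every generator is deterministic given ``FixtureSpec.seed`` and emits the
same record types and TSV/FASTA dialects the loaders read, so the whole
pipeline is testable without any external download. Planted domain-pair
co-occurrence provides exact ground truth for the association-score
recovery tests: the background interaction sample is drawn uniformly over
protein pairs *excluding* any pair that would exhibit a planted domain
pair, so a brute-force recount of a planted pair equals its target
exactly.

The generator makes no attempt to mimic real interactome degree
distributions or domain-family abundances; it provides exchangeable
backgrounds with known signal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotations_io import (DomainHit, Evidence, PPIRecord, ProteinRecord,
                             VariantRecord, canonical_pair)
from .motif_scan import MotifClass

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Motif classes shipped with the simulator: a GSK3-style phospho-site pair
#: (two Ser/Thr separated by three residues), a WW-domain-binding PPxY
#: motif, and a phospho-degron-like pattern.
DEFAULT_MOTIF_CLASSES = (
    MotifClass("MOD_GSK3_LIKE", "GSK3-style S/T pair", "[ST]...[ST]", "elm"),
    MotifClass("LIG_WW_PPXY", "WW-domain binding PPxY", "PP.Y", "elm"),
    MotifClass("DEG_PHOSPHO_DSG", "phospho-degron DSGxxS", "DSG..[ST]", "elm"),
)

DEFAULT_DOMAIN_VOCAB = tuple(f"PF{i:05d}" for i in range(1, 13))


class FixtureError(ValueError):
    """Raised for infeasible fixture specifications."""


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``planted_pairs`` lists (domain pair, target co-occurrence count)
    tuples; each planted domain is assigned to exactly
    ``planted_carriers`` proteins so per-domain protein counts are under
    control of the spec rather than of sampling noise.
    """

    n_proteins: int = 20
    seq_length_range: tuple[int, int] = (150, 400)
    domain_vocab: tuple[str, ...] = DEFAULT_DOMAIN_VOCAB
    domains_per_protein: tuple[int, int] = (1, 2)
    n_interactions: int = 30
    planted_pairs: list[tuple[tuple[str, str], int]] = field(default_factory=list)
    planted_carriers: int = 5
    motif_classes: tuple[MotifClass, ...] = DEFAULT_MOTIF_CLASSES
    variant_density: float = 1.0  # variants per 100 residues
    taxon: str = "human"
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1 or self.n_interactions < 0:
            raise FixtureError("counts must be positive")
        if self.seq_length_range[0] > self.seq_length_range[1] or \
                self.seq_length_range[0] < 20:
            raise FixtureError("bad sequence length range")
        planted_total = sum(c for _, c in self.planted_pairs)
        if planted_total > self.n_interactions:
            raise FixtureError(
                f"planted co-occurrence total {planted_total} exceeds "
                f"n_interactions {self.n_interactions}")
        for (a, b), _ in self.planted_pairs:
            if a not in self.domain_vocab or b not in self.domain_vocab:
                raise FixtureError(f"planted domains ({a}, {b}) not in vocab")


def recovery_spec(seed: int) -> FixtureSpec:
    """A spec in the strong-planting regime used by the association-score
    recovery checks: 80 proteins, 70 interactions, one planted pair with
    5 carriers per domain and target co-occurrence 14. With an interaction
    universe of u proteins the planted expectation is 70*2*(5/u)^2 — below
    1.4 for any u >= 50 — so the planted log-odds sits near 2.9, well
    above the enrichment threshold, while the observed and per-domain
    counts satisfy the count minima by construction."""
    return FixtureSpec(
        n_proteins=80,
        n_interactions=70,
        planted_pairs=[(("PF00001", "PF00002"), 14)],
        planted_carriers=5,
        seed=seed,
    )


def sentinel_spec(seed: int) -> FixtureSpec:
    """A spec for the unobserved-pair sentinel check: 20 proteins, 30
    interactions, a domain pair with 5 carriers each and a target
    co-occurrence of zero — the background sampler then never places the
    two domains on opposite sides of an interaction."""
    return FixtureSpec(
        n_proteins=20,
        n_interactions=30,
        planted_pairs=[(("PF00001", "PF00002"), 0)],
        planted_carriers=5,
        seed=seed,
    )


def _planted_domains(spec: FixtureSpec) -> list[str]:
    out: list[str] = []
    for (a, b), _ in spec.planted_pairs:
        for d in (a, b):
            if d not in out:
                out.append(d)
    return out


def make_proteome(spec: FixtureSpec
                  ) -> tuple[list[ProteinRecord], list[DomainHit]]:
    """Generate proteins with uniform-random sequences and non-overlapping
    domain hits.

    Domains named in ``planted_pairs`` are each assigned to exactly
    ``planted_carriers`` proteins (disjoint carrier sets); remaining domain
    slots are filled uniformly from the rest of the vocabulary. All hits
    carry e-values below the standard ingestion cut-off.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    planted = _planted_domains(spec)
    if len(planted) * spec.planted_carriers > spec.n_proteins:
        raise FixtureError("not enough proteins for the planted carrier sets")

    order = rng.permutation(spec.n_proteins)
    carrier_of: dict[int, str] = {}
    for j, dom in enumerate(planted):
        block = order[j * spec.planted_carriers:(j + 1) * spec.planted_carriers]
        for prot_i in block:
            carrier_of[int(prot_i)] = dom

    background_vocab = [d for d in spec.domain_vocab if d not in planted]
    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    lo_k, hi_k = spec.domains_per_protein
    for i in range(spec.n_proteins):
        acc = f"SYN{i:04d}"
        length = int(rng.integers(spec.seq_length_range[0],
                                  spec.seq_length_range[1] + 1))
        seq = "".join(np.asarray(list(AA20))[rng.integers(0, 20, size=length)])
        prot = ProteinRecord(accession=acc, gene=f"G{i:04d}",
                             taxon=spec.taxon, sequence=seq)
        prot.validate()
        proteins.append(prot)

        assigned: list[str] = []
        if i in carrier_of:
            assigned.append(carrier_of[i])
        k = int(rng.integers(lo_k, hi_k + 1))
        k = max(k, len(assigned))
        pool = [d for d in background_vocab if d not in assigned]
        n_extra = min(k - len(assigned), len(pool))
        if n_extra > 0:
            extras = rng.choice(len(pool), size=n_extra, replace=False)
            assigned.extend(pool[j] for j in sorted(extras))

        # partition the sequence into one block per domain; a hit sits
        # inside its block, so hits never overlap
        k = len(assigned)
        block_len = length // k
        if block_len < 12:
            raise FixtureError(
                f"{acc}: {k} domains do not fit in length {length}")
        for j, dom in enumerate(assigned):
            dlen = int(rng.integers(10, min(60, block_len - 1) + 1))
            start0 = j * block_len + int(rng.integers(0, block_len - dlen + 1))
            hit = DomainHit(
                protein=acc, domain_id=dom, domain_name=dom.lower(),
                start=start0 + 1, end=start0 + dlen,
                evalue=float(10.0 ** rng.uniform(-12, -4)))
            hit.validate(prot)
            hits.append(hit)
    return proteins, hits


def _exhibits(pair_doms_p: set[str], pair_doms_q: set[str],
              a: str, b: str) -> bool:
    if a == b:
        return a in pair_doms_p and a in pair_doms_q
    return (a in pair_doms_p and b in pair_doms_q) or \
           (a in pair_doms_q and b in pair_doms_p)


def plant_enriched_pair(spec: FixtureSpec,
                        proteome: tuple[list[ProteinRecord], list[DomainHit]] | None = None,
                        ) -> list[PPIRecord]:
    """Generate an interaction set with exact planted domain-pair
    co-occurrence over a uniform background.

    For each planted (a, b) with target c, exactly c distinct carrier
    cross-pairs are planted, chosen to cover every carrier at least once
    (round-robin) before random extras. Background pairs are sampled
    uniformly without replacement from pairs exhibiting *no* planted
    domain pair, so a brute-force recount of each planted pair equals its
    target. Every record carries two distinct evidence records, surviving
    the non-redundancy filter.
    """
    spec.validate()
    if proteome is None:
        proteome = make_proteome(spec)
    proteins, hits = proteome
    rng = np.random.default_rng((spec.seed, 1))

    doms_of: dict[str, set[str]] = {}
    for h in hits:
        doms_of.setdefault(h.protein, set()).add(h.domain_id)
    accs = [p.accession for p in proteins]

    def exhibits_any_planted(p: str, q: str) -> bool:
        dp = doms_of.get(p, set())
        dq = doms_of.get(q, set())
        return any(_exhibits(dp, dq, a, b) for (a, b), _ in spec.planted_pairs)

    chosen: list[tuple[str, str]] = []
    chosen_set: set[tuple[str, str]] = set()

    for (a, b), target in spec.planted_pairs:
        carriers_a = sorted(p for p in accs if a in doms_of.get(p, set()))
        carriers_b = sorted(p for p in accs if b in doms_of.get(p, set()))
        candidates = []
        for p in carriers_a:
            for q in carriers_b:
                if p == q:
                    continue
                pair = canonical_pair(p, q)
                if pair in chosen_set:
                    continue
                # must exhibit exactly this planted pair, no other
                other = any(_exhibits(doms_of[p], doms_of[q], x, y)
                            for (x, y), _ in spec.planted_pairs
                            if (x, y) != (a, b))
                if not other:
                    candidates.append(pair)
        candidates = sorted(set(candidates))
        if len(candidates) < target:
            raise FixtureError(
                f"cannot reach target {target} for ({a}, {b}): only "
                f"{len(candidates)} candidate carrier pairs")
        # round-robin cover: walk shuffled a-carriers x b-carriers diagonally
        perm_a = list(rng.permutation(carriers_a))
        perm_b = list(rng.permutation(carriers_b))
        picked: list[tuple[str, str]] = []
        picked_set: set[tuple[str, str]] = set()
        i = 0
        n_diag = max(len(perm_a), len(perm_b))
        while len(picked) < target and i < n_diag:
            p = perm_a[i % len(perm_a)]
            q = perm_b[i % len(perm_b)]
            pair = canonical_pair(p, q)
            if pair in candidates and pair not in picked_set:
                picked.append(pair)
                picked_set.add(pair)
            i += 1
        remaining = [c for c in candidates if c not in picked_set]
        if len(picked) < target:
            idx = rng.choice(len(remaining), size=target - len(picked),
                             replace=False)
            for j in sorted(idx):
                picked.append(remaining[j])
                picked_set.add(remaining[j])
        chosen.extend(picked)
        chosen_set.update(picked)

    n_background = spec.n_interactions - len(chosen)
    background_pool = []
    for i in range(len(accs)):
        for j in range(i + 1, len(accs)):
            pair = canonical_pair(accs[i], accs[j])
            if pair in chosen_set:
                continue
            if exhibits_any_planted(*pair):
                continue
            background_pool.append(pair)
    if n_background > len(background_pool):
        raise FixtureError(
            f"cannot draw {n_background} background interactions from "
            f"{len(background_pool)} admissible pairs")
    if n_background > 0:
        idx = rng.choice(len(background_pool), size=n_background,
                         replace=False)
        chosen.extend(background_pool[j] for j in sorted(idx))

    records: list[PPIRecord] = []
    for n, pair in enumerate(sorted(chosen)):
        evidence = [
            Evidence(f"EXP{2 * n}", "two-hybrid", "high"),
            Evidence(f"EXP{2 * n + 1}", "affinity-capture", "low"),
        ]
        records.append(PPIRecord(pair=pair, evidence=evidence))
    return records


def permute_domain_labels(hits: list[DomainHit], proteins: list[ProteinRecord],
                          seed: int) -> list[DomainHit]:
    """Null model for enrichment recovery: permute which protein owns each
    per-protein domain architecture, breaking any domain/interaction
    association while preserving the domain-count spectrum."""
    rng = np.random.default_rng((seed, 2))
    accs = [p.accession for p in proteins]
    perm = rng.permutation(len(accs))
    relabel = {accs[i]: accs[int(perm[i])] for i in range(len(accs))}
    lengths = {p.accession: p.length for p in proteins}
    out = []
    for h in hits:
        new_acc = relabel[h.protein]
        # clamp the span into the new owner's sequence
        length = lengths[new_acc]
        end = min(h.end, length)
        start = max(1, min(h.start, end))
        out.append(DomainHit(protein=new_acc, domain_id=h.domain_id,
                             domain_name=h.domain_name, start=start, end=end,
                             evalue=h.evalue))
    return out


def make_variants(proteins: list[ProteinRecord],
                  spec: FixtureSpec) -> list[VariantRecord]:
    """Generate missense variants at ``variant_density`` per 100 residues.

    Reference letters always match the sequence. Categories cycle through
    user / disease / cancer; cancer variants draw recurrence counts from a
    heavy-tailed (Zipf) distribution so both sides of the 5-sample display
    filter are populated.
    """
    rng = np.random.default_rng((spec.seed, 3))
    out: list[VariantRecord] = []
    categories = ("user", "disease", "cancer")
    k = 0
    for prot in proteins:
        n = rng.binomial(prot.length, min(1.0, spec.variant_density / 100.0))
        if n == 0:
            continue
        positions = rng.choice(prot.length, size=n, replace=False)
        for pos0 in sorted(int(p) for p in positions):
            ref = prot.sequence[pos0].upper()
            alt = AA20[int(rng.integers(0, 20))]
            while alt == ref:
                alt = AA20[int(rng.integers(0, 20))]
            category = categories[k % 3]
            k += 1
            var = VariantRecord(
                protein=prot.accession, position=pos0 + 1, ref=ref, alt=alt,
                category=category,
                disease_name=f"synthetic disease {k % 7}"
                if category == "disease" else None,
                sample_count=int(rng.zipf(1.7)) if category == "cancer" else None,
                source="synthetic")
            var.validate(prot)
            out.append(var)
    return out


# ---------------------------------------------------------------------------
# Writers (same dialects the loaders read)
# ---------------------------------------------------------------------------

def write_dataset(spec: FixtureSpec, outdir: str | os.PathLike) -> dict[str, Path]:
    """Generate a full synthetic dataset and write it in the loader
    dialects: FASTA + metadata, domain hits, PPI evidence rows, variants
    and the motif class catalog. Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteins, hits = make_proteome(spec)
    ppis = plant_enriched_pair(spec, (proteins, hits))
    variants = make_variants(proteins, spec)

    paths = {
        "fasta": outdir / "proteins.fasta",
        "meta": outdir / "proteins.tsv",
        "domains": outdir / "domains.tsv",
        "ppi": outdir / "ppi.tsv",
        "variants": outdir / "variants.tsv",
        "motif_classes": outdir / "motif_classes.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        for p in proteins:
            fh.write(f">{p.accession}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i:i + 60] + "\n")
    with open(paths["meta"], "w") as fh:
        fh.write("accession\tgene\ttaxon\n")
        for p in proteins:
            fh.write(f"{p.accession}\t{p.gene}\t{p.taxon}\n")
    with open(paths["domains"], "w") as fh:
        fh.write("protein\tdomain_id\tdomain_name\tstart\tend\tevalue\n")
        for h in hits:
            fh.write(f"{h.protein}\t{h.domain_id}\t{h.domain_name}\t"
                     f"{h.start}\t{h.end}\t{h.evalue!r}\n")
    with open(paths["ppi"], "w") as fh:
        fh.write("protein_a\tprotein_b\tsource_id\tmethod\tthroughput\n")
        for rec in ppis:
            for ev in rec.evidence:
                fh.write(f"{rec.pair[0]}\t{rec.pair[1]}\t{ev.source_id}\t"
                         f"{ev.method}\t{ev.throughput}\n")
    with open(paths["variants"], "w") as fh:
        fh.write("protein\tposition\tref\talt\tcategory\tdisease_name\t"
                 "sample_count\tsource\n")
        for v in variants:
            fh.write(f"{v.protein}\t{v.position}\t{v.ref}\t{v.alt}\t"
                     f"{v.category}\t{v.disease_name or ''}\t"
                     f"{'' if v.sample_count is None else v.sample_count}\t"
                     f"{v.source}\n")
    with open(paths["motif_classes"], "w") as fh:
        fh.write("class_id\tname\tpattern\tsource\n")
        for cls in spec.motif_classes:
            fh.write(f"{cls.class_id}\t{cls.name}\t{cls.pattern}\t{cls.source}\n")
    return paths
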