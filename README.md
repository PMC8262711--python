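# mechnet

Region-resolved mechanistic protein interaction networks.

Conventional protein–protein interaction (PPI) graphs connect whole
proteins, which hides *how* two proteins interact and what a mutation in
a particular residue might break. `mechnet` builds networks in which each
protein is a linear track of positional features — Pfam-style domains,
short linear motifs (SLiMs), post-translational modification (PTM) sites,
curated UniProt features, and missense variants — and typed edges connect
the specific elements mediating each interaction: experimental PPIs,
structure-supported domain–domain interactions (DDIs), statistically
inferred DDIs, curated-rule-filtered domain–motif interactions (DMIs),
tertiary-structure predictions, and region–protein associations. It is a
library plus a `mechnet` command-line tool for researchers studying
variant mechanisms, signalling, and interface-level rewiring of
interaction networks.

## The statistics and rules at the core

**Domain–domain association score.** Over an organism's non-redundant set
of interacting pairs *I* (unique unordered pairs with ≥ 2 distinct
experimental evidence records), each domain pair (a, b) is scored by the
log-odds of its observed versus expected co-occurrence:

    score(a,b) = ln( I_ab / E_ab ),   E_ab = I · (2 − δ_ab) · (n_a/N) · (n_b/N)

where I_ab counts interacting pairs with *a* on one side and *b* on the
other (presence, not copy number), N is the number of distinct proteins in
the interaction universe and n_x the number containing domain *x*. Pairs
never observed together get a sentinel score of −5. A pair is *enriched*
— and drawn as an inferred-DDI edge — iff score ≥ 2, I_ab ≥ 4, n_a ≥ 4
and n_b ≥ 4. The observed frequency I_ab / I is attached to DDI and DMI
edges as an empirical P-value.

**Motif discovery and DMI filtering.** Motif classes carry regular
expression patterns; every match (including overlapping ones) is reported
as a *predicted* instance, mergeable with curated *annotated* instances.
Because such patterns are highly permissive, a candidate (motif, domain)
pair becomes a DMI edge only if a curated restriction rule for the
(motif class, domain family) pair exists and passes: taxon restrictions,
gene restrictions on either side, required co-occurring motifs, and
required phosphosites inside the motif span.

**Display rules.** Domain hits are ingested at e-value ≤ 0.001; cancer
variants are displayed at ≥ 5 recurrence samples; networks are capped at
20 proteins (with a warning; the interaction table can still cover the
full set).

## Worked example

```python
import mechnet as mn

# a seeded synthetic dataset with one planted domain pair
spec = mn.recovery_spec(seed=1)
proteins, domain_hits = mn.make_proteome(spec)
ppis = mn.plant_enriched_pair(spec, (proteins, domain_hits))

stats = {s.pair: s for s in mn.score_all_pairs(ppis, domain_hits)}
s = stats[("PF00001", "PF00002")]
print(f"observed={s.observed} expected={s.expected:.3f} "
      f"score={s.score:.3f} enriched={s.enriched} p={s.p_value:.3f}")
```

prints

```
observed=14 expected=0.941 score=2.700 enriched=True p=0.200
```

The planted pair co-occurs in 14 of the 70 interacting pairs while fewer
than one would be expected if the two domains decorated interactions
independently, so its log-odds clears the enrichment threshold and the
pair would be drawn as an inferred-DDI edge (P-value 14/70 = 0.2).

Motif scanning and variant overlap on a single sequence:

```python
prot = mn.ProteinRecord("P51168", "SCNN1B", "human", "GG" + "A"*30 + "PPAY")
cls = mn.MotifClass("LIG_WW_PPXY", "WW-binding PPxY", "PP.Y", "elm")
(inst,) = mn.scan_motifs(prot, [cls])
print(inst.start, inst.end, inst.matched_seq)   # 33 36 PPAY

var = mn.read_variants("P51168/p.P33L", [prot])[0]
(_, overlaps), = mn.map_variants([var], [inst])
print([f.class_id for f in overlaps])           # ['LIG_WW_PPXY']
```

The command line mirrors the library: `mechnet simulate` writes a seeded
synthetic dataset, `mechnet score-ddi` scores domain pairs from PPI and
domain tables, and `mechnet build` assembles a network and exports
Cytoscape JSON / GraphML plus the per-edge interaction table.

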