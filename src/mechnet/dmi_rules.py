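"""Admissibility rules for domain-motif interactions (DMIs).

Regex-discovered motif instances are noisy: a pattern match says nothing
about whether the binding domain ever meets the motif in a relevant
context. Each ELM-derived motif class / binding-domain pair therefore
carries a manually curated restriction record, and a candidate
(motif instance, domain hit) pair is shown only if a rule exists for it
and every populated restriction passes:

* ``taxa_allow`` — the interaction is confined to certain clades
  (e.g. a Metazoa-only motif must not be reported in yeast);
* ``domain_gene_allow`` / ``motif_gene_allow`` — some motifs bind only a
  specific gene product even though the domain family is widespread
  (e.g. a PEX14-binding motif found only in PEX5);
* ``required_comotifs`` — other motif classes that must co-occur in the
  motif-side protein;
* ``phospho_required`` — at least one phosphosite must lie within the
  motif span (phospho-dependent motifs such as the SCF-betaTrCP degron).

Structure-derived (3did) DMIs are evidence-based and bypass this table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotations_io import (DomainHit, LoadError, PTMSite,
                             _cell, _read_tsv)
from .motif_scan import MotifInstance
from .taxa import lineage_tags

#: Restriction-failure tags, in the order they are checked.
FAIL_TAGS = ("no_rule", "taxa", "domain_gene", "motif_gene", "comotif", "phospho")


@dataclass(frozen=True)
class DMIRestriction:
    """Curated restrictions on one (motif class, binding domain) pair.

    Empty optional fields mean "no restriction".
    """

    class_id: str
    domain_id: str
    taxa_allow: frozenset[str] = frozenset()
    domain_gene_allow: frozenset[str] = frozenset()
    motif_gene_allow: frozenset[str] = frozenset()
    required_comotifs: frozenset[str] = frozenset()
    phospho_required: bool = False


@dataclass(frozen=True)
class DMIDecision:
    """Outcome of an admissibility check; admissible iff no reason failed."""

    admissible: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.admissible != (not self.reasons):
            raise ValueError("admissible flag inconsistent with reasons")


@dataclass(frozen=True)
class DMIContext:
    """Everything a rule can ask about besides the motif and the domain:
    the query organism, gene symbols by accession, phosphosites, and the
    full motif-instance set (for co-motif requirements)."""

    taxon: str
    gene_by_accession: Mapping[str, str]
    ptm_sites: Sequence[PTMSite] = ()
    motif_instances: Sequence[MotifInstance] = ()
    comotif_annotated_only: bool = False


def load_restrictions(path: str | os.PathLike) -> list[DMIRestriction]:
    """Read the restriction table.

    TSV columns: ``class_id, domain_id, taxa_allow, domain_gene_allow,
    motif_gene_allow, required_comotifs, phospho_required``; list-valued
    cells are comma-separated, empty cells mean unrestricted. A duplicate
    (class_id, domain_id) row is an error.
    """
    df = _read_tsv(path, ["class_id", "domain_id", "taxa_allow",
                          "domain_gene_allow", "motif_gene_allow",
                          "required_comotifs", "phospho_required"])

    def listcell(row, col, i) -> frozenset[str]:
        raw = _cell(row, col, i, path, optional=True)
        if raw is None:
            return frozenset()
        return frozenset(tok.strip() for tok in str(raw).split(",") if tok.strip())

    rules: list[DMIRestriction] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.to_dict("records"), start=1):
        class_id = _cell(row, "class_id", i, path)
        domain_id = _cell(row, "domain_id", i, path)
        if (class_id, domain_id) in seen:
            raise LoadError(
                f"{path}: row {i}: duplicate rule for ({class_id}, {domain_id})")
        seen.add((class_id, domain_id))
        raw_flag = _cell(row, "phospho_required", i, path, optional=True)
        flag = str(raw_flag).strip().lower() in ("1", "true", "yes") \
            if raw_flag is not None else False
        rules.append(DMIRestriction(
            class_id=class_id, domain_id=domain_id,
            taxa_allow=listcell(row, "taxa_allow", i),
            domain_gene_allow=listcell(row, "domain_gene_allow", i),
            motif_gene_allow=listcell(row, "motif_gene_allow", i),
            required_comotifs=listcell(row, "required_comotifs", i),
            phospho_required=flag,
        ))
    return rules


def index_rules(rules: Iterable[DMIRestriction]
                ) -> dict[tuple[str, str], DMIRestriction]:
    """Index restrictions by (motif class, domain family)."""
    return {(r.class_id, r.domain_id): r for r in rules}


def check_dmi(motif: MotifInstance, domain: DomainHit,
              rules: Mapping[tuple[str, str], DMIRestriction] | Iterable[DMIRestriction],
              ctx: DMIContext) -> DMIDecision:
    """Decide whether a (motif instance, domain hit) pair is an admissible
    domain-motif interaction under the restriction table.

    The pair is admissible iff a rule exists for
    (motif.class_id, domain.domain_id) and every populated restriction
    passes. A pure function: the same inputs always yield the same
    decision. Absence of a rule yields ``reasons = ("no_rule",)``.
    """
    if not isinstance(rules, Mapping):
        rules = index_rules(rules)
    rule = rules.get((motif.class_id, domain.domain_id))
    if rule is None:
        return DMIDecision(admissible=False, reasons=("no_rule",))

    reasons: list[str] = []
    if rule.taxa_allow:
        if not (rule.taxa_allow & lineage_tags(ctx.taxon)):
            reasons.append("taxa")
    if rule.domain_gene_allow:
        gene = ctx.gene_by_accession.get(domain.protein, "")
        if gene.upper() not in {g.upper() for g in rule.domain_gene_allow}:
            reasons.append("domain_gene")
    if rule.motif_gene_allow:
        gene = ctx.gene_by_accession.get(motif.protein, "")
        if gene.upper() not in {g.upper() for g in rule.motif_gene_allow}:
            reasons.append("motif_gene")
    if rule.required_comotifs:
        present = {
            inst.class_id for inst in ctx.motif_instances
            if inst.protein == motif.protein
            and (not ctx.comotif_annotated_only or inst.status == "annotated")
        }
        if not rule.required_comotifs <= present:
            reasons.append("comotif")
    if rule.phospho_required:
        has_phospho = any(
            site.protein == motif.protein
            and site.ptm_type == "phosphorylation"
            and motif.start <= site.position <= motif.end
            for site in ctx.ptm_sites
        )
        if not has_phospho:
            reasons.append("phospho")
    return DMIDecision(admissible=not reasons, reasons=tuple(reasons))


def admissible_dmis(motifs: Sequence[MotifInstance],
                    domains: Sequence[DomainHit],
                    rules: Iterable[DMIRestriction],
                    ctx: DMIContext,
                    cross_protein_only: bool = True,
                    ) -> list[tuple[MotifInstance, DomainHit, DMIDecision]]:
    """Evaluate every candidate (motif, domain) pair, returning the
    admissible ones with their decisions. By default only cross-protein
    pairs are considered (a motif does not bind a domain of its own
    protein in this model)."""
    idx = index_rules(rules)
    out: list[tuple[MotifInstance, DomainHit, DMIDecision]] = []
    for motif in motifs:
        for domain in domains:
            if cross_protein_only and motif.protein == domain.protein:
                continue
            if (motif.class_id, domain.domain_id) not in idx:
                continue
            decision = check_dmi(motif, domain, idx, ctx)
            if decision.admissible:
                out.append((motif, domain, decision))
    return out
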