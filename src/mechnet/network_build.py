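"""Assembly of the region-resolved mechanistic network.

Proteins are linear tracks of positional feature nodes (domains, motifs,
PTM sites, curated features, variants); typed edges connect the specific
elements that mediate each interaction:

========== =====================================================
etype       meaning / weight
========== =====================================================
ppi         experimental protein-protein interaction; weight =
            number of evidence records
ddi_struct  domain pair seen in 3D structures; weight = number of
            supporting structures
ddi_inferred domain pair enriched by co-occurrence scoring; weight =
            association score, empirical P-value attached
dmi_elm     admissible domain-motif interaction (curated rules);
            empirical P-value attached
dmi_struct  domain-motif pair seen in 3D structures; weight = number
            of supporting structures
pred_3d     interaction predicted from tertiary structure (Z-score
            and P-value carried as attributes)
region_assoc curated feature annotated as involving another protein
========== =====================================================

Networks larger than 20 proteins are truncated with a warning (dense
"hairball" views carry no mechanistic insight); the interaction table can
still be computed on the full set by building an uncapped network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .annotations_io import (DomainHit, PPIRecord, PTMSite, PredictedEdge,
                             ProteinRecord, StructCatalogEntry, UniProtFeature,
                             VariantRecord, canonical_pair, protein_index)
from .ddi_stats import DomainPairStats, pair_pvalue
from .dmi_rules import DMIDecision
from .motif_scan import MotifInstance, filter_instances

EDGE_TYPES = ("ppi", "ddi_struct", "ddi_inferred", "dmi_elm",
              "dmi_struct", "pred_3d", "region_assoc")

NODE_KINDS = ("protein", "domain", "motif", "ptm", "uniprot_feature", "variant")

DEFAULT_PROTEIN_CAP = 20
DEFAULT_CANCER_MIN_SAMPLES = 5


class BuildError(ValueError):
    """Raised when network assembly hits dangling references."""


@dataclass(frozen=True)
class NetworkNode:
    node_id: str
    kind: str
    protein: str
    label: str
    start: int | None = None
    end: int | None = None
    attrs: tuple[tuple[str, object], ...] = ()

    def attr_dict(self) -> dict:
        return dict(self.attrs)


@dataclass(frozen=True)
class NetworkEdge:
    edge_id: str
    etype: str
    endpoints: tuple[str, str]
    weight: float = 1.0
    p_value: float | None = None
    evidence: str = ""
    attrs: tuple[tuple[str, object], ...] = ()

    def attr_dict(self) -> dict:
        return dict(self.attrs)


@dataclass
class NetworkConfig:
    """Build-time switches mirroring the viewer's control panel."""

    cap: int | None = DEFAULT_PROTEIN_CAP
    cancer_min_samples: int = DEFAULT_CANCER_MIN_SAMPLES
    confirmed_motifs_only: bool = False
    exclude_motifs_in_domains: bool = False
    min_ddi_score: float = 2.0
    #: per-etype layer toggles; a missing key means "on"
    layers: dict[str, bool] = field(default_factory=dict)

    def layer_on(self, etype: str) -> bool:
        return self.layers.get(etype, True)

    def snapshot(self) -> dict:
        return {
            "cap": self.cap,
            "cancer_min_samples": self.cancer_min_samples,
            "confirmed_motifs_only": self.confirmed_motifs_only,
            "exclude_motifs_in_domains": self.exclude_motifs_in_domains,
            "min_ddi_score": self.min_ddi_score,
            "layers": dict(self.layers),
        }


@dataclass
class MechNetwork:
    """The assembled mechanistic network."""

    nodes: list[NetworkNode] = field(default_factory=list)
    edges: list[NetworkEdge] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def node_index(self) -> dict[str, NetworkNode]:
        return {n.node_id: n for n in self.nodes}

    def validate(self) -> None:
        idx = self.node_index()
        if len(idx) != len(self.nodes):
            raise BuildError("duplicate node ids")
        if len({e.edge_id for e in self.edges}) != len(self.edges):
            raise BuildError("duplicate edge ids")
        proteins = {n.node_id for n in self.nodes if n.kind == "protein"}
        for n in self.nodes:
            if n.kind != "protein" and n.protein not in proteins:
                raise BuildError(f"node {n.node_id}: owning protein missing")
        for e in self.edges:
            for nid in e.endpoints:
                if nid not in idx:
                    raise BuildError(f"edge {e.edge_id}: endpoint {nid} missing")
            if e.weight < 0:
                raise BuildError(f"edge {e.edge_id}: negative weight")


# ---------------------------------------------------------------------------
# Pre-build operations
# ---------------------------------------------------------------------------

def expand_interactors(query: Iterable[str], ppis: Sequence[PPIRecord],
                       k: int) -> set[str]:
    """Add up to *k* known interactors per query protein.

    Partners are ranked by evidence-record count, ties broken
    lexicographically; a partner shared by several query proteins is added
    once.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    query = set(query)
    if k == 0:
        return query
    partners_of: dict[str, list[tuple[int, str]]] = {}
    for rec in ppis:
        a, b = rec.pair
        n = len(rec.evidence)
        partners_of.setdefault(a, []).append((n, b))
        if a != b:
            partners_of.setdefault(b, []).append((n, a))
    out = set(query)
    for q in sorted(query):
        ranked = sorted((t for t in partners_of.get(q, []) if t[1] not in query),
                        key=lambda t: (-t[0], t[1]))
        out.update(partner for _, partner in ranked[:k])
    return out


def enforce_cap(proteins: Sequence[str], cap: int = DEFAULT_PROTEIN_CAP,
                ) -> tuple[list[str], str | None]:
    """Truncate a protein list to *cap* entries, keeping input order.

    Returns the retained list and a warning message when truncation
    happened (None otherwise).
    """
    proteins = list(proteins)
    if cap is None or len(proteins) <= cap:
        return proteins, None
    retained = proteins[:cap]
    warning = (f"network request of {len(proteins)} proteins exceeds the "
               f"{cap}-protein display cap; showing the first {cap} "
               f"(the interaction table can be computed on the full set)")
    return retained, warning


def _span(feature) -> tuple[int, int]:
    if hasattr(feature, "start"):
        return (feature.start, feature.end)
    return (feature.position, feature.position)


def map_variants(variants: Sequence[VariantRecord],
                 features: Sequence[object],
                 ) -> list[tuple[VariantRecord, list[object]]]:
    """Overlap each variant with the positional features of its protein.

    A feature overlaps a variant iff ``start <= position <= end``
    (inclusive on both ends; point features such as PTM sites require
    equality). Every variant is reported, possibly with an empty list.
    """
    by_protein: dict[str, list[object]] = {}
    for feat in features:
        by_protein.setdefault(feat.protein, []).append(feat)
    out = []
    for var in variants:
        hits = [f for f in by_protein.get(var.protein, ())
                if _span(f)[0] <= var.position <= _span(f)[1]]
        out.append((var, hits))
    return out


def filter_cancer_variants(variants: Sequence[VariantRecord],
                           min_samples: int = DEFAULT_CANCER_MIN_SAMPLES,
                           ) -> list[VariantRecord]:
    """Display filter for recurrence: cancer variants need
    ``sample_count >= min_samples``; other categories pass untouched."""
    out = []
    for var in variants:
        if var.category == "cancer":
            if var.sample_count is None:
                raise ValueError(
                    f"{var.protein}@{var.position}: cancer variant without "
                    f"sample_count")
            if var.sample_count < min_samples:
                continue
        out.append(var)
    return out


# ---------------------------------------------------------------------------
# Node / edge identity
# ---------------------------------------------------------------------------

def protein_node_id(acc: str) -> str:
    return acc


def domain_node_id(hit: DomainHit) -> str:
    return f"{hit.protein}|domain|{hit.domain_id}|{hit.start}-{hit.end}"


def motif_node_id(inst: MotifInstance) -> str:
    return f"{inst.protein}|motif|{inst.class_id}|{inst.start}-{inst.end}"


def ptm_node_id(site: PTMSite) -> str:
    return f"{site.protein}|ptm|{site.ptm_type}|{site.position}"


def feature_node_id(feat: UniProtFeature) -> str:
    return f"{feat.protein}|feat|{feat.ftype}|{feat.start}-{feat.end}"


def variant_node_id(var: VariantRecord) -> str:
    return f"{var.protein}|var|{var.ref}{var.position}{var.alt}|{var.category}"


# ---------------------------------------------------------------------------
# Build
# ---------------------------------------------------------------------------

class _EdgeAccumulator:
    """Collects edges keyed by (etype, endpoint pair), merging evidence so
    no layer emits parallel duplicates."""

    def __init__(self) -> None:
        self._edges: dict[tuple, dict] = {}

    def add(self, etype: str, a: str, b: str, weight: float,
            p_value: float | None = None, evidence: str = "",
            attrs: Mapping[str, object] | None = None) -> None:
        lo, hi = canonical_pair(a, b)
        key = (etype, lo, hi)
        if key not in self._edges:
            self._edges[key] = {
                "weight": weight, "p_value": p_value,
                "evidence": [evidence] if evidence else [],
                "attrs": dict(attrs or {}),
            }
        else:
            slot = self._edges[key]
            slot["weight"] = max(slot["weight"], weight)
            if evidence and evidence not in slot["evidence"]:
                slot["evidence"].append(evidence)
            if slot["p_value"] is None:
                slot["p_value"] = p_value
            slot["attrs"].update(attrs or {})

    def build(self) -> list[NetworkEdge]:
        out = []
        for (etype, lo, hi), slot in sorted(self._edges.items()):
            out.append(NetworkEdge(
                edge_id=f"{etype}|{lo}|{hi}",
                etype=etype,
                endpoints=(lo, hi),
                weight=float(slot["weight"]),
                p_value=slot["p_value"],
                evidence=";".join(slot["evidence"]),
                attrs=tuple(sorted(slot["attrs"].items())),
            ))
        return out


def build_network(proteins: Sequence[ProteinRecord],
                  domains: Sequence[DomainHit] = (),
                  motifs: Sequence[MotifInstance] = (),
                  ptms: Sequence[PTMSite] = (),
                  uniprot_features: Sequence[UniProtFeature] = (),
                  variants: Sequence[VariantRecord] = (),
                  ppis: Sequence[PPIRecord] = (),
                  struct_catalog: Sequence[StructCatalogEntry] = (),
                  ddi_statistics: Sequence[DomainPairStats] = (),
                  dmi_decisions: Sequence[tuple[MotifInstance, DomainHit, DMIDecision]] = (),
                  predicted_edges: Sequence[PredictedEdge] = (),
                  config: NetworkConfig | None = None) -> MechNetwork:
    """Assemble the mechanistic network from all evidence layers.

    ``dmi_decisions`` is the output of :func:`mechnet.dmi_rules.admissible_dmis`
    (only admissible triples are drawn); ``ddi_statistics`` the output of
    :func:`mechnet.ddi_stats.score_all_pairs` (only enriched pairs at or
    above ``config.min_ddi_score`` are drawn). Feature nodes are created
    only for the retained (capped) protein set; validation runs before the
    network is returned.
    """
    config = config or NetworkConfig()
    ordered = [p.accession for p in proteins]
    retained, warning = enforce_cap(
        ordered, config.cap if config.cap is not None else len(ordered))
    retained_set = set(retained)
    pidx = protein_index(proteins)
    gene_of = {p.accession: p.gene for p in proteins}

    warnings = [warning] if warning else []

    # ---- filters -------------------------------------------------------
    shown_variants = filter_cancer_variants(
        [v for v in variants if v.protein in retained_set],
        min_samples=config.cancer_min_samples)
    shown_motifs = filter_instances(
        [m for m in motifs if m.protein in retained_set],
        domains=[d for d in domains if d.protein in retained_set],
        confirmed_only=config.confirmed_motifs_only,
        exclude_in_domains=config.exclude_motifs_in_domains)
    shown_domains = [d for d in domains if d.protein in retained_set]
    shown_ptms = [s for s in ptms if s.protein in retained_set]
    shown_feats = [f for f in uniprot_features if f.protein in retained_set]

    # ---- nodes ---------------------------------------------------------
    nodes: dict[str, NetworkNode] = {}

    def add_node(node: NetworkNode) -> None:
        nodes.setdefault(node.node_id, node)

    for acc in retained:
        prot = pidx.get(acc)
        if prot is None:
            raise BuildError(f"protein {acc!r} not among supplied records")
        add_node(NetworkNode(
            node_id=protein_node_id(acc), kind="protein", protein=acc,
            label=prot.gene or acc, start=1, end=prot.length,
            attrs=(("gene", prot.gene), ("taxon", prot.taxon),
                   ("length", prot.length))))
    for hit in shown_domains:
        add_node(NetworkNode(
            node_id=domain_node_id(hit), kind="domain", protein=hit.protein,
            label=hit.domain_name or hit.domain_id,
            start=hit.start, end=hit.end,
            attrs=(("domain_id", hit.domain_id), ("evalue", hit.evalue))))
    for inst in shown_motifs:
        add_node(NetworkNode(
            node_id=motif_node_id(inst), kind="motif", protein=inst.protein,
            label=inst.class_id, start=inst.start, end=inst.end,
            attrs=(("matched_seq", inst.matched_seq), ("status", inst.status))))
    for site in shown_ptms:
        add_node(NetworkNode(
            node_id=ptm_node_id(site), kind="ptm", protein=site.protein,
            label=f"{site.residue}{site.position}-{site.ptm_type[:7]}",
            start=site.position, end=site.position,
            attrs=(("ptm_type", site.ptm_type), ("source", site.source))))
    for feat in shown_feats:
        add_node(NetworkNode(
            node_id=feature_node_id(feat), kind="uniprot_feature",
            protein=feat.protein, label=feat.description or feat.ftype,
            start=feat.start, end=feat.end,
            attrs=(("ftype", feat.ftype),
                   ("partner_gene", feat.partner_gene or ""))))
    for var in shown_variants:
        attrs = [("category", var.category), ("source", var.source)]
        if var.disease_name:
            attrs.append(("disease_name", var.disease_name))
        if var.sample_count is not None:
            attrs.append(("sample_count", var.sample_count))
        add_node(NetworkNode(
            node_id=variant_node_id(var), kind="variant", protein=var.protein,
            label=f"{var.ref}{var.position}{var.alt}",
            start=var.position, end=var.position, attrs=tuple(attrs)))

    # ---- edges ---------------------------------------------------------
    acc_edges = _EdgeAccumulator()
    shown_motif_ids = {motif_node_id(m) for m in shown_motifs}

    if config.layer_on("ppi"):
        for rec in ppis:
            a, b = rec.pair
            if a in retained_set and b in retained_set:
                summary = ";".join(sorted({f"{ev.source_id}:{ev.method}"
                                           for ev in rec.evidence}))
                acc_edges.add("ppi", protein_node_id(a), protein_node_id(b),
                              weight=len(rec.evidence), evidence=summary,
                              attrs={"provenance": "experimental"})

    domains_by_family: dict[str, list[DomainHit]] = {}
    for hit in shown_domains:
        domains_by_family.setdefault(hit.domain_id, []).append(hit)

    if config.layer_on("ddi_struct"):
        for entry in struct_catalog:
            if entry.kind != "ddi":
                continue
            for ha in domains_by_family.get(entry.left, ()):
                for hb in domains_by_family.get(entry.right, ()):
                    if ha.protein == hb.protein:
                        continue
                    acc_edges.add("ddi_struct", domain_node_id(ha),
                                  domain_node_id(hb),
                                  weight=entry.n_structures,
                                  evidence=f"{entry.n_structures} structures",
                                  attrs={"provenance": "3D structures"})

    if config.layer_on("ddi_inferred"):
        for stats in ddi_statistics:
            if not stats.enriched or stats.score < config.min_ddi_score:
                continue
            a, b = stats.pair
            for ha in domains_by_family.get(a, ()):
                for hb in domains_by_family.get(b, ()):
                    if ha.protein == hb.protein:
                        continue
                    acc_edges.add("ddi_inferred", domain_node_id(ha),
                                  domain_node_id(hb),
                                  weight=stats.score, p_value=stats.p_value,
                                  evidence=f"association score {stats.score:.3g}",
                                  attrs={"provenance": "co-occurrence inference",
                                         "observed": stats.observed,
                                         "expected": stats.expected})

    if config.layer_on("dmi_elm"):
        for motif, domain, decision in dmi_decisions:
            if not decision.admissible:
                continue
            mid = motif_node_id(motif)
            if mid not in shown_motif_ids or domain.protein not in retained_set:
                continue
            pv = _dmi_pvalue(motif.class_id, domain.domain_id, ppis,
                             motifs, domains)
            acc_edges.add("dmi_elm", mid, domain_node_id(domain),
                          weight=1.0, p_value=pv,
                          evidence="curated motif-domain rule",
                          attrs={"provenance": "elm"})

    if config.layer_on("dmi_struct"):
        for entry in struct_catalog:
            if entry.kind != "dmi":
                continue
            for hit in domains_by_family.get(entry.left, ()):
                for inst in shown_motifs:
                    if inst.class_id != entry.right or \
                            inst.protein == hit.protein:
                        continue
                    acc_edges.add("dmi_struct", domain_node_id(hit),
                                  motif_node_id(inst),
                                  weight=entry.n_structures,
                                  evidence=f"{entry.n_structures} structures",
                                  attrs={"provenance": "3D structures"})

    if config.layer_on("pred_3d"):
        for pred in predicted_edges:
            a, b = pred.pair
            if a in retained_set and b in retained_set:
                acc_edges.add("pred_3d", protein_node_id(a), protein_node_id(b),
                              weight=1.0, p_value=pred.p_value,
                              evidence=f"template {pred.template}",
                              attrs={"provenance": "3D prediction",
                                     "z_score": pred.z_score})

    if config.layer_on("region_assoc"):
        gene_to_acc = {g.upper(): acc for acc, g in gene_of.items() if g}
        for feat in shown_feats:
            if not feat.partner_gene:
                continue
            partner = gene_to_acc.get(feat.partner_gene.upper())
            if partner and partner in retained_set and partner != feat.protein:
                acc_edges.add("region_assoc", feature_node_id(feat),
                              protein_node_id(partner), weight=1.0,
                              evidence=feat.description or feat.ftype,
                              attrs={"provenance": "curated annotation"})

    network = MechNetwork(
        nodes=[nodes[k] for k in sorted(nodes)],
        edges=acc_edges.build(),
        warnings=warnings,
        config=config.snapshot(),
    )
    network.validate()
    return network


def _dmi_pvalue(class_id: str, domain_id: str,
                ppis: Sequence[PPIRecord],
                motifs: Sequence[MotifInstance],
                domains: Sequence[DomainHit]) -> float | None:
    """Empirical P-value of a domain-motif pair: the fraction of supplied
    interacting pairs in which one partner carries the motif class and the
    other the domain family."""
    if not ppis:
        return None
    motif_carriers = {m.protein for m in motifs if m.class_id == class_id}
    domain_carriers = {d.protein for d in domains if d.domain_id == domain_id}
    pairs = {rec.pair for rec in ppis}
    observed = sum(
        1 for (p, q) in pairs
        if (p in motif_carriers and q in domain_carriers)
        or (q in motif_carriers and p in domain_carriers))
    return pair_pvalue(observed, len(pairs))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_graph(network: MechNetwork, format: str = "cyjs") -> str:
    """Serialize the network losslessly to a graph-exchange document.

    ``cyjs`` is Cytoscape-style element JSON (nodes and edges wrapped in a
    ``data`` envelope); ``graphml`` uses typed attribute keys. Node and
    edge order is stable, so identical networks export byte-identically.
    """
    if format == "cyjs":
        return _export_cyjs(network)
    if format == "graphml":
        return _export_graphml(network)
    raise ValueError(f"unknown export format {format!r}")


def _export_cyjs(network: MechNetwork) -> str:
    nodes = []
    for n in network.nodes:
        data = {"id": n.node_id, "kind": n.kind, "protein": n.protein,
                "label": n.label}
        if n.start is not None:
            data["start"] = n.start
        if n.end is not None:
            data["end"] = n.end
        data.update(n.attr_dict())
        nodes.append({"data": data})
    edges = []
    for e in network.edges:
        data = {"id": e.edge_id, "source": e.endpoints[0],
                "target": e.endpoints[1], "etype": e.etype,
                "weight": e.weight, "evidence": e.evidence}
        if e.p_value is not None:
            data["p_value"] = e.p_value
        data.update(e.attr_dict())
        edges.append({"data": data})
    doc = {"elements": {"nodes": nodes, "edges": edges},
           "data": {"warnings": network.warnings,
                    "config": network.config}}
    return json.dumps(doc, indent=2, sort_keys=True)


def _export_graphml(network: MechNetwork) -> str:
    g = nx.MultiGraph()
    for n in network.nodes:
        attrs = {"kind": n.kind, "protein": n.protein, "label": n.label}
        if n.start is not None:
            attrs["start"] = n.start
        if n.end is not None:
            attrs["end"] = n.end
        for k, v in n.attr_dict().items():
            attrs[k] = v
        g.add_node(n.node_id, **attrs)
    for e in network.edges:
        attrs = {"etype": e.etype, "weight": e.weight, "evidence": e.evidence,
                 "edge_id": e.edge_id}
        if e.p_value is not None:
            attrs["p_value"] = e.p_value
        for k, v in e.attr_dict().items():
            attrs[k] = v
        g.add_edge(e.endpoints[0], e.endpoints[1], key=e.edge_id, **attrs)
    return "\n".join(nx.generate_graphml(g))
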