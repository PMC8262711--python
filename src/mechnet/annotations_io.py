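"""Input/output layer: protein sequences, positional annotations, interaction
evidence and the interaction-table export.

Every loader reads a documented tab-separated dialect (header row required)
or FASTA, validates records at the boundary, and normalizes coordinates to
the UniProt convention: 1-based, inclusive on both ends. Malformed or
inconsistent rows raise :class:`LoadError` / :class:`ValidationError` with
the offending row number or identifier — a silently shifted coordinate
would corrupt every downstream overlap computation, so reference-residue
mismatches are hard errors, never warnings.
"""

from __future__ import annotations

import csv
import math
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO

from .taxa import SUPPORTED_ORGANISMS

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

PTM_TYPES = frozenset({"phosphorylation", "acetylation", "glycosylation"})
VARIANT_CATEGORIES = frozenset({"user", "disease", "cancer"})
FEATURE_TYPES = frozenset(
    {"region", "binding_site", "metal_binding", "dna_binding",
     "transmembrane", "disulfide", "mutagenesis", "other"}
)

#: Columns of the interaction-table export, in order.
INTERACTION_TABLE_COLUMNS = (
    "protein_a", "protein_b", "edge_type", "element_a", "element_b",
    "start_a", "end_a", "start_b", "end_b",
    "weight", "p_value", "evidence_summary", "source",
)


class LoadError(ValueError):
    """Raised when an input file cannot be parsed into valid records."""


class ValidationError(ValueError):
    """Raised when a parsed record contradicts the protein it annotates."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered identifier pair lexicographically."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identity metadata.

    The sequence defines the coordinate frame (1-based, inclusive) for every
    positional annotation attached to the protein.
    """

    accession: str
    gene: str
    taxon: str
    sequence: str
    length: int = 0

    def __post_init__(self) -> None:
        if self.length == 0:
            object.__setattr__(self, "length", len(self.sequence))

    def validate(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        bad = set(self.sequence.upper()) - AA_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.accession}: non-amino-acid characters {sorted(bad)}")
        if self.length != len(self.sequence):
            raise ValidationError(
                f"{self.accession}: length {self.length} != sequence length "
                f"{len(self.sequence)}")
        if self.taxon not in SUPPORTED_ORGANISMS:
            raise ValidationError(
                f"{self.accession}: unsupported taxon {self.taxon!r}")

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= self.length:
            raise ValidationError(
                f"{self.accession}: position {position} outside 1..{self.length}")
        return self.sequence[position - 1].upper()


@dataclass(frozen=True)
class DomainHit:
    """A Pfam-style domain family match on a protein region."""

    protein: str
    domain_id: str
    domain_name: str
    start: int
    end: int
    evalue: float

    def validate(self, protein: ProteinRecord | None = None) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"{self.protein}/{self.domain_id}: bad span {self.start}-{self.end}")
        if self.evalue < 0:
            raise ValidationError(
                f"{self.protein}/{self.domain_id}: negative e-value {self.evalue}")
        if protein is not None and self.end > protein.length:
            raise ValidationError(
                f"{self.protein}/{self.domain_id}: end {self.end} beyond "
                f"sequence length {protein.length}")


@dataclass(frozen=True)
class PTMSite:
    """A post-translational modification at a specific residue."""

    protein: str
    position: int
    residue: str
    ptm_type: str
    source: str = ""

    def validate(self, protein: ProteinRecord | None = None) -> None:
        if self.ptm_type not in PTM_TYPES:
            raise ValidationError(
                f"{self.protein}@{self.position}: unknown PTM type {self.ptm_type!r}")
        if protein is not None:
            actual = protein.residue(self.position)
            if actual != self.residue.upper():
                raise ValidationError(
                    f"{self.protein}@{self.position}: annotated residue "
                    f"{self.residue} but sequence has {actual}")


@dataclass(frozen=True)
class VariantRecord:
    """A missense variant. Cancer variants carry a recurrence sample count."""

    protein: str
    position: int
    ref: str
    alt: str
    category: str = "user"
    disease_name: str | None = None
    sample_count: int | None = None
    source: str = "user"

    def validate(self, protein: ProteinRecord | None = None) -> None:
        if self.category not in VARIANT_CATEGORIES:
            raise ValidationError(
                f"{self.protein}@{self.position}: unknown category {self.category!r}")
        if self.category == "cancer":
            if self.sample_count is None:
                raise ValidationError(
                    f"{self.protein}@{self.position}: cancer variant without "
                    f"sample_count")
            if self.sample_count < 1:
                raise ValidationError(
                    f"{self.protein}@{self.position}: sample_count must be >= 1")
        elif self.sample_count is not None:
            raise ValidationError(
                f"{self.protein}@{self.position}: sample_count only valid for "
                f"cancer variants")
        if protein is not None:
            actual = protein.residue(self.position)
            if actual != self.ref.upper():
                raise ValidationError(
                    f"{self.protein}@{self.position}: reference residue "
                    f"{self.ref} does not match sequence residue {actual}")


@dataclass(frozen=True)
class UniProtFeature:
    """A curated positional feature (region, binding site, ...)."""

    protein: str
    ftype: str
    start: int
    end: int
    description: str = ""
    partner_gene: str | None = None

    def validate(self, protein: ProteinRecord | None = None) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValidationError(
                f"{self.protein}: unknown feature type {self.ftype!r}")
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"{self.protein}: bad feature span {self.start}-{self.end}")
        if protein is not None and self.end > protein.length:
            raise ValidationError(
                f"{self.protein}: feature end {self.end} beyond length "
                f"{protein.length}")


class Evidence(NamedTuple):
    """One experimental evidence record for a protein-protein interaction."""

    source_id: str
    method: str
    throughput: str

    @property
    def identity(self) -> tuple[str, str]:
        """Deduplication identity: throughput class is display metadata."""
        return (self.source_id, self.method)


@dataclass
class PPIRecord:
    """An unordered interacting protein pair with its evidence records."""

    pair: tuple[str, str]
    evidence: list[Evidence] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pair = canonical_pair(*self.pair)

    @property
    def n_distinct_sources(self) -> int:
        return len({ev.identity for ev in self.evidence})

    def validate(self) -> None:
        if not self.evidence:
            raise ValidationError(f"{self.pair}: PPI without evidence")
        if self.pair != canonical_pair(*self.pair):
            raise ValidationError(f"{self.pair}: pair not canonical")


@dataclass(frozen=True)
class StructCatalogEntry:
    """A domain pair (ddi) or domain-motif pair (dmi) seen in 3D structures."""

    kind: str  # "ddi" | "dmi"
    left: str
    right: str
    n_structures: int

    def validate(self) -> None:
        if self.kind not in ("ddi", "dmi"):
            raise ValidationError(f"unknown catalog kind {self.kind!r}")
        if self.n_structures < 1:
            raise ValidationError(
                f"{self.left}-{self.right}: n_structures must be >= 1")
        if self.kind == "ddi" and (self.left, self.right) != canonical_pair(self.left, self.right):
            raise ValidationError(
                f"ddi entry {self.left}-{self.right} not canonically ordered")


@dataclass(frozen=True)
class PredictedEdge:
    """A tertiary-structure-based interaction prediction for a protein pair."""

    pair: tuple[str, str]
    template: str
    z_score: float
    p_value: float
    region_left: tuple[int, int] | None = None
    region_right: tuple[int, int] | None = None

    def validate(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(
                f"{self.pair}: p_value {self.p_value} outside [0,1]")


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

def _read_tsv(path: str | os.PathLike, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                         na_values=[""])
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing columns {missing}")
    return df


def _cell(row, col, rowno: int, path, *, kind=str, optional: bool = False):
    val = row.get(col)
    if val is None or (isinstance(val, float) and math.isnan(val)):
        if optional:
            return None
        raise LoadError(f"{path}: row {rowno}: missing value for {col!r}")
    try:
        return kind(val)
    except (TypeError, ValueError):
        raise LoadError(
            f"{path}: row {rowno}: cannot parse {col}={val!r} as {kind.__name__}"
        ) from None


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def read_proteins(fasta_path: str | os.PathLike,
                  meta_path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a FASTA file plus a metadata table into protein records.

    The metadata TSV has columns ``accession``, ``gene``, ``taxon``; FASTA
    identifiers (first word of the header; UniProt ``db|ACC|name`` headers
    are unwrapped) must correspond one-to-one with metadata rows.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        ident = rec.id
        if "|" in ident:
            parts = ident.split("|")
            if len(parts) >= 3:
                ident = parts[1]
        if ident in seqs:
            raise LoadError(f"{fasta_path}: duplicate FASTA entry {ident!r}")
        seqs[ident] = str(rec.seq).upper()

    meta = _read_tsv(meta_path, ["accession", "gene", "taxon"])
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(meta.to_dict("records"), start=1):
        acc = _cell(row, "accession", i, meta_path)
        if acc in seen:
            raise LoadError(f"{meta_path}: duplicate accession {acc!r}")
        seen.add(acc)
        if acc not in seqs:
            raise LoadError(
                f"{meta_path}: accession {acc!r} has no FASTA sequence")
        rec = ProteinRecord(
            accession=acc,
            gene=_cell(row, "gene", i, meta_path),
            taxon=_cell(row, "taxon", i, meta_path),
            sequence=seqs[acc],
        )
        rec.validate()
        records.append(rec)
    orphans = set(seqs) - seen
    if orphans:
        raise LoadError(
            f"{fasta_path}: FASTA entries without metadata: {sorted(orphans)}")
    return records


def protein_index(proteins: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    """Index proteins by accession."""
    return {p.accession: p for p in proteins}


def read_domain_hits(path: str | os.PathLike, max_evalue: float = 0.001,
                     proteins: Iterable[ProteinRecord] | None = None,
                     ) -> list[DomainHit]:
    """Read a Pfam-style domain hit table, keeping hits with e-value
    ``<= max_evalue`` (the boundary is inclusive).

    Columns: ``protein, domain_id, domain_name, start, end, evalue``.
    When *proteins* is given, spans are validated against sequence lengths.
    """
    df = _read_tsv(path, ["protein", "domain_id", "domain_name",
                          "start", "end", "evalue"])
    idx = protein_index(proteins) if proteins is not None else None
    hits: list[DomainHit] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        hit = DomainHit(
            protein=_cell(row, "protein", i, path),
            domain_id=_cell(row, "domain_id", i, path),
            domain_name=_cell(row, "domain_name", i, path),
            start=_cell(row, "start", i, path, kind=int),
            end=_cell(row, "end", i, path, kind=int),
            evalue=_cell(row, "evalue", i, path, kind=float),
        )
        if hit.evalue > max_evalue:
            continue
        try:
            hit.validate(idx.get(hit.protein) if idx else None)
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
        hits.append(hit)
    return hits


def read_ppi(path: str | os.PathLike) -> list[PPIRecord]:
    """Read a PPI evidence table (one evidence record per row) and group
    rows by canonical unordered pair; (A,B) and (B,A) merge.

    Columns: ``protein_a, protein_b, source_id, method, throughput``.
    """
    df = _read_tsv(path, ["protein_a", "protein_b", "source_id",
                          "method", "throughput"])
    grouped: dict[tuple[str, str], list[Evidence]] = {}
    for i, row in enumerate(df.to_dict("records"), start=1):
        pair = canonical_pair(_cell(row, "protein_a", i, path),
                              _cell(row, "protein_b", i, path))
        ev = Evidence(
            source_id=_cell(row, "source_id", i, path),
            method=_cell(row, "method", i, path),
            throughput=_cell(row, "throughput", i, path),
        )
        grouped.setdefault(pair, []).append(ev)
    records = [PPIRecord(pair=pair, evidence=evs)
               for pair, evs in sorted(grouped.items())]
    for rec in records:
        rec.validate()
    return records


def read_ptms(path: str | os.PathLike,
              proteins: Iterable[ProteinRecord] | None = None) -> list[PTMSite]:
    """Read a PTM site table (``protein, position, residue, ptm_type, source``)."""
    df = _read_tsv(path, ["protein", "position", "residue", "ptm_type", "source"])
    idx = protein_index(proteins) if proteins is not None else None
    sites: list[PTMSite] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        site = PTMSite(
            protein=_cell(row, "protein", i, path),
            position=_cell(row, "position", i, path, kind=int),
            residue=_cell(row, "residue", i, path),
            ptm_type=_cell(row, "ptm_type", i, path),
            source=_cell(row, "source", i, path, optional=True) or "",
        )
        try:
            site.validate(idx.get(site.protein) if idx else None)
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
        sites.append(site)
    return sites


def read_uniprot_features(path: str | os.PathLike,
                          proteins: Iterable[ProteinRecord] | None = None,
                          ) -> list[UniProtFeature]:
    """Read curated positional features
    (``protein, ftype, start, end, description, partner_gene``)."""
    df = _read_tsv(path, ["protein", "ftype", "start", "end",
                          "description", "partner_gene"])
    idx = protein_index(proteins) if proteins is not None else None
    feats: list[UniProtFeature] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        feat = UniProtFeature(
            protein=_cell(row, "protein", i, path),
            ftype=_cell(row, "ftype", i, path),
            start=_cell(row, "start", i, path, kind=int),
            end=_cell(row, "end", i, path, kind=int),
            description=_cell(row, "description", i, path, optional=True) or "",
            partner_gene=_cell(row, "partner_gene", i, path, optional=True),
        )
        try:
            feat.validate(idx.get(feat.protein) if idx else None)
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
        feats.append(feat)
    return feats


# -- variant parsing --------------------------------------------------------

_SLASH_VARIANT = re.compile(
    r"^(?P<id>[A-Za-z0-9_.-]+)/p\.(?P<ref>[A-Za-z])(?P<pos>\d+)(?P<alt>[A-Za-z])$")
_PLAIN_VARIANT = re.compile(
    r"^(?P<id>[A-Za-z0-9_.-]+)\s+(?P<pos>\d+)\s+(?P<ref>[A-Za-z])\s+(?P<alt>[A-Za-z])$")


def _resolve_identifier(ident: str, idx: Mapping[str, ProteinRecord] | None) -> str:
    if idx is None:
        return ident
    if ident in idx:
        return ident
    matches = [p.accession for p in idx.values()
               if p.gene.upper() == ident.upper()]
    if len(matches) == 1:
        return matches[0]
    if len(matches) > 1:
        raise LoadError(f"ambiguous gene symbol {ident!r}: {sorted(matches)}")
    raise LoadError(f"unknown protein identifier {ident!r}")


def read_variants(path_or_text: str | os.PathLike,
                  proteins: Iterable[ProteinRecord] | None = None,
                  ) -> list[VariantRecord]:
    """Parse user-supplied variants from a file or inline text.

    Two grammars are accepted, one entry per line:
    ``ACCESSION/p.<Ref><Pos><Alt>`` (e.g. ``P51168/p.P617L``) and
    whitespace-separated ``ACCESSION POS REF ALT``. Gene symbols may stand
    in for accessions when they resolve unambiguously against *proteins*.
    Reference residues are checked against the sequence when proteins are
    supplied; a mismatch is an error.
    """
    text: str
    if isinstance(path_or_text, os.PathLike) or (
            isinstance(path_or_text, str) and "\n" not in path_or_text
            and os.path.exists(path_or_text)):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)

    idx = protein_index(proteins) if proteins is not None else None
    out: list[VariantRecord] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = _SLASH_VARIANT.match(line) or _PLAIN_VARIANT.match(line)
        if m is None:
            # a line may hold several slash-grammar tokens
            tokens = line.split()
            if len(tokens) > 1 and all(_SLASH_VARIANT.match(t) for t in tokens):
                for tok in tokens:
                    out.extend(read_variants(tok + "\n", proteins))
                continue
            raise LoadError(f"cannot parse variant entry {line!r}")
        acc = _resolve_identifier(m.group("id"), idx)
        var = VariantRecord(
            protein=acc,
            position=int(m.group("pos")),
            ref=m.group("ref").upper(),
            alt=m.group("alt").upper(),
            category="user",
            source="user",
        )
        var.validate(idx.get(acc) if idx else None)
        out.append(var)
    return out


def read_variant_table(path: str | os.PathLike,
                       proteins: Iterable[ProteinRecord] | None = None,
                       ) -> list[VariantRecord]:
    """Read a variant table with categories (disease/cancer/user).

    Columns: ``protein, position, ref, alt, category, disease_name,
    sample_count, source``; ``sample_count`` is required for (and only
    allowed on) cancer variants.
    """
    df = _read_tsv(path, ["protein", "position", "ref", "alt", "category",
                          "disease_name", "sample_count", "source"])
    idx = protein_index(proteins) if proteins is not None else None
    out: list[VariantRecord] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        count = _cell(row, "sample_count", i, path, kind=int, optional=True)
        var = VariantRecord(
            protein=_cell(row, "protein", i, path),
            position=_cell(row, "position", i, path, kind=int),
            ref=_cell(row, "ref", i, path).upper(),
            alt=_cell(row, "alt", i, path).upper(),
            category=_cell(row, "category", i, path),
            disease_name=_cell(row, "disease_name", i, path, optional=True),
            sample_count=count,
            source=_cell(row, "source", i, path, optional=True) or "",
        )
        try:
            var.validate(idx.get(var.protein) if idx else None)
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
        out.append(var)
    return out


def read_struct_catalog(path: str | os.PathLike) -> list[StructCatalogEntry]:
    """Read a structural interaction catalog
    (``kind, left, right, n_structures``); ddi pairs are canonicalized."""
    df = _read_tsv(path, ["kind", "left", "right", "n_structures"])
    entries: list[StructCatalogEntry] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        kind = _cell(row, "kind", i, path)
        left = _cell(row, "left", i, path)
        right = _cell(row, "right", i, path)
        if kind == "ddi":
            left, right = canonical_pair(left, right)
        entry = StructCatalogEntry(
            kind=kind, left=left, right=right,
            n_structures=_cell(row, "n_structures", i, path, kind=int),
        )
        try:
            entry.validate()
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
        entries.append(entry)
    return entries


def read_predicted_edges(path: str | os.PathLike) -> list[PredictedEdge]:
    """Read tertiary-structure interaction predictions.

    Columns: ``protein_a, protein_b, template, z_score, p_value`` plus
    optional interface intervals ``start_a, end_a, start_b, end_b``.
    """
    df = _read_tsv(path, ["protein_a", "protein_b", "template",
                          "z_score", "p_value"])
    edges: list[PredictedEdge] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        def span(s: str, e: str) -> tuple[int, int] | None:
            a = _cell(row, s, i, path, kind=int, optional=True)
            b = _cell(row, e, i, path, kind=int, optional=True)
            if a is None or b is None:
                return None
            return (a, b)

        edge = PredictedEdge(
            pair=canonical_pair(_cell(row, "protein_a", i, path),
                                _cell(row, "protein_b", i, path)),
            template=_cell(row, "template", i, path),
            z_score=_cell(row, "z_score", i, path, kind=float),
            p_value=_cell(row, "p_value", i, path, kind=float),
            region_left=span("start_a", "end_a"),
            region_right=span("start_b", "end_b"),
        )
        try:
            edge.validate()
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
        edges.append(edge)
    return edges


# ---------------------------------------------------------------------------
# Interaction table
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_interaction_table(network, path: str | os.PathLike) -> None:
    """Write the per-edge interaction table of a built mechanistic network.

    One tab-separated row per edge, columns :data:`INTERACTION_TABLE_COLUMNS`.
    Floats are written with full round-trip precision so that re-reading
    reproduces every edge attribute exactly.
    """
    nodes = {n.node_id: n for n in network.nodes}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(INTERACTION_TABLE_COLUMNS)
        for edge in network.edges:
            a = nodes[edge.endpoints[0]]
            b = nodes[edge.endpoints[1]]
            writer.writerow([
                a.protein, b.protein, edge.etype, a.label, b.label,
                _fmt(a.start), _fmt(a.end), _fmt(b.start), _fmt(b.end),
                _fmt(float(edge.weight)), _fmt(edge.p_value),
                edge.evidence, edge.attr_dict().get("provenance", ""),
            ])


def read_interaction_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back an interaction table written by
    :func:`write_interaction_table`, restoring numeric columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[""])
    missing = [c for c in INTERACTION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing columns {missing}")
    for col in ("start_a", "end_a", "start_b", "end_b"):
        df[col] = df[col].astype("Int64")
    for col in ("weight", "p_value"):
        df[col] = pd.to_numeric(df[col])
    return df
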