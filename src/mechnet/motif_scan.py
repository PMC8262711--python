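"""Short linear motif (SLiM) discovery by regular-expression scanning.

Motif classes (ELM- or 3did-derived) carry a regex pattern over the amino
acid alphabet. Scanning reports every match of every pattern, including
mutually overlapping ones: occurrences are positional features, and real
proteins (e.g. adjacent kinase recognition sites) do overlap. Where a
pattern admits matches of several lengths at one start position, the
longest is recorded, which makes output deterministic.

Matching is case-insensitive against the upper-cased sequence; ``^`` and
``$`` anchor to the full sequence, not to window boundaries.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .annotations_io import (DomainHit, LoadError, ProteinRecord,
                             ValidationError, _cell, _read_tsv)

MOTIF_SOURCES = frozenset({"elm", "3did"})


class PatternError(ValueError):
    """Raised when a motif class pattern does not compile."""


@dataclass(frozen=True)
class MotifClass:
    """A motif class: an identifier plus a sequence pattern."""

    class_id: str
    name: str
    pattern: str
    source: str = "elm"

    def validate(self) -> None:
        if not self.pattern:
            raise PatternError(f"{self.class_id}: empty pattern")
        if self.source not in MOTIF_SOURCES:
            raise ValidationError(
                f"{self.class_id}: unknown source {self.source!r}")
        try:
            re.compile(self.pattern, re.IGNORECASE)
        except re.error as exc:
            raise PatternError(
                f"{self.class_id}: pattern {self.pattern!r} does not compile: "
                f"{exc}") from None


@dataclass(frozen=True)
class MotifInstance:
    """An occurrence of a motif class on a protein (1-based inclusive span).

    ``status`` is ``predicted`` for pure pattern matches and ``annotated``
    for curated, experimentally supported instances.
    """

    protein: str
    class_id: str
    start: int
    end: int
    matched_seq: str
    status: str = "predicted"

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.protein, self.class_id, self.start, self.end)

    def validate(self, protein: ProteinRecord,
                 motif_class: MotifClass | None = None) -> None:
        if not 1 <= self.start <= self.end <= protein.length:
            raise ValidationError(
                f"{self.protein}/{self.class_id}: span {self.start}-{self.end} "
                f"outside 1..{protein.length}")
        actual = protein.sequence[self.start - 1:self.end].upper()
        if actual != self.matched_seq.upper():
            raise ValidationError(
                f"{self.protein}/{self.class_id}: matched_seq "
                f"{self.matched_seq!r} != sequence {actual!r}")
        if motif_class is not None:
            core, a_start, a_end = _split_anchors(motif_class.pattern)
            rx = re.compile(core, re.IGNORECASE)
            if not rx.fullmatch(actual) or \
                    (a_start and self.start != 1) or \
                    (a_end and self.end != protein.length):
                raise ValidationError(
                    f"{self.protein}/{self.class_id}: {actual!r} does not "
                    f"match pattern {motif_class.pattern!r}")


def _split_anchors(pattern: str) -> tuple[str, bool, bool]:
    """Strip outer ``^``/``$`` anchors; matching is then done on substrings
    with the anchors enforced as positional constraints on the full sequence."""
    anchored_start = pattern.startswith("^")
    core = pattern[1:] if anchored_start else pattern
    anchored_end = core.endswith("$") and not core.endswith(r"\$")
    if anchored_end:
        core = core[:-1]
    return core, anchored_start, anchored_end


def scan_motifs(protein: ProteinRecord,
                classes: Iterable[MotifClass]) -> list[MotifInstance]:
    """Find every occurrence of every motif class in a protein sequence.

    All matches are reported, including overlapping ones (the scan restarts
    at every residue, it does not skip past a match). For several possible
    match lengths at one start, the longest is kept. Returned instances
    have ``status = "predicted"`` and are sorted by (class_id, start, end).

    Raises :class:`PatternError` for a class whose pattern does not compile.
    """
    seq = protein.sequence.upper()
    n = len(seq)
    out: list[MotifInstance] = []
    for cls in classes:
        cls.validate()
        core, a_start, a_end = _split_anchors(cls.pattern)
        rx = re.compile(core, re.IGNORECASE)
        starts = [0] if a_start else range(n)
        for pos in starts:
            m = rx.match(seq, pos) if not a_end else None
            if a_end:
                # anchored at the C terminus: only the suffix can match
                if rx.fullmatch(seq, pos, n):
                    out.append(MotifInstance(
                        protein=protein.accession, class_id=cls.class_id,
                        start=pos + 1, end=n, matched_seq=seq[pos:n]))
                continue
            if m is None:
                continue
            # regex "match" is leftmost-preferred, not longest; probe longer
            # ends explicitly so the recorded instance is leftmost-longest
            best_end = m.end()
            for end in range(n, best_end, -1):
                if rx.fullmatch(seq, pos, end):
                    best_end = end
                    break
            if best_end == pos:
                continue  # zero-length match carries no positional feature
            out.append(MotifInstance(
                protein=protein.accession, class_id=cls.class_id,
                start=pos + 1, end=best_end,
                matched_seq=seq[pos:best_end]))
    out.sort(key=lambda m: (m.class_id, m.start, m.end))
    return out


def merge_annotated(predicted: Sequence[MotifInstance],
                    curated: Sequence[MotifInstance]) -> list[MotifInstance]:
    """Merge curated instances into a predicted set.

    A predicted instance identical to a curated one in
    (protein, class_id, start, end) is re-labelled ``annotated``; curated
    instances with no matching prediction are appended as ``annotated``.
    """
    curated_keys = {inst.key for inst in curated}
    merged: list[MotifInstance] = []
    seen: set[tuple] = set()
    for inst in predicted:
        if inst.key in curated_keys:
            inst = replace(inst, status="annotated")
        merged.append(inst)
        seen.add(inst.key)
    for inst in curated:
        if inst.key not in seen:
            merged.append(replace(inst, status="annotated"))
            seen.add(inst.key)
    return merged


def filter_instances(instances: Sequence[MotifInstance],
                     domains: Sequence[DomainHit] = (),
                     confirmed_only: bool = False,
                     exclude_in_domains: bool = False) -> list[MotifInstance]:
    """Apply the display toggles to a motif instance list.

    ``confirmed_only`` drops predicted instances; ``exclude_in_domains``
    drops instances whose span is *fully contained* in a same-protein
    domain hit (a motif straddling a domain boundary is still partly in
    disordered sequence and is kept). Output is always a subset of input.
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for d in domains:
        by_protein.setdefault(d.protein, []).append(d)

    def inside_domain(inst: MotifInstance) -> bool:
        return any(d.start <= inst.start and inst.end <= d.end
                   for d in by_protein.get(inst.protein, ()))

    out = []
    for inst in instances:
        if confirmed_only and inst.status != "annotated":
            continue
        if exclude_in_domains and inside_domain(inst):
            continue
        out.append(inst)
    return out


# ---------------------------------------------------------------------------
# Catalog loaders
# ---------------------------------------------------------------------------

def load_motif_classes(path: str | os.PathLike) -> list[MotifClass]:
    """Read a motif class catalog TSV: ``class_id, name, pattern, source``."""
    df = _read_tsv(path, ["class_id", "name", "pattern", "source"])
    classes: list[MotifClass] = []
    seen: set[str] = set()
    for i, row in enumerate(df.to_dict("records"), start=1):
        cls = MotifClass(
            class_id=_cell(row, "class_id", i, path),
            name=_cell(row, "name", i, path, optional=True) or "",
            pattern=_cell(row, "pattern", i, path),
            source=_cell(row, "source", i, path),
        )
        if cls.class_id in seen:
            raise LoadError(f"{path}: row {i}: duplicate class {cls.class_id!r}")
        seen.add(cls.class_id)
        cls.validate()
        classes.append(cls)
    return classes


def load_curated_instances(path: str | os.PathLike,
                           proteins: Iterable[ProteinRecord],
                           classes: Iterable[MotifClass] | None = None,
                           ) -> list[MotifInstance]:
    """Read curated motif instances (``protein, class_id, start, end``),
    validating spans and pattern agreement against the sequences."""
    from .annotations_io import protein_index
    df = _read_tsv(path, ["protein", "class_id", "start", "end"])
    idx = protein_index(proteins)
    cls_idx = {c.class_id: c for c in classes} if classes is not None else {}
    out: list[MotifInstance] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        acc = _cell(row, "protein", i, path)
        if acc not in idx:
            raise LoadError(f"{path}: row {i}: unknown protein {acc!r}")
        start = _cell(row, "start", i, path, kind=int)
        end = _cell(row, "end", i, path, kind=int)
        prot = idx[acc]
        if not 1 <= start <= end <= prot.length:
            raise ValidationError(
                f"{path}: row {i}: span {start}-{end} outside 1..{prot.length}")
        inst = MotifInstance(
            protein=acc,
            class_id=_cell(row, "class_id", i, path),
            start=start, end=end,
            matched_seq=prot.sequence[start - 1:end].upper(),
            status="annotated",
        )
        inst.validate(prot, cls_idx.get(inst.class_id))
        out.append(inst)
    return out
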