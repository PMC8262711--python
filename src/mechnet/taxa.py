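"""Organism tags and their lineage tag sets.

Motif-domain interaction rules may restrict an interaction to a clade
(e.g. Metazoa-only motifs). Rather than carrying a full taxonomy, each
supported organism maps to a flat set of lineage tags; a rule's
``taxa_allow`` passes if it intersects the organism's tag set or names
the organism itself.
"""

from __future__ import annotations

ORGANISM_LINEAGES: dict[str, frozenset[str]] = {
    "human": frozenset({"Eukaryota", "Opisthokonta", "Metazoa", "Chordata", "Vertebrata", "Mammalia"}),
    "mouse": frozenset({"Eukaryota", "Opisthokonta", "Metazoa", "Chordata", "Vertebrata", "Mammalia"}),
    "zebrafish": frozenset({"Eukaryota", "Opisthokonta", "Metazoa", "Chordata", "Vertebrata"}),
    "fly": frozenset({"Eukaryota", "Opisthokonta", "Metazoa", "Arthropoda"}),
    "worm": frozenset({"Eukaryota", "Opisthokonta", "Metazoa", "Nematoda"}),
    "yeast": frozenset({"Eukaryota", "Opisthokonta", "Fungi"}),
}

SUPPORTED_ORGANISMS = frozenset(ORGANISM_LINEAGES)


def lineage_tags(organism: str) -> frozenset[str]:
    """Lineage tags for *organism*, including the organism tag itself."""
    try:
        return ORGANISM_LINEAGES[organism] | {organism}
    except KeyError:
        raise KeyError(f"unsupported organism tag: {organism!r}") from None
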