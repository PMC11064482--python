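"""Shared label sets for the Sphingomonas climate-gradient analysis.

The classifier's label universe is 12 phylogenetic clades (named "1".."12"),
named pseudo clades for reads whose best alignment identity ties across
several clades (e.g. "1-2"), and a catch-all "broad_pseudo" bin for rare
pseudo clades. Trait columns follow the Y-A-S life-history framework:
growth Yield, resource Acquisition, Stress tolerance.
"""

from __future__ import annotations

N_CLADES = 12
MAIN_CLADES: tuple[str, ...] = tuple(str(i) for i in range(1, N_CLADES + 1))
BROAD_PSEUDO = "broad_pseudo"
BACKGROUND = "background"

SITES: tuple[str, ...] = ("desert", "scrubland", "grassland", "pine-oak", "subalpine")
GRASSLAND = "grassland"

#: the eight genome-based trait categories with their life-history strategy tag
TRAIT_STRATEGY: dict[str, str] = {
    "amino_acid_related_enzymes": "Y",
    "lipid_biosynthesis_proteins": "Y",
    "lipopolysaccharide_biosynthesis_proteins": "Y",
    "CAZymes": "A",
    "polycyclic_aromatic_hydrocarbon_degradation": "A",
    "chaperones_and_folding_catalysts": "S",
    "peptidoglycan_biosynthesis_and_degradation": "S",
    "prokaryotic_defense_system": "S",
}
TRAIT_CATEGORIES: tuple[str, ...] = tuple(TRAIT_STRATEGY)


def pseudo_label(clades) -> str:
    """Label for the tie set of clades, sorted numerically: {2, 1} -> "1-2"."""
    ids = sorted({int(c) for c in clades})
    if len(ids) < 2:
        raise ValueError("a pseudo clade needs at least two distinct clades")
    return "-".join(str(i) for i in ids)


def is_pseudo(label: str) -> bool:
    """True for named pseudo-clade labels such as "1-2" (not broad_pseudo)."""
    return "-" in label and label not in SITES


def is_main_clade(label: str) -> bool:
    return label in MAIN_CLADES


def sort_labels(labels) -> list[str]:
    """Canonical column order: main clades 1..12, named pseudo clades, broad."""

    def key(lab: str):
        if lab == BROAD_PSEUDO:
            return (2, ())
        if is_pseudo(lab):
            return (1, tuple(int(c) for c in lab.split("-")))
        return (0, (int(lab),))

    return sorted(labels, key=key)
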