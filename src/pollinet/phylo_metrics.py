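"""Phylogeny-derived community metrics.

Plant phylogenetic diversity (mean tip-to-MRCA distance) and per-plant
phylogenetic uniqueness (mean patristic distance to the other plants in the
same community).  Plants absent from the tree are excluded with a warning
rather than assigned fabricated distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .network_io import PlantPhylogeny

__all__ = [
    "CommunityPhyloMetrics",
    "phylogenetic_diversity",
    "phylogenetic_uniqueness",
    "community_phylo_metrics",
]


@dataclass(frozen=True)
class CommunityPhyloMetrics:
    phylo_diversity: float | None
    uniqueness: dict[str, float]
    excluded: tuple[str, ...]


def phylogenetic_diversity(tree: PlantPhylogeny, taxa) -> float:
    """Mean path length from each taxon tip to the MRCA of the taxon set."""
    taxa = list(taxa)
    if len(taxa) < 2:
        raise ValueError("phylogenetic diversity needs at least 2 taxa")
    mrca = tree.mrca(taxa)
    mrca_depth = tree.depth(mrca)
    dists = [tree.depth(tree._tip(t)) - mrca_depth for t in taxa]
    return sum(dists) / len(dists)


def phylogenetic_uniqueness(tree: PlantPhylogeny, focal: str, others) -> float:
    """Mean patristic distance from the focal plant to each other plant."""
    others = [o for o in others if o != focal]
    if not others:
        raise ValueError("uniqueness needs at least one other taxon")
    return sum(tree.distance(focal, o) for o in others) / len(others)


def community_phylo_metrics(tree: PlantPhylogeny, plant_ids) -> CommunityPhyloMetrics:
    """Diversity plus per-plant uniqueness for one community.

    Plants not resolvable on the tree are excluded from both metrics.
    """
    resolvable = [p for p in plant_ids if p in tree._tips]
    excluded = tuple(p for p in plant_ids if p not in tree._tips)
    if excluded:
        warnings.warn(
            f"{len(excluded)} plants not on the tree were excluded: "
            + ", ".join(excluded),
            stacklevel=2,
        )
    diversity = (
        phylogenetic_diversity(tree, resolvable) if len(resolvable) >= 2 else None
    )
    uniqueness = {
        p: phylogenetic_uniqueness(tree, p, resolvable)
        for p in resolvable
        if len(resolvable) >= 2
    }
    return CommunityPhyloMetrics(
        phylo_diversity=diversity, uniqueness=uniqueness, excluded=excluded
    )
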