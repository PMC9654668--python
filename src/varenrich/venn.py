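"""Partition of enriched pathways across study groups into Venn regions.

After per-group enrichment, each pathway enriched anywhere is assigned to
the region of exactly the groups in which it is enriched: "exclusive"
enriched pathways sit in single-group regions, shared ones in multi-group
regions. Region keys are canonical sorted label tuples so the partition is
deterministic and invariant to input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

from .enrichment import EnrichmentResult


def select_enriched(result: EnrichmentResult, alpha: float | None = None) -> frozenset[str]:
    """Pathways called enriched: adj_p < alpha and fold > 1 (enrichment direction)."""
    if alpha is None:
        alpha = result.alpha
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return frozenset(
        r.pathway_id for r in result.records if r.adj_p < alpha and r.fold > 1.0
    )


@dataclass(frozen=True)
class VennPartition:
    """Mapping from group-label combination to the pathways enriched in
    exactly those groups. Empty regions are omitted from ``region_map`` but
    reported with size 0 by :meth:`region_sizes`."""

    region_map: Mapping[tuple[str, ...], frozenset[str]]
    group_labels: tuple[str, ...]

    def region_sizes(self) -> dict[tuple[str, ...], int]:
        """Sizes for every non-empty subset of groups, zeros included."""
        sizes: dict[tuple[str, ...], int] = {}
        for r in range(1, len(self.group_labels) + 1):
            for combo in combinations(self.group_labels, r):
                sizes[combo] = len(self.region_map.get(combo, frozenset()))
        return sizes


def venn_partition(enriched: Mapping[str, Iterable[str]]) -> VennPartition:
    """Assign each pathway to the region of exactly the groups containing it."""
    if len(enriched) < 2:
        raise ValueError("venn_partition requires at least two groups")
    sets = {label: frozenset(ids) for label, ids in enriched.items()}
    labels = tuple(sorted(sets))
    regions: dict[tuple[str, ...], set[str]] = {}
    for pid in frozenset().union(*sets.values()):
        combo = tuple(lab for lab in labels if pid in sets[lab])
        regions.setdefault(combo, set()).add(pid)
    return VennPartition(
        region_map={combo: frozenset(ids) for combo, ids in regions.items()},
        group_labels=labels,
    )


def write_venn_tsv(partition: VennPartition, path: str | Path) -> None:
    """Venn report TSV: region (labels joined by '+'), n_pathways, sorted ids."""
    sizes = partition.region_sizes()
    with Path(path).open("wt", encoding="utf-8") as fh:
        fh.write("region\tn_pathways\tpathway_ids\n")
        for combo in sorted(sizes, key=lambda c: (len(c), c)):
            ids = sorted(partition.region_map.get(combo, frozenset()))
            fh.write(f"{'+'.join(combo)}\t{sizes[combo]}\t{','.join(ids)}\n")
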