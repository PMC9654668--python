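"""Pathway gene-set databases and reference-population background counts.

A :class:`PathwayDB` maps Reactome-style pathway identifiers to gene-symbol
sets and maintains the inverse gene -> pathway index. :class:`BackgroundCounts`
summarises, per pathway, how many distinct variants a large reference
population (e.g. gnomAD non-Finnish Europeans) carries in that pathway's
genes, together with the single grand total N2 over the whole pathway
universe that every pathway shares as denominator.

Two conventions matter downstream:

* the background total N2 is defined over the *pathway universe* only —
  variants in genes that belong to no pathway do not count, so one constant
  denominator serves every pathway;
* a background variant in a gene shared by k pathways contributes to each of
  the k per-pathway counts but only once to the total, mirroring how
  overlapping gene sets are handled in over-representation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

#: sentinel row carrying the background grand total in the counts file format
TOTAL_KEY = "__TOTAL__"


@dataclass(frozen=True)
class Pathway:
    """One gene set: a Reactome-style identifier, a free-text name, and its genes."""

    pathway_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise ValueError("pathway_id must be non-empty")
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id!r} has an empty gene set")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)


class PathwayDB:
    """Indexed collection of pathways.

    Parameters
    ----------
    pathways
        Pathways with unique identifiers. Gene symbols are case-normalised
        to uppercase by :class:`Pathway`.

    Attributes
    ----------
    gene_index
        Mapping gene symbol -> frozenset of pathway_ids containing it; the
        exact inverse of the pathway -> genes relation.
    universe
        Union of all pathway gene sets.
    """

    def __init__(self, pathways: Iterable[Pathway]):
        self._pathways: dict[str, Pathway] = {}
        index: dict[str, set[str]] = {}
        for pw in pathways:
            if pw.pathway_id in self._pathways:
                raise ValueError(f"duplicate pathway_id {pw.pathway_id!r}")
            self._pathways[pw.pathway_id] = pw
            for g in pw.genes:
                index.setdefault(g, set()).add(pw.pathway_id)
        if not self._pathways:
            raise ValueError("PathwayDB requires at least one pathway")
        self.gene_index: dict[str, frozenset[str]] = {
            g: frozenset(p) for g, p in index.items()
        }
        self.universe: frozenset[str] = frozenset(index)

    @property
    def pathways(self) -> tuple[Pathway, ...]:
        return tuple(self._pathways.values())

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(self._pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        return self._pathways[pathway_id]

    def __contains__(self, pathway_id: object) -> bool:
        return pathway_id in self._pathways

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self._pathways.values())

    def __len__(self) -> int:
        return len(self._pathways)


@dataclass(frozen=True)
class BackgroundCounts:
    """Per-pathway background variant counts c and the shared total N2.

    ``per_pathway[pid]`` is the number of distinct reference-population
    variants falling in genes of pathway ``pid``; ``total`` is the number of
    distinct background variants over the whole pathway universe.
    """

    per_pathway: Mapping[str, int]
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError(f"background total must be positive, got {self.total}")
        for pid, c in self.per_pathway.items():
            if c < 0:
                raise ValueError(f"negative background count for {pid!r}: {c}")
            if c > self.total:
                raise ValueError(
                    f"background count for {pid!r} ({c}) exceeds total ({self.total})"
                )


def read_gmt(path: str | Path) -> PathwayDB:
    """Read a GMT gene-set file (tab-separated: id, description, genes...).

    Gene symbols are uppercased; duplicate symbols within a line are dropped
    (logged). A line with fewer than three fields, a duplicate pathway id, or
    an empty file raises :class:`ValueError`.
    """
    path = Path(path)
    pathways: list[Pathway] = []
    n_dupes = 0
    with path.open("rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs id, description and >=1 gene "
                    f"(got {len(fields)} fields)"
                )
            pid, name, *genes = fields
            genes = [g.strip().upper() for g in genes if g.strip()]
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {pid!r} lists no genes")
            uniq = list(dict.fromkeys(genes))
            n_dupes += len(genes) - len(uniq)
            pathways.append(Pathway(pid, name, frozenset(uniq)))
    if not pathways:
        raise ValueError(f"{path}: empty GMT file")
    if n_dupes:
        logger.info("read_gmt(%s): dropped %d duplicate gene symbols", path, n_dupes)
    return PathwayDB(pathways)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    """Write a PathwayDB in GMT format with genes sorted for determinism."""
    with Path(path).open("wt", encoding="utf-8") as fh:
        for pw in db:
            fh.write("\t".join([pw.pathway_id, pw.name, *sorted(pw.genes)]) + "\n")


def read_background_counts(path: str | Path, db: PathwayDB) -> BackgroundCounts:
    """Read a background-counts table (``pathway_id\\tcount`` + ``__TOTAL__`` row).

    Pathways present in ``db`` but missing from the table get c = 0 (logged).
    Unknown pathway ids, counts exceeding the total, or a non-positive total
    raise :class:`ValueError`.
    """
    path = Path(path)
    counts: dict[str, int] = {}
    total: int | None = None
    with path.open("rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["pathway_id", "count"]:
            raise ValueError(
                f"{path}: expected header 'pathway_id\\tcount', got {header!r}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields")
            key, value = fields
            try:
                count = int(value)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer count {value!r}") from exc
            if key == TOTAL_KEY:
                total = count
            else:
                counts[key] = count
    if total is None:
        raise ValueError(f"{path}: missing {TOTAL_KEY} row")
    unknown = sorted(set(counts) - set(db.pathway_ids))
    if unknown:
        raise ValueError(f"{path}: pathway ids not in database: {unknown}")
    missing = [pid for pid in db.pathway_ids if pid not in counts]
    if missing:
        logger.warning(
            "read_background_counts(%s): %d pathways absent from table, set c=0",
            path,
            len(missing),
        )
        for pid in missing:
            counts[pid] = 0
    return BackgroundCounts(per_pathway=counts, total=total)


def write_background_counts(bg: BackgroundCounts, path: str | Path) -> None:
    """Write background counts in the tab-separated format read_background_counts reads."""
    with Path(path).open("wt", encoding="utf-8") as fh:
        fh.write("pathway_id\tcount\n")
        for pid in sorted(bg.per_pathway):
            fh.write(f"{pid}\t{bg.per_pathway[pid]}\n")
        fh.write(f"{TOTAL_KEY}\t{bg.total}\n")


def background_from_gene_counts(
    gene_counts: Mapping[str, int], db: PathwayDB
) -> BackgroundCounts:
    """Aggregate per-gene background variant counts into per-pathway counts.

    c(pathway) = sum of gene_counts over the pathway's genes; the total N2 is
    the sum over the pathway universe only, so a gene shared by k pathways is
    counted in each of the k pathway sums but once in the total. Genes outside
    the universe are ignored (their variant count is logged).
    """
    norm = {g.upper(): int(n) for g, n in gene_counts.items()}
    for g, n in norm.items():
        if n < 0:
            raise ValueError(f"negative variant count for gene {g!r}: {n}")
    ignored = sum(n for g, n in norm.items() if g not in db.universe)
    if ignored:
        logger.info(
            "background_from_gene_counts: %d variants in genes outside the "
            "pathway universe ignored",
            ignored,
        )
    total = sum(n for g, n in norm.items() if g in db.universe)
    per_pathway = {
        pw.pathway_id: sum(norm.get(g, 0) for g in pw.genes) for pw in db
    }
    if total <= 0:
        raise ValueError("no background variants fall in the pathway universe")
    return BackgroundCounts(per_pathway=per_pathway, total=total)
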