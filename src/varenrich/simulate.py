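"""Synthetic pathway databases, backgrounds and cohorts for end-to-end testing.

The generator emulates the statistical structure the analysis assumes:

* a pathway database whose gene sets overlap (genes are drawn without
  replacement within a pathway but with replacement across pathways);
* a large reference population whose per-gene variant counts follow Poisson
  laws with skewed gene-specific rates, scaled so the realised universe
  total approximates a target;
* small study groups whose members share a core variant set (present in all
  members) plus private variants, both drawn with per-gene probabilities
  proportional to the background rates — optionally inflated multiplicatively
  in the genes of "planted" pathways, which is the ground-truth enrichment
  signal;
* per-record genotype quality (GQ) and alt-allele depth (AD) drawn so a
  configurable fraction of records fails the standard GQ > 30 / AD > 10
  filters, and formalin-artifact C>T / G>A allele pairs injected at a
  configurable rate.

A single integer seed governs every draw through one ``numpy`` SeedSequence
whose children are consumed in a fixed order (pathway database, background,
then one per group), so (spec, seed) -> byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .enrichment import CohortGroup, VEAConfig
from .pathways import (
    BackgroundCounts,
    Pathway,
    PathwayDB,
    background_from_gene_counts,
    write_background_counts,
    write_gmt,
)
from .variants import AnnotatedVariant, apply_quality_filters, is_ffpe_suspect, write_variants_tsv

logger = logging.getLogger(__name__)

# ordered SNV allele pairs; the two formalin-artifact pairs are kept apart so
# their injection rate is controlled explicitly
_FFPE_PAIRS = (("C", "T"), ("G", "A"))
_CLEAN_PAIRS = tuple(
    (r, a)
    for r in "ACGT"
    for a in "ACGT"
    if r != a and (r, a) not in _FFPE_PAIRS
)

_GENE_WINDOW = 90_000  # bp of usable positions per simulated gene


@dataclass(frozen=True)
class GroupSpec:
    """One study group: label, size, and planted per-pathway rate multipliers."""

    label: str
    n_members: int
    planted: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError(f"group {self.label!r} needs at least one member")
        for pid, mult in self.planted.items():
            if mult < 1.0:
                raise ValueError(
                    f"planted multiplier for {pid!r} must be >= 1, got {mult}"
                )


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the generator.

    The defaults are the desk-scale preset: 200 pathways over a 2,000-gene
    pool, a background total of 2 x 10^4, and CTRL/LC/MPM groups of 5/7/7 —
    small enough for seconds-scale runs while keeping the group-common over
    background ratio (~1100/20000) on the scale of real group-level WES runs
    (thousands over ~1.8 x 10^5).
    """

    seed: int
    n_pathways: int = 200
    genes_per_pathway: tuple[int, int] = (10, 40)
    gene_pool: int = 2000
    background_total: int = 20_000
    groups: tuple[GroupSpec, ...] = (
        GroupSpec("CTRL", 5),
        GroupSpec("LC", 7),
        GroupSpec("MPM", 7),
    )
    core_share: float = 0.4
    private_rate: float = 300.0
    quality_fail_rate: float = 0.02
    ffpe_rate: float = 0.10

    def __post_init__(self) -> None:
        lo, hi = self.genes_per_pathway
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid genes_per_pathway range {self.genes_per_pathway}")
        if self.gene_pool < hi:
            raise ValueError(
                f"gene_pool ({self.gene_pool}) smaller than max pathway size ({hi})"
            )
        if self.n_pathways < 1:
            raise ValueError("n_pathways must be positive")
        if self.background_total <= 0:
            raise ValueError("background_total must be positive")
        for p in (self.core_share, self.quality_fail_rate, self.ffpe_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.core_share >= 1.0:
            raise ValueError("core_share must be < 1")
        if self.private_rate < 0:
            raise ValueError("private_rate must be non-negative")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationSpec":
        data = dict(data)
        if "groups" in data:
            data["groups"] = tuple(
                GroupSpec(
                    label=g["label"],
                    n_members=int(g["n_members"]),
                    planted={k: float(v) for k, v in (g.get("planted") or {}).items()},
                )
                for g in data["groups"]
            )
        if "genes_per_pathway" in data:
            data["genes_per_pathway"] = tuple(data["genes_per_pathway"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationSpec":
        import yaml

        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_pathways": self.n_pathways,
            "genes_per_pathway": list(self.genes_per_pathway),
            "gene_pool": self.gene_pool,
            "background_total": self.background_total,
            "groups": [
                {
                    "label": g.label,
                    "n_members": g.n_members,
                    "planted": dict(g.planted),
                }
                for g in self.groups
            ],
            "core_share": self.core_share,
            "private_rate": self.private_rate,
            "quality_fail_rate": self.quality_fail_rate,
            "ffpe_rate": self.ffpe_rate,
        }


def _streams(spec: SimulationSpec) -> list[np.random.SeedSequence]:
    """Fixed stream-splitting order: [db, background, group_0, group_1, ...]."""
    return np.random.SeedSequence(spec.seed).spawn(2 + len(spec.groups))


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def gene_coordinates(gene_index: int) -> tuple[str, int]:
    """Deterministic (chrom, window_start) for a simulated gene."""
    chrom = f"chr{gene_index % 22 + 1}"
    start = (gene_index // 22) * (_GENE_WINDOW + 10_000) + 1
    return chrom, start


def simulate_pathway_db(spec: SimulationSpec) -> PathwayDB:
    """Draw pathway gene sets from the pool; overlap across pathways allowed."""
    rng = np.random.default_rng(_streams(spec)[0])
    genes = _gene_names(spec.gene_pool)
    lo, hi = spec.genes_per_pathway
    pathways = []
    for i in range(spec.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(spec.gene_pool, size=size, replace=False)
        pathways.append(
            Pathway(
                pathway_id=f"R-SIM-{i + 1:06d}",
                name=f"simulated pathway {i + 1}",
                genes=frozenset(genes[j] for j in chosen),
            )
        )
    return PathwayDB(pathways)


def _simulate_gene_counts(db: PathwayDB, spec: SimulationSpec) -> dict[str, int]:
    """Per-gene background variant counts (the whole pool, not just the universe)."""
    rng = np.random.default_rng(_streams(spec)[1])
    genes = _gene_names(spec.gene_pool)
    # skewed gene-specific rates (few hot genes, many cold), scaled so the
    # expected total over the pathway universe hits the target
    rates = rng.gamma(shape=1.2, scale=1.0, size=spec.gene_pool)
    in_universe = np.array([g in db.universe for g in genes])
    universe_rate = rates[in_universe].sum()
    if universe_rate <= 0:
        raise ValueError("degenerate background rates")
    rates *= spec.background_total / universe_rate
    counts = rng.poisson(rates)
    return dict(zip(genes, (int(c) for c in counts)))


def simulate_background(db: PathwayDB, spec: SimulationSpec) -> BackgroundCounts:
    """Aggregate simulated per-gene counts into per-pathway background counts."""
    return background_from_gene_counts(_simulate_gene_counts(db, spec), db)


@dataclass(frozen=True)
class SimulatedCohort:
    """Generator output for one group: raw records plus the planted truth."""

    label: str
    members: tuple[str, ...]
    records: tuple[AnnotatedVariant, ...]
    truth: frozenset[str]

    def to_group(self, config: VEAConfig | None = None) -> CohortGroup:
        """Quality-filter the records and assemble the CohortGroup."""
        cfg = config or VEAConfig()
        kept = apply_quality_filters(
            self.records, gq_min=cfg.gq_min, ad_min=cfg.ad_min, ffpe_mode=cfg.ffpe_mode
        )
        return CohortGroup.from_variants(self.label, kept, members=self.members)


def _weights_from_background(db: PathwayDB, bg: BackgroundCounts) -> dict[str, float]:
    """Approximate per-gene weights from aggregated pathway counts.

    Each pathway's count is split equally over its genes; genes in several
    pathways average their shares (the aggregation double-counts them).
    """
    acc: dict[str, float] = {}
    deg: dict[str, int] = {}
    for pw in db:
        share = bg.per_pathway.get(pw.pathway_id, 0) / len(pw.genes)
        for g in pw.genes:
            acc[g] = acc.get(g, 0.0) + share
            deg[g] = deg.get(g, 0) + 1
    return {g: acc[g] / deg[g] for g in acc}


def simulate_cohort(
    db: PathwayDB,
    bg: BackgroundCounts,
    group_spec: GroupSpec,
    seed: int | np.random.SeedSequence,
    *,
    core_share: float = 0.4,
    private_rate: float = 300.0,
    quality_fail_rate: float = 0.02,
    ffpe_rate: float = 0.10,
    gene_weights: Mapping[str, float] | None = None,
) -> SimulatedCohort:
    """Draw one group: a core variant set shared by all members plus private
    variants per member, with per-gene probabilities proportional to the
    background rates times the planted multiplier.

    ``core_share`` is the probability that a cohort variant is shared by all
    members, so the expected core size is
    ``core_share / (1 - core_share) * n_members * private_rate``.
    """
    for pid in group_spec.planted:
        if pid not in db:
            raise ValueError(f"planted pathway {pid!r} not in the database")
    rng = np.random.default_rng(seed)
    if gene_weights is None:
        gene_weights = _weights_from_background(db, bg)
    genes = sorted(gene_weights)
    gene_pos = {g: i for i, g in enumerate(genes)}

    # stable per-gene integer index for coordinates: genes following the
    # simulator's G##### convention keep their pool index, others fall back
    # to their rank in sorted order
    def _coord_index(g: str) -> int:
        if g.startswith("G") and g[1:].isdigit():
            return int(g[1:])
        return gene_pos[g]

    base = np.array([max(float(gene_weights[g]), 0.0) for g in genes])
    mult = np.ones_like(base)
    for pid, m in group_spec.planted.items():
        for g in db[pid].genes:
            if g in gene_pos:
                mult[gene_pos[g]] = max(mult[gene_pos[g]], float(m))
    weighted = base * mult
    total_w = weighted.sum()
    if total_w <= 0:
        raise ValueError("all gene weights are zero")
    probs = weighted / total_w

    n_members = group_spec.n_members
    members = tuple(f"{group_spec.label}_{i + 1:02d}" for i in range(n_members))
    core_mean = core_share / (1.0 - core_share) * n_members * private_rate

    def _draw_variants(mean_total: float) -> list[tuple[str, str, int, str, str]]:
        counts = rng.poisson(mean_total * probs)
        drawn: list[tuple[str, str, int, str, str]] = []
        for gi in np.nonzero(counts)[0]:
            g = genes[gi]
            k = int(counts[gi])
            chrom, start = gene_coordinates(_coord_index(g))
            positions = rng.choice(_GENE_WINDOW, size=min(k, _GENE_WINDOW), replace=False)
            ffpe = rng.random(len(positions)) < ffpe_rate
            for pos, is_ffpe in zip(positions, ffpe):
                if is_ffpe:
                    ref, alt = _FFPE_PAIRS[int(rng.integers(2))]
                else:
                    ref, alt = _CLEAN_PAIRS[int(rng.integers(len(_CLEAN_PAIRS)))]
                drawn.append((g, chrom, int(start + pos), ref, alt))
        return drawn

    def _quality(n: int) -> tuple[np.ndarray, np.ndarray]:
        gq = rng.uniform(31.0, 99.0, size=n)
        ad = rng.integers(11, 81, size=n)
        fail = rng.random(n) < quality_fail_rate
        fail_gq = rng.random(n) < 0.5
        gq[fail & fail_gq] = rng.uniform(0.0, 30.0, size=int((fail & fail_gq).sum()))
        ad[fail & ~fail_gq] = rng.integers(0, 11, size=int((fail & ~fail_gq).sum()))
        return gq, ad

    records: list[AnnotatedVariant] = []
    core = _draw_variants(core_mean)
    gq, ad = _quality(len(core) * n_members)
    i = 0
    for member in members:
        for g, chrom, pos, ref, alt in core:
            records.append(
                AnnotatedVariant(
                    member, chrom, pos, ref, alt, g,
                    float(gq[i]), int(ad[i]), is_ffpe_suspect(ref, alt),
                )
            )
            i += 1
    for member in members:
        private = _draw_variants(private_rate)
        gq, ad = _quality(len(private))
        for j, (g, chrom, pos, ref, alt) in enumerate(private):
            records.append(
                AnnotatedVariant(
                    member, chrom, pos, ref, alt, g,
                    float(gq[j]), int(ad[j]), is_ffpe_suspect(ref, alt),
                )
            )
    truth = frozenset(pid for pid, m in group_spec.planted.items() if m > 1.0)
    return SimulatedCohort(
        label=group_spec.label, members=members, records=tuple(records), truth=truth
    )


@dataclass(frozen=True)
class SimulatedStudy:
    """Everything one seeded run produces: database, background, cohorts."""

    spec: SimulationSpec
    db: PathwayDB
    gene_counts: Mapping[str, int]
    bg: BackgroundCounts
    cohorts: Mapping[str, SimulatedCohort]


def simulate_study(spec: SimulationSpec) -> SimulatedStudy:
    """Run the full generator under the spec's single seed."""
    streams = _streams(spec)
    db = simulate_pathway_db(spec)
    gene_counts = _simulate_gene_counts(db, spec)
    bg = background_from_gene_counts(gene_counts, db)
    cohorts = {}
    for i, group_spec in enumerate(spec.groups):
        cohorts[group_spec.label] = simulate_cohort(
            db,
            bg,
            group_spec,
            streams[2 + i],
            core_share=spec.core_share,
            private_rate=spec.private_rate,
            quality_fail_rate=spec.quality_fail_rate,
            ffpe_rate=spec.ffpe_rate,
            gene_weights={g: float(c) for g, c in gene_counts.items()},
        )
    return SimulatedStudy(spec=spec, db=db, gene_counts=gene_counts, bg=bg, cohorts=cohorts)


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write GMT, background counts, per-group variant TSVs and a truth file.

    Returns the mapping of artefact name -> path. Output bytes depend only on
    (spec, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["gmt"] = outdir / "pathways.gmt"
    write_gmt(study.db, paths["gmt"])
    paths["background"] = outdir / "background.tsv"
    write_background_counts(study.bg, paths["background"])
    for label, cohort in study.cohorts.items():
        p = outdir / f"variants_{label}.tsv"
        write_variants_tsv(cohort.records, p)
        paths[f"variants_{label}"] = p
    paths["truth"] = outdir / "truth.json"
    with paths["truth"].open("wt", encoding="utf-8") as fh:
        json.dump(
            {
                "spec": study.spec.to_dict(),
                "truth": {
                    label: sorted(c.truth) for label, c in study.cohorts.items()
                },
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
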