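"""Group-common variant sets and pathway-level enrichment statistics.

The variant enrichment analysis (VEA) asks, per pathway, whether the variants
shared by the members of a study group are over-represented in that pathway's
genes relative to a large reference population. For each pathway the 2x2
summary is

=========  ==================  =======================
           in pathway          total
group      a                   n1 (group-common variants)
reference  c                   n2 (background variants)
=========  ==================  =======================

and the reported statistics are the fold enrichment (a/n1)/(c/n2) — the
ratio of the group VariantRatio to the background BgRatio — the one-sided
(upper tail) hypergeometric exact p-value, a 95% interval for the fold, and
Benjamini–Hochberg adjusted p-values across all tested pathways. Pathways
with zero background count are untestable (the fold is undefined) and are
excluded before the FDR adjustment so that the multiple-testing universe
contains only tested hypotheses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .pathways import BackgroundCounts, PathwayDB
from .variants import VariantKey

logger = logging.getLogger(__name__)

__all__ = [
    "CohortGroup",
    "ContingencyRecord",
    "EnrichmentResult",
    "VEAConfig",
    "group_common_variants",
    "pathway_contingency",
    "fold_enrichment",
    "cross_product_or",
    "fisher_upper_p",
    "ratio_ci",
    "bh_adjust",
    "run_vea",
]


@dataclass
class CohortGroup:
    """A labelled study group with per-sample variant key sets.

    ``genes`` retains the gene annotation per variant key so that pathway
    membership can be resolved after set operations across samples.
    """

    label: str
    members: list[str]
    per_sample_variants: dict[str, set[VariantKey]]
    genes: dict[VariantKey, str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("CohortGroup requires at least one member")
        extra = set(self.per_sample_variants) - set(self.members)
        if extra:
            raise ValueError(f"variant sets for unknown members: {sorted(extra)}")

    @classmethod
    def from_variants(cls, label, variants, members=None) -> "CohortGroup":
        """Build a group from annotated variants (e.g. after quality filtering)."""
        per_sample: dict[str, set[VariantKey]] = {}
        genes: dict[VariantKey, str] = {}
        for v in variants:
            per_sample.setdefault(v.sample_id, set()).add(v.key)
            genes[v.key] = v.gene
        members = list(members) if members is not None else sorted(per_sample)
        for m in members:
            per_sample.setdefault(m, set())
        return cls(label=label, members=members, per_sample_variants=per_sample, genes=genes)


def group_common_variants(
    group: CohortGroup, rule: str = "all", k: int | None = None
) -> list[VariantKey]:
    """Variant keys shared within a group, in deterministic VariantKey order.

    ``rule="all"`` takes the intersection over all members (the literal
    reading of "shared in each group of patients"); ``rule="min_share"``
    keeps keys present in at least ``k`` members.
    """
    member_sets = [group.per_sample_variants.get(m, set()) for m in group.members]
    if rule == "all":
        common = set.intersection(*(s for s in member_sets)) if member_sets else set()
    elif rule == "min_share":
        if k is None or not (1 <= k <= len(group.members)):
            raise ValueError(
                f"min_share requires 1 <= k <= {len(group.members)}, got {k}"
            )
        counts: dict[VariantKey, int] = {}
        for s in member_sets:
            for key in s:
                counts[key] = counts.get(key, 0) + 1
        common = {key for key, n in counts.items() if n >= k}
    else:
        raise ValueError(f"unknown sharing rule {rule!r}; expected 'all' or 'min_share'")
    return sorted(common)


def pathway_contingency(
    common: Mapping[VariantKey, str],
    db: PathwayDB,
    bg: BackgroundCounts,
    denominator: str = "universe",
) -> list[tuple[str, int, int, int, int]]:
    """Per-pathway (pathway_id, a, n1, c, n2) rows for a common variant set.

    ``a`` counts common variants whose gene belongs to the pathway. With
    ``denominator="universe"`` (default) n1 counts only common variants whose
    gene is in the pathway universe, matching the convention used for the
    background total; ``"all"`` counts every common variant.
    """
    if denominator not in ("universe", "all"):
        raise ValueError(
            f"unknown denominator mode {denominator!r}; expected 'universe' or 'all'"
        )
    gene_hits: dict[str, int] = {}
    n_universe = 0
    for gene in common.values():
        if gene in db.universe:
            n_universe += 1
            gene_hits[gene] = gene_hits.get(gene, 0) + 1
    outside = len(common) - n_universe
    if outside and denominator == "universe":
        logger.info(
            "pathway_contingency: %d common variants outside the pathway universe "
            "excluded from n1",
            outside,
        )
    n1 = n_universe if denominator == "universe" else len(common)
    rows = []
    for pw in db:
        a = sum(gene_hits.get(g, 0) for g in pw.genes if g in gene_hits)
        c = bg.per_pathway.get(pw.pathway_id, 0)
        rows.append((pw.pathway_id, a, n1, c, bg.total))
    return rows


def fold_enrichment(a: int, n1: int, c: int, n2: int) -> float:
    """Fold enrichment (a/n1)/(c/n2): group VariantRatio over background BgRatio.

    This is the enrichment statistic printed as "OR" in group-level VEA
    reports; it is a ratio of ratios, not the cross-product odds ratio.
    """
    if n1 <= 0 or n2 <= 0 or c <= 0:
        raise ValueError(
            f"fold enrichment undefined for n1={n1}, c={c}, n2={n2} "
            "(requires n1 > 0, c > 0, n2 > 0)"
        )
    if a < 0:
        raise ValueError(f"a must be non-negative, got {a}")
    return (a / n1) / (c / n2)


def cross_product_or(a: int, n1: int, c: int, n2: int) -> float:
    """Sample cross-product odds ratio (a/(n1-a))/(c/(n2-c)); NaN if degenerate."""
    if a >= n1 or c <= 0 or c >= n2:
        return math.nan
    return (a / (n1 - a)) / (c / (n2 - c))


def fisher_upper_p(a: int, n1: int, c: int, n2: int) -> float:
    """Upper-tail exact p-value P(X >= a), X ~ Hypergeom(n1 + n2, a + c, n1).

    This is the one-sided Fisher exact test of the 2x2 table
    [[a, n1 - a], [c, n2 - c]] for enrichment of the pathway in the group.
    """
    if not (0 <= a <= n1 and 0 <= c <= n2):
        raise ValueError(f"counts out of range: a={a}, n1={n1}, c={c}, n2={n2}")
    return float(min(1.0, stats.hypergeom.sf(a - 1, n1 + n2, a + c, n1)))


def _fisher_upper_p_vec(a: np.ndarray, n1: int, c: np.ndarray, n2: int) -> np.ndarray:
    return np.minimum(1.0, stats.hypergeom.sf(a - 1, n1 + n2, a + c, n1))


def ratio_ci(
    a: int,
    n1: int,
    c: int,
    n2: int,
    level: float = 0.95,
    method: str = "katz",
) -> tuple[float, float]:
    """Confidence interval for the enrichment ratio.

    ``method="katz"`` (default) is the Katz log-ratio interval
    ``exp(ln(fold) +/- z * sqrt(1/a - 1/n1 + 1/c - 1/n2))``, the standard
    large-sample interval for a ratio of two independent proportions.
    ``method="conditional"`` returns the conditional exact odds-ratio
    interval of the table [[a, n1], [c, n2]] (totals as second column, the
    convention of R's ``fisher.test`` applied to count/total pairs); it is
    the interval printed by enrichment reports produced that way.
    """
    if a <= 0 or c <= 0:
        raise ValueError(f"interval degenerate for a={a}, c={c} (requires a, c > 0)")
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if method == "katz":
        fold = fold_enrichment(a, n1, c, n2)
        z = stats.norm.ppf(0.5 + level / 2.0)
        var = 1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n2
        se = math.sqrt(max(var, 0.0))
        return fold * math.exp(-z * se), fold * math.exp(z * se)
    if method == "conditional":
        res = stats.contingency.odds_ratio([[a, n1], [c, n2]], kind="conditional")
        ci = res.confidence_interval(confidence_level=level)
        return float(ci.low), float(ci.high)
    raise ValueError(f"unknown CI method {method!r}; expected 'katz' or 'conditional'")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ContingencyRecord:
    """One tested pathway: counts, ratios, fold, interval and p-values."""

    pathway_id: str
    pathway_name: str
    a: int
    n1: int
    c: int
    n2: int
    variant_ratio: float
    bg_ratio: float
    fold: float
    ci_low: float
    ci_high: float
    p: float
    adj_p: float
    cross_or: float = math.nan


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-group VEA output: records sorted by (adj_p, pathway_id)."""

    group_label: str
    records: tuple[ContingencyRecord, ...]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.records:
            n1s = {r.n1 for r in self.records}
            n2s = {r.n2 for r in self.records}
            if len(n1s) != 1 or len(n2s) != 1:
                raise ValueError("n1 and n2 must be constant across records")

    @property
    def n1(self) -> int | None:
        return self.records[0].n1 if self.records else None

    @property
    def n2(self) -> int | None:
        return self.records[0].n2 if self.records else None


@dataclass
class VEAConfig:
    """Tunable analysis parameters with the workflow's standard defaults.

    gq_min/ad_min are strict lower bounds on genotype quality and alt-allele
    depth; ffpe_mode controls formalin-artifact handling; share_rule picks
    how group-common variants are derived; denominator chooses whether n1 is
    restricted to the pathway universe; alpha is the FDR threshold for the
    "enriched" call; ci_method/ci_level parameterise the fold interval;
    two_sided switches the exact test from upper-tail to two-sided.
    """

    gq_min: float = 30.0
    ad_min: int = 10
    ffpe_mode: str = "flag"
    share_rule: str = "all"
    min_share_k: int | None = None
    denominator: str = "universe"
    alpha: float = 0.05
    ci_method: str = "katz"
    ci_level: float = 0.95
    two_sided: bool = False

    @classmethod
    def from_yaml(cls, path) -> "VEAConfig":
        import yaml

        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def run_vea(
    group: CohortGroup,
    db: PathwayDB,
    bg: BackgroundCounts,
    config: VEAConfig | None = None,
) -> EnrichmentResult:
    """Full per-group analysis: common variants -> contingency -> statistics.

    Pathways with zero background count are excluded before the FDR
    adjustment (logged). An empty common variant set yields a result with
    zero records and a warning, not an exception.
    """
    cfg = config or VEAConfig()
    common_keys = group_common_variants(group, rule=cfg.share_rule, k=cfg.min_share_k)
    common = {key: group.genes[key] for key in common_keys}
    if not common:
        logger.warning("run_vea(%s): empty group-common variant set", group.label)
        return EnrichmentResult(group_label=group.label, records=(), alpha=cfg.alpha)
    rows = pathway_contingency(common, db, bg, denominator=cfg.denominator)
    tested = [r for r in rows if r[3] > 0]
    excluded = len(rows) - len(tested)
    if excluded:
        logger.info(
            "run_vea(%s): %d pathways with zero background count excluded", group.label, excluded
        )
    if not tested or tested[0][2] == 0:
        logger.warning("run_vea(%s): nothing testable", group.label)
        return EnrichmentResult(group_label=group.label, records=(), alpha=cfg.alpha)

    pids = [r[0] for r in tested]
    a_arr = np.array([r[1] for r in tested])
    n1 = tested[0][2]
    c_arr = np.array([r[3] for r in tested])
    n2 = bg.total

    if cfg.two_sided:
        pvals = np.array(
            [
                stats.fisher_exact(
                    [[a, n1 - a], [c, n2 - c]], alternative="two-sided"
                )[1]
                for a, c in zip(a_arr, c_arr)
            ]
        )
    else:
        pvals = _fisher_upper_p_vec(a_arr, n1, c_arr, n2)
    adj = bh_adjust(pvals)

    records = []
    for i, pid in enumerate(pids):
        a, c = int(a_arr[i]), int(c_arr[i])
        fold = fold_enrichment(a, n1, c, n2) if a > 0 else 0.0
        if a > 0:
            ci_low, ci_high = ratio_ci(
                a, n1, c, n2, level=cfg.ci_level, method=cfg.ci_method
            )
        else:
            ci_low = ci_high = math.nan
        records.append(
            ContingencyRecord(
                pathway_id=pid,
                pathway_name=db[pid].name,
                a=a,
                n1=n1,
                c=c,
                n2=n2,
                variant_ratio=a / n1,
                bg_ratio=c / n2,
                fold=fold,
                ci_low=ci_low,
                ci_high=ci_high,
                p=float(pvals[i]),
                adj_p=float(adj[i]),
                cross_or=cross_product_or(a, n1, c, n2),
            )
        )
    records.sort(key=lambda r: (r.adj_p, r.pathway_id))
    return EnrichmentResult(group_label=group.label, records=tuple(records), alpha=cfg.alpha)
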