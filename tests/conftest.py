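from __future__ import annotations

import pytest

from varenrich import (
    BackgroundCounts,
    CohortGroup,
    Pathway,
    PathwayDB,
    VariantKey,
    annotated_variant,
)


@pytest.fixture
def toy_db() -> PathwayDB:
    """Two overlapping pathways over four genes."""
    return PathwayDB(
        [
            Pathway("P1", "first", frozenset({"G1", "G2"})),
            Pathway("P2", "second", frozenset({"G2", "G3"})),
        ]
    )


@pytest.fixture
def toy_bg(toy_db) -> BackgroundCounts:
    return BackgroundCounts(per_pathway={"P1": 50, "P2": 30}, total=1000)


def make_variant(sample, chrom="chr1", pos=100, ref="A", alt="G", gene="G1", gq=45.0, ad=20):
    return annotated_variant(sample, chrom, pos, ref, alt, gene, gq, ad)


@pytest.fixture
def toy_group() -> CohortGroup:
    """Three samples sharing one variant; hand-enumerable common sets."""
    v1 = VariantKey("chr1", 100, "A", "G")
    v2 = VariantKey("chr1", 200, "C", "G")
    v3 = VariantKey("chr2", 50, "T", "A")
    return CohortGroup(
        label="TOY",
        members=["S1", "S2", "S3"],
        per_sample_variants={"S1": {v1, v2, v3}, "S2": {v1, v2}, "S3": {v1, v3}},
        genes={v1: "G1", v2: "G2", v3: "G3"},
    )
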