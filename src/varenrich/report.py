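"""Table-shaped result serialisation and run manifests.

Results are written as a TSV mirroring the standard enrichment-report layout
(group, pathway id and name, VariantRatio as "a/n1", BgRatio as "c/n2", fold
and its 95% interval at two decimals, p-values in scientific notation) plus
full-precision companion columns so that a round-trip read reconstructs the
records exactly. All numbers use explicit formats so diffs are stable.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .enrichment import ContingencyRecord, EnrichmentResult

_DISPLAY_COLUMNS = [
    "group",
    "reactome_id",
    "pathway_name",
    "variant_ratio",
    "bg_ratio",
    "fold",
    "ci_low",
    "ci_high",
    "pvalue",
    "adj_pvalue",
    "cross_or",
]
_EXACT_COLUMNS = [
    "a",
    "n1",
    "c",
    "n2",
    "fold_exact",
    "ci_low_exact",
    "ci_high_exact",
    "pvalue_exact",
    "adj_pvalue_exact",
    "cross_or_exact",
]
COLUMNS = _DISPLAY_COLUMNS + _EXACT_COLUMNS


def _f2(x: float) -> str:
    return "NA" if math.isnan(x) else f"{x:.2f}"


def _sci3(x: float) -> str:
    return "NA" if math.isnan(x) else f"{x:.3e}"


def _exact(x: float) -> str:
    return format(x, ".17g")


def write_results_tsv(result: EnrichmentResult, path: str | Path) -> None:
    """Write one group's enrichment records; empty results give a header-only file."""
    with Path(path).open("wt", encoding="utf-8") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for r in result.records:
            display = [
                result.group_label,
                r.pathway_id,
                r.pathway_name,
                f"{r.a}/{r.n1}",
                f"{r.c}/{r.n2}",
                _f2(r.fold),
                _f2(r.ci_low),
                _f2(r.ci_high),
                _sci3(r.p),
                _sci3(r.adj_p),
                _f2(r.cross_or),
            ]
            exact = [
                str(r.a),
                str(r.n1),
                str(r.c),
                str(r.n2),
                _exact(r.fold),
                _exact(r.ci_low),
                _exact(r.ci_high),
                _exact(r.p),
                _exact(r.adj_p),
                _exact(r.cross_or),
            ]
            fh.write("\t".join(display + exact) + "\n")


def read_results_tsv(path: str | Path, alpha: float = 0.05) -> EnrichmentResult:
    """Reconstruct an EnrichmentResult from the full-precision columns."""
    path = Path(path)
    records = []
    label = ""
    with path.open("rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != COLUMNS:
            raise ValueError(f"{path}: unexpected results header")
        idx = {name: i for i, name in enumerate(header)}
        for raw in fh:
            row = raw.rstrip("\n").split("\t")
            label = row[idx["group"]]
            a, n1 = int(row[idx["a"]]), int(row[idx["n1"]])
            c, n2 = int(row[idx["c"]]), int(row[idx["n2"]])
            records.append(
                ContingencyRecord(
                    pathway_id=row[idx["reactome_id"]],
                    pathway_name=row[idx["pathway_name"]],
                    a=a,
                    n1=n1,
                    c=c,
                    n2=n2,
                    variant_ratio=a / n1,
                    bg_ratio=c / n2,
                    fold=float(row[idx["fold_exact"]]),
                    ci_low=float(row[idx["ci_low_exact"]]),
                    ci_high=float(row[idx["ci_high_exact"]]),
                    p=float(row[idx["pvalue_exact"]]),
                    adj_p=float(row[idx["adj_pvalue_exact"]]),
                    cross_or=float(row[idx["cross_or_exact"]]),
                )
            )
    return EnrichmentResult(group_label=label, records=tuple(records), alpha=alpha)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Traceability record for one run: config, input digests, version, time."""

    config: Mapping
    inputs: Mapping[str, str]
    tool_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )
    log_path: str | None = None

    @classmethod
    def for_inputs(
        cls, config: Mapping, input_paths: Mapping[str, str | Path], log_path=None
    ) -> "RunManifest":
        digests = {name: _sha256(Path(p)) for name, p in input_paths.items()}
        return cls(config=dict(config), inputs=digests, log_path=log_path)

    def write(self, path: str | Path) -> None:
        with Path(path).open("wt", encoding="utf-8") as fh:
            json.dump(
                {
                    "config": self.config,
                    "inputs": self.inputs,
                    "tool_version": self.tool_version,
                    "timestamp": self.timestamp,
                    "log_path": self.log_path,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
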