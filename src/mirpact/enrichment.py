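"""miRNA interaction knowledge base and per-pathway enrichment.

A knowledge base holds validated miRNA->gene inhibition interactions and
TF->miRNA activation interactions.  Enrichment adds to a pathway only the
miRNAs that interact with at least one node already in it: each matching
record contributes the miRNA node (once) plus a signed edge — inhibition as
(miRNA -> gene, -1) and TF activation as (gene -> miRNA, +1).  A record may
override the default weight via the optional ``weight`` column.

Enrichment never rewires the gene-gene subgraph, is idempotent, and happens
per pathway at analysis time so enriched and unenriched variants of the same
topology can coexist (the decoy benchmark needs both).
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .model import (
    EdgeClass,
    NodeClass,
    PathwayEdge,
    PathwayGraph,
    PathwayNode,
    PathwayParseError,
    mark_endpoints,
)

log = logging.getLogger(__name__)

_VALID_CLASSES = {EdgeClass.MIRNA_INHIBITION, EdgeClass.TF_ACTIVATION}


@dataclass(frozen=True)
class InteractionRecord:
    """One validated miRNA<->gene interaction.

    For ``mirna_inhibition`` the source is the miRNA and the target the gene;
    for ``tf_activation`` the source is the TF gene and the target the miRNA.
    ``weight`` overrides the default beta of +/-1 when set.
    """

    source_id: str
    target_id: str
    interaction_class: EdgeClass
    provenance: str = ""
    weight: Optional[float] = None

    def __post_init__(self) -> None:
        if self.interaction_class not in _VALID_CLASSES:
            raise ValueError(
                f"interaction class must be one of "
                f"{sorted(c.value for c in _VALID_CLASSES)}, "
                f"got {self.interaction_class!r}"
            )
        # Namespaced ids make the direction checkable.
        if self.interaction_class is EdgeClass.MIRNA_INHIBITION:
            if self.source_id.startswith("gene:") or self.target_id.startswith("mirna:"):
                raise ValueError(
                    f"inhibition record must run miRNA -> gene: "
                    f"{self.source_id} -> {self.target_id}"
                )
        else:
            if self.source_id.startswith("mirna:") or self.target_id.startswith("gene:"):
                raise ValueError(
                    f"TF activation record must run gene -> miRNA: "
                    f"{self.source_id} -> {self.target_id}"
                )

    @property
    def mirna_id(self) -> str:
        if self.interaction_class is EdgeClass.MIRNA_INHIBITION:
            return self.source_id
        return self.target_id

    @property
    def gene_id(self) -> str:
        if self.interaction_class is EdgeClass.MIRNA_INHIBITION:
            return self.target_id
        return self.source_id

    def effective_weight(self) -> float:
        if self.weight is not None:
            return self.weight
        return -1.0 if self.interaction_class is EdgeClass.MIRNA_INHIBITION else 1.0


@dataclass
class InteractionKnowledgeBase:
    """Deduplicated set of interaction records."""

    records: list[InteractionRecord] = field(default_factory=list)

    @classmethod
    def from_records(cls, records: Iterable[InteractionRecord]) -> "InteractionKnowledgeBase":
        seen: dict[tuple[str, str, EdgeClass], InteractionRecord] = {}
        for rec in records:
            key = (rec.source_id, rec.target_id, rec.interaction_class)
            if key not in seen:
                seen[key] = rec
        return cls(records=list(seen.values()))

    @property
    def n_mirnas(self) -> int:
        return len({r.mirna_id for r in self.records})

    @property
    def n_genes(self) -> int:
        return len({r.gene_id for r in self.records})

    def __len__(self) -> int:
        return len(self.records)


def load_interactions(path: Union[str, Path]) -> InteractionKnowledgeBase:
    """Load an interaction TSV (``source target interaction_class provenance``
    with an optional fifth ``weight`` column); duplicates collapse to one
    record."""
    path = Path(path)
    records: list[InteractionRecord] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [c.strip() for c in header[:3]] != [
            "source",
            "target",
            "interaction_class",
        ]:
            raise PathwayParseError(
                f"{path}: expected header starting "
                f"'source\\ttarget\\tinteraction_class', got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise PathwayParseError(f"{path}:{lineno}: too few fields")
            source, target, cls_s = row[0], row[1], row[2]
            provenance = row[3] if len(row) > 3 else ""
            weight: Optional[float] = None
            if len(row) > 4 and row[4].strip():
                try:
                    weight = float(row[4])
                except ValueError as exc:
                    raise PathwayParseError(
                        f"{path}:{lineno}: weight {row[4]!r} is not a number"
                    ) from exc
            try:
                cls = EdgeClass(cls_s)
            except ValueError as exc:
                raise PathwayParseError(
                    f"{path}:{lineno}: unknown interaction class {cls_s!r}"
                ) from exc
            try:
                records.append(InteractionRecord(source, target, cls, provenance, weight))
            except ValueError as exc:
                raise PathwayParseError(f"{path}:{lineno}: {exc}") from exc
    return InteractionKnowledgeBase.from_records(records)


def write_interactions_tsv(kb: InteractionKnowledgeBase, path: Union[str, Path]) -> None:
    lines = ["source\ttarget\tinteraction_class\tprovenance\tweight"]
    for rec in sorted(
        kb.records, key=lambda r: (r.source_id, r.target_id, r.interaction_class.value)
    ):
        w = "" if rec.weight is None else f"{rec.weight:.10g}"
        lines.append(
            f"{rec.source_id}\t{rec.target_id}\t{rec.interaction_class.value}"
            f"\t{rec.provenance}\t{w}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def enrich_pathway(
    graph: PathwayGraph,
    kb: InteractionKnowledgeBase,
    curated_endpoints: Optional[set[str]] = None,
) -> PathwayGraph:
    """Merge the knowledge base into one pathway; input graph unmodified.

    Only records whose gene-side id is already a node of the pathway apply.
    Endpoint marks are recomputed afterwards (added miRNAs are never
    endpoints; a former sink gene gaining a TF->miRNA edge stops being one).
    """
    new = graph.copy()
    existing = {(e.source, e.target, e.edge_class) for e in new.edges}
    for rec in sorted(
        kb.records, key=lambda r: (r.source_id, r.target_id, r.interaction_class.value)
    ):
        if rec.gene_id not in new.nodes:
            continue
        mid = rec.mirna_id
        if mid not in new.nodes:
            new.nodes[mid] = PathwayNode(mid, NodeClass.MIRNA, is_endpoint=False)
        if rec.interaction_class is EdgeClass.MIRNA_INHIBITION:
            edge = PathwayEdge(mid, rec.gene_id, rec.effective_weight(), rec.interaction_class)
        else:
            edge = PathwayEdge(rec.gene_id, mid, rec.effective_weight(), rec.interaction_class)
        key = (edge.source, edge.target, edge.edge_class)
        if key in existing:
            continue
        if edge.weight == 0.0:
            log.warning(
                "record %s->%s has zero weight; skipped", rec.source_id, rec.target_id
            )
            continue
        new.edges.append(edge)
        existing.add(key)
    return mark_endpoints(new, curated=curated_endpoints)
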