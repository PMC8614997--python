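"""Per-CDS ancestor attribution and genome composition summaries.

Each coding sequence of a recombinant progeny genome is assigned the set
of panel ancestors that match it best.  Ties are decided on integer
mismatch counts (within ``tie_margin`` of the minimum), so two ancestors
that are locally identical to the CDS both appear in the label set --
the "AB" case seen when two near-identical ancestors contributed the
same stretch.  A CDS whose best identity falls below ``identity_floor``
is classified *none* (no recognizable relation to any panel member).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genome_io import Genome, HomologHit, extract_cds_sequence, map_homologs
from .synthetic_data import AncestorPanel, CdsRecord

__all__ = [
    "AttributionCall",
    "CompositionSummary",
    "AttributionParams",
    "attribute_cds",
    "attribute_genome",
    "composition_summary",
]

DEFAULT_IDENTITY_FLOOR = 0.8
DEFAULT_TIE_MARGIN = 0


@dataclass(frozen=True)
class AttributionParams:
    tie_margin: int = DEFAULT_TIE_MARGIN
    identity_floor: float = DEFAULT_IDENTITY_FLOOR
    min_coverage: float = 0.5

    def __post_init__(self) -> None:
        if self.tie_margin < 0:
            raise ValueError("tie_margin must be a non-negative mismatch count")
        if not 0 <= self.identity_floor <= 1:
            raise ValueError("identity_floor must be in [0, 1]")


@dataclass(frozen=True)
class AttributionCall:
    """Ancestor assignment for one CDS.

    ``label_set`` holds every ancestor within the mismatch tie margin of
    the best match; ``ambiguity_class`` is derived from its size:
    unique (1), dual (2), multi (>2) or none (0).
    """

    cds_id: str
    label_set: frozenset[str]
    ambiguity_class: str
    identities: Mapping[str, float]
    length: int
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        expected = _class_for(len(self.label_set))
        if self.ambiguity_class != expected:
            raise ValueError(
                f"{self.cds_id}: class {self.ambiguity_class!r} inconsistent with "
                f"label set of size {len(self.label_set)}"
            )


def _class_for(n_labels: int) -> str:
    if n_labels == 0:
        return "none"
    if n_labels == 1:
        return "unique"
    if n_labels == 2:
        return "dual"
    return "multi"


def attribute_cds(
    homologs: Mapping[str, HomologHit],
    tie_margin: int = DEFAULT_TIE_MARGIN,
    *,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    cds_id: str = "",
    length: int | None = None,
    start: int | None = None,
    end: int | None = None,
) -> AttributionCall:
    """Classify one CDS from its per-ancestor homolog hits.

    Ancestors flagged not-found or with identity below
    ``identity_floor`` are excluded; among the rest, every ancestor
    whose mismatch count is within ``tie_margin`` of the minimum joins
    the label set.
    """
    if tie_margin < 0:
        raise ValueError("tie_margin must be non-negative")
    found = {
        label: hit
        for label, hit in homologs.items()
        if hit.found and hit.identity >= identity_floor
    }
    identities = {label: hit.identity for label, hit in homologs.items() if hit.found}
    if length is None:
        any_hit = next((h for h in homologs.values() if h.found), None)
        length = any_hit.n_columns if any_hit else 0
    if not found:
        return AttributionCall(cds_id, frozenset(), "none", identities, length, start, end)
    best = min(hit.n_mismatches for hit in found.values())
    labels = frozenset(
        label for label, hit in found.items() if hit.n_mismatches <= best + tie_margin
    )
    return AttributionCall(cds_id, labels, _class_for(len(labels)), identities, length, start, end)


def attribute_genome(
    progeny: Genome,
    cds_list: Sequence[CdsRecord],
    panel: AncestorPanel,
    params: AttributionParams = AttributionParams(),
) -> list[AttributionCall]:
    """Attribute every annotated CDS of a progeny genome, in genome order."""
    if not cds_list:
        raise ValueError("progeny genome has no CDS annotations")
    calls = []
    for cds in sorted(cds_list, key=lambda c: c.start):
        seq = extract_cds_sequence(progeny, cds)
        hits = map_homologs(seq, panel, min_coverage=params.min_coverage)
        calls.append(
            attribute_cds(
                hits,
                params.tie_margin,
                identity_floor=params.identity_floor,
                cds_id=cds.cds_id,
                length=cds.length,
                start=cds.start,
                end=cds.end,
            )
        )
    return calls


@dataclass(frozen=True)
class CompositionSummary:
    """Coding-region composition by attribution class.

    Keys of ``by_class`` are the single ancestor label for unique calls,
    the concatenated sorted labels for dual/multi calls (e.g. ``"AB"``),
    and ``"none"`` for unattributed CDSs.  Percentages are of the total
    coding length, so they sum to 100.
    """

    total_coding_bp: int
    by_class: Mapping[str, tuple[int, float]]  # key -> (bp, percent)

    def percent(self, key: str) -> float:
        return self.by_class.get(key, (0, 0.0))[1]

    def unique_percent(self, label: str) -> float:
        """Percent of coding bp attributed uniquely to one ancestor."""
        return self.percent(label)

    def to_json(self) -> str:
        payload = {
            "total_coding_bp": self.total_coding_bp,
            "classes": {
                key: {"bp": bp, "percent": round(pct, 3)}
                for key, (bp, pct) in sorted(self.by_class.items())
            },
        }
        return json.dumps(payload, indent=2)


def composition_summary(calls: Sequence[AttributionCall]) -> CompositionSummary:
    """Aggregate attribution calls into per-ancestor coding-bp shares.

    Dual and multi calls are reported as their own joint categories
    rather than split fractionally between ancestors.
    """
    if not calls:
        raise ValueError("no attribution calls to summarize")
    total = sum(call.length for call in calls)
    bp: dict[str, int] = {}
    for call in calls:
        key = "".join(sorted(call.label_set)) if call.label_set else "none"
        bp[key] = bp.get(key, 0) + call.length
    by_class = {key: (v, 100.0 * v / total) for key, v in bp.items()}
    return CompositionSummary(total_coding_bp=total, by_class=by_class)
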