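"""Recombination breakpoint localization by minimal-switch segmentation.

Given a collinear alignment of a recombinant progeny genome with its
candidate ancestors, the informative positions are the *diagnostic
sites*: columns where the ancestors are not all identical.  At each such
site the progeny allele supports the subset of ancestors carrying the
same base.  The segmentation assigns one ancestor label per site so as
to minimize

    mismatch_cost * (#sites whose support set excludes the assigned
    label)  +  switch_penalty * (#label changes along the genome),

solved exactly by dynamic programming over (site, label).  Runs of the
optimal path form segments; within each segment, every ancestor whose
site-cost ties the optimum is merged into the segment's label set, so a
stretch where two near-identical ancestors are indistinguishable is
labelled jointly (e.g. {A, B}).  Breakpoints are reported as the open
genome interval between the flanking diagnostic sites of adjacent
segments -- the true crossover can lie anywhere inside.

Sites where the progeny matches no ancestor (candidate de novo
mutations) cost the same under every label and therefore can never
force a switch; the de novo caller handles them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genome_io import Genome
from .synthetic_data import AncestorPanel, CdsRecord

__all__ = [
    "DiagnosticSite",
    "Segment",
    "Breakpoint",
    "Segmentation",
    "SegmentationParams",
    "find_diagnostic_sites",
    "segment_minimal_switches",
    "localize_breakpoints",
    "segment_extents",
    "segment_cds_aware",
    "CdsAwareResult",
]

DEFAULT_SWITCH_PENALTY = 2.0
DEFAULT_MISMATCH_COST = 1.0
DEFAULT_MIN_SUPPORT = 2


@dataclass(frozen=True)
class DiagnosticSite:
    """One ancestor-informative alignment column."""

    position: int  # 0-based genome coordinate
    alleles: Mapping[str, str]  # per-ancestor base
    progeny_allele: str
    support_set: frozenset[str]  # ancestors matching the progeny allele


@dataclass(frozen=True)
class Segment:
    first_site_index: int
    last_site_index: int  # inclusive
    label_set: frozenset[str]
    start: int  # genome position of first spanned site
    end: int  # genome position of last spanned site (inclusive)
    low_confidence: bool = False

    @property
    def n_sites(self) -> int:
        return self.last_site_index - self.first_site_index + 1


@dataclass(frozen=True)
class Breakpoint:
    """Open genome interval within which the ancestry switch occurred."""

    left_bound: int  # position of last diagnostic site of the left segment
    right_bound: int  # position of first diagnostic site of the right segment
    left_labels: frozenset[str]
    right_labels: frozenset[str]

    @property
    def midpoint(self) -> float:
        return (self.left_bound + self.right_bound) / 2.0

    def contains(self, position: int) -> bool:
        """Whether a (planted) crossover position falls inside the interval."""
        return self.left_bound < position <= self.right_bound


@dataclass(frozen=True)
class Segmentation:
    segments: tuple[Segment, ...]
    breakpoints: tuple[Breakpoint, ...]
    n_switches: int
    objective_value: float

    def __post_init__(self) -> None:
        if self.segments and self.n_switches != len(self.segments) - 1:
            raise ValueError("n_switches must equal len(segments) - 1")


@dataclass(frozen=True)
class SegmentationParams:
    switch_penalty: float = DEFAULT_SWITCH_PENALTY
    mismatch_cost: float = DEFAULT_MISMATCH_COST
    min_support: int = DEFAULT_MIN_SUPPORT

    def __post_init__(self) -> None:
        if self.switch_penalty <= 0:
            raise ValueError("switch_penalty must be positive")
        if self.mismatch_cost <= 0:
            raise ValueError("mismatch_cost must be positive")


# ---------------------------------------------------------------------------
# diagnostic sites
# ---------------------------------------------------------------------------

def find_diagnostic_sites(
    progeny_seq: str,
    ancestor_seqs: Mapping[str, str],
    offset: int = 0,
) -> list[DiagnosticSite]:
    """Scan a collinear region for columns where ancestors disagree.

    All sequences must have equal length (the region is assumed to be a
    gap-free alignment).  ``offset`` shifts reported positions into
    genome coordinates when the region is a slice.
    """
    labels = list(ancestor_seqs)
    lengths = {len(progeny_seq)} | {len(s) for s in ancestor_seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"collinear region required: got lengths {sorted(lengths)}")

    prog = np.frombuffer(progeny_seq.encode("ascii"), dtype="S1")
    mat = np.vstack(
        [np.frombuffer(ancestor_seqs[lab].encode("ascii"), dtype="S1") for lab in labels]
    )
    informative = np.flatnonzero((mat != mat[0]).any(axis=0))

    sites = []
    for col in informative:
        alleles = {lab: mat[i, col].decode("ascii") for i, lab in enumerate(labels)}
        p_allele = prog[col].decode("ascii")
        support = frozenset(lab for lab, base in alleles.items() if base == p_allele)
        sites.append(
            DiagnosticSite(
                position=offset + int(col),
                alleles=alleles,
                progeny_allele=p_allele,
                support_set=support,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# minimal-switch dynamic program
# ---------------------------------------------------------------------------

def _site_costs(
    sites: Sequence[DiagnosticSite], labels: Sequence[str], mismatch_cost: float
) -> np.ndarray:
    """(n_sites, n_labels) matrix of per-site label costs."""
    costs = np.zeros((len(sites), len(labels)))
    for i, site in enumerate(sites):
        if not site.support_set:
            # matches no ancestor: equal cost everywhere, cannot force a switch
            costs[i, :] = mismatch_cost
        else:
            for j, lab in enumerate(labels):
                if lab not in site.support_set:
                    costs[i, j] = mismatch_cost
    return costs


def segment_minimal_switches(
    sites: Sequence[DiagnosticSite],
    labels: Sequence[str],
    switch_penalty: float = DEFAULT_SWITCH_PENALTY,
    mismatch_cost: float = DEFAULT_MISMATCH_COST,
    *,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> Segmentation:
    """Exact minimal-switch labelling of the diagnostic sites.

    Dynamic programming over (site, label); ties between co-optimal
    paths are broken by fewest switches, then by preferring the earliest
    label in panel order.  Single-label runs become segments; labels
    whose within-segment cost ties the optimum are merged into the
    segment's label set.
    """
    if switch_penalty <= 0:
        raise ValueError("switch_penalty must be positive")
    if not sites:
        return Segmentation(segments=(), breakpoints=(), n_switches=0, objective_value=0.0)
    positions = [s.position for s in sites]
    if positions != sorted(positions):
        raise ValueError("diagnostic sites must be sorted by position")

    n, k = len(sites), len(labels)
    costs = _site_costs(sites, labels, mismatch_cost)

    # DP on lexicographic (objective, n_switches); both accumulate additively.
    INF = float("inf")
    obj = np.empty((n, k))
    sw = np.empty((n, k), dtype=int)
    back = np.zeros((n, k), dtype=int)
    obj[0] = costs[0]
    sw[0] = 0
    for i in range(1, n):
        for j in range(k):
            best_obj, best_sw, best_prev = INF, 0, 0
            for p in range(k):
                o = obj[i - 1, p] + (switch_penalty if p != j else 0.0)
                s = sw[i - 1, p] + (1 if p != j else 0)
                if (o, s, p) < (best_obj, best_sw, best_prev) or best_obj == INF:
                    best_obj, best_sw, best_prev = o, s, p
            obj[i, j] = best_obj + costs[i, j]
            sw[i, j] = best_sw
            back[i, j] = best_prev

    # endpoint: minimal objective, then fewest switches, then earliest label
    end = min(range(k), key=lambda j: (obj[n - 1, j], sw[n - 1, j], j))
    objective = float(obj[n - 1, end])
    path = [end]
    for i in range(n - 1, 0, -1):
        path.append(int(back[i, path[-1]]))
    path.reverse()

    # collapse runs into segments
    runs: list[tuple[int, int, int]] = []  # (first, last, label index)
    start = 0
    for i in range(1, n):
        if path[i] != path[i - 1]:
            runs.append((start, i - 1, path[i - 1]))
            start = i
    runs.append((start, n - 1, path[-1]))

    # Label sets are merged over each segment's *core*: boundary sites
    # that are also cost-free under the neighbouring segment's label are
    # ancestry-ambiguous (their assignment to either segment is
    # co-optimal) and carry evidence about breakpoint placement, not
    # about which ancestors explain the segment's interior.
    segments = []
    for idx, (first, last, j) in enumerate(runs):
        lo, hi = first, last
        if idx > 0:
            prev_j = runs[idx - 1][2]
            while lo < hi and costs[lo, prev_j] == 0:
                lo += 1
        if idx < len(runs) - 1:
            next_j = runs[idx + 1][2]
            while hi > lo and costs[hi, next_j] == 0:
                hi -= 1
        totals = costs[lo : hi + 1].sum(axis=0)
        best_total = totals.min()
        label_set = frozenset(labels[m] for m in range(k) if totals[m] <= best_total + 1e-9)
        segments.append(
            Segment(
                first_site_index=first,
                last_site_index=last,
                label_set=label_set,
                start=sites[first].position,
                end=sites[last].position,
                low_confidence=(last - first + 1) < min_support,
            )
        )

    # Breakpoint uncertainty bounds come from the flanking *firm* sites:
    # the last site supporting the left label but not the right one, and
    # the first site supporting the right label but not the left one.
    # Sites in between are compatible with either ancestry (every
    # co-optimal path switches somewhere inside), so this is the only
    # interval guaranteed to contain the true crossover.
    breakpoints = []
    for (lf, ll, lj), (rf, rl, rj), left, right in zip(
        runs, runs[1:], segments, segments[1:]
    ):
        a, b = labels[lj], labels[rj]
        l_idx = ll
        for i in range(ll, lf - 1, -1):
            sup = sites[i].support_set
            if a in sup and b not in sup:
                l_idx = i
                break
        r_idx = rf
        for i in range(rf, rl + 1):
            sup = sites[i].support_set
            if b in sup and a not in sup:
                r_idx = i
                break
        breakpoints.append(
            Breakpoint(
                left_bound=sites[l_idx].position,
                right_bound=sites[r_idx].position,
                left_labels=left.label_set,
                right_labels=right.label_set,
            )
        )
    breakpoints = tuple(breakpoints)
    return Segmentation(
        segments=tuple(segments),
        breakpoints=breakpoints,
        n_switches=len(segments) - 1,
        objective_value=objective,
    )


def localize_breakpoints(
    segmentation: Segmentation,
    planted_crossovers: Sequence[int] | None = None,
) -> list[dict]:
    """Tabulate breakpoint intervals; optionally score planted crossovers.

    Each row reports the open uncertainty interval between flanking
    diagnostic sites, its midpoint, and -- when planted crossover
    positions are given -- whether one falls inside the interval.
    """
    rows = []
    for bp in segmentation.breakpoints:
        row = {
            "left_bound": bp.left_bound,
            "right_bound": bp.right_bound,
            "midpoint": bp.midpoint,
            "left_labels": "".join(sorted(bp.left_labels)),
            "right_labels": "".join(sorted(bp.right_labels)),
        }
        if planted_crossovers is not None:
            row["contains_planted"] = any(bp.contains(p) for p in planted_crossovers)
        rows.append(row)
    return rows


def segment_extents(
    segmentation: Segmentation, region_start: int, region_end: int
) -> list[tuple[int, int]]:
    """Partition ``[region_start, region_end)`` among the segments.

    Segment boundaries are placed at breakpoint midpoints; the first and
    last segments extend to the region edges.  Returns half-open
    (start, end) per segment, in order.
    """
    if not segmentation.segments:
        return []
    cuts = [region_start]
    for bp in segmentation.breakpoints:
        cuts.append(int(round(bp.midpoint)))
    cuts.append(region_end)
    return [(cuts[i], cuts[i + 1]) for i in range(len(segmentation.segments))]


# ---------------------------------------------------------------------------
# genome-level, CDS-aware segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CdsAwareResult:
    segmentation: Segmentation
    sites: tuple[DiagnosticSite, ...]
    chimeric_cds: frozenset[str]  # CDSs containing an internal ancestry switch
    n_switches: int


def segment_cds_aware(
    progeny: Genome | str,
    panel: AncestorPanel,
    cds_list: Sequence[CdsRecord],
    params: SegmentationParams = SegmentationParams(),
) -> CdsAwareResult:
    """Segment a whole collinear genome and flag within-gene chimeras.

    A CDS is chimeric when a breakpoint's uncertainty interval lies
    strictly inside it -- the ancestry switch must then have happened
    within the gene.  A breakpoint straddling a gene boundary (the
    common case for crossovers in intergenic spacers) does not trigger
    the flag, and neither does a de novo mutation, which matches no
    ancestor and so can never force a switch.
    """
    seq = progeny.sequence if isinstance(progeny, Genome) else progeny
    sites = find_diagnostic_sites(seq, panel.sequences())
    segmentation = segment_minimal_switches(
        sites,
        panel.labels,
        switch_penalty=params.switch_penalty,
        mismatch_cost=params.mismatch_cost,
        min_support=params.min_support,
    )

    chimeric = set()
    for cds in cds_list:
        for bp in segmentation.breakpoints:
            if cds.start <= bp.left_bound and bp.right_bound < cds.end:
                chimeric.add(cds.cds_id)
                break

    return CdsAwareResult(
        segmentation=segmentation,
        sites=tuple(sites),
        chimeric_cds=frozenset(chimeric),
        n_switches=segmentation.n_switches,
    )
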