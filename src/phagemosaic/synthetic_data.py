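"""Synthetic ancestor panels, recombinant progeny and microplate data.

This module generates the three kinds of inputs the rest of the package
consumes, each with known ground truth:

* a panel of collinear ancestor phage genomes with controlled pairwise
  nucleotide divergence (two ancestors can be made nearly identical, as
  closely related wild-type phages often are),
* recombinant ("bred") progeny genomes assembled from planted crossovers
  between panel ancestors, optionally carrying planted point mutations,
* 96-well-plate style OD600 tables and spot-assay tables with planted
  susceptibility structure (initial suppression, resistant regrowth,
  plaque outcomes, true efficiencies of plating).

Sequence evolution follows the Jukes-Cantor substitution model along an
additive tree fitted (neighbor joining) to the requested pairwise
divergences, so measured pairwise identity matches the request up to
binomial sampling error.  Substitutions only -- the panel stays collinear,
which is what the attribution and segmentation machinery assumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CdsRecord",
    "Ancestor",
    "AncestorPanel",
    "MosaicTruth",
    "PlantedMutation",
    "SusceptibilityEntry",
    "SusceptibilityTruth",
    "PlateMeasurement",
    "SpotResult",
    "simulate_ancestor_panel",
    "simulate_mosaic_progeny",
    "simulate_plate_data",
    "simulate_moi_plate_data",
    "simulate_spot_data",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

DEFAULT_BLANK_OD = 0.02
DEFAULT_GROWTH_OD = 1.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CdsRecord:
    """A protein-coding feature in 0-based half-open genome coordinates."""

    cds_id: str
    start: int
    end: int
    strand: str = "+"
    product: str = "hypothetical protein"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.cds_id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.cds_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Ancestor:
    label: str
    genome_id: str
    sequence: str
    cds_list: tuple[CdsRecord, ...]


@dataclass(frozen=True)
class AncestorPanel:
    """Ordered, labelled panel of collinear ancestor genomes.

    Labels are single letters (A, B, C, D).  All genomes in a simulated
    panel have identical length and identical CDS coordinates, so the
    panel is a gap-free multiple alignment of itself.
    """

    ancestors: tuple[Ancestor, ...]

    def __post_init__(self) -> None:
        labels = [a.label for a in self.ancestors]
        if len(set(labels)) != len(labels):
            raise ValueError("ancestor labels must be unique")
        for anc in self.ancestors:
            if not anc.sequence:
                raise ValueError(f"ancestor {anc.label} has an empty sequence")
            if set(anc.sequence) - set("ACGT"):
                raise ValueError(f"ancestor {anc.label} has non-ACGT characters")
            prev_end = -1
            for cds in sorted(anc.cds_list, key=lambda c: c.start):
                if cds.end > len(anc.sequence):
                    raise ValueError(f"{anc.label}/{cds.cds_id} extends past genome end")
                if cds.start < prev_end:
                    raise ValueError(f"{anc.label}/{cds.cds_id} overlaps a previous CDS")
                prev_end = cds.end

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(a.label for a in self.ancestors)

    def get(self, label: str) -> Ancestor:
        for anc in self.ancestors:
            if anc.label == label:
                return anc
        raise KeyError(f"no ancestor labelled {label!r} in panel {self.labels}")

    def sequences(self) -> dict[str, str]:
        return {a.label: a.sequence for a in self.ancestors}

    @property
    def genome_length(self) -> int:
        return len(self.ancestors[0].sequence)


@dataclass(frozen=True)
class PlantedMutation:
    position: int
    ref_alleles: Mapping[str, str]  # per ancestor label
    alt: str


@dataclass(frozen=True)
class MosaicTruth:
    """Ground truth for one simulated recombinant progeny genome."""

    source_intervals: tuple[tuple[int, int, str], ...]
    crossover_positions: tuple[int, ...]
    planted_mutations: tuple[PlantedMutation, ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, _label in self.source_intervals:
            if start != prev_end:
                raise ValueError("source intervals must tile the genome without gaps")
            if end <= start:
                raise ValueError("empty source interval")
            prev_end = end
        if list(self.crossover_positions) != sorted(set(self.crossover_positions)):
            raise ValueError("crossover positions must be strictly increasing")
        starts = {iv[0] for iv in self.source_intervals[1:]}
        if set(self.crossover_positions) != starts:
            raise ValueError("each crossover must open a source interval")

    @property
    def length(self) -> int:
        return self.source_intervals[-1][1]

    def label_fractions(self) -> dict[str, float]:
        """Fraction of progeny length contributed by each ancestor label."""
        total = self.length
        out: dict[str, float] = {}
        for start, end, label in self.source_intervals:
            out[label] = out.get(label, 0.0) + (end - start) / total
        return out

    def source_at(self, position: int) -> str:
        for start, end, label in self.source_intervals:
            if start <= position < end:
                return label
        raise IndexError(position)

    def to_json(self) -> str:
        payload = {
            "source_intervals": [list(iv) for iv in self.source_intervals],
            "crossover_positions": list(self.crossover_positions),
            "planted_mutations": [
                {"position": m.position, "ref_alleles": dict(m.ref_alleles), "alt": m.alt}
                for m in self.planted_mutations
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MosaicTruth":
        payload = json.loads(text)
        return cls(
            source_intervals=tuple(tuple(iv) for iv in payload["source_intervals"]),
            crossover_positions=tuple(payload["crossover_positions"]),
            planted_mutations=tuple(
                PlantedMutation(m["position"], m["ref_alleles"], m["alt"])
                for m in payload["planted_mutations"]
            ),
        )


@dataclass(frozen=True)
class SusceptibilityEntry:
    """Planted phenotype of one (strain, phage) pair.

    ``initial_suppression`` -- growth suppressed at 6 h;
    ``resistant_regrowth`` -- suppressed at 6 h but regrown by 24 h
    (the resistance-evolution signature); ``plaque_outcome`` -- spot-assay
    result; ``eop_true`` -- true efficiency of plating relative to the
    propagation host.
    """

    initial_suppression: bool
    resistant_regrowth: bool = False
    plaque_outcome: str = "none"  # {clear, opaque, none}
    eop_true: float = 0.0

    def __post_init__(self) -> None:
        if self.resistant_regrowth and not self.initial_suppression:
            raise ValueError("resistant_regrowth requires initial_suppression")
        if self.plaque_outcome not in ("clear", "opaque", "none"):
            raise ValueError(f"invalid plaque outcome {self.plaque_outcome!r}")
        if self.eop_true < 0:
            raise ValueError("eop_true must be non-negative")
        if (self.eop_true == 0) != (self.plaque_outcome != "clear"):
            raise ValueError("eop_true must be 0 exactly when no clear plaques form")

    @property
    def suppressed_at_24h(self) -> bool:
        return self.initial_suppression and not self.resistant_regrowth


@dataclass(frozen=True)
class SusceptibilityTruth:
    entries: Mapping[tuple[str, str], SusceptibilityEntry]

    def __getitem__(self, key: tuple[str, str]) -> SusceptibilityEntry:
        return self.entries[key]

    def to_json(self) -> str:
        payload = [
            {"strain": s, "phage": p, **asdict(e)} for (s, p), e in self.entries.items()
        ]
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SusceptibilityTruth":
        entries = {}
        for row in json.loads(text):
            key = (row.pop("strain"), row.pop("phage"))
            entries[key] = SusceptibilityEntry(**row)
        return cls(entries)


@dataclass(frozen=True)
class PlateMeasurement:
    """One OD600 reading.  ``phage == "CONTROL"`` marks untreated wells."""

    strain: str
    phage: str
    timepoint_h: int
    replicate: int
    od600: float
    moi: float | None = None


@dataclass(frozen=True)
class SpotResult:
    strain: str
    phage: str
    outcome: str  # {clear, opaque, none}
    pfu_per_ml: float | None = None


# ---------------------------------------------------------------------------
# ancestor panel simulation
# ---------------------------------------------------------------------------

def _check_divergence_matrix(div: np.ndarray, n: int, tol: float = 1e-3) -> None:
    if div.shape != (n, n):
        raise ValueError(f"divergence matrix must be {n}x{n}, got {div.shape}")
    if not np.allclose(div, div.T):
        raise ValueError("divergence matrix must be symmetric")
    if not np.allclose(np.diag(div), 0.0):
        raise ValueError("divergence matrix must have a zero diagonal")
    if div.min() < 0 or div.max() > 0.2:
        raise ValueError("divergence entries must lie in [0, 0.2]")
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if div[i, j] > div[i, k] + div[k, j] + tol:
                    raise ValueError(
                        "inconsistent divergence matrix: "
                        f"d({i},{j})={div[i, j]:.4f} exceeds "
                        f"d({i},{k})+d({k},{j})={div[i, k] + div[k, j]:.4f} "
                        "(triangle inequality violated)"
                    )


def _jc_distance(p: float) -> float:
    """Jukes-Cantor distance for an observed mismatch fraction ``p``."""
    if p >= 0.75:
        raise ValueError("divergence too large for the Jukes-Cantor model")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _jc_mismatch_prob(t: float) -> float:
    """Per-site mismatch probability across a branch of JC length ``t``."""
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))


def _fit_branch_lengths(div: np.ndarray, labels: Sequence[str]) -> list[tuple[int | None, int, float]]:
    """Fit an additive tree to JC-transformed divergences.

    Returns edges as (parent_index, child_index, jc_length) over an
    implicit node numbering where leaves 0..n-1 are the panel ancestors.
    Root is parent ``None``.
    """
    n = len(labels)
    t = np.zeros_like(div)
    for i in range(n):
        for j in range(n):
            if i != j:
                t[i, j] = _jc_distance(float(div[i, j]))
    if n == 2:
        half = t[0, 1] / 2.0
        return [(None, 0, half), (None, 1, half)]

    from skbio import DistanceMatrix
    from skbio.tree import nj

    ids = [str(i) for i in range(n)]
    tree = nj(DistanceMatrix(t, ids=ids))
    edges: list[tuple[int | None, int, float]] = []
    counter = n  # internal node ids start after leaves
    index_of = {id(tree): None}

    def walk(node, parent_index):
        nonlocal counter
        for child in node.children:
            length = child.length or 0.0
            if length < -1e-6:
                raise ValueError(
                    "inconsistent divergence matrix: no additive tree realizes it "
                    f"(negative branch length {length:.3g})"
                )
            length = max(length, 0.0)
            if child.is_tip():
                child_index = int(child.name)
            else:
                child_index = counter
                counter += 1
            edges.append((parent_index, child_index, length))
            if not child.is_tip():
                walk(child, child_index)

    walk(tree, None)
    return edges


def _mutate(seq: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor step: each site flips with ``prob`` to a uniform other base."""
    if prob <= 0:
        return seq.copy()
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < prob)
    if hit.size:
        # shift by 1..3 in base space => always a different base, uniform
        shift = rng.integers(1, 4, size=hit.size)
        idx = np.searchsorted(_BASES, seq[hit])
        out[hit] = _BASES[(idx + shift) % 4]
    return out


def _tile_cds(
    genome_length: int,
    n_cds: int,
    spacer: int,
    cds_length: int | None,
    products: Sequence[str] | None,
) -> tuple[CdsRecord, ...]:
    if cds_length is None:
        per_cds = genome_length // n_cds - spacer
        cds_length = 3 * (per_cds // 3)
    if cds_length <= 0 or cds_length % 3:
        raise ValueError("CDS length must be a positive multiple of 3")
    needed = spacer + n_cds * (cds_length + spacer)
    if needed > genome_length + spacer:
        raise ValueError(
            f"genome_length {genome_length} too short for {n_cds} CDS of {cds_length} bp"
        )
    width = max(3, len(str(n_cds)))
    records = []
    for i in range(n_cds):
        start = spacer + i * (cds_length + spacer)
        product = products[i] if products else "hypothetical protein"
        records.append(
            CdsRecord(
                cds_id=f"CDS_{i + 1:0{width}d}",
                start=start,
                end=start + cds_length,
                strand="+",
                product=product,
            )
        )
    return tuple(records)


def simulate_ancestor_panel(
    n_ancestors: int,
    genome_length: int,
    n_cds: int,
    divergence: np.ndarray | Sequence[Sequence[float]],
    seed: int,
    *,
    labels: Sequence[str] | None = None,
    spacer: int = 60,
    cds_length: int | None = None,
    products: Sequence[str] | None = None,
) -> AncestorPanel:
    """Simulate a panel of collinear ancestor genomes.

    Parameters
    ----------
    n_ancestors : int
        Panel size, 2-4 (labelled A..D by default).
    genome_length : int
        Length of every genome in bp; must allow ``n_cds`` CDS of at
        least 100 codons each.
    n_cds : int
        Number of CDS features tiled along each genome.  Coordinates are
        identical across ancestors (the panel is collinear).
    divergence : (n, n) array-like
        Target pairwise mismatch fractions.  Must be symmetric with zero
        diagonal, entries in [0, 0.2], and realizable by an additive tree
        (triangle-inequality violations are rejected).
    seed : int
        Seed for all randomness; identical inputs give identical panels.

    Returns
    -------
    AncestorPanel
        Measured pairwise identity equals ``1 - divergence`` up to
        binomial sampling error at the given genome length.
    """
    if not 2 <= n_ancestors <= 4:
        raise ValueError("n_ancestors must be between 2 and 4")
    if genome_length < 3 * n_cds * 100:
        raise ValueError("genome_length must be at least 300 bp per CDS")
    div = np.asarray(divergence, dtype=float)
    _check_divergence_matrix(div, n_ancestors)
    if labels is None:
        labels = tuple("ABCD"[:n_ancestors])
    edges = _fit_branch_lengths(div, labels)

    rng = np.random.default_rng(seed)
    root = rng.choice(_BASES, size=genome_length)

    # evolve down the fitted tree, parents before children
    node_seq: dict[int | None, np.ndarray] = {None: root}
    for parent, child, t in edges:  # edges are emitted in pre-order
        node_seq[child] = _mutate(node_seq[parent], _jc_mismatch_prob(t), rng)

    cds_list = _tile_cds(genome_length, n_cds, spacer, cds_length, products)
    ancestors = tuple(
        Ancestor(
            label=labels[i],
            genome_id=f"ancestor_{labels[i]}",
            sequence=node_seq[i].tobytes().decode("ascii"),
            cds_list=cds_list,
        )
        for i in range(n_ancestors)
    )
    return AncestorPanel(ancestors)


# ---------------------------------------------------------------------------
# mosaic progeny simulation
# ---------------------------------------------------------------------------

def simulate_mosaic_progeny(
    panel: AncestorPanel,
    crossovers: Sequence[tuple[int, str]],
    mutations: Sequence[tuple[int, str]] = (),
    seed: int = 0,
    *,
    initial_label: str | None = None,
) -> tuple[str, MosaicTruth]:
    """Assemble a recombinant progeny genome from planted crossovers.

    The progeny starts as ``initial_label`` (first panel ancestor by
    default); each crossover ``(position, label)`` switches the template
    to ``label`` from ``position`` onward.  ``mutations`` are
    ``(position, alt_base)`` point substitutions applied afterwards, so a
    planted mutation may fall on an ancestor-diagnostic site.

    The construction is fully determined by its arguments; ``seed`` is
    accepted for interface symmetry with the other simulators.
    """
    del seed  # deterministic construction
    L = panel.genome_length
    label = initial_label if initial_label is not None else panel.labels[0]
    panel.get(label)  # validate

    positions = [p for p, _ in crossovers]
    if positions != sorted(set(positions)):
        raise ValueError("crossover positions must be strictly increasing")
    if positions and not (0 < positions[0] and positions[-1] < L):
        raise ValueError(f"crossover positions must lie in (0, {L})")

    bounds = [0] + positions + [L]
    source_labels = [label] + [lab for _, lab in crossovers]
    for lab in source_labels:
        panel.get(lab)

    seqs = panel.sequences()
    pieces = []
    intervals = []
    for (start, end), lab in zip(zip(bounds[:-1], bounds[1:]), source_labels):
        pieces.append(seqs[lab][start:end])
        intervals.append((start, end, lab))

    progeny = np.frombuffer("".join(pieces).encode("ascii"), dtype="S1").copy()

    mut_positions = [p for p, _ in mutations]
    if len(set(mut_positions)) != len(mut_positions):
        raise ValueError("mutation positions must be distinct")
    planted = []
    for pos, alt in mutations:
        if not 0 <= pos < L:
            raise ValueError(f"mutation position {pos} outside genome [0, {L})")
        if alt not in "ACGT":
            raise ValueError(f"invalid mutation base {alt!r}")
        planted.append(
            PlantedMutation(
                position=pos,
                ref_alleles={lab: seqs[lab][pos] for lab in panel.labels},
                alt=alt,
            )
        )
        progeny[pos] = alt.encode("ascii")

    truth = MosaicTruth(
        source_intervals=tuple(intervals),
        crossover_positions=tuple(positions),
        planted_mutations=tuple(planted),
    )
    return progeny.tobytes().decode("ascii"), truth


# ---------------------------------------------------------------------------
# plate and spot-assay simulation
# ---------------------------------------------------------------------------

def _noisy(value: float, noise_sd: float, rng: np.random.Generator) -> float:
    """Gaussian noise truncated at zero (OD readings cannot be negative)."""
    if noise_sd <= 0:
        return max(value, 0.0)
    return max(value + rng.normal(0.0, noise_sd), 0.0)


def simulate_plate_data(
    strains: Sequence[str],
    phages: Sequence[str],
    truth: SusceptibilityTruth,
    growth_od: float = DEFAULT_GROWTH_OD,
    noise_sd: float = 0.02,
    n_replicates: int = 2,
    seed: int = 0,
    *,
    blank_od: float = DEFAULT_BLANK_OD,
    control_6h_fraction: float = 0.6,
    regrowth_fraction: float = 0.9,
    moi: float | None = 10.0,
) -> list[PlateMeasurement]:
    """Simulate a kinetic host-range plate read at 6 h and 24 h.

    Untreated control wells grow to ``control_6h_fraction * growth_od``
    at 6 h and ``growth_od`` at 24 h.  Treated wells follow the planted
    :class:`SusceptibilityTruth`: suppressed wells sit at the blank level,
    resistant-regrowth wells are suppressed at 6 h but approach the
    control level by 24 h.  Gaussian noise (sd ``noise_sd``) is truncated
    at zero.
    """
    if not strains:
        raise ValueError("strain list must not be empty")
    if not phages:
        raise ValueError("phage list must not be empty")
    if growth_od <= 0:
        raise ValueError("growth_od must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")

    rng = np.random.default_rng(seed)
    out: list[PlateMeasurement] = []
    for rep in range(1, n_replicates + 1):
        for strain in strains:
            control = {6: growth_od * control_6h_fraction, 24: growth_od}
            for tp in (6, 24):
                out.append(
                    PlateMeasurement(
                        strain, "CONTROL", tp, rep, _noisy(control[tp], noise_sd, rng), moi
                    )
                )
            for phage in phages:
                entry = truth[(strain, phage)]
                od6 = blank_od if entry.initial_suppression else control[6]
                if entry.suppressed_at_24h:
                    od24 = blank_od
                elif entry.resistant_regrowth:
                    od24 = growth_od * regrowth_fraction
                else:
                    od24 = control[24]
                for tp, od in ((6, od6), (24, od24)):
                    out.append(
                        PlateMeasurement(strain, phage, tp, rep, _noisy(od, noise_sd, rng), moi)
                    )
    return out


def simulate_moi_plate_data(
    strains: Sequence[str],
    phage: str,
    suppression_by_moi: Mapping[float, Mapping[str, bool]],
    growth_od: float = DEFAULT_GROWTH_OD,
    noise_sd: float = 0.02,
    n_replicates: int = 3,
    seed: int = 0,
    *,
    blank_od: float = DEFAULT_BLANK_OD,
) -> list[PlateMeasurement]:
    """Simulate a 24 h MOI-titration plate for one phage.

    ``suppression_by_moi[moi][strain]`` is the planted truth: whether the
    phage suppresses that strain's growth at 24 h at that multiplicity of
    infection.  Emits a control and a treated well per (strain, MOI,
    replicate), all at 24 h.
    """
    if not strains:
        raise ValueError("strain list must not be empty")
    rng = np.random.default_rng(seed)
    out: list[PlateMeasurement] = []
    for rep in range(1, n_replicates + 1):
        for moi, by_strain in suppression_by_moi.items():
            for strain in strains:
                out.append(
                    PlateMeasurement(
                        strain, "CONTROL", 24, rep, _noisy(growth_od, noise_sd, rng), moi
                    )
                )
                od = blank_od if by_strain[strain] else growth_od
                out.append(
                    PlateMeasurement(strain, phage, 24, rep, _noisy(od, noise_sd, rng), moi)
                )
    return out


def simulate_spot_data(
    strains: Sequence[str],
    phage: str,
    truth: SusceptibilityTruth,
    reference_pfu: float = 1e7,
) -> list[SpotResult]:
    """Derive spot-assay rows (outcome + titer) from planted truth.

    Clear-plaque strains get ``pfu = eop_true * reference_pfu``; opaque
    lysis and no-lysis strains carry no titer.
    """
    out = []
    for strain in strains:
        entry = truth[(strain, phage)]
        pfu = entry.eop_true * reference_pfu if entry.plaque_outcome == "clear" else None
        out.append(SpotResult(strain, phage, entry.plaque_outcome, pfu))
    return out
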