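"""Ready-made synthetic reconstructions of the studied mosaic loci.

Two constructions are provided, both built from the general simulators:

* :func:`build_chimeric_gene_scenario` -- a single 3000-bp tail-fiber-like gene
  that is an internal chimera: the first 2.3 kbp from the divergent
  ancestor C, ~400 bp from the near-identical pair A/B (locally
  identical, so the stretch is jointly attributable), and the last
  ~300 bp from C again.
* :func:`build_mosaic_region_scenario` -- a ~20-kb region of 17 genes
  (numbered 117-133) carrying eight planted crossovers, the internal
  chimera above, and one de novo Gln->Arg mutation at codon 166 of the
  tail-fiber gene 130.

The panel divergences mirror the breeding setting: two ancestors at
99.5% identity (A, B) and one or two more divergent ancestors at ~95%
(C, D).  Where the reconstruction requires A and B to be *locally*
identical (the described loci), the builders harmonize the two within
that window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .synthetic_data import (
    Ancestor,
    AncestorPanel,
    CdsRecord,
    MosaicTruth,
    simulate_ancestor_panel,
    simulate_mosaic_progeny,
)

__all__ = ["MosaicScenario", "build_chimeric_gene_scenario", "build_mosaic_region_scenario"]

# pairwise mismatch fractions: A-B nearly identical, C (and D) divergent
DIVERGENCE_3 = [
    [0.000, 0.005, 0.050],
    [0.005, 0.000, 0.050],
    [0.050, 0.050, 0.000],
]
DIVERGENCE_4 = [
    [0.000, 0.005, 0.050, 0.070],
    [0.005, 0.000, 0.050, 0.070],
    [0.050, 0.050, 0.000, 0.090],
    [0.070, 0.070, 0.090, 0.000],
]


@dataclass(frozen=True)
class MosaicScenario:
    panel: AncestorPanel
    progeny: str
    truth: MosaicTruth
    cds_list: tuple[CdsRecord, ...]
    region: tuple[int, int]  # the interval of interest, 0-based half-open


def _harmonize(panel: AncestorPanel, src: str, dst: str, window: tuple[int, int]) -> AncestorPanel:
    """Copy ``src``'s sequence onto ``dst`` within ``window`` (locally identical pair)."""
    start, end = window
    ancestors = []
    for anc in panel.ancestors:
        if anc.label == dst:
            seq = panel.get(src).sequence[start:end]
            ancestors.append(
                replace(anc, sequence=anc.sequence[:start] + seq + anc.sequence[end:])
            )
        else:
            ancestors.append(anc)
    return AncestorPanel(tuple(ancestors))


def _edit(panel: AncestorPanel, label: str, start: int, new: str) -> AncestorPanel:
    """Overwrite a short stretch of one ancestor (targeted codon placement)."""
    ancestors = []
    for anc in panel.ancestors:
        if anc.label == label:
            seq = anc.sequence[:start] + new + anc.sequence[start + len(new) :]
            ancestors.append(replace(anc, sequence=seq))
        else:
            ancestors.append(anc)
    return AncestorPanel(tuple(ancestors))


def build_chimeric_gene_scenario(
    seed: int = 0,
    *,
    first_c_bp: int = 2300,
    ab_bp: int = 400,
    last_c_bp: int = 300,
) -> MosaicScenario:
    """A 3000-bp gene chimeric within itself: C / AB / C.

    The gene starts on the divergent ancestor C, switches to the
    near-identical pair (harmonized to be locally identical across the
    middle window) and switches back to C for the tail of the gene.
    """
    spacer = 60
    cds_len = first_c_bp + ab_bp + last_c_bp
    genome_length = cds_len + 2 * spacer
    panel = simulate_ancestor_panel(
        3,
        genome_length,
        1,
        DIVERGENCE_3,
        seed,
        spacer=spacer,
        cds_length=cds_len,
        products=["tail fiber protein"],
    )
    cds = panel.ancestors[0].cds_list[0]
    window = (cds.start + first_c_bp, cds.start + first_c_bp + ab_bp)
    panel = _harmonize(panel, "A", "B", window)
    progeny, truth = simulate_mosaic_progeny(
        panel,
        crossovers=[(window[0], "A"), (window[1], "C")],
        initial_label="C",
    )
    return MosaicScenario(
        panel=panel,
        progeny=progeny,
        truth=truth,
        cds_list=panel.ancestors[0].cds_list,
        region=(cds.start, cds.end),
    )


def build_mosaic_region_scenario(seed: int = 0) -> MosaicScenario:
    """A 17-gene region (CDS 117-133) with eight planted crossovers.

    Planted structure, by gene: 117 from the locally identical pair A/B;
    118-123 from C; 124 from B; 125-126 from D; 127-129 from B;
    130 from C with a de novo Gln->Arg mutation at codon 166;
    131 an internal C/AB/C chimera (2300 / 400 / 300 bp); 132-133 from B.
    """
    spacer = 60
    n_cds = 17
    cds_len = 999
    chimera_len = 3000
    genome_length = spacer + (n_cds - 1) * (cds_len + spacer) + chimera_len + spacer

    # lay out 16 equal genes; gene 131 (index 14) is replaced by a 3000-bp gene
    products = ["hypothetical protein"] * n_cds
    products[13] = "tail fiber protein"  # CDS 130
    products[14] = "tail fiber protein"  # CDS 131
    panel = simulate_ancestor_panel(
        4,
        genome_length + cds_len,  # headroom; custom CDS list below
        n_cds,
        DIVERGENCE_4,
        seed,
        spacer=spacer,
        cds_length=cds_len,
        products=products,
    )

    # rebuild coordinates with the enlarged gene 131 and ids 117..133
    cds_list: list[CdsRecord] = []
    pos = spacer
    for i in range(n_cds):
        length = chimera_len if i == 14 else cds_len
        cds_list.append(
            CdsRecord(
                cds_id=f"CDS_{117 + i}",
                start=pos,
                end=pos + length,
                strand="+",
                product=products[i],
            )
        )
        pos += length + spacer
    ancestors = tuple(
        replace(anc, cds_list=tuple(cds_list)) for anc in panel.ancestors
    )
    panel = AncestorPanel(ancestors)

    by_id = {c.cds_id: c for c in cds_list}
    cds117, cds118 = by_id["CDS_117"], by_id["CDS_118"]
    cds124, cds125, cds127 = by_id["CDS_124"], by_id["CDS_125"], by_id["CDS_127"]
    cds130, cds131, cds132 = by_id["CDS_130"], by_id["CDS_131"], by_id["CDS_132"]

    # gene 117 is attributable to both A and B; the chimera's middle likewise
    panel = _harmonize(panel, "A", "B", (cds117.start, cds117.end))
    ab_window = (cds131.start + 2300, cds131.start + 2700)
    panel = _harmonize(panel, "A", "B", ab_window)

    # place a Gln codon (CAA) at codon 166 of gene 130 in every ancestor so
    # the planted A->G change (CAA->CGA, Q166R) matches no ancestor
    codon_start = cds130.start + 165 * 3
    for label in panel.labels:
        panel = _edit(panel, label, codon_start, "CAA")

    crossovers = [
        (cds118.start, "C"),
        (cds124.start, "B"),
        (cds125.start, "D"),
        (cds127.start, "B"),
        (cds130.start, "C"),
        (ab_window[0], "A"),
        (ab_window[1], "C"),
        (cds132.start, "B"),
    ]
    mutation_pos = codon_start + 1  # CAA -> CGA
    progeny, truth = simulate_mosaic_progeny(
        panel,
        crossovers=crossovers,
        mutations=[(mutation_pos, "G")],
        initial_label="A",
    )
    return MosaicScenario(
        panel=panel,
        progeny=progeny,
        truth=truth,
        cds_list=tuple(cds_list),
        region=(cds117.start, by_id["CDS_133"].end),
    )
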