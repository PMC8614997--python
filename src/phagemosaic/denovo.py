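"""De novo mutation calling against a panel of ancestor genomes.

A progeny position is a de novo variant when its allele matches *none*
of the candidate ancestors in the collinear alignment -- including
positions where the ancestors all agree (non-diagnostic columns) and
positions inside stretches attributed jointly to two ancestors.  Coding
variants are annotated with the standard one-letter substitution
notation (e.g. ``Q166R``) using the bacterial/phage genetic code
(translation table 11); synonymous changes are reported as ``syn``.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .genome_io import Genome
from .synthetic_data import AncestorPanel, CdsRecord

__all__ = ["DeNovoVariant", "call_denovo", "annotate_protein_effect"]

TRANSLATION_TABLE = 11


@dataclass(frozen=True)
class DeNovoVariant:
    position: int  # 0-based genome coordinate
    ancestor_alleles: Mapping[str, str]
    progeny_allele: str
    cds_id: str | None  # None => intergenic
    protein_effect: str  # "Q166R"-style, "syn", or "intergenic"
    codon_number: int | None = None  # 1-based on the coding strand

    def __post_init__(self) -> None:
        if self.progeny_allele in set(self.ancestor_alleles.values()):
            raise ValueError(
                f"position {self.position}: progeny allele matches an ancestor; not de novo"
            )
        if self.cds_id is not None and (self.codon_number is None or self.codon_number < 1):
            raise ValueError(f"position {self.position}: coding variant needs a codon number")


def _modal_allele(alleles: Mapping[str, str], label_order: Sequence[str]) -> str:
    """Most common ancestor allele; ties broken by panel order."""
    counts: dict[str, int] = {}
    for base in alleles.values():
        counts[base] = counts.get(base, 0) + 1
    best = max(counts.values())
    for lab in label_order:
        if counts[alleles[lab]] == best:
            return alleles[lab]
    raise AssertionError("unreachable")


def annotate_protein_effect(
    position: int,
    ref_base: str,
    alt_base: str,
    cds: CdsRecord,
    progeny_seq: str,
) -> tuple[str, int]:
    """Protein-level effect of a substitution inside a CDS.

    The variant codon is read off the progeny; the reference codon is
    the same codon with the variant base reverted to ``ref_base``.
    Returns ``(effect, codon_number)`` where the effect is
    ``"<refAA><codon><altAA>"`` for a nonsynonymous change and
    ``"syn"`` otherwise.  Codon numbers count from 1 on the coding
    strand, so minus-strand genes are handled by reverse complement.
    """
    if not cds.start <= position < cds.end:
        raise ValueError(
            f"position {position} outside CDS {cds.cds_id} [{cds.start}, {cds.end})"
        )
    alt_cds = progeny_seq[cds.start : cds.end]
    offset = position - cds.start
    ref_cds = alt_cds[:offset] + ref_base + alt_cds[offset + 1 :]
    alt_cds = alt_cds[:offset] + alt_base + alt_cds[offset + 1 :]
    if cds.strand == "-":
        ref_cds = str(Seq(ref_cds).reverse_complement())
        alt_cds = str(Seq(alt_cds).reverse_complement())
        offset = cds.length - 1 - offset
    codon_number = offset // 3 + 1
    codon_slice = slice(3 * (codon_number - 1), 3 * codon_number)
    ref_aa = str(Seq(ref_cds[codon_slice]).translate(table=TRANSLATION_TABLE))
    alt_aa = str(Seq(alt_cds[codon_slice]).translate(table=TRANSLATION_TABLE))
    if ref_aa == alt_aa:
        return "syn", codon_number
    return f"{ref_aa}{codon_number}{alt_aa}", codon_number


def call_denovo(
    progeny: Genome | str,
    panel: AncestorPanel,
    cds_list: Sequence[CdsRecord] = (),
    *,
    source_labels: Mapping[str, str] | None = None,
) -> list[DeNovoVariant]:
    """Find every progeny position whose allele matches no ancestor.

    The progeny and panel must be collinear (equal lengths, gap-free).
    ``source_labels`` optionally maps ``cds_id`` to the locally
    attributed ancestor, whose allele then serves as the reference for
    the protein-effect annotation; otherwise the modal ancestor allele
    is used (ancestors may disagree at a de novo position).
    """
    seq = progeny.sequence if isinstance(progeny, Genome) else progeny
    labels = panel.labels
    lengths = {len(seq)} | {len(s) for s in panel.sequences().values()}
    if len(lengths) != 1:
        raise ValueError(f"collinear alignment required: got lengths {sorted(lengths)}")

    prog = np.frombuffer(seq.encode("ascii"), dtype="S1")
    mat = np.vstack(
        [np.frombuffer(panel.get(lab).sequence.encode("ascii"), dtype="S1") for lab in labels]
    )
    novel = np.flatnonzero((mat != prog).all(axis=0))

    ordered = sorted(cds_list, key=lambda c: c.start)
    starts = [c.start for c in ordered]

    variants = []
    for pos in map(int, novel):
        alleles = {lab: mat[i, pos].decode("ascii") for i, lab in enumerate(labels)}
        alt = prog[pos].decode("ascii")
        idx = bisect_right(starts, pos) - 1
        cds = ordered[idx] if idx >= 0 and pos < ordered[idx].end else None
        if cds is None:
            variants.append(DeNovoVariant(pos, alleles, alt, None, "intergenic"))
            continue
        if source_labels and cds.cds_id in source_labels:
            ref = alleles[source_labels[cds.cds_id]]
        else:
            ref = _modal_allele(alleles, labels)
        effect, codon = annotate_protein_effect(pos, ref, alt, cds, seq)
        variants.append(DeNovoVariant(pos, alleles, alt, cds.cds_id, effect, codon))
    return variants
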