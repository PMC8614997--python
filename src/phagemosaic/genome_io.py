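"""Sequence/annotation I/O and homolog mapping.

FASTA is read and written through Biopython.  GFF3 carries the CDS
annotations (1-based inclusive on disk, converted to the package's
internal 0-based half-open convention).  Homolog search places each
progeny CDS into every ancestor genome with edlib infix alignment
(edit distance), the standard fast choice for highly similar collinear
phage genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import Ancestor, AncestorPanel, CdsRecord

__all__ = [
    "Genome",
    "HomologHit",
    "load_genome",
    "write_genome",
    "load_cds_annotations",
    "write_cds_annotations",
    "extract_cds_sequence",
    "map_homologs",
    "gff_to_internal",
    "internal_to_gff",
    "write_panel",
    "load_panel",
]

_VALID = set("ACGTN")

# Best infix identity of an unrelated random sequence against a long
# genome sits near 0.5-0.6; true homologs in a phage panel are >=0.8.
DEFAULT_FOUND_IDENTITY_FLOOR = 0.7
DEFAULT_MIN_COVERAGE = 0.5


@dataclass(frozen=True)
class Genome:
    genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.genome_id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HomologHit:
    """Best placement of one progeny CDS in one ancestor genome."""

    label: str
    found: bool
    identity: float = 0.0
    coverage: float = 0.0
    target_start: int | None = None
    target_end: int | None = None  # 0-based half-open on the ancestor
    n_mismatches: int | None = None  # alignment columns minus matches
    n_columns: int | None = None
    aligned_target: str | None = None


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def gff_to_internal(start: int, end: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> 0-based half-open."""
    if start < 1 or end < start:
        raise ValueError(f"invalid GFF3 interval {start}..{end}")
    return start - 1, end


def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> GFF3 1-based inclusive."""
    if start < 0 or end <= start:
        raise ValueError(f"invalid internal interval [{start}, {end})")
    return start + 1, end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_genome(path: str | Path, max_invalid_fraction: float = 0.0) -> Genome:
    """Load a single-record FASTA genome, upper-cased and validated."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise ValueError(f"{path}: expected a single genome, found {len(records)} records")
    seq = str(records[0].seq).upper()
    invalid = sum(1 for c in seq if c not in _VALID)
    if invalid > max_invalid_fraction * len(seq):
        raise ValueError(f"{path}: {invalid} non-nucleotide characters in sequence")
    return Genome(genome_id=records[0].id, sequence=seq)


def write_genome(path: str | Path, genome: Genome) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.genome_id, description="")
    SeqIO.write([record], str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_cds_annotations(path: str | Path, genome_id: str, cds_list: Iterable[CdsRecord]) -> None:
    lines = ["##gff-version 3"]
    for cds in cds_list:
        start1, end1 = internal_to_gff(cds.start, cds.end)
        attrs = f"ID={cds.cds_id};product={cds.product}"
        lines.append(
            "\t".join(
                [genome_id, "phagemosaic", "CDS", str(start1), str(end1), ".", cds.strand, "0", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            key, value = part.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def load_cds_annotations(path: str | Path) -> list[CdsRecord]:
    """Read CDS rows from a GFF3 file (other feature types are ignored)."""
    records = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9 or fields[2] != "CDS":
            continue
        start, end = gff_to_internal(int(fields[3]), int(fields[4]))
        attrs = _parse_attributes(fields[8])
        cds_id = attrs.get("ID")
        if cds_id is None:
            raise ValueError(f"{path}: CDS row without an ID attribute: {line!r}")
        records.append(
            CdsRecord(
                cds_id=cds_id,
                start=start,
                end=end,
                strand=fields[6] if fields[6] in "+-" else "+",
                product=attrs.get("product", ""),
            )
        )
    records.sort(key=lambda c: c.start)
    return records


def write_panel(out_dir: str | Path, panel: AncestorPanel) -> dict[str, tuple[Path, Path]]:
    """Write one FASTA + GFF3 pair per ancestor; returns paths per label."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for anc in panel.ancestors:
        fasta = out_dir / f"{anc.genome_id}.fasta"
        gff = out_dir / f"{anc.genome_id}.gff3"
        write_genome(fasta, Genome(anc.genome_id, anc.sequence))
        write_cds_annotations(gff, anc.genome_id, anc.cds_list)
        paths[anc.label] = (fasta, gff)
    return paths


def load_panel(paths: Mapping[str, tuple[str | Path, str | Path]]) -> AncestorPanel:
    """Rebuild an :class:`AncestorPanel` from ``label -> (fasta, gff3)``."""
    ancestors = []
    for label, (fasta, gff) in paths.items():
        genome = load_genome(fasta)
        ancestors.append(
            Ancestor(
                label=label,
                genome_id=genome.genome_id,
                sequence=genome.sequence,
                cds_list=tuple(load_cds_annotations(gff)),
            )
        )
    return AncestorPanel(tuple(ancestors))


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------

def extract_cds_sequence(genome: Genome | str, cds: CdsRecord) -> str:
    """Strand-aware CDS sequence: forward slice, reverse-complemented for '-'."""
    seq = genome.sequence if isinstance(genome, Genome) else genome
    if cds.end > len(seq):
        raise ValueError(f"{cds.cds_id}: interval [{cds.start}, {cds.end}) outside genome")
    sub = seq[cds.start : cds.end]
    if cds.strand == "-":
        return str(Seq(sub).reverse_complement())
    return sub


# ---------------------------------------------------------------------------
# homolog mapping
# ---------------------------------------------------------------------------

def map_homologs(
    progeny_cds_seq: str,
    panel: AncestorPanel,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    *,
    identity_floor: float = DEFAULT_FOUND_IDENTITY_FLOOR,
) -> dict[str, HomologHit]:
    """Locate the best match of one CDS in every ancestor genome.

    Infix edit-distance alignment places the whole CDS at its best
    location in each ancestor.  Identity is matches / alignment columns,
    gap columns counting as mismatches.  An ancestor is reported *not
    found* when the aligned fraction of the CDS falls below
    ``min_coverage`` or identity falls below ``identity_floor`` (the
    level separating homology from the best chance placement of an
    unrelated sequence, which sits near 0.55 for nucleotides).
    """
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    hits: dict[str, HomologHit] = {}
    for anc in panel.ancestors:
        result = edlib.align(progeny_cds_seq, anc.sequence, mode="HW", task="path")
        if result["editDistance"] < 0 or not result["locations"]:
            hits[anc.label] = HomologHit(anc.label, found=False)
            continue
        start, end_incl = result["locations"][0]
        nice = edlib.getNiceAlignment(result, progeny_cds_seq, anc.sequence)
        matched = nice["matched_aligned"]
        columns = len(matched)
        matches = matched.count("|")
        identity = matches / columns
        query_cols = sum(1 for c in nice["query_aligned"] if c != "-")
        coverage = query_cols / len(progeny_cds_seq)  # 1.0 for infix alignment
        if coverage < min_coverage or identity < identity_floor:
            hits[anc.label] = HomologHit(anc.label, found=False)
            continue
        t_start, t_end = start, end_incl + 1
        hits[anc.label] = HomologHit(
            label=anc.label,
            found=True,
            identity=identity,
            coverage=coverage,
            target_start=t_start,
            target_end=t_end,
            n_mismatches=columns - matches,
            n_columns=columns,
            aligned_target=anc.sequence[t_start:t_end],
        )
    return hits
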