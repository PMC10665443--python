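"""Concatenated multi-marker supermatrix construction.

Per-marker alignments (MlaD, MlaE) restricted to taxa whose markers sit in a
conserved cluster arrangement are gap-trimmed, concatenated into a character
supermatrix, and written with a RAxML-style partition file ready for external
tree inference.  Alignment computation and tree inference are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY-X")


@dataclass
class MarkerAlignment:
    """One aligned marker: taxon -> aligned sequence, all the same width."""

    marker: str
    sequences: dict = field(default_factory=dict)

    def __post_init__(self):
        widths = {len(s) for s in self.sequences.values()}
        if len(widths) > 1:
            raise ValueError(f"{self.marker}: ragged alignment, widths {sorted(widths)}")
        for taxon, seq in self.sequences.items():
            bad = set(seq.upper()) - AA_ALPHABET
            if bad:
                raise ValueError(f"{self.marker}/{taxon}: illegal characters {sorted(bad)}")

    @property
    def width(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def taxa(self) -> list:
        return list(self.sequences)


@dataclass
class Supermatrix:
    taxa: list
    sequences: dict                 # taxon -> concatenated string
    partitions: list                # (marker, start_col, end_col), 1-based inclusive

    @property
    def width(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0


def read_marker_fasta(path, marker: str) -> MarkerAlignment:
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{marker}: taxon {rec.id} appears twice")
        seqs[rec.id] = str(rec.seq).upper()
    return MarkerAlignment(marker=marker, sequences=seqs)


def write_marker_fasta(aln: MarkerAlignment, path) -> None:
    records = [SeqRecord(Seq(s), id=t, description="") for t, s in aln.sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def trim_alignment(aln: MarkerAlignment, max_gap_fraction: float = 0.5) -> MarkerAlignment:
    """Keep columns whose gap fraction is <= max_gap_fraction, preserving
    column order.  A plain gap-fraction filter is used for trimming (entropy-
    weighted trimmers can be applied externally; pre-trimmed alignments pass
    through untouched at max_gap_fraction=1)."""
    if not 0 <= max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    if not aln.sequences:
        raise ValueError("empty alignment")
    taxa = aln.taxa
    n = len(taxa)
    keep = [
        col for col in range(aln.width)
        if sum(aln.sequences[t][col] == "-" for t in taxa) / n <= max_gap_fraction
    ]
    return MarkerAlignment(
        marker=aln.marker,
        sequences={t: "".join(aln.sequences[t][c] for c in keep) for t in taxa},
    )


def build_supermatrix(
    alignments: list,
    eligible_taxa: set,
    min_markers: int = 1,
) -> Supermatrix:
    """Concatenate marker alignments over taxa from conserved clusters.

    Rows are restricted to ``eligible_taxa`` (taxa whose markers come from a
    conserved MlaDE/MlaDEF cluster arrangement) having at least ``min_markers``
    of the markers; a missing marker is filled with gaps of that partition's
    width.  Paralog resolution (one sequence per taxon per marker) must happen
    upstream; duplicates raise.
    """
    if not alignments:
        raise ValueError("at least one marker alignment required")
    if not eligible_taxa:
        raise ValueError("eligible_taxa is empty")
    partitions = []
    start = 1
    for aln in alignments:
        if aln.width == 0:
            raise ValueError(f"{aln.marker}: empty alignment")
        partitions.append((aln.marker, start, start + aln.width - 1))
        start += aln.width
    taxa = sorted(
        t for t in eligible_taxa
        if sum(t in aln.sequences for aln in alignments) >= min_markers
    )
    sequences = {}
    for t in taxa:
        parts = []
        for aln in alignments:
            parts.append(aln.sequences.get(t, "-" * aln.width))
        sequences[t] = "".join(parts)
    return Supermatrix(taxa=taxa, sequences=sequences, partitions=partitions)


def partition_text(sm: Supermatrix, datatype: str = "PROT") -> str:
    """RAxML-style partition lines: ``PROT, MlaD = 1-100``."""
    return "".join(f"{datatype}, {m} = {s}-{e}\n" for m, s, e in sm.partitions)


def parse_partition_text(text: str) -> list:
    parts = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        _, rest = line.split(",", 1)
        name, span = rest.split("=")
        s, e = span.strip().split("-")
        parts.append((name.strip(), int(s), int(e)))
    return parts


def write_phylip(sm: Supermatrix, path) -> None:
    """Relaxed PHYLIP (name, space, sequence; one row per taxon)."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.width}\n")
        for t in sm.taxa:
            fh.write(f"{t}  {sm.sequences[t]}\n")


def write_supermatrix(sm: Supermatrix, fasta_path, partition_path) -> None:
    records = [SeqRecord(Seq(sm.sequences[t]), id=t, description="") for t in sm.taxa]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(partition_path, "w") as fh:
        fh.write(partition_text(sm))
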