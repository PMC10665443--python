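"""MlaD domain-architecture classification.

Every MlaD homologue is classified from three observables: total length, the
MCE-domain envelope, and a per-residue secondary-structure string over
{H, E, C}.  Short (E. coli-like, ~183 aa) forms end soon after the MCE
domain; long forms carry a C-terminal extension (helical region, with or
without a beta-barrel).  The barrel call counts maximal runs of 'E' after the
MCE envelope.
"""

from __future__ import annotations

import pandas as pd

from .config import ArchitectureThresholds
from .types import ARCHITECTURE_CLASSES, ArchitectureCall

SS_ALPHABET = frozenset("HEC")


def locate_mce(hits: pd.DataFrame, protein_id: str, family: str = "PF02470") -> tuple:
    """MCE-domain span of one protein: envelope of its best PF02470 hit.

    Proteins with tandem MCE domains must be excluded upstream
    (:func:`mlascan.homology.exclude_multi_mce`); among overlapping hits the
    highest bit score wins.
    """
    mine = hits[(hits["protein_id"] == protein_id) & (hits["family_id"] == family)]
    if mine.empty:
        raise ValueError(f"{protein_id}: no {family} hit; not an MlaD candidate")
    best = mine.sort_values(["bit_score", "env_start"], ascending=[False, True], kind="mergesort").iloc[0]
    return int(best["env_start"]), int(best["env_end"])


def cterm_strand_segments(ss: str, mce_end: int, min_run: int = 3) -> list:
    """Maximal runs of 'E' of length >= min_run strictly after the MCE domain.

    Coordinates are 1-based inclusive.  A run straddling ``mce_end`` is
    clipped to its C-terminal part before the length test.
    """
    if mce_end >= len(ss):
        raise ValueError("mce_end must lie before the end of the sequence")
    bad = set(ss) - SS_ALPHABET
    if bad:
        raise ValueError(f"secondary-structure string contains {sorted(bad)}; alphabet is H/E/C")
    segments = []
    start = None
    for pos in range(1, len(ss) + 2):  # 1-based; sentinel pass at len+1
        is_e = pos <= len(ss) and ss[pos - 1] == "E"
        if is_e and start is None:
            start = pos
        elif not is_e and start is not None:
            clipped_start = max(start, mce_end + 1)
            if pos - 1 >= clipped_start and (pos - 1) - clipped_start + 1 >= min_run:
                segments.append((clipped_start, pos - 1))
            start = None
    return segments


def classify_architecture(
    protein_id: str,
    length_aa: int,
    mce_span: tuple,
    segments: list,
    thresholds: ArchitectureThresholds | None = None,
) -> ArchitectureCall:
    """Classify one MlaD homologue.

    short: C-terminal extension after the MCE envelope < long_threshold.
    long_barrel: long with >= barrel_min_strands strand segments.
    long_partial_beta: long with 1..barrel_min_strands-1 segments (hairpin
        remnants / precursors).
    long_no_barrel: long with no strand segments.
    """
    thresholds = thresholds or ArchitectureThresholds()
    mce_start, mce_end = int(mce_span[0]), int(mce_span[1])
    if not (1 <= mce_start <= mce_end <= length_aa):
        raise ValueError(f"{protein_id}: MCE span {mce_span} outside protein of length {length_aa}")
    for s, e in segments:
        if s <= mce_end:
            raise ValueError(f"{protein_id}: strand segment ({s},{e}) not after MCE end {mce_end}")
    cterm_len = length_aa - mce_end
    n_strands = len(segments)
    strand_residues = sum(e - s + 1 for s, e in segments)
    if cterm_len < thresholds.long_threshold:
        arch = "short"
    elif n_strands >= thresholds.barrel_min_strands:
        arch = "long_barrel"
    elif n_strands >= 1:
        arch = "long_partial_beta"
    else:
        arch = "long_no_barrel"
    return ArchitectureCall(
        protein_id=protein_id,
        length_aa=int(length_aa),
        mce_span=(mce_start, mce_end),
        cterm_len=cterm_len,
        strand_segments=tuple(segments),
        n_strands=n_strands,
        strand_residues=strand_residues,
        arch_class=arch,
    )


def classify_mlad_table(
    mlad: pd.DataFrame,
    thresholds: ArchitectureThresholds | None = None,
) -> list:
    """Classify a table with columns protein_id, length_aa, mce_start,
    mce_end, ss; returns a list of :class:`ArchitectureCall`."""
    thresholds = thresholds or ArchitectureThresholds()
    calls = []
    for _, row in mlad.iterrows():
        segs = cterm_strand_segments(row["ss"], int(row["mce_end"]), thresholds.min_run)
        calls.append(
            classify_architecture(
                row["protein_id"], int(row["length_aa"]),
                (int(row["mce_start"]), int(row["mce_end"])), segs, thresholds,
            )
        )
    return calls


def summarize_architectures(calls: list) -> dict:
    """Summary statistics over architecture calls.

    Returns n, per-class fractions, fraction of long forms, and the mean
    length of long-class proteins (the quantity usually quoted alongside the
    long fraction).
    """
    if not calls:
        raise ValueError("no architecture calls to summarize")
    n = len(calls)
    frac = {c: sum(1 for a in calls if a.arch_class == c) / n for c in ARCHITECTURE_CLASSES}
    long_calls = [a for a in calls if a.arch_class != "short"]
    return {
        "n": n,
        "fractions": frac,
        "fraction_long": len(long_calls) / n,
        "mean_long_length": (sum(a.length_aa for a in long_calls) / len(long_calls)) if long_calls else float("nan"),
    }


def write_architecture_calls(calls: list, path) -> None:
    rows = [
        {
            "protein_id": a.protein_id, "length_aa": a.length_aa,
            "mce_start": a.mce_span[0], "mce_end": a.mce_span[1],
            "cterm_len": a.cterm_len, "n_strands": a.n_strands,
            "strand_residues": a.strand_residues, "arch_class": a.arch_class,
            "strand_segments": ";".join(f"{s}-{e}" for s, e in a.strand_segments),
        }
        for a in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ss_table(path) -> pd.DataFrame:
    """Read per-protein secondary-structure strings from two-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "ss": str})
    if not {"protein_id", "ss"} <= set(df.columns):
        raise ValueError("SS table needs columns protein_id and ss")
    return df
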