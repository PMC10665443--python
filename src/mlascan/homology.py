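"""Reading and reducing homology-search output.

Parses HMMER3 per-domain tabular output (``--domtblout``), reduces raw domain
hits to per-protein component candidates, and separates single-MCE (MlaD-like)
proteins from tandem multi-MCE proteins (PqiB/LetB-like), which must be
excluded from the MlaD set.
"""

from __future__ import annotations

import pandas as pd

from .config import HitThresholds
from .types import (
    CALL_COLUMNS,
    COMPONENT_OF_GENERIC_FAMILY,
    COMPONENT_OF_PFAM,
    HIT_COLUMNS,
    empty_call_table,
    empty_hit_table,
)

# domtblout column positions (0-based) among the 23 whitespace-separated fields
_TARGET, _TLEN, _QUERY, _QACC = 0, 2, 3, 4
_IEVALUE, _DOMSCORE = 12, 13
_ENV_FROM, _ENV_TO = 19, 20
_N_FIELDS = 23


def read_domtblout(path) -> pd.DataFrame:
    """Parse a HMMER3 per-domain table into a DomainHit table.

    One row per domain hit, in file order.  Envelope coordinates define the
    domain span; the independent (per-domain) E-value and the domain bit score
    are retained.  The family id is taken from the query accession when it
    looks like one (e.g. ``PF02470.20`` -> ``PF02470``), else the query name.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(None, _N_FIELDS - 1)
            if len(fields) < _ENV_TO + 1:
                raise ValueError(f"{path}: malformed domtblout row at line {lineno}")
            try:
                acc = fields[_QACC]
                family = acc.split(".")[0] if acc != "-" else fields[_QUERY]
                rows.append(
                    {
                        "protein_id": fields[_TARGET],
                        "family_id": family,
                        "protein_len": int(fields[_TLEN]),
                        "env_start": int(fields[_ENV_FROM]),
                        "env_end": int(fields[_ENV_TO]),
                        "bit_score": float(fields[_DOMSCORE]),
                        "e_value": float(fields[_IEVALUE]),
                    }
                )
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed domtblout row at line {lineno}: {exc}"
                ) from None
    if not rows:
        return empty_hit_table()
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_domtblout(hits: pd.DataFrame, path) -> None:
    """Serialize a DomainHit table in the domtblout dialect read back by
    :func:`read_domtblout`.  Unused numeric columns are written as zeros."""
    with open(path, "w") as fh:
        fh.write("# target name        accession   tlen query name           "
                 "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
                 "i-Evalue  score  bias  from    to  from    to  from    to  "
                 "acc description of target\n#\n")
        for _, h in hits.iterrows():
            fam = h["family_id"]
            acc = f"{fam}.1" if str(fam).startswith("PF") else "-"
            qname = fam
            fh.write(
                f"{h['protein_id']:<20s} -          {int(h['protein_len']):5d} "
                f"{qname:<20s} {acc:<11s} {int(h['env_end'] - h['env_start'] + 1):5d} "
                f"{h['e_value']:9.2g} {h['bit_score']:6.1f}   0.0   1   1 "
                f"{h['e_value']:9.2g} {h['e_value']:9.2g} {h['bit_score']:6.1f}   0.0 "
                f"{int(h['env_start']):5d} {int(h['env_end']):5d} "
                f"{int(h['env_start']):5d} {int(h['env_end']):5d} "
                f"{int(h['env_start']):5d} {int(h['env_end']):5d} 0.90 -\n"
            )


def filter_to_component_calls(
    hits: pd.DataFrame,
    thresholds: HitThresholds | None = None,
    generic_families: dict | None = None,
) -> pd.DataFrame:
    """Reduce domain hits to one ComponentCall per (protein, component).

    Hits failing the per-family (max E-value, min bit score) thresholds are
    discarded.  Pfam-identified components carry evidence ``pfam_hit``; hits
    against configured generic families (STAS-domain MlaB, ABC-ATPase MlaF)
    carry ``generic_family`` and remain provisional until synteny gating.  Ties
    resolve to the higher bit score, then the lexicographically smaller
    protein id keeps its row order stable.
    """
    thresholds = thresholds or HitThresholds()
    fam_to_comp = dict(COMPONENT_OF_PFAM)
    generic = generic_families if generic_families is not None else COMPONENT_OF_GENERIC_FAMILY
    fam_to_comp.update(generic)

    if hits.empty:
        return empty_call_table()

    rows = []
    for _, h in hits.iterrows():
        fam = h["family_id"]
        comp = fam_to_comp.get(fam)
        if comp is None:
            continue
        max_e, min_bit = thresholds.for_family(fam)
        if h["e_value"] > max_e or h["bit_score"] < min_bit:
            continue
        rows.append(
            {
                "protein_id": h["protein_id"],
                "component": comp,
                "evidence": "generic_family" if fam in generic else "pfam_hit",
                "env_start": int(h["env_start"]),
                "env_end": int(h["env_end"]),
                "bit_score": float(h["bit_score"]),
                "e_value": float(h["e_value"]),
            }
        )
    if not rows:
        return empty_call_table()
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    calls = calls.sort_values(
        ["protein_id", "component", "bit_score"],
        ascending=[True, True, False],
        kind="mergesort",
    )
    calls = calls.drop_duplicates(["protein_id", "component"], keep="first")
    return calls.reset_index(drop=True)


def count_mce_domains(
    hits: pd.DataFrame,
    family: str = "PF02470",
    max_overlap_fraction: float = 0.2,
) -> int:
    """Count non-overlapping MCE-domain envelopes on one protein.

    Tandem-MCE proteins (PqiB carries seven MCE domains, LetB similar) must be
    told apart from single-MCE MlaD.  Two envelopes conflict when they share
    more than ``max_overlap_fraction`` of the shorter envelope, which absorbs
    alignment jitter without double-counting.  For realistic per-protein hit
    counts (<= 12) the exact maximum set of pairwise compatible envelopes is
    found by enumeration; larger sets fall back to greedy acceptance by
    descending bit score.
    """
    fam_hits = hits[hits["family_id"] == family]
    if fam_hits.empty:
        return 0
    if fam_hits["protein_id"].nunique() > 1:
        raise ValueError("count_mce_domains expects hits from a single protein")
    envs = [(int(h["env_start"]), int(h["env_end"])) for _, h in fam_hits.iterrows()]

    def compatible(a, b):
        ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
        shorter = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
        return ov <= max_overlap_fraction * shorter

    n = len(envs)
    if n <= 12:
        conflict = [
            sum(1 << j for j in range(n) if j != i and not compatible(envs[i], envs[j]))
            for i in range(n)
        ]
        best = 0
        for mask in range(1 << n):
            size = mask.bit_count()
            if size <= best:
                continue
            if all(not (mask & conflict[i]) for i in range(n) if mask & (1 << i)):
                best = size
        return best
    order = fam_hits.sort_values(
        ["bit_score", "env_start"], ascending=[False, True], kind="mergesort"
    )
    accepted: list[tuple[int, int]] = []
    for _, h in order.iterrows():
        env = (int(h["env_start"]), int(h["env_end"]))
        if all(compatible(env, a) for a in accepted):
            accepted.append(env)
    return len(accepted)


def exclude_multi_mce(calls: pd.DataFrame, hits: pd.DataFrame) -> tuple:
    """Split MlaD calls into single-MCE (kept) and multi-MCE (PqiB/LetB-like).

    Returns ``(kept_calls, multi_mce_protein_ids)``: the call table with
    multi-MCE proteins' MlaD rows removed, and the ids of excluded proteins.
    """
    multi = []
    for pid in calls.loc[calls["component"] == "MlaD", "protein_id"].unique():
        if count_mce_domains(hits[hits["protein_id"] == pid]) > 1:
            multi.append(pid)
    mask = (calls["component"] == "MlaD") & calls["protein_id"].isin(multi)
    return calls[~mask].reset_index(drop=True), multi


def write_component_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_component_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
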