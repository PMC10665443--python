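"""Gene-neighborhood detection of Mla systems.

Component genes on the same replicon are chained into clusters whenever at
most ``max_gap`` genes separate consecutive members (the rule used to call a
gene cluster a system), and candidate MlaB/MlaF hits from generic protein
families are retained only when they sit in synteny with an anchor component
(MlaA/C/D/E), mirroring how ABC-ATPase and STAS hits must be synteny-gated to
avoid flooding the call set with false positives.
"""

from __future__ import annotations

import pandas as pd

from .config import SyntenyConfig
from .types import COMPONENTS, SystemCall

ANCHOR_COMPONENTS = frozenset({"MlaA", "MlaC", "MlaD", "MlaE"})


def _positions(genes: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Join calls onto gene coordinates; error on calls with no gene."""
    merged = calls.merge(
        genes[["genome_id", "replicon_id", "gene_index", "protein_id"]],
        on="protein_id",
        how="left",
    )
    orphans = merged.loc[merged["gene_index"].isna(), "protein_id"].tolist()
    if orphans:
        raise ValueError(f"component calls on unknown proteins: {sorted(set(orphans))}")
    merged["gene_index"] = merged["gene_index"].astype(int)
    return merged


def detect_clusters(
    genes: pd.DataFrame,
    calls: pd.DataFrame,
    config: SyntenyConfig | None = None,
) -> tuple:
    """Chain component genes into maximal clusters per replicon.

    Single-linkage chaining: two component genes join the same cluster when
    the number of intervening genes between them is within the gap bound.  On
    circular replicons (config.circular) the junction between the last and
    first gene is also considered.  Returns ``(systems, lone_calls)`` where
    systems is a list of :class:`SystemCall` (clusters with >= 2 distinct
    components) and lone_calls is a DataFrame of single-component occurrences
    with their coordinates.
    """
    config = config or SyntenyConfig()
    max_diff = config.max_index_diff()
    lone_columns = ["genome_id", "replicon_id", "gene_index", "component", "protein_id"]
    if calls.empty:
        return [], pd.DataFrame(columns=lone_columns)
    placed = _positions(genes, calls)

    systems: list[SystemCall] = []
    lone_rows = []
    for (genome, replicon), grp in placed.groupby(["genome_id", "replicon_id"], sort=True):
        grp = grp.sort_values(["gene_index", "component"], kind="mergesort")
        members = list(grp[["gene_index", "component", "protein_id"]].itertuples(index=False, name=None))
        if not members:
            continue
        # chain along the linear order
        chains: list[list] = [[members[0]]]
        for prev, cur in zip(members, members[1:]):
            if cur[0] - prev[0] <= max_diff:
                chains[-1].append(cur)
            else:
                chains.append([cur])
        wrapped = False
        if config.circular and len(chains) > 1:
            n_genes = int(genes[(genes["genome_id"] == genome) & (genes["replicon_id"] == replicon)].shape[0])
            first_idx = chains[0][0][0]
            last_idx = chains[-1][-1][0]
            if n_genes - (last_idx - first_idx) <= max_diff:
                chains[0] = chains.pop() + chains[0]
                wrapped = True
        for i, chain in enumerate(chains):
            comps = {c for _, c, _ in chain}
            if len(comps) >= 2:
                systems.append(
                    SystemCall(
                        genome_id=genome,
                        replicon_id=replicon,
                        members=tuple(chain),
                        circular_wrap=wrapped and i == 0,
                    )
                )
            else:
                for idx, comp, pid in chain:
                    lone_rows.append(
                        {"genome_id": genome, "replicon_id": replicon,
                         "gene_index": idx, "component": comp, "protein_id": pid}
                    )
    lone = pd.DataFrame(lone_rows, columns=lone_columns)
    return systems, lone


def gate_generic_components(
    genes: pd.DataFrame,
    anchor_calls: pd.DataFrame,
    generic_calls: pd.DataFrame,
    config: SyntenyConfig | None = None,
) -> pd.DataFrame:
    """Retain MlaB/MlaF candidates only when in synteny with an anchor.

    A generic-family call survives iff its gene lies within the gap bound of a
    gene carrying a Pfam-evidenced MlaA/C/D/E call on the same replicon.
    """
    config = config or SyntenyConfig()
    bad = set(generic_calls["component"]) - {"MlaB", "MlaF"}
    if bad:
        raise ValueError(f"gate applies only to MlaB/MlaF candidates, got {sorted(bad)}")
    anchors = anchor_calls[anchor_calls["component"].isin(ANCHOR_COMPONENTS)]
    if generic_calls.empty or anchors.empty:
        return generic_calls.iloc[0:0].copy()
    max_diff = config.max_index_diff()
    anchor_pos = _positions(genes, anchors)
    gen_pos = _positions(genes, generic_calls.reset_index(drop=True))
    keep = []
    for i, row in gen_pos.iterrows():
        near = anchor_pos[
            (anchor_pos["genome_id"] == row["genome_id"])
            & (anchor_pos["replicon_id"] == row["replicon_id"])
            & ((anchor_pos["gene_index"] - row["gene_index"]).abs() <= max_diff)
        ]
        if not near.empty:
            keep.append(i)
    return generic_calls.reset_index(drop=True).iloc[keep].reset_index(drop=True)


def call_systems(
    genes: pd.DataFrame,
    calls: pd.DataFrame,
    config: SyntenyConfig | None = None,
) -> tuple:
    """Full synteny stage: gate generic MlaB/MlaF, then detect clusters.

    Returns ``(systems, lone_calls, retained_generic)``.
    """
    config = config or SyntenyConfig()
    pfam_calls = calls[calls["evidence"] != "generic_family"]
    generic_calls = calls[calls["evidence"] == "generic_family"]
    retained = gate_generic_components(genes, pfam_calls, generic_calls, config)
    final_calls = pd.concat([pfam_calls, retained], ignore_index=True)
    systems, lone = detect_clusters(genes, final_calls, config)
    return systems, lone, retained


def summarize_presence(
    systems: list,
    lone_calls: pd.DataFrame,
    genome_ids: list,
) -> pd.DataFrame:
    """Per-genome component presence vectors (MlaA..MlaF, TamB).

    MlaA/C/D/E and TamB count whether clustered or lone; MlaB/MlaF reach this
    point only if synteny-gated (they are cluster members by construction), so
    a gated call never appears without a covering cluster.
    """
    presence = pd.DataFrame(False, index=pd.Index(genome_ids, name="genome_id"), columns=list(COMPONENTS))
    for sc in systems:
        for _, comp, _ in sc.members:
            if comp in presence.columns:
                presence.loc[sc.genome_id, comp] = True
    for _, row in lone_calls.iterrows():
        if row["component"] in {"MlaB", "MlaF"}:
            continue  # ungated generic candidates never count as present
        if row["genome_id"] in presence.index and row["component"] in presence.columns:
            presence.loc[row["genome_id"], row["component"]] = True
    return presence


def write_systems(systems: list, path) -> None:
    rows = []
    for k, sc in enumerate(systems):
        for idx, comp, pid in sc.members:
            rows.append(
                {"system_id": k, "genome_id": sc.genome_id, "replicon_id": sc.replicon_id,
                 "gene_index": idx, "component": comp, "protein_id": pid,
                 "circular_wrap": sc.circular_wrap}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_presence_matrix(presence: pd.DataFrame, path) -> None:
    presence.astype(int).to_csv(path, sep="\t")


def read_presence_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(bool)
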