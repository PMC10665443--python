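"""Phyletic profiling and ancestral-presence inference.

Builds the taxon x component presence matrix, maps it onto a rooted reference
tree, infers ancestral presence under Fitch (Hartigan) parsimony and under a
Dollo (single-gain, loss-only) model, tests clade monophyly, and exports iTOL
binary-dataset annotations.

The reference tree is always an input; nothing here infers trees.  Leaves
without profile data are ignored during parsimony rather than imputed absent.
"""

from __future__ import annotations

import re

import dendropy
import pandas as pd

from .types import AncestralStates, PhyleticProfile

PRESENT, ABSENT = True, False


def read_tree(source: str, is_path: bool = True) -> dendropy.Tree:
    """Read a rooted Newick tree, preserving underscores and internal-node
    labels (used for bootstrap supports)."""
    kwargs = dict(schema="newick", preserve_underscores=True)
    if is_path:
        tree = dendropy.Tree.get(path=source, **kwargs)
    else:
        tree = dendropy.Tree.get(data=source, **kwargs)
    tree.is_rooted = True
    return tree


def normalize_label(label: str, strip_nonalnum: bool = True) -> str:
    """Case-fold and optionally strip non-alphanumerics, the two dominant
    sources of Newick-vs-table label drift."""
    s = str(label).lower()
    if strip_nonalnum:
        s = re.sub(r"[^a-z0-9]", "", s)
    return s


def _leaf_label(node) -> str:
    return node.taxon.label if node.taxon is not None else (node.label or "")


def label_nodes(tree: dendropy.Tree) -> None:
    """Give every unlabeled internal node a stable label N0, N1, ... in
    preorder, so ancestral states can be reported per node."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            node.label = f"N{i}"
        i += 1


def build_matrix(
    presence: pd.DataFrame,
    taxonomy: dict,
    architecture_calls: list | None = None,
    genome_of_protein: dict | None = None,
) -> PhyleticProfile:
    """Aggregate per-genome presence vectors into a taxon-level profile.

    A taxon is scored present for a component when any of its genomes is
    (OR semantics).  When architecture calls are supplied together with a
    protein -> genome map, a derived ``MlaD_barrel`` column records whether any
    genome of the taxon encodes a complete-barrel MlaD.
    """
    unmapped = [g for g in presence.index if g not in taxonomy]
    if unmapped:
        raise ValueError(f"genomes without taxonomy mapping: {unmapped}")
    taxa = sorted(set(taxonomy[g] for g in presence.index))
    mat = pd.DataFrame(False, index=pd.Index(taxa, name="taxon"), columns=list(presence.columns))
    for genome, row in presence.iterrows():
        taxon = taxonomy[genome]
        mat.loc[taxon] = mat.loc[taxon] | row.astype(bool)
    if architecture_calls is not None:
        if genome_of_protein is None:
            raise ValueError("MlaD_barrel column needs a protein -> genome map")
        mat["MlaD_barrel"] = False
        for call in architecture_calls:
            if call.arch_class == "long_barrel":
                genome = genome_of_protein.get(call.protein_id)
                if genome is not None and genome in taxonomy:
                    mat.loc[taxonomy[genome], "MlaD_barrel"] = True
    return PhyleticProfile(matrix=mat)


def map_to_tree(
    profile: PhyleticProfile,
    tree: dendropy.Tree,
    strip_nonalnum: bool = True,
) -> tuple:
    """Attach presence vectors to tree leaves by normalized label matching.

    Returns ``(leaf_vectors, missing_from_tree, unknown_leaves)`` where
    leaf_vectors maps each matched leaf's original label to its boolean
    vector.  Zero overlap raises: that is almost always a naming-scheme
    mismatch, not genuine disjointness.
    """
    norm_profile = {normalize_label(t, strip_nonalnum): t for t in profile.taxa}
    leaf_vectors: dict = {}
    unknown = []
    seen = set()
    for leaf in tree.leaf_node_iter():
        label = _leaf_label(leaf)
        key = normalize_label(label, strip_nonalnum)
        if key in norm_profile:
            taxon = norm_profile[key]
            leaf_vectors[label] = profile.matrix.loc[taxon].astype(bool).to_dict()
            seen.add(key)
        else:
            unknown.append(label)
    missing = [norm_profile[k] for k in norm_profile if k not in seen]
    if not leaf_vectors:
        raise ValueError("no profile taxon matches any tree leaf; check naming schemes")
    return leaf_vectors, missing, unknown


def _require_rooted(tree: dendropy.Tree) -> None:
    if tree.is_rooted is False:
        raise ValueError("a rooted tree is required")


def fitch_parsimony(tree: dendropy.Tree, leaf_states: dict) -> AncestralStates:
    """Minimum-change (Fitch/Hartigan) ancestral presence on a rooted tree.

    ``leaf_states`` maps leaf labels to booleans; leaves absent from the map
    are excluded from scoring.  Works on multifurcating trees (Hartigan's
    generalization).  Root ties resolve to present and set
    ``ambiguous_root``; the same present-bias applies at internal ties so the
    reconstruction is deterministic.
    """
    _require_rooted(tree)
    label_nodes(tree)
    candidate: dict = {}   # node -> frozenset of optimal states
    n_changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = _leaf_label(node)
            if label in leaf_states:
                candidate[node] = frozenset({bool(leaf_states[label])})
            continue
        child_sets = [candidate[c] for c in node.child_nodes() if c in candidate]
        if not child_sets:
            continue
        votes = {s: sum(1 for cs in child_sets if s in cs) for s in (PRESENT, ABSENT)}
        top = max(votes.values())
        candidate[node] = frozenset(s for s, v in votes.items() if v == top)
        n_changes += len(child_sets) - top

    root = tree.seed_node
    if root not in candidate:
        raise ValueError("no scored leaves under the root")
    states: dict = {}
    ambiguous_root = len(candidate[root]) == 2
    order = [root]
    assigned = {root: PRESENT if PRESENT in candidate[root] else ABSENT}
    while order:
        node = order.pop()
        st = assigned[node]
        states[node.label if not node.is_leaf() else _leaf_label(node)] = st
        for child in node.child_nodes():
            if child not in candidate:
                continue
            cs = candidate[child]
            assigned[child] = st if st in cs else (PRESENT if PRESENT in cs else ABSENT)
            order.append(child)
    return AncestralStates(
        states=states,
        n_changes=n_changes,
        root_state=assigned[root],
        ambiguous_root=ambiguous_root,
    )


def dollo_root_inference(tree: dendropy.Tree, leaf_states: dict) -> AncestralStates:
    """Single-gain (Dollo) ancestral presence on a rooted tree.

    The gain is placed at the MRCA of all present leaves; a node is present
    iff it descends from (or is) that MRCA and still has a present descendant.
    Losses (present parent -> absent child) are then minimal under the
    single-gain constraint.  The root is present iff presence occurs in at
    least two of its child subtrees.
    """
    _require_rooted(tree)
    label_nodes(tree)
    has_present: dict = {}
    scored: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = _leaf_label(node)
            if label in leaf_states:
                has_present[node] = bool(leaf_states[label])
                scored[node] = True
            continue
        kids = [c for c in node.child_nodes() if c in has_present]
        if kids:
            has_present[node] = any(has_present[c] for c in kids)
            scored[node] = True

    root = tree.seed_node
    if root not in has_present:
        raise ValueError("no scored leaves under the root")

    # gain node = MRCA of present leaves: deepest node whose subtree holds all
    gain = None
    if has_present[root]:
        gain = root
        while True:
            rich = [c for c in gain.child_nodes() if has_present.get(c, False)]
            if len(rich) == 1:
                gain = rich[0]
            else:
                break

    under_gain: set = set()
    if gain is not None:
        for node in gain.preorder_iter():
            under_gain.add(node)

    states: dict = {}
    n_losses = 0
    for node in tree.preorder_node_iter():
        if node not in has_present:
            continue
        present = node in under_gain and has_present[node]
        label = node.label if not node.is_leaf() else _leaf_label(node)
        states[label] = present
        parent = node.parent_node
        if parent is not None and parent in has_present:
            parent_label = parent.label if not parent.is_leaf() else _leaf_label(parent)
            if states.get(parent_label) and not present:
                n_losses += 1
    return AncestralStates(
        states=states,
        n_changes=n_losses + (1 if gain is not None and gain is not root else 0),
        root_state=states[root.label],
        ambiguous_root=False,
    )


def check_monophyly(tree: dendropy.Tree, taxon_labels: set) -> tuple:
    """Whether ``taxon_labels`` form a clade; returns (bool, support or None).

    Support is the MRCA's internal-node label parsed as a number when
    possible (ultrafast-bootstrap style annotation).
    """
    if not taxon_labels:
        raise ValueError("empty taxon set")
    leaves = {_leaf_label(l): l for l in tree.leaf_node_iter()}
    missing = set(taxon_labels) - set(leaves)
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    target = {leaves[t] for t in taxon_labels}
    mrca = tree.mrca(taxa=[l.taxon for l in target])
    clade_leaves = {_leaf_label(l) for l in mrca.leaf_iter()}
    is_mono = clade_leaves == set(taxon_labels)
    support = None
    if mrca.label:
        try:
            support = float(mrca.label)
        except ValueError:
            support = mrca.label
    return is_mono, (support if is_mono else None)


def export_itol(profile: PhyleticProfile) -> str:
    """iTOL DATASET_BINARY annotation text, one dataset block per component."""
    if profile.matrix.empty:
        raise ValueError("empty profile")
    blocks = []
    for comp in profile.components:
        lines = [
            "DATASET_BINARY",
            "SEPARATOR TAB",
            f"DATASET_LABEL\t{comp}",
            "COLOR\t#1f78b4",
            "FIELD_SHAPES\t1",
            f"FIELD_LABELS\t{comp}",
            "DATA",
        ]
        for taxon in profile.taxa:
            val = 1 if bool(profile.matrix.loc[taxon, comp]) else 0
            lines.append(f"{taxon}\t{val}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def read_itol(text: str) -> PhyleticProfile:
    """Parse annotation text written by :func:`export_itol` back to a profile."""
    comp = None
    data_mode = False
    columns: dict = {}
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line == "DATASET_BINARY":
            comp, data_mode = None, False
            continue
        if line.startswith("DATASET_LABEL\t"):
            comp = line.split("\t", 1)[1]
            columns[comp] = {}
            continue
        if line == "DATA":
            data_mode = True
            continue
        if data_mode and "\t" in line and comp is not None:
            taxon, val = line.split("\t", 1)
            columns[comp][taxon] = bool(int(val))
        elif "\t" in line or line.startswith("SEPARATOR"):
            data_mode = False
    mat = pd.DataFrame(columns).fillna(False).astype(bool)
    mat.index.name = "taxon"
    return PhyleticProfile(matrix=mat)


def write_ancestral_states(anc: AncestralStates, path) -> None:
    rows = [{"node": k, "state": "present" if v else "absent"} for k, v in anc.states.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def annotate_newick(tree: dendropy.Tree, anc: AncestralStates) -> str:
    """Newick string with per-node presence states as comments."""
    label_nodes(tree)
    for node in tree.preorder_node_iter():
        label = node.label if not node.is_leaf() else _leaf_label(node)
        if label in anc.states:
            node.annotations.add_new("state", "present" if anc.states[label] else "absent")
    return tree.as_string(schema="newick", suppress_annotations=False)
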