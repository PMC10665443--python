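"""Synthetic inputs with known ground truth for every pipeline stage.

Generates genome gene-order tables with planted Mla clusters and decoy genes,
noisy domain-hit tables, loss-only (Dollo) presence/absence evolution on a
tree, MlaD sequences of planted architecture classes with per-residue
secondary-structure strings, and ideal-geometry coordinate models (alpha
helices, antiparallel sheets, beta-barrels, cylinders) used as analytic
oracles for the geometry stage.

All generators are deterministic for a fixed seed.  Gene coordinates are
ordinal (gene index per replicon), because the synteny rule counts genes, not
base pairs.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np
import pandas as pd

from .types import (
    GENE_COLUMNS,
    GENERIC_FAMILY_OF_COMPONENT,
    HIT_COLUMNS,
    PFAM_OF_COMPONENT,
    PlantedSystem,
    StructureModel,
    SystemTemplate,
    TruthTable,
    empty_hit_table,
)

# typical protein lengths (aa) used for planted component genes
_TYPICAL_LENGTH = {
    "MlaA": 250, "MlaB": 97, "MlaC": 211, "MlaD": 419,
    "MlaE": 260, "MlaF": 270, "TamB": 1300, "TolC": 450,
}

FAMILY_OF_COMPONENT = dict(PFAM_OF_COMPONENT)
FAMILY_OF_COMPONENT.update(GENERIC_FAMILY_OF_COMPONENT)


# ---------------------------------------------------------------------------
# genomes and domain hits
# ---------------------------------------------------------------------------

def generate_genome_set(
    n_genomes: int,
    genes_per_replicon: tuple = (50, 200),
    system_templates: list | None = None,
    decoy_rate: float = 0.1,
    seed: int = 0,
) -> tuple:
    """Emit a gene-order table with planted component clusters.

    Each genome carries one replicon; templates (ordered component labels with
    intervening-gene gaps) are planted round-robin across genomes at a random
    position.  Non-component genes become decoys with probability
    ``decoy_rate``; decoys carry no true component identity but may later
    receive false-positive domain hits.

    Returns ``(genes, truth)``.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if not 0 <= decoy_rate < 1:
        raise ValueError("decoy_rate must be in [0, 1)")
    templates = [
        t if isinstance(t, SystemTemplate) else SystemTemplate(tuple(t))
        for t in (system_templates or [])
    ]
    rng = np.random.default_rng(seed)
    lo, hi = genes_per_replicon
    truth = TruthTable()
    rows = []
    for g in range(n_genomes):
        genome = f"G{g:04d}"
        replicon = "r1"
        n_genes = int(rng.integers(lo, hi + 1))
        planted: dict = {}
        if templates:
            tpl = templates[g % len(templates)]
            if tpl.span > n_genes:
                raise ValueError(
                    f"template span {tpl.span} exceeds replicon of {n_genes} genes"
                )
            start = int(rng.integers(0, n_genes - tpl.span + 1))
            pos = start
            indices = []
            for i, comp in enumerate(tpl.components):
                planted[pos] = comp
                indices.append(pos)
                if i < len(tpl.gaps):
                    pos += 1 + tpl.gaps[i]
            truth.planted_systems.append(
                PlantedSystem(genome, replicon, tpl.components, tuple(indices))
            )
        for idx in range(n_genes):
            pid = f"{genome}_{idx:04d}"
            comp = planted.get(idx)
            if comp is not None:
                length = int(_TYPICAL_LENGTH.get(comp, 300) + rng.integers(-20, 21))
                truth.component_of[pid] = comp
            else:
                length = int(rng.integers(120, 801))
                if rng.random() < decoy_rate:
                    truth.decoys.add(pid)
            rows.append(
                {
                    "genome_id": genome, "replicon_id": replicon, "gene_index": idx,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "protein_id": pid, "length_aa": length,
                }
            )
    return pd.DataFrame(rows, columns=GENE_COLUMNS), truth


def generate_hit_table(
    genes: pd.DataFrame,
    truth: TruthTable,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    seed: int = 0,
    fp_families: list | None = None,
) -> pd.DataFrame:
    """Domain-hit table for a synthetic genome set.

    Every true component gene receives a hit of its family (dropped with
    probability ``fn_rate``) with an envelope inside the protein and a score
    comfortably above the default acceptance threshold.  Decoy genes receive
    false-positive hits with probability ``fp_rate``; by default these come
    from the generic families (STAS / ABC-ATPase), the realistic noise mode
    the synteny gate exists to absorb.
    """
    for name, rate in (("fp_rate", fp_rate), ("fn_rate", fn_rate)):
        if not 0 <= rate < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    fp_pool = fp_families if fp_families is not None else sorted(GENERIC_FAMILY_OF_COMPONENT.values())
    rows = []
    for _, gene in genes.iterrows():
        pid = gene["protein_id"]
        length = int(gene["length_aa"])
        comp = truth.component_of.get(pid)
        if comp is not None and comp in FAMILY_OF_COMPONENT:
            if rng.random() < fn_rate:
                continue
            if comp == "MlaD" and pid in truth.planted_mce_spans:
                s, e = truth.planted_mce_spans[pid]
            elif comp == "MlaD":
                s, e = 36, min(140, length)
            else:
                s, e = 5, min(length, 5 + int(rng.integers(80, 160)))
            bit = float(max(60.0, rng.normal(180.0, 30.0)))
            rows.append(
                {
                    "protein_id": pid, "family_id": FAMILY_OF_COMPONENT[comp],
                    "protein_len": length, "env_start": s, "env_end": e,
                    "bit_score": round(bit, 1),
                    "e_value": float(f"{10.0 ** (-bit / 4.0):.2g}") or 1e-200,
                }
            )
        elif pid in truth.decoys and rng.random() < fp_rate:
            fam = str(rng.choice(fp_pool))
            e_end = min(length, 1 + int(rng.integers(60, 120)))
            bit = float(np.clip(rng.normal(45.0, 12.0), 15.0, 90.0))
            rows.append(
                {
                    "protein_id": pid, "family_id": fam, "protein_len": length,
                    "env_start": 1, "env_end": e_end, "bit_score": round(bit, 1),
                    "e_value": float(f"{10.0 ** rng.uniform(-9.0, -3.0):.2g}"),
                }
            )
    if not rows:
        return empty_hit_table()
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# trees and Dollo evolution
# ---------------------------------------------------------------------------

def random_rooted_tree(n_leaves: int, seed: int = 0) -> dendropy.Tree:
    """Random rooted binary tree with leaves L1..Ln and unit branch lengths."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    nodes = [f"L{i + 1}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]}:1,{nodes[j]}:1)"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = nodes[0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def simulate_dollo(
    tree: dendropy.Tree,
    root_state: bool = True,
    loss_prob_per_branch: float = 0.1,
    seed: int = 0,
) -> tuple:
    """Single-gain, loss-only character evolution down a rooted tree.

    The character is gained (or not) at the root; on every branch below a
    present node it is lost with probability ``loss_prob_per_branch`` and can
    never be regained.  Returns ``(leaf_states, node_states)`` as label-keyed
    dicts; internal nodes are labelled N0, N1, ... in preorder if unlabeled.
    """
    if tree.is_rooted is False:
        raise ValueError("simulate_dollo requires a rooted tree")
    if not 0 <= loss_prob_per_branch < 1:
        raise ValueError("loss_prob_per_branch must be in [0, 1)")
    from .phyletics import label_nodes  # local import to avoid cycle at import time

    label_nodes(tree)
    rng = np.random.default_rng(seed)
    node_states: dict = {}
    state_of: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            st = bool(root_state)
        else:
            parent = state_of[node.parent_node]
            st = parent and not (rng.random() < loss_prob_per_branch)
        state_of[node] = st
        label = node.label if not node.is_leaf() else node.taxon.label
        node_states[label] = st
    leaf_states = {
        leaf.taxon.label: state_of[leaf] for leaf in tree.leaf_node_iter()
    }
    return leaf_states, node_states


# ---------------------------------------------------------------------------
# MlaD architecture sets
# ---------------------------------------------------------------------------

def _noise(ss: list, rate: float, rng) -> None:
    alphabet = "HEC"
    for i in range(len(ss)):
        if rng.random() < rate:
            others = alphabet.replace(ss[i], "")
            ss[i] = others[int(rng.integers(0, 2))]


def generate_mlad_set(
    n: int,
    class_mix: dict | None = None,
    ss_noise: float = 0.0,
    seed: int = 0,
) -> tuple:
    """MlaD homologues of planted architecture classes.

    Layouts emulate the two observed forms: the short E. coli-like protein
    (~183 aa: TM helix, MCE domain, short C-terminal helix) and long forms
    (~374-419 aa: MCE domain followed by a ~150-residue helical region, then
    either nothing, a few short beta-hairpins, or a ten-strand beta-barrel).
    Each secondary-structure character is flipped with probability
    ``ss_noise``.

    Returns ``(table, truth)`` where table has columns protein_id, length_aa,
    mce_start, mce_end, ss.
    """
    mix = class_mix or {"long_barrel": 0.60, "long_no_barrel": 0.25, "short": 0.15}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class_mix fractions must sum to 1")
    known = {"short", "long_no_barrel", "long_partial_beta", "long_barrel"}
    unknown = set(mix) - known
    if unknown:
        raise ValueError(f"unknown architecture classes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    classes = list(mix)
    probs = np.array([mix[c] for c in classes])
    truth = TruthTable()
    rows = []
    for k in range(n):
        pid = f"mlad{k:05d}"
        cls = classes[int(rng.choice(len(classes), p=probs))]
        mce_start = int(rng.integers(32, 41))
        mce_end = mce_start + int(rng.integers(100, 109))
        ss, length = _build_mlad_ss(cls, mce_start, mce_end, rng)
        _noise(ss, ss_noise, rng)
        truth.planted_architectures[pid] = cls
        truth.planted_mce_spans[pid] = (mce_start, mce_end)
        rows.append(
            {"protein_id": pid, "length_aa": length, "mce_start": mce_start,
             "mce_end": mce_end, "ss": "".join(ss)}
        )
    return pd.DataFrame(rows), truth


def _build_mlad_ss(cls: str, mce_start: int, mce_end: int, rng) -> tuple:
    if cls == "short":
        length = mce_end + int(rng.integers(30, 60))
    elif cls == "long_barrel":
        length = mce_end + 5 + 150 + 4 + 116 + int(rng.integers(2, 20))
    else:
        length = mce_end + 150 + int(rng.integers(60, 110))
    ss = ["C"] * length

    def put(start, end, char):  # 1-based inclusive, clipped
        for p in range(max(1, start), min(length, end) + 1):
            ss[p - 1] = char

    put(6, 28, "H")  # N-terminal TM helix
    # beta-rich MCE interior: strand/loop alternation ending before mce_end
    pos = mce_start + 4
    while pos + 5 <= mce_end - 3:
        put(pos, pos + 5, "E")
        pos += 14
    if cls == "short":
        put(mce_end + 6, mce_end + 18, "H")  # small C-terminal helix
        return ss, length
    helix_start = mce_end + 6
    helix_end = helix_start + 149
    put(helix_start, min(helix_end, length), "H")
    if cls == "long_barrel":
        pos = helix_end + 5
        for _ in range(10):
            put(pos, pos + 7, "E")
            pos += 12
    elif cls == "long_partial_beta":
        k = int(rng.integers(2, 5))
        lo, hi = helix_end + 5, length - 8
        starts = sorted(rng.choice(np.arange(lo, hi, 8), size=min(k, max(1, (hi - lo) // 8)), replace=False))
        for s in starts:
            put(int(s), int(s) + int(rng.integers(2, 5)), "E")
    return ss, length


# ---------------------------------------------------------------------------
# ideal coordinate models
# ---------------------------------------------------------------------------

def _model_from_atoms(chains, resids, resnames, atomnames, coords, elements, source=""):
    return StructureModel(
        chain_ids=np.array(chains, dtype=object),
        res_ids=np.array(resids, dtype=int),
        res_names=np.array(resnames, dtype=object),
        atom_names=np.array(atomnames, dtype=object),
        coords=np.asarray(coords, dtype=float),
        elements=np.array(elements, dtype=object),
        source=source,
    )


def ideal_barrel_radius(n_strands: int, shear: int, rise: float, spacing: float) -> float:
    """Closed-form radius of an ideal beta-barrel lattice:
    R = sqrt((n*a)^2 + (S*b)^2) / (2*pi), with strand spacing a and
    per-residue rise b."""
    return math.sqrt((n_strands * spacing) ** 2 + (shear * rise) ** 2) / (2 * math.pi)


def build_ideal_barrel(
    n_strands: int = 10,
    shear: int = 10,
    rise: float = 3.3,
    spacing: float = 4.4,
    residues_per_strand: int = 12,
    residue_name: str = "VAL",
    rim_residue: str | None = None,
    jitter: float = 0.0,
    seed: int = 0,
) -> StructureModel:
    """Calpha-only ideal antiparallel beta-barrel on a cylinder.

    All Calpha atoms sit exactly on the cylinder of closed-form radius
    (:func:`ideal_barrel_radius`); strands alternate direction and are
    numbered with residue-id gaps so downstream segmentation can separate
    them.  ``rim_residue`` (e.g. "TRP") replaces the first and last residue of
    each strand, for girdle fixtures.  ``jitter`` adds isotropic Gaussian
    coordinate noise (A).
    """
    if n_strands < 3:
        raise ValueError("a barrel needs at least 3 strands")
    if shear < 0:
        raise ValueError("shear must be >= 0")
    R = ideal_barrel_radius(n_strands, shear, rise, spacing)
    alpha = math.atan2(shear * rise, n_strands * spacing)  # strand tilt vs axis
    z_step = rise * math.cos(alpha)
    dtheta = rise * math.sin(alpha) / R
    rng = np.random.default_rng(seed)
    chains, resids, resnames, atomnames, coords, elements = [], [], [], [], [], []
    m = residues_per_strand
    for s in range(n_strands):
        direction = 1 if s % 2 == 0 else -1
        theta0 = 2 * math.pi * s / n_strands
        for j in range(m):
            t = (j - (m - 1) / 2) * direction
            theta = theta0 + t * dtheta
            z = t * z_step
            xyz = np.array([R * math.cos(theta), R * math.sin(theta), z])
            if jitter > 0:
                xyz = xyz + rng.normal(0.0, jitter, size=3)
            name = residue_name
            if rim_residue and j in (0, m - 1):
                name = rim_residue
            chains.append("A")
            resids.append(s * (m + 10) + j + 1)
            resnames.append(name)
            atomnames.append("CA")
            coords.append(xyz)
            elements.append("C")
    return _model_from_atoms(chains, resids, resnames, atomnames, coords, elements,
                             source=f"ideal_barrel_n{n_strands}_S{shear}")


def build_ca_cylinder(
    radius: float = 10.0,
    length: float = 30.0,
    n_per_ring: int = 12,
    ring_step: float = 2.0,
    residue_name: str = "VAL",
    cap_residue: str | None = None,
    cap_length: float = 5.0,
) -> StructureModel:
    """Calpha atoms on rings of a cylinder along z; a pure-geometry fixture.

    ``cap_residue`` swaps residue identity within ``cap_length`` A of either
    end (planted hydrophobic/polar band fixtures).
    """
    chains, resids, resnames, atomnames, coords, elements = [], [], [], [], [], []
    rid = 0
    z = -length / 2
    while z <= length / 2 + 1e-9:
        for k in range(n_per_ring):
            theta = 2 * math.pi * k / n_per_ring + (z * 0.1)
            rid += 1
            name = residue_name
            if cap_residue and (abs(z - (-length / 2)) < cap_length or abs(z - length / 2) < cap_length):
                name = cap_residue
            chains.append("A")
            resids.append(rid)
            resnames.append(name)
            atomnames.append("CA")
            coords.append([radius * math.cos(theta), radius * math.sin(theta), z])
            elements.append("C")
        z += ring_step
    return _model_from_atoms(chains, resids, resnames, atomnames, coords, elements,
                             source="ca_cylinder")


# --- backbone builder (NeRF extension with standard peptide geometry) -------

_BOND_N_CA, _BOND_CA_C, _BOND_C_N, _BOND_C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.2, 121.7, 120.5


def _extend(a, b, c, bond, angle_deg, dihedral_deg):
    """Place atom d with given internal coordinates relative to a-b-c."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(dihedral),
            bond * math.sin(angle) * math.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi_psi: list,
    chain_id: str = "A",
    residue_name: str = "ALA",
    start_res_id: int = 1,
) -> StructureModel:
    """Full-backbone (N, CA, C, O) peptide from a list of (phi, psi) degrees.

    Standard bond lengths/angles, omega fixed at 180.  phi of the first
    residue and psi of the last are still consumed (the last psi places the
    final carbonyl oxygen via a virtual next nitrogen).
    """
    nres = len(phi_psi)
    if nres < 2:
        raise ValueError("need at least 2 residues")
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_BOND_N_CA, 0.0, 0.0])]
    ang = math.radians(_ANG_N_CA_C)
    C = [CA[0] + np.array([-_BOND_CA_C * math.cos(ang), _BOND_CA_C * math.sin(ang), 0.0])]
    for i in range(nres - 1):
        psi = phi_psi[i][1]
        N.append(_extend(N[i], CA[i], C[i], _BOND_C_N, _ANG_CA_C_N, psi))
        CA.append(_extend(CA[i], C[i], N[i + 1], _BOND_N_CA, _ANG_C_N_CA, 180.0))
        phi = phi_psi[i + 1][0]
        C.append(_extend(C[i], N[i + 1], CA[i + 1], _BOND_CA_C, _ANG_N_CA_C, phi))
    # carbonyl oxygens: trans to the next nitrogen
    O = []
    for i in range(nres):
        if i < nres - 1:
            nxt = N[i + 1]
        else:
            nxt = _extend(N[i], CA[i], C[i], _BOND_C_N, _ANG_CA_C_N, phi_psi[i][1])
        O.append(_extend(nxt, CA[i], C[i], _BOND_C_O, _ANG_CA_C_O, 180.0))
    chains, resids, resnames, atomnames, coords, elements = [], [], [], [], [], []
    for i in range(nres):
        for name, pos, elem in (("N", N[i], "N"), ("CA", CA[i], "C"), ("C", C[i], "C"), ("O", O[i], "O")):
            chains.append(chain_id)
            resids.append(start_res_id + i)
            resnames.append(residue_name)
            atomnames.append(name)
            coords.append(pos)
            elements.append(elem)
    return _model_from_atoms(chains, resids, resnames, atomnames, coords, elements, source="backbone")


def build_ideal_helix(n_residues: int = 20, residue_name: str = "ALA") -> StructureModel:
    """Canonical alpha-helix backbone (phi=-57, psi=-47)."""
    return build_backbone([(-57.0, -47.0)] * n_residues, residue_name=residue_name)


def build_ca_helix(
    n_residues: int = 100,
    rise: float = 1.5,
    radius: float = 2.3,
    twist_deg: float = 100.0,
    residue_name: str = "ALA",
) -> StructureModel:
    """Analytic Calpha-only helix with exact per-residue rise (axial-extent
    oracle: extent = (n-1) * rise)."""
    chains, resids, resnames, atomnames, coords, elements = [], [], [], [], [], []
    for i in range(n_residues):
        theta = math.radians(twist_deg) * i
        chains.append("A")
        resids.append(i + 1)
        resnames.append(residue_name)
        atomnames.append("CA")
        coords.append([radius * math.cos(theta), radius * math.sin(theta), i * rise])
        elements.append("C")
    return _model_from_atoms(chains, resids, resnames, atomnames, coords, elements, source="ca_helix")


def build_antiparallel_sheet(n_residues: int = 8) -> StructureModel:
    """Two-stranded antiparallel beta-sheet backbone fixture.

    Strand one is built from canonical strand dihedrals (phi=-139, psi=135);
    strand two is the same strand flipped 180 degrees about the strand axis,
    optionally rotated about that axis (pleat phase) and translated.  The
    placement is chosen by grid search: candidates are pre-scored by how many
    inter-strand O...N distances fall in the hydrogen-bonding window, then
    the best few are re-scored with the exact hydrogen-bond energies, so the
    emitted fixture carries a genuine ladder without hand-tuned coordinates.
    """
    from .geometry import _kabsch_sander_bonds  # fixture quality check only

    strand = build_backbone([(-139.0, 135.0)] * n_residues, chain_id="A")
    ca = strand.coords[strand.atom_names == "CA"]
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    centroid = strand.coords.mean(axis=0)

    def rotate(coords, k, angle_deg):
        theta = math.radians(angle_deg)
        rel = coords - centroid
        return (
            centroid
            + rel * math.cos(theta)
            + np.cross(k, rel) * math.sin(theta)
            + np.outer(rel @ k, k) * (1 - math.cos(theta))
        )

    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    # reverse the strand direction (antiparallel partner), then scan the
    # pleat phase about the strand axis
    reversed_coords = rotate(strand.coords, perp, 180.0)

    def rotate_about_axis(_coords_ignored, angle_deg):
        return rotate(reversed_coords, axis, angle_deg)

    o1 = strand.coords[strand.atom_names == "O"]
    n1 = strand.coords[strand.atom_names == "N"]
    ca1 = ca

    candidates = []
    for pleat in np.arange(0.0, 351.0, 10.0):  # flip angle incl. pleat phase
        flipped = rotate_about_axis(strand.coords, pleat)
        for sign in (1.0, -1.0):
            for sep in np.arange(4.0, 6.01, 0.1):
                for shift in np.arange(-4.0, 4.01, 0.1):
                    offset = sign * sep * perp + shift * axis
                    c2 = flipped + offset
                    o2 = c2[strand.atom_names == "O"]
                    n2 = c2[strand.atom_names == "N"]
                    ca2 = c2[strand.atom_names == "CA"]
                    d_on = np.linalg.norm(o1[:, None] - n2[None, :], axis=2)
                    d_no = np.linalg.norm(n1[:, None] - o2[None, :], axis=2)
                    good = int(np.sum(np.abs(d_on - 2.9) < 0.35)) + int(np.sum(np.abs(d_no - 2.9) < 0.35))
                    clash = int(np.sum(np.linalg.norm(ca1[:, None] - ca2[None, :], axis=2) < 3.8))
                    candidates.append((good - 3 * clash, float(pleat), sign, float(sep), float(shift)))
    candidates.sort(reverse=True)

    best_model, best_inter = None, -1
    for score, pleat, sign, sep, shift in candidates[:20]:
        c2 = rotate_about_axis(strand.coords, pleat) + sign * sep * perp + shift * axis
        model = _two_strand_model(strand, c2)
        bonds = _kabsch_sander_bonds(model, "A")
        inter = sum(1 for (i, j) in bonds if (i < n_residues) != (j < n_residues))
        if inter > best_inter:
            best_model, best_inter = model, inter
    return best_model


def _two_strand_model(strand: StructureModel, coords2: np.ndarray) -> StructureModel:
    n = len(strand)
    nres = int(strand.res_ids.max())
    return _model_from_atoms(
        list(strand.chain_ids) * 2,
        list(strand.res_ids) + [r + nres + 10 for r in strand.res_ids],
        list(strand.res_names) * 2,
        list(strand.atom_names) * 2,
        np.vstack([strand.coords, coords2]),
        list(strand.elements) * 2,
        source="antiparallel_sheet",
    )


# ---------------------------------------------------------------------------
# gene-table serialization (TSV and GFF3 dialects)
# ---------------------------------------------------------------------------

def write_gene_table_tsv(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_gene_table_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df[GENE_COLUMNS]


def write_gene_table_gff3(genes: pd.DataFrame, path) -> None:
    """CDS features, one per gene; ordinal gene order is encoded in start
    coordinates (1 kb per gene slot) and recovered on read."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            seqid = f"{g['genome_id']}|{g['replicon_id']}"
            start = int(g["gene_index"]) * 1000 + 1
            end = start + int(g["length_aa"]) * 3 + 2
            attrs = (
                f"ID=cds-{g['protein_id']};protein_id={g['protein_id']};"
                f"genome_id={g['genome_id']};length_aa={int(g['length_aa'])}"
            )
            fh.write(
                f"{seqid}\tmlascan\tCDS\t{start}\t{end}\t.\t{g['strand']}\t0\t{attrs}\n"
            )


def read_gene_table_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seqid, _, ftype, start, _end, _score, strand, _frame, attrs = line.rstrip("\n").split("\t")
            if ftype != "CDS":
                continue
            genome_id, replicon_id = seqid.split("|", 1)
            a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            rows.append(
                {
                    "genome_id": genome_id, "replicon_id": replicon_id,
                    "start": int(start), "strand": strand,
                    "protein_id": a["protein_id"], "length_aa": int(a["length_aa"]),
                }
            )
    df = pd.DataFrame(rows)
    out = []
    for (_g, _r), grp in df.groupby(["genome_id", "replicon_id"], sort=True):
        grp = grp.sort_values("start", kind="mergesort").reset_index(drop=True)
        grp["gene_index"] = range(len(grp))
        out.append(grp)
    result = pd.concat(out, ignore_index=True)
    return result[GENE_COLUMNS]


def write_truth_table(truth: TruthTable, path) -> None:
    """Flat TSV dump of the ground truth (one section per truth kind)."""
    with open(path, "w") as fh:
        for ps in truth.planted_systems:
            comps = ",".join(ps.components)
            idx = ",".join(str(i) for i in ps.gene_indices)
            fh.write(f"system\t{ps.genome_id}\t{ps.replicon_id}\t{comps}\t{idx}\n")
        for pid, comp in truth.component_of.items():
            fh.write(f"component\t{pid}\t{comp}\n")
        for pid in sorted(truth.decoys):
            fh.write(f"decoy\t{pid}\n")
        for pid, cls in truth.planted_architectures.items():
            fh.write(f"architecture\t{pid}\t{cls}\n")
        for node, st in truth.true_node_states.items():
            fh.write(f"node_state\t{node}\t{int(st)}\n")
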