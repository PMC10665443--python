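"""Quantitative geometry on coordinate models.

Secondary-structure assignment (simplified Kabsch-Sander hydrogen-bond
classing on full backbones, a distance heuristic on Calpha-only models),
strand counting, pore-radius profiles along the principal axis, axial extent,
hydrophobic band detection, aromatic girdle location, and chain stoichiometry
against reference sequences.

All operations are rigid-motion invariant: every measurement is made in the
frame of the model's own principal axis.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

import numpy as np
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

from .config import KYTE_DOOLITTLE, THREE_TO_ONE, GeometryConfig
from .types import PoreProfile, StructureModel

# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def read_pdb(path) -> StructureModel:
    """Read the first model of a PDB file into a :class:`StructureModel`.

    HETATM records are ignored; a file with no ATOM records is an error.
    """
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise ValueError(f"{path}: no ATOM records")
    return StructureModel(
        chain_ids=arr.chain_id.astype(object),
        res_ids=arr.res_id.astype(int),
        res_names=arr.res_name.astype(object),
        atom_names=arr.atom_name.astype(object),
        coords=np.asarray(arr.coord, dtype=float),
        elements=arr.element.astype(object),
        source=str(path),
    )


def write_pdb(model: StructureModel, path) -> None:
    n = len(model)
    arr = AtomArray(n)
    arr.chain_id = np.array([str(c) for c in model.chain_ids])
    arr.res_id = np.asarray(model.res_ids, dtype=int)
    arr.res_name = np.array([str(r) for r in model.res_names])
    arr.atom_name = np.array([str(a) for a in model.atom_names])
    arr.element = np.array([str(e) for e in model.elements])
    arr.coord = np.asarray(model.coords, dtype=float)
    arr.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# residue bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class _Residue:
    res_id: int
    res_name: str
    atoms: dict        # atom name -> coord
    segment: int = 0   # chain-break segment index


def _chain_residues(model: StructureModel, chain_id: str) -> list:
    sub = model.chain(chain_id)
    residues: list[_Residue] = []
    for rid in sub.res_ids:
        if residues and residues[-1].res_id == rid:
            continue
        mask = sub.res_ids == rid
        names = sub.atom_names[mask]
        residues.append(
            _Residue(
                res_id=int(rid),
                res_name=str(sub.res_names[mask][0]),
                atoms={str(n): c for n, c in zip(names, sub.coords[mask])},
            )
        )
    # segment residues at numbering gaps or long CA-CA jumps
    seg = 0
    for i, res in enumerate(residues):
        if i > 0:
            prev = residues[i - 1]
            gap = res.res_id - prev.res_id > 1
            far = False
            if "CA" in res.atoms and "CA" in prev.atoms:
                far = np.linalg.norm(res.atoms["CA"] - prev.atoms["CA"]) > 4.2
            if gap or far:
                seg += 1
        res.segment = seg
    return residues


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------


def _kabsch_sander_bonds(model: StructureModel, chain_id: str, cutoff: float = -0.5) -> set:
    """Backbone hydrogen bonds (i, j): CO of residue i to NH of residue j.

    Energy E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) kcal/mol,
    bond when E < cutoff.  Amide hydrogens are reconstructed 1.0 A from N
    opposite the bisector of the previous residue's C and O directions.
    """
    residues = _chain_residues(model, chain_id)
    n = len(residues)
    H: list = [None] * n
    for i in range(1, n):
        r, p = residues[i], residues[i - 1]
        if r.segment != p.segment:
            continue
        if "N" in r.atoms and "C" in p.atoms and "O" in p.atoms:
            v1 = r.atoms["N"] - p.atoms["C"]
            v2 = r.atoms["N"] - p.atoms["O"]
            d = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
            H[i] = r.atoms["N"] + d / np.linalg.norm(d) * 1.0
    bonds = set()
    q = 0.084 * 332.0
    for i in range(n):
        ri = residues[i]
        if "C" not in ri.atoms or "O" not in ri.atoms:
            continue
        for j in range(n):
            if abs(i - j) < 2:
                continue
            rj = residues[j]
            if "N" not in rj.atoms or H[j] is None:
                continue
            if "CA" in ri.atoms and "CA" in rj.atoms:
                if np.linalg.norm(ri.atoms["CA"] - rj.atoms["CA"]) > 9.0:
                    continue
            r_on = np.linalg.norm(ri.atoms["O"] - rj.atoms["N"])
            r_ch = np.linalg.norm(ri.atoms["C"] - H[j])
            r_oh = np.linalg.norm(ri.atoms["O"] - H[j])
            r_cn = np.linalg.norm(ri.atoms["C"] - rj.atoms["N"])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            e = q * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if e < cutoff:
                bonds.add((i, j))
    return bonds


def _backbone_ss(model: StructureModel, chain_id: str, cutoff: float) -> str:
    residues = _chain_residues(model, chain_id)
    n = len(residues)
    bonds = _kabsch_sander_bonds(model, chain_id, cutoff)
    helix = [False] * n
    for i in range(n):
        if (i, i + 4) in bonds and residues[min(i + 4, n - 1)].segment == residues[i].segment:
            for k in range(i + 1, min(i + 5, n)):
                helix[k] = True
    strand = [False] * n

    def hb(i, j):
        return 0 <= i < n and 0 <= j < n and (i, j) in bonds

    for i in range(n):
        for j in range(i + 3, n):
            anti = (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            para = (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1))
            if anti or para:
                strand[i] = strand[j] = True
    out = []
    for i in range(n):
        if strand[i]:
            out.append("E")
        elif helix[i]:
            out.append("H")
        else:
            out.append("C")
    return "".join(out)


def _ca_fallback_ss(model: StructureModel, chain_id: str) -> str:
    """Distance heuristic for Calpha-only chains.

    Helical: d(CA_i, CA_{i+3}) < 6 A within a segment.  Strand: a ladder
    partner exists (another CA at 3.5-6.0 A, at least 4 residues away in
    sequence or in another segment) and the residue is not helical.
    """
    residues = _chain_residues(model, chain_id)
    n = len(residues)
    ca = np.array([r.atoms.get("CA", [np.nan] * 3) for r in residues], dtype=float)
    seg = np.array([r.segment for r in residues])
    pos_ok = ~np.isnan(ca[:, 0])
    out = []
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
    for i in range(n):
        if not pos_ok[i]:
            out.append("C")
            continue
        helixlike = (
            i + 3 < n and pos_ok[i + 3] and seg[i + 3] == seg[i] and d[i, i + 3] < 6.0
        )
        if helixlike or (i - 3 >= 0 and pos_ok[i - 3] and seg[i - 3] == seg[i] and d[i - 3, i] < 6.0):
            out.append("H")
            continue
        partner = False
        for j in range(n):
            if not pos_ok[j]:
                continue
            if seg[j] == seg[i] and abs(i - j) < 4:
                continue
            if 3.5 <= d[i, j] <= 6.0:
                partner = True
                break
        out.append("E" if partner else "C")
    return "".join(out)


def assign_secondary_structure(
    model: StructureModel,
    chain_id: str,
    config: GeometryConfig | None = None,
) -> str:
    """Per-residue secondary structure over {H, E, C} for one chain.

    Chains with full backbones (N, CA, C, O) are classed by hydrogen-bond
    patterns (Kabsch-Sander energies; ladder bridges give E, i->i+4 bonded
    runs give H); Calpha-only chains fall back to a distance heuristic.
    """
    config = config or GeometryConfig()
    residues = _chain_residues(model, chain_id)
    if not residues:
        raise ValueError(f"chain {chain_id!r} has no residues")
    full = sum(1 for r in residues if {"N", "CA", "C", "O"} <= set(r.atoms))
    if full >= max(2, int(0.8 * len(residues))):
        return _backbone_ss(model, chain_id, config.hbond_cutoff)
    return _ca_fallback_ss(model, chain_id)


def count_strand_segments(
    model: StructureModel,
    chain_id: str,
    min_run: int = 3,
    config: GeometryConfig | None = None,
) -> int:
    """Number of beta-strand segments on a chain: maximal runs of 'E' of
    length >= min_run, split at chain breaks (residue-number gaps or long
    CA-CA jumps)."""
    residues = _chain_residues(model, chain_id)
    ss = assign_secondary_structure(model, chain_id, config)
    count = 0
    run = 0
    prev_seg = None
    for res, s in zip(residues, ss):
        broke = prev_seg is not None and res.segment != prev_seg
        if broke or s != "E":
            if run >= min_run:
                count += 1
            run = 0
        if s == "E":
            run += 1
        prev_seg = res.segment
    if run >= min_run:
        count += 1
    return count


# ---------------------------------------------------------------------------
# axes and pore geometry
# ---------------------------------------------------------------------------


def principal_axis(model: StructureModel, ca_only: bool = True) -> tuple:
    """(unit axis, centroid, eigenvalues) of the coordinate covariance.

    The axis is the dominant eigenvector, sign-fixed so its largest-magnitude
    component is positive (stable under rigid motion up to the inherent +/-
    ambiguity, which no downstream measurement depends on).
    """
    coords = model.coords
    if ca_only and (model.atom_names == "CA").any():
        coords = model.coords[model.atom_names == "CA"]
    centroid = coords.mean(axis=0)
    cov = np.cov((coords - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    k = int(np.argmax(np.abs(axis)))
    if axis[k] < 0:
        axis = -axis
    return axis, centroid, evals[::-1]


def pore_profile(
    model: StructureModel,
    config: GeometryConfig | None = None,
) -> PoreProfile:
    """Accessible-radius profile along the principal axis.

    At each axial sample, the accessible radius is the minimum over atoms in
    the +/- slab/2 window of (distance to axis - vdW radius); a non-positive
    value means a blocked pore.  ``min_radius`` is taken over the central
    ``central_fraction`` of the extent, excluding the membrane-embedded caps.
    """
    config = config or GeometryConfig()
    if len(model) < 10:
        raise ValueError("pore_profile needs at least 10 atoms")
    axis, centroid, evals = principal_axis(model)
    if evals[2] < 1e-9 * max(evals[0], 1e-12) and evals[1] > 1e-6 * max(evals[0], 1e-12):
        raise ValueError("degenerate (planar) model: pore axis undefined")
    rel = model.coords - centroid
    proj = rel @ axis
    radial = np.linalg.norm(rel - np.outer(proj, axis), axis=1)
    ca_only = set(np.unique(model.atom_names)) <= {"CA"}
    if ca_only:
        vdw = np.full(len(model), config.ca_only_vdw)
    else:
        vdw = np.array([config.vdw_radii.get(str(e), 1.7) for e in model.elements])
    access = radial - vdw
    lo, hi = proj.min(), proj.max()
    positions = np.arange(lo, hi + 1e-9, config.step)
    radii = np.full(len(positions), np.nan)
    half = config.slab / 2
    for k, z in enumerate(positions):
        in_slab = np.abs(proj - z) <= half
        if in_slab.any():
            radii[k] = access[in_slab].min()
    span = hi - lo
    margin = (1 - config.central_fraction) / 2 * span
    central = (positions >= lo + margin) & (positions <= hi - margin) & ~np.isnan(radii)
    if not central.any():
        central = ~np.isnan(radii)
    kmin = int(np.nanargmin(np.where(central, radii, np.inf)))
    return PoreProfile(
        axis=axis,
        origin=centroid,
        positions=positions,
        radii=radii,
        min_radius=float(radii[kmin]),
        min_position=float(positions[kmin]),
    )


def axial_extent(model: StructureModel) -> float:
    """Length of the model along its principal axis (max - min projection
    over all atoms), in Angstroms."""
    if len(model) < 2:
        raise ValueError("axial_extent needs at least 2 atoms")
    axis, centroid, _ = principal_axis(model)
    proj = (model.coords - centroid) @ axis
    return float(proj.max() - proj.min())


# ---------------------------------------------------------------------------
# hydrophobicity and girdles
# ---------------------------------------------------------------------------


def _residue_projections(model: StructureModel, axis, centroid, side_chain=False):
    labels, names, projs = [], [], []
    for chain_id in model.chains:
        for res in _chain_residues(model, chain_id):
            atoms = res.atoms
            if side_chain:
                sc = {k: v for k, v in atoms.items() if k not in ("N", "CA", "C", "O")}
                atoms = sc or atoms
            xyz = np.mean(list(atoms.values()), axis=0)
            labels.append((chain_id, res.res_id))
            names.append(res.res_name)
            projs.append(float((xyz - centroid) @ axis))
    return labels, names, np.array(projs)


def hydrophobic_bands(
    model: StructureModel,
    scale: dict | None = None,
    window: float = 6.0,
    threshold: float = 1.5,
    config: GeometryConfig | None = None,
) -> list:
    """Axial intervals of high mean hydropathy (membrane-embedded bands).

    A sliding window of width ``window`` A moves along the principal axis;
    the mean Kyte-Doolittle hydropathy of residues whose centroid falls in
    the window is compared against ``threshold``, and maximal above-threshold
    intervals are returned as (start, end) axial positions.
    """
    config = config or GeometryConfig()
    scale = scale or KYTE_DOOLITTLE
    axis, centroid, _ = principal_axis(model)
    _, names, projs = _residue_projections(model, axis, centroid)
    values = np.array([scale.get(str(n), 0.0) for n in names])
    lo, hi = projs.min(), projs.max()
    positions = np.arange(lo, hi + 1e-9, config.step)
    above = []
    for z in positions:
        sel = np.abs(projs - z) <= window / 2
        above.append(sel.any() and values[sel].mean() > threshold)
    bands = []
    start = None
    for k, flag in enumerate(above):
        if flag and start is None:
            start = positions[k]
        elif not flag and start is not None:
            bands.append((float(start), float(positions[k - 1])))
            start = None
    if start is not None:
        bands.append((float(start), float(positions[-1])))
    return bands


def aromatic_girdles(
    model: StructureModel,
    residue_span: tuple,
    charged_window: float = 3.0,
) -> dict:
    """Locate the two aromatic girdles flanking a membrane beta-barrel.

    Trp/Tyr/Phe side-chain centroids within ``residue_span`` (res_id range,
    inclusive) are projected on the principal axis and split into two
    clusters by the best 1-D variance split; girdle positions are the cluster
    means.  For each girdle the fraction of the span's Asp/Glu residues lying
    within ``charged_window`` A is reported (negatively charged residues
    co-localize with the girdles at the membrane interfaces).  A flat
    (non-bimodal) aromatic distribution is flagged low-confidence; no
    aromatics in the span yields an empty result.
    """
    lo, hi = residue_span
    axis, centroid, _ = principal_axis(model)
    labels, names, projs = _residue_projections(model, axis, centroid, side_chain=True)
    in_span = np.array([(lo <= rid <= hi) for _, rid in labels])
    arom = in_span & np.isin(names, ["TRP", "TYR", "PHE"])
    if not arom.any():
        return {"positions": (), "charged_fraction": (), "low_confidence": False}
    z = np.sort(projs[arom])
    if len(z) < 2:
        return {"positions": (float(z[0]),), "charged_fraction": (0.0,), "low_confidence": True}
    # best split minimizing within-cluster sum of squares
    best_k, best_cost = 1, np.inf
    for k in range(1, len(z)):
        a, b = z[:k], z[k:]
        cost = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if cost < best_cost:
            best_k, best_cost = k, cost
    g1, g2 = float(z[:best_k].mean()), float(z[best_k:].mean())
    # low confidence when the distribution between the modes is not depleted
    mid_lo = g1 + (g2 - g1) / 3
    mid_hi = g2 - (g2 - g1) / 3
    dip_frac = float(np.mean((z > mid_lo) & (z < mid_hi))) if g2 > g1 else 1.0
    charged = in_span & np.isin(names, ["ASP", "GLU"])
    fracs = []
    for g in (g1, g2):
        if charged.any():
            fracs.append(float(np.mean(np.abs(projs[charged] - g) <= charged_window)))
        else:
            fracs.append(0.0)
    return {
        "positions": (g1, g2),
        "charged_fraction": tuple(fracs),
        "low_confidence": dip_frac > 0.15,
    }


# ---------------------------------------------------------------------------
# stoichiometry
# ---------------------------------------------------------------------------


def chain_sequence(model: StructureModel, chain_id: str) -> str:
    residues = _chain_residues(model, chain_id)
    return "".join(THREE_TO_ONE.get(r.res_name, "X") for r in residues)


def chain_stoichiometry(
    model: StructureModel,
    references: dict,
    config: GeometryConfig | None = None,
) -> tuple:
    """Assign each chain to its closest reference sequence; count per
    component.

    Identity is the similarity ratio of the chain's residue sequence against
    each reference; chains below the identity threshold for every reference
    are reported unassigned.  Returns ``(counts, unassigned_chain_ids)``.
    """
    config = config or GeometryConfig()
    if not references:
        raise ValueError("references must be non-empty")
    counts = {comp: 0 for comp in references}
    unassigned = []
    for chain_id in model.chains:
        seq = chain_sequence(model, chain_id)
        best_comp, best_ident = None, -1.0
        for comp, ref in references.items():
            ident = difflib.SequenceMatcher(a=seq, b=ref, autojunk=False).ratio()
            if ident > best_ident:
                best_comp, best_ident = comp, ident
        if best_ident >= config.identity_threshold:
            counts[best_comp] += 1
        else:
            unassigned.append(chain_id)
    return counts, unassigned
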