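"""Measure an ideal ten-strand beta-barrel and a mock 2:2:6 complex.

Builds the analytic barrel oracle (ten antiparallel strands, shear 10),
writes/reads it as PDB, counts strands from assigned secondary structure,
profiles the pore against the closed-form radius, and demonstrates chain
stoichiometry assignment on a synthetic 2 MlaE : 2 MlaF : 6 MlaD complex.
"""

import tempfile
from pathlib import Path

import numpy as np

from mlascan.config import THREE_TO_ONE
from mlascan.geometry import (
    axial_extent,
    chain_stoichiometry,
    count_strand_segments,
    pore_profile,
    read_pdb,
    write_pdb,
)
from mlascan.synthetic_data import build_ideal_barrel, ideal_barrel_radius
from mlascan.types import StructureModel

barrel = build_ideal_barrel(n_strands=10, shear=10, rise=3.3, spacing=4.4)
pdb_path = Path(tempfile.mkdtemp()) / "barrel.pdb"
write_pdb(barrel, pdb_path)
model = read_pdb(pdb_path)

R = ideal_barrel_radius(10, 10, 3.3, 4.4)
prof = pore_profile(model)
print(f"strands counted:       {count_strand_segments(model, 'A')} (built: 10)")
print(f"closed-form radius:    {R:.2f} A")
print(f"accessible pore radius:{prof.min_radius:6.2f} A "
      f"(closed form minus 1.9 A Calpha vdW = {R - 1.9:.2f})")
print(f"pore diameter:         {2 * prof.min_radius:.1f} A")
print(f"axial extent:          {axial_extent(model):.1f} A")

# chain stoichiometry on a mock 2:2:6 complex
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
refs = {
    "MlaE": "MLREWLVALPLAGLGLSLATGNWQVALIAGLGFALASLIFSR" * 2,
    "MlaF": "MNDSKLVRLENVSKRFGDKTVLDGVSLQVNKGEILGLLGPNGAGKS" * 2,
    "MlaD": "MKRNTLEVGVGLFLVLALAVFVFIRLGGGNLFAPEKTYTAYFD" * 2,
}


def ca_chain(seq, chain_id, offset):
    n = len(seq)
    return StructureModel(
        chain_ids=np.array([chain_id] * n, dtype=object),
        res_ids=np.arange(1, n + 1),
        res_names=np.array([ONE_TO_THREE[c] for c in seq], dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        coords=np.column_stack([np.arange(n) * 3.8, np.full(n, offset * 10.0), np.zeros(n)]),
        elements=np.array(["C"] * n, dtype=object),
    )


chains = []
cid = 0
for comp, copies in [("MlaE", 2), ("MlaF", 2), ("MlaD", 6)]:
    for _ in range(copies):
        chains.append(ca_chain(refs[comp], chr(ord("A") + cid), cid))
        cid += 1
complex_model = StructureModel(
    chain_ids=np.concatenate([c.chain_ids for c in chains]),
    res_ids=np.concatenate([c.res_ids for c in chains]),
    res_names=np.concatenate([c.res_names for c in chains]),
    atom_names=np.concatenate([c.atom_names for c in chains]),
    coords=np.vstack([c.coords for c in chains]),
    elements=np.concatenate([c.elements for c in chains]),
)
counts, unassigned = chain_stoichiometry(complex_model, refs)
print(f"\nchain stoichiometry:   {counts} (unassigned: {unassigned})")
print("\nThe pore diameter of the ten-strand barrel (~13-14 A) matches the"
      "\nnarrow lumen expected for a membrane-embedded MlaD barrel; the 2:2:6"
      "\ncount mirrors the MlaE:MlaF:MlaD stoichiometry of the inner-membrane"
      "\ncomplex.")
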