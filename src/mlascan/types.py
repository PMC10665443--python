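"""Shared domain types for the Mla comparative-genomics pipeline.

Tabular data (gene tables, domain hits, component calls) travels as pandas
DataFrames with fixed column schemas; small structured results use frozen
dataclasses.  The schemas are declared here so every module agrees on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

# Closed component vocabulary.  TolC is tracked only as cluster context and is
# never part of the Mla component quorum.
COMPONENTS = ("MlaA", "MlaB", "MlaC", "MlaD", "MlaE", "MlaF", "TamB")

# Pfam families used to identify components directly (one family per protein).
PFAM_OF_COMPONENT = {
    "MlaA": "PF04333",
    "MlaC": "PF05494",
    "MlaD": "PF02470",
    "MlaE": "PF02405",
    "TamB": "PF04357",
}
COMPONENT_OF_PFAM = {v: k for k, v in PFAM_OF_COMPONENT.items()}

# MlaB (STAS domain) and MlaF (ABC ATPase) belong to large generic protein
# families; hits against these profiles are provisional until synteny gating.
GENERIC_FAMILY_OF_COMPONENT = {"MlaB": "NF033618", "MlaF": "PRK11831"}
COMPONENT_OF_GENERIC_FAMILY = {v: k for k, v in GENERIC_FAMILY_OF_COMPONENT.items()}

ARCHITECTURE_CLASSES = ("short", "long_no_barrel", "long_partial_beta", "long_barrel")

GENE_COLUMNS = ["genome_id", "replicon_id", "gene_index", "strand", "protein_id", "length_aa"]
HIT_COLUMNS = ["protein_id", "family_id", "protein_len", "env_start", "env_end", "bit_score", "e_value"]
CALL_COLUMNS = ["protein_id", "component", "evidence", "env_start", "env_end", "bit_score", "e_value"]


def empty_gene_table() -> pd.DataFrame:
    return pd.DataFrame(columns=GENE_COLUMNS)


def empty_hit_table() -> pd.DataFrame:
    return pd.DataFrame(columns=HIT_COLUMNS)


def empty_call_table() -> pd.DataFrame:
    return pd.DataFrame(columns=CALL_COLUMNS)


@dataclass(frozen=True)
class SystemTemplate:
    """Ordered component labels of a gene cluster, with intervening-gene gaps.

    ``gaps[i]`` is the number of unrelated genes between ``components[i]`` and
    ``components[i+1]``; all-zero gaps give a contiguous operon such as the
    Veillonella parvula mlaE-mlaF-mlaD-tolC-tamB arrangement.
    """

    components: tuple
    gaps: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.gaps is None:
            object.__setattr__(self, "gaps", tuple(0 for _ in self.components[1:]))
        if len(self.gaps) != max(len(self.components) - 1, 0):
            raise ValueError("gaps must have len(components)-1 entries")
        if any(g < 0 for g in self.gaps):
            raise ValueError("gap sizes must be >= 0")

    @property
    def span(self) -> int:
        """Number of gene slots the template occupies on a replicon."""
        return len(self.components) + sum(self.gaps)


@dataclass(frozen=True)
class PlantedSystem:
    genome_id: str
    replicon_id: str
    components: tuple
    gene_indices: tuple


@dataclass
class TruthTable:
    """Ground truth emitted alongside every synthetic dataset."""

    planted_systems: list = field(default_factory=list)
    component_of: dict = field(default_factory=dict)   # protein_id -> component
    decoys: set = field(default_factory=set)           # protein_ids with no true identity
    planted_architectures: dict = field(default_factory=dict)  # protein_id -> class
    planted_mce_spans: dict = field(default_factory=dict)      # protein_id -> (start, end)
    true_node_states: dict = field(default_factory=dict)       # node label -> bool
    barrel_spec: Optional[tuple] = None  # (n_strands, shear, rise, spacing)


@dataclass(frozen=True)
class SystemCall:
    """A co-localized cluster of Mla/Tam component genes on one replicon."""

    genome_id: str
    replicon_id: str
    members: tuple  # ordered tuple of (gene_index, component, protein_id)
    circular_wrap: bool = False

    @property
    def span(self) -> tuple:
        idx = [m[0] for m in self.members]
        return (min(idx), max(idx))

    @property
    def component_set(self) -> frozenset:
        return frozenset(m[1] for m in self.members)


@dataclass(frozen=True)
class ArchitectureCall:
    protein_id: str
    length_aa: int
    mce_span: tuple            # (start, end), 1-based inclusive
    cterm_len: int             # residues after mce_end
    strand_segments: tuple     # ((start, end), ...) 1-based, all after mce_end
    n_strands: int
    strand_residues: int
    arch_class: str            # one of ARCHITECTURE_CLASSES


@dataclass
class PhyleticProfile:
    """Taxon x component boolean presence matrix."""

    matrix: pd.DataFrame  # index=taxa, columns=components (+ derived flags)

    def __post_init__(self):
        if self.matrix.index.has_duplicates:
            raise ValueError("duplicate taxon labels in phyletic profile")

    @property
    def taxa(self) -> list:
        return list(self.matrix.index)

    @property
    def components(self) -> list:
        return list(self.matrix.columns)


@dataclass
class AncestralStates:
    """Per-node presence states on a rooted tree plus the parsimony score."""

    states: dict               # node label -> bool (True = present)
    n_changes: int
    root_state: bool
    ambiguous_root: bool = False


@dataclass
class StructureModel:
    """Ordered atom list with chain/residue identity, for geometry operations.

    Arrays are parallel and index-aligned: ``chain_ids[i]`` etc. describe atom
    ``i``.  Coordinates are in Angstroms.
    """

    chain_ids: np.ndarray      # str
    res_ids: np.ndarray        # int, non-decreasing within a chain
    res_names: np.ndarray     # str, three-letter
    atom_names: np.ndarray     # str
    coords: np.ndarray         # (n, 3) float
    elements: np.ndarray       # str
    source: str = ""

    def __post_init__(self):
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in structure model")

    def __len__(self) -> int:
        return len(self.res_ids)

    def chain(self, chain_id: str) -> "StructureModel":
        mask = self.chain_ids == chain_id
        if not mask.any():
            raise KeyError(f"chain {chain_id!r} not present in model")
        return StructureModel(
            chain_ids=self.chain_ids[mask],
            res_ids=self.res_ids[mask],
            res_names=self.res_names[mask],
            atom_names=self.atom_names[mask],
            coords=self.coords[mask],
            elements=self.elements[mask],
            source=self.source,
        )

    @property
    def chains(self) -> list:
        seen = []
        for c in self.chain_ids:
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class PoreProfile:
    axis: np.ndarray           # unit vector
    origin: np.ndarray         # axis origin (centroid)
    positions: np.ndarray      # axial sample positions (A)
    radii: np.ndarray          # accessible radius at each position (A); NaN = empty slab
    min_radius: float          # min over the central span (see pore_profile docs)
    min_position: float
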