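"""Default thresholds and physical constants, grouped by pipeline stage.

Everything a user might reasonably want to tune is exposed here as a frozen
dataclass with documented defaults; functions accept these objects (or plain
keyword overrides) rather than reading global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class HitThresholds:
    """Per-family acceptance thresholds for domain hits.

    The default accepts hits with conditional E-value <= 1e-5 and no bit-score
    floor; ``per_family`` maps family id -> (max_e_value, min_bit_score) and
    overrides the default for that family.
    """

    max_e_value: float = 1e-5
    min_bit_score: float = 0.0
    per_family: dict = field(default_factory=dict)

    def for_family(self, family_id: str) -> tuple:
        return self.per_family.get(family_id, (self.max_e_value, self.min_bit_score))


@dataclass(frozen=True)
class SyntenyConfig:
    """Cluster-detection rule: component genes chained when separated by at
    most ``max_gap`` genes.

    ``semantics`` selects how "five genes separating them" is counted:
    "intervening" (default) bounds the number of unrelated genes between two
    component genes (index difference <= max_gap + 1); "index_diff" bounds the
    index difference itself.
    """

    max_gap: int = 5
    semantics: str = "intervening"  # or "index_diff"
    circular: bool = False

    def max_index_diff(self) -> int:
        if self.semantics == "intervening":
            return self.max_gap + 1
        if self.semantics == "index_diff":
            return self.max_gap
        raise ValueError(f"unknown max_gap semantics: {self.semantics!r}")


@dataclass(frozen=True)
class ArchitectureThresholds:
    """Cut-offs for the short/long/partial-beta/barrel classification.

    long_threshold: a C-terminal extension of at least this many residues
        beyond the MCE envelope makes a protein "long".  The short E. coli-like
        form leaves ~40 residues after the MCE domain while long forms carry a
        ~150-residue helical region, so 80 sits far from both modes.
    barrel_min_strands: minimum number of C-terminal beta-strand segments for a
        complete barrel call; the modelled barrel has ten strands and 8
        tolerates prediction dropout of two while excluding hairpin remnants.
    min_run: minimum length of an 'E' run counted as a strand segment.
    """

    long_threshold: int = 80
    barrel_min_strands: int = 8
    min_run: int = 3


@dataclass(frozen=True)
class GeometryConfig:
    """Physical constants for structure geometry.

    vdw_radii are element-keyed van der Waals radii in Angstroms; ca_only_vdw
    is the effective radius used for Calpha-only models.
    """

    vdw_radii: dict = field(
        default_factory=lambda: {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
    )
    ca_only_vdw: float = 1.9
    step: float = 1.0           # axial sampling step for pore profiles (A)
    slab: float = 3.0           # slab thickness per sample (A)
    central_fraction: float = 0.8  # span fraction over which min pore radius is taken
    hbond_cutoff: float = -0.5  # kcal/mol, Kabsch-Sander bond threshold
    identity_threshold: float = 0.9  # chain-to-reference assignment cutoff


# Kyte-Doolittle hydropathy scale, indexed by three-letter residue name.
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
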