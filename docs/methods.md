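# Methods

This note documents the models, decision rules, parameters and synthetic
data underlying `mlascan`, and what the package's tests do and do not
establish about real genome data.

## Component identification and synteny

Domain hits arrive as HMMER3 per-domain tables (`--domtblout`); envelope
coordinates — not alignment coordinates — define domain spans, since the
envelope bounds the region of homology and is what anchoring the MCE domain
requires.  One component call is kept per (protein, component), the
best-scoring hit winning; the default acceptance threshold is a per-domain
E-value ≤ 1e-5 with no bit-score floor, configurable per family
(`config.HitThresholds`).  No published cutoff exists for this analysis, so
a conventional default is declared rather than hidden.

MlaA, MlaC, MlaD, MlaE and TamB are identified by their dedicated Pfam
families (PF04333, PF05494, PF02470, PF02405, PF04357).  MlaB and MlaF
belong to the large STAS-domain and ABC-ATPase families, so family hits
alone are nearly meaningless; a candidate is retained only when its gene
lies in synteny with an anchor component (MlaA/C/D/E).  The synteny rule —
"no more than five genes separating them" — is read as **at most 5
intervening genes** between consecutive component genes (index difference
≤ 6); `config.SyntenyConfig(semantics="index_diff")` exposes the stricter
reading.  Clusters are maximal single-linkage chains under this bound;
strand is ignored (divergently transcribed clusters remain detectable);
circular replicons optionally consider the wrap junction, with the wrap gap
computed as `n_genes − span`.  A chain needs ≥ 2 distinct components to be
called a system; single occurrences are reported as lone components and
still count toward presence for the Pfam-identified components.  TolC is
cluster context only, never part of the quorum.

Proteins with more than one non-overlapping PF02470 envelope are
PqiB/LetB-like and excluded from the MlaD set.  Two envelopes "overlap"
when they share > 20 % of the shorter envelope — tandem MCE domains in LetB
are near-abutting, and a tolerant rule avoids double-counting alignment
jitter.  The count is the exact maximum set of pairwise compatible
envelopes (enumerated for ≤ 12 hits, greedy by bit score beyond), which
makes the oracle test against exhaustive maximization an identity.

## MlaD architecture classes

Classification is a pure function of protein length, the MCE envelope and a
per-residue secondary-structure string over {H, E, C} (finer classes
collapse as H,G,I→H; E,B→E; rest→C — the decision only needs "residues in
β-strand conformation").  Parameters (`config.ArchitectureThresholds`):

- `long_threshold = 80`: a C-terminal extension ≥ 80 residues beyond the
  MCE envelope makes a protein "long".  Short forms leave ~40 residues
  after the MCE domain; long forms carry a ~150-residue helical region, so
  80 sits far from both modes.
- `min_run = 3`: minimal 'E' run counted as a strand segment; runs
  straddling the MCE end are clipped before the length test.
- `barrel_min_strands = 8`: a complete barrel has ten strands; 8 tolerates
  secondary-structure dropout of two strands while excluding hairpin
  remnants.  1–7 segments give `long_partial_beta` (this is also where
  hexamer-assembled barrels land, each monomer contributing a single
  strand — per-monomer classification cannot and should not call those
  complete barrels); 0 gives `long_no_barrel`.

Lengths are as annotated; signal peptides are not trimmed.  Secondary
structure is consumed as given (from coordinate models via the geometry
module, or any predictor's export) — the package does not re-implement
β-topology predictors.

## Phyletic profiles and ancestral presence

Taxon presence is the OR over the taxon's genomes; a derived `MlaD_barrel`
column records whether any genome of the taxon encodes a complete-barrel
MlaD.  The reference tree is always an input, rooted as given.  Leaf
matching normalizes labels (case-fold, strip non-alphanumerics) because
Newick-vs-table label drift is the dominant practical failure; leaves
without data are ignored during parsimony rather than imputed absent.

Two formalizations of "was the component ancestral" are provided:

- **Fitch parsimony**, implemented as Hartigan's generalization so
  multifurcating nodes are scored optimally; root ties resolve to
  "present" with an explicit ambiguity flag (conservative for loss-prone
  characters, and the flag prevents silent over-claiming).
- **Dollo inference**: one gain, any number of losses.  The gain is placed
  at the MRCA of present leaves; the root is ancestral-present exactly when
  presence survives in ≥ 2 of its child subtrees.  Horizontal transfer is
  not modelled; the recovery tests target the vertical signal.

Annotations export as iTOL `DATASET_BINARY` blocks, one per component,
round-trippable through the module's own reader.

## Supermatrix

Markers are restricted to taxa whose MlaD/MlaE copies come from a conserved
cluster arrangement (MlaDE/MlaDEF), which resolves paralogy upstream — one
sequence per taxon per marker is required and duplicates are an error.
Trimming is a plain gap-fraction column filter (default: drop columns with
> 50 % gaps); entropy-weighted trimming is a documented stand-in users can
apply externally, and pre-trimmed alignments pass through at threshold 1.
Taxa missing a marker are gap-filled to the partition's width, with a
`min_markers` switch to drop sparse rows instead.  Output is aligned FASTA
or relaxed PHYLIP plus `PROT, name = start-end` partition lines; tree
inference itself is out of scope.

## Structure geometry

`read_pdb` consumes ATOM records (first model, HETATM ignored).  Secondary
structure on full backbones follows Kabsch–Sander: amide hydrogens are
rebuilt 1.0 Å from N opposite the bisector of the preceding C=O directions;
the bond energy is `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)`
kcal/mol with a bond below −0.5; ladder bridges (parallel and antiparallel
patterns) give E, i→i+4 bonded runs give H; on conflict E wins (this
package's focus is strand counting; canonical DSSP orders helix first).
Cα-only models use a distance heuristic: helical if d(CAᵢ, CAᵢ₊₃) < 6 Å,
strand if a ladder partner lies at 3.5–6.0 Å at least 4 residues away in
sequence or in another segment.  Chains are segmented at residue-number
gaps or Cα–Cα jumps > 4.2 Å, and strand runs never merge across segments.

Pore profiles: the tunnel axis is the principal axis of the Cα covariance;
at each axial step (1 Å) the accessible radius is the minimum over atoms in
a 3 Å slab of (distance to axis − vdW radius), with vdW C 1.7, N 1.55,
O 1.52, S 1.8 Å and 1.9 Å for Cα-only models.  The reported interior
radius is the minimum over the central 80 % of the extent, excluding
membrane-embedded caps.  Planar models (axis undefined) are rejected;
blocked pores report radii ≤ 0.  Hydrophobic bands use the Kyte–Doolittle
scale in a 6 Å sliding window (threshold 1.5 by default); aromatic girdles
are the two-cluster split of Trp/Tyr/Phe side-chain positions within the
barrel span, flagged low-confidence when the distribution between the modes
is not depleted, with Asp/Glu co-localization fractions per girdle.  Chain
stoichiometry assigns each chain to the reference sequence with the highest
similarity ratio (threshold 0.9).

All measurements are made in the model's own principal-axis frame and are
rigid-motion invariant to 1e-6 Å.

## Synthetic data: what it emulates and what it does not

The generators provide study-condition inputs with planted truth:

- **Genomes**: one replicon per genome, 50–200 genes by default, ordinal
  gene coordinates (the synteny rule counts genes, so base-pair realism is
  unnecessary).  Templates (e.g. the *V. parvula*-like
  mlaE-mlaF-mlaD-tolC-tamB operon) are planted round-robin at random
  positions; non-component genes become decoys at the configured rate.
- **Domain hits**: true component genes receive hits with envelopes inside
  the protein and bit scores ~N(180, 30) (E-values far below the 1e-5
  default threshold); false positives default to the generic families
  (STAS/ABC-ATPase) on decoy genes — the realistic noise mode the synteny
  gate exists to absorb.
- **MlaD sets**: short ≈ 183-residue layout; long layouts ≈ 374–419
  residues with a 150-residue helical region; the barrel class carries ten
  8-residue strand segments; partial-β carries 2–4 short hairpins.  Noise
  flips each secondary-structure character with the given probability.
  The default class mix {barrel 0.60, no-barrel 0.25, short 0.15} yields
  ~85 % long homologues.
- **Dollo simulation**: single gain at the root, per-branch loss
  probability, no regain, no transfer.
- **Ideal models**: Cα-only barrels on the closed-form cylinder (strands
  z-centred and antiparallel, residue-number gaps separating strands);
  analytic Cα helices with exact rise; full-backbone helices/sheets from
  standard peptide geometry (the antiparallel sheet partner is placed by a
  hydrogen-bond-count grid search over separation, registry shift and pleat
  phase).

No amino-acid-level evolution, lipid chemistry, HGT, or sequence realism is
simulated.  Passing recovery tests therefore demonstrates that the decision
logic is correct and robust to the modelled noise — not that the thresholds
would reproduce a manually curated genome-scale survey, which additionally
involves judgment calls on functional annotation that are out of scope.

## Problem sizes and numerical choices

The test suite and acceptance script use 100 genomes of 50–200 genes for
synteny, 400 proteins for architecture recovery, 1000 random trees of ≤ 10
leaves for the Fitch oracle (exhaustive enumeration beyond 10 leaves grows
exponentially and adds nothing), 200 16-leaf Dollo simulations at loss
probability 0.1, barrels with n ∈ {8, 10, 12} and shear ∈ {n, n+2}, and 20
random marker sets — sizes chosen so every oracle is exhaustive or tightly
concentrated while the whole suite runs in well under a minute per stage.
Ties everywhere break deterministically (higher bit score, then
lexicographic id; parsimony ties toward "present" with a flag).  Degenerate
inputs fail loudly: empty alignments, unmapped genomes, zero label overlap
between profile and tree, planar coordinate models, proteins without an
MCE hit.

## Known limitations

- MlaB/MlaF generic-family profiles (NCBI NF033618 / PRK11831) are treated
  as configured family identifiers; profile construction from NCBI
  alignments is not reproduced.
- The Cα-only strand heuristic is tuned for barrel lattices with ~4.4–5.9 Å
  inter-strand spacing; exotic geometries may need the full-backbone path.
- Per-monomer classification deliberately does not detect hexamer-assembled
  six-stranded barrels (flagged as `long_partial_beta`).
- The trimmer is gap-fraction only; entropy-based column selection must be
  done externally if desired.
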