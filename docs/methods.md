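# Methods

## Pipeline model

A solvent-mapping run docks 16 small organic probe molecules over a protein
surface and clusters the docked copies into consensus *crossclusters*, each
marking a candidate binding hot spot. probedock consumes the resulting PDB
file (receptor `ATOM` records plus probe `HETATM` blocks) and converts the
selected crossclusters into labeled docking spheres:

1. **Parse.** Receptor and probes are separated; each probe residue is
   reconstructed against its registry template (elements matched in order,
   bonds copied from the template, explicit hydrogens attached to their
   nearest heavy atom). Crosscluster boundaries are taken from
   `HEADER crosscluster.<rank>.<population>` delimiter lines; without
   delimiters, consecutive `HETATM` records sharing chain and residue number
   form one probe and a gap in residue numbering starts a new cluster. This
   dialect is a package convention — mapping services do not document a
   record layout — so users with differently structured files may need to
   insert delimiter lines.
2. **Perceive.** Each probe gets pharmacophore feature points from a
   hand-curated per-probe template: donors and acceptors on single N/O
   atoms, hydrophobic and aromatic features on atom-group centroids.
   Coinciding features (hydroxyl O: donor + acceptor) stay separate points.
3. **Convert.** One sphere per feature point, all in cluster 1. The color
   table lists the labels present, sorted lexicographically and numbered
   from 1, so identical inputs give identical files.
4. **Prepare.** Bounding box with margin, grid input, docking input
   (defaults or user-supplied custom file with managed-keyword override),
   and — when chemical matching is on — the label definition file and the
   label-pair correlation table.

The docking engine itself, receptor preparation, surface generation, and
classic surface-based sphere generation are external and out of scope; the
package reads classic multi-cluster sphere files so that existing sphere
sets can be filtered and reused (cluster 0 conventionally denotes the whole
set).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| sphere radius | 0.7 Å | probe-derived spheres mark candidate atom positions, not cavity volumes, so they are kept well under a C–C bond length; configurable per run |
| box margin | 5 Å | clearance added on every side of the sphere centers' bounding box; 10 Å is the usual choice when large flexible ligands must fit |
| selection radius | 3 Å | classic sphere-selector emulation: keep spheres within this distance (inclusive) of the reference points |
| match overlap | 1.0 Å | distance under which a ligand feature "overlaps" a sphere for chemical matching |
| success cutoff | 2.0 Å | pose RMSD strictly under this value counts as a prediction success |

The box is computed over sphere centers rather than center±radius: with
sub-Å sphere radii the margin dominates, and corner arithmetic stays exactly
reproducible. The selection boundary is inclusive (≤) — "within a radius"
must be fixed one way or the other for determinism, and inclusive matches
the plain reading.

## Pharmacophore templates and fallback rules

All 16 probes (ethane, ethanol, isopropanol, isobutanol, acetone,
acetaldehyde, dimethyl ether, cyclohexane, acetonitrile, urea, methylamine,
phenol, benzaldehyde, benzene, acetamide, N,N-dimethylformamide) carry
curated templates, which makes perception deterministic, reviewable, and
free of runtime aromaticity perception. The label vocabulary is donor,
acceptor, hydrophobic, aromatic, positive, negative, plus a `null` label
compatible with everything. Curation policy: every O–H/N–H bears donor +
acceptor (or donor only for amide N–H); carbonyl O, ether O and nitrile N
are acceptors; a trisubstituted H-free amide N is neither; hydrophobic
features sit on centroids of carbon groups away from heteroatom-dominated
centers; six-membered aromatic rings get one centroid feature.

Unregistered probes fall back to rules: donor = N/O with ≥1 explicit H;
acceptor = any O, and any N except a trisubstituted H-free one; aromatic =
6-ring with all-aromatic bond orders; hydrophobic = centroid of each maximal
connected carbon set having no N/O neighbor. A molecule yielding no feature
raises a perception error rather than passing silently.

Note the templates are deliberately more generous than the fallback rules
(ethanol's hydrophobic centroid includes the carbinol carbon); the templates
are the authority for registered probes.

## File formats

* **Sphere file.** Header/provenance line, `color <label> <number>` lines,
  `cluster <n> number_of_spheres_in_cluster <m>`, then fixed-width records
  `(I5, 3F10.5, F8.3, I5, I2, I3)` = index, x, y, z, radius, nearest surface
  atom (0 for probe-derived spheres), critical flag, color. Read∘write is
  the identity for values at the printed precision (centers 10⁻⁵ Å, radii
  10⁻³ Å).
* **MOL2.** One `@<TRIPOS>MOLECULE` block per probe, 4-decimal coordinates,
  SYBYL types derived from element + aromatic-bond membership, no charges.
* **Pharmacophore text file.** One point per line:
  `cluster probe label x y z n_source_atoms atom_indices…`, `#` comments.
* **Keyword files.** `keyword value`, one per line, `#` comments. Merging
  managed keywords into a custom file preserves every untouched line
  byte-for-byte (including unknown keywords) and keeps the original
  keyword–value separator when rewriting; the merge is idempotent.

## Statistics

RMSD is computed over matched atom orders in the shared receptor frame — no
superposition, since docked and experimental poses live in the same
coordinate system. An optional symmetry-aware variant minimizes over
element-preserving bond-graph automorphisms (exponential worst case, meant
for small ligands); it is off by default.

Kruskal–Wallis uses mid-ranks and the tie correction
1 − Σ(t³−t)/(N³−N); p comes from χ²(k−1); all-identical data returns H = 0,
p = 1 by convention. Dunn's post-hoc computes
z = (Wᵢ−Wⱼ)/√[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ)] over pooled
mid-ranks. **p-values follow the one-sided convention p = P(Z > |z|)** — half
the two-sided value, so z = 0 maps to p = 0.5; many references report
two-sided Dunn p-values, so compare accordingly. Bonferroni multiplies by
the k(k−1)/2 pairs and clamps at 1; Holm is the standard step-down with
monotonicity enforcement. When the tie-corrected variance vanishes (all
values identical) z = 0 by convention. Quartiles use linear interpolation
between order statistics (the common dataframe default) and the standard
deviation uses n−1 (0 for a single value). Success rates use a strict `<`
at the cutoff.

In tests the implementation is cross-checked against independent routes:
`scipy.stats.kruskal` for H and p, an independently coded
pandas-ranking/statsmodels-adjustment route for Dunn, and a 10,000-replicate
Monte-Carlo null (3 groups of 15 standard-normal values) whose rejection
rate at α = 0.05 must land in [0.04, 0.06].

## Synthetic fixtures

`generate_fixture` fabricates probe-mapping output for testing and
demonstration: a rigid glycine-backbone arc of 40 atoms (10 residues ×
N/CA/C/O) stands in for the receptor, and each crosscluster places its
probes by a seeded random rotation plus a translation within 2 Å of a
declared pocket center, using the templates' idealized geometries. Default
study conditions: 2 crossclusters of 3 probes each, probe types cycling
through the full 16-probe library. The fixtures emulate the *file shape* of
real mapping output — delimited probe blocks concentrated around hot
spots — not its physics: placements are not energy-minimized, probes may
sterically clash, and the pseudo-protein has no real cavities. Passing tests
therefore demonstrate correctness of parsing, perception, conversion,
geometry and statistics, not docking accuracy on real proteins; the
headline accuracy claims of probe-guided docking require external datasets
and an external docking engine and are outside what this package can verify.

## Determinism and numerical choices

Every random draw flows from a single integer seed through
`numpy.random.Generator`. The run log records step order, status and
parameters but no wall-clock timestamps, so a rerun with identical
configuration and inputs is byte-identical across all artifacts (verified
in tests by hashing). Coordinates are written at fixed precision (PDB 10⁻³,
MOL2 10⁻⁴, sphere centers 10⁻⁵ Å); round-trip identities are asserted at
the written precision. Radius selection uses a k-d tree internally and is
tested against an exhaustive distance scan; ties at the selection boundary
are kept (inclusive ≤).

Problem sizes in the test and acceptance runs — 1000 randomized round-trip
instances, 1000 random configurations per geometric oracle, 100 random
datasets per statistical reference check, 10,000 Monte-Carlo replicates —
were chosen to exercise the property space thoroughly while keeping a full
run around a minute on one core.

## Known limitations

* The crosscluster PDB dialect is a package convention; real mapping-service
  files may need delimiter lines added.
* Feature templates are a curated choice; no experimental pharmacophore
  assignments exist for the probe library, and reasonable alternatives
  (e.g. per-atom hydrophobic features) would change sphere counts.
* Chemical-matching evaluation is a validator of the pruning rule, not a
  reimplementation of any engine's scoring; grid energies, pose search and
  scoring are external.
* The symmetry-aware RMSD enumerates graph automorphisms and is exponential
  in highly symmetric molecules; use it only for small ligands.
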