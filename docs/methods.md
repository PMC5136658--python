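# Methods

This note documents the models, conventions and numerical choices behind
`heptahelix`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Structure model and I/O

Structures are parsed with biotite (PDB and mmCIF) into a minimal
chain → residue → atom hierarchy. Conventions:

* first model only (crystal templates are single-model);
* alternate locations resolved to the highest occupancy, ties broken
  alphabetically by altloc id;
* waters and non-amino-acid heteroatoms dropped by default (selenomethionine
  and other amino-acid-like components are kept and sequence as 'X');
* fusion constructs (e.g. a lysozyme domain inserted into a loop) are *not*
  auto-removed — the transmembrane annotation ranges select receptor
  residues, which is both simpler and safer than sequence surgery;
* author numbering (with insertion codes) is the only residue key; no
  renumbering ever happens.

Transmembrane annotations are YAML files giving inclusive author-number
ranges per helix, the chain id, the orientation convention (whether the
first or last residue of TM1 faces the extracellular side — successive
helices alternate), and optional anchor overrides.

## Ballesteros–Weinstein numbering

Anchors are the conserved x.50 positions; every label is a plain arithmetic
offset from its helix anchor, `label(n) = helix.(50 + n − anchor)`. No
bulge/insertion labels (x.45½-style) are used: every printed label this
package is expected to reproduce obeys plain arithmetic, and insertion
handling would add a convention without adding testable value.

Anchor detection: 2.50/3.50/6.50/7.50 from the motif regexes
(N-[LIVMF]-x-x-x-D, [ED]-R-[YW], C-[WMF]-x-P, N-P-x-x-Y); 1.50 and 4.50 as
the unique Asn/Trp inside the annotated TM1/TM4; 5.50 as the TM5 proline
when present. Glycoprotein hormone receptors have Ala at 5.50, so their
configs override it explicitly (TSHR 593, and the stand-in FSHR/LHR configs
549/537). When a motif matches more than once, hits inside the expected
helix win, then the first in sequence, with a warning. Two typographic
conflicts in the source literature (residue 634 labelled both 6.54 and 6.45;
670 labelled 7.40 and 7.45) resolve arithmetically to 6.45 and 7.45.

## Helix geometry

Local axes come from a sliding window (default 7 CAs). Within a window the
axis is estimated from second differences of the CA trace: for a helical
trace these vectors are exactly radial, so consecutive cross products point
along the local screw axis. This estimator is exact on an ideal helix,
where window PCA is biased by several degrees by the non-integral number of
turns per window. Axes are oriented N→C so kink signs never arise.

* **Kink**: maximum angle between axis directions of windows one
  window-length apart (so the two estimates share no residues). Threshold
  15°: ideal helices score < 1°, canonical proline kinks 20–35°. The kink
  angle is invariant under global rigid motion by construction.
* **Bulge**: a residue whose carbonyl O loses its i+4 amide N (> 3.5 Å) and
  contacts i+5 (≤ 3.5 Å) instead. Registry shift is the defining feature of
  an α-bulge and is computable without hydrogens; rise-per-residue
  heuristics are not used. Residues missing backbone atoms are skipped with
  a warning.

## Contact classification

All tiers are heavy-atom distance bands over typed side-chain atoms (charged
groups, donors, acceptors, aromatic ring atoms, apolar carbons; His is
donor+acceptor and aromatic, never charged, by default). First matching rule
wins: salt bridge ≤ 4.0; H-bond ≤ 3.5; weak polar 3.5–4.0; aromatic ≤ 4.5;
hydrophobic ≤ 4.0 (strong) / 4.5 (weak); induced dipole (polar atom to
apolar carbon) ≤ 4.5; donor/acceptor pairs at 4.0–6.0 Å are flagged
water-mediated-possible, reported alongside contacts but never counted as
one. The defaults reproduce the calibration points the package is tested
against — a 3.4 Å apolar pair is a contact, 3.8 Å N/O is weak polar,
4.6 Å Tyr–Tyr is non-interacting yet water-bridgeable, 4.9 Å apolar is
nothing — and are all overridable through `Cutoffs`. No hydrogen positions
or bond-angle criteria anywhere: the crystal templates this vocabulary is
calibrated to lack hydrogens. Glycine contributes its CA as a stand-in
apolar atom.

The interaction map covers all inter-helix pairs of BW-labelled residues
plus intra-helix pairs more than 4 residues apart (beyond one helical turn);
a CA–CA prefilter at 18 Å bounds the pair count.

## Activation fingerprint and state call

Panels: ionic lock (minimum charged-group distance R/K3.50 to D/E6.30,
present ≤ 4.0 Å; `not_applicable` when the residue types are wrong);
tyrosine toggle (minimum side-chain heavy-atom distance 7.53–5.58: bonded
≤ 4.0, water-mediated-possible 4.0–6.0, apart > 6.0); D2.50 H-bond partners
among 7.49/7.46/3.39; core-contact tiers (3.43–6.40/6.41/2.46,
5.50–3.40/3.44); the 3.30–4.58 tier. **Only the lock and toggle vote**:
inactive-like if the lock is present; active-like if the lock is measurably
absent and the toggle is not apart; otherwise indeterminate. The other
panels are reported without thresholds because no decision values exist for
them. Missing residues degrade the panel to `unavailable` entries, never to
exceptions.

## Superposition and movements

`superpose_by_bw` is a closed-form (SVD/Kabsch, reflection-free) CA
superposition over residues matched by identical BW label. For movement
analysis the superposition is *outlier-trimmed* (fit, drop pairs whose
residual exceeds max(2 Å, 2×median), refit, iterate): a plain all-atom fit
absorbs a large single-helix movement into the frame and biases every
component by several tenths of an Å, while the trimmed fit anchors the
frame to the static core — the convention structure-alignment tools use.
The plain fit remains available (`trim=False`).

End displacement is the mean CA shift of the terminal four matched residues
(one helical turn), which damps end fraying; it is decomposed against the
bundle axis (principal axis of all matched CAs, pooled over both states,
oriented extracellular-positive via the TM1 orientation convention) into
radial (outward +), axial (extracellular +) and tangential components.

TM6 rotation is the azimuth change of a marker side-chain centroid (default
6.29, overridable) about the helix's own per-state axis, measured against
the direction to the bundle centre in each state; this cancels helix
translation and tilt. Viewed from the extracellular side counter-clockwise
is positive; the result lies in (−180°, 180°] and is antisymmetric under
swapping the states.

## Mutation annotator

Explicitly heuristic and qualitative: it predicts which conformation a
substitution stabilizes, never a fold change. Interactions carry weights
(strong tiers 1.0; weak polar, weak hydrophobic and induced dipole 0.5 —
the induced-dipole discount because its strength is never quantified). For
every wild-type interaction and near-miss neighbour (side chains within
6.5 Å), the engine computes the best interaction the new side chain could
make with that partner: polar/charged capability is judged at the recorded
distance ("introduced near" the partner — long flexible partners make a
reach correction misleading), while hydrophobic/aromatic/induced-dipole
capability is judged at a reach-adjusted distance using a packaged
maximum-extension table (so Phe gains what Leu could not reach, and Ile
loses what Phe could). The per-conformation score is Σ(new − old); the call
is the conformation with the higher score (destabilizing the other side
counts), ties are neutral. Consistency maps active-stabilizing ↔
CAM/activating and inactive-stabilizing ↔ silencing/inactivating.

Membrane-exposure reasoning (lipid-facing residues shielded or exposed by a
substitution) is outside the rule set — the package has no membrane model —
so residues with no inter-helical interactions or near neighbours return
`untestable` with a note.

The packaged phenotype tables are stored verbatim from their sources,
including their internal numbering conflicts (e.g. two different positions
both labelled 5.55 in the LHR tables); they are reference data, not
derived values, and are never cross-checked against each other.

## Synthetic structures

The generator emulates what the analyses need and nothing more:

* helices are built residue-by-residue (NeRF) with ideal backbone internal
  coordinates and (φ, ψ) solved numerically so the requested rise
  (1.5 Å/residue) and twist (100°/residue) hold exactly; the CA radius
  (~2.3 Å) follows from backbone geometry and is checked, not imposed;
* side chains are grafted from the idealized residue templates of the
  chemical component dictionary bundled with biotite — one canonical
  rotamer per type, sufficient for distance-tier tests without a rotamer
  library;
* seven helices sit on a 9 Å circle, axes vertical, alternating N→C
  direction (odd helices run extracellular→intracellular); residues are
  numbered 100·k+1… per helix with fixed anchor indices, so the whole
  diagnostic panel (1.39…7.53) exists in every bundle;
* planted features: α-bulges are torsion edits at build time (two residues
  at φ=−80°, ψ=−70°, found by scanning for a clean i+4→i+5 registry shift);
  kinks rotate the downstream segment about a perpendicular through the apex
  CA; rigid motions translate/rotate whole helices or half-helices; contact
  pairs graft the requested residue types, face them toward each other and
  translate one helix until the realizing group distance matches the target
  (±0.05 Å, feasibility-checked against van der Waals contact);
* the seed drives a small coordinate jitter (0.02 Å) and a global rigid
  scatter of the bundle; features are planted after the jitter so their
  contracts hold for every seed, and identical spec+seed gives identical
  coordinates.

State pairs plant the R3.50–D6.30 lock at 3.0 Å and a Tyr7.53/Tyr5.58 pair
at 11 Å in the inactive state; the active copy applies a movement plan
(per-helix-end radial/axial/tangential displacements realized as rigid
translation+tilt, an optional TM6 rotation, and an optional re-planting of
the tyrosine pair at a target distance). One deliberate constraint: a
*differential* axial plan (one end up, the other down) is not rigidly
realizable — a rigid body cannot stretch — so axial components should agree
between the ends; the default activation plan moves TM3 down bodily.

What a green synthetic test does **not** establish: realism of helix
packing, rotamer diversity, loops, membrane context, waters, or the actual
geometry of any receptor. The generator validates *detectors*, not models;
conclusions about real receptors require real coordinates (the crystal
pipeline) or deposited models (not available for the GPHR TMDs).

## Crystal-structure pipeline

Packaged configs map the generic positions 7.40/1.39 (and 7.53/5.58 for
metarhodopsin II) to author residue numbers of the six public entries,
derived from each receptor's canonical motif anchors. Distances use the
package's conventions: "side-chain distance" is the minimum side-chain
heavy-atom distance (this convention reproduces the published
interacting/non-interacting dichotomy), "Cα distance" is CA–CA. The
structures themselves are not packaged and are fetched on demand; in an
offline environment this stage is unavailable by design.

## Known limitations

* BW labels have no insertion handling; receptors whose printed labels
  require bulge labels are out of scope.
* The contact vocabulary is purely distance-based: no angles, no energies,
  no explicit water, no π-stacking geometry.
* The mutation engine ignores backbone interactions, rotamer search and
  expression/folding effects; it reasons about direction only.
* The packaged receptor sequences are synthetic stand-ins (documented in
  their FASTA headers): correct at every position the analysis depends on,
  neutral filler elsewhere. Conclusions about residues outside the
  constrained set should not be drawn from them.
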