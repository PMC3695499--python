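# Methods

## The score

`rnasphere` compares a predicted RNA 3D model to a reference structure by
local-neighborhood RMSD. For each nucleotide of the reference, the atoms
within a closed ball of radius *r* around an anchor atom are collected
(the sphere is always constructed in the reference, so all models of a
batch are scored on identical atom sets), matched to the model by
structural key, and superimposed by the Kabsch algorithm; the minimized
RMSD is the score of that (residue, radius) cell. The resulting
residue × radius profile interpolates continuously between a local measure
(small *r*) and the global RMSD (any *r* that covers the molecule).

Assumptions inherited from the problem setting:

* reference and model share chain identifiers, residue numbering,
  insertion codes and atom naming — the tool matches by these keys and
  performs no sequence alignment;
* inputs are single-conformer coordinate sets (one MODEL block of a PDB
  file); altLoc conformers are collapsed at parse time;
* RMSD is unweighted — no mass or occupancy weighting, since every atom is
  an equally valid prediction target.

## Atom correspondence

Atoms are paired when their (chain, residue number, insertion code, atom
name) keys are equal after name normalization (`*` → `'`, whitespace
stripped). Serial numbers are never used: they encode file layout, not
structure. Unpaired atoms on either side are reported and logged, never
silently dropped. Zero shared keys is a hard error (the structures are not
comparable); anything above zero proceeds, with per-sphere *coverage* =
|paired ∩ members| / |members| recording locally how much of each
neighborhood the model actually provides. In strict mode (CLI `--strict`)
any coverage below 1, unmatched atom, or error-severity validation finding
aborts the run with a data-error exit code. The lenient default exists
because real submissions do contain missing atoms and still deserve a
score.

## Superposition

The rotation is obtained from the SVD of the 3×3 cross-covariance of the
centered coordinate sets; if the candidate rotation has determinant −1 its
smallest-singular-value axis is flipped, so the returned matrix is always
a proper rotation even when a reflection would fit better — a mirror-image
model must not score as perfect. Implementation choices:

* **Exact self-comparison.** Bitwise-identical coordinate sets
  short-circuit to RMSD exactly 0.0 with the identity rotation, making the
  self-comparison and radius-limit identities exact rather than ≈1e-14.
* **Minimum pairs.** Three non-collinear pairs are required; fewer yields
  a gap marker (rendered as a break in plots), not a number.
* **Degeneracy.** Collinear or coplanar sets are still superimposed (the
  SVD handles rank deficiency; the determinant correction picks the proper
  branch) but flagged `degenerate` in the result.
* **Shared code path.** The radius sweep and the one-off sphere query run
  through the same precomputed engine (`PairEngine`), with members taken
  in reference file order, so a sphere that covers the molecule equals the
  global RMSD bit for bit — identical atom set, identical arithmetic.

## Sphere construction

Membership uses the closed ball (distance ≤ *r*): with an inclusive
boundary, the "radius covers the molecule" limit is exact at the maximum
pairwise distance instead of requiring an ε above it. Spheres may cross
chain boundaries in multi-chain complexes: a local neighborhood is a
spatial, not a topological, notion. In `center_atoms_only` mode both
membership and superposition are restricted to atoms bearing the anchor
name — a one-atom-per-residue coarse view.

## Aggregation

* Default radii vector: **3, 8, 20, 38, 300 Å** — chemical neighborhood,
  helix-scale, domain-scale, molecule-scale, and a radius that covers any
  RNA this tool will plausibly see (override with `--radii`).
* Averaged curve: unweighted arithmetic mean over residues (not atoms) of
  the defined cells at each radius, with the defined count reported.
* Cutoff curve: per radius, 100 × |{residues with RMSD ≤ t}| / |{residues
  with defined RMSD}|. The comparison is inclusive, so a perfect model
  scores 100 % at any positive threshold.
* Gap cells (missing anchor, < 3 pairs) are excluded from both means and
  cutoff denominators rather than counted as infinitely bad: a missing
  5′-terminal phosphate should not poison a curve. Strict mode is the
  escape hatch for pipelines that want absence to be fatal.

## Input handling

Hydrogens and HETATM records are excluded by default (flags restore them):
models frequently omit hydrogens, and asymmetric inclusion would corrupt
the correspondence. Multi-MODEL files default to the first block,
selectable by `--model-index`. AltLoc conformers collapse to the
highest-occupancy one, ties broken by altLoc letter, so parsing is
deterministic. Validation reports — duplicate residue keys (error),
missing sphere-anchor candidates, non-nucleotide residue names, numbering
breaks (warnings) — are written per structure and are fatal only in strict
mode. PDB output writes fixed-column records with 3-decimal coordinates,
so parse∘write∘parse is idempotent at the format's own precision. Profile
CSVs store values at 17 significant digits (lossless float round trip),
with gaps as empty fields; coverage grids are not persisted.

## Plots

All five renderers are headless and are pure functions of (profile data,
style): line colors are assigned from the sorted model-id list, and the 2D
map / 3D surface color scale is shared across a batch (data min–max), so
per-model images are directly comparable. The blue→red `coolwarm` map
encodes low→high RMSD; gaps use a neutral gray. Radii are drawn as
uniform-height bands in the 2D map and on a linear axis elsewhere (the
300 Å column visually dominates a linear radius axis; `log_radius` in
`PlotStyle` switches the curve plots to a log scale). Tests assert on the
series handed to the renderers, never on pixels.

## Synthetic fixtures

`generate_helix` builds an idealized pseudo-RNA helix: each residue is a
rigid copy of a seeded atom template placed on a regular helix with
A-form-like defaults (rise 2.81 Å, twist 32.7°, C1′ at 9.4 Å from the
axis), rotating with the helical frame. C1′ lies exactly on the helix, so
consecutive C1′ distances follow the closed-form chord
√(rise² + 2R²(1−cos twist)). `perturb` manufactures decoys with known
error structure: global rigid motions, per-residue displacements, hinge
rotations of a segment, i.i.d. Gaussian coordinate noise, and atom
deletions. Everything is a deterministic function of the seed.

What the fixtures deliberately do **not** emulate: real base-pairing
geometry, sugar puckers, chain breaks, modified nucleotides, or the
correlated, motif-level errors of real predictors. Passing tests therefore
demonstrate the geometric correctness of the scoring machinery — exact
invariances, oracle agreement, correct localization and coverage
accounting — not that the score ranks real predictor outputs the way an
expert would.

## Verification strategy

The superposition is checked against two independent routes: a brute-force
axis-angle rotation-grid minimizer (coarse Fibonacci-sphere grid plus
local refinement to 0.05°, using the linearity of tr(RC) for O(1) per
candidate) and Biopython's `SVDSuperimposer`; the PDB writer is
cross-checked against the `gemmi` reader. Statistical recovery uses the
fact that i.i.d. per-coordinate noise of σ gives a whole-molecule RMSD of
σ√3 with standard error ≈ (σ/2)√(2/n); fixtures use n ≥ 500 atoms so the
3-standard-error band is a sharp test. Fixture sizes throughout (8–40
residues, 128–640 atoms) keep the full suite and the acceptance script in
the tens of seconds while leaving every property it checks at full
strength.

## Known limitations

* No sequence-alignment fallback: differently numbered structures must be
  renumbered upstream.
* No symmetry correction: chemically equivalent but differently named
  atoms (e.g. OP1/OP2 swaps) count as errors.
* Base-interaction fidelity (base pairs, stacking) is outside the score;
  a model can match coordinates well while pairing wrongly.
* mmCIF input is not supported; convert to PDB first.
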