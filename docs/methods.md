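# Methods

This note records the models implemented by `neosurf`, the parameters
that matter, the numerical choices, and the known limits of each
approximation. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Solvent-accessible surface area

SASA is computed by Shrake–Rupley quadrature: for atom *i* with
van-der-Waals radius *r_i*, `n_points` quadrature points are placed on
the expanded sphere of radius *r_i + probe*; a point is accessible if it
lies strictly outside every neighbor's expanded sphere, and

    area_i = (accessible fraction) × 4π (r_i + probe)².

Choices:

- **Point set.** A deterministic generalized (golden) spiral. No random
  state enters the main computation, so results are bit-reproducible and
  independent of any seed. Default `n_points = 960`; doubling it moves
  totals by well under 0.5 % (asserted in tests). The error of the
  two-sphere lens case against the exact spherical-cap formula is ≈0.4 %
  at 960 points.
- **Probe radius.** 1.4 Å (water) by default.
- **Neighbor search.** k-d tree; only atoms with
  `d < r_i + r_j + 2·probe` can occlude. Coincident atoms with equal
  radii are well defined: the strict-inequality test leaves both spheres'
  points accessible.
- **Radii.** Two embedded element-keyed tables: `bondi` (C 1.70, N 1.55,
  O 1.52, S 1.80; default) and `chothia` (larger carbon, C 1.87).
  The downstream annotation depends on the *ratio* to a reference
  computed with the same table, so the table choice moves absolute areas
  much more than it moves in/out calls.
- **Decomposition.** Backbone = N, CA, C, O (and OXT); everything else is
  side chain. Apolar area sums carbon and sulfur atoms — the conventional
  rule.
- **Hydrogens** are dropped on input by default (crystal structures and
  models are heavy-atom); a flag retains them.

### Buried/exposed annotation

Relative side-chain exposure is
`ratio = sidechain_area / reference_sidechain_area × 100`, where the
reference is the same residue type in an ideal-geometry *extended*
Gly-X-Gly tripeptide (φ = −139°, ψ = +135°), computed with the same
probe, point count and radius table and cached. A residue is `out` above
50 %, `in` below 20 %, `unassigned` between — the convention of
surface-area servers used for this annotation. Glycine has no side-chain
heavy atoms; its ratio is reported as 0 and its flag is derived from the
backbone area against a Gly-Gly-Gly backbone reference.

Because the reference is one specific conformer, an exposed side chain in
a different conformer can score slightly above 100 % (values up to
~115 % occur in the synthetic groove); the annotation only cares about
the 50 %/20 % cuts, so this is cosmetic.

## Superposition

`kabsch` computes the proper (det = +1) least-squares rotation via SVD
(scipy's `Rotation.align_vectors`); reflections are excluded, and
degenerate point sets still return a valid minimizer. `ca_rmsd`
superposes on the MHC heavy-chain Cα trace by default (the groove is the
natural frame for judging a modeled peptide) and reports RMSD over the
peptide Cα atoms; `peptide` and `all` selections are available because
the alternative convention — superposing on the peptide itself — is also
common and the right choice is genuinely open. Chains without Cα atoms
(pseudo-atom scaffolds) are paired atom-by-atom in file order.

## Template selection

Candidates come from a user-supplied set (manifest TSV or in-memory
structures); no live database search is performed. Two percent metrics
are shipped because reports of "sequence similarity" for short epitopes
rarely state the formula:

- `identity` (default): fraction of identical aligned positions;
- `blosum`: fraction of positions identical *or* BLOSUM62-positive.

Both are ungapped; when lengths differ every placement of the shorter
inside the longer is scored and the best kept, with the percentage over
the shorter length. For 8/9-mers the identity metric yields the familiar
ladder 33 % (3/9), 55 % (5/9), 62 % (5/8), 75 % (6/8), 87 % (7/8).

Ranking is by similarity descending with template-id tie-break (total,
deterministic). Each hit is annotated with the buried/exposed state of
the template residue aligned to the MEP's mutant position, computed on
the template structure itself. Final selection takes the
highest-similarity hit whose mutant-position state matches the requested
one (`out` by default); if none matches, the top hit is returned with an
explicit warning rather than an error.

## Model building

A deliberately transparent stand-in for a homology-modeling +
peptide-docking stack:

1. **Graft.** Backbone atoms are copied verbatim from the template
   peptide; identical residue types keep the template side chain
   bit-identically; differing types are rebuilt from the ideal geometry
   of the chemical component dictionary (via biotite), placed by
   superposing the ideal N/CA/C onto the template frame. χ angles are
   copied from the template residue where the torsion tree is shared,
   otherwise a single embedded most-common rotamer per type is used.
   Length mismatches of one residue are handled by terminal trimming or
   ideal-geometry C-terminal extension; larger mismatches are errors.
2. **Clash score.** `Σ max(0, r_i + r_j − d_ij)²` over non-bonded pairs.
   Excluded: pairs at bond-graph distance ≤ 3 (1-2, 1-3 and the
   torsion-defining 1-4 pairs) and pairs inside a rigid pseudo-atom
   scaffold chain. The 1-4 exclusion keeps ideal rotamers at (near) zero
   score, so refinement cannot "improve" a model by shaving intrinsic
   intra-residue contacts; with 1-3-only exclusion a tryptophan already
   scores ≈1.7 from its rigid cross-ring pairs.
3. **Refine.** Seeded multi-restart greedy torsion search over the
   peptide's χ angles: restart 0 starts from the unperturbed graft (so
   the result is never worse than plain greedy minimization); every other
   restart applies a Gaussian χ kick (σ = 20°), and the first half of the
   perturbed restarts prepends a coarse 30° whole-circle pass before the
   fine ±30/±15/±5° sweeps. The backbone never moves, so the Cα RMSD to
   the template is exactly the graft's. Default 200 restarts,
   configurable down (tests and the acceptance script use 4–20; with the
   toy groove the clash landscape is smooth enough that results are
   stable from a handful of restarts).
4. **Selection.** Candidates are scanned in ascending clash order and the
   first whose mutant residue carries the requested in/out flag wins;
   if none does, the lowest-clash model is returned with a warning.

The clash score is a steric proxy, not an energy; no claim of parity with
full-atom force-field refinement is made.

## Classification

`classify(A_sc, flag)`: immunogenic if `A_sc > 20 Å²` and flag ≠ `in`;
nonimmunogenic if `A_sc < 15 Å²` and flag ≠ `out`; otherwise
indeterminate. Two open points were resolved conservatively: the
15–20 Å² interval is undefined by the thresholds, and the absolute-SASA
and ratio-based readouts can disagree — both cases yield
`indeterminate` with the full evidence attached, never a forced binary
call. The call is a structural propensity only; it asserts nothing about
actual T-cell assays.

## Synthetic groove generator

The generator emulates exactly one thing: the *solvation environment* of
a peptide presented in a two-helix-flanked groove — open top, packed
floor, flanking walls — with per-position ground truth. It is not a
folded MHC.

Geometry (defaults in Å): each residue is built from ideal geometry with
its side-chain centroid pointing up (+z) or down (−z), placed along the
x-axis at a rise of 6.5 per residue with an alternating ±22° splay and a
±1.8 vertical offset (up residues ride high, down residues sink). The
floor is a jittered grid slab (spacing 1.5, top at z = −2.0, depth 9.6 —
deep enough to swallow an extended arginine) from which every grid atom
within `r₁ + r₂ + 0.4` of a peptide atom is carved away, producing snug
cavities around down-pointing side chains; walls are sparse atom rows 20
apart, far enough that an up side chain is never occluded by them (checked
at generation, error if violated). All pseudo-atoms are carbon-radius
spheres, so a written-and-reread groove reproduces the same radii from
the element table.

The rise, splay and vertical offset are larger than the ~3.5 Å/residue of
a real presented peptide: a real epitope splays alternate side chains
into pockets so same-side neighbors are two positions apart, while the
toy groove must support *arbitrary* up/down patterns, including adjacent
bulky up-pointing residues. The defaults were chosen so that the
generated label is unambiguous across random sequences and patterns (over
80 seeded fixtures the worst exposed position keeps ≥ 57 % relative
exposure and the worst buried one ≤ 15 %, against the 50 %/20 % cuts).

`make_template_set` produces candidate pools with prescribed percent
identity (replaced positions get substitution-matrix-non-positive
residues, so the identity and BLOSUM metrics coincide by construction)
and prescribed mutant-position exposure; non-mutant positions follow the
canonical anchor pattern (position 2 and the C-terminus buried). When a
*buried* mutant position is prescribed, the template keeps the MEP's own
residue type there: the scaffold is rigid, and a cavity carved for a
large residue would leave a smaller grafted residue with slack and an
ambiguous (gray-zone) area — a real groove repacks around the peptide,
which the toy cannot do. This size-matching is the generator's check that
excludes gray-zone geometries from ground-truth claims.

What passing tests on the toy groove do **not** show: correct handling of
real MHC pocket chemistry, backbone flexibility, water-mediated contacts,
or numerical parity with any particular surface-area server (whose radius
and reference tables are not public). Threshold-level behavior — exposed
positions above, buried positions below the decision cuts — is the
claim, and is what the acceptance script measures.

## Random atom clouds

Seeded uniform placement with rejection below a minimum separation,
elements drawn from C/N/O/S with table radii. Used as the substrate for
the independent Monte-Carlo surface-sampling oracle (random directions,
≥ 20 000 samples per atom) that cross-checks the quadrature engine within
2 %, alongside a second independent check against biotite's
implementation.

## Determinism and seeds

The SASA path is seed-free. Every stochastic component (groove jitter,
cloud placement, template-set sequence draws, refinement kicks) takes an
explicit seed and fans it out through `numpy.random.default_rng`;
identical inputs and seed reproduce byte-identical model PDB files. The
pipeline seed lives in `PipelineConfig.seed`.

## Known limitations

- The groove is an occlusion abstraction; absolute SASA values of
  modeled MEPs are systematically higher than in a real groove (the toy
  is more open), so only threshold-side agreement is meaningful.
- The clash score ignores electrostatics, solvation and backbone strain;
  model ranking beyond clash relief is outside scope.
- Template search is over user-supplied candidates only; assembling the
  allele-specific pool from a structure database is the user's task.
- Binding-affinity prediction is intentionally not implemented; an
  affinity column supplied by the user is carried through untouched.
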