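# Methods

This note records the model, the numerical choices, and the places where the
design was genuinely open, in enough detail to reproduce or audit any result
the package computes.

## Glycan representation

Structures are condensed linear-code strings over the sugar codes M
(mannose), GN (GlcNAc), A (galactose), F (fucose), NN (NeuAc) and G
(glucose), each residue carrying an anomer (a/b) and the locant of its
attachment on the parent. Strings are written leaf-to-root; at a branch
point the lowest-locant branch is in-line and higher-locant branches are
parenthesized in ascending order. This ordering makes the string canonical,
so structural identity is string identity and networks can be deduplicated
by dictionary lookup. The optional `;Asn` suffix is kept as a flag and plays
no role in matching or mass.

Permethylated masses are computed from elemental composition: each residue
contributes its glycosidically linked, fully methylated formula (hexose
C9H16O5, HexNAc C11H19NO5, deoxyhexose C8H14O4, NeuAc C16H27NO8) and the
free reducing end closes the chain with C2H6O (water plus the two extra
methyl groups as CH2). Glucose counts as a hexose. The mass cutoff during
network generation compares the neutral permethylated mass; spectra use the
sodiated form, [M+Na]+ singly charged, the standard ion for permethylated
MALDI glycomics.

## Pattern grammar

Patterns are substrings of the canonical linear code with five wildcards:
`-` (paren-matched string not ending in `)`: a single unbranched ligand),
`…` (any paren-matched string), `_` (continuation toward the root: every
`(` closed within the binding, unmatched `)` allowed), `|` (a possible
branch point: empty, `(…)`, `)`, or `)(…)`), and `*` (the zero-width
reaction-site anchor, defined as the first position at which the substrate
and product strings differ). `Gnbis` is a macro for the bisecting-GlcNAc
motif `Ma3(GNb4)(…Ma6)Mb4`. A pattern-initial `(` matches a literal `(` or
the start of the string, so it doubles as a non-reducing-terminus marker
(a residue is terminal exactly when preceded by `(` or at offset 0; `((`
never occurs in canonical strings, so the two readings never collide).

Constraint expressions combine pattern atoms with `&`, `or` and `~`
(`|` is never boolean), residue-count comparisons (`#M = 9`, `#NN>1`) and
`Count <pattern>`, which counts distinct match start offsets. Expressions
containing `*` or `_`-anchored atoms are evaluated per reaction site, so one
structure can be a substrate at some sites and vetoed at others.

The production matcher is a recursive generator over compiled pattern
elements; the test suite holds a deliberately naive oracle that enumerates
every substring binding and validates it with stand-alone predicates, and
the two are compared exhaustively over a generated corpus (≥500 structures
of ≤12 residues) for every packaged rule pattern.

## Reaction rules and kinetics tables

The packaged tables (in `src/glygolgi/data/`) carry, column for column, the
model's fifteen reaction rules for the thirteen enzymes, the base kinetic
parameters per rule (kf min⁻¹, Km μM, Kmd μM, with Kmd = 0 meaning the
enzyme is donor-saturated), the structure-dependent adjustment rules
(multipliers on kf/Km/Kmd under a pattern condition), the enzyme spatial
distributions (beta means, α+β = 6), the compartment residence times and
donor concentrations, and the ten fitted cell-line activity profiles
(Pro-5, Lec1, Lec2, Lec3.2.8.1, Lec4, LEC10, LEC11, LEC12, Lec13, LEC30).
Users may supply alternative TSVs with the same columns.

One adjustment row for the branch fucosyltransferase carries the condition
`(*Fa2Ab4`. No rule in the model ever creates an α1,2-linked fucose, so the
condition cannot match any generated structure; the row is transcribed
verbatim and is a structural no-op.

Two conventions in the kinetics were genuinely open and are settable in
config; the defaults were chosen because the alternatives are inconsistent
with the packaged fitted-state outputs at the printed activity values:

- **Adjustment combination** (`RuleSet.combine`): when several adjustment
  rows match one substrate/site, the default applies the *first* satisfied
  row in table order; the alternative multiplies all satisfied rows.
  Stacking the mannosidase-I rows multiplies Km by ~56 on the Man9
  substrate, which would leave the majority of glycans unprocessed at
  wild-type activities — far from the fitted-state profile the packaged
  activities are supposed to reproduce.
- **Activity scale** (`GolgiConfig.activity_convention`): activities are
  reported as a = kf·c_enz/Km. The default (`"per-rule"`) treats a as the
  donor-saturated first-order coefficient of *each* of the enzyme's rules
  at base parameters, so the per-rule base kf/Km cancel out of the rate and
  only the adjustment multipliers, donor factor and competition remain.
  The alternative (`"reference-rule"`) derives a single enzyme
  concentration from the lowest-index rule's kf/Km; for mannosidase I this
  makes the final trimming step ~116× slower than the reported scale and
  bottlenecks the entire pathway.

## Network generation and pruning

Generation is breadth-first closure: every rule is applied to every
structure; products above the 5000 Da permethylated cutoff are discarded;
new products join the queue; reactions are deduplicated by (rule, substrate,
product). The reaction graph is acyclic because mannosidases only remove
mannose and transferases only add their donor residue, which also gives the
audit invariant that every reaction changes the composition by exactly one
residue of its cosubstrate.

The unpruned closure exceeds 150,000 structures, dominated by combinatorial
decoration of low-abundance deep branches, so the default network is pruned
during generation. The heuristic is a competition-free, single-pass flux
estimate: each structure carries an estimated abundance (seeds start at the
inlet fraction); when a structure is expanded, its estimate is split over
its candidate reactions in proportion to τ·k_r/(1 + Σ τ·k), where k_r is
the pseudo-first-order rate of the reaction at nominal wild-type (Pro-5)
activities and τ is the total Golgi residence time (22.2 min). A product
below the threshold (default 3 × 10⁻⁶ of inlet) is not added unless it
already exists. The threshold was calibrated once so the default network
(20,022 structures / 39,920 reactions) matches the scale of the published
pruned network (19,413 / 50,605); a `lec30` preset lowers it to admit the
larger structure set used for the most heavily fucosylated mutant. Because
contributions discovered after a product was first rejected cannot resurrect
it, the pruned set depends mildly on generation order, which is
deterministic (rule order × canonical-string order). A post-hoc
`prune_network` with an explicit topological forward pass is also provided.

## Golgi solver

Four equal CSTRs in series; outlet of compartment k is inlet of k+1; the
inlet of compartment 1 is 500 μM of Man9 (the inert glucosylated seed
defaults to zero inlet and is fit-adjustable). Enzyme amounts per
compartment are total × beta-quartile fraction. Donor concentrations are
fixed per compartment (no depletion). The reverse term of the rate law is
disabled: coproduct concentrations are not tracked and transferase reactions
are treated as irreversible.

Each compartment solves c = c_in + τ·S·r(c) by fixed-point iteration on the
competition sums: with the sums frozen, the balance is linear and sparse
(1→1 reactions only), and the matrix I − τA is an M-matrix, so the exact LU
solve is non-negative and conserves the total by construction. The sums are
then refreshed and the loop repeats until the relative change is below
10⁻¹², after which the full nonlinear residual is verified below 10⁻⁸.
Competition membership defaults to substrates-only (every structure that is
a substrate of the enzyme contributes [P]/Km_eff with its smallest effective
Km over that enzyme's reactions); `"substrates+products"` and a whole-pool
variant are available behind the same flag. Equivalence with a dense Newton
solve is tested on networks of ≤200 structures.

Forward solutions with the packaged activity profiles land within ~3
percentage points of the packaged fitted-state feature values for the
high-mannose (Lec1), bisected (LEC10), terminal-sialic-acid (Lec2) and
ConA-bound (Lec1) checks. The wild-type high-mannose fraction computes
~5–6 points low across profiles; the offset is consistent with a small
fitted inlet fraction of the inert glucosylated Man9 (which counts as
high-mannose) that is not part of the packaged inputs, and the package
defaults that fraction to zero rather than invent a value.

## Spectra

Isotope envelopes come from aggregated-isotopologue convolution of the
elemental formula (exponentiation by squaring per element; isotope masses
and abundances from the standard tables hard-coded in `spectra.py`, with an
independent first-order check in the tests). Isobaric structures (equal
composition) pool into one envelope. Stick spectra are clipped to the
1400–5000 Da window and normalized to a 100% total.

Preprocessing of continuous spectra: rolling-minimum baseline (default 501
points), Savitzky–Golay smoothing (window 5, order 2), `find_peaks`
detection with an automatic height floor (10⁻⁴ of the maximum),
watershed-style integration (each sample within 0.35 Da contributes to its
nearest detected peak, so overlapping peaks split shared signal), grouping
of peaks spaced 1.00336 ± 0.01 Da, and removal of isolated single-peak
groups. All window sizes are config, not claims about the original
instrument processing. Projection onto the model solves a non-negative
least-squares problem over the model envelopes; intensity at non-model
masses is discarded and the result renormalized.

## Fitting

Activities are fitted in log space (positivity; comparable scales across
five orders of magnitude) with bounds log(10⁻⁶)–log(10⁴) min⁻¹, by
`scipy.optimize.least_squares` (trust-region reflective, a bounded
Levenberg–Marquardt variant) on the residuals of individual isotopologue
peak intensities over the model's fixed mass grid, both sides normalized to
100%. The Jacobian is numeric (forward differences, step 10⁻⁵); unit
residual weights. `fit_shared` fits a beta-localization mean jointly across
cases while each case keeps its own activities. `sensitivity_profile`
reports the finite-difference spectrum-change norm per unit log-activity
and defines the identifiable set under noise: an enzyme is identifiable
when a 10% activity change moves the spectrum by more than the noise floor
(the norm of the noise perturbation itself).

## Synthetic data

The fixture generator emulates permethylated [M+Na]+ MALDI-TOF spectra over
1400–5000 Da: Gaussian peak shapes (σ = 0.08 Da on a 0.02 Da grid), seeded
multiplicative log-normal peak noise (default sd 5%), a slow sinusoidal
baseline, and contaminant peaks at masses kept ≥3 Da from any model mass,
each with a small 3-peak isotopic satellite group of its own (so they
survive the isolated-peak filter, as real contaminants would). All
randomness flows through explicit seeds; identical seeds give bit-identical
fixtures, and every fixture carries a JSON sidecar with the generating
activities and ground-truth peak groups.

What the generator does not emulate: detector saturation, mass-accuracy
drift, charge states beyond +1, in-source fragmentation, and real
biological variability of glycan processing between protein sites. Passing
the closure tests therefore demonstrates the internal consistency of the
pipeline under the stated noise model, not instrument-level fidelity.

## Problem sizes used in the tests

The suite runs on reduced networks so the whole run stays within a desktop
budget: ~1,400 structures for solver/fitter integration and noiseless
13-activity recovery, ~600 structures for the ten-seed noisy recovery and
pipeline-closure studies, ≤200 structures for dense-Newton equivalence, and
the full ~20,000-structure default network for the forward feature
reproduction and network-scale checks. The pipeline-closure study uses
fixtures with multiplicative peak noise only, so that the 2-standard-
deviation recovery band isolates the stated noise source; baseline and
contaminant handling are exercised by their own tests. Recovery is assessed
on ground-truth groups above 1% of the base peak, the detectability floor
of the preprocessing at these settings.

## Known limitations

- The pruning heuristic is a reconstruction; only its intent (drop
  negligible structures) and its calibrated scale are anchored, so pruned
  counts are approximate and configuration-dependent.
- The wild-type high-mannose offset discussed above.
- Analytic sensitivities are not implemented; the numeric Jacobian is the
  cost driver of large fits.
- Reversible kinetics (kr, Keq′) are carried in the data model but no
  coproduct tracking exists to drive them.
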