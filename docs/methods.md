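# Methods

## The two-conformation model

The receptor is treated as a single macromolecule that interconverts between
two global conformations: a low-affinity, nonconductive **closed** state and a
high-affinity **open** state.  The open and desensitized conformations are
deliberately merged into the one high-affinity state: both bind agonists more
tightly than the closed state, equilibrium binding cannot distinguish them,
and whether their agonist affinities actually differ is an open experimental
question the model does not try to answer.  No kinetics are modeled; all
quantities are equilibrium expectations.

Each receptor carries `n_ortho` orthosteric sites (neurotransmitter/toxin
sites in the extracellular domain; default 5, one per subunit of a homomeric
pentamer) and `n_allo` allosteric sites (modulator sites in the transmembrane
domain; default 5).  Within a conformation the sites of a class are identical
and independent — there is no inter-site cooperativity; all cooperativity in
observables arises from the global conformational change.  A ligand occupies
exactly one site class (`role`), and is characterized by `kd_closed` and
`kd_open`, its dissociation constants from the two conformations (molar).  A
ligand with `kd_closed > kd_open` is an agonist (it stabilizes the open
state), the reverse an inverse agonist, equality a neutral ligand that is
conformationally silent.

Because the sites are independent within a conformation, the grand partition
function factorizes into per-class binding polynomials:

    W_closed =                      prod_classes (1 + sum_L [L]/kd_closed,L) ** n_class
    W_open   = gating_unliganded *  prod_classes (1 + sum_L [L]/kd_open,L)   ** n_class

`gating_unliganded` is the closed⇌open equilibrium constant of the empty
receptor (dimensionless, ~1e-6 for a resting wild-type-like channel; values
approaching or exceeding 1 describe gain-of-function variants).  The gating
constant with m orthosteric ligands bound follows as
`gating_unliganded * (kd_closed/kd_open)**m`, the thermodynamic-cycle
statement that each bound agonist multiplies the gating equilibrium by its
affinity ratio.

All concentrations in the core are **free** (unbound) molar concentrations.
Weights are evaluated in log space (`n*log1p(S)`), since `(1+S)^5` products
overflow float64 at concentrations far above Kd; `state_weights` raises a
`ComputationError` rather than returning inf if the linear-scale weights are
requested beyond the representable range, while `equilibrium_occupancy`
operates on log-weight differences and is usable at any finite input.

An exhaustive microstate enumeration (`enumerate_microstates_oracle`) sums
over every conformation × per-site ligand assignment (2 × (k_o+1)^n_ortho ×
(k_a+1)^n_allo states; 15,552 for the 5+5-site model with two orthosteric and
one allosteric ligand).  It shares no code path with the closed forms and
serves as the independent oracle in the tests; site counts are capped at 8
and ligands at 4 to keep it feasible.

## Competition-curve simulation

The simulated assay clamps the free labeled-toxin concentration at
`label_level × kd_closed(label)` (default 1.0, the half-saturating condition)
and titrates an unlabeled competitor over a log-spaced grid, optionally with
an allosteric modulator held at constant free concentration.  The signal is
the mean number of label-bound sites normalized to its zero-competitor value
("fraction of control"); the anchor is always computed at competitor = 0
whether or not the grid contains that point.  The default grid helper places
17 log-spaced points across the requested range plus a leading zero.

The half-competition concentration is located on the simulated curve by
shape-preserving (PCHIP) interpolation of signal against log-concentration
followed by bracketed root-finding (relative tolerance 1e-6).  A curve that
never crosses 0.5 inside its grid raises `NotCrossedError` — including the
case where the lowest positive grid point is already below 0.5, which a user
fixes by extending the grid downward rather than by extrapolation.

Ligand depletion is off by default, matching the experimental design (cell
numbers titrated so that free ≈ total).  The opt-in solver converts totals to
free concentrations by solving `free_L + receptor_total * occupancy_L(free) =
total_L` for all ligands simultaneously: damped fixed-point iteration
(damping 0.5) with a cyclic per-ligand bisection fallback, converged to a
relative residual of 1e-10.  The bisection uses an absolute tolerance of
1e-18 × total so that strongly depleted ligands (free ≪ total) are still
resolved.

## Hill fitting

Replicate curves of one condition are pooled and fitted with

    signal(c) = sum_k a_k / (1 + (c / IC50_k) ** nH_k)

The lower plateau is fixed at 0 and the amplitudes are shared across curves:
signals are background-corrected fractions of control, so they start at 1 and
are expected to decay to 0 at saturating competitor.  IC50s are fitted on a
log10 scale (bounded to the data range ±3 decades), Hill slopes in
[0.05, 10] — sub-unity slopes are reported, not clamped — and amplitudes in
[0, 2].  Starting values are deterministic: each component's IC50 starts at
the grid point whose signal is nearest the corresponding evenly spaced level,
nH at 1, amplitudes equal; there are no random restarts.

Standard errors are the square roots of the diagonal of `inv(JᵀJ) × χ²_red`,
the reduced-chi-square-scaled Jacobian covariance of the weighted fit; IC50
errors are delta-method-transformed from the log scale, amplitude-fraction
errors from the amplitude covariance block.  Weights default to 1, or to
1/variance of duplicate signals via `weights_from_duplicates` when replicates
exist (variance from only two duplicates is noisy; the reduced-χ² scaling
absorbs the average misestimation).

Two identifiability guards: the fit raises when the normal-equations matrix
has condition number above 1e10, and when the fitted total decline across the
observed concentration range is smaller than twice the residual RMS — flat or
pure-noise data cannot pin down an IC50, and that is reported as an error
rather than an arbitrary number.

Component count: models with 1..max components are fitted and the smallest is
kept unless a larger one improves the corrected AIC (AICc) by more than 2
*and* all of its parameter SEs stay below 50% of the estimates.  The decision
trail is attached to the returned fit.  The fold shift between two
single-component fits is the IC50 ratio with first-order propagated SE,
`ratio × sqrt(rel_se_num² + rel_se_den²)`; the tests verify this against
Monte-Carlo sampling.

## Synthetic assays

The generator emulates the radioligand design: expected counts at competitor
concentration c are `count_scale × (bg + (1−bg) × s(c))` with `s` the
noiseless normalized curve; each duplicate is an independent Poisson draw.
The nominal nonspecific background `bg` is then subtracted — as the
experimental mock-transfected control subtraction does — and each curve is
normalized to its own mean zero-competitor value, so the generated signal is
a background-corrected fraction of control whose noiseless limit equals the
model curve for any background fraction.  Defaults: `count_scale = 5000`
expected counts at full signal (~1.4% relative counting noise, typical of
1-minute gamma counts), `background_fraction = 0.05` residual nonspecific
binding, duplicates per concentration = 2, independent curves per
condition = 3.  An optional log-normal per-curve scale factor models
day-to-day variability and is off by default; because each curve is
normalized to its own anchor, the factor cancels in expectation and only its
interaction with counting noise remains.  All randomness flows through one
`numpy.random.default_rng(seed)`.

What the generator does *not* emulate: slow equilibration (incubations short
of equilibrium, suggested as a cause of sub-unity Hill slopes in some
full-length-receptor data), cell-number/protein normalization beyond a scale
factor, pipetting serial-dilution error correlations, and receptor-number
variation between transfections.  Passing recovery tests therefore show that
the estimators are correct under counting noise and the stated design, not
that real assays are free of systematic error.

Toy alignments are built column-wise from a gapless random-residue matrix:
a planted deletion at reference position p gaps that column in a chosen
number of non-reference rows; a planted insertion after position p adds a
column in which only the chosen rows carry residues.  The classification of
the result is exactly the planted design, which the tests verify by
round-trip.

## Indel profiling

Columns are classified relative to the designated reference row: a column
where every row has a residue scores frequency 0; a partial column is a
*deletion* with frequency (n−x)/n when the reference keeps its residue, and
an *insertion* with frequency x/n when the reference is gapped (x = rows with
a residue, n = rows).  For 72 sequences both extremes are 71/72 ≈ 0.986.
Ambiguity characters (X, B, Z) count as residues; '-' and '.' both count as
gaps; an all-gap column is rejected as malformed.

`trim_to_reference` restricts the alignment to the columns spanned by a
1-based reference-residue window (e.g. the mature chain), keeping interior
insertion columns and dropping flanking ones — trailing insertions outside
the window are considered outside the analyzed region.

A reference position is *interrupted* when its own column is a deletion
column, or when an insertion column lies between it and the next reference
residue; indel-free stretches are the maximal runs of uninterrupted
positions.  This is the minimal reading of "uninterrupted by indels": an
insertion between p and p+1 ends the stretch at p−1 and restarts it at p+1.
Reported coordinates are 1-based on the analyzed window, with an optional
constant offset for precursor numbering (e.g. mature residue 1 = precursor
residue 23).  Region annotations (binding loops, transmembrane helices, the
pre-M1 linker) are supplied by the user as labeled intervals, never
hard-coded.

## Problem sizes and determinism

The test suite and the acceptance script run in well under a minute on one
CPU with the sizes chosen here: 100 random parameter draws for the
enumeration-oracle equivalence (15,552 states each), 100 seeded synthetic
assays of 3 curves × 2 duplicates × 18 concentrations for the IC50-recovery
coverage check, 1e5 Monte-Carlo draws for the fold-shift SE comparison, and
33–61-point grids for the deterministic curve calculations.  Every stochastic
step is seeded; identical seeds reproduce identical outputs.

## Known limitations

- Two conformations only; partially open or intermediate states, and any
  difference between open and desensitized affinities, are outside the model.
- Site classes are strictly independent; ECD–ECD or TMD–TMD inter-site
  cooperativity within a conformation cannot be represented.
- The mechanistic model is used to *simulate* curves that are then fitted
  with Hill equations, mirroring how the assays are analyzed; direct
  least-squares fitting of the mechanistic parameters to data is deliberately
  not provided.
- The half-competition locator requires a monotone curve; biphasic mixtures
  should be analyzed through the multi-component Hill fit instead.
- Indel statistics are purely column-count-based and inherit whatever biases
  the upstream aligner introduced; the package consumes alignments, it does
  not build them.
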