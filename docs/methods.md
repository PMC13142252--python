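# Methods

This note records the models, conventions, parameter choices and known
limitations behind `fshrdyn`, in the order a user meets them.

## Data model and conventions

Coordinates are in Å, times in ns, residue numbers 1-based in receptor
sequence numbering (mutation labels such as D408 map directly onto
residue 408). Helix ranges are inclusive on both ends. The native
trajectory format is the multi-model PDB, which round-trips
coordinates at the format's 3-decimal precision; binary formats
(DCD/XTC) enter through `trajectory_from_frames`, an adapter taking
any iterable of `(n_atoms, 3)` frames (e.g. a generator over an
MDAnalysis reader), so no binary parser is reimplemented here. Missing
element columns are inferred from the first letter of the atom name,
falling back to carbon with a logged warning.

The TMD1–TMD7 helix boundaries are user configuration, not packaged
truth: published boundary definitions vary, so every analysis takes
the annotation from the `Structure` rather than hard-coding one.

## Activation index

The index is linear in inter-residue distances,
`A(t) = b + Σᵢ cᵢ·dᵢ(t)`. The published coefficient sets for class-A
GPCRs are external training output; this package deliberately does not
re-derive them and treats the model as replaceable configuration
(`ActivationModel.from_config`). For generator-driven tests,
`calibrated_model` builds a model along the matched-filter direction
(coefficients proportional to each pair's active-minus-inactive
distance change) scaled so the noiseless active and inactive
geometries map to 75 and −25 — round values that straddle the
classification thresholds with comparable margins.

Classification uses two thresholds, 0 and 55. The defining
inequalities are strict on both sides, which leaves the boundary
values unassigned; both are mapped to "partial" so the three intervals
partition the real line (a measure-zero convention that keeps
`classify` total).

Distribution summaries use a 60-bin histogram over the padded data
range (5% padding each side) and a Gaussian KDE with Silverman's
bandwidth; modes are KDE local maxima above a prominence fraction
(default 5%) of the global maximum. The SD attached to a summary is
always the blocking plateau, never the naive SD of the mean, because
frames are autocorrelated. Whether an index should be computed on all
frames or a strided subset is left to the caller; all operations
accept any frame spacing.

## Blocking averages

Each pair-averaging step halves the series (`x′ᵢ = (x₂ᵢ₋₁+x₂ᵢ)/2`,
odd trailing elements dropped — averaging a triple instead would bias
the block means). Per level, `s_ℓ = √(var(x⁽ℓ⁾)/(n_ℓ−1))` with
population variance, and `e_ℓ = s_ℓ/√(2(n_ℓ−1))`. Levels stop at 4
blocks, below which the variance of the variance is undefined.

Plateau detection places ℓ\* just after the last *significant rise*,
i.e. the last consecutive pair with `s_{ℓ+1} − s_ℓ > e_ℓ + e_{ℓ+1}`.
An earlier design required all post-plateau levels to agree pairwise
within ±1e, but that criterion is statistically self-defeating: at the
true plateau the estimates scatter by exactly their error bars, so
with ~10 levels some pair essentially always disagrees, pushing the
detected plateau into the noisy tail. The rise criterion reproduces
the textbook behaviour (ℓ\* = 0 for iid data; ℓ\* at the level where
blocks exceed the correlation time for AR(1)). A curve is flagged
converged only when the plateau spans ≥ 3 levels **and** starts with
≥ 32 blocks; with fewer blocks the error bars are wide enough to mask
a still-rising curve (verified on AR(1) with autocorrelation 0.999 at
series lengths far below its correlation time).

## Microswitch distances

Anchors are `(residue, atom)` pairs. When a pair is declared by helix
names only, the anchor defaults to the Cα one third of the way into
the helix range — the cytoplasmic side, where class-A activation
microswitches rearrange — and is overridable per pair, since published
analyses rarely state their anchor atoms. The distribution's *peak*
(KDE argmax), not its mean, is compared against reference distances,
matching how such distributions are read in practice. Overlap
coefficients are computed on a shared grid (union of ranges, 60 bins);
pre-binned densities on mismatched grids are an error rather than
silently rebinned. Reference distances shipped in the demo config are
placeholders computed from this package's own default active geometry,
standing in for experimentally derived values the user should supply.

## Contact maps

A residue is in contact when any scoped atom lies within the cutoff
(inclusive ≤, the standard heavy-atom convention) of any ligand atom;
default 3.5 Å. The default atom scope is side-chain heavy atoms;
Cα-only structures (the synthetic fixtures) automatically fall back to
Cα with a logged warning. The analysis window is anchored to the
trajectory end (default last 40 ns), the boundary frame included.
Distance queries use a KD-tree over ligand atoms and are tested for
exact equality against an all-pairs scan. No periodic-boundary
minimum-image convention is applied: inputs are assumed imaged and
whole; a PBC-aware mode is explicitly out of scope.

## Synthetic generator

The generator emulates the *statistical* structure of TM-bundle MD —
state-dependent helix packing, autocorrelated fluctuations, rare
active/inactive transitions, a persistent pocket ligand — not its
physics. Protein representation is Cα-only: the analysis operators
take atom selections, so atomic detail is a fixture choice, not an
operator limitation.

Geometry: seven ideal Cα helices (1.5 Å rise/residue, 100°
twist/residue, 2.3 Å radius, vertical axes). Axis positions in the
membrane plane are obtained by classical multidimensional scaling of
the 7×7 target inter-axis distance matrix (exact for embeddable
matrices); a relative Frobenius stress above 5% is an error reporting
the stress, never silently repaired. A 2-D (membrane-plane) embedding
was chosen over 3-D because TM bundles are axially aligned. The two
state layouts are Procrustes-aligned so that switching states
displaces only helices whose targets differ. The default geometry
places the axes on an 11.5 Å-radius heptagon (adjacent spacing
≈ 10 Å, typical bundle packing) and moves TMD6 4 Å toward the core in
the inactive state — the classic inward TMD6 motion — giving target
changes of −3.9 Å (TMD6–TMD3) and −1.0 Å (TMD6–TMD5). Off-diagonal
targets below a 6 Å packing floor are rejected.

Dynamics: the hidden state follows a two-state Markov chain
discretised at dt (switch probability `1 − exp(−k·dt)` per step); each
axis coordinate follows an exact-discretisation OU process with
relaxation time τ and stationary SD σ relaxing toward the current
state's layout ("mean-switching OU"). Transitions therefore relax over
~τ rather than teleporting, which mimics the gradual index drift seen
in real trajectories — and has a measurable consequence: a fraction
≈ 1.3·τ·(transition rate) of frames sits in the partial band during
relaxations, slightly depressing recovered active/inactive
occupancies. Ligand atoms are carried rigidly (the pocket ligand does
not diffuse), so contact occupancy fluctuations come entirely from
helix motion.

Defaults (τ = 5 ns, σ = 1 Å, k = 0.005 ns⁻¹, dt = 0.1 ns) describe a
flexible wild-type-like bundle whose index distribution is broad and
multi-state at desk-scale trajectory lengths; the demo config models
the mutant system as rigidified (σ = 0.6 Å, k = 0.002 ns⁻¹).
Ground-truth recovery tests tighten σ to 0.15 Å and slow the switching
so the state means are separated by ≫ 6 index SDs — the regime in
which label occupancy is a faithful estimator of hidden-state
occupancy (verified to 2% at 50 000 frames; the residual bias is the
relaxation effect above).

What passing these tests does *not* show: fidelity to force-field
energetics, side-chain packing, membrane coupling, or ligand-pose
stability. The generator validates the *analysis operators*, not MD
itself.

Ligand placement searches, per declared pocket residue, a
deterministic 400-direction grid for the atom position within reach
(0.92 × contact distance) that maximises clearance from all non-pocket
atoms, and fails loudly (reporting the best clearance) when the
required margin — below the contact distance for pocket residues,
above contact + 1 Å for everything else — is geometrically
infeasible. This pins the frame-0 contact set down exactly, which is
what makes the contact-map examples self-verifying.

## Assay statistics

The 4PL model is fitted by least squares on log₁₀(EC50) (which
enforces EC50 > 0 and conditions the problem), with multi-start
initialisation over hill ∈ {0.5, 1, 2} × EC50 at the positive-dose
quartiles; the best converged start wins and failure leaves an honest
`converged=False` with NaN parameters. Zero doses are handled by the
parameterisation's own limit (response → bottom), not dropped. EC50
standard errors use the delta method from the log-EC50 covariance.
Parameter recovery at the packaged truth blocks (EC50 0.18 nM and
11.3 nM, 8 log-spaced doses, triplicates, 5% CV) is tested at 3 fitted
SEs, and the 200-seed median relative EC50 error is below 10%.

Assay noise is mean-one multiplicative log-normal
(σ_ln = √ln(1+CV²), mean-corrected), so the expected response equals
the truth curve at every dose. Group contrasts use Welch's
unequal-variance t-test (the safer default when only "unpaired t-test"
is specified); multi-condition comparisons use one-way ANOVA followed
by Welch pairwise tests with Holm's step-down adjustment, implemented
directly (sort, multiply by m−i, enforce monotonicity, cap at 1) and
cross-checked against statsmodels in the tests. Replicate nesting
(experiments × technical triplicates) is not modelled; contrasts
operate on experiment-level values.

## Pipeline and reproducibility

Per-replicate seeds derive from the global seed via
`SeedSequence([seed, system_index, state_index, replicate_index])`, so
adding a system or replicate never perturbs existing ones. All floats
are written with a fixed `%.6g` format and every output carries the
SHA-256 hash of the canonical config dump, making runs byte-for-byte
reproducible and config drift detectable. The demo configuration uses
600-frame (60 ns-equivalent) replicates and 8-residue-per-helix test
bundles where only geometry statistics matter; these sizes were chosen
so that the full suite and demo pipeline run in seconds while leaving
every statistical test with comfortable margins.

## Known limitations

- The packaged activation model is a synthetic calibration; real
  analyses must supply published coefficients as config.
- Reference TMD–TMD distances in the demo config are placeholders
  derived from the package's own geometry, not experimental values.
- No PBC handling, no solvent/membrane, no kinetics beyond the hidden
  two-state chain; free-energy surfaces and transition-path analysis
  are out of scope.
- The variant catalogue records rescue outcomes at the granularity of
  three classes; it does not attempt pathogenicity prediction or
  structure mapping.
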