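# Methods

This note documents the models implemented in `synucleo`, their parameter
defaults, the design choices made where the definitions left room, and what
the synthetic generators do and do not emulate.

## Structural metrics (`fibril_metrics`)

**Contact maps.** Residues i, j are in contact when a distance between them
is strictly below the cutoff (default 6.5 Å). The phrase "distance between
residues" is ambiguous between *minimum inter-atomic distance* and
*residue centre-of-mass distance*; we default to the minimum-atom-pair
reading (standard contact-map practice) and expose `method="residue_com"`
for the alternative. Within a chain, pairs closer in sequence than
`min_sequence_separation` (default 1, i.e. only self-pairs) are excluded;
inter-chain pairs are always eligible.

**Hydrogen bonds.** A bond X–H···Y requires d(X,Y) < 3.5 Å and an angle at
the hydrogen ∠(X–H···Y) > 135°, both strict. Donors and acceptors default
to N and O; hydrogens are assigned covalently to the nearest donor-element
atom within 1.2 Å. Models without hydrogens raise an explicit error rather
than silently returning nothing. The angle is measured at H (the natural
reading of "the X–H···Y angle"); inter-subunit bonds are those whose donor
and acceptor chains differ, and the identity inter = total − intra is
enforced and cross-checked against direct counting.

**Salt bridges.** SB = Σᵢⱼ Sᵢⱼ with Sᵢⱼ = 1 iff |rᵢ − rⱼ| − d₀ ≤ 0,
d₀ = 4.5 Å. Note the asymmetry with contacts: the salt-bridge criterion is
*inclusive* (r − d₀ ≤ 0 ⇒ a pair at exactly 4.5 Å counts) while the contact
cutoff is strict; each follows the letter of its own definition. Selectors
default to Lys Nζ (positive) vs Glu Cδ (negative) only — the atom pair the
experiment names — and are user-widenable to Arg/Asp/His.

**Subunit distances.** Per-frame Euclidean distance between chain centres
of mass. The atom set behind published inter-subunit distances is not
stated, so the scope is selectable (`CA` default, `backbone`, `all`); mass
weighting uses standard atomic masses when elements are known, unit masses
otherwise. We implement the operator without claiming to reproduce any
specific published MD trace.

**Secondary structure.** Kabsch–Sander backbone H-bond energies
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a bond iff
E < −0.5 kcal/mol (the published constant). Missing amide hydrogens are
reconstructed 1.0 Å from N along the direction bisecting C(prev)→N and
CA→N. Two consecutive n-turns (n = 3, 4, 5) mark a helix; Kabsch–Sander
parallel/antiparallel bridge patterns mark strands; helix takes priority;
everything else — including residues with missing backbone atoms, which
are warned about — is coil. The 8-state alphabet is reduced to 3 states as
{H,G,I}→H, {E,B}→E, else C, matching the β-sheet/coil reporting
granularity of the experiments. Windowed averaging reports, per residue,
the fraction of in-window frames carrying each label (frame-index or
time windows, e.g. a 200–500 ns production tail).

## Aggregation kinetics (`agg_kinetics`)

The Boltzmann sigmoid is implemented literally as
y = (A₁ − A₂)/(1 + e^((x−x₀)/dx)) + A₂ via the numerically stable logistic.
Fitting is Levenberg–Marquardt least squares with the data-driven start
(A₁ = min y, A₂ = max y, x₀ = time nearest mid-amplitude, dx = span/10) and
up to 5 deterministic jittered restarts (fixed internal seed, best residual
kept); non-convergence returns a diagnostic fit object rather than raising.
Noiseless curves are recovered to 1e-6 relative error; the fit is
equivariant under affine rescaling of the fluorescence axis.

Endpoint comparison averages each curve over a terminal window; the
published figures mark this window graphically without giving numbers, so
the default is the final 10% of the time axis, overridable as an explicit
(t_lo, t_hi). Group testing delegates to the `ephys_analysis` ladder when
every condition has ≥ 3 replicates.

## TEM classification (`tem_particles`)

Thresholds (350, 800, 2000) nm². Boundary reading: "smaller than" and
"larger than" strict, "between 350 and 800" inclusive — so 350 and 800 are
dimers and 2000 itself is unclassified. Particles ≥ 2000 nm² are reported
as `unclassified`, never dropped; non-positive areas are rejected with a
warning. Fractions are over classified particles and sum to 1.
Classification is total and monotone in area (growing a particle never
demotes it).

## Electrophysiology (`ephys_analysis`)

**Detector.** The published analyses used proprietary software whose
algorithm is unpublished, so the detector here is a documented
threshold-plus-slope rule: moving-average smoothing (default 2.5 ms),
running-median baseline (1 s window, computed with an efficient rolling
median), candidate runs where the baselined trace passes the amplitude
threshold (default 20 pA, inward polarity) merged when closer than
10 ms, and a rising-slope gate (default 5 pA/ms). Amplitude is read off
the raw baselined trace at the smoothed-peak sample. Events larger than
5× the median amplitude are flagged "spike-like" (the distinction is
visual in the source experiments); inhibitory and excitatory currents are
not separated. Detector defaults are matched to the generator presets: the
recovery results quantify the generator→detector loop, not a reproduction
of the original event picking.

**Charge.** Charge transferred is |∫(I − baseline) dt| over the whole
recording, converted pA·s → nC (×10⁻³). The signed integral is used
(standard Q = ∫I dt practice): point-wise rectification would add a
noise-dependent bias of ~σ√(2/π) per unit time (≈1.2 nC per 300 s at the
default 5 pA noise), which would be of the same order as the quantities
of interest. With the signed form the noise cancels in expectation and
the statistic is exactly invariant to constant offsets.

**Statistics ladder.** Shapiro–Wilk per group and Levene (mean-centred)
across groups at α = 0.05. Two groups: unpaired two-tailed t-test when both
are normal (Student form when Levene accepts, Welch form otherwise), else
two-tailed Mann–Whitney U. More than two groups: ordinary one-way ANOVA
with Bonferroni-adjusted pairwise t-tests when variances are homogeneous;
Welch's ANOVA (statsmodels `anova_oneway`, unequal variances) with
Dunnett's T3 post hoc when Levene rejects. No installed library provides
T3, so it is implemented as pairwise Welch t statistics with
Welch–Satterthwaite degrees of freedom and the studentized-maximum-modulus
family-wise adjustment in its Šidák form p_adj = 1 − (1 − p)^m; this is
mildly conservative relative to exact SMM tables. Under the null
(10,000 two-group simulations, n = 10) the ladder's empirical type-I error
sits within [0.03, 0.07].

## Synthetic generators (`synthetic_data`)

All generators are deterministic functions of (parameters, seed).

**Fibril.** Six chains by default (the hexameric fibril arrangement),
exact translates stacked at a 4.8 Å rise — a design parameter of the
fixture, not a claim about any deposited structure. The scaffold is
geometric rather than chemically ideal: atom placements are chosen so
that every residue of chain c ≥ 1 donates exactly one N–H···O bond to
chain c−1 (X–Y = 3.16 Å, angle 153°), each planted Lys Nζ–Glu Cδ column
gives one 4.0 Å pair per adjacent chain interface (the intra-chain Nζ–Cδ
distance, 5.6 Å, stays outside the 4.5 Å criterion), and nothing else
meets either criterion. Ground-truth counts are returned alongside the
structure and verified by the metric operators in the test suite, closing
the loop between the forward and inverse models. The dissociation
trajectory translates the first subunit away from the stack on a linear
schedule (optional seeded thermal jitter), leaving all other chains fixed.

**Ideal backbones.** `make_ideal_backbone` builds poly-peptide N/CA/C/O
geometry from standard internal coordinates at uniform (φ, ψ); it provides
the α-helix and extended-chain oracles for the secondary-structure rules.

**ThT curves.** Forward evaluation of the Boltzmann model plus Gaussian
noise. The published fitted parameters are not printed, so preset values
(A₁ = 0, A₂ = 100 on the percent-of-maximum scale, x₀ = 15 h, dx = 2 h for
the aggregating protein; plateau scaled down with inhibitor ratio; flat
for the non-aggregating homolog) are illustrative design choices over the
35 h assay window.

**Particles.** Multinomial class membership at the preset proportions —
(0.93, 0.06, 0.01) for the non-aggregated preparation and
(0.88, 0.11, 0.01) for the oligomerised one, the printed monomer/dimer
values with the small remainder assigned to the unprinted class — with
areas uniform within each class's threshold-aligned range.

**Recordings.** Homogeneous Poisson onsets at the preset rate; log-normal
amplitudes with the printed mean and CV 0.4; unit-peak biexponential
kernels (rise 2 ms) superposed as inward deflections on 5 pA Gaussian
noise at 2 kHz sampling. Rate, mean amplitude and whole-recording charge
are all printed per condition and are jointly satisfiable only if the
kernel area is treated as the free parameter: the kernel decay is solved
per preset from charge = rate × duration × mean event area at preset-load
time (reference duration 300 s — recording durations are not published, so
all rates are duration-normalised). Presets without a printed charge
(miniature conditions) use a 10 ms decay; miniature presets whose
amplitude is unprinted reuse the control amplitude, as no significant
amplitude differences were reported for them. CV, rise/decay and noise SD
are typical hippocampal PSC values, exposed in `data/presets.yaml`.

What the generator does **not** emulate: bursting/non-Poisson timing,
separate spike-like event populations, rundown or drift, access-resistance
artefacts, correlated noise, and any difference between excitatory and
inhibitory currents. Passing recovery tests therefore demonstrates that
the analysis chain is unbiased under these idealised conditions, not that
it reproduces the original recordings' event-by-event content.

## Pipeline (`cli_pipeline`)

Stages run in declared order; the single global seed is expanded into one
`SeedSequence([seed, stage_position])` substream per stage (counter
scheme), so toggling stages does not reshuffle the randomness of the
others, and identical (config, seed) reruns are byte-identical. Unknown
stages fail validation before execution; stage failures halt with a
stage-scoped error.

## Problem sizes

The test suite and recovery script run at desk scale by design: 100 random
≤ 200-atom structures for the brute-force oracle suites, 50 parameter draws
for sigmoid recovery, 5–10 recordings of 300 s per condition preset at
2 kHz, 500-particle TEM draws (10,000 for convergence checks), and 10,000
two-group null simulations for the ladder's type-I calibration.

## Known limitations

* The secondary-structure assigner implements the turn/bridge core of the
  DSSP algorithm, not its full 8-state bookkeeping (π/3₁₀ boundary cases,
  bends, chirality); for the H/E/C reduction used here this is sufficient.
* mmCIF support is minimal (atom_site loop, first model, altloc A/blank);
  NMR-style multi-model files are treated as trajectory frames.
* Compressed/binary trajectory formats are out of scope; converting
  production MD output to multi-model PDB or XYZ is the user's task.
* Dunnett's T3 p-values use the Šidák-form SMM approximation (slightly
  conservative).
* The event detector is not a reimplementation of any proprietary
  software; parameter choices that matched the original analyses are
  unknowable from the published record.
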