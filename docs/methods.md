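# Methods

## Mass model

A proteoform is a set of independently hydrolyzed backbones plus crosslinks
and modifications.  Each chain contributes the sum of its residue masses
plus one water; every crosslink — disulfide or the Cys–His thioether
characteristic of plant catechol oxidases — removes two hydrogens
(2 × 1.00794 Da average, 2 × 1.00783 Da monoisotopic).  Under reducing
conditions the disulfide term is zeroed while the thioether term is kept,
matching the chemistry (DTT opens S–S bonds, not the thioether).  The
proton is 1.00728 Da with the electron mass neglected; at the four-decimal
precision of the peptide-scale comparisons this convention matters and was
chosen to be consistent with the reported doubly charged ion value.

Scale convention: intact-protein species are computed and compared on the
average scale (isotope envelopes are unresolved at 40–60 kDa), peptide-level
species on the monoisotopic scale.  The generic "+80 Da" mark seen on the
active enzyme is modelled as exactly +80.00 Da on the average scale; its two
chemically plausible identities (phosphorylation, +79.96633 mono;
sulfation, +79.95682 mono) are carried as co-ranked candidates and never
resolved — intact mass cannot distinguish them.

Coordinates are 1-based inclusive on the mature protein, the transit
peptide having been removed before any computation.  Cysteines are free
thiols unless consumed by a declared crosslink; crosslink counts per
topology (2 internal disulfides, +1 linking the attached peptide, thioether
always 1) are declared in the search space rather than inferred from
cysteine positions.

## Charge deconvolution

Electrosprayed intact proteins appear as envelopes of [M + zH]z+ ions.  For
any peak pair a > b the adjacent-charge relation z = (b − H⁺)/(a − b) gives
a candidate integer charge; a pair is accepted only if both members map to
the same neutral mass within the cluster tolerance.  Accepted candidates
are clustered by single linkage (default tolerance 1.0 Da for intact mode,
0.02 Da for peptide mode, chosen to match the experimental spreads of
±0.3–1.7 Da), and each cluster is summarized as the intensity-weighted mean
± weighted sd.  Estimates supported by fewer than two charge states are
discarded: a single peak is underdetermined.  Default charge windows are
20–60 (intact) and 1–4 (peptide).

The synthetic spectra are centroided sticks with Gaussian m/z jitter; no
isotopic fine structure, peak widths, or baseline are emulated, so passing
round-trip tests demonstrate correctness of the charge inference and
clustering, not robustness to profile-mode artifacts.

## Proteoform search

The hypothesis space is the Cartesian product of: core C-terminus positions
(ragged by unspecific proteolysis) × attached-peptide presence and end
positions × modification counts × reduction condition, plus uncleaved
latent variants over their own C-terminal window.  Only C-terminal
raggedness is enumerated; all observed species share the mature N-terminus.
Matching tolerance defaults to max(3σ_obs, 0.5 Da) for intact species and
5 ppm at peptide scale.  Assignments are ranked by |Δmass| with parsimony
tie-breaks (fewer modifications, then fewer chains), so oxidized
satellites (+16 k Da, k ≤ oxidation_max, default 3) never outrank an
unmodified hypothesis at equal error.

Mass-shift explanation enumerates combinations of at most two known deltas
(the +80 candidates, oxidation, water, one crosslink's 2H, single-residue
losses) within a caller tolerance, sorted by error.

## Synthetic stand-in sequence

The real enzyme's database accession is not bundled, so
`synthetic_data.SYNTHETIC_AUS1_MATURE` provides a 517-residue stand-in
labelled synthetic throughout.  Its anchors are real: the mature N-terminus
"API", the core C-terminus "…IENSKE", the attached peptide DGVFTTPCDPEYAGG
at 438–452, and the latent C-terminus "…PIPKA".  The composition between
anchors was solved (meet-in-the-middle subset-sum on average residue
masses) so that the four reference proteoforms — active core//peptide with
3 disulfides + thioether; reduced core with thioether only; latent
pro-enzyme; latent minus its final alanine — reproduce the published
calculated masses within 0.003 Da.  The implied architecture (350-residue
core, 87-residue linker removed on activation, 65-residue tail) is the only
one arithmetically consistent with those masses and with the ~19 kDa
shielding domain.  Only the mass arithmetic is faithful; the composition is
not biological, and tests against this sequence validate bookkeeping, not
database identity.

## Kinetic models

**Initial rates.**  v = Vmax·S/(Km + S) is fitted by Levenberg–Marquardt
(lmfit) with standard errors from the covariance at the optimum.  Fits are
flagged non-converged when Km exceeds 10× the largest substrate
concentration — with S ≤ 75 µM such data cannot constrain saturation.  For
low-affinity substrates kcat/Km comes from a through-origin line fit in the
[S] ≪ Km regime; the systematic bias of this estimator is bounded by
max(S)/Km, and a lack-of-fit check (t-test on an added quadratic term, 5 %)
warns when curvature says the regime assumption fails.  kcat conversion
requires an explicit enzyme molarity or molar mass: no default is supplied
because mass-specific and molar activity scales cannot be interconverted
without knowing which species (active ~41.6 kDa or latent ~58.9 kDa) the
preparation contained.

**Suicide inactivation.**  The enzyme dies during catalysis, so product
approaches a plateau proportional to enzyme: P(t) = r·E0·(1 − e^(−k_obs t)),
with partition ratio r = P_∞/E0.  This is the minimal model reproducing the
two observed facts (decelerating curves; plateau ∝ enzyme) — the source
data show the phenomenon without giving an equation, so the exponential
form is this package's own declared choice.  The fitter warns when the
last-decile slope exceeds 10 % of the initial slope (no plateau in view).

**Threshold activation of the latent enzyme.**  dP/dt = v_spec·E0·(a0 +
(1 − a0)·min(P/c\*, 1)): the active fraction rises linearly from the basal
few percent (a0, default 0.03) to 1 at the critical product concentration
c\*.  Again the minimal form reproducing the three observations:
enzyme-dependent lag, enzyme-independent onset product level, and a
basal-rate-only response for non-activating (chalcone) substrates.
Ultrasensitive/quadratic variants are out of scope.  The simulator
integrates with fixed Euler steps bounded by 0.01·c\*/(v_spec·E0)
(default: one fifth of the bound), rejecting larger caller-supplied steps;
the synthetic generator instead uses the piecewise analytic solution, so
generator and simulator are independent code paths.

**Critical-concentration estimation.**  Per curve, signals are smoothed
(Savitzky–Golay, window 31, order 3, when long enough), the running slope
is taken by finite differences, and the steady-state slope s∞ is the median
over the last 15 % of points.  The transition is located at the first
95 %-of-s∞ crossing; because the model's running slope is affine in P below
c\*, the slope-vs-product line fitted over the rising phase is extrapolated
to its 100 % crossing, which removes the (1 − threshold)/(1 − a0) downward
bias a raw 95 % read-off would have and recovers c\* exactly on noiseless
curves.  Curves with no resolvable transition (e.g. purely linear,
non-activating) are excluded with a warning; the across-curve mean is
flagged inconsistent when the spread exceeds 15 % of the mean.

Units: concentrations µM internally, enzyme nM, time minutes; Km is also
exposed in mM for comparability with tabulated constants.  Noise models:
multiplicative Gaussian on rates (instrument-relative error),
additive Gaussian on progress-curve signals.

## Synthetic study conditions

The packaged defaults mirror the characterized assays: two intact species
at 41,559.0/41,639.0 Da mixed 1.4:1 over charges 25–45 (instrument accuracy
better than 5 ppm; the reference deconvolution scenario uses noiseless
sticks); butein initial rates with Km = 52 µM, Vmax = 489, 8 concentrations
spanning 10–75 µM, 4 replicates, 3 % multiplicative noise; suicide ladders
at 1.2/0.6/0.3/0.15 nM enzyme; latent activation at 7.2/3.6/1.8/0.9 nM with
c\* = 23 µM, basal fraction 0.03, and v_spec = 2 µM min⁻¹ nM⁻¹ (order of
magnitude of the fisetin assay at 50 µM substrate), sampled on 400 points
per curve up to three threshold-levels of product with 1 % (of c\*) additive
noise.  Substrate depletion is deliberately not modelled; curves are only
simulated into the early steady-state region where the threshold estimate
lives.

## Numerical and rounding choices

Integer coverage percentages use round-half-up, under which 441/517 → 85
while 272/350 → 78; a source that prints 77 for the latter evidently
truncated, and this package reports both the exact float and the
round-half-up integer rather than matching a floor convention.  Peptide
matching in coverage is exact substring, case-insensitive, I/L not equated.
Digest follows the conventional trypsin rule (C-terminal to K/R, suppressed
before P).  All generators take integer seeds and use numpy's PCG64;
identical spec → identical output on any platform.

## Known limitations

No isotope-level simulation, vendor raw formats, or profile-mode peaks; no
peptide-spectrum matching or modification-site localization (the +80 site
assignment requires MS/MS, out of scope); no mechanistic copper-state or
activation-chemistry model — the threshold model is phenomenological; the
stand-in sequence validates arithmetic only.  Passing tests on synthetic
data show the estimators are correct under the stated noise models, not
that real instrument data meet those models.
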