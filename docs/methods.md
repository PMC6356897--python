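# Methods

## Scientific problem

Thioredoxins reduce protein disulfides through a conserved WC(G/P)PC active
site whose two cysteines play asymmetric roles: the N-terminal cysteine
(CysN) performs the first nucleophilic attack and the C-terminal cysteine
(CysC) resolves the mixed disulfide. Because only the thiolate (deprotonated)
form is nucleophilic, each cysteine's acid dissociation constant (pKa)
controls its reactivity. `thiolprobe` implements the analysis used to measure
those pKa values for a two-cysteine thioredoxin by differential iodoacetamide
(IAM) alkylation read out with intact-protein MALDI-TOF mass spectrometry,
together with the supporting mass arithmetic, inactivation-kinetics analysis,
and active-site geometry computations.

## The measurement model

IAM carbamidomethylates cysteine thiolates irreversibly (+57.02146 Da
monoisotopic, +57.0513 Da average, per site). The alkylation rate of a site
at a given pH is

    k_obs(pH) = k_int * alpha(pH),    alpha = 1 / (1 + 10**(pKa - pH))

where `k_int` (M^-1 s^-1) is the intrinsic second-order rate constant of the
thiolate toward IAM and `alpha` is the Henderson–Hasselbalch thiolate
fraction. The protein alkylates strictly sequentially — reduced -> mono ->
di — because only CysN reacts in the reduced protein (confirmed in the
source experiments by MS/MS localisation of the single label), and CysC
reacts only in the monoalkylated species.

Running a fixed-time alkylation at a ladder of pH values and quantifying the
species by MALDI peak areas converts the titration of each thiol into a
sigmoid of species fractions vs pH:

    F(pH) = bottom + (top - bottom) / (1 + 10**(pH - pKa))

Stage 1 (IAM/protein = 2, 105 s) follows the *non-alkylated* fraction, whose
midpoint estimates the CysN pKa; stage 2 first monoalkylates completely at
pH 7.1, then follows the *monoalkylated* fraction under IAM/protein = 10 for
2 min, whose midpoint estimates the CysC pKa.

## Kinetic forward models

`alkylation_kinetics` provides two integrators for the sequential scheme:

* **Pseudo-first-order closed form** (IAM constant): with k1, k2 the two
  effective first-order coefficients, fR = exp(-k1 t), fM = k1/(k2-k1)
  (exp(-k1 t) - exp(-k2 t)), fD the balance. When |k1-k2|/max < 1e-8 the
  degenerate limit k1 t exp(-k1 t) is used for stability.
* **Reagent-depletion ODE** (default at the protocol's low IAM/protein
  ratios of 2 and 10): the free IAM concentration is eliminated through the
  stoichiometric balance [IAM] = IAM0 - P0 (fM + 2 fD) and the three protein
  fractions are integrated with an adaptive explicit Runge–Kutta (scipy
  `solve_ivp`, RK45, rtol 1e-9, atol 1e-12). Tests validate it against an
  independent four-state integration that carries IAM explicitly.

Temperature, ionic strength and buffer identity are not modelled; pH is
taken as exact.

## Spectrum model and quantification

Synthetic linear-mode spectra are sums of Gaussians centred at the species
masses (base mass 11,712.6 Da plus 57.05 Da per carbamidomethyl group), with
*areas* proportional to species fractions, an optional matrix-adduct
satellite at +206.2 Da carrying 0.15 of its parent's area, and additive
zero-mean Gaussian noise clipped at zero. Defaults: peak sigma 6 Da
(linear-mode resolution at ~11.7 kDa); the adduct offset is a convention,
not a measured value — the adduct identity is matrix/instrument dependent.

Quantification integrates a trapezoidal window of half-width
min(3 sigma, half the gap to the nearest declared peak, adducts included)
around each expected mass, after subtracting a linear baseline anchored one
sigma *outside* each window edge (median over a +/- sigma/2 band). Anchoring
outside the window keeps the Gaussian tail inside the window from being
clipped: an isolated peak integrates to 0.9973 of its total area (the
+/- 3 sigma mass), and the residual anchor-level bias is below 1e-3.
Fractions are area ratios under the equal-response assumption — the central
quantification assumption of converting MALDI peak areas to mole fractions.

## Titration fitting

`fit_hh` minimises unweighted squared residuals of the four-quantity sigmoid
over (pKa, top, bottom), with either plateau optionally fixed, using
Levenberg–Marquardt (scipy `least_squares`, method `lm`, tolerances 1e-12).
Initialisation is deterministic: pKa0 from linear interpolation of the pH at
the half-range fraction, plateaus from the observed extremes. The pKa
standard error comes from the Gauss–Newton covariance (J^T J)^-1 scaled by
residual variance; when replicates are present, per-replicate fits also give
an across-replicate SD, so the uncertainty can be read either way. Replicate
points enter individually, untransformed and unweighted.

For partial sigmoids (stage-2 data stop at pH 10, well short of the lower
plateau) the top plateau is fixed at 1; a fully free fit on data that sample
neither plateau takes a warning path (SE > 0.3 or non-convergence).

## Synthetic experiments

`synthetic_data` generates complete in-silico experiments. Defaults are the
study conditions: pH grid 4.5–10 step 0.5; 3 replicates in stage 1 and 2 in
stage 2; fraction noise sd 0.03; stage-1 concentrations from the protocol's
dilution arithmetic (48.3 uM protein, 100 uM IAM, 105 s); stage-2 at the
stated IAM/protein ratio of 10 (385 uM IAM, 38.5 uM protein, 120 s) with
pre-monoalkylation idealised as 100% complete. Intrinsic rate constants are
*not* reported quantities; the default k_int = 100 M^-1 s^-1 for both sites
(the reactivity difference carried entirely by the pKa values) makes stage-1
monoalkylation partial on the 105 s timescale, matching the qualitative
time-course behaviour. Absolute time courses are therefore only qualitative.

Two generators are kept deliberately distinct:

* the **phenomenological** generator draws fractions from the same sigmoid
  the fit assumes (model-matched, unbiased) — used for pKa-recovery checks;
* the **kinetic** generator integrates the depletion model per pH and
  exposes the *endpoint-saturation bias* inherent in any fixed-time
  protocol: when conversion saturates, the apparent midpoint shifts below
  the true pKa. Tests assert both the unbiased sub-saturating regime and
  the direction of the bias.

What the generators do **not** emulate: buffer-specific chemistry, MALDI
shot-to-shot and calibration drift, detector saturation, isotope structure,
peak asymmetry, and unequal ionisation response between species. Passing
round-trip tests therefore demonstrate correctness of the analysis under
its own assumptions, not robustness to every instrumental artefact of real
spectra.

## Inactivation analysis

The DTNB assay converts A412 slopes to TNB formation rates with
epsilon_412 = 14,150 M^-1 cm^-1. Inactivation constants are fitted by OLS of
ln(activity) on time within a linear window (default 0–3 min). The pH
profile of residual activity is modelled as single-site Poisson survival,
residual = exp(-k_int alpha(pH) [IAM] t): activity loss is attributed
entirely to CysN alkylation, justified because CysC (pKa ~9.5) stays
protonated across the assayed pH range. With an anchor point the profile
shape is parameter-free; agreement with measured percentages is treated as
qualitative (ordering plus ~0.15 absolute) because absolute rates depend on
unreported intrinsic constants and reagent depletion.

## Structure geometry

`structure_site` provides the kernels for active-site analysis: Euclidean
distances; distance-only hydrogen-bond inventories (polar heavy atoms within
4.0 A, no angle criterion); Kabsch superposition by SVD with the determinant
correction enforcing a proper rotation, all point pairs entering (no outlier
rejection); and Shrake–Rupley SASA on a deterministic golden-spiral lattice
(960 points, probe 1.4 A) with a united-atom radii set (C 1.87, N 1.65,
O 1.40, S 1.85 A — configurable). Because published ASA values depend on the
program and radii used, absolute ASA agreement should be expected only to a
few percent. Chain-pair bookkeeping defines buried area ASA_A + ASA_B -
ASA_AB and interface area as half of it. PDB input goes through gemmi;
alternate locations keep the highest occupancy (ties: first altloc
alphabetically); author residue numbering is used verbatim.

## Problem sizes and numerical choices

Tests run the titration ensemble at 200 series, the spectra round-trip at 50
seeds, and the quaternion-grid superposition oracle with ~9,000 rotation
samples plus local refinement; these sizes give stable statistics while
keeping the whole suite in a few seconds. Nominal integer masses round half
away from zero (so +57/+114/+160 Da emerge exactly). Degenerate inputs
(zero total peak area, all-zero activity, collinear point sets, missing
elements in the radii table) raise named errors rather than returning
silent values.

## Known limitations

* The construct sequence behind the 11,712.6 Da parental mass is not
  derivable here; the base mass is an input parameter.
* Deposited crystal structures are optional inputs; the geometry kernels are
  validated against constructed fixtures and analytic oracles, not against
  the deposited coordinates themselves.
* Only carbamidomethylation and an internal disulfide (-2H) are modelled as
  modifications; charge states above 1+ and isotope envelopes are out of
  scope.
* The stage-2 protocol's printed dilution volumes imply IAM/protein ~8
  while its stated ratio is 10; the generator follows the stated ratio.
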