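# Methods

`maturex` implements the computational side of an antibody affinity-maturation
study: quantifying, for every mutation a VH domain acquired during directed
evolution, whether it helps or hurts antigen binding and whether it helps or
hurts thermodynamic stability. The raw observables are yeast-display flow
cytometry titrations (affinity), circular-dichroism thermal melts (stability),
and probe-particle simulation trajectories (surface hydrophobicity). A
synthetic-data module generates all three with known ground truth so the whole
pipeline is testable without instrument data.

## Binding isotherms

Mean APC-channel fluorescence of displayed antibody incubated at antigen
concentration `c` is modelled as a one-site saturable isotherm plus a linear
nonspecific term:

    APC(c) = APC_min + APC_sat * c / (c + K_D) + APC_ns * c

Parameters minimise the mean squared error; K_A = 1/K_D. Units are molar
throughout; signals are arbitrary fluorescence units.

The model has a well-known degeneracy: when K_D lies far above the tested
concentrations, `c/(c + K_D)` is nearly linear and trades off against
`APC_ns`. The fitter therefore multi-starts K_D on a 7-point log grid spanning
[min conc/100, max conc x 100], solves the three linear parameters by bounded
linear least squares at each start (APC_sat, APC_ns >= 0), polishes with
bounded nonlinear least squares in log10 K_D (bounds [min conc/1000,
max conc x 1000]), and keeps the best start. A final linear-subproblem polish
at the returned K_D guarantees the reported optimum is never beaten by its own
linear subproblem.

A fit is flagged **unmeasurable** when any of:

* fitted K_D > 10 x the highest tested concentration;
* fitted APC_sat < 3 x residual RMS (with a 1e-6-of-signal-scale floor so
  exactly noiseless flat data are caught);
* the saturable term fails a nested-model F-test against `APC_min + APC_ns*c`
  at alpha = 0.05. Without this test, noise can be absorbed into a spurious
  saturable component with a plausible mid-range K_D that passes the first two
  screens.

All three thresholds are configurable (`FitConfig`). Replicate K_A values are
summarised by mean and sample (n-1) SD over measurable replicates; a variant
is unmeasurable when more than half of its replicates are.

Fits require >= 5 distinct concentrations spanning >= 2 decades.

## Thermal melts

A melt is ellipticity (235 nm) vs temperature over 25-95 degC. The analysis
is deliberately model-light, matching standard practice for *apparent* melting
temperatures (no reversibility assumed, no dH/dG extracted):

1. **Baseline windows** are located from the data: the smoothed temperature
   derivative of the signal departs strongly from the baseline slopes inside
   the transition, so the windows are everything colder/hotter than the
   contiguous high-|slope| region around the derivative peak (with a
   smoothing-width margin). If no transition stands out, the coldest/hottest
   15% of the span are used. Windows never shrink below max(4 points, 10%).
2. **Baseline lines** start as OLS fits over those windows and are then
   refined by a global six-parameter two-state fit of the entire scan (two
   linear baselines mixed by a van't Hoff sigmoid, Santoro-Bolen style). Only
   the baseline parameters are kept from this fit. Rationale: with a
   transition near the scan edge the window-OLS slope is estimated from few
   points and extrapolated a long way, which was the dominant error source
   (heavy-tailed errors up to ~0.9 degC); the global fit conditions the
   baselines on every point. Users who want pure window-OLS pass explicit
   windows. The refinement assumes a two-state shape for the *baseline
   estimate only*; T_m* never comes from the sigmoid parameters.
3. **Fraction folded** f(T) = (theta - theta_U(T)) / (theta_F(T) - theta_U(T)),
   not clipped to [0, 1]. An error is raised if the baselines cross inside the
   scan or if their separation is within 5x the folded-window residual RMS
   (no discernible transition, e.g. a flat scan).
4. **T_m*** is where the least-squares line through the transition region of
   f(T) equals 0.5. The transition region is the contiguous band with
   0.35 <= f <= 0.65 containing the 0.5 crossing (the steepest crossing, if
   noise creates several), expanded symmetrically to at least 4 points --
   sharp transitions can put no points in the band, and this expansion is
   what makes an ideal step curve resolvable to one grid spacing. Bounds are
   configurable. r^2 of the regression is reported.

Replicate T_m* values are summarised by mean and sample SD (the study design
is two independent melts per sample). Only first-heating scans feed T_m*; a
second heating feeds only the reversibility check, which reports the ratio of
folded-baseline-window amplitude (relative to the first scan's unfolded
baseline) in the second scan vs the first.

Mean residue ellipticity uses the convention
`MRE = theta[mdeg] * MRW[g/mol] / (10 * l[cm] * c[g/L])` (default MRW
110 g/mol); results are invariant under affine signal transforms, so T_m*
does not depend on whether raw mdeg or MRE is supplied.

Measured accuracy under the synthetic conditions below: single-scan errors
~0.15 degC mean absolute (noise sigma = 0.3 mdeg), with replicate means of
two scans within +-0.5 degC of truth across all tested anchors.

## Trade-off classification

Each acquired mutation is probed by a single-reversion construct (evolved
context with that residue reverted to wild type). For each (mutation,
context) pair:

* delta = context - reversion for mean K_A and mean T_m*, so positive deltas
  mean the mutation contributes positively;
* significance by a two-tailed two-sample t-test on the replicate values.
  Default is the classical equal-variance test (df = n_a + n_b - 2); Welch is
  available by flag. n = 2 vs 2 gives df = 2 and is computed anyway, matching
  the study design of duplicate melts. The t statistic is computed explicitly
  so zero-variance degenerate cases are deterministic (p = 1 for equal means,
  p = 0 otherwise); p-values come from the t distribution. Stars: `*` iff
  p < 0.05, `**` iff p < 0.01, strict inequalities;
* classes: neutral iff p >= 0.05, otherwise enhancing/reducing (affinity) or
  stabilizing/destabilizing (stability) by the sign of delta; not-computable
  when either side's affinity is unmeasurable (the dagger convention).

No multiple-testing correction is applied, matching the source analysis; the
report writer can append Benjamini-Hochberg q-values on request. Classes are
invariant under affinity unit changes.

## Structural mapping

Trajectories are multi-model PDB files (angstrom on disk, nm in memory;
CRYST1 carries orthorhombic box lengths). Probe particles are recognised by
residue name (`PRB`/`CH4`, configurable); heavy atoms are non-hydrogen
non-probe atoms.

* **Superposition** is the Kabsch SVD solution restricted to proper rotations
  (no reflections); collinear selections raise. RMSD is reported after the
  fit. The default RMSD selection is backbone N/CA/C.
* **Greedy clustering** on a pairwise RMSD matrix: repeatedly take the frame
  with the most unassigned neighbours within the cutoff (default 0.2 nm,
  ties to the lowest frame index) as a centre, assign it and those
  neighbours to a new cluster, remove them, repeat. Cluster 0 is the dominant
  structure's cluster.
* **Probe density**: for each heavy atom, the mean over frames of the number
  of probe particles within the cutoff (default 0.5 nm; minimum-image
  distances when a box is declared, with cutoff <= half the smallest box
  length enforced). Frames are treated as independent samples. Raw mean
  counts are reported, writable into the B-factor column of a single-model
  PDB (probes excluded) with an optional linear rescaling for display.

## Synthetic data

Generators invert each analysis with the simplest adequate forward model, and
every generator is a deterministic function of (truth, seed); randomness is
split per (variant, replicate) via numpy `SeedSequence` spawn keys so adding
replicates never perturbs earlier ones.

* **Titrations**: the binding model plus i.i.d. Gaussian noise. Default
  design is 10 half-log concentrations bracketing K_D; default noise 20 a.u.
  (1% of the default 2000 a.u. saturation amplitude) -- instrument noise
  magnitudes are not published, so this is a synthetic convention. Default
  3 replicates.
* **Melts**: two-state van't Hoff with zero heat-capacity change,
  f(T) = 1/(1 + exp(-dH (1 - T/Tm)/(R T))) in Kelvin, mixed between sloped
  linear baselines (defaults: folded -0.01 T - 2, unfolded -0.002 T - 14
  mdeg), noise sigma = 0.3 mdeg, 25-95 degC at 0.5 degC, 2 replicates.
  dH defaults to 400 kJ/mol, a typical small-domain van't Hoff enthalpy; it
  is a generator knob only and is never estimated from data.
* **Trajectories**: i.i.d. frames (the analysis treats frames as samples, so
  no dynamics are simulated). Each probe is placed either uniformly in a
  0.35-0.5 nm shell around a randomly chosen designated "hydrophobic" atom,
  or uniformly in the box at >= 0.35 nm from every protein atom. The shell
  probability is calibrated from the shell/free-volume ratio so that
  designated atoms see `enrichment` times the background probe density.
  Defaults (80 probes, 6 nm box) echo the probe-simulation setup the
  generator emulates. The toy protein is a Fibonacci-sphere shell of heavy
  atoms, making all surface atoms symmetry-equivalent for uniformity tests.
* **The P-series study** (`gen_pseries_bundle`) emits a full synthetic
  lineage -- wild type, four evolved variants (P1-P4 with 4/7/9/12
  mutations), every per-round single-reversion construct, all twelve P4
  reversions, and a six-affinity-mutation scaffold -- plus titration and
  melt CSVs and a truth sidecar recording the generating K_A/Tm values and
  the trade-off classes they imply. Where the study reports numeric
  anchors (wild type 75.0, P1 73.2, P2 65.5, P3 63.3, P4 66.0 degC, the
  E45 and E98 reversions 70.9/62.4 degC, six-mutation scaffold 70.5 degC)
  those are the generating truths; unreported reversion effects carry
  invented values with effect sizes >= 2.5 degC so that the encoded
  stabilizing/destabilizing classes are statistically resolvable at n = 2
  melts and sigma = 0.3 mdeg (the df = 2 critical t is 4.30; smaller true
  effects would make the intended classes unattainable for any estimator at
  that noise). The P1 branch is generated below the affinity detection
  range (true K_D = 1e-2 M against a 1e-9 to 3.2e-5 M ladder); the
  strongly-enhancing R100d mutation's reversion is generated measurable but
  40-fold lower so its class is computable.

### The synthetic wild-type sequence

No full VH sequences are machine-readable from the study, so the lineage is
built on a **synthetic** VH3-consensus-style wild type (Kabat-numbered, 126
residues, insertions 82a-c and 100a-i). It satisfies every documented
constraint: the wild-type identities implied by the reversion names (L11,
E45, S50, S52, S62, D72, S82b, E98, G100d, V100f, V100g, I100h); an
Abeta(33-42) graft `GLMVGGVVIA` occupying Kabat 100-100i in CDR3 (so 100d=G,
100e=G, 100h=I, and the I100h reversion shows the 100e-GIIIA-100i patch); no
N-glycosylation sequon anywhere in the wild type; and D72N creating exactly
one sequon (N72-S73-T74) in CDR4. It is a stand-in, not a transcription of
the real sequence.

CDR boundaries ship as the standard Kabat heavy-chain definitions (CDR1
31-35, CDR2 50-65, CDR3 95-102) plus the non-canonical CDR4 loop 71-78;
CDR1-3 bounds are standard-Kabat conventions, not study-verified values, and
are overridable from JSON. Inserted positions inherit the region of their
parent number (so 100d-100i are CDR3).

## What passing tests do and do not show

The generators share their forward models with the analyses they test
(binding model, two-state melt), so parameter-recovery results demonstrate
correctness of the inference machinery, not robustness to real-instrument
artefacts: photobleaching drift, aggregation upturns at high temperature,
non-two-state intermediates, cell-autofluorescence structure and pipetting
error are all outside the synthetic model. The trajectory generator emulates
hydrophobic enrichment geometrically; it says nothing about force-field
realism. Classification accuracy on the synthetic study shows the pipeline
reproduces an encoded pattern at the stated noise, not that the pattern
itself is re-derived from physics.

## Problem sizes

Default test and reproduction runs use 27 variants x 3 titration replicates
x 10 concentrations, 27 x 2 melts x 141 points, and trajectories of 200-500
frames with 30-80 probes around 15-60-atom toy proteins; these sizes give
fully converged checks in seconds on one CPU while exercising every code
path.

## Known limitations

* Apparent T_m* only; no dH, dCp or dG of unfolding, and no comparison of
  melts with different scan rates.
* The measurability F-test assumes i.i.d. Gaussian residuals.
* The greedy clustering is order-deterministic but, like all greedy
  clusterings, not a global optimum of any objective.
* Probe-map normalisation to bulk density is available but off by default;
  raw mean counts depend on probe number and box size.
* Kabat numbering only; no IMGT/Chothia conversion, no germline assignment.
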