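# maturex

Affinity/stability trade-off analysis for affinity-matured antibody variable
(VH) domains.

When an antibody is matured for tighter binding — by somatic hypermutation in
vivo or directed evolution in vitro — individual mutations can raise affinity
while quietly destroying thermodynamic stability, and other mutations must
compensate. Quantifying this requires, for every acquired mutation, a paired
measurement: the change in equilibrium association constant K_A and the change
in apparent melting temperature T_m* when that one residue is reverted to wild
type in its evolved context. `maturex` is the analysis pipeline for such a
study, aimed at protein engineers and antibody-display labs:

* **`maturex.binding`** — fits yeast-display flow-cytometry titrations to the
  saturation-plus-nonspecific model
  `APC(c) = APC_min + APC_sat·c/(c + K_D) + APC_ns·c`
  by multi-start bounded least squares (K_A = 1/K_D), with a principled
  "unmeasurable" flag for low-affinity variants.
* **`maturex.melt`** — converts circular-dichroism thermal scans into T_m*:
  linear folded/unfolded baselines, the fraction-folded transform
  f(T) = (Θ_T − Θ_U)/(Θ_F − Θ_U), and linear regression of the transition
  region solved at f = 0.5, plus a second-scan reversibility check.
* **`maturex.tradeoff`** — two-tailed Student's t-tests on replicate values,
  significance stars (p < 0.05 `*`, p < 0.01 `**`), and per-mutation
  classification into the trade-off quadrants (enhancing/neutral/reducing ×
  stabilizing/neutral/destabilizing).
* **`maturex.kabat`** — Kabat-numbered VH sequences with insertion codes
  (82b, 100d, …), mutation parsing/application/reversion, CDR1–4 annotation
  (CDR4 = the non-canonical loop at Kabat 71–78), and N-X-S/T sequon scanning.
* **`maturex.structmap`** — trajectory analysis: Kabsch superposition and RMSD
  matrices, greedy dominant-structure clustering (0.2 nm cutoff), and
  per-heavy-atom hydrophobic probe-density maps (0.5 nm cutoff) written as
  B-factor-colored PDB files.
* **`maturex.synth`** — generators for titrations, melts, trajectories and a
  complete synthetic affinity-maturation study with a ground-truth sidecar.

The fitters are scikit-learn-style estimators (`IsothermFitter`,
`TwoStateMeltFitter`, `GreedyRMSDClustering`) and compose with sklearn
tooling; the module-level functions are thin wrappers over them.

## Worked example

Estimate T_m* from two replicate synthetic melts of a domain whose true
melting temperature is 66.0 °C, and K_A from three replicate titrations at
true K_D = 50 nM:

```python
from maturex import (MeltTruth, TitrationTruth, gen_melt, gen_titration,
                     estimate_tm, summarize_tm, fit_isotherm)

truth = MeltTruth(variant="P4", tm=66.0, noise_sd=0.3, seed=1)
s = summarize_tm([estimate_tm(c) for c in gen_melt(truth)])
print(f"T_m* = {s.tm_app:.2f} +/- {s.sd:.2f} C  (n={s.n_replicates})")

tt = TitrationTruth(variant="P4", kd=5e-8, noise_sd=20.0, n_replicates=3, seed=1)
for f in (fit_isotherm(d) for d in gen_titration(tt)):
    print(f"K_A = {f.ka:.3e} /M  (measurable={f.measurable})")
```

prints

```
T_m* = 66.10 +/- 0.18 C  (n=2)
K_A = 1.991e+07 /M  (measurable=True)
K_A = 2.044e+07 /M  (measurable=True)
K_A = 1.985e+07 /M  (measurable=True)
```

i.e. the melt pipeline recovers the 66.0 °C truth to within replicate noise,
and the titration fits recover K_A = 2×10⁷ M⁻¹ (K_D = 50 nM) to within a few
percent at 1% signal noise.

The same flow from the shell, on a full synthetic study:

```bash
maturex simulate pseries --seed 0 --out study/
maturex tradeoff --titrations study/titrations.csv --melts study/melts.csv \
                 --lineage study/lineage.json --out tradeoff.csv
```

`tradeoff.csv` holds one row per (mutation, context) with ΔK_A, ΔT_m*,
p-values, stars and the quadrant classes — e.g. in the most evolved variant
the CDR2/CDR4 mutations R50, R62 and N72 classify as affinity-enhancing but
destabilizing, K45 and K98 as enhancing and stabilizing, and R100d as
enhancing with neutral stability.

Trajectory tools:

```bash
maturex simulate traj --seed 0 --out traj/
maturex cluster   --traj traj/traj.pdb --cutoff 0.2 --out clusters.csv
maturex probe-map --traj traj/traj.pdb --cutoff 0.5 --out map.pdb
```

`map.pdb` carries each heavy atom's mean probe count in the B-factor column
for coloring in any molecular viewer.

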