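# Methods

## The measurement and the model

Label-free differential scanning fluorimetry (nDSF) follows the intrinsic
tryptophan/tyrosine fluorescence of a protein (emission at 330 and 350 nm,
usually reported as the 350/330 ratio) during a thermal ramp.  When a ligand
binds the folded state, unfolding costs the additional free energy of
breaking the complex, so melting curves shift to higher temperature with
increasing ligand concentration.  `dsfbind` turns a dilution series of such
curves into a dissociation constant.

The model is a reversible two-state unfolding equilibrium coupled to 1:1
binding of the folded state:

    FL  ⇌(Kd)  F + L  ⇌(KU)  U + L

with `Kd = [F][L]/[FL]` and `KU = [U]/[F]`.  Fluorescence distinguishes
only folded (F + FL) from unfolded (U) protein, so the observable is the
fraction unfolded `fu = [U]/[P]0`.  Ligand binding to the unfolded state is
not modelled, and the folded–bound complex is assumed spectrally identical
to the free folded state.

The Gibbs energy of unfolding is the integrated Gibbs–Helmholtz expression

    ΔG_U(T) = ΔH (1 − T/Tm) + ΔCp (T − Tm − T ln(T/Tm)),

where ΔS(Tm) = ΔH/Tm is implied by ΔG_U(Tm) = 0 — the entropy at Tm is not
an independent parameter.  This arrangement also evaluates to exactly zero
at T = Tm in floating point, which the test suite exploits.  Ligand adds a
coupling penalty

    ΔG(T, L) = ΔG_U(T) + RT ln(1 + [L]free/Kd),

with the free ligand from the 1:1 mass balance in which only the bindable
(folded) pool `[P]0/(KU + 1)` competes for ligand: `[L]free` is the positive
root of `L² + ([P]0/(KU+1) + Kd − [L]0) L − Kd [L]0 = 0`.  We evaluate this
root in a rationalized form that avoids catastrophic cancellation when the
root is much smaller than the coefficients; an exact three-species solver
(`exact_free_ligand`, which scales Kd by (KU+1) in the bound-species mass
balance) is provided as a cross-check utility only — the quadratic is what
the fitting uses.  The apparent unfolding constant is
`K'U(T) = exp(−ΔG/RT)`, `fu = K'U/(K'U + 1)`, and the fluorescence signal
mixes two linear baselines:

    Y(T) = fu (mu T + bu) + (1 − fu)(mf T + bf).

All internal temperatures are Kelvin; file and CLI interfaces use °C.
R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹.  Concentrations are molar.

## Fitting pipeline

1. **Local fit.**  Each curve is fitted with six parameters
   (Tm, ΔH, mf, bf, mu, bu) at a fixed ΔCp.  Tm is bounded to the analysis
   window, ΔH to (0, 1000] kcal/mol.  Initialization: baselines by linear
   regression over the first/last 15% of the window; Tm from the extremum
   of the Savitzky–Golay-smoothed derivative dY/dT (window 7, degree 2),
   trying both the maximum and the minimum since the transition sign is
   unknown and a large ΔCp adds a cold-side feature; ΔH starts at
   100 kcal/mol.  A fit whose transition amplitude is negligible or that
   does not beat a straight line (SSR of the model > 0.5 × SSR of a linear
   fit) is flagged "no transition"; a Tm pinned to the window edge is also
   flagged.  Flagged curves are excluded from the global fit with a logged
   warning — screening data routinely contain bad capillaries.

2. **Global fit.**  One least-squares problem over all remaining curves:
   shared baseline slopes (mf, mu) and optionally a shared ΔCp, plus
   per-curve (Tm, ΔH, bf, bu).  Initialized from the local fits (shared
   slopes at the median of the local slopes).  The optimizer is a bounded
   trust-region reflective least-squares (ftol = xtol = gtol = 1e−10,
   ≤ 5000 evaluations) with analytic Jacobians.  When ΔCp is fitted it
   starts at 0; because local fits at a wrong fixed ΔCp bias the per-curve
   (Tm, ΔH), the joint problem has a self-consistent local minimum at
   small ΔCp, so the fit additionally runs short (≤1500-evaluation)
   deterministic restarts at ΔCp = 0%, 40% and 80% of the bound range and
   polishes the lowest-SSR solution.  Model selection is purely by SSR; no
   ground-truth information enters.  ΔCp bounds default to [0, 20]
   kcal/(mol K) (negative values excluded by default, overridable).
   Standard errors are square roots of the diagonal of the
   residual-variance-scaled covariance matrix, computed by SVD; a
   rank-deficient Jacobian yields NaN errors with fit values retained.

3. **Fraction unfolded.**  At a chosen temperature T_iso, each curve's fu
   is evaluated from its fitted (Tm, ΔH) and the study ΔCp.  No ligand term
   appears here: the ligand effect is already absorbed in the per-curve
   parameters.  Uncertainties are first-order (delta-method) propagated
   from the Tm and ΔH marginal variances; their covariance is ignored
   because it is often ill-conditioned — a documented approximation.

4. **Isothermal binding fit.**  fu vs [L]0 is fitted to
   `fu = KU/(KU + 1 + [L]free/Kd)` with `[L]free` from the quadratic above.
   Both constants are fitted in log10 space for conditioning; KU starts at
   `fu_apo/(1 − fu_apo)` (clipped to [1e−4, 1e4]) and Kd at the geometric
   mean of the nonzero ligand concentrations.  Points are unweighted by
   default (`use_weights=True` enables inverse-variance weights from the
   propagated fu errors, which are approximate).  Fits are flagged
   non-converged when the ligand-dependent fu spread is < 0.02 ("no shift
   detected"), when a parameter bound is hit, or when the relative Kd error
   exceeds 100% (the estimate is then indistinguishable from zero at 1σ).
   Reported percentage errors are 100·stderr/estimate.

5. **Temperature selection.**  The binding fit is repeated over a grid of
   temperatures (default: fitted apo Tm ± 10 °C in 1 °C steps, clipped to
   the analysis window) and T_sel is the temperature with the smallest
   relative Kd fitting error among converged fits.  This error is typically
   U-shaped with its minimum near the apo melting temperature, where the fu
   dynamic range across the dilution series is largest.

## Tm-shift ("apparent Kd") models

Two dose–response models of Tm vs [L]0 are included for comparison.
Model 1 interpolates Tm between an unbound value and an upper plateau using
the exact 1:1 bound-protein fraction; it is an empirical construction with
no physico-chemical foundation (a Kd is defined at one temperature, and Tm
does not converge to a plateau), so its results always carry a warning and
should not be reported as affinities.  Model 2 is the thermodynamic
Tm-shift expression

    Tm([L]0) = Tm0 / (1 − (R·Tm0/ΔH0) ln(1 + [L]0/Kd)),

which requires absolute temperature and approximates free ligand by total
ligand.  By default Tm0 and ΔH0 are fixed from the apo curve's global fit
(a flag releases them), avoiding a 3-parameter fit on few points.  In the
bound-fraction expression of model 1 the fraction is evaluated in a
rationalized form to remain stable in the weak-binding limit.

## The simulator

`simulate_study` generates virtual binding studies from the forward model
exactly: ΔG_U from (Tm, ΔH, ΔCp); per ligand concentration the coupling
term with `[L]free` from the quadratic, with KU at each temperature taken
from the ligand-free ΔG and Kd assumed temperature-independent for
simplicity; then fu, the baseline-mixed signal, and i.i.d. Gaussian noise
whose σ is a stated percentage of the dynamic range (max − min) of the
whole noiseless study — a per-study rather than per-curve convention, so
apo and saturated curves receive identical noise.  Defaults: apo
Tm = 50 °C, ΔH = 120 kcal/mol, ΔCp = 0, ratio-like baselines
(mf = −0.002, bf = 1.5, mu = +0.001, bu = 1.1 on the Kelvin scale), 14
two-fold ligand dilutions from 2 mM plus one apo sample, temperature grid
20–95 °C in 0.5 °C steps, Kd = 1 µM, [P]0 = 0.1 µM — a realistic nDSF
screening layout.  Identical spec and seed give bit-identical output;
benchmark cells derive independent child seeds from the root seed and the
grid indices, so any cell is reproducible in isolation.

Note that with ΔH = 120 kcal/mol a ΔCp of 8–12 kcal/(mol K) places a cold
denaturation midpoint inside the 20–95 °C grid: ΔG_U curves over and
becomes negative again at low temperature.  The simulated curves therefore
show partial low-temperature unfolding, the fitting model represents it
exactly, and it is precisely this curvature that makes ΔCp identifiable
from a single study.

What the simulator does **not** emulate: temperature dependence of Kd
(real binding enthalpies make Kd(T) vary strongly — the main reason
Tm-shift models fail by orders of magnitude on real nM binders, an effect
absent here), irreversible or kinetically controlled unfolding and heating
-rate effects, multiple transitions, ligand autofluorescence or quenching,
and instrument drift.  Passing round-trip tests therefore demonstrates
correctness of the estimator under its own assumptions, not robustness to
these real-data violations.

## Benchmark

`run_benchmark` sweeps (Kd, [P]0, ΔCp, noise) cells, repeating each `reps`
times, and records the deviation Kd,fitted/Kd,true at T_sel together with
the fitted ΔCp.  The default reduced grid (Kd, [P]0 ∈ {0.1, 1, 10 µM},
ΔCp ∈ {0, 8}, noise ∈ {0, 2%}) finishes in minutes on one CPU; the full
decade sweep (10 × 10 × 4 × 5) is available behind `--full-grid`.  Known
behaviours reproduced by the tests: recovery is accurate for [P]0 ≤ Kd and
degrades above that diagonal; fitting ΔCp improves the median
|log10 deviation| over assuming ΔCp = 0 when the true ΔCp ≠ 0; with ΔCp
mis-set to 0, deviations grow rapidly for T_iso above the apo Tm, while
below the Tm they remain small until the fu spread falls under the
no-shift detection limit — so the usable minimum sits near the apo Tm.

## Numerical choices and degenerate inputs

- Quadratic roots (free ligand, bound fraction) are evaluated in
  cancellation-free branches; tests pin them to an independent bisection
  oracle at 1e−12 relative over the full concentration ranges.
- fu is computed through the logistic function of ΔG/RT with clipped
  exponents, so extreme temperatures cannot overflow.
- Constant or windowless curves yield flagged results, not exceptions; a
  study whose window excludes the transition fails the pipeline with a
  nonzero exit and diagnostics rather than producing a number.
- Ties in T_sel resolve to the first (lowest) scanned temperature.
- Problem sizes used by the test suite are the package's own choices:
  the ΔCp-benefit check runs the 3×3 Kd×[P]0 grid at 2% noise with 5
  replicates per cell; the noise-monotonicity check compares 4 replicates
  at 0% and 5% noise; the ΔCp-recovery check averages 10 seeds.

## Known limitations

- Single transition only: multi-domain proteins are handled by windowing
  onto one transition, not by deconvolution.
- 1:1 stoichiometry only; the fu-vs-[L]0 stage is the natural extension
  point for other binding models.
- The fu error propagation ignores parameter covariance, and the binding
  fit is unweighted by default; reported Kd errors are numerical fitting
  errors, not a full uncertainty budget.
- Model 1 is included for comparison only and deliberately warns against
  reporting its output.
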