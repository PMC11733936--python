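# Methods

This note records the model, the estimator conventions, the toy validation
layer, the numerical choices and the limitations of the package.

## Model and assumptions

The method estimates relative dissociation rates from replica simulations
run at a scaled temperature. Two assumptions carry all the weight:

1. **Population scaling.** On a landscape simulated at T_sim = λ·T_ref the
   Boltzmann weight of a microstate is the unscaled weight raised to 1/λ;
   the unscaled populations are recovered by the element-wise power λ
   followed by renormalization (`reweight_population`). This is exact for
   equilibrium populations of a temperature-scaled ensemble.
2. **Common-prefactor Arrhenius kinetics.** Escape rates obey
   k ≈ A·exp(−ΔV‡/k_BT) with a prefactor A that is approximately shared
   across the ligands being compared. Under that assumption the population
   scaling transfers to the log-rate scale as
   log10 k(T_ref) = λ·log10 k(T_sim) + c (`reweight_log_rate`). The
   additive constant c collects the prefactor and the median-to-rate
   convention; it cancels in relative comparisons and is fixed at 0, with
   `normalize_to_reference` (min–max affine onto a known experimental
   range) absorbing it whenever absolute numbers are needed. Reweighting
   preserves rank order for any λ > 0, so ligand prioritisation never
   depends on c.

Consequences: predictions are *relative* log10 k_off values; nothing in the
pipeline estimates absolute prefactors or k_on.

## Estimator conventions

- **Unbinding detection.** Frames are superposed protein-to-protein onto
  frame 1 (Kabsch least-squares fit via MDAnalysis); the ligand heavy-atom
  RMSD versus frame 1 is computed without refitting the ligand; the ligand
  is unbound at the first frame beginning a run of at least `persistence`
  consecutive frames with RMSD > 5.0 Å. Persistence defaults to 5 frames
  (50 ps at the default 10 ps interval) to suppress transient recrossings;
  `persistence=1` recovers the bare single-cutoff rule. The unbinding time
  is the *first* frame of the sustained excursion (earliest evidence), and
  it is reported as a time, not a frame index, so refining the frame
  interval does not change it on noise-free data.
- **Censoring.** Replicas that never unbind are censored at t_max and enter
  the median order statistics at t_max; dropping them would bias the median
  low. The median is flagged RELIABLE only when strictly more than half the
  replicas unbound — otherwise it is a LOWER_BOUND and `fit()` refuses to
  convert it into a rate unless explicitly overridden (the remedy is a
  higher temperature or longer t_max, which is what the temperature scan
  automates). A `drop_censored` policy is available for comparison.
- **Median-to-rate convention.** k(T_sim) = ln 2 / τ_median, exact for an
  exponential first-passage distribution. Any other constant choice shifts
  c only; the constant is configurable on `KoffModel`.
- **Uncertainty.** Percentile bootstrap over replicas (default 500
  resamples, seeded) of the reweighted log10 k_off.
- **Temperature scan.** Given reference-ligand results at several
  temperatures, the recommended setting is the *lowest* temperature at
  which every reference ligand has a RELIABLE median inside the target
  window (default ≤ 4 ns); ties go to the lower temperature because less
  scaling means less extrapolation.

## Units and constants

| quantity | unit | default |
| --- | --- | --- |
| gas constant R | kcal mol⁻¹ K⁻¹ | 1.987×10⁻³ |
| ΔG↔K_d conversion temperature | K | 298 (assay convention) |
| kinetic reweighting reference T_ref | K | 300 (room temperature) |
| bound/unbound RMSD cutoff | Å | 5.0 |
| persistence window | frames | 5 |
| restraint σ | Å | 3.0 |
| binding-site cutoff | Å | 6.0 (closest heavy atom, inclusive) |
| replicas | — | 32 |
| time step | fs | 2 |
| frame interval | ps | 10 |
| thermostat friction | ps⁻¹ | 1 (not a sensitive choice; configurable) |

The restraint σ is read as the standard deviation of a harmonic positional
restraint, giving the Boltzmann-consistent spring constant
k = k_B·T_ref/σ² per coordinate (≈ 0.066 kcal mol⁻¹ Å⁻² at the defaults).
This reading is flagged prominently because restraint strength could
plausibly be specified other ways; both σ and the derived constant are on
`RestraintSpec`. Binding-site residues are determined once from the input
pose, residue-granular: a residue is freed from restraints when any of its
heavy atoms lies within the cutoff of any ligand heavy atom.

## The toy validation layer

The toy layer exists to validate the *statistics* of the pipeline with
known ground truth; it contains no chemistry.

- **Potential.** A C¹ piecewise-harmonic double well in reduced units
  (k_B = 1, energies in k_BT_ref): harmonic well of curvature ω_a² at the
  well position, inverted-harmonic barrier of curvature ω_b² and height
  ΔV‡, mirrored into a second well. Matching value and slope at the joins
  fixes the barrier position, so (well position, ΔV‡, ω_a², ω_b²) fully
  determine the geometry. Defaults ω_a² = ω_b² = 4, γ = 1, dt = 0.01.
- **Dynamics.** Overdamped (Brownian) Euler–Maruyama,
  dx = −V′(x)/γ·dt + √(2T·dt/γ)·ξ — the simplest scheme whose stationary
  distribution and high-friction Kramers limit are both known in closed
  form. dt must satisfy dt < 0.1/γ and dt·max(ω²)/γ ≤ 0.5; violations
  raise before any integration runs.
- **Escape.** First passage beyond barrier + 1 reduced length unit,
  absorbing (no re-entry), mirroring the irreversible reading of the 5 Å
  cutoff. Replica i consumes a private noise stream seeded base + i, so
  results are independent of ensemble size and execution order. Note that
  nearby base seeds therefore share replica streams; independent ensembles
  need base seeds separated by at least the replica count.
- **Oracle.** k = ω_a·ω_b/(2πγ)·exp(−ΔV‡/T), asymptotically exact in the
  high-friction, high-barrier limit; the implementation warns below
  ΔV‡/T = 3. At ΔV‡/T = 5 the exact mean-first-passage integral differs
  from the Kramers formula by ~10%, comfortably inside the factor-2 check
  used in the tests.
- **Scripted trajectories.** The generator plants a permanent ligand
  displacement (default 8 Å, direction away from the protein centre) from
  a scripted departure frame, optional one-frame recrossing excursions
  before it, a rigid rotation/translation of the whole system per frame,
  and Gaussian coordinate noise. With zero noise, superposition followed by
  detection recovers the scripted departure time exactly, which the tests
  assert; the generator and the analysis are exact inverses by
  construction, so these tests validate bookkeeping, not robustness to
  realistic noise.
- **Toy backend.** To exercise the same code path an MD engine would use,
  a replica's 1D escape time is mapped onto a 3D scripted trajectory whose
  ligand departs at the corresponding frame (1 reduced time unit =
  10 ps by default, so escape times land on the frame grid with ~5%
  quantisation at the default interval).

## What the synthetic generators do and do not emulate

The Langevin layer reproduces the features the reweighting relies on —
exponential first-passage times, Arrhenius temperature dependence,
censoring at finite t_max — and nothing else: no solvent, no force field,
no 3D unbinding pathways, no protein flexibility. The scripted-trajectory
generator reproduces rigid-body drift and Gaussian jitter but not
correlated loop motions or partial-unbinding intermediates. The screening
and benchmark table generators plant a strong rescoring signal, a weak
docking signal, per-target affine distortions and a few binding-mode
classes and singleton targets. Passing tests therefore demonstrate that
the estimator, reweighting and metrics are implemented correctly and
recover planted ground truth — not that the method attains any particular
accuracy on real protein–ligand systems, which depends on force fields,
sampling and experimental data outside this package's scope.

## Problem sizes and statistical behaviour of the checks

The statistical checks use 64–256 replicas per condition (hundreds of
replicas run in a few seconds since the integrator is vectorised across
replicas). One behaviour worth recording: the reweighted log10-rate *gap*
between two barriers is λ times noisier than the underlying medians, so at
64 replicas a single-seed gap estimate has a standard deviation near 0.27
log units; the fixed-seed tests assert the spec'd ±0.3 band at 64
replicas, while the acceptance script reports the gap from 512 replicas
per barrier with a paired seed block, tightening the estimate several-fold.

## Numerical and design choices

- R² is the squared Pearson correlation (scatter-plot convention), not
  1 − SS_res/SS_tot; the two differ whenever predictions are biased, and
  the affine per-target normalization makes the Pearson form the natural
  one here. Error bands are boundary-inclusive (|err| ≤ band).
- Per-target normalization is min–max affine (equal ranges), not z-score:
  it maps each target's predicted min/max exactly onto the observed
  min/max and cannot change within-target ranks. Targets without a usable
  range (singletons, or constant values) either raise or, with the drop
  flag, are removed and counted.
- Ranking ties: stable sort keeps the input table order; ROC AUC gives
  ties half credit (Mann–Whitney convention, matching the trapezoidal
  area); EF at a fraction uses n = max(1, floor(fraction·N)). Score
  direction is always an explicit argument — docking scores and relative
  log10 k_off are both "lower is better" when slow dissociation is sought.
- Trajectory frame times always come from the configured interval, never
  from trajectory-file timestamps (DCD/XTC writers disagree about them).
- Result CSVs use a fixed column order and full-precision, locale-free
  number formatting; the JSON report embeds the config SHA-256, seeds and
  package version, and contains no timestamps, so identical configs
  reproduce bitwise-identical outputs.
- The RMSD reference is frame 1 of each trajectory, not the input pose; on
  a restrained protein the two differ only by thermal noise, but the
  choice is recorded because it changes what "RMSD 0" means.
- The production-MD backend is a contract, not a dependency: anything that
  maps a replica descriptor to a trajectory with the declared frame count
  and interval can execute a plan. System preparation, docking and ligand
  parameterisation are consumed as prepared inputs, never performed.

## Known limitations

- Absolute rates require the offset c, i.e. prior experimental anchors;
  the package only ever ranks without them.
- The common-prefactor assumption degrades when ligands differ grossly in
  unbinding mechanism; the benchmark module's binding-mode filters exist
  precisely because mixed-mechanism sets (e.g. type-1 versus type-2 kinase
  inhibitors, or transition-state-directed inhibitors) break the
  k_off–K_d correspondence.
- The censored-median estimator is a lower-bound detector, not a survival
  model; heavily censored conditions should be re-run hotter or longer
  rather than interpreted.
- Restraint selection is computed once from the input pose; binding sites
  that rearrange during unbinding are not re-detected.
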