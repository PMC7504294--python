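# Methods

## Model

`mablabel` simulates the labeling of a single T cell by fluorescent
monoclonal antibodies (mAbs) as a Markov jump process over seven molecule
counts: mAbs in three concentric diffusive shells around the cell
(transition `A_s`, boundary `A_b`, cell layer `A_c`), mAbs nonspecifically
adsorbed on the surface (`A_o`), monovalent and bivalent antibody–receptor
complexes (`AR`, `ARR`), and free CD4 receptors (`R`). Ten reaction
channels — five forward/backward pairs — connect them; each channel's
propensity is its stochastic rate constant times the current reactant count
(or count product for the two bimolecular channels). The simulator is the
exact Gillespie direct method: two uniform variates per event, waiting time
`τ = ln(1/u₁)/Σα`, channel selected by cumulative propensity fraction.

Assumptions inherited from the model design:

- **Diffusion as shell hops.** Transport is represented by per-molecule hop
  rates `D/h²` between 3.75 µm shells (`D = 0.5·10⁻¹⁰ m²/s`), the coarsest
  discretization that still produces a diffusion-limited delivery flux.
  Bulk flow and mixing are absent, so delivery is the slowest it can be.
- **Constant source.** The transition layer count is a boundary condition:
  pinned at `A_s = 3000` molecules during labeling (volume of the shell ×
  1 µmol/m³ bulk concentration × Avogadro, rounded to the nearest thousand)
  and at `A_s = 0` during the wash. The influx channel fires at `k₂₊·A_s`
  without depleting a reservoir; the reverse channel drains tracked
  molecules irreversibly. This models a saturating (respectively clean)
  bulk of effectively infinite extent.
- **Unlimited adsorption sites.** Nonspecific adsorption does not saturate;
  `k_off = 0.5·k_on` keeps the standing adsorbed pool at
  `(k_on/k_off)·A_c = 2·A_c ≈ 6000` at equilibrium.
- **Stochastic bimolecular rates.** `k_mp, k_bp` are per-pair rates (1/s)
  applied directly to count products, with no volume conversion — they are
  surface-reaction constants of the discrete model, not solution-phase
  affinities.
- **Both hop rates between cell layer and boundary equal `D/h_c²`.** All
  shells are equally thick, making the directional distinction immaterial;
  any other reading would break the observed equilibrium structure
  (`A_c ≈ A_b ≈ A_s`, `A_o ≈ 2·A_c`).

Default rate constants (1/s): hops and adsorption `D/h² = 3.556`,
`k_off = 1.778`; binding `k_mp = 10⁻⁴`, `k_mn = 10⁻⁶`, `k_bp = 2·10⁻⁶`,
`k_bn = 10⁻⁸` ("similar" preset, comparable AR and ARR at equilibrium).
Named presets change only the binding block: monovalent-dominant
(`2·10⁻⁴, 10⁻⁶, 10⁻⁷, 10⁻⁹`), bivalent-dominant
(`10⁻⁴, 10⁻⁶, 2·10⁻⁴, 10⁻⁸`), and the two fluctuating-affinity studies
(two-point `k_bp ∈ {10⁻⁷, 10⁻⁶}` with `k_bn = 10⁻⁹`; log₁₀-normal
`k_bp = 10^N`, `N ~ Normal(−6.5, 0.5)` with `k_bn = 10⁻⁸` — each study
keeps its own printed `k_bn`).

## Engine and numerical choices

- The inner loop is a numba-compiled kernel; a pure-Python mirror exists for
  testing. Both consume the same Mersenne-Twister stream, so a given seed
  yields bit-identical state sequences on either backend (waiting times can
  differ by one ulp of libm rounding). `u₁ = 0` is resampled so `ln(1/u₁)`
  stays finite; channel selection uses strict cumulative comparison, so
  zero-propensity channels are never selected; round-off at `u₂ → 1` falls
  back to the last nonzero channel.
- Counts are exact 64-bit integers; receptor conservation
  `R + AR + 2·ARR = R₀` is therefore assertable bit-exactly per event.
- Zero total propensity is an absorbing state and terminates the run; an
  event budget (default 10⁸) guards against runaway parameter sets and
  marks the trajectory truncated.
- Snapshots are recorded on a user grid by carrying the pre-event state onto
  every grid point passed by the event clock; full event logs are opt-in
  (a labeling run generates ~1.3 million events) and capped.
- The mean-field oracle integrates the term-for-term ODE mirror of the
  propensities with LSODA at `rtol = 10⁻⁸` (rate scales span 10⁻⁸–10⁵/s);
  it validates SSA *means* — it has no fluctuations, so SD/CV% are never
  compared against it.

## Scenarios and readout conventions

- **Labeling run**: `R = R₀ = 100,000`, everything else 0, `A_s = 3000`;
  default horizon 30 s for a single trajectory. Free receptors fall below
  1,000 at ~27 s; the boundary/cell layers settle into a 5% band of their
  plateau at ~31–39 s (SSA and ODE agree); complete saturation (`R = 0`)
  arrives at ~36–40 s.
- **Ensemble (equilibrium) readout**: final state at the end of the
  calculation, no time averaging, with a default horizon of 50 s so that
  *every* cell reaches binding saturation. The published summary statistics
  this package reproduces are saturated-state statistics — their SD columns
  satisfy `SD(AR) = 2·SD(ARR) = 2·SD(AR+ARR)`, which is exactly the
  signature of the constraint `R₀ = AR + 2·ARR` with `R = 0` — and the
  tiny intrinsic CV% of ABC only arises under that constraint. At a 30 s
  readout ~170 receptors remain free and the constraint is not yet active.
  At saturation a cell occasionally shows `R_free = 1`: dissociation
  re-releases a receptor every ~26 s and recapture takes ~1.5 s, giving a
  stationary `P(R ≥ 1) ≈ 6%`.
- **Wash run**: starts from a saturated labeling state with `A_s = 0`,
  horizon 3·10⁴ s on a logarithmic snapshot grid. The layers drain within
  seconds; afterwards only slow dissociation/re-binding acts, ABC decays by
  well under 1% over two hours, and the mean inter-event interval in the
  final 10⁴ s is ~2 s (each slow dissociation triggers a short burst of
  sub-second desorption/diffusion events, so the log-binned interval
  histogram peaks below the mean).
- **Equilibrium detector**: earliest snapshot time `t*` such that every
  requested trace stays within a relative tolerance (default 5%) of its
  plateau over `[t*, t* + window]` (default 5 s). The plateau reference is
  the mean over the trailing window, not the single last snapshot — a count
  of 3000 has Poisson σ ≈ 55, so the 5% band is only ~2.6σ wide and a
  single-snapshot reference is often off-center enough to make detection
  fail. For the same reason the detector should be fed a ~0.5 s grid: at
  0.1 s spacing a 5 s window contains ~100 nearly independent samples and
  chance excursions beyond 2.6σ interrupt almost every window.
- **k_off sensitivity scan**: the desorption factor (default 0.5, scanned
  0.4–0.6) proxies cell-area variation through the standing adsorbed pool;
  at a 30 s horizon it moves equilibrium ABC by under 1.5%, and less at
  40 s — adsorption strength changes the time to equilibrium, not the
  equilibrium itself.

## Population ensembles

Per-cell heterogeneity is specified by a receptor-count distribution
(`Fixed` or `Normal(mean, CV%)`, drawn values rounded and floored at 1) and
an optional `k_bp` distribution (`TwoPoint(low, high, p_high)` with
`p_high = 0.5` by default — the two-point study says only "chosen randomly"
— or `Log10Normal`). All draws and per-cell simulation seeds derive from a
single master seed (PCG64 for parameters, a seed sequence for the cells), so
an ensemble is a pure function of its specification regardless of execution
order. Summaries report mean, sample SD (n−1 denominator; at n = 25 the
n vs n−1 choice moves CV% by ~2%, `ddof` is configurable) and
`CV% = 100·SD/mean` for `R_init`, `AR`, `ARR` and `TotalA = ABC`.

Default ensemble size is 25 cells, matching the published protocol; the CV%
of a 25-replicate ensemble carries a relative sampling error of roughly
`1/√48 ≈ 14%`, and validation tests use 100 cells where a tighter estimate
is needed.

## What the simulations do and do not show

The generator reproduces the study conditions exactly — there is no external
data anywhere; every number is a Monte-Carlo output of the model itself.
Consequently, agreement demonstrates the internal consistency of the model
and the correctness of this implementation, not the fidelity of the model to
real T cells. Known limitations:

- No spatial resolution finer than three shells; no electrostatics, no
  hydrodynamic mixing, no adsorption-site depletion, no feedback of binding
  onto the bulk concentration (valid only at saturating label).
- ABC is the endpoint: mapping to measured MFI, fluorescence-detection
  noise, and fitting to cytometry measurements are out of scope.
- Two reproduction targets disagree with the printed values in ways the
  model pins down precisely. (1) The printed fixed-conditions SD triple
  (115, 58, 57) is uniformly ~√2 smaller than the model's saturated-state
  fluctuations (~161, 80, 80 at n = 200), i.e. half the variance, while the
  printed *means* are reproduced to 0.01% — the corresponding CV% check
  (0.08 ± 30%) therefore fails at ~0.12, even though the scientific
  conclusion (intrinsic CV% is negligible, ≲0.2%) holds robustly. (2) The
  layer-equilibration time measured by the 5%-tolerance detector is
  31–39 s, not "about 25 s": 25 s is where the free-receptor trace visually
  reaches zero on a 0–100,000 axis, and both the SSA and the independent
  ODE oracle agree the layers settle later under the printed parameters.
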