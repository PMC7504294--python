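# mablabel

Stochastic reaction–diffusion simulation of monoclonal-antibody (mAb)
labeling of CD4 receptors on T cells, with a cell-population layer that
decomposes the coefficient of variation of **antibodies bound per cell
(ABC)** — the quantity a calibrated flow cytometer reports through mean
fluorescence intensity.

## Who this is for

Quantitative flow cytometry relies on CD4⁺ T cells as a counting standard:
a healthy donor's T cells carry a reproducible ~100,000 accessible CD4
receptors, so the fluorescence of a saturating anti-CD4 stain calibrates the
MFI→ABC scale. The *spread* of that fluorescence across cells (CV%) carries
biological information — receptor-count variability, binding-affinity
variability — but only if the contribution of the labeling reaction itself
can be modeled. `mablabel` simulates that labeling reaction at
single-molecule resolution and predicts the CV% of ABC under controlled
sources of cell-to-cell heterogeneity.

## The model

A single cell sits at the center of three concentric 3.75 µm shells
(transition, boundary, cell layers) that provide a diffusive path from the
bulk suspension to the surface. Ten reaction channels act on the counts
(A_b, A_c, A_o, AR, ARR, R):

```
A_s ⇌ A_b          diffusion, transition ↔ boundary      k₂₊ = D/h_t², k₂₋ = D/h_b²
A_b ⇌ A_c          diffusion, boundary ↔ cell layer      k₁₊ = k₁₋ = D/h_c²
A_c ⇌ A_o          nonspecific adsorption on the surface  k_on = D/h_c², k_off = 0.5·k_on
A_o + R ⇌ AR       monovalent binding                     k_mp = 10⁻⁴, k_mn = 10⁻⁶  (1/s)
AR + R ⇌ ARR       bivalent binding                       k_bp = 2·10⁻⁶, k_bn = 10⁻⁸ (1/s)
```

The transition layer is a boundary condition: its count A_s stays pinned at
3000 during labeling (saturating bulk mAb, 1 µmol/m³ over a 4.76·10⁻¹⁵ m³
shell) and at 0 during the post-labeling wash. The dynamics are an exact
jump process simulated with the Gillespie direct method: waiting time
τ = ln(1/r₁)/Σαᵢ, channel j chosen with probability αⱼ/Σαᵢ, propensities
α = rate × reactant count (or count product). Receptor conservation
R + AR + 2·ARR = R₀ holds exactly, event by event.

ABC ≡ AR + ARR. At saturation (R = 0), AR and ARR are perfectly
anticorrelated through the constraint R₀ = AR + 2·ARR, which is why the
intrinsic CV% of ABC is tiny (~0.1%) while AR and ARR individually fluctuate
much more — and why ABC ranges from R₀ (pure monovalent) down to R₀/2
(pure bivalent) depending on the binding-rate mix.

The ensemble layer runs many independent cells with per-cell parameters —
receptor counts from Normal(100,000, CV 6%), bivalent affinity k_bp from a
two-point cluster/solitary mixture or a log₁₀-normal spread — and tabulates
mean / SD / CV% of R, AR, ARR and ABC. A deterministic mean-field ODE
mirror of the ten propensities (solved with LSODA) serves as an independent
validation oracle for means and equilibria.

## Worked example

Reproduce the fixed-conditions ensemble (25 identical cells, comparable
monovalent/bivalent binding, read out at binding saturation):

```text
$ mablabel ensemble --preset table4 --cells 25 --seed 1 --out out/
        R_init         AR        ARR     TotalA
mean  100000.0  38367.400  30816.280  69183.680
SD         0.0    141.295     70.679     70.616
CV%        0.0      0.368      0.229      0.102
```

Every cell starts with exactly 100,000 receptors; at saturation each run
satisfies AR + 2·ARR + R_free = 100,000 exactly. About 38,000 mAbs end up
monovalently bound and 31,000 bivalently bound, so ABC ≈ 69,200 — between
the monovalent (100,000) and bivalent (50,000) extremes. The CV% of ABC
(0.102) is thirty times smaller than the receptor-number contribution
(preset `table5-similar`, CV% ≈ 5–6) and a hundred times smaller than the
fluctuating-affinity contribution (presets `table6`/`table7`, CV% ≈ 11):
intrinsic reaction noise is negligible against biological heterogeneity.

A single labeling trajectory and the ODE cross-check:

```text
$ mablabel simulate --seed 1 --t-end 50 --out out/
ABC = 69193  (wrote out/trajectory.csv)
$ mablabel oracle --seeds 10 --seed 1 --out out/
max |SSA mean - ODE| = 0.506 x tolerance (3 SE + 0.3%) over 10 seeds x 10 checkpoints; consistent = True
```

Other commands: `postlabel` (wash phase: ABC stays within ~0.5% over two
hours while AR and ARR keep exchanging) and `hist` (log-spaced histograms of
inter-event intervals). `--help` on any command lists options.

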