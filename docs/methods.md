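# Methods

## The model

The package studies how interconnected feedback loops among miR-200, ZEB1,
ESRP1, HAS2/hyaluronic acid (HA) and the CD44 splice isoforms shape
epithelial–hybrid–mesenchymal plasticity. Two circuits are built in:

* **simplified** — the classical miR-200/ZEB1 mutual-inhibition module driven
  by SNAIL, with a direct transcriptional ZEB1 self-activation standing in
  for unresolved mechanism;
* **extended** — the same core with the self-activation resolved: ZEB1
  represses ESRP1; ESRP1 shifts a conserved total CD44 production between the
  standard (CD44s) and variant (CD44v) isoforms; CD44s activates ZEB1
  transcription and CD44v inhibits it; ZEB1 also drives HAS2 → HA, and HA
  activates ZEB1 only in complex with CD44s.

Dynamical species are molecule counts; time is in hours. miR-200 and ZEB1
keep the mRNA/protein/microRNA resolution of the established model family;
ESRP1, HAS2, HA, CD44s and CD44v are single variables, matching the level of
description of the circuit diagram. SNAIL is a control (bifurcation)
parameter, not a dynamical species.

Each species obeys

    dX/dt = production(X) · Π H(regulator) · [L(µ)] − k_X · X − [X · Ym(µ)]

with three kernels:

* **Shifted Hill** `H(X) = (1 + λ (X/X₀)ⁿ) / (1 + (X/X₀)ⁿ)` for
  transcriptional and non-transcriptional regulation — basal value 1,
  saturation at the fold-change λ (λ>1 activation, λ<1 inhibition).
* **MicroRNA silencing** for the miR-200 → ZEB1-mRNA interaction: with `n`
  binding sites the occupancy of `i` sites is binomial with per-site
  probability `µ/(µ₀+µ)`. Occupancy-weighted sums give the residual
  translation rate `L(µ)` (factor on ZEB1 protein production), the
  microRNA-dependent mRNA degradation `Ym(µ)` (loss term `mZ·Ym`), and the
  microRNA turnover `Yµ(µ)` (loss `mZ·Yµ` on miR-200; a degraded complex
  consumes its bound microRNAs).
* **Splicing partition**: total CD44 production `g_C` is split
  `g_C·(1−f(E1))` to CD44s and `g_C·f(E1)` to CD44v with
  `f = (E1/E₀)ⁿ/(1+(E1/E₀)ⁿ)`; the split conserves `g_C` exactly.

The HA→ZEB1 edge carries a cofactor annotation: its Hill input is the
product HA·CD44s (threshold in molecules²), so the HA-dependent activation
vanishes without CD44s, while a separate CD44s→ZEB1 edge provides the
HA-independent route. This reproduces both reported behaviours (CD44s
essential for the HA effect; CD44s acting with and without HA) with the
fewest new parameters.

## Parameters and calibration

The miR-200/ZEB1 core uses the published molecule-count baseline of this
model family (production 2100/11/100 per hour for miR-200 / ZEB1 mRNA /
protein-per-mRNA; degradation 0.05/0.5/0.1 per hour; six microRNA binding
sites with translation factors l = (1, .6, .3, .1, .05, .05, .05), mRNA
degradation weights (0, .04, .2, 1, 1, 1, 1) and microRNA turnover weights
(0, .005, .05, .5, .5, .5, .5); SNAIL and ZEB1 Hill blocks as shipped in
`simplified_default.params`).

The extended circuit replaces the direct self-activation (λ = 7.5, X₀ =
25 000, n = 2 on ZEB1 protein) by the ESRP1/CD44/HAS2 chain. Its five new
edge blocks were calibrated **once**, before any downstream analysis, by a
two-step procedure:

1. At steady state the chain makes the composite ZEB1-transcription factor a
   function of ZEB1 protein alone, `G(Z) = H(Cs(Z))·H(Cv(Z))·H(HA(Z)·Cs(Z))`.
   The thresholds and the gate fold-change were fitted by log least squares
   so `G(Z)` matches the direct self-activation factor over Z ∈ [2·10²,
   3·10⁶] (maximum log deviation ≈ 0.14), with the CD44s and CD44v
   fold-changes held at 2.0 and 0.3 so both isoform routes stay functional.
2. The HA·CD44s gate threshold was then lowered from the fitted 18 940 to
   15 500 molecules² so that the epithelial branch loses stability before
   the hybrid branch dies, restoring the published phase order
   ({E} → {E,M} → {E,E/M,M} → {E/M,M} → {M}).

The final set is frozen in `extended_default.params`. With it the stable
branches sit at ZEB1 mRNA ≈ 35–85 (epithelial), ≈ 190–500 (hybrid) and
≈ 720–1080 molecules (mesenchymal) over the default SNAIL scan
(120 000–260 000 molecules, 400 points) — matching the printed phenotype
thresholds (<150 / ~200–500 / >600).

## Steady states and bifurcation diagrams

Steady states are found by a batched multistart search: log-uniform starts
over the species scales (g/k), a short vectorized RK4 relaxation
("integration-then-Newton"), then damped Newton with forward-difference
Jacobians on the whole batch, projection onto the nonnegative orthant, and a
per-species relative residual criterion `|f_i| ≤ 10⁻⁹·k_i·(x_i + scale_i)`
(species levels span four orders of magnitude, so a global norm would let
small species float). Duplicates merge within 10⁻³ in log-space; stability
is the sign of the largest real part of the central-difference Jacobian's
eigenvalues. The solver is validated on every fixture against a brute-force
oracle (dense grid of initial conditions integrated to `t ≈ 200/min k`,
endpoints clustered with log-space radius 10⁻², convergence at relative
residual 10⁻⁶).

Sweeps warm-start each SNAIL grid point from the previous point's roots plus
fresh multistarts (96 at the first point, 24 thereafter; relaxation horizon
60 h at dt = 0.5 h). Branches link across neighbouring points by
nearest-neighbour matching in log-state space (threshold 0.5 ln-units,
equidistant ties broken toward the lowest ZEB1 branch with a logged
warning). Phenotypes use the printed ZEB1-mRNA thresholds (E < 150, M > 600,
hybrid 200–500); the unlabeled 150–200 and 500–600 gaps are resolved by
branch identity (a state inherits the nearest unambiguous label on its own
branch), falling back to the coarse rule (hybrid) only for branches that
never leave the gaps. Phases are maximal grid intervals with a constant set
of stable phenotypes, with boundaries halfway between grid points;
saddle-node locations can be refined by bisection on branch existence to
10⁻⁴ of the bracket. Grid sweep plus branch matching was chosen over
pseudo-arclength continuation: it is simpler and adequate for one-parameter
diagrams, at the cost of grid-resolution-limited fold locations.

## Sensitivity scan

Every kinetic parameter is multiplied one at a time by 1 ± 10% and the
hybrid-region width (total SNAIL length carrying a stable hybrid state) is
recomputed; the signed percent change relative to the baseline width is
reported and |change| > 20% is flagged. The microRNA-silencing vectors are
perturbed as blocks (one scale factor on the free entries, preserving
l₀ = 1 and γ₀ = 0); binding-site counts are structural and not scanned. Hill
coefficients are scanned like any other parameter, so the computation
accepts real n ≥ 1 even though the shipped defaults are integers. Perturbed
diagrams are warm-started from the baseline branches at every grid point
(the shifts are small), which was verified to reproduce full fresh sweeps;
the baseline width inside the scan is computed by the same sweep the records
are measured against, so a zero-perturbation control run reports exactly 0%.

With the default set, the scan flags the ZEB1→ESRP1 threshold strongly
(raising it collapses the hybrid window) and the ZEB1 biosynthesis rates
(g_Z, g_mZ, k_Z, k_mZ), while most parameters stay inside ±20%; the
fold-change of the ZEB1⊣ESRP1 edge acts directionally as published
(stronger repression narrows, weaker repression widens the window) though
its ±10% effect is below the flag line.

## Random-parameter ensembles and knockouts

Ensembles follow the random-circuit-perturbation recipe on the
miR-200/ZEB/ESRP1/CD44 reduction (no HAS2/HA, no SNAIL input; the full
extended topology can be run the same way by passing it in). Per model:
production uniform on [1, 100] molecules/h, degradation uniform on
[0.1, 1]/h, Hill coefficients integer-uniform on [1, 6], fold-changes
uniform on [1, 100] (reciprocal for inhibitions), and thresholds by the
half-functional rule — uniform on (0.02, 1.98) times the regulator's median
level. That median accounts for the regulator's own regulation: each
incoming edge contributes its median shifted-Hill factor (a scale-free
constant under proportional threshold sampling, computed once by
deterministic Monte Carlo), silencing contributes the half-occupancy
degradation and translation factors, and translated proteins scale with
their template mRNA. Without this correction, strongly repressed regulators
(ESRP1 in particular) would receive thresholds far above the levels they
actually reach, silencing the CD44v arm. The product-of-medians propagation
is an approximation; empirical solution medians still sit a few-fold below
the estimates for deeply repressed species. The microRNA-silencing shape
vectors are kept at the published defaults (they are structural, not scalar
kinetics); the binding threshold is sampled half-functionally.

Each model is solved from 100 log-uniform starts (span 10⁻⁴–300 × scale, to
cover fold-change-amplified levels) with a short relaxation (16 h, dt 0.4 h)
followed by Newton polishing of one representative per loose cluster; only
stable states are kept. Models with no converged stable state are excluded
and counted (the observed exclusion rate is ≲0.1%). Ensembles are fully
determined by (topology, ranges, seed, solver settings); replicate seeds are
spawned from one root seed.

Every stable solution is labeled from z-scored log₁₀ ZEB1-mRNA and miR-200
levels against the pooled **control** ensemble statistics: E if ZEB1 is more
than z* = 0.5 SD below and miR-200 more than z* above the mean, M for the
reverse, hybrid otherwise. Labeling knockouts against control statistics
keeps the frequency axes comparable; control labels are unchanged by
construction. The z-score rule and z* are documented package choices — the
published analysis does not specify its labeling rule. Conditions are
compared per phenotype by the mean per-replicate frequency difference and a
paired two-tailed t test (t = mean d / (sd d/√n), df = n−1; a zero-variance
difference vector is reported as degenerate rather than a fabricated
statistic).

At the desk scale used by the tests and the acceptance script (1000 models ×
3 replicates; sign stability re-checked at 250 × 3 over three further
seeds), deleting ZEB1→ESRP1 reproducibly lowers the mesenchymal fraction
(≈ −0.11) and raises the hybrid fraction (≈ +0.08…+0.13), and deleting
CD44s→ZEB1 lowers mesenchymal (≈ −0.3) and raises epithelial fractions.
Deleting ESRP1→CD44s lowers mesenchymal only weakly and *lowers* the
epithelial fraction in this implementation: making CD44s constitutive
removes a positive feedback loop that stabilizes both extreme phenotypes, so
solutions concentrate in the hybrid band instead. This is a genuine,
sign-stable property of the model as built here and is reported as such
rather than adjusted away; see the limitations below.

## Synthetic fixtures

Fixtures with independently computable structure validate the numerics: a
birth–death motif (closed form g/k, eigenvalue −k), a two-gene toggle switch
(two mirror stable states plus a diagonal saddle from the brute-force
oracle; single state when inhibition is neutral or weak), and a
self-activating gene (bistable with hysteresis; saddle-node production rates
bracketed both by bisection on the 1-D root count and by the analytic fold
condition `H − x H′ = 0`, agreeing to better than 10⁻⁶ relative). The
brute-force oracle uses integration horizon 200/min k, convergence at
relative residual 10⁻⁶ and cluster radius 10⁻² in log-space. Fixtures are
numerical test articles, not biological claims. Grid-of-initial-conditions
integration deliberately includes symmetric starts, so the toggle oracle
also visits the saddle along its stable manifold; comparisons filter oracle
clusters by Jacobian stability.

## Problem sizes and numerical choices

Default analysis sizes: 400-point SNAIL grids for diagrams (300 points
inside the sensitivity scan), 48 scanned parameters × 2 directions,
1000 × 3 models per ensemble condition. Root residual tolerance 10⁻⁹
(relative, per species); dedup 10⁻³ log-space; saddle-node bisection 10⁻⁴ of
the bracket; fixed-step RK4 with dt ≤ 0.5 h (stability margin against the
fastest turnover rates of the default sets); diverged relaxation rows are
reset to the origin basin and re-polished. All randomness flows from
explicit integer seeds.

## Known limitations

* Phase boundaries and the hybrid width are quantized by the SNAIL grid step
  (≈ 350 molecules at 400 points); sensitivity percentages are therefore
  multiples of ≈ 1.3–1.75%.
* The half-functional median propagation underestimates the skew of level
  distributions for deeply repressed species; a pilot-ensemble refinement
  would be more faithful to the cited recipe at the cost of a two-stage
  sampling procedure.
* The ensemble reduction omits HAS2/HA; the extended topology is supported
  but slower and needs a fixed SNAIL input level to sample its thresholds.
* The ESRP1→CD44s knockout contrast does not reproduce the published
  epithelial-fraction increase (see above); the other two knockout contrasts
  and all fixed-parameter results do.
* No stochastic (Langevin/Gillespie) dynamics, no limit-cycle detection (the
  model family is not reported to oscillate in this regime), no
  two-parameter phase diagrams.
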