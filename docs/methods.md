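# Methods

## Scope and observable

`cspfit` analyses protein-observed NMR titrations in the fast-exchange
regime.  The protein (GRB2-like, two proline-rich-motif binding sites on its
SH3 domains plus a phosphopeptide site on SH2 in the motivating system) is
held at a fixed concentration of 200–270 μM and titrated stepwise with a
peptide ligand; at every point the backbone amide ¹H/¹⁵N shifts of assigned
residues are read from an HSQC spectrum.  The fitted observable is the
composite chemical-shift perturbation relative to the ligand-free reference,

    Δδ_ave = sqrt( (Δδ¹H)² + (Δδ¹⁵N/5)² )   [ppm],

with the conventional 1/5 scaling of the ¹⁵N dimension.  Residues enter the
global fit when their maximum Δδ_ave over the titration strictly exceeds
0.03 ppm ("over" read as a strict inequality; the comparator threshold is an
argument of `select_residues`).  Prolines, overlap-excluded and
reference-missing residues are carried in the profile with an explicit
exclusion reason, never silently dropped; a residue broadened beyond
detection at some points contributes its remaining points only.

Fast exchange means one cross-peak at the population-weighted average
position, so the predicted perturbation is linear in species fractions.
Slow-exchange behaviour (disappearing/appearing peaks) is outside the model
and such points should simply be absent from the table.

## Binding models and equilibrium solvers

All five models conserve protein and ligand mass exactly (ligand depletion
is never approximated away: at 200–270 μM protein every fitted K_D in the
system is comparable to or below the protein concentration).  Concentrations
are μM throughout; equilibrium constants are dissociation constants in μM.

* **Single site** — [PL] from the numerically stable root of the quadratic
  mass balance, `2PL/(b + sqrt(b² − 4PL))` with `b = P + L + K_D`.
* **Two-site independent** — free ligand L_f is the unique root of
  `L = L_f + P·(L_f/(K_D1+L_f) + L_f/(K_D2+L_f))` on [0, L]; site
  occupancies are θ_i = L_f/(K_Di+L_f) and the four species (P, L–P, P–L,
  L–P–L) follow binomially.
* **Two-site cooperative** — the second binding event at either site is
  rescaled by a modulation factor α: K_D3 = α·K_D2 and K_D4 = α·K_D2²/K_D1,
  which closes the thermodynamic cycle K_D1·K_D4 = K_D2·K_D3 by
  construction.  Free protein is eliminated analytically and L_f solved by
  the same bracketed root find.  α = 1 reproduces the independent model to
  solver precision.
* **Conformational selection** — free protein pre-equilibrates between an
  inactive and an active conformer, K_f = [active]/[inactive]; only the
  active conformer binds (K_D).  Total binding follows a single-site
  isotherm with apparent K_D,app = K_D·(1 + 1/K_f).
* **Induced fit** — binding (K_D) precedes rearrangement of the complex,
  K_f = [closed]/[open]; K_D,app = K_D/(1 + K_f).

Root finding uses Brent's method on [0, L_total] at relative tolerance
4·eps; mass-balance residuals are checked to < 1e-9 relative on every
solved state.  The K_f direction conventions above are stated explicitly
because the two-state schemes are invariant under K_f → 1/K_f with the
state labels swapped.

Predicted CSP curves are basis expansions: each model yields a
population-fraction basis B(t) (one column per response amplitude; all
columns vanish at the reference point), and a residue's curve is B·a with
amplitudes a = Δ_max, (Δ_LP, Δ_PL) or (Δ_open, Δ_close).  The
conformational-selection basis is referenced to the ligand-free equilibrium
so curves start at exactly zero.

## Fitting

Global fits share the thermodynamic parameters across residues and give
each residue its own amplitudes; residue-specific fits repeat the whole
procedure per residue.  The objective is unweighted least squares on
Δδ_ave over all selected residues and titration points ≥ 1 (the reference
point is identically zero by construction and carries no information).

Because the model is linear in amplitudes, they are profiled out by an
inner linear solve (variable projection); the outer problem over the shared
constants is solved by Levenberg–Marquardt in log10 parameter space, which
guarantees positivity without active bounds and stabilises constants
spanning four decades.  Starts come from a coarse log-space grid (13 points
per decade-spanning axis, kd1 ≤ kd2 half-plane only) plus a half-saturation
heuristic; the best grid point seeds the refinement.  The two-site models
are invariant under relabelling the sites (kd1 ↔ kd2 with amplitudes
swapped); results are canonicalised to kd1 ≤ kd2.

Two numerical choices deserve justification:

* **Amplitudes are unconstrained by default.**  Fitting Δδ_ave suggests
  constraining amplitudes ≥ 0, but a residue that genuinely reports on one
  site has a true amplitude of exactly zero on the other, and non-negative
  truncation then keeps only the positive half of the noise at that
  boundary.  The shared constants absorb the asymmetry: in simulation the
  global K_D1 comes out ~10% low under the constraint, and because the
  residual bootstrap refits under the same constraint the bias is applied
  twice and 95% intervals essentially never cover the truth.  Unconstrained
  amplitudes remove the bias (recovery within a few percent, CI coverage
  ≈ 93%).  `FitSpec(nonneg_amplitudes=True)` restores the constraint, which
  remains useful for data-poor residue-specific fits where per-curve
  overfitting dominates instead.
* **Amplitude box |a| ≤ 5 ppm.**  When two occupancy curves become nearly
  collinear (e.g. K_D1 ≈ K_D2), unconstrained inner solves can cancel huge
  ± amplitude pairs along the machine-precision difference of the columns
  and chase noise.  Saturation amide CSPs are far below 1 ppm, so a 5 ppm
  box excludes only these degenerate solutions.

Degenerate inputs: a fit with fewer observations than parameters raises an
under-determination error; an empty selection is an explicit error; missing
observations are absent rows (no imputation); an all-zero residue
contributes zero amplitudes and leaves the shared constants unchanged.
Refitting from a converged solution moves the RSS by < 1e-10 (fixed point).

## Bootstrap confidence intervals

Parameter precision uses the residual bootstrap: residuals of the converged
fit are resampled with replacement (pooled across the whole fit by default;
a per-curve option restricts resampling within each residue), added to the
fitted values, and the model is refit per replicate, warm-started from the
point estimate.  Interval bounds are order statistics of the replicate
distribution: rank round(n(1−c)/2) and round(n(1+c)/2), 1-based — for
n = 1000 at 95% coverage, the 25th and 975th smallest values.  Replicate
refit failures are counted and excluded; more than 5% flags the summary.
Coverage is configurable (the workflow that motivated this package quotes
both 95% and 98% intervals; 95% with ranks 25/975 is the operational
default).

Model comparison reports RSS, residual SD (sqrt(RSS/dof)) and bootstrap
parameter SDs per model; models whose residual-SD bootstrap intervals
overlap the best model's are marked indistinguishable, and the advisory
"preferred" verdict goes to the most parsimonious of those (fewest
parameters, ties by RSS).  No information criteria are used for selection.

## Synthetic data generator

The generator emulates the experimental designs so the whole pipeline is
testable closed-loop.  Presets (protein concentration, molar-ratio ladder,
truth constants):

| preset | truth model, constants (μM)        | protein (μM) | ratio ladder              |
|--------|------------------------------------|--------------|---------------------------|
| S4     | two-site indep., 38.7 / 520.5      | 250          | 0.25…12 (8 rungs)         |
| S5     | two-site indep., 40.9 / 900.8      | 250          | …12, 18, 24, 36           |
| S9     | two-site indep., 28.4 / 515.9      | 250          | …12, 18, 24, 36           |
| S10    | two-site indep., 483.1 / 579.2     | 250          | …12, 18, 24               |
| EGFR   | single site, 4.2                   | 200          | 0.25, 0.5, 0.75, 1, 1.5, 2|

Only the endpoint ratios of the longer titrations are documented for the
original experiments; the intermediate rungs (and the whole EGFR ladder
below its 1:2 endpoint) extend the 1:12 ladder geometrically and are a
convention of this package.

The residue ensemble defaults to 20 site-1 reporters, 10 site-2 reporters,
5 mixed reporters and 15 null residues.  Saturation amplitudes are drawn
uniformly from 0.05–0.25 ppm (mixed: 0.03–0.15 ppm per site), typical of
amide CSPs at peptide saturation.  Each residue draws one nucleus direction
φ and realises an amplitude A as (Δ¹H, Δ¹⁵N) = (A·cos φ, 5·A·sin φ), so the
composite equals A; both sites of a mixed residue share the direction
(collinear responses), making the σ=0 composite exactly Δ_LP·θ1 + Δ_PL·θ2.
Independent Gaussian noise is added per nucleus per point, reference
included, with defaults σ(¹H) = 0.002 and σ(¹⁵N) = 0.010 ppm — typical
HSQC peak-position repeatability.  Protein concentration is constant
(dilution off by default; a per-point dilution factor can be supplied via a
custom schedule).

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about real data: curved/U-turn shift trajectories
(non-collinear site responses), slow- or intermediate-exchange lineshapes,
peak overlap, assignment errors, dimerisation equilibria, and systematic
concentration errors.

## Known limitations

* **Near-equal constants are not jointly recoverable at realistic noise.**
  When K_D1 ≈ K_D2 (the S10 design: 483 vs 579 μM) the two occupancy curves
  are nearly collinear and the least-squares minimum genuinely sits at
  spread-apart constants; starting the optimiser at the truth converges to
  the same spread solution, so this is estimator bias, not an optimisation
  failure.  Median recovered constants across seeds err by ~±50% there,
  while well-separated designs (S4/S5/S9, ratio ≥ 13) recover to a few
  percent.  Reported uncertainties for near-degenerate pairs should be read
  with this in mind.
* **The cooperative model's α is structurally weakly identified from CSP
  data.**  With free per-residue amplitudes the data constrain only the
  span of (θ1, θ2), and the cooperative family contains a ridge
  (K_D2 → ∞, α → 0 with α·K_D2 fixed: sequential binding) that reproduces
  the independent-model span whenever site 1 saturates well before site 2.
  Comparisons on such data correctly report the models as indistinguishable
  and parsimony selects the independent model — but a fitted α value alone
  should not be interpreted.
* **Two-state models are only identified through K_D,app.**  Conformational
  selection and induced fit fit any single-site-consistent dataset exactly
  (apparent-K_D identities), so CSP titrations alone cannot distinguish
  them; the comparison machinery reports this honestly.
* Percentile bootstrap intervals inherit any estimator bias twice (the
  replicates are refit to data simulated from the biased fit); they are
  accurate for the well-identified regimes and optimistic for degenerate
  ones.
* Problem sizes in the test and acceptance suites (10–20 seeded replicates
  per design, 200 bootstrap replicates inside the coverage study, 200
  coverage replications) are the package's chosen defaults for routine
  verification; the full 1000-replicate bootstrap is used wherever a single
  dataset is analysed.
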