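# Methods

## Model

### Binding scheme

The model tracks the equilibrium of estrogen receptor α (ER) with two
competing ligands — the natural hormone 17β-estradiol (H) and a SERM-type
competitive inhibitor (I, tamoxifen throughout) — and ERE promoter DNA (D).
Ligand binding and dimerisation occur at spatially separate sites of the
receptor, so every combination of (0–2 monomers) × (0–2 ligands) is
allowed; ER monomers do not bind ERE (dimer binding is far more
efficient), and only dimeric species bind D.  That gives 18 species: the
free forms ER, H, I, D; the monomer complexes ERH, ERI; the dimers ER₂,
ER₂H, ER₂H₂, ER₂I, ER₂I₂, ER₂HI; and the ERE-bound dimers ER₂D, ER₂HD,
ER₂H₂D, ER₂ID, ER₂I₂D, ER₂HID.

Each complex is a monomial in the free concentrations divided by a product
of dissociation constants, e.g. ER₂H₂D = ER²·H²·D / (K1·K2·K3·K17).
Twenty constants K1–K20 label the reactions; because several complexes can
form along alternative reaction paths, thermodynamic consistency (detailed
balance around each cycle) forces six constants to be derived:

    K5 = K1·K2/K4        K6 = K1·K2·K3/K4²      K10 = K1·K7/K9
    K11 = K1·K7·K8/K9²   K12 = K1·K7·K13/(K4·K9)  K14 = K7·K13/K2

`BindingConstants` always re-derives these; user code cannot produce a
thermodynamically inconsistent constant set without tripping validation.
Note the published parameter table prints K11 = 41.5 while the cycle
relation gives 41.67 (and the same table's K12 = 26.67 agrees exactly with
its cycle relation); this package always uses the derived value.  K20 is
published only as the range 10–20 nM; the packaged default is the midpoint
15 nM, configurable in the parameter file.

### Conservation and the equilibrium solver

Totals ER_t, H_t, I_t, D_t are conserved.  Substituting the monomials into
the four conservation equations leaves four unknowns — the free
concentrations — solved by a damped Newton iteration on log-transformed
variables (positivity by construction) with an analytic Jacobian; the
initial guess is half of each total.  Residuals are scaled by the nonzero
totals and iterated to 1e-12; components with zero total are eliminated
analytically.  If Newton fails (not observed in testing across totals up
to 300 nM), the solver falls back to nested 1-D root isolation: bisection-
safeguarded Brent on free D, then I, then H, with free ER solved innermost
— each conservation residual is monotone in its own free concentration at
fixed outer variables, so the nesting is globally convergent.  The test
suite carries an independently written oracle of the nested kind and
requires agreement to 1e-6 relative in every species on 100 random
instances.

### Gene expression

Transcription is proportional to the ERE-bound complexes, with
complex-specific rate constants: k_sr for the hormone-laden dimers
(ER₂HD and ER₂H₂D share one constant), k_sr,i for tamoxifen-laden dimers,
k_sr,hi for the mixed complex, k_sr,b for the basal activity of the
unliganded dimer at ERE.  With first-order mRNA/protein turnover the
steady state is r̄ = v_tr/k_dr, p̄ = v_tr/κ with κ = k_dp·k_dr/k_sp.
Steady-state work therefore needs only (k_sr, k_sr,i, k_sr,hi, k_sr,b, κ);
the constituent constants k_dr, k_sp, k_dp matter only for the dynamic
consistency check (`integrate_expression`, an LSODA integration of the
two linear ODEs, checked against the closed-form solution and required to
land within 0.1% of the algebraic steady state).  `decompose_response`
splits p̄ into the six per-complex contributions k_X·X/κ, which sum to p̄
exactly.

## Parameters

All concentrations are nanomolar, all times seconds; no unit detection.
Packaged defaults (see `src/ermodel/data/default_params.ini`):

| group | values |
|---|---|
| dimerisation/hormone | K1=25, K2=0.2, K3=0.1, K4=0.25 |
| inhibitor | K7=10, K8=150, K9=30, K13=0.8 |
| ERE binding | K15=8, K16=2.4, K17=1.2, K18=50, K19=87, K20=15 (10–20 range) |
| transcription (s⁻¹) | k_sr=0.195, k_sr,i=0.02, k_sr,hi=0.05, k_sr,b=0.001 |
| turnover (s⁻¹) | k_dr=2.5e-3, k_sp=1e-3, k_dp=2e-5 → κ=5e-5 |

The reporter-cell (HEK293/hERα-like) condition used by `hek293_totals()`
is ER_t = 20 nM, D_t = 0.1 nM.  These totals are not published; they were
calibrated once against three independently reported dose–response
features of that cell line and then frozen: (i) tamoxifen alone stimulates
reporter expression ~4-fold above basal (model: 3.7×), (ii) the ER₂ID
contribution to expression peaks at ~50 nM tamoxifen (model: ~52 nM), and
(iii) with 0.5 nM estradiol, >1 µM tamoxifen leaves ~15% of the drug-free
expression (model: 15.7%).  The convergence of all three on the same
ER_t ≈ 20 nM supports the choice.

## Cooperativity analysis

The model contains no Hill equation; apparent cooperativity emerges from
the dimerisation linkage (a liganded monomer recruits a partner whose site
is then filled at higher affinity: K2 < K4, K3 < K2, K5 < K1).  To
quantify it, hormone-only binding curves (I_t = D_t = 0) are generated on
a log-spaced total-hormone grid auto-expanded so occupancy spans
0.02–0.98 (50 points), and fitted with B = L^n/(K_A^n + L^n) by unweighted
nonlinear least squares in linear B-space, with L the *free* hormone from
the equilibrium solve.  Exact Hill input is recovered exactly; fits whose
data do not span B < 0.1 to B > 0.9 are flagged rather than rejected.

With the default constants n_H rises from 1.03 at ER_t = 1 nM to 1.20 at
20 nM, and only approaches 1.4 in the fully dimeric limit (1.34 at 300 nM,
1.38 at 1 µM).  The often-quoted experimental ceiling of 1.4–1.5 is
therefore reached by this parameterisation only at receptor levels well
above 20 nM; within 1–20 nM the model's apparent cooperativity tops out
near 1.2 (this is robust to the fit variant — logit–log regression,
restricted occupancy ranges and the maximum local Hill slope all stay
≤ 1.24 at 20 nM).

## Calibration

`fit_block` reimplements the historical block-wise strategy: saturation
binding of purified receptor (ER_b vs labelled estradiol at 0.3/1.2/7/13
nM receptor), competition of labelled estradiol against unlabelled
estradiol (pooled with the label — chemically identical, so the labelled
share of bound sites is the labelled fraction of total hormone) or against
tamoxifen (the inhibitor arm), and reporter dose–response curves with a
free multiplicative scale from nM protein to assay units.  The objective
is the sum of squared deviations, optionally inverse-variance weighted
when datasets carry per-point errors; the optimizer is a hand-rolled
Hooke–Jeeves pattern search (exploratory ± steps per coordinate, pattern
extrapolation, step halving, termination when every step < tol) operating
on log10-transformed parameters inside box bounds (default ×/÷100 around
the start), with a seeded multi-start (default 5) around the initial
point.  Fits vary only independent constants; dependent ones are
re-derived each evaluation, so every candidate obeys detailed balance.

Identifiability, measured by recovery experiments on synthetic data:
noiseless curves return the generating constants to < 0.1%.  At realistic
noise (2% of curve maximum, additive) the monomer affinity K4 is
recovered within ~11% across noise realizations *provided* curves of
different amplitude are inverse-variance weighted — unweighted joint SSE
lets the 7/13 nM curves (large absolute errors, stoichiometric and
uninformative) drown the low-receptor curves that actually pin K4.  The
dimer-site constants K2 and K3 individually are *not* identifiable from
site-occupancy data (a flat ridge trades K2 against K3, with the
detailed-balance re-derivation of K5/K6 providing further compensation);
this mirrors the experimental impossibility of discriminating ER₂H from
ER₂H₂ effects.  Reporter fits recover {k_sr,i, scale} within a few
percent at 5% multiplicative noise.

## Synthetic data

`ermodel.synthetic` generates pseudo-datasets with the structure of the
calibration data (the original raw curves are not deposited anywhere):
noiseless output is exactly the corresponding predictor, so generation is
invertible and every pipeline stage is testable end to end.  Noise models:
additive Gaussian with σ a fraction of the curve maximum (default 2%,
scintillation-counting style) for binding data; multiplicative log-normal
(default 5%, plate-reader style) for reporter data; both truncate at zero,
record the generating σ per point (`y_err`), and are deterministic given
the seed.  What these datasets do not emulate: real replicate structure,
systematic (non-i.i.d.) assay errors, inter-laboratory variability, or
receptor-preparation artefacts — parameter-recovery results therefore
bound what idealised data of this size can identify, not what any
particular published experiment did.

## Global sensitivity analysis

Per fixed tamoxifen dose (I_t is a controlled experimental variable, not
a perturbed parameter): sample N parameter sets by Latin Hypercube
(scipy's implementation; exactly one sample per equal-probability stratum
per parameter), solve the model per row (dependent constants re-derived),
and compute per-parameter PRCC indices: rank-transform all columns
(average ranks on ties), regress each parameter's ranks and the readout's
ranks on the ranks of all *other* parameters by least squares, and
correlate the two residual vectors.  Positive index ⇒ larger parameter
values associate with larger p̄.  Failed solves are dropped pairwise with
a logged count; a failure rate above 1% aborts (pathological bounds).
The dose scan derives a fresh sampling seed per dose from (seed, dose
index), and the default dose grid is 138 log-spaced points over
0.01–3000 nM.

The perturbed set has 22 members: the 14 independent K's, the four
transcription rate constants, the composite κ, and ER_t, H_t, D_t.
Default bounds: ×/÷10 around the published value for constants and κ;
ER_t ∈ [0.001, 300] nM, H_t ∈ [0.03, 3] nM, D_t ∈ [0.01, 1] nM (the
biologically plausible ranges for normal and cancerous breast cells).
Sampling is uniform on each range — plain LHS over the hypercube of
ranges — with log-scale stratification available as an option.  The
choice matters: under log sampling the 5.5-decade ER_t range trivially
dominates every profile, while uniform sampling reproduces the expected
profile structure (D_t and κ on top throughout; K16 influential at low
dose; k_sr,b high at low dose; k_sr,i and ER_t rising sharply at 1000 nM
with K19 turning negative).  At N = 5000, |PRCC(D_t)| and |PRCC(κ)| are
statistically tied (~0.62–0.66 at every dose, differing by less than the
sampling noise across seeds); D_t ranks above every parameter other than
κ at all doses.

## Numerical choices

- Solver tolerance 1e-12 on scaled residuals; no randomness anywhere in
  the equilibrium/expression path — dose curves and surfaces are
  bit-for-bit reproducible.
- Newton steps are clipped to ±5 log-units and damped by backtracking
  halving (≤40 halvings) on the max-norm of scaled residuals.
- Hill fits: scipy `curve_fit`, p0 = (interpolated half-occupancy, 1.0),
  bounds K_A > 0, n_H ∈ [1e-3, 20].
- Hooke–Jeeves treats objective failures (exceptions, non-finite values)
  as +∞ (rejected move) and never returns a point worse than its start;
  ties across multi-starts resolve to the earliest start.
- Degenerate inputs: zero totals short-circuit analytically; ER_t = 0
  makes the bound-fraction H_b undefined (error), not zero.

## Problem sizes used in the shipped analyses

Hill profiles use 50-point hormone grids; dose curves default to the
138-point GSA dose grid; sensitivity profiles in the test suite use
N = 5000 samples at three doses (0.1, 50, 1000 nM); solver–oracle
cross-checks use 100 random instances with totals in [0, 300] nM; recovery
experiments use the 4 × 12-point saturation design and 21-point reporter
curves.  All are the package's own defaults chosen to characterise the
model at interactive run times.

## Known limitations

- Co-regulator proteins are not explicit; their differential recruitment
  is represented only through the transcription rate constants (that is
  the intended use of the k_sr,i dose–response surface).
- The equilibrium approximation assumes ligand-binding kinetics are fast
  relative to gene expression; no ligand depletion by metabolism, export
  or degradation is modelled.
- Monomer–ERE binding and non-palindromic ERE affinities are excluded.
- At the published constants the high-dose (>1 µM) tamoxifen inhibition
  at ER_t = 50 nM, H_t = 0.5 nM is 37–50% for D_t in 0.01–1 nM; the
  weakening of inhibition with increasing promoter density is monotone
  but drops below 30% only for D_t ≳ 10 nM.
- Binding constants other than K4 are only weakly identifiable from
  realistic site-occupancy data (see Calibration above).
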