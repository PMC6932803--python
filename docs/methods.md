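# Methods

## Model

`icisim` simulates the coupled dynamics of antigen-specific cellular
immunity, a growing melanoma, and the PD-1 inhibitor pembrolizumab as a
deterministic ODE system.

**T-cell grid.** CD8⁺ T cells live on a differentiation × senescence grid
T\[i, j\] with differentiation compartments i ∈ {SCM, CM, EM, EFF, EXH}
(T memory stem, central memory, effector memory, effector, fully exhausted)
and senescence index j ∈ {0, …, m} counting cumulative divisions of a
lineage (m = 25; division stops at j = m, replicative senescence). A cell at
(i, j < m) divides at an effective rate r_ij; both daughters move to
senescence level j + 1 and each independently stays in compartment i with
the self-renewal probability a_i or differentiates to i + 1 (EFF
differentiates into EXH, which neither divides nor kills). The mean-field
ODE uses the expected routing: division of T\[i, j\] removes one cell and
adds 2·a_i cells at (i, j+1) and 2·(1−a_i) at (i+1, j+1). Naive T cells are
an unlimited source; they enter at (SCM, 0) at rate σ_N·D_m/(K_D + D_m).

**Dendritic cells.** Tumor antigen activates DCs at rate
ρ_D·C/(C + K_Cdc); activated DCs mature (m_DC) into lymph-node DCs D_m that
decay at d_m. Mature DCs boost SCM/CM division by the factor
1 + s_max·D_m/(K_D + D_m) and drive naive recruitment.

**PD-1/PD-L1 pressure.** All checkpoint effects are carried by one
dimensionless signal

    g(C, B, j) = (j/m) · C/(C + K_PD) · (1 − B),

which rises linearly with the division index (inhibitory-receptor
expression accumulates with divisions), saturates in tumor burden
(PD-L1 ligation), and is scaled down by the blocked receptor fraction
B = P/(P + EC50) set by the drug concentration P. The pressure (a) impairs
EM/EFF division by the factor 1 − ε_div·g, (b) impairs killing by
1 − ε_kill·ĝ (ĝ evaluated at the count-weighted mean j of the killing
compartments), and (c) drives apoptosis of EM cells at kC03·g and EFF cells
at kC04·g.

**Tumor.** Burden C (cells; 10⁹ cells ≡ 1 cm³) follows

    dC/dt = p_C · C^(2/3) − C/(C + K_kill) · (1 − ε_kill·ĝ) · kE0 ·
            (Σ_j T[EFF, j] + φ_EM · Σ_j T[EM, j]),

i.e. power-law growth (surface-limited, exponent 2/3) minus saturating,
PD-1-impaired killing by effector and (at fraction φ_EM) effector-memory
cells.

**Drug.** One-compartment pharmacokinetics: IV doses are instantaneous
boluses P += dose/V_d (the 30-minute infusion is negligible against the
3-week dosing interval) with first-order elimination at ln 2/t_half.

All saturating interactions use Michaelis–Menten forms — the simplest
bounded choice. Internal time is hours.

## Parameters

Patient-specific parameters (defaults = the reference patient's best-fit
values): p_C = 1.828 (tumor growth, cells^⅓/h), kE0 = 0.00603 (effector
cytotoxicity, 1/h per cell), ρ_D = 0.95 (immunogenicity), kC03 = 0.0058 and
kC04 = 0.00535 (PD-1 apoptosis on EM/EFF, 1/h), and the self-renewal
probabilities a_SCM = 0.05, a_CM = 0.9, a_EM = 0.03, a_EFF = 0.92. The
alternating self-renewal pattern (low, high, low, high) acts as a
buffer/delay chain and is what makes a transient tumor-load increase
possible at all.

General parameters were calibrated **once** so that the specific defaults
reproduce the reference clinical course under 120 mg q3w dosing (see
*Calibration target* below), and are not revisited per analysis:

| parameter | value | meaning |
|---|---|---|
| m | 25 | max divisions per lineage |
| p_div | 0.02, 0.0158, 0.0129, 0.01 /h | intrinsic division rates SCM→EFF (decreasing with differentiation) |
| mu | 1e-4, 2e-4, 5e-4, 1.5e-3, 5e-3 /h | death rates SCM→EXH (non-decreasing) |
| σ_N | 213 cells/h | naive→SCM influx at DC saturation |
| s_max | 2.0 | maximal DC fold-boost of SCM/CM division |
| K_D | 20 cells | DC half-saturation |
| K_Cdc | 2×10⁹ cells | tumor half-saturation for DC activation |
| m_DC, d_act, d_m | 0.03, 0.02, 0.01 /h | DC maturation/death rates |
| K_PD | 5×10⁹ cells | tumor half-saturation of PD-1 ligation |
| ε_kill, ε_div | 0.95, 0.9 | maximal PD-1 impairment of killing / division |
| φ_EM | 0.5 | EM cytotoxicity as a fraction of kE0 |
| K_kill | 4×10¹¹ cells | kill-term half-saturation |
| t_half | 528 h | pembrolizumab elimination half-life (~22 d) |
| V_d | 7.7 L | distribution volume |
| EC50 | 12 mg/L | concentration at half receptor blockade |
| τ | 24 h | reinvigoration time constant (mean division time) |

The reference scenario starts from 10 cm³ baseline load, 10⁷ T cells spread
uniformly over all 130 grid bins, and 10 DCs in each DC pool.

Two calibration choices deserve comment. *Partial blockade:* EC50 is of
the order of the trough plasma concentration (~8–15 mg/L at 120 mg q3w),
so blockade is substantial but incomplete (B ≈ 0.4–0.6) and a
burden-dependent residue of PD-1 pruning survives treatment. This residue
is what caps the effector pool while the tumor is large and releases it
after a response — the mechanism behind both the double-peak course and
the hyperprogression of low-kE0 patients. *Nearly linear killing:*
K_kill far above clinical burdens makes the catch threshold (the effector
pool needed to halt growth) scale as C^(−1/3); control is therefore
self-limiting, and a patient whose cytotoxicity is a factor f too low is
caught only at roughly f³ times the burden — a 1.63-fold kE0 deficit
plateaus near 4–6× baseline, matching the reported hyperprogression fold.

## Calibration target

With the above defaults the simulated reference course shows: a first
tumor-load maximum near week 3 (≈1.5× baseline), shrinkage far below
baseline, a second maximum near week 52, 6.5% of baseline at week 162, and
3.1-fold untreated 12-week progression; with kE0/1.63 the treated load
rises monotonically to 4.2× baseline over 28 months. Wave 1 is the
reinvigorated pre-existing pool (uniformly senescence-distributed, hence
senescence-capped); wave 2 is the de-novo naive-influx response.

## Derived statistics

**Tumor load** is C/10⁹ in cm³ against weeks. **Reinvigoration** (Ki67⁺
proxy) is 100·τ·Σ r_ij·T_ij / Σ T_ij, the percentage of T cells currently
dividing, with r_ij the same effective rates the ODE uses (EXH and j = m
rows divide at rate 0; EXH cells stay in the denominator). In trials the
per-patient summary is the maximum over the first six treatment weeks.

## Calibration procedure

The fit minimizes RMSE between simulated and observed load at the data
weeks plus λ_b·Σ(squared bound violations) (λ_b = 10³) plus λ_t = 10² if
the untreated counterpart fails to progress (below 1.2× baseline at 12
untreated weeks) — the only concrete infeasible-trend constraint the model
imposes. Specific parameters move in wide boxes (0.28–3.5× reference),
general parameters in narrow ones (±20%). The optimizer is a seeded hybrid
under a fixed evaluation budget: annealed log-space perturbations of the
incumbent (step ~0.5 → 0.02 over the budget), uniform restarts over the
box, and Nelder-Mead refinement, in proportions 45/20/35. It is a contract
implementation (global/local alternation, reproducibility, best-ever
point), not a reproduction of any particular published optimizer.

Profile confidence intervals threshold the squared-error surface at
SSR* · (1 + χ²₁(level)/(n − p)) (Gaussian-error approximation); the profile
is evaluated on a log grid across the parameter box, optionally
re-optimizing the remaining free parameters. A profile flat above the
optimum (the kC03-type case: the pressure saturates, the likelihood
plateaus) yields a one-sided interval `[lower crossing, box bound]` with a
saturation flag.

## Virtual trials

Populations VP0–VP3 (125 patients) draw baseline load log-uniform in
1–300 cm³, lesion count uniform in 1–10, and patient-specific parameters
log-uniform in 0.28–3.5× (0.5–2× for the division rates in VP3; draws
violating the decreasing-rate hierarchy are rejected and redrawn). In VP2
and VP3, p_C is a deterministic log-linear function of baseline load
(rank correlation exactly 1). Every candidate is screened for untreated
progression (≥1.2× at 12 weeks; rejected candidates are replaced from the
same seeded stream). Treated patients receive 120 mg q3w for 12 weeks and
are classified on total burden: CR below 0.01 cm³, PR at ≤0.70× baseline,
PD at ≥1.20× baseline, SD otherwise; CR/PR are responders. The
responder classifier thresholds reinvigoration / baseline load and is
scored by balanced accuracy (mean of sensitivity and specificity),
maximized over all midpoints between sorted ratios (ties → lowest
threshold).

## Synthetic measurement error

A measured total load is split into equal spherical lesions; each of the
three axes of each lesion is perturbed by an independent uniform error in
±3 mm (the "maximal CT error" read as the half-width of a uniform
distribution), and the volume is recomputed — an exactly unbiased
perturbation. The emitted error bar is the first-order volume error under
identical errors along all axes, (π/6)·3d²·δ per lesion. The shipped
reference series (`fixtures/patient_o_like.csv`) uses noise seed 0,
anchors the week-0 point at the exact baseline, and samples at weeks
0, 3, 6, then every 9 weeks to week 162 (denser early surveillance; a
strictly 9-weekly grid cannot resolve a week-3–5 maximum).

## Numerics

LSODA (stiff-capable) with rtol 10⁻⁶ (10⁻⁹–10⁻¹⁰ in oracle tests) and an
absolute tolerance scaled to the initial state magnitude; dosing is
handled by integrating piecewise between bolus events. Sub-cell negative
excursions (<10⁻⁹ of the state scale) are clipped to zero; larger ones
raise an error. Trajectories are sampled on a uniform 6-hour grid by
default (12–24 h for long scans). Peak detection on treated curves first
smooths with a ±1.5-week moving average so the 3-week dosing ripple does
not register as a maximum.

Problem sizes in the shipped tests were chosen to keep the full suite
desk-scale: trials use the study size (125 patients, 5 seeds where
averaged); calibration recovery uses 24-week series with 9 points, fit
budgets of 40–220 evaluations, and 10–20 replicates.

## What the synthetic data do and do not show

The generator emulates total-burden PET/CT series with bounded axis error;
it does not model per-lesion heterogeneity, mixed responses across organs,
imaging-interval irregularity, inter-reader variability, or
pseudoprogression from infiltration/edema (in this model any transient
increase is true tumor growth). Passing recovery tests therefore show
identifiability under the model's own error structure, not robustness to
real-world imaging artefacts.

## Known limitations

* The right-hand side is a reconstruction from the interaction structure
  described for this model family; the original equations are not public.
  Saturation forms and the linear j/m receptor weight are the simplest
  choices consistent with that structure.
* The untreated-progression screen caps the initial T pool near 10⁷ cells;
  under treatment the pool must then expand ~13 doublings within 3–5
  weeks, so with m = 25 essentially the whole pool is senescent by week 6.
  The reinvigoration statistic consequently tracks DC/burden stimulation
  (hence baseline load) almost deterministically, and per-patient
  cytotoxicity leaves no imprint on it: VP1's ratio classifier performs
  near the load-only floor (~0.54) and VP0's load–reinvigoration
  correlation is positive rather than negative. Reproducing those two
  findings would need a different balance between pre-existing and
  de-novo immunity than this reconstruction can reach.
* No spatial structure, per-lesion dynamics, CD4/B/NK arms, multi-
  compartment PK, or immune-related adverse events.
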