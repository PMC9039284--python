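# Methods

## Scope and model organism

The package analyses steady-state chemostat cultures of carboxydotrophic
acetogens growing on CO ("CO gas": 60% CO, 40% Ar) or syngas (50% CO,
20% H2, 20% CO2, 10% Ar) at dilution rates of roughly 1.0, 2.0 and
2.8 day⁻¹. At steady state the dilution rate D equals the specific growth
rate μ, so the three levels probe μ-dependent physiology directly. All
rates are specific rates in mmol per gram dry cell weight per hour.

## Off-gas rate analysis

Argon is inert, so its molar flow is conserved and the outlet flow is
F_out = F_in·y_Ar,in/y_Ar,out. Specific rates follow from inlet/outlet
molar-flow differences normalised by the biomass inventory X·V. Choices:

- **Molar volume**: flows are interpreted at 0 °C, 1 atm
  (22.414 mL/mmol), the common mass-flow-controller reference; exposed as
  `molar_volume` everywhere since instruments differ.
- **Steady-state window**: traces are averaged over the trailing four
  reactor residence times (the midpoint of the 3–5 working volumes usually
  required for a chemostat steady state), and flagged unstable when any
  species' coefficient of variation within the window exceeds 2%.
- **MS scan normalisation**: windowed mean fractions are renormalised to
  sum to one before inversion; with noise-free input this is a no-op.
- **Sign convention**: `RatePanel` stores positive magnitudes with explicit
  uptake/production roles rather than signed values, because CO2 can switch
  between net uptake and net production depending on the feed.

## C-mol carbon balance

Product fractions are q_i·C_i over total substrate C-mol uptake (CO, plus
cysteine when configured); the biomass term is (μ/24)·c_biomass with
c_biomass = 0.0417 C-mol/gDCW (generic CH1.8O0.5N0.2, 24 g/C-mol), matching
the flux model's precursor draw exactly. Ethanol stripped to the off-gas is
added to the liquid-phase ethanol rate, and dissolved CO2 (Henry constant
0.0246 M/atm, pKa1 6.30 at 37 °C) leaves with the liquid outflow; at pH 5
the bicarbonate correction is below 6% of dissolved CO2 and the whole
dissolved term is minor. Normalised fractions are rescaled to sum to 100%
so carbon distributions are comparable across conditions whose raw
recoveries differ.

## Core stoichiometric model

The model covers the reactions that carry essentially all carbon and
electron flux in acetogen central metabolism (~30 reactions, 33
metabolites) rather than a genome-scale reconstruction; every claim the
package makes is at this resolution. Key stoichiometries:

- CODH: CO + H2O + Fd_ox → CO2 + Fd_red + 2 H⁺
- methylene-THF reductase: electron-bifurcating and NADH-dependent,
  methylene-THF + 2 NADH + Fd_ox → methyl-THF + 2 NAD⁺ + Fd_red
- Rnf: Fd_red + NAD⁺ → Fd_ox + NADH, translocating 2 H⁺
- ATP synthase: 4 H⁺ per ATP
- Hyt (leq000001): 2 H2 + Fd_ox + NADP⁺ → Fd_red + NADPH (the
  electron-balanced lumped form of the bifurcating hydrogenase)
- formate-H2 lyase (rxn08518_c0): CO2 + H2 → formate; FdhA-NADPH
  (rxn00103_c0): CO2 + NADPH → formate + NADP⁺. Both are irreversible
  toward formate: their reverse, combined with Hyt, forms a
  thermodynamically impossible cycle that converts NADPH to Fd_red and
  pumps protons for free, which would unbound the maintenance flux.
- ADH and BDH use NADPH (primary–secondary alcohol dehydrogenase
  chemistry); a config switch to NADH is available on the
  `BiomassComposition`-style parameters if needed.

Internal reactions are validated for elemental carbon balance and
degree-of-reduction closure at build time (CO = 2 e⁻, H2 = 2, acetate = 8,
ethanol = 12, 2,3-butanediol = 22, NAD(P)H and Fd_red = 2 per pair);
exchange and biomass pseudo-reactions are exempt.

**Biomass pseudo-reaction.** 1 gDCW draws 15 mmol acetyl-CoA + 3.9 mmol
pyruvate (41.7 mmol C, consistent with the 0.0417 C-mol/gDCW balance
parameter), 12 mmol NADPH, and 95 mmol ATP. The ATP coefficient follows
the Bauchop–Elsden yield for anaerobes (Y_ATP ≈ 10.5 g biomass per mol
ATP); with this value the maximal-ATP-dissipation estimates on the
reference conditions land in the 9–13 mmol ATP/gDCW/h range with
maintenance at 25–30% of total ATP production, the regime expected for
energy-limited autotrophic acetogens. A much smaller coefficient shifts
that surplus into apparent maintenance.

## FBA procedures

The LP max cᵀv s.t. S·v = 0 with flux bounds is solved with HiGHS
(scipy.optimize.linprog); among alternate optima a secondary minimisation
of Σ|v| picks a reproducible representative flux vector. Infeasible and
unbounded problems are reported as statuses, never silently.

- **Flux estimation** fixes measured exchange rates and the biomass flux
  (μ/24) within a relative tolerance band and maximises ATP dissipation.
  The default band is ±2% (measurement noise makes exact fixing
  infeasible on real data); noise-free synthetic data are estimated at
  tolerance 0. Note that with a nonzero band the maximiser uses the slack
  (≈0.5 mmol extra ATP per extra mmol CO), so exact parameter-recovery
  claims are made at tolerance 0 only.
- **Phenotype prediction** fixes maintenance and treats substrate uptakes
  as capacities (uptake ≤ q); under coupling constraints an exactly-fixed
  H2 uptake strands electrons (the core network has no H2 evolution or
  formate overflow) and is unconditionally infeasible.
- **H2 coupling.** With coupling on, the NADPH-consuming FdhA route is
  zeroed and the bifurcating-hydrogenase flux is tied to the
  formate-H2-lyase flux as v(leq000001) = r·v(rxn08518_c0) with
  r = q_H2/q_CO of the experiment. The transposed orientation
  (lyase = r·hydrogenase) would force more than (1 + 2/r) H2 — over five
  H2-derived electrons at realistic r — into every methyl group, more than
  any product can accept, and admits only the zero flux vector; the
  orientation used here reproduces the expected physiology (most H2
  reduces CO2 to formate directly, Hyt flux small).
- **Theoretical CO2 loss** zeroes biomass and all products but one,
  maximises that product's export at fixed CO (and optional H2) uptake and
  reports CO2 exported per CO consumed. The ethanol values (2/3 from pure
  CO, 1/2 at CO:H2 = 2) follow from electron counting and are recovered by
  the LP exactly.

## Synthetic data generator

The generator emulates the 23-reactor design (2 gases × 3 dilution rates
with 4/3/3 and 6/3/4 bioreplicates) with biomass concentrations of
1.4–1.7 gDCW/L. Per-condition physiologies keep the study-scale anchors —
q_CO of 32/50/70 (CO) and 25/50/73 (syngas), q_H2 of 7/21/21,
acetate/ethanol molar ratios falling from 1.5 to 0.9 (CO) and 0.6
(syngas), 2,3-BDO carbon fractions of 0.4–3.6% — and derive the
acetate/ethanol/CO2 rates from exact C-mol and degree-of-reduction
closure. Because the paper-style printed means do not themselves close a
balance, the derived q_CO2 and fractions differ from the anchors by a few
percent at mid conditions; the μ≈2.8 endpoints (q_CO2 ≈ 42 and 36, acetate
fractions ≈ 15.6% and 14.9%) stay close to the expected magnitudes. The
maintenance-ATP ground truth for each condition is the model's own
maximal-ATP-dissipation value at the derived exchange rates, so flux
estimation on noise-free data is an exact round trip;
`physiology_for_maintenance` root-finds q_CO to hit a requested
maintenance value.

Noise is multiplicative Gaussian with 2% relative SD on off-gas mole
fractions and broth concentrations (matching few-percent replicate
scatter); 5% of produced ethanol is stripped to the off-gas by default.
RNA-seq counts are negative-binomial (dispersion 0.005, reflecting tight
chemostat bioreplicates) with library sizes uniform in 5.6–9.3 million;
planted "slope" genes move their log2 mean expression linearly in μ
(default |slope| = 1 per day, ≈3.5-fold across the μ range), half with
identical slopes on both gases (the tight-control truth) and half with a
two-fold slope difference. The default gene count is 2,000 (desk scale;
a real genome has about twice that), configurable.

What the generator does **not** emulate: gas–liquid mass-transfer dynamics
and transients, pH/temperature excursions, compositional biases of real
RNA-seq (TMM-normalisable), read-level error structure, or correlated
replicate effects. Passing tests therefore demonstrate correctness of the
analysis mathematics and calibrated statistical power, not robustness to
every real-data pathology.

## Transcriptome statistics

The engine is deliberately simple and fully specified: library-size CPM,
log2(CPM + 0.5), Welch t-tests, Benjamini–Hochberg step-up FDR. This is a
documented simplification relative to TMM/moderated-statistics pipelines;
correctness is asserted against synthetic truth and exact oracles, not
against any external tool's internals. Comparisons are restricted to μ
levels within one gas mixture — cross-gas requests raise an error, since
gas mixes at the same μ were not part of the design.

- DEG: fold-change > 1.5 (strict) and q < 0.05.
- Expression filter: RPKM strictly greater than 10 in at least two
  samples; the filter is idempotent.
- Clustering: Ward (D2) on Euclidean distances of row-z-scored profiles;
  the cluster count is the largest relative drop between consecutive
  dendrogram merge heights, ties toward fewer clusters; constant rows are
  excluded with a warning.
- Enrichment: one-sided Fisher exact (over-representation) per term with
  BH correction across terms; classic Fisher only (no elim/weight-style
  decorrelation).
- Tight-control genes: DEGs with consistent direction in both consecutive
  within-gas comparisons on both gases, then per-gas OLS slopes of log2
  CPM against μ, then a two-slope t-test (difference over pooled SE,
  pooled residual dof). A gene is retained when slope equality is *not*
  rejected (p ≥ 0.05) — the reading consistent with selecting genes that
  show the *same* trend on both gases; the literal opposite polarity
  (retain p < 0.05) is available via `require_equal_slopes=False`.
  Whether slopes are fit on log or linear expression is a free choice;
  log2 CPM is used.

## Numerical and design notes

- Single global seed; all randomness flows through
  `numpy.random.default_rng` children, and identical seeds give
  byte-identical datasets and reports.
- LP tolerances: steady-state residual ≤ 1e-6, bounds respected to 1e-9
  (HiGHS defaults are tighter in practice).
- Degenerate inputs raise typed errors (zero Ar in off-gas, zero substrate
  carbon, zero-ethanol product ratio, cross-gas DEG comparisons,
  infeasible physiologies name the offending species).
- Problem sizes in the shipped tests (300–2,000 genes, 23 reactors,
  25 timepoints) keep the full suite and pipeline in the seconds range;
  all sizes are configurable upward.

## Known limitations

- The core model cannot represent genome-scale phenomena (alternative
  pathways, cofactor promiscuity, gene–protein–reaction mapping), so
  absolute maintenance values carry biomass-composition uncertainty.
- Uncoupled phenotype prediction yields acetate as the sole product — the
  known failure mode of yield-maximising FBA for reduced by-products; the
  coupling constraints are an empirical repair, not a thermodynamic
  theory.
- The DE engine does not share information across genes (no empirical
  Bayes moderation); at two or three replicates its q-values are
  conservative relative to moderated pipelines.
- Henry/pKa constants are fixed at 37 °C values; the temperature argument
  is accepted for interface clarity but no van 't Hoff correction is
  applied.
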