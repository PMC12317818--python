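# Methods

## Model structure

One fish is four states — structural volume `V` (cm³), reserve `E` (J),
maturity `E_H` (J), reproduction buffer `E_R` (J) — plus the stomach content
`M_X` (C-mol of ash-free dry food).  Runs start at or after "birth" (first
exogenous feeding); the embryo stage is not modelled.  Life-stage
transitions fire once each, in order birth → metamorphosis → puberty, when
`E_H` crosses the corresponding threshold.

Reserve mobilisation uses the weak-homeostasis closed form

    ṗ_C = [E] (E_G v̇ s_M c_T L² + ṗ_S) / (E_G + κ[E]),   [E] = E/V,

with `ṗ_S = [ṗ_M] c_T V` and `ṗ_J = k_J c_T min(E_H, E_Hp)`.  Growth gets
`κṗ_C − ṗ_S`, maturation/reproduction `(1−κ)ṗ_C − ṗ_J`.  Somatic
maintenance has priority: a shortfall is first paid from the maturity
branch; if mobilisation cannot cover maintenance at all, maintenance is
paid directly from reserve (`ṗ_C` is raised to `ṗ_S + ṗ_J`, growth and
maturation zero, the step flagged as starving) and the run stops with a
diagnostic when `E` reaches zero.  No shrinking or rejuvenation rules are
implemented.  With these rules `ṗ_C = ṗ_S + ṗ_J + ṗ_G + ṗ_R` holds exactly
at every step, which the tests assert to 1e-9.

Acceleration (abj): `s_M = 1` below the birth threshold, `L/L_b` between
birth and metamorphosis, frozen at `L_j/L_b` after.  `s_M` multiplies the
surface-specific assimilation and digestion rates and the conductance `v̇`.
A single Arrhenius factor `c_T = exp(T_A/T_ref − T_A/T)` corrects all rate
parameters; the five-parameter extended correction is out of scope.

## Digestion module

Feed enters as a proximate analysis (protein/fat/carbohydrate/ash mass
fractions of dry matter, apparent digestibility coefficients, dry and wet
specific densities).  Macronutrients are generalised compounds
`CH_nH O_nO N_nN`; defaults are protein CH₁.₆₁O₀.₃₃N₀.₂₈, lipid
CH₁.₉₂O₀.₁₂, carbohydrate CH₂O (glucose monomer), reserve and structure
CH₁.₈O₀.₅N₀.₁₅.  These and the combustion coefficients (23.6 / 39.5 /
17.2 kJ/g) are an overridable configuration table, not hard-coded truth.
`a_P` is the C-mol fraction of ash-free dry matter that is protein; ash is
excluded from all reserve dynamics and traced to the faeces.

### Coupling yields (the reconstructed closure)

The stoichiometry of reserve synthesis is not fully specified by the
published description, so the shipped scheme is a documented
reconstruction, chosen for exact elemental closure with the fewest free
constants:

* `q_P = n_NE / n_N,protein` — absorbed protein C-mol per C-mol reserve,
  anchored by the nitrogen balance (all reserve N comes from protein);
* `q_nP = 1/κ_A − q_P` — absorbed non-protein C-mol, anchored by the
  carbon balance; `κ_A` (default 0.8) is the reserve yield on absorbed
  carbon, the surplus `1/κ_A − 1` being respired as assimilation CO₂;
* `y_PE = (1−adc_P)/adc_P · q_P + (1−adc_nP)/adc_nP · q_nP` — the
  indigestible companions of the absorbed substrate, egested as faeces
  whose composition is their C-mol-weighted mixture.

Every ingested carbon is counted exactly once in `q_P + q_nP + y_PE`, the
stomach-drain coefficient.  Two consequences worth knowing:

* the ammonia flux of assimilation is exactly zero, so the reported TAN,
  `J̇_N = η_ND ṗ_D + η_NG ṗ_G`, carries no assimilation term while the
  four-element audit stays exact (a config flag `include_assimilation_n`
  re-enables the term for sensitivity work);
* nitrogen output *per C-mol of reserve formed* is diet-independent.  Feed
  composition therefore changes nitrogen waste only through how much is
  assimilated (e.g. a protein→carbohydrate swap lowers digestible energy
  and with it TAN).  A protein→fat swap at equal ration changes total N
  output only marginally under this closure; schemes in which dietary
  protein surplus flows directly to waste are incompatible with the SU
  nullification property below, because they require the protein yield to
  scale with `a_P`.

### SU kinetics

With `A = q_P/a_P` and `B = q_nP/(1−a_P)`,

    M_KX = (J̇_EAm,d / J̇_Xg,m) · (A + B − (1/A + 1/B)⁻¹).

The bracket grouping of the published equation is typographically
ambiguous; this parallel-complementary form is adopted because it is the
standard SU closed form and uniquely yields `M_KX → ∞` (assimilation
nullified) as `a_P → 0` or `1`.  Boundary compositions return an infinite
half-saturation rather than an error so composition sweeps run unattended.
Temperature and acceleration scale both surface-specific rates equally, so
`M_KX` depends on neither.

### Stomach capacity and meals

At capacity the dry feed plus its moisturising water fill the stomach
volume `δ_g V`:

    [M_gm] = (y_HXd d_Xd / d_H + 1)⁻¹ · d_Xd / w_X · δ_g .

A meal adds `min([M_gm]V − M_X, k_X (d_Xd/d_Xw) W / w_X)` instantaneously
(feeding lasts minutes, digestion days); offered-minus-eaten is logged as
uneaten feed.  The ration `k_X` is re-evaluated against current model
weight at each meal.  The conversion applies the dry-to-wet ratio only, as
the capacity relation is written; dietary ash rides along into the faeces
at the diet's ash-per-C-mol ratio.  If a meal's diet differs from the
resident stomach content, the content is re-pooled to the mass-weighted
proximate mixture; single-diet runs are unaffected.

## Mineral fluxes

For each basic power the four mineral fluxes (CO₂, H₂O, O₂, NH₃) are the
unique solution of the linear C/H/O/N balance of the organic fluxes that
power drives (food substrates and faeces for assimilation; reserve for
dissipation; reserve and structure for growth, with
`y_VG = [M_V]/E_G` mol structure per J).  Metabolic water is computed for
the balance but not reported.  Elemental conservation is therefore an
algebraic identity, independent of integration error; the acceptance test
audits it at every hourly step of a 30-day run.

## Parameters

The bundled set is a rainbow-trout-like **fixture**: internally consistent,
with magnitudes chosen so that a 150 g fish at 15 °C reaches satiation
around 1 %BW/d, empties a full stomach in roughly a day (5–70 g fish:
one to three days, temperature-ordered), and grows at on-growing rates.
It is not asserted to equal any database entry.

| parameter | value | units | role |
|---|---|---|---|
| κ | 0.65 | – | allocation to soma |
| p_Am | 1200 | J d⁻¹cm⁻² | max assimilation (pre-acceleration, T_ref) |
| v | 0.15 | cm d⁻¹ | energy conductance |
| [p_M] | 150 | J d⁻¹cm⁻³ | somatic maintenance |
| E_G | 5220 | J cm⁻³ | cost of structure |
| k_J | 0.002 | d⁻¹ | maturity maintenance |
| κ_R | 0.95 | – | reproduction efficiency |
| E_Hb, E_Hj, E_Hp | 30, 600, 3·10⁵ | J | stage thresholds |
| T_A, T_ref | 8000, 293.15 | K | Arrhenius correction |
| L_b, L_j, L_p | 0.35, 0.77, 5.5 | cm | stage lengths (s_M max 2.2) |
| μ_E, w_Ed, d_Ed | 5.5·10⁵, 23.9, 0.30 | J/mol, g/mol, g/cm³ | reserve chemistry |
| d_Vw, d_Vd | 1.0, 0.20 | g/cm³ | structure densities |
| J_Xg,m | 0.25 | d⁻¹cm⁻² | digestion rate coefficient |
| δ_g | 0.10 | – | stomach shape (capacity ≈ 2 %BW dry) |
| y_HXd | 0.8425 | g/g | moisturising coefficient |
| κ_A | 0.8 | – | reserve yield on absorbed C |

The wet-weight relation `W = d_Vw V + (E+E_R) w_Ed/(d_Ed μ_E)` reads
`d_Ed` as grams of dry reserve per cm³ of reserve volume, so the second
term is the wet-mass contribution of reserve with water at 1 g/cm³ — the
only dimensionally consistent reading.  Stomach content is excluded from
weight.  Initial states are constructed from a target weight at an assumed
reserve density `e = f`; maturity is assigned from structural length
(cubic interpolation between stage thresholds), a heuristic that only
affects the small maturity-maintenance flux.

## Numerics

* Units are J, mol, cm, g, d throughout; conversions at the I/O boundary.
* Between events the 5 states plus 3 cumulative power integrals are
  integrated with LSODA, rtol 1e-8 and per-state absolute tolerances;
  meals and temperature breakpoints delimit segments (stop–jump–restart).
* Puberty is a switching surface of the dynamics (`dE_H → 0`, `dE_R`
  switches on); it is handled as a terminal integration event with the
  maturity clamped to the threshold before restarting.  Without this the
  multistep step-size control collapses when `E_H` converges onto the
  threshold.
* Reserve exhaustion is a terminal event; the run is truncated with a
  diagnostic.
* Hourly output samples the post-meal state at meal hours; daily output is
  defined as the aggregate of the hourly series (mean rates, summed
  per-meal masses), so the two resolutions are consistent by construction.
* Satiation sweeps refill the stomach to capacity at each of a
  configurable number of meals per day (default 24, approximating ad
  libitum); because refilling resets the state, the daily cycle is
  periodic from the first meal and the per-period intake is solved from
  the separable-ODE implicit form with a bracketing root finder — no time
  stepping, which keeps 200-point composition grids cheap and smooth.
* Calibration fits run on log-parameters with a trust-region least-squares
  solver; residuals are normalised per dataset by the dataset mean, with
  optional per-dataset weights.  The optimiser is deterministic from its
  starting point.  A singular-value check of the final Jacobian warns on
  unidentifiable parameter subsets.

## Synthetic data

The fixtures module emulates the calibration experiments: gastric
evacuation curves over a 3-temperature × 3-size design sampled at 12 times
(1 h–8 d), stomach water-vs-dry-mass pairs on a 0.1–5 g grid with the
moisturising slope 0.8425, and growth-trial weight series from simulated
scenarios.  Observation noise is multiplicative lognormal (observations
are positive and heteroscedastic; default sd 0.05 for evacuation, 0.03 for
the water line, an additive option exists), reproducible from the seed
alone.  Passing the recovery tests shows the estimation machinery is
unbiased at zero noise and accurate to a few percent at realistic noise —
it does not validate the model against real fish, since generator and
fitted model share the same structure.  Real datasets would add
model-structure error (the published validation reports weight MRE ≈ 0.02
but gas-exchange and TAN MRE near 0.9).

## Known limitations

* The yield closure is a reconstruction; per-reserve nitrogen output is
  composition-invariant under it (see above), so composition effects on
  TAN are mediated entirely by assimilation magnitude.
* Diurnal TAN oscillations are small (fractions of a percent of the mean)
  because the reserve pool buffers dissipation; the feeding-frequency
  effect on TAN amplitude is directionally correct but much weaker than
  the post-prandial ammonia peaks of real fish, where excretion tracks
  amino-acid catabolism within hours.  O₂ pulses, driven directly by the
  assimilation term, are pronounced.
* One `[M_gm]` for all stages; no particle-size or gut-compartment
  effects; no NH₃/NH₄⁺ speciation or tank chemistry; no amino-acid or
  fatty-acid quality effects; no body-composition response to diet.
* `n_fish` multiplies identical individuals; no inter-individual
  variability.
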