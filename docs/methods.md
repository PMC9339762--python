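# Methods

## The allometric model

All per-individual resource requirements are modelled as power laws of
adult body mass, `x_i = a_i · M_i^b_i`, the standard allometric form. The
package ships a versioned catalogue (`published-v1`, 18 models) of
published coefficient sets:

| resource | stratification | count | units of x |
|---|---|---|---|
| population density / land area | mammal & bird × trophic level; reptile, insect pooled | 8 | individuals km⁻² (land = reciprocal, km² ind⁻¹) |
| energy (field metabolic rate) | same stratification | 8 | kJ ind⁻¹ day⁻¹ |
| water (active drinking) | mammal, bird (class-pooled) | 2 | m³ ind⁻¹ day⁻¹ |

Conventions and edge cases baked into the catalogue:

- **Trophic pooling.** Reptile and insect models are fitted across trophic
  levels (species-level data are too sparse to stratify); any trophic level
  requested for those classes resolves to the pooled model. Water models
  are pooled across trophic levels for all classes.
- **Insect energy.** The published insect law is a basal-metabolic-rate
  relation, `526 · M^0.832`; field conditions are obtained by multiplying
  the coefficient by 32 below 10⁻⁵ kg and by 8 at or above it, giving the
  two-branch model (16,832 / 4,208) with the boundary mass on the upper
  branch. The branches are deliberately discontinuous (a factor-4 drop at
  the threshold); monotonicity holds within each branch. Note the source
  literature for the multipliers uses a 10⁻⁶ kg size split; the catalogue
  follows the defining equations, which place it at 10⁻⁵ kg.
- **Reptile energy exponent** is stored as 0.889 (the defining equation's
  precision) rather than the 0.89 that appears in tabulated summaries.
- **Water means active drinking only.** Dietary and metabolic water are
  excluded by construction, because the question is competition with human
  users over appropriable water bodies. Reptiles and insects are assumed
  to satisfy water needs through diet, metabolism and atmospheric uptake:
  they return 0 with an `assumed-zero` provenance flag, not an error and
  not a modelled value. Users expecting total water turnover will see much
  smaller numbers.
- **Exponent signs** are validated structurally: negative for density
  (larger animals are sparser), positive for water and energy.

Evaluation keeps full floating precision; the published two-decimal /
few-significant-figure style is a reporting convention (round half away
from zero), applied only at the reporting layer.

### Extrapolation policy

The published equations do not state the body-mass ranges they were fitted
over. The engine therefore warns (never fails) when a mass falls outside a
per-class span chosen generously to bracket real species — mammal
10⁻³–10⁴ kg, bird 10⁻³–2×10² kg, reptile 10⁻³–5×10² kg, insect
10⁻⁹–10⁻¹ kg — and the spans are a keyword argument, not a constant.
This is a package policy, not an empirical statement about the fits.

## Fitting new coefficients

`fit_loglog` performs per-group ordinary least squares of log₁₀ density on
log₁₀ mass (statsmodels `OLS` underneath), with the default grouping
mirroring the catalogue's stratification. Choices a user should know:

- Standard errors of slope and intercept are the usual residual-variance
  estimates and stay **on the log₁₀ scale**; the intercept SE is never
  back-transformed to the coefficient scale (back-transformed SEs of a log
  intercept are not well defined without a distributional choice).
- Plain OLS: no weighting, no phylogenetic correction, no outlier
  handling. Repeated records of one species are independent points by
  default (compilations legitimately carry several density estimates per
  species); `species_average=True` collapses them to geometric means.
- A group needs ≥ 3 points with ≥ 2 distinct masses; failing groups are
  reported per group and do not abort the others.
- `confidence_band` gives the mean-response band
  `t_{n−2} · s · √(1/n + (x − x̄)²/S_xx)`, narrowest at the centroid of
  the fitted log-masses. It is a band for the *mean* log-density, not a
  prediction band for new species.

## Survey aggregation and the land-area constraint

Energy and water scale linearly in individual counts, so their summary
rows are count-weighted sums. Land area is **not** treated as additive
across species: interspecific sharing of the same area is real but
unquantified, so the summary reports both the naive count-weighted sum
(the convention of published population-level tables, kept for
comparability) and the per-individual maximum, which is the quantity with
constraint semantics. The constraint check compares each species' `L_i`
against the terrestrial site area; `L_i` ≤ area means all suitable natural
capital on site is accessible to that species (boundary equality counts as
within), `L_i` > area means the species likely ranges beyond the site.
Population density already embeds intraspecific sharing, which is why the
summed convention multiplies `L_i` by the count.

Body masses are caller-supplied (surveys rarely record them; they are
typically looked up from trait databases); the package deliberately does
not bundle a mass-lookup service.

## The bioproductive land-area budget

`L_BP = E_population,BP / (C_p · η · NPP · s)` converts the plant-derived
share of the population's energy demand into land area. Parameters, with
the demonstration-site preset (`NCL_PRESET`):

| parameter | meaning | units | preset |
|---|---|---|---|
| `C_p` | calorific value of plant matter | kJ kg⁻¹ | 18,812 |
| `η` | assimilation efficiency | kJ kJ⁻¹, (0, 1] | 0.475 |
| `NPP` | above-ground net primary productivity | kg km⁻² day⁻¹ | 918 |
| `s` | fraction of NPP suitable/accessible | kg kg⁻¹, (0, 1] | 0.1 |
| plant fraction | share of omnivore energy from plants | [0, 1] | 0.75 |
| included classes | classes feeding `E_population,BP` | — | mammal, bird |

`E_population,BP` sums 100% of herbivore energy and the plant fraction of
omnivore energy over the included classes; carnivores contribute nothing
(predation is assumed supplied beyond the site). The preset's η is the
midpoint of the commonly cited 15–80% herbivore assimilation range; the
75:25 omnivore plant:meat split and `s` = 0.1 are demonstration
assumptions, not measurements — both are ordinary parameters. The suitability
coefficient appears in some sources under a second symbol clashing with the
power-law intercept; it is one parameter here (`suitability_s`).

Two deliberate dual exposures:

- The report carries both `npp_energy_flux` (NPP·C_p, 1.73×10⁷ kJ km⁻²
  day⁻¹ at the preset) and `suitable_npp_mass_flux` (NPP·s, 91.8 kg km⁻²
  day⁻¹), because "suitable plant energy production" is ambiguous between
  the pre- and post-suitability flux and published summaries quote both.
- `run_assess` computes `E_population,BP` from the demand summary by the
  rule above, but also accepts an externally supplied value
  (`e_population_bp=`). The published worked example's 27,051 kJ day⁻¹
  reflects species-level diet composition not recoverable from class-level
  totals (the class-total hand-sum under the same rules gives 24,023.5),
  so reproducing it requires the override path — which the acceptance
  script uses, exactly as the published calculation does.

The water check is a screening comparison only: demand (ecosystem active
drinking + socioeconomic abstraction) against river throughput
width × velocity, in m³ per metre of depth per day. Proper accounting
belongs at the catchment level, and every report says so.

## Synthetic data

`generate_density_dataset` draws masses log-uniformly over a configurable
log₁₀ range (default −2…3) and adds Gaussian noise on log₁₀ density around
a known line — the exact data-generating process the OLS model assumes.
`generate_survey` draws species masses log-uniformly within plausible
per-class ranges and integer counts uniformly over a range, with a
composition helper matching the demonstration survey's class structure
(6 mammal / 31 bird / 1 reptile / 7 insect species). Both take an explicit
seed and use a private generator (no global state). What these fixtures do
**not** emulate: mass-measurement error, phylogenetic correlation,
heteroscedastic or non-Gaussian density scatter, detection bias in surveys
(the demonstration survey itself undercounts insects), or any spatial
structure. Passing tests therefore certify the estimation and accounting
machinery under the model's own assumptions, not robustness to real-data
pathologies.

## Numerical and testing choices

- Power laws are evaluated directly as `a·M^b`; tests pin them to the
  `exp(b·ln M + ln a)` path at 10⁻¹⁰ relative and land×density
  reciprocity at 10⁻¹² absolute.
- Aggregation accumulates cells, class totals and grand totals in sorted
  key order, making totals exactly reproducible and order-invariant.
- The Monte-Carlo calibration study uses 200 replicates of n = 500 points
  at noise sd 0.5 (runs in seconds); coverage of the 95% slope interval is
  asserted inside the exact central 99% binomial consistency region
  [0.905, 0.985] for 200 trials at p = 0.95, since a hard ±2-point window
  around 95% would reject a perfectly calibrated interval in about one run
  in six.
- Degenerate inputs fail loudly and specifically: nonpositive masses and
  densities, identical-mass groups, unknown labels, duplicate species,
  zero denominators. Survey rows outside the 10⁻⁹–10⁴ kg mass sanity range
  are errors in strict mode, logged warnings otherwise.
- Assessment reports are deterministic: identical inputs yield
  byte-identical canonical JSON (the provenance timestamp is excluded from
  the canonical form).

## Known limitations

- Interspecific competition for land is not modelled; the constraint
  interpretation is the package's hedge, not a resolution.
- Habitat-type and seasonal disaggregation of NPP (and of the allometries
  themselves) is out of scope; one site-average NPP is assumed.
- Carnivore energy supply (prey availability) is not modelled.
- No plant, fungal or marine allometries.
- Minimum-viable-population scaling is deliberately excluded: outputs
  describe the observed individuals, not persistence requirements.
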