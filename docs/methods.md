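# Model description and numerical methods

`boats` couples a size-spectrum model of commercially harvested marine
consumers ("fish") to an open-access economic model of fishing effort, on a
set of independent grid cells forced by net primary production (NPP) and
temperature, and wraps the pair in a Monte Carlo calibration pipeline.
This note records the governing equations as implemented, the closures the
package had to choose where the design was genuinely open, the numerical
scheme, and what the synthetic-data machinery does and does not emulate.

## Ecological module

Each of K groups (default three, labelled small/medium/large, asymptotic
masses m∞ = 30, 10³, 10⁵ g) is a "super-organism" spectrum f_k(m)
(gwB m⁻² g⁻¹, wet-biomass grams) obeying a McKendrick–von Foerster
equation

    ∂f/∂t = −∂(γ f)/∂m + γ f / m − Λ f − q σ E f,

with growth γ, natural mortality Λ, and (when coupled) the harvest sink
q σ E f.  The +γf/m term is the dilation gain: biomass flux grows as
individuals gain mass.

**Growth** is the minimum of two rates:

- the per-individual share of the energy available from primary production,
  ξ_P = φ_C π m / f, where π(m) = NPP_wB (m/m_φ)^τ / (m ln β) is the
  trophic-transfer spectrum with trophic scaling τ = ln α / ln β < 0
  (α trophic efficiency, β predator-to-prey mass ratio), NPP_wB the NPP in
  gwB m⁻² s⁻¹ (10 gwB per gC), and φ_C = 1/K the allocation fraction;
- the physiological (von Bertalanffy) ceiling ξ_VB = A m^b − k_a m, with
  A = A0 a_A(T) and the activity-cost closure k_a = A m∞^{b−1}, the only
  closure for which growth ceases exactly at the group-defining asymptotic
  mass.

Both temperature factors are van't Hoff–Arrhenius,
a(T) = exp[(ω/k_B)(1/T_ref − 1/T_K)], normalized to 1 at T_ref = 283.15 K
so that A0 and the mortality coefficient are interpretable at a
mid-latitude reference temperature.  A0 (default 4.46 g^{1−b} per model
year) is converted to per-second internally; a value of this magnitude is
only physically sensible per year (~550 g yr⁻¹ for a 1 kg fish).

Assimilated energy is split between somatic growth (1−Ψ) and reproduction
Ψ, with Ψ(m) a log-mass sigmoid centred at the maturity mass m_α
(default 0.25 m∞) whose slope is the same c_σ/δ₂ family as the gear
selectivity.  Biomass therefore accumulates just below m_α where somatic
growth stalls — the harvested community's "adult pile" — which is why
harvest spectra peak somewhat above the gear threshold mass for the large
group (within one decade; see the spectrum tests).

**Mortality** follows the empirical length-based law converted to mass:

    Λ = λ0 · e^{ζ1} A0 a_λ(T) · m^{−h} · m∞^{h+b−1},
    λ0 = (1/3) (δ1/m∞)^{(1.61−1.44)/3}.

The structural part (m^{−h} m∞^{h+b−1} with the e^{ζ1} A0 a_λ coefficient)
is the model's published form; λ0 is this package's normalization closure.
It is exactly the constant produced by the length-based estimate
ln M = ζ1 − 1.61 ln L + 1.44 ln L∞ + ln K with K = A m∞^{b−1}/3 and the
cube-law mass–length relationship m = δ1 l^{δ2}.  The normalization is not
cosmetic: the flux budget through the juvenile size range is exponential
in it, and without λ0 every group's juvenile attenuation reaches tens of
e-folds and the community goes extinct at the central parameter values.

**Recruitment** is the flux boundary condition at the recruit mass m0:

    f(m0) γ(m0) = R_P R_e / (R_P + R_e),

a harmonic-mean (limiting-factor) blend of R_P = φ_C π(m0) m0, the
primary-production flux at recruit size, and the egg channel
R_e = (s_e/2)(m0/m_egg) ∫ Ψ ξ_I (f/m) dm.  Here s_e is an egg-to-recruit
*number* survival (its sampled range 0.001–0.05 is meaningless as a
biomass fraction), 1/2 is the female fraction, and m0/m_egg re-expresses
the surviving egg number flux as biomass arriving at m0.  Default
m_egg = 1 mg, a typical pelagic egg mass.

**Recruit mass m0 = 3 g.**  The growth and mortality laws above are adult
fish laws; extended to larval sizes (10 mg) their ratio implies e⁻²⁵-level
survival and certain extinction.  The spectrum therefore starts at 3 g —
below every group's maturity and gear-threshold mass — and the entire
egg/larval phase is collapsed into s_e, exactly the quantity's stated
meaning.  m0 is a config field (`grid.m0`).

**Phytoplankton size partition.**  The representative phytoplankton mass
m_φ anchoring the trophic power law comes from an Eppley-type partition:
large-cell fraction x_L = clip(Π* (npp/npp_ref) / e^{k_E T}, 0, 1) and
ln m_φ interpolates between 10⁻¹⁰ g and 10⁻⁶ g.  Warmer water at fixed NPP
gives smaller cells, hence a longer food chain and less energy at fish
sizes.  This is a documented stand-in with the right dependencies; the
exact published form lives in the companion ecological-module description
and all constants are config-swappable.

## Economic module

Effort E_k (W m⁻², nominal effort in power units) evolves with the
*average* profit of the open-access fishery:

    dE/dt = κ_e (revenue − cost)/E,   revenue = p q E ∫ σ f dm,
    cost = c E,

with globally constant ex-vessel price p, cost per unit effort c, and
fleet-dynamics parameter κ_e = 10⁻⁶ W² m⁻² $⁻¹ (an ~10-year adjustment
timescale).  Since both revenue and cost are linear in E, the equilibrium
condition is purely economic: the selectable biomass ∫σf dm is driven to
the critical biomass F_crit = c/(p q); below it fishing is unprofitable
and effort decays to a floor (10⁻¹⁵ W m⁻²) from which it can re-enter.
Defaults p = 1.1×10⁻³ $ gwB⁻¹ (≈ $1100/tonne) and c = 10⁻⁷ $ W⁻¹ s⁻¹ are
round numbers of the right observed magnitude; the model's equilibrium
depends on them only through F_crit.

Harvest is bilinear, h = q σ E f, with sigmoidal (trawl-type) selectivity
σ(m) = [1+(m/m_Θ)^{−c_σ/δ₂}]⁻¹ and threshold mass m_Θ = d_Θ e_Θ m_α,
d_Θ = (1, 0.5, 0.25) for (small, medium, large) — proportionally more
juvenile bycatch for larger groups.

## Numerical scheme

Mass axis: log-spaced finite volumes, default 50 bins per group from m0 to
m∞ (30 bins in the calibration ensemble).  Time: 15-day steps, 24 per
360-day model year; all per-year conversions use that year.

The growth advection term uses a conservative first-order upwind flux with
the recruitment flux as bottom-edge inflow and zero outflow at m∞ (γ = 0
there by the activity closure).  If the CFL number max(γ Δt/Δm) exceeds
0.9 the advection is sub-stepped with γ frozen over the outer step.  The
mortality and harvest sinks are applied as an *exact exponential decay*
per step rather than explicit Euler: at 15-day steps Λ Δt > 1 in the
smallest mass bins, where explicit sinks would be unstable, and the
exponential form is unconditionally stable and positivity-preserving.
The per-step removals are diagnosed as realized fluxes (f before minus f
after, partitioned between mortality and harvest in proportion to their
rates), so the discrete budget

    Δ∫f dm = recruit_in + dilation_in − mortality_out − harvest_out

closes to rounding error (≲10⁻¹⁰ relative) every step; the tests assert
this.  Effort uses explicit Euler at the ecological step — stable because
κ_e's ~10 yr timescale is ≫ 15 days.

Annual outputs are calendar-year means (biomass, effort) or sums
(harvest, in realized removed biomass).  Halving the step changes annual
aggregates by well under 1% (asserted in the tests).

The integrator carries a leading ensemble-member axis, so a Monte Carlo
batch of parameter draws integrates in one vectorized pass (a 200-member,
16-cell, 300-year batch runs in a few minutes on one core).

## Transient protocol

Runs start from a uniform seed spectrum of 10⁻⁵ gwB m⁻² g⁻¹ and spin up
for 100 years at a constant, low catchability q₀ = 10⁻⁵ m² W⁻¹ s⁻¹
(negligible harvest); catchability then compounds at 5% per year for 200
years, emulating technological progress and guaranteeing a harvest peak.
The seed spectrum must be small enough that spin-up fishing stays
unprofitable (a large seed makes the transient itself harvestable);
initial-condition memory in unharvested biomass decays roughly e-fold per
century, so a residual few-tens-of-percent sensitivity remains at the
100-year protocol mark while peak-harvest diagnostics during the ramp are
governed by the economics.  The
unharvested attractor is approached slowly (the large group's generation
time is decades): successive 50-year means converge below the 0.1% level
only after roughly six centuries, which the steadiness test accounts for
by spinning up 700 years.

## Synthetic forcing and observations

`generate_synthetic_forcing` builds n cells whose NPP and temperature are
evenly spaced across the requested ranges (defaults 500–3000 mg C m⁻² d⁻¹
and 0–30 °C, the ranges of the model's published sensitivity analysis) and
independently shuffled so the two gradients decorrelate, with per-cell
areas of 0.2–2×10¹² m² (the scale of Large Marine Ecosystems) and one
pseudo-LME label per cell.  It emulates the *range* of real forcing, not
its spatial covariance, seasonality (unless enabled), or the real ocean's
NPP–temperature correlation — so passing calibration tests demonstrate
that the pipeline can recover parameters under the stated noise, not that
it would do so against real reconstructions.

`generate_synthetic_observations` runs a known-truth parameter set through
the full protocol, takes each pseudo-LME's mean of its 10 largest annual
harvests, and multiplies by lognormal noise (σ = 0.3 in log₁₀, i.e. a
factor-of-two-scale uncertainty, matching catch-reconstruction error).
The harvest-to-biomass (H:B) reference set is the 8 pseudo-LMEs with the
lowest truth-run H:B at peak: this mirrors how the real cap is
constructed — the reference systems are precisely those whose observed
H:B ratios all fell below 0.4 yr⁻¹.

## Calibration pipeline

Priors follow the published sampling table: uniforms parameterized by
mean and SD get bounds mean ± √3·SD (exact variance match); normals with
physical positivity (A0, k_E, Π*, s_e, β) are resampled at zero; τ is
always derived per draw, never sampled.  The A0 prior is implemented as
N(4.46, 0.50): the tabulated "N(0.46, 0.5)" is inconsistent with the same
table's reported prior means (≈4.46) and is treated as a typo; both
moments are config-overridable.

Constraints are applied in sequence: (1) peak global harvest inside a
window — the real-data absolute window is 70–150×10¹² gwB yr⁻¹; in
synthetic mode the window is [0.5, 2.0]× the observed synthetic global
peak, mirroring the generous real-data envelope around a reconstructed
~64×10¹² gwB yr⁻¹; (2) size structure at peak, M/S ≥ 0.3 and
0.1 ≤ L/S < 0.8 (upper bound strict, as stated); (3) H:B ≤ 0.4 yr⁻¹ at
every reference LME (boundary inclusive by decision); (4) survivors ranked
by Pearson r² of area-specific per-LME peak harvests (Spearman and
log₁₀-r² are also computed and reported), keeping the top fraction *of
the total draws*, ties to the earlier draw id.  Per-stage survival
fractions are reported.  A two-sample Kolmogorov–Smirnov test per
parameter compares selected against non-selected draws.

The parameter-recovery experiment in the acceptance tests uses a
200-member ensemble on a 16-cell grid at 30 mass bins, truth offset from
the prior centre (ζ1* = 0.20, b* = 0.67) so recovery is informative, and
a selection fraction of 5% (1% of 200 draws would keep only two members;
the published fraction applies to a 10⁴-member suite).  Expected outcome,
asserted by the tests: a non-empty selected set whose ζ1, b, τ means are
within one prior SD of truth, and a KS shift concentrated in the
mortality parameters.

## Known limitations

- Single-cell economics: no vessel or fish movement, management, subsidies,
  or spatially varying price/cost — open access everywhere by construction.
- The m_φ partition, Ψ, φ_C, λ0 and the egg channel are closures standing
  in for a companion formulation that is not reproduced here; all are
  config-swappable and their defaults are chosen once for a viable
  community at the central parameters.
- First-order upwind advection is diffusive in mass; spectra near sharp
  features (the maturity pile) are smoothed.  Halved-step agreement is
  ~0.1–0.5% on annual aggregates, far from the ~5 significant figures a
  higher-order scheme would give.
- Real-data mode (SAUP-style catch CSV + LME areas, the 11-LME exclusion
  list, the 8 named reference LMEs) is wired but cannot be exercised here:
  the observational databases are not bundled.
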