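"""Ecological right-hand side of the biomass-spectrum equation.

The biomass spectrum f(m) (gwB m^-2 g^-1) of each group obeys a
McKendrick-von Foerster equation

    df/dt = -d(gamma f)/dm + gamma f / m - Lambda f,

with growth gamma the minimum of the energy available from primary
production (xi_P) and an allometric physiological ceiling (xi_VB), mortality
Lambda an allometric, temperature-dependent rate, and recruitment entering
as the flux boundary condition at the recruit mass m0.

All functions broadcast over numpy arrays; the time-stepping lives in
:mod:`boats.simulator`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core import (
    EcoParams,
    MassGrid,
    SECONDS_PER_DAY,
    SizeGroup,
    activity_coefficient,
    arrhenius_factor,
)

__all__ = [
    "Forcing",
    "GrowthDiagnostics",
    "phytoplankton_mass",
    "production_spectrum",
    "xi_P",
    "xi_VB",
    "maturity_allocation",
    "realized_growth",
    "mortality_rate",
    "recruitment_flux",
    "ecology_tendency",
    "growth_characteristic",
    "von_bertalanffy_mass",
]

#: cap multiplier for xi_P where the spectrum is (numerically) empty
XI_P_CAP_FACTOR = 1e3

#: residual length-exponent (1.61 - 1.44)/3 of the length-based empirical
#: mortality law, used in the coefficient normalization
GISLASON_RESIDUAL_EXP = (1.61 - 1.44) / 3.0


@dataclass(frozen=True)
class Forcing:
    """Environmental forcing for one or many cells.

    ``npp`` in mg C m^-2 d^-1 and ``temperature`` in degC, shaped
    ``(n_cells,)`` for constant (annual-average) forcing or
    ``(n_cells, 12)`` for a monthly climatology.  ``area`` (m^2) and
    ``lme_id`` label the cells for aggregation and pseudo-LME calibration.
    """

    npp: np.ndarray
    temperature: np.ndarray
    area: np.ndarray | None = None
    lme_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        npp = np.atleast_1d(np.asarray(self.npp, dtype=float))
        temp = np.atleast_1d(np.asarray(self.temperature, dtype=float))
        if npp.shape != temp.shape:
            raise ValueError(f"npp shape {npp.shape} != temperature shape {temp.shape}")
        if np.any(npp < 0):
            raise ValueError("npp must be non-negative")
        if np.any((temp < -5) | (temp > 40)):
            warnings.warn("temperature outside the realistic (-5, 40) degC range")
        object.__setattr__(self, "npp", npp)
        object.__setattr__(self, "temperature", temp)
        if self.area is not None:
            object.__setattr__(self, "area", np.atleast_1d(np.asarray(self.area, float)))
        if self.lme_id is not None:
            object.__setattr__(self, "lme_id", np.atleast_1d(np.asarray(self.lme_id)))

    @property
    def n_cells(self) -> int:
        return self.npp.shape[0]

    @property
    def n_phases(self) -> int:
        return 1 if self.npp.ndim == 1 else self.npp.shape[1]


@dataclass(frozen=True)
class GrowthDiagnostics:
    """Per-bin growth limitation diagnostics (g s^-1 per individual)."""

    xi_P: np.ndarray
    xi_VB: np.ndarray
    xi_I: np.ndarray

    @property
    def production_limited(self) -> np.ndarray:
        return self.xi_P <= self.xi_VB


def npp_to_wet_flux(npp, params: EcoParams):
    """mg C m^-2 d^-1 -> g wB m^-2 s^-1."""
    return np.asarray(npp, float) * 1e-3 * params.wetB_per_C / SECONDS_PER_DAY


def phytoplankton_mass(npp, T, params: EcoParams):
    """Representative phytoplankton mass m_phi (g) from NPP and temperature.

    Eppley-type partition: warm, low-nutrient (low NPP) conditions shift the
    community toward small cells.  The large-cell fraction is
    ``x_L = clip(Pi_star * (npp/npp_ref) / exp(kE*T), 0, 1)`` and m_phi is
    the log-linear blend of the small- and large-cell masses.
    """
    npp = np.asarray(npp, float)
    T = np.asarray(T, float)
    x_L = np.clip(
        params.Pi_star * (npp / params.npp_ref) / np.exp(params.kE * T), 0.0, 1.0
    )
    ln_mphi = (1.0 - x_L) * np.log(params.m_phyto_small) + x_L * np.log(
        params.m_phyto_large
    )
    out = np.exp(ln_mphi)
    return out if out.ndim else float(out)


def production_spectrum(npp, T, grid: MassGrid, params: EcoParams):
    """Spectrum of energy available from primary production.

    pi(m) = NPP_wB * (m/m_phi)^tau / (m * ln beta), in gwB m^-2 g^-1 s^-1.
    Trophic transfer dilutes the primary-production flux by the trophic
    efficiency per predator-prey mass step, giving the power law with
    exponent tau = log(alpha)/log(beta) < 0; pi is linear in NPP at fixed
    phytoplankton mass.
    """
    npp = np.asarray(npp, float)
    if np.any(npp < 0):
        raise ValueError("npp must be non-negative")
    m = grid.centers
    m_phi = phytoplankton_mass(npp, T, params)
    flux = npp_to_wet_flux(npp, params)
    return flux * (m / m_phi) ** params.tau / (m * np.log(params.beta_ppmr))


def xi_P(pi, f, phi_C, grid: MassGrid, xi_cap: float = np.inf):
    """Per-individual energy supply from primary production (g s^-1).

    The areal flux density ``phi_C * pi * m`` is partitioned equally among
    the ``f/m`` individuals per unit mass, giving ``phi_C * pi * m^2 / (f m)
    = phi_C * pi * m / f``.  Where the spectrum is empty the supply per
    (vanishing) individual is effectively unlimited: return ``xi_cap`` if
    there is any production, else 0.
    """
    pi = np.asarray(pi, float)
    f = np.asarray(f, float)
    m = grid.centers
    supply = phi_C * pi * m
    nonzero = f > 1e-30
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(nonzero, supply / np.where(nonzero, f, 1.0),
                       np.where(supply > 0, xi_cap, 0.0))
    return np.minimum(out, xi_cap)


def xi_VB(m, T, group: SizeGroup, params: EcoParams):
    """Physiological (von Bertalanffy) growth ceiling A m^b - k_a m (g s^-1).

    A = A0 * a_A(T) with the Arrhenius growth factor; the activity cost
    closure k_a = A m_inf^(b-1) forces growth to vanish at m = m_inf.
    """
    m = np.asarray(m, float)
    if np.any(m > group.m_inf * (1 + 1e-12)):
        raise ValueError("mass exceeds the group's asymptotic mass")
    A = params.A0_per_s * arrhenius_factor(T, params.omega_A, params.T_ref)
    ka = activity_coefficient(A, params.b, group.m_inf)
    out = A * m**params.b - ka * m
    return out if np.ndim(out) else float(out)


def maturity_allocation(m, group: SizeGroup, params: EcoParams, c_slope=16.7787):
    """Fraction Psi(m) of assimilated energy allocated to reproduction.

    Smooth sigmoid in log mass centred at the maturity mass, with the same
    log-slope family as the gear selectivity (exponent c_slope/delta2):
    near 0 for juveniles, 1/2 at m_alpha, approaching 1 toward m_inf.
    """
    m = np.asarray(m, float)
    expo = -np.asarray(c_slope, float) / params.delta2
    out = 1.0 / (1.0 + (m / group.m_alpha) ** expo)
    return out if out.ndim else float(out)


def realized_growth(xi_p, xi_vb, m, group: SizeGroup, params: EcoParams, c_slope=16.7787):
    """Realized somatic growth and reproductive flux density.

    xi_I = min(xi_P, xi_VB); gamma = (1 - Psi) xi_I goes to somatic growth
    and Psi xi_I to reproduction.
    """
    xi_i = np.minimum(np.asarray(xi_p, float), np.asarray(xi_vb, float))
    psi = maturity_allocation(m, group, params, c_slope)
    return (1.0 - psi) * xi_i, psi * xi_i


def mortality_from_lambda(m, lam, h, b, m_inf):
    """Structural mortality law Lambda = lambda * m^-h * m_inf^(h+b-1).

    ``lam`` carries g^(1-b) s^-1 so Lambda is a rate per second; larger
    asymptotic size raises juvenile mortality at a given mass (h+b-1 > 0),
    as in length-based empirical mortality estimates.
    """
    m = np.asarray(m, float)
    out = np.asarray(lam, float) * m ** (-np.asarray(h, float)) * np.asarray(
        m_inf, float
    ) ** (np.asarray(h, float) + np.asarray(b, float) - 1.0)
    return out if np.ndim(out) else float(out)


def mortality_coefficient(T, group: SizeGroup, params: EcoParams):
    """Mass-independent mortality coefficient lambda (g^(1-b) s^-1).

    Proportional to exp(zeta1) * A0 * a_lambda(T) with its own Arrhenius
    temperature dependence.  The proportionality constant
    ``(1/3) * (delta1/m_inf)^((1.61-1.44)/3)`` is the normalization of the
    length-based empirical mortality law (intercept zeta1, length exponent
    -1.61, asymptotic-length exponent 1.44, von Bertalanffy K = A
    m_inf^(b-1)/3) once lengths are converted to masses by the cube law;
    without it juvenile mortality overwhelms growth and no group persists.
    """
    lam0 = (params.delta1 / group.m_inf) ** GISLASON_RESIDUAL_EXP / 3.0
    return (
        lam0
        * np.exp(params.zeta1)
        * params.A0_per_s
        * arrhenius_factor(T, params.omega_lambda, params.T_ref)
    )


def mortality_rate(m, T, group: SizeGroup, params: EcoParams):
    """Natural mortality Lambda(m) (s^-1) for a group at temperature T."""
    out = mortality_from_lambda(
        m, mortality_coefficient(T, group, params), params.h, params.b, group.m_inf
    )
    return out if np.ndim(out) else float(out)


def recruitment_flux(f, pi, repro_flux_density, group: SizeGroup, params: EcoParams,
                     grid: MassGrid, phi_C: float = 1.0):
    """Recruit biomass flux at the bottom boundary (gwB m^-2 s^-1).

    The boundary condition f(m0) gamma(m0) = R_P R_e / (R_P + R_e) blends
    two potential limits as a harmonic mean: R_P, the primary-production
    flux at the recruit size, and R_e, the biomass flux of recruits grown
    from eggs: the egg *number* flux (reproductive mass flux / egg mass,
    halved for the female fraction) times the egg-to-recruit survival s_e,
    re-expressed as biomass at the recruit mass m0 -- hence the mass
    amplification factor m0/m_egg.
    """
    f = np.asarray(f, float)
    pi = np.asarray(pi, float)
    m = grid.centers
    R_P = phi_C * pi[..., 0] * grid.m0
    R_e = 0.5 * params.s_e * (grid.m0 / params.m_egg) * np.sum(
        np.asarray(repro_flux_density, float) * f / m * grid.widths, axis=-1
    )
    denom = R_P + R_e
    out = np.where(denom > 0, R_P * R_e / np.where(denom > 0, denom, 1.0), 0.0)
    return out if np.ndim(out) else float(out)


def ecology_tendency(f, gamma, Lambda, recruit_flux, grid: MassGrid):
    """Pre-harvest df/dt (gwB m^-2 g^-1 s^-1) per bin.

    Conservative first-order upwind finite volume in mass for the advection
    term -d(gamma f)/dm, the dilation source +gamma f/m, a linear mortality
    sink, recruitment as the inflow flux at edges[0], and zero outflow at
    the top edge (growth vanishes at m_inf by the activity closure).
    """
    f = np.asarray(f, float)
    gamma = np.asarray(gamma, float)
    flux = gamma * f  # gwB m^-2 s^-1 through the upper edge of each bin
    inflow = np.concatenate(
        [np.broadcast_to(np.asarray(recruit_flux, float), f.shape[:-1] + (1,)),
         flux[..., :-1]], axis=-1,
    )
    outflow = flux.copy()
    outflow[..., -1] = 0.0
    return (inflow - outflow) / grid.widths + gamma * f / grid.centers - Lambda * f


# ---------------------------------------------------------------------------
# growth-characteristic oracles
# ---------------------------------------------------------------------------


def growth_characteristic(m_start, t_span_s, A, b, m_inf, rtol: float = 1e-10):
    """Integrate the individual growth characteristic dm/dt = A m^b - k_a m.

    High-accuracy ODE integration, used to check the discretized growth flux
    against the analytic von Bertalanffy solution.
    """
    ka = activity_coefficient(A, b, m_inf)
    sol = solve_ivp(
        lambda t, m: A * m**b - ka * m,
        (0.0, t_span_s),
        [float(m_start)],
        rtol=rtol,
        atol=1e-14,
        dense_output=True,
    )
    return float(sol.y[0, -1])


def von_bertalanffy_mass(m_start, t_s, A, m_inf):
    """Closed-form mass at time t for b = 2/3.

    m(t) = m_inf (1 - (1 - (m0/m_inf)^(1/3)) exp(-ka t / 3))^3 with
    k_a = A m_inf^(-1/3).
    """
    ka = A * m_inf ** (-1.0 / 3.0)
    c = 1.0 - (m_start / m_inf) ** (1.0 / 3.0)
    return m_inf * (1.0 - c * np.exp(-ka * t_s / 3.0)) ** 3
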