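"""Open-access fishery economics: harvest, revenue, cost, effort dynamics.

Gordon-Schaefer open access: effort E_k (W m^-2) in each group grows in
proportion to the *average* profit (profit per unit effort), harvest is
bilinear in effort and biomass through the catchability q and the gear
selectivity sigma, cost is linear in effort.  At equilibrium the selectable
biomass is driven to the critical level F_crit = c / (p q), a purely
economic quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EconParams, MassGrid, SECONDS_PER_YEAR

__all__ = [
    "EffortState",
    "HarvestDiagnostics",
    "harvest_spectrum",
    "revenue_rate",
    "cost_rate",
    "effort_step",
    "critical_biomass",
    "estimate_cost_from_equilibrium",
]


@dataclass
class EffortState:
    """Fishing effort per group (W m^-2), never below the effort floor.

    The floor keeps the average-profit dynamics (singular at E = 0) well
    defined and lets effort re-enter when fishing becomes profitable again.
    """

    E: np.ndarray
    floor: float = 1e-15

    def __post_init__(self) -> None:
        self.E = np.maximum(np.asarray(self.E, dtype=float), self.floor)


@dataclass(frozen=True)
class HarvestDiagnostics:
    h_spectrum: np.ndarray  # gwB m^-2 s^-1 g^-1 per bin
    harvest_rate: np.ndarray  # gwB m^-2 s^-1 per group
    revenue_rate: np.ndarray  # $ m^-2 s^-1 per group
    cost_rate: np.ndarray  # $ m^-2 s^-1 per group


def harvest_spectrum(f, E, q, sigma):
    """Harvest spectrum h = q sigma E f (gwB m^-2 s^-1 g^-1)."""
    return np.asarray(q, float) * np.asarray(sigma, float) * np.asarray(E, float) * np.asarray(f, float)


def selectable_biomass(f, sigma, grid: MassGrid):
    """Integral of sigma * f over mass (gwB m^-2)."""
    return np.sum(np.asarray(sigma, float) * np.asarray(f, float) * grid.widths, axis=-1)


def revenue_rate(f, E, q, sigma, price, grid: MassGrid):
    """Revenue q E p * integral(sigma f dm) in $ m^-2 s^-1.

    The ex-vessel price is constant in mass, so revenue is the price times
    the integrated harvest rate.
    """
    return np.asarray(q, float) * np.asarray(E, float) * price * selectable_biomass(f, sigma, grid)


def cost_rate(E, cost_per_effort):
    """Cost c E in $ m^-2 s^-1 (cost proportional to effort)."""
    return cost_per_effort * np.asarray(E, float)


def effort_step(E, revenue, cost, kappa_e, dt, floor: float = 1e-15):
    """One explicit Euler step of dE/dt = kappa_e (revenue - cost)/E.

    Since both revenue and cost are proportional to E, the average profit
    (revenue - cost)/E is finite as E -> floor; the floor prevents E from
    ever reaching zero so effort can re-enter a recovering fishery.
    """
    E = np.asarray(E, float)
    out = np.maximum(E + dt * kappa_e * (np.asarray(revenue, float) - np.asarray(cost, float)) / E, floor)
    return out if out.ndim else float(out)


def critical_biomass(cost_per_effort, price, q):
    """Open-access equilibrium selectable biomass F_crit = c/(p q) (gwB m^-2).

    Below F_crit harvesting is unprofitable and effort decays to the floor;
    above it, effort grows until the selectable biomass is driven down to
    F_crit.
    """
    price = np.asarray(price, float)
    q = np.asarray(q, float)
    if np.any(price <= 0) or np.any(q <= 0):
        raise ValueError("price and q must be positive (fishery undefined)")
    out = np.asarray(cost_per_effort, float) / (price * q)
    return out if out.ndim else float(out)


def estimate_cost_from_equilibrium(total_revenue_per_yr, total_effort_W):
    """Cost per unit effort ($ W^-1 s^-1) from an assumed open-access balance.

    If the fishery is near open-access equilibrium, total revenue equals
    total cost, so c = revenue / (effort * seconds per year).
    """
    total_effort_W = np.asarray(total_effort_W, float)
    if np.any(total_effort_W <= 0):
        raise ValueError("total effort must be positive")
    out = np.asarray(total_revenue_per_yr, float) / (total_effort_W * SECONDS_PER_YEAR)
    return out if out.ndim else float(out)
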