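"""Shared primitives of the size-spectrum fishery model.

Mass-axis discretization, the three-group "super-organism" community,
allometric and van't Hoff-Arrhenius temperature functions, the sigmoidal
gear-selectivity curve and the mass-length relationship.  Everything here is
broadcasting-friendly: scalar arguments give scalars, numpy arrays broadcast.

Internal unit system is strictly SI-gram: mass in g wet biomass (gwB),
area in m^2, time in s.  Per-year parameter values are converted at the
boundary using the model year of 360 days (24 x 15-day steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "K_B",
    "SECONDS_PER_DAY",
    "DAYS_PER_YEAR",
    "SECONDS_PER_YEAR",
    "T_REF_K",
    "MassGrid",
    "SizeGroup",
    "EcoParams",
    "EconParams",
    "build_mass_grid",
    "arrhenius_factor",
    "threshold_mass",
    "selectivity",
    "mass_from_length",
    "length_from_mass",
    "activity_coefficient",
    "default_community",
]

#: Boltzmann constant in eV / K.
K_B = 8.617333262e-5

SECONDS_PER_DAY = 86_400.0
#: The model year: 24 steps of 15 days.
DAYS_PER_YEAR = 360.0
SECONDS_PER_YEAR = DAYS_PER_YEAR * SECONDS_PER_DAY

#: Arrhenius reference temperature (10 degC) at which both the growth and the
#: mortality temperature factors equal one.
T_REF_K = 283.15


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MassGrid:
    """Log-spaced discretization of the individual-mass axis (g).

    ``edges`` has ``n_bins + 1`` entries with ``edges[0] == m0``; ``centers``
    are geometric bin midpoints (strictly inside each bin) and ``widths`` the
    linear bin widths.
    """

    edges: np.ndarray
    centers: np.ndarray
    widths: np.ndarray
    m0: float

    @property
    def n_bins(self) -> int:
        return self.centers.size

    @property
    def m_max(self) -> float:
        return float(self.edges[-1])


@dataclass(frozen=True)
class SizeGroup:
    """One commercial group, a super-organism defined by its asymptotic mass.

    Parameters
    ----------
    m_inf:
        Asymptotic mass (g); growth ceases here.
    m_alpha:
        Maturity mass (g); reproductive allocation ramps up around it.
    d_theta:
        Selectivity mass adjustment; the gear threshold mass is
        ``d_theta * e_theta * m_alpha``.  Defaults per group size are
        (1, 0.5, 0.25) for (small, medium, large), representing greater
        bycatch of juveniles of larger groups.
    e_theta:
        Selectivity mass scaling, used to explore threshold-mass uncertainty.
    """

    label: str
    m_inf: float
    m_alpha: float
    d_theta: float
    e_theta: float = 0.6198

    def __post_init__(self) -> None:
        if not (0.0 < self.m_alpha < self.m_inf):
            raise ValueError(
                f"group {self.label!r}: need 0 < m_alpha < m_inf, "
                f"got m_alpha={self.m_alpha}, m_inf={self.m_inf}"
            )
        if not (0.0 < self.d_theta <= 1.0):
            raise ValueError(f"d_theta must lie in (0, 1], got {self.d_theta}")


@dataclass(frozen=True)
class EcoParams:
    """Ecological parameters.

    Scalar defaults are the central (non-optimized mean) values of the
    Monte Carlo sampling distributions; any field may instead hold a numpy
    array of per-member draws, in which case all derived quantities
    broadcast.

    Units: ``A0`` in g^(1-b) per model year, activation energies in eV,
    ``kE`` per degC; the rest unitless.
    """

    A0: float | np.ndarray = 4.46
    b: float | np.ndarray = 0.70
    omega_A: float | np.ndarray = 0.45
    omega_lambda: float | np.ndarray = 0.45
    zeta1: float | np.ndarray = 0.55
    h: float | np.ndarray = 0.54
    alpha_te: float | np.ndarray = 0.13
    beta_ppmr: float | np.ndarray = 5000.0
    kE: float | np.ndarray = 0.0631
    Pi_star: float | np.ndarray = 0.37
    s_e: float | np.ndarray = 0.025
    delta1: float = 0.01
    delta2: float = 3.0
    T_ref: float = T_REF_K
    wetB_per_C: float = 10.0
    #: NPP normalization for the phytoplankton-size partition (mg C m-2 d-1).
    npp_ref: float = 1000.0
    #: small / large representative phytoplankton masses (g).
    m_phyto_small: float = 1e-10
    m_phyto_large: float = 1e-6
    #: egg mass (g); sets the egg-to-recruit amplification in recruitment.
    m_egg: float = 1e-3
    #: fraction of primary production allocated to each group; None = 1/K.
    phi_C: float | None = None

    @property
    def tau(self) -> float | np.ndarray:
        """Trophic scaling log(alpha)/log(beta); always derived, never set."""
        return np.log(self.alpha_te) / np.log(self.beta_ppmr)

    @property
    def A0_per_s(self) -> float | np.ndarray:
        return self.A0 / SECONDS_PER_YEAR

    def with_(self, **kw) -> "EcoParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class EconParams:
    """Economic forcings and parameters.

    ``price`` in $ per gwB, ``cost_per_effort`` in $ per W per s, ``kappa_e``
    in W^2 m^-2 $^-1 (Eq-consistent units; sets an ~10 yr fleet adjustment
    timescale), ``q0`` in m^2 W^-1 s^-1.
    """

    price: float = 1.1e-3
    cost_per_effort: float = 1e-7
    kappa_e: float = 1e-6
    c_sigma: float | np.ndarray = 16.7787
    q0: float = 1e-5
    ramp_rate: float = 0.05
    effort_floor: float = 1e-15

    def __post_init__(self) -> None:
        if self.price <= 0 or self.cost_per_effort < 0 or self.kappa_e <= 0:
            raise ValueError("price, kappa_e must be > 0 and cost >= 0")

    def with_(self, **kw) -> "EconParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_mass_grid(m0: float, m_max: float, n_bins: int) -> MassGrid:
    """Build a log-spaced mass grid from recruit mass ``m0`` to ``m_max``.

    Centers are geometric midpoints so that the constant edge ratio is
    preserved exactly.
    """
    if not (0.0 < m0 < m_max):
        raise ValueError(f"need 0 < m0 < m_max, got m0={m0}, m_max={m_max}")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    edges = np.geomspace(m0, m_max, n_bins + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    widths = np.diff(edges)
    return MassGrid(edges=edges, centers=centers, widths=widths, m0=float(m0))


def arrhenius_factor(T_celsius, omega, T_ref: float = T_REF_K):
    """van't Hoff-Arrhenius temperature factor, normalized to 1 at ``T_ref``.

    ``exp[(omega/k_B) * (1/T_ref - 1/T_K)]`` with ``T_K = T + 273.15``.
    ``omega`` is an activation energy in eV.
    """
    T_K = np.asarray(T_celsius, dtype=float) + 273.15
    if np.any(T_K <= 0):
        raise ValueError("temperature below absolute zero")
    out = np.exp((np.asarray(omega, dtype=float) / K_B) * (1.0 / T_ref - 1.0 / T_K))
    return out if out.ndim else float(out)


def threshold_mass(group: SizeGroup) -> float:
    """Gear threshold mass m_theta = d_theta * e_theta * m_alpha (g)."""
    return group.d_theta * group.e_theta * group.m_alpha


def selectivity(m, m_theta, c_sigma, delta2: float = 3.0):
    """Sigmoidal (trawl-like) gear selectivity in (0, 1).

    Sigmoidal in *length*, hence the exponent ``c_sigma / delta2`` once
    converted to mass through the cube-law mass-length relationship:
    ``sigma(m) = [1 + (m/m_theta)^(-c_sigma/delta2)]^-1``.  Equals 1/2 at the
    threshold mass and increases monotonically with mass.
    """
    m = np.asarray(m, dtype=float)
    expo = -np.asarray(c_sigma, dtype=float) / delta2
    out = 1.0 / (1.0 + (m / m_theta) ** expo)
    return out if out.ndim else float(out)


def mass_from_length(l, delta1: float = 0.01, delta2: float = 3.0):
    """Mass (g) from length (cm): m = delta1 * l^delta2."""
    l = np.asarray(l, dtype=float)
    out = delta1 * l**delta2
    return out if out.ndim else float(out)


def length_from_mass(m, delta1: float = 0.01, delta2: float = 3.0):
    """Length (cm) from mass (g); exact inverse of :func:`mass_from_length`."""
    m = np.asarray(m, dtype=float)
    out = (m / delta1) ** (1.0 / delta2)
    return out if out.ndim else float(out)


def activity_coefficient(A, b, m_inf):
    """Mass-specific activity cost k_a = A * m_inf^(b-1) (per s).

    This closure makes the physiological growth rate ``A m^b - k_a m`` vanish
    exactly at the asymptotic mass, i.e. von Bertalanffy growth whose
    asymptote is the group-defining trait.
    """
    out = np.asarray(A, dtype=float) * np.asarray(m_inf, dtype=float) ** (
        np.asarray(b, dtype=float) - 1.0
    )
    return out if out.ndim else float(out)


def default_community(
    m_inf: Sequence[float] = (30.0, 1e3, 1e5),
    m_alpha_frac: float = 0.25,
    e_theta: float = 0.6198,
) -> list[SizeGroup]:
    """The default three-group community (small, medium, large).

    Asymptotic masses roughly log-spaced over the commercial range; maturity
    at a fixed fraction of the asymptotic mass; selectivity mass adjustments
    (1, 0.5, 0.25).
    """
    labels = ("small", "medium", "large")
    d_thetas = (1.0, 0.5, 0.25)
    return [
        SizeGroup(
            label=lab,
            m_inf=float(mi),
            m_alpha=m_alpha_frac * float(mi),
            d_theta=d,
            e_theta=e_theta,
        )
        for lab, mi, d in zip(labels, m_inf, d_thetas)
    ]
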