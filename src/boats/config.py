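"""Run configuration: YAML schema, validation, defaults and provenance.

Every model parameter is addressable by a dotted key inside a nested,
schema-validated document.  Unknown keys are rejected with the offending
name; units are documented on each field.  A stable hash of the resolved
configuration is embedded in run outputs so results can be traced back to
the exact parameter set.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import EconParams, EcoParams, SizeGroup
from .simulator import Protocol

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GridConfig(_Section):
    """Mass-axis discretization."""

    m0: float = Field(3.0, gt=0, description="recruit mass [g]")
    n_bins: int = Field(50, ge=2, description="log-spaced bins per group")


class GroupConfig(_Section):
    label: str
    m_inf: float = Field(..., gt=0, description="asymptotic mass [g]")
    m_alpha: float = Field(..., gt=0, description="maturity mass [g]")
    d_theta: float = Field(..., gt=0, le=1, description="selectivity mass adjustment")


class CommunityConfig(_Section):
    """Three size groups by default; maturity at 25% of asymptotic mass."""

    groups: list[GroupConfig] = Field(
        default_factory=lambda: [
            GroupConfig(label="small", m_inf=30.0, m_alpha=7.5, d_theta=1.0),
            GroupConfig(label="medium", m_inf=1e3, m_alpha=250.0, d_theta=0.5),
            GroupConfig(label="large", m_inf=1e5, m_alpha=2.5e4, d_theta=0.25),
        ]
    )


class EcologyConfig(_Section):
    """Ecological parameters (central values of the sampling priors)."""

    A0: float = Field(4.46, gt=0, description="allometric growth constant [g^(1-b) / model yr]")
    b: float = Field(0.70, gt=0, lt=1, description="allometric scaling exponent")
    omega_A: float = Field(0.45, ge=0, description="growth activation energy [eV]")
    omega_lambda: float = Field(0.45, ge=0, description="mortality activation energy [eV]")
    zeta1: float = Field(0.55, description="mortality constant (exponent)")
    h: float = Field(0.54, gt=0, description="mortality allometric scaling")
    alpha_te: float = Field(0.13, gt=0, lt=1, description="trophic efficiency")
    beta_ppmr: float = Field(5000.0, gt=1, description="predator-to-prey mass ratio")
    kE: float = Field(0.0631, gt=0, description="Eppley constant [1/degC]")
    Pi_star: float = Field(0.37, gt=0, description="nutrient concentration parameter")
    s_e: float = Field(0.025, gt=0, lt=1, description="egg survival fraction")
    delta1: float = Field(0.01, gt=0, description="mass-length constant [g cm^-delta2]")
    delta2: float = Field(3.0, gt=0, description="mass-length exponent")
    T_ref_C: float = Field(10.0, description="Arrhenius reference temperature [degC]")
    wetB_per_C: float = Field(10.0, gt=0, description="g wet biomass per g carbon")
    npp_ref: float = Field(1000.0, gt=0, description="NPP normalization [mg C m^-2 d^-1]")
    m_phyto_small: float = Field(1e-10, gt=0, description="small phytoplankton mass [g]")
    m_phyto_large: float = Field(1e-6, gt=0, description="large phytoplankton mass [g]")
    m_egg: float = Field(1e-3, gt=0, description="egg mass [g]")


class EconomicsConfig(_Section):
    """Economic forcings and parameters."""

    price: float = Field(1.1e-3, gt=0, description="ex-vessel price [$ / gwB]")
    cost_per_effort: float = Field(1e-7, ge=0, description="cost per unit effort [$ W^-1 s^-1]")
    kappa_e: float = Field(1e-6, gt=0, description="fleet dynamics parameter [W^2 m^-2 $^-1]")
    c_sigma: float = Field(16.7787, gt=0, description="selectivity slope")
    e_theta: float = Field(0.6198, gt=0, description="selectivity mass scaling")
    q0: float = Field(1e-5, gt=0, description="initial catchability [m^2 W^-1 s^-1]")
    ramp_rate: float = Field(0.05, ge=0, description="catchability increase per year")
    effort_floor: float = Field(1e-15, gt=0, description="effort floor [W m^-2]")


class ProtocolConfig(_Section):
    spinup_years: int = Field(100, ge=0)
    ramp_years: int = Field(200, ge=0)
    steps_per_year: int = Field(24, gt=0, description="15-day steps in the 360-day model year")


class CalibrationConfig(_Section):
    n_draws: int = Field(200, ge=1)
    select_fraction: float = Field(0.01, gt=0, le=1)
    harvest_window: tuple[float, float] = Field(
        (70e12, 150e12), description="constraint-1 window [gwB yr^-1], real-data mode"
    )
    hb_max: float = Field(0.4, gt=0, description="max harvest:biomass at reference LMEs [yr^-1]")
    noise_sd_log10: float = Field(0.3, ge=0, description="synthetic observation noise [log10]")


class SeedsConfig(_Section):
    master: int = Field(0, ge=0)


class RunConfig(_Section):
    """Top-level run configuration; every field has a documented unit."""

    grid: GridConfig = Field(default_factory=GridConfig)
    community: CommunityConfig = Field(default_factory=CommunityConfig)
    ecology: EcologyConfig = Field(default_factory=EcologyConfig)
    economics: EconomicsConfig = Field(default_factory=EconomicsConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    seeds: SeedsConfig = Field(default_factory=SeedsConfig)

    @model_validator(mode="after")
    def _check_masses(self) -> "RunConfig":
        for g in self.community.groups:
            if not (self.grid.m0 < g.m_alpha < g.m_inf):
                raise ValueError(
                    f"group {g.label!r}: need m0 < m_alpha < m_inf "
                    f"(m0={self.grid.m0}, m_alpha={g.m_alpha}, m_inf={g.m_inf})"
                )
        return self

    # -- factories ---------------------------------------------------------

    def eco_params(self) -> EcoParams:
        e = self.ecology
        return EcoParams(
            A0=e.A0, b=e.b, omega_A=e.omega_A, omega_lambda=e.omega_lambda,
            zeta1=e.zeta1, h=e.h, alpha_te=e.alpha_te, beta_ppmr=e.beta_ppmr,
            kE=e.kE, Pi_star=e.Pi_star, s_e=e.s_e, delta1=e.delta1,
            delta2=e.delta2, T_ref=e.T_ref_C + 273.15, wetB_per_C=e.wetB_per_C,
            npp_ref=e.npp_ref, m_phyto_small=e.m_phyto_small,
            m_phyto_large=e.m_phyto_large, m_egg=e.m_egg,
        )

    def econ_params(self) -> EconParams:
        e = self.economics
        return EconParams(
            price=e.price, cost_per_effort=e.cost_per_effort, kappa_e=e.kappa_e,
            c_sigma=e.c_sigma, q0=e.q0, ramp_rate=e.ramp_rate,
            effort_floor=e.effort_floor,
        )

    def community_groups(self) -> list[SizeGroup]:
        return [
            SizeGroup(
                label=g.label, m_inf=g.m_inf, m_alpha=g.m_alpha,
                d_theta=g.d_theta, e_theta=self.economics.e_theta,
            )
            for g in self.community.groups
        ]

    def protocol_obj(self) -> Protocol:
        p = self.protocol
        return Protocol(
            spinup_years=p.spinup_years, ramp_years=p.ramp_years,
            steps_per_year=p.steps_per_year, q0=self.economics.q0,
            ramp_rate=self.economics.ramp_rate,
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML configuration; an empty or missing-keys file
    yields all defaults.  Schema violations name the offending key."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig.model_validate(raw or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 of the resolved configuration (first 16 hex chars)."""
    doc = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]
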