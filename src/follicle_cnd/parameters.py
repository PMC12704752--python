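"""Model parameters, perturbation switches, and scenario configuration I/O.

All concentrations are in nM and all times in minutes; t = 0 is the
moment LH reaches the follicle.  The shipped defaults were obtained by
bounded least squares against the printed kinetic and concentration
landmarks of the imaging experiments (see ``scripts/fit_defaults.py``);
every rate below is therefore an effective, compartment-averaged rate,
not a single-enzyme constant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .geometry import FollicleGeometry


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and time-course parameters of the compartment model.

    Synthesis terms are zero-order rates (nM/min) modulated by
    dimensionless activation factors; hydrolysis in the granulosa
    compartments is first order (1/min); the oocyte PDE3A term is
    Michaelis-Menten with competitive inhibition by cGMP.  Junctional
    exchange coefficients are in um^3/min so that amount, not
    concentration, is conserved across compartments of unequal volume.
    """

    # cAMP synthesis
    k_GPR3: float = 0.6803          # oocyte, constitutive (nM/min)
    k_FSH: float = 200.91          # granulosa, FSH-driven basal (nM/min)
    k_LH: float = 788.19          # mural, maximal LH-induced extra (nM/min)
    tau_LH: float = 2.2398          # LH receptor activation time constant (min)
    # cAMP hydrolysis
    k_degA_g: float = 0.28702       # granulosa, first order (1/min)
    Vmax3: float = 1083.4         # oocyte PDE3A Vmax (nM/min)
    Km3: float = 61.395            # PDE3A Michaelis constant for cAMP (nM)
    Ki3: float = 0.081177             # PDE3A competitive inhibition constant for cGMP (nM)
    # cGMP synthesis (NPR2) and its LH-induced shutdown
    V_NPR2: float = 603.55         # granulosa, maximal (nM/min)
    tau_dephos: float = 12.735       # NPR2 dephosphorylation time constant (min)
    phi_min: float = 0.0030079        # residual NPR2 activity after dephosphorylation
    tau_CNP: float = 55.555        # CNP-content decline time scale (min)
    cnp_hill: float = 0.88387     # CNP decline shape (<1: fast onset, long tail)
    # cGMP hydrolysis
    k5_basal: float = 0.40236        # granulosa PDE5A+others, basal (1/min)
    dk5_LH: float = 1.1431          # LH-induced increment (1/min)
    tau_PDE5: float = 15.0        # PDE5A phosphorylation time constant (min)
    k_degG_o: float = 0.010       # minor oocyte cGMP loss (1/min)
    # Gap junction coupling
    P_mc: float = 2.0800e5           # mural<->cumulus, Cx43 (um^3/min)
    P_co: float = 1.2003e5           # cumulus<->oocyte, Cx37 (um^3/min)
    dip_depth: float = 0.41855       # Cx43 permeability at the bottom of the dip (fraction)
    dip_onset: float = 20.0       # Cx43 closure begins (min)
    dip_min_time: float = 60.0    # Cx43 permeability minimum (min)
    dip_recovery_time: float = 300.0  # Cx43 permeability fully restored (min)

    def __post_init__(self) -> None:
        positive = ("k_GPR3", "k_FSH", "k_LH", "tau_LH", "k_degA_g", "Vmax3",
                    "Km3", "Ki3", "V_NPR2", "tau_dephos", "tau_CNP", "cnp_hill",
                    "k5_basal", "dk5_LH", "tau_PDE5", "k_degG_o", "P_mc", "P_co")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dip_depth <= 1.0:
            raise ValueError("dip_depth must be in [0, 1]")
        if not 0.0 <= self.phi_min <= 1.0:
            raise ValueError("phi_min must be in [0, 1]")
        if not self.dip_onset < self.dip_min_time < self.dip_recovery_time:
            raise ValueError(
                "Cx43 dip landmarks must satisfy dip_onset < dip_min_time "
                "< dip_recovery_time")

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PerturbationConfig:
    """Genotype and drug switches defining an experimental arm.

    npr2_7E
        NPR2 locked phosphorylated: LH cannot dephosphorylate/inactivate it.
    pde5a_S92A
        PDE5A cannot be phosphorylated: no LH-induced increase in cGMP
        hydrolysis.
    ag1478
        EGF-receptor kinase inhibited: the Cx43 permeability dip never
        happens.
    carbenoxolone
        Gap junction blocker, modeled as static residual permeability
        factors ``eps_mc`` / ``eps_co`` applied when the flag is set.
    cnp_clamp
        Exogenous CNP keeps NPR2's agonist saturating: the slow
        CNP-driven decline of cGMP synthesis is disabled.
    """

    npr2_7E: bool = False
    pde5a_S92A: bool = False
    ag1478: bool = False
    carbenoxolone: bool = False
    eps_mc: float = 0.11164
    eps_co: float = 0.011647
    cnp_clamp: bool = False
    lh_time: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.eps_mc <= 1.0 or not 0.0 <= self.eps_co <= 1.0:
            raise ValueError("eps_mc and eps_co must be in [0, 1]")

    @property
    def junction_factors(self) -> tuple[float, float]:
        """(mural<->cumulus, cumulus<->oocyte) static permeability factors."""
        if self.carbenoxolone:
            return self.eps_mc, self.eps_co
        return 1.0, 1.0

    def replace(self, **changes: Any) -> "PerturbationConfig":
        return dataclasses.replace(self, **changes)


DEFAULT_PARAMETERS = ModelParameters()
WILD_TYPE = PerturbationConfig()


@dataclass(frozen=True)
class SimulationConfig:
    t_end: float = 300.0
    dt_out: float = 0.25
    baseline: float = 10.0

    def __post_init__(self) -> None:
        if self.t_end <= 0 or self.dt_out <= 0 or self.baseline < 0:
            raise ValueError("t_end and dt_out must be positive, baseline >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    geometry: FollicleGeometry = field(default_factory=FollicleGeometry)
    parameters: ModelParameters = field(default_factory=ModelParameters)
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)


_BLOCKS = {
    "geometry": FollicleGeometry,
    "parameters": ModelParameters,
    "perturbation": PerturbationConfig,
    "simulation": SimulationConfig,
}


def _build(cls: type, block: Mapping[str, Any], name: str) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown keys in '{name}' block: {sorted(unknown)}")
    return cls(**block)


def load_scenario_config(source: str | Path | Mapping[str, Any]) -> ScenarioConfig:
    """Load a scenario configuration from YAML (path or mapping).

    All blocks and fields are optional; anything omitted takes the
    shipped default.  Unknown blocks or keys raise ``ValueError`` so
    typos do not silently fall back to defaults.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ValueError("scenario configuration must be a mapping")
    unknown = set(data) - set(_BLOCKS)
    if unknown:
        raise ValueError(f"unknown configuration blocks: {sorted(unknown)}")
    kwargs = {name: _build(cls, data.get(name, {}) or {}, name)
              for name, cls in _BLOCKS.items()}
    return ScenarioConfig(**kwargs)
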