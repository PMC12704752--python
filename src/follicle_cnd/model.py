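"""Three-compartment ODE model of follicular cAMP/cGMP dynamics.

The state is six concentrations (nM): cAMP and cGMP in the mural
granulosa, cumulus, and oocyte compartments.  LH acts only on the mural
compartment (extra cAMP synthesis with time constant ``tau_LH``); every
downstream event — NPR2 inactivation, PDE5A activation, the transient
Cx43 permeability dip — is driven by smooth, phenomenological time
courses anchored to the measured landmarks.  Exchange between
compartments is Fickian through gap junctions: amount flux proportional
to the concentration difference, divided by the receiving volume.

Sign conventions: cAMP enters the oocyte from the cumulus while the
gradient is inward, and cGMP leaves the oocyte into the large granulosa
volume once granulosa cGMP collapses; both arise from the same exchange
term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .geometry import DEFAULT_GEOMETRY, FollicleGeometry
from .parameters import (DEFAULT_PARAMETERS, WILD_TYPE, ModelParameters,
                         PerturbationConfig)

__all__ = [
    "CompartmentTraces", "cx43_permeability_factor", "npr2_activity",
    "pde3a_rate", "junction_exchange", "pre_lh_steady_state", "simulate",
    "nebd_time", "SteadyStateError", "IntegrationError",
]

COMPARTMENTS = ("mural", "cumulus", "oocyte")
_COLUMNS = ("cAMP_mural", "cAMP_cumulus", "cAMP_oocyte",
            "cGMP_mural", "cGMP_cumulus", "cGMP_oocyte")


class SteadyStateError(RuntimeError):
    pass


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CompartmentTraces:
    """Time-indexed cAMP/cGMP concentrations (nM) per compartment.

    ``t`` is minutes relative to LH addition and includes the pre-LH
    baseline segment (negative times).
    """

    t: np.ndarray
    cAMP_mural: np.ndarray
    cAMP_cumulus: np.ndarray
    cAMP_oocyte: np.ndarray
    cGMP_mural: np.ndarray
    cGMP_cumulus: np.ndarray
    cGMP_oocyte: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for name in _COLUMNS:
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match time grid")

    def series(self, species: str, compartment: str) -> np.ndarray:
        """Return one trace, e.g. ``series('cAMP', 'oocyte')``."""
        return getattr(self, f"{species}_{compartment}")

    def to_dataframe(self) -> pd.DataFrame:
        data = {"t_min": self.t}
        for c in ("oocyte", "cumulus", "mural"):
            data[f"cAMP_{c}"] = getattr(self, f"cAMP_{c}")
        for c in ("oocyte", "cumulus", "mural"):
            data[f"cGMP_{c}"] = getattr(self, f"cGMP_{c}")
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CompartmentTraces":
        df = pd.read_csv(path)
        return cls(t=df["t_min"].to_numpy(),
                   **{c: df[c].to_numpy() for c in _COLUMNS})


def _smoothstep(x: np.ndarray | float) -> np.ndarray | float:
    """C1 ramp: 0 for x<=0, 1 for x>=1, 3x^2-2x^3 between."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def cx43_permeability_factor(t: float | np.ndarray,
                             params: ModelParameters = DEFAULT_PARAMETERS,
                             perturb: PerturbationConfig = WILD_TYPE):
    """Relative permeability of the Cx43 (mural<->cumulus) junctions.

    Unity before ``dip_onset``, falls smoothly to ``dip_depth`` at
    ``dip_min_time``, and recovers to unity by ``dip_recovery_time``
    (closure begins 10-30 min after LH, is maximal near 1 h, and has
    reversed by ~5 h).  With the EGF-receptor kinase inhibited
    (``ag1478``), the dip is abolished and the factor is 1 throughout.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    if perturb.ag1478:
        return np.ones_like(t) if t.ndim else 1.0
    p = params
    t0 = perturb.lh_time
    down = _smoothstep((t - t0 - p.dip_onset) / (p.dip_min_time - p.dip_onset))
    up = _smoothstep((t - t0 - p.dip_min_time)
                     / (p.dip_recovery_time - p.dip_min_time))
    # the up ramp only restores what the down ramp removed, so the
    # minimum dip_depth is attained exactly at dip_min_time
    d = 1.0 - (1.0 - p.dip_depth) * down * (1.0 - up)
    return d if d.ndim else float(d)


def npr2_activity(t: float | np.ndarray,
                  params: ModelParameters = DEFAULT_PARAMETERS,
                  perturb: PerturbationConfig = WILD_TYPE):
    """NPR2 guanylyl cyclase activity as a fraction of its pre-LH value.

    The product of two relaxations: a fast dephosphorylation component
    phi(t) that decays from 1 to ``phi_min`` with time constant
    ``tau_dephos`` (absent in the Npr2-7E genotype), and a slow
    component psi(t) tracking the gradual post-LH loss of follicular
    CNP, modeled as exp(-((t)/tau_CNP)**cnp_hill) (absent when CNP is
    clamped by exogenous peptide).
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    p = params
    dt = np.maximum(t - perturb.lh_time, 0.0)
    if perturb.npr2_7E:
        phi = np.ones_like(dt)
    else:
        phi = p.phi_min + (1.0 - p.phi_min) * np.exp(-dt / p.tau_dephos)
    if perturb.cnp_clamp:
        psi = np.ones_like(dt)
    else:
        psi = np.exp(-((dt / p.tau_CNP) ** p.cnp_hill))
    a = phi * psi
    return a if a.ndim else float(a)


def pde3a_rate(A: float, G: float,
               params: ModelParameters = DEFAULT_PARAMETERS) -> float:
    """PDE3A cAMP hydrolysis rate (nM/min) with competitive cGMP inhibition.

    rate = Vmax3 * A / (Km3 * (1 + G/Ki3) + A).
    """
    if A < 0 or G < 0:
        raise ValueError("concentrations must be non-negative")
    p = params
    return p.Vmax3 * A / (p.Km3 * (1.0 + G / p.Ki3) + A)


def junction_exchange(conc_a: float, conc_b: float, P: float,
                      V_a: float, V_b: float) -> tuple[float, float]:
    """Concentration rates of change from gap-junction exchange.

    Amount flux J = P * (conc_b - conc_a) flows into compartment a;
    V_a*dC_a/dt + V_b*dC_b/dt = 0 exactly (amount conservation).
    """
    if V_a <= 0 or V_b <= 0:
        raise ValueError("volumes must be positive")
    if P < 0:
        raise ValueError("permeability must be non-negative")
    J = P * (conc_b - conc_a)
    return J / V_a, -J / V_b


def _rhs(t: float, y: np.ndarray, p: ModelParameters, g: FollicleGeometry,
         pert: PerturbationConfig, lh_on: bool = True) -> np.ndarray:
    A_m, A_c, A_o, G_m, G_c, G_o = y
    eps_mc, eps_co = pert.junction_factors
    if lh_on:
        dt_lh = t - pert.lh_time
        lam = 1.0 - math.exp(-dt_lh / p.tau_LH) if dt_lh > 0 else 0.0
        if pert.pde5a_S92A:
            th5 = 0.0
        else:
            th5 = 1.0 - math.exp(-dt_lh / p.tau_PDE5) if dt_lh > 0 else 0.0
        d = float(cx43_permeability_factor(t, p, pert))
        act = float(npr2_activity(t, p, pert))
    else:
        lam, th5, d, act = 0.0, 0.0, 1.0, 1.0

    P_mc = p.P_mc * d * eps_mc
    P_co = p.P_co * eps_co
    V_m, V_c, V_o = g.V_m, g.V_c, g.V_o

    # cAMP
    J_mc = P_mc * (A_m - A_c)          # amount/min, mural -> cumulus
    J_co = P_co * (A_c - A_o)          # cumulus -> oocyte
    dA_m = p.k_FSH + p.k_LH * lam - p.k_degA_g * A_m - J_mc / V_m
    dA_c = p.k_FSH - p.k_degA_g * A_c + J_mc / V_c - J_co / V_c
    pde3 = p.Vmax3 * A_o / (p.Km3 * (1.0 + max(G_o, 0.0) / p.Ki3) + A_o) \
        if A_o > 0 else 0.0
    dA_o = p.k_GPR3 - pde3 + J_co / V_o

    # cGMP
    k5 = p.k5_basal + p.dk5_LH * th5
    Jg_mc = P_mc * (G_m - G_c)
    Jg_co = P_co * (G_c - G_o)
    dG_m = p.V_NPR2 * act - k5 * G_m - Jg_mc / V_m
    dG_c = p.V_NPR2 * act - k5 * G_c + Jg_mc / V_c - Jg_co / V_c
    dG_o = -p.k_degG_o * G_o + Jg_co / V_o
    return np.array([dA_m, dA_c, dA_o, dG_m, dG_c, dG_o])


def pre_lh_steady_state(params: ModelParameters = DEFAULT_PARAMETERS,
                        geometry: FollicleGeometry = DEFAULT_GEOMETRY,
                        perturb: PerturbationConfig = WILD_TYPE) -> np.ndarray:
    """Fixed point of the model with all LH-driven terms off.

    Returns ``[A_m, A_c, A_o, G_m, G_c, G_o]`` in nM.  Any static drug
    factor (carbenoxolone) is applied, since blockers are added before
    LH.  Raises :class:`SteadyStateError` if the residual derivative
    norm exceeds 1e-8 nM/min.
    """
    p, g = params, geometry
    eps_mc, eps_co = perturb.junction_factors
    A_g = p.k_FSH / p.k_degA_g
    G_g = p.V_NPR2 / p.k5_basal
    r = p.P_co * eps_co / g.V_o
    G_o0 = G_g * r / (p.k_degG_o + r) if (p.k_degG_o + r) > 0 else G_g
    guess = np.array([A_g, A_g, A_g, G_g, G_g, G_o0])

    def fun(y: np.ndarray) -> np.ndarray:
        return _rhs(0.0, np.maximum(y, 0.0), p, g, perturb, lh_on=False)

    sol = root(fun, guess, method="hybr", tol=1e-12)
    y = np.maximum(sol.x, 0.0)
    res = float(np.linalg.norm(fun(y)))
    if res > 1e-8:
        raise SteadyStateError(
            f"pre-LH steady state did not converge (residual {res:.3g} nM/min)")
    return y


def simulate(params: ModelParameters = DEFAULT_PARAMETERS,
             geometry: FollicleGeometry = DEFAULT_GEOMETRY,
             perturb: PerturbationConfig = WILD_TYPE,
             t_end: float = 300.0,
             dt_out: float = 0.25,
             baseline: float = 10.0,
             rtol: float = 1e-8,
             atol: float = 1e-9) -> CompartmentTraces:
    """Integrate the model from the pre-LH steady state.

    The output grid runs from ``-baseline`` to ``t_end`` minutes in
    steps of ``dt_out``; internal stepping is adaptive (LSODA).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y0 = pre_lh_steady_state(params, geometry, perturb)
    t0 = -abs(baseline)
    t_grid = np.arange(t0, t_end + dt_out / 2, dt_out)

    sol = solve_ivp(
        _rhs, (t0, t_end), y0, t_eval=t_grid, method="LSODA",
        args=(params, geometry, perturb, True),
        rtol=rtol, atol=atol, max_step=5.0)
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    y = sol.y
    if not np.all(np.isfinite(y)):
        bad = t_grid[np.argmax(~np.isfinite(y).all(axis=0))]
        raise IntegrationError(f"non-finite state near t = {bad:.2f} min")
    y = np.maximum(y, 0.0)  # clip solver-tolerance-level negatives
    return CompartmentTraces(
        t=sol.t, cAMP_mural=y[0], cAMP_cumulus=y[1], cAMP_oocyte=y[2],
        cGMP_mural=y[3], cGMP_cumulus=y[4], cGMP_oocyte=y[5])


def nebd_time(t: Sequence[float], trace: Sequence[float],
              threshold: float = 185.0, hold: float = 15.0) -> float | None:
    """First time oocyte cAMP stays below ``threshold`` for ``hold`` minutes.

    Nuclear envelope breakdown follows the fall in oocyte cAMP; the
    hold requirement rejects transient dips.  Returns the interpolated
    crossing time, or ``None`` if the condition is never met within the
    trace.  Raises ``ValueError`` if ``hold`` exceeds the trace extent.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(trace, dtype=float)
    if hold > t[-1] - t[0]:
        raise ValueError("hold exceeds the trace extent")
    below = y < threshold
    for i in np.flatnonzero(below):
        if t[i] + hold > t[-1] + 1e-9:
            break  # hold window would run past the end of the trace
        j = int(np.searchsorted(t, t[i] + hold, side="left"))
        if below[i:min(j + 1, len(t))].all():
            if i == 0:
                return float(t[0])
            # interpolate the downward crossing of the threshold
            t1, t2 = t[i - 1], t[i]
            y1, y2 = y[i - 1], y[i]
            if y1 == y2:
                return float(t2)
            return float(t1 + (y1 - threshold) / (y1 - y2) * (t2 - t1))
    return None
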