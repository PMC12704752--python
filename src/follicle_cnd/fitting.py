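"""Calibration of the shipped default parameters.

The published record constrains the model through printed landmarks
(basal/peak/minimum concentrations, half-rise and decline times,
perturbation delays), not through rate constants.  This module fits the
free effective rates by bounded least squares on log-parameters so that
the deterministic model reproduces those landmarks simultaneously.

The fit parameterization keeps the exactly-known pre-LH state built in:
``k_FSH`` is tied to the 700 nM granulosa baseline, ``k_GPR3`` closes
the oocyte cAMP balance at 700 nM, and the absolute granulosa cGMP
scale (which the record does not pin down, the dynamics being linear in
cGMP) is fixed at 1500 nM, leaving only the inhibition strength
``G_o0/Ki3`` free.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .geometry import DEFAULT_GEOMETRY, FollicleGeometry
from .parameters import ModelParameters, PerturbationConfig
from .scenarios import ANCHOR_REGISTRY, compute_anchor_values

__all__ = ["build_parameters", "fit_default_parameters", "FIT_X0",
           "FIT_BOUNDS"]

G_GRANULOSA_BASAL = 1500.0   # nM; sets the (unidentified) cGMP scale
A_BASAL = 700.0              # nM; measured basal cAMP, all compartments
K_DEG_G_O = 0.010            # 1/min; minor oocyte cGMP loss, fixed
TAU_PDE5 = 15.0              # min; PDE5A phosphorylation, fixed

# free parameters (fitted in log space)
FIT_NAMES = ("k_degA_g", "tau_LH", "k_LH", "g_c", "q", "Vmax3", "Km3",
             "X_inh", "k5_basal", "dk5_LH", "tau_dephos", "phi_min",
             "tau_CNP", "cnp_hill", "dip_depth", "eps_mc", "eps_co")

FIT_X0 = {
    "k_degA_g": 0.287018,
    "tau_LH": 2.23985,
    "k_LH": 788.193,
    "g_c": 0.25943,
    "q": 0.543369,
    "Vmax3": 1083.41,
    "Km3": 61.3947,
    "X_inh": 18144.2,
    "k5_basal": 0.402364,
    "dk5_LH": 1.14315,
    "tau_dephos": 12.735,
    "phi_min": 0.00300795,
    "tau_CNP": 55.555,
    "cnp_hill": 0.883869,
    "dip_depth": 0.418553,
    "eps_mc": 0.111639,
    "eps_co": 0.0116474,
}

FIT_BOUNDS = {
    "k_degA_g": (0.05, 2.0), "tau_LH": (0.3, 5.0), "k_LH": (100.0, 1e4),
    "g_c": (0.05, 5.0), "q": (0.05, 3.0),
    "Vmax3": (200.0, 5e4), "Km3": (20.0, 5e3),
    "X_inh": (5.0, 1e5),
    "k5_basal": (0.05, 5.0), "dk5_LH": (0.01, 5.0),
    "tau_dephos": (1.0, 30.0), "phi_min": (1e-3, 0.5),
    "tau_CNP": (15.0, 400.0), "cnp_hill": (0.35, 4.0),
    "dip_depth": (0.02, 0.95), "eps_mc": (0.005, 0.5), "eps_co": (0.002, 0.5),
}


def build_parameters(free: Mapping[str, float],
                     geometry: FollicleGeometry = DEFAULT_GEOMETRY
                     ) -> ModelParameters:
    """Assemble a full parameter set from the free fit parameters.

    Derived quantities: junction coefficients from per-volume rates,
    ``k_FSH`` and ``k_GPR3`` from the 700 nM basal closure, ``Ki3``
    from the inhibition strength, ``V_NPR2`` from the fixed granulosa
    cGMP scale.
    """
    g = geometry
    q = free["q"]
    P_co = q * g.V_o
    P_mc = free["g_c"] * g.V_c
    k5 = free["k5_basal"]
    V_NPR2 = G_GRANULOSA_BASAL * k5
    G_o0 = G_GRANULOSA_BASAL * q / (K_DEG_G_O + q)
    Ki3 = G_o0 / free["X_inh"]
    Km3, Vmax3 = free["Km3"], free["Vmax3"]
    k_GPR3 = Vmax3 * A_BASAL / (Km3 * (1.0 + G_o0 / Ki3) + A_BASAL)
    return ModelParameters(
        k_GPR3=k_GPR3,
        k_FSH=A_BASAL * free["k_degA_g"],
        k_LH=free["k_LH"], tau_LH=free["tau_LH"],
        k_degA_g=free["k_degA_g"],
        Vmax3=Vmax3, Km3=Km3, Ki3=Ki3,
        V_NPR2=V_NPR2, tau_dephos=free["tau_dephos"],
        phi_min=free["phi_min"], tau_CNP=free["tau_CNP"],
        cnp_hill=free["cnp_hill"],
        k5_basal=k5, dk5_LH=free["dk5_LH"], tau_PDE5=TAU_PDE5,
        k_degG_o=K_DEG_G_O,
        P_mc=P_mc, P_co=P_co,
        dip_depth=free["dip_depth"])


_TARGETS = {e["id"]: e["target"] for e in ANCHOR_REGISTRY}
_TARGETS["t11"] = 5.2  # aim inside (5, 5.5): the crossing must fall after the wild-type window


def _residuals(x: np.ndarray, geometry: FollicleGeometry,
               eps_store: dict) -> np.ndarray:
    free = dict(zip(FIT_NAMES, np.exp(x)))
    eps_store["eps_mc"] = free["eps_mc"]
    eps_store["eps_co"] = free["eps_co"]
    try:
        params = build_parameters(free, geometry)
        pert_defaults = {"eps_mc": free["eps_mc"], "eps_co": free["eps_co"]}
        vals = compute_anchor_values(params, geometry, dt_out=0.5,
                                     rtol=1e-6, atol=1e-8)
    except Exception:
        return np.full(17, 10.0)
    # carbenoxolone anchor must see the candidate eps factors; recompute
    # with them injected via a perturbation override
    from .model import simulate
    from .scenarios import PRESETS
    from .sensor import CAMPFIRE_M, ratio_from_concentration
    cbx = simulate(params, geometry,
                   PerturbationConfig(carbenoxolone=True, **pert_defaults),
                   t_end=300.0, dt_out=0.5, rtol=1e-6, atol=1e-8)
    wt = simulate(params, geometry, PRESETS["wild_type"], t_end=300.0,
                  dt_out=0.5, rtol=1e-6, atol=1e-8)

    def cum_change(tr):
        r = np.asarray(ratio_from_concentration(tr.cAMP_cumulus, CAMPFIRE_M))
        return float(r[tr.t >= 0].max() - r[tr.t < 0].mean())

    def ooc_change(tr):
        r = np.asarray(ratio_from_concentration(tr.cAMP_oocyte, CAMPFIRE_M))
        return float(r[tr.t >= 0].max() - r[tr.t < 0].mean())

    t12 = 100.0 * cum_change(cbx) / cum_change(wt)
    ooc_frac = ooc_change(cbx) / ooc_change(wt)

    weights = {"t2": 2.0, "t3": 2.0, "t7": 3.0, "t9": 2.0, "t10": 3.0, "t12": 2.0}
    res = []
    for key in ("t1", "t2", "t3", "t5", "t6", "t7", "t9", "t10",
                "t11", "t12"):
        v = t12 if key == "t12" else vals[key]["value"]
        v = v if np.isfinite(np.asarray(v, dtype=float)) else 10.0 * _TARGETS[key]
        res.append(weights.get(key, 1.0) * (v - _TARGETS[key]) / _TARGETS[key])
    # shape of the wild-type oocyte cAMP trace: the minimum (~170 nM)
    # sits at ~3 h, with a flat recovery above it afterwards and a
    # gradual decline before it
    a = wt.cAMP_oocyte

    def at(tq: float) -> float:
        return float(np.interp(tq, wt.t, a))

    res.append(2.0 * (at(180.0) - 170.0) / 170.0)
    late = a[(wt.t >= 220) & (wt.t <= 300)]
    res.append(2.0 * max(0.0, (171.0 - late.min()) / 170.0))
    # the 3-h trough must be the global minimum: late plateau strictly
    # above the value at 180 min
    res.append(4.0 * max(0.0, (at(180.0) + 2.0 - late.min()) / 170.0))
    gmin = a[wt.t >= 0].min()
    res.append(5.0 * max(0.0, (168.0 - gmin) / 170.0))
    res.append(1.5 * (at(300.0) - 172.0) / 170.0)
    res.append(0.3 * (at(120.0) - 320.0) / 320.0)
    # guard: carbenoxolone must nearly abolish the oocyte response
    res.append(5.0 * max(0.0, ooc_frac - 0.08))
    return np.asarray(res)


def fit_default_parameters(geometry: FollicleGeometry = DEFAULT_GEOMETRY,
                           x0: Mapping[str, float] | None = None,
                           seed: int = 0,
                           max_nfev: int = 400,
                           verbose: int = 0):
    """Bounded least-squares calibration against the anchor registry.

    Deterministic (the optimizer itself is); ``seed`` is accepted for
    interface uniformity.  Returns ``(ModelParameters, eps_mc, eps_co,
    scipy result)``.
    """
    x0 = dict(FIT_X0 if x0 is None else x0)
    x = np.log([x0[k] for k in FIT_NAMES])
    lo = np.log([FIT_BOUNDS[k][0] for k in FIT_NAMES])
    hi = np.log([FIT_BOUNDS[k][1] for k in FIT_NAMES])
    eps_store: dict = {}
    result = least_squares(
        _residuals, x, bounds=(lo, hi), args=(geometry, eps_store),
        diff_step=0.03, max_nfev=max_nfev, verbose=verbose)
    free = dict(zip(FIT_NAMES, np.exp(result.x)))
    params = build_parameters(free, geometry)
    return params, free["eps_mc"], free["eps_co"], result
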