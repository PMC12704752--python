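"""Scenario orchestration: experimental arms, anchors, closed-loop checks.

Each scenario corresponds to one experimental arm (wild type, the
Npr2-7E;Pde5a-S92A double phosphomutant, AG1478, carbenoxolone, CNP
clamp).  ``compute_anchor_values`` re-derives every printed kinetic and
concentration landmark from the shipped default model, on the scale the
measurements are reported (minutes, hours, nM, percent); it is the
single source for both the regression suite and the reproduction
script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .analysis import (MetricUndefinedError, compute_kinetic_metrics,
                       time_below_baseline, time_to_fraction_of_peak,
                       time_to_near_minimum)
from .geometry import DEFAULT_GEOMETRY, FollicleGeometry
from .model import CompartmentTraces, pre_lh_steady_state, simulate
from .parameters import (DEFAULT_PARAMETERS, ModelParameters,
                         PerturbationConfig)
from .sensor import CAMPFIRE_M, CGI500, ratio_from_concentration

__all__ = ["PRESETS", "Scenario", "run_scenario", "compute_anchor_values",
           "anchor_report", "closed_loop_validation", "ANCHOR_REGISTRY"]

PRESETS: dict[str, PerturbationConfig] = {
    "wild_type": PerturbationConfig(),
    "npr2_7E_pde5a_S92A": PerturbationConfig(npr2_7E=True, pde5a_S92A=True),
    "ag1478": PerturbationConfig(ag1478=True),
    "carbenoxolone": PerturbationConfig(carbenoxolone=True),
    "cnp_clamp": PerturbationConfig(npr2_7E=True, pde5a_S92A=True,
                                    cnp_clamp=True),
}


@dataclass(frozen=True)
class Scenario:
    name: str = "wild_type"
    parameter_overrides: Mapping[str, float] = field(default_factory=dict)
    perturbation: PerturbationConfig | None = None
    n_follicles: int = 1
    jitter_cv: float = 0.10       # lognormal CV on k_GPR3 / V_NPR2 across follicles
    seed: int = 0
    t_end: float = 300.0
    dt_out: float = 0.25

    def __post_init__(self) -> None:
        if self.perturbation is None and self.name not in PRESETS:
            raise ValueError(f"unknown scenario preset '{self.name}'")
        if self.n_follicles < 1:
            raise ValueError("n_follicles must be >= 1")

    def resolve_perturbation(self) -> PerturbationConfig:
        return self.perturbation if self.perturbation is not None \
            else PRESETS[self.name]


def run_scenario(scenario: Scenario,
                 params: ModelParameters = DEFAULT_PARAMETERS,
                 geometry: FollicleGeometry = DEFAULT_GEOMETRY
                 ) -> dict[str, Any]:
    """Simulate a cohort of follicles for one experimental arm.

    With ``n_follicles == 1`` no inter-follicle jitter is applied, so
    the single trace reproduces the deterministic anchors; larger
    cohorts draw lognormal (CV ``jitter_cv``) per-follicle factors on
    the oocyte cAMP synthesis and granulosa cGMP synthesis rates.
    Kinetic metrics are computed on the CFP/YFP ratio traces that the
    sensors would report.
    """
    pert = scenario.resolve_perturbation()
    p0 = params.replace(**dict(scenario.parameter_overrides)) \
        if scenario.parameter_overrides else params
    rng = np.random.default_rng(scenario.seed)
    traces_list: list[CompartmentTraces] = []
    metrics_rows: list[dict[str, Any]] = []
    sigma = np.sqrt(np.log1p(scenario.jitter_cv**2))
    for i in range(scenario.n_follicles):
        if scenario.n_follicles > 1:
            f1, f2 = np.exp(rng.normal(-sigma**2 / 2, sigma, size=2))
            p = p0.replace(k_GPR3=p0.k_GPR3 * f1, V_NPR2=p0.V_NPR2 * f2)
        else:
            p = p0
        tr = simulate(p, geometry, pert, t_end=scenario.t_end,
                      dt_out=scenario.dt_out)
        traces_list.append(tr)
        for region in ("mural", "cumulus", "oocyte"):
            for species, calib in (("cAMP", CAMPFIRE_M), ("cGMP", CGI500)):
                r = ratio_from_concentration(tr.series(species, region), calib)
                try:
                    m = compute_kinetic_metrics(tr.t, r)
                except MetricUndefinedError:
                    continue
                metrics_rows.append({"follicle": i, "region": region,
                                     "species": species,
                                     **m.__dict__})
    summary = pd.DataFrame(metrics_rows)
    return {"scenario": scenario, "perturbation": pert,
            "traces": traces_list, "metrics": summary}


# -------------------------------------------------------------- anchors

# Printed landmarks of the imaging experiments.  tol: relative width the
# report grades against ("~" figures 15%, mean +/- SEM figures 10%).
ANCHOR_REGISTRY: list[dict[str, Any]] = [
    {"id": "t1", "target": 2.9, "units": "min", "tol": 0.10,
     "desc": "mural cAMP ratio time to 50% of peak (wild type)"},
    {"id": "t2", "target": 5.5, "units": "min", "tol": 0.10,
     "desc": "cumulus cAMP ratio time to 50% of peak (wild type)"},
    {"id": "t3", "target": 7.1, "units": "min", "tol": 0.10,
     "desc": "oocyte cAMP ratio time to 50% of peak (wild type)"},
    {"id": "t4", "target": 700.0, "units": "nM", "tol": 0.15,
     "desc": "pre-LH steady-state oocyte cAMP"},
    {"id": "t5", "target": 170.0, "units": "nM", "tol": 0.15,
     "desc": "post-LH minimum oocyte cAMP (wild type)"},
    {"id": "t6", "target": 3400.0, "units": "nM", "tol": 0.15,
     "desc": "post-LH maximum mural cAMP (wild type)"},
    {"id": "t7", "target": 1.0, "units": "h", "tol": 0.15,
     "desc": "oocyte cAMP first below baseline (wild type)"},
    {"id": "t8", "target": 3.0, "units": "h", "tol": 0.15,
     "desc": "time of oocyte cAMP minimum (wild type)"},
    {"id": "t9", "target": 20.0, "units": "min", "tol": 0.15,
     "desc": "mural cGMP time to minimum level (wild type)"},
    {"id": "t10", "target": 3.0, "units": "h", "tol": 0.15,
     "desc": "mural cGMP time to minimum level (Npr2-7E;Pde5a-S92A)"},
    {"id": "t11", "target": 5.0, "units": "h", "tol": 0.15,
     "desc": "oocyte cAMP reaches wild-type minimum with Cx43 dip disabled"},
    {"id": "t12", "target": 30.0, "units": "%", "tol": 0.15,
     "desc": "cumulus ratio change under carbenoxolone, % of control"},
]


def compute_anchor_values(params: ModelParameters = DEFAULT_PARAMETERS,
                          geometry: FollicleGeometry = DEFAULT_GEOMETRY,
                          dt_out: float = 0.25,
                          rtol: float = 1e-8, atol: float = 1e-9
                          ) -> dict[str, dict[str, float]]:
    """Recompute every registered anchor from scratch.

    Runs the four deterministic arms (wild type, double phosphomutant,
    AG1478, carbenoxolone) and extracts each landmark with the pipeline
    metrics.  Values are reported on the printed scale: minutes, hours,
    nM, or percent of control.
    """
    kw = dict(dt_out=dt_out, rtol=rtol, atol=atol)
    wt = simulate(params, geometry, PRESETS["wild_type"], t_end=300.0, **kw)
    mut = simulate(params, geometry, PRESETS["npr2_7E_pde5a_S92A"],
                   t_end=300.0, **kw)
    ag = simulate(params, geometry, PRESETS["ag1478"], t_end=330.0, **kw)
    cbx = simulate(params, geometry, PRESETS["carbenoxolone"],
                   t_end=300.0, **kw)
    n = len(wt.t)

    def ratio(tr: CompartmentTraces, region: str) -> np.ndarray:
        return np.asarray(
            ratio_from_concentration(tr.series("cAMP", region), CAMPFIRE_M))

    out: dict[str, dict[str, float]] = {}

    def put(key: str, value: float, size: int = n) -> None:
        out[key] = {"value": float(value), "n": int(size)}

    put("t1", time_to_fraction_of_peak(wt.t, ratio(wt, "mural"), 0.5))
    put("t2", time_to_fraction_of_peak(wt.t, ratio(wt, "cumulus"), 0.5))
    put("t3", time_to_fraction_of_peak(wt.t, ratio(wt, "oocyte"), 0.5))

    ss = pre_lh_steady_state(params, geometry)
    put("t4", ss[2])

    post = wt.t >= 0
    a_o = wt.cAMP_oocyte
    wt_min = float(a_o[post].min())
    put("t5", wt_min)
    put("t6", float(wt.cAMP_mural[post].max()))
    tbb = time_below_baseline(wt.t, a_o)
    put("t7", (tbb / 60.0) if tbb is not None else np.nan)
    put("t8", float(wt.t[post][np.argmin(a_o[post])]) / 60.0)

    put("t9", time_to_near_minimum(wt.t, wt.cGMP_mural, 0.05))
    put("t10", time_to_near_minimum(mut.t, mut.cGMP_mural, 0.05) / 60.0,
        len(mut.t))

    ag_o = ag.cAMP_oocyte
    reach = np.flatnonzero((ag.t >= 0) & (ag_o <= wt_min))
    if len(reach):
        i = reach[0]
        if i > 0 and ag_o[i - 1] > wt_min:
            t1_, t2_ = ag.t[i - 1], ag.t[i]
            y1_, y2_ = ag_o[i - 1], ag_o[i]
            t_reach = t1_ + (y1_ - wt_min) / (y1_ - y2_) * (t2_ - t1_)
        else:
            t_reach = ag.t[i]
        put("t11", float(t_reach) / 60.0, len(ag.t))
    else:
        put("t11", np.nan, len(ag.t))

    def cum_change(tr: CompartmentTraces) -> float:
        r = ratio(tr, "cumulus")
        base = float(r[tr.t < 0].mean())
        return float(r[tr.t >= 0].max()) - base

    put("t12", 100.0 * cum_change(cbx) / cum_change(wt))
    return out


def anchor_report(values: Mapping[str, Mapping[str, float]] | None = None,
                  **kwargs: Any) -> pd.DataFrame:
    """Grade computed anchor values against the registered landmarks."""
    if values is None:
        values = compute_anchor_values(**kwargs)
    rows = []
    for entry in ANCHOR_REGISTRY:
        v = values[entry["id"]]["value"]
        dev = abs(v - entry["target"]) / abs(entry["target"])
        rows.append({"id": entry["id"], "description": entry["desc"],
                     "computed": v, "target": entry["target"],
                     "units": entry["units"], "rel_deviation": dev,
                     "tolerance": entry["tol"],
                     "pass": bool(dev <= entry["tol"])})
    return pd.DataFrame(rows)


def closed_loop_validation(seed: int = 0,
                           params: ModelParameters = DEFAULT_PARAMETERS,
                           geometry: FollicleGeometry = DEFAULT_GEOMETRY,
                           t_end: float = 60.0,
                           frame_tolerance: float = 1.0) -> pd.DataFrame:
    """simulate -> render (default noise) -> register -> extract -> metrics.

    Compares the time-to-half-peak recovered through the full imaging
    pipeline with the value computed directly on the simulated ratio
    traces, for all three regions.  Passes when each recovered landmark
    is within one frame interval of the direct one.
    """
    from .analysis import extract_traces, register_stack, rois_from_ground_truth
    from .imaging import FollicleScene, render_timelapse

    tr = simulate(params, geometry, PRESETS["wild_type"], t_end=t_end,
                  dt_out=0.25)
    scene = FollicleScene(geometry=geometry, seed=seed, jitter_sd=0.5)
    stack = render_timelapse(scene, tr, CAMPFIRE_M)
    aligned, _ = register_stack(stack)
    rois = rois_from_ground_truth(aligned)
    measured = extract_traces(aligned, rois)

    roi_to_region = {"outer_mural": "mural", "cumulus": "cumulus",
                     "oocyte": "oocyte"}
    rows = []
    for roi, region in roi_to_region.items():
        direct_r = ratio_from_concentration(tr.series("cAMP", region),
                                            CAMPFIRE_M)
        t_direct = time_to_fraction_of_peak(tr.t, np.asarray(direct_r), 0.5)
        t_meas = time_to_fraction_of_peak(measured.t, measured.ratio[roi], 0.5)
        rows.append({"roi": roi, "t50_direct_min": t_direct,
                     "t50_recovered_min": t_meas,
                     "abs_error_min": abs(t_meas - t_direct),
                     "pass": bool(abs(t_meas - t_direct) <= frame_tolerance)})
    return pd.DataFrame(rows)
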