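"""Named scenario fixtures: one per reproduced figure, at desk scale.

Each scenario assembles the relevant model, runs it with the printed
parameter values (overridable through a validated JSON configuration),
and writes CSV time series / VTK fields plus a JSON summary of headline
observables into an output directory.  Scenarios are pure data plus a
registered pipeline function; re-running with the same configuration and
seed is bit-identical.
"""

from __future__ import annotations

import json
import re
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bifurcation import accumulate_ros, protocol_sequence, relax_to_steady, \
    sweep_parameter
from .constants import um_per_min_to_si
from .mito import (
    build_isolated_mito_model,
    default_mito_initial,
    simulate_ca_pulses,
    simulate_isolated_cii,
)
from .rates import RateSet

__all__ = ["Scenario", "validate_config", "run", "SCENARIOS",
           "glutamate_sweep", "normalize_quantity"]

#: registered scenario names
SCENARIOS = ("fig2", "fig3", "fig4", "fig5", "fig6", "fig7",
             "fig9_normal", "fig9_high")

_DEFAULTS: dict[str, dict] = {
    "fig2": {"myxothiazol_fractions": [4e-8, 1.4e-6, 2e-6, 4e-6],
             "succinate_um": [1.0, 500.0, 12],   # geometric grid: lo, hi, n
             "qo_binding_constant": 700.0},
    "fig3": {"k_fad": 175.0, "glutamate_um": [0.0, 60.0, 31],
             "k_ros": 2e-5},
    "fig4": {"k_leak": [2.0, 40.0], "glutamate_um": 50.0,
             "window_s": 60.0, "horizon_s": 900.0},
    "fig5": {"glutamate_um": 50.0, "t_first_s": 100.0, "t_second_s": 800.0,
             "horizon_s": 2500.0},
    "fig6": {"n_pulses": 2, "pulse_nmol": 20.0, "p_ca": 0.005,
             "f_over_c": 500.0, "glutamate_um": 4.0},
    "fig7": {"presets": ["glu", "GLU", "work"], "horizon_s": 2000.0},
    "fig9_normal": {"report_times_ms": [1.0, 5.0, 20.0, 100.0],
                    "j_high": "5.05 uM/min"},
    "fig9_high": {"report_times_ms": [1.0, 5.0, 20.0, 100.0],
                  "j_high": "106 uM/min"},
}

_UNIT_FACTORS = {
    # target canonical units per quantity kind
    "uM/min": ("mol m^-3 s^-1", um_per_min_to_si),
    "um/min": ("mol m^-3 s^-1", um_per_min_to_si),
    "uM": ("nmol/mg", lambda v: v / 1000.0),
    "um": ("nmol/mg", lambda v: v / 1000.0),
    "mM": ("nmol/mg", lambda v: v),
    "nM": ("nM", lambda v: v),
    "mV": ("mV", lambda v: v),
    "s^-1": ("s^-1", lambda v: v),
}


def normalize_quantity(value):
    """Normalise ``"5.05 uM/min"``-style strings to canonical units.

    Returns the numeric value (floats pass through unchanged).
    """
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"\s*([-+0-9.eE]+)\s*(.+?)\s*", str(value))
    if not m:
        raise ValueError(f"cannot parse quantity {value!r}")
    num, unit = float(m.group(1)), m.group(2)
    unit = unit.replace("μ", "u")
    if unit not in _UNIT_FACTORS:
        raise ValueError(f"unknown unit {unit!r} in {value!r}")
    return _UNIT_FACTORS[unit][1](num)


@dataclass
class Scenario:
    """A validated, fully defaulted scenario document (pure data)."""

    name: str
    seed: int = 0
    settings: dict = field(default_factory=dict)
    rate_overrides: dict = field(default_factory=dict)

    def to_document(self) -> dict:
        return {"name": self.name, "seed": self.seed,
                "settings": dict(self.settings),
                "rate_overrides": dict(self.rate_overrides)}


def validate_config(document: dict) -> Scenario:
    """Schema-check a scenario document, fill defaults, normalise units.

    Unknown top-level keys, unknown setting keys for the scenario, and
    negative rate constants are hard errors.  Quantities given as
    strings with units are normalised to the package's canonical units.
    """
    if not isinstance(document, dict):
        raise TypeError("scenario document must be a mapping")
    allowed = {"name", "seed", "settings", "rate_overrides"}
    unknown = set(document) - allowed
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    name = document.get("name")
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; known: {SCENARIOS}")
    settings = dict(_DEFAULTS[name])
    user = document.get("settings", {})
    bad = set(user) - set(settings)
    if bad:
        raise ValueError(f"unknown settings for {name}: {sorted(bad)}")
    for k, v in user.items():
        settings[k] = normalize_quantity(v) if isinstance(v, str) else v
    overrides = {}
    for k, v in document.get("rate_overrides", {}).items():
        v = normalize_quantity(v)
        if v < 0:
            raise ValueError(f"rate constant {k!r} must be >= 0")
        overrides[k] = v
    return Scenario(name=name, seed=int(document.get("seed", 0)),
                    settings=settings, rate_overrides=overrides)


# --------------------------------------------------------------------------
# pipelines
# --------------------------------------------------------------------------

def glutamate_sweep(glu_lo_um: float = 0.0, glu_hi_um: float = 60.0,
                    n_points: int = 31, direction: str = "up",
                    k_fad: float = 175.0, k_leak: float = 2.0,
                    x_start=None, model=None):
    """Steady-state glutamate sweep of the isolated-mitochondrion model.

    Returns the :class:`~mitoros.bifurcation.Branch`; for a down-sweep an
    explicit starting state (usually the end of an up-sweep) can be given.
    """
    from .chain import default_chain_rates
    from .mito import default_matrix_rates

    if model is None:
        rates = default_chain_rates()
        rates["k_succ_on"] = k_fad
        mr = default_matrix_rates()
        mr["k_leak"] = k_leak
        model = build_isolated_mito_model(rates=rates, matrix_rates=mr)
    grid = np.linspace(glu_lo_um / 1000.0, glu_hi_um / 1000.0, n_points)
    if direction == "down":
        grid = grid[::-1]
    elif direction != "up":
        raise ValueError("direction must be 'up' or 'down'")
    x0 = x_start if x_start is not None else default_mito_initial(model)

    def set_glu(m, x, p):
        m.clamped["glu_ext"] = p
        m.set_pool(x, "glu_ext", p)

    label = "active" if direction == "up" else "inactive"
    return model, sweep_parameter(model, grid, x0, set_glu,
                                  start_label=label, t_cap=1e6)


def _run_fig2(sc: Scenario, out: Path) -> dict:
    lo, hi, n = sc.settings["succinate_um"]
    grid = np.geomspace(lo, hi, int(n))
    rates = None
    if sc.rate_overrides:
        from .chain import default_chain_rates
        rates = default_chain_rates()
        rates.update(sc.rate_overrides)
    peaks = {}
    frames = []
    ref_max = None
    fractions = list(sc.settings["myxothiazol_fractions"])
    # compute the reference (4e-8) curve first: every curve is normalised
    # to its maximum, as in the published presentation
    fractions.sort(key=lambda f: (f != 4e-8, f))
    for frac in fractions:
        df = simulate_isolated_cii(grid, frac, rates=rates, normalize=False)
        if ref_max is None:
            ref_max = float(df.ros_rate.max())
        df["ros_norm"] = df.ros_rate / ref_max
        df["myxothiazol_fraction"] = frac
        frames.append(df)
        peaks[f"{frac:g}"] = float(df.succinate_um[df.ros_rate.idxmax()])
    pd.concat(frames, ignore_index=True).to_csv(out / "fig2_curves.csv",
                                                index=False)
    return {"succinate_at_peak_um": peaks}


def _run_fig3(sc: Scenario, out: Path) -> dict:
    lo, hi, n = sc.settings["glutamate_um"]
    model, up = glutamate_sweep(lo, hi, int(n), "up",
                                k_fad=sc.settings["k_fad"])
    dn = None
    if up.jump_parameter is not None:
        _, dn = glutamate_sweep(lo, hi, int(n), "down",
                                k_fad=sc.settings["k_fad"],
                                x_start=up.points[-1].x, model=model)
    up.to_frame().to_csv(out / "fig3_up.csv", index=False)
    summary = {"jump_up_um": None if up.jump_parameter is None
               else 1000.0 * up.jump_parameter,
               "qh2_fraction_final": up.points[-1].observables["qh2_fraction"]}
    if dn is not None:
        dn.to_frame().to_csv(out / "fig3_down.csv", index=False)
        summary["jump_down_um"] = (None if dn.jump_parameter is None
                                   else 1000.0 * dn.jump_parameter)
    return summary


def _glutamate_switch_trajectory(k_leak: float, glu: float, horizon: float):
    from .chain import default_chain_rates
    from .mito import default_matrix_rates

    mr = default_matrix_rates()
    mr["k_leak"] = k_leak
    model = build_isolated_mito_model(matrix_rates=mr)
    x0 = relax_to_steady(model, default_mito_initial(model), t_cap=1e6).x
    return protocol_sequence(model, x0, [(0.0, "glutamate", glu)],
                             horizon, dt_report=2.0)


def _run_fig4(sc: Scenario, out: Path) -> dict:
    glu = sc.settings["glutamate_um"] / 1000.0
    horizon = sc.settings["horizon_s"]
    window = sc.settings["window_s"]
    summary = {}
    for k_leak in sc.settings["k_leak"]:
        traj = _glutamate_switch_trajectory(k_leak, glu, horizon)
        traj.to_csv(out / f"fig4_leak{k_leak:g}.csv", index=False)
        # accumulate from the glutamate addition over the whole record
        # (complex II's contribution is a transient near the switch) and
        # over the final minute (the steady rates)
        acc = accumulate_ros(traj, window_s=horizon,
                             complex_amounts={"cii": 0.25, "ciii": 0.25})
        acc["total"] = acc["cii"] + acc["ciii"]
        tail = traj[traj.time >= horizon - window].reset_index(drop=True)
        acc_tail = accumulate_ros(tail, window_s=window,
                                  complex_amounts={"cii": 0.25, "ciii": 0.25})
        summary[f"k_leak_{k_leak:g}"] = {"accumulated": acc,
                                         "final_60s": acc_tail}
    return {"accumulated_ros": summary}


def _run_fig5(sc: Scenario, out: Path) -> dict:
    glu = sc.settings["glutamate_um"] / 1000.0
    t1, t2 = sc.settings["t_first_s"], sc.settings["t_second_s"]
    horizon = sc.settings["horizon_s"]
    model = build_isolated_mito_model()
    x0 = relax_to_steady(model, default_mito_initial(model), t_cap=1e6).x
    orange = protocol_sequence(model, x0, [(t1, "glutamate", glu),
                                           (t2, "antimycin", 0.0)],
                               horizon, dt_report=5.0)
    blue = protocol_sequence(model, x0, [(t1, "antimycin", 0.0),
                                         (t2, "glutamate", glu)],
                             horizon, dt_report=5.0)
    orange.to_csv(out / "fig5_glu_then_antimycin.csv", index=False)
    blue.to_csv(out / "fig5_antimycin_then_glu.csv", index=False)
    fo = float(orange.ros_rate_ciii.iloc[-1])
    fb = float(blue.ros_rate_ciii.iloc[-1])
    return {"final_ros_ciii": {"glu_then_antimycin": fo,
                               "antimycin_then_glu": fb},
            "relative_difference": abs(fo - fb) / max(fo, fb)}


def _run_fig6(sc: Scenario, out: Path) -> dict:
    summary = {}
    for wg in (False, True):
        df = simulate_ca_pulses(int(sc.settings["n_pulses"]),
                                pulse_amount=sc.settings["pulse_nmol"],
                                with_glutamate=wg,
                                glu_ext=sc.settings["glutamate_um"] / 1000.0)
        tag = "glutamate" if wg else "control"
        df.to_csv(out / f"fig6_{tag}.csv", index=False)
        pre_psi = float(df[df.pulse == 0].psi.iloc[-1])
        d = df[df.pulse == 1].reset_index(drop=True)
        t0, ca0 = float(d.time.iloc[0]), float(d.ca_out.iloc[0])
        half = d.time[d.ca_out <= ca0 / 2]
        rec = d.time[(d.time > t0 + 5) & (d.psi >= 0.95 * pre_psi)]
        summary[tag] = {
            "pre_pulse_psi_mV": pre_psi,
            "ca_half_clearance_s": None if half.empty
            else float(half.iloc[0]) - t0,
            "psi_recovery95_s": None if rec.empty
            else float(rec.iloc[0]) - t0,
        }
    return summary


def _run_fig7(sc: Scenario, out: Path) -> dict:
    from .cell import run_insitu_scenario

    summary = {}
    for preset in sc.settings["presets"]:
        df = run_insitu_scenario(preset, horizon_s=sc.settings["horizon_s"])
        df.to_csv(out / f"fig7_{preset}.csv", index=False)
        r0 = max(float(df.ros_rate_ciii.iloc[0]), 1e-15)
        summary[preset] = {
            "ros_ciii_fold_final": float(df.ros_rate_ciii.iloc[-1]) / r0,
            "atp_initial_mM": float(df.atp.iloc[0]),
            "atp_final_mM": float(df.atp.iloc[-1]),
            "glu_m_max": float(df.glu_m.max()),
        }
    return summary


def _run_fig9(sc: Scenario, out: Path, high: bool) -> dict:
    from .h2o2 import (FieldState, PdeParams, assemble_operator,
                       axis_profile, solve_transient, steady_state)
    from .phantom import generate_phantom
    from .vtk_io import write_structured_points

    ph = generate_phantom(seed=sc.seed)
    params = PdeParams() if high else PdeParams(j_high_um_min=5.05)
    op = assemble_operator(ph, params)
    c0 = FieldState(ph.initial_concentration(params.c0_cell_nM,
                                             params.c0_isf_nM), 0.0)
    report = [t / 1000.0 for t in sc.settings["report_times_ms"]]
    early = [t for t in report if t <= 0.002]
    fields, info = solve_transient(op, c0, early + [0.002], dt_max=1e-4,
                                   track_axis=ph)
    fields2, info2 = solve_transient(op, fields[-1],
                                     [t for t in report if t > 0.002],
                                     dt_max=2e-3, track_axis=ph)
    axis_max = max(info["axis_max"], info2["axis_max"])
    ss = steady_state(op)
    rows = []
    for fs in fields[:-1] + fields2 + [ss]:
        xs, prof = axis_profile(fs, ph)
        for x, c in zip(xs, prof):
            rows.append({"time_s": fs.time, "x_um": x, "c_nM": c})
    pd.DataFrame(rows).to_csv(out / "axis_profiles.csv", index=False)
    write_structured_points(
        out / "steady.vtk",
        {"labels": ph.labels, "c_steady_nM": ss.concentration},
        spacing=ph.voxel_um, origin=tuple(ph.origin_um))
    report_max = max(float(f.concentration.max())
                     for f in fields[:-1] + fields2)
    return {
        "axis_transient_max_nM": axis_max,
        "axis_excess_percent": 100.0 * (axis_max - params.c0_cell_nM)
        / params.c0_cell_nM,
        "report_time_global_max_nM": report_max,
        "steady_global_max_nM": float(ss.concentration.max()),
        "cell_fraction": ph.cell_fraction_analytic,
        "seed": sc.seed,
    }


_PIPELINES = {
    "fig2": _run_fig2,
    "fig3": _run_fig3,
    "fig4": _run_fig4,
    "fig5": _run_fig5,
    "fig6": _run_fig6,
    "fig7": _run_fig7,
    "fig9_normal": lambda sc, out: _run_fig9(sc, out, high=False),
    "fig9_high": lambda sc, out: _run_fig9(sc, out, high=True),
}


def run(name_or_config, out_dir) -> dict:
    """Execute a registered scenario and write its result bundle.

    ``name_or_config`` is a scenario name or a configuration document;
    returns the JSON summary (also written to ``summary.json``).
    """
    if isinstance(name_or_config, str):
        sc = validate_config({"name": name_or_config})
    elif isinstance(name_or_config, Scenario):
        sc = name_or_config
    else:
        sc = validate_config(name_or_config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = _time.time()
    summary = _PIPELINES[sc.name](sc, out)
    bundle = {"scenario": sc.to_document(), "elapsed_s": _time.time() - t0,
              "summary": summary}
    with (out / "summary.json").open("w") as fh:
        json.dump(bundle, fh, indent=2, default=float)
    return bundle
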