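"""Multi-start one-at-a-time (OAT) sensitivity analysis.

One parameter at a time is swept across its distribution while the rest
are frozen at a start point; the sensitivity is the induced output range
as a percentage of the baseline output (all parameters at the start point,
the swept one at its central value).  Repeating from many randomly drawn
start points captures how a parameter's influence varies across the rest
of the parameter space; the mean and 95% percentile interval across starts
are reported, and parameters below a mean-sensitivity threshold are grouped
into "other parameters".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .uncertainty import (
    Distribution,
    ParameterDraw,
    ScenarioSpace,
    draw_parameters,
    substream,
)

logger = logging.getLogger(__name__)

ModelFn = Callable[[ParameterDraw], float]


@dataclass
class SensitivityResult:
    """Per-parameter mean sensitivity (%) with 95% bounds across starts."""

    table: pd.DataFrame  # index=parameter; mean_sensitivity_pct, lo95, hi95, grouped_flag
    n_starts: int
    n_iterations_per_start: int
    grouped: tuple[str, ...]  # parameters merged into "other parameters"


def _with_value(start: ParameterDraw, name: str, value: float) -> ParameterDraw:
    values = dict(start.values)
    values[name] = float(value)
    return ParameterDraw(values=values, scenario=start.scenario,
                         iteration_index=start.iteration_index, seed_path=start.seed_path)


def _at_modes(start: ParameterDraw, parameters: Mapping[str, Distribution]) -> ParameterDraw:
    """All parameters at their central values; scenario kept from the start."""
    values = dict(start.values)
    for name, dist in parameters.items():
        if dist.kind != "discrete":
            values[name] = dist.mode()
    return ParameterDraw(values=values, scenario=start.scenario,
                         iteration_index=start.iteration_index, seed_path=start.seed_path)


def oat_sensitivity(
    model: ModelFn,
    parameters: Mapping[str, Distribution],
    target_name: str,
    start_point: ParameterDraw,
    n_sweep: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Sensitivity (%) of the model output to one parameter at one start.

    100 * (max - min of the output over ``n_sweep`` draws of the target,
    others frozen at the start point) / |baseline output|.  The baseline
    evaluates every parameter at its central value (scenario kept from the
    start), so the metric is a pure effect of the swept parameter and is
    comparable across starts.  Point-distribution targets have zero range.
    A zero baseline makes the metric undefined (NaN, with a diagnostic).
    """
    dist = parameters[target_name]
    rng = rng or np.random.default_rng(0)
    baseline = model(_at_modes(start_point, parameters))
    if not math.isfinite(baseline) or baseline == 0.0:
        logger.warning("baseline output is %s for %r; sensitivity undefined",
                       baseline, target_name)
        return math.nan
    if dist.kind == "point":
        return 0.0
    sweep = dist.sample(rng, n_sweep)
    outputs = np.array([model(_with_value(start_point, target_name, x)) for x in sweep])
    outputs = outputs[np.isfinite(outputs)]
    if outputs.size == 0:
        return math.nan
    return 100.0 * float(outputs.max() - outputs.min()) / abs(baseline)


def multistart_sensitivity(
    model: ModelFn,
    parameters: Mapping[str, Distribution],
    space: ScenarioSpace | None = None,
    n_starts: int = 30,
    n_iterations: int = 1000,
    threshold_pct: float = 5.0,
    seed: int = 0,
    targets: tuple[str, ...] | None = None,
) -> SensitivityResult:
    """OAT sensitivity from ``n_starts`` random start points per parameter.

    Start points are drawn from the joint parameter distributions;
    ``n_iterations`` is the sweep size per start.  Parameters whose mean
    sensitivity falls below ``threshold_pct`` are flagged as grouped into
    "other parameters".
    """
    if n_starts < 2:
        raise ValueError("multi-start requires n_starts >= 2")
    space = space or ScenarioSpace({})
    targets = targets or tuple(parameters)
    rows = []
    grouped = []
    for name in targets:
        vals = []
        for s in range(n_starts):
            start = draw_parameters(parameters, space, seed, s)
            rng = substream(seed, s, "oat/" + name)
            vals.append(oat_sensitivity(model, parameters, name, start,
                                        n_sweep=n_iterations, rng=rng))
        arr = np.array(vals, dtype=float)
        ok = arr[np.isfinite(arr)]
        if ok.size == 0:
            logger.warning("parameter %r not evaluable at any start", name)
            rows.append({"parameter": name, "mean_sensitivity_pct": math.nan,
                         "lo95": math.nan, "hi95": math.nan, "grouped_flag": False})
            continue
        mean = float(ok.mean())
        row = {
            "parameter": name,
            "mean_sensitivity_pct": mean,
            "lo95": float(np.percentile(ok, 2.5)),
            "hi95": float(np.percentile(ok, 97.5)),
            "grouped_flag": mean < threshold_pct,
        }
        if row["grouped_flag"]:
            grouped.append(name)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("parameter").sort_values(
        "mean_sensitivity_pct", ascending=False)
    return SensitivityResult(table=table, n_starts=n_starts,
                             n_iterations_per_start=n_iterations,
                             grouped=tuple(grouped))
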