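"""Parametric uncertainty: distributions, scenario spaces and Monte Carlo propagation.

Every uncertain model input is a :class:`Distribution` (triangular, uniform,
discrete or point).  Discrete axes such as feedstock geography or waste
handling are grouped into a :class:`ScenarioSpace`.  The engine
:func:`run_monte_carlo` draws one :class:`ParameterDraw` per iteration and
pushes it through an arbitrary deterministic model, so the same draw can feed
the techno-economic and environmental models simultaneously (common random
numbers, which makes paired comparisons between outputs valid).

Reproducibility contract: all randomness derives from one root seed through
counter-based (Philox) substreams keyed by ``(iteration, name)``.  Results are
therefore independent of parameter ordering, and truncating the iteration
count reproduces a prefix of the longer run bit for bit.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_KINDS = ("triangular", "uniform", "discrete", "point")


class ConfigurationError(ValueError):
    """Raised for malformed distributions, scenario spaces or missing setup."""


@dataclass(frozen=True)
class Distribution:
    """A parametric uncertainty specification for one model input.

    Parameters by kind:

    * ``triangular`` — ``params = (minimum, mode, maximum)``
    * ``uniform`` — ``params = (lower, upper)``
    * ``point`` — ``params = (value,)``
    * ``discrete`` — labelled outcomes: ``outcomes`` maps label -> probability
    """

    kind: str
    params: tuple = ()
    outcomes: Mapping[str, float] | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown distribution kind {self.kind!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.kind == "triangular":
            a, c, b = self._require(3)
            if not (a <= c <= b):
                raise ConfigurationError(
                    f"triangular requires minimum <= mode <= maximum, got {self.params}"
                )
        elif self.kind == "uniform":
            lo, hi = self._require(2)
            if not lo < hi:
                raise ConfigurationError(f"uniform requires lower < upper, got {self.params}")
        elif self.kind == "point":
            self._require(1)
        else:  # discrete
            if not self.outcomes:
                raise ConfigurationError("discrete distribution needs >=1 labelled outcome")
            total = sum(self.outcomes.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"discrete probabilities sum to {total}, not 1")
            if any(p < 0 for p in self.outcomes.values()):
                raise ConfigurationError("discrete probabilities must be non-negative")

    def _require(self, n: int) -> tuple:
        if len(self.params) != n:
            raise ConfigurationError(
                f"{self.kind} distribution takes {n} parameters, got {len(self.params)}"
            )
        return self.params

    # -- moments / summaries -------------------------------------------------

    def mean(self) -> float:
        if self.kind == "triangular":
            a, c, b = self.params
            return (a + b + c) / 3.0
        if self.kind == "uniform":
            lo, hi = self.params
            return (lo + hi) / 2.0
        if self.kind == "point":
            return self.params[0]
        raise ConfigurationError("mean undefined for labelled discrete distributions")

    def mode(self) -> float:
        """Central/representative value used as the sensitivity baseline."""
        if self.kind == "triangular":
            return self.params[1]
        if self.kind == "uniform":
            lo, hi = self.params
            return (lo + hi) / 2.0  # flat density: midpoint by convention
        if self.kind == "point":
            return self.params[0]
        raise ConfigurationError("mode undefined for labelled discrete distributions")

    def support(self) -> tuple[float, float]:
        if self.kind == "triangular":
            a, _, b = self.params
            return (a, b)
        if self.kind == "uniform":
            return self.params
        if self.kind == "point":
            v = self.params[0]
            return (v, v)
        raise ConfigurationError("support undefined for labelled discrete distributions")

    # -- sampling ------------------------------------------------------------

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Draw ``n`` values; point distributions return exact copies."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if self.kind == "triangular":
            a, c, b = self.params
            if a == b:  # degenerate triangle
                return np.full(n, c)
            return rng.triangular(a, c, b, size=n)
        if self.kind == "uniform":
            lo, hi = self.params
            return rng.uniform(lo, hi, size=n)
        if self.kind == "point":
            return np.full(n, self.params[0])
        labels = list(self.outcomes)
        probs = np.array([self.outcomes[k] for k in labels])
        idx = rng.choice(len(labels), size=n, p=probs / probs.sum())
        return np.array([labels[i] for i in idx], dtype=object)


def make_conservative_triangular(published_value: float, units: str = "") -> Distribution:
    """Conservative triangular distribution around a single published figure.

    The published value is the mode; the bounds are half and double that
    value.  For negative values the half/double bounds are swapped so the
    ordering invariant holds; exactly zero degenerates to a point mass (the
    half/double rule cannot spread it) and is flagged in the log.
    """
    v = float(published_value)
    if not math.isfinite(v):
        raise ConfigurationError("published value must be finite")
    if v == 0.0:
        logger.warning("half/double rule degenerate at 0; using point distribution")
        return Distribution("point", (0.0,), units=units)
    if v > 0:
        return Distribution("triangular", (v / 2.0, v, 2.0 * v), units=units)
    return Distribution("triangular", (2.0 * v, v, v / 2.0), units=units)


@dataclass(frozen=True)
class ScenarioSpace:
    """Named discrete axes of scenario uncertainty (feedstock, waste handling...)."""

    axes: Mapping[str, Distribution] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, dist in self.axes.items():
            if dist.kind != "discrete":
                raise ConfigurationError(f"scenario axis {name!r} must be a discrete distribution")
            if len(dist.outcomes) < 1:
                raise ConfigurationError(f"scenario axis {name!r} has no outcomes")

    def __bool__(self) -> bool:
        return bool(self.axes)


@dataclass(frozen=True)
class ParameterDraw:
    """One joint sample of all parameters and scenario axes."""

    values: Mapping[str, float]
    scenario: Mapping[str, str]
    iteration_index: int = 0
    seed_path: tuple = ()

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class MCResult:
    """Monte Carlo samples plus mean and 2.5/97.5 percentile summaries."""

    samples: dict[str, np.ndarray]
    n_iterations: int
    n_failed: int = 0
    summaries: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summaries:
            self.summaries = {k: summarize(v) for k, v in self.samples.items()}


def summarize(values: np.ndarray) -> dict[str, float]:
    ok = np.asarray(values, dtype=float)
    ok = ok[np.isfinite(ok)]
    if ok.size == 0:
        return {"mean": math.nan, "p2.5": math.nan, "p97.5": math.nan}
    return {
        "mean": float(np.mean(ok)),
        "p2.5": float(np.percentile(ok, 2.5)),
        "p97.5": float(np.percentile(ok, 97.5)),
    }


# -- substream derivation ----------------------------------------------------


def substream(seed: int, iteration: int, name: str) -> np.random.Generator:
    """Counter-based generator for one (iteration, parameter) cell.

    Philox keyed on the root seed with the counter set from the iteration
    index and a CRC32 of the name: order-independent, resumable, and a run of
    1,000 iterations is a bit-exact prefix of a run of 10,000.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    bitgen = np.random.Philox(key=int(seed) & 0xFFFFFFFFFFFFFFFF,
                              counter=[int(iteration), tag, 0, 0])
    return np.random.Generator(bitgen)


def sample_scenarios(space: ScenarioSpace, seed: int, iteration: int = 0) -> dict[str, str]:
    """One outcome per axis, drawn independently across axes."""
    if not space:
        return {}
    out: dict[str, str] = {}
    for axis, dist in space.axes.items():
        rng = substream(seed, iteration, "scenario/" + axis)
        out[axis] = dist.sample(rng, 1)[0]
    return out


def draw_parameters(
    parameters: Mapping[str, Distribution],
    space: ScenarioSpace,
    seed: int,
    iteration: int,
) -> ParameterDraw:
    values = {}
    for name, dist in parameters.items():
        rng = substream(seed, iteration, "param/" + name)
        values[name] = float(dist.sample(rng, 1)[0])
    scenario = sample_scenarios(space, seed, iteration)
    return ParameterDraw(values=values, scenario=scenario, iteration_index=iteration,
                         seed_path=(seed, iteration))


class MonteCarloError(RuntimeError):
    pass


def run_monte_carlo(
    model: Callable[[ParameterDraw], Mapping[str, float] | float],
    parameters: Mapping[str, Distribution],
    space: ScenarioSpace | None = None,
    n_iterations: int = 10_000,
    seed: int = 0,
    max_failure_fraction: float = 0.01,
) -> MCResult:
    """Propagate parameter and scenario uncertainty through ``model``.

    ``model`` maps a :class:`ParameterDraw` to a scalar or a mapping of named
    outputs.  Iterations where the model raises are recorded as failed (the
    offending draw is logged); more than ``max_failure_fraction`` failures
    aborts the run.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    space = space or ScenarioSpace({})
    columns: dict[str, np.ndarray] = {}
    n_failed = 0
    for i in range(n_iterations):
        draw = draw_parameters(parameters, space, seed, i)
        try:
            out = model(draw)
        except Exception:  # noqa: BLE001 - failure accounting is the contract
            n_failed += 1
            logger.exception("model failed on iteration %d: draw=%s", i, draw)
            if n_failed > max_failure_fraction * n_iterations:
                raise MonteCarloError(
                    f"{n_failed} failed iterations exceed the "
                    f"{max_failure_fraction:.0%} threshold"
                )
            out = None
        if out is None:
            row: Mapping[str, float] = {}
        elif isinstance(out, Mapping):
            row = out
        else:
            row = {"output": float(out)}
        for key, val in row.items():
            col = columns.setdefault(key, np.full(n_iterations, np.nan))
            col[i] = val
        if out is not None:
            for key, col in columns.items():
                if key not in row:
                    col[i] = np.nan
    return MCResult(samples=columns, n_iterations=n_iterations, n_failed=n_failed)


def triangular_cdf(x: np.ndarray, a: float, c: float, b: float) -> np.ndarray:
    """Analytic triangular CDF; used as an independent oracle for the sampler."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    left = (x > a) & (x < c)
    right = (x >= c) & (x < b)
    out[left] = (x[left] - a) ** 2 / ((b - a) * (c - a))
    out[right] = 1.0 - (b - x[right]) ** 2 / ((b - a) * (b - c))
    out[x >= b] = 1.0
    return out
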