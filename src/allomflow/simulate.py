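"""Synthetic branching-network generator.

Produces internode tables with the statistical structure the downstream
analyses assume: area-preserving bifurcations with positive, mean-one,
radius-dependent multiplicative noise on daughter areas; exponentially
distributed internode lengths (the continuum analogue of Poisson-placed
bifurcations along a growing axis); and, optionally, lengths coupled to
diameters through a power law L = c * D**alpha with lognormal scatter and a
smooth blend of the exponent toward 2/3 at large radii.

Two generation modes share one topology engine:

``branching_cascade``
    Each tree starts from ``base_radius``.  Internode lengths are drawn from
    an exponential distribution with mean ``length_scale_mu``.  At every
    bifurcation the parent cross-sectional area is split into fractions
    ``(asymmetry, 1 - asymmetry)`` and each daughter area is multiplied by
    independent mean-one lognormal noise whose standard deviation scales as
    ``ratio_noise_sd0 * (parent_radius / base_radius) ** (-ratio_noise_radius_exp)``.
    A lineage terminates once its radius falls below ``radius_floor``.

``allometric_coupling``
    Identical topology (radii, parentage), but each internode length is set
    to ``coupling_c * D ** alpha_eff * eps`` where ``eps`` is lognormal with
    median 1 and log standard deviation ``coupling_sd``.  When
    ``elastic_blend_radius`` is set, ``alpha_eff`` ramps smoothly (logistic
    in log-radius) from ``alpha`` at small radii toward 2/3 above the blend
    radius, inducing curvature on log-log axes.

All randomness flows from a single seed; each tree consumes an independent
child stream spawned deterministically from it, so tables are bit-identical
across runs for a given configuration.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from allomflow.exceptions import SimulationError, ValidationError

__all__ = [
    "SimulationConfig",
    "Internode",
    "simulate_network",
    "write_internode_table",
    "internodes_to_frame",
    "load_simulation_config",
]

TWO_THIRDS = 2.0 / 3.0

_MODES = ("branching_cascade", "allometric_coupling")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters controlling one simulated forest of branching networks."""

    mode: str = "branching_cascade"
    alpha: float = 2.0
    length_scale_mu: float = 300.0
    base_radius: float = 40.0
    radius_floor: float = 1.0
    asymmetry: float = 0.5
    ratio_noise_sd0: float = 0.0
    ratio_noise_radius_exp: float = 0.0
    coupling_sd: float = 0.0
    coupling_c: float = 15.0
    elastic_blend_radius: Optional[float] = None
    elastic_blend_width: float = 0.5  # logistic ramp width, natural-log radius units
    seed: int = 0
    n_trees: int = 1
    max_internodes: int = 200_000  # per-tree cap before the run is declared runaway

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValidationError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if not self.alpha > 0:
            raise ValidationError(f"alpha must be > 0, got {self.alpha}")
        if not (self.base_radius > self.radius_floor > 0):
            raise ValidationError(
                "require base_radius > radius_floor > 0, got "
                f"base_radius={self.base_radius}, radius_floor={self.radius_floor}"
            )
        if not 0.5 <= self.asymmetry <= 1.0:
            raise ValidationError(f"asymmetry must lie in [0.5, 1.0], got {self.asymmetry}")
        if self.length_scale_mu <= 0:
            raise ValidationError("length_scale_mu must be > 0")
        if self.ratio_noise_sd0 < 0 or self.coupling_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if self.coupling_c <= 0:
            raise ValidationError("coupling_c must be > 0")
        if self.elastic_blend_radius is not None and self.elastic_blend_radius <= 0:
            raise ValidationError("elastic_blend_radius must be > 0 or None")
        if self.elastic_blend_width <= 0:
            raise ValidationError("elastic_blend_width must be > 0")
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.max_internodes < 1:
            raise ValidationError("max_internodes must be >= 1")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class Internode:
    """One branch segment: the atomic observation of an internode table."""

    tree_id: str
    internode_id: str
    parent_id: Optional[str]
    length: float  # mm
    diameter: float  # mm

    def __post_init__(self) -> None:
        if not (math.isfinite(self.length) and self.length > 0):
            raise ValidationError(
                f"internode {self.internode_id!r}: length must be finite and > 0, got {self.length}"
            )
        if not (math.isfinite(self.diameter) and self.diameter > 0):
            raise ValidationError(
                f"internode {self.internode_id!r}: diameter must be finite and > 0, got {self.diameter}"
            )


def _mean_one_lognormal(rng: np.random.Generator, sd: float) -> float:
    """Draw a positive multiplier with mean exactly 1 and linear-scale sd ``sd``."""
    if sd == 0.0:
        return 1.0
    sigma2 = math.log1p(sd * sd)
    return float(np.exp(rng.normal(-0.5 * sigma2, math.sqrt(sigma2))))


def _alpha_effective(radius: float, cfg: SimulationConfig) -> float:
    """Exponent used at ``radius``: cfg.alpha distally, blending to 2/3 basally."""
    if cfg.elastic_blend_radius is None:
        return cfg.alpha
    z = (math.log(radius) - math.log(cfg.elastic_blend_radius)) / cfg.elastic_blend_width
    # logistic weight -> 1 for radii far above the blend radius
    w = 1.0 / (1.0 + math.exp(-z))
    return cfg.alpha + (TWO_THIRDS - cfg.alpha) * w


def _simulate_tree(tree_index: int, cfg: SimulationConfig, rng: np.random.Generator) -> list[Internode]:
    tree_id = f"T{tree_index + 1}"
    out: list[Internode] = []
    serial = 0
    queue: deque[tuple[float, Optional[str]]] = deque([(cfg.base_radius, None)])
    while queue:
        radius, parent_id = queue.popleft()
        serial += 1
        if serial > cfg.max_internodes:
            raise SimulationError(
                f"tree {tree_id}: exceeded max_internodes={cfg.max_internodes}; "
                "runaway network (raise the cap or lower base_radius/radius_floor span)"
            )
        node_id = f"{tree_id}.{serial}"
        diameter = 2.0 * radius
        if cfg.mode == "branching_cascade":
            length = float(rng.exponential(cfg.length_scale_mu))
        else:  # allometric_coupling
            a_eff = _alpha_effective(radius, cfg)
            eps = float(np.exp(rng.normal(0.0, cfg.coupling_sd))) if cfg.coupling_sd > 0 else 1.0
            length = cfg.coupling_c * diameter**a_eff * eps
        if not (math.isfinite(length) and length > 0 and math.isfinite(diameter) and diameter > 0):
            raise SimulationError(
                f"tree {tree_id}, internode {node_id}: sampled non-finite or non-positive "
                f"dimension (length={length}, diameter={diameter})"
            )
        out.append(Internode(tree_id, node_id, parent_id, length, diameter))

        parent_area = radius * radius  # pi cancels throughout
        noise_sd = cfg.ratio_noise_sd0 * (radius / cfg.base_radius) ** (-cfg.ratio_noise_radius_exp)
        for fraction in (cfg.asymmetry, 1.0 - cfg.asymmetry):
            daughter_area = parent_area * fraction * _mean_one_lognormal(rng, noise_sd)
            daughter_radius = math.sqrt(daughter_area)
            if daughter_radius >= cfg.radius_floor:
                queue.append((daughter_radius, node_id))
    return out


def simulate_network(config: SimulationConfig) -> list[Internode]:
    """Simulate ``config.n_trees`` branching networks as a flat internode list.

    Deterministic for a fixed configuration: per-tree generators are spawned
    from a single :class:`numpy.random.SeedSequence` rooted at ``config.seed``.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_trees)
    internodes: list[Internode] = []
    for t, stream in enumerate(streams):
        internodes.extend(_simulate_tree(t, config, np.random.default_rng(stream)))
    return internodes


CSV_COLUMNS = ("tree_id", "internode_id", "parent_id", "length_mm", "diameter_mm")


def internodes_to_frame(internodes: Iterable[Internode]) -> pd.DataFrame:
    """Tabulate internodes using the canonical CSV schema (root parent_id = '')."""
    rows = [
        (n.tree_id, n.internode_id, n.parent_id if n.parent_id is not None else "", n.length, n.diameter)
        for n in internodes
    ]
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_internode_table(internodes: Sequence[Internode], path: str | Path) -> Path:
    """Write internodes to CSV; round-trips losslessly through the table reader."""
    internodes = list(internodes)
    if not internodes:
        raise ValidationError("refusing to write an empty internode table")
    path = Path(path)
    internodes_to_frame(internodes).to_csv(path, index=False, lineterminator="\n")
    return path


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: expected a mapping of SimulationConfig fields")
    known = {f.name for f in fields(SimulationConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValidationError(f"{path}: unknown SimulationConfig fields {unknown}")
    return SimulationConfig(**raw)
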