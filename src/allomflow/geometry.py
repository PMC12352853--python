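"""Cylinder-derived dimensions and the area-ratio test of area-preserving branching."""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from allomflow.exceptions import TopologyError, ValidationError
from allomflow.simulate import Internode

__all__ = [
    "DerivedDimensions",
    "Bifurcation",
    "AreaRatioSummary",
    "cylinder_dimensions",
    "extract_bifurcations",
    "area_ratio_summary",
]


@dataclass(frozen=True)
class DerivedDimensions:
    """Lateral surface area (mm^2) and volume (mm^3) of one cylindrical internode."""

    surface_area: float
    volume: float


@dataclass(frozen=True)
class Bifurcation:
    """A parent internode together with the radii of its measured daughters."""

    parent_id: str
    parent_radius: float
    daughter_radii: tuple[float, ...]
    area_ratio: float


@dataclass(frozen=True)
class AreaRatioSummary:
    """Moments of the area-ratio distribution plus a per-radius-bin variance table.

    ``kurtosis`` is the raw (non-excess) fourth standardized moment, so a
    Gaussian reference is 3; it is NaN (``degenerate=True``) when the ratios
    have zero spread.
    """

    n: int
    mean: float
    sd: float
    kurtosis: float
    degenerate: bool
    bin_table: pd.DataFrame  # columns: radius_low, radius_high, n, variance


def cylinder_dimensions(length: float, diameter: float, row_label: object = None) -> DerivedDimensions:
    """Lateral surface area pi*D*L (no end caps) and volume pi*(D/2)^2*L."""
    if not (length > 0 and diameter > 0) or not (math.isfinite(length) and math.isfinite(diameter)):
        where = "" if row_label is None else f" (row {row_label})"
        raise ValidationError(
            f"cylinder dimensions require positive finite length and diameter{where}: "
            f"length={length}, diameter={diameter}"
        )
    surface_area = math.pi * diameter * length
    volume = math.pi * (diameter / 2.0) ** 2 * length
    return DerivedDimensions(surface_area=surface_area, volume=volume)


def extract_bifurcations(
    internodes: Iterable[Internode], min_daughters: int = 1
) -> list[Bifurcation]:
    """One :class:`Bifurcation` per internode with at least ``min_daughters`` children.

    Nodes with a single measured child are retained by default (field
    truncation can remove the smaller daughter); pass ``min_daughters=2`` to
    restrict to full bifurcations.  Radii are diameter/2 and the area ratio is
    ``sum(daughter_radius**2) / parent_radius**2`` (pi cancels).
    """
    internodes = list(internodes)
    by_id: dict[tuple[str, str], Internode] = {}
    for node in internodes:
        by_id[(node.tree_id, node.internode_id)] = node
    children: dict[tuple[str, str], list[Internode]] = defaultdict(list)
    orphans = []
    for node in internodes:
        if node.parent_id is None:
            continue
        key = (node.tree_id, node.parent_id)
        if key not in by_id:
            orphans.append(node.internode_id)
            continue
        children[key].append(node)
    if orphans:
        raise TopologyError(f"internodes reference missing parents: {sorted(orphans)}")

    out = []
    for key, kids in children.items():
        if len(kids) < min_daughters:
            continue
        parent = by_id[key]
        parent_radius = parent.diameter / 2.0
        daughter_radii = tuple(k.diameter / 2.0 for k in kids)
        area_ratio = sum(r * r for r in daughter_radii) / (parent_radius * parent_radius)
        out.append(
            Bifurcation(
                parent_id=parent.internode_id,
                parent_radius=parent_radius,
                daughter_radii=daughter_radii,
                area_ratio=area_ratio,
            )
        )
    # deterministic order: by tree then numeric-ish id
    out.sort(key=lambda b: b.parent_id)
    return out


def raw_kurtosis(values: Sequence[float] | np.ndarray) -> float:
    """Raw Pearson kurtosis m4/m2^2 computed from plain central moments."""
    x = np.asarray(values, dtype=float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        return float("nan")
    m4 = np.mean((x - m) ** 4)
    return float(m4 / (m2 * m2))


def area_ratio_summary(
    bifurcations: Sequence[Bifurcation], n_bins: int = 8
) -> AreaRatioSummary:
    """Summarize area ratios: moments plus variance binned against parent radius.

    Bins are log-spaced across the observed parent-radius range so the
    small-radius end, where ratio noise grows, is resolved; bins with fewer
    than two ratios report NaN variance.
    """
    if len(bifurcations) < 2:
        raise ValidationError(f"area_ratio_summary requires n >= 2 bifurcations, got {len(bifurcations)}")
    ratios = np.array([b.area_ratio for b in bifurcations], dtype=float)
    radii = np.array([b.parent_radius for b in bifurcations], dtype=float)
    mean = float(ratios.mean())
    sd = float(ratios.std(ddof=1))
    kurt = raw_kurtosis(ratios)
    degenerate = not math.isfinite(kurt)

    lo, hi = radii.min(), radii.max()
    if lo == hi:
        edges = np.array([lo, hi])
    else:
        edges = np.geomspace(lo, hi, n_bins + 1)
        edges[-1] = hi  # guard float round-off on the top edge
    idx = np.clip(np.searchsorted(edges, radii, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = ratios[idx == b]
        var = float(sel.var(ddof=1)) if sel.size >= 2 else float("nan")
        rows.append((float(edges[b]), float(edges[b + 1]), int(sel.size), var))
    bin_table = pd.DataFrame(rows, columns=["radius_low", "radius_high", "n", "variance"])
    return AreaRatioSummary(
        n=int(ratios.size), mean=mean, sd=sd, kurtosis=kurt, degenerate=degenerate, bin_table=bin_table
    )
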