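"""End-to-end orchestration: read, filter, analyse, report.

``run_analysis`` reads an internode table, applies the field truncation
filter (rows shorter than ``length_min`` or thinner than ``diameter_min``
are dropped; thresholds are inclusive, i.e. rows meeting them are kept),
derives cylinder surface area and volume, and then, per tree and pooled:

* fits the six SMA regressions and scores them against the CFS (alpha = 2)
  and WBE (alpha = 2/3) exponent predictions,
* classifies the curvature of each log-log relationship,
* summarizes bifurcation area ratios,
* competes exponential vs power-law fits for length and diameter arrays.

Outputs are plain CSV tables plus a single JSON report with provenance
(config echo, package version, input checksum).  Units are millimetres
throughout (surface area mm^2, volume mm^3); intercepts are reported on
log10 axes in those units.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from allomflow import geometry, sma
from allomflow.curvature import classify_curvature
from allomflow.distfit import compare_models, fit_exponential, fit_power_law
from allomflow.exceptions import TopologyError, ValidationError
from allomflow.simulate import CSV_COLUMNS, Internode

logger = logging.getLogger("allomflow")

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "read_internode_table",
    "apply_truncation_filter",
    "run_analysis",
    "load_analysis_config",
]

POOLED_GROUP = "all"


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration for one end-to-end analysis run."""

    input_path: str
    output_dir: str
    ci_level: float = 0.95
    length_min: float = 100.0  # mm; field truncation threshold (inclusive keep)
    diameter_min: float = 1.5  # mm
    xmin_lengths: Optional[float] = None  # default: length_min
    xmin_diameters: Optional[float] = None  # default: diameter_min
    k_convention: str = "counted_xmin"  # or "conventional"
    groups: str = "both"  # "per_tree" | "pooled" | "both"
    prune_subtrees: bool = False
    min_daughters: int = 1
    seed: int = 0  # reserved for bootstrap diagnostics
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValidationError(f"ci_level must lie in (0, 1), got {self.ci_level}")
        if self.length_min < 0 or self.diameter_min < 0:
            raise ValidationError("truncation thresholds must be >= 0")
        if self.groups not in ("per_tree", "pooled", "both"):
            raise ValidationError(f"groups must be per_tree|pooled|both, got {self.groups!r}")
        if self.k_convention not in ("counted_xmin", "conventional"):
            raise ValidationError(f"k_convention must be counted_xmin|conventional, got {self.k_convention!r}")
        if self.min_daughters < 1:
            raise ValidationError("min_daughters must be >= 1")

    @property
    def effective_xmin_lengths(self) -> float:
        return self.length_min if self.xmin_lengths is None else self.xmin_lengths

    @property
    def effective_xmin_diameters(self) -> float:
        return self.diameter_min if self.xmin_diameters is None else self.xmin_diameters


@dataclass
class AnalysisReport:
    """In-memory analysis result; written to disk as CSVs + report.json."""

    sma_table: pd.DataFrame
    curvature_table: pd.DataFrame
    area_ratio_table: pd.DataFrame
    area_ratio_bins: pd.DataFrame
    distfit_table: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: expected a mapping of AnalysisConfig fields")
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValidationError(f"{path}: unknown AnalysisConfig fields {unknown}")
    return AnalysisConfig(**raw)


# ---------------------------------------------------------------------------
# reading and validation


def _parse_dimension(value: str, column: str, row_number: int) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row_number}: non-numeric {column} value {value!r}") from None
    if not (math.isfinite(out) and out > 0):
        raise ValidationError(f"row {row_number}: {column} must be finite and > 0, got {out}")
    return out


def _check_topology(internodes: Sequence[Internode]) -> None:
    ids = {(n.tree_id, n.internode_id) for n in internodes}
    parent_of = {(n.tree_id, n.internode_id): n.parent_id for n in internodes}
    orphans = [
        n.internode_id
        for n in internodes
        if n.parent_id is not None and (n.tree_id, n.parent_id) not in ids
    ]
    if orphans:
        raise TopologyError(f"parent_id references missing internodes: {sorted(orphans)[:20]}")
    # cycle detection by walking parent chains with memoized clearance
    cleared: set[tuple[str, str]] = set()
    for key in parent_of:
        path = []
        node = key
        while node not in cleared:
            path.append(node)
            parent = parent_of[node]
            if parent is None:
                break
            node = (node[0], parent)
            if node in path:
                raise TopologyError(f"cyclic topology involving internode {node[1]!r} in tree {node[0]!r}")
        cleared.update(path)


def read_internode_table(path: str | Path) -> list[Internode]:
    """Read and validate a CSV internode table (schema: tree_id, internode_id,
    parent_id, length_mm, diameter_mm; blank parent_id marks a root)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path}: table has no data rows")

    internodes: list[Internode] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # data rows start at line 2
        tree_id = row.tree_id.strip()
        internode_id = row.internode_id.strip()
        if not tree_id or not internode_id:
            raise ValidationError(f"row {i}: tree_id and internode_id must be non-empty")
        key = (tree_id, internode_id)
        if key in seen:
            raise ValidationError(f"row {i}: duplicate internode_id {internode_id!r} in tree {tree_id!r}")
        seen.add(key)
        parent = row.parent_id.strip() or None
        length = _parse_dimension(row.length_mm, "length_mm", i)
        diameter = _parse_dimension(row.diameter_mm, "diameter_mm", i)
        internodes.append(Internode(tree_id, internode_id, parent, length, diameter))
    _check_topology(internodes)
    logger.info("read %d internodes across %d trees from %s", len(internodes), df["tree_id"].nunique(), path)
    return internodes


def apply_truncation_filter(
    internodes: Sequence[Internode],
    length_min: float = 100.0,
    diameter_min: float = 1.5,
    prune_subtrees: bool = False,
) -> tuple[list[Internode], int]:
    """Drop internodes below the measurement thresholds (inclusive keep).

    Dropped rows must be leaves of the kept forest: dropping an internode
    whose descendants survive would orphan them, which is an error unless
    ``prune_subtrees`` is set, in which case whole subtrees rooted at dropped
    internodes are removed too.
    """
    internodes = list(internodes)
    dropped = {
        (n.tree_id, n.internode_id)
        for n in internodes
        if n.length < length_min or n.diameter < diameter_min
    }
    if prune_subtrees and dropped:
        # propagate drops to all descendants
        changed = True
        while changed:
            changed = False
            for n in internodes:
                key = (n.tree_id, n.internode_id)
                if key in dropped or n.parent_id is None:
                    continue
                if (n.tree_id, n.parent_id) in dropped:
                    dropped.add(key)
                    changed = True
    else:
        stranded = [
            n.internode_id
            for n in internodes
            if (n.tree_id, n.internode_id) not in dropped
            and n.parent_id is not None
            and (n.tree_id, n.parent_id) in dropped
        ]
        if stranded:
            raise TopologyError(
                "truncation would drop non-leaf internodes, orphaning descendants "
                f"{sorted(stranded)[:20]}; pass prune_subtrees=True to remove whole subtrees"
            )
    kept = [n for n in internodes if (n.tree_id, n.internode_id) not in dropped]
    logger.info(
        "truncation filter (length >= %g mm, diameter >= %g mm): kept %d, dropped %d",
        length_min, diameter_min, len(kept), len(dropped),
    )
    return kept, len(dropped)


# ---------------------------------------------------------------------------
# analysis


def _derived_frame(internodes: Sequence[Internode]) -> pd.DataFrame:
    records = []
    for n in internodes:
        dims = geometry.cylinder_dimensions(n.length, n.diameter, row_label=n.internode_id)
        records.append(
            (n.tree_id, n.internode_id, n.parent_id, n.length, n.diameter, dims.surface_area, dims.volume)
        )
    return pd.DataFrame(
        records,
        columns=["tree_id", "internode_id", "parent_id", "length", "diameter", "surface_area", "volume"],
    )


def _group_frames(df: pd.DataFrame, groups: str) -> list[tuple[str, pd.DataFrame]]:
    out: list[tuple[str, pd.DataFrame]] = []
    if groups in ("pooled", "both"):
        out.append((POOLED_GROUP, df))
    if groups in ("per_tree", "both"):
        for tree_id in sorted(df["tree_id"].unique()):
            out.append((tree_id, df[df["tree_id"] == tree_id]))
    return out


def _sma_and_curvature(
    grouped: list[tuple[str, pd.DataFrame]], ci_level: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    sma_rows = []
    curv_rows = []
    for group, gdf in grouped:
        for pair in sma.PAIRS:
            yname, xname = pair
            x = gdf[xname].to_numpy()
            y = gdf[yname].to_numpy()
            fit = sma.sma_fit(x, y, ci_level=ci_level, pair=pair, group=group)
            ev_cfs = sma.evaluate_model(fit, sma.CFS)
            ev_wbe = sma.evaluate_model(fit, sma.WBE)
            sma_rows.append(
                {
                    "y_variable": yname,
                    "x_variable": xname,
                    "group": group,
                    "n": fit.n,
                    "r_squared": fit.r_squared,
                    "slope": fit.slope,
                    "slope_ci_low": fit.slope_ci_low,
                    "slope_ci_high": fit.slope_ci_high,
                    "cfs_predicted": float(sma.CFS.exponents[pair]),
                    "wbe_predicted": float(sma.WBE.exponents[pair]),
                    "intercept": fit.intercept,
                    "intercept_ci_low": fit.intercept_ci_low,
                    "intercept_ci_high": fit.intercept_ci_high,
                    "cfs_rmse": ev_cfs.rmse,
                    "wbe_rmse": ev_wbe.rmse,
                }
            )
            cres = classify_curvature(x, y, pair=pair, group=group)
            curv_rows.append(
                {
                    "y_variable": yname,
                    "x_variable": xname,
                    "group": group,
                    "quad_coeff": cres.quad_coeff,
                    "classification": cres.classification,
                    "predicted": cres.predicted,
                    "matches_prediction": cres.matches_prediction,
                    "degenerate": cres.degenerate,
                }
            )
    return pd.DataFrame(sma_rows), pd.DataFrame(curv_rows)


def _area_ratios(
    internodes: Sequence[Internode], grouped_ids: list[str], min_daughters: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    summary_rows = []
    bin_frames = []
    by_tree: dict[str, list[Internode]] = {}
    for n in internodes:
        by_tree.setdefault(n.tree_id, []).append(n)
    for group in grouped_ids:
        pool = list(internodes) if group == POOLED_GROUP else by_tree.get(group, [])
        bifs = geometry.extract_bifurcations(pool, min_daughters=min_daughters)
        if len(bifs) < 2:
            logger.warning("group %s: fewer than 2 bifurcations; area-ratio summary skipped", group)
            continue
        summ = geometry.area_ratio_summary(bifs)
        summary_rows.append(
            {
                "group": group,
                "n_bifurcations": summ.n,
                "mean": summ.mean,
                "sd": summ.sd,
                "kurtosis": summ.kurtosis,
                "leptokurtic": (summ.kurtosis > 3) if not summ.degenerate else None,
                "degenerate": summ.degenerate,
            }
        )
        bt = summ.bin_table.copy()
        bt.insert(0, "group", group)
        bin_frames.append(bt)
    bins = pd.concat(bin_frames, ignore_index=True) if bin_frames else pd.DataFrame()
    return pd.DataFrame(summary_rows), bins


def _distribution_fits(
    grouped: list[tuple[str, pd.DataFrame]], cfg: AnalysisConfig
) -> pd.DataFrame:
    rows = []
    for group, gdf in grouped:
        for measure, column, xmin in (
            ("lengths", "length", cfg.effective_xmin_lengths),
            ("diameters", "diameter", cfg.effective_xmin_diameters),
        ):
            data = gdf[column].to_numpy()
            if xmin <= 0:
                xmin = float(np.min(data))
            fe = fit_exponential(data, xmin, k_convention=cfg.k_convention)
            fp = fit_power_law(data, xmin, k_convention=cfg.k_convention)
            comp = compare_models(fe, fp)
            rows.append(
                {
                    "group": group,
                    "measure": measure,
                    "n": fe.n,
                    "xmin": xmin,
                    "exp_rate": fe.params["rate"],
                    "pl_exponent": fp.params["exponent"],
                    "aicc_power_law": fp.aicc,
                    "aicc_exponential": fe.aicc,
                    "winner": comp.winner,
                    "delta_aicc": comp.delta_aicc,
                    "relative_likelihood": comp.relative_likelihood,
                    "log10_relative_likelihood": comp.log10_relative_likelihood,
                }
            )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the full pipeline and write the report to ``config.output_dir``.

    Any stage failure aborts the run and removes partially written outputs.
    Identical input and configuration produce byte-identical outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    from allomflow import __version__

    input_path = Path(config.input_path)
    internodes = read_internode_table(input_path)
    kept, dropped_count = apply_truncation_filter(
        internodes, config.length_min, config.diameter_min, prune_subtrees=config.prune_subtrees
    )
    if not kept:
        raise ValidationError("no internodes remain after the truncation filter; nothing to analyse")

    df = _derived_frame(kept)
    grouped = _group_frames(df, config.groups)
    sma_table, curvature_table = _sma_and_curvature(grouped, config.ci_level)
    group_ids = [g for g, _ in grouped]
    area_table, area_bins = _area_ratios(kept, group_ids, config.min_daughters)
    distfit_table = _distribution_fits(grouped, config)

    provenance = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "input_sha256": _sha256(input_path),
        "rows_read": len(internodes),
        "rows_dropped": dropped_count,
        "rows_analysed": len(kept),
        "groups": group_ids,
    }
    report = AnalysisReport(
        sma_table=sma_table,
        curvature_table=curvature_table,
        area_ratio_table=area_table,
        area_ratio_bins=area_bins,
        distfit_table=distfit_table,
        provenance=provenance,
    )
    _write_report(report, Path(config.output_dir))
    return report


_OUTPUT_FILES = {
    "sma_table": "sma.csv",
    "curvature_table": "curvature.csv",
    "area_ratio_table": "area_ratio_summary.csv",
    "area_ratio_bins": "area_ratio_bins.csv",
    "distfit_table": "distfit.csv",
}


def _write_report(report: AnalysisReport, output_dir: Path) -> None:
    output_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        for attr, filename in _OUTPUT_FILES.items():
            frame: pd.DataFrame = getattr(report, attr)
            target = output_dir / filename
            frame.to_csv(target, index=False, lineterminator="\n")
            written.append(target)
        target = output_dir / "report.json"
        payload = {"provenance": report.provenance,
                   "tables": {attr: name for attr, name in _OUTPUT_FILES.items()}}
        target.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(target)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    logger.info("report written to %s", output_dir)
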