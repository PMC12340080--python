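"""RT-DB calibration onto new chromatographic conditions.

Species detected both in the RT-DB's source conditions and in the current
experiment serve as *anchor points*.  Anchors are binned along the source
RT axis, each bin yields one knot (median source RT, median target RT),
and a natural interpolating cubic spline through the knots maps any
source RT onto the new gradient.  Models are fitted per group (lipid
class, a user-defined group, or all data combined); sparse groups fall
back along class -> user group -> global.  Interpolation (rather than a
smoothing regressor) is deliberate: it is exact at the knots and behaves
well when noise is low, with robustness to replicate jitter coming from
the median-per-bin knots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .rtdb import RTDB

__all__ = [
    "AnchorPoint",
    "GroupModel",
    "CalibrationModel",
    "MappedRT",
    "NoAnchorsError",
    "select_anchors",
    "bin_anchors",
    "fit_rt_mapping",
    "map_rt",
    "evaluate_mapping",
]

logger = logging.getLogger(__name__)

GLOBAL_GROUP = "global"


class NoAnchorsError(ValueError):
    """Source DB and target data share no species usable as anchors."""


@dataclass(frozen=True)
class AnchorPoint:
    """One species observed under both chromatographies."""

    species_key: str
    rt_source: float
    rt_target: float
    reliability: str = "biological"  # or "standard"
    group: str = GLOBAL_GROUP


@dataclass(frozen=True)
class MappedRT:
    value: float
    flags: tuple[str, ...] = ()


@dataclass
class GroupModel:
    """Piecewise mapping for one anchor group."""

    knots_source: np.ndarray
    knots_target: np.ndarray
    kind: str  # "cubic" | "linear"
    _spline: Optional[CubicSpline] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind == "cubic" and self._spline is None:
            self._spline = CubicSpline(self.knots_source, self.knots_target, bc_type="natural")

    @property
    def valid_range(self) -> tuple[float, float]:
        return float(self.knots_source[0]), float(self.knots_source[-1])

    def _boundary_slope(self, at_start: bool) -> float:
        if self.kind == "cubic":
            x = self.knots_source[0] if at_start else self.knots_source[-1]
            return float(self._spline.derivative()(x))
        i = 0 if at_start else -2
        dx = self.knots_source[i + 1] - self.knots_source[i]
        return float((self.knots_target[i + 1] - self.knots_target[i]) / dx)

    def __call__(self, rt: float) -> MappedRT:
        lo, hi = self.valid_range
        if rt < lo:
            return MappedRT(float(self.knots_target[0] + self._boundary_slope(True) * (rt - lo)),
                            ("extrapolated",))
        if rt > hi:
            return MappedRT(float(self.knots_target[-1] + self._boundary_slope(False) * (rt - hi)),
                            ("extrapolated",))
        if self.kind == "cubic":
            return MappedRT(float(self._spline(rt)))
        return MappedRT(float(np.interp(rt, self.knots_source, self.knots_target)))


@dataclass
class CalibrationModel:
    """Per-group spline mappings with a fallback chain.

    Lookup order for a lipid class: its own group model, then the user
    group it belongs to (``user_groups``), then the global model.
    """

    groups: dict[str, GroupModel]
    user_groups: dict[str, str] = field(default_factory=dict)
    min_knots_cubic: int = 4

    def resolve(self, group: str) -> tuple[GroupModel, tuple[str, ...]]:
        if group in self.groups:
            return self.groups[group], ()
        ug = self.user_groups.get(group)
        if ug is not None and ug in self.groups:
            return self.groups[ug], ("fallback",)
        if GLOBAL_GROUP in self.groups:
            return self.groups[GLOBAL_GROUP], ("fallback",)
        raise KeyError(f"no model for group {group!r} and the fallback chain is empty")

    def map(self, group: str, rt_source: float) -> MappedRT:
        model, flags = self.resolve(group)
        res = model(rt_source)
        return MappedRT(res.value, flags + res.flags)

    def map_rtdb(self, db: RTDB) -> RTDB:
        """Return a copy of ``db`` with every reference RT mapped."""
        from dataclasses import replace as _replace

        entries = []
        for e in db.entries:
            res = self.map(e.lipid_class, e.reference_rt)
            entries.append(_replace(e, reference_rt=res.value, flags=e.flags | set(res.flags)))
        meta = dict(db.meta)
        lo_hi = [m.valid_range for m in self.groups.values()]
        if lo_hi and "gradient_span_min" in meta:
            tgt_hi = max(m.knots_target[-1] for m in self.groups.values())
            meta["gradient_span_min"] = float(
                tgt_hi * meta["gradient_span_min"] / max(hi for _, hi in lo_hi)
            )
        meta["calibrated"] = True
        return RTDB(entries=entries, meta=meta)


# ---------------------------------------------------------------------------
# Anchor selection
# ---------------------------------------------------------------------------

def _target_summary(target_runs: pd.DataFrame, peak_sep_min: float) -> pd.DataFrame:
    """Per-species target RT summary: median, replicate SD, peak count.

    Distinct chromatographic peaks are detected by gap-splitting the
    per-species RTs: a gap larger than ``peak_sep_min`` separates peaks.
    """
    rows = []
    for key, sub in target_runs.groupby("species_key"):
        rts = np.sort(sub["rt_min"].to_numpy(float))
        n_peaks = 1 + int(np.sum(np.diff(rts) > peak_sep_min)) if len(rts) > 1 else 1
        rows.append({
            "species_key": key,
            "rt_target": float(np.median(rts)),
            "rt_sd": float(np.std(rts, ddof=1)) if len(rts) > 1 else 0.0,
            "n_peaks": n_peaks,
            "reliability": "standard"
                           if "reliability" in sub.columns
                           and (sub["reliability"] == "standard").any()
                           else "biological",
            "peak_rts": rts,
        })
    return pd.DataFrame(rows)


def select_anchors(
    source_db: RTDB,
    target_runs: pd.DataFrame,
    strategy: int = 2,
    standards_available: Optional[bool] = None,
    replicate_sd_max_min: float = 0.05,
    peak_sep_min: float = 0.5,
    outlier_resid_min: float = 0.5,
) -> list[AnchorPoint]:
    """Pick calibration anchors shared between the RT-DB and target data.

    ``target_runs`` needs columns ``species_key`` (omega level),
    ``rt_min`` and optionally ``reliability`` ("standard"/"biological")
    and ``run_id``; repeated rows per species are treated as replicates.

    Strategies:

    1. anchor *count* prioritized — all shared species admitted; when
       standard anchors are available they screen biological anchors for
       outliers against a provisional standards-only fit;
    2. anchor *reliability* prioritized — only species whose replicate RT
       spread stays below ``replicate_sd_max_min`` and that produce a
       single chromatographic peak;
    3. all potential anchors matched (intended for standards data);
       species with multiple target peaks are kept as multiple candidate
       anchors only if they are standards, else dropped.
    """
    if strategy not in (1, 2, 3):
        raise ValueError("strategy must be 1, 2 or 3")
    if "species_key" not in target_runs.columns or "rt_min" not in target_runs.columns:
        raise ValueError("target_runs needs 'species_key' and 'rt_min' columns")
    source = {}
    for e in source_db.entries:
        if "conflict" in e.flags:
            continue
        source[e.key_omega] = e
    summary = _target_summary(target_runs, peak_sep_min)
    shared = summary[summary["species_key"].isin(source)]
    if shared.empty:
        raise NoAnchorsError("no anchors: source DB and target data share no species")
    if standards_available is None:
        standards_available = bool((shared["reliability"] == "standard").any())

    anchors: list[AnchorPoint] = []
    for _, row in shared.iterrows():
        e = source[row["species_key"]]
        multi = row["n_peaks"] > 1
        if strategy == 2:
            if multi or row["rt_sd"] > replicate_sd_max_min:
                continue
        elif multi and not (strategy == 3 and row["reliability"] == "standard"):
            continue  # ambiguous peak: dropped under strategies 1-2
        targets = [row["rt_target"]]
        if multi and strategy == 3 and row["reliability"] == "standard":
            # keep each peak as a candidate
            splits = np.where(np.diff(row["peak_rts"]) > peak_sep_min)[0] + 1
            targets = [float(np.median(g)) for g in np.split(row["peak_rts"], splits)]
        for t in targets:
            anchors.append(AnchorPoint(
                species_key=row["species_key"],
                rt_source=e.reference_rt,
                rt_target=t,
                reliability=row["reliability"],
                group=e.lipid_class,
            ))

    if strategy == 1 and standards_available:
        std = [a for a in anchors if a.reliability == "standard"]
        if len(std) >= 2:
            xs = np.array([a.rt_source for a in std])
            ys = np.array([a.rt_target for a in std])
            order = np.argsort(xs)
            xs, ys = xs[order], ys[order]
            kept = []
            for a in anchors:
                if a.reliability == "standard":
                    kept.append(a)
                    continue
                pred = np.interp(a.rt_source, xs, ys)
                if abs(a.rt_target - pred) <= outlier_resid_min:
                    kept.append(a)
                else:
                    logger.info("strategy 1: screened out anchor %s (residual %.2f min)",
                                a.species_key, abs(a.rt_target - pred))
            anchors = kept
    if not anchors:
        raise NoAnchorsError("no anchors survived the selection filters")
    anchors.sort(key=lambda a: (a.rt_source, a.species_key, a.rt_target))
    return anchors


# ---------------------------------------------------------------------------
# Binning and fitting
# ---------------------------------------------------------------------------

def bin_anchors(
    anchors: Sequence[AnchorPoint],
    bin_width_min: float = 0.5,
    min_knot_spacing_min: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce anchors to strictly increasing knots.

    Anchors are partitioned into source-RT bins of ``bin_width_min``;
    each occupied bin yields one knot (median source RT, median target
    RT).  Knots whose source RTs collide — duplicate RTs straddling a bin
    boundary — or come closer than ``min_knot_spacing_min`` are re-merged
    (weighted by bin occupancy) until the source coordinates are strictly
    increasing with that spacing.
    """
    if not anchors:
        raise ValueError("no anchors to bin")
    src = np.array([a.rt_source for a in anchors], float)
    tgt = np.array([a.rt_target for a in anchors], float)
    idx = np.floor(src / bin_width_min).astype(int)
    knots = []
    for b in np.unique(idx):
        m = idx == b
        knots.append((float(np.median(src[m])), float(np.median(tgt[m])), int(m.sum())))
    # enforce strictly increasing source coordinates by merging offenders
    changed = True
    while changed and len(knots) > 1:
        changed = False
        for i in range(len(knots) - 1):
            if knots[i + 1][0] - knots[i][0] < min_knot_spacing_min:
                a, b = knots[i], knots[i + 1]
                n = a[2] + b[2]
                merged = ((a[0] * a[2] + b[0] * b[2]) / n,
                          (a[1] * a[2] + b[1] * b[2]) / n, n)
                knots[i:i + 2] = [merged]
                changed = True
                break
    ks = np.array([k[0] for k in knots])
    kt = np.array([k[1] for k in knots])
    return ks, kt


def fit_rt_mapping(
    anchors: Sequence[AnchorPoint],
    bin_width_min: float = 0.5,
    min_knots_cubic: int = 4,
    user_groups: Optional[dict[str, str]] = None,
) -> CalibrationModel:
    """Fit per-group mappings plus the global fallback model.

    Groups reaching ``min_knots_cubic`` knots get a natural cubic
    interpolating spline; the global group (all anchors combined) is
    always fitted, with a piecewise-linear interpolant when it has only
    2-3 knots.  Sparser class groups rely on the fallback chain.
    """
    if not anchors:
        raise ValueError("no anchors to fit")
    user_groups = user_groups or {}
    by_group: dict[str, list[AnchorPoint]] = {GLOBAL_GROUP: list(anchors)}
    for a in anchors:
        by_group.setdefault(a.group, []).append(a)
    for cls, ug in user_groups.items():
        members = [a for a in anchors if user_groups.get(a.group) == ug]
        if members:
            by_group.setdefault(ug, members)
    models: dict[str, GroupModel] = {}
    for group, members in by_group.items():
        ks, kt = bin_anchors(members, bin_width_min)
        if len(ks) >= min_knots_cubic:
            models[group] = GroupModel(ks, kt, "cubic")
        elif group == GLOBAL_GROUP and len(ks) >= 2:
            models[group] = GroupModel(ks, kt, "linear")
    if not models:
        raise ValueError("no group reaches 2 knots; cannot fit any mapping")
    return CalibrationModel(groups=models, user_groups=user_groups,
                            min_knots_cubic=min_knots_cubic)


def map_rt(model: CalibrationModel, group: str, rt_source: float) -> MappedRT:
    """Map one source RT; flags report fallback and extrapolation."""
    return model.map(group, rt_source)


def evaluate_mapping(
    model: CalibrationModel,
    holdout: Sequence[AnchorPoint],
) -> dict:
    """Deviation of mapped holdout anchors from their target RTs, seconds."""
    if not holdout:
        raise ValueError("empty holdout")
    devs = []
    per_group: dict[str, list[float]] = {}
    for a in holdout:
        mapped = model.map(a.group, a.rt_source).value
        d = abs(mapped - a.rt_target) * 60.0
        devs.append(d)
        per_group.setdefault(a.group, []).append(d)
    devs = np.array(devs)
    return {
        "median_abs_dev_s": float(np.median(devs)),
        "mean_abs_dev_s": float(np.mean(devs)),
        "n": int(len(devs)),
        "per_group": {g: {"median_abs_dev_s": float(np.median(v)),
                          "mean_abs_dev_s": float(np.mean(v)),
                          "n": len(v)} for g, v in sorted(per_group.items())},
    }
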