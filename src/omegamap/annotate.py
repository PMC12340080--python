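"""Automated assignment of chain-specific omega positions to peaks.

Given lipid molecular species identified by routine MS/MS (class and
chains known, omega positions unknown) and an RT-DB mapped onto the same
chromatography, each peak is matched against the DB's omega-resolved
isomers of the *same molecular species*.  An assignment is

* ``automated`` — exactly one isomer inside the match window and the
  nearest competitor sufficiently far away,
* ``ambiguous`` — two or more isomers inside the match window,
* ``suggested`` — candidates only inside the wider suggestion window
  (flagged for manual review),
* ``none``     — nothing within reach.

Because matching is keyed on the molecular species, coeluting isomeric
peaks of *different* molecular species (e.g. PC 18:0_22:5 on top of
PC 16:0_24:5) are resolved per peak; the sum composition alone would be
uninformative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .lipids import (
    LipidMolecularSpecies,
    LipidParseError,
    mz_matches,
    parse_chain,
    species_key,
)
from .rtdb import RTDB, RTDBEntry

__all__ = [
    "PeakIdentification",
    "Assignment",
    "AnnotationConfig",
    "GradientMismatchError",
    "find_candidates",
    "assign_omega",
    "annotate_run",
]

logger = logging.getLogger(__name__)


class GradientMismatchError(ValueError):
    """Run RTs fall outside the DB gradient; calibrate the DB first."""


@dataclass(frozen=True)
class PeakIdentification:
    """One identified molecular-species peak (omega unknown)."""

    species: LipidMolecularSpecies
    rt_min: float
    mz: Optional[float] = None
    run_id: str = "run"

    @property
    def matching_key(self) -> str:
        return self.species.matching_key()


@dataclass(frozen=True)
class AnnotationConfig:
    """Decision policy for omega assignment.

    ``match_s`` mirrors the 5 s omega-combination grouping tolerance;
    omega isomers are typically separated by 10 s or more, so the default
    ``margin_factor`` of 2 demands competitors at >= 10 s.  ``wide_s`` is
    the suggestion window for matches that merit manual review.
    """

    match_s: float = 5.0
    wide_s: float = 15.0
    margin_factor: float = 2.0
    mz_tol_ppm: float = 10.0
    span_tol_min: float = 2.0


@dataclass(frozen=True)
class Assignment:
    peak: PeakIdentification
    entry: Optional[RTDBEntry]
    status: str  # automated | suggested | ambiguous | none
    confidence: float
    competitors: tuple[tuple[str, float], ...] = ()


def find_candidates(
    peak: PeakIdentification,
    mapped_rtdb: RTDB,
    rt_window_s: float = 15.0,
    mz_tol_ppm: float = 10.0,
) -> list[tuple[RTDBEntry, float]]:
    """DB isomers of the peak's molecular species within the RT window.

    Candidates must share the peak's molecular-species key (omega
    stripped); entries flagged ``conflict`` are never candidates.  When
    both the peak and the DB can state an m/z (peak observed, DB
    theoretical for the peak's adduct), a ppm filter applies as well.
    Returned sorted by |deltaRT| (seconds).
    """
    out = []
    for entry in mapped_rtdb.by_matching_key().get(peak.matching_key, []):
        if "conflict" in entry.flags:
            continue
        d_s = (entry.reference_rt - peak.rt_min) * 60.0
        if abs(d_s) > rt_window_s:
            continue
        if peak.mz is not None and peak.species.adduct is not None:
            from .lipids import monoisotopic_mass

            theo = monoisotopic_mass(entry.species, peak.species.adduct)
            if not mz_matches(peak.mz, theo, mz_tol_ppm):
                continue
        out.append((entry, d_s))
    out.sort(key=lambda t: (abs(t[1]), t[0].key_omega))
    return out


def assign_omega(
    peak: PeakIdentification,
    candidates: Sequence[tuple[RTDBEntry, float]],
    config: AnnotationConfig = AnnotationConfig(),
) -> Assignment:
    """Apply the automated / suggested / ambiguous / none decision policy.

    Automated requires exactly one candidate with |deltaRT| <= match_s and
    the nearest competitor (if any) at |deltaRT| >= margin_factor * match_s.
    Confidence is ``max(0, 1 - |deltaRT| / match_s)`` for the chosen entry.
    """
    if not candidates:
        return Assignment(peak, None, "none", 0.0)
    inside = [(e, d) for e, d in candidates if abs(d) <= config.match_s]
    competitors = tuple((e.key_omega, d) for e, d in candidates[1:])
    best, best_d = candidates[0]
    confidence = max(0.0, 1.0 - abs(best_d) / config.match_s)
    if len(inside) >= 2:
        return Assignment(peak, best, "ambiguous", confidence, competitors)
    if len(inside) == 1:
        margin_ok = (len(candidates) == 1
                     or abs(candidates[1][1]) >= config.margin_factor * config.match_s)
        if margin_ok:
            return Assignment(peak, inside[0][0], "automated",
                              max(0.0, 1.0 - abs(inside[0][1]) / config.match_s),
                              competitors)
        return Assignment(peak, best, "suggested", confidence, competitors)
    # candidates only in the wide window
    return Assignment(peak, best, "suggested", confidence, competitors)


def _parse_row(row, default_run: str = "run") -> PeakIdentification:
    tokens = str(row["chains"]).replace("/", "_").split("_")
    chains = tuple(parse_chain(t) for t in tokens)
    sp = LipidMolecularSpecies(
        str(row["lipid_class"]), chains, sn_resolved=False,
        adduct=row.get("adduct") if isinstance(row.get("adduct"), str) else None,
    )
    mz = row.get("mz")
    return PeakIdentification(
        species=sp,
        rt_min=float(row["rt_min"]),
        mz=float(mz) if mz is not None and pd.notna(mz) else None,
        run_id=str(row.get("run_id", default_run)),
    )


def annotate_run(
    id_table: pd.DataFrame,
    mapped_rtdb: RTDB,
    config: AnnotationConfig = AnnotationConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Annotate an identification table; returns (annotated table, summary).

    ``id_table`` needs ``lipid_class, chains, rt_min`` (optional ``run_id,
    mz, adduct, intensity``).  Peaks whose chains carry no MS/MS-level
    molecular-species evidence cannot appear here by construction — the
    table is already at the molecular-species level.  A run whose RTs
    exceed the DB gradient span by more than ``span_tol_min`` raises
    :class:`GradientMismatchError` (the DB belongs to another
    chromatography and must be calibrated first).
    """
    annotated = id_table.copy().reset_index(drop=True)
    cols = {c: [] for c in
            ("assigned_key", "assigned_omega_chains", "status", "confidence",
             "delta_rt_s", "n_candidates", "competitors")}
    span = mapped_rtdb.meta.get("gradient_span_min")
    if span is not None and len(annotated):
        worst = float(annotated["rt_min"].max())
        if worst > float(span) + config.span_tol_min:
            raise GradientMismatchError(
                f"run RTs reach {worst:.1f} min but the DB gradient spans "
                f"{span} min; map the RT-DB to this chromatography first"
            )
    counts = {"automated": 0, "suggested": 0, "ambiguous": 0, "none": 0}
    for _, row in annotated.iterrows():
        peak = _parse_row(row)
        cands = find_candidates(peak, mapped_rtdb, config.wide_s, config.mz_tol_ppm)
        a = assign_omega(peak, cands, config)
        counts[a.status] += 1
        chosen = a.entry.key_omega if a.entry is not None else ""
        cols["assigned_key"].append(chosen)
        cols["assigned_omega_chains"].append(chosen.split(" ", 1)[1] if chosen else "")
        cols["status"].append(a.status)
        cols["confidence"].append(round(a.confidence, 4))
        best_d = None
        for e, d in cands:
            if a.entry is not None and e.key_omega == a.entry.key_omega:
                best_d = d
                break
        cols["delta_rt_s"].append(round(best_d, 3) if best_d is not None else float("nan"))
        cols["n_candidates"].append(len(cands))
        cols["competitors"].append(";".join(f"{k}@{d:+.1f}s" for k, d in a.competitors))
    for c, v in cols.items():
        annotated[c] = v
    summary = {"n_peaks": int(len(annotated)), **counts}
    return annotated, summary
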