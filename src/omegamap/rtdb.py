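"""Omega-resolved retention-time databases from SIL labeling experiments.

The workflow: lipids biosynthesized from methyl-terminus-labeled fatty
acids are identified in RPLC-MS/MS runs; the label pins the omega
position but deuterium also shifts the retention time.  This module
(1) estimates the deuterium isotope effect on the retention factor from
labeled/unlabeled standard pairs, (2) corrects observed RTs back to the
native elution time, (3) strips the labels to native species keys, and
(4) groups per-experiment identifications of the same molecular species
into omega-combination entries, so that combinations of chains labeled
in *separate* single-label experiments are inferred computationally.

The isotope effect is quantified as the adjusted total isotope effect

    aTIE = ((k_H / k_D) - 1) / f_a + 1

with retention factors k = (t_R - t_0)/t_0, where k_H and k_D belong to
the unlabeled and deuterated compound, t_0 is the column dead time and
f_a a gradient-adjustment factor (1 by default).  Per-compound ratios
are reduced to a per-deuterium ratio r via k_H/k_D = r**n_D, which makes
the correction additive across chains: each deuterated chain shifts RT
by (t_R,obs - t_0) * (r**n_D - 1) and the shifts of multiple SIL chains
are simply summed.  Carbon-13 labels leave RT untouched.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .lipids import (
    FattyAcyl,
    LabelRegistry,
    LipidMolecularSpecies,
    LipidParseError,
    default_label_registry,
    format_chain,
    parse_chain,
    species_key,
)

__all__ = [
    "IsotopeEffectModel",
    "RTDBEntry",
    "RTDB",
    "InvalidRetentionError",
    "estimate_isotope_effect",
    "correct_labeled_rt",
    "group_omega_combinations",
    "build_rtdb",
    "merge_rtdbs",
    "rtdb_io",
    "RTDB_COLUMNS",
]

logger = logging.getLogger(__name__)

RTDB_COLUMNS = [
    "lipid_class",
    "species_key_omega",
    "chains",
    "sn_resolved",
    "reference_rt_min",
    "batches",
    "evidence",
    "flags",
]

_EVIDENCE_RANK = {"standard": 0, "orthogonal": 1, "SIL-experiment": 2}


class InvalidRetentionError(ValueError):
    """A retention time at or below the dead time has no retention factor."""


@dataclass(frozen=True)
class IsotopeEffectModel:
    """Deuterium isotope effect on the retention factor.

    ``k_ratio`` is k_H/k_D at the reference deuterium count
    ``n_d_reference`` (that of the calibration standard);
    ``per_deuterium_ratio`` is the per-atom ratio r with
    k_ratio = r**n_d_reference.
    """

    k_ratio: float
    f_a: float = 1.0
    t0: float = 0.5
    per_deuterium_ratio: float = 1.0
    n_d_reference: int = 1

    def __post_init__(self) -> None:
        if self.k_ratio <= 0 or self.f_a <= 0 or self.per_deuterium_ratio <= 0:
            raise ValueError("k_ratio, f_a and per_deuterium_ratio must be positive")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")

    @property
    def atie(self) -> float:
        """Adjusted total isotope effect, ((k_H/k_D) - 1)/f_a + 1."""
        return (self.k_ratio - 1.0) / self.f_a + 1.0


def estimate_isotope_effect(
    standard_pairs: Sequence[tuple[float, float, int]],
    f_a: float = 1.0,
    t0: float = 0.5,
) -> IsotopeEffectModel:
    """Fit the isotope-effect model from (native RT, labeled RT, n_D) pairs.

    Retention factors k = (RT - t0)/t0 give a per-pair ratio k_H/k_D; each
    is reduced to a per-deuterium ratio (k_H/k_D)**(1/n_D) and the model
    ratio is their geometric mean, scaled back to the first pair's n_D for
    reporting ``k_ratio``.
    """
    if not standard_pairs:
        raise ValueError("at least one standard pair is required")
    logs = []
    for rt_h, rt_d, n_d in standard_pairs:
        if n_d < 1:
            raise ValueError("standard pairs must carry n_D >= 1")
        if rt_h <= t0 or rt_d <= t0:
            raise InvalidRetentionError(
                f"RT <= dead time t0={t0}: pair ({rt_h}, {rt_d}) has no retention factor"
            )
        k_h = (rt_h - t0) / t0
        k_d = (rt_d - t0) / t0
        logs.append(math.log(k_h / k_d) / n_d)
    per_d = math.exp(float(np.mean(logs)))
    n_ref = int(standard_pairs[0][2])
    return IsotopeEffectModel(
        k_ratio=per_d ** n_ref,
        f_a=f_a,
        t0=t0,
        per_deuterium_ratio=per_d,
        n_d_reference=n_ref,
    )


def correct_labeled_rt(
    species: LipidMolecularSpecies,
    rt_observed: float,
    model: IsotopeEffectModel,
) -> float:
    """Correct the observed RT of a labeled species back to native elution.

    Each deuterium-labeled chain contributes a shift
    (RT_obs - t0) * (r**n_D - 1); shifts of multiple SIL chains are summed.
    13C labels contribute nothing; an unlabeled species passes through
    unchanged.
    """
    shifts = 0.0
    any_label = False
    for chain in species.chains:
        if chain.label is None:
            continue
        any_label = True
        if chain.label.element == "D":
            shifts += (rt_observed - model.t0) * (
                model.per_deuterium_ratio ** chain.label.atom_count - 1.0
            )
        # 13C: negligible RT impact, no correction
    if not any_label:
        logger.debug("correct_labeled_rt: %s carries no label, RT unchanged",
                     species_key(species))
        return rt_observed
    return rt_observed + shifts


# ---------------------------------------------------------------------------
# Entries and grouping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RTDBEntry:
    """One omega-resolved species with its reference RT and provenance."""

    species: LipidMolecularSpecies
    reference_rt: float
    source_batches: frozenset[str]
    evidence: Literal["SIL-experiment", "orthogonal", "standard"] = "SIL-experiment"
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_batches", frozenset(self.source_batches))
        object.__setattr__(self, "flags", frozenset(self.flags))
        if not self.source_batches:
            raise ValueError("source_batches must be non-empty")

    @property
    def lipid_class(self) -> str:
        return self.species.lipid_class

    @property
    def key_omega(self) -> str:
        return species_key(self.species, "molecular")

    @property
    def matching_key(self) -> str:
        return self.species.matching_key()


@dataclass
class RTDB:
    """A retention-time database: entries plus run metadata."""

    entries: list[RTDBEntry] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_matching_key(self) -> dict[str, list[RTDBEntry]]:
        idx: dict[str, list[RTDBEntry]] = {}
        for e in self.entries:
            idx.setdefault(e.matching_key, []).append(e)
        return idx

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in sorted(self.entries, key=lambda e: (e.lipid_class, e.key_omega)):
            key = e.key_omega
            rows.append({
                "lipid_class": e.lipid_class,
                "species_key_omega": key,
                "chains": key.split(" ", 1)[1],
                "sn_resolved": e.species.sn_resolved,
                "reference_rt_min": e.reference_rt,
                "batches": ";".join(sorted(e.source_batches)),
                "evidence": e.evidence,
                "flags": ";".join(sorted(e.flags)),
            })
        return pd.DataFrame(rows, columns=RTDB_COLUMNS)


def _merge_chain_omegas(
    a: Sequence[FattyAcyl], b: Sequence[FattyAcyl]
) -> Optional[tuple[FattyAcyl, ...]]:
    """Union-consistent combination of omega assignments of two chain lists.

    The lists must describe the same molecular species (same multiset of
    (carbons, double_bonds, linkage)); per matched chain the known omega
    wins, and ``None`` is returned when no pairing reconciles them.
    """
    import itertools

    a = tuple(sorted(a, key=FattyAcyl.sort_key))
    for perm in itertools.permutations(b):
        merged = []
        ok = True
        for ca, cb in zip(a, perm):
            if (ca.carbons, ca.double_bonds, ca.linkage) != (cb.carbons, cb.double_bonds, cb.linkage):
                ok = False
                break
            oa, ob = ca.effective_omega, cb.effective_omega
            if oa is not None and ob is not None and oa != ob:
                ok = False
                break
            merged.append(replace(ca, omega=oa if oa is not None else ob))
        if ok and len(merged) == len(a):
            return tuple(sorted(merged, key=FattyAcyl.sort_key))
    return None


def group_omega_combinations(
    entries: Sequence[RTDBEntry],
    grouping_tolerance_s: float = 5.0,
) -> list[RTDBEntry]:
    """Cluster same-species identifications into omega-combination entries.

    Single-linkage clustering on the (corrected) RT with the grouping
    tolerance; every cluster becomes one entry whose reference RT is the
    member median, whose chains carry the union-consistent omega
    assignments, and whose source batches are unioned.  Clusters mixing
    incompatible omega positions for the same chain are flagged
    ``conflict`` and excluded from automated use downstream.

    Aggregating identifications from separate single-label experiments this
    way is what infers mixed-omega chain combinations that no single
    experiment observed directly.
    """
    if not entries:
        return []
    keys = {e.matching_key for e in entries}
    if len(keys) > 1:
        raise ValueError(f"entries span multiple molecular species: {sorted(keys)}")
    tol_min = grouping_tolerance_s / 60.0
    ordered = sorted(entries, key=lambda e: (e.reference_rt, e.key_omega))
    clusters: list[list[RTDBEntry]] = [[ordered[0]]]
    for e in ordered[1:]:
        if e.reference_rt - clusters[-1][-1].reference_rt <= tol_min:
            clusters[-1].append(e)
        else:
            clusters.append([e])
    out: list[RTDBEntry] = []
    for cluster in clusters:
        chains: Optional[tuple[FattyAcyl, ...]] = tuple(
            c.strip_label() for c in cluster[0].species.chains
        )
        for e in cluster[1:]:
            if chains is None:
                break
            chains = _merge_chain_omegas(chains, [c.strip_label() for c in e.species.chains])
        rt = float(np.median([e.reference_rt for e in cluster]))
        batches = frozenset().union(*(e.source_batches for e in cluster))
        evidence = min((e.evidence for e in cluster), key=lambda v: _EVIDENCE_RANK.get(v, 9))
        flags = frozenset().union(*(e.flags for e in cluster))
        if chains is None:
            flags = flags | {"conflict"}
            chains = tuple(c.strip_label() for c in cluster[0].species.chains)
            logger.warning("omega conflict within grouping cluster of %s",
                           cluster[0].matching_key)
        sp = replace(cluster[0].species, chains=chains, sn_resolved=False)
        out.append(RTDBEntry(sp, rt, batches, evidence, flags))
    return out


# ---------------------------------------------------------------------------
# Building and merging
# ---------------------------------------------------------------------------

def build_rtdb(
    identifications: pd.DataFrame,
    model: IsotopeEffectModel,
    grouping_tolerance_s: float = 5.0,
    meta: Optional[dict] = None,
    label_registry: Optional[LabelRegistry] = None,
) -> tuple[RTDB, pd.DataFrame]:
    """RT-DB from a table of (possibly labeled) identifications.

    ``identifications`` needs columns ``batch_id, lipid_class, chains,
    rt_min`` (optional ``sn_resolved``, ``evidence``).  Pipeline per row:
    parse -> correct the deuterium RT shift -> strip labels to the native
    key (keeping the label-implied omega) -> group omega combinations per
    molecular species.  Rows that fail chain parsing are skipped and
    reported in the second return value.
    """
    required = {"batch_id", "lipid_class", "chains", "rt_min"}
    missing = required - set(identifications.columns)
    if missing:
        raise ValueError(f"identification table is missing columns: {sorted(missing)}")
    registry = label_registry or default_label_registry()
    per_species: dict[str, list[RTDBEntry]] = {}
    skipped = []
    for idx, row in identifications.iterrows():
        try:
            tokens = str(row["chains"]).replace("/", "_").split("_")
            chains = tuple(parse_chain(t, registry) for t in tokens)
            sp = LipidMolecularSpecies(str(row["lipid_class"]), chains, sn_resolved=False)
        except (LipidParseError, ValueError) as exc:
            skipped.append({"row": idx, "chains": row.get("chains"), "reason": str(exc)})
            continue
        rt = correct_labeled_rt(sp, float(row["rt_min"]), model)
        native = replace(sp, chains=tuple(c.strip_label() for c in sp.chains))
        entry = RTDBEntry(
            native,
            rt,
            frozenset({str(row["batch_id"])}),
            evidence=str(row.get("evidence", "SIL-experiment")),
        )
        per_species.setdefault(entry.matching_key, []).append(entry)
    entries: list[RTDBEntry] = []
    for key in sorted(per_species):
        entries.extend(group_omega_combinations(per_species[key], grouping_tolerance_s))
    report = pd.DataFrame(skipped, columns=["row", "chains", "reason"])
    if len(report):
        logger.info("build_rtdb skipped %d unparseable row(s)", len(report))
    db = RTDB(entries=entries, meta=dict(meta or {}))
    db.meta.setdefault("t0_min", model.t0)
    return db, report


def merge_rtdbs(
    dbs: Sequence[RTDB],
    calibrations: Optional[Sequence] = None,
    curation_flags: Optional[set[str]] = None,
    grouping_tolerance_s: float = 5.0,
) -> RTDB:
    """Merge measurement-batch RT-DBs into one aggregate database.

    ``dbs[0]`` is the reference; every other DB must come with a
    calibration in ``calibrations`` (aligned with ``dbs``) that maps its
    elution profile onto the reference gradient — either a fitted
    :class:`omegamap.calibrate.CalibrationModel` or the string
    ``"identity"``.  Entries whose omega-level key appears in
    ``curation_flags`` are excluded as curated outliers.  Mapped entries
    are then grouped per molecular species, so every aggregate entry lists
    all contributing batches and the total never exceeds the input sum.
    """
    if not dbs:
        raise ValueError("no databases to merge")
    if calibrations is None:
        calibrations = ["identity"] * len(dbs)
    if len(calibrations) != len(dbs):
        raise ValueError("calibrations must align with dbs")
    curation_flags = curation_flags or set()
    mapped: list[RTDBEntry] = []
    for i, (db, cal) in enumerate(zip(dbs, calibrations)):
        if i > 0 and cal is None:
            raise ValueError(f"missing calibration for non-reference DB #{i}")
        for e in db.entries:
            if e.key_omega in curation_flags:
                logger.info("curated out %s from batch DB #%d", e.key_omega, i)
                continue
            if cal is None or cal == "identity":
                rt, extra = e.reference_rt, frozenset()
            else:
                res = cal.map(e.lipid_class, e.reference_rt)
                rt, extra = res.value, frozenset(res.flags)
            mapped.append(replace(e, reference_rt=rt, flags=e.flags | extra))
    per_species: dict[str, list[RTDBEntry]] = {}
    for e in mapped:
        per_species.setdefault(e.matching_key, []).append(e)
    entries: list[RTDBEntry] = []
    for key in sorted(per_species):
        entries.extend(group_omega_combinations(per_species[key], grouping_tolerance_s))
    return RTDB(entries=entries, meta=dict(dbs[0].meta))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _entry_from_row(row, registry: LabelRegistry) -> RTDBEntry:
    sn = str(row["sn_resolved"]).strip().lower() in ("true", "1", "yes")
    tokens = str(row["chains"]).split("/" if sn else "_")
    chains = tuple(parse_chain(t, registry) for t in tokens)
    sp = LipidMolecularSpecies(str(row["lipid_class"]), chains, sn_resolved=sn)
    flags = frozenset(f for f in str(row.get("flags", "") or "").split(";") if f)
    return RTDBEntry(
        sp,
        float(row["reference_rt_min"]),
        frozenset(str(row["batches"]).split(";")),
        evidence=str(row["evidence"]),
        flags=flags,
    )


def rtdb_io(db_or_path, path=None, direction: str = "write",
            label_registry: Optional[LabelRegistry] = None):
    """Read or write an RT-DB; ``.xlsx`` spreadsheet or tab-separated text.

    The written table doubles as an annotated mass list: one row per
    omega-resolved species with its reference RT, provenance batches,
    evidence tier and flags.  Metadata travels in a ``meta`` sheet (xlsx)
    or ``#key=value`` header lines (text).  Round trips are lossless.
    """
    registry = label_registry or default_label_registry()
    if direction == "write":
        db, p = db_or_path, Path(path)
        df = db.to_frame()
        if p.suffix.lower() in (".xlsx", ".xls"):
            with pd.ExcelWriter(p) as xl:
                df.to_excel(xl, sheet_name="rtdb", index=False)
                pd.DataFrame(
                    [{"key": k, "value": v} for k, v in sorted(db.meta.items())]
                ).to_excel(xl, sheet_name="meta", index=False)
        else:
            with open(p, "w") as fh:
                for k, v in sorted(db.meta.items()):
                    fh.write(f"#{k}={v}\n")
                df.to_csv(fh, sep="\t", index=False)
        return p
    if direction == "read":
        p = Path(db_or_path)
        meta: dict = {}
        if p.suffix.lower() in (".xlsx", ".xls"):
            df = pd.read_excel(p, sheet_name="rtdb")
            try:
                mdf = pd.read_excel(p, sheet_name="meta")
                meta = {str(r["key"]): _coerce(r["value"]) for _, r in mdf.iterrows()}
            except ValueError:
                meta = {}
        else:
            header_lines = []
            with open(p) as fh:
                pos = fh.tell()
                while True:
                    line = fh.readline()
                    if line.startswith("#"):
                        header_lines.append(line[1:].strip())
                        pos = fh.tell()
                    else:
                        fh.seek(pos)
                        break
                df = pd.read_csv(fh, sep="\t", keep_default_na=False)
            for line in header_lines:
                k, _, v = line.partition("=")
                meta[k] = _coerce(v)
        missing = [c for c in RTDB_COLUMNS if c not in df.columns]
        if missing:
            from .masslist import SchemaError

            raise SchemaError(f"RT-DB {p} is missing columns: {missing}")
        entries = [_entry_from_row(row, registry) for _, row in df.iterrows()]
        return RTDB(entries=entries, meta=meta)
    raise ValueError("direction must be 'read' or 'write'")


def _coerce(v):
    try:
        f = float(v)
        return int(f) if f == int(f) and "." not in str(v) else f
    except (TypeError, ValueError):
        return v
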