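"""Combinatorial mass-list generation for native and SIL lipid species.

A mass list is the table an identification engine screens MS1 data
against: one row per (species, adduct) with the theoretical m/z.  For
labeling experiments the generator expands every species into all
feasible label placements — including doubly labeled species and
mixtures of different labels — so that heavy precursors are picked up
alongside the native ones.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .lipids import (
    ClassRegistry,
    FattyAcyl,
    LipidMolecularSpecies,
    SILLabel,
    default_class_registry,
    monoisotopic_mass,
    species_key,
)

__all__ = [
    "Constraints",
    "SchemaError",
    "enumerate_molecular_species",
    "apply_sil_labels",
    "build_masslist",
    "masslist_io",
    "MASSLIST_COLUMNS",
]

logger = logging.getLogger(__name__)

MASSLIST_COLUMNS = [
    "species_key",
    "lipid_class",
    "chains",
    "adduct",
    "mz",
    "label_codes",
    "n_heavy_atoms",
]


class SchemaError(ValueError):
    """A mass-list file is missing mandatory columns."""


@dataclass(frozen=True)
class Constraints:
    """Bounds on the summed chain composition of generated species."""

    min_carbons: int = 0
    max_carbons: int = 10_000
    min_double_bonds: int = 0
    max_double_bonds: int = 10_000

    def admits(self, species: LipidMolecularSpecies) -> bool:
        return (
            self.min_carbons <= species.total_carbons <= self.max_carbons
            and self.min_double_bonds <= species.total_double_bonds <= self.max_double_bonds
        )

    @property
    def contradictory(self) -> bool:
        return (self.min_carbons > self.max_carbons
                or self.min_double_bonds > self.max_double_bonds)


def enumerate_molecular_species(
    lipid_class: str,
    chain_pool: Sequence[FattyAcyl],
    constraints: Optional[Constraints] = None,
    registry: Optional[ClassRegistry] = None,
) -> list[LipidMolecularSpecies]:
    """All multiset combinations of pool chains for a class.

    Chains within a species are unordered (MS1 masses cannot resolve
    sn-positions), so homo-chain pairs appear once.  Output is
    deterministic, sorted by canonical key.
    """
    if not chain_pool:
        raise ValueError("chain_pool must be non-empty")
    registry = registry or default_class_registry()
    n = registry.chain_count(lipid_class)
    if constraints is not None and constraints.contradictory:
        warnings.warn(f"contradictory constraints {constraints}; empty result", stacklevel=2)
        return []
    pool = sorted(set(chain_pool), key=FattyAcyl.sort_key)
    out = {}
    for combo in itertools.combinations_with_replacement(pool, n):
        sp = LipidMolecularSpecies(lipid_class, combo, sn_resolved=False)
        if constraints is not None and not constraints.admits(sp):
            continue
        out[species_key(sp, "molecular")] = sp
    return [out[k] for k in sorted(out)]


def apply_sil_labels(
    species: Iterable[LipidMolecularSpecies],
    labels: Sequence[SILLabel],
    max_labeled_chains: int = 2,
    allow_unknown_omega: bool = False,
) -> list[LipidMolecularSpecies]:
    """Expand species into all distinct label placements.

    A label is eligible for a chain when the chain's omega position equals
    the label's implied omega position (or, with ``allow_unknown_omega``,
    when the chain's omega is unknown).  Every assignment of
    0..``max_labeled_chains`` labels to eligible chains is emitted; the
    native (unlabeled) variant is always retained.  Incompatible
    label/chain pairings are skipped and logged, never raised.
    """
    out: list[LipidMolecularSpecies] = []
    seen: set[str] = set()

    def emit(sp: LipidMolecularSpecies) -> None:
        key = species_key(sp, "molecular") + f"|{sp.adduct}"
        if key not in seen:
            seen.add(key)
            out.append(sp)

    for sp in species:
        emit(sp)
        eligible: list[tuple[int, SILLabel]] = []
        for i, chain in enumerate(sp.chains):
            if chain.label is not None:
                continue
            for lab in labels:
                if lab.omega_implied is not None and chain.effective_omega == lab.omega_implied:
                    eligible.append((i, lab))
                elif allow_unknown_omega and chain.effective_omega is None and chain.double_bonds >= 1:
                    eligible.append((i, lab))
                elif chain.double_bonds >= 1 and chain.effective_omega is not None:
                    logger.debug(
                        "label %s (n-%s) not applicable to chain %d of %s",
                        lab.prefix_code, lab.omega_implied, i, species_key(sp),
                    )
        for k in range(1, max_labeled_chains + 1):
            for assignment in itertools.combinations(eligible, k):
                positions = [i for i, _ in assignment]
                if len(set(positions)) != k:
                    continue  # one label per chain
                chains = list(sp.chains)
                ok = True
                for i, lab in assignment:
                    try:
                        chains[i] = replace(chains[i], label=lab,
                                            omega=chains[i].effective_omega or lab.omega_implied)
                    except ValueError as exc:  # e.g. too few substitutable atoms
                        logger.info("skipping label combination on %s: %s", species_key(sp), exc)
                        ok = False
                        break
                if ok:
                    emit(replace(sp, chains=tuple(chains)))
    return out


def build_masslist(
    species: Iterable[LipidMolecularSpecies],
    adducts: Optional[Sequence[str]] = None,
    registry: Optional[ClassRegistry] = None,
) -> pd.DataFrame:
    """Tabulate (species, adduct) rows with theoretical m/z.

    When ``adducts`` is None each class's registry defaults are used.
    Duplicate (species_key, adduct) rows are emitted once.
    """
    registry = registry or default_class_registry()
    rows = []
    seen = set()
    for sp in species:
        cls_adducts = adducts or registry.default_adducts(sp.lipid_class)
        key = species_key(sp, "molecular")
        for adduct in cls_adducts:
            if (key, adduct) in seen:
                continue
            seen.add((key, adduct))
            labels = sp.labels
            rows.append({
                "species_key": key,
                "lipid_class": sp.lipid_class,
                "chains": key.split(" ", 1)[1],
                "adduct": adduct,
                "mz": monoisotopic_mass(sp, adduct, registry),
                "label_codes": "".join(sorted(l.prefix_code for l in labels)),
                "n_heavy_atoms": sum(l.atom_count for l in labels),
            })
    return pd.DataFrame(rows, columns=MASSLIST_COLUMNS)


def masslist_io(rows_or_path, path=None, direction: str = "write"):
    """Read or write a mass list; dialect chosen by file suffix.

    ``.xlsx`` uses a spreadsheet, anything else tab-separated text.
    ``masslist_io(df, path)`` writes; ``masslist_io(path, direction="read")``
    reads and validates the schema.
    """
    if direction == "write":
        df, p = rows_or_path, Path(path)
        if p.suffix.lower() in (".xlsx", ".xls"):
            df.to_excel(p, index=False)
        else:
            df.to_csv(p, sep="\t", index=False)
        return p
    if direction == "read":
        p = Path(rows_or_path)
        if p.suffix.lower() in (".xlsx", ".xls"):
            df = pd.read_excel(p)
        else:
            df = pd.read_csv(p, sep="\t", keep_default_na=False)
        missing = [c for c in MASSLIST_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"mass list {p} is missing columns: {missing}")
        df["label_codes"] = df["label_codes"].fillna("").astype(str)
        df["n_heavy_atoms"] = df["n_heavy_atoms"].astype(int)
        return df[MASSLIST_COLUMNS]
    raise ValueError("direction must be 'read' or 'write'")
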