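"""Lipid shorthand parsing, stable-isotope labels and mass arithmetic.

Chains are written in the common shorthand ``<label?><linkage?>C:D(n-x)?``,
e.g. ``18:1(n−9)`` (oleoyl), ``O-16:0`` (alkyl ether), ``A18:1`` (the
deuterium-labeled counterpart of 18:1(n−9)).  Species combine a class
name with chains joined by ``_`` (sn-positions unknown) or ``/``
(sn-resolved), e.g. ``PC 16:0_20:4(n−6)`` vs ``PI 18:0/20:3(n−9)``.

The label registry and the class/adduct registry are editable YAML files
shipped with the package (``data/labels.yaml``, ``data/classes.yaml``); user
registries with the same layout can be passed to every function that takes a
``registry`` argument.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import Iterable, Literal, Optional

import yaml
from pyteomics import mass as _pmass

__all__ = [
    "MINUS",
    "SILLabel",
    "FattyAcyl",
    "LipidMolecularSpecies",
    "LabelRegistry",
    "ClassRegistry",
    "LipidParseError",
    "RegistryError",
    "default_label_registry",
    "default_class_registry",
    "parse_chain",
    "format_chain",
    "parse_species",
    "species_key",
    "monoisotopic_mass",
    "label_mass_shift",
    "mz_matches",
]

#: Unicode minus sign used when emitting omega positions, e.g. "(n−9)".
MINUS = "−"

_H_MASS = _pmass.nist_mass["H"][1][0]
_D_MASS = _pmass.nist_mass["H"][2][0]
_C12_MASS = _pmass.nist_mass["C"][12][0]
_C13_MASS = _pmass.nist_mass["C"][13][0]
_ELECTRON_MASS = 0.00054857990946

#: Exact monoisotopic mass difference per heavy atom, by label element.
PER_ATOM_SHIFT = {"D": _D_MASS - _H_MASS, "13C": _C13_MASS - _C12_MASS}


class LipidParseError(ValueError):
    """A shorthand token could not be interpreted."""


class RegistryError(KeyError):
    """A class, adduct or label is not present in the registry."""


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SILLabel:
    """A stable-isotope label carried by one fatty-acyl chain.

    Parameters
    ----------
    prefix_code:
        Single capital letter prepended to the chain shorthand ("A18:1").
    element:
        ``"D"`` (deuterium) or ``"13C"``.
    atom_count:
        Number of heavy atoms the label introduces (>= 1).
    omega_implied:
        The n-x position the label pins down, or ``None``.
    """

    prefix_code: str
    element: Literal["D", "13C"]
    atom_count: int
    omega_implied: Optional[int] = None

    def __post_init__(self) -> None:
        if not (len(self.prefix_code) == 1 and self.prefix_code.isupper()):
            raise ValueError(f"label code must be a single capital letter, got {self.prefix_code!r}")
        if self.prefix_code in ("O", "P"):
            raise ValueError("label codes 'O' and 'P' clash with the ether linkage prefixes")
        if self.element not in PER_ATOM_SHIFT:
            raise ValueError(f"unsupported label element {self.element!r}")
        if self.atom_count < 1:
            raise ValueError("atom_count must be >= 1")


class LabelRegistry:
    """Mapping of prefix codes to :class:`SILLabel` definitions."""

    def __init__(self, labels: Iterable[SILLabel]):
        self._by_code: dict[str, SILLabel] = {}
        for lab in labels:
            if lab.prefix_code in self._by_code:
                raise ValueError(f"duplicate label code {lab.prefix_code!r}")
            self._by_code[lab.prefix_code] = lab

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __iter__(self):
        return iter(self._by_code.values())

    def __len__(self) -> int:
        return len(self._by_code)

    def get(self, code: str) -> SILLabel:
        try:
            return self._by_code[code]
        except KeyError:
            raise RegistryError(f"unknown SIL label prefix {code!r}") from None

    def for_omega(self, omega: int) -> Optional[SILLabel]:
        """Return the label implying ``omega``, if one is registered."""
        for lab in self._by_code.values():
            if lab.omega_implied == omega:
                return lab
        return None

    @classmethod
    def from_yaml(cls, path) -> "LabelRegistry":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            SILLabel(str(row["code"]), str(row["element"]), int(row["count"]),
                     None if row.get("omega") is None else int(row["omega"]))
            for row in doc["labels"]
        )


@lru_cache(maxsize=1)
def default_label_registry() -> LabelRegistry:
    """The built-in five-label registry (A/B/C/D/E)."""
    with resources.as_file(resources.files("omegamap.data") / "labels.yaml") as p:
        return LabelRegistry.from_yaml(p)


def label_mass_shift(label: SILLabel, mode: Literal["nominal", "exact"] = "exact") -> float:
    """Mass shift introduced by a label, in Da.

    ``exact`` is ``atom_count`` times the heavy-minus-light monoisotopic mass
    difference; ``nominal`` rounds that to the nearest integer (the unit-mass
    shift seen in a low-resolution spectrum).
    """
    exact = label.atom_count * PER_ATOM_SHIFT[label.element]
    if mode == "nominal":
        return float(round(exact))
    if mode == "exact":
        return exact
    raise ValueError(f"mode must be 'nominal' or 'exact', got {mode!r}")


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------

_LINKAGE_PREFIX = {"acyl": "", "alkyl": "O-", "alkenyl": "P-"}
_PREFIX_LINKAGE = {"O-": "alkyl", "P-": "alkenyl"}

_CHAIN_RE = re.compile(
    r"^(?P<label>[A-Z])?(?P<link>O-|P-)?(?P<c>\d+):(?P<d>\d+)"
    r"(?:\(n[−-](?P<omega>\d+)\))?$"
)


@dataclass(frozen=True)
class FattyAcyl:
    """One fatty acyl/alkyl/alkenyl chain."""

    carbons: int
    double_bonds: int
    omega: Optional[int] = None
    linkage: Literal["acyl", "alkyl", "alkenyl"] = "acyl"
    label: Optional[SILLabel] = None

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"chain needs >= 2 carbons, got {self.carbons}")
        if not (0 <= self.double_bonds <= (self.carbons - 1) // 2):
            raise ValueError(
                f"{self.carbons}:{self.double_bonds} violates 0 <= d <= (c-1)//2"
            )
        if self.omega is not None and self.double_bonds >= 1 and self.omega > self.carbons - 1:
            raise ValueError(f"omega n-{self.omega} impossible on a {self.carbons}-carbon chain")
        if self.linkage not in _LINKAGE_PREFIX:
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.label is not None:
            comp = self._residue_composition_native()
            avail = comp["H"] if self.label.element == "D" else comp["C"]
            if self.label.atom_count > avail:
                raise ValueError(
                    f"label {self.label.prefix_code} needs {self.label.atom_count} "
                    f"substitutable atoms but the chain residue has only {avail}"
                )

    # residue = chain as incorporated in the glycerophospholipid (condensed)
    def _residue_composition_native(self) -> dict[str, int]:
        c, d = self.carbons, self.double_bonds
        if self.linkage == "acyl":
            return {"C": c, "H": 2 * c - 2 - 2 * d, "O": 1}
        if self.linkage == "alkyl":
            return {"C": c, "H": 2 * c - 2 * d}
        return {"C": c, "H": 2 * c - 2 - 2 * d}  # alkenyl

    def residue_composition(self) -> dict[str, int]:
        """Elemental composition of the condensed residue, isotope-resolved.

        Heavy atoms appear under pyteomics-style keys ``"H[2]"``/``"C[13]"``.
        """
        comp = dict(self._residue_composition_native())
        if self.label is not None:
            n = self.label.atom_count
            if self.label.element == "D":
                comp["H"] -= n
                comp["H[2]"] = n
            else:
                comp["C"] -= n
                comp["C[13]"] = n
        return comp

    @property
    def effective_omega(self) -> Optional[int]:
        """The omega position, falling back to the one implied by the label."""
        if self.omega is not None:
            return self.omega
        if self.label is not None:
            return self.label.omega_implied
        return None

    def strip_label(self) -> "FattyAcyl":
        """Native counterpart of a labeled chain, keeping the omega position."""
        if self.label is None:
            return self
        return replace(self, label=None, omega=self.effective_omega)

    def strip_omega(self) -> "FattyAcyl":
        return replace(self, omega=None) if self.omega is not None else self

    def sort_key(self) -> tuple:
        link_order = ("acyl", "alkyl", "alkenyl").index(self.linkage)
        return (link_order, self.carbons, self.double_bonds,
                -1 if self.omega is None else self.omega,
                "" if self.label is None else self.label.prefix_code)


def parse_chain(text: str, registry: Optional[LabelRegistry] = None) -> FattyAcyl:
    """Parse one chain shorthand token.

    Accepts both the Unicode minus and the ASCII hyphen inside ``(n-x)``.
    A leading capital letter is resolved against the label registry; the
    label's implied omega position is adopted when the token does not spell
    one out.
    """
    if not text:
        raise LipidParseError("empty chain token")
    registry = registry or default_label_registry()
    m = _CHAIN_RE.match(text.strip())
    if m is None:
        raise LipidParseError(f"malformed chain token {text!r}")
    label = None
    if m.group("label"):
        code = m.group("label")
        if code not in registry:
            raise LipidParseError(f"unknown SIL prefix {code!r} in token {text!r}")
        label = registry.get(code)
    omega = int(m.group("omega")) if m.group("omega") else None
    if omega is None and label is not None:
        omega = label.omega_implied
    if label is not None and label.omega_implied is not None and omega != label.omega_implied:
        raise LipidParseError(
            f"token {text!r}: explicit omega n-{omega} contradicts label "
            f"{label.prefix_code} (n-{label.omega_implied})"
        )
    linkage = _PREFIX_LINKAGE.get(m.group("link") or "", "acyl")
    try:
        return FattyAcyl(int(m.group("c")), int(m.group("d")), omega, linkage, label)
    except ValueError as exc:
        raise LipidParseError(f"token {text!r}: {exc}") from None


def format_chain(chain: FattyAcyl, include_omega: bool = True) -> str:
    """Canonical shorthand for a chain (inverse of :func:`parse_chain`).

    An omega position that is implied by the label is not spelled out, so
    labeled chains render compactly ("A18:1" rather than "A18:1(n−9)").
    """
    parts = []
    if chain.label is not None:
        parts.append(chain.label.prefix_code)
    parts.append(_LINKAGE_PREFIX[chain.linkage])
    parts.append(f"{chain.carbons}:{chain.double_bonds}")
    omega_implied = chain.label.omega_implied if chain.label is not None else None
    if include_omega and chain.omega is not None and chain.omega != omega_implied:
        parts.append(f"(n{MINUS}{chain.omega})")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Classes, adducts, species
# ---------------------------------------------------------------------------

class ClassRegistry:
    """Lipid class backbones, chain counts and adduct definitions."""

    def __init__(self, classes: dict, adducts: dict):
        self._classes = classes
        self._adducts = adducts

    @classmethod
    def from_yaml(cls, path) -> "ClassRegistry":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(doc["classes"], doc["adducts"])

    @property
    def class_names(self) -> list[str]:
        return list(self._classes)

    @property
    def adduct_names(self) -> list[str]:
        return list(self._adducts)

    def _cls(self, name: str) -> dict:
        try:
            return self._classes[name]
        except KeyError:
            # ether variants share the base-class backbone
            base = name.split(" ")[0]
            if base in self._classes:
                return self._classes[base]
            raise RegistryError(f"unregistered lipid class {name!r}") from None

    def chain_count(self, name: str) -> int:
        return int(self._cls(name)["chains"])

    def backbone_composition(self, name: str) -> dict[str, int]:
        return dict(_pmass.Composition(formula=self._cls(name)["backbone"]))

    def default_adducts(self, name: str) -> list[str]:
        return list(self._cls(name)["adducts"])

    def adduct(self, name: str) -> tuple[dict[str, int], int]:
        try:
            spec = self._adducts[name]
        except KeyError:
            raise RegistryError(f"unregistered adduct {name!r}") from None
        return dict(spec["composition"]), int(spec["charge"])


@lru_cache(maxsize=1)
def default_class_registry() -> ClassRegistry:
    with resources.as_file(resources.files("omegamap.data") / "classes.yaml") as p:
        return ClassRegistry.from_yaml(p)


@dataclass(frozen=True)
class LipidMolecularSpecies:
    """A lipid at the molecular-species level: class + individual chains.

    ``sn_resolved=True`` means the chain order is the sn-position order and
    is significant; otherwise chains form an unordered multiset.
    """

    lipid_class: str
    chains: tuple[FattyAcyl, ...]
    sn_resolved: bool = False
    adduct: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chains", tuple(self.chains))
        registry = default_class_registry()
        try:
            expected = registry.chain_count(self.lipid_class)
        except RegistryError:
            expected = None  # extensible vocabulary: unknown classes allowed
        if expected is not None and len(self.chains) != expected:
            raise ValueError(
                f"{self.lipid_class} expects {expected} chain(s), got {len(self.chains)}"
            )

    def sorted_chains(self) -> tuple[FattyAcyl, ...]:
        if self.sn_resolved:
            return self.chains
        return tuple(sorted(self.chains, key=FattyAcyl.sort_key))

    def strip_labels(self) -> "LipidMolecularSpecies":
        return replace(self, chains=tuple(c.strip_label() for c in self.chains))

    def strip_omega(self) -> "LipidMolecularSpecies":
        return replace(self, chains=tuple(c.strip_omega() for c in self.chains))

    def as_unordered(self) -> "LipidMolecularSpecies":
        return replace(self, sn_resolved=False)

    @property
    def total_carbons(self) -> int:
        return sum(c.carbons for c in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return sum(c.double_bonds for c in self.chains)

    @property
    def labels(self) -> tuple[SILLabel, ...]:
        return tuple(c.label for c in self.chains if c.label is not None)

    def matching_key(self) -> str:
        """Key used to match species across tables: labels and omega
        positions stripped, chains unordered."""
        return species_key(self.strip_labels().strip_omega().as_unordered(), "molecular")


def parse_species(text: str, sn_resolved: Optional[bool] = None,
                  registry: Optional[LabelRegistry] = None) -> LipidMolecularSpecies:
    """Parse ``"PC 16:0_20:4(n-6)"`` / ``"PI 18:0/20:3(n-9)"`` style strings.

    The separator decides sn-resolution unless ``sn_resolved`` is forced:
    ``/`` means sn-resolved, ``_`` means unordered.
    """
    text = text.strip()
    if " " not in text:
        raise LipidParseError(f"species string {text!r} lacks a class/chains separator")
    cls, chain_part = text.split(" ", 1)
    # class names like "PC O-" are written with the linkage on the chain
    if "/" in chain_part:
        tokens, resolved = chain_part.split("/"), True
    elif "_" in chain_part:
        tokens, resolved = chain_part.split("_"), False
    else:
        tokens, resolved = [chain_part], False
    chains = tuple(parse_chain(t, registry) for t in tokens)
    if sn_resolved is None:
        sn_resolved = resolved
    return LipidMolecularSpecies(cls, chains, sn_resolved=sn_resolved)


def species_key(species: LipidMolecularSpecies,
                level: Literal["sum", "molecular", "sn", "omega"] = "molecular") -> str:
    """Deterministic canonical identifier of a species at a given level.

    * ``sum``       - class + total C:D, e.g. ``"PI 38:3"``
    * ``molecular`` - individual chains; unordered chains are sorted and
      joined with ``_``, sn-resolved chains keep their order with ``/``
    * ``sn``        - like ``molecular`` but requires ``sn_resolved``
    * ``omega``     - like ``molecular`` but requires an omega position on
      every unsaturated chain
    """
    cls = species.lipid_class
    if level == "sum":
        link = ""
        for chain in species.chains:
            if chain.linkage != "acyl":
                link = _LINKAGE_PREFIX[chain.linkage]
                break
        return f"{cls} {link}{species.total_carbons}:{species.total_double_bonds}"
    if level == "sn" and not species.sn_resolved:
        raise ValueError("sn-level key requested for a species without sn resolution")
    if level == "omega":
        missing = [format_chain(c) for c in species.chains
                   if c.double_bonds >= 1 and c.effective_omega is None]
        if missing:
            raise ValueError(f"omega-level key requires omega on unsaturated chains: {missing}")
    sep = "/" if species.sn_resolved else "_"
    chains = species.sorted_chains()
    return f"{cls} " + sep.join(format_chain(c) for c in chains)


# ---------------------------------------------------------------------------
# Masses
# ---------------------------------------------------------------------------

def neutral_composition(species: LipidMolecularSpecies,
                        registry: Optional[ClassRegistry] = None) -> dict[str, int]:
    """Elemental composition of the neutral (uncharged) species."""
    registry = registry or default_class_registry()
    comp = _pmass.Composition(registry.backbone_composition(species.lipid_class))
    for chain in species.chains:
        for el, n in chain.residue_composition().items():
            comp[el] = comp.get(el, 0) + n
    return dict(comp)


def monoisotopic_mass(species: LipidMolecularSpecies, adduct: Optional[str] = None,
                      registry: Optional[ClassRegistry] = None) -> float:
    """Monoisotopic neutral mass, or m/z when an adduct is given.

    Heavy-isotope substitutions from SIL labels are included.  m/z is
    ``(M + adduct delta - z * m_e) / |z|``.
    """
    registry = registry or default_class_registry()
    m = _pmass.calculate_mass(composition=_pmass.Composition(neutral_composition(species, registry)))
    adduct = adduct or species.adduct
    if adduct is None:
        return m
    delta_comp, charge = registry.adduct(adduct)
    delta = _pmass.calculate_mass(composition=_pmass.Composition(delta_comp))
    return (m + delta - charge * _ELECTRON_MASS) / abs(charge)


def mz_matches(observed_mz: float, theoretical_mz: float, tol_ppm: float = 10.0) -> bool:
    """Precursor match within a ppm tolerance (default 10 ppm)."""
    return abs(observed_mz - theoretical_mz) / theoretical_mz * 1e6 <= tol_ppm
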