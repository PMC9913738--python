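"""Chemistry core for high-resolution shotgun lipidomics.

Sum-composition grammar (``PC(38:6)``, ``SM(36:1:2)``), elemental-composition
arithmetic, monoisotopic adduct m/z values, fine isotope envelopes and the
Orbitrap-style resolution model.  Every downstream stage (simulation,
identification, correction, quantification) consumes this module.

Lipid species are annotated at the sum-composition level: a class name plus the
total number of chain carbons, total double bonds and, for sphingolipids, total
hydroxyl groups.  Isomeric pairs that direct-infusion MS1 cannot distinguish are
merged into one registry entry: alkyl-acyl ``PC-O(x:y)`` together with
alkenyl-acyl ``PC-P(x:y-1)`` (same for PE), and PG together with BMP.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterator, Mapping

import yaml

__all__ = [
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
    "ElementalComposition",
    "AdductType",
    "ADDUCTS",
    "LipidClassDef",
    "LipidSpecies",
    "LipidRegistry",
    "default_registry",
    "parse_sum_formula",
    "composition_of",
    "adduct_mz",
    "isotope_distribution",
    "monoisotopic_fraction",
    "isotopologue_fractions",
    "resolution_at",
    "fwhm_at",
]

# Monoisotopic atomic masses (Da), embedded so results are bit-stable.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740,
    "O": 15.9949146,
    "P": 30.9737615,
    "S": 31.97207069,
    "Na": 22.9897693,
    "Cl": 34.9688527,
}
ELECTRON_MASS = 0.0005486

_ELEMENTS = ("C", "H", "N", "O", "P", "S", "Na", "Cl")

# Natural heavy-isotope parameters.  Only 13C is modelled for all compositions;
# 37Cl is added for chlorine-containing ions (chloride adducts).  The
# monoisotopic peak of a chloride adduct uses 35Cl; the 37Cl isotopologue is
# carried in the envelope.
C13_ABUNDANCE = 0.0107
C12_ABUNDANCE = 1.0 - C13_ABUNDANCE
C13_SHIFT = 1.0033548378
CL37_ABUNDANCE = 0.2424
CL35_ABUNDANCE = 1.0 - CL37_ABUNDANCE
CL37_SHIFT = 1.99704991

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_LABEL_RE = re.compile(
    r"^\s*([A-Za-z][A-Za-z0-9/\-]*?)\s*\(\s*(\d+)\s*:\s*(\d+)\s*(?::\s*(\d+)\s*)?\)\s*$"
)


class ImpossibleSpeciesError(ValueError):
    """Raised when composition arithmetic would yield a negative element count."""


@dataclass(frozen=True)
class ElementalComposition:
    """Element counts of a neutral molecule or ion skeleton.

    Addition and subtraction are element-wise; subtraction raises
    :class:`ImpossibleSpeciesError` if any count would become negative.
    """

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "ElementalComposition":
        items = []
        for el in _ELEMENTS:
            n = int(d.get(el, 0))
            if n < 0:
                raise ImpossibleSpeciesError(f"negative count for {el}: {n}")
            if n:
                items.append((el, n))
        for el in d:
            if el not in _ELEMENTS:
                raise ValueError(f"unsupported element {el!r}")
        return cls(tuple(items))

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula such as ``C42H80NO8P``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            if not m.group(1):
                break
            el, n = m.group(1), int(m.group(2) or 1)
            counts[el] = counts.get(el, 0) + n
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls.from_dict(counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, el: str) -> int:
        return dict(self.counts).get(el, 0)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return ElementalComposition.from_dict(d)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) - n
            if d[el] < 0:
                raise ImpossibleSpeciesError(
                    f"subtraction yields negative {el} count"
                )
        return ElementalComposition.from_dict(d)

    def shifted(self, delta: Mapping[str, int]) -> "ElementalComposition":
        """Apply a signed element delta (used for adduct ions)."""
        d = self.as_dict()
        for el, n in delta.items():
            d[el] = d.get(el, 0) + n
            if d[el] < 0:
                raise ImpossibleSpeciesError(
                    f"adduct delta yields negative {el} count"
                )
        return ElementalComposition.from_dict(d)

    @property
    def monoisotopic_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts)

    @property
    def is_empty(self) -> bool:
        return not self.counts

    def formula(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in self.counts
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.formula()


@dataclass(frozen=True)
class AdductType:
    """An ionized form of a neutral lipid.

    ``mz = (monoisotopic mass + delta mass - charge * electron mass) / |charge|``
    where the delta mass is the signed sum over the element delta.
    """

    name: str
    charge: int
    delta: tuple[tuple[str, int], ...]

    @property
    def delta_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.delta)

    @property
    def polarity(self) -> str:
        return "+" if self.charge > 0 else "-"

    def mz(self, neutral_mass: float) -> float:
        return (
            neutral_mass + self.delta_mass - self.charge * ELECTRON_MASS
        ) / abs(self.charge)

    def ion_composition(self, neutral: ElementalComposition) -> ElementalComposition:
        return neutral.shifted(dict(self.delta))


ADDUCTS: dict[str, AdductType] = {
    a.name: a
    for a in (
        AdductType("[M-H]-", -1, (("H", -1),)),
        AdductType("[M-2H]2-", -2, (("H", -2),)),
        AdductType("[M+Cl]-", -1, (("Cl", 1),)),
        AdductType("[M+H]+", 1, (("H", 1),)),
        AdductType("[M+Na]+", 1, (("Na", 1),)),
        AdductType("[M+NH4]+", 1, (("N", 1), ("H", 4))),
    )
}

_CH2 = ElementalComposition.from_dict({"C": 1, "H": 2})
_H2 = ElementalComposition.from_dict({"H": 2})
_O = ElementalComposition.from_dict({"O": 1})


@dataclass(frozen=True)
class LipidClassDef:
    """One lipid class: backbone chemistry plus acquisition routing and grids."""

    name: str
    backbone: ElementalComposition
    chains: int
    sphingoid: bool
    quant_polarity: str
    quant_adduct: str
    extra_adducts: tuple[tuple[str, str], ...]  # (adduct name, polarity)
    c_range: tuple[int, int]
    c_step: int
    db_range: tuple[int, int]
    oh_values: tuple[int, ...]
    membrane: bool
    db_step: int = 1

    def adduct_polarities(self) -> dict[str, str]:
        """All detectable adducts of the class, mapped to their polarity."""
        out = {self.quant_adduct: self.quant_polarity}
        out.update(dict(self.extra_adducts))
        return out


@dataclass(frozen=True)
class LipidSpecies:
    """A sum-composition annotation: class, total C, total DB (and OH)."""

    class_name: str
    c: int
    db: int
    oh: int = 0

    @property
    def label(self) -> str:
        if self.oh:
            return f"{self.class_name}({self.c}:{self.db}:{self.oh})"
        return f"{self.class_name}({self.c}:{self.db})"

    def __str__(self) -> str:
        return self.label


# Input aliases for the merged isomeric entries.  PC-P(x:y) is isomeric with
# PC-O(x:y+1) (one vinyl-ether double bond is implicit in the -P notation);
# PE-O(x:y) is isomeric with PE-P(x:y-1); PG and BMP are collective.
_ALIASES: dict[str, tuple[str, int]] = {
    "PC-P": ("PC-O", +1),
    "PE-O": ("PE-P", -1),
    "PG": ("PG/BMP", 0),
    "BMP": ("PG/BMP", 0),
}


class LipidRegistry:
    """The set of known lipid classes, loaded from an editable YAML config."""

    def __init__(self, classes: dict[str, LipidClassDef]):
        self.classes = classes
        self._comp_cache: dict[str, ElementalComposition] = {}

    # -- construction ---------------------------------------------------
    @classmethod
    def from_yaml(cls, path=None) -> "LipidRegistry":
        if path is None:
            text = (
                resources.files("lmdlipidomics.data")
                .joinpath("lipid_classes.yaml")
                .read_text()
            )
            raw = yaml.safe_load(text)
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        classes = {}
        for name, c in raw["classes"].items():
            classes[name] = LipidClassDef(
                name=name,
                backbone=ElementalComposition.from_formula(str(c["backbone"])),
                chains=int(c["chains"]),
                sphingoid=bool(c["sphingoid"]),
                quant_polarity=str(c["quant_polarity"]),
                quant_adduct=str(c["quant_adduct"]),
                extra_adducts=tuple(dict(c.get("extra_adducts") or {}).items()),
                c_range=tuple(c["c_range"]),
                c_step=int(c.get("c_step", 1)),
                db_range=tuple(c["db_range"]),
                db_step=int(c.get("db_step", 1)),
                oh_values=tuple(c.get("oh_values", (0,))),
                membrane=bool(c["membrane"]),
            )
        return cls(classes)

    # -- grammar --------------------------------------------------------
    def parse(self, label: str) -> LipidSpecies:
        m = _LABEL_RE.match(label)
        if not m:
            raise ValueError(f"cannot parse lipid label {label!r}")
        name, c, db = m.group(1), int(m.group(2)), int(m.group(3))
        oh = int(m.group(4)) if m.group(4) is not None else None
        db_shift = 0
        if name in _ALIASES:
            name, db_shift = _ALIASES[name]
        if name not in self.classes:
            raise ValueError(f"unknown lipid class {m.group(1)!r}")
        cls = self.classes[name]
        if cls.sphingoid:
            if oh is None:
                raise ValueError(
                    f"sphingolipid class {name} requires a (C:DB:OH) label"
                )
        else:
            if oh is not None:
                raise ValueError(
                    f"glycerolipid class {name} takes a (C:DB) label"
                )
            oh = 0
        db += db_shift
        if db < 0:
            raise ValueError(f"negative double-bond count after {m.group(1)} aliasing")
        if c < 2:
            raise ValueError(f"total carbon number must be >= 2, got {c}")
        return LipidSpecies(name, c, db, oh)

    def composition_of(self, species: LipidSpecies | str) -> ElementalComposition:
        if isinstance(species, str):
            species = self.parse(species)
        key = species.label
        hit = self._comp_cache.get(key)
        if hit is not None:
            return hit
        cls = self.classes[species.class_name]
        comp = cls.backbone
        comp = comp + ElementalComposition.from_dict(
            {"C": species.c, "H": 2 * species.c}
        )
        try:
            comp = comp - ElementalComposition.from_dict({"H": 2 * species.db})
        except ImpossibleSpeciesError as err:
            raise ImpossibleSpeciesError(
                f"{species.label}: {err}"
            ) from err
        if species.oh:
            comp = comp + ElementalComposition.from_dict({"O": species.oh})
        self._comp_cache[key] = comp
        return comp

    def class_of(self, species: LipidSpecies | str) -> LipidClassDef:
        if isinstance(species, str):
            species = self.parse(species)
        return self.classes[species.class_name]

    def adduct_mz(self, species: LipidSpecies | str, adduct: AdductType | str) -> float:
        if isinstance(species, str):
            species = self.parse(species)
        if isinstance(adduct, str):
            adduct = ADDUCTS[adduct]
        cls = self.classes[species.class_name]
        if adduct.name not in cls.adduct_polarities():
            raise ValueError(
                f"adduct {adduct.name} not admissible for class {cls.name}"
            )
        return adduct.mz(self.composition_of(species).monoisotopic_mass)

    def grid_species(self, class_name: str) -> Iterator[LipidSpecies]:
        """All species on the class's realistic C/DB(/OH) grid (DB <= C//3)."""
        cls = self.classes[class_name]
        for c in range(cls.c_range[0], cls.c_range[1] + 1, cls.c_step):
            for db in range(cls.db_range[0], cls.db_range[1] + 1, cls.db_step):
                if db > c // 3:
                    continue
                for oh in cls.oh_values:
                    yield LipidSpecies(class_name, c, db, oh)

    @property
    def membrane_classes(self) -> list[str]:
        return [n for n, c in self.classes.items() if c.membrane]


@lru_cache(maxsize=1)
def default_registry() -> LipidRegistry:
    return LipidRegistry.from_yaml()


def positive_pc_registry(registry: LipidRegistry | None = None) -> LipidRegistry:
    """Registry variant quantifying choline glycerophospholipids in positive mode.

    PC-type classes (those forming sodiated adducts) switch their
    quantification to [M+H]+ in positive mode -- the configuration in which
    the sodiated-adduct isobaric overlap directly biases quantities and the
    overlap correction matters.  The chloride adduct stays as a detectable
    negative-mode ion so it can serve as the interference-free reference
    profile.
    """
    import dataclasses

    registry = registry or default_registry()
    classes = dict(registry.classes)
    for name, cls in registry.classes.items():
        extras = dict(cls.extra_adducts)
        if "[M+Na]+" not in extras:
            continue
        extras.pop("[M+H]+", None)
        extras[cls.quant_adduct] = cls.quant_polarity
        classes[name] = dataclasses.replace(
            cls,
            quant_polarity="+",
            quant_adduct="[M+H]+",
            extra_adducts=tuple(extras.items()),
        )
    return LipidRegistry(classes)


# -- module-level convenience wrappers ---------------------------------------

def parse_sum_formula(label: str, registry: LipidRegistry | None = None) -> LipidSpecies:
    """Parse a sum-composition label, e.g. ``PC(38:6)`` or ``SM(36:1:2)``."""
    return (registry or default_registry()).parse(label)


def composition_of(
    species: LipidSpecies | str, registry: LipidRegistry | None = None
) -> ElementalComposition:
    return (registry or default_registry()).composition_of(species)


def adduct_mz(
    species: LipidSpecies | str,
    adduct: AdductType | str,
    registry: LipidRegistry | None = None,
) -> float:
    return (registry or default_registry()).adduct_mz(species, adduct)


# -- isotope envelopes -------------------------------------------------------

def isotope_distribution(
    composition: ElementalComposition, n_peaks: int = 4
) -> list[tuple[float, float]]:
    """Fine isotope envelope relative to the monoisotopic peak.

    Returns ``[(mass offset, abundance relative to A0), ...]`` for neutron
    numbers 0 .. n_peaks-1.  Only 13C (all compositions) and 37Cl (chlorine
    present) are modelled; other elements' heavy isotopes are negligible at
    the envelope precision the corrections need.  Mixed isotopologues falling
    on the same neutron number are aggregated with an abundance-weighted mean
    mass offset.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if composition.is_empty:
        raise ValueError("empty composition has no isotope envelope")
    n_c = composition["C"]
    n_cl = composition["Cl"]
    if n_c == 0 and n_cl == 0:
        return [(0.0, 1.0)]
    r_c = C13_ABUNDANCE / C12_ABUNDANCE
    r_cl = CL37_ABUNDANCE / CL35_ABUNDANCE
    acc: dict[int, tuple[float, float]] = {}
    for i in range(0, min(n_c, n_peaks - 1) + 1):
        for j in range(0, min(n_cl, (n_peaks - 1) // 2) + 1):
            k = i + 2 * j
            if k >= n_peaks:
                continue
            ab = math.comb(n_c, i) * r_c**i * math.comb(n_cl, j) * r_cl**j
            off = i * C13_SHIFT + j * CL37_SHIFT
            s_ab, s_off = acc.get(k, (0.0, 0.0))
            acc[k] = (s_ab + ab, s_off + ab * off)
    out = []
    for k in sorted(acc):
        ab, w_off = acc[k]
        out.append((w_off / ab if ab else 0.0, ab))
    return out


def monoisotopic_fraction(composition: ElementalComposition) -> float:
    """Fraction of a species' total signal carried by its monoisotopic peak."""
    return C12_ABUNDANCE ** composition["C"] * CL35_ABUNDANCE ** composition["Cl"]


def isotopologue_fractions(
    composition: ElementalComposition, n_peaks: int = 4
) -> list[tuple[float, float]]:
    """Envelope as fractions of the species' *total* signal (A0 fraction first)."""
    f0 = monoisotopic_fraction(composition)
    return [(off, ab * f0) for off, ab in isotope_distribution(composition, n_peaks)]


# -- resolution model --------------------------------------------------------

def resolution_at(mz: float, resolution_at_200: float = 240000.0) -> float:
    """Orbitrap-style resolving power, R proportional to 1/sqrt(m/z)."""
    return resolution_at_200 * math.sqrt(200.0 / mz)


def fwhm_at(mz: float, resolution_at_200: float = 240000.0) -> float:
    """Peak full width at half maximum implied by the resolution model."""
    return mz / resolution_at(mz, resolution_at_200)
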