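"""Synthetic laser-microdissection shotgun-lipidomics data.

Generates ground-truth regional lipidomes, LMD spot geometries and realistic
polarity-switched centroid peak lists, so that identification, correction,
quantification, QC and clustering can be exercised without instrument data.

What is emulated
----------------
* LMD spots of 5,000-160,000 um^2 cut from 10 um cryosections; wet weight is
  area x thickness x tissue density (1 g/cm^3 by default, which reproduces the
  0.3 ug weight of a 30,000 um^2 spot and the 490 ug weight of a 7x7 mm
  section).
* Class-structured lipidomes with log-normal species abundances, spiked
  per-class internal standards, full fine isotope envelopes, class-routed
  adducts ([M-H]-/[M-2H]2-/[M+Cl]-/[M+H]+/[M+Na]+/[M+NH4]+), Gaussian ppm mass
  error, multiplicative log-normal intensity noise, a detection floor, and
  centroid coalescence below the resolution limit (R = 240,000 at m/z 200 with
  R ~ 1/sqrt(m/z) scaling) -- the coalescence is what makes the sodiated-PC
  isobaric overlap and the type-II isotope overlap real in the spectra.
* An optional laser-ablation degradation channel that moves a fraction delta of
  each diacyl glycerophospholipid into the matching lyso species and PA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .lipids import (
    ADDUCTS,
    LipidRegistry,
    LipidSpecies,
    default_registry,
    fwhm_at,
    isotopologue_fractions,
)

__all__ = [
    "SpotSpec",
    "RegionProfile",
    "StandardSet",
    "AcquisitionSpec",
    "PeakList",
    "ROISpec",
    "SimulatedSpot",
    "spot_wet_weight",
    "cells_equivalent",
    "make_lipidome",
    "make_cell_culture_lipidome",
    "make_region_profiles",
    "simulate_spot",
    "simulate_area_series",
    "simulate_regions",
    "default_hippocampus_plan",
    "DEFAULT_AREA_SERIES",
    "write_dataset",
    "read_peaklist_tsv",
]

# Diacyl glycerophospholipid -> lyso class produced by the laser-ablation
# degradation channel (the other product is PA with the parent's C:DB).
_DEGRADATION_LYSO = {
    "PC": "LPC",
    "PE": "LPE",
    "PI": "LPI",
    "PS": "LPS",
    "PG/BMP": "LPG",
}

DEFAULT_AREA_SERIES = (5_000.0, 10_000.0, 20_000.0, 40_000.0, 80_000.0, 160_000.0)

# Liver-like membrane class weights (fractions of the membrane total) plus
# storage classes expressed relative to the membrane total.
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "PC": 0.30,
    "PC-O": 0.03,
    "PE": 0.22,
    "PE-P": 0.05,
    "PI": 0.09,
    "PS": 0.05,
    "PA": 0.010,
    "PG/BMP": 0.015,
    "CL": 0.05,
    "LPC": 0.006,
    "LPE": 0.004,
    "LPI": 0.002,
    "LPS": 0.002,
    "LPG": 0.001,
    "LCL": 0.001,
    "Cer": 0.012,
    "HexCer": 0.010,
    "GM3": 0.004,
    "Sulf": 0.006,
    "SM": 0.060,
    "DG": 0.04,
    "TG": 0.25,
    "CE": 0.03,
}

CELL_CULTURE_CLASS_WEIGHTS: dict[str, float] = {
    "PC": 0.44,
    "PC-O": 0.03,
    "PE": 0.18,
    "PE-P": 0.04,
    "PI": 0.10,
    "PS": 0.06,
    "PA": 0.012,
    "PG/BMP": 0.012,
    "CL": 0.035,
    "LPC": 0.006,
    "LPE": 0.004,
    "Cer": 0.010,
    "HexCer": 0.006,
    "GM3": 0.004,
    "SM": 0.075,
    "DG": 0.02,
    "TG": 0.08,
    "CE": 0.02,
}


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpotSpec:
    """Geometry of one laser-microdissected spot.

    density defaults to 1e-6 ug/um^3 (1 g/cm^3), the implicit convention that
    reproduces the printed wet weights of both a 30,000 um^2 spot (0.3 ug) and
    a full 7x7 mm section (490 ug).
    """

    area_um2: float
    thickness_um: float = 10.0
    region: str = ""
    replicate: int = 0
    density_ug_per_um3: float = 1e-6

    def __post_init__(self):
        if self.area_um2 <= 0:
            raise ValueError("spot area must be positive")
        if self.thickness_um <= 0:
            raise ValueError("section thickness must be positive")
        if self.density_ug_per_um3 <= 0:
            raise ValueError("tissue density must be positive")

    @property
    def wet_weight_ug(self) -> float:
        return self.area_um2 * self.thickness_um * self.density_ug_per_um3


def spot_wet_weight(spot: SpotSpec) -> float:
    """Wet weight of a dissected spot in ug (area x thickness x density)."""
    return spot.wet_weight_ug


def cells_equivalent(
    area_um2: float, thickness_um: float, cell_volume_um3: float = 4000.0
) -> float:
    """Dissected volume expressed as typical mammalian cell equivalents."""
    if area_um2 <= 0 or thickness_um <= 0 or cell_volume_um3 <= 0:
        raise ValueError("area, thickness and cell volume must be positive")
    return area_um2 * thickness_um / cell_volume_um3


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionProfile:
    """Ground-truth regional lipidome: pmol of each species per ug wet weight."""

    region: str
    concentrations: Mapping[str, float]  # species label -> pmol/ug ww

    def __post_init__(self):
        for label, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {label}")

    def scaled(self, factors: Mapping[str, float], region: str | None = None) -> "RegionProfile":
        return RegionProfile(
            region if region is not None else self.region,
            {s: c * factors.get(s, 1.0) for s, c in self.concentrations.items()},
        )


@dataclass(frozen=True)
class StandardSet:
    """One internal standard per class: (species label, spiked pmol)."""

    entries: Mapping[str, tuple[str, float]]  # class -> (label, pmol)

    def __post_init__(self):
        seen = {}
        for cls, (label, pmol) in self.entries.items():
            if pmol <= 0:
                raise ValueError(f"standard amount for {cls} must be positive")
            if cls in seen:
                raise ValueError(f"duplicate standard for class {cls}")
            seen[cls] = label

    @classmethod
    def default(cls) -> "StandardSet":
        text = (
            resources.files("lmdlipidomics.data")
            .joinpath("standards.yaml")
            .read_text()
        )
        raw = yaml.safe_load(text)["standards"]
        return cls({k: (v["species"], float(v["pmol"])) for k, v in raw.items()})

    @classmethod
    def from_yaml(cls, path) -> "StandardSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)["standards"]
        return cls({k: (v["species"], float(v["pmol"])) for k, v in raw.items()})

    def labels(self) -> list[str]:
        return [label for label, _ in self.entries.values()]

    def for_class(self, class_name: str) -> tuple[str, float] | None:
        return self.entries.get(class_name)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Instrument/acquisition model parameters.

    ppm_sd            Gaussian mass-error SD in ppm (sub-ppm calibration).
    intensity_cv      multiplicative log-normal intensity noise, as a CV.
    f_na              sodiated/protonated adduct ratio of choline lipids.
    f_cl              chloride-adduct ionization fraction in negative mode.
    noise_floor       centroids below this absolute intensity are dropped.
    mass_range        acquisition window in m/z.
    degradation       fraction of each diacyl glycerophospholipid converted to
                      lyso + PA by laser ablation (delta).
    intensity_per_pmol  arbitrary response scale (counts per pmol at factor 1).
    resolution_at_200 resolving power at m/z 200 (R ~ 1/sqrt(m/z)).
    n_iso_peaks       isotopologue peaks simulated per ion.
    """

    ppm_sd: float = 0.5
    intensity_cv: float = 0.05
    f_na: float = 0.10
    f_cl: float = 0.50
    noise_floor: float = 20.0
    mass_range: tuple[float, float] = (400.0, 1300.0)
    degradation: float = 0.0
    intensity_per_pmol: float = 1e4
    resolution_at_200: float = 240000.0
    n_iso_peaks: int = 4
    response_factors: Mapping[str, float] | None = None
    seed: int | None = None

    def __post_init__(self):
        for name in ("f_na", "f_cl", "degradation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mass_range[0] >= self.mass_range[1]:
            raise ValueError("mass range low must be below high")

    def response(self, class_name: str) -> float:
        if self.response_factors is None:
            return 1.0
        return float(self.response_factors.get(class_name, 1.0))


# ---------------------------------------------------------------------------
# peak lists
# ---------------------------------------------------------------------------

@dataclass
class PeakList:
    """Centroided (m/z, intensity) pairs for one sample and polarity."""

    polarity: str
    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.polarity not in ("+", "-"):
            raise ValueError("polarity must be '+' or '-'")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(self.intensity <= 0):
            raise ValueError("all intensities must be positive")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.mz)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"mz": self.mz, "intensity": self.intensity}).to_csv(
            path, sep="\t", index=False
        )


def read_peaklist_tsv(path, polarity: str, sample_id: str = "") -> PeakList:
    """Read a two-column (mz, intensity) TSV centroid list."""
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("mz")
    return PeakList(polarity, df["mz"].to_numpy(), df["intensity"].to_numpy(), sample_id)


def read_peaklist_mzml(path, polarity: str, sample_id: str = "") -> PeakList:
    """Read the first centroid spectrum from an mzML file (requires pyteomics)."""
    from pyteomics import mzml  # optional dependency

    with mzml.read(str(path)) as reader:
        spectrum = next(iter(reader))
    order = np.argsort(spectrum["m/z array"])
    return PeakList(
        polarity,
        spectrum["m/z array"][order],
        spectrum["intensity array"][order],
        sample_id,
    )


@dataclass(frozen=True)
class ROISpec:
    """A region of interest marked for dissection."""

    roi_id: int
    region: str
    area_um2: float
    centroid: tuple[float, float] = (0.0, 0.0)
    polygon: tuple[tuple[float, float], ...] | None = None


@dataclass
class SimulatedSpot:
    """One simulated LMD spot: peak-list pair plus the generating ground truth."""

    spot: SpotSpec
    sample_id: str
    negative: PeakList
    positive: PeakList
    true_pmol: dict[str, float]
    standards: StandardSet
    roi: ROISpec | None = None

    def __iter__(self) -> Iterator[PeakList]:
        # allows ``neg, pos = simulate_spot(...)``
        yield self.negative
        yield self.positive


# ---------------------------------------------------------------------------
# lipidome generation
# ---------------------------------------------------------------------------

def make_lipidome(
    class_weights: Mapping[str, float] | None = None,
    species_per_class: int | Mapping[str, int] = 8,
    seed: int = 0,
    total_membrane_conc: float = 20.0,
    conc_sigma: float = 1.0,
    region: str = "tissue",
    registry: LipidRegistry | None = None,
) -> RegionProfile:
    """Draw a ground-truth lipidome on the per-class C/DB grids.

    ``total_membrane_conc`` is the summed membrane-lipid concentration in
    pmol/ug wet weight (20 pmol/ug = 20 nmol/mg, a liver-scale value).
    Species identity depends only on ``seed`` and ``species_per_class``, so
    two profiles drawn with the same seed but different class weights share
    their species and differ exactly in the direction of the weights.
    Storage-lipid weights (DG/TG/CE) are interpreted relative to the membrane
    total and do not enter the membrane normalization.
    """
    registry = registry or default_registry()
    weights = dict(class_weights if class_weights is not None else DEFAULT_CLASS_WEIGHTS)
    if not weights:
        raise ValueError("class_weights must not be empty")
    for name, w in weights.items():
        if name not in registry.classes:
            raise ValueError(f"unknown class in weights: {name}")
        if w < 0:
            raise ValueError(f"negative weight for class {name}")
    membrane_w = sum(w for n, w in weights.items() if registry.classes[n].membrane)
    if membrane_w <= 0:
        raise ValueError("at least one membrane class must have positive weight")

    rng = np.random.default_rng(seed)
    concentrations: dict[str, float] = {}
    for name in registry.classes:  # registry order: deterministic
        if name not in weights:
            continue
        grid = list(registry.grid_species(name))
        n_req = (
            species_per_class.get(name, 8)
            if isinstance(species_per_class, Mapping)
            else species_per_class
        )
        k = min(int(n_req), len(grid))
        idx = sorted(rng.choice(len(grid), size=k, replace=False))
        factors = rng.lognormal(mean=0.0, sigma=conc_sigma, size=k)
        if k == 0:
            continue
        factors /= factors.sum()
        if registry.classes[name].membrane:
            class_conc = weights[name] / membrane_w * total_membrane_conc
        else:
            class_conc = weights[name] * total_membrane_conc
        for i, f in zip(idx, factors):
            concentrations[grid[i].label] = class_conc * f
    return RegionProfile(region, concentrations)


def make_cell_culture_lipidome(
    per_cell_pmol: float = 0.06,
    cell_volume_um3: float = 4000.0,
    density_ug_per_um3: float = 1e-6,
    seed: int = 0,
    **kwargs,
) -> RegionProfile:
    """Cell-monolayer ground truth stated per cell.

    The per-cell membrane content is converted to pmol/ug through the typical
    mammalian cell volume (4000 um^3), so a 5000 um^2 spot from a 10 um
    "section" of confluent monolayer (~10 cells) holds below 1 pmol of
    membrane lipid with the defaults.
    """
    total = per_cell_pmol / (cell_volume_um3 * density_ug_per_um3)
    kwargs.setdefault("class_weights", CELL_CULTURE_CLASS_WEIGHTS)
    kwargs.setdefault("region", "cell_culture")
    return make_lipidome(
        seed=seed, total_membrane_conc=total, **kwargs
    )


def make_region_profiles(
    regions: Sequence[str],
    seed: int = 0,
    divergence: float = 0.5,
    base_profile: RegionProfile | None = None,
    registry: LipidRegistry | None = None,
    **make_kwargs,
) -> dict[str, RegionProfile]:
    """Derive per-region profiles from one shared species set.

    Each region multiplies every species concentration of the base profile by
    an independent log-normal factor (sigma = ``divergence``), giving regions
    that share a lipidome backbone but differ in composition -- the structure
    hierarchical clustering is expected to recover.
    """
    base = base_profile or make_lipidome(seed=seed, registry=registry, **make_kwargs)
    out = {}
    for i, region in enumerate(regions):
        rng = np.random.default_rng(np.random.SeedSequence((seed, 7919 + i)))
        factors = {
            s: float(rng.lognormal(0.0, divergence)) for s in sorted(base.concentrations)
        }
        out[region] = base.scaled(factors, region=region)
    return out


# ---------------------------------------------------------------------------
# spectrum synthesis
# ---------------------------------------------------------------------------

def _adduct_fractions(cls, acq: AcquisitionSpec) -> dict[str, float]:
    """Ionization fraction of each detectable adduct of a class."""
    fractions = {
        cls.quant_adduct: acq.f_cl if cls.quant_adduct == "[M+Cl]-" else 1.0
    }
    for adduct, _pol in cls.extra_adducts:
        if adduct == "[M+H]+":
            fractions[adduct] = 1.0
        elif adduct == "[M+Na]+":
            fractions[adduct] = acq.f_na
        elif adduct == "[M+Cl]-":
            fractions[adduct] = acq.f_cl
        else:
            fractions[adduct] = 0.1
    return fractions


def _apply_degradation(
    amounts: dict[str, float], delta: float, registry: LipidRegistry
) -> dict[str, float]:
    """Move a fraction delta of each diacyl glycerophospholipid to lyso + PA.

    Half the degraded amount appears as the lyso species with round(C/2)
    carbons and DB//2 double bonds, half as PA with the parent's C:DB; total
    pmol is conserved.
    """
    if delta == 0.0:
        return dict(amounts)
    out = dict(amounts)
    for label in sorted(amounts):
        sp = registry.parse(label)
        lyso_cls = _DEGRADATION_LYSO.get(sp.class_name)
        if lyso_cls is None:
            continue
        moved = delta * amounts[label]
        if moved == 0.0:
            continue
        out[label] = out[label] - moved
        lyso = LipidSpecies(lyso_cls, round(sp.c / 2), sp.db // 2)
        pa = LipidSpecies("PA", sp.c, sp.db)
        out[lyso.label] = out.get(lyso.label, 0.0) + moved / 2.0
        out[pa.label] = out.get(pa.label, 0.0) + moved / 2.0
    return out


def _cluster_apexes(
    c_mz: np.ndarray, c_int: np.ndarray, sigma: float
) -> tuple[list[float], list[float]]:
    """Peak-pick a group of overlapping profile peaks.

    The group is modelled as a mixture of Gaussians of common width; each local
    maximum of the mixture becomes one centroid at the apex position, carrying
    the summed area of the component peaks nearest to it.  This mirrors how a
    profile-mode peak picker reports partially coalesced ions: a dominated
    neighbour shifts the apex slightly, near-equal neighbours within ~2 sigma
    collapse to a single centroid between them.
    """
    lo, hi = c_mz.min() - 3 * sigma, c_mz.max() + 3 * sigma
    grid = np.linspace(lo, hi, max(200, int((hi - lo) / (sigma / 50.0))))
    mix = (c_int[None, :] * np.exp(-((grid[:, None] - c_mz[None, :]) ** 2) / (2 * sigma**2))).sum(axis=1)
    interior = (mix[1:-1] >= mix[:-2]) & (mix[1:-1] > mix[2:])
    apexes = grid[1:-1][interior]
    if len(apexes) == 0:  # numerically flat; fall back to weighted mean
        return [float(np.dot(c_mz, c_int) / c_int.sum())], [float(c_int.sum())]
    nearest = np.argmin(np.abs(c_mz[:, None] - apexes[None, :]), axis=1)
    out_mz, out_int = [], []
    for k in range(len(apexes)):
        members = nearest == k
        if members.any():
            out_mz.append(float(apexes[k]))
            out_int.append(float(c_int[members].sum()))
    return out_mz, out_int


def _merge_centroids(
    mz: np.ndarray, intensity: np.ndarray, resolution_at_200: float
) -> tuple[np.ndarray, np.ndarray]:
    """Coalesce centroids below the resolution limit, as the detector would.

    Greedy chaining over the sorted list: a peak joins the current cluster when
    its gap to the previous peak is below the FWHM at that m/z; each cluster is
    then peak-picked by :func:`_cluster_apexes`.
    """
    if len(mz) == 0:
        return mz, intensity
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    out_mz: list[float] = []
    out_int: list[float] = []

    def flush(c_mz, c_int):
        if len(c_mz) == 1:
            out_mz.append(c_mz[0])
            out_int.append(c_int[0])
        else:
            center = float(np.mean(c_mz))
            sigma = fwhm_at(center, resolution_at_200) / 2.3548
            a_mz, a_int = _cluster_apexes(np.asarray(c_mz), np.asarray(c_int), sigma)
            out_mz.extend(a_mz)
            out_int.extend(a_int)

    c_mz = [mz[0]]
    c_int = [intensity[0]]
    for m, i in zip(mz[1:], intensity[1:]):
        if m - c_mz[-1] < fwhm_at(m, resolution_at_200):
            c_mz.append(m)
            c_int.append(i)
        else:
            flush(c_mz, c_int)
            c_mz, c_int = [m], [i]
    flush(c_mz, c_int)
    order = np.argsort(out_mz, kind="stable")
    return np.asarray(out_mz)[order], np.asarray(out_int)[order]


def simulate_spot(
    profile: RegionProfile,
    spot: SpotSpec,
    standards: StandardSet | None = None,
    acq: AcquisitionSpec | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
    registry: LipidRegistry | None = None,
) -> SimulatedSpot:
    """Simulate the polarity-switched acquisition of one LMD spot.

    Per species, amount = concentration x wet weight; the optional degradation
    channel then reroutes a fraction of each diacyl glycerophospholipid.  Each
    (species, adduct) ion receives amount x response x adduct fraction counts,
    perturbed by mean-preserving log-normal noise, distributed over its fine
    isotope envelope, shifted by a common Gaussian ppm error, coalesced below
    the resolution limit and cut at the noise floor.  Internal standards are
    spiked after the degradation step, as in the wet protocol.
    """
    registry = registry or default_registry()
    standards = standards or StandardSet.default()
    acq = acq or AcquisitionSpec()
    if rng is None:
        rng = np.random.default_rng(acq.seed)
    ww = spot.wet_weight_ug

    amounts = {s: c * ww for s, c in profile.concentrations.items() if c > 0}
    amounts = _apply_degradation(amounts, acq.degradation, registry)
    for cls_name in sorted({registry.parse(s).class_name for s in amounts}):
        if standards.for_class(cls_name) is None:
            raise ValueError(f"no internal standard configured for class {cls_name}")

    truth = dict(amounts)
    spiked = [
        (label, pmol) for _, (label, pmol) in sorted(standards.entries.items())
    ]

    sigma = math.sqrt(math.log1p(acq.intensity_cv**2)) if acq.intensity_cv > 0 else 0.0
    peaks: dict[str, tuple[list[float], list[float]]] = {"-": ([], []), "+": ([], [])}

    for label, amount in list(sorted(amounts.items())) + spiked:
        if amount <= 0:
            continue
        species = registry.parse(label)
        cls = registry.classes[species.class_name]
        neutral = registry.composition_of(species)
        mass = neutral.monoisotopic_mass
        base = amount * acq.response(cls.name) * acq.intensity_per_pmol
        polarities = cls.adduct_polarities()
        for adduct_name, fraction in sorted(_adduct_fractions(cls, acq).items()):
            adduct = ADDUCTS[adduct_name]
            total = base * fraction
            if total <= 0:
                continue
            if sigma > 0:
                total *= math.exp(rng.normal(-sigma**2 / 2.0, sigma))
            ppm = rng.normal(0.0, acq.ppm_sd) if acq.ppm_sd > 0 else 0.0
            ion_comp = adduct.ion_composition(neutral)
            mono_mz = adduct.mz(mass)
            pol = polarities[adduct_name]
            for offset, frac in isotopologue_fractions(ion_comp, acq.n_iso_peaks):
                mz = (mono_mz + offset / abs(adduct.charge)) * (1.0 + ppm * 1e-6)
                peaks[pol][0].append(mz)
                peaks[pol][1].append(total * frac)

    sid = sample_id or f"{profile.region}_r{spot.replicate}"
    lists = {}
    for pol in ("-", "+"):
        mz = np.asarray(peaks[pol][0])
        inten = np.asarray(peaks[pol][1])
        mz, inten = _merge_centroids(mz, inten, acq.resolution_at_200)
        keep = (
            (inten >= acq.noise_floor)
            & (mz >= acq.mass_range[0])
            & (mz <= acq.mass_range[1])
        )
        lists[pol] = PeakList(pol, mz[keep], inten[keep], sid)
    return SimulatedSpot(spot, sid, lists["-"], lists["+"], truth, standards)


def simulate_area_series(
    profile: RegionProfile,
    areas: Sequence[float] | None = None,
    replicates: int = 4,
    standards: StandardSet | None = None,
    acq: AcquisitionSpec | None = None,
    seed: int = 0,
    thickness_um: float = 10.0,
    registry: LipidRegistry | None = None,
) -> list[SimulatedSpot]:
    """One spot pair per (area, replicate), all from the same homogeneous profile."""
    areas = tuple(areas if areas is not None else DEFAULT_AREA_SERIES)
    if any(a <= 0 for a in areas):
        raise ValueError("areas must be positive")
    if list(areas) != sorted(areas):
        raise ValueError("areas must be sorted ascending")
    rng = np.random.default_rng(seed)
    dataset = []
    for area in areas:
        for rep in range(replicates):
            spot = SpotSpec(area, thickness_um, region=profile.region, replicate=rep)
            dataset.append(
                simulate_spot(
                    profile,
                    spot,
                    standards,
                    acq,
                    rng=rng,
                    sample_id=f"A{int(area)}_r{rep}",
                    registry=registry,
                )
            )
    return dataset


def default_hippocampus_plan() -> list[ROISpec]:
    """Eleven ROIs over six anatomically defined hippocampal layers.

    ROIs 1-2 granule cell layer (dentate gyrus), 3-5 stratum pyramidale CA1,
    6 stratum pyramidale CA2, 7 molecular layer, 8 stratum lacunosum-moleculare,
    9-11 stratum radiatum CA1; areas between 50,000 and 130,000 um^2.
    """
    plan = [
        (1, "DG_granule", 80_000, (1200.0, 400.0)),
        (2, "DG_granule", 90_000, (1500.0, 500.0)),
        (3, "CA1_pyramidale", 70_000, (600.0, 1200.0)),
        (4, "CA1_pyramidale", 65_000, (900.0, 1350.0)),
        (5, "CA1_pyramidale", 60_000, (1200.0, 1450.0)),
        (6, "CA2_pyramidale", 50_000, (350.0, 1000.0)),
        (7, "DG_molecular", 130_000, (1400.0, 800.0)),
        (8, "CA1_lacunosum", 75_000, (900.0, 950.0)),
        (9, "CA1_radiatum", 110_000, (600.0, 1500.0)),
        (10, "CA1_radiatum", 120_000, (950.0, 1650.0)),
        (11, "CA1_radiatum", 100_000, (1300.0, 1750.0)),
    ]
    return [ROISpec(i, reg, area, cen) for i, reg, area, cen in plan]


def simulate_regions(
    region_profiles: Mapping[str, RegionProfile],
    roi_plan: Sequence[ROISpec] | None = None,
    replicates: int = 3,
    standards: StandardSet | None = None,
    acq: AcquisitionSpec | None = None,
    seed: int = 0,
    thickness_um: float = 10.0,
    registry: LipidRegistry | None = None,
) -> list[SimulatedSpot]:
    """Simulate an ROI panel; anatomically-same ROIs share a ground-truth profile.

    ``replicates`` emulates dissecting the same ROI from successive sections.
    """
    if len(region_profiles) < 2:
        raise ValueError("need at least two region profiles")
    roi_plan = list(roi_plan if roi_plan is not None else default_hippocampus_plan())
    missing = {r.region for r in roi_plan} - set(region_profiles)
    if missing:
        raise ValueError(f"no profile for regions: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    dataset = []
    for roi in roi_plan:
        profile = region_profiles[roi.region]
        for rep in range(replicates):
            spot = SpotSpec(
                roi.area_um2, thickness_um, region=roi.region, replicate=rep
            )
            sim = simulate_spot(
                profile,
                spot,
                standards,
                acq,
                rng=rng,
                sample_id=f"ROI{roi.roi_id}_s{rep}",
                registry=registry,
            )
            sim.roi = roi
            dataset.append(sim)
    return dataset


# ---------------------------------------------------------------------------
# dataset IO
# ---------------------------------------------------------------------------

def write_dataset(dataset: Iterable[SimulatedSpot], out_dir) -> Path:
    """Write peak-list TSVs plus a sample manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sim in dataset:
        for pol, pl in (("-", sim.negative), ("+", sim.positive)):
            tag = "neg" if pol == "-" else "pos"
            fname = f"{sim.sample_id}_{tag}.tsv"
            pl.to_tsv(out_dir / fname)
            rows.append(
                {
                    "sample_id": sim.sample_id,
                    "polarity": pol,
                    "region": sim.spot.region,
                    "area_um2": sim.spot.area_um2,
                    "thickness_um": sim.spot.thickness_um,
                    "replicate": sim.spot.replicate,
                    "path": fname,
                }
            )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
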