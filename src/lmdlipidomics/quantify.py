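"""Isotopic correction, sodium-adduct overlap correction and quantification.

The correction chain converts raw matched monoisotopic intensities into
species-total intensities that are comparable across carbon numbers and free
of the two systematic isobaric interferences of high-resolution direct
infusion:

type I   every monoisotopic intensity is divided by its envelope's
         monoisotopic fraction (A0 / sum A), recovering the species total.
type II  the two-neutron isotopologue of the (C:DB+1) homolog sits only
         ~0.0089/|z| m/z below the monoisotopic peak of (C:DB); where that
         spacing falls below the instrument FWHM the detector reports one
         centroid, and the predicted contribution is subtracted, cascading
         from the most unsaturated (uncontaminated) species downward.
Na       the sodiated ion of PC(x:y) is isobaric with the protonated ion of
         PC(x+2:y+3) (delta m/z = 0.0024); with an estimated sodiation
         fraction the predicted sodiated contribution is subtracted from the
         heavier species' protonated peak, cascading in ascending mass.

Quantification then compares corrected intensities with the class internal
standard (amount = I / I_std x pmol_std) and expresses results as mol% of
membrane lipids (summed glycerophospho- plus sphingolipids; DG/TG/CE are
excluded from the denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .identify import CandidateIndex, build_candidates, match_peaks
from .lipids import (
    ADDUCTS,
    LipidRegistry,
    default_registry,
    fwhm_at,
    isotopologue_fractions,
    monoisotopic_fraction,
)
from .simulate import PeakList, SimulatedSpot, SpotSpec, StandardSet

__all__ = [
    "isotope_correct",
    "SodiationEstimate",
    "estimate_sodiation",
    "na_overlap_correct",
    "QuantifiedLipidome",
    "quantify_pmol",
    "quantify_dataset",
    "normalize_outputs",
    "process_spot",
    "process_dataset",
    "lipidome_matrix",
    "write_lipidomes",
]

# m/z offset between the monoisotopic peak of (C:DB) and the two-neutron
# isotopologue of (C:DB+1): mass(H2) - 2 x neutron(13C), per charge.
_TYPE2_GAP = 2 * 1.0078250319 - 2 * 1.0033548378


def _ion_fractions(registry, species_label, adduct_name, n_peaks):
    sp = registry.parse(species_label)
    comp = ADDUCTS[adduct_name].ion_composition(registry.composition_of(sp))
    return isotopologue_fractions(comp, n_peaks)


def _ion_f0(registry, species_label, adduct_name):
    sp = registry.parse(species_label)
    comp = ADDUCTS[adduct_name].ion_composition(registry.composition_of(sp))
    return monoisotopic_fraction(comp)


def isotope_correct(
    matches: pd.DataFrame,
    registry: LipidRegistry | None = None,
    resolution_at_200: float = 240000.0,
    type2: bool = True,
    n_peaks: int = 4,
    peaklists: Iterable[PeakList] | None = None,
) -> pd.DataFrame:
    """Apply type-I and (optionally) type-II isotope corrections.

    Adds ``corrected_intensity`` and ``correction_flag`` columns; only
    ``assigned`` rows receive corrected values.  Negative results of the
    type-II subtraction clip to zero and are flagged ``clipped``.

    When the original ``peaklists`` are supplied, a contaminator isotopologue
    is attributed to a target peak exactly when the observed centroid nearest
    to its theoretical position is the target's matched peak -- which also
    captures chains of coalescence the pairwise FWHM test misses.  Without
    peak lists the pairwise test against the resolution model is used.
    """
    registry = registry or default_registry()
    df = matches.copy()
    df["corrected_intensity"] = np.nan
    df["correction_flag"] = ""
    if df.empty:
        return df

    f0_cache: dict[tuple[str, str], float] = {}

    def f0(label, adduct):
        key = (label, adduct)
        if key not in f0_cache:
            f0_cache[key] = _ion_f0(registry, label, adduct)
        return f0_cache[key]

    mask = df["assigned"].to_numpy(dtype=bool)
    idx = df.index[mask]
    f0s = np.array([f0(df.at[i, "species"], df.at[i, "adduct"]) for i in idx])
    df.loc[idx, "corrected_intensity"] = df.loc[idx, "intensity"].to_numpy() / f0s

    if not type2:
        return df

    # Type II: subtract, from each monoisotopic peak, the predicted heavy
    # isotopologues (k >= 1) of every lighter matched ion that coalesced with
    # it.  The canonical case is the homolog pair (C:DB+1) contaminating
    # (C:DB) through its two-neutron isotopologue (spacing ~0.0089/|z|), but
    # the same cascade also removes e.g. a 1- ion's A1 sitting on a [M-2H]2-
    # monoisotopic peak.  Contaminator monoisotopic peaks always lie below
    # their isotopologues, so ascending-m/z order guarantees every
    # contaminator is fully corrected before it is used.
    observed: dict[tuple[str, str], np.ndarray] = {}
    if peaklists is not None:
        for pl in peaklists:
            observed[(pl.sample_id, pl.polarity)] = pl.mz

    for (sample_id, polarity), g in df.loc[mask].groupby(
        ["sample_id", "polarity"], sort=False
    ):
        order = g.sort_values("mz_theoretical").index.to_list()
        mzs = df.loc[order, "mz_theoretical"].to_numpy()
        obs_mz = observed.get((sample_id, polarity))
        max_reach = (n_peaks - 1) * 1.01  # widest isotopologue offset (z >= 1)

        def coalesced(iso_mz: float, target_idx) -> bool:
            mz_t = df.at[target_idx, "mz_theoretical"]
            fw = fwhm_at(mz_t, resolution_at_200)
            if obs_mz is None:
                return abs(iso_mz - mz_t) < fw
            if abs(iso_mz - df.at[target_idx, "mz_observed"]) > 3 * fw:
                return False
            k = np.searchsorted(obs_mz, iso_mz)
            near = min(
                (abs(obs_mz[j] - iso_mz), obs_mz[j])
                for j in (max(k - 1, 0), min(k, len(obs_mz) - 1))
            )[1]
            return near == df.at[target_idx, "mz_observed"]

        for pos, target in enumerate(order):
            mz_t = mzs[pos]
            lo = np.searchsorted(mzs, mz_t - max_reach)
            spill = 0.0
            for cpos in range(lo, pos):
                cont = order[cpos]
                charge = abs(ADDUCTS[df.at[cont, "adduct"]].charge)
                fracs = _ion_fractions(
                    registry, df.at[cont, "species"], df.at[cont, "adduct"], n_peaks
                )
                hit = sum(
                    f
                    for off, f in fracs[1:]
                    if coalesced(mzs[cpos] + off / charge, target)
                )
                if hit > 0:
                    spill += df.at[cont, "corrected_intensity"] * hit
            if spill <= 0:
                continue
            new = df.at[target, "corrected_intensity"] - spill / f0(
                df.at[target, "species"], df.at[target, "adduct"]
            )
            if new < 0:
                new = 0.0
                df.at[target, "correction_flag"] = "clipped"
            df.at[target, "corrected_intensity"] = new
    return df


@dataclass
class SodiationEstimate:
    """Per-sample sodiated/protonated adduct fraction of choline lipids."""

    per_sample: dict[str, float]
    n_species: dict[str, int] = field(default_factory=dict)
    fallback_used: set[str] = field(default_factory=set)

    def for_sample(self, sample_id: str) -> float:
        return self.per_sample[sample_id]


def estimate_sodiation(
    matches: pd.DataFrame,
    registry: LipidRegistry | None = None,
    fallback: float = 0.10,
    rel_threshold: float = 0.01,
    detectability_factor: float = 20.0,
    value_col: str = "corrected_intensity",
) -> SodiationEstimate:
    """Estimate f_Na from interference-free PC species, guided by the chloride profile.

    The negative-mode [M+Cl]- profile of the same sample reveals which PC
    species are actually present; a species is usable when neither the species
    whose protonated ion would sit on its sodiated peak (two more carbons,
    three more double bonds) nor the species whose sodiated ion would sit on
    its own protonated peak (two fewer carbons, three fewer double bonds)
    carries more than ``rel_threshold`` of its chloride signal.  f_Na is the
    median of I([M+Na]+) / I([M+H]+) over those species.  A missing sodiated
    match counts as a zero ratio only when the protonated peak is at least
    ``detectability_factor`` times the weakest matched positive-mode peak of
    the sample -- i.e. when a sodiated peak at the few-percent level could not
    have dropped below the detection floor; weaker species are skipped so the
    floor does not censor the estimate downward.  Samples without usable
    species fall back to ``fallback`` with a warning.
    """
    registry = registry or default_registry()
    na_classes = [
        n for n, c in registry.classes.items() if "[M+Na]+" in dict(c.extra_adducts)
    ]
    est = SodiationEstimate({})
    for sample_id, g in matches.groupby("sample_id", sort=True):
        pos = g[(g["polarity"] == "+") & g["assigned"]]
        floor_proxy = float(pos["intensity"].min()) if not pos.empty else 0.0
        ratios = []
        for cls in na_classes:
            rows = g[(g["class_name"] == cls) & g["assigned"]]
            h = {
                (int(r.c), int(r.db)): (r[value_col], r["intensity"])
                for _, r in rows[rows["adduct"] == "[M+H]+"].iterrows()
            }
            na = {
                (int(r.c), int(r.db)): r[value_col]
                for _, r in rows[rows["adduct"] == "[M+Na]+"].iterrows()
            }
            cl = {
                (int(r.c), int(r.db)): r[value_col]
                for _, r in rows[rows["adduct"] == "[M+Cl]-"].iterrows()
            }
            for (c, db), (i_h, raw_h) in h.items():
                ref = cl.get((c, db), 0.0)
                if i_h <= 0 or ref <= 0:
                    continue
                up = cl.get((c + 2, db + 3), 0.0)
                down = cl.get((c - 2, db - 3), 0.0)
                if up > rel_threshold * ref or down > rel_threshold * ref:
                    continue
                i_na = na.get((c, db))
                if i_na is None:
                    if raw_h < detectability_factor * floor_proxy:
                        continue  # sodiated peak may be floor-censored
                    i_na = 0.0
                ratios.append(i_na / i_h)
        if ratios:
            est.per_sample[sample_id] = float(np.median(ratios))
            est.n_species[sample_id] = len(ratios)
        else:
            warnings.warn(
                f"{sample_id}: no interference-free choline-lipid species; "
                f"using fallback sodiation fraction {fallback}"
            )
            est.per_sample[sample_id] = fallback
            est.n_species[sample_id] = 0
            est.fallback_used.add(sample_id)
    return est


def na_overlap_correct(
    matches: pd.DataFrame,
    f_na: float | Mapping[str, float] | SodiationEstimate,
    registry: LipidRegistry | None = None,
    resolution_at_200: float = 240000.0,
    value_col: str = "corrected_intensity",
) -> pd.DataFrame:
    """Subtract the sodiated-PC contribution from interfered protonated peaks.

    Iterating species of each choline-lipid class in ascending mass, the
    predicted sodiated intensity of PC(x:y) -- f_Na times its already-corrected
    protonated intensity, rescaled by the two ions' monoisotopic-fraction
    ratio -- is subtracted from the peak at the [PC(x+2:y+3)+H]+ position
    whenever the two theoretical positions fall within one FWHM.  Negative
    results clip to zero with a flag.
    """
    registry = registry or default_registry()
    df = matches.copy()
    if df.empty:
        return df
    if isinstance(f_na, SodiationEstimate):
        get_f = lambda s: f_na.per_sample[s]
    elif isinstance(f_na, Mapping):
        get_f = lambda s: f_na[s]
    else:
        get_f = lambda s: float(f_na)

    na_classes = [
        n for n, c in registry.classes.items() if "[M+Na]+" in dict(c.extra_adducts)
    ]
    for sample_id, g in df.groupby("sample_id", sort=True):
        f = get_f(sample_id)
        if f <= 0:
            continue
        for cls in na_classes:
            rows = g[
                (g["class_name"] == cls) & (g["adduct"] == "[M+H]+") & g["assigned"]
            ].sort_values("mz_theoretical")
            by_cd = {(int(r.c), int(r.db)): i for i, r in rows.iterrows()}
            for (c, db), target in sorted(
                by_cd.items(), key=lambda kv: df.at[kv[1], "mz_theoretical"]
            ):
                src = by_cd.get((c - 2, db - 3))
                if src is None:
                    continue
                sp_src = df.at[src, "species"]
                mz_na = registry.adduct_mz(sp_src, "[M+Na]+")
                mz_t = df.at[target, "mz_theoretical"]
                if abs(mz_t - mz_na) >= fwhm_at(mz_t, resolution_at_200):
                    continue
                ratio = _ion_f0(registry, sp_src, "[M+Na]+") / _ion_f0(
                    registry, df.at[target, "species"], "[M+H]+"
                )
                new = df.at[target, value_col] - f * df.at[src, value_col] * ratio
                if new < 0:
                    new = 0.0
                    df.at[target, "correction_flag"] = "clipped"
                df.at[target, value_col] = new
    return df


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

@dataclass
class QuantifiedLipidome:
    """Per-species pmol and mol%-of-membrane values for one spot/ROI replicate."""

    sample_id: str
    species: pd.DataFrame  # species, class_name, pmol, mol_percent, membrane, flag
    class_totals: pd.DataFrame  # class_name, pmol, mol_percent
    membrane_total_pmol: float
    unquantifiable_classes: list[str] = field(default_factory=list)
    nmol_per_mg: float | None = None
    spot: SpotSpec | None = None

    def mol_percent(self, species_label: str) -> float:
        row = self.species[self.species["species"] == species_label]
        if row.empty:
            raise KeyError(species_label)
        return float(row["mol_percent"].iloc[0])


def quantify_pmol(
    matches: pd.DataFrame,
    standards: StandardSet,
    registry: LipidRegistry | None = None,
    value_col: str = "corrected_intensity",
) -> QuantifiedLipidome:
    """Internal-standard quantification of a single sample's match table.

    amount(species) = I(species) / I(class standard) x pmol(standard), using
    each class's quantification adduct and polarity.  A class whose standard
    is missing or has zero intensity is marked unquantifiable; its species are
    flagged and excluded from the membrane denominator.
    """
    registry = registry or default_registry()
    samples = matches["sample_id"].unique() if not matches.empty else []
    if len(samples) > 1:
        raise ValueError("quantify_pmol expects one sample; use quantify_dataset")
    sample_id = samples[0] if len(samples) else ""

    std_labels = set(standards.labels())
    rows = []
    unquantifiable = []
    quant = matches[matches["assigned"]] if not matches.empty else matches
    for class_name, cls in registry.classes.items():
        crows = (
            quant[
                (quant["class_name"] == class_name)
                & (quant["adduct"] == cls.quant_adduct)
                & (quant["polarity"] == cls.quant_polarity)
            ]
            if not quant.empty
            else quant
        )
        if crows.empty:
            continue
        std = standards.for_class(class_name)
        i_std = 0.0
        if std is not None:
            srow = crows[crows["species"] == std[0]]
            if not srow.empty:
                i_std = float(srow[value_col].iloc[0])
        ok = std is not None and i_std > 0
        if not ok and not crows[~crows["species"].isin(std_labels)].empty:
            unquantifiable.append(class_name)
        for _, r in crows.iterrows():
            if r["species"] in std_labels:
                continue
            rows.append(
                {
                    "sample_id": sample_id,
                    "species": r["species"],
                    "class_name": class_name,
                    "pmol": r[value_col] / i_std * std[1] if ok else np.nan,
                    "membrane": cls.membrane,
                    "flag": "" if ok else "no_standard",
                }
            )
    species = pd.DataFrame(
        rows, columns=["sample_id", "species", "class_name", "pmol", "membrane", "flag"]
    )
    membrane_total = float(
        species.loc[species["membrane"], "pmol"].sum(skipna=True)
    ) if not species.empty else 0.0
    if membrane_total > 0:
        # storage lipids are also expressed relative to the membrane denominator
        species["mol_percent"] = species["pmol"] / membrane_total * 100.0
    else:
        species["mol_percent"] = np.nan
    class_totals = (
        species.groupby("class_name", sort=True)
        .agg(pmol=("pmol", "sum"), mol_percent=("mol_percent", "sum"))
        .reset_index()
        if not species.empty
        else pd.DataFrame(columns=["class_name", "pmol", "mol_percent"])
    )
    return QuantifiedLipidome(
        sample_id=sample_id,
        species=species,
        class_totals=class_totals,
        membrane_total_pmol=membrane_total,
        unquantifiable_classes=unquantifiable,
    )


def quantify_dataset(
    matches: pd.DataFrame,
    standards: StandardSet,
    registry: LipidRegistry | None = None,
    value_col: str = "corrected_intensity",
) -> list[QuantifiedLipidome]:
    return [
        quantify_pmol(g, standards, registry, value_col)
        for _, g in matches.groupby("sample_id", sort=True)
    ]


def normalize_outputs(q: QuantifiedLipidome, spot: SpotSpec) -> QuantifiedLipidome:
    """Attach wet-weight-normalized output (nmol membrane lipid per mg ww).

    pmol/ug equals nmol/mg, so the conversion is a direct ratio to the spot's
    wet weight.
    """
    if not q.membrane_total_pmol > 0:
        raise ValueError("membrane total must be positive to normalize")
    ww = spot.wet_weight_ug
    species = q.species.copy()
    species["conc_nmol_per_mg"] = species["pmol"] / ww
    return replace(
        q,
        species=species,
        nmol_per_mg=q.membrane_total_pmol / ww,
        spot=spot,
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def build_indexes(
    registry: LipidRegistry | None = None,
    standards: StandardSet | None = None,
    mass_range: tuple[float, float] = (400.0, 1300.0),
) -> dict[str, CandidateIndex]:
    """Candidate indexes for both polarities, standards included."""
    registry = registry or default_registry()
    standards = standards or StandardSet.default()
    return {
        pol: build_candidates(
            registry,
            polarity=pol,
            mass_range=mass_range,
            extra_labels=standards.labels(),
        )
        for pol in ("-", "+")
    }


def process_spot(
    negative: PeakList,
    positive: PeakList,
    standards: StandardSet | None = None,
    registry: LipidRegistry | None = None,
    tol_ppm: float = 2.0,
    resolution_at_200: float = 240000.0,
    mass_range: tuple[float, float] = (400.0, 1300.0),
    type2: bool = True,
    na_correction: bool = True,
    f_na_fallback: float = 0.10,
    indexes: dict[str, CandidateIndex] | None = None,
    spot: SpotSpec | None = None,
) -> QuantifiedLipidome:
    """identify -> correct -> quantify for one polarity-switched spot pair."""
    registry = registry or default_registry()
    standards = standards or StandardSet.default()
    if indexes is None:
        indexes = build_indexes(registry, standards, mass_range)
    matches = pd.concat(
        [
            match_peaks(negative, indexes["-"], tol_ppm),
            match_peaks(positive, indexes["+"], tol_ppm),
        ],
        ignore_index=True,
    )
    matches = isotope_correct(
        matches,
        registry,
        resolution_at_200=resolution_at_200,
        type2=type2,
        peaklists=(negative, positive),
    )
    if na_correction:
        est = estimate_sodiation(matches, registry, fallback=f_na_fallback)
        matches = na_overlap_correct(
            matches, est, registry, resolution_at_200=resolution_at_200
        )
    q = quantify_pmol(matches, standards, registry)
    if spot is not None and q.membrane_total_pmol > 0:
        q = normalize_outputs(q, spot)
    return q


def process_dataset(
    dataset: Iterable[SimulatedSpot],
    registry: LipidRegistry | None = None,
    **kwargs,
) -> list[QuantifiedLipidome]:
    """Run the pipeline over simulated spots, reusing one candidate index."""
    registry = registry or default_registry()
    dataset = list(dataset)
    if not dataset:
        return []
    mass_range = kwargs.pop("mass_range", (400.0, 1300.0))
    indexes = build_indexes(registry, dataset[0].standards, mass_range)
    out = []
    for sim in dataset:
        out.append(
            process_spot(
                sim.negative,
                sim.positive,
                sim.standards,
                registry,
                mass_range=mass_range,
                indexes=indexes,
                spot=sim.spot,
                **kwargs,
            )
        )
    return out


def lipidome_matrix(
    lipidomes: Sequence[QuantifiedLipidome], value: str = "mol_percent"
) -> pd.DataFrame:
    """Wide matrix (samples x species) of pmol or mol% values."""
    frames = [
        q.species.set_index("species")[value].rename(q.sample_id) for q in lipidomes
    ]
    return pd.concat(frames, axis=1).T.rename_axis(index="sample_id")


def write_lipidomes(lipidomes: Sequence[QuantifiedLipidome], prefix) -> None:
    """Write long-format and wide-matrix CSVs of a quantified dataset."""
    long = pd.concat([q.species for q in lipidomes], ignore_index=True)
    long.to_csv(f"{prefix}_long.csv", index=False)
    lipidome_matrix(lipidomes).to_csv(f"{prefix}_wide.csv")
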