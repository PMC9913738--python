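"""Peak identification: theoretical candidate ion indexes and ppm matching.

Only monoisotopic candidate ions are indexed; no deisotoping happens at match
time.  Isotopologue peaks of one species that coalesce with another candidate
are handled downstream by the correction stage, mirroring the
isotopic-correction-then-annotation order of direct-infusion workflows.
Matching is per sample -- direct infusion has no retention dimension to align.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lipids import ADDUCTS, LipidRegistry, LipidSpecies, default_registry
from .simulate import PeakList

__all__ = ["CandidateIndex", "build_candidates", "match_peaks", "MATCH_COLUMNS"]

MATCH_COLUMNS = [
    "sample_id",
    "polarity",
    "species",
    "class_name",
    "c",
    "db",
    "oh",
    "adduct",
    "mz_theoretical",
    "mz_observed",
    "ppm_error",
    "intensity",
    "ambiguous",
    "assigned",
]


@dataclass
class CandidateIndex:
    """Sorted (theoretical m/z, species, adduct) candidates for one polarity."""

    polarity: str
    mz: np.ndarray
    species: list[LipidSpecies]
    adducts: list[str]

    def __len__(self) -> int:
        return len(self.mz)


def build_candidates(
    registry: LipidRegistry | None = None,
    c_range: Iterable[int] | None = None,
    db_range: Iterable[int] | None = None,
    polarity: str = "-",
    mass_range: tuple[float, float] = (400.0, 1300.0),
    extra_labels: Sequence[str] = (),
) -> CandidateIndex:
    """Enumerate every admissible (species, adduct) ion inside the mass range.

    ``c_range``/``db_range`` default to each class's own realistic grid; when
    given, they filter that grid globally.  ``extra_labels`` adds off-grid
    species (internal standards) to the index.
    """
    registry = registry or default_registry()
    if not registry.classes:
        raise ValueError("empty class registry")
    c_set = None if c_range is None else set(c_range)
    db_set = None if db_range is None else set(db_range)

    species: list[LipidSpecies] = []
    for name in registry.classes:
        for sp in registry.grid_species(name):
            if c_set is not None and sp.c not in c_set:
                continue
            if db_set is not None and sp.db not in db_set:
                continue
            species.append(sp)
    for label in extra_labels:
        sp = registry.parse(label)
        if sp not in species:
            species.append(sp)

    mzs, specs, adds = [], [], []
    for sp in species:
        cls = registry.classes[sp.class_name]
        mass = registry.composition_of(sp).monoisotopic_mass
        for adduct_name, pol in cls.adduct_polarities().items():
            if pol != polarity:
                continue
            mz = ADDUCTS[adduct_name].mz(mass)
            if mass_range[0] <= mz <= mass_range[1]:
                mzs.append(mz)
                specs.append(sp)
                adds.append(adduct_name)

    order = np.argsort(np.asarray(mzs, dtype=float), kind="stable")
    return CandidateIndex(
        polarity,
        np.asarray(mzs, dtype=float)[order] if mzs else np.empty(0),
        [specs[i] for i in order],
        [adds[i] for i in order],
    )


def match_peaks(
    peaks: PeakList, index: CandidateIndex, tol_ppm: float = 2.0
) -> pd.DataFrame:
    """Assign centroid peaks to candidate ions within a symmetric ppm tolerance.

    Each candidate is matched to its nearest peak; the tolerance is inclusive
    (|ppm| <= tol).  A peak claimed by more than one candidate is assigned to
    the candidate with the smallest |ppm error| (ties broken by lower
    theoretical m/z); every candidate involved keeps its row with the
    ambiguity flag set, but only the winner is marked ``assigned``.
    """
    if peaks.polarity != index.polarity:
        raise ValueError("peak list and candidate index polarities differ")
    if len(index) == 0 or len(peaks) == 0:
        return pd.DataFrame(columns=MATCH_COLUMNS)

    pos = np.searchsorted(peaks.mz, index.mz)
    lo = np.clip(pos - 1, 0, len(peaks.mz) - 1)
    hi = np.clip(pos, 0, len(peaks.mz) - 1)
    pick = np.where(
        np.abs(peaks.mz[hi] - index.mz) < np.abs(peaks.mz[lo] - index.mz), hi, lo
    )
    ppm = (peaks.mz[pick] - index.mz) / index.mz * 1e6
    within = np.abs(ppm) <= tol_ppm + 1e-9  # inclusive boundary, float-safe
    if not within.any():
        return pd.DataFrame(columns=MATCH_COLUMNS)

    rows = []
    for i in np.flatnonzero(within):
        sp = index.species[i]
        rows.append(
            {
                "sample_id": peaks.sample_id,
                "polarity": peaks.polarity,
                "species": sp.label,
                "class_name": sp.class_name,
                "c": sp.c,
                "db": sp.db,
                "oh": sp.oh,
                "adduct": index.adducts[i],
                "mz_theoretical": index.mz[i],
                "mz_observed": peaks.mz[pick[i]],
                "ppm_error": ppm[i],
                "intensity": peaks.intensity[pick[i]],
                "_peak": int(pick[i]),
            }
        )
    df = pd.DataFrame(rows)
    df["ambiguous"] = df.groupby("_peak")["_peak"].transform("size") > 1
    best = (
        df.assign(abs_ppm=df["ppm_error"].abs())
        .sort_values(["abs_ppm", "mz_theoretical"], kind="stable")
        .drop_duplicates("_peak")
        .index
    )
    df["assigned"] = df.index.isin(best)
    df = df.drop(columns=["_peak"]).reset_index(drop=True)
    return df[MATCH_COLUMNS]
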