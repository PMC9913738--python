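"""Reproducibility and linearity quality control.

Precision is described by the coefficient of variation, CV% = SD/mean x 100
(sample SD, n-1 denominator), with an eligibility cut at CV% <= 30.
Linearity of quantification over a dissected-area series is validated by
ordinary least squares of amount versus area and its R^2; the per-species
eligibility criterion is R^2 > 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import QuantifiedLipidome, lipidome_matrix

__all__ = [
    "QCReport",
    "cv_filter",
    "LinearityReport",
    "linearity_fit",
    "area_series_table",
    "group_summary",
    "LYSO_PA_CLASSES",
]

LYSO_PA_CLASSES = ("LPC", "LPE", "LPI", "LPS", "LPG", "LCL", "PA")


@dataclass
class QCReport:
    """Per-species replicate statistics and the CV-based eligibility filter."""

    table: pd.DataFrame  # index species; mean, sd, sem, cv_percent, eligible, flag
    cv_limit: float
    n_eligible: int
    frac_cv_le_20: float

    def eligible_species(self) -> list[str]:
        return list(self.table.index[self.table["eligible"]])


def cv_filter(matrix: pd.DataFrame, cv_limit: float = 30.0) -> QCReport:
    """CV% filter over a species x replicate matrix.

    Rows are species, columns replicate measurements (pmol or mol%).  Species
    with CV% above the limit -- or with zero mean, where the CV is undefined --
    are flagged ineligible.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two replicates per species")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    n = matrix.notna().sum(axis=1)
    sem = sd / np.sqrt(n)
    cv = pd.Series(np.nan, index=matrix.index)
    nonzero = mean != 0
    cv[nonzero] = sd[nonzero] / mean[nonzero] * 100.0
    table = pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "sem": sem,
            "cv_percent": cv,
            "eligible": cv.le(cv_limit).fillna(False),
            "flag": np.where(nonzero, "", "zero_mean"),
        }
    )
    n_eligible = int(table["eligible"].sum())
    with_cv = table["cv_percent"].dropna()
    frac20 = float((with_cv <= 20.0).mean()) if len(with_cv) else 0.0
    return QCReport(table, cv_limit, n_eligible, frac20)


@dataclass
class LinearityReport:
    """OLS of amount versus dissected area, per species and for the membrane total."""

    table: pd.DataFrame  # index species; slope, intercept, r2, eligible
    quantifiable_per_area: pd.Series  # area -> species count
    r2_limit: float = 0.7

    @property
    def membrane_r2(self) -> float:
        return float(self.table.at["membrane_total", "r2"])


def linearity_fit(
    series: pd.DataFrame,
    area_col: str = "area_um2",
    r2_limit: float = 0.7,
    floor_pmol: float = 0.0,
    fit_intercept: bool = True,
) -> LinearityReport:
    """Fit amount-versus-area regressions over an LMD dilution series.

    ``series`` holds one row per replicate spot: an area column plus one
    column per species (and optionally ``membrane_total``) in pmol.  All
    replicate points enter one ordinary least-squares fit per species; the
    intercept is kept free by default.  A species counts as quantifiable at an
    area level when its amount exceeds ``floor_pmol`` in at least half of the
    replicates there.
    """
    if area_col not in series.columns:
        raise ValueError(f"missing area column {area_col!r}")
    x = series[area_col].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least three distinct area levels")
    rows = {}
    for col in series.columns:
        if col == area_col:
            continue
        y = series[col].to_numpy(dtype=float)
        keep = ~np.isnan(y)
        if keep.sum() < 3 or len(np.unique(x[keep])) < 2:
            rows[col] = (np.nan, np.nan, np.nan, False)
            continue
        if fit_intercept:
            fit = stats.linregress(x[keep], y[keep])
            slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue**2
        else:
            xk, yk = x[keep], y[keep]
            slope = float(np.dot(xk, yk) / np.dot(xk, xk))
            intercept = 0.0
            ss_res = float(np.sum((yk - slope * xk) ** 2))
            ss_tot = float(np.sum((yk - yk.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        rows[col] = (slope, intercept, r2, bool(r2 > r2_limit))
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["slope", "intercept", "r2", "eligible"]
    ).rename_axis(index="species")

    species_cols = [c for c in series.columns if c not in (area_col, "membrane_total")]
    counts = {}
    for area, g in series.groupby(area_col):
        present = (g[species_cols].fillna(0.0) > floor_pmol).mean(axis=0) >= 0.5
        counts[area] = int(present.sum())
    return LinearityReport(
        table, pd.Series(counts).sort_index().rename("n_quantifiable"), r2_limit
    )


def area_series_table(lipidomes: Sequence[QuantifiedLipidome]) -> pd.DataFrame:
    """Assemble the per-replicate pmol table a linearity fit consumes."""
    wide = lipidome_matrix(lipidomes, value="pmol")
    meta = pd.DataFrame(
        {
            "area_um2": [q.spot.area_um2 if q.spot else np.nan for q in lipidomes],
            "membrane_total": [q.membrane_total_pmol for q in lipidomes],
        },
        index=[q.sample_id for q in lipidomes],
    )
    return pd.concat([meta, wide], axis=1)


def group_summary(
    lipidomes: Sequence[QuantifiedLipidome],
    grouping: Mapping[str, str],
) -> pd.DataFrame:
    """Class-level mol% mean +/- SEM per sample group.

    Returns one row per (group, class) plus a ``Lyso+PA`` aggregate (the
    laser-ablation degradation signature: summed lysolipid and PA mol%).
    Single-sample groups report SEM = 0 with a flag.
    """
    rows = []
    for q in lipidomes:
        if q.sample_id not in grouping:
            continue
        cls = q.class_totals.set_index("class_name")["mol_percent"]
        rec = {"group": grouping[q.sample_id], "sample_id": q.sample_id}
        rec.update(cls.to_dict())
        rec["Lyso+PA"] = float(
            sum(cls.get(c, 0.0) for c in LYSO_PA_CLASSES)
        )
        rows.append(rec)
    if not rows:
        raise ValueError("no samples matched the grouping")
    df = pd.DataFrame(rows).set_index(["group", "sample_id"])
    out = []
    for group, g in df.groupby(level="group"):
        n = len(g)
        mean = g.mean(axis=0)
        sem = (
            g.std(axis=0, ddof=1) / np.sqrt(n)
            if n > 1
            else pd.Series(0.0, index=g.columns)
        )
        for cls in g.columns:
            out.append(
                {
                    "group": group,
                    "class_name": cls,
                    "mean_mol_percent": float(mean[cls]),
                    "sem_mol_percent": float(sem[cls]),
                    "n": n,
                    "flag": "single_sample" if n == 1 else "",
                }
            )
    return pd.DataFrame(out)
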