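"""Isotope/sodium corrections and internal-standard quantification."""

import numpy as np
import pandas as pd
import pytest

import lmdlipidomics as L
from lmdlipidomics.identify import match_peaks
from lmdlipidomics.lipids import positive_pc_registry
from lmdlipidomics.quantify import (
    build_indexes,
    estimate_sodiation,
    isotope_correct,
    lipidome_matrix,
    na_overlap_correct,
    normalize_outputs,
    process_dataset,
    quantify_pmol,
)


def matched(sim, registry, standards=None):
    idx = build_indexes(registry, standards or sim.standards)
    return pd.concat(
        [
            match_peaks(sim.negative, idx["-"]),
            match_peaks(sim.positive, idx["+"]),
        ],
        ignore_index=True,
    )


@pytest.fixture
def na_demo_profile():
    """Constructed sodiated-overlap scenario: abundant PC(x:y) interferers with
    polyenoic PC(x+2:y+3) partners at one fifth of their amount, plus
    interference-free species for the estimator."""
    conc = {}
    for (c1, d1), (c2, d2) in [
        ((34, 1), (36, 4)),
        ((36, 2), (38, 5)),
        ((34, 0), (36, 3)),
        ((38, 3), (40, 6)),
    ]:
        conc[f"PC({c1}:{d1})"] = 2.0
        conc[f"PC({c2}:{d2})"] = 0.4
    for c, d in [(30, 0), (30, 1), (32, 0), (32, 1), (40, 1), (40, 2), (38, 6), (34, 4)]:
        conc[f"PC({c}:{d})"] = 1.0
    conc["PE(34:1)"] = 2.0
    conc["SM(34:1:2)"] = 1.0
    return L.RegionProfile("na_demo", conc)


class TestIsotopeCorrection:
    def test_type1_factor_is_monoisotopic_fraction(self, registry, noiseless_spot):
        m = isotope_correct(matched(noiseless_spot, registry), registry, type2=False)
        row = m[(m["species"] == "PE(34:1)") & m["assigned"]]
        if row.empty:
            row = m[m["assigned"] & (m["class_name"] == "PE")].iloc[[0]]
        comp = L.ADDUCTS["[M-H]-"].ion_composition(
            registry.composition_of(row["species"].iloc[0])
        )
        f0 = L.monoisotopic_fraction(comp)
        assert row["corrected_intensity"].iloc[0] == pytest.approx(
            row["intensity"].iloc[0] / f0, rel=1e-12
        )

    def test_no_carbon_no_change(self, registry):
        # a composition without C or Cl has monoisotopic fraction exactly 1
        comp = L.ElementalComposition.from_dict({"H": 3, "O": 4, "P": 1})
        assert L.monoisotopic_fraction(comp) == 1.0

    def test_homolog_pair_recovery(self, registry, standards):
        """GM3-range homologs whose A2 coalesces with the lighter-DB mono are
        both recovered after the type-II cascade."""
        conc = {
            "LCL(54:2)": 0.5,
            "LCL(54:0)": 0.3,
            "PE(34:1)": 2.0,
        }
        prof = L.RegionProfile("pair", conc)
        acq = L.AcquisitionSpec(ppm_sd=0.0, intensity_cv=0.0, noise_floor=1e-9)
        sim = L.simulate_spot(prof, L.SpotSpec(30_000.0), acq=acq, sample_id="s")
        q = process_dataset([sim])[0]
        sp = q.species.set_index("species")
        for label, truth in sim.true_pmol.items():
            assert sp.at[label, "pmol"] == pytest.approx(truth, rel=0.01)

    def test_negative_results_clip_with_flag(self, registry):
        df = pd.DataFrame(
            [
                # heavy contaminator directly below a tiny target at the A2 spacing
                dict(sample_id="s", polarity="-", species="LCL(54:1)", class_name="LCL",
                     c=54, db=1, oh=0, adduct="[M-H]-",
                     mz_theoretical=registry.adduct_mz(L.LipidSpecies("LCL", 54, 1), "[M-H]-"),
                     mz_observed=0.0, ppm_error=0.0, intensity=1e6,
                     ambiguous=False, assigned=True),
                dict(sample_id="s", polarity="-", species="LCL(54:0)", class_name="LCL",
                     c=54, db=0, oh=0, adduct="[M-H]-",
                     mz_theoretical=registry.adduct_mz(L.LipidSpecies("LCL", 54, 0), "[M-H]-"),
                     mz_observed=0.0, ppm_error=0.0, intensity=1.0,
                     ambiguous=False, assigned=True),
            ]
        )
        out = isotope_correct(df, registry)
        target = out[out["species"] == "LCL(54:0)"].iloc[0]
        assert target["corrected_intensity"] == 0.0
        assert target["correction_flag"] == "clipped"


class TestSodiationEstimation:
    def test_noiseless_exact(self, registry, na_demo_profile):
        acq = L.AcquisitionSpec(ppm_sd=0.0, intensity_cv=0.0, noise_floor=1e-9, f_na=0.10)
        sim = L.simulate_spot(na_demo_profile, L.SpotSpec(30_000.0), acq=acq, sample_id="s")
        m = isotope_correct(matched(sim, registry), registry)
        est = estimate_sodiation(m, registry)
        assert est.per_sample["s"] == pytest.approx(0.10, abs=1e-9)
        assert est.n_species["s"] >= 5

    def test_zero_sodiation_detected(self, registry, na_demo_profile):
        acq = L.AcquisitionSpec(ppm_sd=0.0, intensity_cv=0.0, noise_floor=1e-9, f_na=0.0)
        sim = L.simulate_spot(na_demo_profile, L.SpotSpec(30_000.0), acq=acq, sample_id="s")
        m = isotope_correct(matched(sim, registry), registry)
        assert estimate_sodiation(m, registry).per_sample["s"] == 0.0

    def test_noisy_recovery_within_two_points(self, registry):
        prof = L.make_lipidome(species_per_class={"PC": 24}, seed=5)
        vals = []
        for seed in range(1, 6):
            acq = L.AcquisitionSpec(intensity_cv=0.05, f_na=0.10)
            sim = L.simulate_spot(
                prof,
                L.SpotSpec(30_000.0),
                acq=acq,
                rng=np.random.default_rng(seed),
                sample_id="s",
            )
            m = isotope_correct(matched(sim, registry), registry)
            vals.append(estimate_sodiation(m, registry).per_sample["s"])
        assert 0.08 <= float(np.median(vals)) <= 0.12

    def test_fallback_with_warning(self, registry, noiseless_spot):
        m = isotope_correct(matched(noiseless_spot, registry), registry)
        no_cl = m[m["adduct"] != "[M+Cl]-"]
        with pytest.warns(UserWarning, match="fallback"):
            est = estimate_sodiation(no_cl, registry, fallback=0.07)
        assert est.per_sample[noiseless_spot.sample_id] == 0.07
        assert est.fallback_used


class TestNaOverlapCorrection:
    def test_interfered_species_recovered(self, na_demo_profile):
        pos_reg = positive_pc_registry()
        acq = L.AcquisitionSpec(ppm_sd=0.0, intensity_cv=0.0, noise_floor=1e-9, f_na=0.10)
        sim = L.simulate_spot(
            na_demo_profile, L.SpotSpec(30_000.0), acq=acq, sample_id="s", registry=pos_reg
        )
        q = process_dataset([sim], registry=pos_reg, na_correction=True)[0]
        sp = q.species.set_index("species")
        for label in ("PC(36:4)", "PC(38:5)", "PC(36:3)", "PC(40:6)"):
            assert sp.at[label, "pmol"] == pytest.approx(
                sim.true_pmol[label], rel=0.02
            )

    def test_skipping_correction_overestimates_polyenoics(self, na_demo_profile):
        pos_reg = positive_pc_registry()
        acq = L.AcquisitionSpec(ppm_sd=0.0, intensity_cv=0.0, noise_floor=1e-9, f_na=0.10)
        sim = L.simulate_spot(
            na_demo_profile, L.SpotSpec(30_000.0), acq=acq, sample_id="s", registry=pos_reg
        )
        q = process_dataset([sim], registry=pos_reg, na_correction=False)[0]
        sp = q.species.set_index("species")
        for label in ("PC(36:4)", "PC(38:5)", "PC(36:3)", "PC(40:6)"):
            assert sp.at[label, "pmol"] > 1.2 * sim.true_pmol[label]

    def test_monotone_and_isolated(self, registry, na_demo_profile):
        """Correction never increases an intensity and leaves species without a
        two-carbon/three-double-bond partner untouched."""
        pos_reg = positive_pc_registry()
        acq = L.AcquisitionSpec(ppm_sd=0.0, intensity_cv=0.0, noise_floor=1e-9, f_na=0.10)
        sim = L.simulate_spot(
            na_demo_profile, L.SpotSpec(30_000.0), acq=acq, sample_id="s", registry=pos_reg
        )
        m = isotope_correct(
            matched(sim, pos_reg), pos_reg, peaklists=(sim.negative, sim.positive)
        )
        out = na_overlap_correct(m, 0.10, pos_reg)
        h = m["adduct"] == "[M+H]+"
        assert (
            out.loc[h, "corrected_intensity"] <= m.loc[h, "corrected_intensity"] + 1e-9
        ).all()
        free = m["species"] == "PC(30:0)"
        pd.testing.assert_series_equal(
            out.loc[free, "corrected_intensity"], m.loc[free, "corrected_intensity"]
        )


class TestQuantification:
    def test_ratio_one_gives_standard_amount(self, registry, standards, noiseless_spot):
        m = isotope_correct(matched(noiseless_spot, registry), registry,
                            peaklists=(noiseless_spot.negative, noiseless_spot.positive))
        # scale one species' corrected intensity to equal its class standard's
        std_label, std_pmol = standards.for_class("PE")
        std_i = m.loc[(m["species"] == std_label) & m["assigned"], "corrected_intensity"].iloc[0]
        target = m[(m["class_name"] == "PE") & (m["species"] != std_label) & m["assigned"]].index[0]
        m.loc[target, "corrected_intensity"] = std_i
        q = quantify_pmol(m, standards, registry)
        assert q.species.set_index("species").at[
            m.at[target, "species"], "pmol"
        ] == pytest.approx(std_pmol, rel=1e-9)

    def test_noiseless_end_to_end_recovery(self, registry, noiseless_spot):
        q = process_dataset([noiseless_spot])[0]
        sp = q.species.set_index("species")
        for label, truth in noiseless_spot.true_pmol.items():
            assert sp.at[label, "pmol"] == pytest.approx(truth, rel=1e-6)

    def test_membrane_mol_percent_sums_to_100(self, noiseless_spot):
        q = process_dataset([noiseless_spot])[0]
        total = q.species.loc[q.species["membrane"], "mol_percent"].sum()
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_missing_standard_isolated(self, registry, noiseless_spot):
        m = isotope_correct(matched(noiseless_spot, registry), registry,
                            peaklists=(noiseless_spot.negative, noiseless_spot.positive))
        incomplete = L.StandardSet(
            {k: v for k, v in L.StandardSet.default().entries.items() if k != "SM"}
        )
        q = quantify_pmol(m, incomplete, registry)
        assert "SM" in q.unquantifiable_classes
        sm = q.species[q.species["class_name"] == "SM"]
        assert sm["pmol"].isna().all() and (sm["flag"] == "no_standard").all()
        pe = q.species[q.species["class_name"] == "PE"]
        assert pe["pmol"].notna().all()

    def test_scale_invariance_of_mol_percent(self, registry, standards, noiseless_spot):
        m = isotope_correct(matched(noiseless_spot, registry), registry,
                            peaklists=(noiseless_spot.negative, noiseless_spot.positive))
        q1 = quantify_pmol(m, standards, registry)
        m2 = m.copy()
        m2["corrected_intensity"] *= 3.7  # same scale on species and standards
        q2 = quantify_pmol(m2, standards, registry)
        pd.testing.assert_series_equal(
            q1.species.set_index("species")["mol_percent"],
            q2.species.set_index("species")["mol_percent"],
        )


class TestNormalization:
    def test_nmol_per_mg_arithmetic(self):
        # 0.3 ug spot at 0.9 nmol/mg membrane density -> 0.27 pmol recovered
        spot = L.SpotSpec(30_000.0)
        q = L.QuantifiedLipidome(
            sample_id="s",
            species=pd.DataFrame(
                {
                    "sample_id": ["s"],
                    "species": ["PC(34:1)"],
                    "class_name": ["PC"],
                    "pmol": [0.27],
                    "membrane": [True],
                    "flag": [""],
                    "mol_percent": [100.0],
                }
            ),
            class_totals=pd.DataFrame(),
            membrane_total_pmol=0.27,
        )
        out = normalize_outputs(q, spot)
        assert out.nmol_per_mg == pytest.approx(0.9)

    def test_zero_membrane_rejected(self):
        q = L.QuantifiedLipidome(
            sample_id="s",
            species=pd.DataFrame(),
            class_totals=pd.DataFrame(),
            membrane_total_pmol=0.0,
        )
        with pytest.raises(ValueError):
            normalize_outputs(q, L.SpotSpec(30_000.0))


class TestParameterRecoveryNoisy:
    def test_median_relative_error_under_noise(self, registry, liver_profile):
        """Median per-species pmol error stays within 5% at CV 5% over seeded spots."""
        errors = []
        floor = 20.0
        for seed in range(1, 11):
            acq = L.AcquisitionSpec(intensity_cv=0.05)
            sim = L.simulate_spot(
                liver_profile,
                L.SpotSpec(30_000.0),
                acq=acq,
                rng=np.random.default_rng(seed),
                sample_id="s",
            )
            q = process_dataset([sim])[0]
            sp = q.species.set_index("species")
            for label, truth in sim.true_pmol.items():
                if truth * acq.intensity_per_pmol < 10 * floor:
                    continue
                if label in sp.index and np.isfinite(sp.at[label, "pmol"]):
                    errors.append(abs(sp.at[label, "pmol"] - truth) / truth)
        assert float(np.median(errors)) <= 0.05

    def test_lipidome_matrix_shape(self, noiseless_spot):
        qs = process_dataset([noiseless_spot])
        mat = lipidome_matrix(qs)
        assert mat.shape[0] == 1
        assert mat.index[0] == noiseless_spot.sample_id
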