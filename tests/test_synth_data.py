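import dataclasses
import hashlib

import numpy as np
import pytest

from glycoce import report_io, synth_data
from glycoce.ce_model import DEFAULT_GRID, sweep_grid
from glycoce.curve_opt import EligibilityPolicy, build_curves, fit_optima
from glycoce.glyco_chem import feature_table, glycan_features, parse_glycan_composition
from glycoce.synth_data import (
    GLYCAN_CENTRIC,
    PEPTIDE_CENTRIC,
    CohortConfig,
    emit_reports,
    glycan_catalog,
    sample_species,
    simulate_sweep,
    true_optimum,
    weak_covariate_variant,
)


class TestSampleSpecies:
    def test_seeding_reproducible(self):
        a = sample_species(10, seed=7)
        b = sample_species(10, seed=7)
        assert a == b

    def test_different_seed_differs(self):
        assert sample_species(10, seed=7) != sample_species(10, seed=8)

    def test_single_species_valid(self):
        (sp,) = sample_species(1, seed=0)
        assert sp.charge >= 2
        assert sp.peptide.sequence[-1] in "KR"

    def test_n_zero_rejected(self):
        with pytest.raises(ValueError):
            sample_species(0, seed=1)

    def test_strata_coverage_default_cohort(self):
        species = sample_species(300, seed=1)
        feats = feature_table(species)
        low_z = feats["charge"] <= 2
        sialylated = feats["n_sialic"] > 0
        # all four charge x sialylation strata populated
        for zmask in (low_z, ~low_z):
            for smask in (sialylated, ~sialylated):
                assert (zmask & smask).sum() > 0

    def test_tryptic_like(self):
        for sp in sample_species(50, seed=3):
            seq = sp.peptide.sequence
            assert seq[-1] in "KR"
            assert "K" not in seq[:-1] and "R" not in seq[:-1]
            assert 7 <= len(seq) <= 25

    def test_lengths_respect_config(self):
        config = CohortConfig(min_length=9, max_length=12)
        for sp in sample_species(30, seed=4, config=config):
            assert 9 <= len(sp.peptide.sequence) <= 12

    def test_catalog_spans_structures(self):
        catalog = glycan_catalog()
        feats = [glycan_features(c) for c in catalog]
        assert any(f["is_high_mannose"] for f in feats)
        assert any(f["n_antennae"] == 4 for f in feats)
        assert any(f["n_sialic"] == 4 for f in feats)
        assert any(f["n_fucose"] == 1 for f in feats)


class TestTrueOptimum:
    def test_degenerate_persona_exact(self):
        persona = dataclasses.replace(
            PEPTIDE_CENTRIC, coef_hydrophobicity=0.0, coef_mobile_protons=0.0,
            coef_glycan_mass=0.0, optimum_noise_sd=0.0)
        row = {"mz": 1000.0, "hydrophobicity": 5.0, "mobile_protons": 2,
               "glycan_mass": 2000.0}
        mu = true_optimum(row, persona)
        assert mu == pytest.approx(persona.intercept + persona.slope_mz * 1000.0)

    def test_half_energy_ratio_at_cohort_means(self):
        feats = feature_table(sample_species(300, seed=1))
        row = {"mz": 1200.0,
               "hydrophobicity": feats["hydrophobicity"].mean(),
               "mobile_protons": feats["mobile_protons"].mean(),
               "glycan_mass": feats["glycan_mass"].mean()}
        ratio = true_optimum(row, GLYCAN_CENTRIC) / true_optimum(row, PEPTIDE_CENTRIC)
        assert 0.4 <= ratio <= 0.6

    def test_half_energy_band_across_mz(self):
        feats = feature_table(sample_species(300, seed=1))
        means = {"hydrophobicity": feats["hydrophobicity"].mean(),
                 "mobile_protons": feats["mobile_protons"].mean(),
                 "glycan_mass": feats["glycan_mass"].mean()}
        for mz in np.linspace(700, 1800, 12):
            row = {"mz": mz, **means}
            ratio = true_optimum(row, GLYCAN_CENTRIC) / true_optimum(row, PEPTIDE_CENTRIC)
            assert 0.35 <= ratio <= 0.65

    def test_mobile_proton_sign(self):
        row = {"mz": 1200.0, "hydrophobicity": 0.0, "mobile_protons": 0,
               "glycan_mass": 2000.0}
        row_up = {**row, "mobile_protons": 1}
        assert true_optimum(row_up, GLYCAN_CENTRIC) < true_optimum(row, GLYCAN_CENTRIC)

    def test_weak_variant_mz_only(self):
        weak = weak_covariate_variant(GLYCAN_CENTRIC)
        a = true_optimum({"mz": 1200.0, "hydrophobicity": 30.0, "mobile_protons": 2,
                          "glycan_mass": 4000.0}, weak)
        b = true_optimum({"mz": 1200.0, "hydrophobicity": -30.0, "mobile_protons": -1,
                          "glycan_mass": 1000.0}, weak)
        assert a == b


class TestSimulateSweep:
    def test_noiseless_full_presence(self):
        persona = dataclasses.replace(
            PEPTIDE_CENTRIC, optimum_noise_sd=0.0, detection_threshold=0.0,
            multiplicative_score_noise_sd=0.0)
        species = sample_species(5, seed=2)
        records, truth = simulate_sweep(species, personas={"byonic": persona},
                                        seed=3, p_duplicate=0.0)
        assert len(records) == 5 * len(DEFAULT_GRID)
        # scores exactly Gaussian in the applied CE
        rec = records[0]
        i = [sp.key for sp in truth.species].index(rec.species.key)
        from glycoce.ce_model import applied_ce
        from glycoce.glyco_chem import theoretical_mz
        ce = applied_ce(theoretical_mz(rec.species), rec.scale_pct)
        expected = truth.amplitudes["byonic"][i] * np.exp(
            -((ce - truth.true_mu["byonic"][i]) ** 2)
            / (2 * truth.sigmas["byonic"][i] ** 2))
        assert rec.score == pytest.approx(expected, rel=1e-9)

    def test_threshold_above_all_peaks_no_records(self):
        persona = dataclasses.replace(PEPTIDE_CENTRIC, detection_threshold=1e12)
        records, _ = simulate_sweep(sample_species(5, seed=2),
                                    personas={"byonic": persona}, seed=3)
        assert records == ()

    def test_missingness_monotone_in_threshold(self):
        species = sample_species(40, seed=5)
        counts = []
        for thr in (0.0, 30.0, 100.0, 300.0):
            persona = dataclasses.replace(PEPTIDE_CENTRIC, detection_threshold=thr)
            records, _ = simulate_sweep(species, personas={"byonic": persona}, seed=6)
            counts.append(len(records))
        assert counts == sorted(counts, reverse=True)

    def test_duplicates_injected(self):
        species = sample_species(30, seed=7)
        records, _ = simulate_sweep(species, seed=8, p_duplicate=0.5)
        table = report_io.aggregate_best_per_run(records)
        assert len(table) < len(records)

    def test_end_to_end_recovery(self):
        species = sample_species(200, seed=1)
        records, truth = simulate_sweep(species, seed=2)
        table = report_io.aggregate_best_per_run(records)
        optima = fit_optima(build_curves(table), EligibilityPolicy())
        key2i = {sp.key: i for i, sp in enumerate(truth.species)}
        for channel in ("byonic", "glycoquest"):
            sub = optima[optima["channel"] == channel]
            assert len(sub) > 50
            errors = []
            for r in sub.itertuples():
                key = (r.sequence,
                       tuple(parse_glycan_composition(r.glycan_composition).counts().values()),
                       r.charge)
                errors.append(abs(r.optimal_ce_ev - truth.true_mu[channel][key2i[key]]))
            assert np.median(errors) < 1.5


class TestEmitReports:
    def _checksums(self, paths):
        return [hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(paths)]

    def test_one_file_per_setting_plus_manifest(self, tmp_path):
        species = sample_species(10, seed=1)
        records, _ = simulate_sweep(species, seed=2)
        paths = emit_reports(records, tmp_path / "reports")
        assert len(paths) == len(DEFAULT_GRID) + 1
        manifest = report_io.read_run_manifest(tmp_path / "reports" / "manifest.tsv")
        assert len(manifest) == len(DEFAULT_GRID)

    def test_empty_setting_header_only(self, tmp_path):
        paths = emit_reports([], tmp_path / "reports", grid=sweep_grid(100, 106.25, 6.25))
        report_files = [p for p in paths if p.name != "manifest.tsv"]
        assert len(report_files) == 2
        for p in report_files:
            assert p.read_text().startswith("run_id\t")
            assert len(p.read_text().splitlines()) == 1

    def test_byte_identical_rerun(self, tmp_path):
        species = sample_species(20, seed=9)
        records, _ = simulate_sweep(species, seed=10)
        p1 = emit_reports(records, tmp_path / "a")
        records2, _ = simulate_sweep(sample_species(20, seed=9), seed=10)
        p2 = emit_reports(records2, tmp_path / "b")
        assert self._checksums(p1) == self._checksums(p2)

    def test_roundtrip_through_report_io(self, tmp_path):
        species = sample_species(15, seed=11)
        records, _ = simulate_sweep(species, seed=12)
        emit_reports(records, tmp_path / "reports")
        result = report_io.read_report_dir(tmp_path / "reports",
                                           tmp_path / "reports" / "manifest.tsv")
        assert len(result.records) == len(records)
        assert result.n_skipped == 0


class TestParameterRecoveryInvariant:
    def test_coefficient_recovery_small(self):
        # reduced-seed version of the full-pipeline recovery check
        truth_coefs = np.array([PEPTIDE_CENTRIC.slope_mz,
                                PEPTIDE_CENTRIC.coef_hydrophobicity,
                                PEPTIDE_CENTRIC.coef_mobile_protons,
                                PEPTIDE_CENTRIC.coef_glycan_mass])
        rel_errors = []
        for seed in range(5):
            species = sample_species(300, seed=seed)
            records, _ = simulate_sweep(species, personas={"byonic": PEPTIDE_CENTRIC},
                                        seed=seed + 100)
            table = report_io.aggregate_best_per_run(records)
            optima = fit_optima(build_curves(table), EligibilityPolicy())
            feats = feature_table(species)
            key2i = {sp.key: i for i, sp in enumerate(species)}
            rows, y = [], []
            for r in optima.itertuples():
                key = (r.sequence,
                       tuple(parse_glycan_composition(r.glycan_composition).counts().values()),
                       r.charge)
                rows.append(key2i[key])
                y.append(r.optimal_ce_ev)
            f = feats.iloc[rows]
            X = np.column_stack([np.ones(len(f)), f["mz"], f["hydrophobicity"],
                                 f["mobile_protons"], f["glycan_mass"]])
            beta = np.linalg.lstsq(X, np.asarray(y), rcond=None)[0][1:]
            rel_errors.append(np.abs((beta - truth_coefs) / truth_coefs))
        assert np.all(np.median(rel_errors, axis=0) < 0.15)
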