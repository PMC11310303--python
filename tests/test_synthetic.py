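"""Generator tests: determinism, count bookkeeping, planted-effect recovery,
decoy realization, and the metabolite panel simulation."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import lipidcbm as L
from lipidcbm.synthetic import (DECOY_KINDS, MetaboliteGeneratorConfig,
                                null_config, planted_cbm_only_config)


def test_single_entry_library():
    cfg = L.GeneratorConfig(n_variables_per_class={"positive": {"TG": 1}},
                            cbm_species={"TG(54:5)": 0.0}, dlk1_species={})
    lib = L.build_library(cfg)
    assert len(lib) == 1
    v = lib[0]
    assert (v.lipid_class, v.total_carbons, v.total_double_bonds) == ("TG", 54, 5)
    assert 150.0 <= v.theoretical_mz <= 1200.0


def test_library_deterministic_under_seed():
    cfg = L.GeneratorConfig(seed=1)
    a = L.build_library(cfg)
    b = L.build_library(cfg)
    assert [(v.variable_id, v.theoretical_mz) for v in a] == \
           [(v.variable_id, v.theoretical_mz) for v in b]


def test_paper_sized_library_counts_match_request():
    cfg = L.paper_like_config("plasma", decoys_per_kind=0)
    lib = L.build_library(cfg)
    by_mode = pd.Series([v.mode for v in lib]).value_counts()
    assert by_mode["positive"] == 100
    assert by_mode["negative"] == 212
    # unique species keys by construction
    assert len({v.key for v in lib}) == len(lib)


def test_truth_decoys_disjoint_from_effects(fixture_cohort):
    truth = fixture_cohort["truth"]
    assert not set(truth.effects) & set(truth.decoys)
    counts = pd.Series(list(truth.decoys.values())).value_counts()
    assert all(counts[k] == 3 for k in DECOY_KINDS)


def test_cohort_fully_reproducible(design):
    cfg = L.fixture_config(seed=11)
    out = []
    for _ in range(2):
        truth = L.make_truth(L.build_library(cfg), cfg)
        tables, peaks, _ = L.simulate_cohort(design, truth, cfg)
        out.append((tables, peaks))
    for mode in out[0][0]:
        pd.testing.assert_frame_equal(out[0][0][mode].intensities,
                                      out[1][0][mode].intensities)
        pd.testing.assert_frame_equal(out[0][1][mode], out[1][1][mode])


def test_deterministic_limit_ratio_two(design):
    """log2FC = 1 on TG with vanishing noise gives a pregnant/virgin mean
    ratio of 2 for every TG variable."""
    cfg = L.GeneratorConfig(
        n_variables_per_class={"positive": {"TG": 5, "SM": 3}},
        sigma_log=1e-9, missing_rate=0.0, tg_up=1.0,
        pc_high_db_up=0.0, pc_low_db_down=0.0, cbm_species={}, dlk1_species={})
    truth = L.make_truth(L.build_library(cfg), cfg)
    tables, _, _ = L.simulate_cohort(design, truth, cfg)
    t = tables["positive"]
    bio = t.biological
    groups = t.samples.loc[bio.index, "group_id"]
    pregnant = {g.group_id for g in design.groups if g.pregnant}
    ratio = (bio[groups.isin(pregnant)].mean()
             / bio[~groups.isin(pregnant)].mean())
    for v in t.library:
        expected = 2.0 if v.lipid_class == "TG" else 1.0
        assert ratio[v.variable_id] == pytest.approx(expected, rel=1e-6)


def test_empirical_log_ratios_recover_planted_effects(pregnancy_design):
    """Monte-Carlo: per-variable empirical log2 ratios sit within 3 SE of the
    planted effects."""
    cfg = replace(L.fixture_config(seed=7), decoys_per_kind=0, n_per_group=8)
    truth = L.make_truth(L.build_library(cfg), cfg)
    tables, _, _ = L.simulate_cohort(pregnancy_design, truth, cfg)
    for mode, t in tables.items():
        bio = np.log2(t.biological)
        groups = t.samples.loc[bio.index, "group_id"]
        pregnant = {g.group_id for g in pregnancy_design.groups if g.pregnant}
        mask = groups.isin(pregnant)
        est = bio[mask].mean() - bio[~mask].mean()
        n1, n2 = int(mask.sum()), int((~mask).sum())
        se = (cfg.sigma_log / np.log(2)) * np.sqrt(1 / n1 + 1 / n2)
        for v in t.library:
            planted = truth.effects.get(v.variable_id, {}).get(
                "virgin_vs_pregnant", 0.0)
            assert abs(est[v.variable_id] - planted) < 3 * se * 1.2


def test_log_ratio_estimator_unbiased(pregnancy_design):
    """Mean log2-ratio over 200 tiny replicates is within 2 SE of truth."""
    base = L.GeneratorConfig(
        n_variables_per_class={"positive": {"TG": 2}}, n_per_group=4,
        tg_up=0.7, pc_high_db_up=0.0, pc_low_db_down=0.0,
        cbm_species={}, dlk1_species={}, missing_rate=0.0)
    estimates = []
    for rep in range(200):
        cfg = replace(base, seed=20_000 + rep)
        truth = L.make_truth(L.build_library(cfg), cfg)
        tables, _, _ = L.simulate_cohort(pregnancy_design, truth, cfg)
        t = tables["positive"]
        bio = np.log2(t.biological)
        groups = t.samples.loc[bio.index, "group_id"]
        pregnant = {g.group_id for g in pregnancy_design.groups if g.pregnant}
        mask = groups.isin(pregnant)
        estimates.append(float((bio[mask].mean() - bio[~mask].mean()).iloc[0]))
    est = np.asarray(estimates)
    se = est.std(ddof=1) / np.sqrt(len(est))
    assert abs(est.mean() - 0.7) < 2 * se + 1e-3


def test_qc_samples_scale_with_dilution(fixture_cohort):
    truth = fixture_cohort["truth"]
    for mode, t in fixture_cohort["tables"].items():
        qc = t.qc_samples
        dil = t.samples.loc[qc.index, "qc_dilution"]
        clean = [v for v in t.intensities.columns if v not in truth.decoys]
        full = qc.loc[dil == 1.0, clean].mean()
        quarter = qc.loc[dil == 0.25, clean].mean()
        # multiplicative noise is 5%, so the ratio is near 4 for every variable
        np.testing.assert_allclose(full / quarter, 4.0, rtol=0.25)


def test_truth_rejects_unknown_variables(design):
    cfg = L.fixture_config(seed=0)
    truth = L.SyntheticTruth(effects={"nonexistent": {"virgin_vs_pregnant": 1.0}})
    with pytest.raises(ValueError, match="nonexistent"):
        L.simulate_cohort(design, truth, cfg)


def test_config_validation():
    with pytest.raises(ValueError, match="qc_dilutions"):
        L.GeneratorConfig(qc_dilutions=(0.1, 0.5, 1.0))
    with pytest.raises(ValueError, match="sigma_log"):
        L.GeneratorConfig(sigma_log=0.0)
    with pytest.raises(ValueError, match="n_per_group"):
        L.GeneratorConfig(n_per_group=2)


def test_null_and_power_presets_strip_effects():
    cfg = L.fixture_config(seed=0)
    nul = null_config(cfg)
    assert not L.make_truth(L.build_library(nul), nul).effects
    pw = planted_cbm_only_config(cfg, log2fc=1.0)
    truth = L.make_truth(L.build_library(pw), pw)
    planted = {tuple(v.values()) for v in truth.effects.values()}
    assert planted <= {(1.0,), (-1.0,)}


# -- metabolite generator ---------------------------------------------------

def test_metabolite_panel_counts(design):
    panel = L.load_panel()
    responses, standards, truth = L.simulate_metabolites(
        design, panel, MetaboliteGeneratorConfig(seed=2))
    assert len(panel) == 45
    assert int(panel["never_detected"].sum()) == 7
    curves = L.calibrate_panel(standards, panel)
    assert sum(c.detected for c in curves.values()) == 38
    assert standards.groupby("metabolite").size().eq(10).all()
    conc = standards["concentration"]
    assert conc.min() == pytest.approx(0.95) and conc.max() == pytest.approx(500)


def test_metabolite_group_means_track_planted_effects(design):
    cfg = MetaboliteGeneratorConfig(seed=3, response_cv=0.01)
    panel = L.load_panel()
    responses, standards, truth = L.simulate_metabolites(design, panel, cfg)
    curves = L.calibrate_panel(standards, panel)
    conc = L.quantify_table(responses, curves)
    groups = conc["group_id"]
    pregnant = {g.group_id for g in design.groups if g.pregnant}
    for met in ("PGD2", "PGE2", "5-HETE"):
        vals = np.log2(conc[met])
        mask = groups.isin(pregnant)
        diff = vals[mask].mean() - vals[~mask].mean()
        se = (cfg.sigma_log_conc / np.log(2)) * np.sqrt(
            1 / mask.sum() + 1 / (~mask).sum())
        assert abs(diff - truth["metabolites"][met]["log2fc"]) < 3 * se * 1.3


def test_never_detected_stay_sub_lod(design):
    panel = L.load_panel()
    responses, standards, _ = L.simulate_metabolites(
        design, panel, MetaboliteGeneratorConfig(seed=4))
    curves = L.calibrate_panel(standards, panel)
    conc = L.quantify_table(responses, curves)
    from lipidcbm.metabolites import NEVER_DETECTED
    for met in NEVER_DETECTED:
        assert not curves[met].detected
        assert conc[met].isna().all()


def test_panel_validation_rejects_bad_panels():
    panel = L.load_panel()
    with pytest.raises(ValueError, match="45"):
        L.simulate_metabolites(L.default_design(), panel.iloc[:40],
                               MetaboliteGeneratorConfig())
    bad = panel.copy()
    bad["never_detected"] = False
    with pytest.raises(ValueError, match="never-detected"):
        L.simulate_metabolites(L.default_design(), bad,
                               MetaboliteGeneratorConfig())
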