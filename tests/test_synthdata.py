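"""Generator contracts: arithmetic, determinism, limits and planted truth."""

import numpy as np
import pandas as pd
import pytest

from xenodissect import synthdata as sd, tumormetrics as tm
from xenodissect.iotables import HUMAN, MOUSE

SMALL_SETS = (sd.TreatmentSet("NFKB_TARGETS", 10, 1.2, 0.3),)


def _cfg(**kw):
    kw.setdefault("n_probesets", 100)
    kw.setdefault("treatment_sets", SMALL_SETS)
    return sd.SynthConfig(**kw)


class TestUniverse:
    def test_probe_count_arithmetic(self):
        uni = sd.generate_universe(_cfg(seed=1, n_probesets=100, probes_per_set=11))
        for sp in (HUMAN, MOUSE):
            assert len(uni.probeset_maps[sp].probe_to_set) == 1100
            assert len(uni.probeset_maps[sp].probeset_ids) == 100

    def test_zero_crosshyb_fraction_empty_truth(self):
        uni = sd.generate_universe(_cfg(seed=1, crosshyb_fraction=0.0))
        assert uni.truth.crosshyb_sets[HUMAN] == set()
        assert uni.truth.crosshyb_sets[MOUSE] == set()

    def test_same_seed_identical(self):
        a = sd.generate_universe(_cfg(seed=3))
        b = sd.generate_universe(_cfg(seed=3))
        assert a.probeset_maps[HUMAN].probe_to_set == b.probeset_maps[HUMAN].probe_to_set
        assert a.truth.true_log2fc == b.truth.true_log2fc
        assert a.truth.crosshyb_sets == b.truth.crosshyb_sets

    def test_truth_covers_every_probeset(self):
        uni = sd.generate_universe(_cfg(seed=2))
        for sp in (HUMAN, MOUSE):
            assert set(uni.truth.true_log2fc[sp]) == set(uni.probeset_maps[sp].probeset_ids)

    def test_crosshyb_fraction_realised(self):
        uni = sd.generate_universe(_cfg(seed=4, n_probesets=200, crosshyb_fraction=0.15))
        assert len(uni.truth.crosshyb_sets[HUMAN]) == 30

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="crosshyb_fraction"):
            sd.SynthConfig(crosshyb_fraction=1.5)
        with pytest.raises(ValueError, match="n_per_group"):
            sd.SynthConfig(n_per_group=1)

    def test_planted_effect_means_calibrated(self):
        # distributional sanity: across replicate universes the mean of
        # drawn effects sits within 3 s.e. of the configured mean
        effects = []
        for seed in range(100):
            uni = sd.generate_universe(_cfg(seed=seed))
            fc = uni.truth.true_log2fc[MOUSE]
            effects += [v for v in fc.values() if v != 0.0]
        effects = np.array(effects)
        se = effects.std(ddof=1) / np.sqrt(len(effects))
        assert abs(effects.mean() - 1.2) < 3 * se + 1e-12


class TestControlHybs:
    def test_four_configurations(self, small_universe):
        controls = sd.generate_control_hybs(small_universe)
        assert set(controls) == set(sd.CONTROL_CONFIGS)

    def test_kappa_zero_other_species_is_background(self):
        cfg = _cfg(seed=5, kappa=0.0)
        uni = sd.generate_universe(cfg)
        controls = sd.generate_control_hybs(uni)
        vals = controls[(HUMAN, "mouse_only")].values.to_numpy()
        sem = cfg.background_sd / np.sqrt(vals.size)
        assert abs(vals.mean() - cfg.background_mean) < 3 * sem

    def test_kappa_one_leakage_matches_ortholog_signal(self):
        cfg = _cfg(seed=6, kappa=1.0, noise_sd=0.05)
        uni = sd.generate_universe(cfg)
        controls = sd.generate_control_hybs(uni)
        other = controls[(HUMAN, "mouse_only")].values
        pm = uni.probeset_maps[HUMAN]
        truth = uni.truth
        leak, expected = [], []
        for ps in truth.crosshyb_sets[HUMAN]:
            sym = pm.symbol_of(ps)
            orth = uni.ortholog_map.to_mouse(sym)
            ps_o = truth.symbol_to_probeset[MOUSE][orth]
            for probe in pm.probes_of(ps):
                leak.append(other.loc[probe].mean() - cfg.background_mean)
                expected.append(
                    2.0 ** (truth.baseline_log2[MOUSE][ps_o]
                            + uni.probe_affinity[HUMAN][probe])
                )
        ratio = np.sum(leak) / np.sum(expected)
        assert 0.8 < ratio < 1.25

    def test_seeded_reproducibility(self):
        cfg = _cfg(seed=8)
        a = sd.generate_control_hybs(sd.generate_universe(cfg))
        b = sd.generate_control_hybs(sd.generate_universe(cfg))
        for key in a:
            pd.testing.assert_frame_equal(a[key].values, b[key].values)


class TestXenograftArrays:
    def test_sample_sheet_lists_two_n_per_group_per_chip(self):
        cfg = _cfg(seed=9, n_per_group=5)
        xeno, sheet = sd.generate_xenograft_arrays(sd.generate_universe(cfg))
        for sp in (HUMAN, MOUSE):
            assert len(xeno[sp].sample_ids) == 10
            groups = sheet.groups(sp)
            assert len(groups["untreated"]) == 5
            assert len(groups["treated"]) == 5

    def test_null_config_has_no_group_difference(self):
        cfg = _cfg(seed=10, treatment_sets=())
        uni = sd.generate_universe(cfg)
        xeno, sheet = sd.generate_xenograft_arrays(uni)
        m = xeno[MOUSE].values
        groups = sheet.groups(MOUSE)
        logd = (np.log2(m[groups["treated"]]).mean(axis=1)
                - np.log2(m[groups["untreated"]]).mean(axis=1))
        se = logd.std(ddof=1) / np.sqrt(len(logd))
        assert abs(logd.mean()) < 4 * se + 1e-12

    def test_planted_effect_recovered_at_probe_level(self):
        # plant log2FC = 2 with zero spread; after removing the additive
        # background the observed group difference matches within 3 s.e.
        cfg = _cfg(
            seed=11,
            baseline_log2_mean=10.0,  # bright, so background subtraction is clean
            treatment_sets=(sd.TreatmentSet("NFKB_TARGETS", 10, 2.0, 0.0),),
        )
        uni = sd.generate_universe(cfg)
        xeno, sheet = sd.generate_xenograft_arrays(uni)
        pm = uni.probeset_maps[MOUSE]
        truth = uni.truth
        member_ps = [ps for ps, v in truth.true_log2fc[MOUSE].items() if v != 0.0]
        probes = [p for ps in member_ps for p in pm.probes_of(ps)]
        m = xeno[MOUSE].values.loc[probes]
        groups = sheet.groups(MOUSE)
        sig = np.log2(np.maximum(m - cfg.background_mean, 1.0))
        deltas = (sig[groups["treated"]].mean(axis=1)
                  - sig[groups["untreated"]].mean(axis=1))
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean() - 2.0) < 3 * se + 0.02


class TestCytokinePanel:
    def _run(self, seed=12, cytokines=None):
        kw = {"seed": seed}
        if cytokines is not None:
            kw["cytokines"] = cytokines
        cfg = _cfg(**kw)
        uni = sd.generate_universe(cfg)
        return sd.generate_cytokine_panel(uni), cfg

    def test_three_mice_per_group(self):
        (panel, _), cfg = self._run()
        counts = panel.groupby(["analyte", "group"]).size()
        assert (counts == cfg.n_mice_per_group).all()

    def test_gamma_one_protein_fold_equals_rna_fold(self):
        (_, truth), _ = self._run()
        g1 = truth[truth["gamma"] == 1.0]
        np.testing.assert_allclose(g1["protein_fold"], g1["rna_fold"], rtol=1e-12)

    def test_gamma_68_gives_68_fold_protein_with_flat_rna(self):
        (_, truth), _ = self._run()
        gcsf = truth[truth["analyte"] == "GCSF_like"].iloc[0]
        assert gcsf["rna_fold"] == pytest.approx(1.0)
        assert gcsf["protein_fold"] == pytest.approx(68.0)
        assert bool(gcsf["post_transcriptional"])

    def test_induced_genes_live_in_treatment_sets(self):
        (_, truth), _ = self._run()
        for row in truth.itertuples():
            if row.gamma == 1.0 and row.rna_fold > 1.0:
                continue  # induced, fold from the planted effect
            if not row.post_transcriptional:
                continue
            assert row.rna_fold == pytest.approx(1.0)


class TestGrowthCurves:
    def test_untreated_monotone_in_expectation(self):
        cfg = _cfg(seed=13)
        cfg = cfg.with_(growth=sd.GrowthModel(noise_sd=0.0, v0_cv=0.0))
        records, truth = sd.generate_growth_curves(cfg)
        for _, sub in records[records["group"] == "untreated"].groupby("mouse_id"):
            vols = [tm.tumour_volume(a, b) for a, b in zip(sub["a_mm"], sub["b_mm"])]
            assert np.all(np.diff(vols) >= -1e-9)

    def test_noise_free_delay_equals_interpolated_crossing(self):
        cfg = _cfg(seed=14).with_(growth=sd.GrowthModel(noise_sd=0.0, v0_cv=0.0))
        records, truth = sd.generate_growth_curves(cfg)
        _, group_mean = tm.relative_growth(records)
        treated = group_mean[group_mean["group"] == "treated"]
        delay = tm.growth_delay(treated[["day", "mean"]])
        assert delay == pytest.approx(truth.growth_expected_measured_delay, abs=1e-9)
        # and close to the analytic piecewise-exponential crossing
        assert delay == pytest.approx(truth.growth_crossing_time, abs=2.0)

    def test_seeded_reproducibility(self):
        cfg = _cfg(seed=15)
        a, _ = sd.generate_growth_curves(cfg)
        b, _ = sd.generate_growth_curves(cfg)
        pd.testing.assert_frame_equal(a, b)


class TestNecrosisMask:
    def test_target_zero_empty(self):
        cfg = _cfg(seed=16).with_(necrosis=sd.NecrosisMaskSpec(target_fraction=0.0))
        mask, realised = sd.generate_necrosis_mask(cfg)
        assert realised == 0.0
        assert not mask.any()

    def test_target_one_full(self):
        cfg = _cfg(seed=17).with_(necrosis=sd.NecrosisMaskSpec(target_fraction=1.0))
        mask, realised = sd.generate_necrosis_mask(cfg)
        assert realised == 1.0
        assert mask.all()

    def test_target_half_within_tolerance(self):
        cfg = _cfg(seed=18).with_(necrosis=sd.NecrosisMaskSpec(target_fraction=0.5))
        _, realised = sd.generate_necrosis_mask(cfg)
        assert 0.49 <= realised <= 0.51

    def test_unreachable_target_errors(self):
        cfg = _cfg(seed=19).with_(necrosis=sd.NecrosisMaskSpec(
            target_fraction=0.9, blob_radius_px=(1, 1), max_iter=5))
        with pytest.raises(RuntimeError, match="not reached"):
            sd.generate_necrosis_mask(cfg)

    def test_png_round_trip(self, tmp_path):
        cfg = _cfg(seed=20).with_(necrosis=sd.NecrosisMaskSpec(target_fraction=0.3))
        mask, _ = sd.generate_necrosis_mask(cfg)
        path = tmp_path / "m.png"
        sd.write_mask_png(mask, path, 2.0)
        back = sd.read_mask_png(path)
        np.testing.assert_array_equal(back, mask)
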