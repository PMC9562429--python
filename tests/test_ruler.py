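"""Proteomic-ruler copy numbers, fraction weighting, organelle masses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spatmap as sm
from _utils import build_cmap, classify_both, prep_experiment
from spatmap.dl_detect import merge_nuclear
from spatmap.ruler import (
    RulerConfig,
    copies_per_cell,
    cross_method_agreement,
    derive_ploidy,
    organelle_masses,
    top_contributors,
    weight_tmt_fractions,
)
from spatmap.synthetic import AVOGADRO, BP_MOLAR_MASS, fraction_yields


class TestPloidy:
    def test_cho_against_mouse_is_1_76(self):
        assert derive_ploidy(2.399e9, 2.72e9) == pytest.approx(1.76)

    def test_equal_genomes_diploid(self):
        assert derive_ploidy(3e9, 3e9) == 2.0

    def test_half_reference_haploid(self):
        assert derive_ploidy(1.5e9, 3e9) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            derive_ploidy(0, 3e9)


class TestWeighting:
    def _map(self, rows):
        return pd.DataFrame(
            rows, index=[f"P{i}" for i in range(len(rows))],
            columns=range(1, len(rows[0]) + 1),
        )

    def test_equal_yields_single_protein_proportional_to_plain_sum(self):
        m = self._map([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]])
        yields = pd.Series(2.0, index=m.columns)
        summed, _ = weight_tmt_fractions(m, yields)
        # single protein: each channel normalizes to 1, weighted sum = sum of yields
        assert summed.iloc[0] == pytest.approx(20.0)

    def test_fraction1_only_protein_has_nucleus_share_one(self):
        m = self._map([[5.0] + [0.0] * 9, [1.0] * 10])
        yields = pd.Series(1.0, index=m.columns)
        _, shares = weight_tmt_fractions(m, yields)
        np.testing.assert_allclose(shares.loc["P0"], [1.0, 0.0, 0.0])

    def test_uniform_protein_equal_yields_shares(self):
        m = self._map([[1.0] * 10])
        yields = pd.Series(1.0, index=m.columns)
        _, shares = weight_tmt_fractions(m, yields)
        np.testing.assert_allclose(shares.loc["P0"], [0.1, 0.8, 0.1])

    def test_zero_channel_total_is_error(self):
        m = self._map([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="channel"):
            weight_tmt_fractions(m, pd.Series(1.0, index=m.columns),
                                 nucleus_fractions=(1,), cytosol_fractions=(2,))


class TestCopies:
    def test_hand_arithmetic_oracle(self):
        # target m_DNA * N_A = 3.613e12 g/mol
        cfg = RulerConfig(genome_size_bp=3.613e12 / BP_MOLAR_MASS, ploidy=1.0)
        intensities = pd.Series({"X": 10.0, "H1": 60.0, "H2": 40.0})
        mw = pd.Series({"X": 1e4, "H1": 1.4e4, "H2": 1.4e4})
        out = copies_per_cell(intensities, mw, ["H1", "H2"], cfg)
        assert out.loc["X", "copies_per_cell"] == pytest.approx(
            0.1 * 3.613e12 / 1e4, rel=1e-9
        )
        assert out.loc["X", "mass_per_cell"] == pytest.approx(
            out.loc["X", "copies_per_cell"] * 1e4 / AVOGADRO
        )

    def test_scale_invariance(self):
        cfg = RulerConfig(genome_size_bp=2.7e9, ploidy=2.0)
        intensities = pd.Series({"X": 10.0, "H": 100.0})
        mw = pd.Series({"X": 1e4, "H": 1.4e4})
        a = copies_per_cell(intensities, mw, ["H"], cfg)
        b = copies_per_cell(intensities * 7.3, mw, ["H"], cfg)
        pd.testing.assert_series_equal(a["copies_per_cell"], b["copies_per_cell"])

    def test_no_histones_is_error(self):
        cfg = RulerConfig(genome_size_bp=2.7e9, ploidy=2.0)
        with pytest.raises(ValueError, match="histone"):
            copies_per_cell(pd.Series({"X": 1.0}), pd.Series({"X": 1e4}), [], cfg)

    def test_derived_ploidy_config(self):
        cfg = RulerConfig(genome_size_bp=2.399e9, reference_genome_size_bp=2.72e9)
        assert cfg.effective_ploidy == pytest.approx(1.76)


def _ruler_inputs(noise_sd=0.05, seed=41, **kwargs):
    cfg = sm.SimulationConfig(
        n_proteins=440, marker_fraction=0.5, noise_sd=noise_sd, seed=seed, **kwargs
    )
    truth = sm.generate_truth(cfg)
    return cfg, truth


class TestRecovery:
    def test_copies_recovered_from_weighted_fractions(self):
        cfg, truth = _ruler_inputs()
        raw = sm.simulate_replicate_map(truth, cfg, "A", 1)
        yields = fraction_yields(truth, cfg, "A")
        summed, _ = weight_tmt_fractions(raw, yields)
        rcfg = RulerConfig(genome_size_bp=cfg.genome_size_bp, ploidy=cfg.ploidy)
        hist = truth.table.loc[truth.table.is_histone, "accession"].tolist()
        out = copies_per_cell(summed, truth.mw, hist, rcfg)
        err = np.abs(np.log2(out["copies_per_cell"] / truth.copies("A")))
        assert err.median() <= 0.15

    def test_exact_recovery_in_zero_noise_limit(self):
        cfg, truth = _ruler_inputs(noise_sd=0.0, organelle_shift_sd=0.0)
        raw = sm.simulate_replicate_map(truth, cfg, "A", 1)
        yields = fraction_yields(truth, cfg, "A")
        summed, _ = weight_tmt_fractions(raw, yields)
        rcfg = RulerConfig(genome_size_bp=cfg.genome_size_bp, ploidy=cfg.ploidy)
        hist = truth.table.loc[truth.table.is_histone, "accession"].tolist()
        out = copies_per_cell(summed, truth.mw, hist, rcfg)
        np.testing.assert_allclose(
            out["copies_per_cell"], truth.copies("A"), rtol=1e-6
        )


class TestOrganelleMasses:
    def _setup(self, labels, shares_rows, masses):
        accs = list(labels)
        cm = build_cmap({a: (labels[a], 0.9, False) for a in accs})
        copies = pd.DataFrame(
            {"mass_per_cell": pd.Series(masses, index=accs, dtype=float)}
        )
        shares = pd.DataFrame(
            shares_rows, index=accs, columns=["nucleus", "organelle", "cytosol"]
        )
        return copies, cm, shares

    def test_single_er_protein_all_organelle_share(self):
        copies, cm, shares = self._setup(
            {"P1": "ER"}, [[0.0, 1.0, 0.0]], {"P1": 2.0}
        )
        out = organelle_masses(copies, cm, shares)
        assert out["ER"] == pytest.approx(1.0)

    def test_all_unknown_pools_to_one(self):
        copies, cm, shares = self._setup(
            {"P1": "unknown", "P2": "unknown"},
            [[0.2, 0.6, 0.2]] * 2, {"P1": 1.0, "P2": 3.0},
        )
        out = organelle_masses(copies, cm, shares)
        assert out["unknown"] == pytest.approx(1.0)

    def test_mass_closure(self, small_experiment):
        truth, reps, combined, marker_set = small_experiment
        cfg = truth.config
        cms = classify_both(combined, marker_set, threshold=0.0)
        raw = sm.simulate_replicate_map(truth, cfg, "A", 1)
        yields = fraction_yields(truth, cfg, "A")
        summed, shares = weight_tmt_fractions(raw, yields)
        rcfg = RulerConfig(genome_size_bp=cfg.genome_size_bp, ploidy=cfg.ploidy)
        hist = truth.table.loc[truth.table.is_histone, "accession"].tolist()
        copies = copies_per_cell(summed, truth.mw, hist, rcfg)
        out = organelle_masses(copies, merge_nuclear(cms["A"]), shares)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert (out >= 0).all()

    def test_inflated_er_mass_detected_across_replicates(self):
        base = sm.SimulationConfig(n_proteins=440, marker_fraction=0.5,
                                   noise_sd=0.1, seed=43)
        truth0 = sm.generate_truth(base)
        er = truth0.table.loc[
            truth0.table.compartment_A == "ER", "accession"
        ].tolist()
        cfg = base.replace(
            expression_changes=tuple((a, np.log2(1.5)) for a in er)
        )
        truth = sm.generate_truth(cfg)
        rcfg = RulerConfig(genome_size_bp=cfg.genome_size_bp, ploidy=cfg.ploidy)
        hist = truth.table.loc[truth.table.is_histone, "accession"].tolist()
        labels = truth.compartment("A")
        fracs = {}
        for cond in ("A", "B"):
            yields = fraction_yields(truth, cfg, cond)
            vals = []
            for rep in (1, 2, 3):
                raw = sm.simulate_replicate_map(truth, cfg, cond, rep)
                summed, shares = weight_tmt_fractions(raw, yields)
                copies = copies_per_cell(summed, truth.mw, hist, rcfg)
                cm = build_cmap(
                    {a: (labels[a], 0.9, False) for a in raw.index},
                    taxonomy=cfg.compartments, n_fractions=10,
                )
                vals.append(organelle_masses(copies, cm, shares)["ER"])
            fracs[cond] = vals
        t = stats.ttest_ind(fracs["B"], fracs["A"])
        assert np.mean(fracs["B"]) > np.mean(fracs["A"])
        assert t.pvalue < 0.05


class TestTopContributors:
    def _inputs(self):
        cm = build_cmap({f"P{i}": ("ER", 0.9, False) for i in range(3)})
        copies = pd.DataFrame(
            {"mass_per_cell": [5.0, 1.0, 0.5]}, index=["P0", "P1", "P2"]
        )
        return copies, cm

    def test_k_larger_than_cluster_returns_all(self):
        copies, cm = self._inputs()
        out = top_contributors(copies, cm, "ER", k=10)
        assert len(out) == 3

    def test_dominant_protein_first_and_shares_bounded(self):
        copies, cm = self._inputs()
        out = top_contributors(copies, cm, "ER", k=2)
        assert out.index[0] == "P0"
        assert out["mass_share"].sum() <= 1.0 + 1e-12


class TestCrossMethod:
    def test_identical_tables(self):
        c = pd.Series([10.0, 100.0, 1000.0], index=list("abc"))
        r, slope = cross_method_agreement(c, c)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_constant_factor_offsets_only(self):
        c = pd.Series([10.0, 100.0, 1000.0], index=list("abc"))
        r, slope = cross_method_agreement(c, 2 * c)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_noisy_estimates_still_correlate(self):
        rng = np.random.default_rng(5)
        true = pd.Series(
            np.exp(rng.normal(10, 1.5, 300)), index=[f"P{i}" for i in range(300)]
        )
        a = true * np.exp(rng.normal(0, 0.3, 300))
        b = true * np.exp(rng.normal(0, 0.3, 300))
        r, _ = cross_method_agreement(a, b)
        assert r > 0.6

    def test_small_overlap_is_error(self):
        with pytest.raises(ValueError):
            cross_method_agreement(
                pd.Series({"a": 1.0, "b": 2.0}), pd.Series({"a": 1.0, "b": 2.0})
            )
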