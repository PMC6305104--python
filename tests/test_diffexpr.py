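"""Paired NB differential expression: recovery, calibration, gating, FDR."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mirpair as mp
from mirpair.diffexpr import DEFit
from conftest import make_paired_set


def _flat_offsets(pes, value=10.0):
    return pd.Series(value, index=pes.sample_ids)


class TestFitPairedNB:
    def test_doubled_counts_recover_twofold_effect(self):
        rng = np.random.default_rng(60)
        normal = rng.negative_binomial(8, 8 / (8 + 60.0), size=30)
        vals = np.empty((1, 60))
        vals[0, 0::2] = normal
        vals[0, 1::2] = 2 * normal
        pes = make_paired_set(vals, 30)
        fit = mp.fit_paired_nb(pes.values.iloc[0], pes.subject_of, pes.tissue_of, _flat_offsets(pes))
        assert 1.8 <= np.exp(fit.beta_t) <= 2.2

    def test_identical_tissues_give_null_effect(self):
        rng = np.random.default_rng(61)
        normal = rng.negative_binomial(5, 5 / (5 + 40.0), size=25) + 1
        vals = np.repeat(normal[None, :], 2, axis=0).T.reshape(1, -1, order="F")
        vals = np.empty((1, 50))
        vals[0, 0::2] = normal
        vals[0, 1::2] = normal
        pes = make_paired_set(vals, 25)
        fit = mp.fit_paired_nb(pes.values.iloc[0], pes.subject_of, pes.tissue_of, _flat_offsets(pes))
        assert abs(fit.beta_t) < 0.05
        assert fit.p_raw > 0.5

    def test_all_zero_gene_flagged_with_unit_p(self):
        pes = make_paired_set(np.zeros((1, 10)), 5)
        fit = mp.fit_paired_nb(pes.values.iloc[0], pes.subject_of, pes.tissue_of, _flat_offsets(pes))
        assert fit.p_raw == 1.0 and fit.flag == "all_zero"

    def test_too_few_pairs_rejected(self):
        pes = make_paired_set(np.ones((1, 4)), 2)
        with pytest.raises(ValueError, match="3 complete pairs"):
            mp.fit_paired_nb(pes.values.iloc[0], pes.subject_of, pes.tissue_of, _flat_offsets(pes))

    def test_random_and_fixed_intercepts_agree_on_simulated_gene(self):
        lfc = np.r_[0.7, np.zeros(99)]
        cfg = mp.SimulationConfig(n_subjects=25, n_genes=100, n_mirnas=2, seed=62, tumor_log_fc=lfc)
        counts, _ = mp.simulate_paired_counts(cfg)
        off = pd.Series(np.log(counts.values.sum(0).astype(float)), index=counts.sample_ids)
        y = counts.values.loc["G0000"]
        rand = mp.fit_paired_nb(y, counts.subject_of, counts.tissue_of, off, method="random")
        fixed = mp.fit_paired_nb(y, counts.subject_of, counts.tissue_of, off, method="fixed")
        assert rand.beta_t == pytest.approx(fixed.beta_t, abs=0.1)
        assert (rand.p_raw < 0.01) == (fixed.p_raw < 0.01)

    def test_wald_and_lrt_agree_in_order_of_magnitude(self):
        cfg = mp.SimulationConfig(n_subjects=40, n_genes=50, n_mirnas=2, seed=63,
                                  tumor_log_fc=np.r_[0.5, np.zeros(49)])
        counts, _ = mp.simulate_paired_counts(cfg)
        off = pd.Series(np.log(counts.values.sum(0).astype(float)), index=counts.sample_ids)
        y = counts.values.loc["G0000"]
        lrt = mp.fit_paired_nb(y, counts.subject_of, counts.tissue_of, off, test="lrt")
        wald = mp.fit_paired_nb(y, counts.subject_of, counts.tissue_of, off, test="wald")
        assert lrt.beta_t == wald.beta_t
        # the two tests share the estimate and agree broadly in the tail
        assert np.log10(lrt.p_raw) == pytest.approx(np.log10(wald.p_raw), abs=2.5)
        assert lrt.p_raw < 1e-3 and wald.p_raw < 1e-3

    def test_agrees_with_independent_glmm_implementation(self, tmp_path):
        """Cross-check the Gauss-Hermite ML fit against R's glmmTMB (Laplace)."""
        cfg = mp.SimulationConfig(n_subjects=60, n_genes=100, n_mirnas=2, seed=42,
                                  tumor_log_fc=np.r_[0.8, np.zeros(99)], subject_sd=0.4)
        counts, _ = mp.simulate_paired_counts(cfg)
        off = pd.Series(np.log(counts.values.sum(0).astype(float)), index=counts.sample_ids)
        y = counts.values.loc["G0000"]
        fit = mp.fit_paired_nb(y, counts.subject_of, counts.tissue_of, off)
        df = pd.DataFrame({
            "y": y.values,
            "subject": counts.subject_of.loc[y.index].values,
            "tumor": (counts.tissue_of.loc[y.index] == "carcinoma").astype(int).values,
            "off": off.loc[y.index].values,
        })
        csv = tmp_path / "gene.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(glmmTMB))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmmTMB(y ~ tumor + (1|subject) + offset(off), family=nbinom2, data=d)\n"
            "cat(fixef(m)$cond['tumor'], sigma(m), '\\n')\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, check=True)
        beta_r, theta_r = map(float, out.stdout.split())
        assert fit.beta_t == pytest.approx(beta_r, abs=5e-3)
        assert fit.theta == pytest.approx(theta_r, rel=0.02)

    def test_type_one_error_near_nominal_under_null(self):
        cfg = mp.SimulationConfig(n_subjects=40, n_genes=400, n_mirnas=2, seed=64)
        counts, _ = mp.simulate_paired_counts(cfg)
        off = pd.Series(np.log(counts.values.sum(0).astype(float)), index=counts.sample_ids)
        ps = np.array([
            mp.fit_paired_nb(counts.values.loc[g], counts.subject_of, counts.tissue_of, off).p_raw
            for g in cfg.gene_ids
        ])
        rate = (ps < 0.05).mean()
        # binomial 95% band around 0.05 at 400 tests
        assert 0.0286 <= rate <= 0.0714

    def test_power_increases_with_effect_size(self):
        # the effect is planted in 40 of 300 genes so the protein-coding
        # offset (a relative-abundance denominator) is barely moved
        powers = []
        for i, lfc in enumerate((0.0, 0.25, 0.6)):
            effects = np.r_[np.full(40, lfc), np.zeros(260)]
            cfg = mp.SimulationConfig(n_subjects=30, n_genes=300, n_mirnas=2, seed=70 + i,
                                      tumor_log_fc=effects)
            counts, _ = mp.simulate_paired_counts(cfg)
            off = pd.Series(np.log(counts.values.sum(0).astype(float)), index=counts.sample_ids)
            ps = np.array([
                mp.fit_paired_nb(counts.values.loc[g], counts.subject_of, counts.tissue_of, off).p_raw
                for g in cfg.gene_ids[:40]
            ])
            powers.append((ps < 0.05).mean())
        assert powers[0] < powers[1] < powers[2]
        assert powers[2] > 0.9


class TestFoldChange:
    def test_identical_tissues_unity(self):
        vals = np.tile(np.array([[7.0, 7.0, 3.0, 3.0]]), (1, 1))
        norm = mp.rpmpcg_normalize(make_paired_set(vals, 2))
        _, _, fc = mp.fold_change(norm, "F000")
        assert fc == pytest.approx(1.0)

    def test_printed_convention_on_myc_like_means(self):
        # normalized set whose tissue means are the printed MYC values
        from mirpair.containers import NormalizedSet
        base = make_paired_set(np.array([[49.00, 181.11, 49.00, 181.11]]), 2)
        norm = NormalizedSet(base.values, base.subject_of, base.tissue_of, normalization="RPMPCG")
        mc, mn, fc = mp.fold_change(norm, "F000")
        assert (round(mc, 2), round(mn, 2), round(fc, 2)) == (181.11, 49.00, 3.70)

    def test_zero_normal_mean_flagged_nan(self):
        from mirpair.containers import NormalizedSet
        base = make_paired_set(np.array([[0.0, 5.0, 0.0, 5.0]]), 2)
        norm = NormalizedSet(base.values, base.subject_of, base.tissue_of, normalization="RPMPCG")
        assert np.isnan(mp.fold_change(norm, "F000")[2])


class TestBHAndGate:
    def test_hand_stepup(self):
        np.testing.assert_allclose(mp.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert mp.bh_adjust([0.03]) == pytest.approx([0.03])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw(self, ps):
        adj = mp.bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            mp.bh_adjust([0.5, 1.5])

    def test_gate_boundaries(self):
        records = pd.DataFrame({
            "gene": ["HRAS_like", "TSLP_like", "weak", "insignificant"],
            "fc": [1.50, 0.66, 1.20, 3.0],
            "p_adj": [0.001, 0.047, 0.001, 0.06],
        })
        assert mp.fc_gate(records) == ["TSLP_like"]

    def test_gate_fdr_threshold_inclusive(self):
        records = pd.DataFrame({"gene": ["a"], "fc": [2.0], "p_adj": [0.05]})
        assert mp.fc_gate(records) == ["a"]


class TestStrata:
    def test_set_difference_semantics(self):
        assert mp.stratum_unique({"A", "B"}, {"B", "C"}) == {"C"}
        assert mp.stratum_unique({"A", "B"}, {"A"}) == set()

    def test_msi_only_effect_found_in_stratum(self):
        # MSI subjects carry a 2-fold effect on G0000; MSS subjects are null,
        # so the pooled fold change stays below the 1.50 gate.
        lfc = np.r_[np.log(2.0), np.zeros(59)]
        msi_cfg = mp.SimulationConfig(n_subjects=15, n_genes=60, n_mirnas=2, seed=80, tumor_log_fc=lfc)
        mss_cfg = mp.SimulationConfig(n_subjects=60, n_genes=60, n_mirnas=2, seed=81)
        msi_counts, _ = mp.simulate_paired_counts(msi_cfg)
        mss_counts, _ = mp.simulate_paired_counts(mss_cfg)
        msi_vals = msi_counts.values.rename(columns=lambda c: "MSI-" + c)
        mss_vals = mss_counts.values.rename(columns=lambda c: "MSS-" + c)
        values = pd.concat([mss_vals, msi_vals], axis=1)
        subject_of = pd.Series({c: c.rsplit("-", 1)[0] for c in values.columns})
        tissue_of = pd.Series({c: ("normal" if c.endswith("-N") else "carcinoma") for c in values.columns})
        combined = mp.PairedExpressionSet(values, subject_of, tissue_of)
        meta = pd.DataFrame({
            "sample_id": values.columns,
            "subject_id": [subject_of[c] for c in values.columns],
            "tissue": [tissue_of[c] for c in values.columns],
            "age": 65.0,
            "sex": 1,
            "msi": [int(c.startswith("MSI")) for c in values.columns],
        })
        from mirpair.pipeline import run_stratified_de

        fits, unique = run_stratified_de(combined, meta, genes=["G0000", "G0001", "G0002"])
        assert "G0000" in unique["MSI"]
        assert "G0000" not in fits["overall"].passed_genes_


class TestPairedNBDEEstimator:
    def test_end_to_end_gate_recovers_planted_gene(self, small_study):
        cfg, counts, truth = small_study
        de = mp.PairedNBDE(genes=cfg.gene_ids[:10]).fit(counts)
        assert de.results_.shape[0] == 10
        assert "G0000" in de.passed_genes_
        res = de.results_.set_index("gene")
        assert (res["p_adj"].dropna() >= res["p_raw"].dropna() - 1e-12).all()

    def test_gate_invariant_to_gene_ordering(self, small_study):
        cfg, counts, _ = small_study
        genes = cfg.gene_ids[:8]
        a = mp.PairedNBDE(genes=genes).fit(counts).passed_genes_
        b = mp.PairedNBDE(genes=genes[::-1]).fit(counts).passed_genes_
        assert set(a) == set(b)
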