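"""Quantification and enrichment statistics against independent oracles,
including a Bioconductor limma cross-check of the moderated test."""

import json
import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from thermolock.proteomics import (
    BAIT,
    CONTROL,
    ProteinQuant,
    SyntheticProteomeSpec,
    enrichment_pipeline,
    fit_variance_prior,
    fold_change_call,
    impute_missing,
    moderated_test,
    simulate_peptide_table,
    simulate_protein_table,
    top3_protein_area,
)


def quant_from_matrix(bait, control):
    bait = np.asarray(bait, dtype=float)
    control = np.asarray(control, dtype=float)
    cols = pd.MultiIndex.from_tuples(
        [(BAIT, r + 1) for r in range(bait.shape[1])]
        + [(CONTROL, r + 1) for r in range(control.shape[1])],
        names=["condition", "replicate"])
    df = pd.DataFrame(np.concatenate([bait, control], axis=1),
                      index=[f"P{i}" for i in range(len(bait))], columns=cols)
    return ProteinQuant(areas=df)


class TestTop3:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["protein", "peptide", "replicate",
                                           "condition", "area"])

    def test_mean_of_top_three(self):
        rows = [("P1", f"pep{k}", 1, BAIT, a) for k, a in
                enumerate([10.0, 20.0, 30.0, 40.0])]
        quant = top3_protein_area(self._table(rows))
        assert quant.areas.loc["P1", (BAIT, 1)] == pytest.approx(30.0)

    def test_fewer_than_three_uses_all(self):
        rows = [("P1", "a", 1, BAIT, 10.0), ("P1", "b", 1, BAIT, 20.0)]
        quant = top3_protein_area(self._table(rows))
        assert quant.areas.loc["P1", (BAIT, 1)] == pytest.approx(15.0)

    def test_matches_sort_and_average_oracle(self):
        spec = SyntheticProteomeSpec(n_proteins=50, n_enriched=5,
                                     missing_rate=0.0, seed=7)
        table, _ = simulate_peptide_table(spec)
        quant = top3_protein_area(table)
        for (prot, cond, rep), grp in table.groupby(
                ["protein", "condition", "replicate"]):
            top = np.sort(grp["area"].to_numpy())[::-1][:3].mean()
            assert quant.areas.loc[prot, (cond, rep)] == pytest.approx(top)

    def test_negative_areas_rejected(self):
        rows = [("P1", "a", 1, BAIT, -4.0)]
        with pytest.raises(ValueError):
            top3_protein_area(self._table(rows))


class TestImputation:
    def test_mean_of_column_minima(self):
        quant = quant_from_matrix([[1.0, 2.0], [5.0, np.nan]],
                                  [[3.0, 4.0], [7.0, 8.0]])
        filled, summary = impute_missing(quant)
        assert summary.value == pytest.approx((1 + 2 + 3 + 4) / 4)
        assert filled.areas.loc["P1", (BAIT, 2)] == pytest.approx(2.5)
        assert summary.n_imputed == 1

    def test_no_missing_identity(self):
        quant = quant_from_matrix([[1.0, 2.0]], [[3.0, 4.0]])
        filled, summary = impute_missing(quant)
        assert summary.n_imputed == 0
        pd.testing.assert_frame_equal(filled.areas, quant.areas)

    def test_random_pattern_fills_everything_preserving_observed(self):
        spec = SyntheticProteomeSpec(n_proteins=200, n_enriched=20,
                                     missing_rate=0.15, seed=3)
        quant, _ = simulate_protein_table(spec)
        assert quant.has_missing
        filled, _ = impute_missing(quant)
        assert not filled.has_missing
        obs = ~quant.areas.isna()
        assert np.array_equal(filled.areas.values[obs.values],
                              quant.areas.values[obs.values])

    def test_empty_column_rejected(self):
        quant = quant_from_matrix([[np.nan, 2.0], [np.nan, 3.0]],
                                  [[1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError):
            impute_missing(quant)


class TestFoldChange:
    def test_two_fold_rule(self):
        quant = quant_from_matrix([[400.0, 400.0], [190.0, 190.0]],
                                  [[100.0, 100.0], [100.0, 100.0]])
        out = fold_change_call(quant)
        assert out.loc["P0", "log2_fold_change"] == pytest.approx(2.0)
        assert bool(out.loc["P0", "enriched"])
        assert out.loc["P1", "log2_fold_change"] == pytest.approx(
            np.log2(1.9))
        assert not bool(out.loc["P1", "enriched"])

    def test_planted_fourfold_recall(self):
        spec = SyntheticProteomeSpec(n_proteins=1000, n_enriched=50,
                                     log2_effect=2.0, seed=11)
        quant, truth = simulate_protein_table(spec)
        out = enrichment_pipeline(quant, "turboid")
        called = out["enriched"].to_numpy()
        recall = (called & truth).sum() / truth.sum()
        assert recall >= 0.9


def straight_line_moderated(bait_log2, ctrl_log2):
    """Independent re-implementation of the shrinkage formulas."""
    b, c = np.asarray(bait_log2), np.asarray(ctrl_log2)
    n1, n2 = b.shape[1], c.shape[1]
    df = n1 + n2 - 2
    diff = b.mean(1) - c.mean(1)
    s2 = (((b - b.mean(1, keepdims=True)) ** 2).sum(1)
          + ((c - c.mean(1, keepdims=True)) ** 2).sum(1)) / df
    ok = s2 > 0
    e = np.log(s2[ok]) - special.digamma(df / 2) + np.log(df / 2)
    ebar = e.mean()
    evar = ((e - ebar) ** 2).sum() / len(e)
    target = evar - special.polygamma(1, df / 2)
    if target > 0:
        # invert trigamma by bisection (deliberately different from the
        # package's Newton iteration)
        lo, hi = 1e-6, 1e8
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if special.polygamma(1, mid) > target:
                lo = mid
            else:
                hi = mid
        half_d0 = np.sqrt(lo * hi)
        d0 = 2 * half_d0
        s0 = np.exp(ebar + special.digamma(half_d0) - np.log(half_d0))
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_tot = df + d0
        t = diff / np.sqrt(s2_post * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(np.abs(t), df_tot)
    else:
        s0 = np.exp(ebar)
        t = diff / np.sqrt(s0 * (1 / n1 + 1 / n2))
        p = 2 * stats.norm.sf(np.abs(t))
    return t, p


class TestModerated:
    def _fixture(self, seed=5, n=20):
        rng = np.random.default_rng(seed)
        base = rng.normal(20, 2, n)
        bait = 2.0 ** (base[:, None] + rng.normal(0, 0.5, (n, 4))
                       + np.where(np.arange(n)[:, None] < 5, 2.0, 0.0))
        ctrl = 2.0 ** (base[:, None] + rng.normal(0, 0.5, (n, 4)))
        return quant_from_matrix(bait, ctrl)

    def test_matches_straight_line_oracle(self):
        quant = self._fixture()
        out = moderated_test(quant)
        b = np.log2(quant.condition(BAIT).to_numpy())
        c = np.log2(quant.condition(CONTROL).to_numpy())
        t_ref, p_ref = straight_line_moderated(b, c)
        assert np.allclose(out["moderated_t"].to_numpy(), t_ref, atol=1e-8)
        assert np.allclose(out["p_value"].to_numpy(), p_ref, atol=1e-8)

    def test_null_table_calls_nothing(self):
        rng = np.random.default_rng(0)
        base = 2.0 ** rng.normal(20, 2, (50, 1))
        bait = np.repeat(base, 4, axis=1)
        ctrl = np.repeat(base, 4, axis=1)
        # identical within-condition values, zero effect: nothing enriched
        out = moderated_test(quant_from_matrix(bait, ctrl))
        assert not out["enriched"].any()

    def test_scale_equivariance(self):
        quant = self._fixture()
        scaled = ProteinQuant(areas=quant.areas * 1000.0)
        a = moderated_test(quant)
        b = moderated_test(scaled)
        for col in ("log2_fold_change", "moderated_t", "p_value", "adjusted_p"):
            assert np.allclose(a[col].to_numpy(), b[col].to_numpy(),
                               rtol=1e-10, equal_nan=True)

    def test_determinism(self):
        quant = self._fixture()
        pd.testing.assert_frame_equal(moderated_test(quant),
                                      moderated_test(quant))

    def test_single_seed_planted_recovery(self):
        spec = SyntheticProteomeSpec(seed=1)
        quant, truth = simulate_protein_table(spec)
        out = enrichment_pipeline(quant, "ipms")
        called = out["enriched"].to_numpy()
        recall = (called & truth).sum() / truth.sum()
        fdp = (called & ~truth).sum() / max(called.sum(), 1)
        assert recall >= 0.9
        assert fdp <= 0.1

    def test_null_fdr_controlled_single_seed(self):
        spec = SyntheticProteomeSpec(n_proteins=2000, n_enriched=0,
                                     missing_rate=0.0, seed=2)
        quant, _ = simulate_protein_table(spec)
        out = enrichment_pipeline(quant, "ipms")
        assert (out["adjusted_p"] < 0.05).mean() <= 0.05


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
class TestLimmaCrossCheck:
    def test_moderated_t_agrees_with_limma(self, tmp_path):
        rng = np.random.default_rng(9)
        n = 40
        base = rng.normal(20, 2, n)
        bait = base[:, None] + rng.normal(0, rng.uniform(0.2, 1.0, n)[:, None],
                                          (n, 4))
        ctrl = base[:, None] + rng.normal(0, 0.5, (n, 4)) \
            + np.where(np.arange(n)[:, None] < 8, -1.5, 0.0)
        quant = quant_from_matrix(2.0 ** bait, 2.0 ** ctrl)
        ours = moderated_test(quant)

        mat = np.concatenate([bait, ctrl], axis=1)
        csv = tmp_path / "log2.csv"
        pd.DataFrame(mat).to_csv(csv, index=False)
        script = tmp_path / "limma.R"
        script.write_text(f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.csv("{csv}"))
        design <- cbind(Intercept=1, Bait=c(rep(1,4), rep(0,4)))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(t=fit$t[, "Bait"], p=fit$p.value[, "Bait"],
                          d0=fit$df.prior, s02=fit$s2.prior)
        write.csv(out, "{tmp_path / 'limma_out.csv'}", row.names=FALSE)
        """)
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "limma_out.csv")
        t_ours = ours["moderated_t"].to_numpy()
        # sign: our contrast is bait - control == limma's Bait coefficient
        assert np.corrcoef(t_ours, ref["t"])[0, 1] > 0.999
        assert np.allclose(t_ours, ref["t"], rtol=0.05, atol=0.05)
        assert np.allclose(ours["p_value"], ref["p"], rtol=0.1, atol=1e-3)


class TestGenerator:
    def test_planted_truth_shape_and_effect(self):
        spec = SyntheticProteomeSpec(n_proteins=300, n_enriched=30,
                                     missing_rate=0.0, seed=4)
        quant, truth = simulate_protein_table(spec)
        assert truth.sum() == 30
        log2fc = np.log2(quant.condition(BAIT).mean(1)
                         / quant.condition(CONTROL).mean(1))
        assert log2fc[truth].mean() == pytest.approx(2.0, abs=0.3)
        assert abs(log2fc[~truth].mean()) < 0.15

    def test_mnar_low_censors_low_values(self):
        spec = SyntheticProteomeSpec(n_proteins=400, n_enriched=0,
                                     missing_rate=0.1, seed=5)
        quant, _ = simulate_protein_table(spec)
        observed = quant.areas.to_numpy()
        missing_frac = np.isnan(observed).mean()
        assert missing_frac == pytest.approx(0.1, abs=0.01)
        # censored cells are the lowest: every observed value exceeds the
        # implied censoring threshold of its table
        spec_full = SyntheticProteomeSpec(n_proteins=400, n_enriched=0,
                                          missing_rate=0.0, seed=5)
        full, _ = simulate_protein_table(spec_full)
        censored = full.areas.to_numpy()[np.isnan(observed)]
        kept = full.areas.to_numpy()[~np.isnan(observed)]
        assert censored.max() <= kept.min() + 1e-9

    def test_determinism(self):
        a, _ = simulate_protein_table(SyntheticProteomeSpec(seed=8))
        b, _ = simulate_protein_table(SyntheticProteomeSpec(seed=8))
        pd.testing.assert_frame_equal(a.areas, b.areas)
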