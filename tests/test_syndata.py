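"""Synthetic cohort generator: LD structure, planted effects, annotations."""

import numpy as np
import pytest

from qtlkit import syndata
from qtlkit.ld import _pairwise_r2
from qtlkit.syndata import SimConfig

from conftest import make_dosages


class TestConfigValidation:
    def test_degenerate_maf_range_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(maf_range=(0.0, 0.0))

    @pytest.mark.parametrize("field, value", [("eqtl_fraction", 1.5), ("ld_decay", 1.0), ("n_samples", 1)])
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ValueError):
            SimConfig(**{field: value})


class TestGenotypes:
    def test_hardy_weinberg_dosage_values(self, small_sim):
        assert set(np.unique(small_sim.genotypes.dosages)) <= {0.0, 1.0, 2.0}

    def test_determinism_under_fixed_seed(self):
        cfg = SimConfig(n_samples=60, n_genes=4, seed=5)
        a = syndata.simulate_all(cfg)
        b = syndata.simulate_all(SimConfig(n_samples=60, n_genes=4, seed=5))
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
        assert a.expression.values.equals(b.expression.values)
        assert a.states.df.equals(b.states.df)
        assert a.truth.planted_eqtls.equals(b.truth.planted_eqtls)

    def test_zero_ld_decay_gives_independence(self):
        cfg = SimConfig(n_samples=300, n_genes=2, ld_decay=0.0, seed=3)
        geno = syndata.simulate_genotypes(cfg)
        r2 = _pairwise_r2(geno.dosages[:50])
        off = r2[np.triu_indices(50, 1)]
        assert np.nanmean(off) < 3.0 / cfg.n_samples

    def test_high_ld_decay_blocks_exceed_crossblock(self):
        cfg = SimConfig(n_samples=300, n_genes=2, ld_decay=0.99, ld_block_size=10, seed=4)
        geno = syndata.simulate_genotypes(cfg)
        r2 = _pairwise_r2(geno.dosages[:50])
        blocks = np.arange(50) // 10
        same = blocks[:, None] == blocks[None, :]
        triu = np.triu(np.ones((50, 50), bool), 1)
        within = np.nanmean(r2[same & triu])
        across = np.nanmean(r2[~same & triu])
        assert within > across + 0.1

    def test_realized_maf_tracks_sampled_maf(self):
        cfg = SimConfig(n_samples=500, n_genes=10, seed=9)
        geno = syndata.simulate_genotypes(cfg)
        p = geno.dosages.mean(axis=1) / 2
        dev = np.abs(np.minimum(p, 1 - p) - np.minimum(geno.sampled_maf, 1 - geno.sampled_maf))
        assert np.quantile(dev, 0.99) < 0.05
        assert dev.mean() < 0.02


class TestTruth:
    def test_causal_variants_within_cis_window(self, small_sim):
        geno, cfg = small_sim.genotypes, small_sim.config
        for row in small_sim.truth.planted_eqtls.itertuples(index=False):
            g = int(row.gene_id.replace("gene", ""))
            tss = syndata.gene_tss(g, cfg)
            pos = geno.pos[geno.index_of(row.variant_id)]
            assert abs(int(pos) - tss) <= cfg.window_bp

    def test_cell_fractions_on_simplex(self, small_sim):
        fr = small_sim.truth.cell_fractions.to_numpy()
        assert (fr >= 0).all()
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-9)

    def test_gwas_leads_mix_causal_and_background(self, small_sim):
        leads = small_sim.truth.gwas_leads
        assert leads["variant_id"].is_unique
        n_causal = int(leads["on_causal"].sum())
        requested = round(small_sim.config.gwas_enriched_fraction * small_sim.config.n_gwas_leads)
        # capped by the number of planted causal variants available
        assert n_causal == min(requested, len(small_sim.truth.planted_eqtls))
        assert 0 < n_causal < len(leads)


class TestExpression:
    def test_noiseless_ols_recovers_slope_exactly(self):
        cfg = SimConfig(
            n_samples=80, n_genes=6, eqtl_fraction=1.0, secondary_fraction=0.0,
            noise_sd=0.0, batch_sd=0.0, cell_signature_sd=0.0, seed=21,
        )
        sim = syndata.simulate_all(cfg)
        row = sim.truth.planted_eqtls.iloc[0]
        exon = row.affected_exons[0]
        y = sim.expression.values.loc[f"{row.gene_id}_exon{exon}"].to_numpy()
        d = sim.genotypes.row(row.variant_id)
        slope = np.polyfit(d, y, 1)[0]
        assert slope == pytest.approx(row.slope, abs=1e-10)

    def test_two_variant_ols_recovers_both_slopes(self):
        cfg = SimConfig(
            n_samples=400, n_genes=8, eqtl_fraction=1.0, secondary_fraction=1.0,
            batch_sd=0.0, cell_signature_sd=0.0, seed=22,
        )
        sim = syndata.simulate_all(cfg)
        planted = sim.truth.planted_eqtls
        two = planted.groupby("gene_id").filter(lambda g: len(g) == 2)
        assert len(two) > 0
        gene = two["gene_id"].iloc[0]
        pri, sec = [r for r in two[two["gene_id"] == gene].itertuples(index=False)]
        exon = set(pri.affected_exons) & set(sec.affected_exons) or set(pri.affected_exons)
        # pick an exon affected by the primary; drop secondary term if unaffected
        e = sorted(exon)[0]
        y = sim.expression.values.loc[f"{gene}_exon{e}"].to_numpy()
        X = np.column_stack(
            [np.ones(cfg.n_samples), sim.genotypes.row(pri.variant_id), sim.genotypes.row(sec.variant_id)]
        )
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = res[0] / (cfg.n_samples - 3)
        se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
        true1 = pri.slope if e in pri.affected_exons else 0.0
        true2 = sec.slope if e in sec.affected_exons else 0.0
        assert abs(beta[1] - true1) < 3 * se[1]
        assert abs(beta[2] - true2) < 3 * se[2]

    def test_monomorphic_planted_variant_rejected(self, small_sim):
        import copy

        truth = copy.deepcopy(small_sim.truth)
        geno = small_sim.genotypes
        vid = truth.planted_eqtls["variant_id"].iloc[0]
        geno2 = copy.deepcopy(geno)
        geno2.dosages[geno2.index_of(vid)] = 1.0
        with pytest.raises(ValueError, match="monomorphic"):
            syndata.simulate_expression(geno2, truth, small_sim.config)

    def test_counts_nonnegative(self, small_sim):
        assert small_sim.expression.values.to_numpy().min() >= 0.0


class TestAnnotations:
    def test_segmentation_disjoint_sorted_and_covering(self, small_sim):
        df = small_sim.states.df.sort_values("start")
        assert (df["start"].to_numpy()[1:] >= df["end"].to_numpy()[:-1]).all()
        span = int(small_sim.genotypes.pos.max()) + 1000
        covered = int((df["end"] - df["start"]).sum())
        assert covered >= 0.95 * span

    def test_stretch_enhancers_longer_than_3kb(self, small_sim):
        from qtlkit.annot_enrich import derive_stretch_typical

        stretch, typical = derive_stretch_typical(small_sim.states, ("enhancer",))
        assert len(stretch) > 0
        assert ((stretch.df["end"] - stretch.df["start"]) > 3000).all()
        assert ((typical.df["end"] - typical.df["start"]) < 800).all()

    def test_footprints_nested_in_peaks(self, small_sim):
        peaks = list(zip(small_sim.peaks.df["start"], small_sim.peaks.df["end"]))
        for s, e in zip(small_sim.footprints.df["start"], small_sim.footprints.df["end"]):
            assert any(ps <= s and e <= pe for ps, pe in peaks)

    def test_region_too_short_rejected(self, rng):
        tiny = make_dosages(rng.binomial(2, 0.4, size=(2, 30)).astype(float), pos=[100, 200])
        with pytest.raises(ValueError, match="region"):
            syndata.simulate_annotations(tiny, SimConfig(n_samples=30))

    def test_footprint_pwms_have_informative_positions(self, small_sim):
        for pwm in small_sim.pwms.values():
            assert (pwm.information_content >= 0.7).any()
            assert np.allclose(pwm.matrix.sum(axis=1), 1.0, atol=1e-9)


class TestWriters:
    def test_write_all_roundtrip(self, tmp_path, small_sim):
        from qtlkit.expr_prep import FeatureMatrix
        from qtlkit.ld import DosageMatrix
        from qtlkit.motif_directionality import read_jaspar

        syndata.write_all(small_sim, tmp_path)
        geno = DosageMatrix.read_tsv(tmp_path / "dosages.tsv")
        assert np.allclose(geno.dosages, small_sim.genotypes.dosages)
        expr = FeatureMatrix.read_tsv(tmp_path / "expression.tsv", tmp_path / "features.tsv")
        assert np.allclose(expr.values.to_numpy(), small_sim.expression.values.to_numpy())
        pwms = read_jaspar(tmp_path / "motifs.jaspar")
        assert set(pwms) == set(small_sim.pwms)
        for k in pwms:
            assert np.allclose(pwms[k].matrix, small_sim.pwms[k].matrix, atol=1e-5)
        assert (tmp_path / "truth.json").exists()
        assert (tmp_path / "states.bed").exists()


def test_replication_pvalue_generator_calibrated():
    p_null, shared = syndata.simulate_replication_pvalues(1500, sharing=0.0, seed=3)
    assert not shared.any()
    from scipy.stats import kstest

    assert kstest(p_null, "uniform").pvalue > 0.01
    p_all, shared_all = syndata.simulate_replication_pvalues(400, sharing=1.0, seed=4)
    assert shared_all.all()
    assert np.median(p_all) < 1e-6
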