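"""Interval overlap, matched-control enrichment, context contrasts, binned footprints."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qtlkit import annot_enrich
from qtlkit.annot_enrich import (
    AnnotationTrack,
    build_proxy_cache,
    derive_stretch_typical,
    effect_size_by_context,
    filter_esnps,
    locus_overlap_flags,
    matched_control_enrichment,
    _poisson_binomial_sf,
)

from conftest import make_dosages


def _track(intervals, label="feat"):
    df = pd.DataFrame(intervals, columns=["start", "end"])
    df.insert(0, "chrom", "chr1")
    df["label"] = label
    return AnnotationTrack(df)


def _world(rng, n_variants=400, n_samples=120, spacing=500):
    """Independent variants on one chromosome plus matching profiles."""
    dos = rng.binomial(2, rng.uniform(0.1, 0.5, size=(n_variants, 1)), size=(n_variants, n_samples))
    dm = make_dosages(dos.astype(float), pos=np.arange(1, n_variants + 1) * spacing)
    prof = pd.DataFrame(
        {
            "n_ld_partners": rng.integers(0, 10, n_variants),
            "tss_distance": rng.uniform(100, 1e6, n_variants),
            "n_nearby_genes": rng.integers(0, 4, n_variants),
            "maf": dm.maf,
        },
        index=dm.variant_ids,
    )
    return dm, prof


class TestAnnotationTrack:
    def test_overlap_matches_bruteforce(self, rng):
        starts = rng.integers(0, 100_000, size=2000)
        lens = rng.integers(1, 500, size=2000)
        track = _track(list(zip(starts, starts + lens)))
        positions = rng.integers(1, 100_500, size=300)
        for pos in positions:
            brute = bool(np.any((starts <= pos - 1) & (pos - 1 < starts + lens)))
            assert track.overlaps_snp("chr1", int(pos)) == brute

    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            _track([(10, 10)])

    def test_bed_roundtrip(self, tmp_path, rng):
        track = _track([(0, 10), (20, 35)])
        path = tmp_path / "t.bed"
        track.write_bed(path)
        back = AnnotationTrack.read_bed(path)
        assert back.df[["chrom", "start", "end", "label"]].equals(
            track.df[["chrom", "start", "end", "label"]]
        )


class TestFilterEsnps:
    def test_toy_six_esnps_three_survive(self, rng):
        # 6 significant eSNPs: 2 fail the MAF floor, 2 are mutual proxies
        common = rng.binomial(2, 0.4, size=300).astype(float)
        rows = [
            common,
            common.copy(),  # proxy pair
            rng.binomial(2, 0.45, 300).astype(float),
            rng.binomial(2, 0.35, 300).astype(float),
            rng.binomial(2, 0.03, 300).astype(float),  # low MAF
            rng.binomial(2, 0.04, 300).astype(float),  # low MAF
        ]
        dm = make_dosages(rows, pos=np.arange(1, 7) * 100)
        eqtls = pd.DataFrame(
            {
                "variant_id": dm.variant_ids,
                "q_value": [1e-4] * 6,
                "p_beta": [1e-7, 1e-6, 1e-5, 1e-5, 1e-8, 1e-8],
                "maf": dm.maf,
            }
        )
        kept = filter_esnps(eqtls, dm, maf_min=0.2, r2_prune=0.8)
        assert len(kept) == 3
        assert "v0" in kept and "v1" not in kept

    def test_empty_significant_set(self, rng):
        dm = make_dosages(rng.binomial(2, 0.4, size=(2, 50)).astype(float))
        eqtls = pd.DataFrame(
            {"variant_id": dm.variant_ids, "q_value": [0.5, 0.9], "p_beta": [0.2, 0.3], "maf": dm.maf}
        )
        assert filter_esnps(eqtls, dm) == []

    def test_independent_high_maf_unchanged(self, rng):
        dm = make_dosages(rng.binomial(2, 0.4, size=(4, 400)).astype(float))
        eqtls = pd.DataFrame(
            {
                "variant_id": dm.variant_ids,
                "q_value": [1e-3] * 4,
                "p_beta": [1e-6, 1e-5, 1e-4, 1e-3],
                "maf": dm.maf,
            }
        )
        assert filter_esnps(eqtls, dm) == dm.variant_ids


class TestPoissonBinomial:
    def test_matches_binomial_for_equal_probs(self):
        probs = np.full(30, 0.3)
        for k in (0, 5, 9, 15, 30):
            assert _poisson_binomial_sf(k, probs) == pytest.approx(
                stats.binom.sf(k - 1, 30, 0.3), abs=1e-10
            )

    def test_normal_approx_close_to_exact_shape(self):
        rng = np.random.default_rng(0)
        probs = rng.uniform(0.1, 0.6, size=60)  # uses normal approximation
        mu = probs.sum()
        assert _poisson_binomial_sf(int(mu), probs) == pytest.approx(0.5, abs=0.1)
        assert _poisson_binomial_sf(0, probs) == 1.0


class TestMatchedControlEnrichment:
    def test_whole_genome_feature_fold_exactly_one(self, rng):
        dm, prof = _world(rng, n_variants=100)
        genome = _track([(0, 10_000_000)])
        snps = dm.variant_ids[:30]
        res = matched_control_enrichment(snps, genome, dm, prof, n_controls=50, seed=1)
        assert res.fold == 1.0
        assert res.n_unique_overlaps == 30
        assert res.p_enrich == 1.0

    def test_matches_bruteforce_overlap_oracle(self, rng):
        dm, prof = _world(rng, n_variants=150)
        ivals = [(s, s + rng.integers(50, 400)) for s in rng.integers(0, 75_000, size=40)]
        track = _track(ivals)
        cache = build_proxy_cache(dm)
        flags = locus_overlap_flags(dm.variant_ids, dm, track, proxy_cache=cache)
        # brute force: all-pairs scan over intervals and locus positions
        for i, v in enumerate(dm.variant_ids):
            locus = cache[v]
            brute = any(
                s <= dm.pos[j] - 1 < e for j in locus for (s, e) in ivals
            )
            assert flags[i] == brute
        snps = dm.variant_ids[:40]
        res = matched_control_enrichment(
            snps, track, dm, prof, n_controls=30, seed=2,
            overlap_flags=pd.Series(flags, index=dm.variant_ids),
        )
        assert res.n_unique_overlaps == int(flags[:40].sum())

    def test_planted_enrichment_detected(self, rng):
        dm, prof = _world(rng, n_variants=300)
        # feature tiles the positions of the first 40 variants only
        ivals = [(int(dm.pos[i]) - 1, int(dm.pos[i])) for i in range(40)]
        track = _track(ivals)
        res = matched_control_enrichment(dm.variant_ids[:40], track, dm, prof, n_controls=100, seed=3)
        assert res.fold > 2.0
        assert res.p_enrich < 0.01

    def test_null_placement_fold_near_one(self, rng):
        folds = []
        for rep in range(8):
            dm, prof = _world(rng, n_variants=250)
            ivals = [(s, s + 250) for s in rng.integers(0, 125_000, size=120)]
            track = _track(ivals)
            snps = list(rng.choice(dm.variant_ids, size=60, replace=False))
            res = matched_control_enrichment(snps, track, dm, prof, n_controls=80, seed=rep)
            folds.append(res.fold)
        assert 0.8 <= np.mean(folds) <= 1.25

    def test_fold_invariant_to_interval_split_and_order(self, rng):
        dm, prof = _world(rng, n_variants=120)
        track_a = _track([(1000, 5000), (7000, 9000)])
        track_b = _track([(7000, 9000), (1000, 3000), (3000, 5000)])  # split + reshuffled
        snps = dm.variant_ids[:25]
        ra = matched_control_enrichment(snps, track_a, dm, prof, n_controls=40, seed=4)
        rb = matched_control_enrichment(snps, track_b, dm, prof, n_controls=40, seed=4)
        assert ra.fold == rb.fold
        assert ra.n_unique_overlaps == rb.n_unique_overlaps

    def test_empty_track_rejected(self, rng):
        dm, prof = _world(rng, n_variants=30)
        empty = AnnotationTrack(pd.DataFrame(columns=["chrom", "start", "end", "label"]))
        with pytest.raises(ValueError, match="empty"):
            matched_control_enrichment(dm.variant_ids[:5], empty, dm, prof)


class TestEffectSizeByContext:
    def test_identical_distributions_calibrated(self, rng):
        pvals = []
        for rep in range(40):
            dm, _ = _world(rng, n_variants=120)
            half = [(int(dm.pos[i]) - 1, int(dm.pos[i])) for i in range(0, 60)]
            other = [(int(dm.pos[i]) - 1, int(dm.pos[i])) for i in range(60, 120)]
            esnps = pd.DataFrame({"variant_id": dm.variant_ids, "slope": rng.normal(0, 0.5, 120)})
            _, tests = effect_size_by_context(
                esnps, {"a": _track(half), "b": _track(other)}, dm
            )
            pvals.append(tests["p_wilcoxon"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_shift_detected(self, rng):
        dm, _ = _world(rng, n_variants=200)
        in_stretch = [(int(dm.pos[i]) - 1, int(dm.pos[i])) for i in range(100)]
        in_tss = [(int(dm.pos[i]) - 1, int(dm.pos[i])) for i in range(100, 200)]
        slopes = np.r_[rng.normal(0, 0.4, 100), rng.normal(0, 0.4, 100) + 0.5]
        esnps = pd.DataFrame({"variant_id": dm.variant_ids, "slope": slopes})
        dists, tests = effect_size_by_context(
            esnps, {"stretch": _track(in_stretch), "tss": _track(in_tss)}, dm
        )
        assert tests["p_wilcoxon"].iloc[0] < 0.01
        assert np.median(dists["stretch"]) < np.median(dists["tss"])

    def test_small_context_skipped(self, rng):
        dm, _ = _world(rng, n_variants=50)
        tiny = [(int(dm.pos[0]) - 1, int(dm.pos[0]))]
        esnps = pd.DataFrame({"variant_id": dm.variant_ids, "slope": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="skipped"):
            dists, _ = effect_size_by_context(esnps, {"tiny": _track(tiny)}, dm)
        assert "tiny" not in dists


class TestBinnedFootprintEnrichment:
    def test_median_split_balanced_and_directional(self, rng):
        # eSNPs are a quarter of the tested universe; the motif sits only
        # under the high-|slope| half of them
        dm, prof = _world(rng, n_variants=400)
        esnp_ids = dm.variant_ids[:100]
        slopes = rng.normal(0, 0.5, 100)
        esnps = pd.DataFrame({"variant_id": esnp_ids, "slope": slopes})
        order = np.argsort(-np.abs(slopes))
        hits = order[:50]
        fp = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": dm.pos[hits] - 5,
                "end": dm.pos[hits] + 7,
                "label": "motifX",
                "strand": "+",
            }
        )
        res = annot_enrich.binned_footprint_enrichment(
            esnps, AnnotationTrack(fp), dm, prof, n_controls=40, seed=5
        )
        assert len(res) == 1
        row = res.iloc[0]
        assert row["fold_high"] > row["fold_low"]
        assert row["q_bulk"] < 0.01

    def test_symmetric_motif_near_equal_folds(self, rng):
        logs = []
        for rep in range(6):
            dm, prof = _world(rng, n_variants=250)
            esnps = pd.DataFrame({"variant_id": dm.variant_ids, "slope": rng.normal(0, 0.5, 250)})
            hits = rng.choice(250, size=100, replace=False)
            fp = pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start": dm.pos[hits] - 5,
                    "end": dm.pos[hits] + 7,
                    "label": "motifY",
                    "strand": "+",
                }
            )
            res = annot_enrich.binned_footprint_enrichment(
                esnps, AnnotationTrack(fp), dm, prof, n_controls=40, seed=10 + rep, fdr=1.1
            )
            if len(res) and res["fold_low"].iloc[0] > 0 and np.isfinite(res["fold_high"].iloc[0]):
                logs.append(np.log(res["fold_high"].iloc[0] / res["fold_low"].iloc[0]))
        assert np.abs(np.mean(logs)) < 0.3


class TestStretchTypicalDerivation:
    def test_adjacent_enhancers_merged(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "start": [0, 2000, 10_000, 20_000],
                "end": [2000, 3500, 10_600, 26_000],
                "label": ["enhancer", "enhancer", "enhancer", "enhancer"],
            }
        )
        stretch, typical = derive_stretch_typical(AnnotationTrack(df), ("enhancer",))
        # [0,3500) merged -> stretch; [10000,10600) typical; [20000,26000) stretch
        assert len(stretch) == 2
        assert len(typical) == 1
        assert ((stretch.df["end"] - stretch.df["start"]) > 3000).all()
        assert ((typical.df["end"] - typical.df["start"]) < 800).all()
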