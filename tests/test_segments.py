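"""Transcribed-segment detection, ANOVA gating and classification."""

import numpy as np
import pandas as pd
import pytest

from rnasetiling.datatypes import (
    EffectSpec,
    Feature,
    GenomeAnnotation,
    GeneratorConfig,
    HybridizationSet,
    NoiseConfig,
)
from rnasetiling.probes import estimate_probe_profiles
from rnasetiling.segments import (
    SegmentConfig,
    chromosome_median,
    classify_segment,
    detect_segments,
    segment_anova,
)
from rnasetiling.simulate import design_probes, simulate_expression


def _fixture(features, genome_length, seg_offset, effects=(), resid=0.0, seed=1):
    """Noise-free hybridizations over a custom annotation; segments sit
    ``seg_offset`` log2 units above a flat background of 6.0."""
    ann = GenomeAnnotation(list(features), genome_length=genome_length)
    design = design_probes(ann)
    cfg = GeneratorConfig(
        segment_level_offset=seg_offset,
        segment_level_sd=0.0,
        baseline_mean=10.0,
        baseline_sd=0.0,
        background_level=6.0,
    )
    hyb = simulate_expression(
        ann,
        design,
        effects=list(effects),
        noise=NoiseConfig(0, 0, resid, 0),
        seed=seed,
        config=cfg,
    )
    profiles = estimate_probe_profiles(hyb, design=design)
    return ann, design, hyb, profiles


class TestDetection:
    def test_flat_genome_yields_no_segments(self):
        ann, design, hyb, prof = _fixture([], 8000, seg_offset=3.0)
        assert detect_segments(hyb, prof, ann, design) == []

    def test_threshold_sandwich_s_not_t(self):
        """A segment at 8x the median passes the 5x expressed rule but is
        not promoted to a new (T) segment: it misses the 10x bar and has
        no condition structure."""
        feats = [Feature("segA", 4000, 4400, "+", "segment")]
        ann, design, hyb, prof = _fixture(feats, 10000, seg_offset=np.log2(8))
        segs = detect_segments(hyb, prof, ann, design)
        assert len(segs) == 1
        assert segs[0].label_prefix == "S"

    def test_differential_high_segment_promoted_to_t(self):
        """12x background plus a planted depletion effect: 10x rule and
        ANOVA both pass, so the segment is labelled T."""
        feats = [Feature("segA", 4000, 4400, "+", "segment")]
        ann, design, hyb, prof = _fixture(
            feats,
            10000,
            seg_offset=np.log2(12),
            effects=[EffectSpec("segA", "Y", 1.0)],
            resid=0.05,
        )
        segs = detect_segments(hyb, prof, ann, design)
        assert len(segs) == 1
        assert segs[0].label_prefix == "T"
        assert segs[0].anova_p <= 0.05

    def test_boundaries_within_one_probe_spacing(self):
        feats = [Feature("segA", 3003, 3401, "+", "segment")]
        ann, design, hyb, prof = _fixture(feats, 10000, seg_offset=4.0)
        (seg,) = detect_segments(hyb, prof, ann, design)
        assert abs(seg.start - 3003) <= design.spacing
        assert abs(seg.end - 3401) <= design.spacing

    def test_s_set_contains_t_set(self):
        """Everything promoted to T also satisfies the S (5x) rule."""
        feats = [
            Feature("lo", 2000, 2300, "+", "segment"),
            Feature("hi", 6000, 6300, "+", "segment"),
        ]
        ann = GenomeAnnotation(feats, genome_length=10000)
        design = design_probes(ann)
        cfg = GeneratorConfig(
            segment_level_offset=np.log2(12), segment_level_sd=0.0,
            baseline_mean=10.0, baseline_sd=0.0,
        )
        hyb = simulate_expression(
            ann, design, effects=[EffectSpec("hi", "J1", 1.5)],
            noise=NoiseConfig(0, 0, 0.05, 0), seed=2, config=cfg,
        )
        prof = estimate_probe_profiles(hyb, design=design)
        segs = detect_segments(hyb, prof, ann, design)
        med = chromosome_median(hyb, design)
        for seg in segs:
            if seg.label_prefix == "T":
                raw_max = hyb.intensities.loc[seg.probe_ids].max(axis=1)
                assert (raw_max >= med.min() + np.log2(5)).any()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SegmentConfig(expressed_factor=0.5)
        with pytest.raises(ValueError):
            SegmentConfig(anova_alpha=1.5)


class TestSegmentAnova:
    def test_hand_computed_sums_of_squares(self, main_samples):
        """{1,1; 1,1; 1,1; 3,3.2}: SSB and SSW computed by hand."""
        vals = pd.Series(
            [1, 1, 1, 1, 1, 1, 3, 3.2], index=main_samples.index, dtype=float
        )
        F, p = segment_anova(vals, main_samples)
        means = np.array([1, 1, 1, 3.1])
        grand = vals.mean()
        ssb = 2 * ((means - grand) ** 2).sum()
        ssw = 0.02  # only the last condition varies: (0.1)^2 * 2
        expected_F = (ssb / 3) / (ssw / 4)
        assert F == pytest.approx(expected_F, rel=1e-6)
        from scipy import stats

        assert p == pytest.approx(stats.f.sf(expected_F, 3, 4), rel=1e-6)

    def test_degenerate_equal_values_flagged_undefined(self, main_samples):
        vals = pd.Series([2.0] * 8, index=main_samples.index)
        F, p = segment_anova(vals, main_samples)
        assert np.isnan(F) and np.isnan(p)

    def test_type_one_error_near_alpha(self, main_samples):
        rng = np.random.default_rng(17)
        n = 2000
        rejected = 0
        conds = main_samples["condition"].to_numpy()
        for _ in range(n):
            vals = pd.Series(rng.normal(0, 0.3, 8), index=main_samples.index)
            _, p = segment_anova(vals, main_samples)
            if p <= 0.05:
                rejected += 1
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(rejected / n - 0.05) < 3 * se


class TestClassification:
    def test_utr_contiguous_with_gene_is_5prime(self):
        feats = [
            Feature("utr", 1850, 2000, "+", "segment"),
            Feature("geneA", 2000, 3200, "+", "CDS"),
        ]
        ann, design, hyb, prof = _fixture(feats, 8000, seg_offset=3.0)
        (seg,) = detect_segments(hyb, prof, ann, design)
        med = float(chromosome_median(hyb, design).median())
        classify_segment(seg, ann, prof, design, background=med)
        assert seg.klass == "5prime"

    def test_isolated_sharp_segment_is_indep(self):
        feats = [Feature("segA", 5000, 5400, "+", "segment")]
        ann, design, hyb, prof = _fixture(feats, 10000, seg_offset=3.5)
        (seg,) = detect_segments(hyb, prof, ann, design)
        med = float(chromosome_median(hyb, design).median())
        classify_segment(seg, ann, prof, design, background=med)
        assert seg.klass == "indep"

    def test_downstream_extension_with_downshift_is_3prime(self):
        feats = [
            Feature("geneA", 2000, 3200, "+", "CDS"),
            Feature("ext", 3200, 3600, "+", "segment"),
        ]
        ann, design, hyb, prof = _fixture(feats, 9000, seg_offset=3.0)
        (seg,) = detect_segments(hyb, prof, ann, design)
        med = float(chromosome_median(hyb, design).median())
        classify_segment(seg, ann, prof, design, background=med)
        assert seg.klass == "3prime"

    def test_bridging_segment_between_cotranscribed_genes_is_intra(self):
        feats = [
            Feature("geneA", 2000, 3000, "+", "CDS"),
            Feature("link", 3000, 3300, "+", "segment"),
            Feature("geneB", 3300, 4300, "+", "CDS"),
        ]
        ann, design, hyb, prof = _fixture(feats, 9000, seg_offset=3.5)
        (seg,) = detect_segments(hyb, prof, ann, design)
        med = float(chromosome_median(hyb, design).median())
        classify_segment(seg, ann, prof, design, background=med)
        assert seg.klass == "intra"

    def test_antisense_overlap_recorded_by_exhaustive_arithmetic(self):
        """A segment covering ~70% of an opposite-strand CDS lists it,
        verified against a brute-force interval scan."""
        feats = [
            Feature("geneC", 7000, 7600, "-", "CDS"),
            Feature("asC", 7100, 7520, "+", "segment"),
        ]
        ann, design, hyb, prof = _fixture(feats, 10000, seg_offset=3.0)
        (seg,) = detect_segments(hyb, prof, ann, design)
        med = float(chromosome_median(hyb, design).median())
        classify_segment(seg, ann, prof, design, background=med)

        expected = []
        floor = min(50, int(0.25 * seg.length))
        for f in ann.features:
            if f.strand != seg.strand:
                ov = min(seg.end, f.end) - max(seg.start, f.start)
                if ov >= floor:
                    expected.append(f.id)
        assert seg.antisense_to == sorted(expected)
        assert "geneC" in seg.antisense_to

    def test_every_segment_gets_exactly_one_class(self):
        feats = [
            Feature("utr", 1850, 2000, "+", "segment"),
            Feature("geneA", 2000, 3200, "+", "CDS"),
            Feature("segB", 6000, 6400, "+", "segment"),
            Feature("geneC", 7000, 8000, "-", "CDS"),
            Feature("asC", 7300, 7700, "+", "segment"),
        ]
        ann, design, hyb, prof = _fixture(feats, 11000, seg_offset=3.0)
        segs = detect_segments(hyb, prof, ann, design)
        assert len(segs) == 3
        med = float(chromosome_median(hyb, design).median())
        from rnasetiling.segments import SEGMENT_CLASSES

        for seg in segs:
            classify_segment(seg, ann, prof, design, background=med)
            assert seg.klass in SEGMENT_CLASSES

    def test_out_of_bounds_segment_rejected(self):
        feats = [Feature("segA", 5000, 5400, "+", "segment")]
        ann, design, hyb, prof = _fixture(feats, 10000, seg_offset=3.5)
        (seg,) = detect_segments(hyb, prof, ann, design)
        seg.end = 99999
        with pytest.raises(ValueError, match="bounds"):
            classify_segment(seg, ann, prof, design)
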