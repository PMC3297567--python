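"""Discovery and classification of transcribed segments outside genes.

Segments are maximal same-strand runs of expressed probes (raw signal at
least ``expressed_factor`` times the chromosome median in at least one
hybridization, evaluated before normalization), after removal of probes
lying within annotated same-strand genes.  Candidates that additionally
reach ``new_segment_factor`` times background and show condition
structure (one-way ANOVA over the four main experiments at
``anova_alpha``) are promoted to "T" (new) segments; the rest keep the
"S" label.  Classification by position relative to same-strand
neighbours and boundary signal shape follows the 5'/3'/independent/
inter/intra scheme; antisense relationships are recorded from
opposite-strand overlaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenomeAnnotation, HybridizationSet, ProbeDesign
from .probes import ProbeProfileSet

log = logging.getLogger(__name__)

__all__ = [
    "SegmentConfig",
    "Segment",
    "detect_segments",
    "segment_anova",
    "classify_segment",
    "chromosome_median",
]

SEGMENT_CLASSES = (
    "5prime",
    "3prime",
    "3primeMT",
    "3primePT",
    "indep",
    "indepMT",
    "inter",
    "intra",
)


@dataclass(frozen=True)
class SegmentConfig:
    expressed_factor: float = 5.0  # x chromosome median, pre-normalization
    new_segment_factor: float = 10.0  # x background for "T" promotion
    anova_alpha: float = 0.05
    min_probes: int = 3
    max_gap: int = 1  # tolerated run of sub-threshold probes inside a segment
    downshift_factor: float = 2.0  # log2 drop defining a boundary downshift
    boundary_window: int = 3  # probes per flanking window
    background_margin: float = 1.0  # log2 above median still "background"

    def __post_init__(self) -> None:
        if self.expressed_factor <= 1 or self.new_segment_factor <= 1:
            raise ValueError("threshold factors must exceed 1")
        if not 0 < self.anova_alpha < 1:
            raise ValueError("anova_alpha must be in (0, 1)")


@dataclass
class Segment:
    start: int
    end: int
    strand: str
    label_prefix: str  # 'S' or 'T'
    probe_ids: list[str] = field(default_factory=list)
    klass: str | None = None
    antisense_to: list[str] = field(default_factory=list)
    anova_F: float = np.nan
    anova_p: float = np.nan
    max_fold_log2: float = np.nan  # peak aggregated signal above median
    touches_gene_5prime: bool = False  # run continued into a gene on the 5' side
    touches_gene_3prime: bool = False

    @property
    def id(self) -> str:
        return f"{self.label_prefix}_{self.strand}_{self.start}"

    @property
    def length(self) -> int:
        return self.end - self.start


def chromosome_median(raw: HybridizationSet, design: ProbeDesign) -> pd.Series:
    """Per-hybridization global median over unique probes (the background)."""
    uniq = [p.id for p in design if p.unique]
    return raw.intensities.loc[raw.intensities.index.intersection(uniq)].median(axis=0)


def segment_anova(values: pd.DataFrame, samples: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA F-test across the four main conditions.

    ``values`` holds one row (the segment's aggregated expression) or is a
    Series indexed by sample.  Returns (F, p); zero within-group variance
    makes the test undefined and yields (nan, nan).
    """
    if isinstance(values, pd.DataFrame):
        if len(values) != 1:
            raise ValueError("expected a single segment row")
        values = values.iloc[0]
    conds = samples.loc[values.index, "condition"]
    groups = [values[conds == c].to_numpy(float) for c in pd.unique(conds)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 conditions with >= 2 replicates each")
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if sse <= 0:
        return np.nan, np.nan
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def _runs(flags: np.ndarray, max_gap: int, min_probes: int) -> list[tuple[int, int]]:
    """Maximal runs of True entries tolerating gaps of <= max_gap False."""
    runs = []
    i, n = 0, len(flags)
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        last_true = i
        gap = 0
        while j + 1 < n:
            if flags[j + 1]:
                j += 1
                last_true = j
                gap = 0
            elif gap < max_gap:
                j += 1
                gap += 1
            else:
                break
        if flags[i : last_true + 1].sum() >= min_probes:
            runs.append((i, last_true))
        i = last_true + 1
    return runs


def detect_segments(
    raw: HybridizationSet,
    profiles: ProbeProfileSet,
    annotation: GenomeAnnotation,
    design: ProbeDesign,
    config: SegmentConfig = SegmentConfig(),
) -> list[Segment]:
    """Find candidate transcribed segments outside annotated genes.

    The 5x expressed rule is applied to raw (pre-normalization)
    intensities relative to the per-hybridization chromosome median; runs
    are built from probes outside same-strand genes; the T promotion
    requires the 10x rule plus a significant segment-level ANOVA on
    aggregated probe profiles across the four main conditions.
    """
    med = chromosome_median(raw, design)
    thr_expr = med + np.log2(config.expressed_factor)
    thr_new = med + np.log2(config.new_segment_factor)

    pframe = design.to_frame()
    y = raw.intensities
    main = raw.main_condition_samples()
    segments: list[Segment] = []
    genes = annotation.genes

    for strand in ("+", "-"):
        ids = [p.id for p in design if p.strand == strand and p.id in y.index]
        ids.sort(key=lambda pid: pframe.at[pid, "start"])
        if not ids:
            continue
        sub = y.loc[ids]
        expressed = (sub >= thr_expr).any(axis=1).to_numpy()
        in_gene = np.zeros(len(ids), dtype=bool)
        starts = pframe.loc[ids, "start"].to_numpy()
        ends = pframe.loc[ids, "end"].to_numpy()
        for g in genes:
            if g.strand != strand:
                continue
            in_gene |= (starts >= g.start) & (ends <= g.end)

        candidate = expressed & ~in_gene
        for i0, i1 in _runs(candidate, config.max_gap, config.min_probes):
            probe_ids = [ids[k] for k in range(i0, i1 + 1) if candidate[k]]
            seg_start = int(starts[i0])
            seg_end = int(ends[i1])
            agg = profiles.profiles.loc[probe_ids].median(axis=0)
            peak = float((sub.loc[probe_ids] - med).max().max())
            seg = Segment(
                start=seg_start,
                end=seg_end,
                strand=strand,
                label_prefix="S",
                probe_ids=probe_ids,
                max_fold_log2=peak,
            )
            # contiguity with gene expression at the run edges; boundary
            # probes straddling the gene edge are neither candidates nor
            # in-gene, so scan past up to max_gap+1 of them
            def _adjacent_gene(from_idx: int, step: int) -> bool:
                k = from_idx
                for _ in range(config.max_gap + 2):
                    if k < 0 or k >= len(ids):
                        return False
                    if in_gene[k]:
                        return bool(expressed[k])
                    if candidate[k]:
                        return False
                    k += step
                return False

            left_adj = _adjacent_gene(i0 - 1, -1)
            right_adj = _adjacent_gene(i1 + 1, +1)
            if strand == "+":
                seg.touches_gene_5prime, seg.touches_gene_3prime = left_adj, right_adj
            else:
                seg.touches_gene_5prime, seg.touches_gene_3prime = right_adj, left_adj

            reaches_new = bool((sub.loc[probe_ids] >= thr_new).any(axis=1).any())
            try:
                F, p = segment_anova(agg[main], raw.samples)
            except ValueError:
                F, p = np.nan, np.nan
            seg.anova_F, seg.anova_p = F, p
            if reaches_new and np.isfinite(p) and p <= config.anova_alpha:
                seg.label_prefix = "T"
            segments.append(seg)
    log.info("detect_segments: %d candidates", len(segments))
    return segments


def _boundary_signal(
    signal: pd.Series, pframe: pd.DataFrame, strand: str, pos: int, side: str, window: int
) -> tuple[float, float]:
    """Mean signal of the `window` probes just inside vs just outside `pos`."""
    ids = [pid for pid in signal.index if pframe.at[pid, "strand"] == strand]
    ids.sort(key=lambda pid: pframe.at[pid, "start"])
    starts = np.array([pframe.at[pid, "start"] for pid in ids])
    vals = signal[ids].to_numpy(float)
    if side == "right":  # boundary at genomic end
        inside = vals[(starts < pos)][-window:]
        outside = vals[(starts >= pos)][:window]
    else:  # boundary at genomic start
        inside = vals[(starts >= pos)][:window]
        outside = vals[(starts < pos)][-window:]
    mi = float(np.mean(inside)) if len(inside) else np.nan
    mo = float(np.mean(outside)) if len(outside) else np.nan
    return mi, mo


def classify_segment(
    segment: Segment,
    annotation: GenomeAnnotation,
    profiles: ProbeProfileSet,
    design: ProbeDesign,
    config: SegmentConfig = SegmentConfig(),
    background: float | None = None,
) -> Segment:
    """Assign exactly one positional/shape class and antisense partners.

    Contiguity with a same-strand gene on the 3' side makes a 5'UTR; on
    the 5' side a 3' extension whose subtype depends on the presence of a
    terminal downshift and on whether downstream signal returns to
    background; contiguity on both sides marks an intra-operon segment.
    Isolated segments split into independent (sharp 5' rise) or
    inter-genic classes, with an MT (no terminator) variant when the 3'
    boundary lacks a downshift.
    """
    if segment.start < 0 or segment.end > annotation.genome_length:
        raise ValueError("segment outside genome bounds")
    pframe = design.to_frame()
    # cross-sample maximum captures the condition where the segment is
    # most stabilized, which is where boundaries are sharpest
    signal = profiles.profiles.max(axis=1)
    if background is None:
        background = float(signal.median())

    # boundary positions in 5'->3' orientation of the segment
    if segment.strand == "+":
        end3_pos, end5_pos = segment.end, segment.start
        side3, side5 = "right", "left"
    else:
        end3_pos, end5_pos = segment.start, segment.end
        side3, side5 = "left", "right"

    in3, out3 = _boundary_signal(
        signal, pframe, segment.strand, end3_pos, side3, config.boundary_window
    )
    in5, out5 = _boundary_signal(
        signal, pframe, segment.strand, end5_pos, side5, config.boundary_window
    )
    has_downshift = np.isfinite(in3) and np.isfinite(out3) and (in3 - out3) >= config.downshift_factor
    sharp_rise = np.isfinite(in5) and np.isfinite(out5) and (in5 - out5) >= config.downshift_factor
    downstream_above_bg = np.isfinite(out3) and out3 > background + config.background_margin

    adj5, adj3 = segment.touches_gene_5prime, segment.touches_gene_3prime
    if adj3 and not adj5:
        klass = "5prime"
    elif adj5 and adj3:
        klass = "intra"
    elif adj5:
        if has_downshift and not downstream_above_bg:
            klass = "3prime"
        elif has_downshift:
            klass = "3primePT"
        else:
            klass = "3primeMT"
    else:
        if has_downshift:
            klass = "indep" if sharp_rise else "inter"
        else:
            klass = "indepMT"
    segment.klass = klass

    floor = min(50, max(1, int(0.25 * segment.length)))
    partners = []
    for f in annotation.features:
        if f.strand == segment.strand:
            continue
        ov = min(segment.end, f.end) - max(segment.start, f.start)
        if ov >= floor:
            partners.append(f.id)
    segment.antisense_to = sorted(partners)
    return segment
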