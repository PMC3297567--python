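"""Synthetic genomes, tiling designs and hybridization signals.

The generator produces data with the statistical structure the analysis
assumes: two-strand tiling probes at fixed spacing, per-probe affinity
offsets, per-hybridization shifts, residual noise, planted depletion
effects applied only in the matching -IPTG samples, and low-abundance
regulatory elements (5'UTRs, antisense RNAs, independent small RNAs).
Every draw flows through ``numpy.random.SeedSequence(seed)`` children so
that identical seeds reproduce every output bit-for-bit and individual
noise components can be switched off without perturbing the others.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    CONDITION_OF_RNASE,
    EffectSpec,
    Feature,
    GenomeAnnotation,
    GeneratorConfig,
    DepletionScenario,
    HybridizationSet,
    NoiseConfig,
    Probe,
    ProbeDesign,
    SampleMeta,
    sample_frame,
)

log = logging.getLogger(__name__)

__all__ = [
    "make_genome",
    "design_probes",
    "simulate_expression",
    "simulate_gene_matrix",
    "sample_effects",
    "make_random_categories",
]


def make_genome(config: GeneratorConfig, seed: int) -> GenomeAnnotation:
    """Lay out a synthetic annotation: genes, 5'UTRs, asRNAs, free segments.

    Genes are packed left to right with exponential intergenic gaps; a
    configured fraction carries a contiguous 5'UTR segment upstream
    (strand-aware) and a configured fraction an antisense segment nested
    on the opposite strand.  Raises ``ValueError`` when an explicit
    ``genome_length`` cannot hold the content.
    """
    rng = np.random.default_rng(seed)
    features: list[Feature] = []
    if config.n_genes > 0:
        lengths = np.maximum(
            120,
            rng.lognormal(
                np.log(config.mean_gene_length), config.sd_log_gene_length, config.n_genes
            ).astype(int),
        )
        gaps = config.min_gap + rng.exponential(
            max(config.mean_gap - config.min_gap, 1), config.n_genes
        ).astype(int)
        strands = np.where(rng.random(config.n_genes) < config.frac_plus_strand, "+", "-")
        has_utr = rng.random(config.n_genes) < config.utr5_fraction
        has_as = rng.random(config.n_genes) < config.asRNA_fraction
        utr_len = max(100, config.segment_length // 2)

        cursor = config.min_gap
        for i in range(config.n_genes):
            gid = f"gene_{i:04d}"
            cursor += int(gaps[i])
            L = int(lengths[i])
            if strands[i] == "+" and has_utr[i]:
                features.append(
                    Feature(f"utr5_{gid}", cursor, cursor + utr_len, "+", "segment")
                )
                cursor += utr_len
            gene_start = cursor
            features.append(Feature(gid, gene_start, gene_start + L, strands[i], "CDS"))
            cursor = gene_start + L
            if strands[i] == "-" and has_utr[i]:
                features.append(
                    Feature(f"utr5_{gid}", cursor, cursor + utr_len, "-", "segment")
                )
                cursor += utr_len
            if has_as[i]:
                as_len = min(config.segment_length, L - 60)
                if as_len >= 80:
                    off = int(rng.integers(20, max(21, L - as_len - 20)))
                    features.append(
                        Feature(
                            f"as_{gid}",
                            gene_start + off,
                            gene_start + off + as_len,
                            "+" if strands[i] == "-" else "-",
                            "segment",
                        )
                    )
        for j in range(config.n_indep_segments):
            cursor += config.min_gap + int(rng.exponential(config.mean_gap))
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                Feature(f"sRNA_{j:03d}", cursor, cursor + config.segment_length, strand, "segment")
            )
            cursor += config.segment_length
        content_end = cursor + config.min_gap
    else:
        content_end = 0

    if config.genome_length is None:
        genome_length = max(content_end, 1000)
    else:
        genome_length = config.genome_length
        if content_end > genome_length:
            raise ValueError(
                f"cannot pack {config.n_genes} genes into genome_length={genome_length} "
                f"(need >= {content_end})"
            )
    log.info("make_genome(seed=%d): %d features over %d bp", seed, len(features), genome_length)
    return GenomeAnnotation(features=features, genome_length=genome_length)


def _count_occurrences(haystack: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def design_probes(
    annotation: GenomeAnnotation,
    spacing: int = 22,
    probe_length: int | None = None,
    strands: tuple[str, ...] = ("+", "-"),
    repeat_regions: list[tuple[int, int]] | None = None,
    sequence: str | None = None,
) -> ProbeDesign:
    """Tile each strand at fixed spacing.

    Probes fully inside a designated repeat region, or (when ``sequence``
    is given) whose subsequence occurs more than once in the genome or its
    reverse complement, are flagged ``unique=False`` but kept.
    """
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    if spacing > annotation.genome_length:
        raise ValueError("spacing exceeds genome length")
    plen = probe_length if probe_length is not None else spacing
    rc = sequence.translate(_RC)[::-1] if sequence is not None else None

    probes = []
    for strand in strands:
        tag = "p" if strand == "+" else "m"
        for start in range(0, annotation.genome_length - plen + 1, spacing):
            end = start + plen
            unique = True
            if repeat_regions:
                unique = not any(start >= rs and end <= re for rs, re in repeat_regions)
            if unique and sequence is not None:
                sub = sequence[start:end]
                if _count_occurrences(sequence, sub) + _count_occurrences(rc, sub) > 1:
                    unique = False
            probes.append(Probe(f"P{tag}_{start:07d}", start, end, strand, unique))
    return ProbeDesign(probes=probes, spacing=spacing)


def _assign_baselines(
    annotation: GenomeAnnotation, config: GeneratorConfig, rng: np.random.Generator
) -> dict[str, float]:
    baselines = {}
    for f in annotation.features:
        if f.kind == "segment":
            baselines[f.id] = (
                config.background_level
                + config.segment_level_offset
                + rng.normal(0.0, config.segment_level_sd)
            )
        else:
            baselines[f.id] = rng.normal(config.baseline_mean, config.baseline_sd)
    return baselines


def simulate_expression(
    annotation: GenomeAnnotation,
    design: ProbeDesign,
    effects: list[EffectSpec] = (),
    scenario: DepletionScenario = DepletionScenario(),
    noise: NoiseConfig = NoiseConfig(),
    seed: int = 0,
    n_replicates: int = 2,
    config: GeneratorConfig | None = None,
    include_iptg_plus: bool = False,
) -> HybridizationSet:
    """Emit probe x sample log2 intensities with a populated truth block.

    Signal model per probe ``p`` and hybridization ``h``::

        y_ph = base_p + delta_ph + a_p + s_h + eps_ph

    where ``base_p`` is the baseline of the covering same-strand feature
    (or the background level with a fixed per-probe jitter at
    untranscribed positions), ``delta_ph`` adds the planted effect only in
    the matching RNase's -IPTG samples, ``a_p`` is probe affinity, ``s_h``
    a per-hybridization shift and ``eps`` residual noise.  +IPTG samples
    (optional) are generated fully complemented (no effect).
    """
    cfg = config if config is not None else GeneratorConfig()
    known = {f.id for f in annotation.features}
    for e in effects:
        if e.gene_id not in known:
            raise KeyError(f"effect references unknown gene {e.gene_id!r}")

    samples: list[SampleMeta] = []
    for r in range(1, n_replicates + 1):
        samples.append(SampleMeta("wt", "na", r))
    for cond in ("rnc", "rnjA", "rny"):
        for r in range(1, n_replicates + 1):
            samples.append(SampleMeta(cond, "minus", r))
        if include_iptg_plus:
            for r in range(1, n_replicates + 1):
                samples.append(SampleMeta(cond, "plus", r))
    names = [s.name for s in samples]

    ss = np.random.SeedSequence(seed)
    rng_base, rng_bg, rng_aff, rng_shift, rng_resid = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )
    baselines = _assign_baselines(annotation, cfg, rng_base)

    P, S = len(design), len(names)
    pframe = design.to_frame()
    starts = pframe["start"].to_numpy()
    ends = pframe["end"].to_numpy()
    pstrand = pframe["strand"].to_numpy()

    base = np.full(P, cfg.background_level) + noise.sigma_background * rng_bg.standard_normal(P)
    covering = np.full(P, None, dtype=object)
    # smallest covering same-strand feature wins (UTRs/asRNAs are never
    # nested inside a same-strand gene by construction)
    for f in sorted(annotation.features, key=lambda f: -f.length):
        mask = (pstrand == f.strand) & (starts >= f.start) & (ends <= f.end)
        base[mask] = baselines[f.id]
        covering[mask] = f.id

    delta = np.zeros((P, S))
    for e in effects:
        cond = CONDITION_OF_RNASE[e.rnase]
        cols = [
            j
            for j, s in enumerate(samples)
            if s.condition == cond and s.iptg == "minus"
        ]
        rows = covering == e.gene_id
        delta[np.ix_(rows, cols)] += e.delta_log2

    a = noise.sigma_affinity * rng_aff.standard_normal(P)
    s = noise.sigma_shift * rng_shift.standard_normal(S)
    eps = noise.sigma_resid * rng_resid.standard_normal((P, S))

    clean = base[:, None] + delta
    y = clean + a[:, None] + s[None, :] + eps

    index = pframe.index
    intensities = pd.DataFrame(y, index=index, columns=names)
    truth = {
        "expression": pd.DataFrame(clean, index=index, columns=names),
        "affinity": pd.Series(a, index=index, name="affinity"),
        "shift": pd.Series(s, index=pd.Index(names, name="sample"), name="shift"),
        "baselines": baselines,
        "covering": pd.Series(covering, index=index, name="feature"),
        "scenario": scenario,
    }
    log.info("simulate_expression(seed=%d): %d probes x %d samples", seed, P, S)
    return HybridizationSet(intensities=intensities, samples=sample_frame(samples), truth=truth)


def simulate_gene_matrix(
    n_null: int,
    n_affected: int,
    delta_log2: float,
    sigma: float,
    seed: int,
    n_replicates: int = 2,
    baseline_mean: float = 9.0,
    baseline_sd: float = 1.0,
):
    """Aggregated gene x sample matrix for calibration studies.

    ``n_null`` genes have equal means in all four main conditions;
    ``n_affected`` genes carry ``delta_log2`` in one RNase's depletion
    condition each (assigned round-robin across the three RNases).
    Gaussian noise of scale ``sigma`` is added throughout.  Returns the
    matrix together with the set of planted (gene, RNase) pairs.
    """
    from .datatypes import ExpressionMatrix, RNASES

    rng = np.random.default_rng(seed)
    samples: list[SampleMeta] = [SampleMeta("wt", "na", r) for r in range(1, n_replicates + 1)]
    for cond in ("rnc", "rnjA", "rny"):
        samples += [SampleMeta(cond, "minus", r) for r in range(1, n_replicates + 1)]
    meta = sample_frame(samples)
    names = meta.index.tolist()

    n = n_null + n_affected
    gene_ids = [f"g{i:05d}" for i in range(n)]
    base = rng.normal(baseline_mean, baseline_sd, n)
    vals = np.tile(base[:, None], len(names)) + sigma * rng.standard_normal((n, len(names)))

    truth: set[tuple[str, str]] = set()
    conds = meta["condition"].to_numpy()
    for j, gi in enumerate(range(n_null, n)):
        rnase = RNASES[j % len(RNASES)]
        cols = np.flatnonzero(conds == CONDITION_OF_RNASE[rnase])
        vals[gi, cols] += delta_log2
        truth.add((gene_ids[gi], rnase))

    matrix = ExpressionMatrix(
        values=pd.DataFrame(vals, index=pd.Index(gene_ids, name="unit"), columns=names),
        samples=meta,
    )
    return matrix, truth


def sample_effects(
    annotation: GenomeAnnotation,
    seed: int,
    frac_affected: float = 0.25,
    up_fraction: float = 0.7,
    mean_abs_delta: float = 1.5,
) -> list[EffectSpec]:
    """Plant an imbalanced up/down effect program across the three RNases.

    Emulates the severe-depletion situation the pipeline is built for:
    many more transcripts up than down, with per-RNase target sets that
    overlap only partially.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f.id for f in annotation.genes]
    effects = []
    for rnase in ("III", "J1", "Y"):
        n = int(round(frac_affected * len(gene_ids)))
        chosen = rng.choice(gene_ids, size=min(n, len(gene_ids)), replace=False)
        for g in chosen:
            mag = max(0.6, rng.lognormal(np.log(mean_abs_delta), 0.35))
            sign = 1.0 if rng.random() < up_fraction else -1.0
            effects.append(EffectSpec(g, rnase, sign * mag))
    return effects


def make_random_categories(
    gene_ids: list[str],
    n_categories: int = 110,
    seed: int = 0,
    size_range: tuple[int, int] = (10, 300),
) -> dict[str, list[str]]:
    """Random (null) functional-category memberships for calibration runs."""
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    hi = min(hi, len(gene_ids))
    cats = {}
    for i in range(n_categories):
        size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        members = rng.choice(gene_ids, size=size, replace=False)
        cats[f"cat_{i:03d}"] = sorted(members.tolist())
    return cats
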