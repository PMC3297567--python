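"""Probe-level profile estimation and gene/segment aggregation.

The raw intensity of a probe confounds the transcriptional signal with a
probe-specific hybridization affinity and a per-hybridization shift.  The
decomposition here is deliberately robust and deterministic:

* the per-sample shift is estimated by Tukey median polish of the matrix
  of deviations from each probe's condition medians (only within-condition
  shift components are identifiable at this stage; the between-condition
  component is handled later by the least-variant-set normalization);
* the probe affinity is estimated positionally, as the deviation of each
  probe's across-sample median from a running median over neighbouring
  same-strand probes — neighbours measure the same transcript, which is
  what makes the affinity separable from expression level.

Aggregated expression is the median of probe-level values over probes
lying entirely within a unit's interval, on the same strand, with a
unique genomic match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenomeAnnotation, HybridizationSet, ProbeDesign

log = logging.getLogger(__name__)

__all__ = ["ProbeProfileSet", "estimate_probe_profiles", "aggregate_expression", "median_polish"]


def median_polish(x: np.ndarray, tol: float = 1e-9, max_iter: int = 20):
    """Tukey's two-way median polish: x ~ overall + row + col + resid.

    Sweeps rows and columns alternately, subtracting medians, until the
    largest adjustment falls below ``tol`` or ``max_iter`` sweeps elapse.
    Ties in medians follow numpy's midpoint convention.
    """
    r = x.astype(float).copy()
    overall = 0.0
    row = np.zeros(x.shape[0])
    col = np.zeros(x.shape[1])
    for _ in range(max_iter):
        rmed = np.median(r, axis=1)
        row += rmed
        r -= rmed[:, None]
        cmed_of_row = np.median(row)
        overall += cmed_of_row
        row -= cmed_of_row
        cmed = np.median(r, axis=0)
        col += cmed
        r -= cmed[None, :]
        rmed_of_col = np.median(col)
        overall += rmed_of_col
        col -= rmed_of_col
        if max(np.abs(rmed).max(initial=0.0), np.abs(cmed).max(initial=0.0)) < tol:
            break
    return overall, row, col, r


@dataclass
class ProbeProfileSet:
    """Estimated probe-level expression with the removed offsets.

    ``profiles + affinity_hat (by probe) + shift_hat (by sample)``
    reconstructs the input intensities exactly; ``residual`` stores each
    value's deviation from its probe/condition median for QC.
    """

    profiles: pd.DataFrame  # probe x sample
    affinity_hat: pd.Series  # per probe, median 0
    shift_hat: pd.Series  # per sample, median 0
    residual: pd.DataFrame
    samples: pd.DataFrame
    qc: dict = field(default_factory=dict)

    def reconstruct(self) -> pd.DataFrame:
        return self.profiles.add(self.affinity_hat, axis=0).add(self.shift_hat, axis=1)


def _running_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with truncated windows at the edges."""
    n = len(values)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = np.median(values[lo:hi])
    return out


def estimate_probe_profiles(
    raw: HybridizationSet,
    design: ProbeDesign | None = None,
    affinity_window: int = 9,
    tol: float = 1e-9,
    max_iter: int = 20,
) -> ProbeProfileSet:
    """Decompose raw intensities into profile + affinity + shift (+ residual).

    All-missing probe rows are dropped with a warning and listed in the QC
    report.  When ``design`` is omitted the positional affinity term is
    unavailable and reported as zero.
    """
    y = raw.intensities
    if y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need at least 2 probes and 2 samples")
    dropped = y.index[y.isna().all(axis=1)].tolist()
    if dropped:
        log.warning("dropping %d all-missing probe rows", len(dropped))
        y = y.drop(index=dropped)

    conds = raw.samples.loc[y.columns, "condition"].to_numpy()
    iptg = raw.samples.loc[y.columns, "iptg"].to_numpy()
    groups = np.array([f"{c}|{i}" for c, i in zip(conds, iptg)])

    # per-probe condition medians and the deviation matrix
    ymat = y.to_numpy(float)
    cond_median = np.empty_like(ymat)
    for g in np.unique(groups):
        cols = groups == g
        cond_median[:, cols] = np.median(ymat[:, cols], axis=1, keepdims=True)
    dev = ymat - cond_median

    overall, _row, col, _resid = median_polish(dev, tol=tol, max_iter=max_iter)
    shift = overall + col
    shift = shift - np.median(shift)

    # positional affinity: probe-level median (shift removed) vs running
    # median over same-strand neighbours
    if design is not None:
        pframe = design.to_frame().loc[y.index]
        level = np.median(ymat - shift[None, :], axis=1)
        affinity = np.zeros(len(y))
        for strand in ("+", "-"):
            mask = pframe["strand"].to_numpy() == strand
            idx = np.where(mask)[0]
            idx = idx[np.argsort(pframe["start"].to_numpy()[idx])]
            if len(idx) == 0:
                continue
            vals = level[idx]
            affinity[idx] = vals - _running_median(vals, affinity_window)
        affinity = affinity - np.median(affinity)
    else:
        affinity = np.zeros(len(y))

    profiles = ymat - affinity[:, None] - shift[None, :]
    # residual for QC: deviation of each corrected value from its
    # probe/condition median after correction
    corr_cond_median = np.empty_like(profiles)
    for g in np.unique(groups):
        cols = groups == g
        corr_cond_median[:, cols] = np.median(profiles[:, cols], axis=1, keepdims=True)
    residual = profiles - corr_cond_median

    return ProbeProfileSet(
        profiles=pd.DataFrame(profiles, index=y.index, columns=y.columns),
        affinity_hat=pd.Series(affinity, index=y.index, name="affinity_hat"),
        shift_hat=pd.Series(shift, index=y.columns, name="shift_hat"),
        residual=pd.DataFrame(residual, index=y.index, columns=y.columns),
        samples=raw.samples,
        qc={"dropped_probes": dropped},
    )


def aggregate_expression(
    profiles: ProbeProfileSet,
    annotation: GenomeAnnotation,
    design: ProbeDesign,
    min_probes: int = 3,
    units: list | None = None,
) -> ExpressionMatrix:
    """Median over unique probes lying entirely within each unit's interval.

    Probes overhanging a unit boundary, on the other strand, or without a
    unique genomic match never contribute.  Units with fewer than
    ``min_probes`` eligible probes are kept but flagged.
    """
    pframe = design.to_frame().loc[profiles.profiles.index]
    starts = pframe["start"].to_numpy()
    ends = pframe["end"].to_numpy()
    strands = pframe["strand"].to_numpy()
    uniq = pframe["unique"].to_numpy()

    feats = units if units is not None else list(annotation.features)
    rows, counts, flagged = {}, {}, []
    mat = profiles.profiles.to_numpy(float)
    for f in feats:
        mask = (
            uniq
            & (strands == f.strand)
            & (starts >= f.start)
            & (ends <= f.end)
        )
        n = int(mask.sum())
        counts[f.id] = n
        if n == 0:
            rows[f.id] = np.full(mat.shape[1], np.nan)
            flagged.append(f.id)
            continue
        rows[f.id] = np.median(mat[mask], axis=0)
        if n < min_probes:
            flagged.append(f.id)
    if feats and all(counts[f.id] == 0 for f in feats):
        raise ValueError(
            "no eligible probes for any unit: check strand conventions and coordinates"
        )
    values = pd.DataFrame.from_dict(rows, orient="index", columns=profiles.profiles.columns)
    values.index.name = "unit"
    return ExpressionMatrix(
        values=values,
        samples=profiles.samples,
        n_probes=pd.Series(counts, name="n_probes"),
        flagged=frozenset(flagged),
    )
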