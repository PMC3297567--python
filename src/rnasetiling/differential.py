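"""Per-gene depletion model, q-values, profile calls and overlap summaries.

For each gene the expression in condition *i*, replicate *j* follows a
one-way layout

    x_ij = wt + dRNase_i + eps_ij,   eps_ij ~ N(0, sigma^2)

fitted by ordinary least squares with a pooled residual variance over the
four main conditions (wild type and the three -IPTG depletions).  Each
dRNase_i is tested against zero with a two-sided t-test on the pooled
residual degrees of freedom; p-values become Benjamini-Hochberg q-values;
a gene's profile for an RNase is U (up), D (down) or - (unchanged) by the
joint rule q <= fdr and |delta| >= log2(fold-change), evaluated at 2-fold
and 1.5-fold.

The public surface is ``DepletionModel(matrix).fit() -> DepletionResults``;
the underlying steps (``fit_gene_models``, ``compute_qvalues``,
``call_profiles``, ``overlap_sets``, ``assign_primary_rnase``) are exposed
for use on their own.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CONDITION_OF_RNASE, ExpressionMatrix, RNASES

log = logging.getLogger(__name__)

__all__ = [
    "DifferentialConfig",
    "GeneModelFrame",
    "DepletionModel",
    "DepletionResults",
    "fit_gene_models",
    "compute_qvalues",
    "call_profiles",
    "overlap_sets",
    "assign_primary_rnase",
]

TIE_ORDER = ("Y", "J1", "III")  # fixed tie-break for the primary RNase


@dataclass(frozen=True)
class DifferentialConfig:
    fdr: float = 0.1
    fold_changes: tuple[float, ...] = (2.0, 1.5)
    pool_qvalues: bool = True  # one BH pass over all gene x RNase tests


@dataclass
class GeneModelFrame:
    """Vectorised per-gene OLS fits of the one-way depletion layout."""

    wt_hat: pd.Series
    delta: pd.DataFrame  # genes x RNases
    sigma_hat: pd.Series
    dof: int
    pvalues: pd.DataFrame  # genes x RNases; NaN where undefined
    qc: dict = field(default_factory=dict)


def fit_gene_models(matrix: ExpressionMatrix) -> GeneModelFrame:
    """OLS of the one-way layout per gene, pooled residual variance.

    Requires the four main conditions with >= 2 replicates each.  Genes
    with zero residual variance get NaN p-values (flagged in ``qc``), not
    p = 0.
    """
    samples = [
        s
        for s in matrix.values.columns
        if matrix.samples.at[s, "condition"] == "wt"
        or matrix.samples.at[s, "iptg"] == "minus"
    ]
    conds = matrix.samples.loc[samples, "condition"]
    counts = conds.value_counts()
    for cond in ("wt", "rnc", "rnjA", "rny"):
        if counts.get(cond, 0) < 2:
            raise ValueError(f"need >= 2 replicates of condition {cond!r}")

    values = matrix.values[samples]
    x = values.to_numpy(float)
    n_total = x.shape[1]
    n_conditions = 4
    dof = n_total - n_conditions

    group_cols = {c: np.flatnonzero(conds.to_numpy() == c) for c in counts.index}
    means = {c: np.nanmean(x[:, idx], axis=1) for c, idx in group_cols.items()}
    sse = np.zeros(x.shape[0])
    for c, idx in group_cols.items():
        sse += np.nansum((x[:, idx] - means[c][:, None]) ** 2, axis=1)
    s2 = sse / dof
    sigma = np.sqrt(s2)

    wt_hat = means["wt"]
    n_wt = len(group_cols["wt"])
    delta = {}
    pvals = {}
    for rnase in RNASES:
        cond = CONDITION_OF_RNASE[rnase]
        d = means[cond] - wt_hat
        n_c = len(group_cols[cond])
        se = np.sqrt(s2 * (1.0 / n_c + 1.0 / n_wt))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = d / se
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        p[s2 <= 0] = np.nan  # undefined, never "significant at 0"
        delta[rnase] = d
        pvals[rnase] = p

    idx = values.index
    zero_var = idx[s2 <= 0].tolist()
    if zero_var:
        log.warning("%d genes with zero residual variance: p undefined", len(zero_var))
    return GeneModelFrame(
        wt_hat=pd.Series(wt_hat, index=idx, name="WT"),
        delta=pd.DataFrame(delta, index=idx),
        sigma_hat=pd.Series(sigma, index=idx, name="sigma_hat"),
        dof=dof,
        pvalues=pd.DataFrame(pvals, index=idx),
        qc={"zero_variance": zero_var},
    )


def compute_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order.

    ``q_(i) = min_{j>=i} p_(j) * m / j`` capped at 1, with m counting only
    the defined (non-NaN) p-values; NaN inputs give NaN q-values.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    flat = p.ravel()
    ok = ~np.isnan(flat)
    pv = flat[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.minimum(q, 1.0)
        qflat = np.empty(m)
        qflat[order] = q
        res = np.full(flat.shape, np.nan)
        res[ok] = qflat
        out = res.reshape(p.shape)
    return out


def call_profiles(
    fits: GeneModelFrame,
    qvalues: pd.DataFrame,
    config: DifferentialConfig = DifferentialConfig(),
) -> pd.DataFrame:
    """Combine FDR and fold-change gates into U/D/- profile codes."""
    if not fits.delta.index.equals(qvalues.index):
        raise ValueError("fits and qvalues are not aligned")
    frames = {"WT": fits.wt_hat}
    for rnase in RNASES:
        frames[f"delta_{rnase}"] = fits.delta[rnase]
        frames[f"p_{rnase}"] = fits.pvalues[rnase]
        frames[f"q_{rnase}"] = qvalues[rnase]
    table = pd.DataFrame(frames)
    for fc in config.fold_changes:
        thr = np.log2(fc)
        tag = f"{fc:g}".replace(".", "p")
        for rnase in RNASES:
            d = fits.delta[rnase]
            q = qvalues[rnase]
            sig = q <= config.fdr
            profile = np.where(
                sig & (d >= thr), "U", np.where(sig & (d <= -thr), "D", "-")
            )
            table[f"profile_{rnase}_{tag}"] = profile
    return table


def _profile_cols(fc: float) -> dict[str, str]:
    tag = f"{fc:g}".replace(".", "p")
    return {r: f"profile_{r}_{tag}" for r in RNASES}


@dataclass
class VennSummary:
    """Counts over the 7 disjoint regions of the three depletion sets."""

    up: dict[frozenset, int]
    down: dict[frozenset, int]
    mixed: int
    total_affected: int

    def region(self, *rnases: str, direction: str = "up") -> int:
        return (self.up if direction == "up" else self.down).get(frozenset(rnases), 0)


def overlap_sets(table: pd.DataFrame, fc: float = 2.0) -> VennSummary:
    """Venn decomposition of the per-RNase U/D calls.

    A unit is "up" ("down") in the region defined by the exact set of
    RNases for which it is U (D); units that are U for one RNase and D
    for another are counted once in a separate mixed class.
    """
    cols = _profile_cols(fc)
    regions = [
        frozenset(c)
        for k in (1, 2, 3)
        for c in itertools.combinations(RNASES, k)
    ]
    up = {r: 0 for r in regions}
    down = {r: 0 for r in regions}
    mixed = 0
    total = 0
    for _, row in table[[cols[r] for r in RNASES]].iterrows():
        ups = frozenset(r for r in RNASES if row[cols[r]] == "U")
        downs = frozenset(r for r in RNASES if row[cols[r]] == "D")
        if not ups and not downs:
            continue
        total += 1
        if ups and downs:
            mixed += 1
        elif ups:
            up[ups] += 1
        else:
            down[downs] += 1
    return VennSummary(up=up, down=down, mixed=mixed, total_affected=total)


def assign_primary_rnase(table: pd.DataFrame, fc: float = 2.0) -> pd.Series:
    """Which depletion had the greatest effect on each affected unit.

    Among significant increases the RNase with the largest delta wins
    (ties broken Y > J1 > III); units with only significant decreases are
    labelled "down"; unaffected units get None.
    """
    cols = _profile_cols(fc)
    labels = []
    for _, row in table.iterrows():
        ups = [r for r in RNASES if row[cols[r]] == "U"]
        downs = [r for r in RNASES if row[cols[r]] == "D"]
        if ups:
            best = max(
                ups,
                key=lambda r: (row[f"delta_{r}"], -TIE_ORDER.index(r)),
            )
            labels.append(best)
        elif downs:
            labels.append("down")
        else:
            labels.append(None)
    return pd.Series(labels, index=table.index, name="primary_rnase")


class DepletionModel:
    """Depletion linear model over an aggregated expression matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Normalized unit x sample log2 expression with sample metadata
        covering the four main conditions in >= 2 replicates each.
    """

    def __init__(self, matrix: ExpressionMatrix, config: DifferentialConfig | None = None):
        self.matrix = matrix
        self.config = config if config is not None else DifferentialConfig()

    @classmethod
    def from_dataframe(
        cls, values: pd.DataFrame, samples: pd.DataFrame, **kwargs
    ) -> "DepletionModel":
        return cls(ExpressionMatrix(values=values, samples=samples), **kwargs)

    def fit(self) -> "DepletionResults":
        fits = fit_gene_models(self.matrix)
        if self.config.pool_qvalues:
            q = compute_qvalues(fits.pvalues.to_numpy())
            qvalues = pd.DataFrame(q, index=fits.pvalues.index, columns=fits.pvalues.columns)
        else:
            qvalues = fits.pvalues.apply(lambda col: pd.Series(compute_qvalues(col), index=col.index))
        table = call_profiles(fits, qvalues, self.config)
        return DepletionResults(self, fits, qvalues, table)


class DepletionResults:
    """Fitted per-gene effects, significance and profile codes."""

    def __init__(
        self,
        model: DepletionModel,
        fits: GeneModelFrame,
        qvalues: pd.DataFrame,
        table: pd.DataFrame,
    ):
        self.model = model
        self.fits = fits
        self.qvalues = qvalues
        self.table = table

    @property
    def delta(self) -> pd.DataFrame:
        return self.fits.delta

    @property
    def pvalues(self) -> pd.DataFrame:
        return self.fits.pvalues

    def venn(self, fc: float = 2.0) -> VennSummary:
        return overlap_sets(self.table, fc=fc)

    def primary_rnase(self, fc: float = 2.0) -> pd.Series:
        return assign_primary_rnase(self.table, fc=fc)

    def supplementary_table(self) -> pd.DataFrame:
        """Result table mirroring the supplementary fold-change layout."""
        out = pd.DataFrame(index=self.table.index)
        out["WT"] = self.table["WT"]
        for r in RNASES:
            out[f"dRNase {r}"] = self.table[f"delta_{r}"]
        for r in RNASES:
            out[f"Qval_RNase {r}"] = self.table[f"q_{r}"]
        for r in RNASES:
            out[f"Pval_RNase {r}"] = self.table[f"p_{r}"]
        for fc in self.model.config.fold_changes:
            tag = f"{fc:g}".replace(".", "p")
            for r in RNASES:
                out[f"Profile {r} ({fc:g})"] = self.table[f"profile_{r}_{tag}"]
        return out

    def summary(self, fc: float = 2.0) -> str:
        cols = _profile_cols(fc)
        lines = [
            "Depletion model (one-way OLS, pooled variance)",
            f"  units: {len(self.table)}    residual dof: {self.fits.dof}",
            f"  FDR threshold: {self.model.config.fdr}   fold-change gate: {fc:g}x",
        ]
        for r in RNASES:
            n_up = int((self.table[cols[r]] == "U").sum())
            n_down = int((self.table[cols[r]] == "D").sum())
            lines.append(f"  RNase {r:>3}: {n_up} up, {n_down} down")
        venn = self.venn(fc)
        lines.append(
            f"  affected by >= 1 RNase: {venn.total_affected} "
            f"({venn.mixed} mixed up/down)"
        )
        return "\n".join(lines)

    def plot_volcano(self, rnase: str = "Y", ax=None, fc: float = 2.0):
        """Volcano plot of delta vs -log10 q for one RNase."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.table[f"delta_{rnase}"]
        q = self.table[f"q_{rnase}"]
        with np.errstate(divide="ignore"):
            y = -np.log10(q)
        sig = q <= self.model.config.fdr
        ax.scatter(d[~sig], y[~sig], s=6, c="0.7")
        ax.scatter(d[sig], y[sig], s=6, c="crimson")
        for thr in (np.log2(fc), -np.log2(fc)):
            ax.axvline(thr, ls="--", c="0.4", lw=0.8)
        ax.set_xlabel(f"log2 change under RNase {rnase} depletion")
        ax.set_ylabel("-log10 q")
        return ax
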