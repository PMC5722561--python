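"""Group-wise hypothesis testing and correlation screens.

Per-taxon differential abundance uses the Kruskal-Wallis rank test (tie
corrected, chi-square reference) on within-kingdom relative abundances,
with a Bonferroni correction over the taxon family tested; multi-group
follow-up uses Dunn's z on the pooled mid-ranks with Bonferroni over group
pairs.  Correlation screens use Spearman rank correlation (Pearson via
``method``) with Benjamini-Hochberg adjustment across all pairs in scope.

Tumor-vs-normal comparisons deliberately treat the two tissues as
independent groups (unpaired), matching common practice for these screens; a
paired Wilcoxon signed-rank variant is available as an extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import (
    AbundanceTable,
    PairedCohort,
    TaxonLineage,
    ValidationError,
    aggregate_to_rank,
    to_relative_abundance,
)
from .diversity import sample_diversity


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p over >= 2 groups."""
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("empty group")
    if sum(a.size for a in arrays) < 3:
        raise ValidationError("need total n >= 3")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def dunn_bonferroni(groups: Sequence[Sequence[float]]) -> pd.DataFrame:
    """Dunn's post-hoc z tests on pooled mid-ranks, Bonferroni-adjusted.

    Returns one row per group pair with columns ``group_i, group_j, z,
    p_raw, p_adjusted`` (adjusted = raw x number of pairs, capped at 1).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValidationError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term: sum(t^3 - t) / (12 (n - 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1)))
    splits = np.cumsum([a.size for a in arrays])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]
    sizes = [a.size for a in arrays]
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_i": i,
                "group_j": j,
                "z": float(z),
                "p_raw": float(p),
                "p_adjusted": float(min(1.0, p * n_pairs)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TaxonTestResult:
    lineage: TaxonLineage
    group_means: dict[str, float]  # group label -> mean relative abundance
    group_sds: dict[str, float]
    h_statistic: float
    p_raw: float
    p_adjusted: float
    direction: Optional[str]  # "tumor_up" / "tumor_down" when tissue grouping


def _grouping_values(cohort: PairedCohort, grouping: str, tissue: Optional[str]) -> pd.Series:
    meta = cohort.metadata_frame()
    if grouping not in meta.columns:
        raise ValidationError(f"unknown grouping variable {grouping!r}")
    if tissue is not None:
        meta = meta[meta["tissue"] == tissue]
    vals = meta[grouping].dropna()
    if vals.empty or vals.nunique() < 2:
        raise ValidationError(
            f"grouping {grouping!r} has fewer than 2 defined groups"
            + (f" within tissue {tissue!r}" if tissue else "")
        )
    return vals


def per_taxon_differential(
    cohort: PairedCohort,
    rank: str = "genus",
    grouping: str = "tissue",
    tissue: Optional[str] = None,
    kingdoms: Sequence[str] = ("bacteria", "fungi"),
    paired: bool = False,
) -> list[TaxonTestResult]:
    """Kruskal-Wallis screen of per-taxon relative abundance across groups.

    Relative abundance is computed within each kingdom at ``rank``; taxa with
    zero total across the analyzed samples are excluded (logged by the
    aggregation layer).  ``p_adjusted`` is Bonferroni over the set of taxa
    actually tested.  With ``paired=True`` and a two-level grouping aligned
    with the cohort's pairs, a Wilcoxon signed-rank test replaces
    Kruskal-Wallis (extension beyond the reference workflow).
    Results are sorted by adjusted then raw p.
    """
    vals = _grouping_values(cohort, grouping, tissue)
    levels = sorted(vals.unique())
    results: list[TaxonTestResult] = []
    for kingdom in kingdoms:
        table = aggregate_to_rank(cohort.table(kingdom), rank)
        table = table.select_samples([s for s in table.samples if s in vals.index])
        table = table.drop_empty_taxa()
        props = to_relative_abundance(table)
        labels = vals.loc[props.samples].to_numpy()
        for i, lineage in enumerate(props.taxa):
            row = props.counts[i]
            groups = [row[labels == lev] for lev in levels]
            if paired and grouping == "tissue" and len(levels) == 2:
                per = {s: v for s, v in zip(props.samples, row)}
                t_vals = np.array([per[t] for t, _ in cohort.pairs.values()])
                n_vals = np.array([per[n] for _, n in cohort.pairs.values()])
                if np.all(t_vals == n_vals):
                    h, p = 0.0, 1.0
                else:
                    stat, p = sps.wilcoxon(t_vals, n_vals)
                    h = float(stat)
            else:
                h, p = kruskal_wallis(groups)
            means = {lev: float(g.mean()) for lev, g in zip(levels, groups)}
            sds = {lev: float(g.std(ddof=1)) if g.size > 1 else 0.0 for lev, g in zip(levels, groups)}
            direction = None
            if grouping == "tissue" and {"tumor", "nontumor"} <= set(levels):
                direction = "tumor_up" if means["tumor"] >= means["nontumor"] else "tumor_down"
            results.append(
                TaxonTestResult(
                    lineage=lineage,
                    group_means=means,
                    group_sds=sds,
                    h_statistic=h,
                    p_raw=p,
                    p_adjusted=p,  # family-adjusted below
                    direction=direction,
                )
            )
    m = len(results)
    for r in results:
        r.p_adjusted = min(1.0, r.p_raw * m)
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw))
    return results


@dataclass
class DiversityTestResult:
    kingdom: str
    metric: str
    rank: str
    group_means: dict[str, float]
    h_statistic: float
    p_value: float


def diversity_comparison(
    cohort: PairedCohort,
    rank: str = "genus",
    metric: str = "shannon",
    grouping: str = "tissue",
    tissue: Optional[str] = None,
) -> list[DiversityTestResult]:
    """Compare per-sample Shannon diversity or richness across groups,
    one Kruskal-Wallis test per kingdom."""
    if metric not in ("shannon", "richness"):
        raise ValidationError(f"unknown metric {metric!r}")
    vals = _grouping_values(cohort, grouping, tissue)
    levels = sorted(vals.unique())
    out = []
    for kingdom in ("bacteria", "fungi"):
        table = aggregate_to_rank(cohort.table(kingdom), rank)
        table = table.select_samples([s for s in table.samples if s in vals.index])
        div = sample_diversity(table)
        x = div.shannon if metric == "shannon" else div.richness.astype(float)
        labels = vals.loc[div.sample_ids].to_numpy()
        groups = [x[labels == lev] for lev in levels]
        h, p = kruskal_wallis(groups)
        out.append(
            DiversityTestResult(
                kingdom=kingdom,
                metric=metric,
                rank=rank,
                group_means={lev: float(g.mean()) for lev, g in zip(levels, groups)},
                h_statistic=h,
                p_value=p,
            )
        )
    return out


@dataclass
class CorrelationMatrixResult:
    scope: str  # intra-bacteria / intra-fungi / inter-kingdom
    tissue: str
    row_labels: list[str]
    col_labels: list[str]
    r: np.ndarray  # correlation coefficients, NaN where undefined
    p_raw: np.ndarray
    p_adjusted: np.ndarray  # Benjamini-Hochberg within scope

    def tidy(self) -> pd.DataFrame:
        rows = []
        square = self.row_labels == self.col_labels
        for i, a in enumerate(self.row_labels):
            for j, b in enumerate(self.col_labels):
                if square and j <= i:
                    continue
                rows.append(
                    {
                        "taxon_a": a,
                        "taxon_b": b,
                        "r": self.r[i, j],
                        "p_raw": self.p_raw[i, j],
                        "p_adjusted": self.p_adjusted[i, j],
                    }
                )
        return pd.DataFrame(rows)


def correlation_screen(
    cohort: PairedCohort,
    rank: str = "genus",
    tissue: str = "tumor",
    scope: str = "inter-kingdom",
    method: str = "spearman",
) -> CorrelationMatrixResult:
    """Taxon-taxon abundance correlations across samples of one tissue.

    ``scope`` selects within-kingdom ('intra-bacteria', 'intra-fungi') or the
    rectangular bacteria x fungi screen ('inter-kingdom').  Constant taxa
    give undefined coefficients, reported as NaN and excluded from the BH
    family.
    """
    if scope not in ("intra-bacteria", "intra-fungi", "inter-kingdom"):
        raise ValidationError(f"unknown scope {scope!r}")
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown method {method!r}")
    meta = cohort.metadata_frame()
    keep = meta.index[meta["tissue"] == tissue].tolist()
    if len(keep) < 4:
        raise ValidationError(f"need >= 4 samples in tissue {tissue!r}")

    def _props(kingdom: str) -> pd.DataFrame:
        table = aggregate_to_rank(cohort.table(kingdom), rank)
        table = table.select_samples([s for s in table.samples if s in set(keep)])
        table = table.drop_empty_taxa()
        rel = to_relative_abundance(table)
        return pd.DataFrame(
            rel.counts.T, index=rel.samples, columns=[t.taxon_id for t in rel.taxa]
        )

    if scope == "inter-kingdom":
        left, right = _props("bacteria"), _props("fungi")
    elif scope == "intra-bacteria":
        left = right = _props("bacteria")
    else:
        left = right = _props("fungi")

    nl, nr = left.shape[1], right.shape[1]
    r = np.full((nl, nr), np.nan)
    p = np.full((nl, nr), np.nan)
    la = left.to_numpy()
    ra = right.to_numpy()
    if method == "spearman":
        la = sps.rankdata(la, axis=0)
        ra = sps.rankdata(ra, axis=0)
    const_l = np.ptp(la, axis=0) == 0
    const_r = np.ptp(ra, axis=0) == 0
    n = la.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        lz = (la - la.mean(axis=0)) / la.std(axis=0)
        rz = (ra - ra.mean(axis=0)) / ra.std(axis=0)
        r_full = lz.T @ rz / n
    r_full = np.clip(r_full, -1.0, 1.0)
    # t-distributed p for the correlation coefficient
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r_full * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r_full**2))
    p_full = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p_full[np.abs(r_full) >= 1.0] = 0.0
    valid = ~np.outer(const_l, np.ones(nr, bool)) & ~np.outer(np.ones(nl, bool), const_r)
    r[valid] = r_full[valid]
    p[valid] = p_full[valid]

    square = scope != "inter-kingdom"
    p_adj = np.full_like(p, np.nan)
    if square:
        iu = np.triu_indices(nl, k=1)
        mask = ~np.isnan(p[iu])
        adj = np.full(iu[0].size, np.nan)
        if mask.any():
            adj[mask] = multipletests(p[iu][mask], method="fdr_bh")[1]
        p_adj[iu] = adj
        p_adj.T[iu] = adj
        np.fill_diagonal(p_adj, 0.0)
        np.fill_diagonal(r, np.where(const_l, np.nan, 1.0))
        np.fill_diagonal(p, 0.0)
    else:
        flat = p.ravel()
        mask = ~np.isnan(flat)
        adj = np.full(flat.size, np.nan)
        if mask.any():
            adj[mask] = multipletests(flat[mask], method="fdr_bh")[1]
        p_adj = adj.reshape(p.shape)
    return CorrelationMatrixResult(
        scope=scope,
        tissue=tissue,
        row_labels=list(left.columns),
        col_labels=list(right.columns),
        r=r,
        p_raw=p,
        p_adjusted=p_adj,
    )
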