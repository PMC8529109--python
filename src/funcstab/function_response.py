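"""Function-specific responses to species loss.

Works on the top-level ("level 1") functional categories: per-level mean
relative abundances, one-way ANOVA of each category's abundance against
loss level, PERMANOVA of the *internal* composition of each category
(member functions renormalized to sum to one within the category, so only
the internal mix matters, not the category's overall share), the
correlation of those statistics with category abundance, and
average-linkage/Spearman heatmap clustering of the category x level trend
matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.stats

from . import betadiv
from .errors import ContractError
from .io_profiles import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class CategoryResponse:
    """Per-category summary across loss levels."""

    category: str
    mean_relative_abundance: pd.Series  # indexed by level name
    overall_mean: float
    anova_F: float | None = None
    anova_p: float | None = None
    within_permanova: betadiv.PermanovaResult | None = None


@dataclass
class HeatmapResult:
    matrix: pd.DataFrame  # z-scored categories x levels
    row_order: list[str]  # dendrogram leaf order
    linkage: np.ndarray  # scipy linkage matrix
    constant_rows: list[str]


def category_trends(
    level_tables: dict[str, AbundanceTable],
    dominance_cutoff: float = 0.01,
) -> tuple[pd.DataFrame, list[str]]:
    """Mean relative abundance per category and loss level.

    ``level_tables`` maps level name -> level-1 relative-abundance table.
    Mismatched category universes are reconciled by union with zeros.
    Returns the full trend matrix (categories x levels) and the list of
    dominant categories whose grand mean exceeds ``dominance_cutoff``.
    """
    all_cats: list[str] = []
    for t in level_tables.values():
        for c in t.features:
            if c not in all_cats:
                all_cats.append(c)
    cols = {}
    grand = {}
    for name, table in level_tables.items():
        vals = table.values
        if not table.relative:
            totals = vals.sum(axis=1)
            vals = vals.div(totals.where(totals > 0, 1.0), axis=0)
        missing = [c for c in all_cats if c not in vals.columns]
        if missing:
            logger.info("level %s: %d categories absent, filled with zeros", name, len(missing))
        vals = vals.reindex(columns=all_cats, fill_value=0.0)
        cols[name] = vals.mean(axis=0)
        grand[name] = vals
    trend = pd.DataFrame(cols)
    trend.index.name = "category"
    overall = pd.concat(grand.values()).mean(axis=0)
    dominant = [c for c in all_cats if overall[c] > dominance_cutoff]
    return trend, dominant


def anova_per_category(
    level_tables: dict[str, AbundanceTable],
    categories: list[str] | None = None,
) -> pd.DataFrame:
    """Classical one-way ANOVA per category, loss level as the factor.

    Uses per-sample relative abundances at each level. Categories whose
    between- and within-group variances are both zero get NaN statistics.
    """
    if len(level_tables) < 2:
        raise ContractError("ANOVA needs at least two loss levels")
    trend, _ = category_trends(level_tables, dominance_cutoff=0.0)
    cats = categories if categories is not None else list(trend.index)
    rows = []
    for cat in cats:
        samples = []
        for table in level_tables.values():
            vals = table.values
            if not table.relative:
                totals = vals.sum(axis=1)
                vals = vals.div(totals.where(totals > 0, 1.0), axis=0)
            samples.append(vals[cat].to_numpy() if cat in vals.columns
                           else np.zeros(len(vals)))
        if any(len(s) < 2 for s in samples):
            raise ContractError("every loss level needs at least two samples")
        flat = np.concatenate(samples)
        if np.ptp(flat) == 0:
            rows.append({"category": cat, "F": np.nan, "p": np.nan})
            logger.info("category %s constant everywhere; ANOVA undefined", cat)
            continue
        F, p = scipy.stats.f_oneway(*samples)
        rows.append({"category": cat, "F": float(F), "p": float(p)})
    return pd.DataFrame(rows).set_index("category")


def within_category_permanova(
    level_tables: dict[str, AbundanceTable],
    category_of: dict[str, str],
    n_permutations: int = 999,
    seed: int | None = None,
    categories: list[str] | None = None,
) -> dict[str, betadiv.PermanovaResult]:
    """PERMANOVA of each category's internal function-level composition.

    ``level_tables`` maps level name -> function-resolution table;
    ``category_of`` maps each function id to its level-1 category. Member
    functions are renormalized to sum to one within the category per
    sample (so a uniform scaling of the whole category changes nothing),
    then levels are concatenated and tested with Bray-Curtis PERMANOVA,
    loss level as the factor. Single-function categories are skipped.
    """
    by_cat: dict[str, list[str]] = {}
    for fn, cat in category_of.items():
        by_cat.setdefault(cat, []).append(fn)
    wanted = categories if categories is not None else sorted(by_cat)
    out: dict[str, betadiv.PermanovaResult] = {}
    for cat in wanted:
        members = sorted(by_cat.get(cat, []))
        if len(members) < 2:
            logger.info("category %s has <2 member functions; skipped", cat)
            continue
        blocks, labels = [], []
        for name, table in level_tables.items():
            sub = table.values.reindex(columns=members, fill_value=0.0)
            totals = sub.sum(axis=1)
            sub = sub.div(totals.where(totals > 0, 1.0), axis=0)
            sub.index = [f"{name}:{s}" for s in sub.index]
            blocks.append(sub)
            labels.extend([name] * len(sub))
        stacked = AbundanceTable(
            values=pd.concat(blocks), kind="function", level="function", relative=True
        )
        dist = betadiv.bray_curtis(stacked, relative=False)
        try:
            out[cat] = betadiv.permanova(
                dist, labels, n_permutations=n_permutations, seed=seed
            )
        except ContractError as exc:
            logger.info("category %s: PERMANOVA undefined (%s)", cat, exc)
    return out


def abundance_response_correlation(
    overall_means: pd.Series, statistics: pd.Series
) -> betadiv.CorrelationResult:
    """Pearson correlation of a per-category statistic with category abundance.

    Both series are aligned on their (category) index; categories missing a
    statistic are dropped.
    """
    joined = pd.concat(
        {"abundance": overall_means, "stat": statistics}, axis=1
    ).dropna()
    if len(joined) < 3:
        raise ContractError("need at least three categories with a defined statistic")
    return betadiv.pearson(joined["stat"].to_numpy(), joined["abundance"].to_numpy())


def heatmap_cluster(matrix: pd.DataFrame) -> HeatmapResult:
    """Cluster category trend rows: Spearman distance, average linkage.

    Rows are z-scored across loss levels. Row distance is
    1 - Spearman rank correlation (average ranks for ties). A constant row
    has undefined rank correlation; it is kept, flagged, and assigned the
    maximal distance 2 to every other row. Leaf order is deterministic
    (scipy's agglomerative ordering, input order for ties).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ContractError("heatmap clustering needs >= 2 rows and >= 2 columns")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    constant = sd == 0
    Z = np.where(
        constant[:, None], 0.0, (X - X.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1, sd)[:, None]
    )
    const_rows = [str(matrix.index[i]) for i in np.flatnonzero(constant)]
    if const_rows:
        logger.warning("constant rows flagged (distance 2 to all others): %s", const_rows)
    ranks = np.apply_along_axis(scipy.stats.rankdata, 1, X)
    n = X.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if constant[i] or constant[j]:
                d = 2.0
            else:
                rho = np.corrcoef(ranks[i], ranks[j])[0, 1]
                d = 1.0 - rho
            dist[i, j] = dist[j, i] = d
    condensed = dist[np.triu_indices(n, 1)]
    linkage = scipy.cluster.hierarchy.linkage(condensed, method="average")
    order = scipy.cluster.hierarchy.leaves_list(linkage)
    zed = pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)
    return HeatmapResult(
        matrix=zed,
        row_order=[str(matrix.index[i]) for i in order],
        linkage=linkage,
        constant_rows=const_rows,
    )
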