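"""Directed, abundance-ordered sequential species loss.

Extinction is simulated by ranking phyla by pooled relative abundance and
retaining only the top-k phyla at each loss level, least-abundant phyla
going extinct first. Because the joint profile keys every functional hit
to a genus, filtering taxa removes their functional hits too — the
function-level and taxonomy-level views of a loss level always count the
same surviving records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import betadiv
from .errors import ContractError
from .io_profiles import (
    AbundanceTable,
    CommunitySummary,
    LinkedProfile,
    project,
    summarize,
)

logger = logging.getLogger(__name__)

_NUMBER_NAMES = {
    1: "One", 2: "Two", 3: "Three", 4: "Four", 5: "Five",
    6: "Six", 7: "Seven", 8: "Eight", 9: "Nine", 10: "Ten",
    11: "Eleven", 12: "Twelve",
}


@dataclass(frozen=True)
class LossLevel:
    """One step of directed extinction: the set of phyla that survive."""

    name: str
    retained_phyla: frozenset[str]

    def __post_init__(self) -> None:
        if not self.retained_phyla:
            raise ValueError("a loss level must retain at least one phylum")


@dataclass
class LossSeriesReport:
    """Per-level community summaries for both classification kinds.

    ``table`` has one row per (level, kind) with S, N and the percent
    reduction of each relative to the first (full) level. ``s_trend`` /
    ``n_trend`` hold the Pearson correlation of S and N against level index,
    one entry per kind, when the series has at least three levels.
    """

    table: pd.DataFrame
    s_trend: dict[str, betadiv.CorrelationResult]
    n_trend: dict[str, betadiv.CorrelationResult]


def rank_phyla(profile: LinkedProfile) -> list[str]:
    """Phyla in descending order of pooled relative abundance.

    Ties are broken lexicographically so the ranking is deterministic.
    """
    if len(profile.data) == 0:
        raise ContractError("cannot rank phyla of an empty profile")
    pooled = profile.data.groupby("phylum", observed=True)["hits"].sum()
    order = sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in order]


def default_levels(ranking: list[str], sizes: list[int] | None = None) -> list[LossLevel]:
    """Nested retention sets for the top ``sizes[k]`` phyla of ``ranking``.

    Defaults to the all/8/5/2/1 design (clipped to the number of phyla
    present). The first (largest) level is named "All"; smaller levels are
    named by their remaining phylum count.
    """
    n = len(ranking)
    if sizes is None:
        sizes = [n] + [s for s in (8, 5, 2, 1) if s < n]
    if any(b >= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError(f"sizes must be strictly decreasing, got {sizes}")
    if sizes[0] > n:
        raise ValueError(f"cannot retain {sizes[0]} phyla; ranking has only {n}")
    levels = []
    for k in sizes:
        name = "All" if k == n else _NUMBER_NAMES.get(k, f"Top{k}")
        levels.append(LossLevel(name=name, retained_phyla=frozenset(ranking[:k])))
    return levels


def apply_loss_level(profile: LinkedProfile, level: LossLevel) -> LinkedProfile:
    """Keep only records whose genus belongs to a retained phylum."""
    present = set(profile.data["phylum"])
    missing = level.retained_phyla - present
    if missing:
        logger.warning("level %s retains phyla absent from profile: %s",
                       level.name, sorted(missing))
    out = LinkedProfile(profile.data[profile.data["phylum"].isin(level.retained_phyla)])
    if len(out.data) == 0:
        logger.warning("level %s retains no records", level.name)
    return out


def _check_nested(levels: list[LossLevel]) -> None:
    for earlier, later in zip(levels, levels[1:]):
        if not later.retained_phyla <= earlier.retained_phyla:
            raise ContractError(
                f"loss levels must be nested: {later.name} is not a subset of {earlier.name}"
            )


def loss_series(
    profile: LinkedProfile,
    levels: list[LossLevel],
    taxonomy_level: str = "genus",
    function_level: str = "function",
) -> tuple[LossSeriesReport, dict[str, dict[str, AbundanceTable]]]:
    """Run the whole extinction series.

    Returns the S/N report and, per level name, the count tables
    ``{"taxonomy": ..., "function": ...}`` (genus- and function-resolution
    by default). Relative-abundance versions are obtained downstream with
    :func:`~funcstab.io_profiles.to_relative_abundance`, so a level's
    functional profile renormalizes over surviving records only.
    """
    _check_nested(levels)
    tables: dict[str, dict[str, AbundanceTable]] = {}
    rows = []
    baseline: dict[str, CommunitySummary] = {}
    for idx, level in enumerate(levels):
        sub = apply_loss_level(profile, level)
        per_kind = {
            "taxonomy": project(sub, "taxonomy", taxonomy_level),
            "function": project(sub, "function", function_level),
        }
        tables[level.name] = per_kind
        for kind, table in per_kind.items():
            summ = summarize(table)
            if idx == 0:
                baseline[kind] = summ
            base = baseline[kind]
            rows.append(
                {
                    "level": level.name,
                    "level_index": idx,
                    "kind": kind,
                    "S": summ.S,
                    "N": summ.N,
                    "S_reduction_pct": 100.0 * (1 - summ.S / base.S) if base.S else 0.0,
                    "N_reduction_pct": 100.0 * (1 - summ.N / base.N) if base.N else 0.0,
                }
            )
        logger.info("level %s: %d of %d records survive", level.name,
                    len(sub.data), len(profile.data))
    report = pd.DataFrame(rows)
    for kind in ("taxonomy", "function"):
        sub = report[report["kind"] == kind]
        for col in ("S", "N"):
            if (sub[col].diff().dropna() > 0).any():
                raise ContractError(f"{col} increased along a nested series ({kind})")
    s_trend, n_trend = {}, {}
    if len(levels) >= 3:
        for kind in ("taxonomy", "function"):
            sub = report[report["kind"] == kind]
            idx = sub["level_index"].to_numpy(dtype=float)
            for col, store in (("S", s_trend), ("N", n_trend)):
                vals = sub[col].to_numpy(dtype=float)
                if vals.std() > 0:
                    store[kind] = betadiv.pearson(idx, vals)
    return LossSeriesReport(table=report, s_trend=s_trend, n_trend=n_trend), tables
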