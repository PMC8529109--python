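"""Joint taxonomy x function profile containers and tab-separated I/O.

The central object is the :class:`LinkedProfile`: a long-format table of
per-sample hit counts keyed by (sample, genus, function), where each genus
carries its phylum and each function its three-level category lineage.
Keeping taxonomy and function on the same records is what makes
taxonomy-filtered functional profiles possible: removing a phylum removes
its genera's functional hits too.

Counts project to single-classification abundance tables (samples x
features) at any taxonomic or functional level, and those tables can be
standardized to per-sample relative abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ContractError, ProfileFormatError, ProfileValidationError

logger = logging.getLogger(__name__)

#: canonical long-format columns, in writing order
COLUMNS = (
    "sample",
    "genus",
    "phylum",
    "function",
    "level1",
    "level2",
    "level3",
    "hits",
)

#: sentinel labels for records lacking a classification
UNCLASSIFIED_TAXON = "unclassified_taxon"
UNCLASSIFIED_FUNCTION = "unclassified_function"

TAXONOMY_LEVELS = ("phylum", "genus")
FUNCTION_LEVELS = ("level1", "level2", "level3", "function")


@dataclass
class LinkedProfile:
    """Per-sample joint taxonomy x function hit counts.

    Parameters
    ----------
    data:
        Long-format frame with columns :data:`COLUMNS`. One row per
        (sample, genus, function) key; duplicate keys are summed on
        construction. ``hits`` must be non-negative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ProfileFormatError(f"missing required column(s): {', '.join(missing)}")
        df = self.data.loc[:, list(COLUMNS)].copy()
        hits = pd.to_numeric(df["hits"], errors="coerce")
        if hits.isna().any():
            bad = int(np.flatnonzero(hits.isna().to_numpy())[0])
            raise ProfileValidationError(f"non-numeric hits value at row {bad}")
        if (hits < 0).any():
            bad = int(np.flatnonzero((hits < 0).to_numpy())[0])
            raise ProfileValidationError(f"negative hits value at row {bad}")
        df["hits"] = hits
        for col in ("genus", "function"):
            sentinel = UNCLASSIFIED_TAXON if col == "genus" else UNCLASSIFIED_FUNCTION
            blank = df[col].isna() | (df[col].astype(str).str.strip() == "")
            if blank.any():
                logger.info("%d records with blank %s kept as %r", blank.sum(), col, sentinel)
                df.loc[blank, col] = sentinel
                if col == "genus":
                    df.loc[blank, "phylum"] = UNCLASSIFIED_TAXON
                else:
                    df.loc[blank, ["level1", "level2", "level3"]] = UNCLASSIFIED_FUNCTION
        # genus -> phylum and function -> lineage must be single-valued
        tax = df[["genus", "phylum"]].drop_duplicates()
        dup = tax["genus"].duplicated()
        if dup.any():
            raise ProfileValidationError(
                f"genus {tax.loc[dup, 'genus'].iloc[0]!r} maps to more than one phylum"
            )
        fun = df[["function", "level1", "level2", "level3"]].drop_duplicates()
        dup = fun["function"].duplicated()
        if dup.any():
            raise ProfileValidationError(
                f"function {fun.loc[dup, 'function'].iloc[0]!r} maps to more than one lineage"
            )
        if df.duplicated(subset=["sample", "genus", "function"]).any():
            df = (
                df.groupby(list(COLUMNS[:-1]), sort=False, observed=True, as_index=False)["hits"]
                .sum()
            )
        self.data = df.reset_index(drop=True)

    # -- views ---------------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        """Sample identifiers in first-appearance order."""
        return list(pd.unique(self.data["sample"]))

    @property
    def taxonomy_map(self) -> dict[str, str]:
        """genus -> phylum."""
        tax = self.data[["genus", "phylum"]].drop_duplicates()
        return dict(zip(tax["genus"], tax["phylum"]))

    @property
    def function_map(self) -> dict[str, tuple[str, str, str]]:
        """function -> (level3, level2, level1)."""
        fun = self.data[["function", "level3", "level2", "level1"]].drop_duplicates()
        return {r.function: (r.level3, r.level2, r.level1) for r in fun.itertuples()}

    @property
    def total_hits(self) -> float:
        return float(self.data["hits"].sum())

    def drop_unclassified(self) -> "LinkedProfile":
        """Profile without the unclassified sentinel records."""
        keep = (self.data["genus"] != UNCLASSIFIED_TAXON) & (
            self.data["function"] != UNCLASSIFIED_FUNCTION
        )
        return LinkedProfile(self.data.loc[keep])

    def record_multiset(self) -> set[tuple]:
        """Hashable record set (for equality checks irrespective of row order)."""
        return set(map(tuple, self.data[list(COLUMNS)].itertuples(index=False)))


@dataclass
class AbundanceTable:
    """Samples x features matrix of counts or relative abundances.

    ``kind`` is ``"taxonomy"`` or ``"function"``; ``level`` names the
    hierarchy level the features live at. ``relative`` records whether rows
    have been standardized to sum to one.
    """

    values: pd.DataFrame
    kind: str
    level: str
    relative: bool = False

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ProfileValidationError("duplicate feature identifiers in table")
        if (self.values.to_numpy() < 0).any():
            raise ProfileValidationError("abundance values must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class CommunitySummary:
    """Corpus-level richness S (features with pooled hits > 0) and size N (total hits)."""

    S: int
    N: float

    def __post_init__(self) -> None:
        if (self.S == 0) != (self.N == 0):
            raise ContractError("S and N must be zero together")


# -- operations ---------------------------------------------------------------


def read_linked_profile(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> LinkedProfile:
    """Read a long-format TSV into a validated :class:`LinkedProfile`.

    ``dialect`` maps canonical column names to the names used in the file,
    e.g. ``{"function": "Subsystem function"}``. Duplicate
    (sample, genus, function) rows are summed; row order is irrelevant.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    rename = {v: k for k, v in (dialect or {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ProfileFormatError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    return LinkedProfile(df)


def write_linked_profile(profile: LinkedProfile, path: str | Path) -> None:
    """Write the profile as canonical tab-separated text."""
    df = profile.data.copy()
    df["hits"] = [_fmt(v) for v in df["hits"]]
    df.to_csv(path, sep="\t", index=False)


def _fmt(v: float) -> str:
    """Numbers rendered with >= 10 significant digits; integers stay integral."""
    f = float(v)
    return str(int(f)) if f == int(f) else format(f, ".12g")


def project(profile: LinkedProfile, kind: str, level: str) -> AbundanceTable:
    """Collapse the joint profile to a samples x features count table.

    Total hits are conserved: the table's grand sum equals the profile's.
    """
    if kind == "taxonomy":
        valid = TAXONOMY_LEVELS
    elif kind == "function":
        valid = FUNCTION_LEVELS
    else:
        raise ValueError(f"kind must be 'taxonomy' or 'function', got {kind!r}")
    if level not in valid:
        raise ValueError(f"unknown {kind} level {level!r}; expected one of {valid}")
    wide = (
        profile.data.groupby(["sample", level], sort=False, observed=True)["hits"]
        .sum()
        .unstack(fill_value=0.0)
    )
    wide = wide.reindex(index=profile.samples)
    wide = wide.loc[:, sorted(wide.columns)]
    wide.index.name = "sample"
    wide.columns.name = level
    return AbundanceTable(values=wide, kind=kind, level=level)


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample row by its own total hits.

    All-zero rows stay all-zero (logged); applying the operation twice is a
    no-op.
    """
    vals = table.values.to_numpy(dtype=float)
    totals = vals.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        logger.warning(
            "%d all-zero sample row(s) left unnormalized: %s",
            zero.sum(),
            [s for s, z in zip(table.samples, zero) if z],
        )
    safe = np.where(totals == 0, 1.0, totals)
    rel = pd.DataFrame(vals / safe, index=table.values.index, columns=table.values.columns)
    return AbundanceTable(values=rel, kind=table.kind, level=table.level, relative=True)


def summarize(table: AbundanceTable) -> CommunitySummary:
    """Pooled species count S and individual count N of a count table."""
    if table.relative:
        raise ContractError("summarize requires counts; N is meaningless on relative abundance")
    pooled = table.values.sum(axis=0)
    return CommunitySummary(S=int((pooled > 0).sum()), N=float(pooled.sum()))


def write_abundance_table(
    table: AbundanceTable, path: str | Path, header_comment: str | None = None
) -> None:
    """Write a samples x features table as TSV with >= 10 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("sample\t" + "\t".join(map(str, table.features)) + "\n")
        for sample, row in table.values.iterrows():
            fh.write(str(sample) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_abundance_table(path: str | Path, kind: str, level: str) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    relative = bool(np.allclose(df.sum(axis=1), 1.0)) if len(df) else False
    return AbundanceTable(values=df, kind=kind, level=level, relative=relative)
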