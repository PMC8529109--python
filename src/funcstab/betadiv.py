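"""Beta-diversity statistics implemented from first principles.

Bray-Curtis dissimilarity, principal coordinates analysis (PCoA),
one-factor PERMANOVA with its pairwise pseudo-t companion, and Pearson
correlation. These are the analytical core of the package and are written
directly against their definitions rather than delegating to an external
multivariate-ecology library, so that every sum of squares, permutation
scheme and tie-break is explicit and testable.

Definitions
-----------
For two non-negative abundance rows x, y the Bray-Curtis dissimilarity is

    D(x, y) = sum_k |x_k - y_k| / sum_k (x_k + y_k)

(the familiar percentage similarity is ``100 * (1 - D)``).

PERMANOVA partitions the squared-distance sums of squares: with N samples
in a groups,

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    pseudo-F  = (SS_between / (a-1)) / (SS_within / (N-a))

and significance comes from permuting group labels; the reported p-value is
``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)``. The two-group pairwise
statistic is pseudo-t = sqrt(pseudo-F).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .errors import ContractError
from .io_profiles import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities among samples, entries in [0, 1]."""

    ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(D)) > 1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.D = D

    @property
    def n(self) -> int:
        return len(self.ids)

    def similarity_pct(self) -> np.ndarray:
        """100 * (1 - D)."""
        return 100.0 * (1.0 - self.D)

    def mean_offdiag_similarity_pct(self) -> float:
        iu = np.triu_indices(self.n, k=1)
        return float(self.similarity_pct()[iu].mean())

    def submatrix(self, idx: np.ndarray) -> "DistanceMatrix":
        return DistanceMatrix(ids=[self.ids[i] for i in idx], D=self.D[np.ix_(idx, idx)])


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # descending, may contain negatives
    percent_variation: np.ndarray  # over positive eigenvalues; sums to 100


@dataclass
class PermanovaResult:
    pseudo_F: float
    df_between: int
    df_within: int
    p: float
    R2: float
    n_permutations: int
    seed: int | None
    ss_between: float = 0.0
    ss_within: float = 0.0
    ss_total: float = 0.0


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    pseudo_t: float
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r2: float
    p: float
    n: int


# -- Bray-Curtis --------------------------------------------------------------


def bray_curtis(table: AbundanceTable, relative: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity among the table's sample rows.

    With ``relative=True`` rows are first standardized to sum to one. A
    pair of all-zero rows gets distance 0 by convention (and a log entry).
    """
    X = table.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ContractError("Bray-Curtis needs at least two samples")
    if np.any(X < 0):
        raise ContractError("abundances must be non-negative")
    if relative and not table.relative:
        totals = X.sum(axis=1, keepdims=True)
        X = X / np.where(totals == 0, 1.0, totals)
    # |x_i - x_j| summed over features, via broadcasting in manageable blocks
    n = X.shape[0]
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    row_sums = X.sum(axis=1)
    for i in range(n):
        num[i] = np.abs(X[i] - X).sum(axis=1)
        den[i] = row_sums[i] + row_sums
    zero_pair = den == 0
    if zero_pair[np.triu_indices(n, 1)].any():
        logger.warning("all-zero sample pair(s) assigned Bray-Curtis distance 0")
    D = np.where(zero_pair, 0.0, num / np.where(zero_pair, 1.0, den))
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(ids=list(table.samples), D=0.5 * (D + D.T))


# -- PCoA ---------------------------------------------------------------------


def pcoa(dist: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Classical metric multidimensional scaling of a distance matrix.

    Gower-centers ``-0.5 * D**2``, eigendecomposes, and scales eigenvectors
    by the square root of their (non-negative) eigenvalues. Negative
    eigenvalues are retained in ``eigenvalues`` but excluded from
    ``percent_variation``. Axis signs are fixed by making the
    largest-magnitude coordinate on each axis positive.
    """
    n = dist.n
    max_axes = n - 1
    if n_axes is None:
        n_axes = max_axes
    elif n_axes > max_axes:
        logger.warning("n_axes=%d clipped to %d (= n_samples - 1)", n_axes, max_axes)
        n_axes = max_axes
    A = -0.5 * dist.D**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = J @ A @ J
    B = 0.5 * (B + B.T)
    eigvals, eigvecs = scipy.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))[None, :]
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    pos = np.clip(eigvals, 0.0, None)
    pct = 100.0 * pos / pos.sum() if pos.sum() > 0 else np.zeros_like(pos)
    coords = coords[:, :n_axes]
    frame = pd.DataFrame(
        coords,
        index=pd.Index(dist.ids, name="sample"),
        columns=[f"PCo{j + 1}" for j in range(coords.shape[1])],
    )
    return PcoaResult(coordinates=frame, eigenvalues=eigvals, percent_variation=pct)


# -- PERMANOVA ----------------------------------------------------------------


def _group_codes(groups) -> tuple[np.ndarray, list[str]]:
    labels = pd.Categorical(list(groups))
    return labels.codes.astype(np.int64), [str(c) for c in labels.categories]


def _ss_within(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    total = 0.0
    for g in range(n_groups):
        mask = codes == g
        total += D2[np.ix_(mask, mask)].sum() / (2.0 * mask.sum())
    return total


def permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    blocks=None,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    ``groups`` assigns each sample a group label (aligned with
    ``dist.ids``). Labels are permuted freely by default; passing
    ``blocks`` (one label per sample) restricts permutations to shuffling
    group labels within each block, for repeated-measures designs where the
    same underlying samples appear once per group.
    """
    codes, names = _group_codes(groups)
    N = dist.n
    if len(codes) != N:
        raise ValueError("groups length does not match distance matrix")
    a = len(names)
    if a < 2:
        raise ContractError("PERMANOVA needs at least two groups")
    sizes = np.bincount(codes, minlength=a)
    if (sizes < 2).any():
        raise ContractError("every group needs at least two samples")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    D2 = dist.D**2
    ss_total = D2.sum() / (2.0 * N)
    ss_within = _ss_within(D2, codes, a)
    if ss_within == 0:
        raise ContractError("within-group sum of squares is zero; pseudo-F undefined")
    ss_between = ss_total - ss_within
    df_b, df_w = a - 1, N - a
    f_obs = (ss_between / df_b) / (ss_within / df_w)

    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, N), dtype=np.int64)
    base = np.arange(N)
    if blocks is None:
        for i in range(n_permutations):
            perms[i] = rng.permutation(base)
    else:
        block_codes, _ = _group_codes(blocks)
        members = [np.flatnonzero(block_codes == b) for b in range(block_codes.max() + 1)]
        for i in range(n_permutations):
            perm = base.copy()
            for m in members:
                perm[m] = m[rng.permutation(len(m))]
            perms[i] = perm
    # permuted label vector: sample j takes the label of sample perms[:, j]
    permuted = codes[perms]
    ssw = np.zeros(n_permutations)
    for g in range(a):
        Z = (permuted == g).astype(float)  # (perms, N)
        ssw += np.einsum("pi,pi->p", Z @ D2, Z) / (2.0 * sizes[g])
    with np.errstate(divide="ignore"):
        f_perm = ((ss_total - ssw) / df_b) / (ssw / df_w)
    exceed = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        df_between=df_b,
        df_within=df_w,
        p=float(p),
        R2=float(ss_between / ss_total),
        n_permutations=n_permutations,
        seed=seed,
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
    )


def permanova_pairwise(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    adjust: str | None = None,
) -> list[PairwiseResult]:
    """Two-group PERMANOVA on every unordered group pair.

    Reports pseudo-t = sqrt(pseudo-F) per pair. P-values are unadjusted by
    default; ``adjust`` may be ``"bonferroni"`` or ``"holm"``.
    """
    codes, names = _group_codes(groups)
    results = []
    raw_p = []
    for ia, ib in combinations(range(len(names)), 2):
        idx = np.flatnonzero((codes == ia) | (codes == ib))
        sub = dist.submatrix(idx)
        res = permanova(sub, codes[idx], n_permutations=n_permutations, seed=seed)
        results.append(
            PairwiseResult(
                group_a=names[ia],
                group_b=names[ib],
                pseudo_t=float(np.sqrt(res.pseudo_F)),
                p=res.p,
            )
        )
        raw_p.append(res.p)
    if adjust is not None:
        if adjust not in ("bonferroni", "holm"):
            raise ValueError(f"unknown adjustment {adjust!r}")
        m = len(raw_p)
        if adjust == "bonferroni":
            adj = [min(1.0, p * m) for p in raw_p]
        else:
            order = np.argsort(raw_p)
            adj = [0.0] * m
            running = 0.0
            for rank, i in enumerate(order):
                running = max(running, min(1.0, (m - rank) * raw_p[i]))
                adj[i] = running
        results = [
            PairwiseResult(r.group_a, r.group_b, r.pseudo_t, p)
            for r, p in zip(results, adj)
        ]
    return results


# -- Pearson ------------------------------------------------------------------


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ContractError("Pearson correlation needs at least three observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ContractError("zero variance in x or y")
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, r2=r * r, p=p, n=n)
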