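"""Alpha diversity, Bray-Curtis ordination, PERMANOVA, and SIMPER.

Alpha indices: species richness, Shannon entropy (nats), Gini-Simpson
(1 - sum p^2), and Pielou's evenness (Shannon / ln richness; undefined for a
single-taxon sample).

Beta diversity uses Bray-Curtis dissimilarity, BC(x, y) =
sum|x_i - y_i| / sum(x_i + y_i), ordinated by classical scaling (PCoA) and
tested by one-way PERMANOVA (Anderson's pseudo-F with label permutations;
the permutation null is enumerated exhaustively whenever the number of
distinct relabelings is at most 10,000, so small designs get exact p-values).
SIMPER decomposes the mean between-group Bray-Curtis dissimilarity into
additive per-species contributions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = [
    "AlphaIndices",
    "PermanovaResult",
    "alpha_diversity",
    "alpha_diversity_table",
    "bray_curtis_matrix",
    "pcoa",
    "permanova",
    "simper",
]

EXHAUSTIVE_LIMIT = 10_000


@dataclass(frozen=True)
class AlphaIndices:
    richness: int
    shannon: float
    simpson: float
    pielou: float  # NaN when richness <= 1


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    exhaustive: bool


def alpha_diversity(counts) -> AlphaIndices:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    p = counts[counts > 0] / total
    richness = int((counts > 0).sum())
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p**2).sum())
    pielou = shannon / np.log(richness) if richness > 1 else np.nan
    return AlphaIndices(richness, shannon, simpson, float(pielou))


def alpha_diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Alpha indices per sample from a taxa x samples count table."""
    rows = {s: vars(alpha_diversity(counts[s])) for s in counts.columns}
    return pd.DataFrame(rows).T


def bray_curtis_matrix(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples (rows) of an abundance table."""
    x = table.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    row_tot = x.sum(axis=1)
    if (row_tot == 0).any():
        bad = list(table.index[row_tot == 0])
        raise ValueError(f"zero-total sample(s): {bad}")
    return DistanceMatrix(squareform(pdist(x, metric="braycurtis")),
                          ids=[str(i) for i in table.index])


def pcoa(dist: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Classical scaling (principal coordinates) of a distance matrix.

    Returns (coordinates, eigenvalues, proportion_explained).  Coordinates use
    the positive eigenvalues only; negative eigenvalues are reported as-is
    (no Lingoes/Cailliez correction) and the explained proportions are taken
    over the positive part of the spectrum.
    """
    d = dist.data
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(eigvals.max(), 0) * 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    prop = np.where(eigvals > 0, eigvals / eigvals[eigvals > 0].sum(), 0.0)
    cols = [f"PCo{i+1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=list(dist.ids), columns=cols), eigvals, prop


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = len(codes)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_between / ss_total


def _multiset_permutations(items: list):
    """All distinct orderings of a multiset (recursive, lexicographic)."""
    counter = Counter(items)
    keys = sorted(counter)
    n = len(items)

    def rec(prefix):
        if len(prefix) == n:
            yield list(prefix)
            return
        for k in keys:
            if counter[k] > 0:
                counter[k] -= 1
                prefix.append(k)
                yield from rec(prefix)
                prefix.pop()
                counter[k] += 1

    yield from rec([])


def _n_multiset_perms(counts: list[int]) -> float:
    from math import comb
    total, n = 1, 0
    for c in counts:
        n += c
        total *= comb(n, c)
    return total


def permanova(
    dist: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    p = (#{permuted F >= observed} + 1) / (n_perm + 1) for sampled
    permutations; when the number of distinct relabelings is <= 10,000 the
    null is enumerated exhaustively and p is exact.
    """
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    n_groups = len(uniq)
    if n_groups < 2:
        raise ValueError("need >= 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("each group needs >= 2 samples")
    d2 = dist.data**2
    f_obs, r2 = _pseudo_f(d2, codes, n_groups)

    total = _n_multiset_perms(list(counts))
    if total <= EXHAUSTIVE_LIMIT:
        hits = 0
        n_done = 0
        for perm in _multiset_permutations(list(codes)):
            f_p, _ = _pseudo_f(d2, np.asarray(perm), n_groups)
            if f_p >= f_obs - 1e-12:
                hits += 1
            n_done += 1
        return PermanovaResult(f_obs, r2, hits / n_done, n_done, True)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_p, _ = _pseudo_f(d2, rng.permutation(codes), n_groups)
        if f_p >= f_obs - 1e-12:
            hits += 1
    return PermanovaResult(f_obs, r2, (hits + 1) / (n_perm + 1), n_perm, False)


def simper(table: pd.DataFrame, labels) -> pd.DataFrame:
    """SIMPER decomposition of mean between-group Bray-Curtis dissimilarity.

    ``table`` is samples x taxa.  Per species k the contribution is the mean
    over between-group sample pairs (i, j) of |x_ik - x_jk| / sum_l(x_il +
    x_jl); contributions sum to the mean between-group Bray-Curtis.  Output is
    sorted by contribution descending (ties by species name) with percent and
    cumulative-percent columns and per-group mean abundances.
    """
    labels = pd.Series(np.asarray(labels), index=table.index)
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError("SIMPER requires exactly 2 groups")
    a = table.loc[labels == groups[0]].to_numpy(float)
    b = table.loc[labels == groups[1]].to_numpy(float)
    contrib = np.zeros(table.shape[1])
    n_pairs = 0
    for i in range(a.shape[0]):
        for j in range(b.shape[0]):
            denom = (a[i] + b[j]).sum()
            if denom == 0:
                raise ValueError("pair of all-zero samples")
            contrib += np.abs(a[i] - b[j]) / denom
            n_pairs += 1
    contrib /= n_pairs
    total = contrib.sum()
    out = pd.DataFrame(
        {
            "contribution": contrib,
            "percent": 100.0 * contrib / total if total > 0 else 0.0,
            f"mean_{groups[0]}": a.mean(axis=0),
            f"mean_{groups[1]}": b.mean(axis=0),
        },
        index=table.columns,
    )
    out = out.loc[
        out.assign(_name=out.index.astype(str))
        .sort_values(["contribution", "_name"], ascending=[False, True])
        .index
    ]
    out["cumulative_percent"] = out["percent"].cumsum()
    out.attrs["mean_between_group_dissimilarity"] = float(total)
    return out
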