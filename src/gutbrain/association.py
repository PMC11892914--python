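"""Mantel matrix correlation, per-species OLS screens, and ROC analysis.

The Mantel statistic is the Pearson correlation between the upper-triangle
entries of two distance matrices over the same samples (species Bray-Curtis
vs. z-scored Euclidean clinical distances in the pipeline); significance
comes from permuting the sample order of one matrix, one-sided (greater),
enumerated exhaustively for n <= 7 samples.

The regression screen fits one simple OLS per (species, clinical variable)
pair and keeps pairs with R^2 strictly > 0.55 and p < 0.05; a
Benjamini-Hochberg column is emitted for reference but not used to filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "MantelResult",
    "RocResult",
    "mantel_test",
    "euclidean_clinical_distance",
    "species_clinical_screen",
    "roc_auc",
]

MANTEL_EXHAUSTIVE_N = 7


@dataclass(frozen=True)
class MantelResult:
    r: float
    r_squared: float
    p_value: float
    n_permutations: int
    exhaustive: bool


@dataclass(frozen=True)
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    cutoff: float | None
    sensitivity_at_cutoff: float | None
    specificity_at_cutoff: float | None


def _upper(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(m.shape[0], 1)]


def mantel_test(
    dist_x: DistanceMatrix,
    dist_y: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test between two distance matrices with matching labels.

    One-sided (greater) permutation p-value; exhaustive over all n!
    relabelings when n <= 7.
    """
    if set(dist_x.ids) != set(dist_y.ids):
        raise ValueError("distance matrices must share sample labels")
    dist_y = dist_y.filter(dist_x.ids)
    x, y = dist_x.data, dist_y.data
    n = x.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs >= 4 samples")
    vx, vy = _upper(x), _upper(y)
    if vx.std() == 0 or vy.std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(vx, vy)[0, 1])

    def r_perm(order):
        return np.corrcoef(vx, _upper(y[np.ix_(order, order)]))[0, 1]

    if n <= MANTEL_EXHAUSTIVE_N:
        hits = total = 0
        for order in _permutations(range(n)):
            if r_perm(list(order)) >= r_obs - 1e-12:
                hits += 1
            total += 1
        return MantelResult(r_obs, r_obs**2, hits / total, total, True)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r_perm(rng.permutation(n)) >= r_obs - 1e-12:
            hits += 1
    return MantelResult(r_obs, r_obs**2, (hits + 1) / (n_perm + 1), n_perm, False)


def euclidean_clinical_distance(clinical: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between subjects on z-scored clinical variables."""
    z = (clinical - clinical.mean()) / clinical.std(ddof=0)
    z = z.dropna(axis=1, how="all").fillna(0.0)
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(squareform(pdist(z.to_numpy(float))),
                          ids=[str(i) for i in clinical.index])


def species_clinical_screen(
    abundances: pd.DataFrame,
    clinical: pd.DataFrame,
    r2_threshold: float = 0.55,
    alpha: float = 0.05,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Simple OLS of each clinical variable on each species abundance.

    abundances: samples x species; clinical: samples x variables (aligned on
    index).  Returns rows with R^2 strictly > r2_threshold and p < alpha
    (all rows when keep_all), with a BH-adjusted p column for reference.
    """
    common = abundances.index.intersection(clinical.index)
    if len(common) < 3:
        raise ValueError("need >= 3 paired observations")
    ab = abundances.loc[common]
    cl = clinical.loc[common]
    rows = []
    for sp in ab.columns:
        x = ab[sp].to_numpy(float)
        if np.std(x) == 0:
            logger.warning("constant predictor %s skipped", sp)
            continue
        for var in cl.columns:
            y = cl[var].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or np.std(y[ok]) == 0:
                continue
            fit = stats.linregress(x[ok], y[ok])
            rows.append(
                {
                    "species": sp,
                    "variable": var,
                    "r_squared": fit.rvalue**2,
                    "slope": fit.slope,
                    "p_value": fit.pvalue,
                }
            )
    out = pd.DataFrame(rows, columns=["species", "variable", "r_squared", "slope", "p_value"])
    if len(out):
        out["p_bh"] = stats.false_discovery_control(out["p_value"], method="bh")
        out["retained"] = (out["r_squared"] > r2_threshold) & (out["p_value"] < alpha)
    else:
        out["p_bh"] = []
        out["retained"] = []
    return out if keep_all else out[out["retained"]].reset_index(drop=True)


def roc_auc(scores, labels, cutoff: float | None = None) -> RocResult:
    """Empirical ROC curve and AUC (Mann-Whitney / trapezoid; ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    y = (labels == classes.max()).astype(int) if labels.dtype.kind in "biu" \
        else (labels == classes[1]).astype(int)
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, thr = roc_curve(y, scores)
    sens = spec = None
    if cutoff is not None:
        pred = scores > cutoff
        pos, neg = y == 1, y == 0
        sens = float(pred[pos].mean()) if pos.any() else None
        spec = float((~pred[neg]).mean()) if neg.any() else None
    return RocResult(auc, fpr, tpr, thr, cutoff, sens, spec)
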