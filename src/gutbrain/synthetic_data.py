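"""Synthetic two-group cohorts with planted, recoverable structure.

The study design emulated here is a case-control dementia cohort: 40 cases
and 40 matched controls with serum hormones (acylated/unacylated ghrelin,
insulin) and cognitive instruments (MMSE, MoCA, GADL, HADS), of which 9 per
group carry 16S-style species count data.  Three planted structures make the
downstream estimators testable:

* a group shift of Cohen's d on log-AG (lognormal hormone model), so
  two-group tests have known null behaviour and known power;
* compositional counts from a logistic-normal/multinomial model -- log-basis
  abundances are multivariate normal with unit variances and a configurable
  basis correlation, closed to proportions and sampled multinomially at a
  fixed depth.  This is exactly the data-generating model SparCC assumes, so
  the planted basis correlations are the recoverable target;
* a two-latent-factor measurement model with opposite-signed structural
  effects on a binary outcome (latent logistic threshold), the generative
  twin of the structural equation model.

All randomness flows through one numpy Generator seeded explicitly; a fixed
seed reproduces cohorts bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .otu_processing import OtuTable

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_compositional_counts",
    "generate_factor_cohort",
]

_PHYLA = ["Firmicutes", "Bacteroidetes", "Actinobacteria",
          "Proteobacteria", "Verrucomicrobia"]

# Baseline clinical distributions (mean, sd, low, high) per group, calibrated
# to the magnitudes of a typical elderly case-control cohort (MMSE/MoCA on
# their 0-30 instrument scales, GADL 0-27, HADS subscales 0-21).
_CLINICAL = {
    "MMSE": ((28.5, 1.2), (19.0, 3.0), 0, 30),
    "MoCA": ((28.0, 1.3), (21.0, 3.5), 0, 30),
    "GADL": ((26.0, 0.6), (13.0, 3.0), 0, 27),
    "HADS_A": ((2.0, 1.2), (9.5, 1.6), 0, 21),
    "HADS_D": ((2.0, 1.1), (9.0, 1.2), 0, 21),
}
_LOG_AG_MEAN, _LOG_AG_SD = np.log(0.58), 0.45
_LOG_UAG_MEAN, _LOG_UAG_SD = np.log(0.021), 0.35


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; defaults are the emulated study design."""

    n_control: int = 40
    n_case: int = 40
    n_microbiome_per_group: int = 9
    age_range: tuple[float, float] = (60, 85)
    ag_effect_size: float = 0.631  # Cohen's d on log-AG
    n_taxa: int = 53
    sequencing_depth: int = 50_000
    basis_correlation: dict = field(default_factory=dict)  # (taxon, taxon) -> r
    differential_taxa: dict = field(default_factory=dict)  # taxon -> log-fold change
    factor_loadings: dict = field(default_factory=dict)    # {"lv1": {...}, "lv2": {...}}
    structural_effects: tuple[float, float] = (1.0, -1.0)
    noise_sd: float | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_control", "n_case", "n_microbiome_per_group", "n_taxa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_microbiome_per_group > min(self.n_control, self.n_case):
            raise ValueError("n_microbiome_per_group exceeds group size")
        for pair, r in self.basis_correlation.items():
            if not abs(r) < 1:
                raise ValueError(f"|correlation| must be < 1 for pair {pair}")


@dataclass
class SyntheticCohort:
    clinical: pd.DataFrame
    otu: OtuTable
    truth: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.clinical.to_csv(outdir / "clinical.csv", index_label="subject")
        self.otu.to_tsv(outdir / "otu_table.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(_jsonable(self.truth), fh, indent=1, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {("|".join(k) if isinstance(k, tuple) else str(k)): _jsonable(v)
                for k, v in obj.items()}
    if isinstance(obj, (np.ndarray, pd.Series)):
        return np.asarray(obj).tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _taxon_names(n: int) -> list[str]:
    return [f"sp{i+1:03d}" for i in range(n)]


def _build_basis_corr(names: list[str], pairs: Mapping) -> pd.DataFrame:
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for (a, b), r in pairs.items():
        if a not in corr.index or b not in corr.index:
            raise ValueError(f"unknown taxon in basis_correlation pair ({a}, {b})")
        corr.loc[a, b] = corr.loc[b, a] = r
    try:
        np.linalg.cholesky(corr.to_numpy())
    except np.linalg.LinAlgError:
        worst = max(pairs.items(), key=lambda kv: abs(kv[1]))[0] if pairs else None
        raise ValueError(
            f"basis correlation matrix not positive-definite (check pair {worst})"
        ) from None
    return corr


def generate_compositional_counts(
    basis_corr,
    mean_logs,
    n_samples: int,
    depth: int,
    seed: int | None = None,
    sample_ids: Sequence[str] | None = None,
) -> OtuTable:
    """Logistic-normal / multinomial count table (taxa x samples).

    Log-basis abundances ~ MVN(mean_logs, R) with unit variances and
    correlation R; per sample the basis is closed to proportions (softmax)
    and counts drawn multinomially at ``depth`` reads.
    """
    if depth <= 0:
        raise ValueError("depth must be >= 1")
    if isinstance(basis_corr, pd.DataFrame):
        names = list(basis_corr.index)
        r = basis_corr.to_numpy(float)
    else:
        r = np.asarray(basis_corr, float)
        names = _taxon_names(r.shape[0])
    d = r.shape[0]
    if d < 4:
        raise ValueError("need >= 4 taxa (downstream basis-variance estimation)")
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("basis_corr must be symmetric")
    try:
        chol = np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        off = np.abs(r - np.eye(d))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            f"basis_corr not positive-definite (check pair ({names[i]}, {names[j]}))"
        ) from None
    mean_logs = np.broadcast_to(np.asarray(mean_logs, float), (d,))
    rng = np.random.default_rng(seed)
    z = mean_logs[None, :] + rng.standard_normal((n_samples, d)) @ chol.T
    # closure: softmax per sample (proportions sum to 1 before the draw)
    z = z - z.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, p[s]) for s in range(n_samples)]).T
    if sample_ids is None:
        sample_ids = [f"s{i+1:03d}" for i in range(n_samples)]
    taxonomy = pd.Series([f"Species {n}" for n in names], index=names)
    phylum = pd.Series([_PHYLA[i % len(_PHYLA)] for i in range(d)], index=names)
    return OtuTable(
        pd.DataFrame(counts, index=names, columns=list(sample_ids)),
        taxonomy, phylum,
    )


def generate_factor_cohort(
    lv1_loadings,
    lv2_loadings,
    structural_effects: tuple[float, float],
    n: int,
    seed: int | None = None,
    noise_sd: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Two-factor cohort: indicators = loading * factor + residual noise.

    Factors are independent standard normals; the binary outcome is 1 when
    b1*lv1 + b2*lv2 + logistic noise > 0.  Residual sd defaults to
    sqrt(1 - loading^2) so indicators have unit variance and the planted
    loadings are directly the standardized loadings.  Returns (table, truth).
    """
    def as_dict(loadings, prefix):
        if isinstance(loadings, Mapping):
            return dict(loadings)
        return {f"{prefix}_x{i+1}": v for i, v in enumerate(loadings)}

    lv1 = as_dict(lv1_loadings, "lv1")
    lv2 = as_dict(lv2_loadings, "lv2")
    if set(lv1) & set(lv2):
        raise ValueError("indicator sets must be disjoint")
    for name, lam in {**lv1, **lv2}.items():
        if abs(lam) > 1.5:
            raise ValueError(f"|loading| must be <= 1.5 ({name})")
    p = len(lv1) + len(lv2)
    n_free = 2 * p + 4  # loadings + residuals + factor corr + 2 structural + outcome resid
    if n <= n_free:
        raise ValueError(f"n={n} too small for {n_free} free parameters")
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal((n, 2))
    cols = {}
    for j, (name, lam) in enumerate([*lv1.items(), *lv2.items()]):
        k = 0 if name in lv1 else 1
        sd = noise_sd if noise_sd is not None else np.sqrt(max(1 - lam**2, 0.01))
        cols[name] = lam * eta[:, k] + sd * rng.standard_normal(n)
    b1, b2 = structural_effects
    lp = b1 * eta[:, 0] + b2 * eta[:, 1] + rng.logistic(size=n)
    table = pd.DataFrame(cols, index=[f"S{i+1:04d}" for i in range(n)])
    table["dementia"] = (lp > 0).astype(int)
    truth = {
        "loadings": {"lv1": lv1, "lv2": lv2},
        "structural_effects": [float(b1), float(b2)],
        "factor_scores": eta,
        "noise_sd": noise_sd,
    }
    return table, truth


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Full synthetic cohort: clinical table, OTU table, and planted truth.

    The group label is exogenous (fixed group sizes); AG carries the
    configured Cohen's-d shift on the log scale, cognitive scores are
    group-shifted and truncated to instrument ranges, and the microbiome
    subset (first n_microbiome_per_group subjects of each group) gets
    compositional counts with group-specific mean log-abundances for the
    differential taxa.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_c, n_d = config.n_control, config.n_case
    n = n_c + n_d
    subjects = [f"S{i+1:04d}" for i in range(n)]
    group = np.array(["control"] * n_c + ["dementia"] * n_d)

    lo, hi = config.age_range
    age = np.round(rng.uniform(lo, hi, n), 1)
    log_ag = _LOG_AG_MEAN + _LOG_AG_SD * rng.standard_normal(n)
    log_ag[group == "dementia"] += config.ag_effect_size * _LOG_AG_SD
    ag = np.exp(log_ag)
    uag = np.exp(_LOG_UAG_MEAN + _LOG_UAG_SD * rng.standard_normal(n))
    insulin = np.clip(rng.normal(9.7, 5.0, n), 0.5, None)
    sex = rng.choice(["male", "female"], size=n, p=[0.66, 0.34])
    ses = rng.integers(1, 4, n)

    clinical = pd.DataFrame(
        {
            "group": group,
            "age": age,
            "sex": sex,
            "SES": ses,
            "AG": ag,
            "UAG": uag,
            "insulin": insulin,
        },
        index=pd.Index(subjects, name="subject"),
    )
    for var, (ctrl, case, low, high) in _CLINICAL.items():
        vals = np.where(
            group == "control",
            rng.normal(*ctrl, n),
            rng.normal(*case, n),
        )
        clinical[var] = np.clip(np.round(vals, 1), low, high)
    clinical["ag_uag_ratio"] = clinical["AG"] / clinical["UAG"]
    clinical["AAGR"] = 6 + np.log10(clinical["ag_uag_ratio"]) - clinical["age"] / 10

    names = _taxon_names(config.n_taxa)
    corr = _build_basis_corr(names, config.basis_correlation)
    base_logs = pd.Series(rng.normal(0.0, 1.5, config.n_taxa), index=names)
    mean_logs = {"control": base_logs.copy(), "dementia": base_logs.copy()}
    for taxon, lfc in config.differential_taxa.items():
        if taxon not in base_logs.index:
            raise ValueError(f"unknown differential taxon {taxon}")
        mean_logs["control"][taxon] -= lfc / 2
        mean_logs["dementia"][taxon] += lfc / 2
    m = config.n_microbiome_per_group
    micro_subjects = {
        "control": subjects[:m],
        "dementia": subjects[n_c:n_c + m],
    }
    tables = []
    for g in ("control", "dementia"):
        tables.append(
            generate_compositional_counts(
                corr,
                mean_logs[g].to_numpy(),
                m,
                config.sequencing_depth,
                seed=int(rng.integers(2**31)),
                sample_ids=micro_subjects[g],
            )
        )
    counts = pd.concat([t.counts for t in tables], axis=1)
    sample_group = pd.Series(
        {s: g for g in micro_subjects for s in micro_subjects[g]}
    )
    otu = OtuTable(counts, tables[0].taxonomy, tables[0].phylum, sample_group)

    factor_truth = None
    if config.factor_loadings:
        _, factor_truth = generate_factor_cohort(
            config.factor_loadings.get("lv1", {}),
            config.factor_loadings.get("lv2", {}),
            config.structural_effects,
            n,
            seed=int(rng.integers(2**31)),
            noise_sd=config.noise_sd,
        )
    truth = {
        "config": {k: v for k, v in asdict(config).items()
                   if k not in ("basis_correlation", "differential_taxa",
                                "factor_loadings")},
        "basis_correlation": dict(config.basis_correlation),
        "differential_taxa": dict(config.differential_taxa),
        "mean_logs": {g: v.to_dict() for g, v in mean_logs.items()},
        "log_ag_shift": config.ag_effect_size * _LOG_AG_SD,
        "factor_model": factor_truth,
    }
    return SyntheticCohort(clinical=clinical, otu=otu, truth=truth)
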