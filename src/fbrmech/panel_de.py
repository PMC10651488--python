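"""Two-group differential expression on a biomarker count panel.

The model is the negative binomial with variance mu + phi * mu^2.  Library
sizes are normalised by trimmed-mean-of-log-ratios (TMM-style) factors
against a geometric-mean pseudo-reference; per-gene dispersions are
method-of-moments estimates shrunk toward the pooled common dispersion; the
two-group test is a likelihood-ratio test of equal NB means (shared
dispersion, size factors as offsets) referred to an F(1, df) distribution
whose denominator df combines the residual df with the prior df implied by
the dispersion shrinkage (quasi-likelihood-style small-sample reference:
the chi-square(1) asymptote is anticonservative in the deep tail at
n = 10 per group, which breaks BH's FDR guarantee).
Multiplicity is handled by Benjamini-Hochberg step-up q-values, and ordered
top-k signatures (e.g. the top-25 or top-100 genes up in the severe
capsular-contracture grade) are built from the ranked table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: default weight of the common dispersion in the shrinkage estimator; also
#: sets the prior df of the F reference: df_prior = w / (1 - w) * df_residual
DEFAULT_SHRINK_WEIGHT = 0.7

__all__ = [
    "CountMatrix",
    "DEResult",
    "Signature",
    "normalize_library_sizes",
    "estimate_dispersion",
    "nb_two_group_test",
    "bh_adjust",
    "rank_and_signature",
]


@dataclass
class CountMatrix:
    """Genes x samples nonnegative integer counts with a two-level grouping."""

    counts: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(counts.values, np.round(counts.values)):
            raise ValueError("counts must be integers")
        self.group = pd.Series(self.group).reindex(counts.columns)
        if self.group.isna().any():
            raise ValueError("every sample needs a group label")
        levels = self.levels
        if len(levels) != 2:
            raise ValueError(f"exactly two group levels required, got {levels}")
        for lv in levels:
            if (self.group == lv).sum() == 0:
                raise ValueError(f"group {lv!r} is empty")

    @property
    def levels(self) -> list:
        return sorted(pd.unique(self.group))

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class DEResult:
    """Per-gene test results; ``table`` columns: log2_fold_change, p_value,
    q_value, mean_expression, dispersion.  group2-vs-group1 convention with
    groups in sorted label order."""

    table: pd.DataFrame
    group1: object
    group2: object

    def __getitem__(self, col):
        return self.table[col]


@dataclass
class Signature:
    """Ordered top-k gene list with its direction of regulation."""

    gene_ids: list
    direction: str  # "up_in_group2" | "up_in_group1"
    k: int

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("signature contains duplicate genes")
        if self.direction not in ("up_in_group2", "up_in_group1"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.gene_ids)


def normalize_library_sizes(
    cm: CountMatrix, log_ratio_trim: float = 0.3, abundance_trim: float = 0.05
) -> np.ndarray:
    """TMM-style per-sample size factors (geometric mean 1).

    Log ratios are taken against the per-gene geometric-mean pseudo-
    reference over genes expressed everywhere; the most extreme
    ``log_ratio_trim`` fraction of ratios and ``abundance_trim`` fraction
    of abundances are trimmed symmetrically before averaging.  The factor
    absorbs the raw library size, so it is the model's effective library
    scale (a sample with all counts doubled gets ~2x the factor of its
    peers).
    """
    y = cm.counts.values.astype(float)
    lib = y.sum(axis=0)
    if np.any(lib <= 0):
        bad = cm.sample_ids[lib <= 0].tolist()
        raise ValueError(f"samples with zero total count: {bad}")

    expressed = (y > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene expressed in all samples; cannot build reference")
    z = y[expressed] / lib
    ref = np.exp(np.mean(np.log(z), axis=1))

    factors = np.empty(y.shape[1])
    for j in range(y.shape[1]):
        m = np.log2(z[:, j] / ref)
        a = 0.5 * np.log2(z[:, j] * ref)
        keep = np.ones(m.size, dtype=bool)
        for v, trim in ((m, log_ratio_trim), (a, abundance_trim)):
            lo, hi = np.quantile(v, [trim / 2, 1 - trim / 2])
            keep &= (v >= lo) & (v <= hi)
        tmm = float(np.mean(m[keep])) if keep.any() else 0.0
        factors[j] = lib[j] * 2.0**tmm
    return factors / np.exp(np.mean(np.log(factors)))


def _groupwise_moments(z: np.ndarray, masks) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled within-group variance and overall mean of normalised counts."""
    num = np.zeros(z.shape[0])
    den = 0
    for mask in masks:
        n = int(mask.sum())
        if n >= 2:
            num += z[:, mask].var(axis=1, ddof=1) * (n - 1)
            den += n - 1
    return num / max(den, 1), z.mean(axis=1), den


def estimate_dispersion(
    cm: CountMatrix,
    factors: np.ndarray,
    shrink: bool = True,
    shrink_weight: float = DEFAULT_SHRINK_WEIGHT,
) -> np.ndarray:
    """Per-gene NB dispersion phi (variance = mu + phi mu^2), floored at 0.

    Method of moments on size-factor-normalised counts with the group
    structure removed (pooled within-group variance), optionally shrunk
    toward the common dispersion: phi <- w * phi_common + (1 - w) * phi_g.
    Degenerate genes (zero mean) receive the common value.
    """
    y = cm.counts.values.astype(float)
    z = y / factors[None, :]
    masks = [(cm.group == lv).values for lv in cm.levels]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("each group needs >= 2 samples to estimate dispersion")

    var, mean, _ = _groupwise_moments(z, masks)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = (var - mean) / mean**2
    phi_raw = np.where(mean > 0, np.maximum(phi_raw, 0.0), np.nan)

    informative = np.isfinite(phi_raw) & (mean > 1.0)
    phi_common = float(np.median(phi_raw[informative])) if informative.any() else 0.0
    phi = np.where(np.isfinite(phi_raw), phi_raw, phi_common)
    if shrink:
        phi = shrink_weight * phi_common + (1.0 - shrink_weight) * phi
    return np.maximum(phi, 0.0)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB log-likelihood per gene up to y-only terms (cancel in the LRT)."""
    phi = phi[:, None]
    out = np.zeros_like(mu)
    pos = mu > 0
    logmu = np.where(pos, np.log(np.where(pos, mu, 1.0)), 0.0)
    small = np.broadcast_to(phi < 1e-10, mu.shape)
    poisson = y * logmu - mu
    with np.errstate(invalid="ignore"):
        nb = y * logmu - (y + 1.0 / np.where(phi < 1e-10, 1.0, phi)) * np.log1p(
            phi * mu
        )
    out = np.where(small, poisson, nb)
    out = np.where(pos | (y == 0), out, -np.inf)
    return out.sum(axis=1)


def _fit_nb_mean(y: np.ndarray, s: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """MLE of the common mean m (mu_j = s_j m) per gene, Newton in log m."""
    tot = y.sum(axis=1)
    S = s.sum()
    m0 = tot / S  # Poisson MLE; exact when phi = 0
    zero = tot == 0
    active = ~zero & (phi >= 1e-10)
    m = m0.copy()
    if active.any():
        eta = np.log(m0[active])
        ya = y[active]
        pha = phi[active][:, None]
        for _ in range(50):
            mu = s[None, :] * np.exp(eta)[:, None]
            w = pha * mu / (1.0 + pha * mu)
            score = (ya - (ya + 1.0 / pha) * w).sum(axis=1)
            hess = -((ya + 1.0 / pha) * w * (1.0 - w)).sum(axis=1)
            step = np.clip(score / np.where(hess == 0, -1.0, hess), -2.0, 2.0)
            eta = eta - step
            if np.max(np.abs(step)) < 1e-12:
                break
        m[active] = np.exp(eta)
    m[zero] = 0.0
    return m


def nb_two_group_test(
    cm: CountMatrix,
    factors: np.ndarray,
    dispersion: np.ndarray,
    shrink_weight: float = DEFAULT_SHRINK_WEIGHT,
) -> DEResult:
    """NB likelihood-ratio test of equal means between the two groups.

    Null: one mean per gene across all samples; alternative: one mean per
    group; shared per-gene dispersion and log size-factor offsets.  The
    statistic is referred to F(1, df) with denominator df = residual df /
    (1 - shrink_weight), i.e. residual plus the prior df implied by the
    dispersion shrinkage; pass ``shrink_weight=1`` for the chi-square(1)
    asymptote.  log2 fold changes come from the fitted group means with a
    half-count pseudo-fraction at average depth added to both, so boundary
    genes stay finite.  All-zero genes get p = 1 and logFC = 0.
    """
    y = cm.counts.values.astype(float)
    s = np.asarray(factors, dtype=float)
    phi = np.asarray(dispersion, dtype=float)
    g1, g2 = cm.levels
    m1mask = (cm.group == g1).values
    m2mask = (cm.group == g2).values
    if m1mask.sum() < 2 or m2mask.sum() < 2:
        raise ValueError("each group needs >= 2 samples")

    m_null = _fit_nb_mean(y, s, phi)
    m_1 = _fit_nb_mean(y[:, m1mask], s[m1mask], phi)
    m_2 = _fit_nb_mean(y[:, m2mask], s[m2mask], phi)

    ll_null = _nb_loglik(y, s[None, :] * m_null[:, None], phi)
    ll_alt = _nb_loglik(
        y[:, m1mask], s[m1mask][None, :] * m_1[:, None], phi
    ) + _nb_loglik(y[:, m2mask], s[m2mask][None, :] * m_2[:, None], phi)

    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    df_resid = int(m1mask.sum() + m2mask.sum()) - 2
    if 0.0 <= shrink_weight < 1.0:
        df_denom = df_resid / (1.0 - shrink_weight)
        p = stats.f.sf(lrt, 1, df_denom)
    else:  # asymptotic reference
        p = stats.chi2.sf(lrt, df=1)

    pseudo = 0.5 / s.mean()
    log2fc = np.log2((m_2 + pseudo) / (m_1 + pseudo))

    allzero = y.sum(axis=1) == 0
    p[allzero] = 1.0
    log2fc[allzero] = 0.0

    table = pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "p_value": p,
            "q_value": bh_adjust(p),
            "mean_expression": m_null,
            "dispersion": phi,
        },
        index=cm.gene_ids,
    )
    return DEResult(table=table, group1=g1, group2=g2)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def rank_and_signature(
    de: DEResult, k: int, direction: str = "up_in_group2", alpha: float = 0.05
) -> Signature:
    """Top-k signature: direction-matched genes with p < alpha, ranked by
    ascending p, ties broken by descending \\|logFC\\| then gene id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    t = de.table
    if direction == "up_in_group2":
        eligible = t[(t["log2_fold_change"] > 0) & (t["p_value"] < alpha)]
    elif direction == "up_in_group1":
        eligible = t[(t["log2_fold_change"] < 0) & (t["p_value"] < alpha)]
    else:
        raise ValueError(f"unknown direction {direction!r}")

    if eligible.empty:
        warnings.warn(f"no eligible genes for {direction}; empty signature")
        return Signature(gene_ids=[], direction=direction, k=k)

    ranked = eligible.assign(_abs=eligible["log2_fold_change"].abs(), _id=eligible.index)
    ranked = ranked.sort_values(
        ["p_value", "_abs", "_id"], ascending=[True, False, True], kind="mergesort"
    )
    return Signature(
        gene_ids=ranked.index[:k].tolist(), direction=direction, k=k
    )
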