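"""Negative-binomial differential expression for a 2x2 genotype/treatment design.

The experiment compares wild-type cells with a redox-insensitive mutant
(genotype ``WT`` vs ``C3S``) under ``basal`` and ``oxidation`` treatments,
with a small number of biological replicates per condition.  Differential
expression for each of the four canonical pairwise comparisons is assessed
with a conditional negative-binomial exact test on size-factor-normalised
counts, followed by Benjamini-Hochberg correction, and genes are called
significant when ``q < 0.05`` and ``|log2FC| > 1`` (both strict).

Statistical model
-----------------
Counts for gene *g* in condition *c* are NB with mean ``mu`` and dispersion
``alpha`` such that ``var = mu + alpha * mu**2``.  Writing ``r = 1/alpha``
for the NB size, the sum of ``n`` i.i.d. NB(mu, r) replicates is
NB(n*mu, n*r).  Under the null hypothesis of equal means, the group-A
subtotal conditioned on the two-group total ``t`` follows a negative
hypergeometric (two-category Dirichlet-multinomial) law::

    P(S_a = s | t) = C(s + r_a - 1, s) * C(t - s + r_b - 1, t - s)
                     / C(t + r_a + r_b - 1, t)

with ``r_a = n_a / alpha`` and ``r_b = n_b / alpha``.  The two-sided exact
p-value sums the probabilities of all splits no more probable than the
observed one.  As ``alpha -> 0`` this conditional law converges to
Binomial(t, n_a / (n_a + n_b)); the implementation switches to that exact
limit when the dispersion falls at or below the floor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

logger = logging.getLogger("oxpattern")

#: relative tolerance when comparing outcome probabilities to the observed
#: one while summing the two-sided tail (guards against float ties).
_TIE_RTOL = 1e-7

GENOTYPES = ("WT", "C3S")
TREATMENTS = ("basal", "oxidation")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene-by-sample integer counts plus the per-sample design labels.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample, non-negative
        integers.
    samples
        DataFrame indexed by sample name with columns ``genotype``,
        ``treatment`` and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if not set(self.counts.columns) <= set(self.samples.index):
            missing = set(self.counts.columns) - set(self.samples.index)
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("counts must be finite and >= 0")
        for col in ("genotype", "treatment", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        # every condition cell needs at least one replicate
        cells = self.samples.groupby(["genotype", "treatment"]).size()
        if (cells < 1).any():  # pragma: no cover - groupby omits empty cells
            raise ValueError("every (genotype, treatment) cell needs >= 1 replicate")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def condition_columns(self, genotype: str, treatment: str) -> list[str]:
        """Sample names belonging to one (genotype, treatment) cell."""
        mask = (self.samples["genotype"] == genotype) & (
            self.samples["treatment"] == treatment
        )
        cols = [s for s in self.counts.columns if mask.get(s, False)]
        if not cols:
            raise ValueError(f"no samples for condition ({genotype}, {treatment})")
        return cols

    def conditions(self) -> list[tuple[str, str]]:
        """Observed (genotype, treatment) cells, in design order."""
        seen: list[tuple[str, str]] = []
        for s in self.counts.columns:
            key = (self.samples.loc[s, "genotype"], self.samples.loc[s, "treatment"])
            if key not in seen:
                seen.append(key)
        return seen


@dataclass(frozen=True)
class ComparisonSpec:
    """One pairwise comparison; log fold changes are ``log2(B / A)``."""

    name: str
    group_a: tuple[str, str]
    group_b: tuple[str, str]
    position: int

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("group_a and group_b must differ")
        if self.position not in (1, 2, 3, 4):
            raise ValueError("position must be 1..4")


#: The four canonical comparisons of the 2x2 design, in pattern-code order:
#: position 1 = oxidation vs basal in WT, 2 = C3S vs WT at basal,
#: 3 = oxidation vs basal in C3S, 4 = C3S vs WT after oxidation.
CANONICAL_COMPARISONS: tuple[ComparisonSpec, ...] = (
    ComparisonSpec("WT_oxidation_vs_basal", ("WT", "basal"), ("WT", "oxidation"), 1),
    ComparisonSpec("C3S_vs_WT_basal", ("WT", "basal"), ("C3S", "basal"), 2),
    ComparisonSpec("C3S_oxidation_vs_basal", ("C3S", "basal"), ("C3S", "oxidation"), 3),
    ComparisonSpec("C3S_vs_WT_oxidation", ("WT", "oxidation"), ("C3S", "oxidation"), 4),
)


# ---------------------------------------------------------------------------
# filtering and normalisation
# ---------------------------------------------------------------------------

def filter_expressed(cm: CountMatrix, threshold: float = 10.0) -> CountMatrix:
    """Keep genes whose replicate-averaged count reaches *threshold* somewhere.

    A gene is expressed when the maximum over conditions of its mean count
    across that condition's replicates is ``>= threshold``.  Gene order is
    preserved; the operation is idempotent.
    """
    cond_means = pd.DataFrame(
        {
            f"{g}:{t}": cm.counts[cm.condition_columns(g, t)].mean(axis=1)
            for g, t in cm.conditions()
        }
    )
    keep = cond_means.max(axis=1) >= threshold
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return CountMatrix(cm.counts.loc[keep], cm.samples)


def estimate_size_factors(cm: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors (DESeq-style).

    For each sample *s*, ``factor_s = median_g(count_gs / geomean_g)`` where
    the geometric mean runs across samples and genes with a zero count in
    any sample are excluded from the reference.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ref = mat[all_pos]
    geomean = np.exp(np.log(ref).mean(axis=1))
    factors = np.median(ref / geomean[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def _neg_hypergeom_logpmf(s: np.ndarray, t: int, r_a: float, r_b: float) -> np.ndarray:
    """log P(S_a = s | total = t) for the NB conditional split distribution."""
    s = np.asarray(s, dtype=float)
    return (
        gammaln(s + r_a)
        - gammaln(s + 1.0)
        - gammaln(r_a)
        + gammaln(t - s + r_b)
        - gammaln(t - s + 1.0)
        - gammaln(r_b)
        - (gammaln(t + r_a + r_b) - gammaln(t + 1.0) - gammaln(r_a + r_b))
    )


def nb_conditional_logpmf(
    t: int, n_a: int, n_b: int, dispersion: float, dispersion_floor: float = 1e-8
) -> np.ndarray:
    """Log-probabilities of every split ``s = 0..t`` of the total *t*.

    ``dispersion <= dispersion_floor`` uses the exact Poisson-limit
    conditional, Binomial(t, n_a / (n_a + n_b)).
    """
    s = np.arange(t + 1)
    if dispersion <= dispersion_floor:
        return binom.logpmf(s, t, n_a / (n_a + n_b))
    r_a = n_a / dispersion
    r_b = n_b / dispersion
    return _neg_hypergeom_logpmf(s, t, r_a, r_b)


def nb_conditional_pvalue(
    sum_a: int,
    n_a: int,
    sum_b: int,
    n_b: int,
    dispersion: float,
    dispersion_floor: float = 1e-8,
) -> float:
    """Two-sided conditional exact NB p-value for one gene.

    Conditions on ``t = sum_a + sum_b`` and sums the probability of every
    split whose probability does not exceed the observed split's (with a
    small relative tie tolerance).
    """
    t = int(sum_a) + int(sum_b)
    if t == 0:
        return 1.0
    logp = nb_conditional_logpmf(t, n_a, n_b, dispersion, dispersion_floor)
    log_obs = logp[int(sum_a)]
    take = logp <= log_obs + np.log1p(_TIE_RTOL)
    return float(min(1.0, np.exp(logsumexp(logp[take]))))


def _raw_mom_dispersion(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Unfloored method-of-moments dispersion pooled across the two groups.

    Per group: ``alpha = (var - mean) / mean**2`` (sample variance, ddof 1),
    pooled with degrees-of-freedom weights.  Returns ``(estimate, df)``;
    the estimate may be negative (variance below the Poisson line) and is
    NaN when no group has two replicates and a positive mean.
    """
    num = 0.0
    den = 0.0
    for grp in (a, b):
        n = len(grp)
        m = grp.mean()
        if n < 2 or m <= 0:
            continue
        v = grp.var(ddof=1)
        num += (n - 1) * (v - m) / (m * m)
        den += n - 1
    if den == 0:
        return float("nan"), 0.0
    return num / den, den


def _pooled_mom_dispersion(a: np.ndarray, b: np.ndarray, floor: float) -> float:
    """Per-gene pooled method-of-moments dispersion, floored."""
    est, df = _raw_mom_dispersion(a, b)
    if df == 0 or not np.isfinite(est):
        return floor
    return max(floor, est)


def moderated_dispersions(
    a: np.ndarray,
    b: np.ndarray,
    prior_df: float = 10.0,
    floor: float = 1e-8,
) -> np.ndarray:
    """Per-gene dispersions shrunk toward the common (all-gene) estimate.

    With two replicates per group a per-gene moment estimate has ~2 degrees
    of freedom and is so noisy that roughly half the genes collapse onto
    the Poisson floor, which badly inflates the null rejection rate.  The
    per-gene estimate (``_raw_mom_dispersion``) is therefore combined with
    the degrees-of-freedom-weighted mean across all genes::

        alpha_g = (df_g * raw_g + prior_df * common) / (df_g + prior_df)

    floored afterwards.  ``prior_df=10`` restores null calibration at two
    replicates while leaving room for gene-specific departures when
    replication is deeper; ``prior_df=0`` recovers the unshrunken
    estimator.
    """
    n = a.shape[0]
    raw = np.empty(n)
    dfs = np.empty(n)
    for i in range(n):
        raw[i], dfs[i] = _raw_mom_dispersion(a[i], b[i])
    ok = np.isfinite(raw)
    if not ok.any() or prior_df == 0:
        return np.maximum(np.where(ok, raw, floor), floor)
    common = float(np.sum(raw[ok] * dfs[ok]) / np.sum(dfs[ok]))
    shrunk = np.where(
        ok, (dfs * np.where(ok, raw, 0.0) + prior_df * common) / (dfs + prior_df),
        common,
    )
    return np.maximum(shrunk, floor)


def nb_exact_test(
    cm: CountMatrix,
    spec: ComparisonSpec,
    size_factors: pd.Series | None = None,
    dispersion_floor: float = 1e-8,
    pseudocount: float = 0.5,
    dispersion_prior_df: float = 10.0,
) -> pd.DataFrame:
    """Per-gene conditional NB exact test for one pairwise comparison.

    Counts are divided by median-of-ratios size factors and rounded to the
    nearest integer (ties to even) before the exact test, which requires
    integer totals.  ``logfc = log2((mean_b + c) / (mean_a + c))`` with
    pseudocount ``c`` on the *unrounded* normalised means.  Dispersions
    come from :func:`moderated_dispersions` (per-gene method of moments
    shrunk toward the common value; ``dispersion_prior_df=0`` disables the
    shrinkage).

    Returns a DataFrame with columns ``gene_id, mean_a, mean_b, logfc, p``;
    ``q``/``significant`` are added by :func:`call_de` after BH correction.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(cm)
    cols_a = cm.condition_columns(*spec.group_a)
    cols_b = cm.condition_columns(*spec.group_b)
    norm = cm.counts.div(size_factors, axis=1)
    a = norm[cols_a].to_numpy(dtype=float)
    b = norm[cols_b].to_numpy(dtype=float)
    a_int = np.rint(a).astype(np.int64)
    b_int = np.rint(b).astype(np.int64)

    n_a, n_b = a.shape[1], b.shape[1]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    logfc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    alphas = moderated_dispersions(a, b, dispersion_prior_df, dispersion_floor)
    pvals = np.ones(len(cm.gene_ids))
    for i in range(len(pvals)):
        pvals[i] = nb_conditional_pvalue(
            a_int[i].sum(), n_a, b_int[i].sum(), n_b, alphas[i], dispersion_floor
        )

    return pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "logfc": logfc,
            "p": pvals,
        }
    ).set_index("gene_id", drop=False)


# ---------------------------------------------------------------------------
# multiple testing and calling
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_de(
    results: pd.DataFrame,
    q_threshold: float = 0.05,
    logfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Attach BH-adjusted q-values and strict significance flags.

    ``significant`` iff ``q < q_threshold`` AND ``|logfc| > logfc_threshold``
    (both inequalities strict, matching the published thresholds).
    """
    out = results.copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["q"] < q_threshold) & (
        np.abs(out["logfc"]) > logfc_threshold
    )
    return out


def run_comparisons(
    cm: CountMatrix,
    specs: Sequence[ComparisonSpec] = CANONICAL_COMPARISONS,
    q_threshold: float = 0.05,
    logfc_threshold: float = 1.0,
    dispersion_floor: float = 1e-8,
) -> dict[int, pd.DataFrame]:
    """Run every comparison end to end; returns ``position -> called table``."""
    sf = estimate_size_factors(cm)
    tables: dict[int, pd.DataFrame] = {}
    for spec in specs:
        res = nb_exact_test(cm, spec, size_factors=sf, dispersion_floor=dispersion_floor)
        tables[spec.position] = call_de(res, q_threshold, logfc_threshold)
        n_sig = int(tables[spec.position]["significant"].sum())
        logger.info("comparison %s: %d/%d significant", spec.name, n_sig, len(res))
    return tables
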