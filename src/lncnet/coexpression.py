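"""Co-expression analysis: normalization, correlation, edge calling and the
permutation validation of the correlation cutoff.

The screen computes the Pearson correlation of each lncRNA's expression vector
with each mRNA's across all libraries, and calls a co-expressed pair whenever
|r| >= 0.95 and the (raw, two-sided) correlation p-value is < 0.05.  P-values
use the t transform t = r*sqrt(n-2)/sqrt(1-r^2) with n-2 degrees of freedom,
which is exact under a bivariate-normal null.

The cutoff is validated by an individualized permutation test: repeatedly
sample a panel of lncRNAs, permute each sampled lncRNA's library vector
independently (the mRNAs stay fixed), recompute every correlation, pool the
|r| values across repetitions and report the proportion at or above the
cutoff.  Correlations are undefined for constant vectors; such vectors are
excluded from both the edge scan and the permutation pool, and counted, so no
NaN ever propagates silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, ConstantVectorError
from .records import CountMatrix


# ---------------------------------------------------------------------------
# normalization (median-of-ratios convention)
# ---------------------------------------------------------------------------

def normalize_counts(counts: CountMatrix | pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    The reference is the per-transcript geometric mean across libraries,
    computed over transcripts positive in every library; each library's size
    factor is the median ratio of its counts to the reference, and normalized
    counts are raw counts divided by the factor.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] < 2:
        raise ValueError("normalization needs at least two libraries")
    values = df.to_numpy(dtype=float)
    all_positive = np.all(values > 0, axis=1)
    if not np.any(all_positive):
        raise ValueError(
            "no transcript has positive counts in every library; "
            "filter all-zero transcripts before normalizing"
        )
    log_ref = np.mean(np.log(values[all_positive]), axis=1)
    log_ratios = np.log(values[all_positive]) - log_ref[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    size_factors = pd.Series(factors, index=df.columns, name="size_factor")
    normalized = df / factors
    return size_factors, normalized


def log_expression(normalized: pd.DataFrame) -> pd.DataFrame:
    """log1p of normalized counts, the default correlation scale."""
    return np.log1p(normalized)


# ---------------------------------------------------------------------------
# correlation statistics
# ---------------------------------------------------------------------------

def pearson(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Raises :class:`ConstantVectorError` when either vector is constant (the
    correlation is undefined; callers exclude the pair and log it).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("pearson needs n >= 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt(np.sum(xd * xd) * np.sum(yd * yd))
    if denom == 0.0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    return float(np.clip(np.sum(xd * yd) / denom, -1.0, 1.0))


def pcc_pvalue(pcc: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation under the t approximation.

    p = 2 * P(T_{n-2} >= |r| sqrt(n-2) / sqrt(1-r^2)); |r| = 1 gives p = 0.
    """
    if n < 3:
        raise ValueError("pcc_pvalue needs n >= 3")
    r = float(pcc)
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(t, df=n - 2))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


# ---------------------------------------------------------------------------
# edge calling
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionConfig:
    """Edge-calling thresholds: |r| >= pcc_threshold (inclusive) and raw
    p < pvalue_max, with at least ``min_libraries`` observations."""

    pcc_threshold: float = 0.95
    pvalue_max: float = 0.05
    min_libraries: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.pcc_threshold <= 1:
            raise ConfigError("pcc_threshold must be in (0, 1]")
        if not 0 < self.pvalue_max <= 1:
            raise ConfigError("pvalue_max must be in (0, 1]")
        if self.min_libraries < 3:
            raise ConfigError("min_libraries must be >= 3")


@dataclass(frozen=True)
class CoexpressionEdge:
    """A called lncRNA-mRNA co-expression pair."""

    lncrna_id: str
    mrna_id: str
    pcc: float
    pvalue: float


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows centered and scaled to unit sum of squares; flags constant rows."""
    centered = values - values.mean(axis=1, keepdims=True)
    ss = np.sqrt(np.sum(centered**2, axis=1))
    constant = ss == 0.0
    ss_safe = np.where(constant, 1.0, ss)
    return centered / ss_safe[:, None], constant


def correlation_matrix(
    lncrna_expr: pd.DataFrame, mrna_expr: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """All lncRNA x mRNA Pearson correlations (vectorized).

    Returns (r matrix, constant-lncRNA mask, constant-mRNA mask); rows/columns
    for constant vectors are NaN.
    """
    if list(lncrna_expr.columns) != list(mrna_expr.columns):
        raise ValueError("lncRNA and mRNA matrices must share the same library order")
    zl, const_l = _standardize_rows(lncrna_expr.to_numpy(dtype=float))
    zm, const_m = _standardize_rows(mrna_expr.to_numpy(dtype=float))
    r = np.clip(zl @ zm.T, -1.0, 1.0)
    r[const_l, :] = np.nan
    r[:, const_m] = np.nan
    return (
        pd.DataFrame(r, index=lncrna_expr.index, columns=mrna_expr.index),
        const_l,
        const_m,
    )


def call_edges(
    lncrna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    config: CoexpressionConfig | None = None,
) -> tuple[list[CoexpressionEdge], dict]:
    """Call co-expressed lncRNA-mRNA pairs at the configured thresholds.

    Returns the edge list and a QC report counting pairs skipped because a
    correlation was undefined (constant vector).
    """
    config = config or CoexpressionConfig()
    n = lncrna_expr.shape[1]
    if n < config.min_libraries:
        raise ValueError(f"need >= {config.min_libraries} libraries, got {n}")
    rmat, const_l, const_m = correlation_matrix(lncrna_expr, mrna_expr)
    r = rmat.to_numpy()
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(t, df=df)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    called = (np.abs(r) >= config.pcc_threshold) & (p < config.pvalue_max)
    called &= ~np.isnan(r)
    edges = [
        CoexpressionEdge(str(rmat.index[i]), str(rmat.columns[j]), float(r[i, j]), float(p[i, j]))
        for i, j in zip(*np.nonzero(called))
    ]
    qc = {
        "n_lncrnas": int(lncrna_expr.shape[0]),
        "n_mrnas": int(mrna_expr.shape[0]),
        "n_constant_lncrnas": int(const_l.sum()),
        "n_constant_mrnas": int(const_m.sum()),
        "n_pairs_skipped_undefined": int(
            const_l.sum() * mrna_expr.shape[0]
            + (lncrna_expr.shape[0] - const_l.sum()) * const_m.sum()
        ),
        "n_pairs_tested": int((~np.isnan(r)).sum()),
        "n_edges": len(edges),
    }
    return edges, qc


def edges_to_frame(edges: list[CoexpressionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lncrna_id": [e.lncrna_id for e in edges],
            "mrna_id": [e.mrna_id for e in edges],
            "pcc": [e.pcc for e in edges],
            "pvalue": [e.pvalue for e in edges],
        },
        columns=["lncrna_id", "mrna_id", "pcc", "pvalue"],
    )


# ---------------------------------------------------------------------------
# permutation validation of the cutoff
# ---------------------------------------------------------------------------

@dataclass
class PermutationConfig:
    """Design of the individualized permutation test.

    Per repetition, ``n_lncrnas_sampled`` lncRNAs are drawn without
    replacement and each sampled lncRNA's library vector is permuted
    independently (``shared_permutation`` applies one permutation to the whole
    panel instead); correlations against every mRNA are pooled across
    ``n_repetitions`` repetitions.
    """

    n_lncrnas_sampled: int = 100
    n_repetitions: int = 1000
    threshold: float = 0.95
    seed: int = 0
    shared_permutation: bool = False

    def __post_init__(self) -> None:
        if self.n_lncrnas_sampled < 1 or self.n_repetitions < 1:
            raise ConfigError("sample size and repetitions must be positive")
        if not 0 <= self.threshold <= 1:
            raise ConfigError("threshold must be in [0, 1]")


@dataclass
class PermutationSummary:
    """Pooled null-correlation summary of one permutation run."""

    n_lncrnas_sampled: int
    n_repetitions: int
    threshold: float
    seed: int
    shared_permutation: bool
    n_pooled: int
    n_exceed: int
    n_excluded_constant: int

    @property
    def proportion(self) -> float:
        return self.n_exceed / self.n_pooled if self.n_pooled else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_lncrnas_sampled": self.n_lncrnas_sampled,
            "n_repetitions": self.n_repetitions,
            "threshold": self.threshold,
            "seed": self.seed,
            "shared_permutation": self.shared_permutation,
            "n_pooled": self.n_pooled,
            "n_exceed": self.n_exceed,
            "n_excluded_constant": self.n_excluded_constant,
            "proportion": self.proportion,
        }


def permutation_validate(
    lncrna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    config: PermutationConfig | None = None,
) -> PermutationSummary:
    """Estimate the null exceedance proportion of the correlation cutoff.

    Fully seeded and reproducible bit for bit: the same config and input
    matrices always yield the same pooled counts.
    """
    config = config or PermutationConfig()
    if list(lncrna_expr.columns) != list(mrna_expr.columns):
        raise ValueError("lncRNA and mRNA matrices must share the same library order")
    n_lnc = lncrna_expr.shape[0]
    if n_lnc < config.n_lncrnas_sampled:
        raise ValueError(
            f"need >= {config.n_lncrnas_sampled} lncRNAs, got {n_lnc}"
        )
    n = lncrna_expr.shape[1]
    lvals = lncrna_expr.to_numpy(dtype=float)
    zl_all, const_l = _standardize_rows(lvals)
    zm, const_m = _standardize_rows(mrna_expr.to_numpy(dtype=float))
    zm = zm[~const_m]
    usable = np.flatnonzero(~const_l)
    if usable.size < config.n_lncrnas_sampled:
        raise ValueError("too few non-constant lncRNA vectors to sample the panel")

    rng = np.random.default_rng(config.seed)
    k = config.n_lncrnas_sampled
    n_exceed = 0
    n_pooled = 0
    for _ in range(config.n_repetitions):
        panel = rng.choice(usable, size=k, replace=False)
        block = lvals[panel]
        if config.shared_permutation:
            order = rng.permutation(n)
            block = block[:, order]
        else:
            orders = np.argsort(rng.random((k, n)), axis=1)
            block = np.take_along_axis(block, orders, axis=1)
        zb, const_b = _standardize_rows(block)
        zb = zb[~const_b]
        r = np.abs(zb @ zm.T)
        n_pooled += r.size
        n_exceed += int(np.count_nonzero(r >= config.threshold - 1e-12))
    return PermutationSummary(
        n_lncrnas_sampled=k,
        n_repetitions=config.n_repetitions,
        threshold=config.threshold,
        seed=config.seed,
        shared_permutation=config.shared_permutation,
        n_pooled=n_pooled,
        n_exceed=n_exceed,
        n_excluded_constant=int(const_l.sum() + const_m.sum()),
    )
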