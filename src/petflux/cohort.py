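"""Cohort-level significance machinery for imaging-expression associations.

Three complementary checks of the enrichment results:

* a permuted-phenotype study -- the imaging measure is permuted across
  patients many times and the full GSEA re-run each time, counting how
  many gene sets clear the same 0.035/N cut-off; the count distribution
  is the empirical false-positive yield of the whole pipeline;
* bootstrap resampling of patients (with replacement) to compare the
  numbers of significant pathways found for two different imaging
  measures, tested with a paired t-test over resamples;
* per-gene correlation heatmap tables and Wilcoxon signed-rank
  comparisons of correlation-coefficient distributions between measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel, wilcoxon

from .gsea import (
    DEFAULT_ALPHA_NUMERATOR,
    DEFAULT_MAX_SIZE,
    DEFAULT_MIN_SIZE,
    GeneSetCollection,
    gsea_run,
)

log = logging.getLogger(__name__)


@dataclass
class FalsePositiveStudy:
    measure_name: str
    counts: np.ndarray  # significant-set count per permuted dataset
    median: float
    minimum: int
    maximum: int
    percentile_95: float

    @classmethod
    def from_counts(cls, measure_name, counts):
        counts = np.asarray(counts, dtype=int)
        return cls(
            measure_name=measure_name,
            counts=counts,
            median=float(np.median(counts)),
            minimum=int(counts.min()),
            maximum=int(counts.max()),
            percentile_95=float(np.percentile(counts, 95)),
        )


def _count_significant(results) -> int:
    return sum(r.significant for r in results)


def dataset_seed(master_seed: int, dataset_index: int) -> int:
    """GSEA seed used for the ``dataset_index``-th permuted dataset.

    Exposed so an unpermuted run at the same derived seed can be compared
    with the identity-debug path.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(dataset_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def permuted_phenotype_study(
    expression: pd.DataFrame,
    measure_values,
    collection: GeneSetCollection,
    n_datasets: int = 100,
    alpha_numerator: float = DEFAULT_ALPHA_NUMERATOR,
    seed: int = 0,
    method: str = "pearson",
    n_perm: int = 10_000,
    measure_name: str = "measure",
    identity_debug: bool = False,
    **gsea_kwargs,
) -> FalsePositiveStudy:
    """False-positive pathway counts over permuted-measure datasets.

    Each synthetic dataset permutes the measure across patients (seeded)
    and reruns the full GSEA at the alpha_numerator/N threshold.  With
    ``identity_debug`` the identity permutation is forced, so the count
    equals the unpermuted analysis count.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    y = np.asarray(measure_values, dtype=float)
    root = np.random.SeedSequence(seed)
    counts = np.empty(n_datasets, dtype=int)
    for d, ss in enumerate(root.spawn(n_datasets)):
        rng = np.random.default_rng(ss)
        perm = np.arange(y.size) if identity_debug else rng.permutation(y.size)
        results = gsea_run(
            expression, y[perm], collection, method=method, n_perm=n_perm,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            alpha_numerator=alpha_numerator, **gsea_kwargs,
        )
        counts[d] = _count_significant(results)
    return FalsePositiveStudy.from_counts(measure_name, counts)


@dataclass
class MeasureComparison:
    measure_a: str
    measure_b: str
    observed_difference: int  # significant-count difference on the real data
    differences: np.ndarray  # per-bootstrap-resample count differences (a - b)
    counts_a: np.ndarray
    counts_b: np.ndarray
    t_statistic: float
    p: float
    degenerate: bool = False


def bootstrap_count_difference(
    expression: pd.DataFrame,
    measures_table: pd.DataFrame,
    collection: GeneSetCollection,
    measure_a: str,
    measure_b: str,
    n_boot: int = 100,
    seed: int = 0,
    method: str = "pearson",
    n_perm: int = 10_000,
    alpha_numerator: float = DEFAULT_ALPHA_NUMERATOR,
    max_redraws: int = 20,
    **gsea_kwargs,
) -> MeasureComparison:
    """Bootstrap comparison of significant-pathway counts for two measures.

    Each resample draws patients with replacement (expression columns and
    measure rows jointly), reruns GSEA for both measures with a
    per-resample derived seed (tie-breaks re-randomised per resample),
    and records the difference in significant counts; the paired t-test
    is applied to the two count vectors.  Resamples in which either
    measure has zero variance are redrawn (logged).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    for m in (measure_a, measure_b):
        if measures_table[m].isna().any():
            raise ValueError(f"measure {m!r} missing for some patients")
    n_pat = expression.shape[1]
    ya = measures_table[measure_a].to_numpy(dtype=float)
    yb = measures_table[measure_b].to_numpy(dtype=float)

    def run(y, idx, run_seed):
        return _count_significant(
            gsea_run(
                expression.iloc[:, idx], y[idx], collection, method=method,
                n_perm=n_perm, seed=run_seed,
                alpha_numerator=alpha_numerator, **gsea_kwargs,
            )
        )

    root = np.random.SeedSequence(seed)
    obs_ss, boot_ss = root.spawn(2)
    obs_seed = int(obs_ss.generate_state(1)[0] % (2**31))
    all_idx = np.arange(n_pat)
    observed = run(ya, all_idx, obs_seed) - run(yb, all_idx, obs_seed + 1)

    counts_a = np.empty(n_boot, dtype=int)
    counts_b = np.empty(n_boot, dtype=int)
    for b, ss in enumerate(boot_ss.spawn(n_boot)):
        rng = np.random.default_rng(ss)
        for attempt in range(max_redraws):
            idx = rng.integers(0, n_pat, size=n_pat)
            if np.ptp(ya[idx]) > 0 and np.ptp(yb[idx]) > 0:
                break
            log.info("resample %d redrawn (zero-variance measure)", b)
        else:
            raise RuntimeError("could not draw a non-degenerate resample")
        rs = int(ss.generate_state(1)[0] % (2**31))
        counts_a[b] = run(ya, idx, rs)
        counts_b[b] = run(yb, idx, rs + 1)

    diffs = counts_a - counts_b
    if np.all(diffs == 0):
        return MeasureComparison(
            measure_a, measure_b, int(observed), diffs, counts_a, counts_b,
            t_statistic=np.nan, p=np.nan, degenerate=True,
        )
    t_stat, p = ttest_rel(counts_a, counts_b)
    return MeasureComparison(
        measure_a, measure_b, int(observed), diffs, counts_a, counts_b,
        t_statistic=float(t_stat), p=float(p),
        degenerate=not np.isfinite(p),
    )


def correlation_heatmap_table(
    expression: pd.DataFrame,
    measures_table: pd.DataFrame,
    gene_ids,
    mean_log2_floor: float = 1.0,
) -> pd.DataFrame:
    """Pearson r of each selected gene against each imaging measure.

    Genes whose mean log2 expression falls below ``mean_log2_floor``
    (low-count exclusion) or with zero variance are excluded with a
    warning.  Rows are genes, columns the measures.
    """
    missing = [g for g in gene_ids if g not in expression.index]
    if missing:
        raise KeyError(f"genes not in the expression matrix: {missing[:5]}")
    sub = expression.loc[list(gene_ids)]
    keep = sub.mean(axis=1) >= mean_log2_floor
    low = list(sub.index[~keep])
    if low:
        log.warning("excluding %d low-expression genes", len(low))
    sub = sub.loc[keep]
    var_ok = sub.std(axis=1) > 0
    if (~var_ok).any():
        log.warning("excluding %d zero-variance genes", int((~var_ok).sum()))
    sub = sub.loc[var_ok]
    from .gsea import _pearson_rows

    out = {}
    for m in measures_table.columns:
        out[m] = _pearson_rows(sub.to_numpy(dtype=float),
                               measures_table[m].to_numpy(dtype=float))
    return pd.DataFrame(out, index=sub.index)


@dataclass
class WilcoxonComparison:
    statistic: float  # signed rank sum W+ - W-; positive means a > b
    p: float
    n_nonzero: int
    degenerate: bool = False


def wilcoxon_compare(r_vector_a, r_vector_b) -> WilcoxonComparison:
    """Two-sided Wilcoxon signed-rank test on paired correlation vectors.

    Zero differences are dropped (Wilcoxon convention); with fewer than
    5 non-zero differences the test is reported as degenerate (p nan).
    The statistic is the signed rank sum W+ - W- of a - b, so swapping
    the arguments flips its sign while leaving p unchanged.
    """
    a = np.asarray(r_vector_a, dtype=float)
    b = np.asarray(r_vector_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0.0]
    nz = d.size
    if nz < 5:
        return WilcoxonComparison(np.nan, np.nan, nz, degenerate=True)
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    signed_sum = float(np.sum(np.sign(d) * ranks))
    _, p = wilcoxon(d, zero_method="wilcox", alternative="two-sided")
    return WilcoxonComparison(signed_sum, float(p), nz)
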