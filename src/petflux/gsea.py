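"""Preranked gene-set enrichment of imaging-transcriptome correlations.

Genes are ranked by the Pearson or Spearman correlation of their log2
expression with an imaging measure across patients (exact coefficient
ties broken uniformly at random under a dedicated seed), and gene sets
are scored with the weighted Kolmogorov-Smirnov running-sum statistic of
the standard preranked GSEA ("simple" FGSEA) algorithm:

    hit  step:  +|r_g|^p / sum_{g in set} |r_g|^p
    miss step:  -1 / (N - N_hit)

The enrichment score (ES) is the extremum of the walk; normalised scores
and permutation p-values come from a gene-wise permutation null --
random same-size gene sets scored against the fixed ranking -- which is
shared across gene sets of equal size.  Note the caveat of this null:
because it ignores inter-gene correlation it can overstate significance;
the permuted-phenotype study in :mod:`petflux.cohort` quantifies the
resulting false-positive behaviour.  Significance is declared at a
Bonferroni-style threshold alpha / N over the N sets tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_ALPHA_NUMERATOR = 0.035
DEFAULT_MIN_SIZE = 15
DEFAULT_MAX_SIZE = 500


# --------------------------------------------------------------------------
# gene-set collections (GMT dialect)
# --------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets; GMT lines are name, description, members..."""

    sets: dict  # name -> list of gene ids
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self):
        return len(self.sets)

    def filtered(self, gene_universe, min_size=DEFAULT_MIN_SIZE,
                 max_size=DEFAULT_MAX_SIZE) -> "GeneSetCollection":
        """Restrict members to the expression universe and apply size limits."""
        universe = set(gene_universe)
        kept = {}
        for name, members in self.sets.items():
            inter = [g for g in members if g in universe]
            if min_size <= len(inter) <= max_size:
                kept[name] = inter
        return GeneSetCollection(
            sets=kept,
            descriptions={n: self.descriptions.get(n, "") for n in kept},
        )


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "na") or "na"
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"malformed GMT line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r} (line {lineno})")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


# --------------------------------------------------------------------------
# ranking
# --------------------------------------------------------------------------


@dataclass
class RankedGeneList:
    genes: np.ndarray  # gene ids, best-to-worst
    stats: np.ndarray  # ranking statistic, non-increasing
    method: str
    tie_seed: int
    dropped: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.genes.size


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of X with y (zero-variance rows -> nan)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r[(sx == 0) | (sy == 0)] = np.nan
    return r


def rank_genes(
    expression: pd.DataFrame,
    measure_values,
    method: str = "pearson",
    seed: int = 0,
) -> RankedGeneList:
    """Order genes by correlation with an imaging measure, best first.

    ``expression`` is genes x patients (log2 values); columns must align
    with ``measure_values``.  Spearman correlations are Pearson
    correlations of midranks.  Genes with zero variance have no defined
    coefficient and are dropped with a warning entry.  Exact coefficient
    ties are ordered uniformly at random under ``seed``.
    """
    y = np.asarray(measure_values, dtype=float)
    if expression.shape[1] != y.size:
        raise ValueError("expression columns must align with measure values")
    if y.size < 3:
        raise ValueError("need at least 3 patients")
    X = expression.to_numpy(dtype=float)
    if method == "pearson":
        r = _pearson_rows(X, y)
    elif method == "spearman":
        from scipy.stats import rankdata

        r = _pearson_rows(rankdata(X, axis=1), rankdata(y))
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")

    genes = np.asarray(expression.index)
    keep = np.isfinite(r)
    dropped = list(genes[~keep])
    r, genes = r[keep], genes[keep]

    rng = np.random.default_rng(seed)
    tiebreak = rng.random(r.size)
    order = np.lexsort((tiebreak, -r))
    return RankedGeneList(
        genes=genes[order], stats=r[order], method=method, tie_seed=seed,
        dropped=dropped,
    )


# --------------------------------------------------------------------------
# enrichment score
# --------------------------------------------------------------------------


def enrichment_score(
    ranked: RankedGeneList,
    gene_set,
    weight_exponent: float = 1.0,
):
    """Weighted KS running-sum enrichment score of one gene set.

    Returns (ES, leading_edge_genes, running_walk).  The walk starts at 0
    and records the value after each list position; ES is the extremum
    (at equal magnitude, the one reached earlier in the list).  The
    leading edge comprises the set members up to (for positive ES) or
    from (for negative ES) the extremal position.
    """
    members = set(gene_set)
    hit = np.isin(ranked.genes, list(members))
    n_hit = int(hit.sum())
    n = ranked.n
    if n_hit == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the entire ranked list")
    wts = np.abs(ranked.stats) ** weight_exponent
    denom = wts[hit].sum()
    if denom == 0:
        # all hit statistics are exactly zero: fall back on equal weights
        steps_hit = np.where(hit, 1.0 / n_hit, 0.0)
    else:
        steps_hit = np.where(hit, wts / denom, 0.0)
    steps = steps_hit - np.where(hit, 0.0, 1.0 / (n - n_hit))
    walk = np.cumsum(steps)
    i_max = int(np.argmax(walk))
    i_min = int(np.argmin(walk))
    if walk[i_max] >= -walk[i_min]:
        if abs(walk[i_max]) == abs(walk[i_min]) and i_min < i_max:
            es, extremum = float(walk[i_min]), i_min
        else:
            es, extremum = float(walk[i_max]), i_max
    else:
        es, extremum = float(walk[i_min]), i_min
    if es >= 0:
        leading = ranked.genes[: extremum + 1][hit[: extremum + 1]]
    else:
        leading = ranked.genes[extremum:][hit[extremum:]]
    return es, list(leading), walk


def _batch_null_es(
    stats: np.ndarray, set_size: int, n_perm: int, rng, weight_exponent=1.0,
    chunk: int = 512,
) -> np.ndarray:
    """Null ES sample for random same-size gene sets against a fixed ranking.

    Vectorised equivalent of scoring ``n_perm`` uniformly drawn sets with
    :func:`enrichment_score` (the brute-force oracle the tests compare
    against).  Positions are sampled without replacement per draw.
    """
    n = stats.size
    wts = np.abs(stats) ** weight_exponent
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # m x set_size sorted hit positions, sampled without replacement
        keys = rng.random((m, n))
        pos = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        pos.sort(axis=1)
        w = wts[pos]
        denom = w.sum(axis=1, keepdims=True)
        cum_hit = np.cumsum(w, axis=1)
        cum_hit = np.where(denom > 0, cum_hit / np.where(denom == 0, 1, denom),
                           (np.arange(1, set_size + 1) / set_size)[None, :])
        # walk value at hit j: cum_hit_j - (pos_j + 1 - j) / (n - k)
        j = np.arange(1, set_size + 1)[None, :]
        miss_before = (pos + 1 - j) / (n - set_size)
        at_hit = cum_hit - miss_before
        before_hit = at_hit - np.where(
            denom > 0,
            w / np.where(denom == 0, 1, denom),
            1.0 / set_size,
        )
        walk_max = at_hit.max(axis=1)
        walk_min = np.minimum(before_hit.min(axis=1), 0.0)
        # extremum by magnitude, earlier position at exact ties is
        # irrelevant for the null magnitude distribution
        es = np.where(walk_max >= -walk_min, walk_max, walk_min)
        out[done:done + m] = es
        del keys
        done += m
    return out


def permutation_null(
    ranked: RankedGeneList,
    set_size: int,
    n_perm: int,
    seed: int,
    weight_exponent: float = 1.0,
) -> np.ndarray:
    """Gene-wise permutation null ES sample for one set size."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if set_size >= ranked.n:
        raise ValueError("set_size must be smaller than the ranked list")
    rng = np.random.default_rng(seed)
    return _batch_null_es(ranked.stats, set_size, n_perm, rng, weight_exponent)


# --------------------------------------------------------------------------
# full GSEA run
# --------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int
    es: float
    nes: float
    p: float
    significant: bool
    leading_edge: list


def bonferroni_threshold(n_sets: int, alpha_numerator: float = DEFAULT_ALPHA_NUMERATOR) -> float:
    """Per-set p-value cut-off alpha / N over the N sets tested."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    return alpha_numerator / n_sets


def gsea_run(
    expression: pd.DataFrame,
    measure_values,
    collection: GeneSetCollection,
    method: str = "pearson",
    n_perm: int = 10_000,
    seed: int = 0,
    alpha_numerator: float = DEFAULT_ALPHA_NUMERATOR,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    weight_exponent: float = 1.0,
) -> list:
    """Rank genes against one measure and score every gene set.

    Per set: ES; sign-stratified NES (ES over the mean |null ES| of the
    matching sign) and permutation p with the +1 convention,
    p = (1 + #{same-sign nulls at least as extreme}) / (1 + #same-sign
    nulls); significance at alpha_numerator / N where N is the post-filter
    set count.  Nulls are shared across sets of equal size.  The ranking
    tie-break and the permutation draws consume independent seeded
    streams derived from ``seed``.
    """
    root = np.random.SeedSequence(seed)
    tie_ss, perm_ss = root.spawn(2)
    ranked = rank_genes(
        expression, measure_values, method=method,
        seed=int(tie_ss.generate_state(1)[0] % (2**31)),
    )
    filtered = collection.filtered(ranked.genes, min_size, max_size)
    if len(filtered) == 0:
        raise ValueError("no gene set survives the size filter")
    threshold = bonferroni_threshold(len(filtered), alpha_numerator)

    sizes = sorted({len(m) for m in filtered.sets.values()})
    size_seeds = {
        size: int(ss.generate_state(1)[0] % (2**31))
        for size, ss in zip(sizes, perm_ss.spawn(len(sizes)))
    }
    nulls = {
        size: permutation_null(ranked, size, n_perm, size_seeds[size],
                               weight_exponent)
        for size in sizes
    }

    results = []
    for name, members in filtered.sets.items():
        es, leading, _ = enrichment_score(ranked, members, weight_exponent)
        null = nulls[len(members)]
        if es >= 0:
            same = null[null >= 0]
            extreme = int(np.sum(same >= es))
            mean_mag = same.mean() if same.size else np.nan
        else:
            same = null[null < 0]
            extreme = int(np.sum(same <= es))
            mean_mag = -same.mean() if same.size else np.nan
        p = (1.0 + extreme) / (1.0 + same.size)
        nes = es / mean_mag if np.isfinite(mean_mag) and mean_mag > 0 else np.nan
        results.append(
            EnrichmentResult(
                set_name=name, set_size=len(members), es=es, nes=float(nes),
                p=float(p), significant=bool(p < threshold),
                leading_edge=leading,
            )
        )
    return results


def results_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "size": [r.set_size for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p for r in results],
            "significant": [r.significant for r in results],
            "leading_edge": [";".join(r.leading_edge) for r in results],
        }
    )


# --------------------------------------------------------------------------
# leading-edge overlap
# --------------------------------------------------------------------------


def leading_edge_overlap(results, significant_only: bool = True):
    """Binary gene x pathway membership matrix over leading edges.

    Returns (DataFrame genes x pathways of 0/1, Series per-gene pathway
    counts sorted descending).  Row and column sums conserve the total
    number of leading-edge memberships.
    """
    chosen = [r for r in results if (r.significant or not significant_only)]
    chosen = [r for r in chosen if len(r.leading_edge) > 0]
    if not chosen:
        raise ValueError("no result with a leading edge")
    genes = sorted({g for r in chosen for g in r.leading_edge})
    mat = pd.DataFrame(0, index=genes, columns=[r.set_name for r in chosen])
    for r in chosen:
        mat.loc[list(r.leading_edge), r.set_name] = 1
    counts = mat.sum(axis=1).sort_values(ascending=False)
    return mat, counts
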