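"""Profile clustering, functional enrichment, and the fold-change test.

Expression profiles are grouped by k-means under a Pearson correlation
distance (d = 1 - r, k = 8 in the original design); synthesis-rate
residual traces are grouped by ordinary Euclidean k-means (k = 5).  Both
run the same Lloyd iteration with seeded multi-restart initialisation;
under the correlation metric the centroid update is the arithmetic mean
trace re-standardised to zero mean and unit variance each iteration, so
centroids stay on the same scale as the (standardised) profiles.

Cluster function enrichment uses the upper-tail hypergeometric test on
COG category membership; p-values are raw (flagged at p < 0.01), with a
Benjamini-Hochberg q-value column added as a labelled extension.

The fold-change test asks whether a gene moved by at least a given
factor across the perturbation: a one-sided Welch t-test comparing the
post-perturbation values with the fold-scaled pre-perturbation values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core_data import DataError

PEARSON = "pearson"
EUCLIDEAN = "euclidean"

#: Cluster counts of the original design.
K_EXPRESSION = 8
K_RESIDUAL = 5

DEFAULT_RESTARTS = 25
MAX_ITER = 300


# ---------------------------------------------------------------------------
# K-means with correlation or Euclidean distance
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    k: int
    metric: str
    gene_ids: list[str]
    assignments: np.ndarray          # cluster id per gene
    centroids: np.ndarray            # (k, T)
    seed: int
    restarts: int
    inertia: float                   # total within-cluster distance

    def members(self, cluster: int) -> list[str]:
        return [g for g, a in zip(self.gene_ids, self.assignments) if a == cluster]

    def as_mapping(self) -> dict[str, int]:
        return dict(zip(self.gene_ids, (int(a) for a in self.assignments)))


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise DataError("constant trace under the correlation metric; "
                        "standardize/exclude constant genes first")
    return (x - mean) / sd


def _pearson_distance(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """1 - r between every row of x and every row of c -> (n, k)."""
    t = x.shape[1]
    zx = _standardize_rows(x)
    zc = _standardize_rows(c)
    r = zx @ zc.T / (t - 1)
    return 1.0 - r


def _sq_euclidean_distance(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    d2 = (np.sum(x ** 2, axis=1)[:, None] - 2 * x @ c.T
          + np.sum(c ** 2, axis=1)[None, :])
    return np.maximum(d2, 0.0)


def _lloyd(x: np.ndarray, k: int, metric: str,
           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float]:
    """One seeded Lloyd run; returns (assignments, centroids, objective).

    The objective is the total within-cluster distance: 1 - r under the
    correlation metric (for standardised traces this is the squared
    z-vector distance over 2(T-1), so the mean-then-restandardise
    centroid update is the exact minimiser) and squared Euclidean
    distance otherwise.  Both steps therefore never increase the
    objective, which is asserted per iteration; re-seeding an emptied
    cluster is the one move allowed to break monotonicity.
    """
    n = x.shape[0]
    dist_fn = _pearson_distance if metric == PEARSON else _sq_euclidean_distance
    centroids = x[rng.choice(n, size=k, replace=False)].copy()
    d = dist_fn(x, centroids)
    assign = np.argmin(d, axis=1)
    prev_obj = float(d[np.arange(n), assign].sum())
    for _ in range(MAX_ITER):
        reseeded = False
        for j in range(k):
            mask = assign == j
            if not mask.any():
                # re-seed an emptied cluster at the worst-fitted point
                far = int(np.argmax(d[np.arange(n), assign]))
                assign[far] = j
                mask = assign == j
                reseeded = True
            centroids[j] = x[mask].mean(axis=0)
            if metric == PEARSON:
                centroids[j] = _standardize_rows(centroids[j][None, :])[0]
        d = dist_fn(x, centroids)
        new_assign = np.argmin(d, axis=1)
        obj = float(d[np.arange(n), new_assign].sum())
        if not reseeded:
            assert obj <= prev_obj + 1e-9, "k-means objective increased"
            if np.array_equal(new_assign, assign):
                break
        assign, prev_obj = new_assign, obj
    return assign, centroids, prev_obj


def kmeans(profiles: Mapping[str, np.ndarray] | np.ndarray, k: int,
           metric: str = PEARSON, seed: int = 0,
           restarts: int = DEFAULT_RESTARTS,
           gene_ids: Sequence[str] | None = None) -> ClusterResult:
    """Cluster traces by k-means under a Pearson or Euclidean distance.

    ``profiles`` is either a gene -> trace mapping or an (n, T) array
    (then ``gene_ids`` labels the rows).  The best of ``restarts`` seeded
    random initialisations by total within-cluster distance is returned;
    results are deterministic for a given seed.  Under the correlation
    metric constant traces are rejected (their correlation is undefined).
    """
    if isinstance(profiles, Mapping):
        gene_ids = list(profiles.keys())
        x = np.array([np.asarray(profiles[g], dtype=float) for g in gene_ids])
    else:
        x = np.asarray(profiles, dtype=float)
        gene_ids = list(gene_ids) if gene_ids is not None else [
            f"g{i}" for i in range(x.shape[0])]
    if x.ndim != 2:
        raise DataError("profiles must form a 2-D (genes x times) array")
    if metric not in (PEARSON, EUCLIDEAN):
        raise DataError(f"unknown metric {metric!r}")
    if k >= x.shape[0]:
        raise DataError(f"k = {k} must be smaller than {x.shape[0]} profiles")
    if metric == PEARSON and np.any(x.std(axis=1) == 0):
        bad = [gene_ids[i] for i in np.flatnonzero(x.std(axis=1) == 0)]
        raise DataError(f"constant traces under pearson metric: {bad}; "
                        "standardize or exclude them")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(restarts):
        assign, centroids, inertia = _lloyd(x, k, metric, rng)
        if best is None or inertia < best[0]:
            best = (inertia, assign, centroids)
    inertia, assign, centroids = best
    return ClusterResult(k=k, metric=metric, gene_ids=gene_ids,
                         assignments=assign, centroids=centroids, seed=seed,
                         restarts=restarts, inertia=inertia)


# ---------------------------------------------------------------------------
# Hypergeometric category enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    cluster: int
    term: str
    p_value: float
    in_cluster_annotated: int
    cluster_size: int
    population_annotated: int
    population_size: int
    significant: bool       # raw p < 0.01, the reporting threshold
    bh_q: float = field(default=float("nan"), compare=False)


def hypergeom_upper_tail(observed: int, population: int, annotated: int,
                         drawn: int) -> float:
    """P(X >= observed) drawing ``drawn`` genes from ``population`` of
    which ``annotated`` carry the term."""
    if observed <= 0:
        return 1.0
    return float(stats.hypergeom.sf(observed - 1, population, annotated, drawn))


def cog_enrichment(clusters: Mapping[str, int],
                   annotations: Mapping[str, str],
                   alpha: float = 0.01) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of every (cluster, term) pair.

    Genes missing from ``annotations`` get the category ``"none"``.  The
    population is the full set of clustered genes.  Raw p-values are
    reported for all pairs and flagged at ``p < alpha``; a
    Benjamini-Hochberg q-value is attached as a labelled extension (no
    correction is applied to the flags themselves).
    """
    genes = list(clusters.keys())
    pop_size = len(genes)
    terms = sorted({annotations.get(g, "none") for g in genes})
    cluster_ids = sorted(set(clusters.values()))
    pop_count = {t: sum(1 for g in genes if annotations.get(g, "none") == t)
                 for t in terms}
    raw: list[EnrichmentResult] = []
    for c in cluster_ids:
        members = [g for g in genes if clusters[g] == c]
        for t in terms:
            obs = sum(1 for g in members if annotations.get(g, "none") == t)
            if pop_count[t] == 0:
                p = 1.0
            else:
                p = hypergeom_upper_tail(obs, pop_size, pop_count[t],
                                         len(members))
            raw.append(EnrichmentResult(
                cluster=c, term=t, p_value=p, in_cluster_annotated=obs,
                cluster_size=len(members), population_annotated=pop_count[t],
                population_size=pop_size, significant=p < alpha))
    qs = benjamini_hochberg([r.p_value for r in raw])
    return [EnrichmentResult(**{**r.__dict__, "bh_q": q})
            for r, q in zip(raw, qs)]


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up q-values (monotone adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# One-sided Welch fold-change test
# ---------------------------------------------------------------------------

def fold_change_test(pre_values: Sequence[float], post_values: Sequence[float],
                     fold: float = 1.5, direction: str = "up") -> float:
    """One-sided Welch t-test for an at-least-``fold`` change.

    ``direction="up"`` tests H0: mean(post) <= fold * mean(pre) against
    the upregulation alternative by scaling the pre-perturbation group by
    the fold factor and applying the one-sided Welch statistic
    (Welch-Satterthwaite degrees of freedom); ``"down"`` mirrors it with
    the pre group divided by the fold factor.  Values are on the linear
    scale.  Vectorised: 2-D inputs are tested row-wise and return an
    array of p-values.
    """
    pre = np.atleast_2d(np.asarray(pre_values, dtype=float))
    post = np.atleast_2d(np.asarray(post_values, dtype=float))
    if pre.shape[1] < 2 or post.shape[1] < 2:
        raise DataError("need >=2 values in each group for the Welch test")
    if np.any(pre <= 0) or np.any(post <= 0):
        raise DataError("fold-change test requires positive values")
    if fold <= 0:
        raise DataError(f"fold must be positive, got {fold}")
    if direction not in ("up", "down"):
        raise DataError(f"direction must be 'up' or 'down', got {direction!r}")
    if direction == "up":
        ref, alternative = pre * fold, "greater"
    else:
        ref, alternative = pre / fold, "less"
    if np.any((np.var(ref, axis=1) == 0) & (np.var(post, axis=1) == 0)):
        raise DataError("zero variance in both groups: p-value undefined")
    res = stats.ttest_ind(post, ref, axis=1, equal_var=False,
                          alternative=alternative)
    p = np.asarray(res.pvalue)
    return float(p[0]) if p.size == 1 else p.reshape(-1)
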