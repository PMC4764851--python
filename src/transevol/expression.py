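"""Expression quantification and differential expression.

Implements TPM normalization from counts and effective lengths, a weighted
two-group beta-binomial proportions test (the Baggerly-style test used for
SAGE/RNA-seq library comparisons), the fold-change/Bonferroni differential
expression screen, hypergeometric annotation enrichment, and
bootstrap-supported average-linkage clustering of samples on a
correlation-based dissimilarity of square-root transformed TPMs.

The proportions test models the per-library transcript proportion
``p_i = y_i / n_i`` with variance ``p(1-p) * (1/n_i + theta)`` — a binomial
sampling component plus a between-library (beta-binomial) overdispersion
component ``theta`` estimated by the method of moments.  Group proportions
are library-size-weighted; the statistic is referred to a t distribution
with ``k1 + k2 - 2`` degrees of freedom (the reference distribution of the
weighted t-type statistic for between-library SAGE/RNA-seq comparisons);
with a single library per group it reduces exactly to the pooled
two-proportion z statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "CountMatrix",
    "DEResult",
    "EnrichmentResult",
    "compute_tpm",
    "baggerly_proportions_test",
    "run_differential_expression",
    "hypergeometric_enrichment",
    "bootstrap_average_linkage",
    "ClusterResult",
]


@dataclass
class CountMatrix:
    """Transcripts-by-samples integer read counts with effective lengths.

    ``counts`` is indexed by transcript id with one column per sample;
    ``lengths`` gives each transcript's effective length in nucleotides;
    ``groups`` assigns each sample label to a group (tissue, sex, ...).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()].tolist()[:3]
            raise ValueError(f"missing lengths for transcripts {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if (self.lengths.to_numpy() <= 0).any():
            raise ValueError("non-positive transcript length")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample labels")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups.get(s) == group]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def compute_tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts Per Million: per-base read rates rescaled to sum to 1e6.

    Raises if a sample has no mapped reads at all (its rates sum to zero and
    the scaling is undefined).
    """
    rates = cm.counts.div(cm.lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has all-zero counts")
    return rates.div(totals, axis=1) * 1e6


# ---------------------------------------------------------------------------
# Beta-binomial (Baggerly-style) proportions test


def _group_moments(y: np.ndarray, n: np.ndarray, p_pool: np.ndarray):
    """Weighted proportion and its variance for one group.

    ``y``: (G, K) counts; ``n``: (K,) library sizes; ``p_pool``: (G,) pooled
    proportion used for the binomial variance component.  Returns
    ``(p_hat, var, k)``.
    """
    n = np.asarray(n, dtype=float)
    y = np.asarray(y, dtype=float)
    k = n.size
    n_tot = n.sum()
    p_hat = y.sum(axis=1) / n_tot
    pq = p_pool * (1.0 - p_pool)
    if k == 1:
        return p_hat, pq / n_tot, k
    # method-of-moments between-library variance on the proportion scale:
    # E[sum_i n_i (p_i - p_hat)^2] = (k-1) p(1-p) + sigma_b^2 (n_tot - sum n_i^2/n_tot)
    p_i = y / n
    wss = (n * (p_i - p_hat[:, None]) ** 2).sum(axis=1)
    denom = n_tot - (n**2).sum() / n_tot
    sigma_b2 = np.maximum(0.0, (wss - (k - 1) * pq) / denom)
    var = (pq * n_tot + sigma_b2 * (n**2).sum()) / n_tot**2
    return p_hat, var, k


def _baggerly_arrays(y1, n1, y2, n2):
    """Vectorized test over G transcripts; returns (stat, p, p1_hat, p2_hat)."""
    y1 = np.atleast_2d(np.asarray(y1, dtype=float))
    y2 = np.atleast_2d(np.asarray(y2, dtype=float))
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if (n1 <= 0).any() or (n2 <= 0).any():
        raise ValueError("library sizes must be positive")
    p_pool = (y1.sum(axis=1) + y2.sum(axis=1)) / (n1.sum() + n2.sum())
    p1, v1, k1 = _group_moments(y1, n1, p_pool)
    p2, v2, k2 = _group_moments(y2, n2, p_pool)
    var = v1 + v2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(var > 0, (p1 - p2) / np.sqrt(var), 0.0)
    if k1 == 1 and k2 == 1:
        p = 2.0 * stats.norm.sf(np.abs(stat))
    else:
        # reference distribution of the weighted t-type statistic:
        # t with k1+k2-2 degrees of freedom
        p = 2.0 * stats.t.sf(np.abs(stat), k1 + k2 - 2)
    # absent transcript (zero everywhere): p = 1 by convention
    absent = (y1.sum(axis=1) + y2.sum(axis=1)) == 0
    p = np.where(absent, 1.0, np.clip(p, 0.0, 1.0))
    stat = np.where(absent, 0.0, stat)
    return stat, p, p1, p2


def baggerly_proportions_test(counts_g1, lib_sizes_g1, counts_g2, lib_sizes_g2):
    """Two-group weighted proportions test for a single transcript.

    ``counts_g*`` are per-library counts of the transcript; ``lib_sizes_g*``
    the corresponding total library sizes.  Returns ``(statistic,
    p_two_sided)``.  With one library per group this is exactly the pooled
    two-proportion z test.
    """
    stat, p, _, _ = _baggerly_arrays(
        np.asarray(counts_g1, dtype=float)[None, :],
        lib_sizes_g1,
        np.asarray(counts_g2, dtype=float)[None, :],
        lib_sizes_g2,
    )
    return float(stat[0]), float(p[0])


@dataclass(frozen=True)
class DEResult:
    transcript_id: str
    proportion_g1: float
    proportion_g2: float
    fold_change: float
    statistic: float
    p_raw: float
    p_bonferroni: float
    tested: bool
    significant: bool


def _signed_fold_change(p1: np.ndarray, p2: np.ndarray, floor: float) -> np.ndarray:
    """Signed ratio of weighted proportions with a pseudo-proportion floor.

    Positive when group 1 exceeds group 2.  The floor (1 / total library
    size) avoids division by zero for transcripts absent from one group.
    """
    a = np.maximum(p1, floor)
    b = np.maximum(p2, floor)
    ratio = a / b
    return np.where(ratio >= 1.0, ratio, -1.0 / ratio)


def run_differential_expression(
    cm: CountMatrix,
    group1: str,
    group2: str,
    fc_min: float = 2.0,
    alpha: float = 0.01,
    min_total_count: int = 10,
) -> pd.DataFrame:
    """Screen all transcripts for differential expression between two groups.

    A transcript is flagged significant iff |fold change| >= ``fc_min`` AND
    its Bonferroni-corrected p < ``alpha``.  The Bonferroni family size is
    the number of transcripts passing the ``min_total_count`` reliability
    filter (only those are tested); every transcript is reported.
    """
    s1 = cm.samples_in_group(group1)
    s2 = cm.samples_in_group(group2)
    if not s1 or not s2:
        raise ValueError(f"empty group among {group1!r}, {group2!r}")
    if set(s1) & set(s2):
        raise ValueError("groups are not disjoint")
    y1 = cm.counts[s1].to_numpy(dtype=float)
    y2 = cm.counts[s2].to_numpy(dtype=float)
    n1 = cm.counts[s1].sum(axis=0).to_numpy(dtype=float)
    n2 = cm.counts[s2].sum(axis=0).to_numpy(dtype=float)
    tested = (y1.sum(axis=1) + y2.sum(axis=1)) >= min_total_count
    n_tests = int(tested.sum())
    stat, p_raw, p1, p2 = _baggerly_arrays(y1, n1, y2, n2)
    floor = 1.0 / (n1.sum() + n2.sum())
    fc = _signed_fold_change(p1, p2, floor)
    p_bonf = np.minimum(1.0, p_raw * max(n_tests, 1))
    significant = tested & (np.abs(fc) >= fc_min) & (p_bonf < alpha)
    return pd.DataFrame(
        {
            "proportion_g1": p1,
            "proportion_g2": p2,
            "fold_change": fc,
            "statistic": stat,
            "p_raw": p_raw,
            "p_bonferroni": np.where(tested, p_bonf, np.nan),
            "tested": tested,
            "significant": significant,
        },
        index=cm.counts.index,
    )


# ---------------------------------------------------------------------------
# Hypergeometric enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    observed: int
    universe_annotated: int
    drawn: int
    universe: int
    p_hypergeom: float
    over_represented: bool


def hypergeometric_enrichment(
    flagged: set[str],
    universe: set[str],
    annotation: dict[str, set[str]],
    p_max: float = 1e-5,
    min_observed: int = 5,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation test per annotation term.

    For each term, the p-value is the probability of drawing at least the
    observed number of term-annotated items when sampling ``len(flagged)``
    items without replacement from the universe.  A term is called
    over-represented iff ``p < p_max`` and ``observed > min_observed``
    (both strict).  Terms annotating nothing in the universe are skipped.
    """
    if not flagged <= universe:
        raise ValueError("flagged set is not a subset of the universe")
    n_universe = len(universe)
    n_drawn = len(flagged)
    results: list[EnrichmentResult] = []
    for term, items in sorted(annotation.items()):
        annotated = items & universe
        if not annotated:
            continue
        observed = len(items & flagged)
        p = float(stats.hypergeom.sf(observed - 1, n_universe, len(annotated), n_drawn))
        results.append(
            EnrichmentResult(
                term=term,
                observed=observed,
                universe_annotated=len(annotated),
                drawn=n_drawn,
                universe=n_universe,
                p_hypergeom=p,
                over_represented=(p < p_max and observed > min_observed),
            )
        )
    results.sort(key=lambda r: (r.p_hypergeom, r.term))
    return results


# ---------------------------------------------------------------------------
# Bootstrap-supported clustering


@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray
    support: dict[frozenset, float]  # sample bipartition -> % of bootstrap trees
    newick: str


def _correlation_dissimilarity(mat: np.ndarray, labels) -> np.ndarray:
    sd = mat.std(axis=0)
    if (sd == 0).any():
        bad = labels[int(np.argmax(sd == 0))]
        raise ValueError(f"sample {bad!r} has constant expression vector")
    return 1.0 - np.corrcoef(mat.T)


def _clusters_of(linkage: np.ndarray, labels: list[str]) -> list[frozenset]:
    """Sample memberships of every internal node of a linkage tree."""
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for i, (a, b, _, _) in enumerate(linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        out.append(merged)
    return out


def _to_newick(linkage: np.ndarray, labels: list[str], support) -> str:
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}

    def rec(node: int) -> str:
        if node < n:
            return labels[node]
        a, b, dist, _ = linkage[node - n]
        merged = members[int(a)] | members[int(b)]
        members[node] = merged
        sup = support.get(merged)
        lab = "" if sup is None else f"{sup:.0f}"
        return f"({rec(int(a))},{rec(int(b))}){lab}"

    # fill members bottom-up first
    for i, (a, b, _, _) in enumerate(linkage):
        members[n + i] = members[int(a)] | members[int(b)]
    return rec(n + len(linkage) - 1) + ";"


def bootstrap_average_linkage(
    tpm: pd.DataFrame, n_boot: int = 1000, seed: int | None = None
) -> ClusterResult:
    """Average-linkage clustering of samples with bootstrap node support.

    Samples are clustered on the dissimilarity ``1 - Pearson correlation`` of
    square-root transformed TPMs.  Support for each internal node is the
    percentage of ``n_boot`` gene-resampled bootstrap trees containing the
    node's sample bipartition (ordinary bootstrap probability).
    """
    if tpm.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    labels = list(tpm.columns)
    x = np.sqrt(tpm.to_numpy(dtype=float))
    d = _correlation_dissimilarity(x, labels)
    link = hierarchy.average(squareform(d, checks=False))
    obs_clusters = _clusters_of(link, labels)
    counts = {c: 0 for c in obs_clusters}
    rng = np.random.default_rng(seed)
    n_genes = x.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n_genes, size=n_genes)
        xb = x[idx]
        sd = xb.std(axis=0)
        if (sd == 0).any():  # degenerate resample: no bipartition is supported
            continue
        db = 1.0 - np.corrcoef(xb.T)
        lb = hierarchy.average(squareform((db + db.T) / 2.0, checks=False))
        boot_clusters = set(_clusters_of(lb, labels))
        for c in counts:
            if c in boot_clusters:
                counts[c] += 1
    support = {c: 100.0 * k / n_boot for c, k in counts.items()}
    return ClusterResult(
        labels=labels,
        linkage=link,
        support=support,
        newick=_to_newick(link, labels, support),
    )
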