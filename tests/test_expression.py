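import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from transevol.expression import (
    CountMatrix,
    baggerly_proportions_test,
    bootstrap_average_linkage,
    compute_tpm,
    hypergeometric_enrichment,
    run_differential_expression,
)


def one_sample_cm(counts, lengths):
    return CountMatrix(
        counts=pd.DataFrame({"s": counts}, index=[f"t{i}" for i in range(len(counts))]),
        lengths=pd.Series(lengths, index=[f"t{i}" for i in range(len(counts))]),
        groups={"s": "g"},
    )


class TestTPM:
    def test_single_transcript_is_million(self):
        tpm = compute_tpm(one_sample_cm([42], [500]))
        assert tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_equal_rates_share_equally(self):
        tpm = compute_tpm(one_sample_cm([10, 20, 30], [1000, 2000, 3000]))
        assert np.allclose(tpm["s"], 1e6 / 3)

    def test_symmetry_two_equal_transcripts(self):
        tpm = compute_tpm(one_sample_cm([7, 7], [300, 300]))
        assert np.allclose(tpm["s"], 5e5)

    def test_all_zero_sample_is_error(self):
        with pytest.raises(ValueError, match="'s'"):
            compute_tpm(one_sample_cm([0, 0], [100, 100]))

    def test_column_sums_and_scale_invariance(self, small_counts):
        tpm = compute_tpm(small_counts)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)
        scaled = CountMatrix(
            counts=small_counts.counts * 10,
            lengths=small_counts.lengths,
            groups=small_counts.groups,
        )
        assert np.allclose(compute_tpm(scaled), tpm)


def z_oracle(y1, n1, y2, n2):
    """Pooled two-proportion z statistic, computed independently."""
    p1, p2 = y1 / n1, y2 / n2
    p = (y1 + y2) / (n1 + n2)
    se = math.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    return (p1 - p2) / se


class TestBaggerlyTest:
    def test_identical_groups_null(self):
        stat, p = baggerly_proportions_test([50], [1000], [50], [1000])
        assert stat == 0.0 and p == 1.0

    @pytest.mark.parametrize(
        "y1,n1,y2,n2",
        [(30, 1000, 60, 1200), (5, 500, 40, 800), (120, 10_000, 80, 9_000)],
    )
    def test_single_replicate_equals_two_proportion_z(self, y1, n1, y2, n2):
        stat, p = baggerly_proportions_test([y1], [n1], [y2], [n2])
        assert stat == pytest.approx(z_oracle(y1, n1, y2, n2), rel=1e-12)

    def test_antisymmetric_in_group_order(self):
        a = baggerly_proportions_test([30, 40], [1000, 1100], [80, 90], [1000, 1050])
        b = baggerly_proportions_test([80, 90], [1000, 1050], [30, 40], [1000, 1100])
        assert a[0] == pytest.approx(-b[0]) and a[1] == pytest.approx(b[1])

    def test_absent_transcript_p_one(self):
        stat, p = baggerly_proportions_test([0, 0], [100, 100], [0, 0], [100, 100])
        assert p == 1.0


class TestDifferentialExpression:
    def test_threshold_conjunction(self, small_counts):
        """A tiny p-value does not flag a transcript below the fold cutoff."""
        de = run_differential_expression(small_counts, "brain", "liver",
                                         fc_min=2.0, alpha=0.01)
        sub_threshold = de[(de.fold_change.abs() < 2.0) & de.tested]
        assert not sub_threshold.significant.any()
        # t1 is >2-fold between tissues and extreme: must be flagged
        assert de.loc["t1", "significant"]

    def test_bonferroni_flags_subset_of_raw(self, small_counts):
        de = run_differential_expression(small_counts, "brain", "liver")
        tested = de[de.tested]
        assert ((tested.p_bonferroni < 0.01) <= (tested.p_raw < 0.01)).all()

    def test_fold_change_sign_matches_proportions(self, small_counts):
        de = run_differential_expression(small_counts, "brain", "liver")
        up = de.proportion_g1 > de.proportion_g2
        down = de.proportion_g1 < de.proportion_g2
        assert (de.fold_change[up] > 0).all()
        assert (de.fold_change[down] < 0).all()


def enumeration_oracle(universe, annotated, drawn, observed):
    """P(X >= observed) by exhaustive enumeration of all draws."""
    items = range(universe)
    hits = 0
    total = 0
    for subset in itertools.combinations(items, drawn):
        total += 1
        if sum(1 for i in subset if i < annotated) >= observed:
            hits += 1
    return hits / total


class TestEnrichment:
    def run_one(self, universe, annotated, drawn, observed, **kw):
        uni = {f"g{i}" for i in range(universe)}
        ann = {"T": {f"g{i}" for i in range(annotated)}}
        flagged = {f"g{i}" for i in range(observed)} | {
            f"g{i}" for i in range(annotated, annotated + drawn - observed)
        }
        assert len(flagged) == drawn
        (res,) = hypergeometric_enrichment(flagged, uni, ann, **kw)
        return res

    def test_worked_example(self):
        res = self.run_one(10, 4, 5, 4)
        assert res.p_hypergeom == pytest.approx(6 / 252)

    def test_observed_zero_gives_p_one(self):
        res = self.run_one(10, 3, 4, 0)
        assert res.p_hypergeom == pytest.approx(1.0)

    def test_min_observed_is_strict(self):
        uni = {f"g{i}" for i in range(40)}
        ann = {"T": {f"g{i}" for i in range(5)}}
        flagged = {f"g{i}" for i in range(5)}
        (res,) = hypergeometric_enrichment(flagged, uni, ann, p_max=0.5,
                                           min_observed=5)
        assert res.observed == 5 and not res.over_represented

    @pytest.mark.parametrize("universe", [6, 9, 12])
    def test_matches_exhaustive_enumeration(self, universe):
        for annotated in range(1, universe):
            for drawn in range(1, universe):
                lo = max(0, drawn - (universe - annotated))
                for observed in range(lo, min(annotated, drawn) + 1):
                    res = self.run_one(universe, annotated, drawn, observed)
                    assert res.p_hypergeom == pytest.approx(
                        enumeration_oracle(universe, annotated, drawn, observed),
                        abs=1e-12,
                    ), (universe, annotated, drawn, observed)

    def test_term_annotating_nothing_skipped(self):
        out = hypergeometric_enrichment({"a"}, {"a", "b"}, {"T": {"zzz"}})
        assert out == []


class TestBootstrapClustering:
    @staticmethod
    def two_group_tpm(seed=0, n_genes=300):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(3, 1, size=(n_genes, 1))
        block = np.zeros((n_genes, 6))
        block[: n_genes // 2, :3] = 1.0
        block[n_genes // 2 :, 3:] = 1.0
        expr = base * (0.05 + block) * rng.lognormal(0, 0.05, size=(n_genes, 6))
        cols = ["a1", "a2", "a3", "b1", "b2", "b3"]
        return pd.DataFrame(expr, columns=cols)

    def test_separated_groups_get_high_support(self):
        tpm = self.two_group_tpm()
        res = bootstrap_average_linkage(tpm, n_boot=200, seed=1)
        bip = frozenset({"a1", "a2", "a3"})
        other = frozenset({"b1", "b2", "b3"})
        sup = max(res.support.get(bip, 0.0), res.support.get(other, 0.0))
        assert sup >= 95.0

    def test_supports_within_range_and_reproducible(self):
        tpm = self.two_group_tpm(seed=3)
        r1 = bootstrap_average_linkage(tpm, n_boot=50, seed=9)
        r2 = bootstrap_average_linkage(tpm, n_boot=50, seed=9)
        assert r1.support == r2.support
        assert all(0.0 <= v <= 100.0 for v in r1.support.values())
        assert r1.newick.endswith(";")

    def test_constant_sample_rejected(self):
        tpm = pd.DataFrame(
            {"a": [1.0, 1.0, 1.0], "b": [1, 2, 3], "c": [3, 1, 2]}
        )
        with pytest.raises(ValueError, match="'a'"):
            bootstrap_average_linkage(tpm, n_boot=5, seed=0)
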