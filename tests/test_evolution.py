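import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from transevol.evolution import (
    AMINO_ACIDS,
    AlignmentBlock,
    concatenate,
    count_motif,
    filter_columns,
    kaks_counting,
    select_121_orthologs,
    tajima_rrt,
)
from transevol.io import HitRecord


def hit(q, s, e=1e-60, bits=500.0):
    return HitRecord(q, s, 90.0, 100, 5, 0, 1, 100, 1, 100, e, bits)


class TestOrthologSelection:
    SPECIES = ["anchor", "sp1", "sp2"]

    def tables(self, extra=None):
        t = {
            ("anchor", "sp1"): [hit("g1", "a1")],
            ("sp1", "anchor"): [hit("a1", "g1")],
            ("anchor", "sp2"): [hit("g1", "b1")],
            ("sp2", "anchor"): [hit("b1", "g1")],
        }
        if extra:
            for k, v in extra.items():
                t[k] = t.get(k, []) + v
        return t

    def test_mutual_best_everywhere_selected(self):
        fams = select_121_orthologs(self.tables(), "anchor", self.SPECIES)
        assert fams == {"g1": {"anchor": "g1", "sp1": "a1", "sp2": "b1"}}

    def test_gene_missing_in_one_species_excluded(self):
        t = self.tables()
        t[("anchor", "sp2")] = []
        assert select_121_orthologs(t, "anchor", self.SPECIES) == {}

    def test_equal_best_coorthologs_excluded(self):
        """Two subjects tied on (e-value, bitscore) break the 1:1 ratio."""
        t = self.tables(extra={("anchor", "sp1"): [hit("g1", "a2")]})
        assert select_121_orthologs(t, "anchor", self.SPECIES) == {}

    def test_evalue_threshold_applied(self):
        t = self.tables()
        t[("anchor", "sp1")] = [hit("g1", "a1", e=1e-20)]
        assert select_121_orthologs(t, "anchor", self.SPECIES, e_max=1e-50) == {}

    def test_missing_table_is_error(self):
        t = self.tables()
        del t[("sp2", "anchor")]
        with pytest.raises(ValueError, match="sp2"):
            select_121_orthologs(t, "anchor", self.SPECIES)


class TestFilterColumns:
    def test_gap_free_block_unchanged(self):
        b = AlignmentBlock({"A": "MKVL", "B": "MKVL", "C": "MRVL"},
                           partitions={"g": (0, 4)})
        out = filter_columns(b)
        assert out.rows == b.rows and out.partitions == {"g": (0, 4)}

    def test_single_gap_column_removed_at_zero_tolerance(self):
        b = AlignmentBlock({"A": "M-VL", "B": "MKVL", "C": "MKVL"})
        out = filter_columns(b, max_gap_fraction=0.0)
        assert out.rows == {"A": "MVL", "B": "MVL", "C": "MVL"}

    def test_hand_filtered_toy_block(self):
        # columns: 0 ok, 1 gap in A, 2 ok, 3 gap in both, 4 X in C, 5 ok
        b = AlignmentBlock(
            {"A": "M-K-LT", "B": "MRK-LT", "C": "MRK-XT"},
            partitions={"g1": (0, 3), "g2": (3, 6)},
        )
        out = filter_columns(b, max_gap_fraction=0.0)
        assert out.rows == {"A": "MKT", "B": "MKT", "C": "MKT"}
        assert out.partitions == {"g1": (0, 2), "g2": (2, 3)}

    def test_all_columns_removed_flagged_empty(self):
        b = AlignmentBlock({"A": "--", "B": "MK", "C": "MK"})
        out = filter_columns(b)
        assert out.length == 0 and out.partitions == {}

    def test_never_increases_length(self):
        b = AlignmentBlock({"A": "M-KV", "B": "MKKV", "C": "MKK-"})
        assert filter_columns(b, max_gap_fraction=0.4).length <= b.length


class TestConcatenate:
    def test_lengths_and_partitions(self):
        b1 = AlignmentBlock({"A": "M" * 10, "B": "K" * 10}, {"g1": (0, 10)})
        b2 = AlignmentBlock({"A": "V" * 15, "B": "L" * 15}, {"g2": (0, 15)})
        out = concatenate([b1, b2])
        assert out.length == 25
        assert out.partitions == {"g1": (0, 10), "g2": (10, 25)}

    def test_single_block_identity(self):
        b = AlignmentBlock({"A": "MKV", "B": "MRV"}, {"g": (0, 3)})
        out = concatenate([b])
        assert out.rows == b.rows

    def test_rows_joined_by_name_not_position(self):
        b1 = AlignmentBlock({"A": "MM", "B": "KK"})
        b2 = AlignmentBlock({"B": "RR", "A": "VV"})  # reversed insertion order
        out = concatenate([b1, b2])
        assert out.rows["A"] == "MMVV" and out.rows["B"] == "KKRR"

    def test_taxon_mismatch_is_error(self):
        b1 = AlignmentBlock({"A": "M", "B": "K"})
        b2 = AlignmentBlock({"A": "M", "C": "K"})
        with pytest.raises(ValueError, match="C"):
            concatenate([b1, b2])


def rrt_site_oracle(a: str, b: str, c: str):
    """Brute-force per-site classification of the three-taxon patterns."""
    m1 = m2 = used = 0
    aa = set(AMINO_ACIDS)
    for x, y, z in zip(a.upper(), b.upper(), c.upper()):
        if {x, y, z} - aa:
            continue
        used += 1
        if y == z and x != y:
            m1 += 1
        elif x == z and y != x:
            m2 += 1
    return m1, m2, used


class TestTajimaRRT:
    def test_identical_rows_null(self):
        b = AlignmentBlock({"A": "MKVL", "B": "MKVL", "O": "MKVL"})
        r = tajima_rrt(b, "A", "B", "O")
        assert (r.m1, r.m2, r.chi2, r.p) == (0, 0, 0.0, 1.0)

    def test_ingroup_swap_symmetry(self):
        b = AlignmentBlock({"A": "MKVLAAWT", "B": "MRVLAAWS", "O": "MKVLAAWS"})
        r1 = tajima_rrt(b, "A", "B", "O")
        r2 = tajima_rrt(b, "B", "A", "O")
        assert (r1.m1, r1.m2) == (r2.m2, r2.m1)
        assert r1.chi2 == r2.chi2 and r1.p == r2.p

    def test_twelve_column_toy_matches_site_oracle(self):
        a = "MKVLA-WTXSDE"
        b = "MRVLAAWSXSDK"
        o = "MKVLAAWSYSDE"
        blk = AlignmentBlock({"A": a, "B": b, "O": o})
        r = tajima_rrt(blk, "A", "B", "O")
        m1, m2, used = rrt_site_oracle(a, b, o)
        assert (r.m1, r.m2, r.n_used) == (m1, m2, used)
        expected_chi2 = (m1 - m2) ** 2 / (m1 + m2)
        assert r.chi2 == pytest.approx(expected_chi2)
        assert r.p == pytest.approx(float(stats.chi2.sf(expected_chi2, 1)))

    def test_missing_taxon_is_error(self):
        b = AlignmentBlock({"A": "MK", "B": "MK", "O": "MK"})
        with pytest.raises(ValueError, match="Z"):
            tajima_rrt(b, "A", "Z", "O")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("MKVX-"), min_size=6, max_size=30),
           st.integers(0, 2**31 - 1))
    def test_random_columns_match_site_oracle(self, col_pool, seed):
        rng = np.random.default_rng(seed)
        n = len(col_pool)
        rows = ["".join(rng.choice(list("MKVX-"), n)) for _ in range(3)]
        blk = AlignmentBlock({"A": rows[0], "B": rows[1], "O": rows[2]})
        r = tajima_rrt(blk, "A", "B", "O")
        assert (r.m1, r.m2, r.n_used) == rrt_site_oracle(*rows)


CODON_TABLE = None


def _bio_translate(codon):
    from Bio.Seq import Seq
    return str(Seq(codon).translate())


def kaks_path_oracle(c1, c2):
    """Average syn/nonsyn differences over substitution orders, using the
    Biopython translation table as the independent genetic code."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in set(itertools.permutations(diff)):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _bio_translate(nxt) == "*":
                ok = False
                break
            if _bio_translate(nxt) == _bio_translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


class TestKaKs:
    PAD = "ATGGCTGCTAAGGATGAACGTCTTCCAGGT"  # 10 identical codons

    def test_identical_sequences(self):
        ka, ks, omega = kaks_counting(self.PAD, self.PAD)
        assert ka == 0.0 and ks == 0.0 and omega is None

    def test_single_synonymous_change(self):
        ka, ks, omega = kaks_counting(self.PAD + "GGG", self.PAD + "GGA")
        assert ka == 0.0 and ks > 0.0 and omega == 0.0

    def test_single_nonsynonymous_change(self):
        ka, ks, omega = kaks_counting(self.PAD + "ATG", self.PAD + "CTG")
        assert ks == 0.0 and ka > 0.0 and omega is None

    @pytest.mark.parametrize(
        "c1,c2", [("TTT", "TTA"), ("TTT", "CTA"), ("AAA", "AGG"),
                  ("GGG", "GAA"), ("ATG", "ATA"), ("CCC", "GCA")]
    )
    def test_two_position_codons_match_path_enumeration(self, c1, c2):
        from transevol.evolution import _path_differences
        assert _path_differences(c1, c2) == pytest.approx(kaks_path_oracle(c1, c2))

    def test_swap_invariance(self):
        s1 = self.PAD + "GGGTTTAAA"
        s2 = self.PAD + "GGATTGAGA"
        assert kaks_counting(s1, s2) == kaks_counting(s2, s1)

    def test_internal_stop_is_error_with_index(self):
        s1 = self.PAD[:9] + "TAA" + self.PAD[12:]
        with pytest.raises(ValueError, match="codon index 3"):
            kaks_counting(s1, self.PAD)

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="3"):
            kaks_counting("ATGG", "ATGG")


class TestMotif:
    def test_eleven_tandem_copies(self):
        count, _ = count_motif("CNPAADPAC" * 11)
        assert count == 11

    def test_second_position_alternatives(self):
        assert count_motif("CDPQQDPLC")[0] == 1
        assert count_motif("CQPQQDPLC")[0] == 0

    def test_overlapping_matches_counted(self):
        # windows at 0 and 4 both match: C N P C C|D P C C -> need engineered
        s = "CNPCCDPCCDPCC"
        count, positions = count_motif(s)
        brute = [
            i for i in range(len(s) - 8)
            if s[i] == "C" and s[i + 1] in "ND" and s[i + 2] == "P"
            and s[i + 5] == "D" and s[i + 6] == "P" and s[i + 8] == "C"
        ]
        assert positions == brute and count == len(brute) >= 2
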