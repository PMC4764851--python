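"""Molecular-evolution analyses on concatenated 1:1 ortholog alignments.

Provides 1:1 ortholog selection from reciprocal best hits against an anchor
species, gap-column filtering, column-wise concatenation into a supermatrix
with a partition map, Tajima's relative rate test on three-taxon
restrictions, a Nei–Gojobori counting estimator of Ka/Ks with Jukes–Cantor
correction, and a sliding-window scanner for the actinodin repeat motif
C(N/D)PXXDPXC.

Tajima's relative rate test compares the number of sites at which each of
two ingroup lineages carries a unique state (the other ingroup agreeing with
the outgroup).  Under rate equality the two counts m1 and m2 have equal
expectation, and (m1-m2)^2/(m1+m2) is asymptotically chi-square with 1
degree of freedom.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import stats

from .io import HitRecord

__all__ = [
    "AlignmentBlock",
    "RRTResult",
    "select_121_orthologs",
    "filter_columns",
    "concatenate",
    "tajima_rrt",
    "rrt_table",
    "kaks_counting",
    "count_motif",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


@dataclass
class AlignmentBlock:
    """Equal-length aligned residue rows keyed by taxon, with a partition map.

    ``partitions`` maps gene id -> (start, end) half-open column interval;
    intervals are disjoint, ordered, and cover at most the full length.
    """

    rows: dict[str, str]
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        prev_end = 0
        for gene, (start, end) in self.partitions.items():
            if not (prev_end <= start <= end <= self.length):
                raise ValueError(f"partition {gene!r} out of order or out of range")
            prev_end = end

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


# ---------------------------------------------------------------------------
# 1:1 ortholog selection


def _best_subjects(hits: list[HitRecord], e_max: float) -> dict[str, str | None]:
    """Best subject per query (min e-value, then max bitscore, then lexical
    subject id).  A tie after all criteria (same subject impossible) means
    co-orthologs: queries whose two best subjects are indistinguishable on
    (e-value, bitscore) map to ``None`` so 1:1 selection can reject them."""
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        if h.e_value <= e_max:
            by_query.setdefault(h.query_id, []).append(h)
    out: dict[str, str | None] = {}
    for q, hs in by_query.items():
        hs.sort(key=lambda h: (h.e_value, -h.bitscore, h.subject_id))
        best = hs[0]
        ambiguous = any(
            h.subject_id != best.subject_id
            and h.e_value == best.e_value
            and h.bitscore == best.bitscore
            for h in hs[1:]
        )
        out[q] = None if ambiguous else best.subject_id
    return out


def select_121_orthologs(
    hit_tables: dict[tuple[str, str], list[HitRecord]],
    anchor: str,
    species: list[str],
    e_max: float = 1e-50,
) -> dict[str, dict[str, str]]:
    """Select genes with exactly one member per species, via the anchor.

    ``hit_tables`` must contain, for every non-anchor species ``s``, the two
    directed tables ``(anchor, s)`` and ``(s, anchor)``.  An anchor gene is
    kept iff, in every species, it has an unambiguous reciprocal best hit at
    e-value <= ``e_max``.  Returns anchor gene id -> {species: member id}.
    """
    others = [s for s in species if s != anchor]
    best: dict[tuple[str, str], dict[str, str | None]] = {}
    for s in others:
        for pair in ((anchor, s), (s, anchor)):
            if pair not in hit_tables:
                raise ValueError(f"missing hit table for species pair {pair}")
            best[pair] = _best_subjects(hit_tables[pair], e_max)
    anchor_genes = set.intersection(
        *[set(best[(anchor, s)]) for s in others]
    ) if others else set()
    families: dict[str, dict[str, str]] = {}
    for g in sorted(anchor_genes):
        members = {anchor: g}
        for s in others:
            m = best[(anchor, s)].get(g)
            if m is None:  # ambiguous co-ortholog tie: not 1:1
                break
            if best[(s, anchor)].get(m) != g:  # not reciprocal
                break
            members[s] = m
        else:
            families[g] = members
    return families


# ---------------------------------------------------------------------------
# Alignment manipulation


def _is_missing(ch: str, alphabet: str) -> bool:
    if ch in "-.?*":
        return True
    if alphabet == "protein":
        return ch.upper() not in _AA_SET
    return ch.upper() not in "ACGT"


def filter_columns(
    block: AlignmentBlock,
    max_gap_fraction: float = 0.0,
    min_conservation: float | None = None,
) -> AlignmentBlock:
    """Drop alignment columns with too many gaps/ambiguities.

    A column is removed iff its gap/ambiguity fraction exceeds
    ``max_gap_fraction`` (the default 0.0 removes any column with a missing
    position), or, when ``min_conservation`` is given, the frequency of its
    most common resolved residue falls below that threshold.  The partition
    map is re-indexed to the surviving columns.
    """
    taxa = block.taxa
    arr = np.array([list(block.rows[t]) for t in taxa])
    missing = np.array(
        [[_is_missing(c, block.alphabet) for c in row] for row in arr]
    )
    keep = missing.mean(axis=0) <= max_gap_fraction
    if min_conservation is not None:
        n_taxa = len(taxa)
        for j in np.nonzero(keep)[0]:
            col = [c.upper() for c in arr[:, j][~missing[:, j]]]
            if not col or max(col.count(c) for c in set(col)) / n_taxa < min_conservation:
                keep[j] = False
    new_index = np.cumsum(keep) - 1
    rows = {t: "".join(arr[i, keep]) for i, t in enumerate(taxa)}
    partitions: dict[str, tuple[int, int]] = {}
    for gene, (start, end) in block.partitions.items():
        kept = keep[start:end].sum()
        if kept == 0:
            continue
        new_start = int(new_index[start:end][keep[start:end]][0])
        partitions[gene] = (new_start, new_start + int(kept))
    return AlignmentBlock(rows=rows, partitions=partitions, alphabet=block.alphabet)


def concatenate(blocks: list[AlignmentBlock]) -> AlignmentBlock:
    """Column-wise concatenation of per-gene blocks sharing one taxon set.

    Rows are joined by taxon name (row order within blocks is irrelevant);
    the partition map records each input block's column interval, named by
    its single partition key when present, else by position.
    """
    if not blocks:
        raise ValueError("no blocks to concatenate")
    taxa = set(blocks[0].rows)
    for b in blocks[1:]:
        if set(b.rows) != taxa:
            diff = set(b.rows) ^ taxa
            raise ValueError(f"taxon set mismatch: {sorted(diff)}")
    order = list(blocks[0].rows)
    rows = {t: "".join(b.rows[t] for b in blocks) for t in order}
    partitions: dict[str, tuple[int, int]] = {}
    offset = 0
    for i, b in enumerate(blocks):
        name = next(iter(b.partitions), f"block_{i}")
        partitions[name] = (offset, offset + b.length)
        offset += b.length
    return AlignmentBlock(rows=rows, partitions=partitions, alphabet=blocks[0].alphabet)


# ---------------------------------------------------------------------------
# Tajima relative rate test


@dataclass(frozen=True)
class RRTResult:
    ingroup1: str
    ingroup2: str
    outgroup: str
    m1: int
    m2: int
    n_used: int
    chi2: float
    p: float


def tajima_rrt(
    block: AlignmentBlock, ingroup1: str, ingroup2: str, outgroup: str
) -> RRTResult:
    """Tajima's relative rate test on a three-taxon restriction.

    Sites with a gap or ambiguity in any of the three rows are excluded.
    ``m1`` counts sites where ``ingroup1`` carries a unique state (ingroup2
    equals the outgroup); ``m2`` symmetrically.  ``chi2 = (m1-m2)^2/(m1+m2)``
    with 1 df; when ``m1+m2 == 0`` the test is undefined-null: chi2=0, p=1.
    """
    for name in (ingroup1, ingroup2, outgroup):
        if name not in block.rows:
            raise ValueError(f"taxon {name!r} not present in alignment")
    a, b, c = (
        np.frombuffer(block.rows[t].upper().encode(), dtype="S1")
        for t in (ingroup1, ingroup2, outgroup)
    )
    allowed = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    valid = np.isin(a, allowed) & np.isin(b, allowed) & np.isin(c, allowed)
    a, b, c = a[valid], b[valid], c[valid]
    m1 = int(((b == c) & (a != b)).sum())
    m2 = int(((a == c) & (b != a)).sum())
    if m1 + m2 > 0:
        chi2 = (m1 - m2) ** 2 / (m1 + m2)
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0
    return RRTResult(ingroup1, ingroup2, outgroup, m1, m2, int(valid.sum()), chi2, p)


def rrt_table(
    block: AlignmentBlock,
    focal: str,
    others: list[str],
    outgroups: list[str],
    alpha: float = 0.05,
):
    """Run the relative rate test for every (focal, other) pair under each
    outgroup; returns a list of ``(RRTResult, significant)`` rows."""
    rows = []
    for og in outgroups:
        for other in others:
            if other in (focal, og):
                continue
            res = tajima_rrt(block, focal, other, og)
            rows.append((res, res.p < alpha))
    return rows


# ---------------------------------------------------------------------------
# Nei–Gojobori counting Ka/Ks

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_BASES = "ACGT"


def _syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (changes to stops count as
    non-synonymous, per the standard counting convention)."""
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _CODON_TABLE[alt] == aa and _CODON_TABLE[alt] != "*":
                syn += 1
        s += syn / 3.0
    return s


def _path_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/non-synonymous difference counts over all shortest
    substitution paths between two codons, skipping paths through stops."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in set(permutations(diff_pos)):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_TABLE[nxt] == "*":
                blocked = True
                break
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:  # all paths pass through a stop: count every change as
        return 0.0, float(len(diff_pos))  # non-synonymous
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jc_correct(p: float) -> float:
    if p <= 0:
        return 0.0
    if p >= 0.75:
        raise ValueError(f"proportion of differences {p:.3f} saturates the "
                         "Jukes-Cantor correction")
    return -0.75 * float(np.log(1.0 - 4.0 * p / 3.0))


def kaks_counting(seq1: str, seq2: str) -> tuple[float, float, float | None]:
    """Nei–Gojobori counting estimate of (Ka, Ks, omega) for two in-frame CDSs.

    Synonymous/non-synonymous site counts are averaged over the two
    sequences; differences are averaged over all shortest substitution paths
    per codon; both proportions receive the Jukes–Cantor multiple-hit
    correction.  ``omega`` is None when Ks = 0.  Codons containing gaps or
    ambiguities are skipped; an internal stop raises with the codon index.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    if len(seq1) % 3:
        raise ValueError("length not divisible by 3")
    n_codons = len(seq1) // 3
    S = N = Sd = Nd = 0.0
    for i in range(n_codons):
        c1, c2 = seq1[3 * i : 3 * i + 3], seq2[3 * i : 3 * i + 3]
        if set(c1 + c2) - set(_BASES):
            continue
        if _CODON_TABLE[c1] == "*" or _CODON_TABLE[c2] == "*":
            if i < n_codons - 1:
                raise ValueError(f"internal stop codon at codon index {i}")
            continue  # terminal stop: excluded from counting
        s1, s2 = _syn_sites(c1), _syn_sites(c2)
        S += (s1 + s2) / 2.0
        N += 3.0 - (s1 + s2) / 2.0
        sd, nd = _path_differences(c1, c2)
        Sd += sd
        Nd += nd
    if S == 0 or N == 0:
        raise ValueError("no comparable codons")
    ks = _jc_correct(Sd / S)
    ka = _jc_correct(Nd / N)
    omega = (ka / ks) if ks > 0 else None
    return ka, ks, omega


# ---------------------------------------------------------------------------
# Actinodin repeat motif

def _motif_to_regex(pattern: str) -> str:
    # 'x'/'X' are wildcard positions; other letters are literal residues;
    # bracketed alternatives pass through.
    out = []
    in_brackets = False
    for ch in pattern:
        if ch == "[":
            in_brackets = True
            out.append(ch)
        elif ch == "]":
            in_brackets = False
            out.append(ch)
        elif ch in "xX" and not in_brackets:
            out.append(".")
        else:
            out.append(ch)
    return "".join(out)


def count_motif(sequence: str, pattern: str = "C[ND]PxxDPxC"):
    """Count (possibly overlapping) occurrences of a residue motif.

    Returns ``(count, positions)`` with 0-based match start positions; the
    default pattern is the 9-residue actinodin repeat C(N/D)PXXDPXC.
    """
    regex = re.compile(f"(?=({_motif_to_regex(pattern)}))")
    positions = [m.start() for m in regex.finditer(sequence.upper())]
    return len(positions), positions
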