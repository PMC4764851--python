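"""Gene-family (protein-domain) expansion detection.

Redundancy among focal-species proteins is first reduced by greedy
longest-first clustering at a stringent amino-acid identity threshold, so
splice variants, alleles and sequencing errors do not inflate domain
counts.  Each sufficiently abundant domain is then tested for
over-representation in the focal species against each reference species
group with a one-sided Grubbs outlier test on the pooled counts.

The Grubbs statistic for the focal (designated) observation is
``G = (x_focal - mean) / sd`` over the pooled sample of N values.  The
exact relation ``t = G * sqrt((N-2) / ((N-1)^2/N - G^2))`` maps G to a
Student-t variate with N-2 degrees of freedom, giving the one-sided
p-value; the critical value at level alpha is
``((N-1)/sqrt(N)) * sqrt(t_a^2 / (N-2+t_a^2))`` with ``t_a`` the upper-alpha
t quantile.  Because the outlying species is designated in advance (the
focal species), no Bonferroni factor of N is applied, so the per-domain
false-positive rate under the null is alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord
from scipy import stats

__all__ = [
    "cluster_reduce",
    "pairwise_identity",
    "GrubbsResult",
    "grubbs_one_sided",
    "grubbs_critical_value",
    "scan_expansions",
]


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matched columns / alignment columns.

    Uses a Needleman–Wunsch alignment (edit-distance optimal); identity is
    ``(alignment_length - edit_distance) / alignment_length``, i.e. matches
    over all alignment columns including gap columns.
    """
    if not seq_a or not seq_b:
        return 0.0
    res = edlib.align(seq_a.upper(), seq_b.upper(), mode="NW", task="path")
    aln_len = sum(int(n) for n in _cigar_lengths(res["cigar"]))
    return (aln_len - res["editDistance"]) / aln_len


def _cigar_lengths(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num
            num = ""


def cluster_reduce(
    proteins: list[SeqRecord], identity_min: float = 0.75
) -> list[SeqRecord]:
    """Greedy longest-first redundancy reduction at an identity threshold.

    Sequences are visited longest first; each joins the first existing
    representative with global identity >= ``identity_min``, otherwise it
    founds a new cluster.  Returns the representatives (cluster founders),
    longest first.
    """
    ordered = sorted(proteins, key=lambda r: (-len(r.seq), r.id))
    reps: list[SeqRecord] = []
    for rec in ordered:
        s = str(rec.seq)
        for rep in reps:
            if pairwise_identity(s, str(rep.seq)) >= identity_min:
                break
        else:
            reps.append(rec)
    return reps


# ---------------------------------------------------------------------------
# Grubbs outlier test (designated observation, one-sided upper)


@dataclass(frozen=True)
class GrubbsResult:
    G: float
    critical: float
    p_one_sided: float
    expanded: bool
    n: int
    testable: bool = True


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """One-sided critical value of G at level ``alpha`` for sample size n."""
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    t_a = stats.t.isf(alpha, n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t_a**2 / (n - 2 + t_a**2))


def grubbs_one_sided(
    focal: float, references: list[float], alpha: float = 0.05
) -> GrubbsResult:
    """One-sided (upper) Grubbs test of the focal value against references.

    The focal value is included in the pooled mean and standard deviation
    (classic Grubbs pooling).  ``expanded`` requires the focal value to be
    the pooled maximum and ``p_one_sided < alpha``.  A zero pooled standard
    deviation makes the domain untestable (``expanded=False``).
    """
    values = np.asarray([focal, *references], dtype=float)
    n = values.size
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 values (focal + references)")
    sd = values.std(ddof=1)
    if sd == 0:
        return GrubbsResult(
            G=0.0, critical=np.nan, p_one_sided=1.0, expanded=False, n=n,
            testable=False,
        )
    g = (focal - values.mean()) / sd
    g_max = (n - 1) / np.sqrt(n)  # algebraic maximum of |G|
    if abs(g) >= g_max:
        p = 0.0 if g > 0 else 1.0
    else:
        t_val = g * np.sqrt((n - 2) / ((n - 1) ** 2 / n - g**2))
        p = float(stats.t.sf(t_val, n - 2))
    crit = float(grubbs_critical_value(n, alpha))
    expanded = bool(focal >= values.max() and p < alpha and g > 0)
    return GrubbsResult(
        G=float(g), critical=crit, p_one_sided=p, expanded=expanded, n=n
    )


def scan_expansions(
    table: pd.DataFrame,
    focal: str,
    reference_groups: dict[str, list[str]],
    min_focal_count: int = 20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Scan a domains × species count table for focal-species expansions.

    Domains with focal count >= ``min_focal_count`` are tested against each
    reference group independently; the returned frame has one row per
    tested domain with per-group G/p/expanded columns, an
    ``expanded_in_all`` intersection column, and the number of domains
    tested (the caveat column: no multiple-testing correction is applied
    across domains).  Results are invariant to species and domain order.
    """
    if focal not in table.columns:
        raise ValueError(f"focal species {focal!r} not in table")
    for gname, members in reference_groups.items():
        if len(members) < 2:
            raise ValueError(f"reference group {gname!r} needs >= 2 species")
        missing = set(members) - set(table.columns)
        if missing:
            raise ValueError(f"species {sorted(missing)} missing from table")
    tested = table.index[table[focal] >= min_focal_count]
    rows = []
    group_names = sorted(reference_groups)
    for dom in sorted(tested):
        row: dict = {"domain": dom, "focal_count": int(table.at[dom, focal])}
        flags = []
        for gname in group_names:
            refs = [float(table.at[dom, sp]) for sp in sorted(reference_groups[gname])]
            res = grubbs_one_sided(float(table.at[dom, focal]), refs, alpha=alpha)
            row[f"G_{gname}"] = res.G
            row[f"p_{gname}"] = res.p_one_sided
            row[f"expanded_{gname}"] = res.expanded
            flags.append(res.expanded)
        row["expanded_in_all"] = all(flags)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("domain") if rows else pd.DataFrame(
        columns=["focal_count"]
    )
    out.attrs["n_domains_tested"] = len(tested)
    out.attrs["alpha"] = alpha
    return out
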