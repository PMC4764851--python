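"""Reciprocal-best-hit orthology and ortholog-hit-ratio assembly integrity.

The ortholog hit ratio (OHR) of an assembled transcript is the fraction of
its orthologous reference gene covered by the transcript's best similarity
hit — a proxy for transcript completeness.  Integrity of a whole assembly
is summarized as the share of high-identity ortholog pairs whose OHR
reaches a full-length cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import HitRecord

__all__ = [
    "OrthologPair",
    "IntegritySummary",
    "reciprocal_best_hits",
    "ortholog_hit_ratio",
    "merged_hit_ratio",
    "integrity_summary",
]


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit pair between an assembly (a) and a reference (b)."""

    id_a: str
    id_b: str
    percent_identity: float
    e_value_ab: float
    e_value_ba: float
    ohr: float | None = None

    def __post_init__(self) -> None:
        if self.ohr is not None and not (0.0 <= self.ohr <= 1.0):
            raise ValueError(f"ohr {self.ohr} outside [0, 1]")


def _best_hit_per_query(hits: list[HitRecord]) -> dict[str, HitRecord]:
    """Deterministic best hit per query: minimal e-value, ties broken by
    maximal bitscore, then lexicographic subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.e_value, -h.bitscore, h.subject_id) < (
            cur.e_value,
            -cur.bitscore,
            cur.subject_id,
        ):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab: list[HitRecord], hits_ba: list[HitRecord]
) -> list[OrthologPair]:
    """Pairs (a, b) where b is a's best subject and a is b's best subject."""
    best_ab = _best_hit_per_query(hits_ab)
    best_ba = _best_hit_per_query(hits_ba)
    pairs = []
    for a, hab in sorted(best_ab.items()):
        hba = best_ba.get(hab.subject_id)
        if hba is not None and hba.subject_id == a:
            pairs.append(
                OrthologPair(
                    id_a=a,
                    id_b=hab.subject_id,
                    percent_identity=hab.percent_identity,
                    e_value_ab=hab.e_value,
                    e_value_ba=hba.e_value,
                )
            )
    return pairs


def ortholog_hit_ratio(hit: HitRecord, ortholog_length: int) -> float:
    """Fraction of the ortholog covered by the hit's subject interval.

    ``(s_end - s_start + 1) / ortholog_length``, capped at 1.0.
    """
    if ortholog_length <= 0:
        raise ValueError(f"ortholog_length must be positive, got {ortholog_length}")
    lo, hi = sorted((hit.s_start, hit.s_end))
    return min(1.0, (hi - lo + 1) / ortholog_length)


def merged_hit_ratio(hits: list[HitRecord], ortholog_length: int) -> float:
    """OHR variant merging all subject intervals of a query before measuring
    coverage (optional; the default integrity path uses the single best hit)."""
    if ortholog_length <= 0:
        raise ValueError("ortholog_length must be positive")
    intervals = sorted(tuple(sorted((h.s_start, h.s_end))) for h in hits)
    covered = 0
    cur_lo, cur_hi = None, None
    for lo, hi in intervals:
        if cur_hi is None or lo > cur_hi + 1:
            if cur_hi is not None:
                covered += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        covered += cur_hi - cur_lo + 1
    return min(1.0, covered / ortholog_length)


@dataclass(frozen=True)
class IntegritySummary:
    n_pairs_total: int
    n_pairs_used: int
    fraction_full_length: float | None  # None when no pair passes the filter
    histogram_edges: tuple[float, ...]
    histogram_counts: tuple[int, ...]


def integrity_summary(
    pairs: list[OrthologPair],
    identity_min: float = 90.0,
    full_length_min: float = 0.8,
    n_bins: int = 10,
) -> IntegritySummary:
    """Share of full-length transcripts among high-identity ortholog pairs.

    Only pairs with ``percent_identity > identity_min`` (strict, to limit
    the divergence-driven underestimate of coverage) enter the summary;
    ``fraction_full_length`` is the share of those with OHR >=
    ``full_length_min``.  Every pair must carry a computed OHR.
    """
    if any(p.ohr is None for p in pairs):
        raise ValueError("all pairs must carry a computed ohr")
    used = [p for p in pairs if p.percent_identity > identity_min]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if not used:
        return IntegritySummary(
            n_pairs_total=len(pairs),
            n_pairs_used=0,
            fraction_full_length=None,
            histogram_edges=tuple(edges),
            histogram_counts=tuple([0] * n_bins),
        )
    ohrs = np.array([p.ohr for p in used])
    counts, _ = np.histogram(ohrs, bins=edges)
    return IntegritySummary(
        n_pairs_total=len(pairs),
        n_pairs_used=len(used),
        fraction_full_length=float((ohrs >= full_length_min).mean()),
        histogram_edges=tuple(edges),
        histogram_counts=tuple(int(c) for c in counts),
    )
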