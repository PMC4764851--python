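"""Repeat-library filtering and transposable-element transcription summaries.

Three stages: false-positive filtering of a de novo repeat library (drop
candidates matching host proteomes or carrying non-TE protein domains,
re-including those whose domains are TE-diagnostic); RepeatMasker-style
summary tables of repeat hits on a transcriptome (element counts, merged
base pairs, percentages of scanned sequence); and a cross-species TE
transcription activity statistic in which the per-million scaling factor is
computed on a calibration set of unequivocal orthologous genes rather than
on the whole transcriptome, making activities comparable across species
with different transcriptome sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .io import RepeatHit

__all__ = [
    "RepeatCandidate",
    "filter_repeat_library",
    "ClassStat",
    "RepeatSummary",
    "summarize_repeat_hits",
    "compose_summary",
    "calibrated_te_activity",
]


@dataclass(frozen=True)
class RepeatCandidate:
    """A de novo repeat-library candidate with precomputed evidence."""

    id: str
    sequence: str
    proteome_hit: bool = False
    domains: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"candidate {self.id!r} has empty sequence")


def filter_repeat_library(
    candidates: list[RepeatCandidate],
    te_domain_whitelist: set[str],
    min_length: int = 100,
) -> list[RepeatCandidate]:
    """False-positive filtering of a de novo repeat library.

    A candidate is retained iff it is longer than ``min_length`` (strict)
    AND either shows no host-proteome match and no protein domain, or
    carries at least one TE-diagnostic domain from the whitelist (the
    re-inclusion rule, which overrides both removal rules).
    """
    whitelist = set(te_domain_whitelist)
    kept = []
    for c in candidates:
        if len(c.sequence) <= min_length:
            continue
        clean = not c.proteome_hit and not c.domains
        reincluded = bool(set(c.domains) & whitelist)
        if clean or reincluded:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# Summary tables


def _merge_bp(intervals: list[tuple[int, int]]) -> int:
    """Total bases covered by 1-based inclusive intervals after merging."""
    total = 0
    cur_lo = cur_hi = None
    for lo, hi in sorted(intervals):
        if cur_hi is None or lo > cur_hi + 1:
            if cur_hi is not None:
                total += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        total += cur_hi - cur_lo + 1
    return total


@dataclass
class ClassStat:
    n_elements: int
    bp: int
    subfamilies: dict[str, "ClassStat"] = field(default_factory=dict)


@dataclass
class RepeatSummary:
    """Per-class repeat statistics plus derived totals and percentages."""

    classes: dict[str, ClassStat]
    scanned_bp: int
    masked_bp: int
    table: pd.DataFrame | None = None


def _pct(bp: int, scanned_bp: int) -> float:
    """Percentage of scanned bases, rounded half-up to 2 decimals (the
    rounding used by RepeatMasker-style summary tables)."""
    raw = Decimal(bp) / Decimal(scanned_bp) * 100
    return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


#: Row vocabulary of the summary table, in print order.  The retroelement
#: block aggregates SINEs, LINEs and LTR elements; "Total interspersed"
#: aggregates retroelements, DNA transposons and unclassified repeats.
_RETRO_CLASSES = ("SINE", "LINE", "LTR")
_INTERSPERSED_CLASSES = ("SINE", "LINE", "LTR", "DNA", "Retroelement", "Unclassified")
_TANDEM_CLASSES = ("SmallRNA", "Satellite", "SimpleRepeat", "LowComplexity")
_ROW_LABELS = {
    "SINE": "SINEs:",
    "LINE": "LINEs:",
    "LTR": "LTR elements:",
    "DNA": "DNA transposons",
    "Retroelement": "Retroelements (unresolved):",
    "Unclassified": "Unclassified:",
    "SmallRNA": "Small RNA:",
    "Satellite": "Satellites:",
    "SimpleRepeat": "Simple repeats:",
    "LowComplexity": "Low complexity:",
}


def compose_summary(
    classes: dict[str, ClassStat], scanned_bp: int, masked_bp: int
) -> RepeatSummary:
    """Derive the full summary table from per-class (leaf) statistics.

    Adds the derived rows: the retroelement aggregate (SINE + LINE + LTR),
    the interspersed-repeat total, and the overall masked percentage.  Class
    rows may carry subfamily breakdowns that sum to at most the class total
    (an implicit remainder of unlisted subfamilies is allowed).
    """
    if scanned_bp <= 0:
        raise ValueError("scanned_bp must be positive")
    rows = []

    def add(label, n, bp, indent=0):
        rows.append(
            {
                "category": ("  " * indent) + label,
                "n_elements": n,
                "bp": bp,
                "pct": _pct(bp, scanned_bp),
            }
        )

    retro_n = sum(classes[c].n_elements for c in _RETRO_CLASSES if c in classes)
    retro_bp = sum(classes[c].bp for c in _RETRO_CLASSES if c in classes)
    add("Retroelements", retro_n, retro_bp)
    for cls in _RETRO_CLASSES:
        if cls not in classes:
            continue
        st = classes[cls]
        add(_ROW_LABELS[cls], st.n_elements, st.bp, indent=1)
        for sub, sst in st.subfamilies.items():
            add(sub, sst.n_elements, sst.bp, indent=2)
    for cls in ("DNA", "Retroelement", "Unclassified"):
        if cls not in classes:
            continue
        st = classes[cls]
        add(_ROW_LABELS[cls], st.n_elements, st.bp)
        for sub, sst in st.subfamilies.items():
            add(sub, sst.n_elements, sst.bp, indent=1)
    inter_bp = sum(classes[c].bp for c in _INTERSPERSED_CLASSES if c in classes)
    rows.append(
        {
            "category": "Total interspersed repeats:",
            "n_elements": None,
            "bp": inter_bp,
            "pct": _pct(inter_bp, scanned_bp),
        }
    )
    for cls in _TANDEM_CLASSES:
        if cls not in classes:
            continue
        st = classes[cls]
        add(_ROW_LABELS[cls], st.n_elements, st.bp)
    rows.append(
        {
            "category": "Total masked:",
            "n_elements": None,
            "bp": masked_bp,
            "pct": _pct(masked_bp, scanned_bp),
        }
    )
    table = pd.DataFrame(rows, columns=["category", "n_elements", "bp", "pct"])
    return RepeatSummary(
        classes=classes, scanned_bp=scanned_bp, masked_bp=masked_bp, table=table
    )


def summarize_repeat_hits(
    hits: list[RepeatHit],
    scanned_bp: int,
    transcript_lengths: dict[str, int],
) -> RepeatSummary:
    """Summarize repeat hits into a RepeatMasker-style table.

    Element counts are raw hit counts; base-pair totals merge overlapping
    same-class intervals per transcript (subfamily totals merge within the
    subfamily); ``masked_bp`` counts each base once across all classes.
    Percentages are computed against ``scanned_bp``.
    """
    if scanned_bp <= 0:
        raise ValueError("scanned_bp must be positive")
    by_class: dict[str, dict] = {}
    all_intervals: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        tl = transcript_lengths.get(h.query_id)
        if tl is None:
            raise ValueError(f"hit on unknown transcript {h.query_id!r}")
        if h.end > tl:
            raise ValueError(
                f"hit end {h.end} exceeds length {tl} of {h.query_id!r}"
            )
        cls = by_class.setdefault(
            h.repeat_class, {"n": 0, "intervals": {}, "subfamilies": {}}
        )
        cls["n"] += 1
        cls["intervals"].setdefault(h.query_id, []).append((h.begin, h.end))
        if h.subfamily:
            sub = cls["subfamilies"].setdefault(
                h.subfamily, {"n": 0, "intervals": {}}
            )
            sub["n"] += 1
            sub["intervals"].setdefault(h.query_id, []).append((h.begin, h.end))
        all_intervals.setdefault(h.query_id, []).append((h.begin, h.end))
    classes: dict[str, ClassStat] = {}
    for name, data in by_class.items():
        bp = sum(_merge_bp(iv) for iv in data["intervals"].values())
        subfams = {
            s: ClassStat(
                n_elements=sd["n"],
                bp=sum(_merge_bp(iv) for iv in sd["intervals"].values()),
            )
            for s, sd in sorted(data["subfamilies"].items())
        }
        classes[name] = ClassStat(n_elements=data["n"], bp=bp, subfamilies=subfams)
    masked_bp = sum(_merge_bp(iv) for iv in all_intervals.values())
    return compose_summary(classes, scanned_bp, masked_bp)


# ---------------------------------------------------------------------------
# Calibrated cross-species TE activity


def calibrated_te_activity(
    cm: CountMatrix,
    te_ids: dict[str, str],
    calibration_ids: set[str],
) -> pd.DataFrame:
    """Cumulative per-class TE expression calibrated on orthologous genes.

    Per sample, the per-million scaling factor is the summed per-base read
    rate of the calibration genes only (the "reduced transcriptome"), so the
    statistic is invariant to overall library scaling and to transcriptome
    content outside the calibration set.  Each TE element contributes
    ``1e6 * (count/length) / S`` and class activity is the sum over the
    class's elements.  Returns a classes × samples DataFrame.
    """
    idx = set(cm.counts.index)
    missing = set(calibration_ids) - idx
    if missing:
        raise ValueError(f"calibration genes absent from counts: {sorted(missing)[:3]}")
    if set(te_ids) & set(calibration_ids):
        raise ValueError("TE set and calibration set must be disjoint")
    missing_te = set(te_ids) - idx
    if missing_te:
        raise ValueError(f"TE elements absent from counts: {sorted(missing_te)[:3]}")
    cal = sorted(calibration_ids)
    rates = cm.counts.div(cm.lengths, axis=0)
    scaling = rates.loc[cal].sum(axis=0)
    zero = scaling[scaling == 0]
    if len(zero):
        raise ValueError(
            f"sample {zero.index[0]!r}: calibration genes have zero counts"
        )
    te_list = sorted(te_ids)
    activity = rates.loc[te_list].div(scaling, axis=1) * 1e6
    activity["te_class"] = [te_ids[t] for t in te_list]
    out = activity.groupby("te_class").sum()
    out.index.name = "te_class"
    return out
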