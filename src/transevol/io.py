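"""Readers and writers for the tabular and sequence formats the pipeline touches.

Covers FASTA sequence sets, 12-column tabular similarity-hit files (the
``blastn -outfmt 6`` dialect), and RepeatMasker ``.out`` repeat-hit files.
All file coordinates are 1-based inclusive, following the conventions of the
source formats; conversion to half-open intervals happens only inside length
arithmetic elsewhere in the package.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "HitRecord",
    "RepeatHit",
    "ParseError",
    "REPEAT_CLASSES",
    "REPEATMASKER_CLASS_MAP",
    "read_fasta",
    "write_fasta",
    "read_hit_table",
    "write_hit_table",
    "parse_repeatmasker_out",
    "write_repeatmasker_out",
]


class ParseError(ValueError):
    """Raised when a data line does not conform to its declared dialect."""


#: Canonical repeat-class vocabulary used throughout the mobilome summaries.
REPEAT_CLASSES = (
    "SINE",
    "LINE",
    "LTR",
    "DNA",
    "Retroelement",
    "Unclassified",
    "SmallRNA",
    "Satellite",
    "SimpleRepeat",
    "LowComplexity",
)

#: Editable mapping from RepeatMasker class labels onto the canonical
#: vocabulary.  Canonical names map to themselves so that files written by
#: this package round-trip.  Users may add entries for custom libraries.
REPEATMASKER_CLASS_MAP: dict[str, str] = {
    **{c: c for c in REPEAT_CLASSES},
    "SINE?": "SINE",
    "LINE?": "LINE",
    "LTR?": "LTR",
    "DNA?": "DNA",
    "RC": "DNA",
    "Retroposon": "Retroelement",
    "Unknown": "Unclassified",
    "Unspecified": "Unclassified",
    "ARTEFACT": "Unclassified",
    "snRNA": "SmallRNA",
    "scRNA": "SmallRNA",
    "srpRNA": "SmallRNA",
    "tRNA": "SmallRNA",
    "rRNA": "SmallRNA",
    "Simple_repeat": "SimpleRepeat",
    "Low_complexity": "LowComplexity",
}


@dataclass(frozen=True)
class HitRecord:
    """One pairwise sequence-similarity hit (12-column tabular dialect)."""

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.e_value < 0:
            raise ValueError(f"e_value {self.e_value} negative")


@dataclass(frozen=True)
class RepeatHit:
    """One masked interval on a transcript, with repeat name and class.

    ``begin``/``end`` are 1-based inclusive transcript coordinates with
    ``begin <= end`` (complement-strand hits are normalized; strand is not
    retained because the downstream analysis is transcript-level and
    strandless).
    """

    query_id: str
    begin: int
    end: int
    repeat_name: str
    repeat_class: str
    subfamily: str = ""
    divergence_pct: float = 0.0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.begin > self.end:
            raise ValueError(f"begin {self.begin} > end {self.end}")

    @property
    def span(self) -> int:
        return self.end - self.begin + 1


# ---------------------------------------------------------------------------
# FASTA


def _as_handle(source) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source)
    return source


def read_fasta(source, alphabet: str | None = None) -> list[SeqRecord]:
    """Read a FASTA file into a list of Biopython ``SeqRecord`` objects.

    Enforces the sequence-set invariants: non-empty, unique ids and non-empty
    sequences.  ``alphabet`` may be ``"nucleotide"`` or ``"protein"`` to
    request a consistency check.
    """
    handle = _as_handle(source)
    records = list(SeqIO.parse(handle, "fasta"))
    seen: set[str] = set()
    for rec in records:
        if not rec.id:
            raise ParseError("record with empty id")
        if rec.id in seen:
            raise ParseError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise ParseError(f"empty sequence for id {rec.id!r}")
        if alphabet == "nucleotide":
            bad = set(str(rec.seq).upper()) - set("ACGTUNRYSWKMBDHV-")
            if bad:
                raise ParseError(f"non-nucleotide characters {bad} in {rec.id!r}")
    return records


def write_fasta(records: Iterable[SeqRecord], destination) -> None:
    handle = destination
    close = False
    if isinstance(destination, (str, Path)):
        handle = open(destination, "w")
        close = True
    try:
        SeqIO.write(records, handle, "fasta")
    finally:
        if close:
            handle.close()


def make_record(seq_id: str, sequence: str, description: str = "") -> SeqRecord:
    return SeqRecord(Seq(sequence), id=seq_id, description=description)


# ---------------------------------------------------------------------------
# 12-column tabular hits


def read_hit_table(source) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table; '#' comment lines skipped."""
    handle = _as_handle(source)
    records: list[HitRecord] = []
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise ParseError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            rec = HitRecord(
                query_id=fields[0],
                subject_id=fields[1],
                percent_identity=float(fields[2]),
                aln_length=int(fields[3]),
                mismatches=int(fields[4]),
                gap_opens=int(fields[5]),
                q_start=int(fields[6]),
                q_end=int(fields[7]),
                s_start=int(fields[8]),
                s_end=int(fields[9]),
                e_value=float(fields[10]),
                bitscore=float(fields[11]),
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_hit_table(hits: Iterable[HitRecord], destination) -> None:
    handle = destination
    close = False
    if isinstance(destination, (str, Path)):
        handle = open(destination, "w")
        close = True
    try:
        for h in hits:
            handle.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        h.aln_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        f"{h.e_value:.3g}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER_TOKENS = {"SW", "score"}


def _map_class(label: str) -> tuple[str, str]:
    """Split a RepeatMasker 'class/subfamily' label and map to the canonical
    class vocabulary."""
    if "/" in label:
        cls, sub = label.split("/", 1)
    else:
        cls, sub = label, ""
    mapped = REPEATMASKER_CLASS_MAP.get(cls)
    if mapped is None:
        mapped = "Unclassified"
    return mapped, sub


def parse_repeatmasker_out(
    source, transcript_lengths: dict[str, int] | None = None
) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` file into :class:`RepeatHit` records.

    The dialect has two header lines plus one blank line, then
    whitespace-delimited data columns::

        SW_score div% del% ins% query begin end (left) strand repeat class/family ...

    Complement-strand hits ('C') are normalized so ``begin <= end``.  When
    ``transcript_lengths`` is supplied, each hit is checked against the
    length of its transcript.
    """
    handle = _as_handle(source)
    hits: list[RepeatHit] = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if fields[0] in _RM_HEADER_TOKENS:
            continue
        if len(fields) < 11:
            raise ParseError(
                f"line {lineno}: expected >=11 whitespace-delimited columns, "
                f"got {len(fields)}"
            )
        try:
            score = float(fields[0])
            divergence = float(fields[1])
            begin = int(fields[5])
            end = int(fields[6])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric field ({exc})") from exc
        query = fields[4]
        strand = fields[8]
        if strand not in {"+", "C"}:
            raise ParseError(f"line {lineno}: unexpected strand field {strand!r}")
        if begin > end:
            begin, end = end, begin
        repeat_name = fields[9]
        repeat_class, subfamily = _map_class(fields[10])
        if transcript_lengths is not None:
            tl = transcript_lengths.get(query)
            if tl is None:
                raise ParseError(f"line {lineno}: unknown transcript {query!r}")
            if end > tl:
                raise ParseError(
                    f"line {lineno}: hit end {end} exceeds length {tl} of {query!r}"
                )
        hits.append(
            RepeatHit(
                query_id=query,
                begin=begin,
                end=end,
                repeat_name=repeat_name,
                repeat_class=repeat_class,
                subfamily=subfamily,
                divergence_pct=divergence,
                score=score,
            )
        )
    return hits


def write_repeatmasker_out(hits: Iterable[RepeatHit], destination) -> None:
    """Write hits in the RepeatMasker ``.out`` dialect (canonical class names).

    Parsing the written stream yields an identical record list (round-trip
    property); deletion/insertion percentages and repeat-side coordinates,
    which the hit model does not retain, are written as zeros.
    """
    handle = destination
    close = False
    if isinstance(destination, (str, Path)):
        handle = open(destination, "w")
        close = True
    try:
        handle.write(
            "   SW   perc perc perc  query     position in query    matching"
            "  repeat          position in repeat\n"
            "score   div. del. ins.  sequence  begin end     (left) repeat"
            "  class/family    begin  end    (left)  ID\n\n"
        )
        for i, h in enumerate(hits, start=1):
            label = h.repeat_class + (f"/{h.subfamily}" if h.subfamily else "")
            handle.write(
                f"{h.score:7.0f} {h.divergence_pct:5.1f}  0.0  0.0  "
                f"{h.query_id}  {h.begin}  {h.end}  (0)  +  "
                f"{h.repeat_name}  {label}  1  {h.span}  (0)  {i}\n"
            )
    finally:
        if close:
            handle.close()


def hits_roundtrip(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Write then re-parse a hit list (convenience used by the round-trip
    property tests)."""
    buf = _stdio.StringIO()
    write_repeatmasker_out(hits, buf)
    buf.seek(0)
    return parse_repeatmasker_out(buf)
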