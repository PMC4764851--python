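"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: transcript sets
with planted TE-derived segments (emitted as repeat hits), overdispersed
count matrices with tissue structure and planted fold changes, ortholog
hit tables with controlled truncation, domain-count tables with planted
expansions, and tree-evolved protein alignments with per-lineage rate
multipliers.  All generators are pure functions of (config, seed).

The generators emulate the statistical structure the analyses assume —
beta-binomial counts for the proportions test, negative-binomial domain
counts for the outlier scan, an exchangeable 20-state substitution process
for the relative rate test — not sequencing-level realism (no read
simulation, no error models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evolution import AMINO_ACIDS, AlignmentBlock
from .expression import CountMatrix
from .io import HitRecord, RepeatHit, make_record

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "te_consensus_library",
    "simulate_transcriptome",
    "simulate_counts",
    "simulate_ortholog_pairs",
    "evolve_alignment",
    "simulate_domain_tables",
]

_DEFAULT_GROUPS = {
    "brain_m": "brain",
    "brain_f": "brain",
    "brain_j": "brain",
    "liver_m": "liver",
    "liver_f": "liver",
    "liver_j": "liver",
}

#: TE classes carried by the packaged synthetic consensus library.
TE_CLASSES = ("LINE", "SINE", "LTR", "DNA", "Retroelement")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions the analyses were designed around:
    contigs of at least 250 nt with a log-normal length distribution, a few
    percent of transcripts carrying a TE segment, two tissues with three
    libraries each, million-read libraries with beta-binomial
    overdispersion, and a small set of strongly expressed/expanded planted
    signals for power checks.
    """

    n_transcripts: int = 2000
    length_meanlog: float = 7.1
    length_sdlog: float = 0.7
    min_length: int = 250
    te_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "LINE": 0.025,
            "DNA": 0.018,
            "SINE": 0.008,
            "LTR": 0.005,
            "Retroelement": 0.004,
        }
    )
    groups: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_GROUPS))
    library_size: int = 1_000_000
    overdispersion_cv: float = 0.3
    # relative expression multiplier per TE class (emulating the observed
    # activity ordering: LTR elements most transcribed, then LINEs, DNA
    # transposons, SINEs, unresolved retroelements)
    te_class_expression: dict[str, float] = field(
        default_factory=lambda: {
            "LTR": 4.0,
            "LINE": 2.0,
            "DNA": 1.0,
            "SINE": 0.5,
            "Retroelement": 0.25,
        }
    )
    n_de: int = 50
    de_fold: float = 8.0
    n_domains: int = 150
    n_reference_species: int = 9
    n_planted_expansions: int = 5
    expansion_factor: float = 10.0
    nb_dispersion: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0 or self.min_length <= 0:
            raise ValueError("counts must be positive")
        total = sum(self.te_fraction.values())
        if any(f < 0 or f > 1 for f in self.te_fraction.values()) or total > 1:
            raise ValueError(
                f"te_fraction values must lie in [0,1] and sum to <= 1 (sum={total})"
            )
        unknown = set(self.te_fraction) - set(TE_CLASSES)
        if unknown:
            raise ValueError(f"unknown TE classes {sorted(unknown)}")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.overdispersion_cv < 0:
            raise ValueError("overdispersion_cv must be >= 0")
        if self.n_reference_species < 3:
            raise ValueError("need at least 3 reference species for the outlier scan")


@dataclass
class SyntheticTruth:
    """Hidden generator parameters, sufficient to score every downstream stage."""

    transcript_lengths: dict[str, int] = field(default_factory=dict)
    te_class: dict[str, str] = field(default_factory=dict)  # transcript -> class
    repeat_hits: list[RepeatHit] = field(default_factory=list)
    proportions: pd.DataFrame | None = None  # transcripts x groups (read proportions)
    de_genes: dict[str, float] = field(default_factory=dict)  # id -> signed fold
    truncated_pairs: set[str] = field(default_factory=set)
    expanded_domains: set[str] = field(default_factory=set)
    species_groups: dict[str, list[str]] = field(default_factory=dict)
    rate_multipliers: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Per-transcript truth as a tidy table (serializable as TSV)."""
        ids = sorted(self.transcript_lengths)
        return pd.DataFrame(
            {
                "transcript": ids,
                "length": [self.transcript_lengths[i] for i in ids],
                "te_class": [self.te_class.get(i, "") for i in ids],
                "de_fold": [self.de_genes.get(i, 0.0) for i in ids],
            }
        )


# ---------------------------------------------------------------------------
# TE consensus library (packaged, deterministic)


def te_consensus_library(
    n_per_class: int = 3, length: int = 1500
) -> dict[str, list[tuple[str, str]]]:
    """Deterministic synthetic consensus sequences per TE class.

    Returns class -> list of (name, sequence).  The library is a fixed
    pseudorandom artifact (seeded independently of any simulation seed) so
    that planted repeat-hit truth is exact and reproducible across runs.
    """
    rng = np.random.default_rng(20160224)
    lib: dict[str, list[tuple[str, str]]] = {}
    for cls in TE_CLASSES:
        entries = []
        for i in range(1, n_per_class + 1):
            seq = "".join(rng.choice(list("ACGT"), size=length))
            entries.append((f"{cls}-syn{i}", seq))
        lib[cls] = entries
    return lib


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


_DNA = np.array(list("ACGT"))


def simulate_transcriptome(config: SimConfig, seed: int | None = None):
    """Generate transcripts with planted TE-derived segments.

    Returns ``(records, repeat_hits, truth)``: Biopython sequence records of
    length >= ``config.min_length``; one :class:`RepeatHit` per planted TE
    segment; and the truth object recording every transcript's length and
    planted class.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lib = te_consensus_library()
    classes = list(config.te_fraction)
    probs = [config.te_fraction[c] for c in classes] + [
        1.0 - sum(config.te_fraction.values())
    ]
    lengths = np.maximum(
        config.min_length,
        np.rint(
            rng.lognormal(config.length_meanlog, config.length_sdlog,
                          size=config.n_transcripts)
        ).astype(int),
    )
    assignment = rng.choice(len(classes) + 1, size=config.n_transcripts, p=probs)
    width = len(str(config.n_transcripts))
    records, hits = [], []
    truth = SyntheticTruth()
    for i in range(config.n_transcripts):
        tid = f"contig_{i + 1:0{width}d}"
        tlen = int(lengths[i])
        seq = _random_dna(rng, tlen)
        truth.transcript_lengths[tid] = tlen
        if assignment[i] < len(classes):
            cls = classes[assignment[i]]
            name, consensus = lib[cls][rng.integers(0, len(lib[cls]))]
            seg_len = int(min(tlen, len(consensus), rng.integers(150, 601)))
            c_start = int(rng.integers(0, len(consensus) - seg_len + 1))
            t_start = int(rng.integers(0, tlen - seg_len + 1))
            segment = np.array(
                [_DNA.tolist().index(b) for b in consensus[c_start : c_start + seg_len]]
            )
            divergence = float(np.round(rng.uniform(2.0, 25.0), 1))
            mutate = rng.random(seg_len) < divergence / 100.0
            shift = rng.integers(1, 4, size=mutate.sum())
            segment[mutate] = (segment[mutate] + shift) % 4
            seq[t_start : t_start + seg_len] = segment
            truth.te_class[tid] = cls
            hits.append(
                RepeatHit(
                    query_id=tid,
                    begin=t_start + 1,
                    end=t_start + seg_len,
                    repeat_name=name,
                    repeat_class=cls,
                    subfamily=name,
                    divergence_pct=divergence,
                    score=float(round(2 * seg_len * (1 - divergence / 100.0))),
                )
            )
        records.append(make_record(tid, "".join(_DNA[seq])))
    truth.repeat_hits = list(hits)
    return records, hits, truth


# ---------------------------------------------------------------------------
# Counts


def simulate_counts(
    config: SimConfig, truth: SyntheticTruth, seed: int | None = None
) -> CountMatrix:
    """Draw per-sample counts around true group proportions.

    Per sample, each transcript's proportion is perturbed by a beta draw
    whose between-library coefficient of variation is
    ``config.overdispersion_cv`` for every transcript (a per-transcript
    beta-binomial dispersion; cv 0 degenerates to the exact proportions),
    renormalized, and counts are drawn multinomially at the configured
    library size — so column sums equal the library size exactly.

    Planted fold changes (``config.n_de`` transcripts at ±``config.de_fold``
    between the first two groups) are recorded in ``truth.de_genes`` and
    realized in expectation.  Updates ``truth.proportions`` in place.
    """
    if not truth.transcript_lengths:
        raise ValueError("truth carries no transcripts; run simulate_transcriptome")
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 1_000_003
    )
    ids = sorted(truth.transcript_lengths)
    n = len(ids)
    group_names = sorted(set(config.groups.values()))
    base = rng.lognormal(0.0, 1.0, size=n)
    # planted per-class TE expression levels
    for i, tid in enumerate(ids):
        cls = truth.te_class.get(tid)
        if cls is not None:
            base[i] *= config.te_class_expression.get(cls, 1.0)
    rates = pd.DataFrame(
        {g: base.copy() for g in group_names}, index=ids, dtype=float
    )
    if config.n_de > 0 and len(group_names) >= 2:
        de_idx = rng.choice(n, size=min(config.n_de, n), replace=False)
        g2 = group_names[1]
        for j, gi in enumerate(de_idx):
            fold = config.de_fold if j % 2 == 0 else 1.0 / config.de_fold
            rates.iloc[gi, rates.columns.get_loc(g2)] *= fold
            truth.de_genes[ids[gi]] = fold if fold >= 1 else -1.0 / fold
    props = rates / rates.sum(axis=0)
    truth.proportions = props
    cv = config.overdispersion_cv
    counts = {}
    for sample, group in config.groups.items():
        p = props[group].to_numpy()
        if cv > 0:
            # beta draw with mean p and variance (cv*p)^2 per transcript
            p_safe = np.where(p > 0, p, 0.5)
            ab_sum = np.maximum((1.0 - p_safe) / (cv**2 * p_safe) - 1.0, 1e-6)
            a = np.maximum(p_safe * ab_sum, 1e-12)
            b = np.maximum((1.0 - p_safe) * ab_sum, 1e-12)
            q = np.where(p > 0, rng.beta(a, b), 0.0)
        else:
            q = p
        total = q.sum()
        if total == 0:
            raise ValueError("all proportions zero")
        counts[sample] = rng.multinomial(config.library_size, q / total)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=ids),
        lengths=pd.Series(truth.transcript_lengths).reindex(ids),
        groups=dict(config.groups),
    )
    return cm


def simulate_betabinomial_counts(
    p: float,
    rho: float,
    library_size: int,
    n_libraries: int,
    n_replicates: int,
    seed: int = 0,
) -> np.ndarray:
    """Classic beta-binomial library counts for calibration studies.

    Draws an ``(n_replicates, n_libraries)`` array where each entry is
    ``Binomial(library_size, q)`` with ``q ~ Beta`` of mean ``p`` and
    intraclass correlation ``rho`` (``rho=0`` degenerates to the plain
    binomial).  Used for size/power studies of the proportions test, where
    each replicate row plays the role of one transcript.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    shape = (n_replicates, n_libraries)
    if rho == 0:
        q = np.full(shape, p)
    else:
        a = p * (1.0 - rho) / rho
        b = (1.0 - p) * (1.0 - rho) / rho
        q = rng.beta(a, b, size=shape)
    return rng.binomial(library_size, q)


# ---------------------------------------------------------------------------
# Ortholog pairs with controlled truncation


def simulate_ortholog_pairs(
    n_pairs: int = 1000,
    truncation_fraction: float = 0.3,
    identity_mean: float = 96.0,
    seed: int = 0,
):
    """Reciprocal hit tables for ortholog pairs with planted truncation.

    A fraction ``truncation_fraction`` of query transcripts covers only
    20–75% of its ortholog (ortholog hit ratio below the conventional 0.8
    full-length cutoff); the rest cover it end to end.  Returns
    ``(hits_ab, hits_ba, subject_lengths, truth)`` where ``truth`` is a
    :class:`SyntheticTruth` with the truncated query ids.
    """
    rng = np.random.default_rng(seed)
    hits_ab: list[HitRecord] = []
    hits_ba: list[HitRecord] = []
    subject_lengths: dict[str, int] = {}
    truth = SyntheticTruth()
    truncated = rng.random(n_pairs) < truncation_fraction
    for i in range(n_pairs):
        q, s = f"T{i + 1:05d}", f"P{i + 1:05d}"
        length = int(rng.integers(300, 901))
        subject_lengths[s] = length
        if truncated[i]:
            coverage = rng.uniform(0.20, 0.75)
            truth.truncated_pairs.add(q)
        else:
            coverage = 1.0
        s_end = max(1, int(round(coverage * length)))
        identity = float(np.clip(rng.normal(identity_mean, 2.0), 70.0, 100.0))
        aln = s_end
        bitscore = float(round(2.0 * aln * identity / 100.0, 1))
        common = dict(
            percent_identity=round(identity, 2),
            aln_length=aln,
            mismatches=int(round(aln * (1 - identity / 100.0))),
            gap_opens=0,
            e_value=1e-60,
            bitscore=bitscore,
        )
        hits_ab.append(
            HitRecord(query_id=q, subject_id=s, q_start=1, q_end=3 * aln,
                      s_start=1, s_end=s_end, **common)
        )
        hits_ba.append(
            HitRecord(query_id=s, subject_id=q, q_start=1, q_end=s_end,
                      s_start=1, s_end=3 * aln, **common)
        )
    return hits_ab, hits_ba, subject_lengths, truth


# ---------------------------------------------------------------------------
# Protein alignment evolution


def _toposort_edges(edges):
    children = {c for _, c, _ in edges}
    parents = {p for p, _, _ in edges}
    roots = parents - children
    if len(roots) != 1:
        raise ValueError(f"tree must have exactly one root, found {sorted(roots)}")
    ordered, known = [], set(roots)
    pending = list(edges)
    while pending:
        progress = False
        rest = []
        for e in pending:
            if e[0] in known:
                ordered.append(e)
                known.add(e[1])
                progress = True
            else:
                rest.append(e)
        if not progress:
            raise ValueError("tree edges do not form a rooted tree")
        pending = rest
    leaves = sorted(children - parents)
    return ordered, leaves


def evolve_alignment(
    edges: list[tuple[str, str, float]],
    n_sites: int,
    seed: int = 0,
    multipliers: dict[str, float] | None = None,
) -> AlignmentBlock:
    """Evolve amino-acid sites i.i.d. along a rooted tree.

    ``edges`` are ``(parent, child, branch_length)`` with branch lengths in
    expected substitutions per site; ``multipliers`` scales the rate on the
    branch leading to the named child (a per-lineage rate multiplier).  The
    substitution process is the 20-state equal-exchangeability (Jukes–Cantor
    style) chain: substitution events are Poisson with rate length×multiplier
    and each event moves to a uniformly chosen different residue.  Returns an
    alignment over the leaf taxa.
    """
    multipliers = multipliers or {}
    if any(l < 0 for _, _, l in edges):
        raise ValueError("branch lengths must be >= 0")
    ordered, leaves = _toposort_edges(edges)
    if len(leaves) < 3:
        raise ValueError("need at least 3 leaf taxa")
    rng = np.random.default_rng(seed)
    root = ordered[0][0]
    states: dict[str, np.ndarray] = {root: rng.integers(0, 20, size=n_sites)}
    for parent, child, length in ordered:
        lam = length * multipliers.get(child, 1.0)
        cur = states[parent]
        if lam == 0:
            states[child] = cur.copy()
            continue
        k = rng.poisson(lam, size=n_sites)
        out = cur.copy()
        hit = np.nonzero(k > 0)[0]
        if hit.size:
            # exact k-jump distribution of the uniform-jump chain on 20 states
            p_same = 1.0 / 20.0 + (19.0 / 20.0) * (-1.0 / 19.0) ** k[hit]
            stay = rng.random(hit.size) < p_same
            change = hit[~stay]
            j = rng.integers(0, 19, size=change.size)
            out[change] = j + (j >= cur[change])
        states[child] = out
    aa = np.array(list(AMINO_ACIDS))
    rows = {leaf: "".join(aa[states[leaf]]) for leaf in leaves}
    return AlignmentBlock(rows=rows, partitions={"sim": (0, n_sites)})


# ---------------------------------------------------------------------------
# Domain count tables


def simulate_domain_tables(config: SimConfig, seed: int | None = None):
    """Negative-binomial domain counts with planted focal expansions.

    Reference species in two groups (emulating ray-finned fish and
    tetrapods) draw counts from a shared per-domain negative binomial; the
    focal species draws from the same distribution except for
    ``config.n_planted_expansions`` domains whose mean is inflated by
    ``config.expansion_factor``.  Returns ``(table, truth)`` where ``table``
    is a domains × species DataFrame with the focal species first, and
    ``truth.species_groups`` maps group name -> species list.
    """
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 9_000_017
    )
    n_dom = config.n_domains
    if config.n_planted_expansions > n_dom:
        raise ValueError("more planted expansions than domains")
    domains = [f"DOM{i + 1:04d}" for i in range(n_dom)]
    focal = "focal"
    groups = {
        "actinopterygii": [f"act{i + 1}" for i in range(config.n_reference_species)],
        "tetrapoda": [f"tet{i + 1}" for i in range(config.n_reference_species)],
    }
    mu = rng.lognormal(np.log(80.0), 0.5, size=n_dom)
    k = config.nb_dispersion

    def nb(mean: np.ndarray) -> np.ndarray:
        return rng.negative_binomial(k, k / (k + mean))

    table = {}
    planted = rng.choice(n_dom, size=config.n_planted_expansions, replace=False)
    focal_mu = mu.copy()
    focal_mu[planted] *= config.expansion_factor
    table[focal] = nb(focal_mu)
    for sp in groups["actinopterygii"] + groups["tetrapoda"]:
        table[sp] = nb(mu)
    truth = SyntheticTruth(
        expanded_domains={domains[i] for i in planted},
        species_groups=groups,
    )
    return pd.DataFrame(table, index=domains), truth
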