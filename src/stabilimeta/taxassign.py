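"""rRNA read assignment, frequency-based disambiguation, OTU construction.

Reads are assigned to reference identifiers by the best alignment hit that
passes inclusive thresholds (E-value <= 1e-20, alignment length >= 180 bp,
identity >= 97% by default).  The top hit is the minimum E-value, ties
broken by maximum bitscore; an exact tie across several identifiers (a
conserved region) yields an *ambiguous* verdict which is later resolved to
the identifier most frequent among the unambiguous assignments of the same
stabilization method (a parsimony argument: the commonest organism is the
likeliest source).  Detected references are then clustered into OTUs by
greedy centroid clustering at 95% identity, and OTU abundances are sums of
member-identifier abundances.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from stabilimeta.align import pairwise_identity

logger = logging.getLogger(__name__)

ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"


class HitRecord(NamedTuple):
    query_id: str
    subject_id: str
    percent_identity: float
    align_len: int
    evalue: float
    bitscore: float


@dataclasses.dataclass(frozen=True)
class AssignmentThresholds:
    max_evalue: float = 1e-20
    min_align_len: int = 180
    min_identity: float = 97.0

    def __post_init__(self):
        if self.max_evalue < 0 or self.min_align_len < 1:
            raise ValueError("invalid thresholds")
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError(f"min_identity must be in [0, 100], got {self.min_identity}")


@dataclasses.dataclass(frozen=True)
class Verdict:
    status: str                      # assigned | ambiguous | unassigned
    identifiers: tuple[str, ...]     # 1 for assigned, >=2 for ambiguous, 0 otherwise


def assign_reads(hits: Sequence[HitRecord], thresholds: AssignmentThresholds) -> Verdict:
    """Verdict for a single read from its hit list (all criteria inclusive)."""
    surviving: dict[str, HitRecord] = {}
    for h in hits:
        if h.evalue > thresholds.max_evalue:
            continue
        if h.align_len < thresholds.min_align_len:
            continue
        if h.percent_identity < thresholds.min_identity:
            continue
        prev = surviving.get(h.subject_id)
        if prev is not None:
            logger.warning("duplicate hit rows for (%s, %s); keeping best",
                           h.query_id, h.subject_id)
            if (h.evalue, -h.bitscore) >= (prev.evalue, -prev.bitscore):
                continue
        surviving[h.subject_id] = h
    if not surviving:
        return Verdict(UNASSIGNED, ())
    best = min(surviving.values(), key=lambda h: (h.evalue, -h.bitscore))
    tied = sorted(s for s, h in surviving.items()
                  if h.evalue == best.evalue and h.bitscore == best.bitscore)
    if len(tied) == 1:
        return Verdict(ASSIGNED, (tied[0],))
    return Verdict(AMBIGUOUS, tuple(tied))


def assign_hit_table(hits: pd.DataFrame, thresholds: AssignmentThresholds,
                     all_queries: Iterable[str] | None = None) -> dict[str, Verdict]:
    """Vectorized :func:`assign_reads` over a 12-column hit table.

    ``all_queries`` optionally lists every read in the sample so that reads
    with no hit rows at all appear as unassigned verdicts.
    """
    verdicts: dict[str, Verdict] = {}
    if all_queries is not None:
        for q in all_queries:
            verdicts[q] = Verdict(UNASSIGNED, ())
    if len(hits) == 0:
        return verdicts

    ok = (
        (hits["evalue"] <= thresholds.max_evalue)
        & (hits["length"] >= thresholds.min_align_len)
        & (hits["pident"] >= thresholds.min_identity)
    )
    f = hits.loc[ok, ["qseqid", "sseqid", "evalue", "bitscore"]]
    for q in hits["qseqid"].unique():
        verdicts.setdefault(q, Verdict(UNASSIGNED, ()))
    if len(f) == 0:
        return verdicts
    if f.duplicated(["qseqid", "sseqid"]).any():
        logger.warning("duplicate (query, subject) hit rows; keeping best per pair")
        f = (f.sort_values(["evalue", "bitscore"], ascending=[True, False])
               .drop_duplicates(["qseqid", "sseqid"]))
    f = f.sort_values(["qseqid", "evalue", "bitscore"], ascending=[True, True, False])
    top = f.drop_duplicates("qseqid")[["qseqid", "evalue", "bitscore"]]
    tied = f.merge(top, on=["qseqid", "evalue", "bitscore"])
    for q, group in tied.groupby("qseqid", sort=False):
        subjects = tuple(sorted(set(group["sseqid"])))
        if len(subjects) == 1:
            verdicts[q] = Verdict(ASSIGNED, subjects)
        else:
            verdicts[q] = Verdict(AMBIGUOUS, subjects)
    return verdicts


# ---------------------------------------------------------------------------
# Disambiguation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Resolution:
    identifier: str | None   # None = unassigned
    fallback: bool = False   # True when resolved by the zero-frequency tie rule


def disambiguate(
    verdicts: Mapping[str, Mapping[str, Verdict]],
    sample_meta: pd.DataFrame,
) -> dict[str, dict[str, Resolution]]:
    """Resolve ambiguous verdicts by within-method identifier frequency.

    Two passes: pass 1 counts *unambiguous* assignments per identifier within
    each stabilization method; pass 2 resolves each ambiguous read to the
    member of its tied set with the highest pass-1 count in that read's
    method.  Resolved reads never feed back into the frequencies, so the
    result is independent of read order.  Frequency ties (including all-zero
    counts) fall back to the lexicographically smallest identifier and are
    flagged.
    """
    unknown = set(verdicts) - set(sample_meta.index)
    if unknown:
        raise ValueError(f"samples missing from metadata: {sorted(unknown)}")

    freq: dict[str, dict[str, int]] = {}
    for sample, per_read in verdicts.items():
        method = sample_meta.loc[sample, "method"]
        counts = freq.setdefault(method, {})
        for v in per_read.values():
            if v.status == ASSIGNED:
                counts[v.identifiers[0]] = counts.get(v.identifiers[0], 0) + 1

    out: dict[str, dict[str, Resolution]] = {}
    for sample, per_read in verdicts.items():
        method = sample_meta.loc[sample, "method"]
        counts = freq.get(method, {})
        resolved: dict[str, Resolution] = {}
        for read, v in per_read.items():
            if v.status == ASSIGNED:
                resolved[read] = Resolution(v.identifiers[0])
            elif v.status == UNASSIGNED:
                resolved[read] = Resolution(None)
            else:
                best = max(v.identifiers, key=lambda i: (counts.get(i, 0), ), default=None)
                top_count = counts.get(best, 0)
                winners = sorted(i for i in v.identifiers if counts.get(i, 0) == top_count)
                resolved[read] = Resolution(winners[0], fallback=len(winners) > 1)
        out[sample] = resolved
    return out


def tabulate(
    assignments: Mapping[str, Mapping[str, Resolution]],
    sample_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Identifier-by-sample count table from final read assignments."""
    samples = [s for s in sample_meta.index if s in assignments]
    identifiers = sorted(
        {r.identifier for per_read in assignments.values() for r in per_read.values()
         if r.identifier is not None}
    )
    table = pd.DataFrame(0, index=pd.Index(identifiers, name="identifier"), columns=samples)
    for sample in samples:
        for r in assignments[sample].values():
            if r.identifier is not None:
                table.loc[r.identifier, sample] += 1
    return table


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    sums = table.sum(axis=0)
    if (sums == 0).any():
        empty = list(table.columns[sums == 0])
        raise ValueError(f"samples with zero assigned reads: {empty}")
    return table / sums


# ---------------------------------------------------------------------------
# OTU clustering
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class OTUMap:
    member_to_otu: dict[str, str]
    representatives: dict[str, str]   # otu id -> representative identifier
    threshold: float

    def members(self, otu: str) -> list[str]:
        return sorted(i for i, o in self.member_to_otu.items() if o == otu)


def cluster_references(sequences: Mapping[str, str], threshold: float = 0.95) -> OTUMap:
    """Greedy centroid clustering of detected reference sequences.

    Sequences are processed in decreasing length (ties broken by id); each
    joins the first existing centroid with pairwise identity >= threshold,
    else founds a new OTU.  Identity is matches / alignment columns.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    order = sorted(sequences, key=lambda i: (-len(sequences[i]), i))
    centroids: list[str] = []
    member_to_otu: dict[str, str] = {}
    representatives: dict[str, str] = {}
    for ident in order:
        seq = sequences[ident]
        home = None
        for c in centroids:
            if pairwise_identity(seq, sequences[c]) >= threshold:
                home = c
                break
        if home is None:
            otu = f"OTU{len(centroids) + 1:04d}"
            centroids.append(ident)
            representatives[otu] = ident
            member_to_otu[ident] = otu
        else:
            otu = next(o for o, rep in representatives.items() if rep == home)
            member_to_otu[ident] = otu
    return OTUMap(member_to_otu, representatives, threshold)


def otu_abundance(table: pd.DataFrame, otu_map: OTUMap) -> pd.DataFrame:
    """Sum identifier abundances into OTU abundances (column sums preserved)."""
    missing = [i for i in table.index if i not in otu_map.member_to_otu]
    if missing:
        raise ValueError(f"identifiers missing from OTU map: {missing}")
    groups = [otu_map.member_to_otu[i] for i in table.index]
    out = table.groupby(pd.Index(groups, name="otu")).sum()
    return out.sort_index()


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def expected_richness(counts: np.ndarray, depth: int) -> float:
    """Analytic expected richness at subsampling depth ``depth``:
    E[S_m] = S - sum_i C(N - N_i, m) / C(N, m)."""
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds sample total {total}")
    if depth == 0:
        return 0.0
    log_denom = _log_comb(total, depth)
    miss = 0.0
    for n_i in counts:
        if total - n_i >= depth:
            miss += math.exp(_log_comb(total - int(n_i), depth) - log_denom)
    return float(len(counts) - miss)


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def rarefy_curve(
    table: pd.DataFrame,
    depths: Sequence[int],
    replicates: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected OTU richness per depth per sample.

    ``replicates == 0`` uses the exact hypergeometric expectation; otherwise
    the mean observed richness over ``replicates`` random subsamples drawn
    without replacement.
    """
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=pd.Index(depths, name="depth"),
                       columns=table.columns, dtype=float)
    for sample in table.columns:
        counts = table[sample].to_numpy().astype(int)
        total = int(counts.sum())
        for depth in depths:
            if replicates == 0:
                out.loc[depth, sample] = expected_richness(counts, int(depth))
            else:
                if depth > total:
                    out.loc[depth, sample] = np.nan
                    continue
                vals = [
                    int((rng.multivariate_hypergeometric(counts, int(depth)) > 0).sum())
                    for _ in range(replicates)
                ]
                out.loc[depth, sample] = float(np.mean(vals))
    return out
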