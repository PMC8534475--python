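"""Taxon-restricted taxonomic and functional annotation of mRNA features.

Features are CDSs, or whole contigs when a contig carries no predicted CDS.
Taxonomic annotation keeps only hits whose subject maps to an allowed TaxID
set (the three major episymbiont taxa, or synthetic analogues) and E-value
<= 1e-5, then takes the top hit (minimum E-value, ties by maximum bitscore,
remaining ties by lexicographic subject id).  Functional annotation uses
the top hit's KO *if one is assigned* — a KO-less top hit yields no
annotation, with no fallback to lower-ranked hits.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class CDSRecord:
    contig_id: str
    cds_id: str
    start: int   # 1-based inclusive
    end: int
    strand: str
    length: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.cds_id}: invalid coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.cds_id}: invalid strand {self.strand!r}")
        if self.length != self.end - self.start + 1:
            raise ValueError(f"{self.cds_id}: length != end - start + 1")


@dataclasses.dataclass
class TaxonomyMap:
    subject_to_taxid: dict[str, int]
    taxid_to_label: dict[int, str]
    allowed_taxids: frozenset[int]

    def __post_init__(self):
        if not self.allowed_taxids:
            raise ValueError("allowed TaxID set must be non-empty")

    @classmethod
    def from_table(cls, table: pd.DataFrame, allowed_labels: set[str]) -> "TaxonomyMap":
        """Build from a (subject, taxid, label) table, allowing the TaxIDs
        whose label is in ``allowed_labels``."""
        s2t = dict(zip(table["subject"], table["taxid"].astype(int)))
        t2l = dict(zip(table["taxid"].astype(int), table["label"]))
        allowed = frozenset(t for t, lab in t2l.items() if lab in allowed_labels)
        return cls(s2t, t2l, allowed)


@dataclasses.dataclass(frozen=True)
class Annotation:
    feature_id: str
    taxon: str | None = None
    ko: str | None = None
    evalue: float | None = None
    bitscore: float | None = None
    tie_flagged: bool = False


def _top_hit(hits: pd.DataFrame) -> tuple[pd.Series, bool]:
    """Winner by (min E-value, max bitscore, lexicographic subject)."""
    ordered = hits.sort_values(["evalue", "bitscore", "sseqid"],
                               ascending=[True, False, True])
    best = ordered.iloc[0]
    tie = ((ordered["evalue"] == best["evalue"])
           & (ordered["bitscore"] == best["bitscore"])).sum() > 1
    return best, bool(tie)


def annotate_taxon(
    hits: pd.DataFrame,
    taxmap: TaxonomyMap,
    max_evalue: float = 1e-5,
) -> dict[str, Annotation]:
    """Per-feature taxon label from hits restricted to the allowed TaxIDs."""
    out: dict[str, Annotation] = {}
    if len(hits) == 0:
        return out
    taxids = hits["sseqid"].map(taxmap.subject_to_taxid)
    unmapped = taxids.isna()
    if unmapped.any():
        logger.info("%d hits to subjects without a TaxID ignored", int(unmapped.sum()))
    ok = (~unmapped) & taxids.isin(taxmap.allowed_taxids) & (hits["evalue"] <= max_evalue)
    for feature, group in hits.loc[ok].groupby("qseqid", sort=False):
        best, tie = _top_hit(group)
        label = taxmap.taxid_to_label[taxmap.subject_to_taxid[best["sseqid"]]]
        out[feature] = Annotation(feature, taxon=label, evalue=float(best["evalue"]),
                                  bitscore=float(best["bitscore"]), tie_flagged=tie)
    return out


def annotate_function(
    hits: pd.DataFrame,
    subject_ko: Mapping[str, str] | pd.DataFrame,
    max_evalue: float = 1e-5,
) -> dict[str, Annotation]:
    """Per-feature KO from the top hit against a KO-labelled database.

    The top hit's KO is used if one is assigned; a KO-less top hit yields no
    annotation (strictly no fallback to lower hits).
    """
    if isinstance(subject_ko, pd.DataFrame):
        subject_ko = dict(zip(subject_ko["subject"], subject_ko["ko"]))
    out: dict[str, Annotation] = {}
    if len(hits) == 0:
        return out
    ok = hits["evalue"] <= max_evalue
    for feature, group in hits.loc[ok].groupby("qseqid", sort=False):
        best, tie = _top_hit(group)
        ko = subject_ko.get(best["sseqid"], "")
        if not ko:
            continue
        out[feature] = Annotation(feature, ko=ko, evalue=float(best["evalue"]),
                                  bitscore=float(best["bitscore"]), tie_flagged=tie)
    return out


def split_feature_hits(
    hits: pd.DataFrame,
    cds_table: pd.DataFrame,
) -> pd.DataFrame:
    """Keep CDS-level hits for contigs with CDSs and contig-level hits only
    for CDS-less contigs."""
    contigs_with_cds = set(cds_table["contig_id"])
    cds_ids = set(cds_table["cds_id"])
    keep = hits["qseqid"].map(
        lambda q: q in cds_ids or q not in contigs_with_cds
    )
    return hits.loc[keep]


def annotation_summary(
    annotations: Mapping[str, Annotation],
    total_features: int,
) -> dict:
    """Counts per taxon, per KO, and the annotated fraction."""
    by_taxon: dict[str, int] = {}
    by_ko: dict[str, int] = {}
    for a in annotations.values():
        if a.taxon:
            by_taxon[a.taxon] = by_taxon.get(a.taxon, 0) + 1
        if a.ko:
            by_ko[a.ko] = by_ko.get(a.ko, 0) + 1
    n_annotated = sum(1 for a in annotations.values() if a.taxon or a.ko)
    fraction = n_annotated / total_features if total_features else 0.0
    return {
        "total_features": total_features,
        "annotated": n_annotated,
        "annotated_fraction": fraction,
        "per_taxon": dict(sorted(by_taxon.items())),
        "per_ko": dict(sorted(by_ko.items())),
    }


def annotations_to_table(annotations: Mapping[str, Annotation]) -> pd.DataFrame:
    rows = [
        (a.feature_id, a.taxon or "", a.ko or "",
         a.evalue if a.evalue is not None else "",
         a.bitscore if a.bitscore is not None else "",
         a.tie_flagged)
        for a in annotations.values()
    ]
    return pd.DataFrame(rows, columns=["feature", "taxon", "ko", "evalue",
                                       "bitscore", "tie_flagged"])
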