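"""TPM quantification and sum-aggregation over a KO/module/pathway hierarchy.

TPM_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j) with effective length equal to
the CDS/contig length in bp.  KO values are sums of member-feature TPM with
the unannotated remainder reported; module/pathway values are sums of member
KOs, and overlapping sets double-count by design (set totals are reported
per set, never re-normalized).
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from typing import Mapping

import pandas as pd

REMAINDER = "__unannotated__"


def _load_panels() -> dict:
    with resources.files("stabilimeta.data").joinpath("kegg_panels.json").open() as fh:
        return json.load(fh)


_PANELS = _load_panels()
STRESS_PANEL: dict[str, str] = _PANELS["stress_panel"]
PMOA_KO: str = _PANELS["markers"]["pmoA"]
HUPL_KO: str = _PANELS["markers"]["hupL"]
SULFUR_GLOBULE_PANEL: dict[str, str] = _PANELS["sulfur_globule_panel"]
FUNCTIONAL_CATEGORIES: dict[str, dict] = _PANELS["functional_categories"]


@dataclasses.dataclass
class KEGGHierarchy:
    """KO set memberships plus the named gene panels used in the comparison."""

    ko_to_modules: dict[str, set[str]]
    ko_to_pathways: dict[str, set[str]]
    stress_panel: dict[str, str] = dataclasses.field(default_factory=lambda: dict(STRESS_PANEL))
    markers: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(_PANELS["markers"]))
    functional_categories: dict[str, dict] = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in FUNCTIONAL_CATEGORIES.items()})

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "KEGGHierarchy":
        """Load from a (ko, module, pathway) membership table, one row per
        membership."""
        k2m: dict[str, set[str]] = {}
        k2p: dict[str, set[str]] = {}
        for _, row in table.iterrows():
            if row.get("module"):
                k2m.setdefault(row["ko"], set()).add(row["module"])
            if row.get("pathway"):
                k2p.setdefault(row["ko"], set()).add(row["pathway"])
        return cls(k2m, k2p)

    def members(self, level: str) -> dict[str, set[str]]:
        src = self.ko_to_modules if level == "module" else self.ko_to_pathways
        out: dict[str, set[str]] = {}
        for ko, sets in src.items():
            for s in sets:
                out.setdefault(s, set()).add(ko)
        return out


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def tpm(counts: pd.DataFrame | pd.Series, lengths: pd.Series) -> pd.DataFrame | pd.Series:
    """Transcripts-per-million from counts and feature lengths.

    Accepts a feature-by-sample matrix or a single sample vector; columns
    sum to 1e6 (to 1e-6 relative).
    """
    single = isinstance(counts, pd.Series)
    mat = counts.to_frame() if single else counts
    lens = lengths.reindex(mat.index)
    if lens.isna().any():
        missing = list(mat.index[lens.isna()])
        raise ValueError(f"features without lengths: {missing[:5]}")
    if (lens <= 0).any():
        raise ValueError("feature lengths must be > 0")
    rate = mat.div(lens, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"all-zero samples: {list(zero.index)}")
    out = rate.div(totals, axis=1) * 1.0e6
    return out.iloc[:, 0] if single else out


def rpk(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Length-normalized counts (reads per kilobase) *without* per-sample
    rescaling.  TPM is compositional — per-sample renormalization to 1e6
    erases absolute between-condition shifts — so absolute fold-change
    recovery uses this scale."""
    lens = lengths.reindex(counts.index)
    if lens.isna().any() or (lens <= 0).any():
        raise ValueError("invalid feature lengths")
    return counts.div(lens / 1000.0, axis=0)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_ko(
    tpm_matrix: pd.DataFrame,
    annotations: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Sum feature TPM into KO TPM; unannotated TPM goes to a remainder row
    (``__unannotated__``) so column totals are conserved."""
    if isinstance(annotations, pd.Series):
        annotations = annotations.to_dict()
    ko_of = pd.Series(
        [annotations.get(f, "") or REMAINDER for f in tpm_matrix.index],
        index=tpm_matrix.index,
    )
    out = tpm_matrix.groupby(ko_of.rename("ko")).sum()
    if REMAINDER not in out.index:
        out.loc[REMAINDER] = 0.0
    return out.sort_index()


def aggregate_sets(
    ko_tpm: pd.DataFrame,
    hierarchy: KEGGHierarchy,
    level: str = "pathway",
) -> pd.DataFrame:
    """Sum KO TPM into module/pathway TPM.  A KO in k sets contributes to
    all k, so overlapping set totals may exceed 1e6."""
    if level not in ("module", "pathway"):
        raise ValueError(f"level must be 'module' or 'pathway', got {level!r}")
    members = hierarchy.members(level)
    rows = {}
    for set_id in sorted(members):
        kos = [k for k in members[set_id] if k in ko_tpm.index]
        if kos:
            rows[set_id] = ko_tpm.loc[kos].sum(axis=0)
    if not rows:
        return pd.DataFrame(columns=ko_tpm.columns,
                            index=pd.Index([], name=level), dtype=float)
    out = pd.DataFrame(rows).T
    out.index.name = level
    return out.sort_index()


def taxon_totals(
    tpm_matrix: pd.DataFrame,
    taxon_annotations: Mapping[str, str] | pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-taxon TPM sums and relative shares (taxon sum / 1e6)."""
    if isinstance(taxon_annotations, pd.Series):
        taxon_annotations = taxon_annotations.to_dict()
    taxon_of = pd.Series(
        [taxon_annotations.get(f, "") for f in tpm_matrix.index], index=tpm_matrix.index)
    annotated = tpm_matrix.loc[taxon_of != ""]
    if len(annotated) == 0:
        taxa = pd.DataFrame(columns=tpm_matrix.columns, dtype=float)
        return taxa, taxa.copy()
    totals = annotated.groupby(taxon_of[taxon_of != ""].rename("taxon")).sum().sort_index()
    shares = totals / 1.0e6
    return totals, shares


def filter_pathways(pathway_tpm: pd.DataFrame, min_tpm: float = 1000.0) -> pd.DataFrame:
    """Keep pathways whose TPM strictly exceeds ``min_tpm`` in >= 1 sample."""
    if len(pathway_tpm) == 0:
        return pathway_tpm
    keep = (pathway_tpm > min_tpm).any(axis=1)
    return pathway_tpm.loc[keep]
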