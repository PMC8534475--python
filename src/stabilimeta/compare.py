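"""Two-condition comparison: taxon-wide vs. gene-specific expression shifts.

The model: retrieval without stabilization multiplies each taxon's whole
transcriptome by a single factor (a transcriptome-wide shift), on top of
which individual genes may carry condition-specific effects.  The
decomposition reports, per gene, the fold change between method means, the
taxon-wide fold change of its taxon, and the deviation log-ratio
log2(gene FC) - log2(taxon FC); a gene whose |deviation| exceeds a
threshold went against the global trend.  Fold changes are oriented
in_situ / onboard, so a "1.5-fold decrease onboard" reads as FC = 1.5.

Global per-method scale factors (such as the expected effect of TPM's
per-sample renormalization) cancel in the deviation, so flagging is robust
to the compositional scale; absolute taxon-wide fold changes are recovered
on a length-normalized but not per-sample-rescaled matrix (see
:func:`stabilimeta.quant.rpk`).
"""

from __future__ import annotations

import re
from typing import Mapping

import numpy as np
import pandas as pd

KO_PATTERN = re.compile(r"^K\d{5}$")


def method_means(matrix: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean per stabilization method; columns ``in_situ`` and
    ``onboard``."""
    out = {}
    for method in ("in_situ", "onboard"):
        samples = [s for s in matrix.columns if sample_meta.loc[s, "method"] == method]
        if not samples:
            raise ValueError(f"no samples for method {method!r}")
        out[method] = matrix[samples].mean(axis=1)
    return pd.DataFrame(out)


def taxon_wide_fc(
    means: pd.DataFrame,
    taxon_annotations: Mapping[str, str] | pd.Series,
) -> pd.Series:
    """Taxon-wide fold change: taxon-total in_situ mean / onboard mean.

    A value > 1 means the taxon's transcripts were lower onboard (degraded
    during retrieval)."""
    if isinstance(taxon_annotations, pd.Series):
        taxon_annotations = taxon_annotations.to_dict()
    taxon_of = pd.Series(
        [taxon_annotations.get(f, "") for f in means.index], index=means.index)
    annotated = means.loc[taxon_of != ""]
    totals = annotated.groupby(taxon_of[taxon_of != ""].rename("taxon")).sum()
    if (totals["onboard"] <= 0).any() or (totals["in_situ"] <= 0).any():
        bad = list(totals.index[(totals["onboard"] <= 0) | (totals["in_situ"] <= 0)])
        raise ValueError(f"taxa with zero method totals: {bad}")
    fc = totals["in_situ"] / totals["onboard"]
    fc.name = "fold_change"
    return fc


def gene_fc_and_deviation(
    means: pd.DataFrame,
    taxon_fc: pd.Series,
    taxon_annotations: Mapping[str, str] | pd.Series,
    pseudo: float = 0.01,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-gene fold change, taxon-wide fold change, and deviation log-ratio.

    deviation = log2(gene FC) - log2(taxon FC); ``flag`` marks
    |deviation| > threshold.  A pseudocount keeps ratios finite for zero
    TPM.  Genes without a taxon annotation are omitted (no taxon-wide
    reference exists for them).
    """
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    if isinstance(taxon_annotations, pd.Series):
        taxon_annotations = taxon_annotations.to_dict()
    rows = []
    for feature in means.index:
        taxon = taxon_annotations.get(feature, "")
        if not taxon or taxon not in taxon_fc.index:
            continue
        x = means.loc[feature, "in_situ"] + pseudo
        y = means.loc[feature, "onboard"] + pseudo
        gene_fc = x / y
        tfc = taxon_fc.loc[taxon]
        deviation = np.log2(gene_fc) - np.log2(tfc)
        rows.append((feature, taxon, gene_fc, 1.0 / gene_fc, tfc, deviation,
                     abs(deviation) > threshold))
    return pd.DataFrame(
        rows,
        columns=["feature", "taxon", "fc_insitu_over_onboard",
                 "fc_onboard_over_insitu", "taxon_fc", "deviation_log2", "flag"],
    ).set_index("feature")


def normalized_heatmap_values(
    tpm_matrix: pd.DataFrame,
    pseudo: float = 0.01,
    mode: str = "per_sample",
) -> pd.DataFrame:
    """log10 + z-score normalization of a pathway-by-sample TPM block for
    one taxon.

    ``per_sample`` (default): each column (one taxon-sample vector across
    pathways) is normalized on its own.  ``per_taxon``: one mean/sd over
    the whole block.  Vectors with zero sd (e.g., a single pathway) map to
    zeros."""
    if mode not in ("per_sample", "per_taxon"):
        raise ValueError(f"unknown mode {mode!r}")
    v = np.log10(tpm_matrix + pseudo)
    if mode == "per_taxon":
        sd = float(v.to_numpy().std(ddof=0))
        mean = float(v.to_numpy().mean())
        return (v - mean) / sd if sd > 1e-9 else v * 0.0
    sd = v.std(axis=0, ddof=0)
    mean = v.mean(axis=0)
    z = (v - mean) / sd.where(sd > 1e-9)  # constant vectors map to zeros
    return z.fillna(0.0)


def method_regression(means: pd.DataFrame, through_origin: bool = True):
    """Regression of onboard mean on in_situ mean over all genes of a taxon.

    A purely transcriptome-wide multiplicative shift predicts a line through
    the origin with slope = the onboard multiplier (1 / taxon-wide FC), so
    the default fit is through the origin: slope = sum(xy) / sum(x^2).  The
    free-intercept mode returns ``(slope, intercept)`` for diagnostics.
    """
    if len(means) < 2:
        raise ValueError("regression requires >= 2 genes")
    x = means["in_situ"].to_numpy(dtype=float)
    y = means["onboard"].to_numpy(dtype=float)
    sxx = float((x * x).sum())
    if sxx <= 0:
        raise ValueError("all-zero in_situ means")
    if through_origin:
        return float((x * y).sum() / sxx)
    a = np.vstack([x, np.ones_like(x)]).T
    (slope, intercept), *_ = np.linalg.lstsq(a, y, rcond=None)
    return float(slope), float(intercept)


def panel_report(
    ko_tpm_by_taxon: Mapping[str, pd.DataFrame],
    panel: Mapping[str, str],
    sample_meta: pd.DataFrame,
    floor: float = 50.0,
) -> pd.DataFrame:
    """Per-taxon, per-method report for a named KO panel.

    ``expressed`` is True when the KO's TPM strictly exceeds ``floor`` in
    *all* samples of that taxon's block.  A panel KO absent from the data
    reports zero means and not-expressed.
    """
    for gene, ko in panel.items():
        if not KO_PATTERN.match(str(ko)):
            raise ValueError(f"panel entry {gene!r} has invalid KO id {ko!r}")
    rows = []
    for taxon in sorted(ko_tpm_by_taxon):
        block = ko_tpm_by_taxon[taxon]
        means = method_means(block, sample_meta)
        for gene, ko in panel.items():
            if ko in block.index:
                x = float(means.loc[ko, "in_situ"])
                y = float(means.loc[ko, "onboard"])
                expressed = bool((block.loc[ko] > floor).all())
            else:
                x = y = 0.0
                expressed = False
            fc = (x or np.nan) / y if y > 0 else np.nan
            rows.append((taxon, gene, ko, x, y, fc, expressed))
    return pd.DataFrame(
        rows, columns=["taxon", "gene", "ko", "in_situ_mean", "onboard_mean",
                       "fc_insitu_over_onboard", "expressed"])
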