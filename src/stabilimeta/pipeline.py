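"""End-to-end driver: simulate -> QC -> assign -> cluster -> diversity and
simulate -> annotate -> TPM -> aggregate -> compare, with a hash manifest.

Every stage writes plain-text outputs into the run directory and the
manifest records a SHA-256 per file; re-running with the same configuration
reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd

from stabilimeta import compare, diversity, io, mrna_annot, qc, quant, synthio, taxassign

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: io.RunConfig,
    sim_config: synthio.SimConfig | None = None,
) -> dict:
    """Run the full synthetic-data pipeline; returns the manifest dict."""
    config.validate()
    if sim_config is None:
        sim_config = synthio.SimConfig(seed=config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: simulate -------------------------------------------------
    truth = synthio.build_ground_truth(sim_config)
    rrna = synthio.simulate_rrna_samples(sim_config, truth)
    mrna = synthio.simulate_mrna_samples(sim_config, truth)

    io.write_fasta(out / "reference.fasta", truth.references)
    io.write_newick(out / "tree.nwk", truth.tree)
    io.write_sample_meta(out / "sample_meta.tsv", rrna.sample_meta)
    io.write_sample_meta(out / "mrna_sample_meta.tsv", mrna.sample_meta)
    with open(out / "ground_truth.json", "w") as fh:
        fh.write(truth.to_json())
    hits_dir = out / "rrna_hits"
    hits_dir.mkdir(exist_ok=True)
    fastq_dir = out / "rrna_fastq"
    fastq_dir.mkdir(exist_ok=True)
    for sample in rrna.sample_meta.index:
        io.write_hits(hits_dir / f"{sample}.tsv", rrna.hits[sample])
        io.write_fastq(fastq_dir / f"{sample}.fastq", rrna.reads[sample])
    io.write_fasta(out / "contigs.fasta", mrna.contigs)
    io.write_table(out / "cds_table.tsv", mrna.cds_table)
    io.write_matrix(out / "mrna_counts.tsv", mrna.counts)
    io.write_hits(out / "mrna_tax_hits.tsv", mrna.tax_hits)
    io.write_hits(out / "mrna_ko_hits.tsv", mrna.ko_hits)
    io.write_table(out / "taxonomy_map.tsv", mrna.taxonomy_map)
    io.write_table(out / "subject_ko.tsv", mrna.subject_ko)
    io.write_table(out / "hierarchy.tsv", mrna.hierarchy)

    # --- stage: qc --------------------------------------------------------
    qc_rows = []
    survivors: dict[str, set[str]] = {}
    for sample in rrna.sample_meta.index:
        report = qc.QCReport()
        kept = list(qc.trim_and_filter(
            rrna.reads[sample], config.q_left, config.q_right, config.min_len, report))
        survivors[sample] = {r.id for r in kept}
        qc_rows.append((sample, report.input, report.trimmed, report.dropped, report.output))
    io.write_table(out / "qc_summary.tsv", pd.DataFrame(
        qc_rows, columns=["sample_id", "input", "trimmed", "dropped", "output"]))

    # --- stage: assign ----------------------------------------------------
    thresholds = taxassign.AssignmentThresholds(
        config.max_evalue, config.min_align_len, config.min_identity)
    verdicts = {}
    for sample in rrna.sample_meta.index:
        hits = rrna.hits[sample]
        hits = hits[hits["qseqid"].isin(survivors[sample])]
        verdicts[sample] = taxassign.assign_hit_table(
            hits, thresholds,
            all_queries=sorted(survivors[sample] & set(rrna.hits[sample]["qseqid"])))
    resolved = taxassign.disambiguate(verdicts, rrna.sample_meta)
    table = taxassign.tabulate(resolved, rrna.sample_meta)
    io.write_matrix(out / "identifier_counts.tsv", table, index_label="identifier")

    counter_rows = []
    for sample in rrna.sample_meta.index:
        v = verdicts[sample].values()
        counter_rows.append((
            sample,
            sum(1 for x in v if x.status == taxassign.ASSIGNED),
            sum(1 for x in v if x.status == taxassign.AMBIGUOUS),
            sum(1 for x in v if x.status == taxassign.UNASSIGNED),
        ))
    io.write_table(out / "assignment_summary.tsv", pd.DataFrame(
        counter_rows, columns=["sample_id", "assigned", "ambiguous", "unassigned"]))

    # --- stage: cluster ---------------------------------------------------
    detected = {i: truth.references[i] for i in table.index}
    otu_map = taxassign.cluster_references(detected, config.cluster_threshold)
    io.write_table(out / "otu_map.tsv", pd.DataFrame(
        {"identifier": list(otu_map.member_to_otu),
         "otu": list(otu_map.member_to_otu.values()),
         "representative": [otu_map.representatives[o]
                            for o in otu_map.member_to_otu.values()]}))
    otu_table = taxassign.otu_abundance(table, otu_map)
    # re-key the table by representative identifier so it matches the tree tips
    rep_table = otu_table.rename(index=otu_map.representatives)
    io.write_matrix(out / "otu_counts.tsv", otu_table, index_label="otu")

    # --- stage: diversity -------------------------------------------------
    alpha_rows = []
    for sample in rep_table.columns:
        col = rep_table[sample]
        alpha_rows.append((
            sample,
            diversity.richness(col),
            diversity.shannon(col, base=config.shannon_base),
            diversity.faith_pd(col, truth.tree),
        ))
    alpha = pd.DataFrame(alpha_rows,
                         columns=["sample_id", "richness", "shannon", "faith_pd"])
    io.write_table(out / "alpha_diversity.tsv", alpha)

    dm = diversity.beta_diversity(rep_table, truth.tree)
    io.write_matrix(out / "weighted_unifrac.tsv", dm, index_label="sample_id")
    coords, explained, eigvals = diversity.pcoa(dm)
    io.write_matrix(out / "pcoa_coordinates.tsv", coords, index_label="sample_id")
    io.write_json(out / "pcoa_eigen.json", {
        "eigenvalues": eigvals.to_dict(),
        "proportion_explained": explained.to_dict(),
    })

    methods = rrna.sample_meta["method"]
    groups_is = list(methods[methods == "in_situ"].index)
    groups_ob = list(methods[methods == "onboard"].index)
    tests = {}
    for name in ("richness", "shannon", "faith_pd"):
        s = alpha.set_index("sample_id")[name]
        u, p = diversity.mann_whitney(s[groups_is], s[groups_ob])
        tests[name] = {"U": u, "p": p}
    f_stat, p_perm = diversity.permanova(
        dm, methods, n_perm=config.n_permutations, seed=config.seed)
    tests["permanova"] = {"pseudo_F": f_stat, "p": p_perm,
                          "n_permutations": config.n_permutations}
    io.write_json(out / "diversity_tests.json", tests)

    # --- stage: annotate --------------------------------------------------
    taxmap = mrna_annot.TaxonomyMap.from_table(
        mrna.taxonomy_map, set(sim_config.taxon_names))
    tax_hits = mrna_annot.split_feature_hits(mrna.tax_hits, mrna.cds_table)
    ko_hits = mrna_annot.split_feature_hits(mrna.ko_hits, mrna.cds_table)
    tax_ann = mrna_annot.annotate_taxon(tax_hits, taxmap, config.annot_max_evalue)
    ko_ann = mrna_annot.annotate_function(ko_hits, mrna.subject_ko, config.annot_max_evalue)
    merged = {}
    for f in set(tax_ann) | set(ko_ann):
        merged[f] = mrna_annot.Annotation(
            f,
            taxon=tax_ann[f].taxon if f in tax_ann else None,
            ko=ko_ann[f].ko if f in ko_ann else None,
        )
    io.write_table(out / "annotations.tsv",
                   mrna_annot.annotations_to_table(merged).sort_values("feature"))
    summary = mrna_annot.annotation_summary(merged, total_features=len(mrna.counts))
    io.write_json(out / "annotation_summary.json", summary)

    # --- stage: quant -----------------------------------------------------
    tpm_matrix = quant.tpm(mrna.counts, mrna.lengths)
    io.write_matrix(out / "tpm.tsv", tpm_matrix)
    ko_of = {f: a.ko for f, a in merged.items() if a.ko}
    taxon_of = {f: a.taxon for f, a in merged.items() if a.taxon}
    ko_tpm = quant.aggregate_ko(tpm_matrix, ko_of)
    io.write_matrix(out / "ko_tpm.tsv", ko_tpm, index_label="ko")
    hierarchy = quant.KEGGHierarchy.from_table(mrna.hierarchy)
    pathway_tpm = quant.aggregate_sets(ko_tpm, hierarchy, "pathway")
    module_tpm = quant.aggregate_sets(ko_tpm, hierarchy, "module")
    io.write_matrix(out / "pathway_tpm.tsv", pathway_tpm, index_label="pathway")
    io.write_matrix(out / "module_tpm.tsv", module_tpm, index_label="module")
    io.write_matrix(out / "pathway_tpm_filtered.tsv",
                    quant.filter_pathways(pathway_tpm, config.pathway_min_tpm),
                    index_label="pathway")
    totals, shares = quant.taxon_totals(tpm_matrix, taxon_of)
    io.write_matrix(out / "taxon_tpm_shares.tsv", shares, index_label="taxon")

    # --- stage: compare ---------------------------------------------------
    rpk_matrix = quant.rpk(mrna.counts, mrna.lengths)
    means_abs = compare.method_means(rpk_matrix, mrna.sample_meta)
    means_tpm = compare.method_means(tpm_matrix, mrna.sample_meta)
    fc_abs = compare.taxon_wide_fc(means_abs, taxon_of)
    fc_tpm = compare.taxon_wide_fc(means_tpm, taxon_of)
    io.write_json(out / "taxon_fold_changes.json", {
        "absolute_scale": fc_abs.to_dict(),
        "tpm_compositional": fc_tpm.to_dict(),
    })
    report = compare.gene_fc_and_deviation(
        means_tpm, fc_tpm, taxon_of,
        pseudo=config.pseudo_tpm, threshold=config.deviation_threshold)
    io.write_matrix(out / "gene_deviations.tsv", report, index_label="feature")

    slopes = {}
    for taxon in fc_abs.index:
        feats = [f for f, t in taxon_of.items() if t == taxon and f in means_abs.index]
        slopes[taxon] = compare.method_regression(means_abs.loc[feats])
    slopes["total"] = compare.method_regression(means_abs)
    io.write_json(out / "regression_slopes.json", slopes)

    ko_by_taxon = {}
    for taxon in fc_abs.index:
        feats = [f for f, t in taxon_of.items() if t == taxon]
        block = tpm_matrix.loc[[f for f in feats if f in tpm_matrix.index]]
        ko_by_taxon[taxon] = quant.aggregate_ko(block, ko_of)
    panel = dict(quant.STRESS_PANEL)
    panel.update(quant._PANELS["markers"])
    panel.update(quant.SULFUR_GLOBULE_PANEL)
    io.write_table(out / "panel_report.tsv", compare.panel_report(
        ko_by_taxon, panel, mrna.sample_meta))

    heat = {}
    for taxon, block in ko_by_taxon.items():
        ptpm = quant.aggregate_sets(block.drop(index=quant.REMAINDER, errors="ignore"),
                                    hierarchy, "pathway")
        z = compare.normalized_heatmap_values(ptpm, pseudo=config.pseudo_tpm)
        z.index = [f"{taxon}|{p}" for p in z.index]
        heat[taxon] = z
    io.write_matrix(out / "heatmap_z.tsv", pd.concat(heat.values()),
                    index_label="taxon|pathway")

    # --- manifest ---------------------------------------------------------
    manifest = {"seed": config.seed, "files": {}}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    io.write_json(out / "manifest.json", manifest)
    return manifest
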