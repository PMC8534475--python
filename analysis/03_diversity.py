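#!/usr/bin/env python
"""Diversity analysis of the rRNA OTU tables: alpha diversity per sample,
weighted UniFrac + PCoA between samples, and the two hypothesis tests
(Mann-Whitney U on alpha metrics and per-taxon abundances; PERMANOVA on
the UniFrac matrix, 999 permutations).

Expects 02_rrna_assignment.py to have produced results/rrna/; re-simulates
the same community (same seed) for the tree and metadata.
"""

from pathlib import Path

import pandas as pd

from stabilimeta import diversity, io, synthio, taxassign

SEED = 1
RESULTS = Path("results/diversity")


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    cfg = synthio.SimConfig(seed=SEED)
    truth = synthio.build_ground_truth(cfg)
    meta = truth.sample_meta

    otu_path = Path("results/rrna/otu_counts.tsv")
    if not otu_path.exists():
        raise SystemExit("run analysis/02_rrna_assignment.py first")
    otu = io.read_matrix(otu_path)
    # tips are identifiers: re-key OTUs by their representative
    ident = io.read_matrix(Path("results/rrna/identifier_counts.tsv"))
    otu_map = taxassign.cluster_references(
        {i: truth.references[i] for i in ident.index}, 0.95)
    rep_table = otu.rename(index=otu_map.representatives)

    alpha = pd.DataFrame({
        "richness": [diversity.richness(rep_table[s]) for s in rep_table],
        "shannon": [diversity.shannon(rep_table[s], 2) for s in rep_table],
        "faith_pd": [diversity.faith_pd(rep_table[s], truth.tree)
                     for s in rep_table],
    }, index=rep_table.columns)
    io.write_matrix(RESULTS / "alpha_diversity.tsv", alpha, index_label="sample_id")

    depths = [10, 50, 100, 500, 1000, 5000, 10000]
    depths = [d for d in depths if d <= int(rep_table.sum(axis=0).min())]
    io.write_matrix(RESULTS / "rarefaction.tsv",
                    taxassign.rarefy_curve(rep_table, depths).round(3),
                    index_label="depth")

    dm = diversity.beta_diversity(rep_table, truth.tree)
    io.write_matrix(RESULTS / "weighted_unifrac.tsv", dm.round(8),
                    index_label="sample_id")
    coords, explained, eigvals = diversity.pcoa(dm)
    io.write_matrix(RESULTS / "pcoa_coordinates.tsv",
                    coords.iloc[:, :4].round(6), index_label="sample_id")
    io.write_json(RESULTS / "pcoa_eigen.json", {
        "proportion_explained": explained.round(4).to_dict()})

    groups_is = list(meta.index[meta["method"] == "in_situ"])
    groups_ob = list(meta.index[meta["method"] == "onboard"])
    tests = {}
    for name in alpha.columns:
        u, p = diversity.mann_whitney(alpha.loc[groups_is, name],
                                      alpha.loc[groups_ob, name])
        tests[name] = {"U": u, "p": p}
    f_stat, p_perm = diversity.permanova(dm, meta["method"], n_perm=999,
                                         seed=SEED)
    tests["permanova_unifrac"] = {"pseudo_F": f_stat, "p": p_perm}
    io.write_json(RESULTS / "hypothesis_tests.json", tests)

    print("alpha diversity (mean in_situ vs onboard):")
    for name in alpha.columns:
        print(f"  {name:>9}: {alpha.loc[groups_is, name].mean():8.2f} vs "
              f"{alpha.loc[groups_ob, name].mean():8.2f}  "
              f"(Mann-Whitney p = {tests[name]['p']:.3f})")
    print(f"PERMANOVA on weighted UniFrac: pseudo-F = {f_stat:.2f}, "
          f"p = {p_perm:.3f} (999 permutations)")
    print(f"PCoA axis 1 explains {explained['PC1']:.1%}")


if __name__ == "__main__":
    main()
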