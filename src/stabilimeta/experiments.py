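"""Simulation studies over the synthetic communities.

Each function runs a self-contained experiment at the study conditions and
returns plain dictionaries of summary numbers: read-assignment recovery,
taxon-wide fold-change / regression-slope recovery, gene-specific deviation
detection (power and false-positive rate), and PERMANOVA type-I error
calibration.  These back both the numbered analysis scripts and the
acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from stabilimeta import compare, diversity, mrna_annot, quant, synthio, taxassign


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(entropy=int(seed), spawn_key=(k,)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# rRNA assignment recovery
# ---------------------------------------------------------------------------

def assignment_recovery(
    seed: int = 0,
    reads_per_sample: int = 10_000,
    n_samples_per_method: tuple[int, int] = (6, 7),
    ambiguity_rate: float = 0.2,
) -> dict:
    """Assign and disambiguate simulated rRNA reads against ground truth.

    Reports the accuracy on unambiguous above-threshold reads (should be
    exact), the accuracy of the two-pass disambiguation on ambiguous reads,
    and the majority-class baseline of the tied sets (the best constant
    per-set guess under the true composition).
    """
    cfg = synthio.SimConfig(
        seed=seed,
        reads_per_sample=reads_per_sample,
        n_samples_per_method=n_samples_per_method,
        ambiguity_rate=ambiguity_rate,
    )
    truth = synthio.build_ground_truth(cfg)
    rrna = synthio.simulate_rrna_samples(cfg, truth)
    thresholds = taxassign.AssignmentThresholds()
    verdicts = {
        s: taxassign.assign_hit_table(rrna.hits[s], thresholds,
                                      all_queries=rrna.truth[s].keys())
        for s in rrna.sample_meta.index
    }
    resolved = taxassign.disambiguate(verdicts, rrna.sample_meta)

    # per-method mean true composition drives the majority-class baseline
    method_pi = {}
    for method in ("in_situ", "onboard"):
        cols = rrna.sample_meta.index[rrna.sample_meta["method"] == method]
        method_pi[method] = truth.composition[cols].mean(axis=1)

    n_unamb = n_unamb_ok = 0
    n_amb = n_amb_ok = n_amb_baseline = 0
    for sample in rrna.sample_meta.index:
        method = rrna.sample_meta.loc[sample, "method"]
        pi = method_pi[method]
        for read, v in verdicts[sample].items():
            true_id = rrna.truth[sample].get(read)
            if true_id is None:
                continue  # sub-threshold by construction
            if v.status == taxassign.ASSIGNED:
                n_unamb += 1
                n_unamb_ok += v.identifiers[0] == true_id
            elif v.status == taxassign.AMBIGUOUS:
                n_amb += 1
                n_amb_ok += resolved[sample][read].identifier == true_id
                majority = max(v.identifiers, key=lambda i: (pi.loc[i], i))
                n_amb_baseline += majority == true_id
    return {
        "n_unambiguous": n_unamb,
        "unambiguous_accuracy": n_unamb_ok / n_unamb if n_unamb else float("nan"),
        "n_ambiguous": n_amb,
        "ambiguous_accuracy": n_amb_ok / n_amb if n_amb else float("nan"),
        "majority_baseline": n_amb_baseline / n_amb if n_amb else float("nan"),
    }


# ---------------------------------------------------------------------------
# Taxon-wide fold-change and slope recovery
# ---------------------------------------------------------------------------

def parameter_recovery(seed: int = 0, n_genes_per_taxon: int = 500,
                       mrna_depth: float = 1.0e6) -> dict:
    """Simulate the mRNA arm, annotate from the hit tables, and recover the
    taxon-wide fold changes and regression slopes on the absolute
    (length-normalized, not per-sample-rescaled) scale."""
    cfg = synthio.SimConfig(seed=seed, n_genes_per_taxon=n_genes_per_taxon,
                            mrna_depth=mrna_depth)
    truth = synthio.build_ground_truth(cfg)
    mrna = synthio.simulate_mrna_samples(cfg, truth)

    taxmap = mrna_annot.TaxonomyMap.from_table(mrna.taxonomy_map, set(cfg.taxon_names))
    tax_hits = mrna_annot.split_feature_hits(mrna.tax_hits, mrna.cds_table)
    tax_ann = mrna_annot.annotate_taxon(tax_hits, taxmap)
    taxon_of = {f: a.taxon for f, a in tax_ann.items()}

    rpk = quant.rpk(mrna.counts, mrna.lengths)
    means = compare.method_means(rpk, mrna.sample_meta)
    fc = compare.taxon_wide_fc(means, taxon_of)
    slopes = {}
    for taxon in cfg.taxon_names:
        feats = [f for f, t in taxon_of.items() if t == taxon]
        slopes[taxon] = compare.method_regression(means.loc[feats])

    tpm = quant.tpm(mrna.counts, mrna.lengths)
    fc_tpm = compare.taxon_wide_fc(
        compare.method_means(tpm, mrna.sample_meta), taxon_of)
    return {
        "degradation_fold": {t: 1.0 / m for t, m in cfg.degradation_by_taxon().items()},
        "true_fold_change": truth.expected_mrna_taxon_fc().to_dict(),
        "recovered_fold_change": fc.to_dict(),
        "recovered_slope": slopes,
        "true_slope": truth.expected_regression_slope().to_dict(),
        "tpm_compositional_fold_change": fc_tpm.to_dict(),
    }


# ---------------------------------------------------------------------------
# Gene-specific deviation detection
# ---------------------------------------------------------------------------

def deviation_detection(
    n_replicates: int = 100,
    seed: int = 0,
    threshold: float = 1.0,
    n_genes_per_taxon: int = 500,
    mrna_depth: float = 1.0e6,
    multiplier: float = 4.0,
) -> dict:
    """Power and false-positive rate of deviation flagging.

    Each replicate injects a few ``multiplier``-fold onboard-specific gene
    effects (|log2 deviation| = 2 in expectation for 4-fold) and flags genes
    with |log2 deviation| > ``threshold``.  The detection operating point
    (default 1.0, i.e. two-fold) sits midway between the sampling noise and
    the injected signal.  Power counts injected genes flagged; the
    false-positive rate counts unperturbed genes flagged.
    """
    n_inj = n_fp = n_pert_total = n_null_total = 0
    for r in range(n_replicates):
        cfg = synthio.SimConfig(
            seed=_child_seed(seed, r),
            n_genes_per_taxon=n_genes_per_taxon,
            mrna_depth=mrna_depth,
            perturbed_genes=None,  # default few injected effects per taxon
        )
        cfg.perturbed_genes = cfg.default_perturbations(multiplier=multiplier)
        truth = synthio.build_ground_truth(cfg)
        mrna = synthio.simulate_mrna_samples(cfg, truth)
        taxon_of = truth.gene_info["taxon"]
        tpm = quant.tpm(mrna.counts, mrna.lengths)
        means = compare.method_means(tpm, mrna.sample_meta)
        fc = compare.taxon_wide_fc(means, taxon_of)
        report = compare.gene_fc_and_deviation(means, fc, taxon_of,
                                               threshold=threshold)
        perturbed = set(truth.perturbed)
        flagged = set(report.index[report["flag"]])
        n_pert_total += len(perturbed)
        n_inj += len(flagged & perturbed)
        n_null = len(report) - len(perturbed)
        n_null_total += n_null
        n_fp += len(flagged - perturbed)
    return {
        "threshold_log2": threshold,
        "n_replicates": n_replicates,
        "power": n_inj / n_pert_total,
        "false_positive_rate": n_fp / n_null_total,
    }


# ---------------------------------------------------------------------------
# PERMANOVA calibration
# ---------------------------------------------------------------------------

def permanova_type1(
    n_sims: int = 500,
    seed: int = 0,
    group_sizes: tuple[int, int] = (6, 7),
    reads_per_sample: int = 500,
    n_perm: int = 999,
    alpha: float = 0.05,
    species_per_taxon: int = 5,
) -> dict:
    """Type-I error of PERMANOVA on weighted UniFrac under a true null.

    Both groups are drawn from the same jittered composition (no degradation)
    so the labels are exchangeable; reports the rejection rate at ``alpha``.
    Group sizes default to the study design (6 vs. 7 samples): with very
    small equal groups the permutation distribution collapses onto a few
    distinct partitions and the achievable significance levels become
    coarse, so 6/7 keeps the null p-value effectively uniform.
    """
    cfg = synthio.SimConfig(seed=seed, species_per_taxon=species_per_taxon,
                            degradation_factors=(1.0,) * 3)
    truth = synthio.build_ground_truth(cfg)
    ids = list(truth.references)
    v = 0.75 ** np.arange(cfg.species_per_taxon)
    v = v / v.sum()
    base = np.concatenate([w * v for w in cfg.taxon_weights])
    rng = np.random.default_rng(_child_seed(seed, 999))

    pvals = []
    n = sum(group_sizes)
    labels = pd.Series(["a"] * group_sizes[0] + ["b"] * group_sizes[1],
                       index=[f"s{i}" for i in range(n)])
    for s in range(n_sims):
        cols = {}
        for i in range(n):
            comp = rng.dirichlet(base * cfg.composition_alpha)
            cols[f"s{i}"] = rng.multinomial(reads_per_sample, comp)
        table = pd.DataFrame(cols, index=ids)
        dm = diversity.beta_diversity(table, truth.tree)
        _, p = diversity.permanova(dm, labels, n_perm=n_perm,
                                   seed=_child_seed(seed, s))
        pvals.append(p)
    pvals = np.array(pvals)
    return {
        "n_sims": n_sims,
        "alpha": alpha,
        "rejection_rate": float((pvals <= alpha).mean()),
        "mean_p": float(pvals.mean()),
    }
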