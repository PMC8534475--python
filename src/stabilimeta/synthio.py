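"""Synthetic two-condition episymbiont community generator.

Emulates every input the analysis consumes, with known ground truth:

* a labelled reference database (one 16S-like sequence per species) evolved
  along a birth-process tree under a Jukes-Cantor-style substitution model
  (no indels, fixed length, so pairwise identity is positionwise-exact);
* rRNA libraries for two stabilization methods (``in_situ`` and
  ``onboard``): each taxon's expected abundance is multiplied by a
  taxon-wide degradation factor in the onboard condition and renormalized,
  then reads are drawn multinomially and emitted as blast-style hit tables
  (plus FASTQ for the QC stage), with a controllable rate of ambiguous
  (tied) top hits and of sub-threshold hits;
* an mRNA arm: per-taxon gene sets with lognormal baseline expression,
  Poisson read counts whose onboard expectation carries the same taxon-wide
  factor plus a few injected gene-specific perturbations, contigs/CDS
  coordinates, and hit tables for taxonomic and functional annotation.

The degradation model is deliberately simple: a single multiplicative
factor per taxon applied to expected abundance before sampling.  This is
the package's operationalization of a transcriptome-wide shift, not a
mechanistic RNA-decay model.

A fixed seed gives byte-identical outputs; each stage derives its own child
generator from the root seed at a fixed offset.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd
import skbio

from stabilimeta.qc import ReadRecord

NUCLEOTIDES = np.array(list("ACGT"))

# fixed per-stage offsets for child RNGs (root-seed reproducibility)
_STAGE_TREE = 11
_STAGE_COMPOSITION = 23
_STAGE_RRNA = 37
_STAGE_MRNA = 53

DEFAULT_TAXA = ("Thiotrichales", "Methylococcales", "Sulfurovum")


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stage,)))


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the study conditions emulated throughout: three major
    taxa whose onboard RNA pools are scaled by per-taxon degradation factors
    (1, 1/1.5, 1/2 — the stable taxon and two faster-degrading ones), six
    in-situ and seven onboard rRNA samples of 10^4 reads, two mRNA samples
    per method at ~10^6 mapped reads over 500 genes per taxon with lognormal
    (sd 1) baselines, a 0.2 ambiguous-top-hit rate, and a handful of 4-fold
    onboard-specific gene perturbations.
    """

    n_taxa: int = 3
    species_per_taxon: int = 10
    ref_len: int = 1500
    tree_birth_rate: float = 1.0
    subst_rate: float = 1.0          # scales all branch lengths (substitutions/site)
    taxon_names: tuple[str, ...] | None = None
    taxon_weights: tuple[float, ...] | None = None   # default (0.45, 0.30, 0.25)-style
    degradation_factors: tuple[float, ...] | None = None  # onboard multiplier per taxon
    n_samples_per_method: tuple[int, int] = (6, 7)   # (in_situ, onboard) rRNA samples
    reads_per_sample: int = 10_000
    composition_alpha: float = 400.0  # Dirichlet concentration for per-sample jitter
    ambiguity_rate: float = 0.2
    subthreshold_rate: float = 0.05
    qc_fail_rate: float = 0.03        # extra junk reads dropped at QC, no hits
    read_len_range: tuple[int, int] = (210, 250)
    # mRNA arm
    n_genes_per_taxon: int = 500
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    n_mrna_samples_per_method: int = 2
    mrna_depth: float = 1.0e6
    gene_len_range: tuple[int, int] = (300, 3000)
    perturbed_genes: tuple[tuple[str, float], ...] | None = None  # None -> default panel
    contigless_fraction: float = 0.05
    annotatable_fraction_taxon: float = 0.86
    annotatable_fraction_ko: float = 0.50
    seed: int = 0
    # tree geometry (substitutions/site before subst_rate scaling)
    within_taxon_height: float = 0.06
    species_floor_height: float = 0.045
    between_taxon_stem: float = 0.08

    def __post_init__(self):
        if self.n_taxa < 1 or self.species_per_taxon < 1:
            raise ValueError("n_taxa and species_per_taxon must be >= 1")
        if self.taxon_names is None:
            base = list(DEFAULT_TAXA)
            names = [base[i] if i < len(base) else f"Taxon{i + 1}" for i in range(self.n_taxa)]
            self.taxon_names = tuple(names)
        if len(self.taxon_names) != self.n_taxa:
            raise ValueError("taxon_names length must equal n_taxa")
        if self.taxon_weights is None:
            w = np.array([0.45, 0.30, 0.25][: self.n_taxa] or [1.0])
            if len(w) < self.n_taxa:
                w = np.ones(self.n_taxa)
            self.taxon_weights = tuple(w / w.sum())
        if self.degradation_factors is None:
            base = [1.0, 1.0 / 1.5, 0.5]
            self.degradation_factors = tuple(
                base[i] if i < 3 else 1.0 for i in range(self.n_taxa)
            )
        if len(self.degradation_factors) != self.n_taxa:
            raise ValueError("degradation_factors length must equal n_taxa")
        if any(f <= 0 for f in self.degradation_factors):
            raise ValueError("degradation factors must be > 0")
        if not 0.0 <= self.ambiguity_rate <= 1.0:
            raise ValueError("ambiguity_rate must be in [0, 1]")
        if self.subst_rate < 0 or self.tree_birth_rate <= 0:
            raise ValueError("rates must be non-negative (birth rate > 0)")

    @property
    def identifiers(self) -> list[str]:
        return [
            f"{t}_sp{s + 1:02d}"
            for t in self.taxon_names
            for s in range(self.species_per_taxon)
        ]

    @property
    def taxon_of_identifier(self) -> dict[str, str]:
        return {
            f"{t}_sp{s + 1:02d}": t
            for t in self.taxon_names
            for s in range(self.species_per_taxon)
        }

    def degradation_by_taxon(self) -> dict[str, float]:
        return dict(zip(self.taxon_names, self.degradation_factors))

    def default_perturbations(self, per_taxon: int = 5, multiplier: float = 4.0,
                              start_index: int = 100) -> tuple[tuple[str, float], ...]:
        """Default injected gene-specific onboard effects: ``per_taxon`` genes
        per taxon at the given onboard-specific multiplier."""
        out = []
        for t in self.taxon_names:
            for i in range(start_index, start_index + per_taxon):
                if i < self.n_genes_per_taxon:
                    out.append((f"{t}_g{i:04d}", multiplier))
        return tuple(out)


# ---------------------------------------------------------------------------
# Reference database and tree
# ---------------------------------------------------------------------------

def _yule_topology(tips: list[str], rng: np.random.Generator):
    """Random bifurcating topology over ``tips`` (nested-tuple form)."""
    nodes: list = list(tips)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = (nodes[i], nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


def _heights(node, parent_h: float, floor: float, rng: np.random.Generator, out: dict):
    """Assign node heights: children shrink geometrically but never below the
    species floor, which bounds minimum between-species divergence."""
    if isinstance(node, str):
        out[id(node)] = (node, 0.0)
        return node
    h = max(floor, parent_h * rng.uniform(0.75, 0.92))
    h = min(h, parent_h)  # branch lengths stay >= 0
    left = _heights(node[0], h, floor, rng, out)
    right = _heights(node[1], h, floor, rng, out)
    out[id(node)] = (node, h)
    return node


def _to_newick(node, heights: dict, parent_h: float) -> str:
    if isinstance(node, str):
        return f"{node}:{parent_h:.10f}"
    h = heights[id(node)][1]
    left = _to_newick(node[0], heights, h)
    right = _to_newick(node[1], heights, h)
    return f"({left},{right}):{parent_h - h:.10f}"


def build_tree(config: SimConfig) -> skbio.TreeNode:
    """Birth-process species tree: taxa hang off the root on long stems so
    between-taxon divergence safely exceeds within-taxon divergence."""
    rng = _rng(config.seed, _STAGE_TREE)
    taxon_newicks = []
    root_h = config.within_taxon_height + config.between_taxon_stem
    for t in config.taxon_names:
        tips = [f"{t}_sp{s + 1:02d}" for s in range(config.species_per_taxon)]
        if len(tips) == 1:
            taxon_newicks.append(f"{tips[0]}:{root_h:.10f}")
            continue
        topo = _yule_topology(tips, rng)
        heights: dict = {}
        _heights(topo, config.within_taxon_height, config.species_floor_height, rng, heights)
        heights[id(topo)] = (topo, config.within_taxon_height)
        sub = _to_newick(topo, heights, root_h)
        taxon_newicks.append(sub)
    newick = "(" + ",".join(taxon_newicks) + "):0.0;"
    tree = skbio.TreeNode.read([newick], format="newick", convert_underscores=False)
    if config.subst_rate != 1.0:
        for node in tree.traverse(include_self=False):
            if node.length is not None:
                node.length *= config.subst_rate
    return tree


def _evolve_jc(tree: skbio.TreeNode, ref_len: int, rng: np.random.Generator) -> dict[str, str]:
    """Evolve sequences down the tree under a Jukes-Cantor-style model."""
    root_seq = rng.integers(0, 4, size=ref_len)
    seqs: dict[str, str] = {}

    def recurse(node, seq):
        for child in node.children:
            ell = child.length or 0.0
            p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * ell))
            child_seq = seq.copy()
            if p > 0:
                hit = rng.random(ref_len) < p
                n_hit = int(hit.sum())
                if n_hit:
                    # jump to one of the three other bases uniformly
                    child_seq[hit] = (child_seq[hit] + rng.integers(1, 4, size=n_hit)) % 4
            if child.is_tip():
                seqs[child.name] = "".join(NUCLEOTIDES[child_seq])
            else:
                recurse(child, child_seq)

    recurse(tree, root_seq)
    return seqs


def make_reference_db(config: SimConfig):
    """Build the labelled reference database.

    Returns ``(references, taxon_table, tree)``: an ``{identifier: sequence}``
    mapping, a DataFrame with columns ``identifier``/``taxon``, and the
    species tree whose tips are the identifiers.
    """
    tree = build_tree(config)
    rng = _rng(config.seed, _STAGE_TREE + 1)
    refs = _evolve_jc(tree, config.ref_len, rng)
    refs = {i: refs[i] for i in config.identifiers}  # stable order
    taxon_table = pd.DataFrame(
        {"identifier": list(refs), "taxon": [config.taxon_of_identifier[i] for i in refs]}
    )
    return refs, taxon_table, tree


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GroundTruth:
    """Everything needed to compute downstream expected values without
    re-simulation."""

    config: SimConfig
    references: dict[str, str]
    taxon_of: dict[str, str]
    otu_of: dict[str, str]            # species resolution: one OTU per identifier
    tree: skbio.TreeNode
    composition: pd.DataFrame          # identifier x rRNA sample, expected proportions
    sample_meta: pd.DataFrame          # rRNA samples
    read_truth: dict[str, dict[str, str | None]] = dataclasses.field(default_factory=dict)
    gene_info: pd.DataFrame | None = None
    expected_expression: pd.DataFrame | None = None  # gene x {in_situ, onboard}
    perturbed: tuple[str, ...] = ()
    mrna_sample_meta: pd.DataFrame | None = None

    def expected_taxon_fold_change(self) -> pd.Series:
        """True taxon-wide fold change on the absolute scale, oriented as
        in_situ / onboard (a value > 1 means degradation onboard)."""
        return pd.Series(
            {t: 1.0 / m for t, m in self.config.degradation_by_taxon().items()},
            name="fold_change",
        )

    def expected_mrna_taxon_fc(self) -> pd.Series:
        """Expected taxon-total fold change of the simulated mRNA arm,
        including any injected gene-specific perturbations (which shift the
        taxon total away from the pure degradation factor)."""
        if self.gene_info is None or self.expected_expression is None:
            raise ValueError("mRNA arm not simulated yet")
        e = self.expected_expression.join(self.gene_info["taxon"])
        totals = e.groupby("taxon").sum()
        return (totals["in_situ"] / totals["onboard"]).rename("fold_change")

    def expected_regression_slope(self) -> pd.Series:
        """Expected through-origin slope of onboard vs. in_situ expected
        expression per taxon: sum(x*y) / sum(x^2)."""
        if self.gene_info is None or self.expected_expression is None:
            raise ValueError("mRNA arm not simulated yet")
        e = self.expected_expression.join(self.gene_info["taxon"])
        out = {}
        for taxon, grp in e.groupby("taxon"):
            x, y = grp["in_situ"], grp["onboard"]
            out[taxon] = float((x * y).sum() / (x * x).sum())
        return pd.Series(out, name="slope")

    def expected_onboard_composition(self, base: np.ndarray) -> np.ndarray:
        m = np.array([
            self.config.degradation_by_taxon()[self.taxon_of[i]]
            for i in self.composition.index
        ])
        scaled = base * m
        return scaled / scaled.sum()

    def to_json(self) -> str:
        payload = {
            "taxon_of": self.taxon_of,
            "otu_of": self.otu_of,
            "degradation_factors": self.config.degradation_by_taxon(),
            "perturbed": list(self.perturbed),
            "composition": {s: self.composition[s].to_dict() for s in self.composition},
        }
        if self.gene_info is not None:
            payload["genes"] = self.gene_info.to_dict(orient="list")
        return json.dumps(payload, indent=2, sort_keys=True)


def build_ground_truth(config: SimConfig) -> GroundTruth:
    refs, taxon_table, tree = make_reference_db(config)
    taxon_of = config.taxon_of_identifier
    otu_of = {i: i for i in refs}  # one species, one sequence, one OTU

    rng = _rng(config.seed, _STAGE_COMPOSITION)
    ids = list(refs)
    # baseline composition: taxon weights split geometrically over species
    v = 0.75 ** np.arange(config.species_per_taxon)
    v = v / v.sum()
    base = np.concatenate([w * v for w in config.taxon_weights])

    n_is, n_ob = config.n_samples_per_method
    samples, methods, specimens = [], [], []
    comp = {}
    deg = np.array([config.degradation_by_taxon()[taxon_of[i]] for i in ids])
    specimen = 0
    for method, n in (("in_situ", n_is), ("onboard", n_ob)):
        for k in range(n):
            specimen += 1
            name = f"{'IS' if method == 'in_situ' else 'OB'}{k + 1}"
            jitter = rng.dirichlet(base * config.composition_alpha)
            expected = jitter if method == "in_situ" else (jitter * deg) / (jitter * deg).sum()
            comp[name] = expected
            samples.append(name)
            methods.append(method)
            specimens.append(specimen)
    composition = pd.DataFrame(comp, index=ids)
    sample_meta = pd.DataFrame(
        {"method": methods, "specimen": specimens}, index=pd.Index(samples, name="sample_id")
    )
    return GroundTruth(
        config=config,
        references=refs,
        taxon_of=taxon_of,
        otu_of=otu_of,
        tree=tree,
        composition=composition,
        sample_meta=sample_meta,
    )


# ---------------------------------------------------------------------------
# rRNA arm
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RrnaSim:
    hits: dict[str, pd.DataFrame]           # sample -> 12-column hit table
    sample_meta: pd.DataFrame
    reads: dict[str, list[ReadRecord]]      # sample -> FASTQ reads (incl. QC casualties)
    truth: dict[str, dict[str, str | None]]  # sample -> read id -> true identifier


def _hit_row(read_id, subject, pident, length, evalue, bitscore):
    return (read_id, subject, round(pident, 1), int(length), 0, 0,
            1, int(length), 1, int(length), evalue, round(bitscore, 1))


def simulate_rrna_samples(config: SimConfig, truth: GroundTruth) -> RrnaSim:
    """Draw rRNA reads multinomially from each sample's expected composition
    and emit FASTQ plus blast-style hit tables.

    Each read's top hit points to its source identifier.  With probability
    ``ambiguity_rate`` the top hit is duplicated at equal E-value/bitscore
    across >= 2 identifiers of the same taxon (a conserved region).  With
    probability ``subthreshold_rate`` the read's hits all fail one assignment
    criterion, exercising the filters.
    """
    if truth.composition.shape[1] == 0:
        raise ValueError("no samples in ground-truth composition")
    rng = _rng(config.seed, _STAGE_RRNA)
    ids = list(truth.composition.index)
    by_taxon: dict[str, list[str]] = {}
    for i in ids:
        by_taxon.setdefault(truth.taxon_of[i], []).append(i)

    hits, reads, read_truth = {}, {}, {}
    lmin, lmax = config.read_len_range
    for sample in truth.composition.columns:
        p = truth.composition[sample].to_numpy()
        if p.sum() <= 0:
            raise ValueError(f"sample {sample}: empty composition")
        counts = rng.multinomial(config.reads_per_sample, p / p.sum())
        rows: list[tuple] = []
        recs: list[ReadRecord] = []
        truths: dict[str, str | None] = {}
        read_no = 0
        source = np.repeat(np.arange(len(ids)), counts)
        rng.shuffle(source)
        for src in source:
            read_no += 1
            rid = f"{sample}_r{read_no:06d}"
            ident = ids[src]
            length = int(rng.integers(lmin, lmax + 1))
            ref = truth.references[ident]
            start = int(rng.integers(0, max(1, len(ref) - length + 1)))
            seq = ref[start:start + length]
            quals = [int(q) for q in rng.integers(30, 39, size=length)]
            # occasional low-quality end bases (trimmed by QC, read survives)
            if rng.random() < 0.2:
                for k in range(int(rng.integers(1, 5))):
                    if k < length:
                        quals[-(k + 1)] = int(rng.integers(2, 18))
            recs.append(ReadRecord(rid, seq, tuple(quals)))

            u = rng.random()
            if u < config.subthreshold_rate:
                # hits that fail exactly one criterion
                mode = rng.integers(0, 3)
                if mode == 0:
                    rows.append(_hit_row(rid, ident, 95.0, length, 1e-40, 1.8 * length))
                elif mode == 1:
                    rows.append(_hit_row(rid, ident, 99.0, 150, 1e-40, 1.8 * 150))
                else:
                    rows.append(_hit_row(rid, ident, 99.0, length, 1e-10, 1.8 * length))
                truths[rid] = None
                continue
            truths[rid] = ident
            pident = float(rng.uniform(98.0, 100.0))
            evalue = 10.0 ** (-float(rng.uniform(30, 80)))
            bitscore = 1.9 * length
            if u < config.subthreshold_rate + config.ambiguity_rate and len(by_taxon[truth.taxon_of[ident]]) >= 2:
                pool = [x for x in by_taxon[truth.taxon_of[ident]] if x != ident]
                k = int(min(len(pool), rng.integers(1, 3)))
                others = list(rng.choice(pool, size=k, replace=False))
                for subject in [ident] + others:
                    rows.append(_hit_row(rid, subject, pident, length, evalue, bitscore))
            else:
                rows.append(_hit_row(rid, ident, pident, length, evalue, bitscore))
                if rng.random() < 0.3 and len(ids) > 1:
                    # a clearly worse secondary hit to some other identifier
                    other = ids[int(rng.integers(0, len(ids)))]
                    if other != ident:
                        rows.append(_hit_row(rid, other, pident - 1.5, length,
                                             evalue * 1e6, bitscore - 30))
        # junk reads with no hits, destined to fail QC
        n_junk = rng.binomial(config.reads_per_sample, config.qc_fail_rate)
        for j in range(n_junk):
            read_no += 1
            rid = f"{sample}_junk{read_no:06d}"
            length = int(rng.integers(40, 120))
            seq = "".join(NUCLEOTIDES[rng.integers(0, 4, size=length)])
            quals = tuple(int(q) for q in rng.integers(2, 15, size=length))
            recs.append(ReadRecord(rid, seq, quals))

        df = pd.DataFrame(rows, columns=[
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"])
        hits[sample] = df
        reads[sample] = recs
        read_truth[sample] = truths
    truth.read_truth = read_truth
    return RrnaSim(hits=hits, sample_meta=truth.sample_meta.copy(),
                   reads=reads, truth=read_truth)


# ---------------------------------------------------------------------------
# mRNA arm
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MrnaSim:
    contigs: dict[str, str]
    cds_table: pd.DataFrame            # contig_id, cds_id, start, end, strand, length
    counts: pd.DataFrame               # feature x sample read counts
    lengths: pd.Series                 # feature -> effective length (bp)
    tax_hits: pd.DataFrame             # feature vs protein-db hit table
    ko_hits: pd.DataFrame              # feature vs KO-labelled-db hit table
    taxonomy_map: pd.DataFrame         # subject, taxid, label
    subject_ko: pd.DataFrame           # subject, ko
    hierarchy: pd.DataFrame            # ko, module, pathway (one row per membership)
    sample_meta: pd.DataFrame


def _panel_kos(taxon_index: int) -> list[str]:
    """KOs deterministically present in each taxon's gene set: the stress
    panel everywhere, pmoA in the methanotroph-like taxon, sulfur-globule
    genes in the thioautotroph-like taxon."""
    from stabilimeta.quant import STRESS_PANEL, PMOA_KO, SULFUR_GLOBULE_PANEL

    kos = list(STRESS_PANEL.values())
    if taxon_index == 0:
        kos += list(SULFUR_GLOBULE_PANEL.values())
    if taxon_index == 1:
        kos.append(PMOA_KO)
    return kos


def simulate_mrna_samples(config: SimConfig, truth: GroundTruth) -> MrnaSim:
    """Simulate the mRNA arm: counts ~ Poisson(lognormal baseline x length
    factor x taxon degradation factor onboard x gene-specific multiplier).

    Counts are on an absolute scale (no per-sample renormalization): onboard
    totals genuinely shrink, as a transcriptome-wide degradation would make
    them.  Hit tables name the true taxon and KO for a configurable fraction
    of features; the rest are unannotatable.
    """
    rng = _rng(config.seed, _STAGE_MRNA)
    perturb = config.perturbed_genes
    if perturb is None:
        perturb = config.default_perturbations()

    genes, taxa, kos = [], [], []
    for t_idx, t in enumerate(config.taxon_names):
        panel = _panel_kos(t_idx)
        for i in range(config.n_genes_per_taxon):
            gene = f"{t}_g{i:04d}"
            genes.append(gene)
            taxa.append(t)
            if i < len(panel):
                kos.append(panel[i])
            else:
                # generic KOs, shared by consecutive gene pairs and across taxa
                kos.append(f"K{50000 + (i - len(panel)) // 2:05d}")
    gene_set = set(genes)
    pert_map = {}
    for gene, mult in perturb:
        if gene not in gene_set:
            raise ValueError(f"perturbed gene {gene!r} not in simulated gene set")
        pert_map[gene] = float(mult)

    n = len(genes)
    lengths = rng.integers(config.gene_len_range[0], config.gene_len_range[1] + 1, size=n)
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    deg = np.array([config.degradation_by_taxon()[t] for t in taxa])
    pert = np.array([pert_map.get(g, 1.0) for g in genes])

    rate_is = baseline * (lengths / 1000.0)
    scale = config.mrna_depth / rate_is.sum()
    rate_is = rate_is * scale
    rate_ob = rate_is * deg * pert

    n_per = config.n_mrna_samples_per_method
    samples, methods = [], []
    counts = {}
    for method, rate in (("in_situ", rate_is), ("onboard", rate_ob)):
        for k in range(n_per):
            name = f"{'mIS' if method == 'in_situ' else 'mOB'}{k + 1}"
            counts[name] = rng.poisson(rate)
            samples.append(name)
            methods.append(method)

    # contigs / CDS coordinates; a small fraction are CDS-less contigs whose
    # feature id is the contig itself
    contigless = rng.random(n) < config.contigless_fraction
    contig_ids, feature_ids, cds_rows = [], [], []
    contigs = {}
    for j, gene in enumerate(genes):
        contig = f"ctg_{gene}"
        contig_ids.append(contig)
        glen = int(lengths[j])
        flank = int(rng.integers(0, 60))
        seq = "".join(NUCLEOTIDES[rng.integers(0, 4, size=glen + 2 * flank)])
        contigs[contig] = seq
        if contigless[j]:
            feature_ids.append(contig)
        else:
            cds_id = f"{contig}.p1"
            feature_ids.append(cds_id)
            strand = "+" if rng.random() < 0.5 else "-"
            cds_rows.append((contig, cds_id, flank + 1, flank + glen, strand, glen))
    cds_table = pd.DataFrame(
        cds_rows, columns=["contig_id", "cds_id", "start", "end", "strand", "length"])

    # annotation hit tables
    annot_tax = rng.random(n) < config.annotatable_fraction_taxon
    annot_ko = rng.random(n) < config.annotatable_fraction_ko
    tax_rows, ko_rows = [], []
    tax_subjects, ko_subjects = {}, {}
    for j, feat in enumerate(feature_ids):
        t = taxa[j]
        evalue = 10.0 ** (-float(rng.uniform(10, 60)))
        bitscore = float(rng.uniform(80, 400))
        if annot_tax[j]:
            subject = f"prot_{t}_{j}"
            tax_subjects[subject] = t
            tax_rows.append(_hit_row(feat, subject, rng.uniform(40, 95), lengths[j] // 3,
                                     evalue, bitscore))
            if rng.random() < 0.3:  # worse hit to another (still allowed) taxon
                t2 = config.taxon_names[int(rng.integers(0, config.n_taxa))]
                subject2 = f"prot_{t2}_alt{j}"
                tax_subjects[subject2] = t2
                tax_rows.append(_hit_row(feat, subject2, rng.uniform(30, 80),
                                         lengths[j] // 3, evalue * 1e4, bitscore - 40))
        else:
            mode = rng.integers(0, 3)
            if mode == 0:
                pass  # no hits at all
            elif mode == 1:
                subject = f"prot_Other_{j}"
                tax_subjects[subject] = "Other"
                tax_rows.append(_hit_row(feat, subject, rng.uniform(40, 95),
                                         lengths[j] // 3, evalue, bitscore))
            else:  # allowed taxon but sub-cutoff E-value
                subject = f"prot_{t}_weak{j}"
                tax_subjects[subject] = t
                tax_rows.append(_hit_row(feat, subject, rng.uniform(30, 60),
                                         lengths[j] // 3, 1e-3, 40.0))
        if annot_ko[j]:
            subject = f"kdb_{kos[j]}_{j}"
            ko_subjects[subject] = kos[j]
            ko_rows.append(_hit_row(feat, subject, rng.uniform(40, 95), lengths[j] // 3,
                                    evalue, bitscore))
        elif rng.random() < 0.5:  # top hit without a KO label
            subject = f"kdb_unlabelled_{j}"
            ko_subjects[subject] = ""
            ko_rows.append(_hit_row(feat, subject, rng.uniform(40, 95), lengths[j] // 3,
                                    evalue, bitscore))

    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    tax_hits = pd.DataFrame(tax_rows, columns=cols)
    ko_hits = pd.DataFrame(ko_rows, columns=cols)

    label_to_taxid = {t: 1000 + i for i, t in enumerate(config.taxon_names)}
    label_to_taxid["Other"] = 9999
    taxonomy_map = pd.DataFrame(
        {"subject": list(tax_subjects),
         "taxid": [label_to_taxid[t] for t in tax_subjects.values()],
         "label": list(tax_subjects.values())})
    subject_ko = pd.DataFrame({"subject": list(ko_subjects), "ko": list(ko_subjects.values())})

    # synthetic KO -> module -> pathway hierarchy covering every simulated KO;
    # consecutive modules share every 7th KO to exercise overlapping sets
    uniq_kos = sorted(set(kos))
    rows = []
    for r, ko in enumerate(uniq_kos):
        module = f"M9{r // 5:04d}"
        pathway = f"path{r // 20:03d}"
        rows.append((ko, module, pathway))
        if r % 7 == 0 and r // 5 + 1 <= (len(uniq_kos) - 1) // 5:
            rows.append((ko, f"M9{r // 5 + 1:04d}", pathway))
    hierarchy = pd.DataFrame(rows, columns=["ko", "module", "pathway"])

    sample_meta = pd.DataFrame(
        {"method": methods,
         "specimen": np.arange(1, len(samples) + 1)},
        index=pd.Index(samples, name="sample_id"))

    feature_index = pd.Index(feature_ids, name="feature")
    counts_df = pd.DataFrame(counts, index=feature_index)
    truth.gene_info = pd.DataFrame(
        {"gene": genes, "feature": feature_ids, "taxon": taxa, "ko": kos,
         "contig": contig_ids, "length": lengths,
         "annotatable_taxon": annot_tax, "annotatable_ko": annot_ko,
         "perturbation": pert}).set_index("feature")
    truth.expected_expression = pd.DataFrame(
        {"in_situ": rate_is, "onboard": rate_ob}, index=feature_index)
    truth.perturbed = tuple(
        truth.gene_info.index[truth.gene_info["perturbation"] != 1.0])
    truth.mrna_sample_meta = sample_meta
    return MrnaSim(
        contigs=contigs, cds_table=cds_table, counts=counts_df,
        lengths=pd.Series(lengths, index=feature_index, name="length"),
        tax_hits=tax_hits, ko_hits=ko_hits, taxonomy_map=taxonomy_map,
        subject_ko=subject_ko, hierarchy=hierarchy, sample_meta=sample_meta)
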