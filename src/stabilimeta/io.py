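"""Readers/writers for the plain-text formats the pipeline exchanges.

All tabular formats are TSV.  Hit tables follow the 12-column blast outfmt-6
convention; abundance/count matrices have a header row of sample ids and a
first column of feature ids.  Round-trips are canonicalizing: line endings
are normalized and floats are written with repr-fidelity.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from pathlib import Path
from typing import Iterable

import pandas as pd
import skbio
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class FormatError(ValueError):
    """Malformed input file; the message names file, line and record."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_fastq(path: str | Path):
    """Yield :class:`stabilimeta.qc.ReadRecord` objects from Sanger FASTQ."""
    from stabilimeta.qc import ReadRecord

    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield ReadRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:  # Biopython names the offending record
        raise FormatError(f"{path}: {exc}") from exc


def write_fastq(path: str | Path, reads: Iterable) -> None:
    with open(path, "w") as fh:
        for read in reads:
            rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
            rec.letter_annotations["phred_quality"] = list(read.qualities)
            SeqIO.write(rec, fh, "fastq")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path), format="newick", convert_underscores=False)


def write_newick(path: str | Path, tree: skbio.TreeNode) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Hit tables (12-column blast-style TSV, no header)
# ---------------------------------------------------------------------------

def read_hits(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            rows.append(fields)
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    if len(df) == 0:
        return empty_hits()
    for col in ("pident", "evalue", "bitscore"):
        df[col] = df[col].astype(float)
    for col in ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"):
        df[col] = df[col].astype(int)
    return df


def empty_hits() -> pd.DataFrame:
    df = pd.DataFrame({c: [] for c in HIT_COLUMNS})
    for col in ("pident", "evalue", "bitscore"):
        df[col] = df[col].astype(float)
    for col in ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"):
        df[col] = df[col].astype(int)
    df["qseqid"] = df["qseqid"].astype(str)
    df["sseqid"] = df["sseqid"].astype(str)
    return df


def write_hits(path: str | Path, hits: pd.DataFrame) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# Matrices and generic tables
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Feature-by-sample matrix: header row = sample ids, first column = feature ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(path: str | Path, matrix: pd.DataFrame, index_label: str = "feature") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    bad = set(meta["method"]) - {"in_situ", "onboard"}
    if bad:
        raise FormatError(f"{path}: unknown stabilization methods {sorted(bad)}")
    return meta


def write_sample_meta(path: str | Path, meta: pd.DataFrame) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """All stage parameters with their standard defaults.

    Defaults reproduce the canonical settings of the analysis: rRNA assignment
    at E <= 1e-20, alignment length >= 180 bp, identity >= 97%; reference OTU
    clustering at 95% identity; functional/taxonomic mRNA annotation at
    E <= 1e-5; PERMANOVA with 999 permutations; pathway display floor at
    TPM > 1000; quality trimming at Q20 with a 200-bp length floor for total
    RNA and Q26/50 bp for rRNA-depleted libraries.
    """

    seed: int = 0
    out_dir: str = "run"
    # qc
    q_left: int = 20
    q_right: int = 20
    min_len: int = 200
    # rRNA assignment
    max_evalue: float = 1e-20
    min_align_len: int = 180
    min_identity: float = 97.0
    # OTU clustering
    cluster_threshold: float = 0.95
    # mRNA annotation
    annot_max_evalue: float = 1e-5
    # diversity
    n_permutations: int = 999
    shannon_base: float = 2.0
    # quant / compare
    pathway_min_tpm: float = 1000.0
    pseudo_tpm: float = 0.01
    deviation_threshold: float = 2.0

    def validate(self) -> None:
        if not (0.0 <= self.min_identity <= 100.0):
            raise ValueError(f"min_identity must be in [0, 100], got {self.min_identity}")
        if not (0.0 <= self.cluster_threshold <= 1.0):
            raise ValueError(f"cluster_threshold must be in [0, 1], got {self.cluster_threshold}")
        if self.max_evalue < 0 or self.annot_max_evalue < 0:
            raise ValueError("E-value cutoffs must be non-negative")
        if self.min_align_len < 1 or self.min_len < 1:
            raise ValueError("length thresholds must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
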