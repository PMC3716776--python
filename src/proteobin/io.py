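"""Shared file I/O: FASTA, TSV tables, and pipeline configuration.

Conventions used across the package:

* every tabular file is TSV with a single header line; ``#`` starts a
  comment line; ``NA`` encodes a missing value;
* gene coordinates are 1-based inclusive (GFF convention);
* DNA sequences are upper-cased on read and validated against
  ``{A, C, G, T, N}``; protein sequences against the 20 standard amino
  acids plus ``X``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("proteobin")

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

NA = "NA"


class ValidationError(ValueError):
    """Raised when an input file violates the package's format contracts."""


def read_fasta(path: str | Path, alphabet: str = "dna") -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` dict.

    Sequences are upper-cased; mixed-case input is accepted and logged.
    ``alphabet`` is ``"dna"`` or ``"protein"``; characters outside the
    alphabet raise :class:`ValidationError` naming the offending record.
    Duplicate ids and empty sequences are hard errors.
    """
    allowed = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            log.info("record %s: mixed-case sequence upcased on read", rec.id)
            seq = seq.upper()
        if rec.id in records:
            raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
        if not seq:
            raise ValidationError(f"empty sequence for record {rec.id!r} in {path}")
        bad = set(seq) - allowed
        if bad:
            raise ValidationError(
                f"record {rec.id!r} in {path}: characters {sorted(bad)} "
                f"outside the {alphabet} alphabet"
            )
        records[rec.id] = seq
    return records


def write_fasta(records: Iterable[tuple[str, str]] | dict[str, str],
                path: str | Path, width: int = 80) -> None:
    """Write ``(id, sequence)`` pairs (or a dict) as wrapped FASTA."""
    if isinstance(records, dict):
        records = records.items()
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a package-dialect TSV (header line, '#' comments, NA missing)."""
    return pd.read_csv(path, sep="\t", comment="#",
                       na_values=[NA], keep_default_na=False, **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False,
              comment: str | None = None) -> None:
    """Write a DataFrame as package-dialect TSV, optional '#' header comment."""
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep=NA)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with published defaults.

    Thresholds default to the study's operating point: composition score
    cutoff 0.01 with a 120% second-best margin, 1000 bp minimum contig
    length, order-3 chain, 95% dereplication identity, top-33% rollup,
    data-relative abundance floor, alpha 0.05 and enrichment FDR 0.10.
    """

    seed: int = 17
    out_dir: str = "proteobin_out"

    # stage toggles
    run_binning: bool = True
    run_genome_stats: bool = True
    run_refdb: bool = True
    run_quant: bool = True

    # binning thresholds
    score_max: float = 0.01
    margin: float = 1.2
    min_len: int = 1000
    order: int = 3

    # reference-database construction
    derep_identity: float = 0.95

    # quantitation
    top_fraction: float = 0.33
    floor: float | str = "auto"
    alpha: float = 0.05
    fdr: float = 0.10
    supernatant_label: str = "supernatant"

    # optional file inputs; when None the synthetic generator is used
    contigs_fasta: str | None = None
    contigs_meta: str | None = None
    peptides_tsv: str | None = None

    # synthetic community / proteome sizes for the demo path
    n_populations: int = 4
    genome_length: int = 250_000
    composition_divergence: float = 0.3
    n_proteins: int = 400
    n_categories: int = 20

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
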