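"""Genome-reconstruction quality metrics.

* **Completeness** — fraction of a 54-gene single-copy marker set (COGs)
  observed in a reconstruction, down-weighting the 30 ribosomal markers
  to 1/30 of a non-ribosomal marker each because ribosomal proteins
  co-occur in large gene clusters and are not independent evidence.
  With the default 54/30 set the denominator is 24 + 30/30 = 25.
* **AAI** — average amino acid identity against a reference proteome:
  the unweighted mean identity of best one-way hits, keeping a hit only
  if it has >= 30% identity over >= 70% of the query gene's length.
* **Assembly statistics** — total bp, contig count, N50, GC%.

The module consumes precomputed tabular alignment hits (BLAST outfmt-6
dialect) and can also produce hit tables itself for desk-scale proteomes
with an exact local aligner (BLOSUM62, affine gap open 11 / extend 1),
so no external aligner is needed in tests.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from . import io as pio

RIBOSOMAL_WEIGHT = 1.0 / 30.0

HIT_COLUMNS = ["query_id", "subject_id", "percent_identity",
               "alignment_length", "query_length", "bitscore"]

#: blast outfmt-6 standard column order (first 12 columns)
OUTFMT6 = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
           "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


# ---------------------------------------------------------------------------
# Marker sets and completeness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerSet:
    """Single-copy marker COGs; ribosomal ones flagged for down-weighting."""

    cogs: tuple[tuple[str, bool], ...]

    def __post_init__(self):
        ids = [c for c, _ in self.cogs]
        if len(ids) != len(set(ids)):
            raise ValueError("marker COG ids must be unique")

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(c for c, _ in self.cogs)

    @property
    def ribosomal_ids(self) -> frozenset[str]:
        return frozenset(c for c, r in self.cogs if r)

    @property
    def n_total(self) -> int:
        return len(self.cogs)

    @property
    def n_ribosomal(self) -> int:
        return len(self.ribosomal_ids)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerSet":
        df = pio.read_tsv(path, dtype={"cog_id": str})
        return cls(tuple(
            (row["cog_id"], bool(int(row["is_ribosomal"])))
            for _, row in df.iterrows()))

    @classmethod
    def default(cls) -> "MarkerSet":
        """The bundled 54-marker set (30 ribosomal-flagged).

        The ids are a documented stand-in list of universal single-copy
        COG families; any 54/30 set with the same structure behaves
        identically under the weighting.
        """
        ref = importlib.resources.files("proteobin.data") / "markers_default.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)


def completeness(present_cogs: Iterable[str],
                 markers: MarkerSet | None = None) -> float:
    """Weighted single-copy-marker completeness, in [0, 1].

    ``(n_nonribosomal_present + n_ribosomal_present/30) /
    (n_nonribosomal_total + n_ribosomal_total/30)``.
    """
    markers = markers or MarkerSet.default()
    present = set(present_cogs)
    unknown = present - markers.ids
    if unknown:
        raise ValueError(f"unknown marker ids: {sorted(unknown)[:5]}")
    ribo = markers.ribosomal_ids
    num = (len(present - ribo)
           + RIBOSOMAL_WEIGHT * len(present & ribo))
    den = ((markers.n_total - markers.n_ribosomal)
           + RIBOSOMAL_WEIGHT * markers.n_ribosomal)
    return num / den


# ---------------------------------------------------------------------------
# AAI
# ---------------------------------------------------------------------------

@dataclass
class AaiResult:
    """Average amino acid identity over retained best one-way hits.

    ``mean_identity`` is NaN (undefined, not zero) when no hit survives
    the filters.  ``coverage_of_reference`` is the fraction of queries
    with a retained hit.
    """

    mean_identity: float
    n_pairs: int
    coverage_of_reference: float

    @property
    def defined(self) -> bool:
        return self.n_pairs > 0


def aai(hits: pd.DataFrame, min_identity: float = 30.0,
        min_coverage: float = 0.70) -> AaiResult:
    """AAI from a hit table (columns: ``HIT_COLUMNS``).

    Per query the single best hit wins (highest bitscore; ties broken by
    identity, then subject id); it is retained iff
    ``percent_identity >= min_identity`` and
    ``alignment_length / query_length >= min_coverage``.  The AAI is the
    unweighted mean identity of retained hits.
    """
    missing = set(HIT_COLUMNS) - set(hits.columns)
    if missing:
        raise ValueError(f"hit table lacks columns {sorted(missing)}")
    if hits.empty:
        return AaiResult(float("nan"), 0, 0.0)
    best = (hits.sort_values(
                ["query_id", "bitscore", "percent_identity", "subject_id"],
                ascending=[True, False, False, True], kind="stable")
            .drop_duplicates("query_id", keep="first"))
    kept = best[
        (best["percent_identity"] >= min_identity)
        & (best["alignment_length"] / best["query_length"] >= min_coverage)
    ]
    n_queries = best["query_id"].nunique()
    if kept.empty:
        return AaiResult(float("nan"), 0, 0.0)
    return AaiResult(
        mean_identity=float(kept["percent_identity"].mean()),
        n_pairs=len(kept),
        coverage_of_reference=len(kept) / n_queries,
    )


def symmetric_aai(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame,
                  min_identity: float = 30.0,
                  min_coverage: float = 0.70) -> AaiResult:
    """Mean of both one-way AAIs (n_pairs summed)."""
    a = aai(hits_ab, min_identity, min_coverage)
    b = aai(hits_ba, min_identity, min_coverage)
    if not (a.defined and b.defined):
        return a if a.defined else b
    return AaiResult((a.mean_identity + b.mean_identity) / 2,
                     a.n_pairs + b.n_pairs,
                     (a.coverage_of_reference + b.coverage_of_reference) / 2)


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


def align_proteomes(queries: Mapping[str, str],
                    subjects: Mapping[str, str]) -> pd.DataFrame:
    """Exact all-vs-all local alignment hit table for small proteomes.

    BLOSUM62 with affine gaps (open 11, extend 1); ``bitscore`` carries
    the raw alignment score, which preserves the best-hit ordering the
    AAI computation needs.  Intended for test- and demo-scale inputs.
    """
    aligner = _protein_aligner()
    rows = []
    for qid, qseq in queries.items():
        for sid, sseq in subjects.items():
            aln = aligner.align(qseq, sseq)
            if len(aln) == 0:
                continue
            top = aln[0]
            counts = top.counts()
            columns = counts.identities + counts.mismatches + counts.gaps
            if columns == 0:
                continue
            rows.append({
                "query_id": qid, "subject_id": sid,
                "percent_identity": 100.0 * counts.identities / columns,
                "alignment_length": columns,
                "query_length": len(qseq),
                "bitscore": float(top.score),
            })
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def read_hits(path: str | Path,
              query_lengths: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Read a blast outfmt-6 dialect hit table into ``HIT_COLUMNS``.

    Accepts the standard 12 columns (then ``query_lengths`` must supply
    each query's length) or 13 columns with ``qlen`` appended.  Columns
    beyond those used are ignored.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", header=None)
    if raw.shape[1] < 12:
        raise ValueError(f"{path}: expected >= 12 tab-separated columns")
    names = OUTFMT6 + [f"extra{i}" for i in range(raw.shape[1] - 12)]
    raw.columns = names
    if raw.shape[1] >= 13:
        qlen = raw["extra0"].astype(int)
    elif query_lengths is not None:
        qlen = raw["qseqid"].map(query_lengths)
        if qlen.isna().any():
            bad = raw.loc[qlen.isna(), "qseqid"].iloc[0]
            raise ValueError(f"no query length for {bad!r}")
    else:
        raise ValueError("12-column input needs query_lengths")
    return pd.DataFrame({
        "query_id": raw["qseqid"], "subject_id": raw["sseqid"],
        "percent_identity": raw["pident"].astype(float),
        "alignment_length": raw["length"].astype(int),
        "query_length": qlen.astype(int),
        "bitscore": raw["bitscore"].astype(float),
    })


# ---------------------------------------------------------------------------
# Assembly statistics
# ---------------------------------------------------------------------------

@dataclass
class AssemblyStats:
    total_bp: int
    n_contigs: int
    n50: int
    gc_percent: float
    n_ge_1kbp: int


def n50(lengths: Sequence[int]) -> int:
    """Largest length L such that contigs >= L sum to >= half the total."""
    if not lengths:
        raise ValueError("N50 of an empty length set is undefined")
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2.0
    cum = np.cumsum(arr)
    return int(arr[np.searchsorted(cum, half)])


def assembly_stats(sequences: Iterable[str]) -> AssemblyStats:
    """Summary statistics over contig sequences (GC over non-N bases)."""
    lengths: list[int] = []
    gc_count = 0
    acgt_count = 0
    for seq in sequences:
        lengths.append(len(seq))
        gc_count += seq.count("G") + seq.count("C")
        acgt_count += len(seq) - seq.count("N")
    if not lengths:
        raise ValueError("no contigs given")
    return AssemblyStats(
        total_bp=sum(lengths),
        n_contigs=len(lengths),
        n50=n50(lengths),
        gc_percent=100.0 * gc_count / acgt_count if acgt_count else float("nan"),
        n_ge_1kbp=sum(1 for L in lengths if L >= 1000),
    )
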