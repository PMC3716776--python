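"""Non-redundant proteomics reference database construction.

Metagenome gene calls are redundant (closely related strains, overlapping
assemblies), which inflates a mass-spectrometry search database.  Each
protein gets a reliability score — contigs with higher read coverage are
less likely to contain sequencing errors, longer sequences are less
likely to be truncated, and genes within 200 bp of a contig end are
penalized — and near-identical sequences (>= 95% global identity) are
collapsed greedily so that only the highest-scoring member of each
cluster is retained.

The default score is additive on a log scale,

    total = log10(1 + coverage) + w_len * log10(length) - w_edge * [near_edge]

with unit weights; a strict lexicographic comparator
(coverage, length, not-near-edge) is available as an alternative
ordering.  Identity is matches over alignment columns of a global
alignment (gaps count against), with a 5-mer prefilter to skip
hopeless pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from . import io as pio

EDGE_DISTANCE = 200  # bp; genes this close to a contig end are penalized


@dataclass
class ProteinRecord:
    """A called protein with its contig context (1-based inclusive coords)."""

    protein_id: str
    contig_id: str
    aa_sequence: str
    contig_coverage: float
    start: int
    end: int
    strand: str
    contig_length: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end <= self.contig_length:
            raise ValueError(
                f"{self.protein_id}: coordinates {self.start}..{self.end} "
                f"invalid on a {self.contig_length} bp contig")

    @property
    def length(self) -> int:
        return len(self.aa_sequence)

    @property
    def near_edge(self) -> bool:
        """Within 200 bp of either contig end (strand-agnostic)."""
        return (self.start <= EDGE_DISTANCE
                or self.end >= self.contig_length - (EDGE_DISTANCE - 1))


@dataclass(frozen=True)
class ReliabilityScore:
    coverage_term: float
    length_term: float
    edge_penalty: float

    @property
    def total(self) -> float:
        return self.coverage_term + self.length_term - self.edge_penalty


def score_protein(rec: ProteinRecord, w_len: float = 1.0,
                  w_edge: float = 1.0) -> ReliabilityScore:
    """Reliability score; higher = more trustworthy sequence."""
    import math
    if rec.length <= 0:
        raise ValueError(f"{rec.protein_id}: non-positive length")
    return ReliabilityScore(
        coverage_term=math.log10(1.0 + rec.contig_coverage),
        length_term=w_len * math.log10(rec.length),
        edge_penalty=w_edge * (1.0 if rec.near_edge else 0.0),
    )


def sort_records(records: Sequence[ProteinRecord],
                 mode: str = "score", w_len: float = 1.0,
                 w_edge: float = 1.0) -> list[ProteinRecord]:
    """Sort descending by reliability (ties by protein_id, ascending).

    ``mode="score"`` uses the additive log-scale score;
    ``mode="lexicographic"`` compares (coverage, length, not near_edge)
    strictly in that order.
    """
    if mode == "score":
        return sorted(records,
                      key=lambda r: (-score_protein(r, w_len, w_edge).total,
                                     r.protein_id))
    if mode == "lexicographic":
        return sorted(records,
                      key=lambda r: (-r.contig_coverage, -r.length,
                                     r.near_edge, r.protein_id))
    raise ValueError(f"unknown sort mode {mode!r}")


@dataclass
class DerepResult:
    """Greedy clusters: representative id -> member ids (incl. itself)."""

    clusters: list[tuple[str, list[str]]]
    identity_threshold: float

    @property
    def representative_ids(self) -> list[str]:
        return [rep for rep, _ in self.clusters]

    def membership(self) -> dict[str, str]:
        """Map every member id to its representative."""
        return {m: rep for rep, members in self.clusters for m in members}


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def global_identity(a: str, b: str,
                    aligner: Align.PairwiseAligner | None = None) -> float:
    """Matches over alignment columns of a global alignment (gaps count)."""
    if a == b:
        return 1.0
    aligner = aligner or _global_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


def _kmer_set(seq: str, k: int = 5) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def dereplicate(records: Sequence[ProteinRecord], threshold: float = 0.95,
                sort_mode: str = "score",
                prefilter_min_shared: float = 0.5) -> DerepResult:
    """Greedy incremental clustering at a global-identity threshold.

    Records are processed in descending reliability order; each joins the
    first existing cluster whose representative it matches at
    ``>= threshold`` identity, else founds a new cluster, so every
    representative is its cluster's highest-scoring member by
    construction.  A 5-mer prefilter (shared fraction of the shorter
    sequence's 5-mers >= ``prefilter_min_shared``) skips alignments that
    cannot reach the threshold.  Deterministic: score ties break on
    protein_id.
    """
    if not records:
        raise ValueError("no records to dereplicate")
    ordered = sort_records(records, mode=sort_mode)
    aligner = _global_aligner()
    reps: list[ProteinRecord] = []
    rep_kmers: list[set[str]] = []
    members: list[list[str]] = []
    for rec in ordered:
        km = _kmer_set(rec.aa_sequence)
        placed = False
        for i, rep in enumerate(reps):
            shared = len(km & rep_kmers[i])
            denom = min(len(km), len(rep_kmers[i]))
            if denom == 0 or shared / denom < prefilter_min_shared:
                continue
            if global_identity(rec.aa_sequence, rep.aa_sequence,
                               aligner) >= threshold:
                members[i].append(rec.protein_id)
                placed = True
                break
        if not placed:
            reps.append(rec)
            rep_kmers.append(km)
            members.append([rec.protein_id])
    return DerepResult(
        clusters=[(rep.protein_id, mem) for rep, mem in zip(reps, members)],
        identity_threshold=threshold,
    )


def dereplicate_bruteforce(records: Sequence[ProteinRecord],
                           threshold: float = 0.95,
                           sort_mode: str = "score") -> DerepResult:
    """Reference greedy clustering from a full pairwise identity matrix.

    No prefilter, no shortcuts: computes all pairwise global identities
    up front and replays the greedy rule.  Quadratic in alignments —
    oracle use only (<= ~50 sequences).
    """
    if not records:
        raise ValueError("no records to dereplicate")
    ordered = sort_records(records, mode=sort_mode)
    aligner = _global_aligner()
    n = len(ordered)
    ident = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i, n):
            d = global_identity(ordered[i].aa_sequence,
                                ordered[j].aa_sequence, aligner)
            ident[i][j] = ident[j][i] = d
    rep_idx: list[int] = []
    members: list[list[str]] = []
    for i, rec in enumerate(ordered):
        for pos, r in enumerate(rep_idx):
            if ident[i][r] >= threshold:
                members[pos].append(rec.protein_id)
                break
        else:
            rep_idx.append(i)
            members.append([rec.protein_id])
    return DerepResult(
        clusters=[(ordered[r].protein_id, mem)
                  for r, mem in zip(rep_idx, members)],
        identity_threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Assembly of records and database export
# ---------------------------------------------------------------------------

def build_records(proteins: Mapping[str, str], genes: pd.DataFrame,
                  contig_info: Mapping[str, tuple[float, int]],
                  ) -> list[ProteinRecord]:
    """Join protein sequences, gene coordinates and contig coverage/length.

    ``contig_info`` maps contig id to ``(coverage, contig_length)``.
    """
    records = []
    for _, row in genes.iterrows():
        pid = row["protein_id"]
        if pid not in proteins:
            raise pio.ValidationError(f"gene table names unknown protein {pid!r}")
        cid = row["contig_id"]
        if cid not in contig_info:
            raise pio.ValidationError(f"no coverage for contig {cid!r}")
        coverage, clen = contig_info[cid]
        records.append(ProteinRecord(
            protein_id=pid, contig_id=cid, aa_sequence=proteins[pid],
            contig_coverage=coverage, start=int(row["start"]),
            end=int(row["end"]), strand=str(row["strand"]),
            contig_length=clen))
    return records


def export_database(result: DerepResult,
                    records: Sequence[ProteinRecord],
                    fasta_path: str | Path,
                    members_path: str | Path | None = None) -> None:
    """Write representatives as FASTA; headers carry provenance.

    Header format: ``>protein_id contig=... score=... cluster_size=N``.
    Optionally writes the cluster membership TSV.
    """
    by_id = {r.protein_id: r for r in records}
    with open(fasta_path, "w") as fh:
        for rep, mem in result.clusters:
            rec = by_id[rep]
            total = score_protein(rec).total
            fh.write(f">{rep} contig={rec.contig_id} score={total:.4f} "
                     f"cluster_size={len(mem)}\n")
            seq = rec.aa_sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    if members_path is not None:
        rows = [{"representative_id": rep, "member_id": m}
                for rep, mem in result.clusters for m in mem]
        pio.write_tsv(pd.DataFrame(rows), members_path,
                      comment=f"greedy clusters at >= "
                              f"{result.identity_threshold:.2f} identity")


def read_database_headers(fasta_path: str | Path) -> pd.DataFrame:
    """Parse the exported database headers back into a summary table."""
    rows = []
    with open(fasta_path) as fh:
        for line in fh:
            if not line.startswith(">"):
                continue
            parts = line[1:].split()
            fields = dict(p.split("=", 1) for p in parts[1:])
            rows.append({"protein_id": parts[0],
                         "contig_id": fields["contig"],
                         "score": float(fields["score"]),
                         "cluster_size": int(fields["cluster_size"])})
    return pd.DataFrame(rows)
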