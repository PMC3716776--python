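"""Seeded synthetic consortium metagenomes and censored metaproteomes.

The generators emulate the statistical structure the downstream analysis
assumes, with full ground truth:

* **Community** — each population's contigs are emitted by its own
  order-3 Markov chain over {A,C,G,T}.  The baseline chain is an i.i.d.
  model matched to the population's GC target; distinctness between
  populations is controlled by ``composition_divergence``, applied as a
  Dirichlet perturbation of the transition rows with concentration
  inversely proportional to the divergence (divergence 0 reproduces the
  baseline exactly, so two such populations are compositionally
  indistinguishable).  Per-contig read coverage is the population mean
  times log-normal noise; single-copy marker genes are planted on
  randomly chosen contigs.
* **Proteome** — a proteins x (fractions x replicates) design with
  log-normal base abundances, per-fraction log-scale effects, log-normal
  replicate noise, 2–8 peptides per protein (a configurable fraction
  shared between two proteins), peptide-level noise following a
  variance–mean power law ``var = a * mean^b``, and hard left-censoring:
  any abundance below the detection floor is reported missing.

Every generator is a pure function of its spec: identical seeds give
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .binning import Contig
from .genome_stats import MarkerSet

_ENC = bytes.maketrans(bytes([0, 1, 2, 3]), b"ACGT")

DEFAULT_FRACTIONS = ("supernatant", "planktonic", "fiber")


# ---------------------------------------------------------------------------
# Community simulation
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """One population: genome size, GC, compositional distinctness, depth."""

    label: str
    genome_length: int = 1_000_000
    gc_target: float = 0.60
    composition_divergence: float = 0.3
    mean_coverage: float = 50.0
    coverage_cv: float = 0.1
    n_marker_genes: int = 54

    def validate(self, n_markers_available: int = 54) -> None:
        if not 0 < self.gc_target < 1:
            raise ValueError(f"{self.label}: gc_target must be in (0,1)")
        if self.mean_coverage <= 0:
            raise ValueError(f"{self.label}: mean_coverage must be > 0")
        if self.composition_divergence < 0:
            raise ValueError(f"{self.label}: divergence must be >= 0")
        if self.genome_length <= 0:
            raise ValueError(f"{self.label}: genome_length must be > 0")
        if self.n_marker_genes > n_markers_available:
            raise ValueError(
                f"{self.label}: n_marker_genes exceeds the marker set size")


@dataclass
class CommunitySpec:
    """A synthetic consortium: populations plus contig-length model.

    ``contig_length_distribution`` is ``(mu, sigma)`` of a log-normal in
    natural-log bp; lengths are clipped to
    ``[min_contig_length, max_contig_length]``.
    """

    populations: list[PopulationSpec]
    contig_length_distribution: tuple[float, float] = (math.log(8000.0), 1.0)
    min_contig_length: int = 1000
    max_contig_length: int | None = 50_000
    rng_seed: int = 0

    def validate(self, n_markers_available: int = 54) -> None:
        if not self.populations:
            raise ValueError("community needs at least one population")
        labels = [p.label for p in self.populations]
        if len(labels) != len(set(labels)):
            raise ValueError("population labels must be unique")
        if self.min_contig_length <= 0:
            raise ValueError("min_contig_length must be > 0")
        for p in self.populations:
            p.validate(n_markers_available)


def baseline_transitions(gc: float, order: int = 3) -> np.ndarray:
    """GC-matched i.i.d. baseline: every k-mer row is (A,C,G,T) probs."""
    row = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return np.tile(row, (4 ** order, 1))


def population_transitions(pop: PopulationSpec,
                           rng: np.random.Generator,
                           order: int = 3,
                           concentration_scale: float = 10.0) -> np.ndarray:
    """Dirichlet-perturbed transition matrix for one population.

    Rows are drawn ``Dirichlet(c * baseline_row)`` with concentration
    ``c = concentration_scale / divergence``; divergence 0 returns the
    baseline exactly.  Larger divergence means rows wander further from
    the GC-matched baseline, i.e. a more distinctive oligonucleotide
    signature.
    """
    base = baseline_transitions(pop.gc_target, order)
    if pop.composition_divergence == 0:
        return base
    conc = concentration_scale / pop.composition_divergence
    rows = np.vstack([rng.dirichlet(conc * r) for r in base])
    # guard against numerically zero entries, renormalize
    rows = np.maximum(rows, 1e-9)
    return rows / rows.sum(axis=1, keepdims=True)


def sample_chain(transitions: np.ndarray, length: int,
                 rng: np.random.Generator, order: int = 3) -> str:
    """Emit ``length`` bases from an order-k Markov chain."""
    if length <= order:
        raise ValueError(f"cannot sample a {length} bp sequence at order {order}")
    marginal = transitions.mean(axis=0)
    first = rng.choice(4, size=order, p=marginal / marginal.sum())
    cum = np.cumsum(transitions, axis=1)
    cum[:, -1] = 1.0
    c0 = cum[:, 0].tolist()
    c1 = cum[:, 1].tolist()
    c2 = cum[:, 2].tolist()
    u = rng.random(length)
    out = list(first)
    mask = 4 ** order - 1
    state = 0
    for b in first:
        state = ((state << 2) & mask) | int(b)
    append = out.append
    for i in range(order, length):
        ui = u[i]
        if ui < c0[state]:
            b = 0
        elif ui < c1[state]:
            b = 1
        elif ui < c2[state]:
            b = 2
        else:
            b = 3
        append(b)
        state = ((state << 2) & mask) | b
    return bytes(out).translate(_ENC).decode("ascii")


def _sample_contig_lengths(spec: CommunitySpec, genome_length: int,
                           rng: np.random.Generator) -> list[int]:
    mu, sigma = spec.contig_length_distribution
    lengths: list[int] = []
    total = 0
    attempts = 0
    while total < genome_length:
        L = int(round(float(rng.lognormal(mu, sigma))))
        attempts += 1
        if attempts > 100_000:
            raise ValueError(
                "min_contig_length rejects essentially all sampled lengths")
        if L < spec.min_contig_length:
            continue
        if spec.max_contig_length is not None:
            L = min(L, spec.max_contig_length)
        remaining = genome_length - total
        if total + L > genome_length and remaining >= spec.min_contig_length:
            L = remaining
        lengths.append(L)
        total += L
    return lengths


def simulate_community(spec: CommunitySpec,
                       markers: MarkerSet | None = None,
                       ) -> tuple[list[Contig], dict[str, str]]:
    """Generate contigs for every population plus the truth map.

    Returns ``(contigs, truth)`` where ``truth`` maps contig id to its
    population label.  Marker genes are planted on randomly chosen
    contigs of each population (a contig may host several markers; each
    planted marker appears on exactly one contig) and labelled with the
    population's taxon.
    """
    markers = markers or MarkerSet.default()
    marker_ids = sorted(markers.ids)
    spec.validate(len(marker_ids))
    rng = np.random.default_rng(spec.rng_seed)
    contigs: list[Contig] = []
    truth: dict[str, str] = {}
    for pop in spec.populations:
        trans = population_transitions(pop, rng)
        lengths = _sample_contig_lengths(spec, pop.genome_length, rng)
        sigma = math.sqrt(math.log(1 + pop.coverage_cv ** 2))
        pop_contigs = []
        for i, L in enumerate(lengths):
            seq = sample_chain(trans, L, rng)
            cov = pop.mean_coverage * float(
                rng.lognormal(-sigma ** 2 / 2, sigma))
            cid = f"{pop.label}_c{i:04d}"
            contig = Contig(id=cid, sequence=seq, coverage=cov)
            pop_contigs.append(contig)
            truth[cid] = pop.label
        planted = rng.choice(len(marker_ids), size=pop.n_marker_genes,
                             replace=False)
        hosts = rng.integers(0, len(pop_contigs), size=pop.n_marker_genes)
        for m, h in zip(planted, hosts):
            pop_contigs[int(h)].markers.append((marker_ids[int(m)], pop.label))
        contigs.extend(pop_contigs)
    return contigs, truth


def write_community(contigs: list[Contig], fasta_path: str | Path,
                    meta_path: str | Path) -> None:
    """Write contigs as wrapped FASTA plus the coverage/markers TSV."""
    pio.write_fasta([(c.id, c.sequence) for c in contigs], fasta_path)
    df = pd.DataFrame([{
        "contig_id": c.id,
        "length": c.length,
        "coverage": round(c.coverage, 4),
        "gc": round(c.gc, 4),
        "markers": ";".join(f"{cog}:{taxon}" for cog, taxon in c.markers),
    } for c in contigs])
    pio.write_tsv(df, meta_path,
                  comment="synthetic community contig metadata; "
                          "markers encoded COGid:taxon;...")


# ---------------------------------------------------------------------------
# Proteome simulation
# ---------------------------------------------------------------------------

@dataclass
class ProteomeSimSpec:
    """Design and noise model for the synthetic metaproteome.

    Abundances are on a linear intensity scale; ``log_*`` parameters are
    natural-log.  ``variance_power_law = (a, b)`` sets the peptide-level
    noise variance ``a * mean^b``.  ``fraction_effect_sd`` draws each
    protein's per-fraction log-fold change (first fraction is the
    reference, effect 0); ``planted_effects`` overrides specific
    ``(protein_index, fraction_index)`` log effects for ground-truth
    power studies.  Observations strictly below ``detection_floor`` are
    reported missing; ``dropout_rate`` adds optional missing-at-random
    dropout (default 0: censoring only).
    """

    n_proteins: int = 400
    n_fractions: int = 3
    n_replicates: int = 3
    log_abundance_mean: float = 11.5
    log_abundance_sd: float = 1.8
    fraction_effect_sd: float = 0.5
    replicate_noise_sd: float = 0.3
    peptides_per_protein: tuple[int, int] = (2, 8)
    peptide_efficiency_sd: float = 0.5
    shared_peptide_fraction: float = 0.10
    variance_power_law: tuple[float, float] = (0.01, 2.0)
    detection_floor: float = 30_000.0
    dropout_rate: float = 0.0
    planted_effects: dict = field(default_factory=dict)
    rng_seed: int = 0

    def validate(self) -> None:
        if min(self.n_proteins, self.n_fractions, self.n_replicates) <= 0:
            raise ValueError("counts must be positive")
        if self.detection_floor <= 0:
            raise ValueError("detection_floor must be > 0")
        for name in ("log_abundance_sd", "fraction_effect_sd",
                     "replicate_noise_sd", "peptide_efficiency_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        a, b = self.variance_power_law
        if a < 0:
            raise ValueError("variance power law coefficient must be >= 0")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ValueError("peptides_per_protein must be a valid range")
        if not 0 <= self.shared_peptide_fraction < 1:
            raise ValueError("shared_peptide_fraction must be in [0, 1)")

    @property
    def fraction_labels(self) -> list[str]:
        if self.n_fractions <= len(DEFAULT_FRACTIONS):
            return list(DEFAULT_FRACTIONS[: self.n_fractions])
        return list(DEFAULT_FRACTIONS) + [
            f"fraction{k}" for k in range(len(DEFAULT_FRACTIONS),
                                          self.n_fractions)]


def simulate_proteome(spec: ProteomeSimSpec,
                      ) -> tuple[pd.DataFrame, dict]:
    """Generate the peptide table plus ground truth.

    Returns ``(peptide_table, truth)``.  The peptide table has columns
    ``peptide_id, protein_ids, fraction, replicate, abundance`` with
    missing (censored) abundances as NaN; ``protein_ids`` is a single id
    or two ids joined by ``;`` for shared peptides.  ``truth`` carries
    ``base_abundance`` (Series), ``fraction_effects`` (protein x fraction
    log effects) and ``sample_abundance`` (protein x (fraction,
    replicate) true means).
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_proteins
    fractions = spec.fraction_labels
    reps = [f"rep{j + 1}" for j in range(spec.n_replicates)]
    protein_ids = [f"P{i + 1:05d}" for i in range(n)]

    base = np.exp(rng.normal(spec.log_abundance_mean,
                             spec.log_abundance_sd, size=n))
    effects = np.zeros((n, spec.n_fractions))
    if spec.fraction_effect_sd > 0 and spec.n_fractions > 1:
        effects[:, 1:] = rng.normal(0.0, spec.fraction_effect_sd,
                                    size=(n, spec.n_fractions - 1))
    for (pi, fk), eff in sorted(spec.planted_effects.items()):
        effects[pi, fk] = eff

    rep_noise = rng.normal(
        0.0, spec.replicate_noise_sd,
        size=(n, spec.n_fractions, spec.n_replicates)
    ) if spec.replicate_noise_sd > 0 else np.zeros(
        (n, spec.n_fractions, spec.n_replicates))
    sample_true = base[:, None, None] * np.exp(
        effects[:, :, None] + rep_noise)  # (n, F, R)

    lo, hi = spec.peptides_per_protein
    n_pep = rng.integers(lo, hi + 1, size=n)
    parent1 = np.repeat(np.arange(n), n_pep)
    total_pep = len(parent1)
    shared = rng.random(total_pep) < spec.shared_peptide_fraction
    parent2 = np.where(shared, rng.integers(0, n, size=total_pep), -1)
    parent2 = np.where(parent2 == parent1, -1, parent2)  # no self-sharing
    eff_pep = np.exp(rng.normal(0.0, spec.peptide_efficiency_sd,
                                size=total_pep))

    flat_true = sample_true.reshape(n, -1)  # (n, F*R)
    mu = eff_pep[:, None] * flat_true[parent1]
    second = parent2 >= 0
    mu[second] += (eff_pep[second, None]
                   * flat_true[parent2[second]])
    a, b = spec.variance_power_law
    obs = mu + rng.normal(size=mu.shape) * np.sqrt(a * mu ** b)
    censored = obs < spec.detection_floor
    if spec.dropout_rate > 0:
        censored |= rng.random(obs.shape) < spec.dropout_rate
    obs = np.where(censored, np.nan, obs)

    n_samples = spec.n_fractions * spec.n_replicates
    frac_col = np.tile(np.repeat(fractions, spec.n_replicates), total_pep)
    rep_col = np.tile(reps * spec.n_fractions, total_pep)
    pep_ids = np.repeat([f"pep{i + 1:06d}" for i in range(total_pep)],
                        n_samples)
    prot_col = [
        protein_ids[p1] if p2 < 0
        else f"{protein_ids[p1]};{protein_ids[p2]}"
        for p1, p2 in zip(parent1, parent2)
    ]
    table = pd.DataFrame({
        "peptide_id": pep_ids,
        "protein_ids": np.repeat(prot_col, n_samples),
        "fraction": frac_col,
        "replicate": rep_col,
        "abundance": obs.reshape(-1),
    })
    cols = pd.MultiIndex.from_product([fractions, reps],
                                      names=["fraction", "replicate"])
    truth = {
        "base_abundance": pd.Series(base, index=protein_ids),
        "fraction_effects": pd.DataFrame(effects, index=protein_ids,
                                         columns=fractions),
        "sample_abundance": pd.DataFrame(flat_true, index=protein_ids,
                                         columns=cols),
    }
    return table, truth


def write_peptides(table: pd.DataFrame, path: str | Path) -> None:
    pio.write_tsv(table, path,
                  comment="synthetic peptide abundances; NA = censored "
                          "below the detection floor")


# ---------------------------------------------------------------------------
# Synthetic gene calls (plumbing for the reference-database stage)
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"
# roughly uniprot-like amino acid background frequencies
_AA_FREQ = np.array([8.3, 1.4, 5.5, 6.8, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7,
                     2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


def simulate_gene_calls(contigs: list[Contig], rng_seed: int = 0,
                        mean_gene_aa: int = 250,
                        duplicate_rate: float = 0.15,
                        mutation_rate: float = 0.02,
                        ) -> tuple[dict[str, str], pd.DataFrame]:
    """Synthetic gene calls: coordinates on contigs plus protein sequences.

    Genes are tiled along each contig with random lengths and gaps;
    protein sequences are drawn from an amino-acid background model (a
    synthetic stand-in — they are not translations of the contig DNA).
    With probability ``duplicate_rate`` a gene instead copies a random
    earlier protein with per-residue ``mutation_rate``, planting the
    near-identical redundancy the dereplication stage exists to remove.

    Returns ``(proteins, genes)``: an ``{id: aa_sequence}`` dict and a
    table with 1-based inclusive ``start``/``end`` nucleotide coordinates.
    """
    rng = np.random.default_rng(rng_seed)
    aa = np.frombuffer(_AA.encode(), dtype=np.uint8)
    proteins: dict[str, str] = {}
    rows = []
    seqs: list[str] = []
    k = 0
    for contig in contigs:
        pos = 1 + int(rng.integers(0, 300))
        while pos + 3 * 60 < contig.length:
            if seqs and rng.random() < duplicate_rate:
                template = seqs[int(rng.integers(0, len(seqs)))]
                arr = np.frombuffer(template.encode(), dtype=np.uint8).copy()
                mut = rng.random(len(arr)) < mutation_rate
                arr[mut] = aa[rng.choice(20, size=int(mut.sum()), p=_AA_FREQ)]
                prot = arr.tobytes().decode()
            else:
                L_aa = int(np.clip(rng.lognormal(math.log(mean_gene_aa), 0.4),
                                   60, 800))
                prot = bytes(
                    aa[rng.choice(20, size=L_aa, p=_AA_FREQ)]).decode()
            nt_len = 3 * (len(prot) + 1)
            if pos + nt_len - 1 > contig.length:
                break
            k += 1
            pid = f"prot{k:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append({"protein_id": pid, "contig_id": contig.id,
                         "start": pos, "end": pos + nt_len - 1,
                         "strand": strand})
            proteins[pid] = prot
            seqs.append(prot)
            pos += nt_len + int(rng.integers(1, 400))
    genes = pd.DataFrame(rows,
                         columns=["protein_id", "contig_id", "start", "end",
                                  "strand"])
    return proteins, genes
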