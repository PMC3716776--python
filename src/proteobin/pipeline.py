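"""End-to-end pipeline: community -> bins -> genome stats -> reference DB
-> quantitative proteome statistics.

Runs either on user-supplied files or, by default, on the synthetic
consortium and proteome generators, and emits one deterministic run
report (versions, seeds, thresholds, per-stage summaries).  All
randomness derives from the single config seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import binning, genome_stats, proteodb, quant, synthetic
from . import io as pio
from .io import PipelineConfig


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage_seed(config: PipelineConfig, offset: int) -> int:
    return (config.seed * 1000 + offset) % (2 ** 31)


def _make_community(config: PipelineConfig):
    coverages = [70.0, 35.0, 25.0, 10.0, 6.0, 4.0]
    gcs = [0.68, 0.65, 0.71, 0.48, 0.63, 0.60]
    pops = [
        synthetic.PopulationSpec(
            label=f"Taxon{i + 1:02d}",
            genome_length=config.genome_length,
            gc_target=gcs[i % len(gcs)],
            composition_divergence=config.composition_divergence,
            mean_coverage=coverages[i % len(coverages)],
            coverage_cv=0.1,
            n_marker_genes=54,
        )
        for i in range(config.n_populations)
    ]
    spec = synthetic.CommunitySpec(populations=pops,
                                   rng_seed=_stage_seed(config, 1))
    return synthetic.simulate_community(spec)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every enabled stage; returns the run report (also written
    to ``<out_dir>/report.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "proteobin",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "score_max": config.score_max, "margin": config.margin,
            "min_len": config.min_len, "order": config.order,
            "derep_identity": config.derep_identity,
            "top_fraction": config.top_fraction, "floor": config.floor,
            "alpha": config.alpha, "fdr": config.fdr,
        },
        "stages": {},
    }

    # ----- inputs ---------------------------------------------------------
    truth: dict[str, str] = {}
    if config.contigs_fasta:
        if not Path(config.contigs_fasta).exists():
            raise StageError("binning",
                             f"contig FASTA {config.contigs_fasta} not found")
        contigs = binning.read_contigs(config.contigs_fasta,
                                       config.contigs_meta)
    else:
        contigs, truth = _make_community(config)
        synthetic.write_community(contigs, out / "contigs.fa",
                                  out / "contigs.tsv")

    # ----- binning --------------------------------------------------------
    bin_of: dict[str, str] = {}
    clusters: list[binning.CoverageCluster] = []
    if config.run_binning:
        try:
            binset = binning.run_binning(
                contigs, order=config.order, score_max=config.score_max,
                margin=config.margin, min_len=config.min_len)
        except ValueError as exc:
            raise StageError("binning", str(exc)) from exc
        binning.write_assignments(binset, out / "assignments.tsv")
        bin_of = binset.bin_of()
        for b in binset.bins:
            members = [c for c in contigs if c.id in set(b.members)]
            if members:
                clusters.extend(
                    binning.extract_coverage_clusters(b.label, members))
        binning.write_cluster_report(clusters, out / "clusters.tsv")
        summary = {
            "n_bins": len(binset.bins),
            "n_assigned": sum(len(b.members) for b in binset.bins),
            "n_unassigned": len(binset.unassigned),
            "n_clusters": len(clusters),
        }
        if truth:
            eligible = [c for c in contigs
                        if c.length >= max(config.min_len, 5000)]
            correct = sum(
                1 for c in eligible
                if bin_of.get(c.id, "").split("+")[0] == truth[c.id])
            summary["recovery_5kbp"] = round(correct / len(eligible), 4)
        report["stages"]["binning"] = summary

    # ----- genome stats ---------------------------------------------------
    if config.run_genome_stats:
        astats = genome_stats.assembly_stats(c.sequence for c in contigs)
        markers = genome_stats.MarkerSet.default()
        per_bin_completeness = {}
        for label in sorted(set(bin_of.values())):
            present = {cog for c in contigs if bin_of.get(c.id) == label
                       for cog, _ in c.markers}
            per_bin_completeness[label] = round(
                genome_stats.completeness(present & markers.ids, markers), 4)
        report["stages"]["genome_stats"] = {
            "total_bp": astats.total_bp,
            "n_contigs": astats.n_contigs,
            "n50": astats.n50,
            "gc_percent": round(astats.gc_percent, 2),
            "n_ge_1kbp": astats.n_ge_1kbp,
            "bin_completeness": per_bin_completeness,
        }

    # ----- reference database --------------------------------------------
    protein_contig: dict[str, str] = {}
    if config.run_refdb:
        proteins, genes = synthetic.simulate_gene_calls(
            contigs, rng_seed=_stage_seed(config, 2))
        contig_info = {c.id: (c.coverage, c.length) for c in contigs}
        records = proteodb.build_records(proteins, genes, contig_info)
        derep = proteodb.dereplicate(records,
                                     threshold=config.derep_identity)
        proteodb.export_database(derep, records, out / "refdb.fa",
                                 out / "refdb_members.tsv")
        protein_contig = dict(zip(genes["protein_id"], genes["contig_id"]))
        report["stages"]["refdb"] = {
            "n_proteins": len(records),
            "n_clusters": len(derep.clusters),
            "identity_threshold": config.derep_identity,
        }

    # ----- quantitative proteomics ----------------------------------------
    if config.run_quant:
        if config.peptides_tsv:
            if not Path(config.peptides_tsv).exists():
                raise StageError(
                    "quant_stats",
                    f"peptide table {config.peptides_tsv} not found")
            peptides = pio.read_tsv(config.peptides_tsv)
        else:
            pspec = synthetic.ProteomeSimSpec(
                n_proteins=config.n_proteins,
                rng_seed=_stage_seed(config, 3))
            peptides, _ = synthetic.simulate_proteome(pspec)
            synthetic.write_peptides(peptides, out / "peptides.tsv")
        try:
            matrix = quant.qrollup(peptides, config.top_fraction)
            norm, sf = quant.normalize(matrix)
            model = quant.fit_variance_model(norm)
            floor = (quant.default_floor(norm)
                     if config.floor in (None, "auto")
                     else float(config.floor))
            diff = quant.differential_test(
                norm, model, floor=floor,
                supernatant_label=config.supernatant_label,
                alpha=config.alpha)
        except ValueError as exc:
            raise StageError("quant_stats", str(exc)) from exc
        pio.write_tsv(norm.reset_index(), out / "abundance_normalized.tsv")
        pio.write_tsv(diff.reset_index(), out / "differential.tsv")

        rng = np.random.default_rng(_stage_seed(config, 4))
        cats = pd.DataFrame({
            "protein_id": norm.index,
            "category": [f"PWY{rng.integers(config.n_categories):03d}"
                         for _ in norm.index],
        })
        flagged = set(diff.index[diff["flagged"]])
        enr = quant.enrichment(flagged, cats, set(norm.index),
                               fdr=config.fdr) if flagged else None
        if enr is not None:
            pio.write_tsv(enr.reset_index(), out / "enrichment.tsv")
        if protein_contig and bin_of:
            # map quant proteins onto bins round-robin via the refdb contigs
            refdb_bins = [bin_of.get(c, "unbinned")
                          for c in protein_contig.values()]
            bin_map = {p: refdb_bins[i % len(refdb_bins)]
                       for i, p in enumerate(norm.index)}
        else:
            bin_map = {}
        summary_tbl = quant.bin_abundance_summary(norm, bin_map, floor)
        pio.write_tsv(summary_tbl.reset_index(names="bin"),
                      out / "bin_abundance.tsv")
        report["stages"]["quant_stats"] = {
            "n_proteins_quantified": int(matrix.shape[0]),
            "n_complete_global": sf.n_complete_global,
            "variance_model": {"a": round(model.a, 6),
                               "b": round(model.b, 4)},
            "floor": round(floor, 2),
            "n_flagged": int(diff["flagged"].sum()),
            "n_enriched": (int(enr["significant"].sum())
                           if enr is not None else 0),
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
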