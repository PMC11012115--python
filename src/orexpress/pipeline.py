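"""End-to-end orchestration: simulate -> trim -> mine -> classify -> quantify
-> call -> tree -> report.

Every stage reads and writes plain-text artifacts in the run directory so
any number in the summary can be recomputed from disk.  The summary JSON
reports the status breakdown of the mined repertoire, per-sample beta-actin
FPKM, the expression criterion and negative-control maximum, expressed-call
counts per sample, and the class of every called gene.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify_locus, predict_tm
from .expression import (
    build_expression_matrix,
    build_kmer_index,
    compute_criterion,
    quantify_sample,
    rank_and_name,
)
from .io_utils import (
    read_fasta,
    read_manifest,
    read_truth_gff3,
    write_fasta,
    write_manifest,
    write_models,
    write_truth_gff3,
)
from .mining import (
    best_hit_filter,
    merge_hits,
    resolve_overlapping_loci,
    search,
    six_frame_translate,
)
from .phylo import align, bootstrap_and_root, write_fasta_alignment, write_phylip
from .qc import TrimParams, trim_fastq_pair
from .synthetic import (
    DEFAULT_CONTROLS,
    GenomeSpec,
    gene_sequences,
    generate_genome,
    simulate_reads,
    table2_like_plans,
)

__all__ = ["RunConfig", "run_pipeline", "report_tables", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    simulate: bool = True
    # external inputs (used when simulate=False)
    genome_fasta: str | None = None
    truth_gff: str | None = None
    queries_faa: str | None = None
    decoys_faa: str | None = None
    class2_refs_fasta: str | None = None
    nonclass2_refs_fasta: str | None = None
    manifest: str | None = None
    # simulation scale
    total_fragments: int = 20_000
    duplicate_fraction: float = 0.1
    # stage parameters
    evalue_cutoff: float = 1e-5
    k: int = 31
    merge_distance: int = 1000
    gap_length: int = 50
    leading_q: int = 20
    trailing_q: int = 20
    window_len: int = 4
    window_q: int = 20
    min_len: int = 36
    controls: list[str] = field(default_factory=lambda: list(DEFAULT_CONTROLS))
    include_controls_in_pool: bool = True
    actin_gene: str = "ACTB"
    omp_gene: str = "OMP"
    reference_sample: str | None = None  # for FPKM ranking; default = first sample
    bootstrap: int = 100
    run_tree: bool = True

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        data = dataclasses.asdict(self)
        data.pop("outdir", None)
        payload = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def trim_params(self) -> TrimParams:
        return TrimParams(
            leading_q=self.leading_q,
            trailing_q=self.trailing_q,
            window_len=self.window_len,
            window_q=self.window_q,
            min_len=self.min_len,
        )


def validate_config(config: RunConfig, manifest: pd.DataFrame) -> None:
    missing = set(config.controls) - set(manifest.sample_id)
    if missing:
        raise ValueError(f"declared control samples missing from manifest: {sorted(missing)}")
    if config.reference_sample and config.reference_sample not in set(manifest.sample_id):
        raise ValueError(f"reference sample {config.reference_sample!r} not in manifest")


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return the summary dict (also written to disk)."""
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    config.to_yaml(os.path.join(out, "config.yaml"))

    # ---- simulate ----------------------------------------------------
    stage = "simulate"
    try:
        if config.simulate:
            spec = GenomeSpec(rng_seed=config.seed, gap_length=config.gap_length)
            genome = generate_genome(spec)
            contigs = genome.contigs
            truth = genome.annotations
            queries = genome.queries
            decoys = genome.decoys
            class2_refs = {"class2_ref": genome.class_refs["class2"]}
            nonclass2_refs = {"nonclass2_ref": genome.class_refs["nonclass2"]}
            write_fasta(contigs, os.path.join(out, "genome.fasta"))
            write_truth_gff3(truth, os.path.join(out, "truth.gff3"))
            write_fasta(queries, os.path.join(out, "queries.faa"))
            write_fasta(decoys, os.path.join(out, "decoys.faa"))
            write_fasta(class2_refs, os.path.join(out, "class2_refs.fasta"))
            write_fasta(nonclass2_refs, os.path.join(out, "nonclass2_refs.fasta"))
            plans, truth_pct = table2_like_plans(
                genome,
                total_fragments=config.total_fragments,
                duplicate_fraction=config.duplicate_fraction,
                seed=config.seed,
            )
            truth_pct.to_csv(os.path.join(out, "truth_expression_percent.tsv"), sep="\t")
            rows = []
            for plan in plans:
                fq1 = os.path.join(out, f"{plan.sample_id}_R1.fastq.gz")
                fq2 = os.path.join(out, f"{plan.sample_id}_R2.fastq.gz")
                simulate_reads(contigs, truth, plan, fq1, fq2)
                rows.append(
                    {
                        "sample_id": plan.sample_id,
                        "tissue_label": plan.tissue_label,
                        "fastq1": fq1,
                        "fastq2": fq2,
                    }
                )
            write_manifest(rows, os.path.join(out, "manifest.tsv"))
            manifest = read_manifest(os.path.join(out, "manifest.tsv"))
        else:
            for name in ("genome_fasta", "truth_gff", "queries_faa", "manifest"):
                if getattr(config, name) is None:
                    raise ValueError(f"simulate=False requires {name}")
            contigs = read_fasta(config.genome_fasta)
            truth = read_truth_gff3(config.truth_gff)
            queries = read_fasta(config.queries_faa)
            decoys = read_fasta(config.decoys_faa) if config.decoys_faa else {}
            class2_refs = read_fasta(config.class2_refs_fasta)
            nonclass2_refs = read_fasta(config.nonclass2_refs_fasta)
            manifest = read_manifest(config.manifest)
        validate_config(config, manifest)
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- trim --------------------------------------------------------
    stage = "trim"
    try:
        params = config.trim_params()
        trimmed = {}
        trim_stats = {}
        for _, row in manifest.iterrows():
            t1 = os.path.join(out, f"{row.sample_id}_trimmed_R1.fastq")
            t2 = os.path.join(out, f"{row.sample_id}_trimmed_R2.fastq")
            stats = trim_fastq_pair(row.fastq1, row.fastq2, t1, t2, None, params)
            trimmed[row.sample_id] = (t1, t2)
            trim_stats[row.sample_id] = stats
    except (ValueError, OSError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- mine --------------------------------------------------------
    stage = "mine"
    try:
        frames = [f for name, seq in sorted(contigs.items()) for f in six_frame_translate(name, seq)]
        hits = search(queries, frames, evalue_cutoff=config.evalue_cutoff)
        loci = merge_hits(hits, config.merge_distance, contigs, config.gap_length)
        kept = resolve_overlapping_loci(
            [l for l in loci if best_hit_filter(l, queries, decoys)[0]]
        )
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- classify ----------------------------------------------------
    stage = "classify"
    try:
        query_tm = {name: predict_tm(prot) for name, prot in queries.items()}
        models = []
        for i, locus in enumerate(sorted(kept, key=lambda l: (l.contig, l.start))):
            models.append(
                classify_locus(
                    f"ORloc{i + 1:04d}",
                    locus,
                    contigs,
                    queries,
                    class2_refs,
                    nonclass2_refs,
                    query_tm,
                    config.gap_length,
                )
            )
        intact = [m for m in models if m.status == "intact"]
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- quantify ----------------------------------------------------
    stage = "quantify"
    try:
        gene_seqs = {m.gene_id: m.coding_seq for m in intact}
        truth_seqs = gene_sequences(contigs, truth)
        # quantify the annotated non-OR transcripts too (normalization gene,
        # OMP and generic housekeeping transcripts) so the per-million
        # denominator reflects the whole library
        for a in truth:
            if not a.is_or:
                gene_seqs[a.gene_id] = truth_seqs[a.gene_id]
        if config.actin_gene not in gene_seqs:
            raise ValueError(f"normalization gene {config.actin_gene!r} not in annotation")
        index = build_kmer_index(gene_seqs, k=config.k)
        quants = [
            quantify_sample(t1, t2, index, sample_id=sid)
            for sid, (t1, t2) in trimmed.items()
        ]
        matrix = build_expression_matrix(
            quants, {g: len(s) for g, s in gene_seqs.items()}, config.actin_gene
        )
        matrix.counts.to_csv(os.path.join(out, "counts.tsv"), sep="\t")
        matrix.fpkm.to_csv(os.path.join(out, "fpkm.tsv"), sep="\t")
        matrix.expression_percent.to_csv(os.path.join(out, "expression_percent.tsv"), sep="\t")
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- call --------------------------------------------------------
    stage = "call"
    try:
        intact_ids = [m.gene_id for m in intact]
        criterion = compute_criterion(
            matrix.expression_percent,
            intact_ids,
            config.controls,
            config.include_controls_in_pool,
        )
        ref_sample = config.reference_sample or manifest.sample_id.iloc[0]
        naming = rank_and_name(matrix.fpkm[ref_sample], intact_ids)
        for m in intact:
            m.fpkm_rank, m.name = naming[m.gene_id]
        write_models(models, os.path.join(out, "models.tsv"), os.path.join(out, "models.gff3"))
        write_fasta(
            {m.gene_id: m.coding_seq for m in intact}, os.path.join(out, "intact_cds.fasta")
        )
        criterion.calls.to_csv(os.path.join(out, "expressed_calls.tsv"), sep="\t")
        criterion.per_sample_stats.to_csv(os.path.join(out, "per_sample_stats.tsv"), sep="\t")
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- tree --------------------------------------------------------
    stage = "tree"
    tree_info: dict = {"built": False}
    try:
        nonclass2 = [m.gene_id for m in intact if m.or_class == "nonclass2"]
        if config.run_tree and len(intact) >= 3 and nonclass2:
            aln = align({m.gene_id: m.coding_seq for m in intact})
            tree = bootstrap_and_root(aln, config.bootstrap, config.seed + 1, nonclass2)
            with open(os.path.join(out, "tree.nwk"), "w") as fh:
                fh.write(tree.newick() + "\n")
            write_fasta_alignment(aln, os.path.join(out, "intact_alignment.fasta"))
            write_phylip(aln, os.path.join(out, "intact_alignment.phy"))
            tree_info = {
                "built": True,
                "n_leaves": len(tree.leaves()),
                "monophyletic_outgroup": tree.monophyletic_outgroup,
                "n_replicates": tree.n_replicates,
            }
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- report ------------------------------------------------------
    stage = "report"
    try:
        status_counts = {
            s: sum(1 for m in models if m.status == s)
            for s in ("intact", "pseudogene", "truncated")
        }
        pct = matrix.expression_percent
        called = [
            (g, s)
            for g in criterion.calls.index
            for s in criterion.calls.columns
            if bool(criterion.calls.loc[g, s])
        ]
        class_by_gene = {m.gene_id: m.or_class for m in models}
        summary = {
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "status_counts": status_counts,
            "beta_actin_fpkm": {s: round(float(matrix.actin_fpkm[s]), 3) for s in pct.columns},
            "criterion_value": round(criterion.criterion_value, 6),
            "negative_control_max": round(criterion.negative_control_max, 6),
            "expressed_calls_per_sample": {
                s: int(criterion.calls[s].sum()) for s in criterion.calls.columns
            },
            "called_genes": sorted({g for g, _s in called}),
            "called_gene_classes": {g: class_by_gene[g] for g, _s in called},
            "trim_stats": trim_stats,
            "tree": tree_info,
        }
        with open(os.path.join(out, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        report_tables(out, matrix, criterion, intact_ids, config)
    except (ValueError, OSError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    return summary


def report_tables(outdir, matrix, criterion, intact_ids, config) -> None:
    """Write the per-sample summary table and the long-format expression table.

    The summary table rows are: beta-actin FPKM; OMP FPKM and expression %;
    mean +/- sd (ddof=1, 0 when n=1) of FPKM and expression % over intact ORs
    with non-zero expression.  Values are rendered to 3 decimal places.
    """
    fpkm_df = matrix.fpkm
    pct = matrix.expression_percent
    samples = list(fpkm_df.columns)
    sub_f = fpkm_df.loc[[g for g in intact_ids if g in fpkm_df.index]]
    sub_p = pct.loc[sub_f.index]

    def mean_sd(series: pd.Series) -> str:
        nz = series[series > 0]
        if nz.empty:
            return "0.000 ± 0.000"
        sd = float(nz.std(ddof=1)) if len(nz) > 1 else 0.0
        return f"{float(nz.mean()):.3f} ± {sd:.3f}"

    rows = {"beta_actin_fpkm": [f"{float(matrix.actin_fpkm[s]):.3f}" for s in samples]}
    if config.omp_gene in fpkm_df.index:
        rows["omp_fpkm"] = [f"{float(fpkm_df.loc[config.omp_gene, s]):.3f}" for s in samples]
        rows["omp_expression_pct"] = [f"{float(pct.loc[config.omp_gene, s]):.3f}" for s in samples]
    rows["intact_or_fpkm_mean_sd"] = [mean_sd(sub_f[s]) for s in samples]
    rows["intact_or_expression_pct_mean_sd"] = [mean_sd(sub_p[s]) for s in samples]
    rows["n_nonzero_intact_ors"] = [str(int((sub_p[s] > 0).sum())) for s in samples]
    table2 = pd.DataFrame(rows, index=samples).T
    table2.to_csv(f"{outdir}/table2_analog.tsv", sep="\t")

    long = (
        sub_p.reset_index(names="gene_id")
        .melt(id_vars="gene_id", var_name="sample_id", value_name="expression_pct")
        .sort_values(["gene_id", "sample_id"])
    )
    long["called"] = [
        bool(criterion.calls.loc[g, s]) for g, s in zip(long.gene_id, long.sample_id)
    ]
    long.to_csv(f"{outdir}/expression_long.tsv", sep="\t", index=False)
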