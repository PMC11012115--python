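"""Generate the synthetic study inputs: genome, truth annotation, libraries.

Writes a whale-like toy genome (24 planted OR genes: 12 intact across the
two classes, 9 pseudogenes across three defect modes, 3 gap-truncated, plus
beta-actin/OMP analogs, filler transcripts and a decoy gene), the truth
GFF3, the ancestral query and decoy proteins, and six paired-end RNA-seq
libraries with the study's expression structure (frontoturbinal high,
ethmoturbinal intermediate, anterior/respiratory low, three negative
controls).
"""

import argparse
import collections
import os

from orexpress.io_utils import write_fasta, write_manifest, write_truth_gff3
from orexpress.synthetic import (
    GenomeSpec,
    generate_genome,
    simulate_reads,
    table2_like_plans,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default="results/run")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--total-fragments", type=int, default=100_000)
    args = ap.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    genome = generate_genome(GenomeSpec(rng_seed=args.seed))
    write_fasta(genome.contigs, f"{args.outdir}/genome.fasta")
    write_truth_gff3(genome.annotations, f"{args.outdir}/truth.gff3")
    write_fasta(genome.queries, f"{args.outdir}/queries.faa")
    write_fasta(genome.decoys, f"{args.outdir}/decoys.faa")
    write_fasta({"class2_ref": genome.class_refs["class2"]}, f"{args.outdir}/class2_refs.fasta")
    write_fasta(
        {"nonclass2_ref": genome.class_refs["nonclass2"]}, f"{args.outdir}/nonclass2_refs.fasta"
    )

    status = collections.Counter(
        a.true_status for a in genome.annotations if a.is_or
    )
    print(f"genome: {len(genome.contigs)} contigs, {sum(map(len, genome.contigs.values()))} bp")
    print(f"planted ORs by status: {dict(status)}")

    plans, truth_pct = table2_like_plans(
        genome, total_fragments=args.total_fragments, seed=args.seed
    )
    truth_pct.to_csv(f"{args.outdir}/truth_expression_percent.tsv", sep="\t")
    rows = []
    for plan in plans:
        fq1 = f"{args.outdir}/{plan.sample_id}_R1.fastq.gz"
        fq2 = f"{args.outdir}/{plan.sample_id}_R2.fastq.gz"
        res = simulate_reads(genome.contigs, genome.annotations, plan, fq1, fq2)
        rows.append(
            {"sample_id": plan.sample_id, "tissue_label": plan.tissue_label, "fastq1": fq1, "fastq2": fq2}
        )
        print(
            f"  {plan.sample_id} ({plan.tissue_label}): {res.n_pairs_written} pairs "
            f"({res.n_duplicates} planted duplicates)"
        )
    write_manifest(rows, f"{args.outdir}/manifest.tsv")
    print(f"inputs written to {args.outdir}")


if __name__ == "__main__":
    main()
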