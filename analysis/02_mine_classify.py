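"""Mine OR loci from the genome and classify intact / pseudogene / truncated.

Runs the six-frame translated search against the ancestral OR queries
(E-value cut-off 1e-5), merges hits into candidate loci, discards loci whose
best reference is a non-OR decoy, reconstructs each surviving open reading
frame and classifies its status and class.  Compares the result against the
planted truth.
"""

import argparse

import pandas as pd

from orexpress.classify import classify_locus, predict_tm
from orexpress.io_utils import read_fasta, read_truth_gff3, write_fasta, write_models
from orexpress.mining import (
    best_hit_filter,
    merge_hits,
    resolve_overlapping_loci,
    search,
    six_frame_translate,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default="results/run")
    ap.add_argument("--evalue", type=float, default=1e-5)
    args = ap.parse_args()
    out = args.outdir

    contigs = read_fasta(f"{out}/genome.fasta")
    truth = read_truth_gff3(f"{out}/truth.gff3")
    queries = read_fasta(f"{out}/queries.faa")
    decoys = read_fasta(f"{out}/decoys.faa")
    class2_refs = read_fasta(f"{out}/class2_refs.fasta")
    nonclass2_refs = read_fasta(f"{out}/nonclass2_refs.fasta")

    frames = [f for name, seq in sorted(contigs.items()) for f in six_frame_translate(name, seq)]
    hits = search(queries, frames, evalue_cutoff=args.evalue)
    loci = merge_hits(hits, 1000, contigs)
    kept = resolve_overlapping_loci(
        [l for l in loci if best_hit_filter(l, queries, decoys)[0]]
    )
    print(f"{len(hits)} hits -> {len(loci)} candidate loci -> {len(kept)} kept after best-hit filter")

    qtm = {n: predict_tm(p) for n, p in queries.items()}
    models = [
        classify_locus(f"ORloc{i + 1:04d}", locus, contigs, queries, class2_refs, nonclass2_refs, qtm)
        for i, locus in enumerate(sorted(kept, key=lambda l: (l.contig, l.start)))
    ]
    write_models(models, f"{out}/models.tsv", f"{out}/models.gff3")
    write_fasta(
        {m.gene_id: m.coding_seq for m in models if m.status == "intact"},
        f"{out}/intact_cds.fasta",
    )

    counts = pd.Series([m.status for m in models]).value_counts()
    print("status counts:", counts.to_dict())

    # accuracy against the planted truth
    n_status = n_class = n_intact = 0
    for ann in truth:
        if not ann.is_or:
            continue
        match = [m for m in models if m.contig == ann.contig and m.start < ann.end and m.end > ann.start - 1]
        if len(match) == 1 and match[0].status == ann.true_status:
            n_status += 1
        if ann.true_status == "intact":
            n_intact += 1
            if len(match) == 1 and match[0].or_class == ann.true_class:
                n_class += 1
    n_or = sum(1 for a in truth if a.is_or)
    print(f"status recovery: {n_status}/{n_or}; intact class recovery: {n_class}/{n_intact}")


if __name__ == "__main__":
    main()
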