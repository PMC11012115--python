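import os

import pytest

from orexpress.classify import classify_locus, predict_tm
from orexpress.expression import build_expression_matrix, build_kmer_index, quantify_sample
from orexpress.mining import (
    best_hit_filter,
    merge_hits,
    resolve_overlapping_loci,
    search,
    six_frame_translate,
)
from orexpress.synthetic import (
    GenomeSpec,
    gene_sequences,
    generate_genome,
    simulate_reads,
    table2_like_plans,
)


@pytest.fixture(scope="session")
def genome():
    """One default synthetic genome (24 ORs, housekeeping, OMP, fillers)."""
    return generate_genome(GenomeSpec(rng_seed=1))


@pytest.fixture(scope="session")
def mined(genome):
    """Frames, hits and kept candidate loci for the session genome."""
    frames = [
        f for name, seq in sorted(genome.contigs.items()) for f in six_frame_translate(name, seq)
    ]
    hits = search(genome.queries, frames)
    loci = merge_hits(hits, 1000, genome.contigs)
    kept = resolve_overlapping_loci(
        [l for l in loci if best_hit_filter(l, genome.queries, genome.decoys)[0]]
    )
    return {"frames": frames, "hits": hits, "loci": loci, "kept": kept}


def locus_overlaps(locus, ann) -> bool:
    return locus.contig == ann.contig and locus.start < ann.end and locus.end > ann.start - 1


@pytest.fixture(scope="session")
def truth_locus_map(genome, mined):
    """Truth OR gene id -> its (unique) kept candidate locus."""
    out = {}
    for ann in genome.annotations:
        if not ann.is_or:
            continue
        matches = [l for l in mined["kept"] if locus_overlaps(l, ann)]
        out[ann.gene_id] = matches
    return out


@pytest.fixture(scope="session")
def models(genome, truth_locus_map):
    """Classified gene models keyed by truth gene id."""
    qtm = {n: predict_tm(p) for n, p in genome.queries.items()}
    c2 = {"c2": genome.class_refs["class2"]}
    c1 = {"c1": genome.class_refs["nonclass2"]}
    out = {}
    for gid, loci in truth_locus_map.items():
        if len(loci) == 1:
            out[gid] = classify_locus(gid, loci[0], genome.contigs, genome.queries, c2, c1, qtm)
    return out


@pytest.fixture(scope="session")
def table2_run(genome, tmp_path_factory):
    """Six simulated libraries at full desk scale, quantified end to end."""
    tmp = tmp_path_factory.mktemp("table2")
    plans, truth_pct = table2_like_plans(genome, total_fragments=100_000, seed=1)
    seqs = gene_sequences(genome.contigs, genome.annotations)
    intact = sorted(
        a.gene_id for a in genome.annotations if a.is_or and a.true_status == "intact"
    )
    non_or = sorted(a.gene_id for a in genome.annotations if not a.is_or)
    idx_genes = {g: seqs[g] for g in intact + non_or}
    index = build_kmer_index(idx_genes, 31)
    quants = []
    sims = {}
    for plan in plans:
        fq1 = os.path.join(tmp, f"{plan.sample_id}_R1.fastq")
        fq2 = os.path.join(tmp, f"{plan.sample_id}_R2.fastq")
        sims[plan.sample_id] = simulate_reads(genome.contigs, genome.annotations, plan, fq1, fq2)
        quants.append(quantify_sample(fq1, fq2, index, sample_id=plan.sample_id))
    matrix = build_expression_matrix(quants, {g: len(s) for g, s in idx_genes.items()})
    return {
        "plans": plans,
        "truth_pct": truth_pct,
        "matrix": matrix,
        "quants": {q.sample_id: q for q in quants},
        "sims": sims,
        "intact_or_ids": intact,
        "index": index,
    }
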