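"""Status and class assignment: TM prediction, defects, precedence, truth."""

import numpy as np
import pytest

from orexpress.classify import (
    assign_class,
    classify_locus,
    classify_status,
    predict_tm,
    reconstruct_orf,
)
from orexpress.mining import best_hit_filter, merge_hits, search, six_frame_translate
from orexpress.synthetic import (
    GenomeSpec,
    gene_sequences,
    generate_genome,
    revcomp,
)


# ---------------------------------------------------------------------------
# transmembrane prediction


def test_tm_span_on_ile_block_hand_computed():
    # 19 Ile (KD +4.5) flanked by Arg (KD -4.5): the all-Ile window has mean
    # 4.5 > 1.6 and seeds a span; trimming removes the Arg flanks exactly.
    pep = "R" * 10 + "I" * 19 + "R" * 10
    topo = predict_tm(pep)
    assert topo.spans == [(10, 29)]


def test_no_tm_span_in_all_arg_peptide():
    assert predict_tm("R" * 60).spans == []


def test_short_peptide_has_no_spans():
    assert predict_tm("I" * 10).spans == []


def test_query_templates_show_exactly_seven_spans(genome):
    for qid, prot in genome.queries.items():
        topo = predict_tm(prot)
        truth = genome.query_tm_spans[qid]
        assert len(topo.spans) == 7
        for found, planted in zip(topo.spans, truth):
            assert found == planted


# ---------------------------------------------------------------------------
# status rules


@pytest.mark.parametrize(
    "defects,gap,expected",
    [
        ([], False, "intact"),
        (["frameshift"], False, "pseudogene"),
        (["premature_stop"], False, "pseudogene"),
        (["missing_tm_block"], False, "pseudogene"),
        (["contig_gap"], False, "truncated"),
        (["contig_gap", "premature_stop"], False, "truncated"),  # gap wins
        ([], True, "truncated"),
        (["boundary"], False, "intact"),  # boundary notes do not change status
    ],
)
def test_classify_status_precedence(defects, gap, expected):
    assert classify_status(defects, gap) == expected


# ---------------------------------------------------------------------------
# reconstruction and defect detection on planted truth


def test_intact_or_reconstructs_planted_orf(genome, truth_locus_map):
    seqs = gene_sequences(genome.contigs, genome.annotations)
    intact = [a for a in genome.annotations if a.is_or and a.true_status == "intact"]
    for ann in intact[:4]:
        locus = truth_locus_map[ann.gene_id][0]
        recon = reconstruct_orf(locus, genome.contigs, genome.queries)
        assert recon.coding_seq == seqs[ann.gene_id]
        assert recon.atg_found and recon.stop_found
        assert recon.translation.startswith("M") and "*" not in recon.translation


EXPECTED_DEFECTS = {
    "premature_stop": {"premature_stop"},
    "tm_deletion": {"missing_tm_block"},
}


def test_planted_defects_are_detected_exactly(genome, models):
    for ann in genome.annotations:
        if not ann.is_or:
            continue
        model = models[ann.gene_id]
        assert model.status == ann.true_status, (
            f"{ann.gene_id}: {ann.true_status} classified as {model.status} ({model.defects})"
        )
        if ann.defect_mode in EXPECTED_DEFECTS:
            assert set(model.defects) == EXPECTED_DEFECTS[ann.defect_mode], ann.gene_id
        elif ann.defect_mode == "frameshift":
            assert "frameshift" in model.defects, ann.gene_id
        elif ann.true_status == "truncated":
            assert "contig_gap" in model.defects, ann.gene_id


def test_intact_class_assignment_is_exact(genome, models):
    for ann in genome.annotations:
        if ann.is_or and ann.true_status == "intact":
            model = models[ann.gene_id]
            assert model.or_class == ann.true_class
            assert model.class_margin > 0


def test_intact_models_have_clean_translations(genome, models):
    # stop-codon soundness, independent of the defect detector
    for model in models.values():
        if model.status == "intact":
            assert model.translation.startswith("M")
            assert "*" not in model.translation


# ---------------------------------------------------------------------------
# the loop-deletion boundary case: >=5 deleted residues OUTSIDE any TM span
# must not fire the missing-TM rule, so the gene remains intact


def _plant_single_gene(cds: str, seed: int = 9) -> dict:
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    lead = "".join(bases[rng.integers(0, 4, 800)])
    tail = "".join(bases[rng.integers(0, 4, 800)])
    return {"mini": lead + cds + tail}


def test_loop_deletion_stays_intact(genome):
    cds = genome.class_refs["class2"]
    spans = genome.query_tm_spans["ORQ_class2"]
    # centre of the loop between TM4 and TM5, comfortably outside both spans
    loop_start = spans[3][1] + 4
    assert loop_start + 5 < spans[4][0] - 4
    deleted = cds[: 3 * loop_start] + cds[3 * (loop_start + 5) :]
    contigs = _plant_single_gene(deleted)
    frames = [f for f in six_frame_translate("mini", contigs["mini"])]
    hits = search(genome.queries, frames)
    loci = merge_hits(hits, 1000, contigs)
    assert len(loci) == 1
    model = classify_locus(
        "loopdel",
        loci[0],
        contigs,
        genome.queries,
        {"c2": genome.class_refs["class2"]},
        {"c1": genome.class_refs["nonclass2"]},
    )
    assert "missing_tm_block" not in model.defects
    assert model.status == "intact"


def test_tm_deletion_in_planted_mini_genome_is_pseudogene(genome):
    cds = genome.class_refs["class2"]
    spans = genome.query_tm_spans["ORQ_class2"]
    start = spans[2][0] + 2  # inside TM3
    deleted = cds[: 3 * start] + cds[3 * (start + 5) :]
    contigs = _plant_single_gene(deleted)
    frames = [f for f in six_frame_translate("mini", contigs["mini"])]
    loci = merge_hits(search(genome.queries, frames), 1000, contigs)
    model = classify_locus(
        "tmdel",
        loci[0],
        contigs,
        genome.queries,
        {"c2": genome.class_refs["class2"]},
        {"c1": genome.class_refs["nonclass2"]},
    )
    assert model.defects == ["missing_tm_block"]
    assert model.status == "pseudogene"


# ---------------------------------------------------------------------------
# class assignment edge cases


def test_assign_class_tie_is_unclassified(genome):
    cds = genome.class_refs["class2"]
    same = {"r": cds}
    or_class, margin = assign_class(cds, same, same)
    assert or_class == "unclassified" and margin == 0.0


def test_assign_class_requires_references(genome):
    with pytest.raises(ValueError):
        assign_class(genome.class_refs["class2"], {}, {"r": genome.class_refs["nonclass2"]})


def test_partition_of_kept_loci(genome, models):
    statuses = [m.status for m in models.values()]
    assert len(statuses) == sum(
        statuses.count(s) for s in ("intact", "pseudogene", "truncated")
    ), "every kept locus receives exactly one status"
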