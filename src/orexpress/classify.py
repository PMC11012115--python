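"""Classification of candidate OR loci: intact / pseudogene / truncated.

A locus kept by the best-hit filter is turned into a gene model by extending
its merged hit interval to the nearest in-frame start codon upstream and
stop codon downstream (bounded by 1.5x the query length), translating it
with internal stops retained, and aligning the best query protein against
that translation.  Defects are then read off:

* ``premature_stop`` - an internal stop codon in the reconstructed reading
  frame before the end of the aligned query;
* ``frameshift`` - the locus's supporting hits fall in more than one reading
  frame on the same strand (the signature a 1- or 2-bp indel leaves in a
  translated search);
* ``missing_tm_block`` - at least five consecutive query residues are
  deleted in the subject and the deleted query span intersects a predicted
  transmembrane helix of the query;
* ``contig_gap`` - an assembly-gap N-run overlaps the locus.

A gap-interrupted sequence is labeled ``truncated`` regardless of other
defects; otherwise any of the first three defects makes a ``pseudogene``,
and a defect-free model is ``intact``.  Class-2 versus non-class-2 is
assigned by nearest-reference global alignment of the coding nucleotide
sequence; ties are flagged unclassified.

Transmembrane helices are predicted with a classic Kyte-Doolittle hydropathy
scan: sliding window of 19 residues, windows with mean > 1.6 seed a span,
overlapping seed windows are merged, span ends are trimmed to hydrophobic
residues, and spans shorter than 17 residues are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .mining import CandidateLocus, _free_end_gaps, find_gap_runs, protein_aligner, translate
from .synthetic import CODON_TABLE, revcomp

__all__ = [
    "TMTopology",
    "ORGeneModel",
    "predict_tm",
    "reconstruct_orf",
    "detect_defects",
    "classify_status",
    "assign_class",
    "classify_locus",
    "KYTE_DOOLITTLE",
]

KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

CORE_DEFECTS = ("premature_stop", "frameshift", "missing_tm_block")


@dataclass
class TMTopology:
    hydropathy: np.ndarray
    spans: list[tuple[int, int]]  # aa intervals, 0-based half-open


@dataclass
class ORGeneModel:
    gene_id: str
    contig: str
    start: int  # 0-based half-open, contig coordinates
    end: int
    strand: str
    coding_seq: str
    translation: str
    status: str  # intact | pseudogene | truncated
    or_class: str  # class2 | nonclass2 | unclassified
    class_margin: float
    defects: list[str]
    best_query_id: str
    fpkm_rank: int | None = None
    name: str | None = None


def predict_tm(
    peptide: str, window: int = 19, threshold: float = 1.6, min_span: int = 17
) -> TMTopology:
    """Kyte-Doolittle sliding-window transmembrane-span prediction.

    Unknown residues (X) and stops score 0.  Returns per-residue hydropathy
    and the predicted spans; peptides shorter than the window yield none.
    """
    kd = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in peptide])
    if len(kd) < window:
        return TMTopology(kd, [])
    means = np.convolve(kd, np.ones(window) / window, mode="valid")
    seeds = np.flatnonzero(means > threshold)
    spans: list[tuple[int, int]] = []
    for s in seeds:
        lo, hi = int(s), int(s) + window
        if spans and lo < spans[-1][1]:
            spans[-1] = (spans[-1][0], hi)
        else:
            spans.append((lo, hi))
    trimmed = []
    for lo, hi in spans:
        while lo < hi and kd[lo] < threshold:
            lo += 1
        while hi > lo and kd[hi - 1] < threshold:
            hi -= 1
        if hi - lo >= min_span:
            trimmed.append((lo, hi))
    return TMTopology(kd, trimmed)


@dataclass
class ReconstructedORF:
    coding_seq: str
    translation: str  # internal stops retained as '*', terminal stop excluded
    start: int  # contig coordinates, 0-based half-open
    end: int
    strand: str
    frame: int
    atg_found: bool
    stop_found: bool

    @property
    def boundary_defect(self) -> bool:
        return not (self.atg_found and self.stop_found)


_STOPS = {c for c, aa in CODON_TABLE.items() if aa == "*"}


def reconstruct_orf(
    locus: CandidateLocus,
    contigs: dict[str, str],
    queries: dict[str, str],
    upstream_slack: int = 90,
    end_margin: int = 30,
    length_factor: float = 1.5,
) -> ReconstructedORF:
    """Extend a locus to a full open reading frame in its best hit's frame.

    Scans upstream (in frame) for the nearest ATG within the aligned query
    offset plus ``upstream_slack`` bases, and downstream for a stop codon at
    or beyond the merged hit interval (stops more than ``end_margin`` bases
    before the last hit are premature and retained as '*' in the
    translation).  The scan is bounded by ``length_factor`` times the query
    length; a missing start or stop is recorded as a boundary defect.
    """
    contig_seq = contigs[locus.contig]
    L = len(contig_seq)
    if locus.strand == "+":
        s = contig_seq

        def orient(a, b):
            return a, b
    else:
        s = revcomp(contig_seq)

        def orient(a, b):
            return L - b, L - a

    ostarts = [orient(h.start, h.end) for h in locus.hits]
    leftmost = min(range(len(locus.hits)), key=lambda i: ostarts[i][0])
    hit0 = locus.hits[leftmost]
    start0 = ostarts[leftmost][0]
    hit_end = max(e for _s, e in ostarts)
    query = queries[locus.best_query]

    atg = None
    max_up = 3 * hit0.query_start + upstream_slack
    p = start0
    while p >= 0 and start0 - p <= max_up:
        if s[p : p + 3] == "ATG":
            atg = p
            break
        p -= 3
    atg_found = atg is not None
    if atg is None:
        atg = start0

    bound = atg + 3 * int(length_factor * len(query)) + 3
    codons = []
    stop_found = False
    p = atg
    while p + 3 <= min(bound, len(s)):
        codon = s[p : p + 3]
        codons.append(codon)
        if codon in _STOPS and p + 3 >= hit_end - end_margin:
            stop_found = True
            p += 3
            break
        p += 3
    end = atg + 3 * len(codons)
    cds = "".join(codons)
    translation = translate(cds[:-3] if stop_found else cds)
    g_start, g_end = (atg, end) if locus.strand == "+" else (L - end, L - atg)
    return ReconstructedORF(
        coding_seq=cds,
        translation=translation,
        start=g_start,
        end=g_end,
        strand=locus.strand,
        frame=hit0.frame,
        atg_found=atg_found,
        stop_found=stop_found,
    )


def detect_defects(
    recon: ReconstructedORF,
    locus: CandidateLocus,
    query_protein: str,
    query_tm: TMTopology | None = None,
    contigs: dict[str, str] | None = None,
    gap_length: int = 50,
    min_deletion: int = 5,
) -> list[str]:
    """Defect list for one reconstructed locus (see module docstring)."""
    defects: set[str] = set()

    if len({h.frame for h in locus.hits}) > 1:
        defects.add("frameshift")
    if "*" in recon.translation:
        defects.add("premature_stop")

    if query_tm is None:
        query_tm = predict_tm(query_protein)
    if query_tm.spans and recon.translation:
        for dstart, dend in _deleted_query_runs(query_protein, recon.translation, min_deletion):
            if any(dstart < hi and dend > lo for lo, hi in query_tm.spans):
                defects.add("missing_tm_block")
                break

    contains_gap = locus.contains_gap
    if contigs is not None and not contains_gap:
        region = contigs[locus.contig][min(locus.start, recon.start) : max(locus.end, recon.end)]
        contains_gap = bool(find_gap_runs(region, gap_length))
    if contains_gap:
        defects.add("contig_gap")
    if recon.boundary_defect:
        defects.add("boundary")
    return sorted(defects)


def _deleted_query_runs(query: str, subject: str, min_len: int):
    """Runs of >= min_len consecutive query residues aligned to nothing."""
    aligner = protein_aligner("global")
    aln = aligner.align(query, subject)[0]
    q_blocks, s_blocks = aln.aligned
    for i in range(1, len(q_blocks)):
        q_gap = int(q_blocks[i][0]) - int(q_blocks[i - 1][1])
        s_gap = int(s_blocks[i][0]) - int(s_blocks[i - 1][1])
        if s_gap == 0 and q_gap >= min_len:
            yield int(q_blocks[i - 1][1]), int(q_blocks[i][0])


def classify_status(defects: list[str], contains_gap: bool = False) -> str:
    """Gap wins; else any core defect makes a pseudogene; else intact."""
    if contains_gap or "contig_gap" in defects:
        return "truncated"
    if any(d in CORE_DEFECTS for d in defects):
        return "pseudogene"
    return "intact"


def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    _free_end_gaps(aligner)
    return aligner


def assign_class(
    coding_seq: str,
    class2_refs: dict[str, str],
    nonclass2_refs: dict[str, str],
) -> tuple[str, float]:
    """Nearest-reference class assignment on the coding nucleotide sequence.

    Returns ``(class, margin)`` where margin is the score gap between the
    winning class and the other; an exact tie yields ``("unclassified", 0)``.
    """
    if not class2_refs or not nonclass2_refs:
        raise ValueError("both class reference sets must be non-empty")
    aligner = _nt_aligner()
    best2 = max(float(aligner.score(coding_seq, r)) for r in class2_refs.values())
    best1 = max(float(aligner.score(coding_seq, r)) for r in nonclass2_refs.values())
    if best2 == best1:
        return "unclassified", 0.0
    if best2 > best1:
        return "class2", best2 - best1
    return "nonclass2", best1 - best2


def classify_locus(
    gene_id: str,
    locus: CandidateLocus,
    contigs: dict[str, str],
    queries: dict[str, str],
    class2_refs: dict[str, str],
    nonclass2_refs: dict[str, str],
    query_tm: dict[str, TMTopology] | None = None,
    gap_length: int = 50,
) -> ORGeneModel:
    """Full classification of one kept locus into an :class:`ORGeneModel`."""
    recon = reconstruct_orf(locus, contigs, queries)
    qprot = queries[locus.best_query]
    tm = (query_tm or {}).get(locus.best_query) or predict_tm(qprot)
    defects = detect_defects(recon, locus, qprot, tm, contigs, gap_length)
    status = classify_status(defects, locus.contains_gap)
    or_class, margin = assign_class(recon.coding_seq, class2_refs, nonclass2_refs)
    return ORGeneModel(
        gene_id=gene_id,
        contig=locus.contig,
        start=recon.start,
        end=recon.end,
        strand=locus.strand,
        coding_seq=recon.coding_seq,
        translation=recon.translation,
        status=status,
        or_class=or_class,
        class_margin=margin,
        defects=defects,
        best_query_id=locus.best_query,
    )
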