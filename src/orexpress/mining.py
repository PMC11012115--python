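"""Translated homology search for candidate OR loci.

The genome is translated in all six frames (stop codons kept as ``*``,
codons containing N as ``X``).  Query proteins are aligned locally against
the translated frames under BLOSUM62 with affine gaps (open 11, extend 1),
and raw scores are converted to E-values with the Karlin-Altschul formula
``E = K * m * n * exp(-lambda * S)`` using the standard gapped BLOSUM62
parameters (lambda = 0.267, K = 0.041); ``m`` is the query length and ``n``
the total translated length actually searched.  E-values here are used for
ranking and thresholding (default cut-off 1e-5), not for BLAST bit-exactness.

Because OR genes are single-exon and stop-free in their reading frame while
random DNA is stop-rich, each frame is split at stop codons and only
segments of a minimum length are aligned; after a significant hit the
flanking sub-segments are searched recursively so several genes sharing one
stop-free stretch are all recovered.  Same-strand hits within a merge
distance are merged into candidate loci, and a locus is kept only if the
best-scoring subject of its translation among OR queries plus non-OR decoys
is an OR (ties discard, conservatively).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .synthetic import CODON_TABLE, revcomp

__all__ = [
    "TranslatedFrame",
    "HomologyHit",
    "CandidateLocus",
    "six_frame_translate",
    "search",
    "merge_hits",
    "best_hit_filter",
    "karlin_altschul_evalue",
    "protein_aligner",
]

#: Karlin-Altschul parameters for gapped BLOSUM62 with open 11 / extend 1.
LAMBDA = 0.267
K_PARAM = 0.041
DEFAULT_EVALUE = 1e-5


def translate(seq: str) -> str:
    """Standard-code translation; stops kept as '*', any codon with N -> 'X'."""
    n = len(seq) // 3
    return "".join(CODON_TABLE.get(seq[3 * i : 3 * i + 3], "X") for i in range(n))


@dataclass
class TranslatedFrame:
    """One of the six conceptual translations of a contig.

    ``frame`` is +1/+2/+3 (forward, offset frame-1) or -1/-2/-3 (reverse
    complement, offset |frame|-1).  :meth:`genomic_interval` maps a peptide
    slice back to a 0-based half-open genomic interval on the contig.
    """

    contig: str
    frame: int
    peptide: str
    contig_length: int

    def genomic_interval(self, pep_start: int, pep_end: int) -> tuple[int, int]:
        off = abs(self.frame) - 1
        if self.frame > 0:
            return off + 3 * pep_start, off + 3 * pep_end
        # positions on the reverse-complement strand, mapped to forward coords
        end = self.contig_length - off - 3 * pep_start
        start = self.contig_length - off - 3 * pep_end
        return start, end

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


def six_frame_translate(contig: str, seq: str) -> list[TranslatedFrame]:
    """All six reading frames of ``seq`` (may be empty for short input)."""
    frames = []
    rc = revcomp(seq)
    for off in range(3):
        frames.append(TranslatedFrame(contig, off + 1, translate(seq[off:]), len(seq)))
        frames.append(TranslatedFrame(contig, -(off + 1), translate(rc[off:]), len(seq)))
    return frames


@dataclass
class HomologyHit:
    query_id: str
    contig: str
    start: int  # genomic, 0-based half-open
    end: int
    strand: str
    frame: int
    score: float
    evalue: float
    query_start: int
    query_end: int
    subject_peptide: str


@dataclass
class CandidateLocus:
    contig: str
    start: int
    end: int
    strand: str
    hits: list[HomologyHit]
    best_query: str
    contains_gap: bool = False

    @property
    def frames(self) -> set[int]:
        return {h.frame for h in self.hits}

    @property
    def best_hit(self) -> HomologyHit:
        return max(self.hits, key=lambda h: h.score)


def protein_aligner(mode: str = "local") -> Align.PairwiseAligner:
    """BLOSUM62 affine-gap aligner (open 11, extend 1)."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = mode
    if mode == "global":
        _free_end_gaps(aligner)
    return aligner


def _free_end_gaps(aligner: Align.PairwiseAligner) -> None:
    """Do not charge terminal overhangs (semi-global alignment)."""
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    """E = K * m * n * exp(-lambda * S)."""
    return float(K_PARAM * m * n * np.exp(-LAMBDA * score))


def _segments(peptide: str, min_len: int):
    """Stop-free segments of a frame peptide, as (offset, subsequence)."""
    pos = 0
    for part in peptide.split("*"):
        if len(part) >= min_len:
            yield pos, part
        pos += len(part) + 1


_SAFE = set("ARNDCQEGHILKMFPSTWYVBZX*")


def _sanitize(peptide: str) -> str:
    return "".join(c if c in _SAFE else "X" for c in peptide)


def search(
    queries: dict[str, str],
    frames: list[TranslatedFrame],
    evalue_cutoff: float = DEFAULT_EVALUE,
    min_segment: int = 30,
    split_at_stops: bool = True,
) -> list[HomologyHit]:
    """Local alignment of every query against every translated frame.

    Returns all hits with ``E <= evalue_cutoff``, highest score first.  With
    ``split_at_stops`` (default) only stop-free segments of at least
    ``min_segment`` residues are aligned - the speed path appropriate for
    stop-free single-exon genes; with ``False`` whole frame peptides are
    searched.  In both modes, significant hits are masked by recursing into
    the flanking subject regions so every gene copy yields its own hit.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    total_n = sum(len(f.peptide) for f in frames)
    if total_n == 0 or not queries:
        return []
    aligner = protein_aligner("local")
    hits: list[HomologyHit] = []

    for qid, qseq in queries.items():
        qseq = _sanitize(qseq)
        m = len(qseq)
        for fr in frames:
            if split_at_stops:
                segs = list(_segments(fr.peptide, min_segment))
            else:
                segs = [(0, fr.peptide)] if fr.peptide else []
            for off, seg in segs:
                _search_segment(
                    aligner, qid, qseq, m, fr, off, _sanitize(seg), total_n, evalue_cutoff, min_segment, hits
                )
    hits.sort(key=lambda h: (-h.score, h.contig, h.start, h.query_id))
    return hits


def _search_segment(aligner, qid, qseq, m, fr, off, seg, total_n, cutoff, min_len, hits) -> None:
    if len(seg) < min(8, min_len):
        return
    score = aligner.score(seg, qseq)
    if score <= 0:
        return
    evalue = karlin_altschul_evalue(score, m, total_n)
    if evalue > cutoff:
        return
    aln = aligner.align(seg, qseq)[0]
    t_blocks, q_blocks = aln.aligned
    t_start, t_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    g_start, g_end = fr.genomic_interval(off + t_start, off + t_end)
    hits.append(
        HomologyHit(
            query_id=qid,
            contig=fr.contig,
            start=g_start,
            end=g_end,
            strand=fr.strand,
            frame=fr.frame,
            score=float(score),
            evalue=evalue,
            query_start=q_start,
            query_end=q_end,
            subject_peptide=seg[t_start:t_end],
        )
    )
    # recurse into the flanks so co-linear gene copies are all found
    _search_segment(aligner, qid, qseq, m, fr, off, seg[:t_start], total_n, cutoff, min_len, hits)
    _search_segment(
        aligner, qid, qseq, m, fr, off + t_end, seg[t_end:], total_n, cutoff, min_len, hits
    )


def find_gap_runs(seq: str, min_run: int) -> list[tuple[int, int]]:
    """0-based half-open intervals of N-runs of at least ``min_run`` bases."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "N":
            j = i
            while j < n and seq[j] == "N":
                j += 1
            if j - i >= min_run:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def merge_hits(
    hits: list[HomologyHit],
    merge_distance: int = 1000,
    contigs: dict[str, str] | None = None,
    gap_length: int = 50,
) -> list[CandidateLocus]:
    """Merge same-strand hits within ``merge_distance`` into candidate loci.

    If ``contigs`` is provided, each locus is flagged ``contains_gap`` when an
    N-run of at least ``gap_length`` bases lies inside its merged interval.
    """
    loci: list[CandidateLocus] = []
    by_key: dict[tuple[str, str], list[HomologyHit]] = {}
    for h in hits:
        by_key.setdefault((h.contig, h.strand), []).append(h)
    for (contig, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: (h.start, h.end))
        current: list[HomologyHit] = []
        cur_end = None
        for h in group:
            if current and h.start - cur_end > merge_distance:
                loci.append(_build_locus(contig, strand, current, contigs, gap_length))
                current = []
                cur_end = None
            current.append(h)
            cur_end = h.end if cur_end is None else max(cur_end, h.end)
        if current:
            loci.append(_build_locus(contig, strand, current, contigs, gap_length))
    loci.sort(key=lambda l: (l.contig, l.start, l.strand))
    return loci


def _build_locus(contig, strand, group, contigs, gap_length) -> CandidateLocus:
    start = min(h.start for h in group)
    end = max(h.end for h in group)
    best = max(group, key=lambda h: h.score)
    contains_gap = False
    if contigs is not None:
        seq = contigs[contig][start:end]
        contains_gap = bool(find_gap_runs(seq, gap_length))
    return CandidateLocus(
        contig=contig,
        start=start,
        end=end,
        strand=strand,
        hits=list(group),
        best_query=best.query_id,
        contains_gap=contains_gap,
    )


def resolve_overlapping_loci(loci: list[CandidateLocus]) -> list[CandidateLocus]:
    """Keep one locus per genomic place.

    Overlapping candidate loci (including antisense shadows of a strong gene,
    which can clear a permissive E-value cut-off) cannot be distinct
    single-exon genes; the locus with the highest-scoring hit wins.
    """
    chosen: list[CandidateLocus] = []
    for locus in sorted(loci, key=lambda l: (-l.best_hit.score, l.contig, l.start)):
        if all(
            l.contig != locus.contig or l.end <= locus.start or l.start >= locus.end
            for l in chosen
        ):
            chosen.append(locus)
    chosen.sort(key=lambda l: (l.contig, l.start, l.strand))
    return chosen


def best_hit_filter(
    locus: CandidateLocus,
    or_set: dict[str, str],
    decoy_set: dict[str, str],
) -> tuple[bool, str, dict[str, float]]:
    """Keep a locus only if its translation scores best against an OR.

    Aligns the locus's best subject peptide against every protein in
    ``or_set`` union ``decoy_set``; returns ``(keep, best_subject_id, scores)``.
    A score tie between the best OR and the best non-OR discards the locus.
    """
    if not or_set and not decoy_set:
        raise ValueError("empty OR + decoy reference set")
    aligner = protein_aligner("local")
    subject = _sanitize(locus.best_hit.subject_peptide)
    scores: dict[str, float] = {}
    for name, prot in {**or_set, **decoy_set}.items():
        scores[name] = float(aligner.score(subject, _sanitize(prot)))
    best_or = max((scores[n] for n in or_set), default=float("-inf"))
    best_decoy = max((scores[n] for n in decoy_set), default=float("-inf"))
    keep = best_or > best_decoy
    best_id = max(sorted(scores), key=lambda n: scores[n])
    return keep, best_id, scores
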