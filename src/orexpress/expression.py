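"""Expression quantification, normalization and the expression criterion.

Quantification replaces a full spliced aligner with unique-k-mer fragment
assignment, which preserves the quantity of interest for single-exon genes:
each gene is indexed by the canonical k-mers (k = 31 by default) private to
it, a read pair votes for the gene owning the majority of its matched
unique k-mers (conflicting mates -> unassigned), duplicate pairs (identical
mate sequences) are counted once, and

    FPKM = count * 1e9 / (gene_length * total_assigned)

with ``total_assigned`` the number of assigned, duplicate-removed fragments
in the sample.  Expression is then normalized to the sample's beta-actin
FPKM and expressed as a percentage (``FPKM / FPKM_actin * 100``).

The expression criterion pools every non-zero intact-OR expression
percentage across all samples (negative controls included) and takes the
mean; a gene-sample cell at or above the criterion is called expressed.
The maximum intact-OR percentage seen in the negative controls is reported
alongside, as are per-sample mean +/- sd statistics of the non-zero cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .synthetic import revcomp

__all__ = [
    "KmerIndex",
    "SampleQuant",
    "ExpressionMatrix",
    "ExpressionCriterion",
    "build_kmer_index",
    "quantify_sample",
    "fpkm",
    "expression_percent",
    "build_expression_matrix",
    "compute_criterion",
    "rank_and_name",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_COMP = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("TGCA"):
    _COMP[ord("ACGT"[_i])] = 3 - _i  # A<->T, C<->G in 2-bit space


@dataclass
class KmerIndex:
    k: int
    codes: np.ndarray  # sorted uint64 canonical k-mer codes
    gene_idx: np.ndarray  # same length; index into gene_ids
    gene_ids: list[str]
    gene_lengths: dict[str, int]
    unquantifiable: list[str]  # genes without a single private k-mer


def _encode_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical (strand-symmetric) uint64 codes of all N-free k-mers."""
    b = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(b) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes, win_ok = _encode_read_matrix(b[None, :], k)
    return codes[0][win_ok[0]]


def _encode_read_matrix(base: np.ndarray, k: int):
    """Canonical k-mer codes for a matrix of reads (rows padded with N)."""
    n_reads, L = base.shape
    w = L - k + 1
    if w <= 0:
        return np.empty((n_reads, 0), dtype=np.uint64), np.empty((n_reads, 0), dtype=bool)
    bad = base == 255
    bb = base.astype(np.uint64)
    if bad.any():
        bb[bad] = 0
    two = np.uint64(2)
    three = np.uint64(3)
    mask = np.uint64((1 << (2 * k)) - 1)
    shift_top = np.uint64(2 * (k - 1))
    f = np.zeros(n_reads, dtype=np.uint64)
    r = np.zeros(n_reads, dtype=np.uint64)
    for i in range(k):
        f = (f << two) | bb[:, i]
        r = (r << two) | (three - bb[:, k - 1 - i])
    fwd = np.empty((n_reads, w), dtype=np.uint64)
    rev = np.empty((n_reads, w), dtype=np.uint64)
    fwd[:, 0] = f
    rev[:, 0] = r
    for j in range(1, w):
        nxt = bb[:, j + k - 1]
        f = ((f << two) & mask) | nxt
        r = (r >> two) | ((three - nxt) << shift_top)
        fwd[:, j] = f
        rev[:, j] = r
    canon = np.minimum(fwd, rev)
    # a window is valid when it contains no N
    cnt = np.zeros((n_reads, L + 1), dtype=np.int16)
    np.cumsum(bad, axis=1, out=cnt[:, 1:])
    ok = (cnt[:, k:] - cnt[:, :-k]) == 0
    return canon, ok


def build_kmer_index(gene_seqs: dict[str, str], k: int = 31) -> KmerIndex:
    """Index k-mers private to exactly one gene (both strands collapsed)."""
    if k < 21:
        raise ValueError("k must be >= 21 to keep k-mers effectively unique")
    gene_ids = sorted(gene_seqs)
    owner: dict[int, int] = {}
    shared: set[int] = set()
    too_short = []
    for gi, gid in enumerate(gene_ids):
        seq = gene_seqs[gid]
        if len(seq) < k:
            too_short.append(gid)
            continue
        for code in np.unique(_encode_kmers(seq, k)):
            code = int(code)
            if code in shared:
                continue
            if code in owner and owner[code] != gi:
                del owner[code]
                shared.add(code)
            else:
                owner[code] = gi
    codes = np.fromiter(owner.keys(), dtype=np.uint64, count=len(owner))
    gidx = np.fromiter(owner.values(), dtype=np.int64, count=len(owner))
    order = np.argsort(codes)
    codes, gidx = codes[order], gidx[order]
    have = set(gidx.tolist())
    unq = [gid for gi, gid in enumerate(gene_ids) if gi not in have]
    unq = sorted(set(unq) | set(too_short))
    return KmerIndex(
        k=k,
        codes=codes,
        gene_idx=gidx,
        gene_ids=gene_ids,
        gene_lengths={g: len(s) for g, s in gene_seqs.items()},
        unquantifiable=unq,
    )


@dataclass
class SampleQuant:
    sample_id: str
    counts: dict[str, int]
    n_pairs: int  # total input pairs
    n_duplicates: int  # pairs removed as duplicates
    n_assigned: int  # assigned, duplicate-removed pairs
    n_unassigned: int  # duplicate-removed pairs with no/conflicting votes


def _lookup(index: KmerIndex, codes: np.ndarray, ok: np.ndarray):
    """Gene index per matched k-mer (-1 = no match), flattened positions."""
    flat = codes.ravel()
    if len(index.codes) == 0:
        return np.full(codes.shape, -1, dtype=np.int64)
    pos = np.clip(np.searchsorted(index.codes, flat), 0, len(index.codes) - 1)
    hit = (index.codes[pos] == flat) & ok.ravel()
    genes = np.where(hit, index.gene_idx[pos], -1)
    return genes.reshape(codes.shape)


def _vote(index: KmerIndex, seq1: list[str], seq2: list[str]) -> np.ndarray:
    """Majority-vote gene assignment per pair (-1 = unassigned)."""
    n = len(seq1)
    G = len(index.gene_ids)
    votes = np.zeros((n, G), dtype=np.int32)
    for seqs in (seq1, seq2):
        L = max((len(s) for s in seqs), default=0)
        if L < index.k:
            continue
        buf = "".join(s.ljust(L, "N") for s in seqs)
        base = _CODE[np.frombuffer(buf.encode(), dtype=np.uint8)].reshape(n, L)
        codes, ok = _encode_read_matrix(base, index.k)
        genes = _lookup(index, codes, ok)
        rows = np.repeat(np.arange(n), codes.shape[1])
        g = genes.ravel()
        m = g >= 0
        np.add.at(votes, (rows[m], g[m]), 1)
    best = votes.argmax(axis=1)
    best_votes = votes[np.arange(n), best]
    votes[np.arange(n), best] = -1
    second = votes.max(axis=1)
    assigned = np.where((best_votes > 0) & (best_votes > second), best, -1)
    return assigned


def quantify_sample(
    fastq1: str,
    fastq2: str,
    index: KmerIndex,
    sample_id: str | None = None,
    chunk_size: int = 200_000,
) -> SampleQuant:
    """Duplicate-removed unique-k-mer quantification of one paired library."""
    counts = np.zeros(len(index.gene_ids), dtype=np.int64)
    n_pairs = n_dup = n_unassigned = 0
    seen: set[int] = set()
    f1 = pysam.FastxFile(fastq1)
    f2 = pysam.FastxFile(fastq2)
    try:
        while True:
            s1: list[str] = []
            s2: list[str] = []
            for r1 in f1:
                try:
                    r2 = next(f2)
                except StopIteration:
                    raise ValueError("mate count mismatch between FASTQ files") from None
                n_pairs += 1
                h = hash((r1.sequence, r2.sequence))
                if h in seen:
                    n_dup += 1
                else:
                    seen.add(h)
                    s1.append(r1.sequence)
                    s2.append(r2.sequence)
                if len(s1) >= chunk_size:
                    break
            if not s1:
                break
            assigned = _vote(index, s1, s2)
            n_unassigned += int((assigned < 0).sum())
            np.add.at(counts, assigned[assigned >= 0], 1)
            if len(s1) < chunk_size:
                break
    finally:
        f1.close()
        f2.close()
    return SampleQuant(
        sample_id=sample_id or fastq1,
        counts={g: int(c) for g, c in zip(index.gene_ids, counts)},
        n_pairs=n_pairs,
        n_duplicates=n_dup,
        n_assigned=int(counts.sum()),
        n_unassigned=n_unassigned,
    )


def fpkm(count: int, gene_length: int, total_assigned: int) -> float:
    """Fragments per kilobase of exon per million mapped fragments."""
    if gene_length <= 0:
        raise ValueError("gene_length must be > 0")
    if total_assigned <= 0:
        raise ValueError("total_assigned must be > 0 (sample has no assigned fragments)")
    return count * 1e9 / (gene_length * total_assigned)


def expression_percent(gene_fpkm: float, actin_fpkm: float) -> float:
    """A gene's FPKM as a percentage of the sample's beta-actin FPKM."""
    if actin_fpkm <= 0:
        raise ValueError("beta-actin FPKM must be > 0 for normalization")
    return gene_fpkm / actin_fpkm * 100.0


@dataclass
class ExpressionMatrix:
    fpkm: pd.DataFrame  # genes x samples
    counts: pd.DataFrame
    total_assigned: pd.Series  # per sample
    actin_gene: str

    @property
    def actin_fpkm(self) -> pd.Series:
        return self.fpkm.loc[self.actin_gene]

    @property
    def expression_percent(self) -> pd.DataFrame:
        return self.fpkm.div(self.actin_fpkm, axis=1) * 100.0


def build_expression_matrix(
    quants: list[SampleQuant],
    gene_lengths: dict[str, int],
    actin_gene: str = "ACTB",
) -> ExpressionMatrix:
    genes = sorted(gene_lengths)
    samples = [q.sample_id for q in quants]
    counts = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    for q in quants:
        for g in genes:
            counts.loc[g, q.sample_id] = q.counts.get(g, 0)
    total = pd.Series({q.sample_id: q.n_assigned for q in quants})
    fpkm_df = pd.DataFrame(
        {
            q.sample_id: [fpkm(counts.loc[g, q.sample_id], gene_lengths[g], q.n_assigned) for g in genes]
            for q in quants
        },
        index=genes,
    )
    if actin_gene not in fpkm_df.index:
        raise ValueError(f"normalization gene {actin_gene!r} not quantified")
    return ExpressionMatrix(fpkm=fpkm_df, counts=counts, total_assigned=total, actin_gene=actin_gene)


@dataclass
class ExpressionCriterion:
    criterion_value: float
    contributing: list[tuple[str, str]]  # (gene, sample) cells pooled
    negative_control_max: float
    calls: pd.DataFrame  # bool, intact-OR genes x samples
    per_sample_stats: pd.DataFrame  # mean, sd (ddof=1), n of non-zero cells


def compute_criterion(
    pct: pd.DataFrame,
    intact_or_ids: list[str],
    control_samples: list[str],
    include_controls_in_pool: bool = True,
) -> ExpressionCriterion:
    """Pooled-mean expression criterion and the expressed calls it induces.

    ``pct`` is the expression-percent table (genes x samples).  The criterion
    is the mean of every non-zero intact-OR cell, pooled across samples
    (controls included unless ``include_controls_in_pool`` is False); a cell
    is called expressed when its percentage is >= the criterion.
    """
    missing = set(control_samples) - set(pct.columns)
    if missing:
        raise ValueError(f"control samples not in table: {sorted(missing)}")
    sub = pct.loc[[g for g in intact_or_ids if g in pct.index]]
    pool_cols = list(pct.columns) if include_controls_in_pool else [
        c for c in pct.columns if c not in control_samples
    ]
    pooled = sub[pool_cols]
    cells = [
        (g, s)
        for g in pooled.index
        for s in pooled.columns
        if pooled.loc[g, s] > 0
    ]
    if not cells:
        raise ValueError("criterion undefined: no non-zero intact-OR expression")
    values = np.array([pooled.loc[g, s] for g, s in cells])
    criterion = float(values.mean())
    controls = sub[control_samples]
    neg_max = float(controls.max().max()) if control_samples else 0.0
    calls = sub >= criterion
    stats = pd.DataFrame(
        {
            s: {
                "mean": float(sub[s][sub[s] > 0].mean()) if (sub[s] > 0).any() else 0.0,
                "sd": float(sub[s][sub[s] > 0].std(ddof=1)) if (sub[s] > 0).sum() > 1 else 0.0,
                "n": int((sub[s] > 0).sum()),
            }
            for s in sub.columns
        }
    ).T
    return ExpressionCriterion(
        criterion_value=criterion,
        contributing=cells,
        negative_control_max=neg_max,
        calls=calls,
        per_sample_stats=stats,
    )


def rank_and_name(
    ref_fpkm: pd.Series, intact_or_ids: list[str], prefix: str = "OR"
) -> dict[str, tuple[int, str]]:
    """Rank intact ORs by FPKM in the reference sample (1 = highest).

    Ties break lexicographically by gene id; names are OR001, OR002, ...
    """
    present = [g for g in sorted(intact_or_ids)]
    order = sorted(present, key=lambda g: (-float(ref_fpkm.get(g, 0.0)), g))
    return {g: (i + 1, f"{prefix}{i + 1:03d}") for i, g in enumerate(order)}
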