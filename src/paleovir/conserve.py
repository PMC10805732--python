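"""Ancient-vs-modern genome pair analysis and the genome-conservation
probability model.

Covers the comparative layer of the analysis: global pairwise genome
alignment (optionally banded), separation of a prophage core from host
flanking sequence, SNV and indel-event calling on an alignment,
sliding-window identity with hypervariable-window flagging (the
signature of a diversity-generating retroelement), per-gene nucleotide
or amino-acid identity, and a binomial model for the probability that
a genome of n sites retains at least a fraction q of unaltered sites
after t years at a per-site alteration rate r:

    p_t = 1 - (1 - r)^t          (compound; or p_t = min(r t, 1) linear)
    P(conserved) = P(X <= floor(n (1-q))),  X ~ Binomial(n, p_t)

evaluated in log space so that astronomically small probabilities are
still reportable as log10 values.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import special

from .io import Gene, GenomeRecord


@dataclasses.dataclass
class AlignmentScoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0  # score of the first gap column
    gap_extend: float = -2.0  # each further gap column


@dataclasses.dataclass
class PairwiseAlignment:
    """A global pairwise alignment as two equal-length gapped rows."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float | None = None

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows must have equal length")
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-" and y == "-":
                raise ValueError("column with gaps in both rows")

    def __len__(self) -> int:
        return len(self.aligned_a)

    def positions_a(self) -> np.ndarray:
        """1-based ungapped position in sequence A per column (0 at gaps)."""
        gaps = np.frombuffer(self.aligned_a.encode(), dtype=np.uint8) == ord("-")
        pos = np.cumsum(~gaps)
        return np.where(gaps, 0, pos)

    def positions_b(self) -> np.ndarray:
        gaps = np.frombuffer(self.aligned_b.encode(), dtype=np.uint8) == ord("-")
        pos = np.cumsum(~gaps)
        return np.where(gaps, 0, pos)

    @property
    def identity(self) -> float:
        """% identical columns over columns (no double gaps exist)."""
        matches = sum(1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y)
        return 100.0 * matches / len(self.aligned_a)


@dataclasses.dataclass
class SNVTable:
    """Substitutions and collapsed indel events from one alignment.

    Positions are 1-based on sequence A (the query/ancient genome);
    indel events sit at the last A base preceding the gap run.
    """

    snvs: list[tuple[int, str, str]]  # (position_a, base_a, base_b)
    indels: list[tuple[int, int, str]]  # (position_a, length, "insertion"/"deletion")

    @property
    def n_snvs(self) -> int:
        return len(self.snvs)


@dataclasses.dataclass
class IdentityTrack:
    window_starts: list[int]  # 1-based alignment column of each window
    identities: list[float]  # % per window
    flagged: list[bool]
    mean: float
    sd: float


@dataclasses.dataclass
class ConservationParams:
    """Inputs to the binomial conservation model."""

    n: int = 36_630
    q: float = 0.977
    rate_r: float = 1.154e-4
    years_t: float = 1300.0
    compounding: str = "compound"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not 0.0 < self.q <= 1.0:
            raise ValueError("q must lie in (0,1]")
        if self.compounding not in ("compound", "linear"):
            raise ValueError("compounding must be 'compound' or 'linear'")

    @property
    def m(self) -> int:
        """Maximum tolerated altered-site count, floor(n (1-q)).

        The product is rounded at 1e-9 before flooring so that exactly
        representable fractions (e.g. q = 0.8 of n = 10) are not pushed
        below the integer by float error.
        """
        return math.floor(round(self.n * (1.0 - self.q), 9))

    @property
    def p_site(self) -> float:
        if self.compounding == "compound":
            return 1.0 - (1.0 - self.rate_r) ** self.years_t
        return min(self.rate_r * self.years_t, 1.0)


# ---------------------------------------------------------------------------
# alignment


def align_pair(
    a: GenomeRecord | str,
    b: GenomeRecord | str,
    scoring: AlignmentScoring | None = None,
    band: int | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences.

    Unbanded alignment delegates to the dynamic-programming aligner in
    Biopython with the given affine scoring; banded alignment restricts
    the DP to |i - j| <= band and requires |len(a) - len(b)| < band.
    """
    scoring = scoring or AlignmentScoring()
    id_a, seq_a = (a.id, a.sequence) if isinstance(a, GenomeRecord) else ("A", a)
    id_b, seq_b = (b.id, b.sequence) if isinstance(b, GenomeRecord) else ("B", b)
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if band is not None:
        if abs(len(seq_a) - len(seq_b)) >= band:
            raise ValueError("band infeasible: length difference exceeds band")
        row_a, row_b, score = _banded_global(seq_a, seq_b, scoring, band)
        return PairwiseAlignment(id_a, id_b, row_a, row_b, score=score)
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    return PairwiseAlignment(id_a, id_b, str(aln[0]), str(aln[1]), score=float(aln.score))


def _banded_global(
    a: str, b: str, sc: AlignmentScoring, band: int
) -> tuple[str, str, float]:
    """Affine-gap global DP restricted to the diagonal band |i-j|<=band."""
    n, m = len(a), len(b)
    neg = -math.inf
    width = 2 * band + 1

    def k_of(i: int, j: int) -> int:
        return j - i + band

    # three layers: 0=M (diagonal), 1=Ix (gap in b, consumes a), 2=Iy (gap in a)
    M = [[neg] * width for _ in range(n + 1)]
    Ix = [[neg] * width for _ in range(n + 1)]
    Iy = [[neg] * width for _ in range(n + 1)]
    ptr: dict[tuple[int, int, int], int] = {}
    M[0][band] = 0.0
    for j in range(1, min(m, band) + 1):
        k = k_of(0, j)
        Iy[0][k] = sc.gap_open + sc.gap_extend * (j - 1)
    for i in range(1, n + 1):
        lo = max(0, i - band)
        hi = min(m, i + band)
        for j in range(lo, hi + 1):
            k = k_of(i, j)
            if j == 0:
                Ix[i][k] = sc.gap_open + sc.gap_extend * (i - 1)
                continue
            s = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            # M from (i-1, j-1): same k
            cands = (M[i - 1][k], Ix[i - 1][k], Iy[i - 1][k])
            best = max(cands)
            if best > neg:
                M[i][k] = best + s
                ptr[(0, i, k)] = cands.index(best)
            # Ix from (i-1, j): offset k+1
            if k + 1 < width:
                open_sc = M[i - 1][k + 1] + sc.gap_open
                ext_sc = Ix[i - 1][k + 1] + sc.gap_extend
                if open_sc >= ext_sc:
                    Ix[i][k] = open_sc
                    ptr[(1, i, k)] = 0
                else:
                    Ix[i][k] = ext_sc
                    ptr[(1, i, k)] = 1
            # Iy from (i, j-1): offset k-1, same row (already computed)
            if k - 1 >= 0:
                open_sc = M[i][k - 1] + sc.gap_open
                ext_sc = Iy[i][k - 1] + sc.gap_extend
                if open_sc >= ext_sc:
                    Iy[i][k] = open_sc
                    ptr[(2, i, k)] = 0
                else:
                    Iy[i][k] = ext_sc
                    ptr[(2, i, k)] = 1
    k_end = k_of(n, m)
    finals = (M[n][k_end], Ix[n][k_end], Iy[n][k_end])
    score = max(finals)
    if score == neg:
        raise ValueError("band infeasible: no alignment path inside the band")
    layer = finals.index(score)
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        k = k_of(i, j)
        if j == 0:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            layer = 1
            continue
        if i == 0:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
            layer = 2
            continue
        if layer == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            layer = ptr[(0, i, k)]
            i -= 1
            j -= 1
        elif layer == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            layer = 0 if ptr[(1, i, k)] == 0 else 1
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            layer = 0 if ptr[(2, i, k)] == 0 else 2
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


# ---------------------------------------------------------------------------
# core/flank separation


def trim_flanks(
    alignments: Sequence[PairwiseAlignment], min_presence: int
) -> tuple[int, int, tuple[int, int]]:
    """Separate the shared core of a query genome from its unique flanks.

    Each alignment pairs the query (row A) with one relative. A query
    position is "present" in a relative when its column is aligned to a
    base (not a gap) in that relative. The core is the largest
    contiguous run of query positions present in at least
    ``min_presence`` relatives. Returns (core_start, core_end) 1-based
    on the query, plus (left_flank_len, right_flank_len).
    """
    k = len(alignments)
    if k < 1:
        raise ValueError("need at least one relative")
    if min_presence > k:
        raise ValueError(f"min_presence {min_presence} exceeds number of relatives {k}")
    qlen = max(int(aln.positions_a().max()) for aln in alignments)
    presence = np.zeros(qlen, dtype=np.int32)
    for aln in alignments:
        pos_a = aln.positions_a()
        gaps_b = np.frombuffer(aln.aligned_b.encode(), dtype=np.uint8) == ord("-")
        covered = pos_a[(pos_a > 0) & ~gaps_b]
        presence[covered - 1] += 1
    ok = presence >= min_presence
    if not ok.any():
        raise ValueError("no query position present in enough relatives")
    # largest contiguous run of True
    best_len = best_start = 0
    run_start = None
    for i, v in enumerate(np.append(ok, False)):
        if v and run_start is None:
            run_start = i
        elif not v and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    core_start = best_start + 1
    core_end = best_start + best_len
    return core_start, core_end, (core_start - 1, qlen - core_end)


# ---------------------------------------------------------------------------
# SNVs, windows, genes


def call_snvs(aln: PairwiseAlignment) -> SNVTable:
    """Substitution and indel-event calls from a pairwise alignment.

    A SNV is a column where both rows carry a base and the bases
    differ. A maximal run of gap columns in one row collapses into a
    single event: a gap run in row A is an insertion (sequence B has
    extra bases), in row B a deletion, positioned at the last preceding
    A base.
    """
    snvs: list[tuple[int, str, str]] = []
    indels: list[tuple[int, int, str]] = []
    pos_a = 0
    run_len = 0
    run_kind: str | None = None
    run_pos = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        kind = "insertion" if x == "-" else ("deletion" if y == "-" else None)
        if x != "-":
            pos_a += 1
        if kind is None:
            if run_kind is not None:
                indels.append((run_pos, run_len, run_kind))
                run_kind, run_len = None, 0
            if x != y:
                snvs.append((pos_a, x, y))
        elif kind == run_kind:
            run_len += 1
        else:
            if run_kind is not None:
                indels.append((run_pos, run_len, run_kind))
            run_kind = kind
            run_len = 1
            run_pos = pos_a - 1 if kind == "deletion" else pos_a
    if run_kind is not None:
        indels.append((run_pos, run_len, run_kind))
    return SNVTable(snvs=snvs, indels=indels)


def window_identity(
    aln: PairwiseAlignment,
    window: int = 100,
    step: int = 50,
    flag_k: float = 3.0,
) -> IdentityTrack:
    """Sliding-window % identity over alignment columns, flagging
    windows whose identity falls below mean - flag_k * sd (candidate
    hypervariable / DGR-target regions)."""
    if window < 10:
        raise ValueError("window must be at least 10 columns")
    cols = len(aln)
    a = np.frombuffer(aln.aligned_a.encode(), dtype=np.uint8)
    b = np.frombuffer(aln.aligned_b.encode(), dtype=np.uint8)
    match = (a == b).astype(float)  # no double-gap columns by invariant
    if cols <= window:
        ident = 100.0 * match.mean()
        return IdentityTrack([1], [ident], [False], mean=ident, sd=0.0)
    starts = list(range(0, cols - window + 1, step))
    if starts[-1] + window < cols:
        starts.append(cols - window)
    idents = [100.0 * match[s : s + window].mean() for s in starts]
    mean = float(np.mean(idents))
    sd = float(np.std(idents))
    cutoff = mean - flag_k * sd
    flagged = [v < cutoff for v in idents]
    return IdentityTrack(
        window_starts=[s + 1 for s in starts],
        identities=idents,
        flagged=flagged,
        mean=mean,
        sd=sd,
    )


def per_gene_identity(
    aln: PairwiseAlignment,
    genes: Sequence[Gene],
    level: str = "amino_acid",
) -> tuple[list[tuple[str, float | None]], float | None]:
    """Per-gene % identity between the two aligned genomes.

    Genes are annotated on sequence A. For each gene the aligned
    segment is extracted via the coordinate maps; at ``nucleotide``
    level identity is over the aligned columns, at ``amino_acid`` level
    both ungapped sub-sequences are translated and locally re-aligned
    (BLOSUM62). A gene whose interval is entirely deleted in B is
    reported as None and excluded from the unweighted mean.
    """
    if level not in ("nucleotide", "amino_acid"):
        raise ValueError("level must be 'nucleotide' or 'amino_acid'")
    pos_a = aln.positions_a()
    results: list[tuple[str, float | None]] = []
    values: list[float] = []
    for gene in genes:
        cols = np.flatnonzero((pos_a >= gene.start) & (pos_a <= gene.end))
        if cols.size == 0:
            results.append((gene.gene_id, None))
            continue
        lo, hi = int(cols.min()), int(cols.max()) + 1
        sub_a = aln.aligned_a[lo:hi]
        sub_b = aln.aligned_b[lo:hi]
        seq_b = sub_b.replace("-", "")
        if not seq_b:
            results.append((gene.gene_id, None))
            continue
        if level == "nucleotide":
            matches = sum(1 for x, y in zip(sub_a, sub_b) if x == y)
            ident = 100.0 * matches / len(sub_a)
        else:
            from Bio.Seq import Seq

            seq_a = sub_a.replace("-", "")
            prot_a = str(Seq(seq_a[: 3 * (len(seq_a) // 3)]).translate()).rstrip("*")
            prot_b = str(Seq(seq_b[: 3 * (len(seq_b) // 3)]).translate()).rstrip("*")
            if not prot_a or not prot_b:
                results.append((gene.gene_id, None))
                continue
            ident = _protein_identity(prot_a, prot_b)
        results.append((gene.gene_id, ident))
        values.append(ident)
    mean = float(np.mean(values)) if values else None
    return results, mean


def _protein_identity(p: str, q: str) -> float:
    from .cluster import _local_protein_hit

    hit = _local_protein_hit(p, q)
    if hit is None:
        return 0.0
    return hit[1]


# ---------------------------------------------------------------------------
# binomial conservation model


def _log_binom_pmf(n: int, k: np.ndarray, p: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return (
        special.gammaln(n + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n - k + 1)
        + k * math.log(p)
        + (n - k) * math.log1p(-p)
    )


def prob_conserved(params: ConservationParams) -> tuple[float, float]:
    """Probability that at most m = floor(n(1-q)) of n sites are altered.

    Returns (probability, log10 probability). The CDF is accumulated
    in log space (stable log-sum-exp over the m+1 pmf terms), so the
    log10 value remains meaningful far below float underflow.
    """
    p = params.p_site
    if p <= 0.0:
        return 1.0, 0.0
    if p >= 1.0:
        # all sites altered almost surely; conserved only if m = n
        return (1.0, 0.0) if params.m >= params.n else (0.0, -math.inf)
    ks = np.arange(0, params.m + 1)
    log_terms = _log_binom_pmf(params.n, ks, p)
    log_cdf = float(special.logsumexp(log_terms))
    log_cdf = min(log_cdf, 0.0)
    return math.exp(log_cdf), log_cdf / math.log(10.0)


def expected_identity(rate_r: float, years_t: float, compounding: str = "compound") -> float:
    """Expected % of unaltered sites after t years at rate r."""
    params = ConservationParams(rate_r=rate_r, years_t=years_t, compounding=compounding)
    return 100.0 * (1.0 - params.p_site)


NEVER = None  # sentinel for years_to_threshold when the rate is zero


def years_to_threshold(
    n: int,
    q: float,
    rate_r: float,
    prob_target: float = 1e-3,
    compounding: str = "compound",
    t_max: int = 1_000_000,
) -> int | None:
    """Smallest integer t with P(conserved at t) < prob_target.

    The probability is non-increasing in t, so an exponential search
    followed by integer bisection is exact. Returns 0 when
    prob_target >= 1 and None ("never") when the rate is zero.
    """
    if prob_target >= 1.0:
        return 0
    if not 0.0 < prob_target < 1.0:
        raise ValueError("prob_target must lie in (0,1)")
    if rate_r == 0.0:
        return NEVER

    def prob(t: int) -> float:
        return prob_conserved(
            ConservationParams(n=n, q=q, rate_r=rate_r, years_t=float(t), compounding=compounding)
        )[0]

    hi = 1
    while prob(hi) >= prob_target:
        hi *= 2
        if hi > t_max:
            return NEVER
    lo = hi // 2  # prob(lo) >= target (or lo==0)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if prob(mid) < prob_target:
            hi = mid
        else:
            lo = mid
    return hi


def conservation_curve(
    n: int,
    q: float,
    rates: Iterable[float],
    t_max: int = 1300,
    t_step: int = 10,
    compounding: str = "compound",
):
    """Tabulate P(conserved) and log10 P against years for several rates."""
    import pandas as pd

    rows = []
    for r in rates:
        for t in range(0, t_max + 1, t_step):
            p, log10p = prob_conserved(
                ConservationParams(n=n, q=q, rate_r=r, years_t=float(t), compounding=compounding)
            )
            rows.append({"rate": r, "years": t, "prob": p, "log10_prob": log10p})
    return pd.DataFrame(rows)
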