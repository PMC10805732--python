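"""Terminal deamination profiling and ancient-contig authentication.

Ancient DNA carries an excess of C->T mismatches at the 5' ends of
sequencing reads, decaying roughly exponentially into the read. This
module measures that signal per contig from read alignments, fits a
decaying damage model against a flat-background null by maximum
likelihood, converts the likelihood-ratio test into an authentication
score, selects a score threshold from the knee of the sorted score
curve (Kneedle), and applies the final two-part filter: score above
threshold AND an empirical first-position C->T frequency of at least
0.01.

The score here is a likelihood-ratio significance (1 - p_value of the
damage-vs-flat test), not a trained classifier output; its threshold is
data-driven via the knee of the score curve, exactly as one would
threshold any monotone authenticity ranking.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

from .io import GenomeRecord, SamRead, check_cigar, cigar_tuples

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclasses.dataclass
class DamageProfile:
    """Per-position C->T mismatch counts over the first ``P`` read
    positions (1-based, counted from the 5' end in read coordinates)."""

    contig_id: str
    P: int
    n_c_sites: np.ndarray  # reads' positions whose reference base is C
    n_ct: np.ndarray  # of those, positions read as T
    n_reads: int

    def __post_init__(self) -> None:
        self.n_c_sites = np.asarray(self.n_c_sites, dtype=np.int64)
        self.n_ct = np.asarray(self.n_ct, dtype=np.int64)
        if self.n_c_sites.shape != (self.P,) or self.n_ct.shape != (self.P,):
            raise ValueError("count arrays must have length P")
        if np.any(self.n_ct > self.n_c_sites) or np.any(self.n_ct < 0):
            raise ValueError("0 <= n_ct[i] <= n_c_sites[i] violated")

    @property
    def freq(self) -> np.ndarray:
        """C->T frequency per position; NaN where no C sites observed."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_c_sites > 0, self.n_ct / self.n_c_sites, np.nan)

    @property
    def n_informative(self) -> int:
        return int(np.count_nonzero(self.n_c_sites))


@dataclasses.dataclass
class DamageFit:
    """Maximum-likelihood damage-model fit and its significance."""

    contig_id: str
    d1_hat: float
    lam_hat: float
    b_hat: float
    loglik_alt: float
    loglik_null: float
    lr_stat: float
    p_value: float
    score: float
    converged: bool = True


FailReason = str
BELOW_SCORE = "below_score_threshold"
BELOW_FIRST_POS = "first_position_below_minimum"
INSUFFICIENT = "insufficient_data"


@dataclasses.dataclass
class AuthenticationDecision:
    contig_id: str
    passed: bool
    reasons: list[FailReason]

    def __post_init__(self) -> None:
        if self.passed != (not self.reasons):
            raise ValueError("passed must be equivalent to an empty reason list")


# ---------------------------------------------------------------------------
# profiling


def _read_terminal_pairs(read: SamRead, P: int):
    """Yield (read_position_1based_from_5prime, ref_offset_0based) for the
    first P read positions that are aligned to the reference.

    For reverse-strand records the stored sequence is the reverse
    complement of the sequenced read, so the read's 5' end is the
    rightmost stored base; positions are walked from the right.
    """
    ops = cigar_tuples(read.cigar)
    if read.is_reverse:
        ops = ops[::-1]
        # compute rightmost reference offset (0-based, inclusive)
        ref_end = read.pos - 1 + sum(n for op, n in ops if op in "MD=X") - 1
        qpos = 0  # 1-based read position from the 5' end
        ref = ref_end
        for op, n in ops:
            if op in "M=X":
                for i in range(n):
                    qpos += 1
                    if qpos > P:
                        return
                    yield qpos, ref - i
                ref -= n
            elif op == "S":
                qpos += n
                if qpos >= P:
                    return
            elif op == "I":
                qpos += n
                if qpos >= P:
                    return
            elif op == "D":
                ref -= n
    else:
        qpos = 0
        ref = read.pos - 1
        for op, n in ops:
            if op in "M=X":
                for i in range(n):
                    qpos += 1
                    if qpos > P:
                        return
                    yield qpos, ref + i
                ref += n
            elif op in "SI":
                qpos += n
                if qpos >= P:
                    return
            elif op == "D":
                ref += n


def compute_damage_profile(
    alignments: Iterable[SamRead],
    reference: GenomeRecord,
    P: int = 20,
) -> DamageProfile:
    """Count C->T mismatches at the first ``P`` read positions.

    Forward reads contribute reference-C positions read as T; reverse
    reads contribute reference-G positions read as A in stored
    orientation, which is the same C->T event in read coordinates.
    Unmapped records are skipped (logged); records aligned to another
    contig raise ``ValueError``.
    """
    n_c = np.zeros(P, dtype=np.int64)
    n_ct = np.zeros(P, dtype=np.int64)
    n_reads = 0
    n_skipped = 0
    ref_seq = reference.sequence
    for read in alignments:
        if read.is_unmapped:
            n_skipped += 1
            continue
        if read.rname != reference.id:
            raise ValueError(
                f"read {read.qname!r} aligned to {read.rname!r}, expected {reference.id!r}"
            )
        check_cigar(read.cigar, read.qname)
        n_reads += 1
        rev = read.is_reverse
        seq = read.sequence
        qlen = len(seq)
        for qpos, ref_off in _read_terminal_pairs(read, P):
            if not 0 <= ref_off < len(ref_seq):
                continue
            ref_base = ref_seq[ref_off]
            # read coordinates: stored index for reverse reads counts from the right
            base = seq[qlen - qpos] if rev else seq[qpos - 1]
            if rev:
                ref_base = _COMPLEMENT[ref_base]
                base = _COMPLEMENT[base]
            if ref_base == "C":
                n_c[qpos - 1] += 1
                if base == "T":
                    n_ct[qpos - 1] += 1
    if n_skipped:
        logger.info("contig %s: skipped %d unmapped records", reference.id, n_skipped)
    return DamageProfile(
        contig_id=reference.id, P=P, n_c_sites=n_c, n_ct=n_ct, n_reads=n_reads
    )


def profiles_from_sam(
    reads: Sequence[SamRead],
    references: Mapping[str, GenomeRecord],
    P: int = 20,
) -> dict[str, DamageProfile]:
    """Group reads by contig and profile each reference present."""
    by_contig: dict[str, list[SamRead]] = {rid: [] for rid in references}
    for r in reads:
        if r.rname in by_contig:
            by_contig[r.rname].append(r)
    return {
        rid: compute_damage_profile(by_contig[rid], ref, P=P)
        for rid, ref in references.items()
    }


# ---------------------------------------------------------------------------
# model fit


def _damage_curve(d1: float, lam: float, b: float, positions: np.ndarray) -> np.ndarray:
    return b + (d1 - b) * np.exp(-lam * (positions - 1.0))


def _binom_loglik(n: np.ndarray, k: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    # binomial coefficients are constant across models and cancel in the LRT,
    # but keep them so log-likelihoods are true log-probabilities
    return float(
        np.sum(
            special.gammaln(n + 1)
            - special.gammaln(k + 1)
            - special.gammaln(n - k + 1)
            + k * np.log(p)
            + (n - k) * np.log1p(-p)
        )
    )


_STARTS = [
    (0.05, 0.3, 0.005),
    (0.2, 0.5, 0.01),
    (0.5, 1.0, 0.001),
    (0.02, 0.1, 0.002),
    (0.1, 2.0, 0.02),
]
_BOUNDS = [(1e-6, 0.99), (1e-3, 10.0), (1e-6, 0.99)]


def fit_damage_model(profile: DamageProfile) -> DamageFit:
    """Fit d(i) = b + (d1-b)·exp(-lam·(i-1)) to per-position binomial
    counts and test it against a flat-background null.

    The alternative maximizes the product of per-position binomial
    likelihoods over (d1, lam, b) with box constraints (five
    deterministic starts, L-BFGS-B, ties to the first start); the null
    has the single parameter b, whose MLE is the pooled frequency. The
    p-value is the chi-square(2 df) upper tail of the likelihood-ratio
    statistic, and score = 1 - p_value.
    """
    mask = profile.n_c_sites > 0
    if int(mask.sum()) < 3:
        raise ValueError(
            f"contig {profile.contig_id!r}: need >=3 informative positions, got {int(mask.sum())}"
        )
    pos = np.arange(1, profile.P + 1, dtype=float)[mask]
    n = profile.n_c_sites[mask].astype(float)
    k = profile.n_ct[mask].astype(float)

    b_null = float(np.clip(k.sum() / n.sum(), 1e-6, 0.99))
    loglik_null = _binom_loglik(n, k, np.full_like(n, b_null))

    def neg_loglik(theta: np.ndarray) -> float:
        d1, lam, b = theta
        return -_binom_loglik(n, k, _damage_curve(d1, lam, b, pos))

    best = None
    converged = False
    for start in _STARTS:
        res = optimize.minimize(
            neg_loglik, np.asarray(start), method="L-BFGS-B", bounds=_BOUNDS
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
            converged = bool(res.success)
    d1_hat, lam_hat, b_hat = (float(v) for v in best.x)
    if d1_hat < b_hat:
        # flat or inverted curve: collapse to the null for a clean decision
        d1_hat = b_hat = b_null
    loglik_alt = -float(best.fun)
    lr = 2.0 * (loglik_alt - loglik_null)
    lr = max(lr, 0.0)  # guard tiny negative values from optimizer tolerance
    p_value = float(stats.chi2.sf(lr, df=2))
    return DamageFit(
        contig_id=profile.contig_id,
        d1_hat=d1_hat,
        lam_hat=lam_hat,
        b_hat=b_hat,
        loglik_alt=loglik_alt,
        loglik_null=loglik_null,
        lr_stat=lr,
        p_value=p_value,
        score=1.0 - p_value,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# thresholding and decisions


def kneedle_threshold(scores: Sequence[float], tol: float = 1e-3) -> float | None:
    """Locate the knee of a descending score curve (Kneedle).

    The curve (index, score) is normalized to the unit square and the
    point of maximum deviation below/above the chord from the first to
    the last point is returned (as a score). When no point deviates
    from the chord by more than ``tol``, the curve has no knee and None
    is returned.
    """
    y = np.asarray(scores, dtype=float)
    if y.size < 3:
        raise ValueError("kneedle needs at least 3 points")
    if np.any(np.diff(y) > 1e-12):
        y = np.sort(y)[::-1]
    x = np.linspace(0.0, 1.0, y.size)
    span = y[0] - y[-1]
    if span <= 0:
        return None
    yn = (y - y[-1]) / span
    chord = yn[0] + (yn[-1] - yn[0]) * x
    diff = np.abs(yn - chord)
    if float(diff.max()) <= tol:
        return None
    return float(y[int(np.argmax(diff))])


def authenticate_contigs(
    fits: Mapping[str, DamageFit | None],
    profiles: Mapping[str, DamageProfile],
    score_threshold: float,
    min_first_pos: float = 0.01,
) -> list[AuthenticationDecision]:
    """Apply the two-part ancient-origin filter per contig.

    A contig passes iff its fit score reaches ``score_threshold`` AND
    the empirical first-position C->T frequency reaches
    ``min_first_pos`` (default 0.01, guarding against flat sequencing
    noise) AND the profile had enough data to fit. The empirical
    frequency, not the fitted amplitude, feeds the minimum-frequency
    rule.
    """
    decisions = []
    for contig_id, profile in profiles.items():
        if contig_id not in fits:
            raise ValueError(f"missing fit for contig {contig_id!r}")
        fit = fits[contig_id]
        reasons: list[FailReason] = []
        if fit is None or profile.n_informative < 3 or profile.n_c_sites[0] == 0:
            reasons.append(INSUFFICIENT)
        else:
            if fit.score < score_threshold:
                reasons.append(BELOW_SCORE)
            if float(profile.freq[0]) < min_first_pos:
                reasons.append(BELOW_FIRST_POS)
        decisions.append(
            AuthenticationDecision(
                contig_id=contig_id, passed=not reasons, reasons=reasons
            )
        )
    return decisions


def fit_all(profiles: Mapping[str, DamageProfile]) -> dict[str, DamageFit | None]:
    """Fit every profile; profiles with too little data map to None."""
    fits: dict[str, DamageFit | None] = {}
    for contig_id, profile in profiles.items():
        try:
            fits[contig_id] = fit_damage_model(profile)
        except ValueError:
            fits[contig_id] = None
    return fits
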