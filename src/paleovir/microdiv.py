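"""Read-level intra-population diversity (microdiversity).

Builds per-site allele counts from read alignments and computes the
two standard strain-level statistics: per-site nucleotide diversity
(the unbiased pairwise-difference form) and divergent-site counts,
i.e. sites where a non-reference allele is carried by enough reads to
be distinguishable from sequencing noise.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .io import GenomeRecord, SamRead, cigar_tuples

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclasses.dataclass
class Pileup:
    """Per-site A/C/G/T counts over a reference genome (1-based sites)."""

    ref_id: str
    reference: str
    counts: np.ndarray  # shape (L, 4)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.reference), 4):
            raise ValueError("counts must have shape (reference length, 4)")
        if np.any(self.counts < 0):
            raise ValueError("negative allele count")

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclasses.dataclass
class DiversityConfig:
    min_cov: int = 5
    min_allele_freq: float = 0.05
    #: divergent alleles additionally need this many supporting reads,
    #: which suppresses singleton sequencing errors
    min_allele_count: int = 2

    def __post_init__(self) -> None:
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        if not 0.0 < self.min_allele_freq <= 0.5:
            raise ValueError("min_allele_freq must lie in (0, 0.5]")


@dataclasses.dataclass
class DiversityStats:
    sites_considered: int
    mean_pi: float | None
    divergent_count: int
    divergent_fraction: float | None


def build_pileup(alignments: Iterable[SamRead], reference: GenomeRecord) -> Pileup:
    """Attribute read bases to reference sites by walking each CIGAR.

    Deletions contribute nothing to the deleted sites; inserted and
    soft-clipped bases are skipped. Bases outside A/C/G/T are ignored.
    """
    L = len(reference)
    counts = np.zeros((L, 4), dtype=np.int64)
    for read in alignments:
        if read.is_unmapped or read.rname != reference.id:
            continue
        ref = read.pos - 1
        q = 0
        seq = read.sequence
        for op, n in cigar_tuples(read.cigar):
            if op in "M=X":
                for i in range(n):
                    if 0 <= ref + i < L:
                        code = _CODE.get(seq[q + i])
                        if code is not None:
                            counts[ref + i, code] += 1
                ref += n
                q += n
            elif op in "IS":
                q += n
            elif op == "D":
                ref += n
            else:
                raise ValueError(f"read {read.qname!r}: unsupported CIGAR op {op!r}")
    return Pileup(ref_id=reference.id, reference=reference.sequence, counts=counts)


def site_pi(counts: np.ndarray) -> np.ndarray:
    """Unbiased per-site nucleotide diversity 1 - sum_a C(c_a,2)/C(c,2)."""
    counts = np.asarray(counts, dtype=float)
    c = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        same = (counts * (counts - 1)).sum(axis=1) / (c * (c - 1))
    return np.where(c >= 2, 1.0 - same, np.nan)


def nucleotide_diversity(pileup: Pileup, cfg: DiversityConfig | None = None) -> DiversityStats:
    """Mean per-site nucleotide diversity over sufficiently covered sites."""
    cfg = cfg or DiversityConfig()
    cov = pileup.coverage
    mask = cov >= cfg.min_cov
    n_sites = int(mask.sum())
    if n_sites == 0:
        return DiversityStats(0, None, 0, None)
    pi = site_pi(pileup.counts[mask])
    div_mask, _ = _divergent_mask(pileup, cfg)
    n_div = int(div_mask.sum())
    return DiversityStats(
        sites_considered=n_sites,
        mean_pi=float(np.nanmean(pi)),
        divergent_count=n_div,
        divergent_fraction=n_div / n_sites,
    )


def _divergent_mask(pileup: Pileup, cfg: DiversityConfig) -> tuple[np.ndarray, np.ndarray]:
    cov = pileup.coverage
    ref_codes = np.array([_CODE.get(b, -1) for b in pileup.reference])
    alt = pileup.counts.copy()
    valid = ref_codes >= 0
    alt[valid, ref_codes[valid]] = 0  # zero out the reference allele
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / cov[:, None]
    qualifying = (alt >= cfg.min_allele_count) & (freq >= cfg.min_allele_freq)
    mask = (cov >= cfg.min_cov) & qualifying.any(axis=1)
    return mask, alt


def divergent_sites(
    pileup: Pileup, cfg: DiversityConfig | None = None
) -> tuple[pd.DataFrame, int]:
    """Table of divergent sites and their count.

    A site is divergent when coverage >= min_cov and at least one
    non-reference allele reaches both the frequency and the absolute
    count floors.
    """
    cfg = cfg or DiversityConfig()
    mask, alt = _divergent_mask(pileup, cfg)
    sites = np.flatnonzero(mask)
    cov = pileup.coverage
    rows = []
    for s in sites:
        alt_code = int(np.argmax(alt[s]))
        rows.append(
            {
                "pos": int(s) + 1,
                "ref_base": pileup.reference[s],
                "alt_base": _BASES[alt_code],
                "coverage": int(cov[s]),
                "alt_count": int(alt[s, alt_code]),
                "alt_freq": float(alt[s, alt_code] / cov[s]),
            }
        )
    table = pd.DataFrame(
        rows, columns=["pos", "ref_base", "alt_base", "coverage", "alt_count", "alt_freq"]
    )
    return table, len(rows)


def per_site_table(pileup: Pileup, cfg: DiversityConfig | None = None) -> pd.DataFrame:
    """Full per-site report: counts, coverage, pi and divergent flag."""
    cfg = cfg or DiversityConfig()
    pi = site_pi(pileup.counts)
    mask, _ = _divergent_mask(pileup, cfg)
    return pd.DataFrame(
        {
            "pos": np.arange(1, len(pileup.reference) + 1),
            "ref_base": list(pileup.reference),
            "A": pileup.counts[:, 0],
            "C": pileup.counts[:, 1],
            "G": pileup.counts[:, 2],
            "T": pileup.counts[:, 3],
            "coverage": pileup.coverage,
            "pi": pi,
            "divergent": mask,
        }
    )
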