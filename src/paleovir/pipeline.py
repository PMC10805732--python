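"""End-to-end orchestration and workflow plumbing filters.

The plumbing filters reproduce the selection steps a virome workflow
applies before any of the quantitative analyses: an assembly filter
(length strictly greater than 4000 nt and fold-coverage of at least
20), a consensus viral call (flagged viral by at least two independent
classifiers), and the analysis-set rule (at least 20 kb long OR
medium-or-better completeness tier).

``run_end_to_end`` re-enacts the workflow at fixture scale: simulate a
community, profile damage, authenticate, cluster into vOTUs, tabulate
the conservation model, and measure microdiversity — writing TSV/JSON
reports plus a manifest that fully determines the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import cluster as vc
from . import conserve, damage, microdiv, synthgen
from .io import ensure_dir, write_tsv

logger = logging.getLogger(__name__)

QUALITY_TIERS = ("complete", "high", "medium", "low", "unknown")
PASSING_TIERS = ("complete", "high", "medium")


@dataclasses.dataclass
class ContigMeta:
    contig_id: str
    length: int
    assembly_coverage: float = 0.0
    viral_votes: dict[str, bool] = dataclasses.field(default_factory=dict)
    quality_tier: str = "unknown"
    ancient_flag: bool | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.contig_id!r}: length must be >= 1")
        if self.quality_tier not in QUALITY_TIERS:
            raise ValueError(f"unknown quality tier {self.quality_tier!r}")


def filter_contigs(
    metas: Sequence[ContigMeta], min_len: int = 4000, min_cov: float = 20.0
) -> list[ContigMeta]:
    """Assembly filter: keep contigs longer than ``min_len`` (strict)
    with coverage at least ``min_cov``."""
    return [m for m in metas if m.length > min_len and m.assembly_coverage >= min_cov]


def consensus_viral_call(metas: Sequence[ContigMeta], min_votes: int = 2) -> list[ContigMeta]:
    """Keep contigs called viral by at least ``min_votes`` tools."""
    return [m for m in metas if sum(bool(v) for v in m.viral_votes.values()) >= min_votes]


def select_analysis_set(metas: Sequence[ContigMeta], min_len_alt: int = 20_000) -> list[ContigMeta]:
    """Keep contigs at least ``min_len_alt`` long OR of medium-or-better
    completeness tier."""
    return [
        m for m in metas if m.length >= min_len_alt or m.quality_tier in PASSING_TIERS
    ]


# ---------------------------------------------------------------------------
# run config + end-to-end


@dataclasses.dataclass
class RunConfig:
    """Configuration of a fixture-scale end-to-end run."""

    outdir: str = "paleovir_run"
    seed: int = 0
    # community
    n_ancient: int = 5
    n_modern: int = 5
    genome_length: int = 20_000
    coverage: float = 60.0
    frag_len_mean: float = 60.0
    frag_len_sd: float = 15.0
    ancient_d1: float = 0.042
    ancient_lam: float = 0.3
    ancient_background: float = 0.001
    modern_background: float = 0.002
    # stages
    stage_simulate: bool = True
    stage_damage: bool = True
    stage_cluster: bool = True
    stage_conserve: bool = True
    stage_microdiv: bool = True
    # damage
    positions: int = 20
    min_first_pos: float = 0.01
    score_threshold_fallback: float = 0.5
    # conservation (defaults mirror the three literature rates)
    cons_n: int = 36_630
    cons_q: float = 0.977
    cons_rates: tuple[float, ...] = (4.690e-3, 1.976e-4, 1.154e-4)
    cons_t_max: int = 1300
    # microdiversity
    min_cov: int = 5
    min_allele_freq: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "cons_rates" in raw:
            raw["cons_rates"] = tuple(float(r) for r in raw["cons_rates"])
        return cls(**raw)

    def validate(self) -> None:
        dataclasses.replace(self)  # re-runs field checks on dataclasses used later
        if self.n_ancient + self.n_modern < 1 and self.stage_simulate:
            raise ValueError("community must contain at least one genome")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_end_to_end(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict.

    Re-running with the same config and seed is bit-identical: every
    stochastic step derives its seed from ``config.seed`` and outputs
    carry no timestamps.
    """
    config.validate()
    out = ensure_dir(config.outdir)
    manifest: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": [],
        "outputs": {},
    }
    community = None
    t0 = time.time()

    def stage(name: str, enabled: bool):
        def wrap(fn):
            nonlocal community
            if not enabled:
                return
            start = time.time()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - report which stage failed
                raise StageError(name, exc) from exc
            logger.info("stage %s done in %.2fs", name, time.time() - start)
            manifest["stages"].append(name)

        return wrap

    @stage("simulate", config.stage_simulate)
    def _simulate():
        nonlocal community
        rp = synthgen.ReadSimParams(
            coverage=config.coverage,
            frag_len_mean=config.frag_len_mean,
            frag_len_sd=config.frag_len_sd,
            seed=config.seed,
        )
        dp = synthgen.DamageParams(
            d1=config.ancient_d1,
            lam=config.ancient_lam,
            background=config.ancient_background,
        )
        community = synthgen.make_community(
            n_ancient=config.n_ancient,
            n_modern=config.n_modern,
            rp=rp,
            dp=dp,
            modern_background=config.modern_background,
            genome_length=config.genome_length,
            seed=config.seed,
            outdir=out / "fixture",
        )

    @stage("damage", config.stage_damage and config.stage_simulate)
    def _damage():
        refs = {g.id: g for g in community.genomes}
        reads = [r for g in community.genomes for r in community.reads[g.id]]
        profiles = damage.profiles_from_sam(reads, refs, P=config.positions)
        fits = damage.fit_all(profiles)
        scores = sorted(
            (f.score for f in fits.values() if f is not None), reverse=True
        )
        threshold = (
            damage.kneedle_threshold(scores) if len(scores) >= 3 else None
        )
        if threshold is None:
            threshold = config.score_threshold_fallback
        decisions = damage.authenticate_contigs(
            fits, profiles, threshold, min_first_pos=config.min_first_pos
        )
        rows = []
        for d in decisions:
            fit = fits[d.contig_id]
            prof = profiles[d.contig_id]
            rows.append(
                {
                    "contig_id": d.contig_id,
                    "n_reads": prof.n_reads,
                    "freq_pos1": float(prof.freq[0]) if prof.n_c_sites[0] else float("nan"),
                    "score": fit.score if fit else float("nan"),
                    "p_value": fit.p_value if fit else float("nan"),
                    "passed": d.passed,
                    "reasons": ",".join(d.reasons),
                    "truth": community.truth.age_labels[d.contig_id],
                }
            )
        write_tsv(
            out / "authentication.tsv",
            pd.DataFrame(rows).sort_values("contig_id").reset_index(drop=True),
            comment="damage authentication; score threshold "
            f"{threshold:.6g}; positions 1-based",
        )
        prof_rows = [
            {
                "contig_id": cid,
                "position": i + 1,
                "n_c_sites": int(p.n_c_sites[i]),
                "n_ct": int(p.n_ct[i]),
                "freq": float(p.freq[i]) if p.n_c_sites[i] else float("nan"),
            }
            for cid, p in sorted(profiles.items())
            for i in range(p.P)
        ]
        write_tsv(
            out / "damage_profiles.tsv",
            pd.DataFrame(prof_rows),
            comment="per-contig C->T profile; position 1-based from the read 5' end",
        )

    @stage("cluster", config.stage_cluster and config.stage_simulate)
    def _cluster():
        clusters = vc.votu_cluster(community.genomes)
        frame = pd.DataFrame(
            {
                "genome_id": list(clusters.assignments),
                "cluster_id": list(clusters.assignments.values()),
                "is_centroid": [
                    clusters.centroids.get(cid) == gid
                    for gid, cid in clusters.assignments.items()
                ],
            }
        ).sort_values("genome_id").reset_index(drop=True)
        write_tsv(out / "votu_clusters.tsv", frame, comment="species-level vOTU clusters")

    @stage("conserve", config.stage_conserve)
    def _conserve():
        curve = conserve.conservation_curve(
            n=config.cons_n,
            q=config.cons_q,
            rates=config.cons_rates,
            t_max=config.cons_t_max,
        )
        write_tsv(
            out / "conservation_curve.tsv",
            curve,
            comment=f"P(>= {config.cons_q:.1%} unaltered) for an {config.cons_n}-site genome",
        )

    @stage("microdiv", config.stage_microdiv and config.stage_simulate)
    def _microdiv():
        rows = []
        for g in community.genomes:
            pile = microdiv.build_pileup(community.reads[g.id], g)
            cfg = microdiv.DiversityConfig(
                min_cov=config.min_cov, min_allele_freq=config.min_allele_freq
            )
            stats = microdiv.nucleotide_diversity(pile, cfg)
            rows.append(
                {
                    "genome_id": g.id,
                    "sites_considered": stats.sites_considered,
                    "mean_pi": stats.mean_pi,
                    "divergent_count": stats.divergent_count,
                    "divergent_fraction": stats.divergent_fraction,
                }
            )
        write_tsv(
            out / "microdiversity.tsv",
            pd.DataFrame(rows).sort_values("genome_id").reset_index(drop=True),
            comment="read-level diversity per genome",
        )

    outputs = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest["outputs"] = {str(p.relative_to(out)): _checksum(p) for p in outputs}
    logger.info("run complete in %.2fs", time.time() - t0)
    # no timestamps in the manifest: same config + seed => identical bytes
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
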