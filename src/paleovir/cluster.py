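"""Genome and proteome similarity, and viral taxonomic clustering.

Three layers of granularity, mirroring common practice for
uncultivated-virus genomics:

* species-level vOTUs: fragment-based ANI with an alignment-fraction
  requirement (>=95% ANI over >=85% of the shorter genome), greedy
  centroid clustering by descending genome length;
* genus/family levels: amino-acid identity over reciprocal-best-hit
  protein pairs and the fraction of shared genes, thresholded into an
  undirected graph (strict inequalities), partitioned with the Markov
  cluster algorithm (inflation 2.0 at genus, 1.2 at family rank).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import numpy as np

from .io import GenomeRecord

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ANIResult:
    id_a: str
    id_b: str
    ani: float  # length-weighted mean fragment identity, %
    af_shorter: float  # aligned fraction of the shorter genome, %

    def __post_init__(self) -> None:
        if not (0 <= self.ani <= 100 and 0 <= self.af_shorter <= 100):
            raise ValueError("ANI and alignment fraction must lie in [0,100]")


@dataclasses.dataclass
class AAIResult:
    id_a: str
    id_b: str
    aai: float  # unweighted mean % identity over RBH pairs
    shared_fraction: float  # RBH count / genes in the smaller proteome, %
    n_shared: int = 0


@dataclasses.dataclass
class VOTUConfig:
    """Species-rank clustering thresholds (inclusive)."""

    ani_min: float = 95.0
    af_min: float = 85.0
    fragment_len: int = 500
    #: a fragment counts as aligned only above this identity; random
    #: unrelated DNA aligns at well under 70% under edit distance
    min_frag_identity: float = 70.0

    def __post_init__(self) -> None:
        if not (0 < self.ani_min <= 100 and 0 < self.af_min <= 100):
            raise ValueError("thresholds must lie in (0,100]")


@dataclasses.dataclass
class AAIConfig:
    """Protein hit filter for the AAI computation."""

    min_identity: float = 30.0  # % identity over the local alignment
    min_coverage: float = 50.0  # % of the shorter protein covered


@dataclasses.dataclass
class TaxonLevelConfig:
    level: str  # "family" or "genus"
    aai_min: float
    shared_min: float
    inflation: float

    def __post_init__(self) -> None:
        if self.level not in ("family", "genus"):
            raise ValueError("level must be 'family' or 'genus'")

    @classmethod
    def family(cls) -> "TaxonLevelConfig":
        return cls(level="family", aai_min=20.0, shared_min=10.0, inflation=1.2)

    @classmethod
    def genus(cls) -> "TaxonLevelConfig":
        return cls(level="genus", aai_min=50.0, shared_min=20.0, inflation=2.0)


@dataclasses.dataclass
class ClusterSet:
    """A disjoint, total partition of genome IDs."""

    assignments: dict[str, str]  # genome_id -> cluster_id
    centroids: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        clusters: dict[str, list[str]] = {}
        for gid, cid in self.assignments.items():
            clusters.setdefault(cid, []).append(gid)
        self._clusters = clusters

    @property
    def n_clusters(self) -> int:
        return len(self._clusters)

    def members(self, cluster_id: str) -> list[str]:
        return sorted(self._clusters[cluster_id])

    def as_partition(self) -> list[frozenset[str]]:
        return sorted(
            (frozenset(v) for v in self._clusters.values()), key=lambda s: sorted(s)[0]
        )


# ---------------------------------------------------------------------------
# ANI


def _fragment_identity(fragment: str, target: str) -> tuple[float, int]:
    """Best infix alignment of a fragment against a genome.

    Returns (identity fraction, alignment columns); identity is
    matches / alignment columns from the edit-distance alignment.
    """
    res = edlib.align(fragment, target, mode="HW", task="distance")
    dist = res["editDistance"]
    # alignment columns ~ fragment length + deletions; the distance form
    # (len - dist)/len is a lower bound that is exact without target gaps
    cols = len(fragment)
    matches = cols - dist
    if matches < 0:
        matches = 0
    return matches / cols, cols


def pairwise_ani(a: GenomeRecord, b: GenomeRecord, cfg: VOTUConfig | None = None) -> ANIResult:
    """Fragment-based ANI and aligned fraction of the shorter genome.

    The shorter genome (ties broken lexicographically by ID) is cut
    into consecutive ``fragment_len`` windows (the trailing partial
    window included, so AF of a self-comparison is exactly 100); each
    window is aligned to the full longer genome by banded edit
    distance; windows above the identity floor count as aligned. ANI is
    the aligned-length-weighted mean identity, AF the aligned length
    over the shorter genome length.
    """
    cfg = cfg or VOTUConfig()
    if len(a) < len(b) or (len(a) == len(b) and a.id <= b.id):
        short, long_ = a, b
    else:
        short, long_ = b, a
    frag_len = cfg.fragment_len
    starts = list(range(0, len(short), frag_len))
    windows = [(s, min(s + frag_len, len(short))) for s in starts]
    if len(windows) > 1 and windows[-1][1] - windows[-1][0] < 20:
        # merge a tiny trailing remainder into the previous window so a
        # self-comparison covers the full genome (AF(A,A) = 100)
        last = windows.pop()
        prev = windows.pop()
        windows.append((prev[0], last[1]))
    aligned_len = 0
    weighted_id = 0.0
    for s, e in windows:
        frag = short.sequence[s:e]
        ident, _ = _fragment_identity(frag, long_.sequence)
        if ident * 100.0 >= cfg.min_frag_identity:
            aligned_len += len(frag)
            weighted_id += ident * len(frag)
    ani = 100.0 * weighted_id / aligned_len if aligned_len else 0.0
    af = 100.0 * aligned_len / len(short)
    return ANIResult(id_a=a.id, id_b=b.id, ani=ani, af_shorter=min(af, 100.0))


def all_pairwise_ani(
    genomes: Sequence[GenomeRecord], cfg: VOTUConfig | None = None
) -> list[ANIResult]:
    return [pairwise_ani(a, b, cfg) for a, b in itertools.combinations(genomes, 2)]


def votu_cluster(
    genomes: Sequence[GenomeRecord],
    results: Iterable[ANIResult] | None = None,
    cfg: VOTUConfig | None = None,
) -> ClusterSet:
    """Greedy centroid clustering into species-level vOTUs.

    Genomes are visited by descending length (ties lexicographic by
    ID); each joins the earliest-founded centroid it matches at
    ani >= ani_min and af >= af_min, otherwise founds a new cluster.
    Pairs absent from ``results`` are computed on demand.
    """
    cfg = cfg or VOTUConfig()
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome IDs")
    by_id = {g.id: g for g in genomes}
    table: dict[frozenset[str], ANIResult] = {}
    for r in results or []:
        table[frozenset((r.id_a, r.id_b))] = r

    def lookup(x: str, y: str) -> ANIResult:
        key = frozenset((x, y))
        if key not in table:
            table[key] = pairwise_ani(by_id[x], by_id[y], cfg)
        return table[key]

    order = sorted(genomes, key=lambda g: (-len(g), g.id))
    centroids: list[str] = []
    assignments: dict[str, str] = {}
    for g in order:
        placed = False
        for c in centroids:
            r = lookup(g.id, c)
            if r.ani >= cfg.ani_min and r.af_shorter >= cfg.af_min:
                assignments[g.id] = f"vOTU_{centroids.index(c) + 1}"
                placed = True
                break
        if not placed:
            centroids.append(g.id)
            assignments[g.id] = f"vOTU_{len(centroids)}"
    return ClusterSet(
        assignments=assignments,
        centroids={f"vOTU_{i + 1}": c for i, c in enumerate(centroids)},
    )


# ---------------------------------------------------------------------------
# AAI

_blosum_aligner = None


def _protein_aligner():
    global _blosum_aligner
    if _blosum_aligner is None:
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        _blosum_aligner = aligner
    return _blosum_aligner


def _local_protein_hit(p: str, q: str) -> tuple[float, float, float] | None:
    """Score, % identity and % coverage (of the shorter protein) of the
    best local alignment, or None for an empty alignment."""
    aligner = _protein_aligner()
    alns = aligner.align(p, q)
    if len(alns) == 0:
        return None
    aln = alns[0]
    a_rows = str(aln[0]), str(aln[1])
    cols = len(a_rows[0])
    if cols == 0:
        return None
    matches = sum(1 for x, y in zip(*a_rows) if x == y and x != "-")
    aligned_q = sum(1 for x in a_rows[0] if x != "-")
    aligned_s = sum(1 for y in a_rows[1] if y != "-")
    coverage = 100.0 * min(aligned_q, aligned_s) / min(len(p), len(q))
    identity = 100.0 * matches / cols
    return float(aln.score), identity, coverage


def pairwise_aai(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    id_a: str = "A",
    id_b: str = "B",
    cfg: AAIConfig | None = None,
) -> AAIResult:
    """AAI and shared-gene fraction via reciprocal best hits.

    All-vs-all local protein alignment (BLOSUM62, gap open 11 / extend
    1); hits below 30% identity or 50% coverage of the shorter protein
    are discarded; reciprocal best hits (by score, ties to the
    lexicographically first partner) define the shared genes. AAI is
    the unweighted mean identity over RBH pairs; the shared fraction is
    relative to the smaller proteome.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("empty proteome")
    cfg = cfg or AAIConfig()
    best_ab: dict[str, tuple[float, str, float]] = {}
    best_ba: dict[str, tuple[float, str, float]] = {}
    for ga, pa in proteome_a.items():
        for gb, pb in proteome_b.items():
            hit = _local_protein_hit(pa, pb)
            if hit is None:
                continue
            score, ident, cov = hit
            if ident < cfg.min_identity or cov < cfg.min_coverage:
                continue
            if ga not in best_ab or score > best_ab[ga][0] or (
                score == best_ab[ga][0] and gb < best_ab[ga][1]
            ):
                best_ab[ga] = (score, gb, ident)
            if gb not in best_ba or score > best_ba[gb][0] or (
                score == best_ba[gb][0] and ga < best_ba[gb][1]
            ):
                best_ba[gb] = (score, ga, ident)
    rbh_idents = [
        ident
        for ga, (score, gb, ident) in best_ab.items()
        if best_ba.get(gb, (None, None))[1] == ga
    ]
    n_small = min(len(proteome_a), len(proteome_b))
    if rbh_idents:
        aai = float(np.mean(rbh_idents))
        shared = 100.0 * len(rbh_idents) / n_small
    else:
        aai = 0.0
        shared = 0.0
    return AAIResult(
        id_a=id_a, id_b=id_b, aai=aai, shared_fraction=min(shared, 100.0),
        n_shared=len(rbh_idents),
    )


# ---------------------------------------------------------------------------
# graph + MCL


def similarity_graph(results: Iterable[AAIResult], cfg: TaxonLevelConfig) -> nx.Graph:
    """Threshold AAI results into an undirected weighted graph.

    Edges require aai > aai_min AND shared_fraction > shared_min
    (strict, matching the '>' semantics of the rank thresholds); the
    edge weight is the AAI. Every genome mentioned becomes a node.
    """
    g = nx.Graph()
    for r in results:
        g.add_node(r.id_a)
        g.add_node(r.id_b)
        if r.aai > cfg.aai_min and r.shared_fraction > cfg.shared_min:
            g.add_edge(r.id_a, r.id_b, weight=r.aai)
    return g


def mcl_cluster(
    graph: nx.Graph,
    inflation: float,
    expansion: int = 2,
    tol: float = 1e-6,
    max_iter: int = 200,
    prune: float = 1e-8,
) -> ClusterSet:
    """Markov clustering of a weighted graph.

    Self-loops are added with the maximum incident edge weight (1 for
    isolated nodes), columns are normalized to stochastic, and the
    expansion (matrix power) / inflation (elementwise power +
    renormalization) cycle runs with pruning of entries below
    ``prune`` until the largest column change falls below ``tol``.
    Clusters are read off attractor rows; overlapping attractor
    supports are merged so the output is a partition.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must exceed 1")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return ClusterSet(assignments={})
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    for i in range(n):
        inc = m[:, i].max()
        m[i, i] = inc if inc > 0 else 1.0
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        expanded = np.linalg.matrix_power(m, expansion)
        inflated = expanded**inflation
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if float(np.abs(inflated - m).max()) < tol:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        logger.warning("MCL did not converge after %d iterations", max_iter)

    # attractors: rows with non-negligible diagonal mass
    attractors = [i for i in range(n) if m[i, i] > tol]
    clusters: list[set[int]] = []
    for a in attractors:
        support = set(np.flatnonzero(m[a] > tol).tolist()) | {a}
        merged = False
        for c in clusters:
            if c & support:
                c |= support
                merged = True
                break
        if merged:
            # cascading merge in case the new support bridged two clusters
            changed = True
            while changed:
                changed = False
                for i in range(len(clusters)):
                    for j in range(i + 1, len(clusters)):
                        if clusters[i] & clusters[j]:
                            clusters[i] |= clusters.pop(j)
                            changed = True
                            break
                    if changed:
                        break
        else:
            clusters.append(set(support))
    assigned = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in assigned:
            clusters.append({i})
            assigned.add(i)
    clusters.sort(key=lambda c: min(c))
    assignments = {
        nodes[i]: f"{'mcl'}_{k + 1}" for k, c in enumerate(clusters) for i in sorted(c)
    }
    return ClusterSet(assignments=assignments)
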