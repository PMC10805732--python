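# Methods

`paleovir` implements the quantitative core of an ancient-virome
analysis: deciding from read-level damage patterns whether assembled
phage contigs are ancient, organising viral genomes into species /
genus / family groups, asking how surprising the long-term conservation
of a phage genome is under published mutation rates, and measuring
within-sample strain diversity. Everything is exercisable on synthetic
data with exhaustive ground truth, so the statistical behaviour of each
stage can be verified without any external downloads.

## Synthetic ancient metagenomes (`paleovir.synthgen`)

**Genomes and evolution.** Genomes are i.i.d. random DNA with a chosen
GC fraction. A descendant evolves from an ancestor by independent
per-site substitution: a rate *r* (alterations per site per year) over
*t* years maps to a per-site alteration probability

    p_t = 1 − (1 − r)^t        (compound, default)
    p_t = min(r·t, 1)          (linear, optional)

The two differ by < 3×10⁻⁴ at temperate-phage scales (r ≈ 1.15×10⁻⁴,
t ≈ 200 y), so the choice is immaterial there; the compound form is the
default because it remains a probability at any horizon. Altered sites
receive one of the three other bases uniformly — no
transition/transversion bias is modelled, because none is needed for
any downstream statistic (identity, SNV counts and the conservation
model are substitution-count statistics). Every alteration is recorded
in a truth table, and a test asserts that the Hamming distance between
ancestor and descendant equals the truth-table length exactly.

**Genes.** Planted genes are non-overlapping, forward-strand CDS
intervals whose content is rewritten with stop-free codons (ATG
first), so a gene of length 3k translates to exactly k amino acids.
This gives clean proteomes for amino-acid-identity tests; strand
handling is still honoured by all consumers.

**Reads.** Fragment lengths are normal, truncated to
[20 bp, genome length] (defaults: mean 60 bp, sd 15 bp, 30×
coverage — stand-ins for short aDNA libraries, chosen as typical values
for degraded-DNA sequencing rather than reconstructions of any
particular library). Read count is coverage·L/mean length; fragments
are drawn uniformly, half on each strand.

**Deamination.** Cytosine deamination is the canonical aDNA signal:
C→T mismatches concentrated at the 5′ ends of reads. The simulator
applies, in read orientation *before* reverse-complementing,

    d(i) = b + (d1 − b)·exp(−λ(i−1)),   i = 1, 2, … (5′ read position)

so the 5′ pattern is preserved in read coordinates on both strands. A
modern control is the flat curve d(i) = b. Defaults follow the damage
regimes seen in well-preserved palaeofaeces gut-phage data: a strong
ancient signal of d1 = 0.042, a collection-mean signal of 0.025, a
modern background of 0.002, and decay λ = 0.3 per position. A uniform
sequencing-error channel (any base to any other, applied after
damage) is available and off by default; the flat C→T background term
is the right way to plant a modern-control C→T level, since uniform
errors reach T from C only a third of the time. 3′ G→A mirroring is
available behind `mirror_3prime` and off by default.

**Communities.** `make_community` builds a mixed set of ancient
(damaged reads) and modern (flat-background reads) genomes. Declared
species clusters are produced by evolving each member from a shared
ancestor at *half* the declared divergence, so the *pairwise* identity
between members matches the declared within-cluster ANI in
expectation (two independent branches of divergence d give pairwise
mismatch probability 2d(1−d) + ⅔d²). Fixtures are written as plain
FASTA / FASTQ (constant Q37) / SAM (FLAG 0/16, single-M CIGAR) / TSV
truth tables.

What the simulator does **not** emulate: indels during evolution
(indel events are handled at the alignment-consumption layer),
circular-genome wrap-around reads, quality-score error profiles,
library-preparation-specific damage chemistry, mapping ambiguity
(true alignments are emitted directly). Passing tests therefore
demonstrate correctness of the statistical machinery under a clean
substitution-and-deamination model, not robustness to mapper artefacts
or reference bias in real data.

## Damage authentication (`paleovir.damage`)

The per-contig damage profile counts, over the first P = 20 read
positions from the 5′ end (read coordinates on both strands): n_C[i],
the read positions whose aligned reference base is C, and n_CT[i],
those read as T. Reverse-flagged reads are walked from their right
(stored) end with complemented bases, which is the same C→T event in
read coordinates.

The profile is scored by a likelihood-ratio test: the alternative
maximises ∏ᵢ Binom(n_CT[i] | n_C[i], d(i)) over (d1, λ, b) with box
constraints d1, b ∈ [10⁻⁶, 0.99], λ ∈ [10⁻³, 10] (L-BFGS-B from five
fixed starts, ties to the first); the null is a constant background
whose MLE is the pooled frequency. The p-value is the χ²(2 df) upper
tail of 2·ΔlogL and the authentication score is 1 − p. The χ²
reference distribution is formally an approximation here (λ is not
identifiable under the null), but its calibration was checked by
simulation: p-values of flat-background profiles pass a
Kolmogorov–Smirnov uniformity test, so the score behaves as a proper
significance. This score replaces the trained "predicted accuracy" of
external damage tools with a transparent, self-contained statistic;
the downstream filter semantics are unchanged.

The score threshold is taken at the knee of the descending score curve
(Kneedle: normalise the curve to the unit square, return the score at
maximum deviation from the chord; no knee → caller falls back to a
configurable constant, default 0.5). The final decision requires, per
contig: score ≥ threshold AND **empirical** first-position frequency
≥ 0.01 (the minimum-frequency rule guards against flat sequencing
noise; the empirical rather than fitted frequency is used because the
rule is stated as a transition-frequency cutoff) AND at least 3
informative positions. Failures carry machine-readable reasons.

## Viral clustering (`paleovir.cluster`)

**Species (vOTU).** ANI between two genomes is fragment-based: the
shorter genome (ties broken lexicographically, making ANI exactly
symmetric) is cut into consecutive 500-bp windows (a trailing
remainder < 20 bp is merged into the previous window so a
self-comparison has AF = 100 exactly); each window is aligned to the
full partner by infix edit distance (edlib); windows at ≥ 70% identity
count as aligned. ANI is the aligned-length-weighted mean identity and
AF the aligned length over the shorter genome. The identity floor
plays the role a hit E-value/coverage cutoff plays in BLAST-based ANI
pipelines: unrelated random DNA aligns far below it, so unrelated
genomes give AF ≈ 0, while genuinely homologous windows at
species-level divergence pass untouched. Both the window size and the
floor are config-exposed. Clustering is greedy centroid formation by
descending genome length: a genome joins the earliest centroid with
ANI ≥ 95 and AF ≥ 85 (inclusive thresholds), else founds a cluster.

**Genus/family.** AAI between two proteomes is the unweighted mean
identity over reciprocal best hits of an all-vs-all local protein
alignment (BLOSUM62, gap open 11 / extend 1); hits need ≥ 30% identity
over ≥ 50% of the shorter protein. The shared-gene fraction is the RBH
count over the smaller proteome. Pairs enter an undirected graph when
AAI and shared fraction strictly exceed the rank thresholds
(genus: 50% / 20%; family: 20% / 10%), with AAI as edge weight. The
graph is partitioned by Markov clustering: add self-loops at the
maximum incident weight (1 for isolated nodes), column-normalise,
then iterate expansion (matrix square) and inflation (elementwise
power 2.0 at genus rank, 1.2 at family rank; renormalise; prune
entries < 10⁻⁸) to convergence (max column change < 10⁻⁶, cap 200
iterations — non-convergence returns the current interpretation with
a warning). Clusters are read off attractor rows; overlapping
supports are merged, and untouched nodes become singletons, so the
output is always a total partition. MCL provably cannot merge
disconnected components, and tests enforce both properties.

## Genome-pair analysis and the conservation model (`paleovir.conserve`)

**Alignment.** Global pairwise alignment uses match +2 / mismatch −3 /
gap open −5 / gap extend −2 (the first gap column costs the open
score, each further column the extend score). The unbanded path is
Biopython's aligner; a banded mode restricts the affine DP to
|i − j| ≤ band for long near-collinear pairs and is checked against
the unbanded result and against a brute-force DP on toy strings.

**Core vs flanks.** A prophage contig carries host sequence at its
ends. Given alignments of the query against k relatives, a query
position is "present" in a relative when its column is non-gap there;
the core is the largest contiguous run of positions present in ≥
min_presence relatives, and the flank lengths fall out as the
remainder. End-trimming is alignment-dependent by ±1–2 bp, which the
tests tolerate.

**SNVs and indel events.** A SNV is a both-bases-differ column;
maximal one-row gap runs collapse to single insertion/deletion events
(positioned at the last preceding query base, 1-based on the query).
On gapless pairs the SNV count equals the planted substitution count
exactly.

**Window identity.** Identity over sliding alignment-column windows
(default 100 columns, step 50); a window is flagged hypervariable when
its identity falls below mean − 3·sd of all windows. This is a simple
outlier rule for localising the mutational hotspot a
diversity-generating retroelement leaves in its target gene; the 3-sd
factor is a package choice (config-exposed), adequate because DGR
hotspots are an order of magnitude more divergent than background.

**Per-gene identity.** Genes annotated on the query are extracted
through the alignment's coordinate maps; nucleotide identity is over
the aligned columns, amino-acid identity re-aligns the two translated
sub-sequences locally (BLOSUM62). Fully deleted genes are reported as
missing and excluded from the unweighted mean.

**Conservation probability.** The probability that an n-site genome
still has at least a fraction q of unaltered sites after t years at
per-site rate r is the binomial tail

    P(X ≤ m),   X ~ Binomial(n, p_t),   m = ⌊n(1−q)⌋

with p_t as in the simulator. The CDF is accumulated in log space
(log-sum-exp over the m+1 log-pmf terms, gammaln coefficients), so
values far below float underflow are still reported as log₁₀
probabilities; it agrees with an independent binomial-CDF oracle to
10⁻¹⁰ relative in log₁₀. (The m product is rounded at 10⁻⁹ before
flooring so exactly-representable fractions are not pushed down by
float error.) `years_to_threshold` finds the smallest integer t with
P < p* (default 10⁻³, the operationalisation of "approaches zero") by
exponential search plus bisection — valid because P is non-increasing
in t; r = 0 returns the sentinel None ("never"). With n = 36,630,
q = 0.977 and the temperate-phage rate r = 1.154×10⁻⁴, expected
identity after 200 years is 97.7% and the conservation probability
crosses 10⁻³ at t = 224 years, collapsing below 10⁻³⁰⁰ by 1300 years.

## Microdiversity (`paleovir.microdiv`)

Pileups attribute read bases to reference sites by a CIGAR walk
(deletions contribute nothing; insertions and soft clips are skipped).
Per site with coverage c ≥ 5, nucleotide diversity uses the unbiased
pairwise-difference form π = 1 − Σₐ C(cₐ,2)/C(c,2); the genome value
is the mean over considered sites. A site is divergent when a
non-reference allele reaches frequency ≥ 0.05 **and** at least 2
supporting reads — the absolute floor suppresses singleton sequencing
errors. Mapping-quality/base-quality and read-pair filters of
full-featured strain profilers are deliberately not reproduced; the
definitions here are pure count statistics with config-exposed
thresholds, which makes them exactly testable (a 5/5 biallelic site
gives π = 1 − 20/45 = 0.5556 in closed form).

## Workflow plumbing and orchestration (`paleovir.pipeline`)

The selection filters mirror a virome workflow: assembly filter
(length strictly > 4000 nt — "longer than" is strict — and coverage
≥ 20), consensus viral call (≥ 2 tool votes), analysis set (≥ 20 kb
OR medium-or-better completeness tier; tiers are an input column, not
recomputed). `run_end_to_end` chains simulate → damage → cluster →
conserve → microdiv at fixture scale, emits TSV reports with 1-based
fully-closed coordinates stated in each header, and writes a manifest
(config, stage list, sha256 of every output) that fully determines the
run: same config + seed ⇒ identical bytes. A stage failure aborts with
an error naming the stage; the CLI maps validation errors to exit
code 2 and stage failures to 3.

## Problem sizes used in the shipped checks

The test-suite and the reproduction script run at desk scale by
design: 40-kb references with ~50,000 60-bp reads for damage-recovery
checks; 10-contig communities (10-kb contigs, ≥ 20,000 reads each)
over 20 seeds for the classifier operating point; 36,630-nt genome
pairs for evolution/ANI checks; ≤ 10-node graphs for MCL equivalence.
Dataset-scale counts from real surveys (hundreds of vOTUs from
thousands of contigs) are outside what synthetic desk-scale fixtures
can or should reproduce.

## Known limitations

- The damage score is a within-package likelihood-ratio significance;
  absolute score values are not comparable to trained-classifier
  accuracies from external tools, only the filter semantics are.
- Fragment ANI with unit-cost edit distance slightly favours gapped
  over mismatch-only explanations in repetitive regions; at
  species-level divergence on non-repetitive genomes the planted-truth
  bias measured in tests is < 0.01 ANI points.
- The conservation model treats alterations as i.i.d. across sites,
  as the rate definitions imply; rate heterogeneity or recombination
  hotspots would make the tail less extreme than reported.
- `trim_flanks` consumes per-relative pairwise alignments (star
  layout); a joint multiple alignment is not constructed.
- Genus/family MCL clustering operates on user-supplied proteomes;
  gene calling is out of scope.
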