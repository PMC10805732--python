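# paleovir

Tools for analysing ancient bacteriophage genomes recovered from
palaeofaeces and other archaeological metagenomes — for researchers who
assemble viral contigs from degraded DNA and need to (a) authenticate
their ancient origin, (b) organise them taxonomically, and (c) reason
about how conserved a phage genome can plausibly remain over centuries.

## What it does

**Damage authentication.** Ancient DNA accumulates cytosine
deamination, visible as C→T mismatches concentrated at the 5′ ends of
sequencing reads. `paleovir.damage` profiles, per contig, the C→T
frequency at the first 20 read positions, fits the decaying damage
model d(i) = b + (d1 − b)e^{−λ(i−1)} against a flat-background null by
maximum likelihood, scores contigs with the likelihood-ratio
significance, picks a score threshold at the knee of the score curve
(Kneedle), and applies the final filter: score above threshold *and*
empirical first-position frequency ≥ 0.01.

**Viral clustering.** `paleovir.cluster` computes fragment-based ANI
with the aligned fraction of the shorter genome and groups genomes into
species-level vOTUs (≥95% ANI over ≥85% AF, greedy centroid by length);
at genus/family ranks it computes amino-acid identity over reciprocal
best hits, thresholds pairs into a graph (genus: AAI >50%, shared genes
>20%, MCL inflation 2.0; family: >20%, >10%, inflation 1.2) and
partitions it with an in-package Markov clustering implementation.

**Genome conservation.** `paleovir.conserve` aligns genome pairs
(optionally banded), separates a prophage core from host-derived
flanks, calls SNVs and indel events, scans window identity to flag
hypervariable (DGR-target) regions, computes per-gene
nucleotide/amino-acid identity, and evaluates the binomial
conservation model: the probability that an n-site genome keeps at
least a fraction q of sites unaltered after t years at per-site rate r,

    P(X ≤ ⌊n(1−q)⌋),  X ~ Binomial(n, 1−(1−r)^t),

computed in log space so that astronomically small tails remain
reportable.

**Microdiversity.** `paleovir.microdiv` builds pileups from read
alignments and computes per-site nucleotide diversity
π = 1 − Σₐ C(cₐ,2)/C(c,2) and divergent-site counts.

**Simulation.** `paleovir.synthgen` generates genomes, evolved
descendants, planted genes, and damaged/undamaged read sets with full
truth tables, so every stage above is testable end to end without any
external data.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

```python
from paleovir import synthgen as sg, damage as dk, conserve as ck

# simulate an ancient contig: 40 kb, ~50,000 damaged 60-bp reads
genome = sg.simulate_genome(length=40_000, gc=0.45, seed=2)
reads, truth = sg.simulate_reads(
    genome,
    sg.ReadSimParams(coverage=75, frag_len_mean=60, seed=5),
    sg.DamageParams(d1=0.042, lam=0.3, background=0.001),
)

profile = dk.compute_damage_profile(reads, genome)
fit = dk.fit_damage_model(profile)
print(f"freq[1] = {profile.freq[0]:.4f}")
print(f"fitted d1 = {fit.d1_hat:.4f}, lambda = {fit.lam_hat:.3f}, b = {fit.b_hat:.4f}")

t = ck.years_to_threshold(36_630, 0.977, 1.154e-4, prob_target=1e-3)
_, log10p = ck.prob_conserved(ck.ConservationParams(years_t=1300.0))
print(f"P < 1e-3 after t = {t} years; log10 P at 1300 y = {log10p:.1f}")
```

prints

```
freq[1] = 0.0417
fitted d1 = 0.0418, lambda = 0.296, b = 0.0008
P < 1e-3 after t = 224 years; log10 P at 1300 y = -1313.3
```

The recovered first-position C→T frequency (0.0417) matches the
planted deamination amplitude 0.042 within binomial sampling error,
and the model fit recovers all three damage parameters. The
conservation numbers say: a 36,630-nt genome has essentially no chance
(P < 10⁻³) of staying ≥97.7% unaltered for more than ~224 years under
a temperate-phage substitution rate of 1.154×10⁻⁴ /site/year — and by
1300 years the probability is ~10⁻¹³¹³ — so observing such a conserved
pair implies the mutation-accumulation assumptions, not chance, must
give way.

A command-line interface mirrors the library
(`paleovir simulate | damage | cluster | conserve | microdiv | run`);
`paleovir run --outdir out --seed 1` re-enacts the whole workflow on a
simulated community and writes TSV reports plus a manifest that makes
the run bit-reproducible.

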