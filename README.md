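# abselect

Sitewise mutation–selection modeling of antibody affinity maturation.

During an immune response, B-cell receptor genes mutate by somatic
hypermutation (SHM) and the resulting variants are selected for antigen
binding.  `abselect` separates these two forces: given parent–child pairs
(PCPs) of aligned in-frame sequences from clonal-family trees and a fixed
neutral SHM model, it infers a **selection factor** `f_j ≥ 0` for every codon
site `j` of a sequence — the multiplier on the neutral probability of
nonsynonymous substitution at that site.  `f_j > 1` indicates diversifying
selection, `f_j < 1` purifying selection, `0` the strongest possible
purifying selection; the interpretation parallels dN/dS, but on the
probability scale.  The package is aimed at computational immunologists
working with BCR repertoire data who want per-site, per-sequence selection
maps rather than repertoire-wide averages.

## Model

Neutral SHM is an independent Poisson process per nucleotide site: over a
branch of length `t`, site `i` keeps its base with probability
`exp(-λ_i t)` and substitutes to base `b` with probability
`(1 - exp(-λ_i t)) s_{i,b}`.  Codon transition probabilities `p_{j,c}(t, X)`
are products of the three per-position terms.  The mutation–selection
transition probability to a non-parent codon `c` at site `j` is

    m_{j,c}(t, X) = f_j(X̄) p_{j,c}(t, X)   if c codes a non-parent amino acid
                  = p_{j,c}(t, X)           if c is synonymous with the parent
                  = 0                       if c is a stop codon,

with the parent codon taking the remaining mass.  `f` is parameterized by a
transformer encoder over the parent amino-acid sequence (baselines: a single
shared factor, or one factor per position), with a "wiggle" output activation
`exp(β(x−1))` below 1 and `x^β` above (β = 0.3) that keeps factors positive
with sub-linear growth.  Selection parameters train on a per-site binary
cross-entropy; branch lengths are jointly re-optimized against the full
codon-level likelihood, whose synonymous signal makes `t` and `f`
identifiable.  A simulator draws child sequences from `m_{j,·}` down trees
(it cannot create stop codons), and evaluation provides the observed-vs-
expected per-site histogram overlap, a log-factor R² against the identity
line, and weighted Shannon entropies.  Details: `docs/methods.md`.

## Worked example

Simulate training data under a known ground truth, fit the one-parameter
repertoire-wide baseline, and compare both against what actually happened:

```python
import numpy as np
from abselect import (
    GroundTruthSpec, gen_ground_truth, gen_kmer_table, gen_pcp_dataset,
    build_selection_model, fit, predict_selection, site_obs_exp, pooled_overlap,
)
from abselect.selection import SelectionModelConfig

rates = gen_kmer_table(rng=0)                      # 5-mer neutral SHM table
truth = gen_ground_truth(GroundTruthSpec(family="context",
                                         hydrophobic_penalty=0.5))
pcps = gen_pcp_dataset(3000, truth, rates, seed=42)

single = build_selection_model(SelectionModelConfig(family="single"))
state = fit(pcps, single, rates, cycles=2, epochs_per_cycle=2, lr=3e-2, seed=0)
print(f"single-factor model: f = {single.factor:.3f}")
print(f"median fitted branch length: {np.median(state.branch_lengths):.4f}")

for p, t in zip(pcps, state.branch_lengths):
    p.branch_length = t
print(f"single-factor overlap: {pooled_overlap(site_obs_exp(pcps, single, rates)):.3f}")
print(f"ground-truth overlap:  {pooled_overlap(site_obs_exp(pcps, truth, rates)):.3f}")

profile = predict_selection(truth, "QVQLVQSGAEVKKPGSSVKVSCKAS")
print("ground-truth factors, first 6 sites:", np.round(profile[:6], 3))
```

Output:

```
single-factor model: f = 0.892
median fitted branch length: 0.0362
single-factor overlap: 0.850
ground-truth overlap:  0.948
ground-truth factors, first 6 sites: [1.    0.562 1.241 0.671 0.711 1.476]
```

The fitted global factor (0.89) says these simulated lineages are, on
average, mildly purifying — but averaging is exactly what it gets wrong:
its per-site expected substitution counts overlap the observed counts at
only 0.85, while the sequence-aware ground-truth model reaches 0.95 on the
same pairs.  The per-site profile shows why: factors swing from strong
purifying (0.56, a hydrophobic valine) to diversifying (1.48) within six
sites.  (Overlap at a few thousand pairs is also noise-limited; it climbs
toward 1 as the dataset grows.)

## Command line

```bash
abselect make-fixtures --seed 1 --out fixtures/         # synthetic data
abselect extract-pcps --tree t.nwk --seqs s.fasta --out pcps.tsv
abselect fit --pcps pcps.tsv --neutral rates.tsv --out ckpt/ --cycles 4 --seed 1
abselect predict --model ckpt/model --fasta seqs.fasta --out factors.tsv
abselect simulate --trees t.nwk --naive naive.fasta --model ckpt/model \
         --neutral rates.tsv --seed 1 --out sim.tsv
abselect evaluate --pcps test.tsv --model ckpt/model --neutral rates.tsv --out report/
```

All seeded commands are byte-for-byte reproducible for a fixed seed.

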