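# boacall

Breed-origin-of-alleles (BOA) assignment for crossbred dairy cattle, plus the
stochastic crossbreeding simulator used to validate it.

## The problem

Smallholder dairy production in low- and middle-income countries relies on
crossing local cows with imported exotic bulls, usually without pedigree
records. Knowing which *allele copy* of a crossbred animal descends from the
exotic versus the local founder breeds enables breed-specific genomic
evaluation and targeted introgression of adaptive haplotypes. `boacall`
assigns that breed origin from phased genotypes alone, with no pedigree.

## The algorithm

The chromosome is tiled into **cores** — windows of `L` consecutive SNPs —
both plainly and with the boundaries shifted forward by `L/2` (**offset**
mode). Within each core, the unique haplotype sequences observed in each
purebred reference panel form that breed's **haplotype library**. A crossbred
haplotype `h` restricted to a core `c` is assigned by fewest-mismatch
matching:

```
m_B(h, c) = min over library entries g of breed B of  Hamming(h[c], g)
call(h, c) = EXOTIC  if m_E < m_L
             LOCAL   if m_L < m_E
             MISSING if m_E = m_L
```

and the call is broadcast to every locus in the core. Running all core
lengths (100, 120, …, 280 SNPs) in both modes gives 20 votes per allele;
the **consensus** call at agreement threshold τ ∈ {0.50, …, 0.95} is the
majority breed among the non-missing votes, accepted only if it holds a
strict majority and a fraction ≥ τ of those votes.

Performance is quantified per stratum as %correct, %incorrect and
%unassigned of all allele cells (they sum to 100 exactly), assignment
yield = assigned fraction, and accuracy = correct / assigned.

## The validation simulator

Founders (1 exotic breed, 4 closely related local breeds; 500 diploids each,
1000 SNPs on a 1-Morgan chromosome) are drawn from a coalescent split model
(`msprime`) whose split depths are calibrated so the exotic-vs-local Hudson
FST is ≈ 0.09. The breeding program then mates the pooled local breeds at
random for 10 generations, selects the 1000 best cows on a polygenic trait
(h² = 0.3, mild dominance), and runs 5 rounds of crossing to 25 freshly
imported exotic bulls (2000 calves per round, all heifers retained). Every
meiosis cuts haplotypes and founder-breed origin at the same recombination
breakpoints, so the true BOA of every crossbred allele is known and scoring
is exact.

## Worked example

```python
from boacall import ExperimentConfig, run_experiment

result = run_experiment(ExperimentConfig(n_replicates=10, master_seed=1))
s = result.summary()
print(f"core-based:  %correct={s['core_pct_correct']:.2f}  "
      f"%incorrect={s['core_pct_incorrect']:.2f}  accuracy={s['core_accuracy']:.3f}")
print(f"consensus:   %correct={s['consensus_pct_correct']:.2f}  "
      f"accuracy={s['consensus_accuracy']:.3f}")
print(f"founder FST: {s['founder_fst_mean']:.3f}")
```

prints (about 3 minutes on one CPU):

```
core-based:  %correct=98.36  %incorrect=1.33  accuracy=0.987
consensus:   %correct=97.87  accuracy=0.997
founder FST: 0.091
```

i.e. with perfect phasing, ~98% of crossbred alleles are assigned the right
breed, ~1.3% the wrong one (cores straddling an ancestry switch point), and
only ~0.3% are left unassigned by library ties; consensus voting trades a
little yield for near-zero error. `result.table_by_core_length()` and
`result.table_by_threshold()` give the per-core-length and per-threshold
breakdowns.

The same pipeline is scriptable from the shell:

```
boacall simulate --seed 3 --out sim/ --pop-size 50 --n-dams 100
boacall assign --crossbreds sim/crossbred_1.vcf --crossbreds-samples sim/crossbred_1.samples.tsv \
    --exotic sim/exotic_panel_round1.vcf --exotic-samples sim/exotic_panel_round1.samples.tsv \
    --local sim/local_panel_round1.vcf --local-samples sim/local_panel_round1.samples.tsv \
    --out calls.tsv
boacall consensus --calls calls.tsv --out consensus.tsv
boacall evaluate --calls consensus.tsv --truth sim/crossbred_1.truth.tsv --out metrics.csv
boacall reproduce-tables --seed 1 --out results/
```

`boacall assign` also accepts any user-supplied phased VCF (GT with `|`)
plus a sample-sheet TSV, so the assignment stages run on real data.

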