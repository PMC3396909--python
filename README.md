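# conselmk

Two complementary analyses of positive selection in *Drosophila*
protein-coding genes, both stratified by the local conservatism of the
protein segment a site sits in:

1. **Conservation-binned McDonald–Kreitman (MK) test.** Codon sites are
   binned by the number of gapless, amino-acid-invariant columns in a
   21-site sliding window of a designated species set. Within each bin,
   divergence and polymorphism are pooled over strictly non-degenerate
   ("non-synonymous") and fourfold-degenerate ("synonymous") nucleotide
   positions, and the fraction of adaptive amino acid substitutions is

   α = 1 − (d_S·p_N)/(d_N·p_S),  ω_a = α·d_N/d_S,

   with low-frequency variants (enriched for segregating deleterious
   alleles that bias α downward) removed by an allele-count cutoff
   (count > ⌊0.15·n⌋, e.g. >24 of 162 genotypes), and 95% CIs from
   bootstrapping sites within bins.

2. **Double-substitution clumping.** Codons with two non-synonymous
   substitutions between the *D. simulans–sechellia* and
   *D. pseudoobscura–persimilis* clades carry a temporal signature of
   selection: under independence the two substitutions fall in
   *different* lineages with probability 2·l₁·l₂ ≈ 0.48 (proportional
   lineage lengths 0.68 and 1.03 d_S), so a shortage of that pattern
   measures the fraction of pairs whose second substitution was driven
   by positive selection, δ = (2l₁l₂ − f(P₁))/(2l₁l₂). For pairs on the
   *sim–sec* path, the *D. ananassae* and *D. yakuba* branch points
   bracket each substitution on a path segment; the fraction of pairs
   straddling the *ananassae* point closely gives the mean lag between
   the substitutions in d_S units, whose inverse is the acceleration
   over neutral drift, ≈ 4Nₑs.

The package is organised as statsmodels-style model objects —
`MKModel(...).fit() -> MKResults` and
`DoubleSubstitutionModel(...).fit() -> ClumpingResults` — over plain
containers (`CodonAlignment`, `PopulationSample`, `PhylogenySpec`).
A first-class synthetic-data module generates codon alignments,
population samples with selection-shaped site-frequency spectra, and
two-substitution codon pairs with known ground truth, so every stage is
testable without the original population-genomic datasets.

## Worked example

```python
import conselmk as cm

cfg = cm.SimConfig(seed=42, sites_per_bin=50_000,
                   bin_mixtures={21: (0.15, 0.61, 0.24),   # conservative: mostly constrained
                                 5:  (0.60, 0.33, 0.07)})  # rapid: mostly neutral
aln, samples, truth = cm.simulate_mk_dataset(cfg)
print(truth[["bin", "alpha_true"]].to_string(index=False))
res = cm.MKModel(aln, samples).fit(cutoff=0.15, bootstrap=500, seed=0)
print(res.summary())
```

prints

```
 bin  alpha_true
   5    0.223023
  21    0.789762
Conservation-binned McDonald-Kreitman test
  scheme=MK22  cutoff=0.15  polarity=derived  bootstrap=500
  genes=200  sites pooled=100000
  overall: alpha=0.457  omega_a=0.240
     nsites_N  nsites_S     dN     dS     pN     pS  alpha  alpha_lo  alpha_hi  omega_a
bin
5       50009     15010 0.1376 0.2516 0.0072 0.0153 0.1419   -0.0086    0.2713   0.0776
21      50016     15191 0.1315 0.2615 0.0018 0.0163 0.7760    0.7186    0.8300   0.3903
```

The fitted per-bin α (0.14 and 0.78) recovers the planted adaptive
fractions (0.22 and 0.79) within the bootstrap intervals. (In this
synthetic configuration both bins share the same overall substitution
rate, so ω_a tracks α; in real data conservative segments have much
lower d_N, which lowers their ω_a even when their α is highest.)

The clumping side, on the same config (bins simulated with selected
fractions 0.82 and 0.21):

```python
pairs = cm.simulate_double_subs(cfg)
ds = cm.DoubleSubstitutionModel.from_pairs(pairs, cfg.phylo).fit()
print(ds.summary())
```

```
Double-substitution clumping analysis
  records: 30000 resolved, 0 dropped (outgroup unresolved)
  non-synonymous pairs (bin -1 = pooled):
 bin  n_pairs  n_P1   f_P1  f_P1_lo  f_P1_hi  expected_P1  delta  delta_lo  delta_hi
   2    10000  3800 0.3800   0.3705   0.3896       0.4791 0.2068    0.1867    0.2267
  20    10000   855 0.0855   0.0801   0.0912       0.4791 0.8215    0.8097    0.8328
  -1    20000  4655 0.2328   0.2269   0.2387       0.4791 0.5141    0.5018    0.5263
  synonymous control pairs:
 bin  n_pairs  n_P1   f_P1  f_P1_lo  f_P1_hi  expected_P1   delta  delta_lo  delta_hi
   2     5000  2416 0.4832   0.4693   0.4972       0.4791 -0.0087   -0.0378    0.0204
  20     5000  2466 0.4932   0.4792   0.5072       0.4791 -0.0295   -0.0587   -0.0004
  -1    10000  4882 0.4882   0.4784   0.4980       0.4791 -0.0191   -0.0397    0.0015
  lag: f_straddle=0.1526 (95% CI 0.1455-0.1599), lag=0.1572 dS, 4Ne*s ~ 6.4
```

δ̂ per bin (0.82 and 0.21) matches the simulated selected fractions, and
the synonymous control shows no clumping (f(P₁) ≈ 0.48). With a pure
selected class (`pi_sel=1, accel=40`) the straddle-fraction estimator
recovers the selection strength: f_straddle ≈ 0.025, lag ≈ 0.025 d_S,
4Nₑs ≈ 39.5.

A thin CLI wraps the same pipeline:

```bash
consel-mk simulate --config run.yaml --seed 1 --out sim/
consel-mk mk --config run.yaml --seed 1 --out mk_out/
consel-mk doublesub --config run.yaml --out ds_out/
```

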