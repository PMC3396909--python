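# Methods

This note records the models implemented, the choices made where the
procedures left freedom, and what the synthetic data do and do not
establish.

## Conservation bins

A codon column is *invariant* for a species set when every species
carries a gapless ACGT codon translating to one identical, non-stop
amino acid. Two windowing schemes are implemented:

* **MK22** (bins 0–21): a 21-site window centred on the focal site
  (10 before, the site, 10 after), scored over the seven species outside
  the *melanogaster* subgroup. Because the scored species are disjoint
  from the clade used for divergence and polymorphism, binning cannot
  bias the MK counts.
* **DS21** (bins 0–20): the 20 flanking sites only, scored over all 12
  species. The focal column is excluded because the double-substitution
  analysis spans the whole phylogeny, so the focal site's own state is
  not independent of the quantity being measured.

Sites within 10 codons of a gene end are never assessable; windows are
never truncated. Columns interrupted by gaps simply count zero toward
the bin — only the end trim removes sites.

## MK test

Degeneracy is strict: a position is non-synonymous only if each of the
four bases yields a distinct amino acid, and synonymous only if all
four yield the same one; positions with a stop among the variants are
neither (a stop is not an amino acid). The classification must hold both
in the focal-population consensus codon and in the divergence-pair
codon; disagreeing positions contribute to neither class.

Site filters (all must hold): valid codons in all species; unmasked;
assessable; polymorphism data from ≥50% of genotypes; the two
divergence-pair species carry identical codons; the polarizing species
agree with each other and with at least one sampled genotype. Attrition
per filter is logged. The polarization rule is implemented as "the
sister-species codon occurs in the sample" because synthetic samples
have no privileged reference genotype.

Polymorphism at a position enters the count only if the qualifying
allele (derived by default, polarized against the first polarizing
species; minor optionally) is present in more than ⌊n_called·cutoff⌋
genotypes, clamped to >1 for any positive cutoff so that tiny samples
(6 genotypes) still require more than a single observation. Positions
with three or more segregating bases are excluded from polymorphism
(polarity is ambiguous); they stay in the denominators. Default cutoff
0.15.

α = 1 − (d_S·p_N)/(d_N·p_S) and ω_a = α·d_N/d_S; both are undefined
(raised, never silently zero) when d_N = 0 or p_S = 0. Because the four
fractions share two denominators, α reduces to a ratio of raw counts,
which is what the bootstrap resamples. The site bootstrap collapses
per-site integer feature rows to their distinct profiles and draws a
multinomial over profile multiplicities — distributionally identical to
resampling sites, and fast at 10⁵–10⁶ sites. CIs are percentile
intervals from B = 1000 resamples by default; a CI is flagged unstable
when the statistic is undefined in >10% of resamples.

A pooled-synonymous control recomputes each bin's α with genome-wide
site-weighted d_S and p_S substituted, to separate conservation trends
in α from bin-to-bin differences in synonymous constraint.

## Double substitutions

Candidates require identical amino acids within each species pair
(sim–sec, pse–per, vir–moj; one sequencing error cannot then fabricate a
candidate), clade codons differing at exactly two nucleotide positions,
and both steps of *both* two-step paths non-synonymous (or, for the
control set, all four square states synonymous); a stop anywhere on the
square disqualifies.

Lineage assignment is outgroup parsimony at the amino-acid level
(codon level for the synonymous control, where amino acids carry no
signal): the outgroup amino acid must match exactly one of the four
square states — the opposite clade state implies both substitutions on
the other lineage, an intermediate implies one per lineage (pattern P1).
No match, or an ambiguous match (including both intermediates sharing
the outgroup amino acid), drops the record. Segment placement compares
the ananassae and yakuba amino acids with the ancestral, intermediate
and final states; the six consistent witness pairs map bijectively onto
segment assignments, and anything else (including witnesses matching
two states because the square has repeated amino acids) is unplaced.

δ = (2l₁l₂ − f(P₁))/(2l₁l₂) with l₁ = 0.68/1.71, l₂ = 1.03/1.71 by
default. The lag estimator is f_straddle × L_path with acceleration
(≈ 4Nₑs) its inverse; when no straddling pair is observed, the
Clopper–Pearson upper bound on f_straddle yields a lower bound on 4Nₑs.
All binomial intervals are exact Clopper–Pearson from beta quantiles.

The three segments of the 1.03-d_S path (to the ananassae and yakuba
branch points and beyond) default to 0.55/0.33/0.15. The exact interior
split is not fixed by the analysis inputs we consume; these values give
the ananassae branch point at roughly the midpoint of the path with the
yakuba split close to the tips, sum exactly to 1.03, and are
configurable wherever a `PhylogenySpec` is accepted. δ and f(P₁) do not
depend on them; only segment placement and the lag do.

## Synthetic data

`simulate_mk_dataset` emulates the statistical structure the MK pipeline
consumes, not molecular evolution in full. Each codon site carries one
informative position: fourfold (carrier codon GGA, position 3) with
probability 0.3, else non-degenerate (carrier GAA, position 2) assigned
to a neutral / deleterious / adaptive class by the per-bin mixture.
Divergence events occur with probability depth × class rate
(depth 0.25 d_S; rates 1 / 0.02 / 2.5 by default) and are placed on the
focal stem or the divergence-pair stem with equal probability (never on
the focal stem at a polymorphic site, so polarization stays coherent).
Within-population derived counts are drawn from the genic-selection
sampled SFS, f(x) ∝ (1 − e^{−S(1−x)})/(x(1−x)(1−e^{−S})) integrated
against binomial sampling and normalized over counts 1..n−1 (1/x at
S = 0); per-site segregation probabilities are 0.05 for neutral and
synonymous sites (the fraction of fourfold sites segregating in ~160
*Drosophila* lines), 0.05 for deleterious sites (S = −50) and 0.0005 for
adaptive sites (S = +50; beneficial alleles segregate only briefly).
Missing genotypes (rate 0.02) thin population counts hypergeometrically.
Conservation bins are planted exactly via a period-21 pattern of
amino-acid-variable columns in one scored species, so every window of an
interior site contains exactly 21 − bin variable columns.

The generator's truth records the *realized* adaptive fraction of
non-synonymous substitutions per bin. Recovery holds to ±0.05 at the
scales the tests run (6×10⁵ sites per bin, chosen so the binomial noise
in the polymorphism counts sits well inside the tolerance). Two known
small distortions are inherent to the MK procedure itself and
reproduced, not hidden: high-frequency derived polymorphisms flip the
consensus and register as divergence, and adaptive polymorphism
contributes slightly to p_N.

`simulate_double_subs` places the first substitution
length-proportionally on the two-lineage tree; with probability π_sel
the second follows on the same lineage after an Exponential(mean 1/A)
lag in d_S units (A = 4Nₑs; overshoots redrawn, which slightly biases
placements away from lineage ends at small A), otherwise independently.
Witness codons (outgroup, ananassae, yakuba) are emitted consistently
with the latent placement, drawn from precomputed codon squares with
four distinct amino acids so outgroup parsimony is always decisive.
Synonymous control pairs are always placed independently. δ̂ estimates
π_sel consistently. The straddle-fraction lag estimator recovers A when
the selected class dominates (π_sel = 1, A = 40 → ≈ 39.5); at
intermediate π_sel neutral same-lineage pairs contaminate the straddle
fraction upward, so the reported 4Nₑs is then a lower bound on the
selected pairs' strength — a property of the estimator, not of the
implementation.

What passing tests show: the estimators are consistent and the filters,
windows and parsimony rules implement their definitions exactly. What
they do not show: robustness to alignment error, linkage and
hitchhiking, demography, within-gene rate heterogeneity, or
codon-usage selection — none of which the generators model (the
pooled-synonymous control exists precisely because the last is real).

## Numerical and interface choices

* Internal coordinates 0-based half-open; reports 1-based inclusive.
* Consensus ties break lexicographically; a codon site is masked if any
  of its three bases overlaps a BED interval.
* Genotypes with gap/N codons are excluded from that site's counts, not
  imputed; the 50% coverage filter uses called genotypes.
* All randomness flows through `numpy.random.default_rng(seed)`; seeds
  are mandatory in `SimConfig` and identical seeds give identical
  outputs byte for byte.
* The SFS sampler's density is validated by chi-square goodness of fit
  at 10⁵ draws; the sampled-SFS discretization uses a 4001-point
  trapezoid grid on (10⁻⁶, 1−10⁻⁶).
* Bootstrap B = 1000 default (tests use less where only determinism is
  at stake); percentile CIs; the multinomial-over-profiles resampler is
  exact, not an approximation.
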