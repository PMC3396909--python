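"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the statistical structure of the real inputs:

* ``simulate_mk_dataset`` — 12-species codon alignments plus focal
  population samples. Fourfold positions evolve neutrally; non-degenerate
  positions are a mixture of neutral, deleterious and adaptive site
  classes. Divergence events occur with probability depth x relative
  rate; within-sample derived-allele counts are drawn from the genic
  selection site-frequency spectrum
  f(x) proportional to (1 - exp(-S(1-x))) / (x(1-x)(1-exp(-S))), with
  the neutral 1/x limit at S = 0. The latent truth records the realized
  adaptive fraction of non-synonymous substitutions (alpha_true) per
  conservatism bin.
* ``simulate_double_subs`` — two-substitution codon pairs placed on the
  fixed two-lineage phylogeny. The first substitution lands
  length-proportionally; with probability pi_sel the second follows on
  the same lineage after an Exponential(mean 1/A) lag in d_S units
  (A = 4*Ne*s), redrawn on overshoot, otherwise it lands independently.
  Witness codons for the outgroup and the ananassae/yakuba branch points
  are emitted consistently with the latent placement.
* ``simulate_conserved_alignment`` — alignments with planted
  sliding-window conservatism bins (exact by a period-21 variable-column
  pattern).

All generators are deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom as _binom

from ._codes import codon_aa, encode_codon
from .io import CodonAlignment, PhylogenySpec, PopulationSample

#: species order used in generated alignments
SPECIES_12 = (
    "melanogaster",
    "simulans",
    "sechellia",
    "yakuba",
    "erecta",
    "ananassae",
    "pseudoobscura",
    "persimilis",
    "willistoni",
    "virilis",
    "mojavensis",
    "grimshawi",
)

# carrier codons: GAA contributes one non-degenerate position (2nd),
# GGA additionally a fourfold one (3rd); GTA differs from both in amino acid
_NONSYN_BASE = "GAA"  # Glu; position 2 non-degenerate
_SYN_BASE = "GGA"  # Gly; position 3 fourfold
_VARIABLE_CODON = "GTA"  # Val; marks planted non-invariant columns
_SYN_TARGETS = ("GGC", "GGG", "GGT")
_NONSYN_TARGETS = ("GCA", "GGA", "GTA")  # pos-2 variants of GAA, all non-stop

_EDGE = 10


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DoubleSubClass:
    """One simulated class of two-substitution codons."""

    bin: int = 20
    n_pairs: int = 10000
    pi_sel: float = 0.82
    accel: float = 40.0


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    MK side: per-bin mixtures (w_neutral, w_deleterious, w_adaptive) of
    non-degenerate sites, scaled selection coefficients S = 4*Ne*s for
    the deleterious and adaptive classes, per-class substitution rates
    relative to neutral, divergence depth in d_S, and the per-site
    probability of segregating in the population. Double-substitution
    side: per-class pair counts with the selected-pair fraction pi_sel
    and acceleration A = 4*Ne*s.
    """

    seed: int
    # MK dataset
    n_genotypes: int = 162
    sites_per_bin: int = 200_000
    gene_length: int = 520  # codon sites incl. the 10-site end trims
    bin_mixtures: Mapping[int, tuple[float, float, float]] = field(
        default_factory=lambda: {21: (0.10, 0.80, 0.10), 5: (0.50, 0.30, 0.20)}
    )
    f_fourfold: float = 0.30
    depth: float = 0.25  # d_S divergence to the yakuba-erecta ancestor
    rate_deleterious: float = 0.02
    rate_adaptive: float = 2.5
    S_del: float = -50.0
    S_adv: float = 50.0
    theta: float = 0.05  # P(site segregates) for neutral/synonymous sites
    theta_deleterious: float = 0.05
    theta_adaptive: float = 0.0005
    missing_rate: float = 0.02
    # double substitutions
    double_subs: tuple[DoubleSubClass, ...] = (
        DoubleSubClass(bin=20, n_pairs=10000, pi_sel=0.82, accel=40.0),
        DoubleSubClass(bin=2, n_pairs=10000, pi_sel=0.21, accel=5.0),
    )
    n_syn_pairs: int = 10000
    phylo: PhylogenySpec = field(default_factory=PhylogenySpec)

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for b, w in self.bin_mixtures.items():
            if len(w) != 3 or any(x < 0 for x in w) or abs(sum(w) - 1) > 1e-9:
                raise ConfigError(f"bin {b}: mixture {w} must be >=0 and sum to 1")
            if w[2] > 0 and (self.depth <= 0 or self.rate_adaptive <= 0):
                raise ConfigError(
                    f"bin {b}: w_adaptive > 0 needs positive depth and adaptive rate"
                )
        for ds in self.double_subs:
            if ds.pi_sel > 0 and ds.accel <= 0:
                raise ConfigError("pi_sel > 0 requires acceleration A > 0")
            if not 0 <= ds.pi_sel <= 1:
                raise ConfigError("pi_sel must be in [0, 1]")


# ---------------------------------------------------------------------------
# site-frequency spectra


@lru_cache(maxsize=64)
def sfs_pmf(n: int, S: float = 0.0) -> np.ndarray:
    """Sampled-SFS pmf over derived counts 1..n-1 under genic selection.

    Integrates binomial sampling against the diffusion density
    f(x) ~ (1-exp(-S(1-x)))/(x(1-x)(1-exp(-S))) (1/x at S = 0) on a
    fine grid and normalizes over polymorphic-in-sample counts.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    x = np.linspace(1e-6, 1 - 1e-6, 4001)
    if abs(S) < 1e-12:
        dens = 1.0 / x
    else:
        dens = np.expm1(-S * (1.0 - x)) / np.expm1(-S) / (x * (1.0 - x))
    k = np.arange(1, n)
    pk = np.trapezoid(_binom.pmf(k[:, None], n, x[None, :]) * dens[None, :], x, axis=1)
    return pk / pk.sum()


def sample_derived_counts(
    rng: np.random.Generator, n: int, S: float, size: int
) -> np.ndarray:
    """Draw derived-allele counts (1..n-1) from the sampled SFS."""
    if size == 0:
        return np.zeros(0, dtype=np.int64)
    return rng.choice(np.arange(1, n), p=sfs_pmf(n, round(float(S), 9)), size=size)


# ---------------------------------------------------------------------------
# planted-conservation alignments


def _variable_pattern(n_sites: int, bin_: int, max_bin: int = 21) -> np.ndarray:
    """Period-21 boolean pattern with exactly max_bin - bin_ variable
    columns inside every window of 21 consecutive sites."""
    n_var = max_bin - bin_
    if not 0 <= n_var <= 21:
        raise ConfigError(f"bin {bin_} outside 0..{max_bin}")
    return (np.arange(n_sites) % 21) < n_var


def _planted_gene_codons(n_sites: int, bin_: int, base: np.ndarray) -> np.ndarray:
    """12 x n_sites codon matrix whose interior MK22 bins all equal bin_.

    ``base`` gives the per-site carrier codon; planted variable columns
    carry a different amino acid in willistoni only, so bins scored on
    the seven outer species are exact while the melanogaster-subgroup
    rows stay untouched.
    """
    codons = np.tile(base, (len(SPECIES_12), 1)).astype("U3")
    var = _variable_pattern(n_sites, bin_)
    wil = SPECIES_12.index("willistoni")
    codons[wil, var] = _VARIABLE_CODON
    return codons


def simulate_conserved_alignment(
    config: SimConfig, bins: Sequence[int] | None = None, n_sites: int | None = None
) -> list[CodonAlignment]:
    """Event-free alignments with planted MK22 conservatism bins."""
    bins = list(bins) if bins is not None else sorted(config.bin_mixtures)
    n_sites = n_sites or config.gene_length
    out = []
    for b in bins:
        base = np.full(n_sites, _NONSYN_BASE, dtype="U3")
        codons = _planted_gene_codons(n_sites, b, base)
        out.append(CodonAlignment(f"planted_bin{b}", list(SPECIES_12), codons))
    return out


# ---------------------------------------------------------------------------
# MK dataset

_CLS_EDGE, _CLS_SYN, _CLS_NEU, _CLS_DEL, _CLS_ADV = range(5)


def simulate_mk_dataset(
    config: SimConfig,
) -> tuple[list[CodonAlignment], dict[str, PopulationSample], pd.DataFrame]:
    """Generate alignments, samples and the per-bin truth record.

    Returns (alignments, {gene_id: sample}, truth) where truth has one
    row per conservatism bin with realized substitution counts and
    alpha_true = adaptive / all non-synonymous substitutions.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genotypes
    L = config.gene_length
    interior = L - 2 * _EDGE
    if interior <= 0:
        raise ConfigError("gene_length must exceed 20 codon sites")

    p_div = {
        _CLS_SYN: config.depth,
        _CLS_NEU: config.depth,
        _CLS_DEL: config.depth * config.rate_deleterious,
        _CLS_ADV: config.depth * config.rate_adaptive,
    }
    if max(p_div.values()) >= 1:
        raise ConfigError("depth x rate must stay below 1")
    p_poly = {
        _CLS_SYN: config.theta,
        _CLS_NEU: config.theta,
        _CLS_DEL: config.theta_deleterious,
        _CLS_ADV: config.theta_adaptive,
    }
    S_of = {_CLS_SYN: 0.0, _CLS_NEU: 0.0, _CLS_DEL: config.S_del, _CLS_ADV: config.S_adv}

    i_mel, i_sim, i_sec = (SPECIES_12.index(s) for s in ("melanogaster", "simulans", "sechellia"))
    i_yak, i_ere = SPECIES_12.index("yakuba"), SPECIES_12.index("erecta")

    alignments: list[CodonAlignment] = []
    samples: dict[str, PopulationSample] = {}
    truth_rows = []

    for b in sorted(config.bin_mixtures):
        w_neu, w_del, w_adv = config.bin_mixtures[b]
        n_genes = math.ceil(config.sites_per_bin / interior)
        subs = {"adaptive": 0, "neutral": 0, "deleterious": 0, "synonymous": 0}
        for g in range(n_genes):
            gene_id = f"bin{b}_g{g:04d}"
            cls = np.full(L, _CLS_EDGE, dtype=np.int8)
            inner = slice(_EDGE, L - _EDGE)
            u = rng.random(interior)
            is_syn = u < config.f_fourfold
            v = rng.random(interior)
            nonsyn_cls = np.where(
                v < w_neu, _CLS_NEU, np.where(v < w_neu + w_del, _CLS_DEL, _CLS_ADV)
            )
            cls[inner] = np.where(is_syn, _CLS_SYN, nonsyn_cls)

            base = np.where(cls == _CLS_SYN, _SYN_BASE, _NONSYN_BASE).astype("U3")
            codons = _planted_gene_codons(L, b, base)

            div_p = np.zeros(L)
            poly_p = np.zeros(L)
            for c, p in p_div.items():
                div_p[cls == c] = p
            for c, p in p_poly.items():
                poly_p[cls == c] = p
            div_event = rng.random(L) < div_p
            poly_event = rng.random(L) < poly_p
            focal_side = (rng.random(L) < 0.5) & ~poly_event  # never both

            called = n - rng.binomial(n, config.missing_rate, size=L)
            called = np.maximum(called, 1)

            # population derived counts for polymorphic sites, then
            # hypergeometric thinning down to the called genotypes
            k_obs = np.zeros(L, dtype=np.int64)
            for c in (_CLS_SYN, _CLS_NEU, _CLS_DEL, _CLS_ADV):
                sites_c = np.flatnonzero(poly_event & (cls == c))
                if len(sites_c) == 0:
                    continue
                k_pop = sample_derived_counts(rng, n, S_of[c], len(sites_c))
                k_obs[sites_c] = rng.hypergeometric(k_pop, n - k_pop, called[sites_c])

            counts: list[dict[str, int]] = []
            for j in range(L):
                m = int(called[j])
                focal = str(base[j])
                c = int(cls[j])
                if div_event[j]:
                    targets = _SYN_TARGETS if c == _CLS_SYN else _NONSYN_TARGETS
                    div_codon = targets[rng.integers(len(targets))]
                    if focal_side[j]:
                        codons[i_mel, j] = codons[i_sim, j] = codons[i_sec, j] = div_codon
                        focal = div_codon
                    else:
                        codons[i_yak, j] = codons[i_ere, j] = div_codon
                    if c == _CLS_SYN:
                        subs["synonymous"] += 1
                    elif c == _CLS_NEU:
                        subs["neutral"] += 1
                    elif c == _CLS_DEL:
                        subs["deleterious"] += 1
                    elif c == _CLS_ADV:
                        subs["adaptive"] += 1
                k = int(k_obs[j])
                if poly_event[j] and 0 < k < m:
                    targets = _SYN_TARGETS if c == _CLS_SYN else _NONSYN_TARGETS
                    choices = [t for t in targets if t != focal]
                    derived = choices[rng.integers(len(choices))]
                    counts.append({focal: m - k, derived: k})
                else:
                    counts.append({focal: m})
            aln = CodonAlignment(gene_id, list(SPECIES_12), codons)
            alignments.append(aln)
            samples[gene_id] = PopulationSample(gene_id, n, counts, called)
        n_nonsyn = subs["adaptive"] + subs["neutral"] + subs["deleterious"]
        truth_rows.append(
            {
                "bin": b,
                "n_genes": n_genes,
                "subs_adaptive": subs["adaptive"],
                "subs_neutral": subs["neutral"],
                "subs_deleterious": subs["deleterious"],
                "subs_synonymous": subs["synonymous"],
                "alpha_true": subs["adaptive"] / n_nonsyn if n_nonsyn else float("nan"),
            }
        )
    return alignments, samples, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# double substitutions


@lru_cache(maxsize=2)
def _codon_squares(kind: str = "nonsyn") -> tuple[tuple[str, str, str, str], ...]:
    """Codon squares (anc, alt_a, alt_b, both) over two positions.

    'nonsyn': all four corners non-stop with four distinct amino acids,
    so every mutational step is non-synonymous and outgroup parsimony is
    always decisive. 'syn': four distinct codons sharing one amino acid.
    """
    squares = []
    bases = "ACGT"
    for anc_i in range(64):
        anc = "".join(bases[(anc_i // 16) % 4] + bases[(anc_i // 4) % 4] + bases[anc_i % 4])
        if codon_aa(anc_i) == "*":
            continue
        for p in range(3):
            for q in range(p + 1, 3):
                for bp in bases:
                    if bp == anc[p]:
                        continue
                    for bq in bases:
                        if bq == anc[q]:
                            continue
                        alt_a = anc[:p] + bp + anc[p + 1 :]
                        alt_b = anc[:q] + bq + anc[q + 1 :]
                        both = alt_a[:q] + bq + alt_a[q + 1 :]
                        aas = [codon_aa(encode_codon(c)) for c in (anc, alt_a, alt_b, both)]
                        if "*" in aas:
                            continue
                        if kind == "nonsyn" and len(set(aas)) == 4:
                            squares.append((anc, alt_a, alt_b, both))
                        elif kind == "syn" and len(set(aas)) == 1:
                            squares.append((anc, alt_a, alt_b, both))
    return tuple(squares)


def _segment_of(t: float, phylo: PhylogenySpec) -> str:
    s1, s2, _ = phylo.segments
    if t <= s1:
        return "I-II"
    if t <= s1 + s2:
        return "II-III"
    return "III-IV"


def _state_at(x: float, t1: float, t2: float, anc: str, mid: str, fin: str) -> str:
    """Codon carried by the path at distance x given substitutions at t1<t2."""
    if x < t1:
        return anc
    if x < t2:
        return mid
    return fin


def simulate_double_subs(config: SimConfig) -> pd.DataFrame:
    """Simulate two-substitution codon pairs with latent truth.

    One row per pair: per-species codons (the analysis input) plus
    ``true_*`` latent columns never read by the pipeline. Synonymous
    control pairs (``n_syn_pairs``) are always placed independently.
    """
    rng = np.random.default_rng(config.seed + 1)
    phylo = config.phylo
    L1, L2 = phylo.L_other, phylo.L_path  # pse-per lineage, sim-sec path
    rows = []

    def one_pair(square, pi_sel: float, accel: float, bin_: int, kind: str):
        anc, alt_a, alt_b, both = square
        if rng.random() < 0.5:  # which of the two mutations happens first
            first_state, second_state = alt_a, alt_b
        else:
            first_state, second_state = alt_b, alt_a
        u = rng.uniform(0, L1 + L2)
        lin1 = "pseper" if u < L1 else "simsec"
        t1 = u if lin1 == "pseper" else u - L1
        len1 = L1 if lin1 == "pseper" else L2
        selected = rng.random() < pi_sel
        if selected:
            lin2 = lin1
            d = rng.exponential(1.0 / accel)
            while t1 + d > len1:  # overshoot: redraw
                d = rng.exponential(1.0 / accel)
            t2 = t1 + d
        else:
            v = rng.uniform(0, L1 + L2)
            lin2 = "pseper" if v < L1 else "simsec"
            t2 = v if lin2 == "pseper" else v - L1
        if lin1 != lin2:
            pattern = "P1"
            t_ss = t1 if lin1 == "simsec" else t2
            c_ss_final = first_state if lin1 == "simsec" else second_state
            c_pp_final = second_state if lin1 == "simsec" else first_state
            s1, s2, _ = phylo.segments
            ana_c = c_ss_final if t_ss <= s1 else anc
            yak_c = c_ss_final if t_ss <= s1 + s2 else anc
            seg1 = seg2 = ""
        else:
            ta, tb = (t1, t2) if t1 <= t2 else (t2, t1)
            if t2 < t1:
                first_state, second_state = second_state, first_state
            t1, t2 = ta, tb
            if lin1 == "simsec":
                pattern = "same_simsec"
                c_ss_final, c_pp_final = both, anc
                s1, s2, _ = phylo.segments
                ana_c = _state_at(s1, t1, t2, anc, first_state, both)
                yak_c = _state_at(s1 + s2, t1, t2, anc, first_state, both)
                seg1, seg2 = _segment_of(t1, phylo), _segment_of(t2, phylo)
            else:
                pattern = "same_pseper"
                c_ss_final, c_pp_final = anc, both
                ana_c = yak_c = anc
                seg1 = seg2 = ""
        rows.append(
            {
                "gene_id": f"{kind}_{bin_}",
                "site": len(rows),
                "bin": bin_,
                "simulans": c_ss_final,
                "sechellia": c_ss_final,
                "pseudoobscura": c_pp_final,
                "persimilis": c_pp_final,
                "virilis": anc,
                "mojavensis": anc,
                "ananassae": ana_c,
                "yakuba": yak_c,
                "true_kind": kind,
                "true_selected": selected,
                "true_pattern": pattern,
                "true_lineage_first": lin1,
                "true_t1": t1,
                "true_t2": t2,
                "true_first_segment": seg1,
                "true_second_segment": seg2,
            }
        )

    nonsyn_squares = _codon_squares("nonsyn")
    syn_squares = _codon_squares("syn")
    for ds in config.double_subs:
        for _ in range(ds.n_pairs):
            sq = nonsyn_squares[rng.integers(len(nonsyn_squares))]
            one_pair(sq, ds.pi_sel, ds.accel, ds.bin, "nonsyn")
    bins_cycle = [ds.bin for ds in config.double_subs] or [-1]
    for i in range(config.n_syn_pairs):
        sq = syn_squares[rng.integers(len(syn_squares))]
        one_pair(sq, 0.0, 1.0, bins_cycle[i % len(bins_cycle)], "syn")
    return pd.DataFrame(rows)


def embed_pairs_in_alignments(
    pairs: pd.DataFrame, context_sites: int = 10
) -> list[CodonAlignment]:
    """Embed simulated pairs into 12-species alignments, one per gene.

    Each pair codon sits at the center of an otherwise invariant gene so
    the DS21 window assigns the flanking-invariance bin 20; this lets the
    alignment-scanning entry point be exercised end to end.
    """
    alignments = []
    L = 2 * context_sites + 1
    for row in pairs.itertuples(index=False):
        d = row._asdict()
        codons = np.full((len(SPECIES_12), L), _NONSYN_BASE, dtype="U3")
        center = context_sites
        per_species = {
            "melanogaster": d["simulans"],
            "erecta": d["yakuba"],
            "willistoni": d["virilis"],
            "grimshawi": d["virilis"],
            **{
                s: d[s]
                for s in (
                    "simulans", "sechellia", "pseudoobscura", "persimilis",
                    "virilis", "mojavensis", "ananassae", "yakuba",
                )
            },
        }
        for s, codon in per_species.items():
            codons[SPECIES_12.index(s), center] = codon
        alignments.append(
            CodonAlignment(f"pair{d['site']:06d}", list(SPECIES_12), codons)
        )
    return alignments
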