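"""Conservation-binned McDonald–Kreitman test.

The MK test contrasts divergence and polymorphism at non-synonymous and
synonymous positions. Here "non-synonymous" means strictly
non-degenerate nucleotide positions (every base change alters the amino
acid) and "synonymous" means fourfold-degenerate positions (no base
change does), with the classification required to hold both in the
focal-population consensus codon and in the divergence-pair codon.
Positions are pooled across genes within each conservatism bin, and per
bin the fraction of adaptive amino acid substitutions is

    alpha = 1 - (d_S * p_N) / (d_N * p_S)

with the adaptive substitution rate relative to the synonymous rate

    omega_a = alpha * d_N / d_S.

Low-frequency variants, which are enriched for segregating deleterious
alleles that bias alpha downward, are excluded by a frequency cutoff: an
allele counts as polymorphism only if present in more than
floor(n_called * cutoff) genotypes (at least 2 of 6 genotypes for very
small samples). Confidence intervals come from bootstrapping individual
codon sites within each bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._codes import BASE_AT, DEGENERACY, encode_codon
from .conservation import ConservationProfile, window_conservation
from .io import CodonAlignment, PopulationSample, consensus_codon


class ConfigurationError(ValueError):
    """A species role is missing or not present in the data."""


class UndefinedEstimateError(ValueError):
    """alpha/omega_a undefined (d_N = 0 or p_S = 0 in this bin)."""


#: default species roles for the melanogaster-variation analysis
MELANOGASTER_SUBGROUP = ("melanogaster", "simulans", "sechellia", "yakuba", "erecta")
OUTER_SEVEN = (
    "ananassae",
    "pseudoobscura",
    "persimilis",
    "willistoni",
    "virilis",
    "mojavensis",
    "grimshawi",
)


@dataclass(frozen=True)
class SpeciesRoles:
    """Which species play which part in the MK analysis.

    ``focal`` owns the population sample; divergence is measured against
    the matched ``divergence_pair`` codon; ``polarizing`` species reveal
    the ancestral allele and must agree with at least one sampled
    genotype; ``conservation_set`` is scored for window conservatism
    (species outside the clade under test, so bins do not bias the MK
    counts).
    """

    focal: str = "melanogaster"
    divergence_pair: tuple[str, str] = ("yakuba", "erecta")
    polarizing: tuple[str, ...] = ("simulans", "sechellia")
    conservation_set: tuple[str, ...] = OUTER_SEVEN

    @staticmethod
    def for_simulans() -> "SpeciesRoles":
        return SpeciesRoles(focal="simulans", polarizing=("melanogaster",))


# degeneracy class codes used throughout: 0 other, 1 non-degenerate, 2 fourfold
_CLASS_NAMES = {0: "other", 1: "nondegenerate", 2: "fourfold"}


def classify_degeneracy(focal_codon: str, divergence_codon: str) -> tuple[str, str, str]:
    """Per-position degeneracy class, required to agree in both codons.

    Returns one of 'nondegenerate' / 'fourfold' / 'other' per position.
    A stop codon on either side makes every position 'other'.
    """
    fi = encode_codon(focal_codon)
    di = encode_codon(divergence_codon)
    if fi < 0 or di < 0:
        raise ValueError("both codons must be valid ACGT triplets")
    out = []
    for pos in range(3):
        c1, c2 = DEGENERACY[fi, pos], DEGENERACY[di, pos]
        out.append(_CLASS_NAMES[int(c1)] if c1 == c2 else "other")
    return tuple(out)  # type: ignore[return-value]


def min_count_threshold(n_called: int, cutoff: float) -> int:
    """Allele-count threshold k; an allele qualifies iff count > k.

    k = floor(n_called * cutoff), clamped to >= 1 for any positive
    cutoff so that tiny samples (6 genotypes) still require more than a
    single observation. cutoff = 0 disables the threshold (k = 0).
    """
    if cutoff <= 0:
        return 0
    return max(int(math.floor(n_called * cutoff)), 1)


def site_filters(
    alignment: CodonAlignment,
    sample: PopulationSample,
    roles: SpeciesRoles,
    profile: ConservationProfile | None = None,
    min_called_frac: float = 0.5,
) -> tuple[np.ndarray, dict[str, int]]:
    """Quality filters applied per codon site before MK counting.

    A site passes iff: all species carry valid codons; it is unmasked;
    its conservatism is assessable (gene-end trim); polymorphism data
    cover at least ``min_called_frac`` of the genotypes; the divergence
    pair codons match; and the polarizing species agree with each other
    and with at least one sampled genotype. Returns the boolean mask and
    a cumulative attrition log.
    """
    for role in (roles.focal, *roles.divergence_pair, *roles.polarizing):
        if role != roles.focal and role not in alignment.species_order:
            raise ConfigurationError(
                f"species role {role!r} not present in alignment {alignment.gene_id}"
            )
    if sample.n_sites != alignment.n_sites:
        raise ConfigurationError(
            f"{alignment.gene_id}: sample has {sample.n_sites} sites, "
            f"alignment has {alignment.n_sites}"
        )
    idx = alignment.codon_indices
    yak = idx[alignment.species_row(roles.divergence_pair[0])]
    ere = idx[alignment.species_row(roles.divergence_pair[1])]
    pol_rows = [alignment.species_row(s) for s in roles.polarizing]

    attrition: dict[str, int] = {"total": alignment.n_sites}
    mask = alignment.site_valid.copy()
    attrition["valid_codons"] = int(mask.sum())
    mask &= ~alignment.site_masked
    attrition["unmasked"] = int(mask.sum())
    if profile is not None:
        mask &= profile.assessable
    attrition["assessable"] = int(mask.sum())
    need = math.ceil(min_called_frac * sample.n_genotypes - 1e-9)
    mask &= sample.called >= need
    attrition["coverage"] = int(mask.sum())
    mask &= (yak == ere) & (yak >= 0)
    attrition["divergence_pair_match"] = int(mask.sum())

    pol = idx[pol_rows]
    pol_ok = (pol >= 0).all(axis=0) & (pol == pol[0]).all(axis=0)
    for j in np.flatnonzero(mask & pol_ok):
        codon = alignment.codons[pol_rows[0], j]
        if sample.counts[j].get(str(codon), 0) < 1:
            pol_ok[j] = False
    mask &= pol_ok
    attrition["polarization_match"] = int(mask.sum())
    return mask, attrition


def site_features(
    alignment: CodonAlignment,
    sample: PopulationSample,
    sites: Sequence[int] | np.ndarray,
    roles: SpeciesRoles,
    cutoff: float = 0.15,
    polarity: str = "derived",
) -> np.ndarray:
    """Per-site MK contributions as integer feature rows.

    Columns: [n_nondeg, n_fourfold, div_N, div_S, poly_N, poly_S] — the
    per-site denominators (positions of each class) and qualifying
    divergence/polymorphism counts. Positions with three or more
    segregating bases, or with an unpolarizable derived allele, are
    excluded from the polymorphism tallies.
    """
    if polarity not in ("derived", "minor"):
        raise ValueError("polarity must be 'derived' or 'minor'")
    idx = alignment.codon_indices
    yak = idx[alignment.species_row(roles.divergence_pair[0])]
    anc_row = alignment.species_row(roles.polarizing[0])
    feats = np.zeros((len(sites), 6), dtype=np.int64)
    for row, j in enumerate(sites):
        j = int(j)
        cons = encode_codon(consensus_codon(sample, j))
        div = int(yak[j])
        counts = sample.counts[j]
        called = int(sample.called[j])
        k = min_count_threshold(called, cutoff)
        anc = int(idx[anc_row, j])
        for pos in range(3):
            c1, c2 = DEGENERACY[cons, pos], DEGENERACY[div, pos]
            if c1 != c2 or c1 == 0:
                continue
            col = 0 if c1 == 1 else 1
            feats[row, col] += 1
            if BASE_AT[cons, pos] != BASE_AT[div, pos]:
                feats[row, 2 + col] += 1
            if len(counts) < 2:
                continue
            base_counts: dict[str, int] = {}
            for codon, c in counts.items():
                b = codon[pos]
                base_counts[b] = base_counts.get(b, 0) + c
            if len(base_counts) == 1:
                continue
            if len(base_counts) > 2:
                continue  # >=3 segregating states: polarity ambiguous
            (b1, c1n), (b2, c2n) = sorted(base_counts.items())
            if polarity == "minor":
                qual = min(c1n, c2n)
            else:
                anc_base = "ACGT"[BASE_AT[anc, pos]]
                if anc_base == b1:
                    qual = c2n
                elif anc_base == b2:
                    qual = c1n
                else:
                    continue  # ancestral state not among segregating bases
            if qual > k:
                feats[row, 4 + col] += 1
    return feats


@dataclass
class MKCounts:
    """Pooled MK counts for one conservatism bin."""

    bin: int
    n_nondeg_sites: int
    n_fourfold_sites: int
    div_n: int
    div_s: int
    poly_n: int
    poly_s: int

    @classmethod
    def from_features(cls, bin_: int, feats: np.ndarray) -> "MKCounts":
        s = feats.sum(axis=0) if len(feats) else np.zeros(6, dtype=np.int64)
        return cls(bin_, *(int(v) for v in s))

    def _frac(self, num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    @property
    def dN(self) -> float:
        return self._frac(self.div_n, self.n_nondeg_sites)

    @property
    def dS(self) -> float:
        return self._frac(self.div_s, self.n_fourfold_sites)

    @property
    def pN(self) -> float:
        return self._frac(self.poly_n, self.n_nondeg_sites)

    @property
    def pS(self) -> float:
        return self._frac(self.poly_s, self.n_fourfold_sites)

    @property
    def undefined(self) -> bool:
        return self.n_nondeg_sites == 0 or self.n_fourfold_sites == 0


def count_mk(
    bin_sites: Sequence[int],
    alignment: CodonAlignment,
    sample: PopulationSample,
    roles: SpeciesRoles,
    cutoff: float = 0.15,
    polarity: str = "derived",
    bin_: int = 0,
) -> MKCounts:
    """Pool MK counts over the given (pre-filtered) sites of one gene."""
    feats = site_features(alignment, sample, bin_sites, roles, cutoff, polarity)
    return MKCounts.from_features(bin_, feats)


def alpha(counts: MKCounts) -> float:
    """Fraction of adaptive amino acid substitutions, 1 - dS*pN/(dN*pS)."""
    if counts.undefined or not (counts.dN > 0 and counts.pS > 0):
        raise UndefinedEstimateError(
            f"bin {counts.bin}: alpha undefined (dN={counts.dN}, pS={counts.pS})"
        )
    return 1.0 - (counts.dS * counts.pN) / (counts.dN * counts.pS)


def omega_a(counts: MKCounts) -> float:
    """Adaptive non-synonymous rate relative to synonymous, alpha*dN/dS."""
    a = alpha(counts)
    if not counts.dS > 0:
        raise UndefinedEstimateError(f"bin {counts.bin}: omega_a undefined (dS=0)")
    return a * counts.dN / counts.dS


def _stat_from_sums(sums: np.ndarray, which: str) -> np.ndarray:
    """alpha / omega_a from summed feature rows; NaN where undefined.

    Because alpha = 1 - DS*PN/(DN*PS) after the shared denominators
    cancel, it can be computed from raw counts directly.
    """
    sums = np.atleast_2d(sums).astype(float)
    nn, ns, dn, ds, pn, ps = sums.T
    with np.errstate(divide="ignore", invalid="ignore"):
        a = 1.0 - (ds * pn) / (dn * ps)
        a = np.where((dn > 0) & (ps > 0), a, np.nan)
        if which == "alpha":
            return a
        if which == "omega_a":
            w = a * (dn / nn) / (ds / ns)
            return np.where((ds > 0) & (nn > 0), w, np.nan)
    raise ValueError(f"unknown statistic {which!r}")


def bootstrap_ci(
    features: np.ndarray,
    statistic: str | Callable[[np.ndarray], np.ndarray] = "alpha",
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    conf: float = 0.95,
) -> tuple[float, float, bool]:
    """Percentile CI from resampling individual sites with replacement.

    Sites are collapsed to their distinct integer feature rows and a
    multinomial is drawn over row multiplicities, which is exactly the
    site-bootstrap distribution. Returns (lo, hi, unstable) where
    ``unstable`` flags the statistic being undefined in more than 10% of
    resamples.
    """
    if B < 1:
        raise ValueError("B must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    features = np.asarray(features)
    n = len(features)
    if n == 0:
        return float("nan"), float("nan"), True
    uniq, mult = np.unique(features, axis=0, return_counts=True)
    draws = rng.multinomial(n, mult / n, size=B)
    sums = draws @ uniq
    stats = (
        _stat_from_sums(sums, statistic)
        if isinstance(statistic, str)
        else np.asarray([statistic(s) for s in sums], dtype=float)
    )
    bad = ~np.isfinite(stats)
    unstable = bad.mean() > 0.10
    good = stats[~bad]
    if len(good) == 0:
        return float("nan"), float("nan"), True
    lo, hi = np.percentile(good, [100 * (1 - conf) / 2, 100 * (1 + conf) / 2])
    return float(lo), float(hi), bool(unstable)


def pooled_synonymous_control(counts_by_bin: Mapping[int, MKCounts]) -> pd.DataFrame:
    """Re-estimate alpha per bin with genome-pooled synonymous dS, pS.

    Controls for bin-to-bin differences in selection on synonymous
    sites: the synonymous divergence and polymorphism fractions are
    replaced by their site-weighted genome-wide means.
    """
    if not counts_by_bin:
        raise ValueError("no bins")
    ns = sum(c.n_fourfold_sites for c in counts_by_bin.values())
    if ns == 0:
        raise UndefinedEstimateError("no fourfold sites in any bin")
    ds_pool = sum(c.div_s for c in counts_by_bin.values()) / ns
    ps_pool = sum(c.poly_s for c in counts_by_bin.values()) / ns
    rows = []
    for b in sorted(counts_by_bin):
        c = counts_by_bin[b]
        if c.dN > 0 and ps_pool > 0:
            a = 1.0 - (ds_pool * c.pN) / (c.dN * ps_pool)
            w = a * c.dN / ds_pool if ds_pool > 0 else float("nan")
        else:
            a = w = float("nan")
        rows.append({"bin": b, "dS_pooled": ds_pool, "pS_pooled": ps_pool,
                     "alpha": a, "omega_a": w})
    return pd.DataFrame(rows)


class MKModel:
    """Conservation-binned McDonald–Kreitman model over a gene set.

    Parameters
    ----------
    alignments : iterable of CodonAlignment
        Per-gene codon alignments carrying all role species.
    samples : mapping gene_id -> PopulationSample
        Focal-population samples aligned to the same codon coordinates.
    roles : SpeciesRoles
        Species role assignment (focal, divergence pair, polarizing,
        conservation set).
    scheme : str
        Conservation scheme, 'MK22' (default) or 'DS21'.
    min_called_frac : float
        Minimum fraction of genotypes with data per site (default 0.5).

    ``fit`` applies the site filters, pools sites by conservatism bin
    and returns an :class:`MKResults` with per-bin alpha, omega_a and
    bootstrap confidence intervals.
    """

    def __init__(
        self,
        alignments: Iterable[CodonAlignment],
        samples: Mapping[str, PopulationSample] | Sequence[PopulationSample],
        roles: SpeciesRoles = SpeciesRoles(),
        scheme: str = "MK22",
        min_called_frac: float = 0.5,
    ):
        self.alignments = list(alignments)
        if not isinstance(samples, Mapping):
            samples = {s.gene_id: s for s in samples}
        self.samples = dict(samples)
        missing = [a.gene_id for a in self.alignments if a.gene_id not in self.samples]
        if missing:
            raise ConfigurationError(f"no population sample for gene(s) {missing}")
        self.roles = roles
        self.scheme = scheme
        self.min_called_frac = min_called_frac

    def fit(
        self,
        cutoff: float = 0.15,
        polarity: str = "derived",
        bootstrap: int = 1000,
        seed: int | None = None,
        conf: float = 0.95,
    ) -> "MKResults":
        rng = np.random.default_rng(seed)
        all_feats: list[np.ndarray] = []
        all_bins: list[np.ndarray] = []
        attrition_total: dict[str, int] = {}
        for aln in self.alignments:
            sample = self.samples[aln.gene_id]
            profile = window_conservation(aln, self.roles.conservation_set, self.scheme)
            mask, att = site_filters(
                aln, sample, self.roles, profile, self.min_called_frac
            )
            for key, v in att.items():
                attrition_total[key] = attrition_total.get(key, 0) + v
            sites = np.flatnonzero(mask)
            if len(sites) == 0:
                continue
            all_feats.append(
                site_features(aln, sample, sites, self.roles, cutoff, polarity)
            )
            all_bins.append(profile.bins[sites])
        if not all_feats:
            raise UndefinedEstimateError("no sites survived filtering")
        feats = np.vstack(all_feats)
        bins = np.concatenate(all_bins)
        counts_by_bin: dict[int, MKCounts] = {}
        rows = []
        for b in sorted(set(int(x) for x in bins)):
            sel = feats[bins == b]
            c = MKCounts.from_features(b, sel)
            counts_by_bin[b] = c
            try:
                a = alpha(c)
                w = omega_a(c)
            except UndefinedEstimateError:
                a = w = float("nan")
            if bootstrap > 0 and len(sel):
                a_lo, a_hi, a_bad = bootstrap_ci(sel, "alpha", bootstrap, rng, conf)
                w_lo, w_hi, w_bad = bootstrap_ci(sel, "omega_a", bootstrap, rng, conf)
            else:
                a_lo = a_hi = w_lo = w_hi = float("nan")
                a_bad = w_bad = True
            rows.append(
                {
                    "bin": b,
                    "nsites_N": c.n_nondeg_sites,
                    "nsites_S": c.n_fourfold_sites,
                    "dN": c.dN,
                    "dS": c.dS,
                    "pN": c.pN,
                    "pS": c.pS,
                    "alpha": a,
                    "alpha_lo": a_lo,
                    "alpha_hi": a_hi,
                    "alpha_ci_unstable": a_bad,
                    "omega_a": w,
                    "omega_a_lo": w_lo,
                    "omega_a_hi": w_hi,
                    "omega_a_ci_unstable": w_bad,
                }
            )
        table = pd.DataFrame(rows).set_index("bin")
        return MKResults(
            model=self,
            table=table,
            counts_by_bin=counts_by_bin,
            features=feats,
            bins=bins,
            attrition=attrition_total,
            params={
                "cutoff": cutoff,
                "polarity": polarity,
                "bootstrap": bootstrap,
                "seed": seed,
                "conf": conf,
                "scheme": self.scheme,
            },
        )


@dataclass
class MKResults:
    """Fitted per-bin MK estimates with bootstrap intervals."""

    model: MKModel
    table: pd.DataFrame
    counts_by_bin: dict[int, MKCounts]
    features: np.ndarray
    bins: np.ndarray
    attrition: dict[str, int]
    params: dict = field(default_factory=dict)

    @property
    def overall(self) -> MKCounts:
        """All bins pooled into one MKCounts."""
        return MKCounts.from_features(-1, self.features)

    @property
    def alpha_overall(self) -> float:
        return alpha(self.overall)

    @property
    def omega_a_overall(self) -> float:
        return omega_a(self.overall)

    def pooled_synonymous_control(self) -> pd.DataFrame:
        """Per-bin alpha with genome-pooled synonymous dS and pS."""
        return pooled_synonymous_control(self.counts_by_bin)

    def attrition_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [{"filter": k, "sites_surviving": v} for k, v in self.attrition.items()]
        )
        total = self.attrition.get("total", 0)
        if total:
            df["fraction"] = df["sites_surviving"] / total
        return df

    def to_tsv(self, path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def plot(self, ax=None):
        """alpha and omega_a against conservatism bin (with CIs)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        ax.errorbar(
            t.index, t["alpha"],
            yerr=[t["alpha"] - t["alpha_lo"], t["alpha_hi"] - t["alpha"]],
            fmt="o-", label=r"$\alpha$", capsize=3,
        )
        ax.errorbar(
            t.index, t["omega_a"],
            yerr=[t["omega_a"] - t["omega_a_lo"], t["omega_a_hi"] - t["omega_a"]],
            fmt="s--", label=r"$\omega_a$", capsize=3,
        )
        ax.set_xlabel("conservatism bin")
        ax.set_ylabel("estimate")
        ax.legend()
        return ax

    def summary(self) -> str:
        p = self.params
        lines = [
            "Conservation-binned McDonald-Kreitman test",
            f"  scheme={p.get('scheme')}  cutoff={p.get('cutoff')}  "
            f"polarity={p.get('polarity')}  bootstrap={p.get('bootstrap')}",
            f"  genes={len(self.model.alignments)}  "
            f"sites pooled={len(self.features)}",
        ]
        try:
            lines.append(
                f"  overall: alpha={self.alpha_overall:.3f}  "
                f"omega_a={self.omega_a_overall:.3f}"
            )
        except UndefinedEstimateError:
            lines.append("  overall: undefined (dN=0 or pS=0)")
        cols = ["nsites_N", "nsites_S", "dN", "dS", "pN", "pS",
                "alpha", "alpha_lo", "alpha_hi", "omega_a"]
        lines.append(self.table[cols].to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)
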