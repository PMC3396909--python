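"""Double-substitution clumping analysis.

Codons that underwent two substitutions between the simulans–sechellia
clade and the pseudoobscura–persimilis clade carry a signature of
positive selection: if the two substitutions were independent, one lands
in each lineage (pattern P1) with probability 2*l1*l2 where l1, l2 are
the proportional lineage lengths; a shortage of P1 means the second
substitution clumped onto the first's lineage, and the fraction of pairs
driven by positive selection is

    delta = (2*l1*l2 - f(P1)) / (2*l1*l2).

For pairs that both occurred on the path to the simulans–sechellia
clade, the ananassae (II) and yakuba (III) branch-off witnesses place
each substitution on a path segment; the fraction of pairs straddling
point II closely (first in I–II, second in II–III) measures the mean lag
between the substitutions in d_S units, whose inverse is the
acceleration factor ~ 4*Ne*s of the selection driving the second one.

Lineage and segment assignment is by outgroup parsimony at the amino
acid level for non-synonymous pairs (codon level for the synonymous
control, where amino acids carry no signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as _beta

from ._codes import codon_aa, encode_codon
from .conservation import window_conservation
from .io import CodonAlignment, PhylogenySpec

PATTERN_P1 = "P1_different_lineages"
PATTERN_SIMSEC = "same_lineage_simsec"
PATTERN_PSEPER = "same_lineage_psepper"
UNRESOLVED = "unresolved"

SEGMENTS = ("I-II", "II-III", "III-IV")

#: species consumed by the double-substitution analysis
DOUBLESUB_SPECIES = {
    "clade_simsec": ("simulans", "sechellia"),
    "clade_pseper": ("pseudoobscura", "persimilis"),
    "outgroup": ("virilis", "mojavensis"),
    "witnesses": ("ananassae", "yakuba"),
}


@dataclass
class DoubleSubRecord:
    """One codon with two substitutions between the clades."""

    gene_id: str
    site: int
    type: str  # 'nonsynonymous' | 'synonymous'
    bin: int
    codon_simsec: str
    codon_pseper: str
    intermediates: tuple[str, str]
    outgroup_codon: str
    ananassae_codon: str | None = None
    yakuba_codon: str | None = None
    pattern: str = UNRESOLVED
    placement: tuple[str, str] | None = None  # (first, second) segments


def _differing_positions(a: str, b: str) -> list[int]:
    return [i for i in range(3) if a[i] != b[i]]


def _square(codon_a: str, codon_b: str) -> tuple[tuple[str, str], list[int]] | None:
    """Intermediate codons of the two mutational paths between a and b."""
    diffs = _differing_positions(codon_a, codon_b)
    if len(diffs) != 2:
        return None
    p, q = diffs
    i1 = codon_a[:p] + codon_b[p] + codon_a[p + 1 :]
    i2 = codon_a[:q] + codon_b[q] + codon_a[q + 1 :]
    return (i1, i2), diffs


def classify_pair(codon_a: str, codon_b: str) -> str | None:
    """'nonsynonymous' / 'synonymous' double-substitution pair, or None.

    Non-synonymous pairs require every step of both two-step paths
    between the codons to change the amino acid, with no stop codon at
    any corner; synonymous pairs require all four corners to share one
    amino acid.
    """
    sq = _square(codon_a, codon_b)
    if sq is None:
        return None
    (i1, i2), _ = sq
    aas = [codon_aa(encode_codon(c)) for c in (codon_a, codon_b, i1, i2)]
    if any(a in ("", "*") for a in aas):
        return None
    a_a, a_b, a_1, a_2 = aas
    if a_a == a_b == a_1 == a_2:
        return "synonymous"
    if a_a != a_1 != a_b and a_a != a_2 != a_b:
        return "nonsynonymous"
    return None


def _states(record: DoubleSubRecord) -> dict[str, str]:
    """Matching keys of the four codon-square states.

    Amino-acid level for non-synonymous records; codon level for the
    synonymous control, where amino acids are all identical.
    """
    if record.type == "synonymous":
        key = lambda c: c  # noqa: E731
    else:
        key = lambda c: codon_aa(encode_codon(c))  # noqa: E731
    i1, i2 = record.intermediates
    return {
        "simsec": key(record.codon_simsec),
        "pseper": key(record.codon_pseper),
        "mid1": key(i1),
        "mid2": key(i2),
        "outgroup": key(record.outgroup_codon),
    }


def assign_lineages(record: DoubleSubRecord) -> str:
    """Outgroup-parsimony lineage pattern of the two substitutions.

    The outgroup state identifies the ancestor among the four
    codon-square states: ancestor = pse–per state means both
    substitutions on the sim–sec lineage (and vice versa); ancestor = an
    intermediate means one substitution per lineage (P1). An outgroup
    matching none of the states, or matching ambiguously, leaves the
    record unresolved.
    """
    st = _states(record)
    out = st["outgroup"]
    hits = [k for k in ("simsec", "pseper", "mid1", "mid2") if st[k] == out]
    if len(hits) != 1:
        # no match, or an ambiguous ancestor (incl. both intermediates
        # sharing the outgroup amino acid): drop as unresolved
        return UNRESOLVED
    which = hits[0]
    if which == "pseper":
        return PATTERN_SIMSEC
    if which == "simsec":
        return PATTERN_PSEPER
    return PATTERN_P1


def place_on_path(
    record: DoubleSubRecord,
    ananassae_codon: str | None = None,
    yakuba_codon: str | None = None,
) -> tuple[str, str] | None:
    """Path-segment placement of a same-lineage sim–sec pair.

    The ananassae and yakuba orthologues witness the state of the path at
    branch points II and III; comparing each witness with the ancestral,
    intermediate and final states brackets both substitutions. Returns
    (first_segment, second_segment) in path order, or None when the
    witnesses are missing, ambiguous or mutually inconsistent.
    """
    if record.pattern != PATTERN_SIMSEC:
        raise ValueError("placement is defined for same-lineage sim-sec pairs only")
    ana = ananassae_codon if ananassae_codon is not None else record.ananassae_codon
    yak = yakuba_codon if yakuba_codon is not None else record.yakuba_codon
    if ana is None or yak is None:
        return None
    st = _states(record)
    if record.type == "synonymous":
        key = lambda c: c  # noqa: E731
    else:
        key = lambda c: codon_aa(encode_codon(c))  # noqa: E731
    anc, fin = st["pseper"], st["simsec"]
    mids = {st["mid1"], st["mid2"]}

    def classify(codon: str) -> str | None:
        w = key(codon)
        labels = set()
        if w == anc:
            labels.add("anc")
        if w == fin:
            labels.add("fin")
        if w in mids:
            labels.add("mid")
        return labels.pop() if len(labels) == 1 else None

    at_ii, at_iii = classify(ana), classify(yak)
    mapping = {
        ("anc", "anc"): ("III-IV", "III-IV"),
        ("anc", "mid"): ("II-III", "III-IV"),
        ("anc", "fin"): ("II-III", "II-III"),
        ("mid", "mid"): ("I-II", "III-IV"),
        ("mid", "fin"): ("I-II", "II-III"),
        ("fin", "fin"): ("I-II", "I-II"),
    }
    return mapping.get((at_ii, at_iii))


def find_double_sub_codons(
    alignment: CodonAlignment,
    profile=None,
    species: Mapping[str, tuple[str, str]] = DOUBLESUB_SPECIES,
) -> list[DoubleSubRecord]:
    """Scan one gene for candidate two-substitution codons.

    Candidates require, at amino-acid level, identical states within
    each of the sim–sec, pse–per and vir–moj species pairs (a sequencing
    error in a single genome cannot then create a candidate), clade
    codons differing at exactly two nucleotide positions, and both
    substitutions non-synonymous (or both synonymous) along each of the
    two possible paths. Non-candidates are skipped silently.
    """
    if profile is None:
        all_species = [s for pair in species.values() for s in pair]
        present = [s for s in alignment.species_order if s in all_species] or list(
            alignment.species_order
        )
        profile = window_conservation(alignment, present, "DS21")
    rows = {
        name: alignment.species_row(name)
        for pair in species.values()
        for name in pair
    }
    records: list[DoubleSubRecord] = []
    for j in range(alignment.n_sites):
        if not profile.assessable[j]:
            continue
        codons = {n: str(alignment.codons[r, j]) for n, r in rows.items()}
        if any(encode_codon(c) < 0 for c in codons.values()):
            continue
        rec = candidate_from_codons(
            codons, gene_id=alignment.gene_id, site=j, bin_=int(profile.bins[j])
        )
        if rec is not None:
            records.append(rec)
    return records


def candidate_from_codons(
    codons: Mapping[str, str], gene_id: str = "", site: int = -1, bin_: int = -1
) -> DoubleSubRecord | None:
    """Build a candidate record from per-species codon strings, or None."""
    for pair_name in ("clade_simsec", "clade_pseper", "outgroup"):
        a, b = (codons[s] for s in DOUBLESUB_SPECIES[pair_name])
        ia, ib = encode_codon(a), encode_codon(b)
        if ia < 0 or ib < 0:
            return None
        if codon_aa(ia) in ("", "*") or codon_aa(ia) != codon_aa(ib):
            return None
    c_ss = codons["simulans"]
    c_pp = codons["pseudoobscura"]
    pair_type = classify_pair(c_ss, c_pp)
    if pair_type is None:
        return None
    (i1, i2), _ = _square(c_ss, c_pp)
    return DoubleSubRecord(
        gene_id=gene_id,
        site=site,
        type=pair_type,
        bin=bin_,
        codon_simsec=c_ss,
        codon_pseper=c_pp,
        intermediates=(i1, i2),
        outgroup_codon=codons["virilis"],
        ananassae_codon=codons.get("ananassae"),
        yakuba_codon=codons.get("yakuba"),
    )


def expected_P1(phylo: PhylogenySpec) -> float:
    """Different-lineage fraction under independence: 2*l1*l2."""
    return 2.0 * phylo.l1 * phylo.l2


def delta(f_P1: float, expected: float) -> float:
    """Fraction of pairs driven by positive selection: (E - f)/E."""
    if expected <= 0:
        raise ValueError("expected P1 fraction must be positive")
    return (expected - f_P1) / expected


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    a = 1.0 - conf
    lo = 0.0 if k == 0 else float(_beta.ppf(a / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(_beta.ppf(1 - a / 2, k + 1, n - k))
    return lo, hi


@dataclass
class ClumpingEstimate:
    """Per-bin shortage of the different-lineage pattern."""

    bin: int
    n_pairs: int
    n_P1: int
    f_P1: float
    f_P1_ci: tuple[float, float]
    expected_P1: float
    delta: float
    delta_ci: tuple[float, float]


@dataclass
class LagEstimate:
    """Phylogenetic-lag estimate of selection strength.

    ``f_straddle`` is the fraction of placed same-lineage pairs whose
    first substitution fell in I–II and second in II–III; the mean lag
    between substitutions is f_straddle * L_path d_S, and its inverse is
    the acceleration over a neutral substitution, ~ 4*Ne*s. When no
    straddling pair is observed only the Clopper–Pearson bound is
    informative: the upper bound on f gives a lower bound on 4*Ne*s.
    """

    n_pairs: int
    n_straddle: int
    f_straddle: float
    f_ci: tuple[float, float]
    lag_dS: float
    acceleration: float
    four_Ne_s: float
    four_Ne_s_bounds: tuple[float, float]

    @property
    def lower_bound_only(self) -> bool:
        return self.n_straddle == 0


def estimate_lag(
    placements: Sequence[tuple[str, str]],
    phylo: PhylogenySpec = PhylogenySpec(),
    conf: float = 0.95,
) -> LagEstimate:
    """Lag and 4*Ne*s from segment placements of same-lineage pairs."""
    n = len(placements)
    if n == 0:
        raise ValueError("at least one placed pair is required")
    k = sum(1 for first, second in placements if (first, second) == ("I-II", "II-III"))
    f = k / n
    f_lo, f_hi = clopper_pearson(k, n, conf)
    lag = f * phylo.L_path
    acc = 1.0 / lag if lag > 0 else float("inf")
    s_lo = 1.0 / (f_hi * phylo.L_path) if f_hi > 0 else float("inf")
    s_hi = 1.0 / (f_lo * phylo.L_path) if f_lo > 0 else float("inf")
    return LagEstimate(
        n_pairs=n,
        n_straddle=k,
        f_straddle=f,
        f_ci=(f_lo, f_hi),
        lag_dS=lag,
        acceleration=acc,
        four_Ne_s=acc,
        four_Ne_s_bounds=(s_lo, s_hi),
    )


class DoubleSubstitutionModel:
    """Clumping and lag analysis over two-substitution codons.

    Build from per-gene alignments (``from_alignments``), from a table
    of per-species codons (``from_pairs``; columns named after the eight
    species), or directly from candidate records. ``fit`` assigns
    lineage patterns, places same-lineage sim–sec pairs on path
    segments, and returns a :class:`ClumpingResults`.
    """

    def __init__(
        self,
        records: Iterable[DoubleSubRecord],
        phylo: PhylogenySpec = PhylogenySpec(),
    ):
        self.records = list(records)
        self.phylo = phylo

    @classmethod
    def from_alignments(
        cls,
        alignments: Iterable[CodonAlignment],
        phylo: PhylogenySpec = PhylogenySpec(),
        conservation_species: Sequence[str] | None = None,
    ) -> "DoubleSubstitutionModel":
        records: list[DoubleSubRecord] = []
        for aln in alignments:
            prof = window_conservation(
                aln, conservation_species or aln.species_order, "DS21"
            )
            records.extend(find_double_sub_codons(aln, prof))
        return cls(records, phylo)

    @classmethod
    def from_pairs(
        cls, pairs: pd.DataFrame, phylo: PhylogenySpec = PhylogenySpec()
    ) -> "DoubleSubstitutionModel":
        records = []
        for i, row in enumerate(pairs.itertuples(index=False)):
            d = row._asdict()
            rec = candidate_from_codons(
                d,
                gene_id=str(d.get("gene_id", "")),
                site=int(d.get("site", i)),
                bin_=int(d.get("bin", -1)),
            )
            if rec is not None:
                records.append(rec)
        return cls(records, phylo)

    def fit(self, conf: float = 0.95) -> "ClumpingResults":
        resolved: list[DoubleSubRecord] = []
        dropped = {"unresolved_outgroup": 0}
        for rec in self.records:
            pattern = assign_lineages(rec)
            rec = replace(rec, pattern=pattern)
            if pattern == UNRESOLVED:
                dropped["unresolved_outgroup"] += 1
                continue
            if pattern == PATTERN_SIMSEC:
                rec = replace(rec, placement=place_on_path(rec))
            resolved.append(rec)

        expected = expected_P1(self.phylo)

        def clump(recs: list[DoubleSubRecord], b: int) -> ClumpingEstimate:
            n = len(recs)
            k = sum(1 for r in recs if r.pattern == PATTERN_P1)
            f = k / n
            ci = clopper_pearson(k, n, conf)
            return ClumpingEstimate(
                bin=b,
                n_pairs=n,
                n_P1=k,
                f_P1=f,
                f_P1_ci=ci,
                expected_P1=expected,
                delta=delta(f, expected),
                delta_ci=(delta(ci[1], expected), delta(ci[0], expected)),
            )

        by_type: dict[str, list[ClumpingEstimate]] = {}
        for pair_type in ("nonsynonymous", "synonymous"):
            recs = [r for r in resolved if r.type == pair_type]
            ests = []
            for b in sorted({r.bin for r in recs}):
                ests.append(clump([r for r in recs if r.bin == b], b))
            if recs:
                ests.append(clump(recs, -1))  # pooled over bins
            by_type[pair_type] = ests

        placements = [
            r.placement
            for r in resolved
            if r.type == "nonsynonymous"
            and r.pattern == PATTERN_SIMSEC
            and r.placement is not None
        ]
        lag = estimate_lag(placements, self.phylo, conf) if placements else None
        return ClumpingResults(
            model=self,
            records=resolved,
            clumping=by_type,
            lag=lag,
            dropped=dropped,
            params={"conf": conf},
        )


@dataclass
class ClumpingResults:
    """Fitted clumping and lag estimates."""

    model: DoubleSubstitutionModel
    records: list[DoubleSubRecord]
    clumping: dict[str, list[ClumpingEstimate]]
    lag: LagEstimate | None
    dropped: dict[str, int]
    params: dict = field(default_factory=dict)

    def clumping_table(self, pair_type: str = "nonsynonymous") -> pd.DataFrame:
        rows = []
        for e in self.clumping.get(pair_type, []):
            rows.append(
                {
                    "bin": e.bin,
                    "n_pairs": e.n_pairs,
                    "n_P1": e.n_P1,
                    "f_P1": e.f_P1,
                    "f_P1_lo": e.f_P1_ci[0],
                    "f_P1_hi": e.f_P1_ci[1],
                    "expected_P1": e.expected_P1,
                    "delta": e.delta,
                    "delta_lo": e.delta_ci[0],
                    "delta_hi": e.delta_ci[1],
                }
            )
        return pd.DataFrame(rows)

    def records_table(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "gene_id": r.gene_id,
                    "site": r.site + 1,  # 1-based in reports
                    "type": r.type,
                    "bin": r.bin,
                    "codon_simsec": r.codon_simsec,
                    "codon_pseper": r.codon_pseper,
                    "outgroup_codon": r.outgroup_codon,
                    "pattern": r.pattern,
                    "first_segment": r.placement[0] if r.placement else "",
                    "second_segment": r.placement[1] if r.placement else "",
                }
            )
        return pd.DataFrame(rows)

    def lag_table(self) -> pd.DataFrame:
        if self.lag is None:
            return pd.DataFrame()
        e = self.lag
        return pd.DataFrame(
            [
                {
                    "n_pairs": e.n_pairs,
                    "n_straddle": e.n_straddle,
                    "f_straddle": e.f_straddle,
                    "f_lo": e.f_ci[0],
                    "f_hi": e.f_ci[1],
                    "lag_dS": e.lag_dS,
                    "acceleration": e.acceleration,
                    "four_Ne_s": e.four_Ne_s,
                    "four_Ne_s_lo": e.four_Ne_s_bounds[0],
                    "four_Ne_s_hi": e.four_Ne_s_bounds[1],
                }
            ]
        )

    def summary(self) -> str:
        lines = ["Double-substitution clumping analysis"]
        lines.append(
            f"  records: {len(self.records)} resolved, "
            f"{self.dropped.get('unresolved_outgroup', 0)} dropped (outgroup unresolved)"
        )
        t = self.clumping_table("nonsynonymous")
        if len(t):
            lines.append("  non-synonymous pairs (bin -1 = pooled):")
            lines.append(t.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        t = self.clumping_table("synonymous")
        if len(t):
            lines.append("  synonymous control pairs:")
            lines.append(t.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        if self.lag is not None:
            e = self.lag
            lines.append(
                f"  lag: f_straddle={e.f_straddle:.4f} "
                f"(95% CI {e.f_ci[0]:.4f}-{e.f_ci[1]:.4f}), "
                f"lag={e.lag_dS:.4f} dS, 4Ne*s ~ {e.four_Ne_s:.1f}"
            )
        return "\n".join(lines)
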