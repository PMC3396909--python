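"""Sliding-window amino-acid conservation bins.

A codon column counts as *invariant* for a species set when every
species in the set carries a gapless ACGT codon there and all of them
translate to one identical, non-stop amino acid. The conservatism bin of
a site is the number of invariant columns in a fixed window around it:

* ``MK22`` — 21-site window spanning the focal site (10 before, the site
  itself, 10 after), scored over a designated species set (classically
  the 7 species outside the melanogaster subgroup); bins 0..21.
* ``DS21`` — the 20 flanking sites only (10 before + 10 after, focal
  site excluded), scored over all species supplied; bins 0..20.

Sites within 10 codons of either gene end are not assessable (their
window would be truncated) and are excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._codes import AA, INVALID
from .io import CodonAlignment

SCHEMES = ("MK22", "DS21")
_EDGE = 10  # codon sites trimmed at each gene end


@dataclass
class ConservationProfile:
    gene_id: str
    scheme: str
    bins: np.ndarray  # int per codon site
    assessable: np.ndarray  # bool per codon site

    @property
    def n_sites(self) -> int:
        return len(self.bins)

    def max_bin(self) -> int:
        return 21 if self.scheme == "MK22" else 20


def invariant_columns(alignment: CodonAlignment, species_set: Sequence[str]) -> np.ndarray:
    """Boolean per codon site: gapless and amino-acid invariant in the set."""
    rows = [alignment.species_row(s) for s in species_set]
    idx = alignment.codon_indices[rows]
    valid = (idx != INVALID).all(axis=0)
    safe = np.where(idx == INVALID, 0, idx)
    aas = AA[safe]
    same = (aas == aas[0]).all(axis=0)
    not_stop = aas[0] != "*"
    return valid & same & not_stop


def window_conservation(
    alignment: CodonAlignment,
    species_set: Sequence[str],
    scheme: str = "MK22",
) -> ConservationProfile:
    """Assign each codon site its sliding-window conservatism bin."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown conservation scheme {scheme!r}")
    missing = [s for s in species_set if s not in alignment.species_order]
    if missing:
        raise KeyError(f"species {missing} not in alignment {alignment.gene_id}")
    inv = invariant_columns(alignment, species_set).astype(np.int64)
    n = len(inv)
    window = np.convolve(inv, np.ones(21, dtype=np.int64), mode="same")
    if scheme == "MK22":
        bins = window
    else:  # DS21: focal column excluded from its own window
        bins = window - inv
    assessable = np.zeros(n, dtype=bool)
    if n > 2 * _EDGE:
        assessable[_EDGE : n - _EDGE] = True
    bins = np.where(assessable, bins, 0)
    return ConservationProfile(alignment.gene_id, scheme, bins, assessable)


def bin_partition(
    profile: ConservationProfile, sites: Iterable[int] | None = None
) -> dict[int, list[int]]:
    """Partition assessable sites by bin (disjoint and exhaustive)."""
    if sites is None:
        sites = np.flatnonzero(profile.assessable)
    groups: dict[int, list[int]] = {}
    for j in sites:
        j = int(j)
        if not profile.assessable[j]:
            raise ValueError(
                f"{profile.gene_id}: site {j} is not assessable (gene-end trim)"
            )
        groups.setdefault(int(profile.bins[j]), []).append(j)
    return groups


def profiles_for(
    alignments: Iterable[CodonAlignment],
    species_set: Sequence[str],
    scheme: str = "MK22",
) -> Mapping[str, ConservationProfile]:
    return {
        a.gene_id: window_conservation(a, species_set, scheme) for a in alignments
    }
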