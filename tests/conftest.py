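"""Shared builders for synthetic toy alignments and samples."""

from __future__ import annotations

import numpy as np
import pytest

from conselmk.io import CodonAlignment, PopulationSample
from conselmk.simulate import SPECIES_12


def make_alignment(
    gene_id: str,
    n_sites: int,
    base: str = "GAA",
    overrides: dict[tuple[str, int], str] | None = None,
    species=SPECIES_12,
    mask=(),
) -> CodonAlignment:
    """Alignment with every species carrying ``base`` at every site,
    except (species, site) -> codon overrides."""
    codons = np.full((len(species), n_sites), base, dtype="U3")
    for (sp, j), codon in (overrides or {}).items():
        codons[list(species).index(sp), j] = codon
    aln = CodonAlignment(gene_id, list(species), codons)
    aln.apply_mask(mask)
    return aln


def make_sample(
    gene_id: str,
    n_sites: int,
    n_genotypes: int,
    base: str = "GAA",
    site_counts: dict[int, dict[str, int]] | None = None,
) -> PopulationSample:
    """Sample monomorphic for ``base`` except per-site count overrides."""
    counts = []
    for j in range(n_sites):
        if site_counts and j in site_counts:
            counts.append(dict(site_counts[j]))
        else:
            counts.append({base: n_genotypes})
    return PopulationSample(gene_id, n_genotypes, counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
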