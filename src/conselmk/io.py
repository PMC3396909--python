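"""Alignment, population-sample and phylogeny containers plus file I/O.

Coordinates are 0-based half-open internally; codon-site indices in all
written reports are 1-based inclusive.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from ._codes import INVALID, encode_codon


class FormatError(ValueError):
    """Malformed input file (named record where possible)."""


class UndefinedConsensusError(ValueError):
    """Consensus requested at a site with no called genotypes."""


@dataclass
class CodonAlignment:
    """One gene's codon-aware multiple alignment across named species.

    ``codons[i, j]`` is the 3-letter string of species ``i`` at codon
    site ``j`` (may contain '-' or 'N'). ``site_valid[j]`` is True iff
    every species carries a gapless ACGT-only codon at ``j``;
    ``site_masked[j]`` is True iff any of the site's three bases
    intersects a supplied mask interval.
    """

    gene_id: str
    species_order: list[str]
    codons: np.ndarray  # (n_species, n_sites) of '<U3'
    site_valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    site_masked: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.codons = np.asarray(self.codons, dtype="U3")
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.species_order):
            raise FormatError(
                f"{self.gene_id}: codon matrix shape {self.codons.shape} does not "
                f"match {len(self.species_order)} species"
            )
        # encode via a unique-value lookup: alignments contain few
        # distinct codon strings, so this is much faster than per-cell calls
        uniq, inv = np.unique(self.codons, return_inverse=True)
        lut = np.array([encode_codon(str(u)) for u in uniq], dtype=np.int16)
        self._indices = lut[inv].reshape(self.codons.shape)
        if self.site_valid is None:
            self.site_valid = (self._indices != INVALID).all(axis=0)
        else:
            self.site_valid = np.asarray(self.site_valid, dtype=bool)
        if self.site_masked is None:
            self.site_masked = np.zeros(self.n_sites, dtype=bool)
        else:
            self.site_masked = np.asarray(self.site_masked, dtype=bool)

    @property
    def n_species(self) -> int:
        return self.codons.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    @property
    def codon_indices(self) -> np.ndarray:
        """Encoded codon matrix (int16; INVALID for gap/N codons)."""
        return self._indices

    def species_row(self, name: str) -> int:
        try:
            return self.species_order.index(name)
        except ValueError:
            raise KeyError(f"species {name!r} not in alignment {self.gene_id}") from None

    def codon_of(self, species: str, site: int) -> str:
        return str(self.codons[self.species_row(species), site])

    @classmethod
    def from_sequences(
        cls,
        gene_id: str,
        sequences: Mapping[str, str] | Sequence[tuple[str, str]],
        mask_intervals: Iterable[tuple[int, int]] = (),
    ) -> "CodonAlignment":
        """Build from per-species nucleotide strings (equal length, /3)."""
        items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
        if not items:
            raise FormatError(f"{gene_id}: no records")
        lengths = {len(s) for _, s in items}
        if len(lengths) != 1:
            bad = [n for n, s in items if len(s) != len(items[0][1])]
            raise FormatError(f"{gene_id}: length mismatch in record(s) {bad}")
        (length,) = lengths
        if length % 3 != 0:
            raise FormatError(
                f"{gene_id}: alignment length {length} is not a multiple of 3 "
                f"(record {items[0][0]})"
            )
        n_sites = length // 3
        codons = np.array(
            [[s[3 * j : 3 * j + 3] for j in range(n_sites)] for _, s in items],
            dtype="U3",
        )
        aln = cls(gene_id, [n for n, _ in items], codons)
        aln.apply_mask(mask_intervals)
        return aln

    def apply_mask(self, intervals: Iterable[tuple[int, int]]) -> None:
        """Mark codon sites overlapping any base interval [start, end)."""
        for start, end in intervals:
            if end <= start:
                continue
            first = max(start // 3, 0)
            last = min((end - 1) // 3, self.n_sites - 1)
            if last >= first:
                self.site_masked[first : last + 1] = True

    def sequences(self) -> dict[str, str]:
        return {
            name: "".join(self.codons[i]) for i, name in enumerate(self.species_order)
        }


@dataclass
class PopulationSample:
    """Per-site codon counts over N genotypes of a focal species.

    ``counts[j]`` maps 3-letter codon strings to the number of called
    genotypes carrying them at site ``j``; genotypes with a gap or N at a
    site are missing there, so ``called[j] = sum(counts[j].values())``
    never exceeds ``n_genotypes``.
    """

    gene_id: str
    n_genotypes: int
    counts: list[dict[str, int]]
    called: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.called is None:
            self.called = np.array([sum(c.values()) for c in self.counts], dtype=np.int64)
        else:
            self.called = np.asarray(self.called, dtype=np.int64)
        if (self.called > self.n_genotypes).any():
            raise FormatError(
                f"{self.gene_id}: called genotypes exceed n_genotypes at some site"
            )

    @property
    def n_sites(self) -> int:
        return len(self.counts)

    @classmethod
    def from_genotypes(
        cls, gene_id: str, sequences: Mapping[str, str] | Sequence[tuple[str, str]]
    ) -> "PopulationSample":
        items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
        lengths = {len(s) for _, s in items}
        if len(lengths) > 1:
            raise FormatError(f"{gene_id}: genotype length mismatch")
        (length,) = lengths or {0}
        if length % 3 != 0:
            raise FormatError(f"{gene_id}: genotype length {length} not a multiple of 3")
        n_sites = length // 3
        counts: list[dict[str, int]] = []
        for j in range(n_sites):
            site: dict[str, int] = {}
            for _, seq in items:
                codon = seq[3 * j : 3 * j + 3].upper()
                if encode_codon(codon) == INVALID:
                    continue  # gap/N genotype missing at this site
                site[codon] = site.get(codon, 0) + 1
            counts.append(site)
        return cls(gene_id, len(items), counts)


def consensus_codon(sample: PopulationSample, site: int) -> str:
    """Most frequent codon at a site; ties broken lexicographically."""
    site_counts = sample.counts[site]
    if not site_counts:
        raise UndefinedConsensusError(
            f"{sample.gene_id}: no called genotypes at codon site {site}"
        )
    best = max(site_counts.items(), key=lambda kv: (kv[1], [-ord(c) for c in kv[0]]))
    return best[0]


@dataclass(frozen=True)
class PhylogenySpec:
    """Fixed two-lineage topology with branch lengths in d_S units.

    ``L_other`` is the length from the basal junction (clade I) to the
    pseudoobscura–persimilis clade; ``L_path`` is the length of the path
    from the junction to the simulans–sechellia clade (IV), which passes
    the ananassae (II) and yakuba (III) branch points. ``segments`` are
    the I–II, II–III and III–IV pieces of that path and must sum to
    ``L_path``.
    """

    L_other: float = 0.68
    L_path: float = 1.03
    segments: tuple[float, float, float] = (0.55, 0.33, 0.15)

    def __post_init__(self):
        if self.L_other <= 0 or self.L_path <= 0:
            raise ValueError("branch lengths must be positive")
        if abs(sum(self.segments) - self.L_path) > 1e-9:
            raise ValueError(
                f"path segments {self.segments} must sum to L_path={self.L_path}"
            )

    @property
    def L_total(self) -> float:
        return self.L_other + self.L_path

    @property
    def l1(self) -> float:
        """Proportional length of the pse–per lineage (0.68/1.71 = 0.40)."""
        return self.L_other / self.L_total

    @property
    def l2(self) -> float:
        """Proportional length of the sim–sec path (1.03/1.71 = 0.60)."""
        return self.L_path / self.L_total


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file into {name: [(start, end), ...]} (0-based half-open)."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: BED line has fewer than 3 fields")
        name, start, end = parts[0], int(parts[1]), int(parts[2])
        intervals.setdefault(name, []).append((start, end))
    return intervals


def read_codon_alignment(
    path: str | Path,
    mask: str | Path | Iterable[tuple[int, int]] | None = None,
    gene_id: str | None = None,
) -> CodonAlignment:
    """Read a per-gene codon-aware FASTA alignment (one record per species).

    ``mask`` may be a BED path (intervals whose name matches the gene id,
    or any interval if the BED names do not match) or an explicit list of
    base intervals.
    """
    path = Path(path)
    gid = gene_id or path.stem
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    intervals: Iterable[tuple[int, int]] = ()
    if mask is not None:
        if isinstance(mask, (str, Path)):
            by_name = read_bed(mask)
            intervals = by_name.get(gid, [])
            if not intervals and len(by_name) == 1:
                intervals = next(iter(by_name.values()))
        else:
            intervals = mask
    return CodonAlignment.from_sequences(gid, records, intervals)


def write_codon_alignment(alignment: CodonAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in alignment.sequences().items():
            fh.write(f">{name}\n{seq}\n")


def read_population_sample(path: str | Path, gene_id: str | None = None) -> PopulationSample:
    """Read a population sample from genotype FASTA or a site x genotype TSV.

    The TSV layout is one header row of genotype names and one row per
    codon site: ``site<TAB>g1<TAB>g2...`` with 3-letter codons ('---' or
    'NNN' for missing). Format is chosen by extension (.tsv/.txt vs FASTA).
    """
    path = Path(path)
    gid = gene_id or path.stem
    if path.suffix.lower() in {".tsv", ".txt"}:
        lines = [l for l in path.read_text().splitlines() if l.strip()]
        if not lines:
            raise FormatError(f"{path}: empty TSV")
        header = lines[0].split("\t")
        genotypes = header[1:]
        if not genotypes:
            raise FormatError(f"{path}: TSV has no genotype columns")
        seqs = {g: [] for g in genotypes}
        for lineno, line in enumerate(lines[1:], 2):
            cells = line.split("\t")
            if len(cells) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} columns")
            for g, codon in zip(genotypes, cells[1:]):
                seqs[g].append(codon)
        return PopulationSample.from_genotypes(
            gid, {g: "".join(c) for g, c in seqs.items()}
        )
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return PopulationSample.from_genotypes(gid, records)


def write_population_sample_fasta(
    sequences: Mapping[str, str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")


def write_population_sample_tsv(sequences: Mapping[str, str], path: str | Path) -> None:
    names = list(sequences)
    length = len(next(iter(sequences.values())))
    n_sites = length // 3
    buf = _io.StringIO()
    buf.write("site\t" + "\t".join(names) + "\n")
    for j in range(n_sites):
        row = [str(j + 1)] + [sequences[n][3 * j : 3 * j + 3] for n in names]
        buf.write("\t".join(row) + "\n")
    Path(path).write_text(buf.getvalue())
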