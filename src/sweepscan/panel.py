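"""Core domain types: haplotype panels, genetic maps and gene models.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open.  The 1-based conventions of
VCF and GFF3 are converted at the I/O boundary (:mod:`sweepscan.io`).
Genetic distances are in centimorgans (cM); recombination rates in cM/Mb.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["HaplotypePanel", "GeneticMap", "GeneModel"]


@dataclass
class HaplotypePanel:
    """Phased biallelic allele matrix over (haplotype, site) with population labels.

    Parameters
    ----------
    chromosome
        Chromosome / scaffold identifier.
    positions
        Physical positions (bp, 0-based), strictly increasing, one per site.
    alleles
        ``(n_haplotypes, n_sites)`` int8 matrix with entries in {0, 1}.
    sample_of_haplotype
        Sample name of each haplotype row; each diploid sample contributes
        exactly two consecutive rows.
    population_of_sample
        Mapping sample name -> population label.
    """

    chromosome: str
    positions: np.ndarray
    alleles: np.ndarray
    sample_of_haplotype: list
    population_of_sample: dict

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (haplotype, site) matrix")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError("positions and alleles disagree on site count")
        if self.alleles.shape[0] != len(self.sample_of_haplotype):
            raise ValueError("sample_of_haplotype length != haplotype count")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        bad = np.setdiff1d(np.unique(self.alleles), [0, 1])
        if bad.size:
            raise ValueError(f"alleles must be 0/1; found {bad}")
        missing = {s for s in self.sample_of_haplotype
                   if s not in self.population_of_sample}
        if missing:
            raise KeyError(
                "samples without a population label: " + ", ".join(sorted(missing)))
        counts = {}
        for s in self.sample_of_haplotype:
            counts[s] = counts.get(s, 0) + 1
        odd = {s for s, c in counts.items() if c != 2}
        if odd:
            raise ValueError(
                "each diploid sample must contribute exactly 2 haplotypes; "
                f"violated by {sorted(odd)}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def populations(self) -> list:
        seen = []
        for s in self.sample_of_haplotype:
            p = self.population_of_sample[s]
            if p not in seen:
                seen.append(p)
        return seen

    def haplotype_indices(self, *populations: str) -> np.ndarray:
        """Row indices of haplotypes belonging to the given population(s)."""
        pops = set(populations)
        unknown = pops - set(self.population_of_sample.values())
        if unknown:
            raise KeyError(f"unknown population(s): {sorted(unknown)}")
        return np.array(
            [i for i, s in enumerate(self.sample_of_haplotype)
             if self.population_of_sample[s] in pops],
            dtype=np.intp)

    def population_alleles(self, *populations: str) -> np.ndarray:
        """Allele sub-matrix for one or more populations (rows copied)."""
        return self.alleles[self.haplotype_indices(*populations), :]

    def subset_sites(self, mask_or_index) -> "HaplotypePanel":
        idx = np.asarray(mask_or_index)
        return HaplotypePanel(
            chromosome=self.chromosome,
            positions=self.positions[idx],
            alleles=self.alleles[:, idx],
            sample_of_haplotype=list(self.sample_of_haplotype),
            population_of_sample=dict(self.population_of_sample),
        )

    def content_digest(self) -> str:
        """SHA-256 over the panel content; used to assert non-mutation."""
        h = hashlib.sha256()
        h.update(self.chromosome.encode())
        h.update(self.positions.tobytes())
        h.update(np.ascontiguousarray(self.alleles).tobytes())
        h.update(repr(sorted(self.population_of_sample.items())).encode())
        h.update(repr(self.sample_of_haplotype).encode())
        return h.hexdigest()


@dataclass
class GeneticMap:
    """Monotone physical -> genetic coordinate transform for one chromosome.

    Built from recombination-rate windows (cM/Mb over bp tiles).  The
    cumulative map is piecewise linear: within a rate window genetic
    position grows linearly with physical position.
    """

    chromosome: str
    window_starts: np.ndarray   # bp starts of rate windows, first must be 0
    rates: np.ndarray           # cM/Mb per window
    chrom_length: int           # bp; windows tile [0, chrom_length)
    _breaks: np.ndarray = field(init=False, repr=False)
    _cum_cm: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.window_starts = np.asarray(self.window_starts, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.window_starts.size != self.rates.size:
            raise ValueError("window_starts and rates must have equal length")
        if self.window_starts.size == 0 or self.window_starts[0] != 0:
            raise ValueError("rate windows must start at position 0")
        if not np.all(np.diff(self.window_starts) > 0):
            raise ValueError("window_starts must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("negative recombination rate")
        if self.window_starts[-1] >= self.chrom_length:
            raise ValueError("last window start beyond chromosome length")
        self._breaks = np.append(self.window_starts, self.chrom_length)
        widths_mb = np.diff(self._breaks) / 1e6
        self._cum_cm = np.concatenate([[0.0], np.cumsum(self.rates * widths_mb)])

    @classmethod
    def uniform(cls, chromosome: str, chrom_length: int, rate_cm_per_mb: float,
                window_bp: int = 100_000) -> "GeneticMap":
        starts = np.arange(0, chrom_length, window_bp, dtype=np.int64)
        return cls(chromosome, starts,
                   np.full(starts.size, float(rate_cm_per_mb)), chrom_length)

    @property
    def total_cm(self) -> float:
        return float(self._cum_cm[-1])

    def bp_to_cm(self, position):
        """Genetic position (cM) of physical position(s); linear within windows."""
        pos = np.asarray(position, dtype=float)
        if np.any(pos < 0) or np.any(pos > self.chrom_length):
            raise ValueError("position outside mapped extent")
        out = np.interp(pos, self._breaks, self._cum_cm)
        return float(out) if np.isscalar(position) else out

    def cm_to_bp(self, genetic_position):
        """Inverse transform; cM values clipped to the mapped genetic extent."""
        cm = np.clip(np.asarray(genetic_position, dtype=float), 0.0, self.total_cm)
        out = np.interp(cm, self._cum_cm, self._breaks)
        return float(out) if np.isscalar(genetic_position) else out


@dataclass(frozen=True)
class GeneModel:
    """A gene body interval (0-based half-open) on a chromosome."""

    accession: str
    chromosome: str
    start: int
    stop: int
    strand: str = "."

    def __post_init__(self):
        if not self.start < self.stop:
            raise ValueError(f"gene {self.accession}: start must be < stop")

    def distance_to(self, position: int) -> int:
        """bp distance from a site to the gene body (0 if inside)."""
        if position < self.start:
            return self.start - position
        if position >= self.stop:
            return position - self.stop + 1
        return 0
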