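"""Three-population phased-panel simulator with planted selective sweeps.

The generator emulates the study design the scan is built for: a small
focal population, a pooled background population twice its size, and a
more diverged outgroup, on a short chromosome with very dense SNPs
(~1 per 30 bp) and extremely high recombination (~25 cM/Mb).

Model
-----
Neutral background.  Site positions are Poisson along the chromosome.
Each site has an ancestral frequency p ~ Uniform(0.05, 0.95); each
population draws its own frequency from a Beta distribution centred on p
with a per-population drift dispersion phi (Balding-Nichols
parameterisation: q ~ Beta(p(1-phi)/phi, (1-p)(1-phi)/phi), so
Var(q) = phi p(1-p) and the expected pairwise F_ST between two
populations with dispersion phi is ~phi).  Within a population, a pool of
F founder haplotypes carries the population frequency (count-matched per
site) and every sampled haplotype is a Markov mosaic over the founder
pool whose switch intensity is scaled in cM, so haplotype sharing -- and
with it LD and EHH -- decays with genetic distance.

Sweeps.  A planted sweep raises the carrier count of allele 1 at the core
site to round(selected_freq_focal * 2 n_focal) in the focal population;
carriers copy one of k sweep founder haplotypes over a flank whose cM
half-width is Exponential(footprint_cm), outside which they revert to
neutral background.  k = 1 plants a hard sweep, k > 1 a soft sweep.  The
selected allele is set rare in the background and outgroup.

Everything is deterministic for a fixed seed (single RNG stream keyed by
seed and chromosome).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import GeneticMap, HaplotypePanel

__all__ = ["SweepSpec", "SimulationConfig", "simulate_panel",
           "write_truth", "read_truth"]


@dataclass
class SweepSpec:
    """A planted sweep: where, how frequent, how many founders, how wide."""

    core_position: int
    selected_freq_focal: float = 0.95
    founder_haplotypes: int = 1          # k = 1 hard, k > 1 soft
    footprint_cm: float = 0.1            # mean exponential half-width per flank
    freq_background: float = 0.05        # selected-allele frequency outside focal

    def __post_init__(self):
        if not 0.0 < self.selected_freq_focal <= 1.0:
            raise ValueError("selected_freq_focal must be in (0, 1]")
        if self.founder_haplotypes < 1:
            raise ValueError("founder_haplotypes must be >= 1")
        if self.footprint_cm <= 0:
            raise ValueError("footprint_cm must be > 0")


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic panel.

    Defaults mirror the study conditions: 10/20/28 diploid individuals
    (focal / background / outgroup), ~1 SNP per 30 bp, ~25 cM/Mb, and a
    focal-background drift dispersion giving genome-wide F_ST ~ 0.044.
    """

    seed: int = 0
    chromosome: str = "chr1"
    chrom_length: int = 1_000_000
    snp_density: float = 1.0 / 30.0      # expected SNPs per bp
    rec_rate: float = 25.0               # cM/Mb, uniform over 100 kb windows
    n_focal: int = 10
    n_background: int = 20
    n_outgroup: int = 28
    drift_focal: float = 0.044
    drift_background: float = 0.044
    drift_outgroup: float = 0.20
    n_founders: int = 10                 # founder-pool size per population
    ld_decay_cm: float = 0.02            # pairwise haplotype-sharing decay scale
    sweeps: list = field(default_factory=list)
    pop_focal: str = "focal"
    pop_background: str = "background"
    pop_outgroup: str = "outgroup"

    def __post_init__(self):
        for name in ("snp_density", "rec_rate", "drift_focal",
                     "drift_background", "drift_outgroup", "ld_decay_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for s in self.sweeps:
            if not 0 <= s.core_position < self.chrom_length:
                raise ValueError("sweep core outside chromosome")


def _rng_for(config: SimulationConfig) -> np.random.Generator:
    # single stream keyed by (seed, chromosome)
    key = zlib.crc32(config.chromosome.encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(config.seed), key])


def _count_matched_pool(rng, q, n_founders):
    """(F, S) founder alleles whose per-site allele-1 count is round(F*q)."""
    S = q.size
    counts = np.rint(n_founders * q).astype(np.int64)
    u = rng.random((n_founders, S))
    ranks = np.argsort(np.argsort(u, axis=0, kind="stable"), axis=0, kind="stable")
    return (ranks < counts[None, :]).astype(np.int8)


def _mosaic(rng, pool, n_hap, d_cm, ld_decay_cm):
    """Sample n_hap haplotypes as Markov mosaics over the founder pool.

    Per-haplotype switch probability between adjacent sites is
    1 - exp(-d_cm / (2 * ld_decay_cm)), so the probability that a PAIR of
    haplotypes keeps a shared founder over d cM decays as exp(-d/ld_decay_cm).
    """
    F, S = pool.shape
    draws = rng.integers(0, F, size=(n_hap, S))
    p_switch = 1.0 - np.exp(-d_cm / (2.0 * ld_decay_cm))
    keep = np.empty((n_hap, S), dtype=bool)
    keep[:, 0] = True
    keep[:, 1:] = rng.random((n_hap, S - 1)) < p_switch[None, :]
    cols = np.arange(S)
    last = np.maximum.accumulate(np.where(keep, cols[None, :], 0), axis=1)
    path = np.take_along_axis(draws, last, axis=1)
    return pool[path, cols[None, :]]


def simulate_panel(config: SimulationConfig):
    """Generate ``(HaplotypePanel, GeneticMap, truth)``.

    ``truth`` is the list of planted :class:`SweepSpec`, with
    ``core_position`` replaced by the realized core-site position.
    """
    rng = _rng_for(config)
    gmap = GeneticMap.uniform(config.chromosome, config.chrom_length,
                              config.rec_rate)

    n_sites = rng.poisson(config.chrom_length * config.snp_density)
    if n_sites < 2:
        raise ValueError("chromosome too short for the configured SNP density")
    positions = np.sort(rng.choice(config.chrom_length, size=n_sites,
                                   replace=False)).astype(np.int64)
    cm = gmap.bp_to_cm(positions)
    d_cm = np.diff(cm)

    # collision check between planted sweeps
    sweeps = sorted(config.sweeps, key=lambda s: s.core_position)
    for s1, s2 in zip(sweeps, sweeps[1:]):
        gd = abs(gmap.bp_to_cm(s2.core_position) - gmap.bp_to_cm(s1.core_position))
        if gd < (s1.footprint_cm + s2.footprint_cm):
            raise ValueError(
                f"sweep cores at {s1.core_position} and {s2.core_position} "
                "collide within each other's footprints")

    p_anc = rng.uniform(0.05, 0.95, size=n_sites)

    pops = [
        (config.pop_focal, config.n_focal, config.drift_focal),
        (config.pop_background, config.n_background, config.drift_background),
        (config.pop_outgroup, config.n_outgroup, config.drift_outgroup),
    ]
    blocks, pop_slices, offset = [], {}, 0
    freqs = {}
    for name, n_dip, phi in pops:
        alpha = p_anc * (1.0 - phi) / phi
        beta = (1.0 - p_anc) * (1.0 - phi) / phi
        q = rng.beta(alpha, beta)
        freqs[name] = q
        pool = _count_matched_pool(rng, q, config.n_founders)
        hap = _mosaic(rng, pool, 2 * n_dip, d_cm, config.ld_decay_cm)
        blocks.append(hap)
        pop_slices[name] = slice(offset, offset + 2 * n_dip)
        offset += 2 * n_dip
    alleles = np.concatenate(blocks, axis=0)

    # ---- plant sweeps -----------------------------------------------------
    truth = []
    focal_rows = np.arange(pop_slices[config.pop_focal].start,
                           pop_slices[config.pop_focal].stop)
    for spec in sweeps:
        core_idx = int(np.argmin(np.abs(positions - spec.core_position)))
        n_car = int(round(spec.selected_freq_focal * focal_rows.size))
        if n_car < 1:
            raise ValueError("sweep frequency too low for any carrier haplotype")
        carriers = rng.choice(focal_rows, size=n_car, replace=False)
        k = min(spec.founder_haplotypes, n_car)
        templates = alleles[carriers[:k], :].copy()
        templates[:, core_idx] = 1
        assignment = rng.integers(0, k, size=n_car)
        # every carrier shares founder material over at least the +/-0.01 cM
        # core haplotype region; beyond it, per-carrier exponential extents
        # emulate recombination gradually breaking the swept haplotypes
        min_share = 0.011
        half_left = np.maximum(rng.exponential(spec.footprint_cm, size=n_car),
                               min_share)
        half_right = np.maximum(rng.exponential(spec.footprint_cm, size=n_car),
                                min_share)
        core_cm = cm[core_idx]
        for c, t, wl, wr in zip(carriers, assignment, half_left, half_right):
            in_span = (cm >= core_cm - wl) & (cm <= core_cm + wr)
            alleles[c, in_span] = templates[t, in_span]
        # core column: carriers selected allele, other focal haplotypes not
        alleles[focal_rows, core_idx] = 0
        alleles[carriers, core_idx] = 1
        # selected allele is rare outside the focal population
        for pname in (config.pop_background, config.pop_outgroup):
            rows = np.arange(pop_slices[pname].start, pop_slices[pname].stop)
            n1 = int(round(spec.freq_background * rows.size))
            col = np.zeros(rows.size, dtype=np.int8)
            col[rng.choice(rows.size, size=n1, replace=False)] = 1
            alleles[rows, core_idx] = col
        realized = SweepSpec(
            core_position=int(positions[core_idx]),
            selected_freq_focal=n_car / focal_rows.size,
            founder_haplotypes=k,
            footprint_cm=spec.footprint_cm,
            freq_background=spec.freq_background,
        )
        truth.append(realized)

    # drop globally monomorphic sites (not segregating -> not in a VCF)
    seg = (alleles.sum(axis=0) > 0) & (alleles.sum(axis=0) < alleles.shape[0])
    # never drop a planted core
    for t in truth:
        seg[np.searchsorted(positions, t.core_position)] = True
    alleles = alleles[:, seg]
    positions = positions[seg]

    samples, pop_of_sample = [], {}
    for name, n_dip, _ in pops:
        for i in range(n_dip):
            s = f"{name}_{i:02d}"
            samples.extend([s, s])
            pop_of_sample[s] = name
    panel = HaplotypePanel(
        chromosome=config.chromosome, positions=positions, alleles=alleles,
        sample_of_haplotype=samples, population_of_sample=pop_of_sample)
    return panel, gmap, truth


# ---------------------------------------------------------------------------
# Truth tables
# ---------------------------------------------------------------------------

_TRUTH_COLS = ["core_position", "selected_freq_focal", "founder_haplotypes",
               "footprint_cm", "freq_background"]


def write_truth(truth, path) -> None:
    """TSV of planted sweeps for test harnesses (round-trips losslessly)."""
    df = pd.DataFrame([asdict(t) for t in truth], columns=_TRUTH_COLS)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TRUTH_COLS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.10g")


def read_truth(path):
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("truth table must start with a '#' header")
        df = pd.read_csv(fh, sep="\t", names=_TRUTH_COLS)
    return [SweepSpec(core_position=int(r.core_position),
                      selected_freq_focal=float(r.selected_freq_focal),
                      founder_haplotypes=int(r.founder_haplotypes),
                      footprint_cm=float(r.footprint_cm),
                      freq_background=float(r.freq_background))
            for r in df.itertuples()]
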