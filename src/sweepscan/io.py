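"""Readers and writers: phased VCF, genetic maps, gene annotations, result tables.

All tabular outputs are TSV with a single ``#``-prefixed header line.
``NaN`` statistics are serialized as empty cells, with a companion boolean
``*_defined`` column; the string ``NaN`` never appears in output.
"""

from __future__ import annotations

import logging
import os
import tempfile

import numpy as np
import pandas as pd

from .panel import GeneModel, GeneticMap, HaplotypePanel

log = logging.getLogger(__name__)

__all__ = [
    "read_phased_vcf", "write_phased_vcf",
    "read_genetic_map", "write_genetic_map",
    "read_genes",
    "write_stats_table", "read_stats_table",
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(path, populations: dict) -> HaplotypePanel:
    """Load a phased, biallelic-SNP VCF into a :class:`HaplotypePanel`.

    Parameters
    ----------
    path
        VCF 4.x file; all genotypes of retained records must be phased
        (``|`` separator) and complete.
    populations
        Mapping sample name -> population label.  Every sample present in
        the VCF must be listed, otherwise a :class:`KeyError` is raised.

    Multiallelic, non-SNP, unphased or incomplete records are skipped and
    counted (logged at INFO level).
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in populations]
    if unknown:
        raise KeyError(
            f"sample(s) {unknown} present in VCF but absent from the population map")

    rows = []           # per-record allele arrays, one per retained site
    positions = []
    chroms = set()
    skipped = {"multiallelic_or_not_snp": 0, "unphased_or_missing": 0}
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            skipped["multiallelic_or_not_snp"] += 1
            continue
        gts = v.genotypes  # [allele_a, allele_b, phased] per sample
        ok = all(len(g) == 3 and g[2] and g[0] in (0, 1) and g[1] in (0, 1)
                 for g in gts)
        if not ok:
            skipped["unphased_or_missing"] += 1
            continue
        rows.append(np.array([a for g in gts for a in g[:2]], dtype=np.int8))
        positions.append(v.POS - 1)  # 1-based VCF -> 0-based internal
        chroms.add(v.CHROM)
    if not rows:
        raise ValueError(f"no usable phased biallelic SNP records in {path}")
    if len(chroms) != 1:
        raise ValueError(
            f"expected a single-chromosome VCF, found {sorted(chroms)}; "
            "split per chromosome first")
    if any(skipped.values()):
        log.info("read_phased_vcf: skipped records %s", skipped)

    alleles = np.stack(rows, axis=1)  # (2*n_samples, n_sites)
    sample_of_hap = [s for s in samples for _ in range(2)]
    panel = HaplotypePanel(
        chromosome=chroms.pop(),
        positions=np.asarray(positions, dtype=np.int64),
        alleles=alleles,
        sample_of_haplotype=sample_of_hap,
        population_of_sample={s: populations[s] for s in samples},
    )
    panel.skipped_records = dict(skipped)
    return panel


def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    """Write a panel as a minimal phased VCF 4.2 file (REF=A, ALT=T).

    Output is deterministic: identical panels give byte-identical files.
    """
    samples = list(dict.fromkeys(panel.sample_of_haplotype))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chromosome}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        A = panel.alleles
        for j in range(panel.n_sites):
            gts = "\t".join(
                f"{A[2 * i, j]}|{A[2 * i + 1, j]}" for i in range(len(samples)))
            fh.write(f"{panel.chromosome}\t{panel.positions[j] + 1}\t.\tA\tT"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Genetic maps
# ---------------------------------------------------------------------------

_RATE_HEADER = "#chrom\tstart_bp\trate_cM_per_Mb"
_CUM_HEADER = "#chrom\tpos_bp\tcum_cM"


def write_genetic_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(_RATE_HEADER + "\n")
        for s, r in zip(gmap.window_starts, gmap.rates):
            fh.write(f"{gmap.chromosome}\t{s}\t{r:.10g}\n")
        # sentinel row marks the chromosome end so the extent round-trips
        fh.write(f"{gmap.chromosome}\t{gmap.chrom_length}\tEND\n")


def read_genetic_map(path, chrom_length: int | None = None) -> GeneticMap:
    """Read a genetic map TSV in either supported dialect.

    ``chrom  start_bp  rate_cM_per_Mb`` (rate windows, sentinel END row
    optional) or ``chrom  pos_bp  cum_cM`` (cumulative map points, first
    point must be at 0 cM).
    """
    with open(path) as fh:
        header = fh.readline().strip()
        body = [ln.rstrip("\n").split("\t") for ln in fh if ln.strip()]
    if not body:
        raise ValueError(f"empty genetic map file: {path}")
    chrom = body[0][0]
    if any(r[0] != chrom for r in body):
        raise ValueError("genetic map must describe a single chromosome")
    if header == _RATE_HEADER or "rate" in header:
        end = None
        starts, rates = [], []
        for r in body:
            if r[2] == "END":
                end = int(r[1])
            else:
                starts.append(int(r[1]))
                rates.append(float(r[2]))
        if end is None:
            end = chrom_length
        if end is None:
            # assume the last window has the modal window width
            widths = np.diff(starts)
            end = starts[-1] + (int(np.median(widths)) if len(widths) else 100_000)
        return GeneticMap(chrom, np.array(starts), np.array(rates), int(end))
    if header == _CUM_HEADER or "cum" in header:
        pos = np.array([int(r[1]) for r in body])
        cum = np.array([float(r[2]) for r in body])
        if pos[0] != 0 or cum[0] != 0:
            raise ValueError("cumulative map must start at (0 bp, 0 cM)")
        if np.any(np.diff(cum) < 0):
            raise ValueError("cumulative cM must be non-decreasing")
        rates = np.diff(cum) / (np.diff(pos) / 1e6)
        return GeneticMap(chrom, pos[:-1], rates, int(pos[-1]))
    raise ValueError(f"unrecognized genetic map header: {header!r}")


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

def read_genes(path) -> list:
    """Read gene models from GFF3 (via gffutils) or BED (0-based half-open)."""
    path = os.fspath(path)
    if path.endswith((".bed", ".bed.txt")):
        genes = []
        with open(path) as fh:
            for ln in fh:
                if not ln.strip() or ln.startswith(("#", "track", "browser")):
                    continue
                f = ln.rstrip("\n").split("\t")
                name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                strand = f[5] if len(f) > 5 else "."
                genes.append(GeneModel(name, f[0], int(f[1]), int(f[2]), strand))
        return genes

    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db", delete=False) as tmp:
        dbfn = tmp.name
    try:
        db = gffutils.create_db(path, dbfn=dbfn, force=True, keep_order=True,
                                merge_strategy="merge")
        genes = []
        for g in db.features_of_type("gene", order_by=("seqid", "start")):
            acc = g.attributes.get("ID", [g.id])[0]
            # GFF3 1-based inclusive -> 0-based half-open
            genes.append(GeneModel(acc, g.seqid, g.start - 1, g.end, g.strand or "."))
        return genes
    finally:
        os.unlink(dbfn)


def write_genes_bed(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start)):
            fh.write(f"{g.chromosome}\t{g.start}\t{g.stop}\t{g.accession}\t.\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Stats tables
# ---------------------------------------------------------------------------

def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Canonical on-disk form: bools as int8, NaN-bearing float columns
    paired with a ``*_defined`` flag column."""
    out = df.copy()
    for col in list(out.columns):
        if out[col].dtype == bool:
            out[col] = out[col].astype(np.int8)
    for col in list(out.columns):
        if pd.api.types.is_float_dtype(out[col]) and out[col].isna().any():
            flag = f"{col}_defined"
            if flag not in out.columns:
                out[flag] = out[col].notna().astype(np.int8)
    return out


def write_stats_table(df: pd.DataFrame, path) -> None:
    """Write a per-SNP / per-window / per-gene statistics table as TSV.

    Fixed, documented column order (the DataFrame's order); header line is
    ``#``-prefixed; NaN cells are empty and flagged via ``*_defined``.
    """
    out = _normalize(df)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, out.columns)) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False, na_rep="",
                   float_format="%.10g")


def read_stats_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError("stats table must start with a '#' header line")
        cols = header[1:].split("\t")
        df = pd.read_csv(fh, sep="\t", names=cols, na_values=[""],
                         keep_default_na=False)
    return df
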