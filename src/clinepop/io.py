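"""Readers and writers for genotype data and plain-text analysis artifacts.

Supported formats: VCF 4.x (biallelic SNP records, GT field; read through
cyvcf2), the PLINK ped/map text dialect, two-column population maps,
two-column transect-position tables and labeled square distance matrices
(tab-separated, km).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationMap


# ---------------------------------------------------------------------------
# population map / transect / distance matrices
# ---------------------------------------------------------------------------

def read_popmap(path, positions_path=None) -> PopulationMap:
    """Read a two-column (sample TAB population) map, optionally with positions.

    ``positions_path`` points to a two-column (population TAB km) table of
    transect positions.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    pops: dict[str, list[str]] = {}
    for s, p in zip(df["sample"], df["population"]):
        pops.setdefault(p, []).append(s)
    positions = None
    if positions_path is not None:
        pos = pd.read_csv(positions_path, sep="\t", header=None,
                          names=["population", "km"], comment="#")
        positions = dict(zip(pos["population"].astype(str), pos["km"].astype(float)))
    return PopulationMap(populations=pops, positions_km=positions)


def write_popmap(popmap: PopulationMap, path, positions_path=None) -> None:
    with open(path, "w") as fh:
        for pop, samples in popmap.populations.items():
            for s in samples:
                fh.write(f"{s}\t{pop}\n")
    if positions_path is not None and popmap.positions_km is not None:
        with open(positions_path, "w") as fh:
            for pop, km in popmap.positions_km.items():
                fh.write(f"{pop}\t{km:.6f}\n")


def read_distance_matrix(path) -> pd.DataFrame:
    """Labeled square tab-separated distance matrix (km)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix row and column labels differ")
    a = df.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("distance matrix is not symmetric")
    if (np.diag(a) != 0).any() or (a < 0).any():
        raise ValueError("distance matrix must be non-negative with zero diagonal")
    return df


def write_distance_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _check_samples(samples: list[str], popmap: PopulationMap | None) -> list[str]:
    if popmap is None:
        return ["UNASSIGNED"] * len(samples)
    s2p = popmap.sample_to_pop()
    missing = [s for s in samples if s not in s2p]
    if missing:
        raise ValueError(f"sample {missing[0]!r} absent from the population map")
    return [s2p[s] for s in samples]


def read_vcf(path, popmap: PopulationMap | None = None) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into alternate-allele dosages.

    Multi-allelic records are rejected with the offending locus named; a
    sample absent from the population map raises an error naming the sample.
    Missing genotypes (``./.``) become :data:`MISSING`; file order of samples
    and records is preserved.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    samples = list(vcf.samples)
    pops = _check_samples(samples, popmap)
    loci: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            locus = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
            raise ValueError(f"multi-allelic record at locus {locus!r}; biallelic SNPs only")
        locus = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append(locus)
        dos = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                dos[i] = a + b
        rows.append(dos)
    vcf.close()
    dosage = (np.array(rows, dtype=np.int8).T if rows
              else np.empty((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples=samples, populations=pops, loci=loci, dosage=dosage)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal VCF 4.2 with GT-only genotype fields.

    Locus IDs of the form ``chrom:pos`` are split back into CHROM/POS;
    anything else goes to CHROM ``1`` with POS = record index + 1.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.samples) + "\n")
        for j, locus in enumerate(G.loci):
            if ":" in locus and locus.rsplit(":", 1)[1].isdigit():
                chrom, pos = locus.rsplit(":", 1)
            else:
                chrom, pos = "1", str(j + 1)
            gts = "\t".join(_GT_STR[int(d)] for d in G.dosage[:, j])
            fh.write(f"{chrom}\t{pos}\t{locus}\tA\tG\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# PLINK text (ped/map)
# ---------------------------------------------------------------------------

_PED_ALLELES = {0: ("B", "B"), 1: ("A", "B"), 2: ("A", "A"), MISSING: ("0", "0")}


def write_plink(G: GenotypeMatrix, prefix) -> None:
    """Write ``prefix.ped`` / ``prefix.map``; dosage counts the A1 ('A') allele."""
    prefix = os.fspath(prefix)
    with open(prefix + ".map", "w") as fh:
        for j, locus in enumerate(G.loci):
            fh.write(f"1\t{locus}\t0\t{j + 1}\n")
    with open(prefix + ".ped", "w") as fh:
        for i, sample in enumerate(G.samples):
            fam = G.populations[i]
            alleles = []
            for d in G.dosage[i]:
                alleles.extend(_PED_ALLELES[int(d)])
            fh.write(f"{fam}\t{sample}\t0\t0\t0\t-9\t" + "\t".join(alleles) + "\n")


def read_plink(prefix, popmap: PopulationMap | None = None) -> GenotypeMatrix:
    """Read a ped/map pair; dosage counts the A1 ('A') allele; '0 0' is missing."""
    prefix = os.fspath(prefix)
    loci = []
    with open(prefix + ".map") as fh:
        for line in fh:
            parts = line.split()
            if parts:
                loci.append(parts[1])
    samples, ped_pops, rows = [], [], []
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            fam, sample = parts[0], parts[1]
            alleles = parts[6:]
            if len(alleles) != 2 * len(loci):
                raise ValueError(f"sample {sample!r}: expected {2 * len(loci)} alleles, "
                                 f"got {len(alleles)}")
            dos = np.full(len(loci), MISSING, dtype=np.int8)
            for j in range(len(loci)):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a != "0" and b != "0":
                    dos[j] = (a == "A") + (b == "A")
            samples.append(sample)
            ped_pops.append(fam)
            rows.append(dos)
    if popmap is not None:
        pops = _check_samples(samples, popmap)
    else:
        pops = ped_pops
    dosage = (np.array(rows, dtype=np.int8) if rows
              else np.empty((0, len(loci)), dtype=np.int8))
    return GenotypeMatrix(samples=samples, populations=pops, loci=loci, dosage=dosage)


def read_genotypes(path, format: str, popmap: PopulationMap | None = None) -> GenotypeMatrix:
    """Dispatch on ``format`` in {'vcf', 'plink-text'}."""
    if format == "vcf":
        return read_vcf(path, popmap)
    if format == "plink-text":
        return read_plink(path, popmap)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(G: GenotypeMatrix, path, format: str) -> None:
    if format == "vcf":
        write_vcf(G, path)
    elif format == "plink-text":
        write_plink(G, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
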