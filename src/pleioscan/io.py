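"""Readers and writers for the study's on-disk formats.

Formats are deliberately plain: VCF 4.2 for genotypes (biallelic, GT only),
tab-separated text for summary statistics, abundances, covariates, gene
coordinates and PPI edges, GMT for annotation sets, JSON for the simulation
truth manifest.  Every writer round-trips losslessly through the matching
reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z", "N", "FREQ"]
GENE_COLUMNS = ["GENE", "CHR", "START", "END"]
PPI_COLUMNS = ["SYMBOL_A", "SYMBOL_B", "EVIDENCE_TYPE"]


@dataclass
class GenotypePanel:
    """A biallelic genotype matrix with SNP metadata.

    ``dosages`` is samples x SNPs, int8, counting copies of A1 (the effect /
    ALT allele).  ``snps`` has columns SNP, CHR, BP, A1, A2 aligned to the
    dosage columns.
    """

    snps: pd.DataFrame
    dosages: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError("dosage columns do not match SNP table")
        if not self.samples:
            self.samples = [f"S{i}" for i in range(self.dosages.shape[0])]
        if self.snps["SNP"].duplicated().any():
            raise ValueError("duplicate SNP identifiers in panel")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages (float64, cached); monomorphic SNPs become 0."""
        cached = getattr(self, "_std_cache", None)
        if cached is None:
            x = self.dosages.astype(np.float64)
            x -= x.mean(axis=0)
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
            cached = x / sd
            object.__setattr__(self, "_std_cache", cached)
        return cached

    def index_of(self, snp_ids) -> np.ndarray:
        pos = pd.Index(self.snps["SNP"])
        idx = pos.get_indexer(list(snp_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"SNPs absent from panel: {missing[:5]}")
        return idx


def write_vcf(panel: GenotypePanel, path: str | Path) -> Path:
    """Write a minimal VCF 4.2 with GT-only genotype fields."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(panel.snps["CHR"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        gt_codes = np.array(["0/0", "0/1", "1/1"])
        for j, row in enumerate(panel.snps.itertuples(index=False)):
            gts = gt_codes[panel.dosages[:, j]]
            fh.write(
                f"{row.CHR}\t{row.BP}\t{row.SNP}\t{row.A2}\t{row.A1}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    return path


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a biallelic VCF into a GenotypePanel (dosage of the ALT allele)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        meta.append((var.ID, str(var.CHROM), int(var.POS), var.ALT[0], var.REF))
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(var.gt_types)
        dos = np.where(gt == 3, 2, gt).astype(np.int8)
        dos[gt == 2] = -1
        cols.append(dos)
    snps = pd.DataFrame(meta, columns=["SNP", "CHR", "BP", "A1", "A2"])
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0), np.int8)
    return GenotypePanel(snps=snps, dosages=dosages, samples=samples)


def write_sumstats(df: pd.DataFrame, path: str | Path) -> Path:
    cols = [c for c in SUMSTATS_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)
    return Path(path)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
    missing = {"SNP", "A1", "A2", "Z", "N"} - set(df.columns)
    if missing:
        raise ValueError(f"sumstats file {path} lacks required columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index)
    return Path(path)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_gene_coords(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"GENE": str, "CHR": str})
    if list(df.columns[:4]) != GENE_COLUMNS:
        raise ValueError(f"gene coordinate file must have columns {GENE_COLUMNS}")
    return df


def write_gmt(sets: dict[str, list[str]], path: str | Path, descriptions: dict[str, str] | None = None) -> Path:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")
    return Path(path)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            sets[parts[0]] = [p for p in parts[2:] if p]
    return sets


def read_ppi(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PPI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"PPI file lacks columns {sorted(missing)}")
    return df[PPI_COLUMNS]


def write_json(obj, path: str | Path) -> Path:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonable)
    return Path(path)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
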