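"""Reading and writing genotype panels.

Supported encodings:

* **VCF 4.2** (uncompressed or bgzipped; only the GT field is consumed,
  phased and unphased calls both accepted). SNP ids are taken from the ID
  column using the ``<locus>_<offset>`` convention of ddRAD tag catalogs;
  records without an ID fall back to ``chrom:pos``.
* **Genotype TSV**: header row of snp_ids, first column the sample id, cells
  coded 0/1/2/NA (alt-allele dosage). An optional ``<path>.loci.tsv`` sidecar
  (columns snp_id, locus_id, chrom, pos) makes the TSV round trip lossless;
  without it chrom/pos are synthesized from the SNP order.
* **Popmap TSV** (Stacks dialect): two columns, sample TAB population, no
  header.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import MISSING, GenotypePanel, PanelError


class PopmapError(ValueError):
    """A sample in the genotype source has no popmap entry (or vice versa)."""


class GenotypeParseError(ValueError):
    """Malformed genotype record, reported with its location."""


def read_popmap(path: str | os.PathLike) -> pd.Series:
    """Read a Stacks-style popmap (sample TAB population, no header)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise PopmapError(f"popmap {path} must have two tab-separated columns")
    return pd.Series(df[1].values, index=df[0].values, name="population")


def write_popmap(populations: pd.Series, path: str | os.PathLike) -> None:
    pd.DataFrame({0: populations.index, 1: populations.values}).to_csv(
        path, sep="\t", header=False, index=False
    )


def _locus_from_snp_id(snp_id: str) -> str:
    """ddRAD convention: snp_id '<tag>_<column>' belongs to tag '<tag>'."""
    if "_" in snp_id:
        return snp_id.rsplit("_", 1)[0]
    return snp_id


def read_panel(
    genotype_source: str | os.PathLike,
    popmap: str | os.PathLike,
    *,
    on_multiallelic: str = "skip",
) -> GenotypePanel:
    """Read a genotype panel (VCF or TSV, chosen by extension) plus popmap.

    Parameters
    ----------
    on_multiallelic
        ``"skip"`` drops multi-allelic VCF records, ``"error"`` raises.
    """
    path = Path(genotype_source)
    pops = read_popmap(popmap)
    suffixes = "".join(path.suffixes).lower()
    if ".vcf" in suffixes:
        panel = _read_vcf(path, on_multiallelic=on_multiallelic)
    else:
        panel = _read_tsv(path)
    missing = [s for s in panel.samples if s not in pops.index]
    if missing:
        raise PopmapError(
            f"sample(s) {missing[:5]} present in {path.name} but absent from popmap"
        )
    return GenotypePanel(
        samples=panel.samples,
        populations=pops.loc[panel.samples],
        loci=panel.loci,
        genotypes=panel.genotypes,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

# cyvcf2 gt_types: 0=HOM_REF 1=HET 2=UNKNOWN 3=HOM_ALT
_GT_TYPE_TO_DOSAGE = np.array([0, 1, MISSING, 2], dtype=np.int8)


def _read_vcf(path: Path, *, on_multiallelic: str = "skip") -> GenotypePanel:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    loci: list[tuple[str, str, str, int]] = []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            if on_multiallelic == "error":
                raise GenotypeParseError(
                    f"{path.name} record {i + 1} ({var.CHROM}:{var.POS}) is "
                    f"multi-allelic"
                )
            continue
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append((_locus_from_snp_id(snp_id), snp_id, var.CHROM, var.POS))
        rows.append(_GT_TYPE_TO_DOSAGE[var.gt_types])
    vcf.close()
    if not rows:
        raise GenotypeParseError(f"no biallelic SNP records in {path}")
    genotypes = np.stack(rows, axis=1)
    loci_df = pd.DataFrame(loci, columns=["locus_id", "snp_id", "chrom", "pos"])
    pops = pd.Series(["unassigned"] * len(samples), index=samples)
    return GenotypePanel(samples=samples, populations=pops, loci=loci_df, genotypes=genotypes)


def write_vcf(panel: GenotypePanel, path: str | os.PathLike) -> None:
    """Write a minimal VCF 4.2 with GT only ('./.' for missing)."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    contigs = list(dict.fromkeys(panel.loci["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=radpop\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        loci = panel.loci
        G = panel.genotypes
        for j in range(panel.n_loci):
            calls = "\t".join(gt_strings[int(g)] for g in G[:, j])
            fh.write(
                f"{loci.at[j, 'chrom']}\t{int(loci.at[j, 'pos'])}\t"
                f"{loci.at[j, 'snp_id']}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def _read_tsv(path: Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    snp_ids = [str(c) for c in df.columns]
    geno = np.full(df.shape, MISSING, dtype=np.int8)
    values = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            v = values[i, j]
            if v is None or (isinstance(v, float) and np.isnan(v)) or v in ("NA", "", "."):
                continue
            if v not in ("0", "1", "2"):
                raise GenotypeParseError(
                    f"{path.name} line {i + 2}, column {snp_ids[j]}: "
                    f"invalid genotype code {v!r}"
                )
            geno[i, j] = int(v)
    sidecar = Path(str(path) + ".loci.tsv")
    if sidecar.exists():
        loci = pd.read_csv(sidecar, sep="\t", dtype={"pos": int})
        loci = loci.set_index("snp_id").loc[snp_ids].reset_index()
        loci = loci[["locus_id", "snp_id", "chrom", "pos"]]
    else:
        loci = pd.DataFrame(
            {
                "locus_id": [_locus_from_snp_id(s) for s in snp_ids],
                "snp_id": snp_ids,
                "chrom": "1",
                "pos": np.arange(1, len(snp_ids) + 1),
            }
        )
    samples = [str(s) for s in df.index]
    pops = pd.Series(["unassigned"] * len(samples), index=samples)
    return GenotypePanel(samples=samples, populations=pops, loci=loci, genotypes=geno)


def write_tsv(
    panel: GenotypePanel, path: str | os.PathLike, *, loci_sidecar: bool = True
) -> None:
    """Write the genotype TSV dialect (and by default its loci sidecar)."""
    df = pd.DataFrame(
        panel.genotypes.astype(object), index=panel.samples, columns=panel.snp_ids
    )
    df = df.where(panel.genotypes != MISSING, "NA")
    df.index.name = "sample"
    df.to_csv(path, sep="\t")
    if loci_sidecar:
        panel.loci[["snp_id", "locus_id", "chrom", "pos"]].to_csv(
            Path(str(path) + ".loci.tsv"), sep="\t", index=False
        )
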