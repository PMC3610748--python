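"""Readers and writers for genotype, phenotype and gene-map files.

Formats:

* Genotypes: VCF 4.x (GT field, biallelic sites) read through ``cyvcf2``, or a
  plain genotype TSV whose header row is ``sample_id`` followed by SNP ids and
  whose cells are alt-allele counts in {0,1,2,NA}.
* Phenotypes: TSV with columns ``sample_id, status, zd, zmd`` (``NA`` allowed
  for the z-scores; controls are expected to have none).
* Gene map: TSV with columns ``snp_id, gene, chromosome, position``.

After loading, genotype codes always count the combined-sample minor allele.
"""

from __future__ import annotations

import json

from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    DataError,
    Dataset,
    SampleRecord,
    SnpAnnotation,
    recode_to_minor,
)

NA_STRINGS = {"", "NA", "nan", "NaN", ".", "None"}

#: Fixed float format used by every writer so identical runs are byte-identical.
FLOAT_FORMAT = "%.10g"


def _parse_optional_float(text: str) -> Optional[float]:
    text = text.strip()
    if text in NA_STRINGS:
        return None
    return float(text)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_vcf_genotypes(path: str) -> tuple[list[str], list[dict], np.ndarray]:
    """Read a biallelic VCF into (sample ids, per-site records, alt-count codes)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    records: list[dict] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise DataError(
                f"{path}: site {var.CHROM}:{var.POS} ({var.ID}) is not biallelic"
            )
        codes = np.full(len(sample_ids), MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                codes[i] = a + b
        records.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chromosome": var.CHROM,
                "position": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
        rows.append(codes)
    if not records:
        raise DataError(f"{path}: no variant records")
    return sample_ids, records, np.array(rows, dtype=np.int8).T


def read_tsv_genotypes(path: str) -> tuple[list[str], list[str], np.ndarray]:
    """Read the genotype TSV alternative (header of SNP ids, one row per sample)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "sample_id":
            raise DataError(f"{path}: line 1: first column must be 'sample_id'")
        snp_ids = header[1:]
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise DataError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            sample_ids.append(parts[0])
            row = []
            for cell in parts[1:]:
                if cell in NA_STRINGS:
                    row.append(MISSING)
                else:
                    code = int(cell)
                    if code not in (0, 1, 2):
                        raise DataError(
                            f"{path}: line {lineno}: genotype code {cell!r} not in 0/1/2/NA"
                        )
                    row.append(code)
            rows.append(row)
    if not rows:
        raise DataError(f"{path}: no sample rows")
    return sample_ids, snp_ids, np.array(rows, dtype=np.int8)


def read_phenotypes(path: str) -> dict[str, SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"sample_id", "status"}
    if not needed.issubset(df.columns):
        raise DataError(f"{path}: phenotype TSV must have columns sample_id, status")
    records: dict[str, SampleRecord] = {}
    for i, row in df.iterrows():
        sid = row["sample_id"]
        if sid in records:
            raise DataError(f"{path}: line {i + 2}: duplicate sample id {sid!r}")
        records[sid] = SampleRecord(
            sample_id=sid,
            status=row["status"],
            zd=_parse_optional_float(row.get("zd", "NA")),
            zmd=_parse_optional_float(row.get("zmd", "NA")),
        )
    return records


def read_gene_map(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene": str, "chromosome": str})
    needed = {"snp_id", "gene", "chromosome", "position"}
    if not needed.issubset(df.columns):
        raise DataError(
            f"{path}: gene map TSV must have columns snp_id, gene, chromosome, position"
        )
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise DataError(f"{path}: duplicate snp_id {dup!r} (one gene per SNP)")
    return df


def load_dataset(genotype_path: str, phenotype_path: str, genemap_path: str) -> Dataset:
    """Assemble a :class:`Dataset` from genotype + phenotype + gene-map files.

    The genotype file may be VCF (``.vcf``) or the genotype TSV; alt/coded
    allele counts are recoded so codes count the combined-sample minor allele.
    """
    if genotype_path.endswith((".vcf", ".vcf.gz")):
        sample_ids, var_records, codes = read_vcf_genotypes(genotype_path)
        snp_ids = [r["snp_id"] for r in var_records]
        allele_pairs = [(r["ref"], r["alt"]) for r in var_records]
    else:
        sample_ids, snp_ids, codes = read_tsv_genotypes(genotype_path)
        var_records = None
        allele_pairs = [("A", "B")] * len(snp_ids)  # TSV carries no allele letters

    phenos = read_phenotypes(phenotype_path)
    unknown = [s for s in phenos if s not in set(sample_ids)]
    if unknown:
        raise DataError(
            f"{phenotype_path}: unknown sample {unknown[0]!r} not present in genotypes"
        )
    missing_pheno = [s for s in sample_ids if s not in phenos]
    if missing_pheno:
        raise DataError(
            f"{genotype_path}: sample {missing_pheno[0]!r} has no phenotype record"
        )

    gmap = read_gene_map(genemap_path).set_index("snp_id")
    absent = [s for s in snp_ids if s not in gmap.index]
    if absent:
        raise DataError(f"{genemap_path}: SNP {absent[0]!r} absent from gene map")

    codes, allele_pairs = recode_to_minor(codes, allele_pairs)

    snps = []
    for j, sid in enumerate(snp_ids):
        row = gmap.loc[sid]
        if var_records is not None:
            chrom = var_records[j]["chromosome"]
            pos = int(var_records[j]["position"])
        else:
            chrom = str(row["chromosome"])
            pos = int(row["position"])
        snps.append(
            SnpAnnotation(
                snp_id=sid,
                gene=str(row["gene"]),
                chromosome=chrom,
                position=pos,
                alleles=allele_pairs[j],
            )
        )

    gene_map: dict[str, list[int]] = {}
    for j, ann in enumerate(snps):
        gene_map.setdefault(ann.gene, []).append(j)
    for gene in gene_map:
        gene_map[gene].sort(key=lambda j: snps[j].position)

    samples = [phenos[s] for s in sample_ids]
    return Dataset(genotypes=codes, samples=samples, snps=snps, gene_map=gene_map)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_vcf(dataset_like: dict, path: str) -> None:
    """Write a minimal VCF 4.2 from raw (pre-recode) simulation output.

    ``dataset_like`` needs keys: sample_ids, snp_ids, chromosomes, positions,
    ref, alt, codes (alt-allele counts, MISSING for no-call).
    """
    codes = dataset_like["codes"]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted(set(dataset_like["chromosomes"]), key=str)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset_like["sample_ids"])
            + "\n"
        )
        order = sorted(
            range(len(dataset_like["snp_ids"])),
            key=lambda j: (str(dataset_like["chromosomes"][j]), dataset_like["positions"][j]),
        )
        for j in order:
            gts = "\t".join(gt_map[int(c)] for c in codes[:, j])
            fh.write(
                f"{dataset_like['chromosomes'][j]}\t{dataset_like['positions'][j]}\t"
                f"{dataset_like['snp_ids'][j]}\t{dataset_like['ref'][j]}\t"
                f"{dataset_like['alt'][j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_phenotypes(samples: list[SampleRecord], path: str) -> None:
    def fmt(x: Optional[float]) -> str:
        return "NA" if x is None else FLOAT_FORMAT % x

    with open(path, "w") as fh:
        fh.write("sample_id\tstatus\tzd\tzmd\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.status}\t{fmt(s.zd)}\t{fmt(s.zmd)}\n")


def write_gene_map(snps: list[SnpAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tgene\tchromosome\tposition\n")
        for s in snps:
            fh.write(f"{s.snp_id}\t{s.gene}\t{s.chromosome}\t{s.position}\n")


def write_genotype_tsv(dataset: Dataset, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(dataset.snp_ids) + "\n")
        for i, s in enumerate(dataset.samples):
            cells = [
                "NA" if c == MISSING else str(int(c)) for c in dataset.genotypes[i]
            ]
            fh.write(s.sample_id + "\t" + "\t".join(cells) + "\n")


def write_table(df: pd.DataFrame, path: str) -> None:
    """TSV writer with a fixed float format (deterministic bytes)."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="NA")


def write_json(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
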