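"""Readers and writers for the pipeline's on-disk formats.

The synthetic generators emit the same formats the analysis reads back:
GTF exon annotations, VCF genotypes, QTL-style phenotype BED (anchored
at the gene TSS, 0-based half-open), TSV tables for junction counts,
covariates and summary statistics, CA-only PDB models with pLDDT in the
B-factor column, and AlphaFold-style PAE JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import gffutils
import numpy as np
import pandas as pd
import pysam
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .containers import GenotypeMatrix, JunctionCounts, PsiPhenotype, StructureModel
from .structure import AA1_TO_3, AA3_TO_1

__all__ = [
    "write_gtf", "read_gtf",
    "write_vcf", "read_vcf",
    "write_phenotype_bed", "read_phenotype_bed",
    "write_junction_counts", "read_junction_counts",
    "write_table", "read_covariates", "read_sumstats",
    "read_ancestral_map",
    "write_credible_sets",
    "write_pdb_model", "read_pdb_model",
    "write_pae_json", "read_pae_json",
    "read_fasta", "write_fasta",
]


# --- GTF ---------------------------------------------------------------

def write_gtf(exons: pd.DataFrame, path: str | Path) -> None:
    """Write an exon annotation table as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for exon_id, row in exons.sort_values(["chrom", "start"]).iterrows():
            attrs = f'gene_id "{row["gene_id"]}"; exon_id "{exon_id}";'
            fh.write(
                "\t".join(
                    [
                        str(row["chrom"]),
                        "psiqtl",
                        "exon",
                        str(int(row["start"])),
                        str(int(row["end"])),
                        ".",
                        row["strand"],
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Read exon records from a GTF into the annotation-table schema.

    Ordinals are recomputed 5'->3' per gene (strand-aware), terminal
    flags mark the first and last ordinal, and the gene TSS is the
    5'-most coordinate of the gene on its strand.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    for feat in db.features_of_type("exon"):
        rows.append(
            {
                "exon_id": feat.attributes["exon_id"][0],
                "gene_id": feat.attributes["gene_id"][0],
                "chrom": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand,
            }
        )
    table = pd.DataFrame(rows).set_index("exon_id")
    parts = []
    for gene, grp in table.groupby("gene_id"):
        asc = grp["strand"].iloc[0] == "+"
        grp = grp.sort_values("start", ascending=asc)
        grp = grp.assign(
            ordinal=np.arange(1, len(grp) + 1),
            n_exons=len(grp),
        )
        grp["is_terminal"] = (grp["ordinal"] == 1) | (grp["ordinal"] == len(grp))
        grp["gene_tss"] = grp["start"].min() if asc else grp["end"].max()
        parts.append(grp)
    out = pd.concat(parts)
    out["length_bp"] = out["end"] - out["start"] + 1
    return out


# --- VCF ---------------------------------------------------------------

def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call genotypes as an uncompressed VCF."""
    samples = list(geno.samples)
    contigs = sorted(geno.variants["chrom"].unique())
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        order = geno.variants.sort_values(["chrom", "pos"]).index
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for vid in order:
            row = geno.variants.loc[vid]
            dos = geno.dosages.loc[vid]
            gts = [gt_map.get(float(d), "./.") if not np.isnan(d) else "./." for d in dos]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['ref']}\t{row['alt']}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic genotypes from a VCF into a dosage matrix."""
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    var_rows, dos_rows, ids = [], [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        vid = rec.id or f"{rec.chrom}_{rec.pos}_{rec.ref}_{rec.alts[0]}"
        var_rows.append(
            {"variant_id": vid, "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alts[0]}
        )
        dos = []
        for s in samples:
            gt = rec.samples[s]["GT"]
            if gt is None or any(a is None for a in gt):
                dos.append(np.nan)
            else:
                dos.append(float(sum(gt)))
        dos_rows.append(dos)
        ids.append(vid)
    variants = pd.DataFrame(var_rows).set_index("variant_id")
    dosages = pd.DataFrame(dos_rows, index=pd.Index(ids, name="variant_id"), columns=samples)
    return GenotypeMatrix(variants=variants, dosages=dosages)


# --- phenotype BED -----------------------------------------------------

def write_phenotype_bed(
    pheno: PsiPhenotype,
    path: str | Path,
    which: str = "psi",
) -> None:
    """Write the phenotype as a QTL-style BED anchored at the gene TSS.

    Every exon row carries the TSS of its gene as the (0-based
    half-open) start/end interval, so the cis window is anchored at the
    gene rather than the exon; the group column enables gene-grouped
    permutation downstream.
    """
    mat = pheno.psi if which == "psi" else pheno.normalized
    if mat is None:
        raise ValueError(f"phenotype has no '{which}' matrix")
    with open(path, "w") as fh:
        fh.write("#chr\tstart\tend\texon_id\tgene_id\tstrand\t" + "\t".join(mat.columns) + "\n")
        for exon_id in mat.index:
            gene = pheno.gene_group.loc[exon_id]
            tss = int(pheno.tss_anchor.loc[gene])
            vals = "\t".join(
                "NA" if np.isnan(v) else f"{v:.6g}" for v in mat.loc[exon_id]
            )
            fh.write(f"chr1\t{tss - 1}\t{tss}\t{exon_id}\t{gene}\t+\t{vals}\n")


def read_phenotype_bed(path: str | Path) -> PsiPhenotype:
    df = pd.read_csv(path, sep="\t")
    df.columns = [df.columns[0].lstrip("#")] + list(df.columns[1:])
    sample_cols = df.columns[6:]
    psi = df.set_index("exon_id")[sample_cols].astype(float)
    gene_group = df.set_index("exon_id")["gene_id"]
    tss = (
        df[["gene_id", "end"]].drop_duplicates("gene_id").set_index("gene_id")["end"]
    )
    return PsiPhenotype(psi=psi, gene_group=gene_group, tss_anchor=tss)


# --- TSV tables --------------------------------------------------------

def write_junction_counts(jc: JunctionCounts, path: str | Path) -> None:
    """Long-format TSV: exon_id, sample, incl_left, incl_right, excl."""
    long = pd.concat(
        {
            "incl_left": jc.incl_left.stack(),
            "incl_right": jc.incl_right.stack(),
            "excl": jc.excl.stack(),
        },
        axis=1,
    )
    long.index.names = ["exon_id", "sample"]
    long.reset_index().to_csv(path, sep="\t", index=False)


def read_junction_counts(path: str | Path) -> JunctionCounts:
    long = pd.read_csv(path, sep="\t")
    piv = {
        c: long.pivot(index="exon_id", columns="sample", values=c)
        for c in ("incl_left", "incl_right", "excl")
    }
    return JunctionCounts(**piv)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Summary-statistic TSV: variant_id, beta, se, n, freq[, trait]."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"beta", "se"}
    if not required <= set(df.columns):
        raise ValueError(f"summary statistics need columns {sorted(required)}")
    return df


def read_ancestral_map(path: str | Path) -> pd.Series:
    """TSV (variant_id, ancestral_base) -> Series."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]]


def write_credible_sets(sets, path: str | Path) -> None:
    """TSV with one row per credible-set member: set_id, variant, pip."""
    rows = []
    for k, cs in enumerate(sets):
        for v, p in zip(cs.variants, cs.pip):
            rows.append({"set_id": k, "exon_id": cs.exon_id, "variant_id": v, "pip": p})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- structures --------------------------------------------------------

def write_pdb_model(model: StructureModel, path: str | Path) -> None:
    """Write a CA-only model with pLDDT in the B-factor column."""
    n = len(model)
    atoms = struc.AtomArray(n)
    atoms.coord = model.coords.astype(np.float32)
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.array([AA1_TO_3.get(a, "UNK") for a in model.sequence])
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.full(n, False)
    atoms.set_annotation("b_factor", model.plddt.astype(np.float32))
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_pdb_model(path: str | Path) -> StructureModel:
    """Read a CA-only model; pLDDT is taken from the B-factor column."""
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, extra_fields=["b_factor"])
    ca = atoms[atoms.atom_name == "CA"]
    seq = "".join(AA3_TO_1.get(rn, "X") for rn in ca.res_name)
    return StructureModel(
        coords=np.asarray(ca.coord, dtype=float),
        sequence=seq,
        plddt=np.asarray(ca.b_factor, dtype=float),
    )


def write_pae_json(pae: np.ndarray, path: str | Path) -> None:
    """AlphaFold-style JSON with a row-major PAE matrix in angstrom."""
    payload = {
        "predicted_aligned_error": np.asarray(pae, dtype=float).round(4).tolist(),
        "max_predicted_aligned_error": float(np.asarray(pae).max()),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_pae_json(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, list):  # AlphaFold DB wraps the object in a list
        payload = payload[0]
    if "predicted_aligned_error" in payload:
        return np.asarray(payload["predicted_aligned_error"], dtype=float)
    raise ValueError("no predicted_aligned_error field in PAE JSON")


# --- FASTA -------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
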