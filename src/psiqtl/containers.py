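"""Core in-memory containers shared across the pipeline.

Tabular data lives in pandas objects with documented schemas; light
dataclasses bundle the pieces that travel together (counts, phenotypes,
genotypes, structure pairs).  All exon/gene annotation tables use GTF
conventions: 1-based inclusive coordinates, strand in {"+", "-"}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Required columns of an exon annotation table (index: exon_id).
EXON_TABLE_COLUMNS = [
    "gene_id",
    "chrom",
    "start",
    "end",
    "strand",
    "ordinal",
    "n_exons",
    "is_terminal",
    "gene_tss",
]


def validate_exon_table(exons: pd.DataFrame) -> pd.DataFrame:
    """Check an exon annotation table against its schema invariants."""
    missing = [c for c in EXON_TABLE_COLUMNS if c not in exons.columns]
    if missing:
        raise ValueError(f"exon table missing columns: {missing}")
    if (exons["start"] > exons["end"]).any():
        raise ValueError("exon start > end")
    for gene, grp in exons.groupby("gene_id"):
        if grp["ordinal"].duplicated().any():
            raise ValueError(f"duplicate exon ordinal in gene {gene}")
    return exons


@dataclass
class JunctionCounts:
    """Split-read evidence per exon x sample.

    ``incl_left``/``incl_right`` count reads supporting the upstream and
    downstream inclusion junctions; ``excl`` counts reads splicing over
    the exon.  All three frames share index (exon_id) and columns
    (sample ids).
    """

    incl_left: pd.DataFrame
    incl_right: pd.DataFrame
    excl: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("incl_left", "incl_right", "excl"):
            df = getattr(self, name)
            if not df.index.equals(self.incl_left.index) or not df.columns.equals(
                self.incl_left.columns
            ):
                raise ValueError("junction count frames are not aligned")
            if (df.to_numpy() < 0).any():
                raise ValueError(f"negative counts in {name}")

    @property
    def exons(self) -> pd.Index:
        return self.incl_left.index

    @property
    def samples(self) -> pd.Index:
        return self.incl_left.columns


@dataclass
class PsiPhenotype:
    """Exon-level percent-spliced-in phenotype.

    ``psi`` holds raw PSI in [0, 1] (NaN = not informative);
    ``normalized`` holds the rank-based inverse-normal transform used
    for QTL mapping.  ``gene_group`` maps exon_id -> gene_id and
    ``tss_anchor`` maps gene_id -> transcription start site, the anchor
    for the cis window.
    """

    psi: pd.DataFrame
    gene_group: pd.Series
    tss_anchor: pd.Series
    normalized: Optional[pd.DataFrame] = None
    filter_log: dict = field(default_factory=dict)

    @property
    def exons(self) -> pd.Index:
        return self.psi.index

    @property
    def samples(self) -> pd.Index:
        return self.psi.columns

    def subset(self, exon_ids) -> "PsiPhenotype":
        exon_ids = pd.Index(exon_ids)
        return PsiPhenotype(
            psi=self.psi.loc[exon_ids],
            gene_group=self.gene_group.loc[exon_ids],
            tss_anchor=self.tss_anchor,
            normalized=None if self.normalized is None else self.normalized.loc[exon_ids],
            filter_log=dict(self.filter_log),
        )


@dataclass
class GenotypeMatrix:
    """Biallelic variant dosages.

    ``variants``: DataFrame indexed by variant_id with columns chrom,
    pos, ref, alt.  ``dosages``: variant x sample frame of {0, 1, 2}
    with NaN for missing calls.
    """

    variants: pd.DataFrame
    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.variants.index.equals(self.dosages.index):
            raise ValueError("variant table and dosage rows are not aligned")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be in {0,1,2} or missing")

    @property
    def samples(self) -> pd.Index:
        return self.dosages.columns

    def alt_freq(self) -> pd.Series:
        """Alt-allele frequency from non-missing dosages."""
        return self.dosages.mean(axis=1, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        af = self.alt_freq()
        return np.minimum(af, 1.0 - af)


@dataclass
class SimTruth:
    """Ground truth recorded by the simulators (per-gene table)."""

    table: pd.DataFrame  # index gene_id: causal_variant, causal_exon, true_beta, true_delta_psi
    shared_gwas_causal: Optional[bool] = None


@dataclass
class StructureModel:
    """CA-only structure model with per-residue confidence."""

    coords: np.ndarray  # (L, 3) angstrom
    sequence: str
    plddt: np.ndarray  # (L,), 0-100

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        L = len(self.sequence)
        if self.coords.shape != (L, 3) or self.plddt.shape != (L,):
            raise ValueError("structure model arrays are not aligned with sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class IsoformStructurePair:
    """Spliced-in vs spliced-out structure models of one protein.

    ``exon_residues`` is the 1-based inclusive residue interval of the
    skipped exon in spliced-in numbering.  PAE matrices are square,
    row-major, in angstrom, matching their model lengths.
    """

    spliced_in: StructureModel
    spliced_out: StructureModel
    pae_in: np.ndarray
    pae_out: np.ndarray
    exon_residues: tuple[int, int]

    def __post_init__(self) -> None:
        self.pae_in = np.asarray(self.pae_in, dtype=float)
        self.pae_out = np.asarray(self.pae_out, dtype=float)
        li, lo = len(self.spliced_in), len(self.spliced_out)
        if self.pae_in.shape != (li, li):
            raise ValueError("pae_in shape does not match spliced-in length")
        if self.pae_out.shape != (lo, lo):
            raise ValueError("pae_out shape does not match spliced-out length")
        s, e = self.exon_residues
        if not (1 <= s <= e <= li):
            raise ValueError("exon interval outside spliced-in numbering")
        if lo != li - (e - s + 1):
            raise ValueError("spliced-out length inconsistent with exon deletion")

    @property
    def exon_length(self) -> int:
        s, e = self.exon_residues
        return e - s + 1


@dataclass
class ExonProteinMap:
    """Best translated-alignment hit of an exon onto a protein."""

    exon_id: str
    protein_id: str
    aa_start: int  # 1-based inclusive on the protein
    aa_end: int
    frame: int  # 0..2 forward frame offset
    bit_score: float
    e_value: float
    peptide: str  # aligned exon peptide (query segment)
    in_target_isoform: bool = True
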