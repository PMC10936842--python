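"""Protein-structural consequences of exon skipping.

Maps exon nucleotide sequences onto protein sequences by translated
local alignment, computes residue-level structural features (solvent
accessibility, AlphaFold-style pLDDT) and exon summaries, and compares
spliced-in vs spliced-out structure models with two metrics:

* the element-wise RMS difference between the predicted-aligned-error
  (PAE) matrices after deleting the exon rows/columns from the
  spliced-in matrix — sensitive to domain rearrangement;
* the Kabsch superposition RMSD over shared CA atoms with iterative
  outlier rejection — sensitive to topological displacement.

The exon->protein mapping translates all three forward frames,
Smith-Waterman-aligns each peptide against the candidate proteins
(BLOSUM62, BLAST-style affine gaps), and converts the raw score to an
e-value with gapped Karlin-Altschul constants.  Hits are kept only when
the e-value is at most ``e_max`` and the best hit lies in the exon's
own gene product, mirroring a conservative translated-BLAST protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from scipy.spatial import cKDTree

from .containers import ExonProteinMap, IsoformStructurePair, StructureModel

__all__ = [
    "map_exon_to_protein",
    "shrake_rupley_sasa",
    "relative_accessibility",
    "summarize_residue_features",
    "pae_distance",
    "superpose_rmsd",
    "kabsch",
    "ResidueFeatureSummary",
]

# Karlin-Altschul constants for gapped BLOSUM62 (open 11 / extend 1)
KA_LAMBDA = 0.267
KA_K = 0.041

MAX_MODEL_RESIDUES = 1300

#: Theoretical maximum accessible surface areas per residue (A^2),
#: Tien et al. 2013, used to convert SASA to relative accessibility.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: Van der Waals radii (A) by element; unknown elements fall back to 1.9
#: (a generous carbon-like radius, also used for CA-only pseudo-atoms).
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2, "P": 1.8, "SE": 1.9}
DEFAULT_RADIUS = 1.9

RSA_BURIED_THRESHOLD = 25.0

DOMAIN_SIGNAL_CATEGORIES = {
    "DOMAIN", "SIGNAL", "TOPOLOGY", "TRANSMEMBRANE", "MOTIF", "TOPO_DOM",
    "ACT_SITE", "MOD_RES", "REGION", "REPEAT", "TRANSMEM", "BINDING",
    "NP_BIND", "COILED", "DISULFID", "CARBOHYD", "DNA_BIND", "CROSSLNK",
    "ZN_FING", "METAL", "SITE", "INTRAMEM", "LIPID",
}


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST "open 11 / extend 1": a length-k gap costs 11 + k
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


def map_exon_to_protein(
    exon_id: str,
    exon_nt: str,
    proteins: Mapping[str, str],
    target_protein: str,
    e_max: float = 0.001,
) -> Optional[ExonProteinMap]:
    """Map an exon nucleotide sequence to a residue interval of a protein.

    All three forward reading frames are translated and locally aligned
    against every candidate protein; the best hit (smallest e-value,
    ties broken by score) survives only if its e-value is at most
    ``e_max`` **and** it falls in ``target_protein`` — an exon aligning
    best to another gene's product is discarded as unmappable.
    Returns ``None`` when no acceptable hit exists.
    """
    exon_nt = exon_nt.upper().replace("U", "T")
    if len(exon_nt) < 9:
        raise ValueError(f"exon {exon_id} shorter than 9 nt")
    aligner = _make_aligner()
    db_len = sum(len(s) for s in proteins.values())
    best = None  # (e_value, -score, protein_id, frame, aln, peptide)
    for frame in range(3):
        sub = exon_nt[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        if len(sub) < 9:
            continue
        peptide = str(Seq(sub).translate())
        if set(peptide) <= {"*"}:
            continue
        for pid, pseq in proteins.items():
            try:
                aln = aligner.align(pseq, peptide)[0]
            except (IndexError, ValueError):
                continue
            score = float(aln.score)
            if score <= 0:
                continue
            e_value = KA_K * len(peptide) * db_len * math.exp(-KA_LAMBDA * score)
            key = (e_value, -score, pid)
            if best is None or key < best[:3]:
                best = (e_value, -score, pid, frame, aln, peptide)
    if best is None:
        return None
    e_value, neg_score, pid, frame, aln, peptide = best
    if e_value > e_max:
        return None
    if pid != target_protein:
        return None
    t_blocks, q_blocks = aln.aligned
    aa_start = int(t_blocks[0][0]) + 1
    aa_end = int(t_blocks[-1][1])
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    bit_score = (KA_LAMBDA * (-neg_score) - math.log(KA_K)) / math.log(2.0)
    return ExonProteinMap(
        exon_id=exon_id,
        protein_id=pid,
        aa_start=aa_start,
        aa_end=aa_end,
        frame=frame,
        bit_score=float(bit_score),
        e_value=float(e_value),
        peptide=peptide[q_start:q_end],
        in_target_isoform=True,
    )


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    elements: Sequence[str],
    probe: float = 1.4,
    n_points: int = 100,
    radii: Optional[Mapping[str, float]] = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere sampling.

    Each atom's solvent sphere (vdW radius + probe) is sampled with a
    golden-spiral point set; the accessible area is the fraction of
    points outside every neighbor's solvent sphere times the full
    sphere area.  Returns an array of per-atom SASA in A^2.
    """
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[0]
    if n_atoms == 0:
        raise ValueError("no atoms")
    table = dict(VDW_RADII)
    if radii:
        table.update(radii)
    r = np.array([table.get(str(e).upper(), DEFAULT_RADIUS) for e in elements]) + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = r.max()
    sasa = np.zeros(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + r[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], r[i] + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > r[j] ** 2
        sasa[i] = 4.0 * np.pi * r[i] ** 2 * accessible.mean()
    return sasa


def relative_accessibility(
    sasa_per_atom: np.ndarray,
    residue_index: Sequence[int],
    residue_names: Sequence[str],
) -> pd.DataFrame:
    """Aggregate atom SASA to residues and normalize by theoretical maxima.

    ``residue_index`` assigns each atom to a residue slot; residue names
    are 3-letter codes.  RSA = 100 * SASA / maxASA; residues of unknown
    type get NaN RSA (flagged via the ``known`` column).  Residues with
    RSA below 25 are classified as buried.
    """
    residue_names = [str(n).upper() for n in residue_names]
    sums = np.zeros(len(residue_names))
    np.add.at(sums, np.asarray(residue_index, dtype=int), np.asarray(sasa_per_atom, dtype=float))
    out = pd.DataFrame(
        {"sasa": sums, "residue_name": residue_names},
        index=pd.RangeIndex(len(residue_names), name="residue"),
    )
    out["max_asa"] = out["residue_name"].map(MAX_ASA)
    out["known"] = out["max_asa"].notna()
    out["rsa"] = 100.0 * out["sasa"] / out["max_asa"]
    out["buried"] = out["rsa"] < RSA_BURIED_THRESHOLD
    return out


@dataclass
class ResidueFeatureSummary:
    """Exon-level summary of residue features (one table row per exon)."""

    exon_id: str
    protein_id: str
    aa_length: int
    rsa_q1: float
    plddt_q3: float
    pct_asn: float
    pct_cys: float
    has_domain_signal: bool
    loeuf: float = np.nan

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def summarize_residue_features(
    mapping: ExonProteinMap,
    rsa: Sequence[float],
    plddt: Sequence[float],
    features: Optional[pd.DataFrame] = None,
    loeuf: float = np.nan,
) -> ResidueFeatureSummary:
    """Summarize per-residue features over an exon's protein interval.

    ``rsa`` and ``plddt`` are full-protein per-residue vectors; the
    exon interval of ``mapping`` selects the slice.  Quantiles use
    linear interpolation between order statistics.  ``features`` is a
    UniProt-style interval table (columns protein_id, category, start,
    end, 1-based inclusive); a domain signal is present when the exon
    interval touches any annotated interval of a recognized category.
    """
    s, e = mapping.aa_start, mapping.aa_end
    if e < s:
        raise ValueError("empty exon interval")
    rsa = np.asarray(rsa, dtype=float)[s - 1 : e]
    plddt_arr = np.asarray(plddt, dtype=float)[s - 1 : e]
    if rsa.size == 0 or plddt_arr.size == 0:
        raise ValueError("exon interval outside the feature vectors")
    pep = mapping.peptide.upper()
    n_aa = len(pep) if pep else e - s + 1
    has_domain = False
    if features is not None and len(features):
        sub = features[features["protein_id"] == mapping.protein_id]
        for _, row in sub.iterrows():
            if str(row["category"]).upper() not in DOMAIN_SIGNAL_CATEGORIES:
                continue
            if row["start"] <= e and s <= row["end"]:
                has_domain = True
                break
    return ResidueFeatureSummary(
        exon_id=mapping.exon_id,
        protein_id=mapping.protein_id,
        aa_length=e - s + 1,
        rsa_q1=float(np.percentile(rsa[~np.isnan(rsa)], 25)) if (~np.isnan(rsa)).any() else np.nan,
        plddt_q3=float(np.percentile(plddt_arr, 75)),
        pct_asn=100.0 * pep.count("N") / n_aa,
        pct_cys=100.0 * pep.count("C") / n_aa,
        has_domain_signal=has_domain,
        loeuf=loeuf,
    )


def pae_distance(
    pair: IsoformStructurePair,
    normalized: bool = True,
) -> float:
    """Distance between the two isoforms' PAE matrices, in angstrom.

    The exon's rows and columns are deleted from the spliced-in matrix
    so both matrices index the shared residues; the distance is the
    element-wise root-mean-square difference (``normalized=True``) or
    the raw Frobenius norm.  The RMS form keeps values on the PAE scale
    and comparable across proteins of different length.
    """
    s, e = pair.exon_residues
    keep = np.ones(len(pair.spliced_in), dtype=bool)
    keep[s - 1 : e] = False
    aligned = pair.pae_in[np.ix_(keep, keep)]
    if aligned.shape != pair.pae_out.shape:
        raise ValueError(
            f"aligned PAE shape {aligned.shape} != spliced-out {pair.pae_out.shape}"
        )
    diff = aligned - pair.pae_out
    if normalized:
        return float(np.sqrt(np.mean(diff**2)))
    return float(np.linalg.norm(diff))


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares superposition of P onto Q.

    Returns (rotation, translation, rmsd) such that P @ R.T + t best
    matches Q; the rotation is proper (determinant +1).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise ValueError("need two aligned coordinate sets of >= 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def superpose_rmsd(
    pair: IsoformStructurePair,
    reject_sigma: float = 2.0,
    max_cycles: int = 5,
    return_details: bool = False,
):
    """Kabsch RMSD over shared residues with iterative outlier rejection.

    Residue correspondence is exact by construction: the spliced-out
    chain equals the spliced-in chain minus the exon.  After an initial
    superposition on all shared CA atoms, pairs deviating by more than
    ``reject_sigma`` times the current RMSD are discarded and the fit
    repeated (up to ``max_cycles`` cycles, never dropping below 3
    pairs), discounting segments genuinely displaced by the splice —
    the analogue of an "align"-style refinement in molecular viewers.
    """
    s, e = pair.exon_residues
    keep = np.ones(len(pair.spliced_in), dtype=bool)
    keep[s - 1 : e] = False
    P = pair.spliced_in.coords[keep]
    Q = pair.spliced_out.coords
    if P.shape != Q.shape:
        raise ValueError("shared-residue coordinate sets are not aligned")
    if P.shape[0] < 3:
        raise ValueError("fewer than 3 shared residues")
    active = np.ones(P.shape[0], dtype=bool)
    rmsd = np.inf
    for _ in range(max_cycles):
        R, t, rmsd = kabsch(P[active], Q[active])
        dev = np.linalg.norm(P @ R.T + t - Q, axis=1)
        new_active = dev <= max(reject_sigma * rmsd, 1e-9)
        new_active &= active
        if new_active.sum() < 3 or new_active.sum() == active.sum():
            break
        active = new_active
    if return_details:
        return rmsd, int(active.sum()), P.shape[0]
    return rmsd
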