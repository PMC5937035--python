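"""Normalization and transformation primitives for counts and TMT ratios.

Count normalization uses the median-of-ratios size factors standard for
bulk RNA-seq.  The variance-stabilized transform used downstream is a
shifted log of size-factor-normalized counts (``modlog``); every later
stage depends only on the contract "a stabilized gene x sample matrix",
not on the particular stabilizer.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import AbundanceMatrix, CountMatrix, ProteinQuant

log = logging.getLogger(__name__)


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For genes with nonzero counts in every sample, each sample's factor is
    the median of ``count / geometric mean across samples``.  Raises if no
    gene is expressed in all samples (a pseudocount fallback is then the
    caller's decision).
    """
    arr = counts.values.to_numpy(dtype=float)
    expressed = (arr > 0).all(axis=1)
    if not expressed.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; consider adding a "
            "pseudocount before computing size factors"
        )
    logs = np.log(arr[expressed])
    geo = logs.mean(axis=1, keepdims=True)
    factors = np.median(np.exp(logs - geo), axis=0)
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def fpkm(counts: CountMatrix, lengths: pd.Series | None = None) -> AbundanceMatrix:
    """Fragments per kilobase of transcript per million mapped reads.

    ``FPKM_gs = count_gs * 1e9 / (length_g * total_counts_s)``.
    """
    if lengths is None:
        if counts.gene_meta is None or "length_bp" not in counts.gene_meta:
            raise ValueError("gene lengths required (gene_meta.length_bp or lengths=)")
        lengths = counts.gene_meta["length_bp"]
    lengths = lengths.reindex(counts.gene_ids).astype(float)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all gene lengths must be positive")
    totals = counts.values.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValueError("zero library size in at least one sample")
    values = counts.values.div(lengths, axis=0).div(totals, axis=1) * 1e9
    return AbundanceMatrix(values, transform="fpkm")


def log2_fpkm(
    counts: CountMatrix, lengths: pd.Series | None = None, pseudo: float = 0.0
) -> AbundanceMatrix:
    """log2(FPKM + pseudo); with pseudo=0, zero counts map to -inf."""
    f = fpkm(counts, lengths)
    with np.errstate(divide="ignore"):
        values = np.log2(f.values + pseudo)
    return AbundanceMatrix(values, transform="log2fpkm")


def modlog(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> AbundanceMatrix:
    """Shifted log of size-factor-normalized counts.

    ``log2(count / size_factor + pseudocount)`` — the variance-stabilized
    stand-in consumed by every stage that expects a "stabilized matrix".
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(counts.sample_ids)
    values = np.log2(counts.values.div(factors, axis=1) + pseudocount)
    return AbundanceMatrix(values, transform="modlog")


def summarize_tmt(psm_records: pd.DataFrame) -> ProteinQuant:
    """Summarize PSM-level TMT reporter ratios to protein-level log2R.

    ``psm_records`` columns: ``peptide``, ``protein_id``, ``gene_id``,
    ``sample_id``, ``ratio`` (linear ratio vs the internal standard
    channel).  Peptides shared between gene symbols are discarded; per
    sample, PSM log2-ratios are median-centered to 0; the protein value is
    the median over its unique-peptide PSMs.  Proteins missing from some
    samples are flagged ``quantified_in_all=False``.
    """
    required = {"peptide", "protein_id", "gene_id", "sample_id", "ratio"}
    missing = required - set(psm_records.columns)
    if missing:
        raise ValueError(f"psm_records missing columns {sorted(missing)}")
    rec = psm_records.copy()
    if (rec["ratio"] <= 0).any():
        raise ValueError("TMT ratios must be positive")

    # peptides unique to one gene symbol only
    pep_genes = rec.groupby("peptide")["gene_id"].nunique()
    shared = pep_genes.index[pep_genes > 1]
    if len(shared):
        log.warning("dropping %d peptides shared between genes", len(shared))
        rec = rec[~rec["peptide"].isin(shared)]

    rec["log2r"] = np.log2(rec["ratio"])
    rec["log2r"] -= rec.groupby("sample_id")["log2r"].transform("median")

    with_pep = rec.groupby("protein_id")["peptide"].nunique()
    empty = with_pep.index[with_pep == 0]
    if len(empty):
        log.warning("excluding %d proteins with no unique peptides", len(empty))

    protein = (
        rec.groupby(["protein_id", "sample_id"])["log2r"].median().unstack("sample_id")
    )
    gene_map = rec.groupby("protein_id")["gene_id"].first()
    return ProteinQuant(protein, gene_map=gene_map.reindex(protein.index))
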