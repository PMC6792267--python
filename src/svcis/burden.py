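"""Per-sample structural-variation burden and its global molecular correlates.

Duplicate SSV calls (both breakpoint ends < 10 bp apart) are collapsed
before counting.  The *global SSV index* is the log2(count+1) of the
collapsed per-sample total, standardized to SD-from-median separately
within the low-pass and high-pass WGS strata, so that sequencing depth
(which drives SSV detection sensitivity) does not masquerade as biology.
Overall methylation is the per-sample median beta across all probes;
overall CNA is the SD of the gene-level log2 copy ratios.  Signature
scores average SD-from-median-normalized log2 expression over a gene set,
normalizing either across all samples or within each cancer type (the
convention for immune-infiltrate signatures).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genomic_model import BreakpointSet, DataError, log2p1
from .association import ScanConfig, scan_features

logger = logging.getLogger("svcis")

COLLAPSE_TOL = 10


def collapse_ssvs(bps: BreakpointSet, tol: int = COLLAPSE_TOL) -> BreakpointSet:
    """Merge near-duplicate calls per sample (both ends < ``tol`` apart).

    Two calls are near-duplicates iff they share the sample and both
    chromosome pairings and |pos1 - pos1'| < tol and |pos2 - pos2'| < tol
    (strict).  Single-linkage clusters are replaced by their
    lowest-coordinate member.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    df = bps.df
    n = len(df)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # candidate pairs: same (sample, chrom1, chrom2), pos1 within tol after sort
    order = df.sort_values(["sample_id", "chrom1", "chrom2", "pos1", "pos2"])
    idx = order.index.to_numpy()
    key = (order["sample_id"].astype(str) + "\0" + order["chrom1"].astype(str)
           + "\0" + order["chrom2"].astype(str)).to_numpy()
    p1 = order["pos1"].to_numpy()
    p2 = order["pos2"].to_numpy()
    for a in range(n):
        b = a + 1
        while b < n and key[b] == key[a] and p1[b] - p1[a] < tol:
            if abs(p2[b] - p2[a]) < tol:
                union(idx[a], idx[b])
            b += 1
    roots = np.array([find(i) for i in range(n)])
    keep = (
        df.assign(_root=roots)
        .sort_values(["pos1", "pos2"], kind="mergesort")
        .groupby("_root", sort=False)
        .head(1)
        .index
    )
    out = df.loc[keep.sort_values()].reset_index(drop=True)
    return BreakpointSet(out)


def sd_from_median(x: np.ndarray) -> np.ndarray:
    """(x - median) / SD, with SD the ordinary (mean-centred, ddof=1) SD."""
    x = np.asarray(x, dtype=float)
    sd = np.nanstd(x, ddof=1) if len(x) > 1 else 0.0
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - np.nanmedian(x)) / sd


def burden_profile(
    bps_collapsed: BreakpointSet,
    sample_info: pd.DataFrame,
    meth=None,
    cna=None,
) -> pd.DataFrame:
    """Per-sample burden table.

    Columns: total_ssv (collapsed count, 0 for samples with no calls),
    log_total (= log2(count+1)), global_ssv_index (SD-from-median within
    each wgs_pass stratum), and, where matrices are supplied,
    overall_methylation (median beta) and overall_cna (SD of log2 ratios).
    """
    counts = bps_collapsed.df.groupby("sample_id").size()
    samples = sample_info.index
    total = counts.reindex(samples).fillna(0).astype(int)
    log_total = pd.Series(log2p1(total.to_numpy()), index=samples)
    index = pd.Series(np.nan, index=samples)
    for stratum, grp in sample_info.groupby("wgs_pass"):
        vals = log_total.loc[grp.index].to_numpy()
        z = sd_from_median(vals)
        if np.all(z == 0) and np.ptp(vals) == 0 and len(vals) > 1:
            logger.warning("wgs_pass stratum %r has zero SD; index set to 0",
                           stratum)
        index.loc[grp.index] = z
    out = pd.DataFrame(
        {
            "sample_id": samples,
            "total_ssv": total,
            "log_total": log_total,
            "global_ssv_index": index,
        }
    ).set_index("sample_id", drop=False)
    if meth is not None:
        med = meth.values.median(axis=0, skipna=True)
        out["overall_methylation"] = med.reindex(samples)
    if cna is not None:
        sd = cna.values.std(axis=0, ddof=1, skipna=True)
        out["overall_cna"] = sd.reindex(samples)
    return out


def signature_score(
    expr,
    gene_set: list[str],
    sample_info: pd.DataFrame | None = None,
    normalization: str = "across_samples",
) -> pd.Series:
    """Mean SD-from-median-normalized log2 expression over a gene set.

    ``normalization="within_cancer_type"`` standardizes each gene inside
    each cancer type before averaging (requires ``sample_info``); absent
    set genes are logged, an empty intersection is an error.
    """
    present = [g for g in gene_set if g in expr.feature_ids]
    missing = [g for g in gene_set if g not in expr.feature_ids]
    if missing:
        logger.info("signature: %d/%d genes absent from matrix",
                    len(missing), len(gene_set))
    if not present:
        raise DataError("no signature genes present in the expression matrix")
    T = expr.transformed().loc[present]
    if normalization == "across_samples":
        norm = T.apply(lambda row: sd_from_median(row.to_numpy()), axis=1,
                       result_type="expand")
        norm.columns = T.columns
    elif normalization == "within_cancer_type":
        if sample_info is None:
            raise ValueError("within_cancer_type normalization needs sample_info")
        norm = T.copy()
        for _, grp in sample_info.groupby("cancer_type"):
            cols = [c for c in grp.index if c in T.columns]
            if not cols:
                continue
            block = T.loc[:, cols].to_numpy()
            norm.loc[:, cols] = np.apply_along_axis(sd_from_median, 1, block)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return norm.mean(axis=0)


def burden_scan(
    M,
    profile: pd.DataFrame,
    sample_info: pd.DataFrame,
    covariates: tuple = (),
    cna=None,
    feature_gene_map: pd.Series | None = None,
    proximal=None,
) -> pd.DataFrame:
    """Association of each feature with the log per-sample SSV total.

    Delegates to the association engine with predictor ``log_total_ssv``;
    ``wgs_pass`` and ``project`` are always in the design (sequencing depth
    and project are the known technical drivers of detected SSV counts).
    Sample-level covariates found in ``profile`` (overall_methylation,
    overall_cna) are joined into the sample table for the scan.
    """
    info = sample_info.copy()
    for col in ("overall_methylation", "overall_cna", "total_bp_count"):
        if col in covariates and col not in info.columns:
            if col == "total_bp_count":
                info[col] = profile["log_total"]
            elif col in profile.columns:
                info[col] = profile[col]
            else:
                raise DataError(f"covariate {col!r} not available")
    covs = tuple(dict.fromkeys(("wgs_pass", "project") + tuple(covariates)))
    cfg = ScanConfig(predictor="log_total_ssv", covariates=covs)
    burden = profile["log_total"]
    return scan_features(
        M, burden, info, cfg, cna=cna, feature_gene_map=feature_gene_map,
        proximal=proximal,
    )
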