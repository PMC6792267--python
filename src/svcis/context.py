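"""Rearrangement context: TAD-disruption classification and enrichment,
carrier alteration calls, and orientation-aware enhancer-hijack tabulation.

An SSV is *TAD-disrupting* when its two breakpoints do not fall inside the
same TAD; inter-chromosomal junctions always disrupt, and breakpoints in
inter-TAD gaps count as disrupting by default.

*Enhancer hijacking* is flagged for a breakpoint-gene association when the
native gene has no applicable enhancer (ubiquitous, or tagged for the
sample's cancer type) within 1 Mb of its TSS, while the rearrangement fuses
an applicable enhancer to within a 500 kb budget of the gene: the fused
distance is |tss - breakpoint| + |mate - enhancer midpoint| with the
enhancer required on the mate's retained flank.  Only breakpoints 0-500 kb
upstream of the gene with the gene-side flank retained (orientation '-' for
'+'-strand genes, '+' for '-'-strand genes) qualify as associations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_model import BreakpointSet, DataError
from .breakpoint_features import explode_breakpoints

HIJACK_BUDGET = 500_000
NATIVE_ENHANCER_LIMIT = 1_000_000
ALTERATION_SD = 0.4
AMP_DEL_LOG2 = 1.0


# ---------------------------------------------------------------------------
# alteration calls


def alteration_calls(
    transformed: pd.DataFrame,
    threshold_sd: float = ALTERATION_SD,
    cna: pd.DataFrame | None = None,
    amp_del_log2: float = AMP_DEL_LOG2,
) -> pd.DataFrame:
    """Per (feature, sample) up/down/none calls on transformed values.

    The deviation is (value - feature median) / feature SD across the
    scanned samples; ``up`` above +threshold, ``down`` below -threshold.
    With a CNA frame supplied, an ``amp_del`` label marks samples with
    |log2 ratio| > 1 for the feature ("amplified"/"deleted"/"neutral").
    Returns a long-format frame (feature_id, sample_id, deviation, altered,
    amp_del).
    """
    vals = transformed.to_numpy(dtype=float)
    med = np.nanmedian(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    sd = np.where(sd == 0, np.nan, sd)
    dev = (vals - med) / sd
    call = np.where(dev > threshold_sd, "up",
                    np.where(dev < -threshold_sd, "down", "none"))
    long = pd.DataFrame(
        {
            "feature_id": np.repeat(transformed.index.to_numpy(),
                                    transformed.shape[1]),
            "sample_id": np.tile(transformed.columns.to_numpy(),
                                 transformed.shape[0]),
            "deviation": dev.ravel(),
            "altered": call.ravel(),
        }
    )
    if cna is not None:
        c = cna.reindex(index=transformed.index, columns=transformed.columns)
        cv = c.to_numpy(dtype=float).ravel()
        long["amp_del"] = np.where(
            cv > amp_del_log2, "amplified",
            np.where(cv < -amp_del_log2, "deleted", "neutral"),
        )
    return long


# ---------------------------------------------------------------------------
# TAD disruption


def _tad_lookup(tads: pd.DataFrame):
    by_chrom = {}
    for chrom, grp in tads.sort_values("start").groupby("chrom"):
        by_chrom[chrom] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp["tad_id"].to_numpy(),
        )
    return by_chrom

def _tad_of(by_chrom, chrom, pos):
    if chrom not in by_chrom:
        return None
    starts, ends, ids = by_chrom[chrom]
    i = np.searchsorted(starts, pos, side="right") - 1
    if i >= 0 and pos < ends[i]:
        return ids[i]
    return None


def classify_tad_disruption(
    bps: BreakpointSet, tads: pd.DataFrame, gap_disrupts: bool = True
) -> pd.Series:
    """Boolean per SSV: True when the two breakpoints do not share a TAD.

    Inter-chromosomal SSVs always disrupt.  A breakpoint in an inter-TAD gap
    counts as disrupting (``gap_disrupts=False`` marks those calls with
    ``pd.NA`` instead, as a separate category).
    """
    lookup = _tad_lookup(tads)
    out = []
    for r in bps.df.itertuples(index=False):
        if r.chrom1 != r.chrom2:
            out.append(True)
            continue
        t1 = _tad_of(lookup, r.chrom1, r.pos1)
        t2 = _tad_of(lookup, r.chrom2, r.pos2)
        if t1 is None or t2 is None:
            out.append(True if gap_disrupts else pd.NA)
            continue
        out.append(t1 != t2)
    return pd.Series(out, index=bps.df.index, name="disrupting")


@dataclass
class EnrichmentResult:
    n_all: int
    n_subset: int
    frac_all: float
    frac_subset: float
    statistic: float
    p_value: float


def tad_enrichment_test(disrupting: pd.Series, subset_mask: pd.Series) -> EnrichmentResult:
    """Chi-squared comparison of disrupting fractions: subset vs the rest.

    ``disrupting`` covers the full SSV set; ``subset_mask`` selects the
    SSVs of interest (e.g. those tied to an expression- or
    methylation-altered association).
    """
    d = disrupting.astype(bool).to_numpy()
    m = subset_mask.astype(bool).to_numpy()
    if m.sum() == 0:
        raise DataError("empty SSV subset")
    table = np.array(
        [
            [d[m].sum(), (~d[m]).sum()],
            [d[~m].sum(), (~d[~m]).sum()],
        ],
        dtype=float,
    )
    if table.sum(0).min() == 0 or table.sum(1).min() == 0:
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return EnrichmentResult(
        n_all=int(len(d)), n_subset=int(m.sum()),
        frac_all=float(d.mean()), frac_subset=float(d[m].mean()),
        statistic=float(stat), p_value=float(p),
    )


# ---------------------------------------------------------------------------
# enhancer hijacking


def applicable_enhancers(
    enhancers: pd.DataFrame, cancer_type: str, type_tags: dict[str, set]
) -> pd.DataFrame:
    """Enhancers active for a cancer type: ubiquitous or matching its tags."""
    tags = set(type_tags.get(cancer_type, set())) | {"ubiquitous"}
    mask = enhancers["tags"].map(lambda t: bool(t & tags))
    return enhancers[mask]


def upstream_associations(
    bps: BreakpointSet,
    genes: pd.DataFrame,
    max_distance: int = HIJACK_BUDGET,
) -> pd.DataFrame:
    """Qualifying breakpoint-gene associations for the hijack tabulation.

    One association per (gene, sample): the breakpoint closest to the TSS
    among those 0-``max_distance`` upstream of the gene whose retained flank
    faces the gene (so the mate is fused on the distal side).
    """
    ends = explode_breakpoints(bps)
    rows = []
    for chrom, grp in ends.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        grp = grp.sort_values("pos").reset_index(drop=True)
        pos = grp["pos"].to_numpy()
        for gene in g.itertuples(index=False):
            if gene.strand == "+":
                lo, hi = gene.tss - max_distance, gene.tss  # [lo, hi)
                i0, i1 = np.searchsorted(pos, lo), np.searchsorted(pos, hi)
                want_orient = "-"
            else:
                lo, hi = gene.tss, gene.tss + max_distance  # (lo, hi]
                i0 = np.searchsorted(pos, lo, "right")
                i1 = np.searchsorted(pos, hi, "right")
                want_orient = "+"
            if i0 == i1:
                continue
            sub = grp.iloc[i0:i1]
            sub = sub[sub["orient"] == want_orient]
            if sub.empty:
                continue
            sub = sub.copy()
            sub["distance"] = np.abs(sub["pos"] - gene.tss)
            best = sub.sort_values("distance").groupby("sample_id").head(1)
            for r in best.itertuples(index=False):
                rows.append(
                    (gene.gene_id, r.sample_id, chrom, r.pos, r.orient,
                     r.mate_chrom, r.mate_pos, r.mate_orient, r.distance,
                     r.ssv_id)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "sample_id", "chrom", "pos", "orient", "mate_chrom",
            "mate_pos", "mate_orient", "distance", "ssv_id",
        ],
    )


def flag_hijack(
    assoc: pd.DataFrame,
    genes: pd.DataFrame,
    enhancers: pd.DataFrame,
    sample_types: pd.Series,
    type_tags: dict[str, set],
    budget: int = HIJACK_BUDGET,
    native_limit: int = NATIVE_ENHANCER_LIMIT,
) -> pd.Series:
    """Hijack flag per association row of :func:`upstream_associations`."""
    gene_tss = genes.set_index("gene_id")[["chrom", "tss"]]
    # per cancer type, sorted enhancer midpoints by chromosome
    cache: dict[str, dict[str, np.ndarray]] = {}

    def mids_for(ctype: str) -> dict[str, np.ndarray]:
        if ctype not in cache:
            app = applicable_enhancers(enhancers, ctype, type_tags)
            cache[ctype] = {
                c: np.sort(g["mid"].to_numpy()) for c, g in app.groupby("chrom")
            }
        return cache[ctype]

    def any_in(mids, chrom, lo, hi) -> bool:
        arr = mids.get(chrom)
        if arr is None or lo > hi:
            return False
        return np.searchsorted(arr, hi, "right") > np.searchsorted(arr, lo, "left")

    flags = []
    for r in assoc.itertuples(index=False):
        ctype = sample_types.get(r.sample_id)
        mids = mids_for(ctype)
        chrom, tss = gene_tss.loc[r.gene_id]
        # (a) native gene must lack an applicable enhancer within 1 Mb
        if any_in(mids, chrom, tss - native_limit, tss + native_limit):
            flags.append(False)
            continue
        # (b) fused distance: |tss - bp| + |mate - enhancer| <= budget,
        # enhancer on the mate's retained flank
        remaining = budget - r.distance
        if remaining < 0:
            flags.append(False)
            continue
        if r.mate_orient == "+":
            ok = any_in(mids, r.mate_chrom, r.mate_pos - remaining, r.mate_pos)
        else:
            ok = any_in(mids, r.mate_chrom, r.mate_pos, r.mate_pos + remaining)
        flags.append(bool(ok))
    return pd.Series(flags, index=assoc.index, name="hijack")


def hijack_summary(
    assoc: pd.DataFrame,
    hijack: pd.Series,
    subsets: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Hijack percentages overall and within association subsets.

    ``subsets`` maps a label (e.g. "overexpressed") to a boolean mask over
    ``assoc`` rows; each subset is compared against the full association
    set with a chi-squared test.
    """
    rows = [("all", int(len(assoc)), int(hijack.sum()),
             100.0 * hijack.mean() if len(assoc) else np.nan, np.nan)]
    h = hijack.to_numpy(dtype=bool)
    for label, mask in (subsets or {}).items():
        m = mask.to_numpy(dtype=bool)
        n, k = int(m.sum()), int(h[m].sum())
        pct = 100.0 * k / n if n else np.nan
        if n and n < len(assoc):
            table = np.array([[k, n - k],
                              [h[~m].sum(), (~m).sum() - h[~m].sum()]], float)
            if table.sum(0).min() > 0 and table.sum(1).min() > 0:
                _, p, _, _ = stats.chi2_contingency(table, correction=False)
            else:
                p = 1.0
        else:
            p = np.nan
        rows.append((label, n, k, pct, p))
    return pd.DataFrame(rows, columns=["subset", "n_associations",
                                       "n_hijack", "pct_hijack", "p_value"])
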