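"""Gene x sample breakpoint predictor matrices.

Two constructions are supported:

* **window matrix** — binary presence/absence of at least one breakpoint of
  the sample within a named genomic region window relative to the gene
  (0-20 kb / 20-50 kb / 50-100 kb, upstream or downstream of the TSS, or
  within the gene body);
* **distance matrix** — for each sample, the absolute distance from the
  breakpoint closest to the gene start, capped and imputed at 1 Mb where no
  breakpoint falls within range.

Upstream/downstream are strand-aware relative to the TSS by default
(``stranded=False`` gives unstranded left/right).  Flank windows are
half-open ``[near, far)`` on the distance from the TSS, and breakpoints
inside the gene body are counted only in the gene-body window, never in a
flank window, so the canonical windows partition the neighbourhood.
A breakpoint exactly at the TSS is stored at distance 1 bp so that the
engine's log2 transform is defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_model import BreakpointSet

D_MAX_DEFAULT = 1_000_000


@dataclass(frozen=True)
class WindowSpec:
    name: str
    side: str  # upstream | downstream | gene_body
    near: int = 0
    far: int = 0

    def __post_init__(self):
        if self.side not in ("upstream", "downstream", "gene_body"):
            raise ValueError(f"unknown window side {self.side!r}")
        if self.side != "gene_body" and not self.near < self.far:
            raise ValueError("window needs near < far")


CANONICAL_WINDOWS = {
    w.name: w
    for w in [
        WindowSpec("0-20kb_upstream", "upstream", 0, 20_000),
        WindowSpec("20-50kb_upstream", "upstream", 20_000, 50_000),
        WindowSpec("50-100kb_upstream", "upstream", 50_000, 100_000),
        WindowSpec("0-20kb_downstream", "downstream", 0, 20_000),
        WindowSpec("20-50kb_downstream", "downstream", 20_000, 50_000),
        WindowSpec("50-100kb_downstream", "downstream", 50_000, 100_000),
        WindowSpec("gene_body", "gene_body"),
    ]
}


@dataclass
class BreakpointFeatureMatrix:
    """Genes x samples predictor matrix (binary window or capped distance)."""

    values: pd.DataFrame
    mode: str  # "window" | "distance"
    window: str = ""
    d_max: int = D_MAX_DEFAULT

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def carriers(self) -> pd.Series:
        """Per-feature carrier count: 1-entries (window) or entries < d_max."""
        if self.mode == "window":
            return (self.values == 1).sum(axis=1)
        return (self.values < self.d_max).sum(axis=1)

    def carrier_mask(self) -> pd.DataFrame:
        if self.mode == "window":
            return self.values == 1
        return self.values < self.d_max


def explode_breakpoints(bps: BreakpointSet) -> pd.DataFrame:
    """One row per breakpoint end; every call yields exactly two rows.

    Each row keeps its own locus and orientation plus the mate's, the SV
    class, and the originating call index (``ssv_id``) so mate links are
    involutive: the mate of end 1 is end 2 of the same ``ssv_id``.
    """
    df = bps.df
    n = len(df)
    if n == 0:
        return pd.DataFrame(
            columns=["ssv_id", "end", "sample_id", "chrom", "pos", "orient",
                     "mate_chrom", "mate_pos", "mate_orient", "sv_class"]
        )
    first = pd.DataFrame(
        {
            "ssv_id": np.arange(n),
            "end": 1,
            "sample_id": df["sample_id"].to_numpy(),
            "chrom": df["chrom1"].to_numpy(),
            "pos": df["pos1"].to_numpy(),
            "orient": df["orient1"].to_numpy(),
            "mate_chrom": df["chrom2"].to_numpy(),
            "mate_pos": df["pos2"].to_numpy(),
            "mate_orient": df["orient2"].to_numpy(),
            "sv_class": df["sv_class"].to_numpy(),
        }
    )
    second = first.copy()
    second["end"] = 2
    second[["chrom", "pos", "orient"]] = first[
        ["mate_chrom", "mate_pos", "mate_orient"]
    ].to_numpy()
    second[["mate_chrom", "mate_pos", "mate_orient"]] = first[
        ["chrom", "pos", "orient"]
    ].to_numpy()
    out = pd.concat([first, second], ignore_index=True)
    out["pos"] = out["pos"].astype(np.int64)
    out["mate_pos"] = out["mate_pos"].astype(np.int64)
    return out


def _window_interval(gene, spec: WindowSpec, stranded: bool):
    """Half-open [lo, hi) genomic interval of a flank window for one gene."""
    plus = (gene.strand == "+") or not stranded
    if spec.side == "gene_body":
        return gene.start, gene.end + 1  # inclusive of both start and end
    if (spec.side == "upstream") == plus:
        # left of the tss: distance u = tss - pos in [near, far)
        return gene.tss - spec.far + 1, gene.tss - spec.near + 1
    return gene.tss + spec.near, gene.tss + spec.far


def window_matrix(
    bps: BreakpointSet,
    genes: pd.DataFrame,
    spec: WindowSpec | str,
    stranded: bool = True,
) -> BreakpointFeatureMatrix:
    """Binary gene x sample matrix: >= 1 breakpoint of the sample in the window."""
    if isinstance(spec, str):
        if spec not in CANONICAL_WINDOWS:
            raise ValueError(f"unknown window name {spec!r}")
        spec = CANONICAL_WINDOWS[spec]
    genes = genes.reset_index(drop=True)
    ends = explode_breakpoints(bps)
    samples = bps.samples
    gene_ids = genes["gene_id"].tolist()
    mat = np.zeros((len(gene_ids), len(samples)), dtype=np.int8)
    sample_idx = {s: j for j, s in enumerate(samples)}

    by_chrom_gene = {c: g for c, g in genes.groupby("chrom")}
    for (sample, chrom), grp in ends.groupby(["sample_id", "chrom"]):
        if chrom not in by_chrom_gene:
            continue
        pos = np.sort(grp["pos"].to_numpy())
        g = by_chrom_gene[chrom]
        j = sample_idx[sample]
        for gi, gene in zip(g.index, g.itertuples(index=False)):
            lo, hi = _window_interval(gene, spec, stranded)
            n_in = np.searchsorted(pos, hi) - np.searchsorted(pos, lo)
            if spec.side != "gene_body" and n_in:
                # exclude breakpoints that also fall in the gene body
                blo, bhi = gene.start, gene.end + 1
                olo, ohi = max(lo, blo), min(hi, bhi)
                if olo < ohi:
                    n_in -= np.searchsorted(pos, ohi) - np.searchsorted(pos, olo)
            if n_in > 0:
                mat[gi, j] = 1
    values = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"),
                          columns=samples)
    return BreakpointFeatureMatrix(values, mode="window", window=spec.name)


def distance_matrix(
    bps: BreakpointSet,
    genes: pd.DataFrame,
    d_max: int = D_MAX_DEFAULT,
) -> BreakpointFeatureMatrix:
    """Closest same-chromosome breakpoint distance to each gene start.

    Entries are min |pos - tss| over the sample's breakpoints, capped at
    ``d_max`` (imputed at ``d_max`` where no breakpoint lies within range);
    exact-TSS hits are stored as 1 bp.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    genes = genes.reset_index(drop=True)
    ends = explode_breakpoints(bps)
    samples = bps.samples
    gene_ids = genes["gene_id"].tolist()
    mat = np.full((len(gene_ids), len(samples)), d_max, dtype=np.int64)
    sample_idx = {s: j for j, s in enumerate(samples)}
    by_chrom_gene = {c: g for c, g in genes.groupby("chrom")}

    for (sample, chrom), grp in ends.groupby(["sample_id", "chrom"]):
        if chrom not in by_chrom_gene:
            continue
        pos = np.sort(grp["pos"].to_numpy())
        g = by_chrom_gene[chrom]
        tss = g["tss"].to_numpy()
        idx = np.searchsorted(pos, tss)
        left = np.where(idx > 0, np.abs(tss - pos[np.maximum(idx - 1, 0)]), d_max)
        right = np.where(
            idx < len(pos), np.abs(pos[np.minimum(idx, len(pos) - 1)] - tss), d_max
        )
        d = np.minimum(np.minimum(left, right), d_max)
        d = np.maximum(d, 1)  # tss-exact hits floored at 1 bp for log2
        mat[g.index.to_numpy(), sample_idx[sample]] = d
    values = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"),
                          columns=samples)
    return BreakpointFeatureMatrix(values, mode="distance", d_max=d_max)
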