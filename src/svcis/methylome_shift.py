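"""Normal-tissue methylation of rearranged regions versus the CGI near the gene.

For each SSV-CGI association, the mean normal-tissue beta over a 50 kb
window anchored at the mate breakpoint (extending into the mate's retained
flank) is compared with the normal-tissue beta at the CGI probe on the gene
side of the junction; ``delta = region mean - CGI beta``.  Positive deltas
mean the rearrangement fuses a more-methylated region next to the CGI.
Subsets of associations with cancer hyper- or hypo-methylation at the CGI
(scan FDR < 5% plus a +/-0.4 SD carrier deviation) are summarised against
the full association set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_model import DataError

REGION_WINDOW = 50_000


@dataclass
class NormalMethylationPanel:
    """Normal-tissue methylation profiles: one beta column per tissue.

    ``probes`` columns: probe_id, chrom, pos, then one column per tissue.
    ``tissue_map`` resolves a cancer type to its surrogate normal tissue.
    """

    probes: pd.DataFrame
    tissue_map: dict[str, str]

    def __post_init__(self):
        self._by_chrom = {}
        tissues = self.tissues
        bad = [
            t for t in tissues
            if ((self.probes[t].dropna() < 0) | (self.probes[t].dropna() > 1)).any()
        ]
        if bad:
            raise DataError(f"panel betas outside [0, 1] for tissues {bad}")
        for chrom, grp in self.probes.sort_values("pos").groupby("chrom"):
            self._by_chrom[chrom] = (
                grp["pos"].to_numpy(),
                {t: grp[t].to_numpy(dtype=float) for t in tissues},
            )

    @property
    def tissues(self) -> list[str]:
        return [c for c in self.probes.columns
                if c not in ("probe_id", "chrom", "pos")]

    def tissue_for(self, cancer_type: str) -> str | None:
        return self.tissue_map.get(cancer_type)

    def beta_at(self, tissue: str, chrom: str, lo: int, hi: int) -> float:
        """Unweighted mean beta over panel probes in [lo, hi]; NaN if none."""
        if tissue not in self.tissues:
            raise DataError(f"unknown tissue {tissue!r}")
        if chrom not in self._by_chrom:
            return np.nan
        pos, cols = self._by_chrom[chrom]
        i0, i1 = np.searchsorted(pos, lo), np.searchsorted(pos, hi, "right")
        if i0 == i1:
            return np.nan
        vals = cols[tissue][i0:i1]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if len(vals) else np.nan


def load_panel(probes_path, tissue_map_path) -> NormalMethylationPanel:
    """Read the panel TSV (probe_id, chrom, pos, tissue columns) and the
    cancer_type -> tissue map TSV (columns cancer_type, tissue)."""
    probes = pd.read_csv(probes_path, sep="\t", dtype={"chrom": str})
    tm = pd.read_csv(tissue_map_path, sep="\t")
    tissue_map = dict(zip(tm["cancer_type"], tm["tissue"]))
    return NormalMethylationPanel(probes, tissue_map)


def rearranged_region_beta(
    panel: NormalMethylationPanel,
    tissue: str,
    mate_chrom: str,
    mate_pos: int,
    mate_orient: str,
    window: int = REGION_WINDOW,
    centered: bool = False,
) -> float:
    """Mean normal beta over the rearranged region at the mate breakpoint.

    The window extends from the mate position into its retained flank
    (orientation '+': upstream/lower coordinates; '-': downstream), or
    symmetrically around the mate with ``centered=True``.  NaN when no
    panel probe falls in the window.
    """
    if centered:
        lo, hi = mate_pos - window // 2, mate_pos + window // 2
    elif mate_orient == "+":
        lo, hi = mate_pos - window, mate_pos
    else:
        lo, hi = mate_pos, mate_pos + window
    return panel.beta_at(tissue, mate_chrom, lo, hi)


def ssv_cgi_beta_difference(
    associations: pd.DataFrame,
    panel: NormalMethylationPanel,
    window: int = REGION_WINDOW,
    centered: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-association normal-methylation shift records plus subset summary.

    ``associations`` needs one row per SSV-CGI association with columns:
    sample_id, cancer_type, probe_id, cgi_chrom, cgi_pos, mate_chrom,
    mate_pos, mate_orient, subset (one of ``all``/``cancer_hyper``/
    ``cancer_hypo``; ``all`` rows are the unsubsetted background and hyper/
    hypo rows are *also* counted in the all summary).

    Returns (records, summary).  Records carry region_mean_beta, cgi_beta
    and delta; associations whose region holds no panel probe, or whose
    cancer type lacks a surrogate tissue, are dropped (the latter with a
    warning).  The summary gives each subset's mean delta with standard
    error, a Spearman rank correlation between subset membership and delta,
    and a Welch t comparison of the subset against the non-subset records.
    """
    if associations.empty:
        raise DataError("empty association list")
    records = []
    for r in associations.itertuples(index=False):
        tissue = panel.tissue_for(r.cancer_type)
        if tissue is None:
            continue
        region = rearranged_region_beta(
            panel, tissue, r.mate_chrom, r.mate_pos, r.mate_orient,
            window=window, centered=centered,
        )
        cgi = panel.beta_at(tissue, r.cgi_chrom, r.cgi_pos, r.cgi_pos)
        if not (np.isfinite(region) and np.isfinite(cgi)):
            continue
        records.append(
            (r.sample_id, r.probe_id, r.subset, region, cgi, region - cgi)
        )
    rec = pd.DataFrame(
        records,
        columns=["sample_id", "probe_id", "subset", "region_mean_beta",
                 "cgi_beta", "delta"],
    )
    rows = []
    deltas_all = rec["delta"].to_numpy()
    for label in ["all", "cancer_hyper", "cancer_hypo"]:
        d = deltas_all if label == "all" else rec.loc[
            rec["subset"] == label, "delta"].to_numpy()
        if len(d) == 0:
            rows.append((label, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        mean = float(d.mean())
        se = float(d.std(ddof=1) / np.sqrt(len(d))) if len(d) > 1 else np.nan
        if label == "all" or len(d) == len(deltas_all):
            rows.append((label, len(d), mean, se, np.nan, np.nan))
            continue
        member = (rec["subset"] == label).to_numpy(dtype=float)
        if np.ptp(deltas_all) == 0 or np.ptp(member) == 0:
            rho_p = np.nan
        else:
            rho_p = stats.spearmanr(member, deltas_all).pvalue
        rest = rec.loc[rec["subset"] != label, "delta"].to_numpy()
        t_p = stats.ttest_ind(d, rest, equal_var=False).pvalue if len(rest) > 1 else np.nan
        rows.append((label, len(d), mean, se, float(rho_p), float(t_p)))
    summary = pd.DataFrame(
        rows, columns=["subset", "n", "mean_delta", "se_delta",
                       "spearman_p", "welch_p"],
    )
    return rec, summary
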