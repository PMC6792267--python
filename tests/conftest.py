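"""Shared fixtures: toy annotation/breakpoints and session-scoped cohorts."""

import numpy as np
import pandas as pd
import pytest

from svcis.genomic_model import BreakpointSet
from svcis.breakpoint_features import distance_matrix
from svcis.association import ScanConfig, scan_features
from svcis.burden import burden_profile, collapse_ssvs
from svcis.simulate import SimConfig, null_config, simulate_cohort

#: default scan covariates of the pipeline
SCAN_COVARIATES = ("cancer_type", "cna", "wgs_pass", "total_bp_count")

N_REPLICATES = 20


def make_genes(rows):
    """rows: (gene_id, chrom, start, end, strand)."""
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"]).astype(np.int64)
    return df


def make_bps(rows):
    """rows: (sample_id, chrom1, pos1, orient1, chrom2, pos2, orient2, sv_class)."""
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "chrom1", "pos1", "orient1", "chrom2", "pos2",
                 "orient2", "sv_class"],
    )
    return BreakpointSet(df)


def run_default_scans(cohort):
    """The pipeline's default expression + methylation distance scans."""
    profile = burden_profile(collapse_ssvs(cohort.bps),
                             cohort.annotation.samples,
                             meth=cohort.methylation, cna=cohort.cna)
    info = cohort.annotation.samples.copy()
    info["total_bp_count"] = profile["log_total"]
    dist = distance_matrix(cohort.bps, cohort.annotation.genes)
    cfg = ScanConfig(predictor="log2_distance", covariates=SCAN_COVARIATES)
    expr_res = scan_features(cohort.expression, dist, info, cfg,
                             cna=cohort.cna)
    probe_gene = cohort.annotation.probes.set_index("probe_id")["gene_id"]
    meth_res = scan_features(cohort.methylation, dist, info, cfg,
                             cna=cohort.cna, feature_gene_map=probe_gene)
    return {"profile": profile, "info": info, "dist": dist,
            "expr": expr_res, "meth": meth_res}


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_scans(default_cohort):
    return run_default_scans(default_cohort)


@pytest.fixture(scope="session")
def null_scan():
    """Zero-effect cohort and its default expression scan."""
    cohort = simulate_cohort(null_config(seed=101))
    return cohort, run_default_scans(cohort)


@pytest.fixture(scope="session")
def replicate_recoveries():
    """Truth ledger + scan results over seeded replicates of the default
    config (cohort objects are dropped to bound memory)."""
    out = []
    for seed in range(N_REPLICATES):
        cohort = simulate_cohort(SimConfig(seed=seed))
        scans = run_default_scans(cohort)
        out.append({"seed": seed, "truth": cohort.truth,
                    "expr": scans["expr"], "meth": scans["meth"]})
    return out
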