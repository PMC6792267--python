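"""Covariate-adjusted linear association scans with q-values and permutation nulls.

Each feature (gene or CGI probe) is tested by ordinary least squares of its
transformed response (log2(x+1) expression or clamped-logit methylation beta)
against a breakpoint predictor — the binary window indicator, the
log2-transformed capped closest-breakpoint distance, or the log-transformed
per-sample SSV total — with cancer type always dummy-encoded and any
requested numeric covariates in the design.  A two-sided t test on the
predictor coefficient gives the p-value; false discovery rates are estimated
with the Storey-Tibshirani q-value over the tested features of a scan.

Sign convention: for the distance predictor the reported direction is the
*negated* coefficient sign, so that "closer breakpoint, higher response"
is a ``+`` association; binary and burden predictors report the plain
coefficient sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, interpolate

from .genomic_model import DataError, apply_transform, intersect_samples
from .breakpoint_features import BreakpointFeatureMatrix

PREDICTORS = ("window_binary", "log2_distance", "log_total_ssv")

NUMERIC_COVARIATES = (
    "cna",
    "purity",
    "ploidy",
    "total_bp_count",
    "age",
    "overall_methylation",
    "proximal_bp",
)


@dataclass
class ScanConfig:
    """Configuration of one association scan."""

    predictor: str = "log2_distance"
    covariates: tuple = ("cancer_type",)
    min_carriers: int = 3
    response_transform: str = ""  # default: the matrix's own declared transform
    clamp_eps: float = 1e-3
    min_fraction_present: float = 0.8
    cancer_type_column: str = "cancer_type"  # "project" for within-type scans

    def __post_init__(self):
        if self.predictor not in PREDICTORS:
            raise ValueError(f"unknown predictor {self.predictor!r}")
        if self.min_carriers < 2:
            raise ValueError("min_carriers must be >= 2")
        self.covariates = tuple(self.covariates)


RESULT_COLUMNS = [
    "feature_id", "n_samples", "n_carriers", "coefficient", "direction",
    "t_stat", "p_value", "q_value", "status",
]


def _design_from_covariates(
    sample_info: pd.DataFrame,
    samples: list[str],
    covariates: tuple,
    type_column: str,
) -> np.ndarray:
    """Sample-level covariate columns (cancer-type dummies + numeric), no intercept.

    Missing numeric covariate values are mean-imputed within the scanned
    sample set.
    """
    info = sample_info.loc[samples]
    cols = []
    if "cancer_type" in covariates or type_column in covariates:
        dummies = pd.get_dummies(info[type_column], drop_first=True, dtype=float)
        cols.append(dummies.to_numpy())
    if "wgs_pass" in covariates:
        cols.append((info["wgs_pass"] == "high").to_numpy(dtype=float)[:, None])
    if "project" in covariates and type_column != "project":
        dummies = pd.get_dummies(info["project"], drop_first=True, dtype=float)
        cols.append(dummies.to_numpy())
    for cov in covariates:
        if cov in ("cancer_type", "wgs_pass", "project", type_column):
            continue
        if cov in ("cna", "proximal_bp"):
            continue  # per-feature, appended in the scan loop
        if cov not in info.columns:
            raise DataError(f"covariate {cov!r} not in sample table")
        v = info[cov].to_numpy(dtype=float)
        if np.isnan(v).any():
            v = np.where(np.isnan(v), np.nanmean(v), v)
        cols.append(v[:, None])
    if not cols:
        return np.empty((len(samples), 0))
    return np.hstack(cols)


def _ols(y: np.ndarray, X: np.ndarray):
    """OLS fit; returns (beta, se, df_resid) after dropping collinear columns.

    Columns other than 0 (intercept) and 1 (the predictor) may be dropped to
    restore full rank; dropped columns get beta = se = nan.
    """
    n, k = X.shape
    keep = list(range(k))
    beta_k, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        # greedy removal of collinear covariate columns, detected by rank
        while True:
            Xk = X[:, keep]
            rank = np.linalg.matrix_rank(Xk)
            if rank == len(keep):
                break
            dropped = None
            for j in range(len(keep) - 1, 1, -1):  # never drop intercept/predictor
                sub = [c for c in keep if c != keep[j]]
                if np.linalg.matrix_rank(X[:, sub]) == rank:
                    dropped = keep[j]
                    break
            if dropped is None:
                return None  # deficiency involves the predictor itself
            keep.remove(dropped)
        beta_k, _, _, _ = np.linalg.lstsq(X[:, keep], y, rcond=None)
    Xk = X[:, keep]
    df = n - len(keep)
    if df < 1:
        return None
    resid = y - Xk @ beta_k
    rss = float(resid @ resid)
    sigma2 = rss / df
    xtx_inv = np.linalg.pinv(Xk.T @ Xk)
    se_k = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    beta = np.full(k, np.nan)
    se = np.full(k, np.nan)
    beta[keep] = beta_k
    se[keep] = se_k
    return beta, se, df


def fit_feature_association(
    y: np.ndarray,
    x: np.ndarray,
    C: np.ndarray | None,
    predictor: str = "window_binary",
):
    """Single-feature OLS of y ~ x + C with a two-sided t test on x.

    ``y`` must already be transformed; ``C`` is the covariate block (no
    intercept column).  Returns (coefficient, t, p, direction) or ``None``
    when the fit is degenerate (constant predictor, or rank deficiency
    involving the predictor).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return None
    n = len(y)
    blocks = [np.ones((n, 1)), x[:, None]]
    if C is not None and C.size:
        blocks.append(C)
    X = np.hstack(blocks)
    fit = _ols(y, X)
    if fit is None:
        return None
    beta, se, df = fit
    if not np.isfinite(se[1]) or se[1] == 0:
        return None
    t = beta[1] / se[1]
    p = 2.0 * stats.t.sf(abs(t), df)
    sign = np.sign(beta[1])
    if predictor == "log2_distance":
        sign = -sign  # closer breakpoint => larger response counts as '+'
    direction = "+" if sign > 0 else "-"
    return float(beta[1]), float(t), float(p), direction


def _predictor_vector(row: np.ndarray, mode: str, d_max: int) -> np.ndarray:
    if mode == "distance":
        return np.log2(np.asarray(row, dtype=float))
    return np.asarray(row, dtype=float)


def scan_features(
    M,
    P,
    sample_info: pd.DataFrame,
    cfg: ScanConfig,
    cna=None,
    feature_gene_map: pd.Series | None = None,
    samples: list[str] | None = None,
    proximal: BreakpointFeatureMatrix | None = None,
) -> pd.DataFrame:
    """Per-feature association scan of an omics matrix against a predictor.

    Parameters
    ----------
    M : OmicsMatrix
        Response (expression or methylation beta).
    P : BreakpointFeatureMatrix or pd.Series
        Predictor: a gene x sample breakpoint matrix, or a per-sample burden
        vector (already log-transformed) for ``log_total_ssv`` scans.
    cna : OmicsMatrix, optional
        Gene-level log2 copy ratio; used when ``"cna"`` is a covariate.
    feature_gene_map : pd.Series, optional
        Maps response feature ids (CGI probes) to gene ids for joining the
        predictor and CNA rows.  Features without a mapping are dropped.
    proximal : BreakpointFeatureMatrix, optional
        Distance matrix supplying the per-feature ``proximal_bp`` covariate
        (the feature's own log2 closest-breakpoint distance) in burden scans.
    samples : list, optional
        Restricts the scan; defaults to the intersection of all inputs.

    Returns a DataFrame with one row per feature (see RESULT_COLUMNS);
    q-values are computed over tested features only.
    """
    burden_mode = isinstance(P, pd.Series)
    p_samples = list(P.index) if burden_mode else list(P.sample_ids)
    pools = [list(M.sample_ids), p_samples, list(sample_info.index)]
    if cna is not None:
        pools.append(list(cna.sample_ids))
    samples = intersect_samples(samples or pools[0], *pools)

    Y = M.transformed(cfg.clamp_eps).loc[:, samples]
    C = _design_from_covariates(sample_info, samples, cfg.covariates, cfg.cancer_type_column)

    if burden_mode:
        xs_all = P.loc[samples].to_numpy(dtype=float)
        carriers_all = None
    else:
        Pv = P.values.loc[:, samples]
        carrier_df = (
            (Pv == 1) if P.mode == "window" else (Pv < P.d_max)
        )

    feature_ids = list(Y.index)
    if feature_gene_map is not None:
        feature_ids = [f for f in feature_ids if f in feature_gene_map.index]

    cna_vals = None
    if cna is not None and "cna" in cfg.covariates:
        cna_vals = cna.values.loc[:, samples]

    use_cna = cna_vals is not None
    rows = []
    p_list, tested_idx = [], []
    for i, fid in enumerate(feature_ids):
        gene = feature_gene_map.loc[fid] if feature_gene_map is not None else fid
        y = Y.loc[fid].to_numpy(dtype=float)
        present = np.isfinite(y)
        if present.mean() < cfg.min_fraction_present:
            rows.append((fid, int(present.sum()), 0, np.nan, "", np.nan,
                         np.nan, np.nan, "skipped_degenerate"))
            continue
        if burden_mode:
            x = xs_all
            n_car = int(present.sum())
        else:
            if gene not in Pv.index:
                continue
            raw = Pv.loc[gene].to_numpy(dtype=float)
            x = _predictor_vector(raw, P.mode, P.d_max)
            n_car = int(carrier_df.loc[gene].to_numpy()[present].sum())
            if n_car < cfg.min_carriers:
                rows.append((fid, int(present.sum()), n_car, np.nan, "",
                             np.nan, np.nan, np.nan, "skipped_min_carriers"))
                continue
        Ci = C
        extra = []
        if use_cna and gene in cna_vals.index:
            cv = cna_vals.loc[gene].to_numpy(dtype=float)
            cv = np.where(np.isfinite(cv), cv, np.nanmean(cv))
            extra.append(cv[:, None])
        if "proximal_bp" in cfg.covariates:
            if proximal is None:
                raise DataError("proximal_bp covariate requires a distance matrix")
            if gene in proximal.values.index:
                pv = proximal.values.loc[gene, samples].to_numpy(dtype=float)
                extra.append(np.log2(pv)[:, None])
        if extra:
            Ci = np.hstack([C] + extra) if C.size else np.hstack(extra)
        fit = fit_feature_association(
            y[present], x[present], Ci[present] if Ci.size else None,
            cfg.predictor,
        )
        if fit is None:
            rows.append((fid, int(present.sum()), n_car, np.nan, "", np.nan,
                         np.nan, np.nan, "skipped_degenerate"))
            continue
        coef, t, p, direction = fit
        tested_idx.append(len(rows))
        p_list.append(p)
        rows.append((fid, int(present.sum()), n_car, coef, direction, t, p,
                     np.nan, "tested"))

    res = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if p_list:
        q, _ = storey_qvalues(np.array(p_list))
        res.loc[np.array(tested_idx), "q_value"] = q
    return res


def storey_qvalues(p: np.ndarray, lambdas: np.ndarray | None = None,
                   pi0: float | None = None):
    """Storey-Tibshirani q-values.

    pi0 is estimated on the grid lambda = 0, 0.05, ..., 0.90 by fitting a
    cubic smoothing spline to pi0_hat(lambda) and evaluating it at the
    largest lambda, then clamping into (0, 1].  q-values are the pi0-scaled
    step-up minima (monotone in p).  Passing ``pi0`` explicitly skips the
    estimate (pi0=1 reduces exactly to Benjamini-Hochberg).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.0, 0.9001, 0.05)
    m = p.size
    if pi0 is None:
        pi0_grid = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
        if m < 8 or np.allclose(pi0_grid, pi0_grid[0]):
            pi0 = pi0_grid[-1]
        else:
            spline = interpolate.UnivariateSpline(lambdas, pi0_grid, k=3)
            pi0 = float(spline(lambdas[-1]))
    pi0 = min(max(pi0, 1.0 / m), 1.0)

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * ranked * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


def permutation_null(
    M,
    P,
    sample_info: pd.DataFrame,
    cfg: ScanConfig,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    cna=None,
    feature_gene_map: pd.Series | None = None,
) -> dict:
    """Patient-shuffling permutation null for a scan.

    Sample labels of the predictor columns are permuted as a unit (each
    sample's whole breakpoint profile moves together) while the response and
    covariates stay with their samples; the count of nominally significant
    features (p < alpha) per permutation is compared with the observed count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = scan_features(M, P, sample_info, cfg, cna=cna,
                             feature_gene_map=feature_gene_map)
    obs_count = int((observed["p_value"] < alpha).sum())
    counts = []
    base_cols = list(P.sample_ids)
    for _ in range(n_perm):
        perm = rng.permutation(len(base_cols))
        shuffled = P.values.copy()
        shuffled.columns = [base_cols[i] for i in perm]
        Pp = BreakpointFeatureMatrix(
            shuffled, mode=P.mode, window=P.window, d_max=P.d_max
        )
        res = scan_features(M, Pp, sample_info, cfg, cna=cna,
                            feature_gene_map=feature_gene_map)
        counts.append(int((res["p_value"] < alpha).sum()))
    counts = np.array(counts)
    n_tested = int((observed["status"] == "tested").sum())
    return {
        "observed": observed,
        "observed_count": obs_count,
        "perm_counts": counts,
        "mean_perm_count": float(counts.mean()),
        "empirical_p": float((counts >= obs_count).mean()),
        "n_tested": n_tested,
        "alpha": alpha,
    }
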