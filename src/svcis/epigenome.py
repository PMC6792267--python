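"""Cancer-type differential methylation, hit-set overlap tests, and
residualized expression-methylation correlation.

The overlap test quantifies whether two feature sets drawn from a common
universe share more members than expected under independence
(expected = |A|·|B| / |U|), with a chi-squared test on the 2x2 table by
default and a one-sided Fisher's exact test in enrichment mode (also used
for flat gene-set / GO enrichment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_model import DataError, logit_clamped, apply_transform
from .association import storey_qvalues


@dataclass
class OverlapTestResult:
    n_universe: int
    n_setA: int
    n_setB: int
    n_overlap: int
    expected_overlap: float
    statistic: float
    p_value: float
    test_used: str  # "chi2" | "fisher_one_sided"


def set_overlap_test(setA, setB, universe, mode: str = "chi2") -> OverlapTestResult:
    """Test overlap of two sets against independence within a universe.

    ``mode``: ``"chi2"`` (two-sided, no continuity correction),
    ``"fisher"`` (one-sided enrichment), or ``"auto"`` (Fisher when any
    expected cell of the 2x2 table is < 5).
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    A = set(setA) & universe
    B = set(setB) & universe
    if set(setA) - universe or set(setB) - universe:
        raise DataError("setA/setB must be subsets of the universe")
    nU, nA, nB = len(universe), len(A), len(B)
    k = len(A & B)
    expected = nA * nB / nU
    table = np.array(
        [[k, nA - k], [nB - k, nU - nA - nB + k]], dtype=float
    )
    if mode == "auto":
        exp_cells = np.outer(table.sum(1), table.sum(0)) / nU
        mode = "fisher" if (exp_cells < 5).any() else "chi2"
    if mode == "chi2":
        if table.sum(1).min() == 0 or table.sum(0).min() == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return OverlapTestResult(nU, nA, nB, k, expected, float(stat),
                                 float(p), "chi2")
    if mode == "fisher":
        # one-sided over-representation: hypergeometric upper tail
        p = float(stats.hypergeom.sf(k - 1, nU, nA, nB))
        odds = np.inf if (nA - k) * (nB - k) == 0 else (
            k * (nU - nA - nB + k) / ((nA - k) * (nB - k))
        )
        return OverlapTestResult(nU, nA, nB, k, expected, float(odds),
                                 p, "fisher_one_sided")
    raise ValueError(f"unknown overlap mode {mode!r}")


def differential_methylation_by_type(
    M_beta,
    sample_info: pd.DataFrame,
    type_label: str,
    clamp_eps: float = 1e-3,
    type_column: str = "cancer_type",
) -> pd.DataFrame:
    """Welch t-test per probe: one cancer type versus all the rest.

    Betas are logit-transformed (clamped) first; positive t means higher
    methylation in the named type.  Probes with a singleton group after
    missing-value handling are skipped; q-values are Storey-Tibshirani over
    tested probes.
    """
    samples = [s for s in M_beta.sample_ids if s in sample_info.index]
    labels = sample_info.loc[samples, type_column] == type_label
    in_type = labels.to_numpy()
    if in_type.sum() == 0 or (~in_type).sum() == 0:
        raise DataError(f"no samples for type {type_label!r} or for the rest")
    Y = logit_clamped(M_beta.values.loc[:, samples].to_numpy(dtype=float),
                      clamp_eps)
    rows, ps, tested = [], [], []
    for i, probe in enumerate(M_beta.feature_ids):
        y = Y[i]
        a = y[in_type & np.isfinite(y)]
        b = y[~in_type & np.isfinite(y)]
        if len(a) < 2 or len(b) < 2:
            rows.append((probe, np.nan, np.nan, np.nan, "skipped"))
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        tested.append(len(rows))
        ps.append(float(p))
        rows.append((probe, float(t), float(p), np.nan, "tested"))
    res = pd.DataFrame(rows, columns=["probe_id", "t_stat", "p_value",
                                      "q_value", "status"])
    if ps:
        q, _ = storey_qvalues(np.array(ps))
        res.loc[np.array(tested), "q_value"] = q
    return res


def _residualize(y: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    n = len(y)
    X = np.ones((n, 1)) if C is None or C.size == 0 else np.hstack(
        [np.ones((n, 1)), C]
    )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def residual_correlation(y1, y2, C=None):
    """Pearson correlation of the OLS residuals of y1 ~ C and y2 ~ C.

    Inputs must already be transformed to their modeling scale.  Returns
    (r, p) with a two-sided p from the t transform of r; ``None`` when
    fewer than 4 complete pairs remain.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    ok = np.isfinite(y1) & np.isfinite(y2)
    if C is not None:
        C = np.asarray(C, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        ok &= np.isfinite(C).all(axis=1)
    if ok.sum() < 4:
        return None
    r1 = _residualize(y1[ok], None if C is None else C[ok])
    r2 = _residualize(y2[ok], None if C is None else C[ok])
    if np.std(r1) == 0 or np.std(r2) == 0:
        return None
    r, _ = stats.pearsonr(r1, r2)
    n = int(ok.sum())
    df = n - 2 - (0 if C is None else C.shape[1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def residual_correlation_scan(
    pairs: list[tuple[str, str]],
    M1,
    M2,
    C: np.ndarray | None = None,
    samples: list[str] | None = None,
    clamp_eps: float = 1e-3,
) -> pd.DataFrame:
    """Residualized correlation across (feature-in-M1, feature-in-M2) pairs.

    Each matrix is transformed per its declared kind; q-values are computed
    over the tested pairs.
    """
    if samples is None:
        samples = [s for s in M1.sample_ids if s in set(M2.sample_ids)]
    T1 = M1.transformed(clamp_eps).loc[:, samples]
    T2 = M2.transformed(clamp_eps).loc[:, samples]
    rows, ps, tested = [], [], []
    for f1, f2 in pairs:
        if f1 not in T1.index or f2 not in T2.index:
            rows.append((f1, f2, np.nan, np.nan, np.nan, "skipped"))
            continue
        out = residual_correlation(T1.loc[f1].to_numpy(),
                                   T2.loc[f2].to_numpy(), C)
        if out is None:
            rows.append((f1, f2, np.nan, np.nan, np.nan, "skipped"))
            continue
        r, p = out
        tested.append(len(rows))
        ps.append(p)
        rows.append((f1, f2, r, p, np.nan, "tested"))
    res = pd.DataFrame(rows, columns=["feature_1", "feature_2", "r",
                                      "p_value", "q_value", "status"])
    if ps:
        q, _ = storey_qvalues(np.array(ps))
        res.loc[np.array(tested), "q_value"] = q
    return res
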