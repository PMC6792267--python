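"""End-to-end orchestration: one config in, a run manifest and stage outputs out.

Stages run in dependency order: features -> expression/methylation scans ->
permutation null (optional) -> overlap tests -> TAD/enhancer context ->
methylome shift -> burden correlates -> recovery scoring (when a planted
truth ledger is available) -> report.  All randomness flows from the single
config seed via a counter-based fan-out (stage k draws from seed + k), so
adding stages does not shift other stages' random streams.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd
import yaml

from . import genomic_model as gm
from .genomic_model import DataError
from .breakpoint_features import (
    CANONICAL_WINDOWS, distance_matrix, explode_breakpoints, window_matrix,
)
from .association import ScanConfig, permutation_null, scan_features
from .epigenome import set_overlap_test
from .context import (
    alteration_calls, classify_tad_disruption, flag_hijack, hijack_summary,
    tad_enrichment_test, upstream_associations,
)
from .methylome_shift import ssv_cgi_beta_difference
from .burden import burden_profile, burden_scan, collapse_ssvs
from .simulate import SimConfig, evaluate_recovery, simulate_cohort


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


DEFAULT_THRESHOLDS = {
    "fdr": 0.05,             # pan-cancer scan cutoff
    "fdr_per_type": 0.10,
    "alteration_sd": 0.4,
    "amp_del_log2": 1.0,
    "d_max": 1_000_000,
    "hijack_budget": 500_000,
    "methshift_window": 50_000,
    "collapse_tol": 10,
}

_STAGE_SEEDS = {"simulate": 0, "permutation": 1, "methshift": 2}


def _validate_config(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    cfg = dict(config)
    cfg.setdefault("seed", 0)
    cfg.setdefault("scan", {})
    cfg.setdefault("thresholds", {})
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(cfg["thresholds"])
    cfg["thresholds"] = thresholds
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs a 'simulate' or 'inputs' section")
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        for key in ("ssvs", "expression", "genes", "samples"):
            if key not in inputs:
                raise ConfigError(f"inputs section missing required key {key!r}")
        stages = cfg.get("stages")
        if stages and "methshift" in stages and "panel" not in inputs:
            raise ConfigError(
                "stage 'methshift' requires inputs key 'panel' "
                "(normal methylation panel TSV) and 'tissue_map'"
            )
        for key, path in inputs.items():
            if not os.path.exists(path):
                raise ConfigError(f"input file for {key!r} not found: {path}")
    return cfg


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return _validate_config(path_or_dict)
    with open(path_or_dict) as fh:
        return _validate_config(yaml.safe_load(fh))


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config, outdir: str | None = None, stages=None) -> dict:
    """Execute the pipeline; returns the manifest dict (also written as JSON).

    ``stages`` restricts execution to a subset (dependencies of a selected
    stage are still computed in memory but only selected stages write
    outputs and manifest rows).
    """
    cfg = load_config(config)
    seed = int(cfg["seed"])
    th = cfg["thresholds"]
    outdir = outdir or cfg.get("output_dir", "svcis_out")
    os.makedirs(outdir, exist_ok=True)
    requested = stages or cfg.get("stages") or [
        "features", "scan_expr", "scan_meth", "overlap", "context",
        "methshift", "burden", "recovery",
    ]
    manifest = {"config_hash": _config_hash(cfg), "seed": seed, "stages": []}
    results: dict = {}

    def record(stage, n_rows, path=None, **params):
        manifest["stages"].append(
            {"stage": stage, "rows": int(n_rows), "output": path,
             "params": params}
        )

    def save(df: pd.DataFrame, name: str) -> str:
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path

    # ---- inputs ----------------------------------------------------------
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        sim_kwargs.setdefault("seed", seed + _STAGE_SEEDS["simulate"])
        cohort = simulate_cohort(SimConfig(**sim_kwargs))
        bps, expr, meth, cna = (cohort.bps, cohort.expression,
                                cohort.methylation, cohort.cna)
        ann, panel, type_tags = cohort.annotation, cohort.panel, cohort.type_tags
        truth = cohort.truth
        record("simulate", len(bps.df), seed=sim_kwargs["seed"])
    else:
        inputs = cfg["inputs"]
        bps = gm.load_ssvs(inputs["ssvs"])
        expr = gm.load_matrix(inputs["expression"], "expression")
        meth = (gm.load_matrix(inputs["methylation"], "methylation_beta")
                if "methylation" in inputs else None)
        cna = (gm.load_matrix(inputs["cna"], "cna_log2")
               if "cna" in inputs else None)
        ann = gm.load_annotation(
            inputs["genes"], inputs.get("probes"), inputs.get("tads"),
            inputs.get("enhancers"), inputs["samples"],
        )
        panel = type_tags = None
        if "panel" in inputs:
            from .methylome_shift import load_panel
            panel = load_panel(inputs["panel"], inputs["tissue_map"])
            type_tags = {
                t: {f"{t}_tissue"} for t in ann.samples["cancer_type"].unique()
            }
        truth = (pd.read_csv(inputs["truth"], sep="\t")
                 if "truth" in inputs else None)
        record("load", len(bps.df))

    if cfg.get("exclude_sex", True):
        ann = ann.exclude_sex()
    genes, probes, samples = ann.genes, ann.probes, ann.samples

    # ---- burden profile (needed as a covariate source) -------------------
    collapsed = collapse_ssvs(bps, th["collapse_tol"])
    profile = burden_profile(collapsed, samples, meth=meth, cna=cna)
    sample_info = samples.copy()
    sample_info["total_bp_count"] = profile["log_total"]
    if "overall_methylation" in profile:
        sample_info["overall_methylation"] = profile["overall_methylation"]

    # ---- features --------------------------------------------------------
    dist = distance_matrix(bps, genes, th["d_max"])
    scan_cfg = cfg["scan"]
    window_names = scan_cfg.get("windows", [])
    windows = {w: window_matrix(bps, genes, w) for w in window_names}
    if "features" in requested:
        path = save(dist.values.reset_index(), "distance_matrix.tsv")
        record("features", len(dist.values), path, mode="distance",
               d_max=th["d_max"], windows=list(window_names))

    covs_expr = tuple(scan_cfg.get(
        "covariates_expr",
        ("cancer_type", "cna", "wgs_pass", "total_bp_count")))
    covs_meth = tuple(scan_cfg.get(
        "covariates_meth",
        ("cancer_type", "cna", "wgs_pass", "total_bp_count")))

    # ---- expression scan -------------------------------------------------
    expr_res = None
    if "scan_expr" in requested:
        c = ScanConfig(predictor="log2_distance", covariates=covs_expr)
        expr_res = scan_features(expr, dist, sample_info, c, cna=cna)
        results["scan_expr"] = expr_res
        record("scan_expr", len(expr_res), save(expr_res, "scan_expr.tsv"),
               covariates=list(covs_expr),
               n_significant=int((expr_res["q_value"] < th["fdr"]).sum()))
        for wname, wm in windows.items():
            cw = ScanConfig(predictor="window_binary", covariates=covs_expr)
            wres = scan_features(expr, wm, sample_info, cw, cna=cna)
            results[f"scan_expr_{wname}"] = wres
            record(f"scan_expr_{wname}", len(wres),
                   save(wres, f"scan_expr_{wname}.tsv"),
                   n_significant=int((wres["q_value"] < th["fdr"]).sum()))

    # ---- methylation scan ------------------------------------------------
    meth_res = None
    probe_gene = None
    if meth is not None and probes is not None and "scan_meth" in requested:
        probe_gene = probes.set_index("probe_id")["gene_id"]
        c = ScanConfig(predictor="log2_distance", covariates=covs_meth)
        meth_res = scan_features(meth, dist, sample_info, c, cna=cna,
                                 feature_gene_map=probe_gene)
        results["scan_meth"] = meth_res
        record("scan_meth", len(meth_res), save(meth_res, "scan_meth.tsv"),
               covariates=list(covs_meth),
               n_significant=int((meth_res["q_value"] < th["fdr"]).sum()))

    # ---- permutation null ------------------------------------------------
    n_perm = int(cfg.get("permutation", {}).get("n_perm", 0))
    if n_perm and expr_res is not None:
        perm = permutation_null(
            expr, dist, sample_info,
            ScanConfig(predictor="log2_distance", covariates=covs_expr),
            n_perm=n_perm, seed=seed + _STAGE_SEEDS["permutation"], cna=cna,
        )
        perm_df = pd.DataFrame({"perm_count": perm["perm_counts"]})
        record("permutation", n_perm, save(perm_df, "permutation.tsv"),
               observed=perm["observed_count"],
               mean_perm=perm["mean_perm_count"],
               empirical_p=perm["empirical_p"])
        results["permutation"] = perm

    # ---- overlap of hit sets ---------------------------------------------
    if ("overlap" in requested and expr_res is not None
            and meth_res is not None):
        expr_hits = set(expr_res.loc[expr_res["q_value"] < th["fdr"],
                                     "feature_id"])
        meth_hit_genes = set(
            probe_gene.loc[
                meth_res.loc[meth_res["q_value"] < th["fdr"], "feature_id"]
            ]
        )
        universe = (set(expr_res.loc[expr_res["status"] == "tested",
                                     "feature_id"])
                    & set(probe_gene.loc[
                        meth_res.loc[meth_res["status"] == "tested",
                                     "feature_id"]]))
        if universe:
            ov = set_overlap_test(expr_hits & universe,
                                  meth_hit_genes & universe, universe, "chi2")
            record("overlap", ov.n_overlap, None,
                   expected=round(ov.expected_overlap, 2), p=ov.p_value)
            results["overlap"] = ov

    # ---- TAD / enhancer context ------------------------------------------
    if "context" in requested and ann.tads is not None and expr_res is not None:
        disrupting = classify_tad_disruption(bps, ann.tads)
        results["tad_disrupting"] = disrupting
        expr_alt = alteration_calls(expr.transformed(), th["alteration_sd"])
        alt_lookup = expr_alt.set_index(["feature_id", "sample_id"])["altered"]
        sig_genes = set(expr_res.loc[expr_res["q_value"] < th["fdr"],
                                     "feature_id"])
        subset = _ssvs_near_altered_genes(bps, genes, sig_genes, alt_lookup,
                                          th["d_max"])
        if subset.any():
            enr = tad_enrichment_test(disrupting, subset)
            record("context_tad", int(subset.sum()), None,
                   frac_all=round(enr.frac_all, 4),
                   frac_subset=round(enr.frac_subset, 4), p=enr.p_value)
            results["tad_enrichment"] = enr
        if ann.enhancers is not None and type_tags is not None:
            assoc = upstream_associations(bps, genes, th["hijack_budget"])
            hj = flag_hijack(assoc, genes, ann.enhancers,
                             samples["cancer_type"], type_tags,
                             th["hijack_budget"])
            over = assoc.apply(
                lambda r: alt_lookup.get((r["gene_id"], r["sample_id"]),
                                         "none") == "up"
                and r["gene_id"] in sig_genes, axis=1,
            ) if len(assoc) else pd.Series(dtype=bool)
            summ = hijack_summary(assoc, hj, {"overexpressed": over}
                                  if len(assoc) else None)
            record("context_hijack", len(assoc),
                   save(summ, "hijack_summary.tsv"))
            results["hijack"] = (assoc, hj, summ)

    # ---- methylome shift --------------------------------------------------
    if ("methshift" in requested and panel is not None
            and meth_res is not None):
        rec, summary = _methylome_shift_stage(
            bps, genes, probes, meth, meth_res, sample_info, panel,
            th, seed + _STAGE_SEEDS["methshift"],
        )
        if summary is not None:
            record("methshift", len(rec), save(summary, "methshift.tsv"),
                   window=th["methshift_window"])
            results["methshift"] = (rec, summary)

    # ---- burden correlates -------------------------------------------------
    if "burden" in requested:
        record("burden_profile", len(profile),
               save(profile.reset_index(drop=True), "burden_profile.tsv"))
        results["burden_profile"] = profile
        bcovs = tuple(cfg.get("burden", {}).get("covariates", ()))
        bres = burden_scan(expr, profile, samples, bcovs, cna=cna)
        results["burden_expr"] = bres
        record("burden_expr", len(bres), save(bres, "burden_expr.tsv"),
               n_significant=int((bres["q_value"] < th["fdr"]).sum()))
        if meth is not None and probes is not None:
            pg = probes.set_index("probe_id")["gene_id"]
            bm = burden_scan(meth, profile, samples, bcovs, cna=cna,
                             feature_gene_map=pg)
            bm_ctrl = burden_scan(meth, profile, samples,
                                  bcovs + ("overall_methylation",),
                                  cna=cna, feature_gene_map=pg)
            results["burden_meth"] = bm
            results["burden_meth_adj"] = bm_ctrl
            record("burden_meth", len(bm), save(bm, "burden_meth.tsv"),
                   n_significant=int((bm["q_value"] < th["fdr"]).sum()),
                   n_significant_overall_meth_adjusted=int(
                       (bm_ctrl["q_value"] < th["fdr"]).sum()))

    # ---- recovery ----------------------------------------------------------
    if "recovery" in requested and truth is not None and expr_res is not None:
        rec = evaluate_recovery(
            truth[truth["effect_type"].isin(["expr_up", "expr_down"])],
            expr_res, th["fdr"])
        results["recovery_expr"] = rec
        record("recovery_expr", rec["n_discoveries"], None, **{
            k: (round(v, 4) if isinstance(v, float) and np.isfinite(v) else v)
            for k, v in rec.items()})
        if meth_res is not None:
            recm = evaluate_recovery(
                truth[truth["effect_type"].isin(["meth_up", "meth_down"])],
                meth_res, th["fdr"])
            results["recovery_meth"] = recm
            record("recovery_meth", recm["n_discoveries"], None, **{
                k: (round(v, 4) if isinstance(v, float) and np.isfinite(v)
                    else v) for k, v in recm.items()})

    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["_results"] = results
    return manifest


def _ssvs_near_altered_genes(bps, genes, sig_genes, alt_lookup, d_max):
    """Mask over SSV rows: breakpoint within 100 kb of a significant gene
    whose carrier sample shows an expression deviation call."""
    ends = explode_breakpoints(bps)
    sig = genes[genes["gene_id"].isin(sig_genes)]
    mask = np.zeros(len(bps.df), dtype=bool)
    for chrom, g in sig.groupby("chrom"):
        sub = ends[ends["chrom"] == chrom]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        for gene in g.itertuples(index=False):
            near = np.abs(pos - gene.tss) <= 100_000
            if not near.any():
                continue
            cand = sub[near]
            for r in cand.itertuples(index=False):
                if alt_lookup.get((gene.gene_id, r.sample_id), "none") != "none":
                    mask[r.ssv_id] = True
    return pd.Series(mask, index=bps.df.index)


def _methylome_shift_stage(bps, genes, probes, meth, meth_res, sample_info,
                           panel, th, seed, max_background: int = 20_000):
    """Compose SSV-CGI associations and run the normal-methylome comparison.

    Subsets: probes significant in the methylation scan (q < fdr) whose
    carrier deviates beyond +/- alteration_sd SD define cancer_hyper /
    cancer_hypo associations; a seeded sample of remaining associations is
    the unsubsetted background.
    """
    from .genomic_model import logit_clamped

    rng = np.random.default_rng(seed)
    ends = explode_breakpoints(bps)
    sig = set(meth_res.loc[meth_res["q_value"] < th["fdr"], "feature_id"])
    meth_t = pd.DataFrame(
        logit_clamped(meth.values.to_numpy(dtype=float)),
        index=meth.values.index, columns=meth.values.columns,
    )
    alt = alteration_calls(meth_t, th["alteration_sd"])
    alt_lookup = alt.set_index(["feature_id", "sample_id"])["altered"]
    gene_info = genes.set_index("gene_id")
    ctype = sample_info["cancer_type"]

    rows = []
    by_chrom = {c: g.sort_values("pos").reset_index(drop=True)
                for c, g in ends.groupby("chrom")}
    for p in probes.itertuples(index=False):
        if p.gene_id not in gene_info.index:
            continue
        ginfo = gene_info.loc[p.gene_id]
        sub = by_chrom.get(ginfo["chrom"])
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, ginfo["tss"] - th["d_max"])
        hi = np.searchsorted(pos, ginfo["tss"] + th["d_max"], "right")
        if lo == hi:
            continue
        window = sub.iloc[lo:hi].copy()
        window["dist"] = np.abs(window["pos"] - ginfo["tss"])
        closest = window.sort_values("dist").groupby("sample_id").head(1)
        for r in closest.itertuples(index=False):
            call = alt_lookup.get((p.probe_id, r.sample_id), "none")
            if p.probe_id in sig and call == "up":
                subset = "cancer_hyper"
            elif p.probe_id in sig and call == "down":
                subset = "cancer_hypo"
            else:
                subset = "all"
            rows.append((r.sample_id, ctype.get(r.sample_id), p.probe_id,
                         p.chrom, p.pos, r.mate_chrom, r.mate_pos,
                         r.mate_orient, subset))
    assoc = pd.DataFrame(
        rows, columns=["sample_id", "cancer_type", "probe_id", "cgi_chrom",
                       "cgi_pos", "mate_chrom", "mate_pos", "mate_orient",
                       "subset"],
    )
    if assoc.empty:
        return assoc, None
    bg = assoc[assoc["subset"] == "all"]
    if len(bg) > max_background:
        keep = rng.choice(bg.index.to_numpy(), max_background, replace=False)
        assoc = pd.concat(
            [assoc[assoc["subset"] != "all"], bg.loc[np.sort(keep)]]
        ).sort_index()
    rec, summary = ssv_cgi_beta_difference(assoc, panel,
                                           window=th["methshift_window"])
    return rec, summary


def write_report(manifest: dict) -> str:
    """Human-readable run summary from a manifest."""
    lines = [
        "svcis run report",
        "================",
        f"config hash : {manifest['config_hash']}",
        f"seed        : {manifest['seed']}",
        "",
    ]
    stages = manifest.get("stages", [])
    if not any(s["rows"] for s in stages):
        lines.append("No tested features in any stage.")
    for s in stages:
        params = ", ".join(f"{k}={v}" for k, v in s.get("params", {}).items())
        lines.append(f"{s['stage']:<24} rows={s['rows']:<8} {params}")
    results = manifest.get("_results", {})
    for key in ("scan_expr", "scan_meth"):
        if key in results:
            res = results[key]
            sig = res[(res["q_value"] < 0.05) & (res["status"] == "tested")]
            lines.append("")
            lines.append(
                f"{key}: {len(sig)} significant at FDR<5% "
                f"({(sig['direction'] == '+').sum()} positive / "
                f"{(sig['direction'] == '-').sum()} negative), "
                f"{int((res['status'] == 'tested').sum())} tested"
            )
    return "\n".join(lines) + "\n"
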