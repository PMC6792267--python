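"""Synthetic multi-omic cancer cohorts with planted breakpoint cis-effects.

The simulator emits the full input bundle the pipeline consumes — BEDPE SSV
calls, expression / methylation-beta / CNA matrices, gene, probe, TAD and
enhancer annotation, sample metadata, a normal-tissue methylation panel —
plus a ground-truth ledger of every planted effect for recovery scoring.

What it emulates (and on which scale):

* per-sample SSV breakpoint sets with a deletion/duplication/inversion/
  translocation class mix and log-uniform sizes (1 kb - 10 Mb), with
  per-sample burden heterogeneity (log-normal rate) and reduced detection
  sensitivity in low-pass WGS samples;
* cancer-type-structured baselines: log2-normal expression with per-type
  offsets, bimodal CGI methylation (promoter islands low, gene bodies
  intermediate, other probes higher) with per-type differential probes;
* planted cis-effects of breakpoints on expression (log2 units) and on CGI
  methylation (logit units) in a fixed carrier fraction of samples, whose
  carrier SSVs are placed in the upstream window of the target gene;
* CNA coupled to breakpoints (genes near a breakpoint may gain or lose
  copy), with a dosage effect on expression;
* burden-coupled global hypomethylation (beta decreasing in the global SSV
  index) and a burden-correlated expression module;
* enhancer-hijack geometry for a subset of planted overexpressed genes
  (no native enhancer within 1 Mb; the mate lands an applicable enhancer
  within the 500 kb fused-distance budget);
* TAD geometry: planted-effect SSVs span TADs with high probability
  (inter-chromosomal mates), background SSVs span as their sizes dictate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .genomic_model import (
    BreakpointSet,
    GenomeAnnotation,
    OmicsMatrix,
    write_ssvs,
    write_matrix,
    write_genes,
)
from .methylome_shift import NormalMethylationPanel

EFFECT_TYPES = ("expr_up", "expr_down", "meth_up", "meth_down", "burden_linked")

#: expected association direction per planted effect type
EFFECT_DIRECTION = {
    "expr_up": "+", "expr_down": "-", "meth_up": "+", "meth_down": "-",
    "burden_linked": "+",
}

_CLASS_ORIENTS = {
    "deletion": ("+", "-"),
    "duplication": ("-", "+"),
}


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort (defaults are the desk scale)."""

    n_samples: int = 300
    cancer_types: dict = field(
        default_factory=lambda: {"breast": 0.4, "prostate": 0.35, "lung": 0.25}
    )
    n_genes: int = 2000
    n_probes_per_gene: int = 3
    chrom_length: int = 100_000_000
    n_chroms: int = 3
    ssv_mean: float = 60.0  # mean SSVs per sample (before detection thinning)
    ssv_sigma: float = 0.6  # log-normal burden heterogeneity
    low_pass_fraction: float = 0.45
    low_pass_detection: float = 1.0  # per-SSV detection prob in low-pass WGS
    class_mix: dict = field(
        default_factory=lambda: {
            "deletion": 0.35, "duplication": 0.25,
            "inversion": 0.20, "translocation": 0.20,
        }
    )
    size_min: int = 1_000
    size_max: int = 10_000_000
    # planted effects
    n_expr_up: int = 30
    n_expr_down: int = 30
    n_meth_up: int = 30
    n_meth_down: int = 30
    n_burden_linked: int = 30
    n_hijack: int = 5  # subset of the expr_up genes
    carrier_fraction: float = 0.10
    effect_expr: float = 1.0  # log2 units
    effect_meth: float = 1.0  # logit units
    burden_module_slope: float = 0.3  # log2 expression per index unit
    cna_coupling: float = 0.3  # P(copy change | breakpoint within 100 kb)
    cna_expr_coef: float = 0.5  # log2 expression per log2 copy ratio
    burden_slope: float = -0.15  # logit(beta) change per global-SSV-index unit
    tad_span_prob: float = 0.9  # planted carrier SSVs drawn TAD-spanning
    noise_sd_expr: float = 0.5  # log2 scale
    noise_sd_meth: float = 0.5  # logit scale
    type_sd_expr: float = 0.7
    type_sd_meth: float = 0.3
    probe_sd: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.cancer_types.values()) - 1.0) > 1e-9:
            raise ValueError("cancer type proportions must sum to 1")
        if self.carrier_fraction * self.n_samples < 1:
            raise ValueError("carrier fraction times samples must be >= 1")
        for v in (self.ssv_mean, self.carrier_fraction, self.cna_coupling,
                  self.noise_sd_expr, self.noise_sd_meth):
            if v < 0:
                raise ValueError("rates and SDs must be >= 0")


def null_config(cfg: SimConfig | None = None, **kw) -> SimConfig:
    """A zero-effect variant of a config: no planted effects, no couplings."""
    cfg = cfg or SimConfig(**kw)
    return replace(
        cfg, n_expr_up=0, n_expr_down=0, n_meth_up=0, n_meth_down=0,
        n_burden_linked=0, n_hijack=0, cna_coupling=0.0, burden_slope=0.0,
    )


@dataclass
class SyntheticCohort:
    """In-memory bundle of one simulated cohort."""

    config: SimConfig
    bps: BreakpointSet
    expression: OmicsMatrix
    methylation: OmicsMatrix
    cna: OmicsMatrix
    annotation: GenomeAnnotation
    panel: NormalMethylationPanel
    type_tags: dict
    truth: pd.DataFrame
    planted_ssv_ids: np.ndarray  # row indices into bps.df of planted carrier SSVs
    gene_sets: dict

    def write_bundle(self, outdir: str) -> dict:
        """Write the cohort as the plain-text file bundle the loaders read."""
        os.makedirs(outdir, exist_ok=True)
        paths = {k: os.path.join(outdir, v) for k, v in {
            "ssvs": "ssvs.bedpe", "expression": "expression.tsv",
            "methylation": "methylation.tsv", "cna": "cna.tsv",
            "genes": "genes.tsv", "probes": "probes.tsv",
            "tads": "tads.bed", "enhancers": "enhancers.bed",
            "samples": "samples.tsv", "panel": "normal_panel.tsv",
            "tissue_map": "tissue_map.tsv", "truth": "truth.tsv",
            "gene_sets": "gene_sets.gmt",
        }.items()}
        write_ssvs(self.bps, paths["ssvs"])
        write_matrix(self.expression, paths["expression"])
        write_matrix(self.methylation, paths["methylation"])
        write_matrix(self.cna, paths["cna"])
        ann = self.annotation
        write_genes(ann.genes, paths["genes"])
        ann.probes.to_csv(paths["probes"], sep="\t", index=False)
        ann.tads[["chrom", "start", "end"]].to_csv(
            paths["tads"], sep="\t", index=False, header=False)
        enh = ann.enhancers[["chrom", "start", "end", "specificity"]]
        enh.to_csv(paths["enhancers"], sep="\t", index=False, header=False)
        ann.samples.to_csv(paths["samples"], sep="\t", index=False)
        self.panel.probes.to_csv(paths["panel"], sep="\t", index=False,
                                 float_format="%.6g")
        pd.DataFrame(
            {"cancer_type": list(self.panel.tissue_map),
             "tissue": list(self.panel.tissue_map.values())}
        ).to_csv(paths["tissue_map"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["gene_sets"], "w") as fh:
            for name, genes in self.gene_sets.items():
                fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")
        return paths


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1.0 - p))


def simulate_cohort(cfg: SimConfig) -> SyntheticCohort:
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i+1}" for i in range(cfg.n_chroms)]
    L = cfg.chrom_length

    # --- samples -----------------------------------------------------------
    types = list(cfg.cancer_types)
    props = np.array([cfg.cancer_types[t] for t in types])
    counts = np.floor(props * cfg.n_samples).astype(int)
    counts[0] += cfg.n_samples - counts.sum()
    type_labels = np.repeat(types, counts)
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    wgs = np.where(rng.random(cfg.n_samples) < cfg.low_pass_fraction,
                   "low", "high")
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "project": [f"PROJ-{t.upper()}" for t in type_labels],
            "cancer_type": type_labels,
            "wgs_pass": wgs,
            "purity": np.round(rng.uniform(0.3, 0.95, cfg.n_samples), 3),
            "ploidy": np.round(rng.normal(2.8, 0.5, cfg.n_samples), 3),
            "age": np.round(rng.normal(60, 12, cfg.n_samples), 1),
        }
    ).set_index("sample_id", drop=False)

    # --- genome layout -----------------------------------------------------
    per_chrom = cfg.n_genes // cfg.n_chroms
    n_extra = cfg.n_genes - per_chrom * cfg.n_chroms
    gene_rows = []
    gi = 0
    for ci, chrom in enumerate(chroms):
        n_here = per_chrom + (1 if ci < n_extra else 0)
        spacing = L // (n_here + 1)
        for k in range(n_here):
            start = (k + 1) * spacing + int(rng.integers(-spacing // 4, spacing // 4))
            length = int(rng.integers(5_000, 80_000))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((f"G{gi:04d}", chrom, start, start + length, strand))
            gi += 1
    genes = pd.DataFrame(gene_rows,
                         columns=["gene_id", "chrom", "start", "end", "strand"])
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"],
                            genes["end"]).astype(np.int64)

    # TADs tile each chromosome (0.5 - 1.5 Mb)
    tad_rows = []
    for chrom in chroms:
        pos = 0
        while pos < L:
            width = int(rng.uniform(0.5e6, 1.5e6))
            tad_rows.append((chrom, pos, min(pos + width, L)))
            pos += width
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])
    tads["tad_id"] = [f"tad{i}" for i in range(len(tads))]

    # CGI probes: ~47% promoter / 43% gene body / 10% other
    probe_rows = []
    pi = 0
    for g in genes.itertuples(index=False):
        for k in range(cfg.n_probes_per_gene):
            u = rng.random()
            if u < 0.47:
                rc = "promoter"
                pos = g.tss + int(rng.integers(-500, 500))
            elif u < 0.90:
                rc = "gene_body"
                pos = int(rng.integers(g.start + 1, g.end))
            else:
                rc = "other"
                pos = g.end + int(rng.integers(2_000, 10_000))
            probe_rows.append(
                (f"cg{pi:06d}", g.chrom, pos, f"CGI_{g.gene_id}_{k}",
                 g.gene_id, rc)
            )
            pi += 1
    probes = pd.DataFrame(
        probe_rows,
        columns=["probe_id", "chrom", "pos", "cgi_id", "gene_id", "region_class"],
    )

    # --- planted feature assignment ---------------------------------------
    n_cis = cfg.n_expr_up + cfg.n_expr_down + cfg.n_meth_up + cfg.n_meth_down
    n_special = n_cis + cfg.n_burden_linked
    chosen = rng.choice(cfg.n_genes, size=n_special, replace=False)
    cursor = 0

    def take(n):
        nonlocal cursor
        out = chosen[cursor:cursor + n]
        cursor += n
        return genes["gene_id"].to_numpy()[out]

    expr_up_genes = take(cfg.n_expr_up)
    expr_down_genes = take(cfg.n_expr_down)
    meth_up_genes = take(cfg.n_meth_up)
    meth_down_genes = take(cfg.n_meth_down)
    burden_genes = take(cfg.n_burden_linked)
    hijack_genes = set(expr_up_genes[: cfg.n_hijack])

    gene_ix = {g: i for i, g in enumerate(genes["gene_id"])}
    n_carriers = max(1, int(round(cfg.carrier_fraction * cfg.n_samples)))

    # --- enhancers ---------------------------------------------------------
    type_tags = {t: {f"{t}_tissue"} for t in types}
    tag_pool = ["ubiquitous"] + [f"{t}_tissue" for t in types]
    tag_probs = [0.3] + [0.7 / len(types)] * len(types)
    n_enh = 900
    enh_rows = []
    hijack_tss = [
        (genes.loc[gene_ix[g], "chrom"], genes.loc[gene_ix[g], "tss"])
        for g in hijack_genes
    ]
    while len(enh_rows) < n_enh:
        chrom = chroms[int(rng.integers(cfg.n_chroms))]
        start = int(rng.integers(0, L - 2_000))
        # keep a clean 1.2 Mb enhancer desert around hijack target genes
        if any(c == chrom and abs(start - t) < 1_200_000 for c, t in hijack_tss):
            continue
        tag = tag_pool[int(rng.choice(len(tag_pool), p=tag_probs))]
        enh_rows.append((chrom, start, start + int(rng.integers(200, 2_000)), tag))
    enhancers = pd.DataFrame(enh_rows,
                             columns=["chrom", "start", "end", "specificity"])
    enhancers["tags"] = enhancers["specificity"].str.split(",").map(frozenset)
    enhancers["mid"] = ((enhancers["start"] + enhancers["end"]) // 2).astype(np.int64)
    ubiq_enh = enhancers[enhancers["specificity"] == "ubiquitous"]

    # --- normal methylome zones and panel ----------------------------------
    # low/high-methylation zones used for the mates of planted methylation SSVs
    low_zone = (chroms[-1], 65_000_000, 85_000_000)
    high_zone = (chroms[-1], 40_000_000, 60_000_000)

    def zone_beta(chrom, pos):
        if chrom == low_zone[0] and low_zone[1] <= pos < low_zone[2]:
            return 0.15
        if chrom == high_zone[0] and high_zone[1] <= pos < high_zone[2]:
            return 0.92
        return 0.80

    class_normal_beta = {"promoter": 0.10, "gene_body": 0.50, "other": 0.65}
    panel_rows = []
    for chrom in chroms:
        for pos in range(12_500, L, 25_000):
            panel_rows.append(("bg", chrom, pos, zone_beta(chrom, pos)))
    for p in probes.itertuples(index=False):
        panel_rows.append((p.probe_id, p.chrom, p.pos,
                           class_normal_beta[p.region_class]))
    panel_df = pd.DataFrame(panel_rows, columns=["probe_id", "chrom", "pos", "base"])
    tissue_map = {t: f"{t}_normal" for t in types}
    for t in types:
        noise = rng.normal(0.0, 0.02, len(panel_df))
        panel_df[tissue_map[t]] = np.clip(panel_df["base"] + noise, 0.001, 0.999)
    panel = NormalMethylationPanel(
        panel_df.drop(columns=["base"]), tissue_map
    )

    # --- SSVs ---------------------------------------------------------------
    tad_starts = {c: tads.loc[tads["chrom"] == c, "start"].to_numpy() for c in chroms}
    tad_ends = {c: tads.loc[tads["chrom"] == c, "end"].to_numpy() for c in chroms}

    def same_tad_mate(chrom, pos):
        starts, ends = tad_starts[chrom], tad_ends[chrom]
        i = np.searchsorted(starts, pos, "right") - 1
        lo, hi = int(starts[i]), int(ends[i]) - 1
        return int(rng.integers(lo, hi + 1))

    class_names = list(cfg.class_mix)
    class_p = np.array([cfg.class_mix[c] for c in class_names])
    rate_mult = rng.lognormal(-cfg.ssv_sigma ** 2 / 2.0, cfg.ssv_sigma,
                              cfg.n_samples)
    lam = cfg.ssv_mean * rate_mult
    n_bg = rng.poisson(lam)

    rows = []  # sample, c1, p1, o1, c2, p2, o2, class
    detect = []

    def orientations(sv_class):
        if sv_class in _CLASS_ORIENTS:
            return _CLASS_ORIENTS[sv_class]
        return ("+" if rng.random() < 0.5 else "-",
                "+" if rng.random() < 0.5 else "-")

    log_smin, log_smax = np.log(cfg.size_min), np.log(cfg.size_max)
    for si, sid in enumerate(sample_ids):
        p_det = cfg.low_pass_detection if wgs[si] == "low" else 1.0
        for _ in range(n_bg[si]):
            sv_class = class_names[int(rng.choice(len(class_names), p=class_p))]
            c1 = chroms[int(rng.integers(cfg.n_chroms))]
            p1 = int(rng.integers(0, L))
            if sv_class == "translocation":
                c2 = chroms[int(rng.integers(cfg.n_chroms))]
                while c2 == c1 and cfg.n_chroms > 1:
                    c2 = chroms[int(rng.integers(cfg.n_chroms))]
                p2 = int(rng.integers(0, L))
            else:
                c2 = c1
                size = int(np.exp(rng.uniform(log_smin, log_smax)))
                p2 = min(p1 + size, L - 1)
            o1, o2 = orientations(sv_class)
            rows.append((sid, c1, p1, o1, c2, p2, o2, sv_class))
            detect.append(rng.random() < p_det)

    # planted carrier SSVs
    truth_rows = []
    planted_rows = []  # (row payload, detected)
    planted_feature_of_row = []

    def plant_cis(gene_id, feature_id, effect_type, effect_size):
        g = genes.iloc[gene_ix[gene_id]]
        carriers = rng.choice(sample_ids, size=n_carriers, replace=False)
        hijack = gene_id in hijack_genes and effect_type == "expr_up"
        spans = []
        for sid in carriers:
            si = sample_ids.index(sid)
            p_det = cfg.low_pass_detection if wgs[si] == "low" else 1.0
            dist = int(rng.integers(1_000, 50_000))
            if g.strand == "+":
                p1 = int(g.tss) - dist
                o1 = "-"
            else:
                p1 = int(g.tss) + dist
                o1 = "+"
            span = bool(rng.random() < cfg.tad_span_prob)
            if hijack:
                enh = ubiq_enh.iloc[int(rng.integers(len(ubiq_enh)))]
                offset = int(rng.integers(10_000, 200_000))
                c2 = enh["chrom"]
                p2 = int(enh["mid"]) + offset
                o2 = "+"  # retained upstream flank covers the enhancer
                span = True
            elif effect_type == "meth_down":
                c2 = low_zone[0]
                p2 = int(rng.integers(low_zone[1] + 100_000, low_zone[2] - 100_000))
                o2 = "+" if rng.random() < 0.5 else "-"
                span = True
            elif effect_type == "meth_up":
                c2 = high_zone[0]
                p2 = int(rng.integers(high_zone[1] + 100_000, high_zone[2] - 100_000))
                o2 = "+" if rng.random() < 0.5 else "-"
                span = True
            elif span:
                c2 = chroms[(chroms.index(g.chrom) + 1 +
                             int(rng.integers(cfg.n_chroms - 1))) % cfg.n_chroms]
                p2 = int(rng.integers(0, L))
                o2 = "+" if rng.random() < 0.5 else "-"
            else:
                c2 = g.chrom
                p2 = same_tad_mate(g.chrom, p1)
                o2 = "+" if rng.random() < 0.5 else "-"
            spans.append(span)
            planted_rows.append(
                ((sid, g.chrom, p1, o1, c2, p2, o2, "translocation"
                  if c2 != g.chrom else "other"),
                 rng.random() < p_det)
            )
            planted_feature_of_row.append(feature_id)
        truth_rows.append(
            (feature_id, gene_id, effect_type, effect_size,
             ";".join(carriers), hijack, float(np.mean(spans)))
        )
        return carriers

    carriers_of = {}
    for gid in expr_up_genes:
        carriers_of[gid] = plant_cis(gid, gid, "expr_up", cfg.effect_expr)
    for gid in expr_down_genes:
        carriers_of[gid] = plant_cis(gid, gid, "expr_down", -cfg.effect_expr)

    # planted hypermethylation targets the gene's promoter probe, planted
    # hypomethylation a gene-body probe (gene-body CGIs start higher), the
    # structure reported for SSV-associated methylation changes in cancer
    probe_of_gene = {}

    def pick_probe(gid, region_class):
        sub = probes[probes["gene_id"] == gid]
        pref = sub[sub["region_class"] == region_class]
        return (pref if len(pref) else sub)["probe_id"].iloc[0]

    for gid in meth_up_genes:
        probe_of_gene[gid] = pick_probe(gid, "promoter")
    for gid in meth_down_genes:
        probe_of_gene[gid] = pick_probe(gid, "gene_body")
    for gid in meth_up_genes:
        pid = probe_of_gene[gid]
        carriers_of[pid] = plant_cis(gid, pid, "meth_up", cfg.effect_meth)
    for gid in meth_down_genes:
        pid = probe_of_gene[gid]
        carriers_of[pid] = plant_cis(gid, pid, "meth_down", -cfg.effect_meth)

    for gid in burden_genes:
        truth_rows.append((gid, gid, "burden_linked", cfg.burden_module_slope,
                           "", False, np.nan))

    all_rows = [r for r, d in zip(rows, detect) if d]
    planted_ids = []
    for (payload, det), fid in zip(planted_rows, planted_feature_of_row):
        if det:
            planted_ids.append(len(all_rows))
            all_rows.append(payload)
    ssv_df = pd.DataFrame(
        all_rows,
        columns=["sample_id", "chrom1", "pos1", "orient1", "chrom2", "pos2",
                 "orient2", "sv_class"],
    )
    bps = BreakpointSet(ssv_df)

    truth = pd.DataFrame(
        truth_rows,
        columns=["feature_id", "gene_id", "effect_type", "effect_size",
                 "carriers", "hijack", "tad_span_frac"],
    )

    # --- global SSV index (drives burden-coupled effects) -------------------
    det_counts = ssv_df.groupby("sample_id").size().reindex(sample_ids).fillna(0)
    log_total = np.log2(det_counts.to_numpy(dtype=float) + 1.0)
    index = np.zeros(cfg.n_samples)
    for stratum in ("low", "high"):
        m = wgs == stratum
        if m.sum() > 1:
            sd = np.std(log_total[m], ddof=1)
            if sd > 0:
                index[m] = (log_total[m] - np.median(log_total[m])) / sd

    # --- CNA ---------------------------------------------------------------
    from .breakpoint_features import distance_matrix

    dist = distance_matrix(bps, genes).values.reindex(
        index=genes["gene_id"], columns=sample_ids).fillna(1_000_000)
    near = dist.to_numpy() < 100_000
    cna_vals = rng.normal(0.0, 0.15, (cfg.n_genes, cfg.n_samples))
    hit = near & (rng.random((cfg.n_genes, cfg.n_samples)) < cfg.cna_coupling)
    amp = rng.uniform(0.5, 1.5, (cfg.n_genes, cfg.n_samples))
    sign = np.where(rng.random((cfg.n_genes, cfg.n_samples)) < 0.5, 1.0, -1.0)
    cna_vals = cna_vals + np.where(hit, amp * sign, 0.0)
    cna = OmicsMatrix(
        pd.DataFrame(cna_vals, index=pd.Index(genes["gene_id"], name="gene_id"),
                     columns=sample_ids),
        "cna_log2",
    )

    # --- expression ---------------------------------------------------------
    type_of = samples["cancer_type"].to_numpy()
    type_ix = np.array([types.index(t) for t in type_of])
    mu = rng.uniform(3.0, 9.0, cfg.n_genes)
    type_eff = rng.normal(0.0, cfg.type_sd_expr, (cfg.n_genes, len(types)))
    log_expr = (mu[:, None] + type_eff[:, type_ix]
                + cfg.cna_expr_coef * cna_vals
                + rng.normal(0.0, cfg.noise_sd_expr, (cfg.n_genes, cfg.n_samples)))
    sample_pos = {s: j for j, s in enumerate(sample_ids)}
    for gid, size in [(g, cfg.effect_expr) for g in expr_up_genes] + [
            (g, -cfg.effect_expr) for g in expr_down_genes]:
        cols = [sample_pos[s] for s in carriers_of[gid]]
        log_expr[gene_ix[gid], cols] += size
    for gid in burden_genes:
        log_expr[gene_ix[gid]] += cfg.burden_module_slope * index
    expr_vals = np.maximum(np.exp2(log_expr) - 1.0, 0.0)
    expression = OmicsMatrix(
        pd.DataFrame(expr_vals, index=pd.Index(genes["gene_id"], name="gene_id"),
                     columns=sample_ids),
        "expression",
    )

    # --- methylation --------------------------------------------------------
    n_probes = len(probes)
    base_beta = probes["region_class"].map(
        {"promoter": 0.10, "gene_body": 0.50, "other": 0.65}).to_numpy()
    logit0 = (_logit(base_beta)[:, None]
              + rng.normal(0.0, cfg.probe_sd, n_probes)[:, None]
              + rng.normal(0.0, cfg.type_sd_meth, (n_probes, len(types)))[
                  np.arange(n_probes)[:, None], type_ix[None, :]]
              + rng.normal(0.0, cfg.noise_sd_meth, (n_probes, cfg.n_samples)))
    probe_pos = {p: i for i, p in enumerate(probes["probe_id"])}
    for gid in meth_up_genes:
        pid = probe_of_gene[gid]
        cols = [sample_pos[s] for s in carriers_of[pid]]
        logit0[probe_pos[pid], cols] += cfg.effect_meth
    for gid in meth_down_genes:
        pid = probe_of_gene[gid]
        cols = [sample_pos[s] for s in carriers_of[pid]]
        logit0[probe_pos[pid], cols] -= cfg.effect_meth
    beta = _sigmoid(logit0 + cfg.burden_slope * index[None, :])
    beta = np.clip(beta, 0.001, 0.999)
    methylation = OmicsMatrix(
        pd.DataFrame(beta, index=pd.Index(probes["probe_id"], name="probe_id"),
                     columns=sample_ids),
        "methylation_beta",
    )

    annotation = GenomeAnnotation(
        genes=genes, probes=probes, tads=tads, enhancers=enhancers,
        samples=samples,
    )
    gene_sets = {
        "burden_module": list(burden_genes),
        "random_set": list(rng.choice(genes["gene_id"].to_numpy(), 30,
                                      replace=False)),
    }
    return SyntheticCohort(
        config=cfg, bps=bps, expression=expression, methylation=methylation,
        cna=cna, annotation=annotation, panel=panel, type_tags=type_tags,
        truth=truth, planted_ssv_ids=np.array(planted_ids, dtype=int),
        gene_sets=gene_sets,
    )


def evaluate_recovery(
    truth: pd.DataFrame,
    results: pd.DataFrame,
    q_threshold: float = 0.05,
    effect_types: tuple | None = None,
) -> dict:
    """Score scan results against the planted-effect ledger.

    Discoveries are tested features with q < threshold.  ``empirical_fdr``
    is false discoveries / discoveries; ``sign_accuracy`` is the fraction
    of true discoveries whose direction matches the planted effect.
    Precision is reported as NaN when there are no discoveries.
    """
    t = truth if effect_types is None else truth[
        truth["effect_type"].isin(effect_types)]
    planted = dict(zip(t["feature_id"], t["effect_type"]))
    res_ids = set(results["feature_id"])
    if planted and not (set(planted) & res_ids):
        raise ValueError("truth features and scan features are disjoint")
    disc = results[(results["status"] == "tested")
                   & (results["q_value"] < q_threshold)]
    n_disc = len(disc)
    tp = disc[disc["feature_id"].isin(planted)]
    n_tp = len(tp)
    sign_ok = sum(
        1 for r in tp.itertuples(index=False)
        if r.direction == EFFECT_DIRECTION[planted[r.feature_id]]
    )
    n_planted_testable = sum(1 for f in planted if f in res_ids)
    return {
        "n_discoveries": n_disc,
        "n_true": n_tp,
        "precision": (n_tp / n_disc) if n_disc else float("nan"),
        "recall": (n_tp / n_planted_testable) if n_planted_testable else float("nan"),
        "sign_accuracy": (sign_ok / n_tp) if n_tp else float("nan"),
        "empirical_fdr": ((n_disc - n_tp) / n_disc) if n_disc else float("nan"),
    }
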