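"""Shared data model and readers/writers for the formats the pipeline touches.

Internal coordinate convention is 0-based half-open throughout; exported
BED/BEDPE keeps that convention, tabular gene models are written as loaded.
Breakpoint orientations denote which flank of each breakpoint is retained in
the derivative junction: '+' keeps the upstream (lower-coordinate) flank,
'-' keeps the downstream (higher-coordinate) flank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("svcis")

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}

#: fixed pairing of matrix kind -> response transform used by the engine
KIND_TRANSFORM = {
    "expression": "log2p1",
    "methylation_beta": "logit_clamped",
    "cna_log2": "identity",
}

SV_CLASSES = ("deletion", "duplication", "inversion", "translocation", "other")

SSV_COLUMNS = [
    "sample_id",
    "chrom1",
    "pos1",
    "orient1",
    "chrom2",
    "pos2",
    "orient2",
    "sv_class",
    "size",
]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# transforms


def log2p1(x):
    """log2(x + 1); the standard expression transform."""
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def logit_clamped(beta, eps: float = 1e-3):
    """Logit of methylation beta values, clamped to [eps, 1 - eps] first."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    return np.log(b / (1.0 - b))


def apply_transform(values, transform: str, eps: float = 1e-3):
    if transform == "log2p1":
        return log2p1(values)
    if transform == "logit_clamped":
        return logit_clamped(values, eps)
    if transform == "identity":
        return np.asarray(values, dtype=float)
    raise ValueError(f"unknown transform: {transform!r}")


# ---------------------------------------------------------------------------
# containers


@dataclass
class BreakpointSet:
    """Collection of somatic SV calls, one row per junction.

    ``df`` columns follow :data:`SSV_COLUMNS`.  Intra-chromosomal calls are
    normalized so pos1 <= pos2 (orientations travel with their positions).
    """

    df: pd.DataFrame

    def __post_init__(self):
        self.df = normalize_ssv_frame(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.df[self.df["sample_id"] == sample_id]

    def subset(self, mask) -> "BreakpointSet":
        return BreakpointSet(self.df[mask].reset_index(drop=True))


def normalize_ssv_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy().reset_index(drop=True)
    missing = [c for c in SSV_COLUMNS if c not in df.columns and c != "size"]
    if missing:
        raise DataError(f"SSV table missing columns: {missing}")
    intra = df["chrom1"] == df["chrom2"]
    swap = intra & (df["pos1"] > df["pos2"])
    if swap.any():
        cols1 = ["chrom1", "pos1", "orient1"]
        cols2 = ["chrom2", "pos2", "orient2"]
        tmp = df.loc[swap, cols1].to_numpy()
        df.loc[swap, cols1] = df.loc[swap, cols2].to_numpy()
        df.loc[swap, cols2] = tmp
    # inter-chromosomal: canonical lexicographic chromosome order
    inter = ~intra
    swap2 = inter & (df["chrom1"] > df["chrom2"])
    if swap2.any():
        cols1 = ["chrom1", "pos1", "orient1"]
        cols2 = ["chrom2", "pos2", "orient2"]
        tmp = df.loc[swap2, cols1].to_numpy()
        df.loc[swap2, cols1] = df.loc[swap2, cols2].to_numpy()
        df.loc[swap2, cols2] = tmp
    size = np.where(intra, df["pos2"] - df["pos1"], np.nan)
    df["size"] = size
    df["pos1"] = df["pos1"].astype(np.int64)
    df["pos2"] = df["pos2"].astype(np.int64)
    return df[SSV_COLUMNS]


@dataclass
class OmicsMatrix:
    """Feature x sample matrix with a declared kind and transform.

    The transform is recorded at load but applied only inside the
    association engine, so the stored values stay on their native scale
    (raw expression, beta in [0, 1], or log2 copy ratio).
    """

    values: pd.DataFrame
    kind: str
    transform: str = ""

    def __post_init__(self):
        if self.kind not in KIND_TRANSFORM:
            raise DataError(f"unknown matrix kind: {self.kind!r}")
        if not self.transform:
            self.transform = KIND_TRANSFORM[self.kind]
        if self.transform != KIND_TRANSFORM[self.kind]:
            raise DataError(
                f"kind {self.kind!r} must pair with transform "
                f"{KIND_TRANSFORM[self.kind]!r}, got {self.transform!r}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise DataError(f"duplicate feature ids: {list(dups)[:5]}")
        if self.kind == "methylation_beta":
            vals = self.values.to_numpy(dtype=float)
            bad = np.argwhere((vals < 0) | (vals > 1))
            if len(bad):
                cells = [
                    (self.values.index[i], self.values.columns[j])
                    for i, j in bad[:10]
                ]
                raise DataError(f"beta values outside [0, 1] at cells: {cells}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def transformed(self, eps: float = 1e-3) -> pd.DataFrame:
        out = apply_transform(self.values.to_numpy(dtype=float), self.transform, eps)
        return pd.DataFrame(out, index=self.values.index, columns=self.values.columns)

    def subset_samples(self, samples) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[:, list(samples)], self.kind, self.transform)


@dataclass
class GenomeAnnotation:
    """Cross-referenced bundle of genes, CGI probes, TADs, enhancers, samples."""

    genes: pd.DataFrame
    probes: pd.DataFrame = None
    tads: pd.DataFrame = None
    enhancers: pd.DataFrame = None
    samples: pd.DataFrame = None
    n_dropped_probes: int = 0

    def exclude_sex(self) -> "GenomeAnnotation":
        """Drop X/Y genes and probes (the pipeline default)."""
        genes = self.genes[~self.genes["chrom"].isin(SEX_CHROMS)]
        probes = self.probes
        if probes is not None:
            probes = probes[
                ~probes["chrom"].isin(SEX_CHROMS)
                & probes["gene_id"].isin(genes["gene_id"])
            ]
        return replace(self, genes=genes.reset_index(drop=True),
                       probes=None if probes is None else probes.reset_index(drop=True))


# ---------------------------------------------------------------------------
# SSV BEDPE i/o

_BEDPE_MIN_COLS = 10


def load_ssvs(path) -> BreakpointSet:
    """Read SSV calls from a BEDPE file.

    Columns 1-6 are the two breakpoint intervals (0-based half-open; the
    interval start is taken as the breakpoint position), 7 the name, 8 the
    score, 9-10 the strands/orientations.  Optional columns 11 and 12 carry
    sample_id and sv_class; otherwise both are parsed from the name field as
    ``sample|class|id``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < _BEDPE_MIN_COLS:
                raise DataError(
                    f"{path}: row {lineno}: BEDPE needs >= {_BEDPE_MIN_COLS} "
                    f"columns, got {len(parts)}"
                )
            try:
                c1, s1, e1, c2, s2, e2 = (
                    parts[0], int(parts[1]), int(parts[2]),
                    parts[3], int(parts[4]), int(parts[5]),
                )
            except ValueError as exc:
                raise DataError(f"{path}: row {lineno}: bad coordinate ({exc})")
            if s1 > e1 or s2 > e2:
                raise DataError(f"{path}: row {lineno}: interval start > end")
            name = parts[6]
            strand1, strand2 = parts[8], parts[9]
            if strand1 not in "+-" or strand2 not in "+-":
                raise DataError(
                    f"{path}: row {lineno}: missing/invalid strand columns "
                    f"({strand1!r}, {strand2!r}); orientations are required"
                )
            if len(parts) >= 12:
                sample_id, sv_class = parts[10], parts[11]
            else:
                bits = name.split("|")
                if len(bits) < 2:
                    raise DataError(
                        f"{path}: row {lineno}: cannot derive sample_id from "
                        f"name field {name!r} (expected 'sample|class|id')"
                    )
                sample_id, sv_class = bits[0], bits[1]
            if sv_class not in SV_CLASSES:
                sv_class = "other"
            rows.append((sample_id, c1, s1, strand1, c2, s2, strand2, sv_class, np.nan))
    df = pd.DataFrame(rows, columns=SSV_COLUMNS)
    return BreakpointSet(df)


def write_ssvs(bps: BreakpointSet, path) -> None:
    """Write a BreakpointSet as 12-column BEDPE (sample, class in 11-12)."""
    df = bps.df
    with open(path, "w") as fh:
        for i, r in enumerate(df.itertuples(index=False)):
            name = f"{r.sample_id}|{r.sv_class}|{i}"
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            r.chrom1, r.pos1, r.pos1 + 1,
                            r.chrom2, r.pos2, r.pos2 + 1,
                            name, ".", r.orient1, r.orient2,
                            r.sample_id, r.sv_class,
                        ],
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# matrix i/o


def load_matrix(path, kind: str) -> OmicsMatrix:
    """Read a feature x sample TSV (first column = feature id, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        raise DataError(f"{path}: duplicate feature ids: {list(dups)[:5]}")
    return OmicsMatrix(df, kind)


def write_matrix(m: OmicsMatrix, path, float_format: str = "%.10g") -> None:
    m.values.to_csv(path, sep="\t", float_format=float_format,
                    index_label="feature_id")


# ---------------------------------------------------------------------------
# annotation i/o


def load_genes(path) -> pd.DataFrame:
    """Read a gene model table: BED12 or TSV with a header.

    Returns a frame with gene_id, chrom, start, end, strand, tss; tss is the
    strand-aware gene start (start for '+', end for '-').
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("gene_id"):
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        required = {"gene_id", "chrom", "start", "end", "strand"}
        if not required <= set(df.columns):
            raise DataError(f"{path}: gene TSV missing {required - set(df.columns)}")
    else:  # BED12 (or BED6+): chrom start end name score strand ...
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 6:
            raise DataError(f"{path}: BED gene model needs >= 6 columns")
        df = df.iloc[:, :6]
        df.columns = ["chrom", "start", "end", "gene_id", "score", "strand"]
        df = df[["gene_id", "chrom", "start", "end", "strand"]]
    if df.empty:
        raise DataError(f"{path}: empty gene annotation")
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]]["gene_id"].tolist()[:5]
        raise DataError(f"{path}: gene start >= end for {bad}")
    if df["gene_id"].duplicated().any():
        raise DataError(f"{path}: duplicate gene ids")
    df = df.copy()
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"]).astype(np.int64)
    return df.reset_index(drop=True)


def write_genes(genes: pd.DataFrame, path) -> None:
    genes[["gene_id", "chrom", "start", "end", "strand"]].to_csv(
        path, sep="\t", index=False
    )


def load_probes(path) -> pd.DataFrame:
    """Read a CGI probe annotation TSV: probe_id, chrom, pos, cgi_id, gene_id, region_class."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"probe_id", "chrom", "pos", "cgi_id", "gene_id", "region_class"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: probe TSV missing {required - set(df.columns)}")
    if df["probe_id"].duplicated().any():
        raise DataError(f"{path}: duplicate probe ids")
    bad = ~df["region_class"].isin(["promoter", "gene_body", "other"])
    if bad.any():
        raise DataError(f"{path}: unknown region_class values: "
                        f"{df.loc[bad, 'region_class'].unique()[:5]}")
    return df.reset_index(drop=True)


def load_bed_intervals(path, what: str = "interval") -> pd.DataFrame:
    """Read a plain BED3(+name) file into chrom/start/end(/name)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise DataError(f"{path}: BED needs >= 3 columns")
    cols = ["chrom", "start", "end"] + [f"c{i}" for i in range(3, df.shape[1])]
    df.columns = cols
    if (df["start"] >= df["end"]).any():
        raise DataError(f"{path}: {what} with start >= end")
    return df


def load_tads(path) -> pd.DataFrame:
    """Read TAD intervals (BED); overlapping TADs on a chromosome are an error."""
    df = load_bed_intervals(path, "TAD")[["chrom", "start", "end"]].copy()
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    for chrom, grp in df.groupby("chrom"):
        ends = grp["end"].to_numpy()
        starts = grp["start"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise DataError(f"{path}: overlapping TADs on {chrom}")
    df["tad_id"] = [f"tad{i}" for i in range(len(df))]
    return df


def load_enhancers(path) -> pd.DataFrame:
    """Read enhancer intervals: BED with a 4th column of specificity tags.

    Tags are comma-separated; the tag ``ubiquitous`` marks enhancers active
    in essentially all tissues.
    """
    df = load_bed_intervals(path, "enhancer")
    if df.shape[1] < 4:
        raise DataError(f"{path}: enhancer BED needs a 4th specificity column")
    df = df.iloc[:, :4].copy()
    df.columns = ["chrom", "start", "end", "specificity"]
    df["tags"] = df["specificity"].astype(str).str.split(",").map(frozenset)
    df["mid"] = ((df["start"] + df["end"]) // 2).astype(np.int64)
    return df.reset_index(drop=True)


def load_samples(path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, project, cancer_type, wgs_pass, ...)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "project", "cancer_type", "wgs_pass"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: sample table missing {required - set(df.columns)}")
    if df["sample_id"].duplicated().any():
        raise DataError(f"{path}: duplicate sample ids")
    bad = ~df["wgs_pass"].isin(["low", "high"])
    if bad.any():
        raise DataError(f"{path}: wgs_pass must be low/high")
    return df.set_index("sample_id", drop=False)


def load_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (set name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def load_annotation(
    genes_path,
    probes_path=None,
    tads_path=None,
    enhancers_path=None,
    samples_path=None,
) -> GenomeAnnotation:
    """Load and cross-reference the annotation bundle.

    Probes whose gene_id is absent from the gene annotation are dropped with
    a warning; the count of dropped records is logged and recorded on the
    bundle.
    """
    genes = load_genes(genes_path)
    probes = tads = enhancers = samples = None
    n_dropped = 0
    if probes_path is not None:
        probes = load_probes(probes_path)
        known = probes["gene_id"].isin(set(genes["gene_id"]))
        n_dropped = int((~known).sum())
        if n_dropped:
            logger.warning(
                "dropping %d probes referencing unknown genes (e.g. %s)",
                n_dropped,
                probes.loc[~known, "gene_id"].unique()[:3],
            )
            probes = probes[known].reset_index(drop=True)
    if tads_path is not None:
        tads = load_tads(tads_path)
    if enhancers_path is not None:
        enhancers = load_enhancers(enhancers_path)
    if samples_path is not None:
        samples = load_samples(samples_path)
    return GenomeAnnotation(
        genes=genes, probes=probes, tads=tads, enhancers=enhancers,
        samples=samples, n_dropped_probes=n_dropped,
    )


def intersect_samples(*collections) -> list[str]:
    """Intersection of sample-id collections, in the order of the first one."""
    sets = [set(c) for c in collections[1:]]
    out = [s for s in collections[0] if all(s in x for x in sets)]
    if not out:
        raise DataError("empty sample intersection across inputs")
    return out
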