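"""Sample tables, genotype calling, and file writers.

The per-marker sample table follows the GenomeStudio-style export: one row
per marker with identifier, chromosome, 1-based position, BAF and LRR.
Positions are 1-based on input; segment BED output is 0-based half-open.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("haplomix")

#: default header-name mapping for GenomeStudio-style exports; lowercase
#: canonical names are always accepted as well.
DEFAULT_COLUMNS = {
    "marker_id": ["marker_id", "Name", "SNP Name"],
    "chrom": ["chrom", "Chr", "Chromosome"],
    "pos": ["pos", "Position", "MapInfo"],
    "baf": ["baf", "B Allele Freq", "BAF"],
    "lrr": ["lrr", "Log R Ratio", "LRR"],
    "gc": ["gc", "GC"],
}


@dataclass
class MarkerTable:
    """Observed per-marker data for one sample, sorted by (chrom, pos)."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["marker_id", "chrom", "pos", "baf", "lrr"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"sample table is missing columns {missing}")
        if "genotype" not in self.df.columns:
            self.df["genotype"] = np.int8(-1)
        if "gc" not in self.df.columns:
            self.df["gc"] = 0.0
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.df["marker_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def baf(self) -> np.ndarray:
        return self.df["baf"].to_numpy(dtype=np.float64)

    @property
    def lrr(self) -> np.ndarray:
        return self.df["lrr"].to_numpy(dtype=np.float64)

    @property
    def genotype(self) -> np.ndarray:
        return self.df["genotype"].to_numpy(dtype=np.int8)

    @property
    def gc(self) -> np.ndarray:
        return self.df["gc"].to_numpy(dtype=np.float64)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _resolve_columns(header, mapping: dict | None) -> dict:
    """Map canonical field names to actual file columns; error if required missing."""
    resolved: dict[str, str] = {}
    candidates = {k: list(v) for k, v in DEFAULT_COLUMNS.items()}
    if mapping:
        for k, v in mapping.items():
            candidates[k] = [v]
    for field_name, names in candidates.items():
        for name in names:
            if name in header:
                resolved[field_name] = name
                break
    required = ["marker_id", "chrom", "pos", "baf", "lrr"]
    missing = [c for c in required if c not in resolved]
    if missing:
        raise ValueError(
            f"could not find required column(s) {missing} in header {list(header)}"
        )
    return resolved


def read_sample(path, columns: dict | None = None) -> MarkerTable:
    """Read a tab-separated sample table.

    Rows with unparseable numeric fields are dropped (counted in the log);
    BAF is clipped to [0, 1]; duplicate (chrom, pos) rows keep the first
    occurrence; output is sorted by (chrom, pos) with chromosome order as
    first encountered in the file.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    resolved = _resolve_columns(raw.columns, columns)
    df = pd.DataFrame(
        {canon: raw[actual] for canon, actual in resolved.items()}
    )
    n_in = len(df)
    for col in ["pos", "baf", "lrr"] + (["gc"] if "gc" in df.columns else []):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df["pos"].isna() | (df["baf"].isna() & df["lrr"].isna())
    if bad.any():
        logger.warning("dropped %d unparseable rows from %s", int(bad.sum()), path)
        df = df[~bad]
    n_clip = int(((df["baf"] < 0) | (df["baf"] > 1)).sum())
    if n_clip:
        logger.warning("clipped %d BAF values outside [0, 1]", n_clip)
    df["baf"] = df["baf"].clip(0.0, 1.0)
    df["pos"] = df["pos"].astype(np.int64)
    # stable sort preserving chromosome order of first appearance
    chrom_order = {c: i for i, c in enumerate(pd.unique(df["chrom"]))}
    df = df.sort_values(
        by=["chrom", "pos"], key=lambda s: s.map(chrom_order) if s.name == "chrom" else s,
        kind="stable",
    )
    dup = df.duplicated(subset=["chrom", "pos"], keep="first")
    if dup.any():
        logger.warning("dropped %d duplicate (chrom, pos) rows", int(dup.sum()))
        df = df[~dup]
    logger.info("read %d of %d markers from %s", len(df), n_in, path)
    return MarkerTable(df.reset_index(drop=True))


def call_genotypes(
    table: MarkerTable, het_low: float = 0.2, het_high: float = 0.8
) -> MarkerTable:
    """Call genotypes by BAF thresholds: AA below, BB above, AB between.

    Boundary values are inclusive to the heterozygous call.  Missing BAF
    gives a missing genotype (-1).
    """
    if het_low >= het_high:
        raise ValueError("het_low must be below het_high")
    baf = table.baf
    g = np.full(len(table), -1, dtype=np.int8)
    ok = ~np.isnan(baf)
    g[ok & (baf < het_low)] = 0
    g[ok & (baf > het_high)] = 2
    g[ok & (baf >= het_low) & (baf <= het_high)] = 1
    df = table.df.copy()
    df["genotype"] = g
    return MarkerTable(df)


def intersect_markers(table: MarkerTable, cluster_model):
    """Restrict a sample table and a cluster model to their shared markers.

    Both are returned in the cluster model's genomic order.
    """
    model_ids = cluster_model.marker_ids
    table_pos = {mid: i for i, mid in enumerate(table.marker_ids)}
    model_idx = [i for i, mid in enumerate(model_ids) if mid in table_pos]
    if not model_idx:
        raise ValueError("no markers shared between sample and cluster model")
    model_idx = np.array(model_idx)
    table_idx = np.array([table_pos[model_ids[i]] for i in model_idx])
    logger.info(
        "marker intersection: %d shared of %d (sample) / %d (model)",
        len(model_idx), len(table), len(model_ids),
    )
    sub_table = MarkerTable(table.df.iloc[table_idx].reset_index(drop=True))
    sub_model = (
        cluster_model
        if len(model_idx) == len(model_ids)
        else cluster_model.subset(model_idx)
    )
    return sub_table, sub_model


def write_posterior_tsv(path, posterior) -> None:
    """Per-marker posterior table: 12 category columns plus allele summary."""
    posterior.to_marker_frame().to_csv(path, sep="\t", index=False,
                                       float_format="%.6f")


def write_segments_bed(path, segments: pd.DataFrame) -> None:
    """Segments as BED: chrom, 0-based start, end, category, markers, mean posterior."""
    out = segments.copy()
    out["start0"] = out["start"] - 1
    out[["chrom", "start0", "end", "category", "n_markers", "mean_posterior"]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.6f"
    )


def write_params_json(path, posterior) -> None:
    payload = {
        "w": posterior.params.w,
        "sigma_b": posterior.params.sigma_b,
        "sigma_r": posterior.params.sigma_r,
        "o": posterior.params.o,
        "q": posterior.params.q,
        "gc_coef": posterior.params.gc_coef,
        "loglik": posterior.loglik,
        "n_iterations": posterior.n_iterations,
        "converged": posterior.converged,
        "runs": [
            {
                "params": p.to_dict(),
                "loglik": ll,
                "n_iterations": ni,
                "w_trace": wt,
                "loglik_trace": lt,
            }
            for p, ll, ni, wt, lt in zip(
                posterior.run_params,
                posterior.run_logliks,
                posterior.run_n_iterations,
                posterior.run_w_traces,
                posterior.run_loglik_traces,
            )
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
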