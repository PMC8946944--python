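"""Cross-timepoint differential-expression summaries.

Collapses several hypoxia-vs-normoxia contrasts (e.g. 6 h, 12 h, 24 h
versus 0 h) into single per-gene coordinates:

* averaged volcano coordinates — mean log2FC (x) and mean −log10(Padj)
  (y) across contrasts;
* heatmap gene selection — members of a hypoxia gene set that are
  significant (Padj < 0.05) with |log2FC| > 2 in *every* contrast;
* a pre-ranked enrichment metric — each gene's Padj rank averaged over
  contrasts and multiplied by the sign of its mean fold change; and
* row mean-centering of a log2-expression matrix for heatmap display.

The rank direction of the pre-ranked metric is deliberately emitted in
both conventions (rank 1 = smallest Padj, and reversed) because either
could have fed the original enrichment run; the ascending convention is
the default.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "average_volcano",
    "select_heatmap_genes",
    "preranked_metric",
    "mean_center_rows",
    "gene_universe",
    "read_de_table",
    "read_gmt",
    "write_rnk",
]

PADJ_FLOOR = 1e-300


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _require_columns(df: pd.DataFrame) -> None:
    missing = {"gene", "log2fc", "padj"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")


def gene_universe(tables: list[pd.DataFrame]) -> tuple[list[str], set[str]]:
    """Inner-join gene universe across tables plus the genes dropped.

    Averaging across contrasts only makes sense for genes measured in all
    of them; genes missing from any table are dropped and reported so a
    caller can write the sidecar list.
    """
    for t in tables:
        _require_columns(t)
    sets = [set(t["gene"]) for t in tables]
    common = set.intersection(*sets)
    if not common:
        raise ValueError("tables share no genes")
    dropped = set.union(*sets) - common
    # keep first table's order for determinism
    ordered = [g for g in tables[0]["gene"] if g in common]
    return ordered, dropped


def _aligned(tables: list[pd.DataFrame]) -> tuple[list[str], list[pd.DataFrame]]:
    genes, _ = gene_universe(tables)
    out = []
    for t in tables:
        out.append(t.set_index("gene").loc[genes])
    return genes, out


def average_volcano(
    tables: list[pd.DataFrame], padj_floor: float = PADJ_FLOOR
) -> pd.DataFrame:
    """Per-gene averaged volcano coordinates across contrasts.

    x = mean log2FC, y = mean −log10(Padj); Padj values of 0 are floored
    at ``padj_floor`` so the y coordinate stays finite.
    """
    genes, aligned = _aligned(tables)
    lfc = np.column_stack([t["log2fc"].to_numpy(float) for t in aligned])
    padj = np.column_stack([t["padj"].to_numpy(float) for t in aligned])
    neglog = -np.log10(np.maximum(padj, padj_floor))
    return pd.DataFrame(
        {
            "gene": genes,
            "avg_log2fc": lfc.mean(axis=1),
            "avg_neglog10_padj": neglog.mean(axis=1),
        }
    )


def select_heatmap_genes(
    tables: list[pd.DataFrame],
    hypoxia_set: set[str],
    padj_cut: float = 0.05,
    abs_lfc_cut: float = 2.0,
) -> set[str]:
    """Hypoxia-set genes differentially expressed in *every* contrast.

    Strict inequalities (Padj < cut, |log2FC| > cut) exactly as the
    selection rule states; a gene absent from any table fails.
    """
    for t in tables:
        _require_columns(t)
    selected = set(hypoxia_set)
    for t in tables:
        idx = t.set_index("gene")
        passing = set(
            idx.index[(idx["padj"] < padj_cut) & (idx["log2fc"].abs() > abs_lfc_cut)]
        )
        selected &= passing
    return selected


def preranked_metric(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Signed average-rank metric for pre-ranked enrichment analysis.

    Within each contrast genes are ranked by Padj ascending (rank 1 =
    most significant; ties get average ranks); ranks are averaged across
    contrasts and multiplied by the sign of the average log2FC, with
    sign(0) = 0. Columns with the ``_desc`` suffix carry the reversed
    convention (rank 1 = least significant).
    """
    genes, aligned = _aligned(tables)
    asc = np.column_stack(
        [t["padj"].rank(method="average", ascending=True).to_numpy(float) for t in aligned]
    )
    desc = np.column_stack(
        [t["padj"].rank(method="average", ascending=False).to_numpy(float) for t in aligned]
    )
    lfc = np.column_stack([t["log2fc"].to_numpy(float) for t in aligned])
    sign = np.sign(lfc.mean(axis=1))
    df = pd.DataFrame(
        {
            "gene": genes,
            "avg_log2fc": lfc.mean(axis=1),
            "avg_rank": asc.mean(axis=1),
            "signed_rank_metric": asc.mean(axis=1) * sign,
            "avg_rank_desc": desc.mean(axis=1),
            "signed_rank_metric_desc": desc.mean(axis=1) * sign,
        }
    )
    return df


def mean_center_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each row's mean (per-gene centering for heatmap display)."""
    if matrix.shape[1] < 1:
        raise ValueError("matrix needs at least one column")
    return matrix.sub(matrix.mean(axis=1), axis=0)


# ---------------------------------------------------------------------------
# file formats


def read_de_table(path: str | Path, comparison: str | None = None) -> pd.DataFrame:
    """Read a TSV of per-gene statistics (gene, log2fc, padj | pvalue).

    If only raw p-values are present they are BH-adjusted on load.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    if "padj" not in df.columns:
        if "pvalue" not in df.columns:
            raise ValueError(f"{path}: need a 'padj' or 'pvalue' column")
        df["padj"] = bh_adjust(df["pvalue"].to_numpy(float))
    _require_columns(df)
    df.attrs["comparison"] = comparison or Path(path).stem
    return df[["gene", "log2fc", "padj"]].copy()


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name TAB description TAB members..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        members = {g for g in parts[2:] if g}
        if not members:
            raise ValueError(f"gene set {parts[0]!r} is empty")
        sets[parts[0]] = members
    return sets


def write_rnk(df: pd.DataFrame, path: str | Path, metric: str = "signed_rank_metric") -> None:
    """Write a 2-column pre-ranked file (gene TAB metric), best first."""
    out = df[["gene", metric]].sort_values(metric, ascending=False)
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.10g")
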