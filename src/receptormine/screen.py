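"""Receptor-category filtering, ranking, clustering, and the final report.

The end product is a hypothesis report: for each receptor-coding gene
present in the expression matrix, its mean log2 expression per biological
category, its rank among receptors of the same class in a target
category, whether it is differentially expressed in each pairwise
contrast (adjusted p below the FDR cutoff), and whether sparse PLS-DA
selected it as class-discriminative.  High rank plus a significant
contrast is the screen's receptor-signaling hypothesis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_io import ChipDefinition, ReceptorAnnotation
from .diffexpr import DEGTable
from .preprocess import ExpressionMatrix
from .splsda import SPLSDAModel

logger = logging.getLogger(__name__)


def filter_receptors(
    table: ExpressionMatrix | pd.DataFrame,
    annotation: ReceptorAnnotation,
    categories: Sequence[str] | None = None,
) -> ExpressionMatrix | pd.DataFrame:
    """Restrict gene-level rows to genes in the selected receptor classes.

    ``categories=None`` keeps every annotated gene.  Genes absent from
    the annotation are dropped with a logged count.  Works on a
    gene-level :class:`ExpressionMatrix` (filters rows) or a DataFrame
    with gene ids in a ``gene`` or ``row_id`` column.
    """
    wanted = set(categories) if categories is not None else None

    def keep(gene: str) -> bool:
        cats = annotation.lookup(gene)
        if not cats:
            return False
        return wanted is None or bool(cats & wanted)

    if isinstance(table, ExpressionMatrix):
        if table.level != "gene":
            raise ValueError("receptor filtering needs a gene-level matrix")
        mask = [keep(g) for g in table.row_ids]
        n_dropped = len(mask) - sum(mask)
        if n_dropped:
            logger.info("%d genes outside the receptor annotation dropped", n_dropped)
        idx = [i for i, k in enumerate(mask) if k]
        return ExpressionMatrix(
            table.values[idx, :],
            [table.row_ids[i] for i in idx],
            list(table.samples),
            level="gene",
        )
    col = "gene" if "gene" in table.columns else "row_id"
    mask = table[col].map(keep)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("%d rows outside the receptor annotation dropped", n_dropped)
    return table[mask].reset_index(drop=True)


def category_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Mean log2 expression per gene and biological category."""
    cats: dict[str, list[int]] = {}
    for j, s in enumerate(matrix.samples):
        if s.assigned:
            cats.setdefault(s.category, []).append(j)
    if not cats:
        raise ValueError("no assigned samples; cannot compute category means")
    data = {c: matrix.values[:, ix].mean(axis=1) for c, ix in sorted(cats.items())}
    return pd.DataFrame(data, index=matrix.row_ids)


def rank_by_expression(
    table: pd.DataFrame, target_category: str, receptor_class: str | None = None
) -> pd.DataFrame:
    """Order genes by target-category mean expression, descending.

    Ties break by gene symbol ascending.  ``table`` needs a ``gene``
    column and one column per category mean; when ``receptor_class`` is
    given and a ``receptor_categories`` column exists, rows are first
    restricted to that class.
    """
    if target_category not in table.columns:
        raise ValueError(f"no column for target category {target_category!r}")
    df = table
    if receptor_class is not None and "receptor_categories" in df.columns:
        df = df[df["receptor_categories"].map(lambda cs: receptor_class in cs)]
    df = df.sort_values(
        by=[target_category, "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df = df.copy()
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def cluster_samples_and_genes(
    matrix: ExpressionMatrix,
) -> dict[str, object]:
    """Hierarchical clustering for heatmap ordering.

    Samples: Euclidean distance, average linkage.  Genes: 1 - Pearson
    correlation, average linkage; zero-variance gene rows get the maximum
    distance (2.0) to everything and are flagged.  Returns linkage
    matrices and leaf orders for both axes.
    """
    V = matrix.values
    if V.shape[0] < 2 or V.shape[1] < 2:
        raise ValueError("clustering needs >=2 genes and >=2 samples")
    sample_link = hierarchy.linkage(V.T, method="average", metric="euclidean")

    sd = V.std(axis=1)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        logger.warning("%d zero-variance rows assigned maximal gene distance", flat.size)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(V)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 2.0
    dist[flat, :] = 2.0
    dist[:, flat] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    gene_link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return {
        "sample_linkage": sample_link,
        "gene_linkage": gene_link,
        "sample_order": list(hierarchy.leaves_list(sample_link)),
        "gene_order": list(hierarchy.leaves_list(gene_link)),
    }


@dataclass
class HypothesisReport:
    """Ranked receptor-expression hypotheses for one target category."""

    frame: pd.DataFrame
    target_category: str

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def top(self, n: int = 20) -> pd.DataFrame:
        return self.frame.head(n)


def _gene_deg_flags(
    deg: DEGTable, genes: Sequence[str], chip: ChipDefinition | None, rule: str
) -> pd.DataFrame:
    """Per gene × contrast significance flags.

    When testing ran at probeset level, a gene is flagged if ANY of its
    probesets is significant (rule="any"; "all" requires every probeset),
    and the gene's adjusted p is the best across its probesets.
    """
    df = deg.frame.copy()
    if chip is not None:
        ps2g = chip.probeset_to_gene
        df["gene"] = df["row_id"].map(lambda r: ps2g.get(r, r))
    else:
        df["gene"] = df["row_id"]
    df = df[df["gene"].isin(set(genes))]
    agg = {"significant": "any" if rule == "any" else "all", "adj_p_value": "min"}
    g = df.groupby(["gene", "contrast"], sort=False).agg(agg).reset_index()
    flags = g.pivot(index="gene", columns="contrast", values="significant")
    best_p = g.pivot(index="gene", columns="contrast", values="adj_p_value")
    flags.columns = [f"deg_{c}" for c in flags.columns]
    best_p.columns = [f"adj_p_{c}" for c in best_p.columns]
    return flags.join(best_p)


def build_report(
    matrix: ExpressionMatrix,
    deg: DEGTable,
    spls: SPLSDAModel | None,
    annotation: ReceptorAnnotation,
    target_category: str,
    chip: ChipDefinition | None = None,
    deg_flag_rule: str = "any",
    min_expression: float | None = None,
) -> HypothesisReport:
    """Join expression means, DEG flags, and sPLS-DA selections per receptor.

    Rows = receptor genes present in the (gene-level) matrix, sorted by
    mean expression in ``target_category`` (ties by symbol).  ``rank`` is
    the overall position; ``class_rank`` the position within each of the
    gene's receptor classes.  Fully deterministic given identical inputs.
    """
    if deg_flag_rule not in ("any", "all"):
        raise ValueError("deg_flag_rule must be 'any' or 'all'")
    receptor_matrix = filter_receptors(matrix, annotation)
    means = category_means(receptor_matrix)
    if target_category not in means.columns:
        raise ValueError(f"target category {target_category!r} not in sample metadata")
    table = means.reset_index(names="gene")
    table["receptor_categories"] = table["gene"].map(
        lambda g: "/".join(sorted(annotation.lookup(g)))
    )
    if min_expression is not None:
        table = table[table[target_category] >= min_expression]

    table = rank_by_expression(table, target_category)

    # rank within each receptor class (a multi-class gene holds one rank per class)
    class_rank: dict[str, dict[str, int]] = {}
    for cls in sorted(annotation.categories):
        members = table[table["receptor_categories"].str.split("/").map(lambda cs: cls in cs)]
        for pos, gene in enumerate(members["gene"], start=1):
            class_rank.setdefault(gene, {})[cls] = pos
    table["class_rank"] = table["gene"].map(
        lambda g: "/".join(f"{c}:{r}" for c, r in sorted(class_rank.get(g, {}).items()))
    )

    flags = _gene_deg_flags(deg, list(table["gene"]), chip, deg_flag_rule)
    table = table.merge(flags, left_on="gene", right_index=True, how="left")
    for col in table.columns:
        if col.startswith("deg_"):
            table[col] = table[col].fillna(False).astype(bool)

    if spls is not None:
        if chip is not None and spls.gene_ids and spls.gene_ids[0] in chip.probeset_to_gene:
            sel = {chip.probeset_to_gene.get(r, r) for r in spls.selected_union()}
        else:
            sel = spls.selected_union()
        table["splsda_selected"] = table["gene"].isin(sel)
    else:
        table["splsda_selected"] = False

    return HypothesisReport(table.reset_index(drop=True), target_category)
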