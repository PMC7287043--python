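"""Sparse partial least squares discriminant analysis for gene selection.

The class response is dummy-coded (one column per category), both X
(samples × genes) and Y are centered and unit-scaled, and each latent
component solves a penalized SVD of M = XᵀY: the gene loading vector is
soft-thresholded so that exactly ``keepX`` genes carry nonzero weight.
X and Y are then deflated by regression on the component score and the
next component repeats on the residue.  Used here for variable selection
(which genes discriminate the categories), not for class prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import DesignSpec
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SPLSDAModel:
    """Fitted sparse PLS-DA: loadings, scores, and the selected genes."""

    gene_ids: list[str]
    sample_ids: list[str]
    categories: tuple[str, ...]
    loadings: np.ndarray  # genes x ncomp, each column unit norm
    y_loadings: np.ndarray  # K x ncomp
    scores: np.ndarray  # samples x ncomp
    keepx: tuple[int, ...]
    ncomp: int
    converged: tuple[bool, ...]
    dropped_constant: list[str] = field(default_factory=list)

    def selected(self, component: int) -> list[str]:
        """Gene ids with nonzero loading on one component (0-based)."""
        nz = np.nonzero(self.loadings[:, component])[0]
        return [self.gene_ids[i] for i in nz]

    def selected_union(self) -> set[str]:
        nz = np.nonzero((self.loadings != 0).any(axis=1))[0]
        return {self.gene_ids[i] for i in nz}


def _soft_threshold_keep(m: np.ndarray, keepx: int) -> np.ndarray:
    """Soft-threshold m so that exactly ``keepx`` entries survive.

    The threshold is the largest |m| among the non-kept entries; ties at
    the boundary are broken deterministically by index order (earlier
    index wins a slot).
    """
    p = m.size
    if keepx >= p:
        return m.copy()
    # rank by (|m| descending, index ascending)
    order = np.lexsort((np.arange(p), -np.abs(m)))
    keep_idx = order[:keepx]
    lam = np.abs(m[order[keepx]])
    out = np.zeros_like(m)
    shrunk = np.abs(m[keep_idx]) - lam
    # boundary ties shrink to exactly zero; nudge to keep the slot filled
    shrunk = np.where(shrunk <= 0, np.finfo(float).tiny, shrunk)
    out[keep_idx] = np.sign(m[keep_idx]) * shrunk
    return out


def splsda_fit(
    matrix: ExpressionMatrix,
    design: DesignSpec | None = None,
    ncomp: int | None = None,
    keepx: int | tuple[int, ...] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> SPLSDAModel:
    """Fit sparse PLS-DA on an expression matrix with assigned categories.

    Defaults: ncomp = K - 1 for K categories; keepx = min(50, p // 10)
    genes per component (at least 1).  Constant gene rows are dropped with
    a log message.  Per component the loading pair is initialized from the
    dominant singular pair of M = XᵀY and iterated
    a ← normalize(soft_threshold(M b)), b ← normalize(Mᵀ a) until the
    loading change falls below ``tol``; non-convergence at ``max_iter``
    warns and returns the partial result.  Loading signs are fixed so the
    largest-magnitude gene loading of each component is positive.
    """
    if design is None:
        design = DesignSpec.from_matrix(matrix)
    cats = design.categories
    K = len(cats)
    sample_idx = [j for j, s in enumerate(matrix.samples) if s.category in cats]
    if len({matrix.samples[j].category for j in sample_idx}) < 2:
        raise ValueError("samples must span >=2 categories")

    X = matrix.values[:, sample_idx].T.astype(float)  # samples x genes
    gene_ids = list(matrix.row_ids)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    dropped = [g for g, c in zip(gene_ids, constant) if c]
    if dropped:
        logger.info("dropped %d constant gene columns before sPLS-DA", len(dropped))
        X = X[:, ~constant]
        gene_ids = [g for g, c in zip(gene_ids, constant) if not c]
        sd = sd[~constant]
    n, p = X.shape
    X = (X - X.mean(axis=0)) / sd

    Y = np.zeros((n, K))
    for r, j in enumerate(sample_idx):
        Y[r, cats.index(matrix.samples[j].category)] = 1.0
    ysd = Y.std(axis=0, ddof=1)
    if np.any(ysd == 0):
        raise ValueError("a category has no variation in the dummy response")
    Y = (Y - Y.mean(axis=0)) / ysd

    if ncomp is None:
        ncomp = K - 1
    ncomp = min(ncomp, n - 1, p)
    if keepx is None:
        keepx = max(1, min(50, p // 10))
    if isinstance(keepx, int):
        keepx_t = (keepx,) * ncomp
    else:
        keepx_t = tuple(keepx)
        if len(keepx_t) != ncomp:
            raise ValueError(f"keepx needs {ncomp} entries, got {len(keepx_t)}")
    if any(k < 1 or k > p for k in keepx_t):
        raise ValueError(f"keepx entries must lie in [1, {p}]")

    loadings = np.zeros((p, ncomp))
    y_loadings = np.zeros((K, ncomp))
    scores = np.zeros((n, ncomp))
    converged = []
    Xh, Yh = X.copy(), Y.copy()
    for h in range(ncomp):
        M = Xh.T @ Yh  # p x K
        U, _, Vt = np.linalg.svd(M, full_matrices=False)
        a, b = U[:, 0], Vt[0, :]
        ok = False
        for _ in range(max_iter):
            a_new = _soft_threshold_keep(M @ b, keepx_t[h])
            norm = np.linalg.norm(a_new)
            if norm == 0:
                break
            a_new /= norm
            b_new = M.T @ a_new
            bnorm = np.linalg.norm(b_new)
            if bnorm == 0:
                break
            b_new /= bnorm
            delta = max(np.abs(a_new - a).max(), np.abs(b_new - b).max())
            a, b = a_new, b_new
            if delta < tol:
                ok = True
                break
        if not ok:
            logger.warning("component %d did not converge in %d iterations", h + 1, max_iter)
        converged.append(ok)
        # sign convention: largest-magnitude loading positive
        top = np.lexsort((np.arange(p), -np.abs(a)))[0]
        if a[top] < 0:
            a, b = -a, -b
        xi = Xh @ a
        denom = xi @ xi
        if denom > 0:
            Xh = Xh - np.outer(xi, (Xh.T @ xi) / denom)
            Yh = Yh - np.outer(xi, (Yh.T @ xi) / denom)
        loadings[:, h] = a
        y_loadings[:, h] = b
        scores[:, h] = xi

    return SPLSDAModel(
        gene_ids=gene_ids,
        sample_ids=[matrix.samples[j].sample_id for j in sample_idx],
        categories=cats,
        loadings=loadings,
        y_loadings=y_loadings,
        scores=scores,
        keepx=keepx_t,
        ncomp=ncomp,
        converged=tuple(converged),
        dropped_constant=dropped,
    )


def splsda_selected_genes(model: SPLSDAModel) -> pd.DataFrame:
    """Selected genes per component, ordered by |loading| descending.

    A gene selected on several components appears once per component; the
    frame also carries ``first_component`` provenance for union queries.
    """
    rows = []
    first_seen: dict[str, int] = {}
    for h in range(model.ncomp):
        idx = np.nonzero(model.loadings[:, h])[0]
        load = model.loadings[idx, h]
        order = np.lexsort((idx, -np.abs(load)))
        for rank, o in enumerate(order, start=1):
            g = model.gene_ids[idx[o]]
            first_seen.setdefault(g, h + 1)
            rows.append(
                {
                    "gene": g,
                    "component": h + 1,
                    "loading": load[o],
                    "rank_in_component": rank,
                }
            )
    df = pd.DataFrame(rows, columns=["gene", "component", "loading", "rank_in_component"])
    if not df.empty:
        df["first_component"] = df["gene"].map(first_seen)
    return df
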