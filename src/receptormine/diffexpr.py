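"""Per-row linear models, empirical-Bayes moderation, threshold testing, FDR.

Each expression row is fit with a group-means linear model over the
sample categories.  Residual variances are shrunk toward a prior
estimated across all rows (empirical Bayes, method of moments on the log
variances).  Significance is tested relative to a log2 fold-change
threshold tau (default 1): the p-value combines the two t tails
P(T >= (|b|-tau)/u) + P(T >= (|b|+tau)/u), which reduces to the ordinary
two-sided moderated t at tau = 0.  Adjusted p-values default to
Benjamini-Hochberg, applied within each contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Prior degrees of freedom used when the between-row variance spread is
#: no larger than sampling noise (effectively infinite shrinkage).
D0_CAP = 1e6


@dataclass(frozen=True)
class DesignSpec:
    """Ordered category list and the implied all-pairs contrast set."""

    categories: tuple[str, ...]
    contrasts: tuple[tuple[str, str], ...] = field(init=False)

    def __init__(self, categories: Sequence[str]):
        cats = tuple(categories)
        if len(cats) < 2:
            raise ValueError("need >=2 categories for contrasts")
        if len(set(cats)) != len(cats):
            raise ValueError("duplicate categories in design")
        object.__setattr__(self, "categories", cats)
        object.__setattr__(self, "contrasts", tuple(combinations(cats, 2)))

    @classmethod
    def from_matrix(cls, matrix: ExpressionMatrix) -> "DesignSpec":
        seen: list[str] = []
        for s in matrix.samples:
            if s.assigned and s.category not in seen:
                seen.append(s.category)
        return cls(seen)


@dataclass
class LinearFit:
    """Group-means OLS fit of every row.

    beta[:, c] is the log2 fold change for contrast c = (a, b), defined
    as mean(a) - mean(b); v[c] = 1/n_a + 1/n_b is its unscaled variance;
    s2 the residual variance with df = n - K.
    """

    design: DesignSpec
    row_ids: list[str]
    group_means: np.ndarray  # rows x K
    beta: np.ndarray  # rows x n_contrasts
    s2: np.ndarray  # rows
    df_residual: float
    v: np.ndarray  # n_contrasts
    ave_expr: np.ndarray  # rows


def fit_group_means(matrix: ExpressionMatrix, design: DesignSpec) -> LinearFit:
    """Fit the group-means model to every row by per-group averaging.

    With a one-way layout the OLS solution is the per-category mean; the
    residual variance pools within-group sums of squares over df = n - K.
    Every design category must appear in the matrix metadata with >=2
    samples.
    """
    cats = design.categories
    col_idx: dict[str, list[int]] = {c: [] for c in cats}
    for j, s in enumerate(matrix.samples):
        if s.category in col_idx:
            col_idx[s.category].append(j)
    missing = [c for c in cats if not col_idx[c]]
    if missing:
        raise ValueError(f"design categories absent from matrix metadata: {missing}")
    small = [c for c in cats if len(col_idx[c]) < 2]
    if small:
        raise ValueError(f"categories with <2 samples: {small}")

    X = matrix.values
    n_used = sum(len(ix) for ix in col_idx.values())
    K = len(cats)
    means = np.column_stack([X[:, col_idx[c]].mean(axis=1) for c in cats])
    rss = np.zeros(X.shape[0])
    for k, c in enumerate(cats):
        block = X[:, col_idx[c]]
        rss += ((block - means[:, [k]]) ** 2).sum(axis=1)
    df = n_used - K
    s2 = rss / df
    cat_pos = {c: k for k, c in enumerate(cats)}
    beta = np.column_stack(
        [means[:, cat_pos[a]] - means[:, cat_pos[b]] for a, b in design.contrasts]
    )
    v = np.array(
        [1.0 / len(col_idx[a]) + 1.0 / len(col_idx[b]) for a, b in design.contrasts]
    )
    used = sorted(j for ix in col_idx.values() for j in ix)
    ave = X[:, used].mean(axis=1)
    return LinearFit(design, list(matrix.row_ids), means, beta, s2, float(df), v, ave)


@dataclass
class EBayesParams:
    """Prior df d0, prior variance s0², and posterior variances.

    s2_post = (d0*s0² + df*s2) / (d0 + df): a convex combination, so it
    always lies between s0² and the row's own s2.
    """

    d0: float
    s0_sq: float
    s2_post: np.ndarray


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def ebayes_moderate(fit: LinearFit) -> EBayesParams:
    """Estimate the variance prior by method of moments on log variances.

    With z_g = log s_g² and d = df, e_g = z_g - psi(d/2) + log(d/2) is an
    unbiased estimate of log s0² up to the prior spread; the excess of
    var(e_g) over trigamma(d/2) identifies trigamma(d0/2).  If that excess
    is <= 0 the rows are consistent with a single common variance and d0
    is capped (posterior variances collapse onto s0²).

    Rows with s_g² = 0 are excluded from estimation (floor them upstream);
    needs >=10 positive-variance rows, errors if all are zero.
    """
    s2 = fit.s2
    pos = s2 > 0
    if not pos.any():
        raise ValueError("all residual variances are zero; cannot moderate")
    if pos.sum() < 10:
        logger.warning(
            "only %d rows with positive variance; prior estimate unstable", pos.sum()
        )
    d = fit.df_residual
    z = np.log(s2[pos])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    G = e.size
    ebar = e.mean()
    rhs = np.mean((e - ebar) ** 2) * G / max(G - 1, 1) - special.polygamma(1, d / 2.0)
    if rhs <= 0:
        # rows consistent with one shared variance: point-mass prior, whose
        # natural scale estimate is the plain mean of the sample variances
        d0 = D0_CAP
        s0_sq = float(np.mean(s2[pos]))
    else:
        d0 = 2.0 * _trigamma_inverse(float(rhs))
        s0_sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    return EBayesParams(float(d0), s0_sq, s2_post)


def treat_test(
    fit: LinearFit, eb: EBayesParams, tau: float = 1.0
) -> np.ndarray:
    """p-values for |log2 fold change| exceeding the threshold tau.

    For each row and contrast, with u = s_post * sqrt(v_c) and
    df = d0 + df_residual:

        p = P(T_df >= (|b| - tau)/u) + P(T_df >= (|b| + tau)/u)

    At tau = 0 this is the ordinary two-sided moderated t.  Returns a
    rows × contrasts array.  Rows with zero posterior variance are an
    error (apply a variance floor first).
    """
    if tau < 0:
        raise ValueError("threshold tau must be >= 0")
    u = np.sqrt(eb.s2_post)[:, None] * np.sqrt(fit.v)[None, :]
    if np.any(u == 0):
        raise ValueError(
            "zero posterior standard error; floor zero variances before testing"
        )
    df = eb.d0 + fit.df_residual
    absb = np.abs(fit.beta)
    p = stats.t.sf((absb - tau) / u, df) + stats.t.sf((absb + tau) / u, df)
    return np.minimum(p, 1.0)


def bh_adjust(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment (default Benjamini-Hochberg step-up).

    method in {"bh", "bonferroni", "holm"}.  Input must lie in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    codes = {"bh": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}
    try:
        code = codes[method]
    except KeyError:
        raise ValueError(f"unknown adjustment {method!r}; choose from {sorted(codes)}") from None
    flat = p.ravel()
    _, adj, _, _ = multipletests(flat, alpha=0.05, method=code)
    return adj.reshape(p.shape)


@dataclass
class DEGTable:
    """Tidy per-row × contrast differential-expression results."""

    frame: pd.DataFrame
    design: DesignSpec
    tau: float
    fdr: float
    eb: EBayesParams

    def significant(self, contrast: tuple[str, str] | None = None) -> pd.DataFrame:
        df = self.frame[self.frame["significant"]]
        if contrast is not None:
            label = f"{contrast[0]}_vs_{contrast[1]}"
            df = df[df["contrast"] == label]
        return df

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def build_deg_table(
    matrix: ExpressionMatrix,
    design: DesignSpec | None = None,
    tau: float = 1.0,
    fdr: float = 0.05,
    adjust: str = "bh",
) -> DEGTable:
    """Full differential-expression pipeline for one expression matrix.

    Fit group means, floor zero residual variances at the 1st percentile
    of the positive ones (flagged in the output), moderate, apply the
    threshold test, and adjust p-values within each contrast.  A row is
    flagged significant when its adjusted p < ``fdr``.
    """
    if design is None:
        design = DesignSpec.from_matrix(matrix)
    fit = fit_group_means(matrix, design)
    floored = fit.s2 == 0
    if floored.any():
        positive = fit.s2[fit.s2 > 0]
        if positive.size == 0:
            raise ValueError("all residual variances are zero")
        floor = float(np.percentile(positive, 1))
        fit.s2 = np.where(floored, floor, fit.s2)
        logger.info("floored %d zero residual variances at %g", floored.sum(), floor)
    eb = ebayes_moderate(fit)
    p = treat_test(fit, eb, tau=tau)
    t_stat = fit.beta / (np.sqrt(eb.s2_post)[:, None] * np.sqrt(fit.v)[None, :])

    frames = []
    for c, (a, b) in enumerate(design.contrasts):
        adj = bh_adjust(p[:, c], method=adjust)
        frames.append(
            pd.DataFrame(
                {
                    "row_id": fit.row_ids,
                    "contrast": f"{a}_vs_{b}",
                    "log2fc": fit.beta[:, c],
                    "ave_expr": fit.ave_expr,
                    "t": t_stat[:, c],
                    "p_value": p[:, c],
                    "adj_p_value": adj,
                    "significant": adj < fdr,
                    "variance_floored": floored,
                }
            )
        )
    frame = pd.concat(frames, ignore_index=True)
    return DEGTable(frame, design, tau, fdr, eb)
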