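"""The RMA normalization chain and gene-level collapsing.

Stages, applied in order to a probe-level experiment:

1. normexp background correction per array — the observed intensity is
   modelled as S = X + Y with true signal X ~ Exponential(mean alpha) and
   optical background Y ~ Normal(mu, sigma^2); the correction replaces S
   with the posterior mean E[X | S], which is strictly positive.
2. quantile normalization across arrays — every column is mapped onto the
   across-array mean of order statistics, so all arrays share one
   empirical distribution.
3. log2 transform.
4. Tukey median-polish summarization of each probeset's probes into one
   expression value per array.

The result is a probeset-level log2 expression matrix, optionally
collapsed to gene level by averaging a gene's probesets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special, stats

from .core_io import ChipDefinition, ProbeExperiment, SampleMeta, write_tsv_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormexpParams:
    """Parameters of the exponential-signal + normal-background model.

    mu, sigma: background mean and sd (intensity units); alpha: mean of
    the exponential signal component.
    """

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and self.sigma > 0 and self.alpha > 0):
            raise ValueError(
                f"invalid normexp parameters mu={self.mu}, sigma={self.sigma}, "
                f"alpha={self.alpha}: need sigma > 0 and alpha > 0"
            )


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression (probesets or genes × samples)."""

    values: np.ndarray
    row_ids: list[str]
    samples: list[SampleMeta]
    level: str = "probeset"  # "probeset" | "gene"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.samples)):
            raise ValueError(
                f"shape {self.values.shape} disagrees with {len(self.row_ids)} rows "
                f"x {len(self.samples)} samples"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("row ids not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.level not in ("probeset", "gene"):
            raise ValueError(f"unknown level tag {self.level!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def category_of(self) -> list[str]:
        return [s.category for s in self.samples]

    def to_tsv(self, path: str | Path, metadata_path: str | Path | None = None) -> None:
        """Write values as TSV plus a sidecar sample-metadata table."""
        write_tsv_matrix(self.values, self.row_ids, self.sample_ids, path)
        if metadata_path is not None:
            with open(metadata_path, "w") as fh:
                fh.write(f"#level={self.level}\n")
                fh.write("sample_id\tseries_id\tplatform_id\tcategory\n")
                for s in self.samples:
                    fh.write(
                        f"{s.sample_id}\t{s.series_id}\t{s.platform_id}\t{s.category}\n"
                    )

    @classmethod
    def from_tsv(
        cls, path: str | Path, metadata_path: str | Path | None = None
    ) -> "ExpressionMatrix":
        from .core_io import UNASSIGNED, load_tsv_matrix

        values, row_ids, col_ids = load_tsv_matrix(path)
        level = "probeset"
        metas = [SampleMeta(sample_id=c) for c in col_ids]
        if metadata_path is not None:
            rows: dict[str, SampleMeta] = {}
            with open(metadata_path) as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if line.startswith("#level="):
                        level = line.split("=", 1)[1].strip()
                        continue
                    if not line or line.startswith("#") or line.startswith("sample_id\t"):
                        continue
                    sid, series, platform, cat = (line.split("\t") + [""] * 4)[:4]
                    rows[sid] = SampleMeta(sid, series, platform, cat or UNASSIGNED)
            metas = [rows.get(c, SampleMeta(sample_id=c)) for c in col_ids]
        return cls(values, row_ids, metas, level=level)


# ---------------------------------------------------------------------------
# normexp background correction


def normexp_correct(column: np.ndarray, params: NormexpParams) -> np.ndarray:
    """Posterior-mean signal E[X | S = s] under the normexp model.

    E[X | S=s] = m + sigma * phi(m/sigma) / Phi(m/sigma) with
    m = s - mu - sigma^2/alpha.  Strictly positive and strictly increasing
    in s.  Evaluated via log-space normal functions so that deeply
    negative m/sigma does not underflow; below t = -30 the asymptotic
    expansion sigma*(1/|t| - 2/|t|^3) is used to avoid cancellation.
    """
    s = np.asarray(column, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("normexp_correct requires finite intensities")
    m = s - params.mu - params.sigma**2 / params.alpha
    t = m / params.sigma
    out = np.empty_like(t)
    far = t < -30.0
    near = ~far
    # stable Mills-ratio evaluation: phi/Phi = exp(logpdf - logcdf)
    tn = t[near]
    ratio = np.exp(stats.norm.logpdf(tn) - special.log_ndtr(tn))
    out[near] = params.sigma * (tn + ratio)
    a = -t[far]
    out[far] = params.sigma * (1.0 / a - 2.0 / a**3)
    return out


def _normexp_nll(theta: np.ndarray, s: np.ndarray) -> float:
    """Negative log-likelihood of the exponential+normal convolution.

    theta = (mu, log sigma, log alpha).  The density is
    f(s) = (1/alpha) exp((mu-s)/alpha + sigma^2/(2 alpha^2)) Phi(t),
    t = (s-mu)/sigma - sigma/alpha, evaluated in log space.
    """
    mu, log_sigma, log_alpha = theta
    sigma, alpha = np.exp(log_sigma), np.exp(log_alpha)
    t = (s - mu) / sigma - sigma / alpha
    ll = -log_alpha + (mu - s) / alpha + sigma**2 / (2 * alpha**2) + special.log_ndtr(t)
    return -float(np.mean(ll))


def _density_mode(x: np.ndarray) -> float:
    """Mode of a kernel density estimate on a 512-point grid.

    Large inputs are thinned to 16384 evenly spaced order statistics
    (deterministic) before KDE.
    """
    xs = np.sort(x)
    if xs.size > 16384:
        idx = np.linspace(0, xs.size - 1, 16384).round().astype(int)
        xs = xs[idx]
    kde = stats.gaussian_kde(xs)
    lo, hi = xs[0], np.quantile(xs, 0.999)
    grid = np.linspace(lo, hi, 512)
    return float(grid[np.argmax(kde(grid))])


def estimate_normexp_params(
    column: np.ndarray, min_probes_warn: int = 1000
) -> NormexpParams:
    """Estimate normexp parameters for one array by maximum likelihood.

    A mode-based scheme provides the starting point (kernel-density mode
    for the background mean, RMS deviation of sub-mode points for its sd,
    mean excess of supra-mode points for the signal mean); the convolution
    likelihood is then maximized with Nelder-Mead.  The mode-based start
    alone overestimates the background mean when the signal dominates
    (the density mode sits ~2 background sd above the background mean for
    alpha >> sigma), which is why the likelihood refinement is not
    optional.

    Raises ValueError on a constant column.
    """
    s = np.asarray(column, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite intensities")
    if s.size < 2 or np.ptp(s) == 0:
        raise ValueError("cannot estimate background from a constant column")
    if s.size < min_probes_warn:
        logger.warning(
            "normexp estimation on only %d probes; >=%d recommended",
            s.size,
            min_probes_warn,
        )
    mode = _density_mode(s)
    below = s[s < mode]
    above = s[s > mode]
    sigma0 = float(np.sqrt(np.mean((below - mode) ** 2))) if below.size else np.std(s)
    alpha0 = float(np.mean(above - mode)) if above.size else np.mean(s) - mode
    sigma0 = max(sigma0, 1e-6 * np.ptp(s))
    alpha0 = max(alpha0, 1e-6 * np.ptp(s))
    theta0 = np.array([mode, np.log(sigma0), np.log(alpha0)])
    res = optimize.minimize(
        _normexp_nll,
        theta0,
        args=(s,),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
    )
    mu, log_sigma, log_alpha = res.x
    return NormexpParams(float(mu), float(np.exp(log_sigma)), float(np.exp(log_alpha)))


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force every column onto the across-column mean of order statistics.

    Ties within a column receive the mean of the reference values at their
    tied ranks, so tied entries stay tied after normalization.  Requires a
    complete matrix with >=2 columns (impute upstream).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("quantile normalization needs a 2-D matrix with >=2 columns")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing values not allowed; impute before normalization")
    n = m.shape[0]
    order = np.argsort(m, axis=0, kind="stable")
    reference = np.take_along_axis(m, order, axis=0).mean(axis=1)
    out = np.empty_like(m)
    for j in range(m.shape[1]):
        col_order = order[:, j]
        sorted_vals = m[col_order, j]
        mapped = reference.copy()
        # tie runs share the mean of the reference values they span
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        for a, b in zip(starts, ends):
            if b - a > 1:
                mapped[a:b] = reference[a:b].mean()
        out[col_order, j] = mapped
    return out


def log2_transform(matrix: np.ndarray) -> np.ndarray:
    """Elementwise log2; raises on non-positive values."""
    m = np.asarray(matrix, dtype=float)
    if np.any(~np.isfinite(m)) or np.any(m <= 0):
        raise ValueError("log2 transform requires finite values > 0")
    return np.log2(m)


# ---------------------------------------------------------------------------
# median polish


def median_polish(
    block: np.ndarray, tol: float = 0.01, max_iter: int = 10
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish: overall + row + column effects + residuals.

    Alternating row-median then column-median sweeps until the sum of
    absolute residual change drops below ``tol`` or ``max_iter`` sweeps.
    Returns (overall, row_effects, col_effects, residuals).
    """
    z = np.array(block, dtype=float)
    if z.ndim != 2:
        raise ValueError("median polish expects a 2-D block")
    nr, nc = z.shape
    overall = 0.0
    row_eff = np.zeros(nr)
    col_eff = np.zeros(nc)
    last_abs = np.abs(z).sum()
    for _ in range(max_iter):
        rmed = np.median(z, axis=1)
        row_eff += rmed
        z -= rmed[:, None]
        cmed_of_row = np.median(row_eff)
        overall += cmed_of_row
        row_eff -= cmed_of_row
        cmed = np.median(z, axis=0)
        col_eff += cmed
        z -= cmed[None, :]
        rmed_of_col = np.median(col_eff)
        overall += rmed_of_col
        col_eff -= rmed_of_col
        cur_abs = np.abs(z).sum()
        if abs(last_abs - cur_abs) < tol:
            break
        last_abs = cur_abs
    return overall, row_eff, col_eff, z


def median_polish_summarize(
    block: np.ndarray, tol: float = 0.01, max_iter: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Summarize one probeset's log2 probe block to per-sample expression.

    expression_j = overall + column_effect_j.  A single-probe block passes
    through unchanged (zero residuals).
    """
    z = np.asarray(block, dtype=float)
    if z.ndim == 1:
        z = z[None, :]
    if z.shape[0] == 1:
        return z[0].copy(), np.zeros_like(z)
    overall, _row, col, resid = median_polish(z, tol=tol, max_iter=max_iter)
    return overall + col, resid


# ---------------------------------------------------------------------------
# full chain


def rma(
    experiment: ProbeExperiment,
    tol: float = 0.01,
    max_iter: int = 10,
    background: bool = True,
) -> ExpressionMatrix:
    """Full RMA: normexp correct → quantile normalize → log2 → median polish.

    Normexp parameters are estimated per array.  Rows of the output are
    sorted probeset ids; probe order within a probeset does not affect the
    result (median polish is row-order invariant).
    """
    if experiment.chip is None:
        raise ValueError("RMA needs a chip definition to group probes into probesets")
    m = experiment.intensities
    if background:
        corrected = np.empty_like(m)
        for j in range(m.shape[1]):
            params = estimate_normexp_params(m[:, j])
            corrected[:, j] = normexp_correct(m[:, j], params)
    else:
        corrected = m.astype(float)
    normalized = quantile_normalize(corrected)
    logged = log2_transform(normalized)

    p2ps = experiment.chip.probe_to_probeset
    groups: dict[str, list[int]] = {}
    n_unmapped = 0
    for i, probe in enumerate(experiment.probe_ids):
        ps = p2ps.get(probe)
        if ps is None:
            n_unmapped += 1
            continue
        groups.setdefault(ps, []).append(i)
    if n_unmapped:
        logger.info("%d probes not in the chip definition; dropped", n_unmapped)
    probeset_ids = sorted(groups)
    values = np.empty((len(probeset_ids), m.shape[1]))
    for r, ps in enumerate(probeset_ids):
        expr, _ = median_polish_summarize(logged[groups[ps], :], tol=tol, max_iter=max_iter)
        values[r] = expr
    return ExpressionMatrix(values, probeset_ids, list(experiment.samples), "probeset")


_COLLAPSE_FUNCS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "mean": lambda block: block.mean(axis=0),
    "median": lambda block: np.median(block, axis=0),
    # the single probeset with the highest average expression represents the gene
    "max": lambda block: block[np.argmax(block.mean(axis=1))],
}


def collapse_to_genes(
    matrix: ExpressionMatrix, chip: ChipDefinition, how: str = "mean"
) -> ExpressionMatrix:
    """Collapse a probeset-level matrix to gene level.

    Per gene and sample, aggregates log2 values across the gene's
    probesets (default: mean).  Probesets without a gene symbol are
    dropped with a logged count.  Gene rows come out sorted by symbol.
    """
    if matrix.level != "probeset":
        raise ValueError(f"expected a probeset-level matrix, got {matrix.level!r}")
    try:
        agg = _COLLAPSE_FUNCS[how]
    except KeyError:
        raise ValueError(
            f"unknown collapse strategy {how!r}; choose from {sorted(_COLLAPSE_FUNCS)}"
        ) from None
    ps2g = chip.probeset_to_gene
    groups: dict[str, list[int]] = {}
    n_unannotated = 0
    for i, ps in enumerate(matrix.row_ids):
        gene = ps2g.get(ps, "")
        if not gene:
            n_unannotated += 1
            continue
        groups.setdefault(gene, []).append(i)
    if n_unannotated:
        logger.info("%d unannotated probesets dropped at gene collapse", n_unannotated)
    genes = sorted(groups)
    values = np.empty((len(genes), matrix.values.shape[1]))
    for r, g in enumerate(genes):
        values[r] = agg(matrix.values[groups[g], :])
    return ExpressionMatrix(values, genes, list(matrix.samples), "gene")
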