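"""Domain types, file parsing, sample categorization, and design-sanity checks.

The entry point for expression data is probe-level intensity matrices,
either as GEO series-matrix text files or as plain TSV tables.  All values
are linear-scale fluorescence intensities; log transformation happens in
the preprocessing chain, never at ingestion.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

#: GEO series-matrix null tokens treated as missing values.
NULL_TOKENS = frozenset({"null", "NULL", "NA", "", "nan", "NaN"})

#: Samples with more than this fraction of missing probes are rejected;
#: below it, missing entries are imputed by the probe's median across the
#: remaining samples.
MAX_MISSING_FRACTION = 0.01


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


class DesignError(ValueError):
    """Raised when a sample/category design is statistically unusable."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one hybridized array (one biological sample)."""

    sample_id: str
    series_id: str = ""
    platform_id: str = ""
    category: str = UNASSIGNED

    @property
    def assigned(self) -> bool:
        return self.category != UNASSIGNED


@dataclass(frozen=True)
class ChipDefinition:
    """Probe → probeset → gene symbol maps defining summarization levels.

    Probesets without a gene symbol are retained but flagged unannotated
    (empty-string symbol); they survive normalization and are dropped only
    at the gene-collapse step.
    """

    probe_to_probeset: Mapping[str, str]
    probeset_to_gene: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(self.probe_to_probeset.values()) - set(self.probeset_to_gene)
        if missing:
            # tolerate probesets absent from the gene map: flag unannotated
            merged = dict(self.probeset_to_gene)
            for ps in missing:
                merged[ps] = ""
            object.__setattr__(self, "probeset_to_gene", merged)

    @property
    def unannotated_probesets(self) -> set[str]:
        return {ps for ps, g in self.probeset_to_gene.items() if not g}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChipDefinition":
        """Read a 3-column TSV: probe_id, probeset_id, gene_symbol."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        cols = [c.lower() for c in df.columns]
        if len(df.columns) < 2:
            raise ParseError(f"chip definition needs >=2 columns, got {list(df.columns)}")
        df.columns = cols[: len(df.columns)]
        probe_col, probeset_col = df.columns[0], df.columns[1]
        dup = df[probe_col][df[probe_col].duplicated()]
        if not dup.empty:
            conflicting = df.groupby(probe_col)[probeset_col].nunique()
            bad = conflicting[conflicting > 1]
            if not bad.empty:
                raise ParseError(f"probe maps to multiple probesets: {bad.index[0]!r}")
            df = df.drop_duplicates(subset=probe_col)
        p2ps = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        if df.shape[1] >= 3:
            ps2g = dict(zip(df.iloc[:, 1], df.iloc[:, 2]))
        else:
            ps2g = {ps: "" for ps in p2ps.values()}
        return cls(p2ps, ps2g)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (probe, ps, self.probeset_to_gene.get(ps, ""))
            for probe, ps in sorted(self.probe_to_probeset.items())
        ]
        pd.DataFrame(rows, columns=["probe_id", "probeset_id", "gene_symbol"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class ReceptorAnnotation:
    """Gene symbol → set of receptor categories (cytokine receptor, GPCR, ...).

    A gene may carry several categories.  Symbol lookup is
    case-insensitive (mouse and human symbol case conventions differ);
    symbols are stored as first given.
    """

    gene_categories: Mapping[str, frozenset[str]]
    _lower_index: Mapping[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for gene, cats in self.gene_categories.items():
            if not cats:
                raise ValueError(f"gene {gene!r} has an empty category set")
        object.__setattr__(
            self, "_lower_index", {g.lower(): g for g in self.gene_categories}
        )

    @property
    def categories(self) -> set[str]:
        """The category universe across all listed genes."""
        out: set[str] = set()
        for cats in self.gene_categories.values():
            out |= cats
        return out

    def lookup(self, gene_symbol: str) -> frozenset[str]:
        """Categories for a symbol, case-insensitively; empty set if absent."""
        key = self._lower_index.get(gene_symbol.lower())
        if key is None:
            return frozenset()
        return self.gene_categories[key]

    def __contains__(self, gene_symbol: str) -> bool:
        return gene_symbol.lower() in self._lower_index


@dataclass
class ProbeExperiment:
    """Raw probe × sample intensity matrix with sample metadata.

    Invariants: intensities finite and strictly positive after ingestion;
    ``intensities.shape == (len(probe_ids), len(samples))``; sample ids
    unique; all samples share one platform.
    """

    intensities: np.ndarray
    probe_ids: list[str]
    samples: list[SampleMeta]
    chip: ChipDefinition | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.probe_ids), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.intensities.shape} disagrees with "
                f"{len(self.probe_ids)} probes x {len(self.samples)} samples"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dup}")
        platforms = {s.platform_id for s in self.samples if s.platform_id}
        if len(platforms) > 1:
            raise DesignError(
                f"mixed platforms in one experiment: {sorted(platforms)}; "
                "pool within a single platform"
            )
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities <= 0):
            raise ValueError("intensities must be finite and > 0 after ingestion")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def categories(self) -> dict[str, int]:
        """Counts of assigned samples per category."""
        out: dict[str, int] = {}
        for s in self.samples:
            if s.assigned:
                out[s.category] = out.get(s.category, 0) + 1
        return out

    def assigned_subset(self) -> "ProbeExperiment":
        """Experiment restricted to category-assigned samples, order kept."""
        keep = [i for i, s in enumerate(self.samples) if s.assigned]
        return ProbeExperiment(
            self.intensities[:, keep],
            list(self.probe_ids),
            [self.samples[i] for i in keep],
            self.chip,
        )


# ---------------------------------------------------------------------------
# parsing


def _resolve_missing(
    matrix: np.ndarray, sample_ids: Sequence[str]
) -> np.ndarray:
    """Apply the missing-value policy: reject samples with >1% missing
    probes, impute the rest by the probe's median over complete samples."""
    miss = ~np.isfinite(matrix)
    if not miss.any():
        return matrix
    frac = miss.mean(axis=0)
    bad = np.nonzero(frac > MAX_MISSING_FRACTION)[0]
    if bad.size:
        names = [sample_ids[i] for i in bad]
        raise ParseError(
            f"samples with >{MAX_MISSING_FRACTION:.0%} missing probes rejected: {names}"
        )
    out = matrix.copy()
    rows = np.nonzero(miss.any(axis=1))[0]
    n_imputed = 0
    for r in rows:
        row = out[r]
        ok = np.isfinite(row)
        if not ok.any():
            raise ParseError(f"probe row {r} entirely missing")
        med = float(np.median(row[ok]))
        row[~ok] = med
        n_imputed += int((~ok).sum())
    logger.info("imputed %d missing intensities by probe median", n_imputed)
    return out


def parse_series_matrix(path: str | Path) -> ProbeExperiment:
    """Parse a GEO series-matrix text file into a :class:`ProbeExperiment`.

    Reads the metadata lines (``!Series_geo_accession``,
    ``!Sample_geo_accession``, ``!Sample_platform_id``,
    ``!Series_matrix_table_begin`` ... ``!Series_matrix_table_end``) and the
    probe × sample table between the markers, preserving file order.
    Two-channel series (``!Sample_channel_count`` other than 1) are
    rejected: only single-channel arrays can be pooled across studies.

    Raises :class:`ParseError` on missing table markers, duplicated probe
    ids, or non-numeric cells other than the declared null tokens.
    """
    path = Path(path)
    series_id = ""
    platform_ids: list[str] = []
    sample_ids: list[str] = []
    channel_counts: list[str] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if line.startswith("!series_matrix_table_begin") or line.startswith(
                "!Series_matrix_table_begin"
            ):
                in_table, saw_begin = True, True
                continue
            if line.startswith("!series_matrix_table_end") or line.startswith(
                "!Series_matrix_table_end"
            ):
                in_table, saw_end = False, True
                continue
            if in_table:
                if line:
                    table_lines.append(line)
                continue
            if line.startswith("!Series_geo_accession"):
                parts = line.split("\t")
                if len(parts) > 1:
                    series_id = parts[1].strip().strip('"')
            elif line.startswith("!Sample_geo_accession"):
                sample_ids = [t.strip().strip('"') for t in line.split("\t")[1:]]
            elif line.startswith("!Sample_platform_id"):
                platform_ids = [t.strip().strip('"') for t in line.split("\t")[1:]]
            elif line.startswith("!Sample_channel_count"):
                channel_counts = [t.strip().strip('"') for t in line.split("\t")[1:]]

    if not (saw_begin and saw_end):
        raise ParseError(f"{path.name}: series-matrix table markers not found")
    if not table_lines:
        raise ParseError(f"{path.name}: empty series-matrix table")
    for cc in channel_counts:
        if cc and cc != "1":
            raise ParseError(
                f"{path.name}: two-channel (competitive) arrays are not supported "
                f"(channel count {cc})"
            )

    header = [t.strip().strip('"') for t in table_lines[0].split("\t")]
    table_sample_ids = header[1:]
    if sample_ids and sample_ids != table_sample_ids:
        # prefer the explicit metadata line; require consistency on length
        if len(sample_ids) != len(table_sample_ids):
            raise ParseError(
                f"{path.name}: sample-id metadata disagrees with table header"
            )
    ids = sample_ids or table_sample_ids

    probe_ids: list[str] = []
    seen: set[str] = set()
    values = np.empty((len(table_lines) - 1, len(ids)), dtype=float)
    for r, line in enumerate(table_lines[1:]):
        cells = [t.strip().strip('"') for t in line.split("\t")]
        if len(cells) != len(ids) + 1:
            raise ParseError(
                f"{path.name}: row {r + 1} has {len(cells) - 1} values, "
                f"expected {len(ids)}"
            )
        probe = cells[0]
        if probe in seen:
            raise ParseError(f"{path.name}: duplicated probe id {probe!r}")
        seen.add(probe)
        probe_ids.append(probe)
        for c, cell in enumerate(cells[1:]):
            if cell in NULL_TOKENS:
                values[r, c] = np.nan
            else:
                try:
                    values[r, c] = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path.name}: non-numeric cell {cell!r} at probe "
                        f"{probe!r}, sample {ids[c]!r}"
                    ) from None

    values = _resolve_missing(values, ids)
    if np.any(values <= 0):
        raise ParseError(f"{path.name}: non-positive intensities present")

    if len(platform_ids) not in (0, len(ids)):
        raise ParseError(f"{path.name}: platform-id metadata length mismatch")
    metas = [
        SampleMeta(
            sample_id=sid,
            series_id=series_id,
            platform_id=platform_ids[i] if platform_ids else "",
        )
        for i, sid in enumerate(ids)
    ]
    return ProbeExperiment(values, probe_ids, metas)


def load_tsv_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a plain probe × sample TSV (header = sample ids, col 0 = probe ids).

    Returns ``(matrix, row_ids, column_ids)`` with values preserved exactly.
    Raises :class:`ParseError` on an empty file, ragged rows, duplicated
    row ids, or non-numeric cells.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [
            ln.rstrip("\n").rstrip("\r")
            for ln in fh
            if ln.strip() and not ln.startswith("#")
        ]
    if not lines:
        raise ParseError(f"{path.name}: empty file")
    header = lines[0].split("\t")
    col_ids = header[1:]
    if not col_ids:
        raise ParseError(f"{path.name}: no sample columns")
    row_ids: list[str] = []
    seen: set[str] = set()
    values = np.empty((len(lines) - 1, len(col_ids)), dtype=float)
    for r, line in enumerate(lines[1:]):
        cells = line.split("\t")
        if len(cells) != len(col_ids) + 1:
            raise ParseError(
                f"{path.name}: ragged row {r + 1}: {len(cells) - 1} values, "
                f"expected {len(col_ids)}"
            )
        rid = cells[0]
        if rid in seen:
            raise ParseError(f"{path.name}: duplicated row id {rid!r}")
        seen.add(rid)
        row_ids.append(rid)
        for c, cell in enumerate(cells[1:]):
            if cell in NULL_TOKENS:
                values[r, c] = np.nan
            else:
                try:
                    values[r, c] = float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path.name}: non-numeric cell {cell!r} at row "
                        f"{rid!r}, column {col_ids[c]!r}"
                    ) from None
    return values, row_ids, col_ids


def write_tsv_matrix(
    matrix: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    path: str | Path,
    float_format: str = "%.17g",
) -> None:
    """Write a matrix as TSV, inverse of :func:`load_tsv_matrix`."""
    matrix = np.asarray(matrix)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(col_ids) + "\n")
        for rid, row in zip(row_ids, matrix):
            fh.write(rid + "\t" + "\t".join(float_format % v for v in row) + "\n")


def serialize_series_matrix(experiment: ProbeExperiment, path: str | Path) -> None:
    """Write an experiment as a GEO-style series-matrix text file."""
    samples = experiment.samples
    series_ids = {s.series_id for s in samples}
    series_id = series_ids.pop() if len(series_ids) == 1 else "POOLED"
    with open(path, "w") as fh:
        fh.write(f'!Series_geo_accession\t"{series_id}"\n')
        fh.write(
            "!Sample_geo_accession\t"
            + "\t".join(f'"{s.sample_id}"' for s in samples)
            + "\n"
        )
        fh.write(
            "!Sample_platform_id\t"
            + "\t".join(f'"{s.platform_id}"' for s in samples)
            + "\n"
        )
        fh.write("!Sample_channel_count\t" + "\t".join('"1"' for _ in samples) + "\n")
        fh.write("!series_matrix_table_begin\n")
        fh.write('"ID_REF"\t' + "\t".join(f'"{s.sample_id}"' for s in samples) + "\n")
        for probe, row in zip(experiment.probe_ids, experiment.intensities):
            fh.write(probe + "\t" + "\t".join("%.17g" % v for v in row) + "\n")
        fh.write("!series_matrix_table_end\n")


def merge_experiments(experiments: Iterable[ProbeExperiment]) -> ProbeExperiment:
    """Pool several series into one experiment (shared probe universe).

    All inputs must share the same probe ids (any order); probes are
    aligned to the first experiment's order.
    """
    experiments = list(experiments)
    if not experiments:
        raise ValueError("no experiments to merge")
    first = experiments[0]
    ref = first.probe_ids
    ref_index = {p: i for i, p in enumerate(ref)}
    mats = [first.intensities]
    samples = list(first.samples)
    chip = first.chip
    for exp in experiments[1:]:
        if set(exp.probe_ids) != set(ref):
            raise ValueError("experiments have different probe universes")
        order = [ref_index[p] for p in exp.probe_ids]
        aligned = np.empty_like(exp.intensities)
        aligned[order, :] = exp.intensities
        mats.append(aligned)
        samples.extend(exp.samples)
        chip = chip or exp.chip
    return ProbeExperiment(np.hstack(mats), list(ref), samples, chip)


# ---------------------------------------------------------------------------
# categorization and design checks


def load_assignment_table(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (sample_id, category) into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError("assignment table needs 2 columns: sample_id, category")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def assign_categories(
    experiment: ProbeExperiment, assignment: Mapping[str, str]
) -> ProbeExperiment:
    """Attach category labels to samples from a sample_id → category map.

    Unassigned samples are kept in the metadata (their count is logged)
    but are dropped from downstream statistics via
    :meth:`ProbeExperiment.assigned_subset`.  The intensity matrix and
    sample order are never reordered.

    Raises :class:`DesignError` for assignments naming unknown samples or
    producing a category with fewer than 2 samples (its variance would be
    undefined).
    """
    known = set(experiment.sample_ids)
    unknown = sorted(set(assignment) - known)
    if unknown:
        raise DesignError(f"assignment references unknown sample ids: {unknown}")
    counts: dict[str, int] = {}
    for cat in assignment.values():
        counts[cat] = counts.get(cat, 0) + 1
    singletons = sorted(c for c, n in counts.items() if n < 2)
    if singletons:
        raise DesignError(
            f"categories with <2 samples (variance undefined): {singletons}"
        )
    new_samples = [
        replace(s, category=assignment.get(s.sample_id, UNASSIGNED))
        for s in experiment.samples
    ]
    n_unassigned = sum(1 for s in new_samples if not s.assigned)
    if n_unassigned:
        logger.info(
            "%d of %d samples left unassigned; excluded from statistics",
            n_unassigned,
            len(new_samples),
        )
    return ProbeExperiment(
        experiment.intensities, list(experiment.probe_ids), new_samples, experiment.chip
    )


def confound_check(experiment: ProbeExperiment) -> list[str]:
    """Warn for every category whose samples all come from one series.

    When a biological category is drawn entirely from a single deposited
    study, batch (technical) and biological variation are inseparable.
    Returns one warning string per fully-confounded category, in sorted
    category order; an empty list means no confound.
    """
    by_cat: dict[str, set[str]] = {}
    for s in experiment.samples:
        if s.assigned:
            by_cat.setdefault(s.category, set()).add(s.series_id)
    warnings = []
    for cat in sorted(by_cat):
        series = by_cat[cat]
        if len(series) == 1:
            (only,) = series
            msg = (
                f"category {cat!r}: all samples come from series {only!r}; "
                "biological and technical effects are confounded"
            )
            warnings.append(msg)
            logger.warning(msg)
    return warnings


def load_receptor_lists(path: str | Path) -> ReceptorAnnotation:
    """Read a 2-column TSV (gene_symbol, category) into a ReceptorAnnotation.

    Repeated genes merge into multi-category membership; exactly duplicated
    rows deduplicate; symbols differing only in case merge under the first
    spelling seen.  Raises :class:`ParseError` on an empty file.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path.name}: empty receptor list")
    # Tolerate an optional header row (detected by common header words).
    first = lines[0].split("\t")
    start = 1 if first and first[0].lower() in {"gene", "gene_symbol", "symbol"} else 0
    rows = lines[start:]
    if not rows:
        raise ParseError(f"{path.name}: receptor list has a header but no rows")
    merged: dict[str, set[str]] = {}
    canonical: dict[str, str] = {}
    for ln in rows:
        cells = ln.split("\t")
        if len(cells) < 2:
            raise ParseError(f"{path.name}: receptor list row needs 2 columns: {ln!r}")
        gene, cat = cells[0].strip(), cells[1].strip()
        if not gene or not cat:
            raise ParseError(f"{path.name}: blank gene or category in row {ln!r}")
        key = canonical.setdefault(gene.lower(), gene)
        merged.setdefault(key, set()).add(cat)
    return ReceptorAnnotation({g: frozenset(c) for g, c in merged.items()})
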