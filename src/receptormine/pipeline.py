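"""End-to-end pipeline orchestration with provenance.

Runs ingest → normalize → differential expression → sPLS-DA → receptor
screen from a single validated configuration, writing every intermediate
artifact as TSV with a provenance header (tool version + config hash).
Stage parameters and input paths live in one YAML/dict config; see
:class:`RunConfig`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .core_io import (
    ChipDefinition,
    ProbeExperiment,
    assign_categories,
    confound_check,
    load_assignment_table,
    load_receptor_lists,
    merge_experiments,
    parse_series_matrix,
)
from .diffexpr import DesignSpec, build_deg_table
from .preprocess import collapse_to_genes, rma
from .screen import build_report, cluster_samples_and_genes
from .splsda import splsda_fit, splsda_selected_genes

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "series_files",
    "chip_definition",
    "assignment",
    "receptor_lists",
    "output_dir",
    "target_category",
    "normalize",
    "deg",
    "splsda",
    "screen",
}
_KNOWN_NORMALIZE = {"collapse", "tol", "max_iter", "background"}
_KNOWN_DEG = {"lfc_threshold", "fdr", "adjust", "level"}
_KNOWN_SPLSDA = {"ncomp", "keepx"}
_KNOWN_SCREEN = {"deg_flag_rule", "min_expression"}


class ValidationError(ValueError):
    """Configuration problems detected before any computation."""


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``deg.level`` controls where testing happens: "probeset" (default;
    genes are flagged via their probesets in the report) or "gene"
    (collapse first, test genes directly).
    """

    series_files: list[Path]
    chip_definition: Path
    assignment: Path
    receptor_lists: Path
    output_dir: Path
    target_category: str
    normalize: dict[str, Any] = field(default_factory=dict)
    deg: dict[str, Any] = field(default_factory=dict)
    splsda: dict[str, Any] = field(default_factory=dict)
    screen: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any], base_dir: Path | None = None) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for block, allowed in (
            ("normalize", _KNOWN_NORMALIZE),
            ("deg", _KNOWN_DEG),
            ("splsda", _KNOWN_SPLSDA),
            ("screen", _KNOWN_SCREEN),
        ):
            extra = set(raw.get(block, {})) - allowed
            if extra:
                raise ValidationError(f"unknown keys in {block!r} block: {sorted(extra)}")
        base = base_dir or Path(".")

        def resolve(p: str) -> Path:
            path = Path(p)
            return path if path.is_absolute() else base / path

        try:
            cfg = cls(
                series_files=[resolve(p) for p in raw["series_files"]],
                chip_definition=resolve(raw["chip_definition"]),
                assignment=resolve(raw["assignment"]),
                receptor_lists=resolve(raw["receptor_lists"]),
                output_dir=resolve(raw["output_dir"]),
                target_category=str(raw["target_category"]),
                normalize=dict(raw.get("normalize", {})),
                deg=dict(raw.get("deg", {})),
                splsda=dict(raw.get("splsda", {})),
                screen=dict(raw.get("screen", {})),
            )
        except KeyError as exc:
            raise ValidationError(f"missing required config key: {exc.args[0]!r}") from None
        missing = [
            str(p)
            for p in [*cfg.series_files, cfg.chip_definition, cfg.assignment, cfg.receptor_lists]
            if not Path(p).exists()
        ]
        if missing:
            raise ValidationError(f"input paths do not exist: {missing}")
        return cfg

    def digest(self) -> str:
        payload = {
            "series_files": [str(p) for p in self.series_files],
            "chip_definition": str(self.chip_definition),
            "assignment": str(self.assignment),
            "receptor_lists": str(self.receptor_lists),
            "target_category": self.target_category,
            "normalize": self.normalize,
            "deg": self.deg,
            "splsda": self.splsda,
            "screen": self.screen,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance_line(config_hash: str) -> str:
    return f"# receptormine={__version__} config={config_hash}\n"


def _write_with_header(path: Path, body: str, config_hash: str) -> None:
    path.write_text(_provenance_line(config_hash) + body)


def _frame_tsv(frame: pd.DataFrame) -> str:
    return frame.to_csv(sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline, returning the artifact paths.

    Deterministic: identical inputs and config produce byte-identical
    artifacts.  Confound warnings are written to ``warnings.txt`` (empty
    file when clean) as well as the log.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.digest()
    artifacts: dict[str, Path] = {}

    # ingest
    experiments = [parse_series_matrix(p) for p in config.series_files]
    merged = merge_experiments(experiments)
    chip = ChipDefinition.from_tsv(config.chip_definition)
    experiment = ProbeExperiment(merged.intensities, merged.probe_ids, merged.samples, chip)
    assignment = load_assignment_table(config.assignment)
    experiment = assign_categories(experiment, assignment)
    warnings = confound_check(experiment)
    wpath = out / "warnings.txt"
    _write_with_header(wpath, "".join(w + "\n" for w in warnings), h)
    artifacts["warnings"] = wpath
    annotation = load_receptor_lists(config.receptor_lists)
    analysis = experiment.assigned_subset()

    # normalize
    ncfg = config.normalize
    probesets = rma(
        analysis,
        tol=float(ncfg.get("tol", 0.01)),
        max_iter=int(ncfg.get("max_iter", 10)),
        background=bool(ncfg.get("background", True)),
    )
    genes = collapse_to_genes(probesets, chip, how=str(ncfg.get("collapse", "mean")))
    for name, mat in (("expression_probesets", probesets), ("expression_genes", genes)):
        path = out / f"{name}.tsv"
        mat.to_tsv(path, out / f"{name}.meta.tsv")
        content = path.read_text()
        _write_with_header(path, content, h)
        artifacts[name] = path

    # differential expression
    dcfg = config.deg
    design = DesignSpec.from_matrix(genes)
    deg_level = str(dcfg.get("level", "probeset"))
    deg_matrix = probesets if deg_level == "probeset" else genes
    deg = build_deg_table(
        deg_matrix,
        design,
        tau=float(dcfg.get("lfc_threshold", 1.0)),
        fdr=float(dcfg.get("fdr", 0.05)),
        adjust=str(dcfg.get("adjust", "bh")),
    )
    dpath = out / "deg_table.tsv"
    _write_with_header(dpath, _frame_tsv(deg.frame), h)
    artifacts["deg_table"] = dpath

    # sPLS-DA on the gene-level matrix
    scfg = config.splsda
    model = splsda_fit(
        genes,
        design,
        ncomp=scfg.get("ncomp"),
        keepx=scfg.get("keepx"),
    )
    loadings = pd.DataFrame(
        model.loadings,
        columns=[f"comp{i + 1}" for i in range(model.ncomp)],
    )
    loadings.insert(0, "gene", model.gene_ids)
    scores = pd.DataFrame(
        model.scores, columns=[f"comp{i + 1}" for i in range(model.ncomp)]
    )
    scores.insert(0, "sample_id", model.sample_ids)
    selected = splsda_selected_genes(model)
    for name, frame in (
        ("splsda_loadings", loadings),
        ("splsda_scores", scores),
        ("splsda_selected", selected),
    ):
        path = out / f"{name}.tsv"
        _write_with_header(path, _frame_tsv(frame), h)
        artifacts[name] = path

    # receptor screen
    rcfg = config.screen
    report = build_report(
        genes,
        deg,
        model,
        annotation,
        config.target_category,
        chip=chip if deg_level == "probeset" else None,
        deg_flag_rule=str(rcfg.get("deg_flag_rule", "any")),
        min_expression=rcfg.get("min_expression"),
    )
    rpath = out / "report.tsv"
    _write_with_header(rpath, _frame_tsv(report.frame), h)
    artifacts["report"] = rpath

    from .screen import filter_receptors

    receptor_matrix = filter_receptors(genes, annotation)
    if receptor_matrix.values.shape[0] >= 2:
        clust = cluster_samples_and_genes(receptor_matrix)
        lines = ["axis\tposition\tid\n"]
        for pos, i in enumerate(clust["gene_order"]):
            lines.append(f"gene\t{pos}\t{receptor_matrix.row_ids[i]}\n")
        for pos, j in enumerate(clust["sample_order"]):
            lines.append(f"sample\t{pos}\t{receptor_matrix.sample_ids[j]}\n")
        cpath = out / "clustering_orders.tsv"
        _write_with_header(cpath, "".join(lines), h)
        artifacts["clustering_orders"] = cpath

    manifest = out / "run_manifest.json"
    manifest.write_text(
        json.dumps(
            {
                "version": __version__,
                "config_hash": h,
                "artifacts": {k: str(v) for k, v in sorted(artifacts.items())},
                "confound_warnings": warnings,
            },
            indent=1,
            sort_keys=True,
        )
    )
    artifacts["manifest"] = manifest
    return artifacts
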