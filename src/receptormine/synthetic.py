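"""Synthetic probe-level experiments with known truth.

Generates single-channel microarray experiments that mimic the pooled-GEO
setting the screen is built for: several deposited series per biological
category, per-series (batch) effects, probe-specific affinities, and
probe intensities following the exponential-signal + normal-background
convolution that the normexp correction assumes.

The intensity of probe p (of gene g's probeset) in sample s of category c:

    I = Normal(bg_mu, bg_sigma^2)  +  Exponential(mean = alpha * 2^L)
    L = theta_gc + batch_{g, series(s)} + affinity_p + eps_gs

theta_gc is the true log2 expression (baseline plus a planted shift of
``de_effect`` for DE genes in the last category), batch is a gene-specific
per-series technical offset, affinity a per-probe offset (removed by
median polish), and eps a per-(gene, sample) biological noise term.  The
exponential draw is independent per (probe, sample): on the log scale it
contributes heavy measurement noise (sd ≈ 1.85 log2 units) that the
multi-probe summarization averages away, as on real arrays.

All randomness derives from one seed, expanded into independent
per-purpose streams so that e.g. enlarging the gene count does not
reshuffle the background draws.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .core_io import (
    ChipDefinition,
    ProbeExperiment,
    ReceptorAnnotation,
    SampleMeta,
    merge_experiments,
    parse_series_matrix,
    serialize_series_matrix,
)

logger = logging.getLogger(__name__)

RECEPTOR_CLASSES = (
    "cytokine receptor",
    "G-protein coupled",
    "ligand-gated ion channel",
    "nuclear hormone",
    "protein kinase",
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated experiment.

    Defaults describe a modest two-category pooling study: 200 genes
    (3-4 probesets each, 16-20 probes per probeset, so a gene is
    interrogated by ~50-80 probes as on multi-probeset in-situ
    oligonucleotide designs), 6 samples per category drawn from 2 series
    each, 5% of genes planted with a ±2 log2 shift (balanced signs) in
    the last category, mild technical structure (batch sd 0.1 log2,
    probe affinity sd 0.5 log2, biological noise sd 0.15 log2) over a
    Normal(8, 1) baseline, and normexp background mu=50, sigma=10 with
    signal scale alpha=1 (signal mean = 2^L).
    """

    seed: int
    n_genes: int = 200
    probesets_per_gene: tuple[int, int] = (3, 4)
    probes_per_probeset: tuple[int, int] = (16, 20)
    categories: Mapping[str, int] = field(
        default_factory=lambda: {"groupA": 6, "groupB": 6}
    )
    series_per_category: int = 2
    confounded: bool = False
    batch_sd: float = 0.1
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    de_fraction: float = 0.05
    de_effect: float = 2.0
    affinity_sd: float = 0.5
    noise_sd: float = 0.15
    bg_mu: float = 50.0
    bg_sigma: float = 10.0
    alpha: float = 1.0
    receptor_fraction: float = 0.25
    #: plant one receptor gene (the first gene) with a high baseline
    #: (+2 log2 over the baseline mean, still inside the bulk intensity
    #: distribution so quantile normalization does not flatten it) plus
    #: the DE effect in the last category — a known-answer probe for
    #: end-to-end report checks
    spike_receptor: bool = False
    platform_id: str = "SIMPL0001"

    def validate(self) -> None:
        problems = []
        if self.n_genes < 1:
            problems.append("n_genes must be >= 1")
        for name, rng in (
            ("probesets_per_gene", self.probesets_per_gene),
            ("probes_per_probeset", self.probes_per_probeset),
        ):
            if rng[0] < 1 or rng[1] < rng[0]:
                problems.append(f"{name} must be an increasing range with min >= 1")
        if not self.categories:
            problems.append("need at least one category")
        if any(n < 1 for n in self.categories.values()):
            problems.append("every category needs >= 1 sample")
        if self.series_per_category < 1:
            problems.append("series_per_category must be >= 1")
        for name in ("batch_sd", "affinity_sd", "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if not (0 <= self.de_fraction <= 1):
            problems.append("de_fraction must lie in [0, 1]")
        if not (0 <= self.receptor_fraction <= 1):
            problems.append("receptor_fraction must lie in [0, 1]")
        if self.bg_sigma <= 0 or self.alpha <= 0:
            problems.append("bg_sigma and alpha must be > 0")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))


@dataclass
class SimTruth:
    """Ground truth behind one simulated experiment."""

    theta: np.ndarray  # genes x categories, true log2 means
    gene_ids: list[str]
    category_names: list[str]
    de_genes: list[str]
    sample_series: dict[str, str]
    receptor_genes: dict[str, str]  # gene -> receptor class

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_ids": self.gene_ids,
            "category_names": self.category_names,
            "theta": self.theta.tolist(),
            "de_genes": self.de_genes,
            "sample_series": self.sample_series,
            "receptor_genes": self.receptor_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["structure", "baseline", "de", "batch", "affinity", "noise", "signal", "background"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_experiment(config: SimConfig) -> tuple[ProbeExperiment, SimTruth, ReceptorAnnotation]:
    """Draw one experiment plus its truth and a receptor annotation.

    Deterministic given ``config.seed``.  DE genes get ``de_effect`` added
    to their log2 mean in the last category.  The receptor annotation
    marks the first ``receptor_fraction`` of genes, cycling through the
    receptor class names.
    """
    config.validate()
    rngs = _streams(config.seed)

    G = config.n_genes
    gene_ids = [f"Gene{i + 1:04d}" for i in range(G)]
    cats = list(config.categories)
    K = len(cats)

    # chip layout
    ps_lo, ps_hi = config.probesets_per_gene
    pr_lo, pr_hi = config.probes_per_probeset
    r = rngs["structure"]
    n_probesets = r.integers(ps_lo, ps_hi + 1, size=G)
    probe_to_probeset: dict[str, str] = {}
    probeset_to_gene: dict[str, str] = {}
    probe_rows: list[tuple[int, int]] = []  # (gene index, probe affinity slot)
    probe_ids: list[str] = []
    gene_sample_rows: list[int] = []
    for gi, gene in enumerate(gene_ids):
        for k in range(n_probesets[gi]):
            ps = f"{gene}_ps{k + 1}"
            probeset_to_gene[ps] = gene
            n_pr = int(r.integers(pr_lo, pr_hi + 1))
            for q in range(n_pr):
                probe = f"{ps}_at{q + 1}"
                probe_to_probeset[probe] = ps
                probe_ids.append(probe)
                probe_rows.append((gi, len(probe_rows)))
    chip = ChipDefinition(probe_to_probeset, probeset_to_gene)
    P = len(probe_ids)

    # true expression
    theta = rngs["baseline"].normal(config.baseline_mean, config.baseline_sd, size=G)
    theta = np.tile(theta[:, None], (1, K)).astype(float)
    n_de = int(round(config.de_fraction * G))
    de_idx = rngs["de"].choice(G, size=n_de, replace=False) if n_de else np.array([], int)
    # balanced signs: half the planted genes go up in the last category,
    # half down, so differential expression does not skew one group's
    # overall intensity distribution (which quantile normalization would
    # otherwise flatten back, compressing the planted fold changes)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    theta[de_idx, K - 1] += signs * config.de_effect
    de_genes = {gene_ids[i] for i in de_idx}
    if config.spike_receptor:
        theta[0, :] = config.baseline_mean + 2.0
        theta[0, K - 1] += config.de_effect
        de_genes.add(gene_ids[0])
    de_genes = sorted(de_genes)

    # samples and series
    samples: list[SampleMeta] = []
    sample_cat_idx: list[int] = []
    sample_series_idx: list[int] = []
    series_names: list[str] = []
    for ci, cat in enumerate(cats):
        n = config.categories[cat]
        n_series = 1 if config.confounded else min(config.series_per_category, n)
        first = len(series_names)
        for t in range(n_series):
            series_names.append(f"SIMSE{ci + 1}{t + 1:02d}")
        for j in range(n):
            sid = f"SIMSM{ci + 1}{j + 1:03d}"
            se = first + (j % n_series)
            samples.append(
                SampleMeta(sid, series_names[se], config.platform_id, cat)
            )
            sample_cat_idx.append(ci)
            sample_series_idx.append(se)
    N = len(samples)
    S = len(series_names)

    batch = rngs["batch"].normal(0.0, config.batch_sd, size=(G, S))
    affinity = rngs["affinity"].normal(0.0, config.affinity_sd, size=P)
    eps = rngs["noise"].normal(0.0, config.noise_sd, size=(G, N))

    gi_arr = np.array([g for g, _ in probe_rows])
    L = (
        theta[gi_arr][:, sample_cat_idx]
        + batch[gi_arr][:, sample_series_idx]
        + affinity[:, None]
        + eps[gi_arr]
    )
    signal_mean = config.alpha * np.exp2(L)
    signal = rngs["signal"].exponential(1.0, size=(P, N)) * signal_mean
    background = rngs["background"].normal(config.bg_mu, config.bg_sigma, size=(P, N))
    intensity = np.maximum(signal + background, 1e-3)

    experiment = ProbeExperiment(intensity, probe_ids, samples, chip)

    n_receptor = int(round(config.receptor_fraction * G))
    receptor_genes = {
        gene_ids[i]: RECEPTOR_CLASSES[i % len(RECEPTOR_CLASSES)]
        for i in range(n_receptor)
    }
    annotation = ReceptorAnnotation(
        {g: frozenset({c}) for g, c in receptor_genes.items()}
    ) if receptor_genes else ReceptorAnnotation({"NONE": frozenset({"none"})})

    truth = SimTruth(
        theta=theta,
        gene_ids=gene_ids,
        category_names=cats,
        de_genes=de_genes,
        sample_series={s.sample_id: s.series_id for s in samples},
        receptor_genes=receptor_genes,
    )
    return experiment, truth, annotation


def write_fixture_bundle(
    experiment: ProbeExperiment,
    truth: SimTruth,
    annotation: ReceptorAnnotation,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a simulated experiment as on-disk pipeline inputs.

    One series-matrix file per simulated series (partitioning the
    samples), plus chip definition, sample-assignment table, receptor
    list, and the truth as JSON.  Returns the paths keyed by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_series: dict[str, list[int]] = {}
    for j, s in enumerate(experiment.samples):
        by_series.setdefault(s.series_id, []).append(j)
    series_paths = []
    for series in sorted(by_series):
        idx = by_series[series]
        sub = ProbeExperiment(
            experiment.intensities[:, idx],
            list(experiment.probe_ids),
            [experiment.samples[j] for j in idx],
            experiment.chip,
        )
        path = out / f"{series}_series_matrix.txt"
        serialize_series_matrix(sub, path)
        series_paths.append(path)

    chip_path = out / "chip_definition.tsv"
    if experiment.chip is None:
        raise ValueError("experiment lacks a chip definition")
    experiment.chip.to_tsv(chip_path)

    assign_path = out / "sample_categories.tsv"
    with open(assign_path, "w") as fh:
        fh.write("sample_id\tcategory\n")
        for s in experiment.samples:
            if s.assigned:
                fh.write(f"{s.sample_id}\t{s.category}\n")

    receptor_path = out / "receptor_lists.tsv"
    with open(receptor_path, "w") as fh:
        fh.write("gene\tcategory\n")
        for gene in sorted(annotation.gene_categories):
            for cat in sorted(annotation.gene_categories[gene]):
                fh.write(f"{gene}\t{cat}\n")

    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    return {
        "series": series_paths,
        "chip": chip_path,
        "assignment": assign_path,
        "receptors": receptor_path,
        "truth": truth_path,
    }


def read_fixture_bundle(bundle_dir: str | Path) -> ProbeExperiment:
    """Re-ingest a written bundle into one pooled experiment."""
    bundle_dir = Path(bundle_dir)
    series_files = sorted(bundle_dir.glob("*_series_matrix.txt"))
    if not series_files:
        raise FileNotFoundError(f"no series-matrix files in {bundle_dir}")
    experiments = [parse_series_matrix(p) for p in series_files]
    merged = merge_experiments(experiments)
    chip = ChipDefinition.from_tsv(bundle_dir / "chip_definition.tsv")
    return ProbeExperiment(merged.intensities, merged.probe_ids, merged.samples, chip)
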