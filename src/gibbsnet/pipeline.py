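"""End-to-end pipeline: ingest → score → aggregate → report.

Reads the TSV trio (expression, metadata, network; optionally a probe map),
computes per-sample network Gibbs free energies, aggregates them into
age-bin summaries, per-sex region-averaged curves, a crossover/convergence
report and trajectory extrema, renders the trend plots, and writes every
table with a provenance block. Identical config + inputs give identical
outputs; any stage error propagates with its stage name and removes partial
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .cohort import (
    DEFAULT_BINNING,
    AgeBinning,
    CrossoverReport,
    TrendExtrema,
    average_over_regions,
    detect_crossover,
    summarize_bins,
    trend_extrema,
)
from .energy import gibbs_per_sample
from .expression import collapse_probes, filter_regions, parse_expression, parse_metadata, parse_probe_map
from .network import build_network, parse_interactions, read_edge_list
from .scorer import GibbsNetworkScorer

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    expression: Path
    metadata: Path
    network: Path
    out_dir: Path
    probe_map: Path | None = None
    rescale_scope: str = "sample"
    rescale_over: str = "all"
    bin_edges: tuple[float, ...] = DEFAULT_BINNING.edges
    bin_labels: tuple[str, ...] = ()
    group_by: tuple[str, ...] = ("region", "sex")
    hemisphere_handling: str = "separate"  # or "average" (per donor-region)
    region_weight: str = "regions"
    convergence_tolerance: float | None = None  # None → 1 pooled SE of final-bin diff
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("expression", "metadata", "network", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.probe_map is not None:
            self.probe_map = Path(self.probe_map)
        if self.hemisphere_handling not in {"separate", "average"}:
            raise ValueError("hemisphere_handling must be 'separate' or 'average'")
        for path_name in ("expression", "metadata", "network"):
            path = getattr(self, path_name)
            if not path.exists():
                raise FileNotFoundError(f"{path_name} input not found: {path}")
        if self.probe_map is not None and not self.probe_map.exists():
            raise FileNotFoundError(f"probe_map input not found: {self.probe_map}")

    @property
    def binning(self) -> AgeBinning:
        return AgeBinning(edges=self.bin_edges, labels=self.bin_labels)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("bin_edges", "bin_labels", "group_by"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    gibbs: pd.DataFrame
    summaries: pd.DataFrame
    sex_curves: pd.DataFrame
    crossover: CrossoverReport | None
    extrema: TrendExtrema | None
    provenance: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_network(path: Path):
    header = path.open().readline()
    if header.startswith("symbol_a\t"):
        with path.open() as fh:
            return read_edge_list(fh)
    with path.open() as fh:
        return build_network(parse_interactions(fh))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write all artifacts to ``out_dir``."""
    logging.getLogger("gibbsnet").setLevel(config.log_level.upper())
    provenance: dict = {
        "tool": f"gibbsnet {__version__}",
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in vars(config).items()
        },
        "inputs": {
            name: {"path": str(getattr(config, name)), "sha256": _sha256(getattr(config, name))}
            for name in ("expression", "metadata", "network", "probe_map")
            if getattr(config, name) is not None
        },
        "counts": {},
    }
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "ingest"
        network = _load_network(config.network)
        with config.expression.open() as fh:
            matrix = parse_expression(fh)
        if config.probe_map is not None:
            with config.probe_map.open() as fh:
                probe_map = parse_probe_map(fh)
            n_probes = len(matrix)
            n_unmapped = int(matrix.index.map(probe_map).isna().sum())
            matrix = collapse_probes(matrix, probe_map)
            provenance["counts"]["probes_in"] = n_probes
            provenance["counts"]["probes_unmapped_deleted"] = n_unmapped
            provenance["counts"]["probes_merged_into_genes"] = (
                n_probes - n_unmapped - len(matrix)
            )
        matrix.index = matrix.index.astype(str).str.strip().str.upper()
        with config.metadata.open() as fh:
            metadata = parse_metadata(fh)
        kept, discarded = filter_regions(metadata)
        provenance["counts"]["samples_in"] = len(metadata)
        provenance["counts"]["samples_region_discarded"] = len(discarded)
        if kept.empty:
            raise ValueError("no samples left after region filtering")
        matrix = matrix[[c for c in matrix.columns if c in set(kept["sample_id"])]]

        stage = "gibbs"
        results = gibbs_per_sample(
            network, matrix,
            rescale_scope=config.rescale_scope, rescale_over=config.rescale_over,
        )
        scorer = GibbsNetworkScorer(network=network).fit(matrix.T)
        provenance["counts"]["network_nodes"] = network.number_of_nodes()
        provenance["counts"]["network_edges"] = network.number_of_edges()
        provenance["counts"]["expression_network_overlap"] = scorer.n_overlap_
        gibbs = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in results],
                "total_G": [r.total_G for r in results],
                "n_nodes_scored": network.number_of_nodes(),
                "n_overlap": scorer.n_overlap_,
            }
        )

        stage = "aggregate"
        analysis_meta = kept
        analysis_gibbs = gibbs
        if config.hemisphere_handling == "average":
            analysis_gibbs, analysis_meta = _average_hemispheres(gibbs, kept)
        binning = config.binning
        summaries = summarize_bins(analysis_gibbs, analysis_meta, binning, config.group_by)
        sex_curves = pd.DataFrame()
        crossover = None
        extrema = None
        if {"region", "sex"} <= set(config.group_by):
            sex_curves = average_over_regions(summaries, weight=config.region_weight)
            female = sex_curves[sex_curves["sex"] == "female"].set_index("bin")["mean_G"]
            male = sex_curves[sex_curves["sex"] == "male"].set_index("bin")["mean_G"]
            if len(female) >= 2 and len(male) >= 2:
                tol = config.convergence_tolerance
                if tol is None:
                    tol = _pooled_final_se(analysis_gibbs, analysis_meta, binning)
                crossover = detect_crossover(female, male, binning.labels, tolerance=tol)
            pooled = summarize_bins(analysis_gibbs, analysis_meta, binning, ())
            pooled_curve = pooled.set_index("bin")["mean_G"]
            if len(pooled_curve) >= 3:
                extrema = trend_extrema(pooled_curve, binning.labels)

        stage = "report"
        config.out_dir.mkdir(parents=True, exist_ok=True)
        paths = _write_outputs(
            config.out_dir, gibbs, summaries, sex_curves, crossover, extrema,
            provenance, binning, written,
        )
        return PipelineResult(gibbs, summaries, sex_curves, crossover, extrema, provenance, paths)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _average_hemispheres(gibbs: pd.DataFrame, metadata: pd.DataFrame):
    """Average per-sample G over hemispheres within each donor-region pair."""
    merged = gibbs.merge(metadata, on="sample_id")
    rows_g, rows_m = [], []
    for (donor, region), group in merged.groupby(["donor_id", "region"], sort=True):
        sid = f"{donor}:{region}"
        rows_g.append(
            {
                "sample_id": sid,
                "total_G": float(group["total_G"].mean()),
                "n_nodes_scored": group["n_nodes_scored"].iloc[0],
                "n_overlap": group["n_overlap"].iloc[0],
            }
        )
        rows_m.append(
            {
                "sample_id": sid,
                "donor_id": donor,
                "age_years": float(group["age_years"].iloc[0]),
                "sex": group["sex"].iloc[0],
                "region": region,
                "hemisphere": "unknown",
            }
        )
    return pd.DataFrame(rows_g), pd.DataFrame(rows_m)


def _pooled_final_se(gibbs: pd.DataFrame, metadata: pd.DataFrame, binning: AgeBinning) -> float:
    """Default convergence tolerance: 1 pooled SE of the final-bin sex difference."""
    by_sex = summarize_bins(gibbs, metadata, binning, ("sex",))
    last_bins = [b for b in binning.labels if b in set(by_sex["bin"])]
    if not last_bins:
        return 0.0
    final = by_sex[by_sex["bin"] == last_bins[-1]]
    ses = final["se_G"].to_numpy(dtype=float)
    ses = ses[np.isfinite(ses)]
    return float(np.sqrt((ses**2).sum())) if ses.size else 0.0


def _write_outputs(
    out_dir: Path,
    gibbs: pd.DataFrame,
    summaries: pd.DataFrame,
    sex_curves: pd.DataFrame,
    crossover: CrossoverReport | None,
    extrema: TrendExtrema | None,
    provenance: dict,
    binning: AgeBinning,
    written: list[Path],
) -> dict[str, Path]:
    paths: dict[str, Path] = {}

    def _table(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        full = out_dir / f"{name}.full.tsv"
        frame.to_csv(full, sep="\t", index=False, float_format="%.17g")
        written.extend([path, full])
        paths[name] = path

    _table("gibbs_per_sample", gibbs)
    _table("bin_summary", summaries)
    if not sex_curves.empty:
        _table("sex_curves", sex_curves)

    report: dict = {"extrema": None, "crossover": None}
    if extrema is not None:
        report["extrema"] = {
            "peak_bin": extrema.peak_bin,
            "trough_bin": extrema.trough_bin,
            "degenerate": extrema.degenerate,
        }
    if crossover is not None:
        report["crossover"] = {
            "crossovers": [list(c) for c in crossover.crossovers],
            "converged": crossover.converged,
            "final_difference": crossover.final_difference,
            "ties": crossover.ties,
        }
    report_path = out_dir / "trend_report.json"
    report_path.write_text(json.dumps(report, indent=2) + "\n")
    written.append(report_path)
    paths["trend_report"] = report_path

    if not summaries.empty and summaries["bin"].nunique() >= 2:
        region_plot = out_dir / "region_trends.png"
        render_trend_plot(summaries, "region", region_plot, binning.labels)
        written.append(region_plot)
        paths["region_plot"] = region_plot
    if not sex_curves.empty and sex_curves["bin"].nunique() >= 2:
        sex_plot = out_dir / "sex_trends.png"
        render_trend_plot(sex_curves, "sex", sex_plot, binning.labels)
        written.append(sex_plot)
        paths["sex_plot"] = sex_plot

    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, default=str) + "\n")
    written.append(prov_path)
    paths["provenance"] = prov_path
    return paths


def render_trend_plot(
    summaries: pd.DataFrame,
    stratify: str,
    path: str | Path,
    bin_order: Sequence[str],
) -> Path:
    """Plot binned mean G per stratum with standard-error bars.

    One line per value of ``stratify`` (e.g. region or sex) across age bins;
    error bars are drawn where a standard error is available (n ≥ 2). The
    plotted points come from the summary table exactly — nothing is
    recomputed here. Raises ``ValueError`` for empty summaries or a
    single-bin input (no trend to draw).
    """
    if summaries.empty:
        raise ValueError("cannot plot empty summaries")
    bins_present = [b for b in bin_order if b in set(summaries["bin"])]
    if len(bins_present) < 2:
        raise ValueError("cannot draw a trend from fewer than two bins")
    fig, ax = plt.subplots(figsize=(9, 5))
    x_of = {b: i for i, b in enumerate(bins_present)}
    for stratum, group in summaries.groupby(stratify, sort=True):
        group = group[group["bin"].isin(x_of)]
        xs = group["bin"].map(x_of).to_numpy()
        order = np.argsort(xs)
        xs = xs[order]
        ys = group["mean_G"].to_numpy(dtype=float)[order]
        yerr = None
        if "se_G" in group:
            se = group["se_G"].to_numpy(dtype=float)[order]
            yerr = np.where(np.isfinite(se), se, 0.0)
        ax.errorbar(xs, ys, yerr=yerr, marker="o", capsize=2, label=str(stratum))
    ax.set_xticks(range(len(bins_present)))
    ax.set_xticklabels(bins_present, rotation=45, ha="right")
    ax.set_xlabel("age bin (years; negative = prenatal)")
    ax.set_ylabel("network Gibbs free energy G")
    ax.legend(fontsize="small", ncol=2)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
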