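"""End-to-end analysis pipeline across developmental timepoints.

Each timepoint is an independent analysis sharing the gene panel: quality
filtering, islet detection, distance-density profiles with divergence
matrix and two-group identification, and per-islet Strauss fits.  Only
the reporting stages join timepoints: the rank trajectory of each gene
toward group 1 (taken from the last timepoint's grouping) and an
interaction table with one "mean +/- std" cell per pair and timepoint.
Outputs and a manifest recording the configuration hash, seed and
software version land in the run directory; a rerun with an identical
configuration reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from ._version import __version__ as _version
from .data import (
    abundance_filter,
    filter_by_quality,
    negative_control_rate,
    read_transcript_table,
    write_transcript_table,
)
from .density import (
    distance_to_islet_boundary,
    divergence_matrix,
    estimate_density,
    group_genes,
    rank_vs_group,
    shared_grid,
)
from .islets import detect_islets, write_islets_json
from .strauss import fit_per_islet

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; defaults follow the study's stated parameters."""

    timepoints: tuple[tuple[str, dict], ...]  # (label, {"transcripts": ..., "nuclei": ...})
    out_dir: str
    quality_threshold: float = 0.55
    marker_genes: tuple[str, ...] = ("SST", "GLUC", "INS")
    density_min_count: int = 100
    strauss_min_count: int = 500
    radius: float = 20.0
    neighborhood_radius: float = 20.0
    min_points: int = 3
    bandwidth: float | str = "auto"
    control_labels: tuple[str, ...] = ()
    column_map: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.quality_threshold <= 1:
            raise ValueError("quality_threshold must be in [0, 1]")
        labels = [t for t, _ in self.timepoints]
        if len(set(labels)) != len(labels):
            raise ValueError("timepoint labels must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        tps = tuple((str(k), dict(v)) for k, v in raw.pop("timepoints").items())
        raw.setdefault("out_dir", "spatcorr_run")
        for key in ("marker_genes", "control_labels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(timepoints=tps, **raw)

    def to_dict(self) -> dict:
        return {
            "timepoints": {t: dict(v) for t, v in self.timepoints},
            "out_dir": self.out_dir,
            "quality_threshold": self.quality_threshold,
            "marker_genes": list(self.marker_genes),
            "density_min_count": self.density_min_count,
            "strauss_min_count": self.strauss_min_count,
            "radius": self.radius,
            "neighborhood_radius": self.neighborhood_radius,
            "min_points": self.min_points,
            "bandwidth": self.bandwidth,
            "control_labels": list(self.control_labels),
            "column_map": dict(self.column_map),
            "seed": self.seed,
        }


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrices: list[tuple[str, "object"]] = []
    strauss_by_tp: dict[str, "object"] = {}
    grouping = None

    for label, paths in config.timepoints:
        tp_dir = out / label
        tp_dir.mkdir(exist_ok=True)

        table = _stage(f"{label}/read")(read_transcript_table)(
            paths["transcripts"],
            column_map=config.column_map,
            control_labels=config.control_labels,
        )
        qc = {"n_input": len(table)}
        if config.control_labels and len(table):
            qc["negative_control_rate_raw"] = negative_control_rate(table)
        table = _stage(f"{label}/quality-filter")(filter_by_quality)(
            table, config.quality_threshold
        )
        qc["n_filtered"] = len(table)
        if config.control_labels and len(table):
            qc["negative_control_rate_filtered"] = negative_control_rate(table)
        write_transcript_table(table, tp_dir / "transcripts_filtered.csv")
        (tp_dir / "qc.json").write_text(json.dumps(qc, indent=1))

        islets = _stage(f"{label}/islets")(detect_islets)(
            table,
            marker_genes=config.marker_genes,
            neighborhood_radius=config.neighborhood_radius,
            min_points=config.min_points,
        )
        write_islets_json(islets, tp_dir / "islets.json")

        def density_stage():
            genes = abundance_filter(table, config.density_min_count)
            samples = distance_to_islet_boundary(table, islets)
            samples = {
                g: s for g, s in samples.items() if g in genes and len(s) >= 2
            }
            grid = shared_grid(samples)
            profiles = {
                g: estimate_density(s, grid, config.bandwidth)
                for g, s in samples.items()
            }
            prof_df = pd.DataFrame({"distance_um": grid})
            for g, p in profiles.items():
                prof_df[g] = p.density
            prof_df.to_csv(tp_dir / "profiles.tsv", sep="\t", index=False)
            dm = divergence_matrix(profiles)
            pd.DataFrame(
                dm.values, index=list(dm.genes), columns=list(dm.genes)
            ).to_csv(tp_dir / "divergence.tsv", sep="\t")
            grouping_tp = group_genes(dm)
            (tp_dir / "grouping.json").write_text(
                json.dumps(
                    {
                        "group1": sorted(grouping_tp.group1),
                        "group2": sorted(grouping_tp.group2),
                    },
                    indent=1,
                )
            )
            return dm, grouping_tp

        dm, grouping = _stage(f"{label}/density")(density_stage)()
        matrices.append((label, dm))

        def strauss_stage():
            res = fit_per_islet(
                table,
                islets,
                r=config.radius,
                min_count=config.strauss_min_count,
                seed=config.seed,
            )
            payload = {
                "radius": config.radius,
                "min_count": config.strauss_min_count,
                "seed": config.seed,
                "version": _version,
                "pairs": {
                    row["pair"]: {
                        "mean": row["mean"],
                        "std": row["std"],
                        "n_windows": row["n_windows"],
                    }
                    for _, row in res.pair_table().iterrows()
                    if pd.notna(row["mean"])
                },
            }
            (tp_dir / "strauss.json").write_text(json.dumps(payload, indent=1))
            return res

        strauss_by_tp[label] = _stage(f"{label}/strauss")(strauss_stage)()

    # --- cross-timepoint reporting -------------------------------------
    def report_stage():
        assert grouping is not None
        group1 = set(grouping.group1)
        rows = []
        for gene in sorted(
            set.intersection(*(set(m.genes) for _, m in matrices))
        ):
            row: dict = {"gene": gene}
            for label, m in matrices:
                row[label] = rank_vs_group(m, gene, group1 & set(m.genes))
            rows.append(row)
        pd.DataFrame(rows).to_csv(
            out / "rank_trajectory.tsv", sep="\t", index=False
        )

        pair_rows: dict[str, dict] = {}
        for label, res in strauss_by_tp.items():
            for _, row in res.pair_table().iterrows():
                if pd.isna(row["mean"]):
                    continue
                cell = f"{row['mean']:.2f} ± {row['std']:.2f}"
                pair_rows.setdefault(row["pair"], {})[label] = cell
        tab = pd.DataFrame.from_dict(pair_rows, orient="index")
        tab.index.name = "pair"
        tab.to_csv(out / "interactions.tsv", sep="\t")

    _stage("report")(report_stage)()

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": _version,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
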