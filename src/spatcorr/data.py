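"""Transcript/nuclei data model, I/O, quality filtering and QC accounting.

A decoded in situ sequencing experiment yields one record per detected RNA
molecule: planar coordinates (micrometres), a gene label, and a quality
score in [0, 1] summarizing decoding confidence.  A subset of barcode
combinations is deliberately left unassigned; reads decoding to those
"negative control" labels estimate the decoding error rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("x", "y", "gene")


class FormatError(ValueError):
    """Input file does not conform to the expected tabular layout."""


class EmptyTableError(ValueError):
    """Operation undefined on a table with no records."""


@dataclass(frozen=True)
class TranscriptTable:
    """Decoded transcript records plus the gene panel and control labels.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``x``, ``y`` (micrometres), ``gene`` (str), ``quality``
        (fraction in [0, 1]).
    panel : tuple of str
        Ordered, unique gene labels targeted by the assay.
    control_labels : frozenset of str
        Labels designated as negative controls (disjoint from genes of
        interest; reads with these labels measure decoding error).
    """

    records: pd.DataFrame
    panel: tuple[str, ...]
    control_labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        df = self.records
        for col in (*_REQUIRED_COLUMNS, "quality"):
            if col not in df.columns:
                raise FormatError(f"records missing required column {col!r}")
        if len(df):
            xy = df[["x", "y"]].to_numpy(float)
            if not np.isfinite(xy).all():
                raise ValueError("non-finite coordinates in transcript table")
            q = df["quality"].to_numpy(float)
            if ((q < 0) | (q > 1)).any() or not np.isfinite(q).all():
                raise ValueError("quality values must lie in [0, 1]")
            allowed = set(self.panel) | set(self.control_labels)
            bad = set(df["gene"].unique()) - allowed
            if bad:
                raise ValueError(
                    f"gene labels outside panel and controls: {sorted(bad)}"
                )
        if len(set(self.panel)) != len(self.panel):
            raise ValueError("panel labels must be unique")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of coordinates in micrometres."""
        return self.records[["x", "y"]].to_numpy(float)

    def subset_genes(self, genes: Sequence[str]) -> "TranscriptTable":
        """Records whose label is in ``genes``; panel order preserved."""
        keep = self.records[self.records["gene"].isin(set(genes))]
        return TranscriptTable(
            keep.reset_index(drop=True), self.panel, self.control_labels
        )

    def gene_counts(self) -> pd.Series:
        """Record count per panel gene, in panel order (controls excluded)."""
        counts = self.records["gene"].value_counts()
        return pd.Series(
            [int(counts.get(g, 0)) for g in self.panel],
            index=list(self.panel),
            name="count",
        )

    def concat(self, other: "TranscriptTable") -> "TranscriptTable":
        if tuple(other.panel) != tuple(self.panel):
            raise ValueError("cannot concatenate tables with different panels")
        return TranscriptTable(
            pd.concat([self.records, other.records], ignore_index=True),
            self.panel,
            self.control_labels | other.control_labels,
        )


@dataclass(frozen=True)
class NucleusSet:
    """Segmented nuclei centroids in micrometres."""

    centroids: pd.DataFrame  # columns x, y

    def __post_init__(self) -> None:
        df = self.centroids
        for col in ("x", "y"):
            if col not in df.columns:
                raise FormatError(f"nuclei table missing column {col!r}")
        if len(df) and not np.isfinite(df[["x", "y"]].to_numpy(float)).all():
            raise ValueError("non-finite nucleus coordinates")
        if df.index.has_duplicates:
            raise ValueError("duplicate nucleus index")

    def __len__(self) -> int:
        return len(self.centroids)

    @property
    def xy(self) -> np.ndarray:
        return self.centroids[["x", "y"]].to_numpy(float)


def read_transcript_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    control_labels: Sequence[str] = (),
    panel: Sequence[str] | None = None,
    sep: str | None = None,
) -> TranscriptTable:
    """Read a delimited transcript table (CSV/TSV).

    Requires columns x, y, gene (remappable through ``column_map``, a
    mapping from canonical name to the file's column name).  A missing
    quality column defaults to 1.0.  Quality columns formatted as percent
    (values > 1) are divided by 100.  Rows with unparseable or non-finite
    coordinates are dropped and counted in the log.

    Parameters
    ----------
    panel : sequence of str, optional
        Gene panel; defaults to the sorted non-control labels observed.
    sep : str, optional
        Field separator; inferred from the extension when omitted.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty and not len(df.columns):
        raise EmptyTableError(f"{path} contains no data")
    colmap = dict(column_map or {})
    rename = {colmap.get(k, k): k for k in ("x", "y", "gene", "quality")}
    df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path} missing required column(s) {missing}")
    if "quality" not in df.columns:
        df["quality"] = 1.0
    if df.empty:
        raise EmptyTableError(f"{path} has a header but no records")

    n_in = len(df)
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    df["quality"] = pd.to_numeric(df["quality"], errors="coerce")
    ok = np.isfinite(df["x"]) & np.isfinite(df["y"]) & np.isfinite(df["quality"])
    df = df.loc[ok, ["x", "y", "gene", "quality"]].reset_index(drop=True)
    n_rejected = n_in - len(df)
    if n_rejected:
        logger.info(
            "read %s: %d records, %d rejected (unparseable coordinates)",
            path, len(df), n_rejected,
        )
    df["gene"] = df["gene"].astype(str)
    # percent-formatted quality: rescale once, for the whole column
    if len(df) and df["quality"].max() > 1.0:
        df["quality"] = df["quality"] / 100.0
    controls = frozenset(map(str, control_labels))
    if panel is None:
        panel = tuple(sorted(set(df["gene"].unique()) - controls))
    return TranscriptTable(df, tuple(panel), controls)


def write_transcript_table(table: TranscriptTable, path: str | Path) -> None:
    """Write records to CSV/TSV (separator inferred from extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table.records.to_csv(path, sep=sep, index=False)


def read_nucleus_set(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> NucleusSet:
    """Read nuclei centroids from a delimited file with x, y columns."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    colmap = dict(column_map or {})
    df = df.rename(columns={colmap.get(k, k): k for k in ("x", "y")})
    missing = [c for c in ("x", "y") if c not in df.columns]
    if missing:
        raise FormatError(f"{path} missing column(s) {missing}")
    return NucleusSet(df[["x", "y"]].astype(float).reset_index(drop=True))


def filter_by_quality(table: TranscriptTable, threshold: float) -> TranscriptTable:
    """Keep records with quality >= threshold.

    The decoding-quality gate: records strictly below the threshold are
    discarded (a threshold of 0.55 removes everything "lower than 55%").
    Idempotent, and monotone in the threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    kept = table.records[table.records["quality"] >= threshold]
    n_in, n_out = len(table.records), len(kept)
    logger.info(
        "quality filter @ %.2f: %d -> %d records (%.1f%% discarded)",
        threshold, n_in, n_out,
        100.0 * (n_in - n_out) / n_in if n_in else 0.0,
    )
    return TranscriptTable(
        kept.reset_index(drop=True), table.panel, table.control_labels
    )


def negative_control_rate(table: TranscriptTable) -> float:
    """Fraction of records carrying a negative-control label.

    Reads decoding to unassigned barcode combinations have no biological
    meaning; their fraction estimates the per-molecule decoding error rate.
    """
    n = len(table.records)
    if n == 0:
        raise EmptyTableError("negative control rate undefined on empty table")
    n_ctrl = int(table.records["gene"].isin(table.control_labels).sum())
    return n_ctrl / n


def barcode_space_size(n_channels: int, n_rounds: int) -> int:
    """Number of decodable barcode combinations: channels ** rounds.

    Four fluorophores over three hybridization rounds give 4**3 = 64
    combinations, of which any not assigned to a gene serve as negative
    controls.
    """
    if n_channels < 1 or n_rounds < 1:
        raise ValueError("n_channels and n_rounds must be positive integers")
    return int(n_channels) ** int(n_rounds)


def abundance_filter(
    table: TranscriptTable,
    min_count: int,
    region_mask: np.ndarray | None = None,
) -> list[str]:
    """Panel genes with at least ``min_count`` records, in panel order.

    ``region_mask`` (boolean, one entry per record) restricts counting to a
    spatial region, e.g. inside or outside detected islets.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    recs = table.records
    if region_mask is not None:
        mask = np.asarray(region_mask, dtype=bool)
        if mask.shape != (len(recs),):
            raise ValueError("region_mask length must equal record count")
        recs = recs[mask]
    counts = recs["gene"].value_counts()
    return [g for g in table.panel if int(counts.get(g, 0)) >= min_count]
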