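"""Synthetic tissue generator with known ground truth.

Emulates the structure of a decoded in situ sequencing experiment on
developing pancreas: a planar tissue window containing circular endocrine
islets densely populated by marker transcripts, genes whose intensity
decays with distance from the islet boundary (islet-proximal), genes
scattered uniformly, nuclei placed by a hard-core process, and — when a
ground-truth interaction matrix is supplied — within-islet multitype
point patterns drawn from the Strauss sampler.  Every placement is
reproducible from a single integer seed, with per-component substreams so
that adding a gene to a spec does not perturb the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import NucleusSet, TranscriptTable
from .density import DistanceSample
from .islets import Islet, IsletSet
from .strauss import StraussParams, Window, simulate_multitype_strauss

_KINDS = ("islet_marker", "islet_proximal", "uniform")


@dataclass(frozen=True)
class GeneSpec:
    """One synthetic gene: label, placement kind, count, and decay scale.

    ``scale`` (micrometres) is the exponential decay scale of the
    boundary-distance distribution; it only applies to islet_proximal
    genes.
    """

    label: str
    kind: str
    count: int
    scale: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown gene kind {self.kind!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


@dataclass(frozen=True)
class TissueSpec:
    """Specification of a synthetic tissue window."""

    window: Window
    islets: tuple[tuple[float, float, float], ...]  # (cx, cy, radius)
    genes: tuple[GeneSpec, ...]
    nuclei_count: int = 0
    nuclei_spacing: float = 10.0
    within_islet_gamma: pd.DataFrame | None = None
    interaction_radius: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.genes]
        if len(set(labels)) != len(labels):
            raise ValueError("gene labels must be unique")
        if self.nuclei_count < 0:
            raise ValueError("nuclei_count must be >= 0")
        for a in range(len(self.islets)):
            cx, cy, r = self.islets[a]
            if r <= 0:
                raise ValueError("islet radius must be > 0")
            for b in range(a + 1, len(self.islets)):
                ox, oy, orr = self.islets[b]
                if np.hypot(cx - ox, cy - oy) < r + orr:
                    raise ValueError(
                        f"islets {a} and {b} overlap; centers must be "
                        "separated by at least the sum of radii"
                    )


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent, label-keyed random substream."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def _sample_in_islets(
    islets: Sequence[tuple[float, float, float]],
    count: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform points inside the union of islets, allocated by area."""
    areas = np.array([r**2 for _, _, r in islets], float)
    alloc = rng.multinomial(count, areas / areas.sum())
    pts, owner = [], []
    for k, ((cx, cy, r), n_k) in enumerate(zip(islets, alloc)):
        rad = r * np.sqrt(rng.uniform(size=n_k))
        th = rng.uniform(0, 2 * np.pi, size=n_k)
        pts.append(np.column_stack([cx + rad * np.cos(th), cy + rad * np.sin(th)]))
        owner.append(np.full(n_k, k))
    return np.vstack(pts) if pts else np.empty((0, 2)), (
        np.concatenate(owner) if owner else np.empty(0, int)
    )


def _sample_proximal(
    spec: TissueSpec, count: int, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Points outside islets with boundary distance ~ Exp(scale)."""
    if not spec.islets:
        raise ValueError("islet_proximal genes require at least one islet")
    centers = np.array([(cx, cy) for cx, cy, _ in spec.islets])
    radii = np.array([r for _, _, r in spec.islets])
    out = np.empty((0, 2))
    while len(out) < count:
        m = max(4 * (count - len(out)), 64)
        k = rng.integers(0, len(spec.islets), size=m)
        d = rng.exponential(scale, size=m)
        th = rng.uniform(0, 2 * np.pi, size=m)
        rr = radii[k] + d
        cand = centers[k] + np.column_stack([rr * np.cos(th), rr * np.sin(th)])
        ok = spec.window.contains(cand)
        # must be outside every islet (may have landed inside a neighbor)
        dd = np.linalg.norm(cand[:, None, :] - centers[None, :, :], axis=2)
        ok &= (dd > radii[None, :]).all(axis=1)
        out = np.vstack([out, cand[ok]])
    return out[:count]


def _hardcore_nuclei(
    window: Window, count: int, spacing: float, rng: np.random.Generator
) -> np.ndarray:
    """Dart-throwing hard-core process: sequential acceptance at >= spacing."""
    accepted = np.empty((0, 2))
    attempts = 0
    while len(accepted) < count and attempts < 200 * max(count, 1):
        cand = window.sample_uniform(256, rng)
        for p in cand:
            attempts += 1
            if len(accepted) == 0 or (
                np.hypot(accepted[:, 0] - p[0], accepted[:, 1] - p[1]).min()
                >= spacing
            ):
                accepted = np.vstack([accepted, p])
                if len(accepted) == count:
                    break
    if len(accepted) < count:
        raise ValueError(
            f"could not place {count} nuclei at {spacing} um spacing in the "
            "window; reduce the count or the spacing"
        )
    return accepted


def make_tissue(
    spec: TissueSpec,
) -> tuple[TranscriptTable, NucleusSet, IsletSet]:
    """Generate a synthetic tissue and its ground truth.

    Returns the transcript table (qualities uniform on [0, 1]), the
    nucleus set, and the planted islets as an IsletSet whose member counts
    are the planted marker counts per islet.
    """
    marker_labels = [g.label for g in spec.genes if g.kind == "islet_marker"]
    if marker_labels and not spec.islets:
        raise ValueError("islet_marker genes require at least one islet")

    frames = []
    islet_members = np.zeros(len(spec.islets), int)

    if spec.within_islet_gamma is not None and marker_labels:
        gamma = spec.within_islet_gamma.loc[marker_labels, marker_labels]
        counts = {g.label: g.count for g in spec.genes if g.kind == "islet_marker"}
        areas = np.array([r**2 for _, _, r in spec.islets], float)
        frac = areas / areas.sum()
        rng_alloc = _substream(spec.seed, "islet-allocation")
        alloc = {
            lab: rng_alloc.multinomial(counts[lab], frac) for lab in marker_labels
        }
        beta = np.array(
            [max(counts[lab], 1) / spec.window.area for lab in marker_labels]
        )
        params = StraussParams(
            tuple(marker_labels), beta, gamma.to_numpy(float),
            spec.interaction_radius,
        )
        for k, (cx, cy, r) in enumerate(spec.islets):
            n_here = {lab: int(alloc[lab][k]) for lab in marker_labels}
            pat = simulate_multitype_strauss(
                params, Window.circle(cx, cy, r), n_here,
                seed=int(_substream(spec.seed, f"islet-{k}").integers(2**31 - 1)),
            )
            islet_members[k] += len(pat)
            frames.append(
                pd.DataFrame(
                    {"x": pat.xy[:, 0], "y": pat.xy[:, 1],
                     "gene": pat.types.astype(str)}
                )
            )
    else:
        for g in spec.genes:
            if g.kind != "islet_marker":
                continue
            rng = _substream(spec.seed, f"gene-{g.label}")
            pts, owner = _sample_in_islets(spec.islets, g.count, rng)
            np.add.at(islet_members, owner, 1)
            frames.append(
                pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "gene": g.label})
            )

    for g in spec.genes:
        if g.kind == "islet_marker":
            continue
        rng = _substream(spec.seed, f"gene-{g.label}")
        if g.kind == "uniform":
            pts = spec.window.sample_uniform(g.count, rng)
        else:
            pts = _sample_proximal(spec, g.count, g.scale, rng)
        frames.append(
            pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "gene": g.label})
        )

    records = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["x", "y", "gene"])
    )
    rng_q = _substream(spec.seed, "quality")
    records["quality"] = rng_q.uniform(size=len(records))
    records["gene"] = records["gene"].astype(str)
    panel = tuple(g.label for g in spec.genes)
    table = TranscriptTable(records, panel)

    rng_n = _substream(spec.seed, "nuclei")
    nuc_xy = (
        _hardcore_nuclei(spec.window, spec.nuclei_count, spec.nuclei_spacing, rng_n)
        if spec.nuclei_count
        else np.empty((0, 2))
    )
    nuclei = NucleusSet(pd.DataFrame({"x": nuc_xy[:, 0], "y": nuc_xy[:, 1]}))

    truth = IsletSet(
        tuple(
            Islet(cx, cy, r, max(int(m), 1))
            for (cx, cy, r), m in zip(spec.islets, islet_members)
        ),
        tuple(marker_labels) or ("SST", "GLUC", "INS"),
    )
    return table, nuclei, truth


def make_profile_fixture(
    group1_scale: float,
    group2_scale: float,
    n_per_gene: int,
    seed: int = 0,
    n_genes_per_group: int = 4,
    feature: str = "islet_boundary",
) -> dict[str, DistanceSample]:
    """Distance samples with a planted two-group structure.

    Group-1 genes draw boundary distances from Exp(group1_scale) (close to
    islets), group-2 genes from Exp(group2_scale); with well separated
    scales the two-group partition is recoverable from the divergence
    matrix.  Gene labels are ``g1_0..`` and ``g2_0..``.
    """
    if group1_scale <= 0 or group2_scale <= 0:
        raise ValueError("scales must be > 0")
    out: dict[str, DistanceSample] = {}
    for grp, scale in ((1, group1_scale), (2, group2_scale)):
        for i in range(n_genes_per_group):
            label = f"g{grp}_{i}"
            rng = _substream(seed, f"profile-{label}")
            out[label] = DistanceSample(
                label, rng.exponential(scale, size=n_per_gene), feature
            )
    return out
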