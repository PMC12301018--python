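"""Volume extraction, mass estimation, depth-resolved composition profiles
and representative-elementary-volume (REV) analysis.

Mass estimation converts fluorescent volume fractions into masses using a
measured biofilm mass m (mg):

    EPS_I  = m * V_I / V          (per-component mass)
    EPS_II = m * (V - V_B) / V    (total EPS mass = everything but cells)

where V is the total biofilm volume, V_I the fluorescent volume of one EPS
component (protein, polysaccharide, lipid or nucleic acid) and V_B the
bacterial volume. Both are scale-invariant in the volumes, so the voxel size
only needs to be consistent across masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from skimage.morphology import convex_hull_image

from .errors import ConfigError, EmptyInputError, ValidationError
from .segment import BACTERIA_COMPONENTS, EPS_COMPONENTS, Component, ComponentMask
from .stack_io import DepthOrigin

__all__ = [
    "BiofilmQuant",
    "DepthProfile",
    "REVResult",
    "component_volume",
    "total_biofilm_volume",
    "eps_component_mass",
    "eps_total_mass",
    "biofilm_quant",
    "depth_profile",
    "rev_analysis",
]


@dataclass
class BiofilmQuant:
    """Per-field quantification: volumes (µm³) and derived masses (mg)."""

    m: float
    V: float
    V_I: dict[str, float]
    V_B: float
    EPS_I: dict[str, float]
    EPS_II: float

    def __post_init__(self) -> None:
        for comp, v in self.V_I.items():
            if not 0 <= v <= self.V * (1 + 1e-12):
                raise ValidationError(f"V_I[{comp}]={v} outside [0, V={self.V}]")
        if not 0 <= self.V_B <= self.V * (1 + 1e-12):
            raise ValidationError(f"V_B={self.V_B} outside [0, V={self.V}]")


@dataclass
class DepthProfile:
    """Per-depth-bin voxel counts and composition fractions.

    ``counts`` is (n_bins, n_components); ``proportions`` normalizes each bin
    across components (bins with zero total are all-zero). Depth is distance
    from the substrate in µm.
    """

    bin_edges: np.ndarray  # n_bins + 1 edges in µm
    components: list[str]
    counts: np.ndarray
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    def component_mode_bin(self, component: str) -> int:
        """Index of the depth bin where ``component`` has the most voxels."""
        j = self.components.index(component)
        return int(np.argmax(self.counts[:, j]))

    def to_frame(self):
        import pandas as pd

        rows = []
        for i in range(len(self.counts)):
            for j, comp in enumerate(self.components):
                rows.append(
                    {
                        "bin_lo_um": self.bin_edges[i],
                        "bin_hi_um": self.bin_edges[i + 1],
                        "component": comp,
                        "count": int(self.counts[i, j]),
                        "proportion": self.proportions[i, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class REVResult:
    """Volume-fraction stability versus sampled subvolume size."""

    subvolume_sizes: np.ndarray  # edge lengths in µm, strictly increasing
    estimates: np.ndarray  # (n_sizes, n_samples) volume fractions
    cv: np.ndarray  # coefficient of variation per size
    rev_size: float | None  # smallest size meeting the cv tolerance, or None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "size_um": self.subvolume_sizes,
                "mean": self.estimates.mean(axis=1),
                "cv": self.cv,
            }
        )


def component_volume(mask: ComponentMask | np.ndarray, voxel_size: Sequence[float]) -> float:
    """Fluorescent volume of a mask in µm³: voxel count x voxel volume."""
    dz, dy, dx = (float(v) for v in voxel_size)
    if min(dz, dy, dx) <= 0:
        raise ConfigError("voxel_size must be positive")
    occ = np.asarray(getattr(mask, "occupancy", mask)).astype(bool)
    return float(occ.sum()) * dz * dy * dx


def total_biofilm_volume(
    masks: Sequence[ComponentMask],
    voxel_size: Sequence[float],
    strategy: Literal["union", "convex_envelope"] = "union",
) -> float:
    """Total biofilm volume V in µm³.

    ``union`` counts the voxelwise OR of all masks — conservative, counts
    only stained voxels. ``convex_envelope`` fills the per-z-slice 2D convex
    hull of the union, approximating a filled biofilm body including unstained
    interstitial space.
    """
    if not masks:
        raise EmptyInputError("no masks given")
    shapes = {tuple(m.occupancy.shape) for m in masks}
    if len(shapes) > 1:
        raise ValidationError(f"masks have differing shapes: {sorted(shapes)}")
    union = np.zeros(masks[0].occupancy.shape, dtype=bool)
    for m in masks:
        union |= m.occupancy
    if not union.any():
        raise EmptyInputError("all masks are empty; total volume undefined")
    if strategy == "union":
        body = union
    elif strategy == "convex_envelope":
        body = np.zeros_like(union)
        for z in range(union.shape[0]):
            if union[z].any():
                body[z] = convex_hull_image(union[z])
    else:
        raise ConfigError(f"unknown volume strategy {strategy!r}")
    return component_volume(body, voxel_size)


def eps_component_mass(m: float, V: float, V_I: float) -> float:
    """Mass (mg) of one EPS component: EPS_I = m * V_I / V."""
    if V <= 0:
        raise ZeroDivisionError("total volume V must be positive")
    if not 0 <= V_I <= V:
        raise ValidationError(f"V_I={V_I} must lie in [0, V={V}]")
    return m * V_I / V


def eps_total_mass(m: float, V: float, V_B: float) -> float:
    """Total EPS mass (mg): EPS_II = m * (V - V_B) / V, cells excluded."""
    if V <= 0:
        raise ZeroDivisionError("total volume V must be positive")
    if not 0 <= V_B <= V:
        raise ValidationError(f"V_B={V_B} must lie in [0, V={V}]")
    return m * (V - V_B) / V


def biofilm_quant(
    masks: Sequence[ComponentMask],
    voxel_size: Sequence[float],
    m_mg: float,
    volume_strategy: Literal["union", "convex_envelope"] = "union",
    bacteria_source: Literal["all_bacteria", "live_only"] = "all_bacteria",
) -> BiofilmQuant:
    """Full mass budget for one imaged field.

    ``bacteria_source`` controls V_B: the all-bacteria mask (default) or the
    all-bacteria mask minus the dead-bacteria (PI) mask.
    """
    by_comp = {Component(m.component): m for m in masks}
    V = total_biofilm_volume(masks, voxel_size, strategy=volume_strategy)
    V_I = {
        c.value: component_volume(by_comp[c], voxel_size) for c in EPS_COMPONENTS if c in by_comp
    }
    if Component.all_bacteria in by_comp:
        bact = by_comp[Component.all_bacteria].occupancy
        if bacteria_source == "live_only" and Component.dead_bacteria in by_comp:
            bact = bact & ~by_comp[Component.dead_bacteria].occupancy
        V_B = component_volume(bact, voxel_size)
    else:
        V_B = 0.0
    EPS_I = {c: eps_component_mass(m_mg, V, v) for c, v in V_I.items()}
    EPS_II = eps_total_mass(m_mg, V, V_B)
    return BiofilmQuant(m=m_mg, V=V, V_I=V_I, V_B=V_B, EPS_I=EPS_I, EPS_II=EPS_II)


def depth_profile(
    masks: Sequence[ComponentMask],
    voxel_size: Sequence[float],
    bin_width_um: float = 10.0,
    origin: DepthOrigin = DepthOrigin.substrate_at_z0,
    normalize: Literal["within_bin", "within_component"] = "within_bin",
) -> DepthProfile:
    """Depth-stratified composition of the biofilm.

    Each voxel is assigned to the depth bin containing its z-center, depth
    measured from the substrate face. ``within_bin`` (default) normalizes
    proportions across components inside each bin, i.e. each non-empty bin's
    proportions sum to 1 — the stacked-composition view. ``within_component``
    instead normalizes each component's counts across bins, showing where
    along the depth axis that component concentrates.
    """
    if not masks:
        raise EmptyInputError("no masks given")
    shapes = {tuple(m.occupancy.shape) for m in masks}
    if len(shapes) > 1:
        raise ValidationError(f"masks have differing shapes: {sorted(shapes)}")
    dz = float(voxel_size[0])
    if bin_width_um <= 0:
        raise ConfigError("bin_width_um must be positive")
    if bin_width_um < dz:
        raise ConfigError(f"bin_width {bin_width_um} µm is finer than the z-spacing {dz} µm")
    nz = masks[0].occupancy.shape[0]
    z_idx = np.arange(nz)
    if DepthOrigin(origin) == DepthOrigin.substrate_at_z0:
        depth = (z_idx + 0.5) * dz
    else:
        depth = (nz - z_idx - 0.5) * dz
    n_bins = int(np.ceil(nz * dz / bin_width_um))
    edges = np.arange(n_bins + 1) * bin_width_um
    bin_of_slice = np.minimum((depth // bin_width_um).astype(int), n_bins - 1)

    comps = [Component(m.component).value for m in masks]
    counts = np.zeros((n_bins, len(masks)), dtype=np.int64)
    for j, m in enumerate(masks):
        per_slice = m.occupancy.reshape(nz, -1).sum(axis=1)
        np.add.at(counts[:, j], bin_of_slice, per_slice)

    proportions = np.zeros_like(counts, dtype=float)
    if normalize == "within_bin":
        totals = counts.sum(axis=1)
        nz_bins = totals > 0
        proportions[nz_bins] = counts[nz_bins] / totals[nz_bins, None]
    elif normalize == "within_component":
        col = counts.sum(axis=0)
        pos = col > 0
        proportions[:, pos] = counts[:, pos] / col[pos]
    else:
        raise ConfigError(f"unknown normalization {normalize!r}")
    return DepthProfile(edges, comps, counts, proportions)


def rev_analysis(
    mask: ComponentMask | np.ndarray,
    voxel_size: Sequence[float],
    sizes_um: Sequence[float],
    n_samples: int = 30,
    cv_tol: float = 0.05,
    seed: int = 0,
) -> REVResult:
    """Representative-elementary-volume analysis of a binary mask.

    For each cubic subvolume edge length, ``n_samples`` axis-aligned
    subvolumes are sampled uniformly (with replacement) and their volume
    fractions recorded; cv = std/mean across samples. The REV size is the
    smallest size whose cv falls at or below ``cv_tol`` — the scale above
    which the measured fraction no longer depends on where you look.
    """
    occ = np.asarray(getattr(mask, "occupancy", mask)).astype(bool)
    if occ.ndim != 3:
        raise ValidationError("mask must be 3D")
    if n_samples < 2:
        raise ConfigError("n_samples must be >= 2")
    sizes_um = np.asarray(sorted(float(s) for s in sizes_um))
    if sizes_um.size == 0 or np.any(np.diff(sizes_um) <= 0):
        raise ConfigError("sizes must be non-empty and distinct")
    vsz = np.asarray(voxel_size, dtype=float)
    extent_vox = np.asarray(occ.shape)
    rng = np.random.default_rng(seed)
    estimates = np.empty((sizes_um.size, n_samples))
    for i, s in enumerate(sizes_um):
        nvox = np.maximum(np.round(s / vsz).astype(int), 1)
        if np.any(nvox > extent_vox):
            raise ConfigError(
                f"subvolume size {s} µm ({tuple(nvox)} voxels) exceeds mask extent {occ.shape}"
            )
        for j in range(n_samples):
            corner = [rng.integers(0, e - n + 1) for e, n in zip(extent_vox, nvox)]
            sub = occ[
                corner[0] : corner[0] + nvox[0],
                corner[1] : corner[1] + nvox[1],
                corner[2] : corner[2] + nvox[2],
            ]
            estimates[i, j] = sub.mean()
    means = estimates.mean(axis=1)
    stds = estimates.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(means > 0, stds / means, np.inf)
    cv = np.where((means == 0) & (stds == 0), np.inf, cv)  # empty everywhere: not representative
    ok = np.flatnonzero(cv <= cv_tol)
    rev_size = float(sizes_um[ok[0]]) if ok.size else None
    return REVResult(sizes_um, estimates, cv, rev_size)
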