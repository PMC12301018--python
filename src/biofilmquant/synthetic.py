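"""Ground-truthed synthetic biofilm stacks and EEM matrices.

The generator emulates the two salinity regimes used throughout the package:

* **FQHC** (low salinity, 3 g/L): components concentrated around mid-depth
  with near-equal volume fractions and uniform depth densities.
* **SQHC** (high salinity, 35 g/L): bacteria enriched in the surface layer
  (depth density centred at 15 µm, inside the 10-20 µm window), extracellular
  DNA enriched deep (centred at 35 µm, inside 30-40 µm), protein and
  polysaccharide weighted toward the deep bins.

Morphology is deliberately simple — overlapping spheres ("microcolonies")
placed until each component reaches its target volume fraction — which is
enough to exercise segmentation, quantification and depth profiling. Optics
are modelled as channel bleed-through (a mixing matrix), a Gaussian blur as a
point-spread-function proxy, and additive Gaussian noise with
sd = foreground/snr. Every call draws from one seeded generator, so a fixed
seed reproduces the dataset bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .eem import EEM_EM_GRID, EEM_EX_GRID, EEMMatrix
from .errors import ConfigError
from .segment import BACTERIA_COMPONENTS, Component
from .stack_io import DepthOrigin, ImageStack

__all__ = [
    "DepthDensity",
    "ComponentSpec",
    "StackRecipe",
    "SyntheticTruth",
    "generate_stack",
    "preset_recipe",
    "generate_eem",
]


@dataclass(frozen=True)
class DepthDensity:
    """Distribution of blob centres along depth (µm from the substrate).

    kind "uniform": uniform over [lo, hi]; kind "gaussian": normal(mean, sd)
    truncated to the stack extent.
    """

    kind: Literal["uniform", "gaussian"]
    a: float  # lo (uniform) or mean (gaussian)
    b: float  # hi (uniform) or sd (gaussian)

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "gaussian"):
            raise ConfigError(f"unknown depth density kind {self.kind!r}")
        if self.kind == "uniform" and self.b <= self.a:
            raise ConfigError("uniform depth density needs hi > lo")
        if self.kind == "gaussian" and self.b <= 0:
            raise ConfigError("gaussian depth density needs sd > 0")

    def sample(self, rng: np.random.Generator, depth_extent: float) -> float:
        if self.kind == "uniform":
            lo = max(self.a, 0.0)
            hi = min(self.b, depth_extent)
            return float(rng.uniform(lo, hi))
        while True:  # truncate to the stack
            z = rng.normal(self.a, self.b)
            if 0.0 <= z <= depth_extent:
                return float(z)


@dataclass(frozen=True)
class ComponentSpec:
    component: Component
    target_fraction: float  # fraction of the stack volume
    depth_density: DepthDensity

    def __post_init__(self) -> None:
        if not 0 < self.target_fraction <= 1:
            raise ConfigError(f"{self.component}: target_fraction must be in (0, 1]")


@dataclass(frozen=True)
class StackRecipe:
    """Everything needed to generate one ground-truthed stack."""

    shape: tuple[int, int, int] = (64, 64, 64)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # µm
    components: tuple[ComponentSpec, ...] = ()
    blob_radius_um: float = 4.0
    snr: float = 5.0  # foreground amplitude / noise sd; inf = noiseless
    blur_sigma_um: float = 0.5
    bleed: tuple[tuple[float, ...], ...] | None = None  # rows: observed channel
    background: float = 20.0
    foreground: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            raise ConfigError("recipe needs at least one component")
        comps = [c.component for c in self.components]
        if len(set(comps)) != len(comps):
            raise ConfigError("duplicate components in recipe")
        total = sum(
            c.target_fraction
            for c in self.components
            if c.component != Component.dead_bacteria
        )
        if total > 0.9:
            raise ConfigError(
                f"total target fraction {total:.2f} > 0.9 of the volume is infeasible"
            )
        if not self.snr > 0:
            raise ConfigError("snr must be positive")
        if self.blob_radius_um <= 0:
            raise ConfigError("blob_radius_um must be positive")
        if self.bleed is not None:
            B = np.asarray(self.bleed, dtype=float)
            n = len(self.components)
            if B.shape != (n, n):
                raise ConfigError(f"bleed matrix must be {n}x{n}")
            if np.any(B < 0) or np.any(B.sum(axis=1) > 1.5):
                raise ConfigError("bleed rows must be non-negative and sum to <= 1.5")


@dataclass
class SyntheticTruth:
    """Exact ground truth accompanying a generated stack."""

    masks: dict[str, np.ndarray]  # component -> boolean volume
    fractions: dict[str, float]  # realized volume fractions
    depth_modes: dict[str, tuple[float, float]]  # argmax 10 µm depth bin per component


def _ball(radius_vox: np.ndarray) -> np.ndarray:
    """Boolean ellipsoid with per-axis voxel radii."""
    rz, ry, rx = radius_vox
    zz, yy, xx = np.ogrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
    return (zz / max(rz, 1e-9)) ** 2 + (yy / max(ry, 1e-9)) ** 2 + (
        xx / max(rx, 1e-9)
    ) ** 2 <= 1.0


def _place_blobs(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    density: DepthDensity,
    radius_um: float,
    target_voxels: int,
    occupied: np.ndarray | None = None,
) -> tuple[np.ndarray, list[tuple[tuple[slice, slice, slice], np.ndarray]]]:
    """Add spherical blobs until ``target_voxels`` NEW voxels are set.

    Voxels already claimed in ``occupied`` (earlier components) do not count
    and are excluded, keeping component truths disjoint where required.
    Returns the union mask plus each blob's (slices, patch) so callers can
    pick blob subsets (e.g. the PI-positive subpopulation).
    """
    nz, ny, nx = shape
    dz, dy, dx = voxel_size
    mask = np.zeros(shape, dtype=bool)
    blobs: list[tuple[tuple[slice, slice, slice], np.ndarray]] = []
    depth_extent = nz * dz
    count = 0
    max_blobs = 50 * max(target_voxels, 1)  # safety valve, never hit in practice
    for _ in range(max_blobs):
        if count >= target_voxels:
            break
        r_um = radius_um * rng.uniform(0.7, 1.3)
        rvox = np.maximum(np.round(r_um / np.asarray(voxel_size)).astype(int), 1)
        zc = int(min(density.sample(rng, depth_extent) / dz, nz - 1))
        yc = int(rng.integers(0, ny))
        xc = int(rng.integers(0, nx))
        ball = _ball(rvox)
        z0, y0, x0 = zc - rvox[0], yc - rvox[1], xc - rvox[2]
        zs = slice(max(z0, 0), min(z0 + ball.shape[0], nz))
        ys = slice(max(y0, 0), min(y0 + ball.shape[1], ny))
        xs = slice(max(x0, 0), min(x0 + ball.shape[2], nx))
        bz = slice(zs.start - z0, zs.stop - z0)
        by = slice(ys.start - y0, ys.stop - y0)
        bx = slice(xs.start - x0, xs.stop - x0)
        patch = ball[bz, by, bx]
        if occupied is not None:
            patch = patch & ~occupied[zs, ys, xs]
        new = patch & ~mask[zs, ys, xs]
        mask[zs, ys, xs] |= new
        count += int(new.sum())
        blobs.append(((zs, ys, xs), patch))
    return mask, blobs


def generate_stack(recipe: StackRecipe) -> tuple[ImageStack, SyntheticTruth]:
    """Generate a multi-channel stack plus its exact ground truth.

    Per component, blobs are placed with z drawn from its depth density until
    its target volume fraction is reached; EPS component truths are kept
    mutually disjoint (a voxel holds one matrix component), while bacterial
    truths may overlap EPS. The dead-bacteria mask, if requested, is a random
    subset of the all-bacteria blobs. Channel intensities are
    background + foreground * truth, mixed by the bleed matrix, blurred, and
    corrupted with seeded Gaussian noise of sd = foreground/snr.
    """
    rng = np.random.default_rng(recipe.seed)
    nz, ny, nx = recipe.shape
    n_total = nz * ny * nx
    truths: dict[Component, np.ndarray] = {}
    eps_occupied = np.zeros(recipe.shape, dtype=bool)

    specs = {c.component: c for c in recipe.components}
    if Component.dead_bacteria in specs and Component.all_bacteria not in specs:
        raise ConfigError("dead_bacteria requires an all_bacteria component")

    for spec in recipe.components:
        comp = spec.component
        if comp == Component.dead_bacteria:
            continue  # derived below from all_bacteria
        target = int(round(spec.target_fraction * n_total))
        exclusive = comp not in BACTERIA_COMPONENTS
        mask, blobs = _place_blobs(
            rng,
            recipe.shape,
            recipe.voxel_size,
            spec.depth_density,
            recipe.blob_radius_um,
            target,
            occupied=eps_occupied if exclusive else None,
        )
        if exclusive:
            eps_occupied |= mask
        truths[comp] = mask
        if comp == Component.all_bacteria and Component.dead_bacteria in specs:
            # PI-positive subpopulation: whole microcolonies die, so the dead
            # mask is the union of a random subset of the bacterial blobs
            dead = np.zeros(recipe.shape, dtype=bool)
            target_dead = min(
                int(round(specs[Component.dead_bacteria].target_fraction * n_total)),
                int(mask.sum()),
            )
            for bi in rng.permutation(len(blobs)):
                if dead.sum() >= target_dead:
                    break
                (zs, ys, xs), patch = blobs[bi]
                dead[zs, ys, xs] |= patch
            truths[Component.dead_bacteria] = dead & mask

    order = [c.component for c in recipe.components]
    n_chan = len(order)
    signal = np.stack([truths[c].astype(float) for c in order])
    if recipe.bleed is not None:
        B = np.asarray(recipe.bleed, dtype=float)
        signal = np.tensordot(B, signal, axes=(1, 0))
    voxels = recipe.background + recipe.foreground * signal
    if recipe.blur_sigma_um > 0:
        sigmas = tuple(recipe.blur_sigma_um / d for d in recipe.voxel_size)
        for c in range(n_chan):
            voxels[c] = ndimage.gaussian_filter(voxels[c], sigma=sigmas)
    if math.isfinite(recipe.snr):
        voxels += rng.normal(0.0, recipe.foreground / recipe.snr, size=voxels.shape)
    voxels = np.clip(voxels, 0.0, None)

    stack = ImageStack(
        voxels,
        recipe.voxel_size,
        [c.value for c in order],
        DepthOrigin.substrate_at_z0,
    )
    fractions = {c.value: float(truths[c].sum()) / n_total for c in order}
    depth_modes = {}
    dz = recipe.voxel_size[0]
    for c in order:
        per_slice = truths[c].reshape(nz, -1).sum(axis=1)
        depth = (np.arange(nz) + 0.5) * dz
        bins = (depth // 10.0).astype(int)
        counts = np.bincount(bins, weights=per_slice)
        mode = int(np.argmax(counts))
        depth_modes[c.value] = (mode * 10.0, (mode + 1) * 10.0)
    truth = SyntheticTruth(
        masks={c.value: truths[c] for c in order},
        fractions=fractions,
        depth_modes=depth_modes,
    )
    return stack, truth


def _default_bleed(order: Sequence[Component]) -> tuple[tuple[float, ...], ...]:
    """Small symmetric bleed between the spectrally closest dyes.

    Nile Red (lipid) and PI (dead bacteria) emit ~20-30 nm apart, and
    rhodamine (all bacteria) sits just below Nile Red, so those channel pairs
    receive a 5% mutual bleed; everything else is clean.
    """
    close_pairs = {
        frozenset({Component.lipid, Component.dead_bacteria}),
        frozenset({Component.lipid, Component.all_bacteria}),
    }
    n = len(order)
    B = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i != j and frozenset({order[i], order[j]}) in close_pairs:
                B[i, j] = 0.05
    return tuple(tuple(row) for row in B)


def preset_recipe(name: str, seed: int = 0) -> StackRecipe:
    """Recipe for one of the two salinity regimes.

    FQHC: every component uniform over mid-depth (16-48 µm in a 64 µm stack)
    with near-equal fractions. SQHC: bacteria gaussian(15, 5) µm — surface
    layer; nucleic acid gaussian(35, 5) µm — deep DNA enrichment; protein and
    polysaccharide weighted to the deep bins (gaussian around 45 µm).
    """
    mid = DepthDensity("uniform", 16.0, 48.0)
    if name == "FQHC":
        components = (
            ComponentSpec(Component.protein, 0.06, mid),
            ComponentSpec(Component.polysaccharide, 0.06, mid),
            ComponentSpec(Component.nucleic_acid, 0.05, mid),
            ComponentSpec(Component.lipid, 0.05, mid),
            ComponentSpec(Component.all_bacteria, 0.08, mid),
            ComponentSpec(Component.dead_bacteria, 0.02, mid),
        )
    elif name == "SQHC":
        components = (
            ComponentSpec(Component.protein, 0.06, DepthDensity("gaussian", 45.0, 8.0)),
            ComponentSpec(Component.polysaccharide, 0.06, DepthDensity("gaussian", 47.0, 8.0)),
            ComponentSpec(Component.nucleic_acid, 0.05, DepthDensity("gaussian", 35.0, 5.0)),
            ComponentSpec(Component.lipid, 0.04, DepthDensity("uniform", 25.0, 50.0)),
            ComponentSpec(Component.all_bacteria, 0.08, DepthDensity("gaussian", 15.0, 5.0)),
            ComponentSpec(Component.dead_bacteria, 0.02, DepthDensity("gaussian", 15.0, 5.0)),
        )
    else:
        raise ConfigError(f"unknown preset {name!r}; expected 'FQHC' or 'SQHC'")
    order = [c.component for c in components]
    return StackRecipe(
        shape=(64, 64, 64),
        voxel_size=(1.0, 1.0, 1.0),
        components=components,
        blob_radius_um=4.0,
        snr=5.0,
        blur_sigma_um=0.5,
        bleed=_default_bleed(order),
        seed=seed,
    )


def generate_eem(
    peaks: Sequence[tuple[float, float, float, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> EEMMatrix:
    """Synthesize an EEM as a sum of 2D Gaussians on the acquisition grid.

    ``peaks`` is a sequence of (ex_nm, em_nm, height, sd_nm); centres must
    lie on the 5 nm grid. Seeded Gaussian noise of sd ``noise_sd`` is added
    and the result clipped at zero.
    """
    rng = np.random.default_rng(seed)
    z = np.zeros((EEM_EX_GRID.size, EEM_EM_GRID.size))
    ex = EEM_EX_GRID[:, None]
    em = EEM_EM_GRID[None, :]
    for ex0, em0, height, sd in peaks:
        if ex0 not in EEM_EX_GRID or em0 not in EEM_EM_GRID:
            raise ConfigError(f"peak centre ({ex0}, {em0}) nm is off the acquisition grid")
        if sd <= 0 or height < 0:
            raise ConfigError("peak height must be >= 0 and sd > 0")
        z += height * np.exp(-((ex - ex0) ** 2 + (em - em0) ** 2) / (2 * sd**2))
    if noise_sd > 0:
        z += rng.normal(0.0, noise_sd, size=z.shape)
    return EEMMatrix(EEM_EX_GRID, EEM_EM_GRID, np.clip(z, 0.0, None), label=label)
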