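"""Threshold segmentation, mask cleanup, component assignment under the
five-stain scheme, fluorophore cross-talk checking, and k-means depth-layer
clustering.

The staining scheme maps one fluorophore to each biofilm component:
FITC -> protein, Calcofluor White -> polysaccharide, Nile Red -> lipid,
rhodamine -> all bacteria, propidium iodide (PI) -> dead bacteria, with the
EPS dyes applied as a mixture and the lipid and bacterial dyes applied
singly. EPS components therefore compete for multi-positive voxels, while
bacterial signal is allowed to coexist with EPS signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

from .errors import ConfigError, DegenerateHistogramError, ValidationError
from .stack_io import ImageStack

log = logging.getLogger(__name__)

__all__ = [
    "Component",
    "EPS_COMPONENTS",
    "BACTERIA_COMPONENTS",
    "ChannelEntry",
    "ChannelMap",
    "table1_channel_map",
    "ComponentMask",
    "LayerClustering",
    "threshold_segment",
    "clean_mask",
    "crosstalk_check",
    "assign_components",
    "kmeans_layers",
]


class Component(str, Enum):
    protein = "protein"
    polysaccharide = "polysaccharide"
    nucleic_acid = "nucleic_acid"
    lipid = "lipid"
    all_bacteria = "all_bacteria"
    dead_bacteria = "dead_bacteria"


#: EPS matrix components that compete for multi-positive voxels.
EPS_COMPONENTS = (
    Component.protein,
    Component.polysaccharide,
    Component.nucleic_acid,
    Component.lipid,
)
#: Cell components allowed to overlap EPS masks.
BACTERIA_COMPONENTS = (Component.all_bacteria, Component.dead_bacteria)


@dataclass(frozen=True)
class ChannelEntry:
    """One fluorophore: its excitation/emission maxima (nm) and the component
    it reports."""

    fluorophore: str
    excitation_nm: tuple[float, ...]
    emission_nm: tuple[float, ...]
    component: Component
    stain_mode: Literal["mixed", "single"] = "mixed"

    def __post_init__(self) -> None:
        if not self.excitation_nm or not self.emission_nm:
            raise ConfigError(f"{self.fluorophore}: excitation and emission lists non-empty")
        for wl in (*self.excitation_nm, *self.emission_nm):
            if not 200 <= wl <= 700:
                raise ConfigError(f"{self.fluorophore}: wavelength {wl} nm outside 200-700 nm")

    @property
    def emission_band(self) -> tuple[float, float]:
        return (min(self.emission_nm), max(self.emission_nm))


@dataclass
class ChannelMap:
    """Ordered fluorophore -> component assignment for a staining scheme."""

    entries: list[ChannelEntry]

    def __post_init__(self) -> None:
        comps = [e.component for e in self.entries]
        if len(set(comps)) != len(comps):
            raise ConfigError("components in a ChannelMap must be unique")

    def __iter__(self):
        return iter(self.entries)

    def entry_for(self, component: Component) -> ChannelEntry:
        for e in self.entries:
            if e.component == component:
                return e
        raise ConfigError(f"no entry for component {component}")

    @property
    def components(self) -> list[Component]:
        return [e.component for e in self.entries]


def table1_channel_map(include_nucleic_acid: bool = False) -> ChannelMap:
    """The five-dye staining scheme with published excitation/emission maxima.

    PI carries a parenthetical UV excitation line at 305 nm in addition to its
    visible maxima; all listed maxima are retained. With
    ``include_nucleic_acid`` a sixth, SYTO 9-like DNA channel is appended for
    datasets that image extracellular DNA separately (the synthetic presets
    do).
    """
    entries = [
            ChannelEntry("FITC", (490, 494), (520, 525), Component.protein, "mixed"),
            ChannelEntry(
                "Calcofluor White", (385, 395, 405), (437, 440, 445), Component.polysaccharide, "mixed"
            ),
            ChannelEntry("Nile Red", (515, 555, 559), (590, 640), Component.lipid, "single"),
            ChannelEntry("Rhodamine", (550,), (573,), Component.all_bacteria, "single"),
            ChannelEntry(
                "Propidium Iodide (PI)", (305, 536, 538), (617,), Component.dead_bacteria, "single"
            ),
        ]
    if include_nucleic_acid:
        entries.append(
            ChannelEntry("DNA stain (SYTO 9-like)", (485,), (498,), Component.nucleic_acid, "mixed")
        )
    return ChannelMap(entries)


@dataclass
class ComponentMask:
    """Binary occupancy of one biofilm component, with threshold provenance."""

    component: Component | str
    occupancy: np.ndarray
    threshold_used: float | None = None
    method: str = "manual"

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy).astype(bool)
        if self.occupancy.ndim != 3:
            raise ValidationError(f"occupancy must be 3D; got ndim={self.occupancy.ndim}")
        if isinstance(self.component, str):
            self.component = Component(self.component)

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())


@dataclass
class LayerClustering:
    """k-means partition of depth bins by composition."""

    k: int
    labels: np.ndarray  # cluster id per clustered (non-empty) bin
    centers: np.ndarray  # k x n_components mean composition vectors
    bin_indices: np.ndarray  # indices of the clustered bins in the profile
    inertia: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValidationError("labels must lie in [0, k)")


def _otsu_threshold(volume: np.ndarray) -> float:
    """Otsu on the full 3D histogram, 256 bins after min-max scaling."""
    lo, hi = float(volume.min()), float(volume.max())
    if hi <= lo:
        raise DegenerateHistogramError(
            "automatic thresholding is undefined on a constant volume; "
            "supply a manual threshold instead"
        )
    t_scaled = threshold_otsu((volume - lo) / (hi - lo), nbins=256)
    return lo + t_scaled * (hi - lo)


def _provisional_regions(volume: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(median-filtered copy, foreground core, background ring).

    A provisional Otsu mask of a 3x3x3-median-filtered copy is eroded
    (foreground core) and dilated (complement = background ring) so plateau
    statistics can be sampled away from the blurred boundary.
    """
    med = ndimage.median_filter(volume, size=3)
    t0 = _otsu_threshold(med)
    mask = med >= t0
    core = ndimage.binary_erosion(mask, structure=_CONN26, iterations=2)
    outside = ~ndimage.binary_dilation(mask, structure=_CONN26, iterations=2)
    # tiny or filamentous foreground leaves no core; fall back to the raw classes
    if core.sum() < 100 or outside.sum() < 100:
        core, outside = mask, ~mask
    return med, core, outside


def _half_level_threshold(volume: np.ndarray) -> float:
    """Half-maximum threshold: midpoint of the two plateau intensities.

    Otsu's criterion places the cut to balance class variances, which under
    blur and noise systematically mis-sizes objects; thresholding at half the
    foreground height instead preserves the volume of a blurred object
    because a symmetric point-spread function moves equal amounts of signal
    across the half-level in both directions.
    """
    med, core, outside = _provisional_regions(volume)
    fg = float(np.median(med[core]))
    bg = float(np.median(med[outside]))
    return 0.5 * (bg + fg)


def _flux_voxel_count(volume: np.ndarray) -> float:
    """Photometric (integrated-intensity) estimate of the foreground voxel count.

    count = (sum(I) - N*bg) / (fg - bg), with the background level taken as
    the mean of the background ring and the foreground plateau as the mean of
    the eroded core. A symmetric point-spread function redistributes but
    conserves integrated signal, and zero-mean noise cancels in the sum, so
    this estimate is immune to the boundary-shift biases that plague
    threshold counting.
    """
    med, core, outside = _provisional_regions(volume)
    bg = float(volume[outside].mean())
    fg = float(volume[core].mean())
    if fg <= bg:
        return 0.0
    count = (float(volume.sum()) - volume.size * bg) / (fg - bg)
    return float(np.clip(count, 0.0, volume.size))


def _rank_threshold(values: np.ndarray, k: int) -> float:
    """Intensity of the k-th brightest value (k >= 1)."""
    flat = np.asarray(values).ravel()
    k = int(np.clip(k, 1, flat.size))
    return float(np.partition(flat, flat.size - k)[flat.size - k])


def threshold_segment(
    volume: np.ndarray,
    method: Literal["otsu", "half_level", "flux", "manual"] = "otsu",
    manual_t: float | None = None,
    component: Component | str = Component.protein,
) -> ComponentMask:
    """Binarize a 3D intensity volume.

    ``otsu`` computes the classic threshold on the full 3D histogram (256
    bins after min-max scaling) so the threshold is depth-consistent;
    ``half_level`` thresholds at half the foreground plateau height, which is
    volume-preserving under symmetric blur (see
    :func:`_half_level_threshold`); ``flux`` places the threshold at the
    intensity rank matching the photometric volume estimate (see
    :func:`_flux_voxel_count`); ``manual`` uses ``manual_t`` directly.
    Foreground is ``volume >= t`` and the threshold actually used is recorded
    on the mask.
    """
    volume = np.asarray(volume, dtype=float)
    if method == "manual":
        if manual_t is None:
            raise ConfigError("manual thresholding requires manual_t")
        t = float(manual_t)
    elif method in ("otsu", "half_level", "flux"):
        if manual_t is not None:
            raise ConfigError(f"manual_t given but method is {method!r}")
        if method == "otsu":
            t = _otsu_threshold(volume)
        elif method == "half_level":
            t = _half_level_threshold(volume)
        else:
            k = int(round(_flux_voxel_count(volume)))
            if k == 0:
                t = float(volume.max()) + 1.0  # no detectable foreground
            else:
                t = _rank_threshold(volume, k)
    else:
        raise ConfigError(f"unknown threshold method {method!r}")
    return ComponentMask(component, volume >= t, threshold_used=t, method=method)


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def clean_mask(
    mask: ComponentMask, min_object_voxels: int = 0, fill_holes: bool = False
) -> ComponentMask:
    """Remove 26-connected objects smaller than ``min_object_voxels`` and
    optionally fill fully enclosed 3D cavities."""
    if min_object_voxels < 0:
        raise ConfigError("min_object_voxels must be >= 0")
    occ = mask.occupancy
    if min_object_voxels > 0:
        labels, n = ndimage.label(occ, structure=_CONN26)
        if n:
            sizes = np.bincount(labels.ravel())
            keep = sizes >= min_object_voxels
            keep[0] = False
            occ = keep[labels]
    if fill_holes:
        occ = ndimage.binary_fill_holes(occ)
    return ComponentMask(mask.component, occ, mask.threshold_used, mask.method)


def crosstalk_check(
    channel_map: ChannelMap, overlap_margin_nm: float = 10.0
) -> list[tuple[tuple[str, str], tuple[float, float]]]:
    """Flag fluorophore pairs whose emission bands overlap.

    Each fluorophore's emission band is the [min, max] of its listed emission
    maxima, dilated by ``overlap_margin_nm`` on both sides; every unordered
    pair whose dilated bands intersect is returned with the overlapping
    wavelength interval. An empty list means the scheme is spectrally
    separable at that margin. The result is symmetric and invariant to entry
    order (pairs sorted alphabetically).
    """
    if overlap_margin_nm < 0:
        raise ConfigError("overlap_margin_nm must be >= 0")
    bands = {}
    for e in channel_map:
        lo, hi = e.emission_band
        bands[e.fluorophore] = (lo - overlap_margin_nm, hi + overlap_margin_nm)
    flagged = []
    for a, b in combinations(sorted(bands), 2):
        lo = max(bands[a][0], bands[b][0])
        hi = min(bands[a][1], bands[b][1])
        if lo <= hi:
            flagged.append(((a, b), (lo, hi)))
    return flagged


def assign_components(
    stack: ImageStack,
    channel_map: ChannelMap,
    thresholds: Mapping[str, Mapping] | None = None,
) -> list[ComponentMask]:
    """Segment every mapped channel and resolve multi-positive voxels.

    Channels are matched to map entries by label (component name or
    fluorophore name). EPS components (protein, polysaccharide, nucleic acid,
    lipid) compete for voxels so each voxel belongs to at most one of them;
    bacterial masks are never competed against EPS masks, and the
    dead-bacteria (PI) mask is intersected with the all-bacteria mask when
    both are present, since PI marks a subpopulation of all cells.

    With the default ``flux`` method the EPS competition is
    volume-calibrated: every voxel is provisionally labelled with the EPS
    channel of highest per-channel z-score, then each component keeps its
    brightest voxels up to its photometric volume estimate
    (:func:`_flux_voxel_count`). This decouples the measured volume from the
    exact boundary placement, which thresholding gets wrong under blur.
    With explicit per-component overrides (``thresholds={"protein":
    {"method": "manual", "manual_t": 40}}``) each channel is thresholded
    independently and multi-positive voxels go to the channel with the
    higher z-score.
    """
    thresholds = thresholds or {}
    channels: dict[Component, np.ndarray] = {}
    for entry in channel_map:
        comp = entry.component
        label = None
        for cand in (comp.value, entry.fluorophore):
            if cand in stack.channel_labels:
                label = cand
                break
        if label is None:
            raise ConfigError(
                f"no stack channel for component {comp.value!r} "
                f"(fluorophore {entry.fluorophore!r}); labels are {stack.channel_labels}"
            )
        channels[comp] = np.asarray(stack.channel(label), dtype=float)

    def cfg_for(comp: Component) -> dict:
        return dict(thresholds.get(comp.value, thresholds.get(comp, {})))

    def single_channel(comp: Component) -> ComponentMask:
        cfg = cfg_for(comp)
        method = cfg.get("method", "flux")
        vol = channels[comp]
        try:
            return threshold_segment(
                vol, method=method, manual_t=cfg.get("manual_t"), component=comp
            )
        except DegenerateHistogramError:
            # a constant (e.g. all-zero) channel carries no signal
            log.warning("channel for %s is constant; mask left empty", comp.value)
            return ComponentMask(
                comp, np.zeros(vol.shape, dtype=bool), threshold_used=None, method=method
            )

    raw_masks: dict[Component, ComponentMask] = {}
    eps_present = [c for c in EPS_COMPONENTS if c in channels]
    eps_flux = [c for c in eps_present if cfg_for(c).get("method", "flux") == "flux"]

    if len(eps_present) > 1 and eps_flux == eps_present:
        # volume-calibrated competition: winner-takes-voxel by z-score, then
        # per-component rank threshold at the photometric volume
        zscores = np.stack([_zscore(channels[c]) for c in eps_present])
        winner = np.argmax(zscores, axis=0)
        for i, comp in enumerate(eps_present):
            vol = channels[comp]
            try:
                k = int(round(_flux_voxel_count(vol)))
            except DegenerateHistogramError:
                log.warning("channel for %s is constant; mask left empty", comp.value)
                raw_masks[comp] = ComponentMask(
                    comp, np.zeros(vol.shape, dtype=bool), None, "flux"
                )
                continue
            won = winner == i
            if k == 0 or not won.any():
                occ = np.zeros(vol.shape, dtype=bool)
                t = None
            else:
                t = _rank_threshold(vol[won], min(k, int(won.sum())))
                occ = won & (vol >= t)
            raw_masks[comp] = ComponentMask(comp, occ, t, "flux")
    else:
        for comp in eps_present:
            raw_masks[comp] = single_channel(comp)
        if len(eps_present) > 1:
            # z-score competition on multi-positive voxels
            zscores = np.stack([_zscore(channels[c]) for c in eps_present])
            positive = np.stack([raw_masks[c].occupancy for c in eps_present])
            winner = np.argmax(np.where(positive, zscores, -np.inf), axis=0)
            any_pos = positive.any(axis=0)
            for i, comp in enumerate(eps_present):
                occ = any_pos & (winner == i)
                m = raw_masks[comp]
                raw_masks[comp] = ComponentMask(comp, occ, m.threshold_used, m.method)

    for comp in BACTERIA_COMPONENTS:
        if comp in channels:
            raw_masks[comp] = single_channel(comp)

    if Component.dead_bacteria in raw_masks and Component.all_bacteria in raw_masks:
        dead = raw_masks[Component.dead_bacteria]
        alive = raw_masks[Component.all_bacteria].occupancy
        pi_only = int((dead.occupancy & ~alive).sum())
        if pi_only:
            log.info("%d PI-positive voxels outside the all-bacteria mask were dropped", pi_only)
        raw_masks[Component.dead_bacteria] = ComponentMask(
            Component.dead_bacteria, dead.occupancy & alive, dead.threshold_used, dead.method
        )

    return [raw_masks[e.component] for e in channel_map]


def _zscore(volume: np.ndarray) -> np.ndarray:
    sd = volume.std()
    return (volume - volume.mean()) / (sd if sd > 0 else 1.0)


def kmeans_layers(profile, k: int, seed: int = 0, n_restarts: int = 10) -> LayerClustering:
    """Cluster depth bins by their composition vectors with seeded k-means.

    The feature of each non-empty depth bin is its per-component proportion
    vector; empty bins are excluded. Deterministic for a fixed seed.
    """
    proportions = np.asarray(profile.proportions, dtype=float)
    totals = np.asarray(profile.counts).sum(axis=1)
    nonempty = np.flatnonzero(totals > 0)
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > nonempty.size:
        raise ConfigError(f"k={k} exceeds the {nonempty.size} non-empty depth bins")
    X = proportions[nonempty]
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_restarts).fit(X)
    return LayerClustering(
        k=k,
        labels=km.labels_,
        centers=km.cluster_centers_,
        bin_indices=nonempty,
        inertia=float(km.inertia_),
    )
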