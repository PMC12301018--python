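"""Three-dimensional excitation-emission matrix (3D-EEM) analysis.

An EEM records fluorescence intensity over an excitation grid (200-400 nm,
5 nm step) by emission grid (220-500 nm, 5 nm step). After Rayleigh-scatter
masking, local intensity maxima are detected and classified into the two
protein-like regions: Peak A (Ex 275-280 / Em 325-350 nm, tryptophan-like)
and Peak B (Ex 225 / Em 300 nm, tyrosine-like). Peak B is published as a
point coordinate; a +/- one-grid-step (5 nm) window is applied around it.
Intensities are instrument-relative, so only ratio comparisons between
conditions are meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, FormatError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "EEM_EX_GRID",
    "EEM_EM_GRID",
    "EEMMatrix",
    "EEMPeak",
    "PEAK_A_WINDOW",
    "PEAK_B_CENTER",
    "read_eem",
    "write_eem",
    "mask_scatter",
    "detect_peaks",
    "classify_peaks",
    "compare_eems",
]

#: Instrument acquisition grids (nm).
EEM_EX_GRID = np.arange(200, 401, 5, dtype=float)
EEM_EM_GRID = np.arange(220, 501, 5, dtype=float)

#: Protein-like peak windows, (ex_lo, ex_hi, em_lo, em_hi) in nm.
PEAK_A_WINDOW = (275.0, 280.0, 325.0, 350.0)
PEAK_B_CENTER = (225.0, 300.0)


@dataclass
class EEMMatrix:
    """Fluorescence intensity on a regular excitation x emission grid."""

    ex_nm: np.ndarray
    em_nm: np.ndarray
    intensity: np.ndarray  # shape (len(ex), len(em)), non-negative
    label: str = ""

    def __post_init__(self) -> None:
        self.ex_nm = np.asarray(self.ex_nm, dtype=float)
        self.em_nm = np.asarray(self.em_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        for name, grid in (("excitation", self.ex_nm), ("emission", self.em_nm)):
            steps = np.diff(grid)
            if grid.size < 2 or np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise FormatError(f"{name} grid must be strictly increasing with constant step")
        if self.intensity.shape != (self.ex_nm.size, self.em_nm.size):
            raise FormatError(
                f"intensity shape {self.intensity.shape} does not match grid "
                f"({self.ex_nm.size}, {self.em_nm.size})"
            )
        if np.any(self.intensity < 0):
            raise ValidationError("intensity must be non-negative (clip on read)")

    def same_grid(self, other: "EEMMatrix") -> bool:
        return (
            self.ex_nm.size == other.ex_nm.size
            and self.em_nm.size == other.em_nm.size
            and np.allclose(self.ex_nm, other.ex_nm)
            and np.allclose(self.em_nm, other.em_nm)
        )


@dataclass
class EEMPeak:
    """A detected fluorescence peak and its protein-like region label."""

    ex_nm: float
    em_nm: float
    intensity: float
    region: str = "other"  # "A", "B" or "other"

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValidationError("peak intensity must be >= 0")


def read_eem(path: str | Path, label: str = "") -> EEMMatrix:
    """Read an EEM from delimited text.

    Layout: header row of emission wavelengths, first column of excitation
    wavelengths, intensities in the body. Separator is sniffed (comma or
    tab). Negative intensities (instrument baseline artifacts) are clipped to
    zero with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        ex = df.index.to_numpy(dtype=float)
        em = np.asarray([float(c) for c in df.columns])
        intensity = df.to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"could not parse {path} as an EEM grid: {exc}") from exc
    n_neg = int((intensity < 0).sum())
    if n_neg:
        log.warning("%s: clipped %d negative intensities to 0", path.name, n_neg)
        intensity = np.clip(intensity, 0.0, None)
    return EEMMatrix(ex, em, intensity, label=label or path.stem)


def write_eem(eem: EEMMatrix, path: str | Path) -> Path:
    """Write an EEM as CSV with emission header row and excitation index column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(eem.intensity, index=eem.ex_nm, columns=eem.em_nm)
    df.to_csv(path)
    return path


def mask_scatter(
    eem: EEMMatrix, order1_width_nm: float = 15.0, order2_width_nm: float = 15.0
) -> EEMMatrix:
    """Zero first- and second-order Rayleigh scatter bands.

    Cells with |em - ex| <= order1 width or |em - 2*ex| <= order2 width are
    set to zero; widths are half-widths in nm.
    """
    if order1_width_nm < 0 or order2_width_nm < 0:
        raise ConfigError("scatter widths must be >= 0")
    ex = eem.ex_nm[:, None]
    em = eem.em_nm[None, :]
    scatter = (np.abs(em - ex) <= order1_width_nm) | (np.abs(em - 2 * ex) <= order2_width_nm)
    out = eem.intensity.copy()
    out[scatter] = 0.0
    return EEMMatrix(eem.ex_nm, eem.em_nm, out, label=eem.label)


def detect_peaks(eem: EEMMatrix, min_prominence: float = 0.1) -> list[EEMPeak]:
    """Detect local maxima on the EEM grid.

    A peak is a cell that attains the maximum of its 8-neighborhood and whose
    height is at least ``min_prominence`` times the global maximum (heights
    are measured from zero since scatter-masked EEMs have near-zero
    baselines). Peaks are returned sorted by intensity, descending. Positions
    are invariant to uniform intensity scaling.
    """
    if not 0 < min_prominence <= 1:
        raise ConfigError("min_prominence must be in (0, 1]")
    z = eem.intensity
    gmax = z.max()
    if gmax <= 0:
        return []
    local_max = z == ndimage.maximum_filter(z, size=3, mode="constant", cval=-np.inf)
    candidates = local_max & (z >= min_prominence * gmax)
    # suppress plateau duplicates: keep one cell per connected plateau
    labels, n = ndimage.label(candidates)
    peaks = []
    for idx in ndimage.center_of_mass(candidates, labels, range(1, n + 1)):
        i, j = int(round(idx[0])), int(round(idx[1]))
        peaks.append(EEMPeak(float(eem.ex_nm[i]), float(eem.em_nm[j]), float(z[i, j])))
    peaks.sort(key=lambda p: -p.intensity)
    return peaks


def classify_peaks(
    peaks: Sequence[EEMPeak], peak_b_tol_nm: float = 5.0
) -> list[EEMPeak]:
    """Label peaks by protein-like region.

    Region A: Ex in [275, 280] and Em in [325, 350] nm (tryptophan-like).
    Region B: within ``peak_b_tol_nm`` of (Ex 225, Em 300) nm
    (tyrosine-like); the default tolerance is one grid step. Anything else is
    "other". Pure function of coordinates: idempotent and order-preserving.
    """
    a_ex_lo, a_ex_hi, a_em_lo, a_em_hi = PEAK_A_WINDOW
    b_ex, b_em = PEAK_B_CENTER
    out = []
    for p in peaks:
        if a_ex_lo <= p.ex_nm <= a_ex_hi and a_em_lo <= p.em_nm <= a_em_hi:
            region = "A"
        elif abs(p.ex_nm - b_ex) <= peak_b_tol_nm and abs(p.em_nm - b_em) <= peak_b_tol_nm:
            region = "B"
        else:
            region = "other"
        out.append(EEMPeak(p.ex_nm, p.em_nm, p.intensity, region))
    return out


def _region_peaks(eem: EEMMatrix, min_prominence: float) -> dict[str, EEMPeak]:
    """Strongest classified peak per region for one EEM."""
    peaks = classify_peaks(detect_peaks(eem, min_prominence=min_prominence))
    best: dict[str, EEMPeak] = {}
    for p in peaks:
        if p.region in ("A", "B") and (p.region not in best or p.intensity > best[p.region].intensity):
            best[p.region] = p
    return best


def compare_eems(
    reference: EEMMatrix, test: EEMMatrix, min_prominence: float = 0.1
) -> dict[str, float | None]:
    """Per-region peak intensity ratios test/reference.

    Returns ``{"A": ratio or None, "B": ratio or None}``; a region absent
    from either matrix is reported as None (absent), never as zero. Ratios
    below 1 mean the test condition's peak is dimmer than the reference's.
    """
    if not reference.same_grid(test):
        raise ValidationError("reference and test EEMs are on different grids")
    ref = _region_peaks(reference, min_prominence)
    tst = _region_peaks(test, min_prominence)
    ratios: dict[str, float | None] = {}
    for region in ("A", "B"):
        if region in ref and region in tst and ref[region].intensity > 0:
            ratios[region] = tst[region].intensity / ref[region].intensity
        else:
            ratios[region] = None
    return ratios
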