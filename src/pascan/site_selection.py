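"""Probe-site selection from position-scan images.

Detects the bright secretion blobs that eccrine pores leave along the
friction-ridge tops, picks the two probing sites used for glucose
calibration — the darkest valley point (non-secreting) and the brightest
blob point (secreting) — and identifies the blob analyte by comparing the
bright-minus-dark difference spectrum against a component library.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure

from .acquisition import InstrumentConfig, PAImage, Spectrum, acquire_spectrum
from .synthetic_skin import ComponentSpectrum, SkinMap, WavenumberGrid

__all__ = [
    "BlobMap",
    "BlobSummary",
    "SiteSelection",
    "AnalyteMatch",
    "SecretionSeries",
    "segment_blobs",
    "select_probe_sites",
    "difference_spectrum",
    "match_analyte",
    "monitor_secretion",
]


@dataclass(frozen=True)
class BlobSummary:
    label: int
    centroid_px: tuple[float, float]   # (row, col)
    centroid_um: tuple[float, float]   # (x, y)
    area_px: int
    mean_intensity: float


@dataclass(frozen=True)
class BlobMap:
    """Labeled secretion blobs of one image."""

    labels: np.ndarray            # (n, n) ints, 0 = background
    threshold: float
    summaries: tuple[BlobSummary, ...]

    @property
    def n_blobs(self) -> int:
        return len(self.summaries)


@dataclass(frozen=True)
class SiteSelection:
    dark_px: tuple[int, int]           # (row, col)
    dark_um: tuple[float, float]       # (x, y)
    bright_px: tuple[int, int]
    bright_um: tuple[float, float]
    degenerate: bool
    blobs: BlobMap

    def to_dict(self) -> dict:
        return {
            "dark_px": list(self.dark_px),
            "dark_um": list(self.dark_um),
            "bright_px": list(self.bright_px),
            "bright_um": list(self.bright_um),
            "degenerate": self.degenerate,
            "blob_table": [
                {
                    "label": b.label,
                    "centroid_px": list(b.centroid_px),
                    "centroid_um": list(b.centroid_um),
                    "area_px": b.area_px,
                    "mean_intensity": b.mean_intensity,
                }
                for b in self.blobs.summaries
            ],
        }


@dataclass(frozen=True)
class AnalyteMatch:
    scores: dict[str, float]
    best: str | None


def segment_blobs(image: PAImage, k_mad: float = 3.0, min_area: int = 2) -> BlobMap:
    """Threshold-and-label blob segmentation.

    Foreground pixels exceed ``median + k_mad * MAD`` (MAD = median absolute
    deviation, robust against the ridge background); 8-connected components
    with at least ``min_area`` pixels count as blobs.  A constant image
    yields zero blobs.
    """
    values = np.asarray(image.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("image contains non-finite values")
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    threshold = med + k_mad * mad
    foreground = values > threshold
    labels = measure.label(foreground, connectivity=2)
    summaries: list[BlobSummary] = []
    keep = np.zeros_like(labels)
    next_label = 0
    for region in measure.regionprops(labels, intensity_image=values):
        if region.area < min_area:
            continue
        next_label += 1
        keep[labels == region.label] = next_label
        r, c = region.centroid
        summaries.append(
            BlobSummary(
                label=next_label,
                centroid_px=(float(r), float(c)),
                centroid_um=(
                    image.origin[0] + image.pixel_pitch * (c + 0.5),
                    image.origin[1] + image.pixel_pitch * (r + 0.5),
                ),
                area_px=int(region.area),
                mean_intensity=float(region.intensity_mean),
            )
        )
    return BlobMap(labels=keep, threshold=threshold, summaries=tuple(summaries))


def select_probe_sites(image: PAImage, blobs: BlobMap, d_min: float = 2.0) -> SiteSelection:
    """Pick the secreting (brightest blob) and non-secreting (darkest) sites.

    The bright site is the maximum pixel inside any blob (whole-image
    maximum when no blob was found).  The dark site is the minimum pixel at
    least ``d_min`` pixels from every blob pixel; if no pixel satisfies the
    exclusion the caller is told to rescan.  Ties break in row-major order;
    an all-equal image returns the first pixel for both and is flagged
    degenerate.
    """
    values = np.asarray(image.values, dtype=float)
    degenerate = bool(values.max() == values.min())
    if blobs.n_blobs > 0:
        masked = np.where(blobs.labels > 0, values, -np.inf)
        bright_flat = int(np.argmax(masked))
    else:
        bright_flat = int(np.argmax(values))
    bright_px = np.unravel_index(bright_flat, values.shape)
    if blobs.n_blobs > 0:
        distance = ndimage.distance_transform_edt(blobs.labels == 0)
        eligible = distance >= d_min
    else:
        eligible = np.ones_like(values, dtype=bool)
    if not eligible.any():
        raise ValueError(
            "no pixel lies far enough from the secretion blobs; rescan a cleaner region"
        )
    dark_flat = int(np.argmin(np.where(eligible, values, np.inf)))
    dark_px = np.unravel_index(dark_flat, values.shape)

    def to_um(px):
        return (
            image.origin[0] + image.pixel_pitch * (px[1] + 0.5),
            image.origin[1] + image.pixel_pitch * (px[0] + 0.5),
        )

    return SiteSelection(
        dark_px=(int(dark_px[0]), int(dark_px[1])),
        dark_um=to_um(dark_px),
        bright_px=(int(bright_px[0]), int(bright_px[1])),
        bright_um=to_um(bright_px),
        degenerate=degenerate,
        blobs=blobs,
    )


def difference_spectrum(bright: Spectrum, dark: Spectrum) -> Spectrum:
    """Pointwise bright minus dark; grids and normalization states must match."""
    if bright.grid != dark.grid:
        raise ValueError("difference requires spectra on the same wavenumber grid")
    if bright.normalized != dark.normalized:
        raise ValueError("difference requires the same normalization state")
    return replace(bright, values=bright.values - dark.values)


def match_analyte(diff: Spectrum, library: list[ComponentSpectrum]) -> AnalyteMatch:
    """Score a difference spectrum against a component library.

    Score = Pearson correlation of the mean-centered spectra; the best
    match is the argmax.  A zero-variance difference spectrum has undefined
    scores and is reported as no-match.
    """
    if not library:
        raise ValueError("component library must not be empty")
    d = np.asarray(diff.values, dtype=float)
    dc = d - d.mean()
    norm_d = np.linalg.norm(dc)
    scores: dict[str, float] = {}
    if norm_d == 0:
        for comp in library:
            scores[comp.analyte] = float("nan")
        return AnalyteMatch(scores=scores, best=None)
    for comp in library:
        if len(comp.grid) != d.size:
            raise ValueError("library spectra must share the difference spectrum's grid")
        c = comp.values - comp.values.mean()
        norm_c = np.linalg.norm(c)
        scores[comp.analyte] = float(dc @ c / (norm_d * norm_c)) if norm_c > 0 else 0.0
    best = max(scores, key=scores.get)
    return AnalyteMatch(scores=scores, best=best)


@dataclass(frozen=True)
class SecretionSeries:
    """Signal time series at the secretion marker wavenumbers."""

    times: np.ndarray
    channels: dict[float, np.ndarray]   # actual grid wavenumber -> values


def monitor_secretion(
    skin: SkinMap,
    site: tuple[float, float],
    times,
    grid: WavenumberGrid,
    config: InstrumentConfig = InstrumentConfig(),
    seed=None,
    marker_wavenumbers: tuple[float, float] = (1070.0, 1140.0),
) -> SecretionSeries:
    """Track the 1070/1140 cm^-1 secretion markers over time at one site.

    Acquires a spectrum at each requested time and keeps the grid points
    nearest the marker wavenumbers.  Times must be sorted ascending from 0.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be sorted strictly ascending and start at >= 0")
    idx = {float(grid.points[grid.nearest_index(nu)]): grid.nearest_index(nu)
           for nu in marker_wavenumbers}
    seeds = np.random.SeedSequence(seed).spawn(times.size)
    series = {nu: np.empty(times.size) for nu in idx}
    for k, t in enumerate(times):
        spec = acquire_spectrum(skin, site, float(t), grid, config, seed=seeds[k])
        for nu, i in idx.items():
            series[nu][k] = spec.values[i]
    return SecretionSeries(times=times, channels=series)
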