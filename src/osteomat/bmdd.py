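"""Bone mineralization density distribution (BMDD).

The BMDD is the frequency histogram of local calcium concentrations over the
mineralized bone area of a calibrated qBEI image, expressed in percent of
mineralized bone area per calcium bin and computed separately for the
cancellous and cortical compartments.  Five scalar parameters summarize it:

- ``CaMean``  — frequency-weighted mean calcium content (wt% Ca);
- ``CaPeak``  — most frequent calcium content, the mode of the curve;
- ``CaWidth`` — full width at half maximum, a heterogeneity measure;
- ``CaLow``   — % of bone area below the 5th percentile of a reference
  population's pooled BMDD;
- ``CaHigh``  — % of bone area above the reference 95th percentile.

The reference cutoffs come from pooling per-subject curves of a healthy
cohort with equal subject weights (each subject is one statistical unit) and
interpolating the pooled cumulative distribution linearly within bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CaImage
from .errors import EmptyCompartmentError, GridMismatchError

#: Default histogram resolution, wt% Ca per bin, over [0, 45] wt%.
DEFAULT_BIN_WIDTH = 0.17
DEFAULT_CA_MAX = 45.0


@dataclass
class BMDDCurve:
    """Calcium-concentration histogram in % of mineralized bone area."""

    bin_edges: np.ndarray
    frequency: np.ndarray  # percent per bin, sums to 100
    compartment: int | None = None
    n_pixels: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.frequency = np.asarray(self.frequency, dtype=float)
        if self.bin_edges.size != self.frequency.size + 1:
            raise ValueError("bin_edges must have one more element than frequency")
        if np.any(self.frequency < -1e-12):
            raise ValueError("frequencies must be non-negative")
        total = self.frequency.sum()
        if total > 0 and abs(total - 100.0) > 1e-6:
            raise ValueError(f"frequencies must sum to 100%, got {total}")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def cdf_at(self, ca: float) -> float:
        """Cumulative % of bone area below ``ca``, linear within bins."""
        edges, freq = self.bin_edges, self.frequency
        if ca <= edges[0]:
            return 0.0
        if ca >= edges[-1]:
            return float(freq.sum())
        k = int(np.searchsorted(edges, ca, side="right") - 1)
        frac = (ca - edges[k]) / (edges[k + 1] - edges[k])
        return float(freq[:k].sum() + frac * freq[k])

    def quantile(self, q_percent: float) -> float:
        """Calcium value below which ``q_percent`` % of bone area lies."""
        cum = np.concatenate([[0.0], np.cumsum(self.frequency)])
        k = int(np.searchsorted(cum, q_percent, side="left"))
        k = min(max(k, 1), len(self.frequency))
        below = cum[k - 1]
        width = self.frequency[k - 1]
        frac = 0.0 if width <= 0 else (q_percent - below) / width
        return float(self.bin_edges[k - 1] + frac * self.bin_width)


@dataclass
class BMDDParams:
    """The five BMDD summary parameters."""

    ca_mean: float    # wt% Ca
    ca_peak: float    # wt% Ca
    ca_width: float   # wt% Ca (FWHM)
    ca_low: float     # % bone area
    ca_high: float    # % bone area


@dataclass
class ReferenceCutoffs:
    """Percentile cutoffs (and pooled curve) of a healthy reference cohort."""

    ca_p5: float
    ca_p95: float
    pooled: BMDDCurve

    def __post_init__(self) -> None:
        if not self.ca_p5 < self.ca_p95:
            raise ValueError("ca_p5 must be below ca_p95")


def compute_bmdd(
    ca_image: CaImage,
    compartment: int | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    ca_max: float = DEFAULT_CA_MAX,
) -> BMDDCurve:
    """Histogram the mineralized pixels of one compartment.

    Only pixels at or above the image's mineralization threshold enter the
    histogram; the result is normalized to 100% of mineralized bone area.

    Raises
    ------
    EmptyCompartmentError
        If the compartment contains no mineralized pixel.
    """
    values = ca_image.ca[ca_image.mineralized_mask(compartment)]
    if values.size == 0:
        raise EmptyCompartmentError(
            f"no mineralized pixels in compartment {compartment!r}")
    n_bins = int(np.ceil(ca_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(np.clip(values, 0, edges[-1] - 1e-9), bins=edges)
    freq = 100.0 * counts / counts.sum()
    return BMDDCurve(bin_edges=edges, frequency=freq,
                     compartment=compartment, n_pixels=int(values.size))


def derive_params(curve: BMDDCurve, cutoffs: ReferenceCutoffs) -> BMDDParams:
    """Extract the five BMDD parameters from a curve.

    ``CaPeak`` ties break toward the lowest-calcium bin.  ``CaWidth`` is the
    distance between the outermost half-maximum crossings of the (possibly
    multimodal) curve, with linear interpolation between bin centers; if the
    half level is not crossed inside the support, the support edge is used.
    ``CaLow``/``CaHigh`` interpolate linearly within the bin containing the
    cutoff, matching the reference-percentile construction.
    """
    freq = curve.frequency
    centers = curve.bin_centers
    ca_mean = float(np.sum(freq * centers) / freq.sum())
    peak_idx = int(np.argmax(freq))  # argmax returns the first (lowest-Ca) tie
    ca_peak = float(centers[peak_idx])

    half = freq[peak_idx] / 2.0
    above = freq >= half
    idx = np.nonzero(above)[0]
    left_i, right_i = idx[0], idx[-1]
    # linear interpolation of the crossing between adjacent bin centers;
    # fall back to the bin edge when the curve starts/ends above half level
    if left_i == 0:
        left = curve.bin_edges[0]
    else:
        f0, f1 = freq[left_i - 1], freq[left_i]
        left = centers[left_i - 1] + (half - f0) / (f1 - f0) * curve.bin_width
    if right_i == len(freq) - 1:
        right = curve.bin_edges[-1]
    else:
        f0, f1 = freq[right_i], freq[right_i + 1]
        right = centers[right_i] + (f0 - half) / (f0 - f1) * curve.bin_width
    ca_width = float(right - left)

    ca_low = curve.cdf_at(cutoffs.ca_p5)
    ca_high = float(freq.sum() - curve.cdf_at(cutoffs.ca_p95))
    return BMDDParams(ca_mean=ca_mean, ca_peak=ca_peak, ca_width=ca_width,
                      ca_low=ca_low, ca_high=ca_high)


def pool_reference(curves: list[BMDDCurve]) -> ReferenceCutoffs:
    """Pool per-subject reference curves and derive percentile cutoffs.

    Subjects are weighted equally (not by pixel count): the pooled frequency
    vector is the unweighted mean of the per-subject vectors, renormalized to
    100%.  The 5th/95th percentiles are read off the pooled cumulative
    distribution with linear interpolation within bins.

    Raises
    ------
    GridMismatchError
        If the curves do not share an identical bin grid.
    """
    if len(curves) < 2:
        raise GridMismatchError("need at least two curves to pool a reference")
    edges = curves[0].bin_edges
    for c in curves[1:]:
        if c.bin_edges.shape != edges.shape or not np.allclose(c.bin_edges, edges):
            raise GridMismatchError("curves have different bin grids")
    mean_freq = np.mean([c.frequency for c in curves], axis=0)
    mean_freq = 100.0 * mean_freq / mean_freq.sum()
    pooled = BMDDCurve(bin_edges=edges, frequency=mean_freq,
                       n_pixels=int(sum(c.n_pixels for c in curves)))
    return ReferenceCutoffs(ca_p5=pooled.quantile(5.0),
                            ca_p95=pooled.quantile(95.0), pooled=pooled)


# ---------------------------------------------------------------------- I/O

def save_curve_csv(curve: BMDDCurve, path) -> None:
    """Write a curve as a two-column CSV (bin_center, frequency)."""
    import pandas as pd

    pd.DataFrame({"bin_center": curve.bin_centers,
                  "frequency": curve.frequency}).to_csv(path, index=False)


def load_curve_csv(path, compartment: int | None = None) -> BMDDCurve:
    """Read a curve written by :func:`save_curve_csv` (uniform bin grid)."""
    import pandas as pd

    df = pd.read_csv(path)
    centers = df["bin_center"].to_numpy(dtype=float)
    width = float(np.median(np.diff(centers)))
    edges = np.concatenate([centers - width / 2, [centers[-1] + width / 2]])
    freq = df["frequency"].to_numpy(dtype=float)
    return BMDDCurve(bin_edges=edges, frequency=100.0 * freq / freq.sum(),
                     compartment=compartment)


def load_reference_curves(directory) -> list[BMDDCurve]:
    """Read every ``*.csv`` curve in a reference-cohort directory."""
    from pathlib import Path

    paths = sorted(Path(directory).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no curve CSVs in {directory}")
    return [load_curve_csv(p) for p in paths]


def mineralized_area_fraction(ca_image: CaImage, compartment: int | None = None) -> float:
    """Mineralized bone area as % of the in-mask tissue area (md.BV/TV-style).

    Raises
    ------
    EmptyCompartmentError
        If the compartment mask is empty.
    """
    tissue = ca_image.in_compartment(compartment)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise EmptyCompartmentError(f"empty compartment {compartment!r}")
    n_min = int(ca_image.mineralized_mask(compartment).sum())
    return 100.0 * n_min / n_tissue
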