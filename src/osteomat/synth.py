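"""Synthetic phantoms, spectra, and cohorts with known ground truth.

No measured biopsy data ship with this package, so every analysis is
exercised against synthetic inputs whose true parameters are known by
construction:

- **qBEI phantoms** — calibrated grey-level images containing a mineralized
  matrix with per-compartment Gaussian calcium fields, elliptical osteocyte
  lacunae, larger vascular-pore-like voids, and sub-resolution specks,
  rendered through the *inverse* calibration map with 8-bit quantization.
- **Raman spectra** — sums of Gaussian/Lorentzian bands at the canonical
  bone positions (ν₂PO₄ ~430, embedding ~500, ν₁PO₄ ~960, amide III ~1250,
  CH₃/proteoglycan ~1375, amide I ~1660 cm⁻¹) on a polynomial fluorescence
  background plus white noise; the five band-ratio metrics are computed in
  closed form from the band parameters.
- **cohorts** — per-subject parameter draws around group means with a
  configurable between-compartment latent correlation, mimicking the
  patient / reference group structure of transiliac-biopsy studies
  (e.g. groups of n = 5 and n = 16 patients vs. n = 25 reference subjects).

Everything is reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import erf

from .calibration import (CANCELLOUS, CORTICAL, OUTSIDE,
                          DEFAULT_MINERALIZATION_THRESHOLD, CalibrationCurve,
                          GreyImage, fit_calibration)
from .errors import PhantomSpecError
from .raman import BAND_WINDOWS, PYD_POSITION, RamanParams, RamanSpectrum


def default_curve() -> CalibrationCurve:
    """Convenience calibration used throughout the synthetic studies."""
    return fit_calibration(25.0, 225.0)


# --------------------------------------------------------------------------
# qBEI phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipse:
    """An elliptical void, in µm (image coordinates: x = column, y = row)."""

    cx: float
    cy: float
    a: float  # major half-axis, µm
    b: float  # minor half-axis, µm
    angle_deg: float = 0.0

    def __post_init__(self):
        if self.a < self.b:
            raise ValueError("require a >= b")

    @property
    def area(self) -> float:
        """Analytic area πab, µm²."""
        return math.pi * self.a * self.b

    @property
    def aspect_ratio(self) -> float:
        return self.a / self.b


@dataclass
class PhantomSpec:
    """Ground-truth description of a synthetic qBEI image.

    ``ca_mean``/``ca_sd`` may be scalars or ``{compartment: value}`` dicts;
    the calcium field is i.i.d. Gaussian per compartment, truncated at the
    mineralization threshold (negligible mass for the defaults, mean 21 and
    sd 1.5 wt%).  ``split`` places a vertical cancellous | cortical boundary
    at that column fraction; ``None`` renders a single cancellous
    compartment.  ``margin`` is an outside-mask border in pixels.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.88          # µm/pixel (1.8 for BMDD-scale images)
    ca_mean: float | dict = 21.0      # wt% Ca
    ca_sd: float | dict = 1.5         # wt% Ca
    lacunae: list[Ellipse] = field(default_factory=list)
    pores: list[Ellipse] = field(default_factory=list)
    specks: list[Ellipse] = field(default_factory=list)
    margin: int = 4                   # px of outside-mask border
    split: float | None = None        # column fraction of the Cn|Ct boundary
    seed: int = 0


@dataclass
class PhantomTruth:
    """Machine-readable ground truth of a rendered phantom."""

    lacunae: list[Ellipse]
    lacuna_areas: np.ndarray          # analytic πab, µm²
    lacuna_aspect_ratios: np.ndarray
    ca_mean: dict                     # per compartment, generating value
    ca_sd: dict
    realized_ca_mean: dict            # pixel mean before quantization
    realized_ca_sd: dict
    mineralized_fraction: dict        # % of in-mask pixels per compartment


def _per_compartment(value, compartments) -> dict:
    if isinstance(value, dict):
        return {c: float(value[c]) for c in compartments}
    return {c: float(value) for c in compartments}


def _rasterize(e: Ellipse, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Center-of-pixel inclusion mask of an ellipse given in µm."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    x = xx * pixel_size - e.cx
    y = yy * pixel_size - e.cy
    t = math.radians(e.angle_deg)
    u = x * math.cos(t) + y * math.sin(t)
    v = -x * math.sin(t) + y * math.cos(t)
    return (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0


def render_phantom(
    spec: PhantomSpec,
    curve: CalibrationCurve | None = None,
    mineralization_threshold: float = DEFAULT_MINERALIZATION_THRESHOLD,
) -> tuple[GreyImage, PhantomTruth]:
    """Render a phantom to an 8-bit grey image via the inverse calibration.

    Raises
    ------
    PhantomSpecError
        If any two void shapes overlap or touch within one pixel (their
        8-connected components would merge and invalidate the ground truth),
        or a shape extends outside the compartment mask.
    """
    curve = curve or default_curve()
    ny, nx = spec.shape
    rng = np.random.default_rng(spec.seed)

    mask = np.full(spec.shape, OUTSIDE, dtype=np.uint8)
    m = spec.margin
    inner = (slice(m, ny - m), slice(m, nx - m))
    if spec.split is None:
        mask[inner] = CANCELLOUS
    else:
        split_col = int(round(nx * spec.split))
        mask[m:ny - m, m:split_col] = CANCELLOUS
        mask[m:ny - m, split_col:nx - m] = CORTICAL
    compartments = sorted(set(np.unique(mask)) - {OUTSIDE})

    means = _per_compartment(spec.ca_mean, compartments)
    sds = _per_compartment(spec.ca_sd, compartments)
    ca = np.zeros(spec.shape, dtype=float)
    for comp in compartments:
        sel = mask == comp
        draw = rng.normal(means[comp], sds[comp], size=int(sel.sum()))
        # truncate into the representable mineralized range
        ca[sel] = np.clip(draw, mineralization_threshold, curve.ca_max)

    occupied = np.zeros(spec.shape, dtype=bool)
    shapes = ([("lacuna", e) for e in spec.lacunae]
              + [("pore", e) for e in spec.pores]
              + [("speck", e) for e in spec.specks])
    grown = np.ones((3, 3), dtype=bool)
    from scipy.ndimage import binary_dilation
    for kind, e in shapes:
        px_mask = _rasterize(e, spec.shape, spec.pixel_size)
        if not px_mask.any():
            continue
        if (binary_dilation(px_mask, grown) & occupied).any():
            raise PhantomSpecError(f"{kind} at ({e.cx:.1f}, {e.cy:.1f}) µm "
                                   "overlaps/touches another void")
        if kind != "pore" and (mask[px_mask] == OUTSIDE).any():
            raise PhantomSpecError(f"{kind} extends outside the mask")
        occupied |= px_mask
        ca[px_mask] = 0.0

    realized_mean, realized_sd, min_frac = {}, {}, {}
    for comp in compartments:
        sel = (mask == comp)
        vals = ca[sel & ~occupied]
        realized_mean[comp] = float(vals.mean())
        realized_sd[comp] = float(vals.std())
        min_frac[comp] = 100.0 * float((ca[sel] >= mineralization_threshold).mean())

    grey = np.clip(np.rint(curve.grey(ca)), 0, 255).astype(np.uint8)
    grey[mask == OUTSIDE] = np.clip(round(curve.grey(0.0)), 0, 255)
    image = GreyImage(pixels=grey, pixel_size=spec.pixel_size, compartment_mask=mask)
    truth = PhantomTruth(
        lacunae=list(spec.lacunae),
        lacuna_areas=np.array([e.area for e in spec.lacunae]),
        lacuna_aspect_ratios=np.array([e.aspect_ratio for e in spec.lacunae]),
        ca_mean=means, ca_sd=sds,
        realized_ca_mean=realized_mean, realized_ca_sd=realized_sd,
        mineralized_fraction=min_frac)
    return image, truth


def scatter_ellipses(
    rng: np.random.Generator,
    n: int,
    region: tuple[float, float, float, float],
    a_range: tuple[float, float],
    aspect_range: tuple[float, float] = (1.0, 2.5),
    min_gap: float = 4.0,
) -> list[Ellipse]:
    """Place ``n`` non-touching random ellipses on a jittered grid.

    ``region`` is (x0, y0, x1, y1) in µm.  Cells are sized to hold the
    largest ellipse plus ``min_gap`` µm of clearance, guaranteeing
    disjointness by construction.

    Raises
    ------
    PhantomSpecError
        If the region cannot hold ``n`` such cells.
    """
    x0, y0, x1, y1 = region
    cell = 2 * a_range[1] + min_gap
    ncols = int((x1 - x0) // cell)
    nrows = int((y1 - y0) // cell)
    if ncols * nrows < n:
        raise PhantomSpecError(
            f"region holds only {ncols * nrows} cells of {cell:.1f} µm, need {n}")
    cells = [(r, c) for r in range(nrows) for c in range(ncols)]
    rng.shuffle(cells)
    out = []
    for r, c in cells[:n]:
        a = rng.uniform(*a_range)
        b = a / rng.uniform(*aspect_range)
        jitter = max(0.0, (cell - 2 * a - min_gap) / 2)
        cx = x0 + c * cell + cell / 2 + rng.uniform(-jitter, jitter)
        cy = y0 + r * cell + cell / 2 + rng.uniform(-jitter, jitter)
        out.append(Ellipse(cx=cx, cy=cy, a=a, b=b,
                           angle_deg=float(rng.uniform(0, 180))))
    return out


def ols_benchmark_spec(seed: int = 0, n_lacunae: int = 40) -> PhantomSpec:
    """Standard OLS filter-fidelity phantom.

    ``n_lacunae`` in-range lacunae (areas ~20–80 µm²) scattered over the left
    part of the field, plus three pores above the 200 µm² size cutoff, five
    sub-5 µm² specks, and one object of axis ratio 12 (caught by the
    aspect-ratio filter): a correct segmentation retains exactly the lacunae.
    """
    rng = np.random.default_rng(seed)
    lacunae = scatter_ellipses(
        rng, n_lacunae, region=(12.0, 12.0, 170.0, 170.0),
        a_range=(3.5, 6.0), aspect_range=(1.0, 2.2))
    pores = [Ellipse(cx=205.0, cy=40.0, a=12.0, b=7.0),     # 264 µm²
             Ellipse(cx=205.0, cy=105.0, a=14.0, b=6.0),    # 264 µm²
             Ellipse(cx=205.0, cy=170.0, a=10.0, b=8.0)]    # 251 µm²
    specks = [Ellipse(cx=232.0, cy=30.0 + 35.0 * k, a=0.9, b=0.5)  # 1.4 µm²
              for k in range(5)]
    elongated = Ellipse(cx=100.0, cy=200.0, a=13.2, b=1.1, angle_deg=25.0)
    return PhantomSpec(shape=(280, 280), pixel_size=0.88,
                       lacunae=lacunae, pores=pores,
                       specks=specks + [elongated], margin=6, seed=seed)


# --------------------------------------------------------------------------
# Raman spectra
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """One spectral band: Gaussian (width = σ) or Lorentzian (width = γ)."""

    shape: str       # "gaussian" | "lorentzian"
    center: float    # cm⁻¹
    width: float
    amplitude: float # peak height

    def evaluate(self, w: np.ndarray) -> np.ndarray:
        d = np.asarray(w, dtype=float) - self.center
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-0.5 * (d / self.width) ** 2)
        if self.shape == "lorentzian":
            return self.amplitude * self.width ** 2 / (d ** 2 + self.width ** 2)
        raise ValueError(f"unknown band shape {self.shape!r}")

    def partial_area(self, lo: float, hi: float) -> float:
        """Closed-form integral over [lo, hi]."""
        if self.shape == "gaussian":
            s = self.width * math.sqrt(2.0)
            return float(self.amplitude * self.width * math.sqrt(math.pi / 2.0)
                         * (erf((hi - self.center) / s) - erf((lo - self.center) / s)))
        return float(self.amplitude * self.width
                     * (math.atan((hi - self.center) / self.width)
                        - math.atan((lo - self.center) / self.width)))


def default_bone_bands(
    mineral_scale: float = 1.0,
    matrix_scale: float = 1.0,
    gag_scale: float = 1.0,
    embedding_scale: float = 1.0,
    crosslink_scale: float = 1.0,
) -> list[Band]:
    """Canonical bone band inventory at the standard band positions.

    The scale factors multiply the amplitudes of the mineral (ν₁/ν₂PO₄),
    organic-matrix (amide III/I), proteoglycan, embedding, and amide-I bands
    respectively, so band-ratio ground truths can be swept.  The default
    amplitudes keep every metric band at a comparable local signal-to-noise
    ratio under peak-relative noise — a deliberate generator design so that
    band-ratio recovery probes the pipeline rather than the photon budget of
    the weakest band; real bone spectra, where the proteoglycan band is much
    weaker than ν₁PO₄, carry proportionally larger GAG uncertainty (see
    docs/methods.md).
    """
    return [
        Band("gaussian", 430.0, 11.0, 0.45 * mineral_scale),    # ν₂PO₄
        Band("gaussian", 501.5, 5.0, 0.30 * embedding_scale),   # embedding resin
        Band("gaussian", 960.0, 7.2, 1.00 * mineral_scale),     # ν₁PO₄
        Band("gaussian", 1255.0, 22.0, 0.55 * matrix_scale),    # amide III
        Band("gaussian", 1376.0, 8.0, 0.35 * gag_scale),        # CH₃/proteoglycan
        Band("gaussian", 1662.0, 18.0, 0.50 * matrix_scale * crosslink_scale),  # amide I
    ]


@dataclass
class SpectrumSpec:
    """Generator parameters of one synthetic Raman spectrum.

    ``background`` holds polynomial coefficients (highest power first)
    evaluated on the normalized coordinate u = (w − 1075)/725, which maps
    the trimmed range onto [−1, 1]; the default emulates a fluorescence
    background that dominates the bands and falls steeply across the
    fingerprint region while staying mildly curved — the regime in which a
    rubber-band correction is meaningful (its residual error grows with the
    background curvature over each hull-anchor gap; see docs/methods.md).
    ``noise_sd`` is the white-noise standard deviation as a fraction of the
    largest band amplitude.
    """

    bands: list[Band] = field(default_factory=default_bone_bands)
    background: tuple[float, ...] = (0.15, -0.55, 0.8)
    noise_sd: float = 0.0
    grid: np.ndarray = field(
        default_factory=lambda: np.arange(340.0, 1810.0 + 0.5, 1.0))
    seed: int = 0


def analytic_params(bands: list[Band], windows: dict = BAND_WINDOWS) -> RamanParams:
    """Closed-form band-ratio metrics of a band model (the recovery oracle).

    Areas are exact partial integrals of all bands over each window.  The
    1660 cm⁻¹ height is the model value; the ν₁PO₄ FWHM is found by bisection
    on the continuous band sum inside 930–980 cm⁻¹, independent of any
    sampling grid or baseline step in the analysis pipeline.
    """
    area = {name: sum(b.partial_area(lo, hi) for b in bands)
            for name, (lo, hi) in windows.items()}
    height_1660 = float(sum(b.evaluate(np.array([PYD_POSITION]))[0] for b in bands))

    lo, hi = windows["nu1_po4"]
    w = np.linspace(lo, hi, 5001)
    y = np.sum([b.evaluate(w) for b in bands], axis=0)
    imax = int(np.argmax(y))
    half = y[imax] / 2.0
    left = np.interp(half, y[:imax + 1], w[:imax + 1])
    right = np.interp(half, y[imax:][::-1], w[imax:][::-1])
    fwhm = float(right - left)

    return RamanParams(
        mineral_matrix=area["nu2_po4"] / area["amide_iii"],
        gag_ratio=area["gag_ch3"] / area["amide_iii"],
        nanoporosity=area["nanopore"] / area["amide_iii"],
        pyd=height_1660 / area["amide_i"],
        mmc=1.0 / fwhm)


def render_spectrum(spec: SpectrumSpec) -> tuple[RamanSpectrum, RamanParams]:
    """Sample a synthetic spectrum and return it with its analytic truth."""
    rng = np.random.default_rng(spec.seed)
    w = np.asarray(spec.grid, dtype=float)
    signal = np.sum([b.evaluate(w) for b in spec.bands], axis=0)
    u = (w - 1075.0) / 725.0
    background = np.polyval(spec.background, u)
    amax = max(b.amplitude for b in spec.bands)
    noise = rng.normal(0.0, spec.noise_sd * amax, size=w.size) if spec.noise_sd else 0.0
    spectrum = RamanSpectrum(wavenumber=w, intensity=signal + background + noise,
                             meta={"seed": spec.seed, "noise_sd": spec.noise_sd})
    return spectrum, analytic_params(spec.bands)


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """One cohort group: name, size, and per-outcome mean shifts."""

    name: str
    n: int
    shifts: dict = field(default_factory=dict)  # outcome -> shift from reference

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("need n >= 3 per group")


@dataclass
class CohortSpec:
    """Cohort simulation parameters.

    ``outcomes`` maps outcome names to (reference mean, between-subject SD).
    ``latent_corr`` couples the cancellous and cortical values of the
    ``ca_mean`` outcome through a shared per-subject latent draw, emulating
    the strong Cn/Ct coupling seen in biopsy cohorts.
    """

    groups: list[GroupSpec] = field(default_factory=lambda: [
        GroupSpec("REF", 25),
        GroupSpec("GROUP-1", 5, {"ca_mean": -1.5}),
        GroupSpec("GROUP-2", 16),
    ])
    outcomes: dict = field(default_factory=lambda: {"ca_mean": (22.0, 0.55)})
    latent_corr: float = 0.9
    seed: int = 0


@dataclass
class SimulatedCohort:
    subjects: pd.DataFrame  # one row per subject, wide outcome columns
    tidy: pd.DataFrame      # (subject, group, compartment, outcome, value)


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Draw per-subject outcome values around the group means.

    The ``ca_mean`` outcome is drawn per compartment from a bivariate normal
    with correlation ``latent_corr``; every other outcome is a single draw
    (no compartment).  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    rows, tidy_rows = [], []
    sid = 0
    for group in spec.groups:
        for _ in range(group.n):
            sid += 1
            subject = f"S{sid:03d}"
            row = {"subject": subject, "group": group.name}
            for name, (ref_mean, sd) in spec.outcomes.items():
                mean = ref_mean + group.shifts.get(name, 0.0)
                if name == "ca_mean":
                    rho = spec.latent_corr
                    cov = sd ** 2 * np.array([[1.0, rho], [rho, 1.0]])
                    cn, ct = rng.multivariate_normal([mean, mean], cov)
                    row["cn_ca_mean"], row["ct_ca_mean"] = cn, ct
                    tidy_rows += [
                        dict(subject=subject, group=group.name,
                             compartment="cancellous", outcome=name, value=cn),
                        dict(subject=subject, group=group.name,
                             compartment="cortical", outcome=name, value=ct)]
                else:
                    value = rng.normal(mean, sd)
                    row[name] = value
                    tidy_rows.append(dict(subject=subject, group=group.name,
                                          compartment="", outcome=name, value=value))
            rows.append(row)
    return SimulatedCohort(subjects=pd.DataFrame(rows), tidy=pd.DataFrame(tidy_rows))


def subject_phantom_spec(
    cn_ca_mean: float,
    ct_ca_mean: float,
    seed: int,
    shape: tuple[int, int] = (160, 160),
    pixel_size: float = 1.8,
    ca_sd: float = 1.5,
) -> PhantomSpec:
    """Two-compartment phantom spec for one simulated subject (no voids)."""
    return PhantomSpec(
        shape=shape, pixel_size=pixel_size,
        ca_mean={CANCELLOUS: cn_ca_mean, CORTICAL: ct_ca_mean},
        ca_sd=ca_sd, split=0.5, margin=4, seed=seed)
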