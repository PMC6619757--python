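"""Zero-charge reconstruction of multiply charged ESI spectra.

The transform is a direct charge summation: for each candidate neutral mass M
on a uniform output grid, the intensities the spectrum holds at
``mz_from_mass(M, z)`` are summed over the searched charge range and
normalized by the number of charges whose m/z falls inside the input window
(which suppresses the M/2 and 2M harmonics that alignment at every other
charge would otherwise produce).  The stick spectrum is first rasterized with
Gaussian peak shapes of FWHM = m/z / resolution, so the summation reads
interpolated intensity, not exact stick positions.  Picked peaks are refined
on a ten-times-finer local grid, bounded by the ``iterations`` setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter
from scipy.signal import find_peaks

from .containers import RawRun, RawSpectrum
from .masschem import PROTON


@dataclass(frozen=True)
class DeconvolutionSettings:
    """Reconstruction parameters (defaults follow a 147 kDa IgG workflow)."""

    mz_start: float = 1000.0
    mz_stop: float = 4000.0
    mass_low: float = 10000.0
    mass_high: float = 200000.0
    step: float = 1.0
    resolution: float = 2500.0
    smooth_points: float = 0.9   # Gaussian sigma in grid steps
    combine: int = 50            # TOF-MS scans to combine
    iterations: int = 20         # apex-refinement budget
    charge_min: int = 5
    charge_max: int = 80

    def __post_init__(self) -> None:
        if self.mz_start >= self.mz_stop:
            raise ValueError("mz_start must be < mz_stop")
        if self.mass_low >= self.mass_high:
            raise ValueError("mass_low must be < mass_high")
        if self.step <= 0:
            raise ValueError("step must be > 0")


@dataclass
class MassPeak:
    """A picked zero-charge mass peak."""

    mass: float
    height: float
    area: float
    snr: float
    relative_abundance: float  # percent of base peak

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be >= 0")
        if not 0.0 < self.relative_abundance <= 100.0 + 1e-9:
            raise ValueError("relative abundance must lie in (0, 100]")


@dataclass
class ReconstructedMassSpectrum:
    """Zero-charge mass axis with reconstructed intensity and provenance."""

    mass: np.ndarray
    intensity: np.ndarray
    settings: DeconvolutionSettings
    scans_combined: int = 1
    _fine_mz: np.ndarray | None = field(default=None, repr=False)
    _fine_intensity: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.mass) > 1:
            steps = np.diff(self.mass)
            if not np.allclose(steps, steps[0]):
                raise ValueError("mass axis must be a uniform grid")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")


def combine_scans(run: RawRun, n: int = 50,
                  rt_window: tuple[float, float] | None = None) -> RawSpectrum:
    """Intensity-sum the n most intense MS1 scans (or all scans in rt_window).

    Sticks are merged on a fixed fine m/z binning (0.02 m/z) with an
    intensity-weighted mean position per bin, so repeated identical scans add
    their intensities without drifting in m/z.
    """
    ms1 = run.ms1()
    if rt_window is not None:
        ms1 = [s for s in ms1 if rt_window[0] <= s.rt <= rt_window[1]]
    if not ms1:
        raise ValueError("run contains no usable MS1 scans")
    ms1 = sorted(ms1, key=lambda s: -s.tic)[:max(1, n)]
    mz = np.concatenate([s.mz for s in ms1])
    inten = np.concatenate([s.intensity for s in ms1])
    if not len(mz):
        return RawSpectrum(0, 1, ms1[0].rt, mz, inten)
    width = 0.02
    keys = np.round(mz / width).astype(np.int64)
    order = np.argsort(keys, kind="stable")
    keys, mz, inten = keys[order], mz[order], inten[order]
    uniq, start = np.unique(keys, return_index=True)
    sums = np.add.reduceat(inten, start)
    wpos = np.add.reduceat(inten * mz, start)
    with np.errstate(invalid="ignore"):
        pos = np.where(sums > 0, wpos / np.maximum(sums, 1e-300), mz[start])
    return RawSpectrum(0, 1, float(np.mean([s.rt for s in ms1])), pos, sums)


def _rasterize(spectrum: RawSpectrum, settings: DeconvolutionSettings
               ) -> tuple[np.ndarray, np.ndarray]:
    """Continuous profile from sticks: Gaussian of FWHM = m/z / resolution each."""
    d = 0.01
    axis = np.arange(settings.mz_start, settings.mz_stop + d, d)
    profile = np.zeros_like(axis)
    sel = (spectrum.mz >= settings.mz_start) & (spectrum.mz <= settings.mz_stop)
    for mz, inten in zip(spectrum.mz[sel], spectrum.intensity[sel]):
        sigma = (mz / settings.resolution) / 2.3548200450309493
        lo = int(max(0, np.floor((mz - 4 * sigma - settings.mz_start) / d)))
        hi = int(min(len(axis) - 1, np.ceil((mz + 4 * sigma - settings.mz_start) / d)))
        if hi <= lo:
            continue
        x = axis[lo:hi + 1]
        profile[lo:hi + 1] += inten * np.exp(-0.5 * ((x - mz) / sigma) ** 2)
    return axis, profile


def _score_masses(masses: np.ndarray, fine_mz: np.ndarray,
                  fine_int: np.ndarray, settings: DeconvolutionSettings
                  ) -> np.ndarray:
    """Charge-summation score with charge-support weighting.

    The plain sum is divided by the number of in-window charges (suppressing
    the M/2 and 2M harmonics) and further weighted by the squared fraction of
    charges that effectively carry the signal (inverse participation ratio of
    the per-charge contributions), which suppresses single-charge coincidence
    artifacts at low trial masses.  The participation ratio is a smooth
    function of the contributions, so relative heights of species sharing one
    charge envelope are preserved.
    """
    score = np.zeros_like(masses, dtype=float)
    sumsq = np.zeros_like(masses, dtype=float)
    n_contrib = np.zeros_like(masses, dtype=float)
    ramp = 25.0  # m/z taper at the window edges: keeps the charge count a
    # smooth function of mass, so normalization steps cannot displace apexes
    for z in range(settings.charge_min, settings.charge_max + 1):
        mz = (masses + z * PROTON) / z
        edge = (np.clip((mz - settings.mz_start) / ramp, 0.0, 1.0)
                * np.clip((settings.mz_stop - mz) / ramp, 0.0, 1.0))
        if not edge.any():
            continue
        c = edge * np.interp(mz, fine_mz, fine_int, left=0.0, right=0.0)
        score += c
        sumsq += c * c
        n_contrib += edge
    n_contrib = np.maximum(n_contrib, 1.0)
    eff_n = np.where(sumsq > 0, score * score / np.maximum(sumsq, 1e-300), 0.0)
    support = eff_n / n_contrib
    return score / n_contrib * support ** 2


def reconstruct(spectrum: RawSpectrum,
                settings: DeconvolutionSettings = DeconvolutionSettings(),
                scans_combined: int = 1) -> ReconstructedMassSpectrum:
    """Direct charge-summation reconstruction onto a uniform mass grid."""
    fine_mz, fine_int = _rasterize(spectrum, settings)
    masses = np.arange(settings.mass_low, settings.mass_high + settings.step,
                       settings.step)
    if fine_int.max(initial=0.0) <= 0.0:
        intensity = np.zeros_like(masses)
    else:
        intensity = _score_masses(masses, fine_mz, fine_int, settings)
        if settings.smooth_points > 0:
            intensity = gaussian_filter1d(intensity, settings.smooth_points)
    return ReconstructedMassSpectrum(masses, intensity, settings,
                                     scans_combined, fine_mz, fine_int)


def reconstruct_run(run: RawRun,
                    settings: DeconvolutionSettings = DeconvolutionSettings()
                    ) -> ReconstructedMassSpectrum:
    """combine_scans + reconstruct in one call."""
    combined = combine_scans(run, settings.combine)
    return reconstruct(combined, settings, scans_combined=settings.combine)


def _refine_apex(recon: ReconstructedMassSpectrum, index: int) -> float:
    """Refine a grid apex on a step/10 local grid (bounded by ``iterations``)."""
    if recon._fine_mz is None:
        return float(recon.mass[index])
    settings = recon.settings
    m0 = recon.mass[index]
    span = settings.step
    for _ in range(max(1, min(settings.iterations, 3))):
        local = np.arange(m0 - span, m0 + span + settings.step / 10,
                          settings.step / 10)
        scores = _score_masses(local, recon._fine_mz, recon._fine_intensity,
                               settings)
        m0 = float(local[int(np.argmin(-scores))])  # ties toward lower mass
        span /= 4.0
    return m0


def baseline_residual(recon: ReconstructedMassSpectrum,
                      window: int = 1001) -> np.ndarray:
    """Trace minus its rolling-median baseline (unclipped).

    Charge summation leaves a smooth coincidence pedestal under the whole
    mass axis; removing it before noise estimation and peak picking keeps
    the signal-to-noise scale meaningful for minor species.
    """
    y = recon.intensity
    if len(y) < window:
        return y - np.median(y)
    return y - median_filter(y, size=window, mode="nearest")


def noise_floor(recon: ReconstructedMassSpectrum,
                residual: np.ndarray | None = None) -> float:
    """Robust noise estimate: 1.4826 x median absolute deviation of the
    baseline-corrected trace."""
    r = baseline_residual(recon) if residual is None else residual
    med = np.median(r)
    mad = np.median(np.abs(r - med))
    floor = 1.4826 * mad
    if floor <= 0:
        floor = max(1e-12, 1e-9 * r.max(initial=0.0))
    return float(floor)


def _drop_harmonics(peaks: list[MassPeak], step: float) -> list[MassPeak]:
    """Remove integer-submultiple artifacts (M/2, M/3, ...).

    Charge summation places an exact replica of a species at M/k (its sticks
    reinterpreted at charge z/k); such a peak is recognisable because a
    substantially tall peak sits at k times its mass.  Genuine co-analysed
    species (light vs heavy chain, glycoform ladders) never sit at integer
    mass ratios, so the filter is safe for this domain.
    """
    keep = []
    for p in peaks:
        harmonic = False
        for q in peaks:
            if q is p:
                continue
            for k in range(2, 11):
                if (abs(q.mass - k * p.mass) <= 2.0 + k * step
                        and q.height > 0.3 * p.height):
                    harmonic = True
                    break
            if harmonic:
                break
        if not harmonic:
            keep.append(p)
    return keep


def pick_mass_peaks(recon: ReconstructedMassSpectrum,
                    sn_min: float = 20.0,
                    rel_min: float = 1.0) -> list[MassPeak]:
    """Local maxima above S/N and relative-abundance thresholds, with areas.

    Peak areas are trapezoids over each peak's support (down to the adjacent
    valleys or the noise floor); apexes are refined off-grid; integer
    submultiple harmonics are removed.  Peaks are returned sorted by mass.
    """
    residual = baseline_residual(recon)
    y = np.clip(residual, 0.0, None)
    if y.max(initial=0.0) <= 0.0:
        return []
    floor = noise_floor(recon, residual)
    base = float(y.max())
    height_min = max(sn_min * floor, rel_min / 100.0 * base)
    idx, _ = find_peaks(y, height=height_min)
    peaks = []
    for p in idx:
        lo = p
        while lo > 0 and y[lo - 1] < y[lo] and y[lo - 1] > floor:
            lo -= 1
        hi = p
        while hi < len(y) - 1 and y[hi + 1] < y[hi] and y[hi + 1] > floor:
            hi += 1
        area = float(np.trapezoid(y[lo:hi + 1], recon.mass[lo:hi + 1]))
        peaks.append(MassPeak(
            mass=_refine_apex(recon, p),
            height=float(y[p]),
            area=area,
            snr=float(y[p] / floor),
            relative_abundance=100.0 * float(y[p]) / base,
        ))
    peaks = _drop_harmonics(peaks, recon.settings.step)
    peaks.sort(key=lambda pk: pk.mass)
    return peaks
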