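"""Released N-glycan identification and quantification.

Compositions are found by exhaustive enumeration over a bounded
monosaccharide lattice at a ppm tolerance (GlycoMod-style), prefiltered by
diagnostic oxonium ions, confirmed by glycosidic B/Y fragment matching, and
quantified by extracted-ion-chromatogram peak areas.  Chromatographic isomer
counting relies on the porous-graphitic-carbon separation the run emulates:
one composition, several retention-separated maxima at a shared m/z.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import masschem
from .containers import RawRun, RawSpectrum
from .masschem import GlycanComposition, PROTON, ppm_error


@dataclass(frozen=True)
class CompositionSearchSettings:
    """Bounds and tolerance for composition enumeration (free reducing glycans)."""

    ppm: float = 10.0
    max_hex: int = 12
    max_hexnac: int = 8
    max_dhex: int = 4
    max_neuac: int = 4
    max_neugc: int = 2

    def __post_init__(self) -> None:
        if self.ppm <= 0:
            raise ValueError("ppm tolerance must be > 0")
        for b in (self.max_hex, self.max_hexnac, self.max_dhex,
                  self.max_neuac, self.max_neugc):
            if b < 0:
                raise ValueError("count bounds must be >= 0")


@dataclass(frozen=True)
class OxoniumMarkers:
    """Diagnostic low-mass glycan fragment ions and the match tolerance."""

    markers: tuple[tuple[str, float], ...] = (
        ("HexNAc+", masschem.OXONIUM_HEXNAC),
        ("Hex-HexNAc+", masschem.OXONIUM_HEXHEXNAC),
        ("NeuAc+", masschem.OXONIUM_NEUAC),
    )
    tol: float = 0.02


def enumerate_compositions(target_mass: float,
                           settings: CompositionSearchSettings = CompositionSearchSettings()
                           ) -> list[tuple[GlycanComposition, float]]:
    """All bounded compositions whose free monoisotopic mass matches the target.

    Returns (composition, ppm error) pairs sorted by |ppm|; exhaustive over
    the full lattice, so an empty list is a definitive negative.
    """
    if target_mass <= 0:
        raise ValueError("target mass must be > 0")
    mono = [masschem.TABLE.sugar_mass(n) for n in
            ("Hex", "HexNAc", "dHex", "NeuAc", "NeuGc")]
    bounds = (settings.max_hex, settings.max_hexnac, settings.max_dhex,
              settings.max_neuac, settings.max_neugc)
    tol = target_mass * settings.ppm * 1e-6
    water = masschem.WATER_MONO
    out = []
    # vectorized scan over the (Hex, HexNAc) plane; the remaining three are tiny
    for f, s, g in itertools.product(range(bounds[2] + 1), range(bounds[3] + 1),
                                     range(bounds[4] + 1)):
        base = water + f * mono[2] + s * mono[3] + g * mono[4]
        if base - tol > target_mass:
            continue
        h = np.arange(bounds[0] + 1)
        n = np.arange(bounds[1] + 1)
        grid = base + h[:, None] * mono[0] + n[None, :] * mono[1]
        hit_h, hit_n = np.nonzero(np.abs(grid - target_mass) <= tol)
        for hh, nn in zip(hit_h, hit_n):
            comp = GlycanComposition(hex=int(h[hh]), hexnac=int(n[nn]),
                                     dhex=f, neuac=s, neugc=g)
            named = _match_short_name(comp)
            out.append((named, ppm_error(target_mass, float(grid[hh, nn]))))
    out.sort(key=lambda t: abs(t[1]))
    return out


def _match_short_name(comp: GlycanComposition) -> GlycanComposition:
    for known in masschem.GLYCANS.values():
        if known.counts == comp.counts:
            return known
    return comp


def oxonium_prefilter(run: RawRun,
                      markers: OxoniumMarkers = OxoniumMarkers()
                      ) -> list[tuple[RawSpectrum, tuple[str, ...]]]:
    """MS2 scans containing at least one oxonium marker, with the labels hit."""
    kept = []
    for scan in run.ms2():
        if not len(scan.mz):
            continue
        hits = tuple(label for label, mz in markers.markers
                     if np.any(np.abs(scan.mz - mz) <= markers.tol))
        if hits:
            kept.append((scan, hits))
    return kept


def fragment_ions(comp: GlycanComposition,
                  charges: tuple[int, ...] = (1, 2)) -> list[tuple[str, float]]:
    """Glycosidic B/Y fragment m/z values of a composition (structure-free).

    B ions are oxonium-type masses of every proper sub-composition; Y ions are
    the free mass minus every proper sub-composition.  Both are emitted for
    the requested charges (2+ only above m/z 500 is not enforced here).
    """
    subs = []
    for h in range(comp.hex + 1):
        for n in range(comp.hexnac + 1):
            for f in range(comp.dhex + 1):
                for s in range(comp.neuac + 1):
                    for g in range(comp.neugc + 1):
                        if (h, n, f, s, g) in ((0, 0, 0, 0, 0), comp.counts):
                            continue
                        subs.append(GlycanComposition(h, n, f, s, g))
    free = comp.free_mass()
    ions = []
    for sub in subs:
        b = sub.residue_mass()
        y = free - sub.residue_mass()
        for z in charges:
            ions.append((f"B:{sub.composition_string()}^{z}", (b + z * PROTON) / z))
            ions.append((f"Y:-{sub.composition_string()}^{z}", (y + z * PROTON) / z))
    return ions


def fragment_match_stats(scan: RawSpectrum, comp: GlycanComposition,
                         tol: float = 0.02,
                         charges: tuple[int, ...] = (1, 2)) -> tuple[int, float]:
    """(matched count, matched fraction) of the composition's distinct B/Y set.

    The fraction discriminates between candidates whose fragment values are
    supersets of each other (e.g. G0 vs G0F): the larger candidate matches
    the same peaks but a smaller share of its own ladder.
    """
    theo = sorted({round(mz, 4) for _, mz in fragment_ions(comp, charges)})
    if not len(scan.mz) or not theo:
        return 0, 0.0
    spec_mz = np.sort(scan.mz)
    count = 0
    for mz in theo:
        idx = np.searchsorted(spec_mz, mz)
        lo = spec_mz[max(idx - 1, 0)]
        hi = spec_mz[min(idx, len(spec_mz) - 1)]
        if min(abs(lo - mz), abs(hi - mz)) <= tol:
            count += 1
    return count, count / len(theo)


def confirm_by_fragments(scan: RawSpectrum, comp: GlycanComposition,
                         tol: float = 0.02,
                         charges: tuple[int, ...] = (1, 2)) -> int:
    """Count distinct B/Y fragments of the composition present in the scan."""
    return fragment_match_stats(scan, comp, tol, charges)[0]


# ------------------------------------------------------------------------ XIC


@dataclass
class Chromatogram:
    """An extracted ion chromatogram with picked elution peaks."""

    times: np.ndarray
    intensity: np.ndarray
    mz: float
    peak_areas: list[float] = field(default_factory=list)
    peak_times: list[float] = field(default_factory=list)

    @property
    def isomer_count(self) -> int:
        return len(self.peak_areas)

    @property
    def total_area(self) -> float:
        return float(sum(self.peak_areas))


def xic(run: RawRun, mz: float, tol_ppm: float = 25.0,
        ms_level: int = 1, min_rel: float = 0.05) -> Chromatogram:
    """XIC at mz +- tol with elution-peak picking.

    Local maxima of the 3-point-smoothed trace at or above ``min_rel`` of the
    XIC base peak are reported as separate chromatographic (isomer) peaks;
    areas are trapezoids over each peak's support (valley to valley).
    """
    half = mz * tol_ppm * 1e-6
    times, values = [], []
    for scan in run.spectra:
        if scan.ms_level != ms_level:
            continue
        sel = np.abs(scan.mz - mz) <= half
        times.append(scan.rt)
        values.append(float(scan.intensity[sel].sum()))
    t = np.asarray(times)
    v = np.asarray(values)
    chrom = Chromatogram(t, v, mz)
    if len(v) < 3 or v.max() <= 0:
        return chrom
    sm = np.convolve(v, np.ones(3) / 3.0, mode="same")
    floor = min_rel * sm.max()
    from scipy.signal import find_peaks
    peaks, _ = find_peaks(sm, height=floor)
    for p in peaks:
        lo = p
        while lo > 0 and sm[lo - 1] < sm[lo] and sm[lo - 1] > 0:
            lo -= 1
        hi = p
        while hi < len(sm) - 1 and sm[hi + 1] < sm[hi] and sm[hi + 1] > 0:
            hi += 1
        if hi > lo:
            chrom.peak_areas.append(float(np.trapezoid(v[lo:hi + 1], t[lo:hi + 1])))
            chrom.peak_times.append(float(t[p]))
    return chrom


# ------------------------------------------------------------- full pipeline


@dataclass
class GlycanAssignment:
    composition: GlycanComposition
    observed_mz: float
    charge: int
    ppm: float
    confirming_fragments: int
    xic_area: float
    isomer_count: int

    def __post_init__(self) -> None:
        if self.isomer_count < 1:
            raise ValueError("reported assignments must have >= 1 isomer peak")


def identify_glycans(run: RawRun,
                     settings: CompositionSearchSettings = CompositionSearchSettings(),
                     markers: OxoniumMarkers = OxoniumMarkers(),
                     min_fragments: int = 2,
                     xic_tol_ppm: float = 25.0) -> list[GlycanAssignment]:
    """End-to-end free-glycan identification on an LC-MS/MS run.

    Oxonium-positive MS2 scans are explained by bounded composition
    enumeration of their precursor neutral mass, confirmed by B/Y fragments,
    deduplicated per (composition, charge), then quantified from MS1 XICs.
    """
    candidates: dict[tuple, GlycanAssignment] = {}
    for scan, _hits in oxonium_prefilter(run, markers):
        if scan.precursor_mz is None or scan.precursor_charge is None:
            continue
        z = scan.precursor_charge
        neutral = masschem.mass_from_mz(scan.precursor_mz, z)
        comps = enumerate_compositions(neutral, settings)
        if not comps:
            continue
        # exactly isobaric compositions exist (e.g. NeuAc+Hex = NeuGc+dHex);
        # fragment confirmation arbitrates among in-tolerance candidates
        comp, ppm, n_frag, best_frac = None, 0.0, -1, -1.0
        for cand, cand_ppm in comps[:8]:
            nf, frac = fragment_match_stats(scan, cand)
            if (frac, -abs(cand_ppm)) > (best_frac, -abs(ppm) if comp else -1e9):
                comp, ppm, n_frag, best_frac = cand, cand_ppm, nf, frac
        if n_frag < min_fragments:
            continue
        key = (comp.counts, z)
        if key in candidates and abs(candidates[key].ppm) <= abs(ppm):
            continue
        chrom = xic(run, scan.precursor_mz, xic_tol_ppm)
        if chrom.isomer_count < 1:
            continue
        candidates[key] = GlycanAssignment(
            comp, scan.precursor_mz, z, ppm, n_frag,
            chrom.total_area, chrom.isomer_count)
    return sorted(candidates.values(), key=lambda a: -a.xic_area)


def relative_glycan_quant(assignments: list[GlycanAssignment]) -> pd.DataFrame:
    """Percent of total XIC area per composition (all charges and isomers)."""
    areas: dict[str, float] = {}
    isomers: dict[str, int] = {}
    for a in assignments:
        label = a.composition.label
        areas[label] = areas.get(label, 0.0) + a.xic_area
        isomers[label] = max(isomers.get(label, 0), a.isomer_count)
    total = sum(areas.values())
    if total <= 0:
        raise ValueError("zero total XIC area; nothing to quantify")
    rows = [{"composition": k, "area": v, "percent": 100.0 * v / total,
             "isomers": isomers[k]}
            for k, v in sorted(areas.items(), key=lambda kv: -kv[1])]
    return pd.DataFrame(rows)
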