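"""Proteoform assignment at the protein level.

Reconstructed masses are matched within a Dalton tolerance (default +-5 Da)
against theoretical species built from chain composition x glycan pair (or
single glycan) x N-terminal pyroglutamate states x formic-acid adducts, on
the average-mass scale.  PNGase differential shifts are matched against
glycan multisets (each released glycan leaves Asn->Asp, +0.98402 per site),
and glycoforms are quantified from reconstructed peak areas.  Ambiguities the
mass scale cannot resolve (e.g. G0F/G2F vs G1F/G1F, which share a composition
mass) are preserved, never silently collapsed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from . import masschem
from .deconvolution import MassPeak
from .masschem import (GlycanComposition, MODIFICATIONS, ModificationSpec,
                       chain_mass, ppm_error)


@dataclass(frozen=True)
class MatchSettings:
    tolerance_da: float = 5.0
    max_adducts: int = 2
    max_pyroglu: int = 2

    def __post_init__(self) -> None:
        if self.tolerance_da <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass(frozen=True)
class ProteoformCandidate:
    """A theoretical chain+glycan+PTM+adduct species (average-mass scale)."""

    composition: str                 # "intact" | "heavy" | "light"
    glycans: tuple[str, ...]         # per-site glycan labels (may be empty)
    pyroglu: int
    adducts: int
    mass: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("theoretical mass must be > 0")

    @property
    def glycoform_label(self) -> str:
        return "/".join(self.glycans) if self.glycans else "aglycosylated"

    @property
    def label(self) -> str:
        out = f"{self.composition} {self.glycoform_label}"
        if self.pyroglu:
            out += f" +{self.pyroglu}pyroGlu"
        if self.adducts:
            out += f" +{self.adducts}HCOOH"
        return out


@dataclass
class ProteoformMatch:
    peak: MassPeak
    candidate: ProteoformCandidate
    error_da: float
    error_ppm: float
    ambiguity_group: list[ProteoformCandidate] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ambiguity_group:
            self.ambiguity_group = [self.candidate]
        if self.candidate not in self.ambiguity_group:
            raise ValueError("ambiguity group must contain the primary candidate")


def _chain_base_mass(light: str, heavy: str, composition: str,
                     n_ss: int) -> float:
    h2 = 2 * masschem.TABLE.constant("hydrogen", "average")
    if composition == "intact":
        return (2 * chain_mass(light, "average")
                + 2 * chain_mass(heavy, "average") - n_ss * h2)
    if composition == "heavy":
        return chain_mass(heavy, "average") - n_ss * h2
    if composition == "light":
        return chain_mass(light, "average") - n_ss * h2
    raise ValueError(f"unknown chain composition {composition!r}")


def enumerate_candidates(light: str, heavy: str,
                         library: list[GlycanComposition],
                         settings: MatchSettings = MatchSettings(),
                         composition: str = "intact",
                         n_disulfides: int | None = None,
                         include_deglycosylated: bool = False
                         ) -> list[ProteoformCandidate]:
    """Theoretical proteoform space for one chain composition.

    ``intact`` pairs glycans without order over two sites; ``heavy`` uses one
    site; ``light`` carries none.  N-terminal pyroglutamate states apply when
    the relevant chain starts with Q (heavy) and formic-acid adduct counts run
    0..max.  Candidates are deduplicated by composition.
    """
    n_sites = {"intact": 2, "heavy": 1, "light": 0}[composition]
    if n_sites and not library and not include_deglycosylated:
        raise ValueError("glycan library must not be empty for glycosylated chains")
    if n_disulfides is None:
        n_disulfides = {"intact": 16, "heavy": 4, "light": 2}[composition]
    base = _chain_base_mass(light, heavy, composition, n_disulfides)
    pyro = MODIFICATIONS["Gln->pyro-Glu"].delta("average")
    deam = MODIFICATIONS["Deamidated"].delta("average")
    formic = masschem.TABLE.constant("formic_acid", "average")

    glycan_sets: list[tuple[tuple[str, ...], float]] = []
    if n_sites == 0:
        glycan_sets.append(((), 0.0))
    else:
        for combo in itertools.combinations_with_replacement(library, n_sites):
            glycan_sets.append((tuple(g.label for g in combo),
                                sum(g.residue_mass("average") for g in combo)))
        if include_deglycosylated:
            glycan_sets.append((("deglycosylated",) * n_sites, n_sites * deam))

    max_pyro = settings.max_pyroglu if composition == "intact" else 1
    if (composition in ("intact", "heavy") and heavy[0] != "Q") or composition == "light":
        max_pyro = 0
    candidates = []
    seen = set()
    for glabels, gmass in glycan_sets:
        for k in range(max_pyro + 1):
            for a in range(settings.max_adducts + 1):
                key = (composition, glabels, k, a)
                if key in seen:
                    continue
                seen.add(key)
                candidates.append(ProteoformCandidate(
                    composition, glabels, k, a,
                    base + gmass + k * pyro + a * formic))
    return candidates


def match_masses(peaks: list[MassPeak],
                 candidates: list[ProteoformCandidate],
                 settings: MatchSettings = MatchSettings()
                 ) -> tuple[list[ProteoformMatch], list[MassPeak]]:
    """Pair every picked peak with candidates within tolerance.

    Primary assignment per peak is the smallest |error| (ties toward lower
    candidate mass); all in-tolerance candidates form the ambiguity group.
    Returns (matches, unmatched peaks).
    """
    matches, unmatched = [], []
    for peak in peaks:
        group = [c for c in candidates
                 if abs(peak.mass - c.mass) <= settings.tolerance_da]
        if not group:
            unmatched.append(peak)
            continue
        group.sort(key=lambda c: (abs(peak.mass - c.mass), c.mass))
        primary = group[0]
        matches.append(ProteoformMatch(
            peak, primary, peak.mass - primary.mass,
            ppm_error(peak.mass, primary.mass), group))
    return matches, unmatched


@dataclass
class PngaseShiftResult:
    shift_da: float
    assignments: list[tuple[tuple[str, ...], float]]  # (glycan labels, error Da)
    consistent: bool = True

    @property
    def best(self) -> tuple[str, ...] | None:
        return self.assignments[0][0] if self.assignments else None


def pngase_shift_analysis(peaks_before: list[MassPeak],
                          peaks_after: list[MassPeak],
                          library: list[GlycanComposition],
                          sites: int = 1,
                          tolerance_da: float = 5.0) -> PngaseShiftResult:
    """Infer the removed glycan(s) from the base-peak mass shift.

    Delta = mass(base before) - mass(base after) is matched against every
    glycan multiset of size ``sites``, each contributing its monoisotopic
    residue mass minus the 0.98402 Da Asn->Asp remainder.  Delta ~ 0 means an
    aglycosylated protein; a significant mass *gain* is flagged inconsistent.
    """
    if not peaks_before or not peaks_after:
        raise ValueError("both runs must have picked peaks")
    before = max(peaks_before, key=lambda p: p.area)
    after = max(peaks_after, key=lambda p: p.area)
    shift = before.mass - after.mass
    if shift < -tolerance_da:
        return PngaseShiftResult(shift, [], consistent=False)
    if abs(shift) <= tolerance_da:
        return PngaseShiftResult(shift, [((), shift)])
    deam = MODIFICATIONS["Deamidated"].delta_mono
    assignments = []
    for combo in itertools.combinations_with_replacement(library, sites):
        theo = sum(g.residue_mass("mono") - deam for g in combo)
        err = shift - theo
        if abs(err) <= tolerance_da:
            assignments.append((tuple(g.label for g in combo), err))
    assignments.sort(key=lambda t: abs(t[1]))
    return PngaseShiftResult(shift, assignments)


def relative_glycoform_quant(matches: list[ProteoformMatch],
                             threshold_pct: float = 1.0) -> pd.DataFrame:
    """Percent of reconstructed peak area per glycoform.

    Satellites (adducts, pyroglutamate states) pool into their glycoform; the
    relative-abundance threshold (percent of the base peak's area) is applied
    before normalization, and the reported percentages sum to exactly 100.
    """
    if not matches:
        raise ValueError("no matches to quantify")
    areas: dict[str, float] = {}
    for m in matches:
        label = m.candidate.glycoform_label
        areas[label] = areas.get(label, 0.0) + m.peak.area
    base = max(areas.values())
    if base <= 0:
        raise ValueError("zero total area")
    kept = {k: v for k, v in areas.items() if 100.0 * v / base >= threshold_pct}
    total = sum(kept.values())
    rows = [{"glycoform": k, "area": v, "percent": 100.0 * v / total}
            for k, v in sorted(kept.items(), key=lambda kv: -kv[1])]
    return pd.DataFrame(rows)


def terminal_mod_inference(observed: float, theoretical_unmodified: float,
                           panel: list[ModificationSpec] | None = None,
                           tolerance_da: float = 5.0,
                           max_each: int = 2,
                           include_formic_adducts: bool = True
                           ) -> list[tuple[dict[str, int], float]]:
    """Explain an observed-theoretical mass offset as modification counts.

    Every combination of 0..max_each copies of each panel entry (plus formic
    adducts, if enabled) whose summed average-scale delta lands within the
    tolerance is returned, ranked by |residual error|; ambiguity is preserved.
    An empty-dict entry means 'unmodified'.
    """
    if panel is None:
        panel = [MODIFICATIONS["Gln->pyro-Glu"], MODIFICATIONS["Glu->pyro-Glu"]]
    if not panel:
        raise ValueError("panel must not be empty")
    delta = observed - theoretical_unmodified
    entries = [(m.name, m.delta("average")) for m in panel]
    if include_formic_adducts:
        entries.append(("Formic acid adduct",
                        masschem.TABLE.constant("formic_acid", "average")))
    results = []
    ranges = [range(max_each + 1)] * len(entries)
    for counts in itertools.product(*ranges):
        total = sum(c * d for c, (_, d) in zip(counts, entries))
        err = delta - total
        if abs(err) <= tolerance_da:
            results.append(({n: c for c, (n, _) in zip(counts, entries) if c},
                            err))
    results.sort(key=lambda t: abs(t[1]))
    return results
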