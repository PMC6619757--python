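"""Peptide mapping: tryptic digestion, b/y fragment matching, target–decoy FDR,
apex-intensity modification quantification, coverage, and glycopeptide detection.

The identification strategy is deliberately transparent: candidate peptide
forms (sequence x bounded variable-modification combinations) are matched to
MS2 spectra by precursor mass, scored as the fraction of the theoretical b/y
ladder found in the spectrum, and filtered by a target-decoy q-value
(pseudo-reversed decoys).  "95% confidence" acceptance maps to q <= 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import masschem
from .containers import RawRun, RawSpectrum
from .masschem import (GlycanComposition, ModificationSpec, PROTON,
                       chain_mass, mass_from_mz, mz_from_mass, ppm_error)

# ------------------------------------------------------------------ digestion


@dataclass(frozen=True)
class PeptideSpec:
    """A tryptic peptide located on its chain (1-based inclusive span)."""

    sequence: str
    chain: str
    start: int
    end: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("peptide start > end")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide span does not match sequence length")


def digest(sequence: str, max_missed: int = 0, chain: str = "chain") -> list[PeptideSpec]:
    """Fully tryptic peptides: cleave C-terminal to K/R except before P.

    Returns peptides with 0..max_missed missed cleavages, ordered by start
    position (then by missed-cleavage count).
    """
    cut_after = [i for i, aa in enumerate(sequence)
                 if aa in "KR" and (i + 1 >= len(sequence) or sequence[i + 1] != "P")]
    boundaries = [0] + [i + 1 for i in cut_after]
    if boundaries[-1] != len(sequence):
        boundaries.append(len(sequence))
    peptides = []
    for i in range(len(boundaries) - 1):
        for m in range(max_missed + 1):
            if i + 1 + m >= len(boundaries):
                break
            start, end = boundaries[i], boundaries[i + 1 + m]
            peptides.append(PeptideSpec(sequence[start:end], chain,
                                        start + 1, end, m))
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages))
    return peptides


# ------------------------------------------------------- forms and fragments

ModPlacement = tuple[ModificationSpec, int]  # position 0 = N-terminus


@dataclass(frozen=True)
class PeptideForm:
    """A peptide with a concrete modification placement (fixed + variable)."""

    peptide: PeptideSpec
    mods: tuple[ModPlacement, ...] = ()
    decoy: bool = False

    def mass(self, mass_type: masschem.MassType = "mono") -> float:
        return chain_mass(self.peptide.sequence, mass_type,
                          [(spec, 1) for spec, _ in self.mods])

    def mod_string(self) -> str:
        if not self.mods:
            return "unmodified"
        parts = []
        for spec, pos in sorted(self.mods, key=lambda m: m[1]):
            site = "N-term" if pos == 0 else f"{self.peptide.sequence[pos - 1]}{pos}"
            parts.append(f"{spec.name}@{site}")
        return "+".join(parts)

    def mod_site_labels(self) -> list[str]:
        """Table-style labels such as ``Deamidated N`` or ``Carbamidomethyl N-term``."""
        labels = []
        for spec, pos in self.mods:
            if pos == 0:
                labels.append(f"{spec.name} N-term")
            else:
                labels.append(f"{spec.name} {self.peptide.sequence[pos - 1]}")
        return labels


def theoretical_fragments(sequence: str,
                          mods: tuple[ModPlacement, ...] = (),
                          charges: tuple[int, ...] = (1, 2)) -> list[tuple[str, float]]:
    """b/y fragment ions of a (modified) peptide for the given charges.

    Modification deltas are placed at their positions: an N-terminal delta
    (position 0) rides on every b ion; a delta at residue i enters b_j for
    j >= i and y_j for j > n - i.
    """
    n = len(sequence)
    if n < 2:
        raise ValueError("peptide must have length >= 2")
    res = np.array([masschem.TABLE.aa_mass(a) for a in sequence])
    delta = np.zeros(n + 1)  # index 0 = N-terminal delta
    for spec, pos in mods:
        if pos < 0 or pos > n:
            raise ValueError(f"modification position {pos} outside peptide")
        if pos >= 1 and not spec.applies_at(sequence, pos):
            raise ValueError(f"{spec.name} cannot sit on {sequence[pos-1]}{pos}")
        delta[pos] += spec.delta("mono")
    b_neutral = np.cumsum(res) + np.cumsum(delta[1:]) + delta[0]
    total = b_neutral[-1] + masschem.WATER_MONO
    ions = []
    for i in range(1, n):
        b = b_neutral[i - 1]
        y = total - b
        for z in charges:
            ions.append((f"b{i}^{z}", (b + z * PROTON) / z))
            ions.append((f"y{n - i}^{z}", (y + z * PROTON) / z))
    return ions


def enumerate_forms(peptide: PeptideSpec,
                    panel: list[ModificationSpec],
                    max_var_mods: int = 2,
                    fixed_cam_cys: bool = True,
                    max_forms: int = 64,
                    decoy: bool = False) -> list[PeptideForm]:
    """All modification placements of a peptide, bounded by ``max_var_mods``.

    Carbamidomethyl is fixed on every Cys when ``fixed_cam_cys``; panel entries
    are applied as variable mods at their applicable sites (at most one mod
    per site, at most ``max_per_peptide`` copies of each mod).
    """
    seq = peptide.sequence
    fixed: list[ModPlacement] = []
    if fixed_cam_cys:
        cam = masschem.MODIFICATIONS["Carbamidomethyl"]
        fixed = [(cam, i + 1) for i, aa in enumerate(seq) if aa == "C"]
    sites: list[ModPlacement] = []
    for spec in panel:
        if any(t.startswith("nterm") for t in spec.targets) and spec.applies_at(seq, 0):
            sites.append((spec, 0))
        for i, aa in enumerate(seq):
            if aa == "C" and fixed_cam_cys and spec.name == "Carbamidomethyl":
                continue
            if any(t == aa for t in spec.targets):
                sites.append((spec, i + 1))
    forms = [PeptideForm(peptide, tuple(fixed), decoy)]
    for k in range(1, max_var_mods + 1):
        for combo in itertools.combinations(sites, k):
            positions = [pos for _, pos in combo]
            if len(set(positions)) != len(positions):
                continue
            per_mod: dict[str, int] = {}
            for spec, _ in combo:
                per_mod[spec.name] = per_mod.get(spec.name, 0) + 1
            if any(per_mod[s.name] > s.max_per_peptide for s, _ in combo):
                continue
            forms.append(PeptideForm(peptide, tuple(fixed) + tuple(combo), decoy))
            if len(forms) >= max_forms:
                return forms
    return forms


def _decoy_peptide(pep: PeptideSpec) -> PeptideSpec:
    """Pseudo-reversed decoy: reverse all but the C-terminal residue."""
    seq = pep.sequence[:-1][::-1] + pep.sequence[-1]
    return replace(pep, sequence=seq, chain="decoy_" + pep.chain)


# --------------------------------------------------------------------- search


@dataclass
class PeptideSpectrumMatch:
    form: PeptideForm
    scan_id: int
    rt: float
    precursor_mz: float
    charge: int
    score: float
    n_matched: int
    n_theoretical: int
    q_value: float | None = None

    @property
    def decoy(self) -> bool:
        return self.form.decoy


class PSMList(list):
    """PSM container that remembers whether decoys were part of the search."""

    decoys_searched: bool = False


def build_form_database(chains: dict[str, str],
                        panel: list[ModificationSpec],
                        max_missed: int = 1,
                        max_var_mods: int = 2,
                        with_decoys: bool = True) -> list[PeptideForm]:
    forms: list[PeptideForm] = []
    for chain_name, seq in chains.items():
        for pep in digest(seq, max_missed, chain=chain_name):
            if len(pep.sequence) < 2:
                continue
            forms.extend(enumerate_forms(pep, panel))
            if with_decoys:
                forms.extend(enumerate_forms(_decoy_peptide(pep), panel, decoy=True))
    return forms


def _matched_count(theo_mz: np.ndarray, spec_mz: np.ndarray, tol: float) -> int:
    idx = np.searchsorted(spec_mz, theo_mz)
    left = np.abs(spec_mz[np.clip(idx - 1, 0, len(spec_mz) - 1)] - theo_mz)
    right = np.abs(spec_mz[np.clip(idx, 0, len(spec_mz) - 1)] - theo_mz)
    return int(np.sum(np.minimum(left, right) <= tol))


def search(run: RawRun,
           chains: dict[str, str],
           panel: list[ModificationSpec] | None = None,
           tol_precursor_ppm: float = 10.0,
           tol_fragment: float = 0.02,
           max_missed: int = 1,
           max_var_mods: int = 2,
           with_decoys: bool = True) -> PSMList:
    """Match every MS2 scan to its best candidate peptide form.

    Candidates within the precursor tolerance (over all bounded modification
    combinations, targets and pseudo-reversed decoys alike) are scored as
    matched b/y fraction; the top-scoring form per spectrum becomes its PSM
    (ties broken toward the target).
    """
    if panel is None:
        panel = [m for m in masschem.MODIFICATIONS.values()]
    forms = build_form_database(chains, panel, max_missed, max_var_mods, with_decoys)
    masses = np.array([f.mass() for f in forms])
    order = np.argsort(masses)
    masses = masses[order]
    forms = [forms[i] for i in order]

    psms = PSMList()
    psms.decoys_searched = with_decoys
    for scan in run.ms2():
        if scan.precursor_mz is None or scan.precursor_charge is None or not len(scan.mz):
            continue
        z = scan.precursor_charge
        neutral = mass_from_mz(scan.precursor_mz, z)
        tol = neutral * tol_precursor_ppm * 1e-6
        lo = np.searchsorted(masses, neutral - tol)
        hi = np.searchsorted(masses, neutral + tol)
        if lo == hi:
            continue
        spec_mz = np.sort(scan.mz)
        best: PeptideSpectrumMatch | None = None
        for i in range(lo, hi):
            form = forms[i]
            theo = np.array([mz for _, mz in
                             theoretical_fragments(form.peptide.sequence, form.mods)])
            matched = _matched_count(theo, spec_mz, tol_fragment)
            score = matched / len(theo)
            cand = PeptideSpectrumMatch(form, scan.scan_id, scan.rt,
                                        scan.precursor_mz, z, score,
                                        matched, len(theo))
            if best is None or (score, not cand.decoy) > (best.score, not best.decoy):
                best = cand
        if best is not None and best.score > 0:
            psms.append(best)
    return psms


def fdr_filter(psms: PSMList, q_max: float = 0.05) -> PSMList:
    """Target-decoy q-value filter; accepts target PSMs with q <= q_max."""
    decoys_searched = getattr(psms, "decoys_searched", None)
    if decoys_searched is None:
        decoys_searched = any(p.decoy for p in psms)
    if not decoys_searched:
        raise ValueError("FDR undefined: no decoys were searched")
    ranked = sorted(psms, key=lambda p: p.score, reverse=True)
    n_target = n_decoy = 0
    raw_q = []
    for p in ranked:
        if p.decoy:
            n_decoy += 1
        else:
            n_target += 1
        raw_q.append(n_decoy / max(n_target, 1))
    # monotonize from the bottom so q never decreases with rank
    q = list(raw_q)
    for i in range(len(q) - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    accepted = PSMList()
    accepted.decoys_searched = True
    for p, qv in zip(ranked, q):
        p.q_value = qv
        if not p.decoy and qv <= q_max:
            accepted.append(p)
    return accepted


def sequence_coverage(accepted: list[PeptideSpectrumMatch],
                      chain_sequence: str, chain_name: str) -> float:
    """Percent of chain residues covered by accepted peptides."""
    covered = np.zeros(len(chain_sequence), dtype=bool)
    for p in accepted:
        if p.form.peptide.chain == chain_name:
            covered[p.form.peptide.start - 1:p.form.peptide.end] = True
    if len(chain_sequence) == 0:
        return 0.0
    return 100.0 * covered.sum() / len(chain_sequence)


# ----------------------------------------------------------- XIC / mod quant


def xic_apex(run: RawRun, mz: float, rt: float,
             tol_ppm: float = 25.0, rt_window: float = 30.0) -> float:
    """Apex of the 3-point-smoothed MS1 XIC at mz +- tol within rt +- window (s)."""
    times, values = [], []
    half = mz * tol_ppm * 1e-6
    for scan in run.ms1():
        if abs(scan.rt - rt) > rt_window:
            continue
        sel = np.abs(scan.mz - mz) <= half
        times.append(scan.rt)
        values.append(float(scan.intensity[sel].sum()))
    if not values:
        return 0.0
    v = np.asarray(values)
    if len(v) >= 3:
        v = np.convolve(v, np.ones(3) / 3.0, mode="same")
    return float(v.max())


@dataclass
class ModificationReport:
    modification: str
    n_modified_peptides: int
    relative_abundance: float  # percent

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_abundance <= 100.0 + 1e-9:
            raise ValueError("relative abundance outside [0, 100]")


def modification_quant(accepted: list[PeptideSpectrumMatch],
                       run: RawRun) -> tuple[list[ModificationReport], pd.DataFrame]:
    """Apex-intensity relative quantification of modifications.

    For every base peptide (chain + span), each accepted form's XIC apex near
    its identification is extracted; the modified percentage of a base peptide
    is the apex share of forms carrying the modification.  The per-modification
    report aggregates those shares across base peptides, weighted by each base
    peptide's total apex, over base peptides with at least one applicable site.
    Returns the Table-style report and a per-form DataFrame.
    """
    base: dict[tuple, dict] = {}
    for p in accepted:
        key = (p.form.peptide.chain, p.form.peptide.start, p.form.peptide.end)
        entry = base.setdefault(key, {"peptide": p.form.peptide, "forms": {}})
        fkey = p.form.mods
        prev = entry["forms"].get(fkey)
        apex = xic_apex(run, p.precursor_mz, p.rt)
        if prev is None or apex > prev[1]:
            entry["forms"][fkey] = (p.form, apex)

    rows = []
    for key, entry in base.items():
        total = sum(apex for _, apex in entry["forms"].values())
        if total <= 0:
            continue  # nothing quantifiable for this base peptide
        for form, apex in entry["forms"].values():
            rows.append({
                "chain": key[0], "start": key[1], "end": key[2],
                "sequence": form.peptide.sequence,
                "form": form.mod_string(),
                "labels": ";".join(form.mod_site_labels()),
                "apex": apex,
                "fraction": apex / total,
                "base_total": total,
            })
    per_form = pd.DataFrame(rows)

    label_counts: dict[str, int] = {}
    for p in accepted:
        for label in set(p.form.mod_site_labels()):
            if label == "Carbamidomethyl C":
                continue  # fixed alkylation, not a monitored attribute
            label_counts[label] = label_counts.get(label, 0) + 1

    reports = []
    if not per_form.empty:
        all_labels = sorted(label_counts)
        for label in all_labels:
            mod_name = label.rsplit(" ", 1)[0]
            site = label.rsplit(" ", 1)[1]
            num = 0.0
            den = 0.0
            for key, entry in base.items():
                forms = entry["forms"].values()
                total = sum(a for _, a in forms)
                if total <= 0:
                    continue
                seq = entry["peptide"].sequence
                spec = masschem.MODIFICATIONS.get(mod_name)
                applicable = (site == "N-term" and spec is not None
                              and spec.applies_at(seq, 0)) or (site in seq)
                if not applicable:
                    continue
                mod_apex = sum(a for f, a in forms if label in f.mod_site_labels())
                num += mod_apex
                den += total
            pct = 100.0 * num / den if den > 0 else 0.0
            reports.append(ModificationReport(label, label_counts[label], pct))
    return reports, per_form


def base_peptide_fraction(per_form: pd.DataFrame, chain: str, start: int,
                          label_substring: str) -> float:
    """Apex fraction of forms of one base peptide whose labels contain a string."""
    sel = per_form[(per_form["chain"] == chain) & (per_form["start"] == start)]
    if sel.empty or sel["apex"].sum() <= 0:
        return float("nan")
    mod = sel[sel["labels"].str.contains(label_substring, regex=False)]
    return float(mod["apex"].sum() / sel["apex"].sum())


# -------------------------------------------------------------- glycopeptides

SEQUON_EXCLUDE = "P"


def has_sequon(sequence: str) -> bool:
    """N-X(!=P)-[S/T] anywhere in the peptide."""
    for i in range(len(sequence) - 2):
        if (sequence[i] == "N" and sequence[i + 1] != SEQUON_EXCLUDE
                and sequence[i + 2] in "ST"):
            return True
    return False


@dataclass
class GlycopeptideAssignment:
    peptide: PeptideSpec
    glycan: GlycanComposition
    charge: int
    scan_id: int
    precursor_mz: float
    theoretical_mz: float
    ppm: float
    markers_hit: tuple[float, ...]
    xic_area: float = 0.0


def _xic_area(run: RawRun, mz: float, tol_ppm: float = 25.0) -> float:
    times, values = [], []
    half = mz * tol_ppm * 1e-6
    for scan in run.ms1():
        sel = np.abs(scan.mz - mz) <= half
        times.append(scan.rt)
        values.append(float(scan.intensity[sel].sum()))
    if len(values) < 2:
        return float(sum(values))
    return float(np.trapezoid(values, times))


def detect_glycopeptides(run: RawRun,
                         peptides: list[PeptideSpec],
                         library: list[GlycanComposition],
                         markers: tuple[float, ...] = (masschem.OXONIUM_HEXNAC,
                                                       masschem.OXONIUM_HEXHEXNAC,
                                                       masschem.OXONIUM_NEUAC),
                         marker_tol: float = 0.02,
                         tol_ppm: float = 10.0,
                         charges: tuple[int, ...] = (2, 3)) -> tuple[
                             list[GlycopeptideAssignment], pd.DataFrame]:
    """Oxonium-prefiltered glycopeptide assignment plus XIC quantification.

    Only MS2 scans containing at least one oxonium marker are tested; their
    precursors are explained as sequon peptide + glycan residue mass over the
    allowed charges, ranked by |ppm|.  Relative quantification uses the summed
    XIC areas of each glycoform's precursor ions across charge states.
    """
    if not library:
        raise ValueError("glycan library must not be empty")
    sequon_peps = [p for p in peptides if has_sequon(p.sequence)]
    assignments: list[GlycopeptideAssignment] = []
    for scan in run.ms2():
        if scan.precursor_mz is None or not len(scan.mz):
            continue
        hits = tuple(m for m in markers if np.any(np.abs(scan.mz - m) <= marker_tol))
        if not hits:
            continue
        zs = (scan.precursor_charge,) if scan.precursor_charge else charges
        best = None
        for pep in sequon_peps:
            pep_mass = chain_mass(pep.sequence)
            for comp in library:
                neutral = pep_mass + comp.residue_mass()
                for z in zs:
                    theo = mz_from_mass(neutral, z)
                    err = ppm_error(mass_from_mz(scan.precursor_mz, z), neutral)
                    if abs(err) <= tol_ppm:
                        cand = GlycopeptideAssignment(
                            pep, comp, z, scan.scan_id, scan.precursor_mz,
                            theo, err, hits)
                        if best is None or abs(cand.ppm) < abs(best.ppm):
                            best = cand
        if best is not None:
            assignments.append(best)

    areas: dict[tuple, float] = {}
    seen_mz: set[tuple] = set()
    for a in assignments:
        key = (a.peptide.sequence, a.glycan.label)
        mz_key = (key, round(a.theoretical_mz, 4))
        if mz_key in seen_mz:
            continue
        seen_mz.add(mz_key)
        area = _xic_area(run, a.theoretical_mz)
        a.xic_area = area
        areas[key] = areas.get(key, 0.0) + area
    total = sum(areas.values())
    rows = [{"peptide": k[0], "glycan": k[1], "area": v,
             "percent": 100.0 * v / total if total > 0 else float("nan")}
            for k, v in sorted(areas.items(), key=lambda kv: -kv[1])]
    return assignments, pd.DataFrame(rows)
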