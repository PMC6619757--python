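"""Seeded synthetic LC-MS(/MS) runs with the statistical structure of each
characterization level of an IgG multi-attribute analysis.

The generator emulates a QTOF instrument acquiring:

* intact-mAb TOF-MS (a ~147 kDa glycoform mixture as an ESI charge envelope,
  optionally PNGase-deglycosylated),
* reduced light/heavy chains (heavy carries the single-site glycan profile),
* a tryptic-digest LC-MS/MS run with IDA-style top-N precursor selection,
  modified peptide forms and glycopeptides,
* a free N-glycan LC-MS/MS run with retention-separated isomers (porous
  graphitic carbon-like behaviour).

Peaks are centroided sticks; an unresolved protein envelope is represented by
one stick per (species, charge) at the average-mass m/z.  Every run carries a
ground-truth sidecar (``RawRun.truth``) recording the simulated species and
fractions for parameter-recovery tests.  Identical (model, settings, seed)
always yields byte-identical runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from . import io as _io
from . import masschem
from .containers import RawRun, RawSpectrum
from .glycans import fragment_ions
from .masschem import (GlycanComposition, MODIFICATIONS, PROTON,
                       chain_mass, glycan, mz_from_mass)
from .peptides import PeptideForm, PeptideSpec, digest, theoretical_fragments

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


# ---------------------------------------------------------------------- model


@dataclass(frozen=True)
class SiteMod:
    """A variable modification site on a chain with its occupied fraction."""

    chain: str        # "heavy" | "light"
    position: int     # 1-based on the chain
    mod_name: str
    fraction: float


@dataclass(frozen=True)
class IgGModel:
    """The simulated antibody: chains, glycan profile, terminal PTMs, adducts."""

    light_chain: str
    heavy_chain: str
    glycosite: int                                # 1-based N on the heavy chain
    glycan_profile: tuple[tuple[GlycanComposition, float], ...]
    heavy_pyroglu_fraction: float = 0.95
    light_pyroglu_fraction: float = 0.01
    ptm_sites: tuple[SiteMod, ...] = ()
    formic_adduct_fraction: float = 0.05
    n_disulfides_intact: int = 16
    n_disulfides_light: int = 2
    n_disulfides_heavy: int = 4

    def __post_init__(self) -> None:
        if self.glycan_profile:
            total = sum(f for _, f in self.glycan_profile)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"glycan fractions sum to {total}, not 1")
        for f in (self.heavy_pyroglu_fraction, self.light_pyroglu_fraction,
                  self.formic_adduct_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.glycosite and self.heavy_chain[self.glycosite - 1] != "N":
            raise ValueError("glycosylation site residue must be N")

    @classmethod
    def default(cls) -> "IgGModel":
        """The bundled IgG1-like model with the G0F/G1F/G2F profile.

        Profile fractions follow the dominant biantennary pattern of a
        CHO-produced IgG1 (78.1/21.7/0.3 as percentages, normalized to 1).
        """
        with resources.as_file(
                resources.files("mamkit.data").joinpath("igg1_synthetic.fasta")) as p:
            light, heavy = _io.read_chains(p)
        site = heavy.index("EEQYNSTYR") + 4 + 1  # the N of the sequon, 1-based
        raw = [(glycan("G0F"), 0.781), (glycan("G1F"), 0.217), (glycan("G2F"), 0.003)]
        total = sum(f for _, f in raw)
        profile = tuple((g, f / total) for g, f in raw)
        ptm_sites = _default_ptm_sites(light, heavy)
        return cls(light_chain=light, heavy_chain=heavy, glycosite=site,
                   glycan_profile=profile, ptm_sites=ptm_sites)

    def chain(self, name: str) -> str:
        return self.heavy_chain if name == "heavy" else self.light_chain


def _default_ptm_sites(light: str, heavy: str) -> tuple[SiteMod, ...]:
    """A small realistic hot-spot panel: NG deamidation, W/M oxidation."""
    sites = []
    ng = heavy.find("NG")
    if ng >= 0:
        sites.append(SiteMod("heavy", ng + 1, "Deamidated", 0.30))
    w = heavy.find("W")
    if w >= 0:
        sites.append(SiteMod("heavy", w + 1, "Oxidation", 0.03))
    m = heavy.find("M")
    if m >= 0:
        sites.append(SiteMod("heavy", m + 1, "Oxidation", 0.012))
    q = light.find("Q", 3)
    if q >= 0:
        sites.append(SiteMod("light", q + 1, "Deamidated", 0.07))
    return tuple(sites)


@dataclass(frozen=True)
class SimulatorSettings:
    """Instrument and acquisition parameters for the simulated QTOF."""

    mz_start: float = 400.0
    mz_stop: float = 4000.0
    resolution: float = 2500.0          # FWHM = m/z / resolution
    envelope_center_mz: float = 2728.0  # ESI envelope center (z ~ 54 at 147 kDa)
    charge_sigma: float | None = None   # Gaussian width over z; None = 8% of center
    base_intensity: float = 1e5
    noise_level: float = 1.0
    noise_scale_frac: float = 1e-5  # baseline stick scale / base_intensity
    n_noise_peaks: int = 150
    jitter: float = 0.02
    seed: int = 0
    # protein-level acquisition
    n_scans: int = 60
    scan_s: float = 1.0
    # LC-MS/MS acquisition
    gradient_start_s: float = 60.0
    gradient_ramp_s: float = 3300.0
    run_length_s: float = 3600.0
    cycle_s: float = 2.3
    elution_sigma_s: float = 6.0
    ida_top_n: int = 40
    ida_charge_min: int = 2
    ida_charge_max: int = 5
    ida_min_intensity: float = 125.0
    ida_exclusion_s: float = 12.0
    ms2_mz_start: float = 150.0
    ms2_mz_stop: float = 1800.0
    max_missed: int = 1

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.ida_top_n < 1:
            raise ValueError("IDA top-N must be >= 1")


def intact_settings(seed: int = 0, **kw) -> SimulatorSettings:
    return SimulatorSettings(seed=seed, **kw)


def reduced_settings(seed: int = 0, **kw) -> SimulatorSettings:
    kw.setdefault("envelope_center_mz", 1400.0)
    return SimulatorSettings(seed=seed, **kw)


def digest_settings(seed: int = 0, **kw) -> SimulatorSettings:
    kw.setdefault("mz_stop", 2000.0)
    kw.setdefault("noise_scale_frac", 1e-4)
    kw.setdefault("base_intensity", 1e5)
    kw.setdefault("n_noise_peaks", 50)
    return SimulatorSettings(seed=seed, **kw)


def glycan_settings(seed: int = 0, **kw) -> SimulatorSettings:
    kw.setdefault("mz_stop", 2000.0)
    kw.setdefault("noise_scale_frac", 1e-4)
    kw.setdefault("base_intensity", 1e6)
    kw.setdefault("n_noise_peaks", 30)
    kw.setdefault("noise_level", 0.5)
    kw.setdefault("cycle_s", 2.25)
    kw.setdefault("gradient_start_s", 60.0)
    kw.setdefault("gradient_ramp_s", 900.0)
    kw.setdefault("run_length_s", 1400.0)
    kw.setdefault("elution_sigma_s", 4.0)
    kw.setdefault("ida_top_n", 20)
    kw.setdefault("ida_charge_max", 4)
    kw.setdefault("ida_min_intensity", 200.0)
    return SimulatorSettings(seed=seed, **kw)


# ------------------------------------------------------------- protein levels


def _charge_weights(mass: float, settings: SimulatorSettings
                    ) -> tuple[np.ndarray, np.ndarray]:
    z_center = mass / (settings.envelope_center_mz - PROTON)
    sigma = settings.charge_sigma if settings.charge_sigma is not None \
        else max(1.5, 0.08 * z_center)
    z_lo = max(1, int(math.floor(z_center - 4 * sigma)))
    z_hi = int(math.ceil(z_center + 4 * sigma))
    z = np.arange(z_lo, z_hi + 1)
    w = np.exp(-0.5 * ((z - z_center) / sigma) ** 2)
    if w.max() <= 0.0:  # vanishing width: all intensity in the nearest charge
        z = np.array([max(1, int(round(z_center)))])
        return z, np.array([1.0])
    keep = w >= 1e-3 * w.max()
    z, w = z[keep], w[keep]
    return z, w / w.sum()


def _adduct_weights(p: float) -> list[tuple[int, float]]:
    # 0, 1 or 2 formic-acid adducts; satellites carry a p-sized total share
    return [(0, 1.0 - p), (1, 0.8 * p), (2, 0.2 * p)]


def _binom2(f: float) -> list[tuple[int, float]]:
    return [(0, (1 - f) ** 2), (1, 2 * f * (1 - f)), (2, f * f)]


def _intact_species(model: IgGModel, pngase_treated: bool
                    ) -> list[tuple[str, str, float, float]]:
    """(label, pair_label, mass, fraction) for every intact proteoform."""
    base = (2 * chain_mass(model.light_chain, "average")
            + 2 * chain_mass(model.heavy_chain, "average")
            - 2 * masschem.TABLE.constant("hydrogen", "average")
            * model.n_disulfides_intact)
    pyro = MODIFICATIONS["Gln->pyro-Glu"].delta("average")
    formic = masschem.TABLE.constant("formic_acid", "average")
    deam = MODIFICATIONS["Deamidated"].delta("average")

    if pngase_treated:
        pairs = [("deglycosylated", 2 * deam, 1.0)]
    else:
        pairs = []
        profile = list(model.glycan_profile)
        for i, (gi, fi) in enumerate(profile):
            for j, (gj, fj) in enumerate(profile):
                if j < i:
                    continue
                frac = fi * fj * (1 if i == j else 2)
                label = f"{gi.label}/{gj.label}"
                pairs.append((label, gi.residue_mass("average")
                              + gj.residue_mass("average"), frac))
    species = []
    nterm = model.heavy_chain[0]
    pyro_states = _binom2(model.heavy_pyroglu_fraction) if nterm == "Q" else [(0, 1.0)]
    for pair_label, pair_mass, pair_frac in pairs:
        for k, fk in pyro_states:
            for a, fa in _adduct_weights(model.formic_adduct_fraction):
                frac = pair_frac * fk * fa
                if frac < 1e-5:
                    continue
                mass = base + pair_mass + k * pyro + a * formic
                label = pair_label
                if k:
                    label += f" +{k}pyroGlu"
                if a:
                    label += f" +{a}HCOOH"
                species.append((label, pair_label, mass, frac))
    return species


def _reduced_species(model: IgGModel, pngase_treated: bool
                     ) -> list[tuple[str, str, float, float]]:
    """(label, group_label, mass, fraction); light and heavy share the run."""
    deam = MODIFICATIONS["Deamidated"].delta("average")
    formic = masschem.TABLE.constant("formic_acid", "average")
    species = []

    light_mass = chain_mass(model.light_chain, "average",
                            n_disulfides=model.n_disulfides_light)
    light_share, heavy_share = 0.45, 0.55
    pyro_e = MODIFICATIONS["Glu->pyro-Glu"].delta("average")
    light_states = ([(0, 1 - model.light_pyroglu_fraction),
                     (1, model.light_pyroglu_fraction)]
                    if model.light_chain[0] == "E" else [(0, 1.0)])
    for k, fk in light_states:
        for a, fa in _adduct_weights(model.formic_adduct_fraction):
            frac = light_share * fk * fa
            if frac < 1e-5:
                continue
            species.append((f"light{' +pyroGlu' if k else ''}"
                            f"{f' +{a}HCOOH' if a else ''}",
                            "light", light_mass + k * pyro_e + a * formic, frac))

    heavy_base = chain_mass(model.heavy_chain, "average",
                            n_disulfides=model.n_disulfides_heavy)
    pyro_q = MODIFICATIONS["Gln->pyro-Glu"].delta("average")
    heavy_states = ([(0, 1 - model.heavy_pyroglu_fraction),
                     (1, model.heavy_pyroglu_fraction)]
                    if model.heavy_chain[0] == "Q" else [(0, 1.0)])
    if pngase_treated:
        glycoforms = [("heavy deglycosylated", deam, 1.0)]
    else:
        if not model.glycan_profile:
            raise ValueError("empty glycan profile on an untreated run")
        glycoforms = [(f"heavy {g.label}", g.residue_mass("average"), f)
                      for g, f in model.glycan_profile]
    for glabel, gmass, gfrac in glycoforms:
        for k, fk in heavy_states:
            for a, fa in _adduct_weights(model.formic_adduct_fraction):
                frac = heavy_share * gfrac * fk * fa
                if frac < 1e-5:
                    continue
                species.append((f"{glabel}{' +pyroGlu' if k else ''}"
                                f"{f' +{a}HCOOH' if a else ''}", glabel,
                                heavy_base + gmass + k * pyro_q + a * formic, frac))
    return species


def _cluster_truth(species: list[tuple[str, str, float, float]],
                   resolution: float) -> dict:
    """Per-group fractions, centroid masses and resolution-blurred apexes.

    The apex is what an ideal zero-charge reconstruction measures: terminal
    PTM and adduct satellites are unresolved at the instrument resolution, so
    each group's reported mass is the local maximum of the Gaussian-blurred
    species mixture (FWHM = mass / resolution), not the modal species mass.
    """
    all_masses = np.array([m for _, _, m, _ in species])
    all_fracs = np.array([f for _, _, _, f in species])
    sigma = all_masses / resolution / 2.3548200450309493

    def profile(x: np.ndarray) -> np.ndarray:
        return np.sum(all_fracs[None, :]
                      * np.exp(-0.5 * ((x[:, None] - all_masses[None, :])
                                       / sigma[None, :]) ** 2), axis=1)

    groups: dict[str, list[tuple[float, float]]] = {}
    for _label, group, mass, frac in species:
        groups.setdefault(group, []).append((mass, frac))
    out = {}
    for group, members in groups.items():
        total = sum(f for _, f in members)
        centroid = sum(m * f for m, f in members) / total
        lo = min(m for m, _ in members) - 60.0
        hi = max(m for m, _ in members) + 60.0
        grid = np.arange(lo, hi, 0.1)
        apex = float(grid[int(np.argmax(profile(grid)))])
        out[group] = {"fraction": total, "cluster_mass": centroid,
                      "cluster_apex": apex}
    return out


def _protein_run(species: list[tuple[str, str, float, float]],
                 settings: SimulatorSettings, name: str, truth: dict) -> RawRun:
    rng = np.random.default_rng(settings.seed)
    mz_list, inten_list = [], []
    for _label, _group, mass, frac in species:
        z, w = _charge_weights(mass, settings)
        mz = (mass + z * PROTON) / z
        sel = (mz >= settings.mz_start) & (mz <= settings.mz_stop)
        mz_list.append(mz[sel])
        inten_list.append(settings.base_intensity * frac * w[sel])
    all_mz = np.concatenate(mz_list) if mz_list else np.empty(0)
    all_int = np.concatenate(inten_list) if inten_list else np.empty(0)

    run = RawRun(name=name, truth=truth)
    n = settings.n_scans
    chrom_center, chrom_sigma = 0.5 * n, n / 6.0
    for i in range(n):
        chrom = math.exp(-0.5 * ((i - chrom_center) / chrom_sigma) ** 2)
        jitter = rng.lognormal(0.0, settings.jitter, size=all_mz.shape)
        sig_int = all_int * chrom * jitter
        noise_mz = rng.uniform(settings.mz_start, settings.mz_stop,
                               settings.n_noise_peaks)
        noise_int = rng.exponential(
            settings.noise_level * settings.base_intensity
            * settings.noise_scale_frac + 1e-300,
            settings.n_noise_peaks)
        mz = np.concatenate([all_mz, noise_mz])
        inten = np.concatenate([sig_int, noise_int])
        order = np.argsort(mz)
        run.spectra.append(RawSpectrum(i + 1, 1, i * settings.scan_s,
                                       mz[order], inten[order]))
    return run


def simulate_intact_run(model: IgGModel, settings: SimulatorSettings,
                        pngase_treated: bool = False) -> RawRun:
    """TOF-MS run of the intact antibody (optionally PNGase-deglycosylated)."""
    if not model.glycan_profile and not pngase_treated:
        raise ValueError("empty glycan profile on an untreated run")
    species = _intact_species(model, pngase_treated)
    clusters = _cluster_truth(species, settings.resolution)
    base_group = max(clusters, key=lambda g: clusters[g]["fraction"])
    truth = {
        "level": "intact", "pngase_treated": pngase_treated,
        "species": [{"label": l, "group": g, "mass": m, "fraction": f}
                    for l, g, m, f in species],
        "groups": clusters,
        "base_group": base_group,
        "base_cluster_mass": clusters[base_group]["cluster_mass"],
        "base_cluster_apex": clusters[base_group]["cluster_apex"],
    }
    return _protein_run(species, settings,
                        f"intact{'_pngase' if pngase_treated else ''}", truth)


def simulate_reduced_run(model: IgGModel, settings: SimulatorSettings,
                         pngase_treated: bool = False) -> RawRun:
    """TOF-MS run of the DTT-reduced antibody (free light + heavy chains)."""
    species = _reduced_species(model, pngase_treated)
    clusters = _cluster_truth(species, settings.resolution)
    heavy_groups = {g: v for g, v in clusters.items() if g.startswith("heavy")}
    base_heavy = max(heavy_groups, key=lambda g: heavy_groups[g]["fraction"])
    heavy_total = sum(v["fraction"] for v in heavy_groups.values())
    truth = {
        "level": "reduced", "pngase_treated": pngase_treated,
        "species": [{"label": l, "group": g, "mass": m, "fraction": f}
                    for l, g, m, f in species],
        "groups": clusters,
        "light_cluster_mass": clusters["light"]["cluster_mass"],
        "light_cluster_apex": clusters["light"]["cluster_apex"],
        "base_heavy_group": base_heavy,
        "base_heavy_cluster_mass": heavy_groups[base_heavy]["cluster_mass"],
        "base_heavy_cluster_apex": heavy_groups[base_heavy]["cluster_apex"],
        "heavy_glycoform_fractions": {
            g.replace("heavy ", ""): v["fraction"] / heavy_total
            for g, v in heavy_groups.items()},
    }
    return _protein_run(species, settings,
                        f"reduced{'_pngase' if pngase_treated else ''}", truth)


# ------------------------------------------------------------ digest LC-MS/MS


@dataclass
class _Species:
    """One simulated LC-MS species: a peptide form (maybe glycosylated) at one charge."""

    form: PeptideForm
    glycan: GlycanComposition | None
    charge: int
    mz: float
    rt: float
    abundance: float
    fraction: float  # within its base peptide


def _peptide_rt(sequence: str, settings: SimulatorSettings, rng) -> float:
    kd = sum(KYTE_DOOLITTLE.get(a, 0.0) for a in sequence) / len(sequence)
    frac = (kd + 4.5) / 9.0
    return (settings.gradient_start_s + frac * settings.gradient_ramp_s
            + rng.normal(0.0, 18.0))


def _charge_split(length: int) -> list[tuple[int, float]]:
    if length < 10:
        return [(2, 0.85), (3, 0.15)]
    if length < 20:
        return [(2, 0.60), (3, 0.35), (4, 0.05)]
    return [(2, 0.25), (3, 0.50), (4, 0.25)]


def _digest_forms(model: IgGModel, pep: PeptideSpec
                  ) -> list[tuple[tuple, GlycanComposition | None, float]]:
    """(mods, glycan, fraction) for every simulated form of a peptide."""
    cam = MODIFICATIONS["Carbamidomethyl"]
    fixed = tuple((cam, i + 1) for i, aa in enumerate(pep.sequence) if aa == "C")
    forms: list[tuple[tuple, float]] = [(fixed, 1.0)]

    if pep.start == 1:
        first = pep.sequence[0]
        frac = (model.heavy_pyroglu_fraction if pep.chain == "heavy"
                else model.light_pyroglu_fraction)
        spec = None
        if first == "Q":
            spec = MODIFICATIONS["Gln->pyro-Glu"]
        elif first == "E":
            spec = MODIFICATIONS["Glu->pyro-Glu"]
        if spec is not None and frac > 0:
            forms = [(mods + ((spec, 0),), f * frac) for mods, f in forms] + \
                    [(mods, f * (1 - frac)) for mods, f in forms]
    for site in model.ptm_sites:
        if site.chain != pep.chain or not pep.start <= site.position <= pep.end:
            continue
        spec = MODIFICATIONS[site.mod_name]
        local = site.position - pep.start + 1
        forms = [(mods + ((spec, local),), f * site.fraction) for mods, f in forms] + \
                [(mods, f * (1 - site.fraction)) for mods, f in forms]
    forms = [(m, f) for m, f in forms if f >= 5e-4]

    glycosylated = (pep.chain == "heavy"
                    and pep.start <= model.glycosite <= pep.end)
    out = []
    for mods, f in forms:
        if glycosylated:
            for g, gf in model.glycan_profile:
                if f * gf >= 5e-4:
                    out.append((mods, g, f * gf))
        else:
            out.append((mods, None, f))
    return out


def _peptide_ms2(species: _Species, settings: SimulatorSettings, rng,
                 precursor_intensity: float) -> tuple[np.ndarray, np.ndarray]:
    seq = species.form.peptide.sequence
    charges = (1,) if species.charge <= 2 else (1, 2)
    frag = theoretical_fragments(seq, species.form.mods, charges)
    scale = 0.2 * precursor_intensity
    mzs, ints = [], []
    backbone_scale = 0.1 if species.glycan is not None else 1.0
    for _label, mz in frag:
        mzs.append(mz)
        ints.append(scale * backbone_scale * (0.2 + 0.8 * rng.random()))
    if species.glycan is not None:
        pep_mass = chain_mass(seq, "mono", [(s, 1) for s, _ in species.form.mods])
        hexnac = masschem.TABLE.sugar_mass("HexNAc")
        hexose = masschem.TABLE.sugar_mass("Hex")
        oxonium = [(masschem.OXONIUM_HEXNAC, 1.0),
                   (masschem.OXONIUM_HEXHEXNAC, 0.6)]
        if species.glycan.neuac:
            oxonium.append((masschem.OXONIUM_NEUAC, 0.5))
        for mz, rel in oxonium:
            mzs.append(mz)
            ints.append(scale * rel * 3.0)
        y_series = [0.0, hexnac, 2 * hexnac,
                    2 * hexnac + masschem.TABLE.sugar_mass("dHex") * min(1, species.glycan.dhex),
                    species.glycan.residue_mass() - hexose,
                    species.glycan.residue_mass()]
        for extra in y_series:
            for z in (1, 2):
                mzs.append((pep_mass + extra + z * PROTON) / z)
                ints.append(scale * (0.3 + 0.4 * rng.random()))
    mz = np.array(mzs)
    inten = np.array(ints)
    sel = (mz >= settings.ms2_mz_start) & (mz <= settings.ms2_mz_stop)
    mz, inten = mz[sel], inten[sel]
    n_noise = 10
    mz = np.concatenate([mz, rng.uniform(settings.ms2_mz_start,
                                         settings.ms2_mz_stop, n_noise)])
    inten = np.concatenate([inten, rng.exponential(
        settings.noise_level * scale * 1e-3 + 1e-9, n_noise)])
    order = np.argsort(mz)
    return mz[order], inten[order]


def _glycan_ms2(comp: GlycanComposition, settings: SimulatorSettings, rng,
                precursor_intensity: float) -> tuple[np.ndarray, np.ndarray]:
    scale = 0.2 * precursor_intensity
    mzs, ints = [], []
    seen = set()
    for _label, mz in fragment_ions(comp):
        key = round(mz, 4)
        if key in seen:
            continue
        seen.add(key)
        mzs.append(mz)
        ints.append(scale * (0.2 + 0.8 * rng.random()))
    mz = np.array(mzs)
    inten = np.array(ints)
    sel = (mz >= settings.ms2_mz_start) & (mz <= settings.ms2_mz_stop)
    mz, inten = mz[sel], inten[sel]
    order = np.argsort(mz)
    return mz[order], inten[order]


def _run_lcms(species: list, settings: SimulatorSettings, name: str,
              truth: dict, ms2_builder) -> RawRun:
    """Shared LC-MS/MS acquisition loop with IDA precursor selection."""
    rng = np.random.default_rng(settings.seed)
    sp_mz = np.array([s.mz for s in species])
    sp_rt = np.array([s.rt for s in species])
    sp_ab = np.array([s.abundance for s in species])
    sp_z = np.array([s.charge for s in species])

    run = RawRun(name=name, truth=truth)
    scan_id = 0
    exclusion: dict[int, float] = {}
    t = 0.0
    sig = settings.elution_sigma_s
    while t <= settings.run_length_s:
        window = np.abs(sp_rt - t) < 4 * sig
        idx = np.nonzero(window)[0]
        chrom = np.exp(-0.5 * ((sp_rt[idx] - t) / sig) ** 2)
        inten = sp_ab[idx] * chrom * rng.lognormal(0.0, settings.jitter, idx.shape)
        noise_mz = rng.uniform(settings.mz_start, settings.mz_stop,
                               settings.n_noise_peaks)
        noise_int = rng.exponential(
            settings.noise_level * settings.base_intensity
            * settings.noise_scale_frac + 1e-9,
            settings.n_noise_peaks)
        mz = np.concatenate([sp_mz[idx], noise_mz])
        inten_all = np.concatenate([inten, noise_int])
        order = np.argsort(mz)
        scan_id += 1
        run.spectra.append(RawSpectrum(scan_id, 1, t, mz[order], inten_all[order]))

        # IDA: top-N eligible signal precursors, charge-filtered, not excluded
        eligible = [(inten[k], idx[k]) for k in range(len(idx))
                    if (settings.ida_charge_min <= sp_z[idx[k]] <= settings.ida_charge_max
                        and inten[k] >= settings.ida_min_intensity)]
        eligible.sort(key=lambda p: -p[0])
        picked = 0
        for prec_int, si in eligible:
            if picked >= settings.ida_top_n:
                break
            key = int(round(sp_mz[si] * 100))
            if exclusion.get(key, -1.0) > t:
                continue
            exclusion[key] = t + settings.ida_exclusion_s
            picked += 1
            mz2, int2 = ms2_builder(species[si], rng, prec_int)
            scan_id += 1
            run.spectra.append(RawSpectrum(scan_id, 2, t + 0.01 * picked,
                                           mz2, int2,
                                           precursor_mz=sp_mz[si],
                                           precursor_charge=int(sp_z[si])))
        t += settings.cycle_s
    return run


def simulate_digest_run(model: IgGModel,
                        settings: SimulatorSettings | None = None) -> RawRun:
    """Tryptic-digest LC-MS/MS run with IDA precursor selection.

    Peptide retention follows a scaled Kyte-Doolittle hydrophobicity mapped
    onto the gradient; apex intensities split across modified forms per the
    model's fractions; glycopeptide MS2 spectra carry oxonium and Y-series
    ions on top of a damped backbone ladder.
    """
    settings = settings or digest_settings()
    rng = np.random.default_rng(settings.seed + 1)  # layout rng (RTs, abundances)
    species: list[_Species] = []
    truth_peptides: dict[str, dict] = {}
    for chain_name in ("heavy", "light"):
        seq = model.chain(chain_name)
        for pep in digest(seq, settings.max_missed, chain=chain_name):
            if len(pep.sequence) < 2:
                continue
            base_ab = (settings.base_intensity * rng.lognormal(0.0, 0.4)
                       * (0.15 if pep.missed_cleavages else 1.0))
            rt = _peptide_rt(pep.sequence, settings, rng)
            forms = _digest_forms(model, pep)
            key = f"{chain_name}:{pep.start}-{pep.end}"
            truth_forms: dict[str, float] = {}
            for mods, gly, frac in forms:
                form = PeptideForm(pep, mods)
                label = form.mod_string() + (f"+glycan:{gly.label}" if gly else "")
                truth_forms[label] = truth_forms.get(label, 0.0) + frac
                mass = chain_mass(pep.sequence, "mono", [(s, 1) for s, _ in mods])
                if gly is not None:
                    mass += gly.residue_mass()
                for z, zw in _charge_split(len(pep.sequence)):
                    mz = mz_from_mass(mass, z)
                    if not settings.mz_start <= mz <= settings.mz_stop:
                        continue
                    species.append(_Species(form, gly, z, mz, rt,
                                            base_ab * frac * zw, frac))
            if truth_forms:
                truth_peptides[key] = {
                    "sequence": pep.sequence,
                    "missed_cleavages": pep.missed_cleavages,
                    "forms": truth_forms,
                }
    truth = {
        "level": "digest",
        "peptides": truth_peptides,
        "heavy_pyroglu_fraction": model.heavy_pyroglu_fraction,
        "light_pyroglu_fraction": model.light_pyroglu_fraction,
        "glycan_fractions": {g.label: f for g, f in model.glycan_profile},
        "true_sequences": sorted({s.form.peptide.sequence for s in species}),
        "glycopeptide_precursors": {
            f"{s.glycan.label}/{s.charge}+": s.mz
            for s in species if s.glycan is not None},
    }
    return _run_lcms(species, settings, "digest", truth,
                     lambda sp, rng_, pi: _peptide_ms2(sp, settings, rng_, pi))


# ----------------------------------------------------------- free glycan run


@dataclass
class _GlycanSpecies:
    composition: GlycanComposition
    charge: int
    mz: float
    rt: float
    abundance: float
    isomer: int

    # attribute names shared with _Species for the acquisition loop
    @property
    def form(self):  # pragma: no cover - interface shim
        return None


def default_glycan_profile() -> list[tuple[GlycanComposition, float, int]]:
    """A realistic released-glycan profile for a CHO IgG1: 14 compositions.

    Dominated by G0F and G1F; truncated, afucosylated, high-mannose and
    sialylated species in the low-percent range; isomer counts reflect
    PGC-type separations (several peaks per composition).
    """
    entries = [
        ("G0F", 0.73, 2), ("G1F", 0.18, 2), ("G2F", 0.02, 1),
        ("G0", 0.015, 1), ("G1", 0.01, 1), ("G0F-GlcNAc", 0.012, 4),
        ("G1F-GlcNAc", 0.008, 5), ("Man5", 0.01, 1), ("G0-GlcNAc", 0.005, 1),
        ("Man6", 0.004, 1), ("G2", 0.003, 1), ("A1F", 0.002, 1),
        ("Man7", 0.0005, 1), ("A2F", 0.0005, 1),
    ]
    return [(glycan(n), f, k) for n, f, k in entries]


def simulate_glycan_run(profile: list[tuple[GlycanComposition, float, int]]
                        | None = None,
                        settings: SimulatorSettings | None = None) -> RawRun:
    """Free N-glycan LC-MS/MS run with retention-separated isomers.

    Each composition elutes as ``isomer_count`` chromatographic peaks sharing
    one m/z (doubly charged; triply charged above ~2 kDa); MS2 spectra carry
    glycosidic B/Y fragments including the oxonium markers.
    """
    profile = profile if profile is not None else default_glycan_profile()
    settings = settings or glycan_settings()
    total = sum(f for _, f, _ in profile)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"profile fractions sum to {total}, not 1")
    for _, _, k in profile:
        if k < 1:
            raise ValueError("isomer_count must be >= 1")

    species: list[_GlycanSpecies] = []
    truth_entries = []
    for idx, (comp, frac, n_isomers) in enumerate(profile):
        free = comp.free_mass()
        charges = [(2, 1.0)] if free < 2000 else [(2, 0.7), (3, 0.3)]
        base_rt = settings.gradient_start_s + 30.0 + (idx % 12) * 60.0
        weights = np.array([0.65 ** i for i in range(n_isomers)])
        weights = weights / weights.sum()
        for i in range(n_isomers):
            rt = base_rt + i * 48.0
            for z, zw in charges:
                mz = mz_from_mass(free, z)
                if not settings.mz_start <= mz <= settings.mz_stop:
                    continue
                species.append(_GlycanSpecies(
                    comp, z, mz, rt,
                    settings.base_intensity * frac * weights[i] * zw, i))
        truth_entries.append({"composition": comp.label,
                              "counts": comp.counts,
                              "fraction": frac, "isomers": n_isomers,
                              "precursor_2plus": mz_from_mass(free, 2)})
    truth = {"level": "glycan", "profile": truth_entries}
    return _run_lcms(species, settings, "free_glycans", truth,
                     lambda sp, rng_, pi: _glycan_ms2(sp.composition, settings,
                                                      rng_, pi))
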