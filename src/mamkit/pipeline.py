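"""Workflow orchestration: the four characterization levels from one config.

Levels: (1) intact mass +- PNGase, (2) reduced chains +- PNGase, (3) tryptic
peptide mapping with PTM quantification and glycopeptides, (4) free N-glycans.
Each level is a thin function over the analysis modules; ``run_pipeline``
executes whichever levels the config provides inputs for, writes per-level
CSV artifacts, and assembles the cross-level glycan comparison table.  Every
threshold applied is logged, and reruns with the same inputs and seed are
deterministic.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import deconvolution as decon
from . import glycans as glycan_mod
from . import io as _io
from . import masschem, peptides, proteoform

logger = logging.getLogger("mamkit")

DEFAULT_LIBRARY = [masschem.glycan(n) for n in ("G0F", "G1F", "G2F", "G0", "G1")]


@dataclass
class PipelineConfig:
    """Inputs and settings for a full multi-attribute run."""

    chains_fasta: str
    output_dir: str = "mam_out"
    intact_run: str | None = None
    intact_pngase_run: str | None = None
    reduced_run: str | None = None
    reduced_pngase_run: str | None = None
    digest_run: str | None = None
    glycan_run: str | None = None
    seed: int = 0
    tolerance_da: float = 5.0
    sn_min: float = 20.0
    rel_min: float = 1.0
    quant_threshold_pct: float = 1.0
    fdr_q: float = 0.05
    glycan_ppm: float = 10.0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat key=value config with [inputs], [output] and [settings] sections."""
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise FileNotFoundError(path)
        inputs = parser["inputs"] if "inputs" in parser else {}
        settings = parser["settings"] if "settings" in parser else {}
        output = parser["output"] if "output" in parser else {}
        cfg = cls(
            chains_fasta=inputs.get("chains_fasta", ""),
            output_dir=output.get("dir", "mam_out"),
            intact_run=inputs.get("intact_run"),
            intact_pngase_run=inputs.get("intact_pngase_run"),
            reduced_run=inputs.get("reduced_run"),
            reduced_pngase_run=inputs.get("reduced_pngase_run"),
            digest_run=inputs.get("digest_run"),
            glycan_run=inputs.get("glycan_run"),
            seed=int(settings.get("seed", 0)),
            tolerance_da=float(settings.get("tolerance_da", 5.0)),
            sn_min=float(settings.get("sn_min", 20.0)),
            rel_min=float(settings.get("rel_min", 1.0)),
            quant_threshold_pct=float(settings.get("quant_threshold_pct", 1.0)),
            fdr_q=float(settings.get("fdr_q", 0.05)),
            glycan_ppm=float(settings.get("glycan_ppm", 10.0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [self.chains_fasta, self.intact_run, self.intact_pngase_run,
                 self.reduced_run, self.reduced_pngase_run, self.digest_run,
                 self.glycan_run]
        for p in paths:
            if p and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        if not any([self.intact_run, self.reduced_run, self.digest_run,
                    self.glycan_run]):
            raise ValueError("no level inputs provided")


@dataclass
class ComparisonReport:
    """Per-glycan relative % across the levels that quantify glycosylation."""

    table: pd.DataFrame
    levels_run: list[str] = field(default_factory=list)
    levels_skipped: list[str] = field(default_factory=list)


# ------------------------------------------------------------- level drivers


def analyze_protein_level(run, run_pngase, light: str, heavy: str,
                          library, composition: str,
                          dsettings: decon.DeconvolutionSettings | None = None,
                          tolerance_da: float = 5.0,
                          sn_min: float = 20.0, rel_min: float = 1.0,
                          quant_threshold_pct: float = 1.0) -> dict:
    """Deconvolve, match and quantify one protein-level run (intact or heavy/light).

    ``composition`` selects the candidate space; for reduced runs use
    ``heavy``+``light`` via :func:`analyze_reduced_level` instead.
    """
    dsettings = dsettings or decon.DeconvolutionSettings()
    recon = decon.reconstruct_run(run, dsettings)
    logger.info("pick_mass_peaks thresholds: S/N >= %g, relative >= %g%%",
                sn_min, rel_min)
    peaks = decon.pick_mass_peaks(recon, sn_min, rel_min)
    msettings = proteoform.MatchSettings(tolerance_da=tolerance_da)
    logger.info("match tolerance: +-%g Da", tolerance_da)
    candidates = proteoform.enumerate_candidates(
        light, heavy, library, msettings, composition=composition,
        include_deglycosylated=run_pngase is not None)
    matches, unmatched = proteoform.match_masses(peaks, candidates, msettings)
    out = {"recon": recon, "peaks": peaks, "matches": matches,
           "unmatched": unmatched}
    glyco = [m for m in matches
             if m.candidate.glycans and "deglycosylated" not in m.candidate.glycans]
    if glyco:
        logger.info("glycoform quant threshold: > %g%% of base area",
                    quant_threshold_pct)
        out["glycoform_quant"] = proteoform.relative_glycoform_quant(
            glyco, quant_threshold_pct)
    if run_pngase is not None:
        recon2 = decon.reconstruct_run(run_pngase, dsettings)
        peaks2 = decon.pick_mass_peaks(recon2, sn_min, rel_min)
        sites = 2 if composition == "intact" else 1
        out["pngase_peaks"] = peaks2
        out["pngase_shift"] = proteoform.pngase_shift_analysis(
            peaks, peaks2, library, sites=sites, tolerance_da=tolerance_da)
    return out


def split_peaks_by_chain(peaks, boundary_da: float = 30000.0):
    """Partition reduced-run mass peaks into (light, heavy) by a mass boundary."""
    light = [p for p in peaks if p.mass < boundary_da]
    heavy = [p for p in peaks if p.mass >= boundary_da]
    return light, heavy


def analyze_reduced_level(run, run_pngase, light: str, heavy: str, library,
                          dsettings=None, tolerance_da: float = 5.0,
                          sn_min: float = 20.0, rel_min: float = 1.0,
                          quant_threshold_pct: float = 1.0) -> dict:
    """Reduced-chain analysis: both chains deconvolved from one run.

    The light chain is matched unglycosylated; the heavy chain carries the
    single-site glycan profile and drives the PNGase differential.
    """
    dsettings = dsettings or decon.DeconvolutionSettings()
    recon = decon.reconstruct_run(run, dsettings)
    peaks = decon.pick_mass_peaks(recon, sn_min, rel_min)
    light_peaks, heavy_peaks = split_peaks_by_chain(peaks)
    msettings = proteoform.MatchSettings(tolerance_da=tolerance_da)
    cands = (proteoform.enumerate_candidates(light, heavy, library, msettings,
                                             composition="heavy",
                                             include_deglycosylated=run_pngase is not None)
             + proteoform.enumerate_candidates(light, heavy, [], msettings,
                                               composition="light"))
    matches, unmatched = proteoform.match_masses(peaks, cands, msettings)
    heavy_glyco = [m for m in matches
                   if m.candidate.composition == "heavy" and m.candidate.glycans
                   and "deglycosylated" not in m.candidate.glycans]
    out = {"recon": recon, "peaks": peaks, "matches": matches,
           "unmatched": unmatched, "light_peaks": light_peaks,
           "heavy_peaks": heavy_peaks}
    if heavy_glyco:
        out["glycoform_quant"] = proteoform.relative_glycoform_quant(
            heavy_glyco, quant_threshold_pct)
    if run_pngase is not None:
        recon2 = decon.reconstruct_run(run_pngase, dsettings)
        peaks2 = decon.pick_mass_peaks(recon2, sn_min, rel_min)
        light2, heavy2 = split_peaks_by_chain(peaks2)
        out["pngase_shift_heavy"] = proteoform.pngase_shift_analysis(
            heavy_peaks, heavy2, library, sites=1, tolerance_da=tolerance_da)
        if light_peaks and light2:
            out["pngase_shift_light"] = proteoform.pngase_shift_analysis(
                light_peaks, light2, library, sites=1, tolerance_da=tolerance_da)
    return out


def analyze_peptide_level(run, light: str, heavy: str, library,
                          fdr_q: float = 0.05,
                          panel=None) -> dict:
    """Peptide mapping: search, FDR, coverage, PTM quant, glycopeptides."""
    chains = {"light": light, "heavy": heavy}
    psms = peptides.search(run, chains, panel)
    logger.info("FDR threshold: q <= %g", fdr_q)
    accepted = peptides.fdr_filter(psms, fdr_q)
    coverage = {name: peptides.sequence_coverage(accepted, seq, name)
                for name, seq in chains.items()}
    reports, per_form = peptides.modification_quant(accepted, run)
    digest_peps = [p for name, seq in chains.items()
                   for p in peptides.digest(seq, 1, chain=name)
                   if len(p.sequence) >= 2]
    assignments, glyco_quant = peptides.detect_glycopeptides(
        run, digest_peps, library)
    return {"psms": psms, "accepted": accepted, "coverage": coverage,
            "modification_report": reports, "per_form": per_form,
            "glycopeptide_assignments": assignments,
            "glycopeptide_quant": glyco_quant}


def analyze_glycan_level(run, ppm: float = 10.0) -> dict:
    """Free N-glycan identification, isomer counting and quantification."""
    settings = glycan_mod.CompositionSearchSettings(ppm=ppm)
    logger.info("composition search tolerance: %g ppm", ppm)
    assignments = glycan_mod.identify_glycans(run, settings)
    quant = glycan_mod.relative_glycan_quant(assignments) if assignments else None
    return {"assignments": assignments, "quant": quant}


# ------------------------------------------------------------------ pipeline


def run_pipeline(config: PipelineConfig) -> tuple[ComparisonReport, dict]:
    """Execute all configured levels and assemble the comparison report.

    Missing level inputs skip that level with a log entry; per-level CSVs and
    the comparison table land in ``config.output_dir``.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    light, heavy = _io.read_chains(config.chains_fasta)
    library = DEFAULT_LIBRARY
    artifacts: dict = {}
    levels_run, levels_skipped = [], []

    def _load(path):
        return _io.read_run(path) if path else None

    if config.intact_run:
        levels_run.append("intact")
        res = analyze_protein_level(
            _load(config.intact_run), _load(config.intact_pngase_run),
            light, heavy, library, "intact",
            tolerance_da=config.tolerance_da, sn_min=config.sn_min,
            rel_min=config.rel_min,
            quant_threshold_pct=config.quant_threshold_pct)
        artifacts["intact"] = res
        _write_matches_csv(res["matches"], out_dir / "intact_proteoforms.csv")
    else:
        levels_skipped.append("intact")
        logger.info("level skipped: intact (no input)")

    reduced_quant = None
    if config.reduced_run:
        levels_run.append("reduced")
        res = analyze_reduced_level(
            _load(config.reduced_run), _load(config.reduced_pngase_run),
            light, heavy, library,
            tolerance_da=config.tolerance_da, sn_min=config.sn_min,
            rel_min=config.rel_min,
            quant_threshold_pct=config.quant_threshold_pct)
        artifacts["reduced"] = res
        _write_matches_csv(res["matches"], out_dir / "reduced_proteoforms.csv")
        reduced_quant = res.get("glycoform_quant")
        if reduced_quant is not None:
            reduced_quant.to_csv(out_dir / "reduced_glycoforms.csv", index=False)
    else:
        levels_skipped.append("reduced")
        logger.info("level skipped: reduced (no input)")

    glycopeptide_quant = None
    if config.digest_run:
        levels_run.append("peptides")
        res = analyze_peptide_level(_load(config.digest_run), light, heavy,
                                    library, fdr_q=config.fdr_q)
        artifacts["peptides"] = res
        _write_psm_csv(res["accepted"], out_dir / "psms.csv")
        pd.DataFrame([{"modification": r.modification,
                       "n_modified_peptides": r.n_modified_peptides,
                       "relative_abundance_pct": r.relative_abundance}
                      for r in res["modification_report"]]).to_csv(
            out_dir / "modifications.csv", index=False)
        glycopeptide_quant = res["glycopeptide_quant"]
        if glycopeptide_quant is not None and not glycopeptide_quant.empty:
            glycopeptide_quant.to_csv(out_dir / "glycopeptides.csv", index=False)
    else:
        levels_skipped.append("peptides")
        logger.info("level skipped: peptides (no input)")

    glycan_quant = None
    if config.glycan_run:
        levels_run.append("glycans")
        res = analyze_glycan_level(_load(config.glycan_run), ppm=config.glycan_ppm)
        artifacts["glycans"] = res
        glycan_quant = res["quant"]
        if glycan_quant is not None:
            glycan_quant.to_csv(out_dir / "free_glycans.csv", index=False)
    else:
        levels_skipped.append("glycans")
        logger.info("level skipped: glycans (no input)")

    table = _comparison_table(reduced_quant, glycopeptide_quant, glycan_quant)
    table.to_csv(out_dir / "comparison.csv", index=False)
    report = ComparisonReport(table, levels_run, levels_skipped)
    return report, artifacts


def _comparison_table(reduced, glycopeptide, free) -> pd.DataFrame:
    """Fig-8-style cross-level glycan comparison (percent per level)."""
    rows: dict[str, dict] = {}

    def add(df, key_col, column):
        if df is None or df.empty:
            return
        for _, r in df.iterrows():
            entry = rows.setdefault(r[key_col], {})
            entry[column] = entry.get(column, 0.0) + r["percent"]

    add(reduced, "glycoform", "reduced_pct")
    add(glycopeptide, "glycan", "glycopeptide_pct")
    add(free, "composition", "free_glycan_pct")
    out = pd.DataFrame(
        [{"glycan": k, **v} for k, v in rows.items()],
        columns=["glycan", "reduced_pct", "glycopeptide_pct", "free_glycan_pct"])
    return out


def _write_matches_csv(matches, path) -> None:
    pd.DataFrame([{
        "peak_mass": m.peak.mass, "candidate": m.candidate.label,
        "error_da": m.error_da, "error_ppm": m.error_ppm,
        "relative_abundance_pct": m.peak.relative_abundance,
        "ambiguity_group": "|".join(c.label for c in m.ambiguity_group),
    } for m in matches]).to_csv(path, index=False)


def _write_psm_csv(psms, path) -> None:
    pd.DataFrame([{
        "chain": p.form.peptide.chain, "start": p.form.peptide.start,
        "end": p.form.peptide.end, "sequence": p.form.peptide.sequence,
        "mods": p.form.mod_string(), "charge": p.charge,
        "precursor_mz": p.precursor_mz, "score": p.score,
        "q_value": p.q_value,
    } for p in psms]).to_csv(path, index=False)
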