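# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `mamkit`. It is written for users who need to judge what the
package's results — and its passing tests — do and do not establish.

## The antibody model

An IgG is modelled as two identical light and two identical heavy chains.
The bundled default (`IgGModel.default()`) is a **synthetic, non-proprietary
IgG1-like pair** (`mamkit/data/igg1_synthetic.fasta`): germline-style
variable domains on IgG1/kappa constant regions. It is not any real
therapeutic's sequence; it exists so that the pipeline has a realistic,
shareable substrate. Its deliberate features:

* the heavy chain starts with Q (so N-terminal pyroglutamate, −17.027 Da,
  can form) and the light chain with E (−18.011 Da variant);
* the Fc tryptic peptide EEQYNSTYR is present and carries the single
  N-glycosylation sequon (N-X≠P-S/T); the default glycan profile is
  G0F/G1F/G2F at 78.1/21.7/0.3 % (normalized to sum to 1), the dominant
  biantennary pattern of a CHO-produced IgG1;
* terminal-PTM defaults: 95 % heavy-chain pyroGlu, 1 % light-chain pyroGlu;
  formic-acid adducts (+46.03 Da) on 5 % of the protein signal; a small
  hot-spot panel (NG-motif deamidation 30 %, Trp oxidation 3 %, Met
  oxidation 1.2 %, a light-chain Gln deamidation 7 %);
* disulfides: 16 in the assembled antibody; DTT reduction cleaves only the
  4 inter-chain bonds, so reduced chains keep their intra-chain bonds
  (2 light, 4 heavy), each worth −2 H.

## Mass scales

Protein-level comparisons (intact, reduced) use **average masses**: at a
QTOF resolution of 2500 the isotope envelope of a 23–147 kDa species is
unresolved and the measured peak sits at the envelope centroid.
Peptide-level and glycan-level comparisons use **monoisotopic masses**.
Every mass function takes `mass_type` explicitly. The bundled residue,
monosaccharide and constant tables are cross-checked in the test suite
against an independent reference (pyteomics' elemental compositions) to
1e-4 Da (monoisotopic) and 0.01 Da (average).

One consequence worth knowing: the G0F PNGase shift is 1443.55 Da on the
monoisotopic scale but 1444.35 Da on the average scale. A reduced-chain
measurement (average scale) therefore reads ≈1444.3 Da; glycan inference
matches shifts against monoisotopic deltas with the protein-level ±5 Da
tolerance, which absorbs the scale difference.

## Synthetic runs

The generator emulates a QTOF acquiring centroided data. Species are sticks:
one (m/z, intensity) point per (proteoform, charge) at
`(M_avg + z·1.00728)/z`, with no isotope structure (unresolved at R = 2500 at
the protein level; a documented simplification at the peptide level). The
ESI charge envelope is Gaussian over integer charge, centred where the
species reaches the instrument's typical m/z (2728 for intact, ~1400 for
reduced chains) with σ = 8 % of the centre charge; a vanishing width
collapses to a single charge state.

Acquisition parameters follow the published workflow's values: protein-level
TOF-MS at 1 s/scan (60 scans simulated per run); the digest run as IDA with
a 2.3 s cycle, top-40 precursor selection, charge 2–5, 125-count threshold
and 12 s dynamic exclusion over a ~55 min gradient; the glycan run with a
2.25 s cycle, top-20, charge 2–4, 200-count threshold over a ~15 min ramp.
Peptide retention is a scaled Kyte–Doolittle hydrophobicity mapped linearly
onto the gradient (plus a small seeded jitter); glycan isomers are fixed
retention offsets (48 s) at a shared m/z with geometrically decreasing
abundances. MS2 content: full b/y ladders for peptides (damped backbone plus
strong oxonium ions and a Y-series for glycopeptides); structure-free
glycosidic B/Y ions for free glycans.

Noise is additive baseline (uniform m/z, exponential intensities) plus
multiplicative 2 % lognormal jitter on peak heights, both seeded. The
baseline scale is 1e-5 of the base intensity at the protein level and 1e-4
in the LC-MS/MS runs — chosen to match the dynamic range the published
workflow demonstrates (0.3 % species quantified at the protein level),
and fixed before any recovery tests were run. Identical (model, settings,
seed) gives byte-identical runs; every run carries a ground-truth sidecar
(species, masses, fractions, per-peptide form fractions, glycopeptide
precursors) used by the parameter-recovery tests.

**Cluster apex truth.** Terminal-PTM and adduct satellites sit 17–46 Da from
their parent — partially merged at a protein-level mass FWHM of M/2500
(≈20 Da at 50 kDa, ≈59 Da at 147 kDa). What any reconstruction measures for
such a cluster is the local maximum of the resolution-blurred mixture, not
the modal species mass nor the abundance centroid. The truth ledger
therefore records, per glycoform group, the apex of the Gaussian-blurred
species mixture; recovery bounds are stated against that apex.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: isotope fine structure and deamidation
isotope overlap, chimeric MS2 spectra, charge-state coalescence, retention
drift, ion-suppression matrix effects, in-source fragmentation, and
profile-mode peak shapes.

## Zero-charge reconstruction

The vendor "reconstruct" step is replaced by a defined, deterministic
transform run at the published parameter values (input window 1000–4000 m/z,
output 10,000–200,000 Da, 1 Da step, resolution 2500, 50 scans combined,
smoothing 0.9 grid steps, 20 refinement iterations):

1. the 50 most intense MS1 scans are intensity-summed on a 0.02 m/z binning
   (intensity-weighted positions, so identical scans add without drift);
2. the stick spectrum is rasterized with Gaussian peak shapes of
   FWHM = m/z / 2500 on a 0.01 m/z grid;
3. for each candidate mass M on the output grid,
   `score(M) = Σ_z I(mz(M, z)) / n(M) · (n_eff(M)/n(M))²`, where the sum
   runs over the searched charges (5–80), `n(M)` counts charges whose m/z
   lies in the input window (tapered over 25 m/z at the window edges so the
   count is a smooth function of mass), and `n_eff` is the inverse
   participation ratio of the per-charge contributions. The 1/n term
   suppresses the M/2 and 2M harmonics that alignment at every other charge
   produces; the smooth participation term suppresses single-charge
   coincidence artifacts without distorting the relative heights of species
   sharing one envelope;
4. Gaussian smoothing with σ = 0.9 grid steps (the published smoothing
   setting, interpreted as grid points since its units are not standard).

Peak picking estimates the noise floor as 1.4826 × MAD of the trace after
subtracting a rolling-median (1001-point) baseline — charge summation leaves
a smooth coincidence pedestal under the whole axis that would otherwise
inflate the floor. Local maxima above S/N ≥ 20 and ≥ 1 % of the base peak
are kept; areas are trapezoids valley-to-valley; apexes are refined on a
step/10 local grid (three refinement passes, bounded by the `iterations`
setting — the vendor's "iterations = 20" is not publicly specified, so the
refinement budget is this implementation's declared stand-in). Finally,
integer-submultiple harmonics (a peak at M/k whose k-fold mass carries a
substantially taller peak, k = 2–10) are removed; genuine co-analysed
species in this domain never sit at integer mass ratios. Ties in apex
location break toward lower mass.

Measured accuracy on synthetic data: single-species apex error ≤ 0.05 Da
over 20–160 kDa; base-peak error ≈ 0.1 Da on the full intact mixture;
glycoform fractions recovered within ~1 percentage point at the reduced
level and ~2 points (pair-level) at the intact level. Rational-harmonic
residues (e.g. 4M/3) above ~1 % relative can survive peak picking; they are
rejected downstream by candidate matching.

## Proteoform assignment

Candidates are the Cartesian product of chain composition × unordered glycan
pair (intact) or single glycan (heavy chain) × N-terminal pyroglutamate
count × 0–2 formic-acid adducts, matched within ±5 Da. All in-tolerance
candidates form the ambiguity group; the primary is the smallest |error|
with ties toward lower mass. G0F/G2F and G1F/G1F have identical composition
mass — the ambiguity is reported, never resolved silently, and at the
intact level quantification stays at pair level. The > 1 % quantification
threshold applies to peak area relative to the base peak before
normalization; reported percentages sum to exactly 100. The reduced-level
analysis driver lowers the picking/quant thresholds to 0.1 % to expose the
minor G2F species; at the default simulated noise it still falls below the
S/N gate and reports 0.

## Peptide identification and quantification

Scoring is the matched fraction of the theoretical b/y ladder (charges 1–2,
0.02 Da fragment tolerance) among candidates within 10 ppm precursor
tolerance; the proprietary engine score it replaces is not reproducible, and
a transparent ratio is oracle-testable. Decoys are pseudo-reversed peptides
(C-terminal residue fixed) searched identically; "95 % confidence" maps to
target–decoy q ≤ 0.05 (monotonized decoy/target ratio). Variable
modifications are bounded at 2 per peptide (configurable);
carbamidomethyl is fixed on Cys and additionally searched as an
over-alkylation artifact on Lys and peptide N-termini. Fixed Cys
alkylation is excluded from the modification report, which lists
Table-style rows (`Deamidated N`, `Carbamidomethyl N-term`, ...).

Modification quantification follows apex intensities: each accepted form's
XIC apex (3-point moving mean, ±0.5 min around the identification, ±25 ppm)
is extracted; a base peptide's modified percentage is the apex share of
forms carrying the modification; the per-modification report aggregates
across base peptides containing at least one applicable site, weighted by
each base peptide's apex total. This aggregation across base peptides is a
declared interpretation — per-site fractions (what the recovery tests pin)
are exact, while the pooled per-modification percentage depends on the
weighting convention.

Glycopeptides: MS2 scans containing ≥ 1 oxonium marker (theoretical values
204.0867 / 366.1395 / 292.1027, 0.02 m/z tolerance; printed vendor values
are rounded) are tested for precursor = sequon peptide + glycan residue mass
(charges 2–3, 10 ppm), ranked by |ppm|; glycoforms are quantified by summed
precursor XIC areas across charge states and backbone peptides (missed
cleavage forms of the sequon peptide contribute to the same glycan).

## Free glycan identification

Composition search is exhaustive over Hex ≤ 12, HexNAc ≤ 8, dHex ≤ 4,
NeuAc ≤ 4, NeuGc ≤ 2 (covering all bundled structures with margin) at
10 ppm on free (reducing, unlabelled) monoisotopic masses — release by
PNGase F without fluorescent labelling, so free mass = residue sum + water.
Exactly isobaric compositions exist (NeuAc + Hex = NeuGc + dHex to the
microdalton); candidates within tolerance are arbitrated by the matched
fraction of their own B/Y ladder, so MS2 evidence decides. Isomer counting
takes local maxima of the 3-point-smoothed XIC at ≥ 5 % of its base peak
(no published criterion exists; 5 % separates real isomer peaks from
baseline at the simulated noise level). Quantification pools all charge
states and isomers per composition and sums to exactly 100 %.

## Pipeline

`run_pipeline` executes whichever of the four levels have configured inputs,
logs every threshold it applies, writes per-level CSVs and the cross-level
glycan comparison table, and is byte-deterministic for fixed inputs. The
config format is flat `key = value` INI with `[inputs]`, `[output]` and
`[settings]` sections. Runs are read/written as a diffable TSV peak-list
dialect (exact float round-trip) or as minimal centroided mzML (64-bit float
arrays; the reader also accepts 32-bit and zlib-compressed arrays).

## Problem sizes

Default simulated runs: 60 TOF-MS scans per protein-level run; ~1570 MS1 +
~650 MS2 scans for the digest run (full 62 min acquisition); ~620 MS1 +
~46 MS2 scans for the glycan run. The full four-level analysis, including
all simulations, completes in well under a minute on one CPU.

## Known limitations

* The reconstruction is a direct charge summation, not maximum entropy;
  rational-harmonic artifacts above ~1 % relative abundance can appear in
  the picked-peak list (they are never matched to candidates).
* PSM scoring has no posterior error model and no site-localization score;
  positional isomers of a modification are not distinguished.
* Intact-level pair ambiguity (G0F/G2F vs G1F/G1F) is inherent to the mass
  scale and deliberately left unresolved.
* The IDA model is cycle-based top-N with an exclusion list; no real-time
  scheduling, no chimeric spectra.
* Glycan structural/linkage isomer identity is out of scope: isomer counting
  is purely chromatographic.
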