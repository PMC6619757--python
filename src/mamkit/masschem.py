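"""Exact-mass bookkeeping for antibody chains, glycans, modifications and adducts.

Every downstream level of the pipeline (intact mass, reduced chains, peptide
mapping, free glycans) consumes the tables and arithmetic defined here.  Two
mass scales are carried throughout:

``mono``
    monoisotopic masses, used wherever isotope envelopes are resolved
    (peptides, glycopeptides, released glycans);
``average``
    average masses, used for intact and reduced protein measurements where a
    QTOF at resolution ~2500 sees only the unresolved envelope centroid.

The bundled tables (amino-acid residues, monosaccharide residues, small
constants, a modification panel and short-name glycan compositions) ship as
versioned TSV files under ``mamkit/data`` and are immutable after load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from types import MappingProxyType
from typing import Iterable, Literal, Mapping

MassType = Literal["mono", "average"]

_MONO_COL = {"mono": 0, "average": 1}


def _read_table(name: str) -> list[list[str]]:
    text = resources.files("mamkit.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


class MonomerTable:
    """Immutable residue/monosaccharide/constant mass table.

    Attributes map a symbol to a ``(monoisotopic, average)`` tuple of Da.
    """

    def __init__(self) -> None:
        aa = {r[0]: (float(r[1]), float(r[2])) for r in _read_table("amino_acids.tsv")}
        sugars = {r[0]: (float(r[1]), float(r[2])) for r in _read_table("monosaccharides.tsv")}
        consts = {r[0]: (float(r[1]), float(r[2])) for r in _read_table("constants.tsv")}
        for tab in (aa, sugars, consts):
            for key, (mono, avg) in tab.items():
                if mono <= 0 or avg <= 0:
                    raise ValueError(f"non-positive mass for {key!r}")
                if mono > avg + 1e-12:
                    raise ValueError(f"monoisotopic > average for {key!r}")
        self.amino_acids: Mapping[str, tuple[float, float]] = MappingProxyType(aa)
        self.monosaccharides: Mapping[str, tuple[float, float]] = MappingProxyType(sugars)
        self.constants: Mapping[str, tuple[float, float]] = MappingProxyType(consts)

    def aa_mass(self, residue: str, mass_type: MassType = "mono") -> float:
        try:
            return self.amino_acids[residue][_MONO_COL[mass_type]]
        except KeyError:
            raise KeyError(f"unknown amino-acid residue {residue!r}") from None

    def sugar_mass(self, name: str, mass_type: MassType = "mono") -> float:
        return self.monosaccharides[name][_MONO_COL[mass_type]]

    def constant(self, name: str, mass_type: MassType = "mono") -> float:
        return self.constants[name][_MONO_COL[mass_type]]


TABLE = MonomerTable()

PROTON = TABLE.constant("proton")
WATER_MONO = TABLE.constant("water", "mono")
WATER_AVG = TABLE.constant("water", "average")


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """An N-glycan composition as counts of the five common monosaccharides."""

    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    neuac: int = 0
    neugc: int = 0
    short_name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "dhex", "neuac", "neugc"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative monosaccharide count: {name}")

    @property
    def counts(self) -> tuple[int, int, int, int, int]:
        return (self.hex, self.hexnac, self.dhex, self.neuac, self.neugc)

    @property
    def total(self) -> int:
        return sum(self.counts)

    def residue_mass(self, mass_type: MassType = "mono") -> float:
        h, n, f, s, g = self.counts
        return (
            h * TABLE.sugar_mass("Hex", mass_type)
            + n * TABLE.sugar_mass("HexNAc", mass_type)
            + f * TABLE.sugar_mass("dHex", mass_type)
            + s * TABLE.sugar_mass("NeuAc", mass_type)
            + g * TABLE.sugar_mass("NeuGc", mass_type)
        )

    def free_mass(self, mass_type: MassType = "mono") -> float:
        """Mass of the released, unlabelled glycan (residues + water)."""
        return self.residue_mass(mass_type) + TABLE.constant("water", mass_type)

    def composition_string(self) -> str:
        parts = []
        for label, count in zip(("HexNAc", "Hex", "dHex", "NeuAc", "NeuGc"),
                                (self.hexnac, self.hex, self.dhex, self.neuac, self.neugc)):
            if count:
                parts.append(f"{label}{count}")
        return "".join(parts) or "empty"

    @property
    def label(self) -> str:
        return self.short_name or self.composition_string()

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.label


def _load_glycan_names() -> Mapping[str, GlycanComposition]:
    table: dict[str, GlycanComposition] = {}
    seen: dict[tuple, str] = {}
    for row in _read_table("glycan_names.tsv"):
        name = row[0]
        comp = GlycanComposition(hex=int(row[1]), hexnac=int(row[2]), dhex=int(row[3]),
                                 neuac=int(row[4]), neugc=int(row[5]), short_name=name)
        if comp.counts in seen:
            raise ValueError(f"glycan short-name table not bijective: {name} vs {seen[comp.counts]}")
        seen[comp.counts] = name
        table[name] = comp
    return MappingProxyType(table)


GLYCANS: Mapping[str, GlycanComposition] = _load_glycan_names()


def glycan(short_name: str) -> GlycanComposition:
    """Look up a bundled glycan composition by its short name (e.g. ``G0F``)."""
    try:
        return GLYCANS[short_name]
    except KeyError:
        raise KeyError(f"unknown glycan short name {short_name!r}; "
                       f"known: {', '.join(sorted(GLYCANS))}") from None


@dataclass(frozen=True)
class ModificationSpec:
    """A (de)modification: a signed mass delta plus its site specificity.

    ``targets`` tokens are residue letters, ``nterm`` (peptide/protein
    N-terminus on any residue) or ``nterm:X`` (N-terminus only when the first
    residue is X).
    """

    name: str
    delta_mono: float
    delta_avg: float
    targets: tuple[str, ...]
    max_per_peptide: int = 1

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"modification {self.name!r} has no targets")
        for d in (self.delta_mono, self.delta_avg):
            if d != d or d in (float("inf"), float("-inf")):
                raise ValueError(f"non-finite delta for {self.name!r}")

    def delta(self, mass_type: MassType = "mono") -> float:
        return self.delta_mono if mass_type == "mono" else self.delta_avg

    def applies_at(self, sequence: str, pos: int) -> bool:
        """Whether this modification can sit at 1-based position ``pos``.

        ``pos == 0`` denotes the N-terminus itself.
        """
        residue = sequence[0] if pos == 0 else sequence[pos - 1]
        for token in self.targets:
            if token == "nterm" and pos in (0, 1):
                return True
            if token.startswith("nterm:") and pos in (0, 1) and sequence[0] == token[6:]:
                return True
            if len(token) == 1 and pos >= 1 and residue == token:
                return True
        return False


def _load_modifications() -> Mapping[str, ModificationSpec]:
    table = {}
    for row in _read_table("modifications.tsv"):
        spec = ModificationSpec(
            name=row[0], delta_mono=float(row[1]), delta_avg=float(row[2]),
            targets=tuple(row[3].split(";")), max_per_peptide=int(row[4]),
        )
        table[spec.name] = spec
    return MappingProxyType(table)


MODIFICATIONS: Mapping[str, ModificationSpec] = _load_modifications()


def chain_mass(sequence: str,
               mass_type: MassType = "mono",
               mods: Iterable[tuple[ModificationSpec, int]] = (),
               n_disulfides: int = 0) -> float:
    """Neutral mass of a polypeptide chain.

    Sum of residue masses + one water, plus signed modification deltas, minus
    two hydrogens per disulfide bond.  An empty sequence yields the mass of
    water.  Unknown residue letters are rejected with their position.
    """
    if n_disulfides < 0:
        raise ValueError("n_disulfides must be >= 0")
    mass = TABLE.constant("water", mass_type)
    col = _MONO_COL[mass_type]
    aa = TABLE.amino_acids
    for i, residue in enumerate(sequence):
        try:
            mass += aa[residue][col]
        except KeyError:
            raise ValueError(f"unknown residue {residue!r} at position {i + 1}") from None
    for spec, count in mods:
        mass += count * spec.delta(mass_type)
    mass -= 2.0 * TABLE.constant("hydrogen", mass_type) * n_disulfides
    return mass


def glycan_mass(comp: GlycanComposition,
                state: Literal["residue", "free"] = "residue",
                mass_type: MassType = "mono") -> float:
    """Mass of a glycan composition, as attached residue or released free glycan."""
    if state == "residue":
        return comp.residue_mass(mass_type)
    if state == "free":
        return comp.free_mass(mass_type)
    raise ValueError(f"state must be 'residue' or 'free', got {state!r}")


def mz_from_mass(neutral_mass: float, z: int) -> float:
    """m/z of the [M + zH]^z+ ion."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + z * PROTON) / z


def mass_from_mz(mz: float, z: int) -> float:
    """Neutral mass from the m/z of an [M + zH]^z+ ion."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return mz * z - z * PROTON


def modification_delta(mod_name: str, count: int = 1,
                       mass_type: MassType = "mono") -> float:
    """Signed mass delta for ``count`` copies of a bundled modification."""
    if mod_name not in MODIFICATIONS:
        raise KeyError(f"unknown modification {mod_name!r}; "
                       f"known: {', '.join(sorted(MODIFICATIONS))}")
    return count * MODIFICATIONS[mod_name].delta(mass_type)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be > 0")
    return 1e6 * (observed - theoretical) / theoretical


# Diagnostic oxonium fragment ions of glycans/glycopeptides (singly charged).
# Theoretical values are used for matching; vendor printouts round them.
OXONIUM_HEXNAC = TABLE.sugar_mass("HexNAc") + PROTON          # 204.0867
OXONIUM_HEXHEXNAC = (TABLE.sugar_mass("HexNAc")
                     + TABLE.sugar_mass("Hex") + PROTON)      # 366.1395
OXONIUM_NEUAC = TABLE.sugar_mass("NeuAc") + PROTON            # 292.1027
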