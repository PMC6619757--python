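"""Run and sequence I/O: the TSV peak-list dialect, centroided mzML, FASTA.

The TSV dialect is deliberately diffable::

    #run <name>
    #scan <id> msLevel=<1|2> rt=<seconds> [precursor=<mz>/<z>]
    <m/z>\t<intensity>
    ...

Floats are written with Python's shortest round-tripping repr, so a
write/read cycle reproduces peak lists exactly.  mzML support is a
minimal centroided reader/writer pair (64-bit float binary arrays, with or
without zlib compression on read) built on lxml.
"""

from __future__ import annotations

import base64
import json
import struct
import zlib
from pathlib import Path

import numpy as np
from lxml import etree

from .containers import RawRun, RawSpectrum


# ---------------------------------------------------------------- TSV dialect

def write_tsv(run: RawRun, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#run {run.name}\n")
        for s in run.spectra:
            header = f"#scan {s.scan_id} msLevel={s.ms_level} rt={float(s.rt)!r}"
            if s.precursor_mz is not None:
                header += f" precursor={float(s.precursor_mz)!r}/{s.precursor_charge}"
            fh.write(header + "\n")
            for mz, inten in zip(s.mz.tolist(), s.intensity.tolist()):
                fh.write(f"{mz!r}\t{inten!r}\n")
    truth_path = path.with_suffix(path.suffix + ".truth.json")
    if run.truth is not None:
        truth_path.write_text(json.dumps(run.truth, indent=1, default=str))


def read_tsv(path: str | Path) -> RawRun:
    path = Path(path)
    run = RawRun(name=path.stem)
    current: RawSpectrum | None = None
    mzs: list[float] = []
    intens: list[float] = []

    def flush() -> None:
        nonlocal current
        if current is not None:
            current.mz = np.array(mzs, dtype=float)
            current.intensity = np.array(intens, dtype=float)
            run.spectra.append(current)
        mzs.clear()
        intens.clear()
        current = None

    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#run"):
                parts = line.split(maxsplit=1)
                run.name = parts[1] if len(parts) > 1 else run.name
            elif line.startswith("#scan"):
                flush()
                try:
                    fields = line.split()
                    scan_id = int(fields[1])
                    kv = dict(f.split("=", 1) for f in fields[2:])
                    pmz, pz = None, None
                    if "precursor" in kv:
                        pmz_s, pz_s = kv["precursor"].split("/")
                        pmz, pz = float(pmz_s), int(pz_s)
                    current = RawSpectrum(scan_id, int(kv["msLevel"]),
                                          float(kv["rt"]), np.empty(0), np.empty(0),
                                          pmz, pz)
                except (ValueError, KeyError, IndexError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed scan header: {exc}") from None
            else:
                if current is None:
                    raise ValueError(f"{path}:{lineno}: peak row outside any scan")
                try:
                    mz_s, inten_s = line.split("\t")
                    mzs.append(float(mz_s))
                    intens.append(float(inten_s))
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: malformed peak row {line!r}") from None
    flush()
    if not run.spectra:
        raise ValueError(f"{path}: no scans found")
    truth_path = path.with_suffix(path.suffix + ".truth.json")
    if truth_path.exists():
        run.truth = json.loads(truth_path.read_text())
    return run


# ----------------------------------------------------------------------- mzML

_NS = "http://psi.hupo.org/ms/mzml"


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "", **extra) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    attrs.update(extra)
    etree.SubElement(parent, f"{{{_NS}}}cvParam", attrs)


def write_mzml(run: RawRun, path: str | Path) -> None:
    """Write a minimal centroided mzML file (64-bit float, no compression)."""
    root = etree.Element(f"{{{_NS}}}mzML", nsmap={None: _NS}, version="1.1.0")
    cv_list = etree.SubElement(root, f"{{{_NS}}}cvList", count="1")
    etree.SubElement(cv_list, f"{{{_NS}}}cv", id="MS", fullName="PSI-MS",
                     URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    run_el = etree.SubElement(root, f"{{{_NS}}}run", id=run.name)
    slist = etree.SubElement(run_el, f"{{{_NS}}}spectrumList",
                             count=str(len(run.spectra)))
    for index, s in enumerate(run.spectra):
        spec = etree.SubElement(
            slist, f"{{{_NS}}}spectrum", index=str(index),
            id=f"scan={s.scan_id}", defaultArrayLength=str(len(s.mz)))
        _cv(spec, "MS:1000511", "ms level", str(s.ms_level))
        _cv(spec, "MS:1000127", "centroid spectrum")
        scan_list = etree.SubElement(spec, f"{{{_NS}}}scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan = etree.SubElement(scan_list, f"{{{_NS}}}scan")
        _cv(scan, "MS:1000016", "scan start time", repr(float(s.rt) / 60.0),
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute")
        if s.precursor_mz is not None:
            plist = etree.SubElement(spec, f"{{{_NS}}}precursorList", count="1")
            prec = etree.SubElement(plist, f"{{{_NS}}}precursor")
            silist = etree.SubElement(prec, f"{{{_NS}}}selectedIonList", count="1")
            sion = etree.SubElement(silist, f"{{{_NS}}}selectedIon")
            _cv(sion, "MS:1000744", "selected ion m/z", repr(float(s.precursor_mz)),
                unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
            if s.precursor_charge is not None:
                _cv(sion, "MS:1000041", "charge state", str(s.precursor_charge))
        balist = etree.SubElement(spec, f"{{{_NS}}}binaryDataArrayList", count="2")
        for accession, name, values in (
                ("MS:1000514", "m/z array", s.mz),
                ("MS:1000515", "intensity array", s.intensity)):
            encoded = _encode_array(values)
            ba = etree.SubElement(balist, f"{{{_NS}}}binaryDataArray",
                                  encodedLength=str(len(encoded)))
            _cv(ba, "MS:1000523", "64-bit float")
            _cv(ba, "MS:1000576", "no compression")
            _cv(ba, accession, name)
            etree.SubElement(ba, f"{{{_NS}}}binary").text = encoded
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
    if run.truth is not None:
        p = Path(path)
        p.with_suffix(p.suffix + ".truth.json").write_text(
            json.dumps(run.truth, indent=1, default=str))


def _decode_binary(binary_el, n: int) -> np.ndarray:
    params = {cv.get("accession") for cv in binary_el.iter(f"{{{_NS}}}cvParam")}
    text_el = binary_el.find(f"{{{_NS}}}binary")
    if text_el is None or not (text_el.text or "").strip():
        return np.empty(0)
    raw = base64.b64decode(text_el.text)
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    if n and len(values) != n:
        raise ValueError(f"binary array length {len(values)} != declared {n}")
    return values


def read_mzml(path: str | Path) -> RawRun:
    """Read a centroided mzML file into a RawRun.

    Covers the common subset: 32/64-bit float m/z and intensity arrays (plain
    or zlib base64), MS level, scan start time (minute or second) and the
    first selected ion's m/z / charge for MS2 scans.
    """
    path = Path(path)
    run = RawRun(name=path.stem)
    tree = etree.parse(str(path))
    for i, spec in enumerate(tree.iter(f"{{{_NS}}}spectrum")):
        scan_id = i + 1
        for token in (spec.get("id") or "").split():
            if token.startswith("scan="):
                scan_id = int(token[5:])
        n_declared = int(spec.get("defaultArrayLength") or 0)
        ms_level, rt, pmz, pz = 1, 0.0, None, None
        arrays: dict[str, np.ndarray] = {}
        for cv in spec.iter(f"{{{_NS}}}cvParam"):
            acc = cv.get("accession")
            if acc == "MS:1000511":
                ms_level = int(cv.get("value"))
            elif acc == "MS:1000016":
                unit = cv.get("unitName") or "minute"
                rt = float(cv.get("value")) * (60.0 if unit.startswith("min") else 1.0)
            elif acc == "MS:1000744":
                pmz = float(cv.get("value"))
            elif acc == "MS:1000041":
                pz = int(cv.get("value"))
        for ba in spec.iter(f"{{{_NS}}}binaryDataArray"):
            accs = {cv.get("accession") for cv in ba.iter(f"{{{_NS}}}cvParam")}
            values = _decode_binary(ba, n_declared)
            if "MS:1000514" in accs:
                arrays["mz"] = values
            elif "MS:1000515" in accs:
                arrays["intensity"] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"{path}: spectrum {scan_id} lacks m/z or intensity array")
        run.spectra.append(RawSpectrum(
            scan_id=scan_id, ms_level=ms_level, rt=rt,
            mz=arrays["mz"], intensity=arrays["intensity"],
            precursor_mz=pmz, precursor_charge=pz))
    if not run.spectra:
        raise ValueError(f"{path}: no spectra found")
    truth_path = path.with_suffix(path.suffix + ".truth.json")
    if truth_path.exists():
        run.truth = json.loads(truth_path.read_text())
    return run


def read_run(path: str | Path, fmt: str | None = None) -> RawRun:
    """Read a run, dispatching on extension (``.mzML`` vs ``.tsv``)."""
    path = Path(path)
    fmt = fmt or ("mzml" if path.suffix.lower() == ".mzml" else "tsv")
    return read_mzml(path) if fmt == "mzml" else read_tsv(path)


def write_run(run: RawRun, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("mzml" if path.suffix.lower() == ".mzml" else "tsv")
    (write_mzml if fmt == "mzml" else write_tsv)(run, path)


# ---------------------------------------------------------------------- FASTA

def read_chains(path: str | Path) -> tuple[str, str]:
    """Read (light, heavy) chain sequences from a two-record FASTA.

    Records named ``LC``/``HC`` (or ``light``/``heavy``) are matched by name;
    otherwise the first record is taken as the light chain and the second as
    the heavy chain.
    """
    records: list[tuple[str, str]] = []
    header = None
    seq: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                records.append((header, "".join(seq)))
            header = line[1:].split()[0].upper()
            seq = []
        else:
            seq.append(line.upper())
    if header is not None:
        records.append((header, "".join(seq)))
    if len(records) < 2:
        raise ValueError(f"{path}: expected two chain records, found {len(records)}")
    named = {h: s for h, s in records}
    light = named.get("LC") or named.get("LIGHT")
    heavy = named.get("HC") or named.get("HEAVY")
    if light is None or heavy is None:
        light, heavy = records[0][1], records[1][1]
    return light, heavy
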