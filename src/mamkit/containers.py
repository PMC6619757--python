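"""In-memory containers for centroided LC-MS(/MS) runs."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class RawSpectrum:
    """A single centroided scan: stick (m/z, intensity) pairs plus metadata.

    Retention time is in seconds.  ``precursor_mz``/``precursor_charge`` are
    set for MS2 scans only.
    """

    scan_id: int
    ms_level: int
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    precursor_charge: int | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())

    def sorted_by_mz(self) -> "RawSpectrum":
        order = np.argsort(self.mz, kind="stable")
        return RawSpectrum(self.scan_id, self.ms_level, self.rt,
                           self.mz[order], self.intensity[order],
                           self.precursor_mz, self.precursor_charge)


@dataclass
class RawRun:
    """An ordered collection of scans plus an optional ground-truth sidecar.

    ``truth`` is populated by the synthetic-data generator and records the
    simulated species, fractions and sites for parameter-recovery tests; it is
    absent for runs read from disk unless the sidecar file is also loaded.
    """

    spectra: list[RawSpectrum] = field(default_factory=list)
    name: str = "run"
    truth: dict[str, Any] | None = None

    def ms1(self) -> list[RawSpectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2(self) -> list[RawSpectrum]:
        return [s for s in self.spectra if s.ms_level == 2]

    def __len__(self) -> int:
        return len(self.spectra)
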