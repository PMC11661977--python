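"""Peak-ion matching under a user-defined tolerance and spectrum annotation.

Each theoretical ion is matched to its nearest observed peak (binary search
over the sorted centroid array); the match is kept when the signed error is
within tolerance. Several ions may land on the same peak — all matches are
recorded, and rendering picks one label per peak by a fixed priority
(peptide series > glycan Y > glycan B > oxonium, lower charge first, then
smaller absolute error), so output is deterministic regardless of the order
ions were enumerated in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chemistry import peptide_neutral_mass
from .errors import ValidationError
from .fragments import (
    DissociationMethod,
    OxoniumEntry,
    TheoreticalIon,
    assemble_ions,
)
from .spectra import Identification, Spectrum

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Tolerance:
    """Mass tolerance with unit ``"ppm"`` or ``"Da"``."""

    value: float
    unit: str = "ppm"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValidationError("tolerance must be positive")
        if self.unit not in ("ppm", "Da"):
            raise ValidationError(f"tolerance unit must be 'ppm' or 'Da', got {self.unit!r}")

    def error(self, observed: float, theoretical: float) -> float:
        """Signed error (observed - theoretical) in this tolerance's unit."""
        if self.unit == "ppm":
            return (observed - theoretical) / theoretical * 1e6
        return observed - theoretical

    def accepts(self, observed: float, theoretical: float) -> bool:
        return abs(self.error(observed, theoretical)) <= self.value


@dataclass(frozen=True)
class PeakMatch:
    peak_index: int
    ion: TheoreticalIon
    mass_error: float  # signed, in the tolerance's unit


#: Label priority per series; lower sorts first.
_SERIES_PRIORITY = {"b": 0, "y": 0, "c": 0, "z": 0, "Y": 1, "B": 2, "oxonium": 3, "precursor": 4}


def _ion_sort_key(ion: TheoreticalIon):
    return (ion.mz, ion.series, ion.charge, ion.label)


def match_peaks(
    spectrum: Spectrum, ions: Sequence[TheoreticalIon], tol: Tolerance
) -> list[PeakMatch]:
    """Match every ion to its nearest in-tolerance peak.

    Ties between two equidistant straddling peaks break toward the lower
    index. The result is independent of the input ion order.
    """
    mz = spectrum.mz
    matches: list[PeakMatch] = []
    if mz.size == 0:
        return matches
    for ion in sorted(ions, key=_ion_sort_key):
        idx = int(np.searchsorted(mz, ion.mz))
        best = -1
        best_dist = np.inf
        for cand in (idx - 1, idx):
            if 0 <= cand < mz.size:
                dist = abs(mz[cand] - ion.mz)
                if dist < best_dist:
                    best_dist = dist
                    best = cand
        if best < 0:
            continue
        if tol.accepts(mz[best], ion.mz):
            matches.append(PeakMatch(best, ion, tol.error(mz[best], ion.mz)))
    return matches


@dataclass
class AnnotationConfig:
    """Knobs of the annotation stage."""

    tolerance: Tolerance = field(default_factory=lambda: Tolerance(20.0, "ppm"))
    max_fragment_charge: int | None = None  # None: precursor charge - 1 (min 1), or 2 if unknown
    dissociation_override: DissociationMethod | None = None
    oxonium_table: Sequence[OxoniumEntry] | None = None

    def effective_max_charge(self, spectrum: Spectrum) -> int:
        auto = spectrum.precursor_charge - 1 if spectrum.precursor_charge else 2
        auto = max(1, auto)
        if self.max_fragment_charge is None:
            return auto
        return max(1, min(self.max_fragment_charge, auto))


@dataclass
class AnnotatedSpectrum:
    """A spectrum joined with its identification and peak-ion matches."""

    spectrum: Spectrum
    identification: Identification
    ions: list[TheoreticalIon]
    matches: list[PeakMatch]
    tolerance: Tolerance

    def coverage(self) -> dict[str, tuple[int, int]]:
        """Per-series (matched, total) counts over unique theoretical ions."""
        total: dict[str, int] = {}
        for ion in self.ions:
            total[ion.series] = total.get(ion.series, 0) + 1
        matched_labels = {(m.ion.series, m.ion.label) for m in self.matches}
        matched: dict[str, int] = {s: 0 for s in total}
        for series, _label in matched_labels:
            matched[series] += 1
        return {s: (matched[s], total[s]) for s in sorted(total)}

    def coverage_fraction(self, series: str | None = None) -> float:
        cov = self.coverage()
        if series is not None:
            m, t = cov.get(series, (0, 0))
            return m / t if t else 0.0
        m = sum(v[0] for v in cov.values())
        t = sum(v[1] for v in cov.values())
        return m / t if t else 0.0

    def peak_labels(self) -> dict[int, PeakMatch]:
        """One representative match per peak, by the fixed label priority."""
        best: dict[int, PeakMatch] = {}
        for match in self.matches:
            key = (
                _SERIES_PRIORITY.get(match.ion.series, 9),
                match.ion.charge,
                abs(match.mass_error),
                match.ion.label,
            )
            current = best.get(match.peak_index)
            if current is None:
                best[match.peak_index] = match
                continue
            cur_key = (
                _SERIES_PRIORITY.get(current.ion.series, 9),
                current.ion.charge,
                abs(current.mass_error),
                current.ion.label,
            )
            if key < cur_key:
                best[match.peak_index] = match
        return best

    def coverage_table(self) -> str:
        """Coverage summary as CSV text (series, matched, total, fraction)."""
        lines = ["series,matched,total,fraction"]
        for series, (m, t) in self.coverage().items():
            lines.append(f"{series},{m},{t},{m / t:.4f}" if t else f"{series},0,0,0")
        return "\n".join(lines) + "\n"


def annotate(
    spectrum: Spectrum,
    identification: Identification,
    config: AnnotationConfig | None = None,
) -> AnnotatedSpectrum:
    """Assemble theoretical ions for the identification and match them.

    Peptide series follow the spectrum's activation method (overridable);
    glycan Y/B/oxonium ions are added only when a glycan is present and the
    activation has a collisional component. An identification flagged as
    glycosylated but carrying neither structure nor composition proceeds
    with peptide ions only (logged).
    """
    cfg = config or AnnotationConfig()
    method = cfg.dissociation_override or spectrum.activation
    max_charge = cfg.effective_max_charge(spectrum)
    if (
        identification.glycosite is not None
        and identification.glycan_tree is None
        and not identification.glycan_composition
    ):
        logger.warning(
            "scan %d: glycosite given without glycan structure/composition; "
            "annotating peptide ions only",
            spectrum.scan_number,
        )
    ions = assemble_ions(
        identification.peptide,
        method,
        max_charge,
        glycan_tree=identification.glycan_tree,
        glycan_composition=identification.glycan_composition,
        oxonium_table=cfg.oxonium_table,
    )
    matches = match_peaks(spectrum, ions, cfg.tolerance)
    return AnnotatedSpectrum(spectrum, identification, ions, matches, cfg.tolerance)
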