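"""Spectrum and identification input: mzML reading, result tables, pairing.

The mzML reader is a focused lxml parser for the subset the tool needs:
centroided MS2 scans with binary m/z / intensity arrays (32- or 64-bit
float, optionally zlib-compressed) and precursor activation terms. The
activation method is inferred from the controlled-vocabulary terms (ETD
plus a supplemental collisional term maps to the hybrid EThcD/ETciD
methods). Identification tables are plain CSV/TSV with a header; per-tool
column layouts are expressed as dialects (header -> field maps) that users
can override, since exports differ across search engines.
"""

from __future__ import annotations

import base64
import logging
import re
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from lxml import etree

from .chemistry import Modification, Peptide, parse_modified_sequence
from .errors import SchemaError, ValidationError
from .fragments import DissociationMethod
from .glycan import GlycanComposition, GlycanTree, parse_glycan

logger = logging.getLogger(__name__)


@dataclass
class Spectrum:
    """One MS2 scan: centroided peaks plus precursor metadata."""

    scan_number: int
    ms_level: int
    precursor_mz: float
    precursor_charge: int  # 0 = unknown
    activation: DissociationMethod
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValidationError("peak arrays have different lengths")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class Identification:
    """One row of an identification result table."""

    scan_number: int
    peptide: Peptide
    glycan_composition: GlycanComposition | None = None
    glycan_tree: GlycanTree | None = None
    glycosite: int | None = None
    source_tool: str = "generic"

    def __post_init__(self) -> None:
        if self.glycosite is not None and not 1 <= self.glycosite <= len(self.peptide):
            raise ValidationError(
                f"glycosite {self.glycosite} outside peptide of length {len(self.peptide)}"
            )


_SCAN_RE = re.compile(r"scan=(\d+)")


def _activation_from_cv(names: Iterable[str]) -> DissociationMethod | None:
    lowered = {n.lower() for n in names}
    etd = any("electron transfer" in n for n in lowered)
    ecd = any("electron capture" in n for n in lowered)
    hcd = any("beam-type collision" in n for n in lowered)
    cid = any(
        "collision-induced" in n and "beam-type" not in n and "supplemental" not in n
        for n in lowered
    )
    supplemental = any("supplemental" in n for n in lowered)
    if etd:
        if hcd or (supplemental and not cid):
            return DissociationMethod.ETHCD
        if cid or supplemental:
            return DissociationMethod.ETCID
        return DissociationMethod.ETD
    if ecd:
        return DissociationMethod.ECD
    if hcd:
        return DissociationMethod.HCD
    if cid:
        return DissociationMethod.CID
    return None


def _local(tag: object) -> str:
    text = tag if isinstance(tag, str) else ""
    return text.rsplit("}", 1)[-1]


def _decode_binary_array(element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, values)."""
    dtype = None
    compressed = False
    kind = None
    payload = b""
    for child in element.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif name == "binary" and child.text:
            payload = base64.b64decode(child.text)
    if dtype is None:
        raise IOError("binaryDataArray without a recognized precision term")
    if compressed:
        payload = zlib.decompress(payload)
    return kind, np.frombuffer(payload, dtype=dtype).astype(float)


def _parse_spectrum_element(element, index: int) -> Spectrum | None:
    native_id = element.get("id", "")
    m = _SCAN_RE.search(native_id)
    scan = int(m.group(1)) if m else index + 1

    ms_level = None
    profile = False
    precursor_mz = 0.0
    charge = 0
    activation_names: list[str] = []
    arrays: dict[str, np.ndarray] = {}

    for child in element.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000511":
                ms_level = int(child.get("value", "0"))
            elif acc == "MS:1000128":
                profile = True
        elif name == "selectedIon":
            for cv in child:
                if _local(cv.tag) != "cvParam":
                    continue
                acc = cv.get("accession", "")
                if acc == "MS:1000744":
                    precursor_mz = float(cv.get("value", "0") or 0)
                elif acc == "MS:1000041":
                    charge = int(cv.get("value", "0") or 0)
        elif name == "activation":
            activation_names.extend(
                cv.get("name", "") for cv in child if _local(cv.tag) == "cvParam"
            )
        elif name == "binaryDataArray":
            kind, values = _decode_binary_array(child)
            if kind:
                arrays[kind] = values

    if ms_level != 2:
        return None
    if profile:
        logger.warning("scan %d is profile mode; matching expects centroids", scan)
    method = _activation_from_cv(activation_names)
    if method is None:
        logger.warning("scan %d: unknown activation terms, defaulting to HCD", scan)
        method = DissociationMethod.HCD
    mz = arrays.get("mz", np.empty(0))
    intensity = arrays.get("intensity", np.empty(0))
    return Spectrum(
        scan_number=scan,
        ms_level=2,
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        activation=method,
        mz=mz,
        intensity=intensity,
    )


def read_mzml(path: str | Path) -> Iterator[Spectrum]:
    """Yield one :class:`Spectrum` per MS2 scan of an mzML file.

    Activation is inferred from the activation CV terms; scans without a
    recognizable term default to HCD with a logged warning. Profile-mode
    spectra pass through with a warning (matching expects centroids).
    Truncated or malformed XML raises ``IOError``.
    """
    path = Path(path)
    index = 0

    def _generate() -> Iterator[Spectrum]:
        nonlocal index
        try:
            saw_mzml = False
            for _event, element in etree.iterparse(str(path), events=("end",)):
                name = _local(element.tag)
                if name == "mzML":
                    saw_mzml = True
                if name != "spectrum":
                    continue
                spectrum = _parse_spectrum_element(element, index)
                index += 1
                element.clear(keep_tail=True)
                if spectrum is not None:
                    yield spectrum
            if not saw_mzml:
                raise IOError(f"{path}: not an mzML document")
        except etree.XMLSyntaxError as exc:
            raise IOError(f"unreadable mzML {path}: {exc}") from exc

    return _generate()


@dataclass(frozen=True)
class Dialect:
    """Column layout of one identification tool's export.

    ``columns`` maps our field names (scan, peptide, glycan, glycosite,
    charge) to the tool's header names (matched case-insensitively).
    """

    name: str
    columns: Mapping[str, str]

    def resolve(self, headers: Sequence[str]) -> dict[str, str]:
        lookup = {h.strip().lower(): h for h in headers}
        resolved: dict[str, str] = {}
        for fieldname, header in self.columns.items():
            actual = lookup.get(header.strip().lower())
            if actual is not None:
                resolved[fieldname] = actual
        return resolved


#: Shipped dialects. Column names for third-party tools are best-effort
#: reconstructions of their exports and are user-overridable.
DIALECTS: dict[str, Dialect] = {
    "generic": Dialect(
        "generic",
        {"scan": "scan", "peptide": "peptide", "glycan": "glycan",
         "glycosite": "glycosite", "charge": "charge"},
    ),
    "glyco_decipher": Dialect(
        "glyco_decipher",
        {"scan": "Scan", "peptide": "Peptide", "glycan": "Glycan",
         "glycosite": "GlycoSite", "charge": "Charge"},
    ),
    "byonic": Dialect(
        "byonic",
        {"scan": "Scan #", "peptide": "Peptide", "glycan": "Glycans",
         "charge": "z"},
    ),
    "pglyco3": Dialect(
        "pglyco3",
        {"scan": "Scan", "peptide": "Peptide", "glycan": "GlycanComposition",
         "glycosite": "GlySite", "charge": "Charge"},
    ),
    "msfragger_glyco": Dialect(
        "msfragger_glyco",
        {"scan": "Spectrum", "peptide": "Modified Peptide",
         "glycan": "Total Glycan Composition", "charge": "Charge"},
    ),
    "maxquant": Dialect(
        "maxquant",
        {"scan": "Scan number", "peptide": "Modified sequence", "charge": "Charge"},
    ),
    "msgf": Dialect(
        "msgf",
        {"scan": "ScanNum", "peptide": "Peptide", "charge": "Charge"},
    ),
    "gpquest": Dialect(
        "gpquest",
        {"scan": "Scan", "peptide": "Peptide", "glycan": "Glycan", "charge": "Charge"},
    ),
}


def load_dialect_config(path: str | Path, name: str = "custom") -> Dialect:
    """Build a dialect from ``field=Header`` lines (``#`` comments allowed)."""
    columns: dict[str, str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        columns[key.strip().lower()] = value.strip()
    return Dialect(name, columns)


def _coerce_scan(value: object) -> int:
    if isinstance(value, str):
        m = _SCAN_RE.search(value)
        if m:
            return int(m.group(1))
        # MSFragger "file.scan.scan.charge" spectrum ids
        parts = value.split(".")
        for part in parts[1:]:
            if part.isdigit():
                return int(part)
    return int(value)  # type: ignore[arg-type]


def read_results(
    path: str | Path,
    dialect: str | Dialect = "generic",
    registry: Mapping[str, Modification] | None = None,
) -> list[Identification]:
    """Read an identification table into :class:`Identification` records.

    Mandatory fields are scan and peptide; glycan cells are auto-dispatched
    to the composition / GlycoCT / WURCS parser by their leading token.
    Unparseable rows are skipped with a logged row number; a missing
    mandatory column raises :class:`SchemaError`.
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise ValidationError(
                f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
            ) from None
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    resolved = dialect.resolve(list(frame.columns))
    missing = [f for f in ("scan", "peptide") if f not in resolved]
    if missing:
        raise SchemaError(
            f"missing mandatory column(s) {missing} for dialect {dialect.name!r}; "
            f"expected headers {dict(dialect.columns)!r}, found {list(frame.columns)}"
        )

    out: list[Identification] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        record = dict(zip(frame.columns, row))
        try:
            scan = _coerce_scan(record[resolved["scan"]])
            peptide = parse_modified_sequence(record[resolved["peptide"]], registry)
            tree = comp = None
            glycan_cell = record.get(resolved.get("glycan", ""), "").strip()
            if glycan_cell:
                tree, comp = parse_glycan(glycan_cell)
            site_cell = record.get(resolved.get("glycosite", ""), "").strip()
            glycosite = int(site_cell) if site_cell else None
            out.append(
                Identification(
                    scan_number=scan,
                    peptide=peptide,
                    glycan_composition=comp,
                    glycan_tree=tree,
                    glycosite=glycosite,
                    source_tool=dialect.name,
                )
            )
        except Exception as exc:  # noqa: BLE001 - row-level resilience is the contract
            logger.warning("skipping row %d of %s: %s", row_number, path.name, exc)
    return out


@dataclass
class PairReport:
    """Scan-number join of spectra and identifications."""

    pairs: list[tuple[Spectrum, Identification]]
    unmatched_identifications: list[Identification]

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def pair(
    spectra: Iterable[Spectrum], identifications: Iterable[Identification]
) -> PairReport:
    """Join identifications to spectra on scan number.

    Duplicate scans in the results (several identifications of one spectrum,
    as in cross-tool comparisons) each produce their own pair. Identifications
    whose scan has no spectrum are reported, not dropped.
    """
    by_scan: dict[int, Spectrum] = {}
    for s in spectra:
        if s.scan_number in by_scan:
            logger.warning("duplicate scan number %d in spectra; keeping first", s.scan_number)
            continue
        by_scan[s.scan_number] = s
    pairs: list[tuple[Spectrum, Identification]] = []
    unmatched: list[Identification] = []
    for ident in identifications:
        spectrum = by_scan.get(ident.scan_number)
        if spectrum is None:
            logger.warning("identification for scan %d has no spectrum", ident.scan_number)
            unmatched.append(ident)
        else:
            pairs.append((spectrum, ident))
    return PairReport(pairs, unmatched)
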