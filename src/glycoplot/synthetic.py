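"""Synthetic glycopeptide spectra with known ground truth.

The generator fabricates an MS2 scan from a peptide + glycan structure: it
enumerates the full theoretical ion set, emits a seeded random subset of
those ions as peaks (Gaussian m/z jitter in ppm, intensities decaying with
the fragment's rank within its series), adds uniform decoy peaks, and keeps
the emitted ion list so tests can assert exact recovery. A companion writer
produces standards-conformant indexed mzML (float32, zlib, correct
activation CV accessions) that round-trips through :func:`~glycoplot.spectra.read_mzml`,
and a run generator lays down the mzML + identification CSV pair the CLI
consumes — so the whole pipeline is exercised without any downloaded data.

What this emulates: fragment m/z accuracy, partial fragmentation coverage
and chemical noise. What it does not: isotope envelopes, realistic intensity
structure, co-isolation chimerism, or retention time.
"""

from __future__ import annotations

import base64
import csv
import hashlib
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chemistry import PROTON, Peptide, peptide_neutral_mass
from .errors import ValidationError
from .fragments import DissociationMethod, TheoreticalIon, assemble_ions
from .glycan import GlycanTree, format_composition, glycan_mass, to_glycoct, tree_from_nested
from .spectra import Identification, Spectrum


def nglycan_core() -> GlycanTree:
    """The pentasaccharide N-glycan core: HexNAc2 Hex3."""
    return tree_from_nested(
        ("HexNAc", [("HexNAc", [("Hex", [("Hex", []), ("Hex", [])])])])
    )


def biantennary_sialofucosylated() -> GlycanTree:
    """Hex(4)HexNAc(4)NeuAc(1)Fuc(1): core-fucosylated biantennary N-glycan
    with two antenna HexNAc, one galactosylated and sialylated arm."""
    return tree_from_nested(
        (
            "HexNAc",
            [
                ("Fuc", []),
                (
                    "HexNAc",
                    [
                        (
                            "Hex",
                            [
                                ("Hex", [("HexNAc", [])]),
                                ("Hex", [("HexNAc", [("Hex", [("NeuAc", [])])])]),
                            ],
                        )
                    ],
                ),
            ],
        )
    )


@dataclass
class SynthSpec:
    """Parameters of one synthetic glycopeptide spectrum."""

    peptide: Peptide
    glycan_tree: GlycanTree | None = None
    precursor_charge: int = 3
    activation: DissociationMethod = DissociationMethod.HCD
    fraction: float = 1.0       # fraction of theoretical ions emitted as peaks
    n_decoys: int = 0           # uniform-random noise peaks
    jitter_ppm: float = 0.0     # Gaussian sigma of the m/z error
    intensity_decay: float = 0.92  # per-rank exponential decay within a series
    seed: int = 0
    scan_number: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError("fraction must be within [0, 1]")
        if self.jitter_ppm < 0:
            raise ValidationError("jitter must be non-negative")


@dataclass
class SyntheticSpectrum:
    spectrum: Spectrum
    identification: Identification
    true_ions: list[TheoreticalIon]  # the ions actually emitted as peaks
    all_ions: list[TheoreticalIon]   # the full theoretical set


def synth_spectrum(spec: SynthSpec) -> SyntheticSpectrum:
    """Generate one spectrum; all randomness flows from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    max_charge = max(1, spec.precursor_charge - 1)
    ions = assemble_ions(
        spec.peptide,
        spec.activation,
        max_charge,
        glycan_tree=spec.glycan_tree,
    )
    keep = rng.random(len(ions)) < spec.fraction
    emitted = [ion for ion, k in zip(ions, keep) if k]

    rank_in_series: dict[str, int] = {}
    mzs: list[float] = []
    intens: list[float] = []
    for ion in emitted:
        rank = rank_in_series.get(ion.series, 0)
        rank_in_series[ion.series] = rank + 1
        jitter = rng.normal(0.0, spec.jitter_ppm) * 1e-6 if spec.jitter_ppm else 0.0
        mzs.append(ion.mz * (1.0 + jitter))
        intens.append(100.0 * spec.intensity_decay**rank)

    if mzs:
        lo, hi = 100.0, max(mzs) + 100.0
    else:
        lo, hi = 100.0, 2000.0
    for _ in range(spec.n_decoys):
        mzs.append(float(rng.uniform(lo, hi)))
        intens.append(float(rng.uniform(1.0, 8.0)))

    mz_arr = np.asarray(mzs)
    int_arr = np.asarray(intens)
    order = np.argsort(mz_arr, kind="stable")
    mz_arr, int_arr = mz_arr[order], int_arr[order]
    if mz_arr.size:
        dedup = np.concatenate(([True], np.diff(mz_arr) > 1e-9))
        mz_arr, int_arr = mz_arr[dedup], int_arr[dedup]

    neutral = peptide_neutral_mass(spec.peptide)
    comp = None
    if spec.glycan_tree is not None:
        comp = spec.glycan_tree.composition()
        neutral += glycan_mass(comp)
    z = max(1, spec.precursor_charge)
    spectrum = Spectrum(
        scan_number=spec.scan_number,
        ms_level=2,
        precursor_mz=(neutral + z * PROTON) / z,
        precursor_charge=spec.precursor_charge,
        activation=spec.activation,
        mz=mz_arr,
        intensity=int_arr,
    )
    ident = Identification(
        scan_number=spec.scan_number,
        peptide=spec.peptide,
        glycan_composition=comp,
        glycan_tree=spec.glycan_tree,
        source_tool="synthetic",
    )
    return SyntheticSpectrum(spectrum, ident, emitted, ions)


# --------------------------------------------------------------------------
# mzML writing
# --------------------------------------------------------------------------

_ACTIVATION_CV = {
    DissociationMethod.CID: [("MS:1000133", "collision-induced dissociation")],
    DissociationMethod.HCD: [("MS:1000422", "beam-type collision-induced dissociation")],
    DissociationMethod.ETD: [("MS:1000598", "electron transfer dissociation")],
    DissociationMethod.ECD: [("MS:1000250", "electron capture dissociation")],
    DissociationMethod.ETHCD: [
        ("MS:1000598", "electron transfer dissociation"),
        ("MS:1000422", "beam-type collision-induced dissociation"),
    ],
    DissociationMethod.ETCID: [
        ("MS:1000598", "electron transfer dissociation"),
        ("MS:1000133", "collision-induced dissociation"),
    ],
}


def _encode_f32(values: np.ndarray) -> tuple[str, int]:
    raw = struct.pack(f"<{values.size}f", *values.astype(np.float32))
    compressed = zlib.compress(raw)
    return base64.b64encode(compressed).decode("ascii"), len(compressed)


def _binary_array(values: np.ndarray, accession: str, name: str, unit: str) -> str:
    b64, enc_len = _encode_f32(values)
    return (
        f'<binaryDataArray encodedLength="{len(b64)}">'
        f'<cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>'
        f'<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>'
        f'<cvParam cvRef="MS" accession="{accession}" name="{name}" value="" {unit}/>'
        f"<binary>{b64}</binary>"
        f"</binaryDataArray>"
    )


def _spectrum_xml(s: Spectrum, index: int, generic_activation: bool) -> tuple[str, str]:
    """Return (native id, serialized <spectrum> element)."""
    native_id = f"controllerType=0 controllerNumber=1 scan={s.scan_number}"
    if generic_activation:
        activation = '<cvParam cvRef="MS" accession="MS:1000044" name="dissociation method" value=""/>'
    else:
        activation = "".join(
            f'<cvParam cvRef="MS" accession="{acc}" name="{name}" value=""/>'
            for acc, name in _ACTIVATION_CV[s.activation]
        )
    charge = (
        f'<cvParam cvRef="MS" accession="MS:1000041" name="charge state" '
        f'value="{s.precursor_charge}"/>'
        if s.precursor_charge
        else ""
    )
    mz_unit = (
        'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'
    )
    int_unit = (
        'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"'
    )
    xml = (
        f'<spectrum index="{index}" id="{native_id}" defaultArrayLength="{len(s)}">'
        f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>'
        f'<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>'
        f'<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
        f"<precursorList count=\"1\"><precursor>"
        f'<selectedIonList count="1"><selectedIon>'
        f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" '
        f'value="{s.precursor_mz:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
        f"{charge}"
        f"</selectedIon></selectedIonList>"
        f"<activation>{activation}</activation>"
        f"</precursor></precursorList>"
        f'<binaryDataArrayList count="2">'
        f'{_binary_array(s.mz, "MS:1000514", "m/z array", mz_unit)}'
        f'{_binary_array(s.intensity, "MS:1000515", "intensity array", int_unit)}'
        f"</binaryDataArrayList>"
        f"</spectrum>"
    )
    return native_id, xml


def write_mzml(
    spectra: Sequence[Spectrum], path: str | Path, generic_activation: bool = False
) -> Path:
    """Write spectra as indexed mzML (float32 peaks, zlib compressed).

    ``generic_activation`` replaces the per-method CV terms with the generic
    "dissociation method" term, to exercise the reader's HCD fallback.
    """
    if not spectra:
        raise ValidationError("cannot write an empty spectrum list")
    path = Path(path)

    header = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<indexedmzML xmlns="http://psi.hupo.org/ms/mzml">\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="glycoplot_synthetic">\n'
        '<cvList count="1">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        "</cvList>\n"
        '<fileDescription><fileContent>'
        '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>'
        "</fileContent></fileDescription>\n"
        '<softwareList count="1"><software id="glycoplot" version="0"/></softwareList>\n'
        '<instrumentConfigurationList count="1">'
        '<instrumentConfiguration id="IC1"/></instrumentConfigurationList>\n'
        '<dataProcessingList count="1"><dataProcessing id="dp">'
        '<processingMethod order="1" softwareRef="glycoplot"/>'
        "</dataProcessing></dataProcessingList>\n"
        '<run id="run" defaultInstrumentConfigurationRef="IC1">\n'
        f'<spectrumList count="{len(spectra)}" defaultDataProcessingRef="dp">\n'
    )

    chunks: list[str] = [header]
    offsets: list[tuple[str, int]] = []
    position = len(header.encode("utf-8"))
    for index, s in enumerate(spectra):
        native_id, xml = _spectrum_xml(s, index, generic_activation)
        offsets.append((native_id, position))
        xml += "\n"
        chunks.append(xml)
        position += len(xml.encode("utf-8"))

    tail_body = "</spectrumList>\n</run>\n</mzML>\n"
    chunks.append(tail_body)
    position += len(tail_body.encode("utf-8"))

    index_offset = position
    index_xml = '<indexList count="1">\n<index name="spectrum">\n'
    for native_id, off in offsets:
        index_xml += f'<offset idRef="{native_id}">{off}</offset>\n'
    index_xml += "</index>\n</indexList>\n"
    index_xml += f"<indexListOffset>{index_offset}</indexListOffset>\n"
    chunks.append(index_xml)

    body = "".join(chunks) + "<fileChecksum>"
    sha1 = hashlib.sha1(body.encode("utf-8")).hexdigest()
    body += f"{sha1}</fileChecksum>\n</indexedmzML>\n"
    path.write_text(body, encoding="utf-8")
    return path


def generate_run(
    out_dir: str | Path,
    specs: Sequence[SynthSpec],
    name: str = "run",
) -> tuple[Path, Path, list[SyntheticSpectrum]]:
    """Write an mzML + identification-CSV pair from synthetic ground truth.

    The CSV uses the generic dialect (scan, peptide, glycan, charge); glycan
    structures are serialized as GlycoCT so the structure survives the
    round-trip into Y/B enumeration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = [synth_spectrum(spec) for spec in specs]
    mzml_path = write_mzml([r.spectrum for r in results], out_dir / f"{name}.mzML")
    csv_path = out_dir / f"{name}.csv"
    with open(csv_path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, quoting=csv.QUOTE_ALL)
        writer.writerow(["scan", "peptide", "glycan", "charge"])
        for r in results:
            glycan_text = ""
            if r.identification.glycan_tree is not None:
                glycan_text = to_glycoct(r.identification.glycan_tree)
            elif r.identification.glycan_composition:
                glycan_text = format_composition(r.identification.glycan_composition)
            writer.writerow(
                [
                    r.spectrum.scan_number,
                    str(r.identification.peptide),
                    glycan_text,
                    r.spectrum.precursor_charge,
                ]
            )
    return mzml_path, csv_path, results
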