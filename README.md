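# glycoplot

Annotation and visualization of glycopeptide tandem mass spectra.

Manual inspection of annotated MS2 spectra is how proteomics practitioners
validate peptide identifications and localize modifications — and for intact
glycopeptides it is often the only way to arbitrate between the discrepant
glycan assignments that different search engines report for the same scan.
Generic spectrum viewers cannot do this because they know nothing about
glycan fragment ions. `glycoplot` fills that gap for people who run
glycoproteomics searches (Glyco-Decipher, Byonic, pGlyco3, MSFragger-Glyco,
…) or ordinary proteomics searches and want publication-quality annotated
spectra from open formats: mzML in, CSV identifications in, annotated
figures out.

## What it computes

**Peptide backbone ions.** For a peptide of *n* residues the enabled series
follow the dissociation method — b/y for collisional activation (CID, HCD),
c/z• for electron-driven activation (ETD, ECD), all four for the hybrids
(EThcD, ETciD). Fragment neutral masses are residue sums with modification
deltas assigned to the fragment carrying the modified residue, satisfying
b\_i + y\_{n−i} = M and c\_i + z\_{n−i} = M + m(H). Modifications with
declared neutral losses (e.g. phospho, −97.977 Da H3PO4) get satellite ions.

**Glycan ions.** Given a glycan topology (GlycoCT condensed, a WURCS 2.0
subset, or built programmatically), Y ions are enumerated by stepping every
branch outward from the reducing-end root and combining partial branches at
each junction; the resulting set is exactly the compositions of all
root-containing connected subtrees, deduplicated by composition, plus Y0
(the bare peptide). B ions come from the direction-reversed walk: the
complete subtree below each single glycosidic cleavage. A diagnostic
oxonium-ion table (HexNAc 204.087 ladder, NeuAc 292.103, NeuGc 308.098, …)
is emitted for the composition at hand. Glycan ions are matched only for
collisionally activated spectra, where glycosidic bonds actually break.

**Matching and rendering.** Every theoretical ion is matched to its nearest
observed peak within a user-defined tolerance (ppm or Da). Annotated spectra
render in single, mirrored (two spectra sharing the x-axis, one drawn
downward) and vertically aligned modes, to `.svg`, `.pdf`, `.eps` and
`.png`, with per-series colors and text labels that stay searchable in the
SVG.

## Worked example

No data files are needed — the `synthetic` module fabricates a glycopeptide
spectrum with known ground truth, writes it as standards-conformant mzML,
and the rest of the stack consumes it like any instrument file:

```python
import glycoplot as gp
from glycoplot.matching import annotate
from glycoplot.plotting import RenderSpec, render_single

tree = gp.biantennary_sialofucosylated()   # Hex(4)HexNAc(4)NeuAc(1)Fuc(1)
truth = gp.synth_spectrum(gp.SynthSpec(
    peptide=gp.Peptide("TPASDPHGDNLTYSVFYTK"),
    glycan_tree=tree, precursor_charge=3, fraction=0.9,
    n_decoys=25, jitter_ppm=3.0, seed=7,
))
gp.write_mzml([truth.spectrum], "example.mzML")
(spectrum,) = gp.read_mzml("example.mzML")
ann = annotate(spectrum, truth.identification)
print(f"scan {spectrum.scan_number}: {len(spectrum)} peaks, "
      f"{len(ann.matches)} ion matches at {ann.tolerance.value:g} {ann.tolerance.unit}")
print(ann.coverage_table())
render_single(ann, RenderSpec(fmt="svg"), "example.svg")
```

prints:

```
scan 1: 165 peaks, 143 ion matches at 20 ppm
series,matched,total,fraction
B,18,20,0.9000
Y,48,54,0.8889
b,33,36,0.9167
oxonium,10,11,0.9091
y,34,36,0.9444
```

90% of the theoretical ions were emitted as peaks (`fraction=0.9`), and the
per-series coverage recovers that rate: the 54 Y ions are the deduplicated
compositions of the glycan's root-containing subtrees at fragment charges
1–2, the B series its 10 subtree compositions, and the oxonium rows include
the HexNAc ladder (204.087 / 186.076 / 168.066 / 138.055 / 126.055) and the
NeuAc diagnostics. `example.svg` is the annotated figure with matched peaks
colored by series.

The same flow runs from a shell:

```sh
glycoplot --mzml run.mzML --results ids.csv --dialect generic \
          --tol 20 --tol-unit ppm --mode mirrored --format svg --out figures/
```

`--dialect` selects a column map for the supported search-tool exports (or a
`key=value` config file for anything else); a summary CSV with per-scan
match counts and coverage is written next to the images.

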