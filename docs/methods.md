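# Methods

## Scope and model

`glycoplot` is a viewer-side tool: it takes identifications as given and
asks only "which observed peaks does this assignment explain?". It performs
no scoring, FDR control, deisotoping or precursor mass correction. The unit
of work is one (spectrum, identification) pair; the output is the matched
ion list, per-series coverage, and an annotated figure.

## Mass conventions

* Monoisotopic masses throughout; average masses are out of scope.
* Atomic masses come from the NIST table shipped with pyteomics; amino-acid
  residue masses from the same source. Every derived constant (water,
  ammonia, monosaccharide residues, oxonium m/z values) is computed from
  elemental formulas at import time rather than stored as literals.
* Proton mass 1.007276466 Da; for a fragment of neutral mass *M*, charge
  *z* and neutral loss *L*, m/z = (M − L + z·m\_p)/z.
* Monosaccharide residue masses are the dehydrated in-chain values:
  Hex 162.052824 (C6H10O5), HexNAc 203.079373 (C8H13NO5), Fuc 146.057909
  (C6H10O4), NeuAc 291.095417 (C11H17NO8), NeuGc 307.090331 (C11H17NO9),
  Xyl 132.042259 (C5H8O4). dHex is treated as an alias of Fuc and Pent of
  Xyl; the table is extensible at run time.

## Peptide fragments

Modification positions are 1-based; `N-term`/`C-term` tags attach to the
first/last residue's fragment set. b ions are plain prefix residue sums,
y ions suffix sums + water, c = b + NH3, and z is the z-dot radical
z• = y − NH3 + H — the convention of ETD search engines, chosen because the
activation methods that produce c/z here are electron-driven. A fragment
containing a modification with declared neutral losses yields one satellite
per distinct loss mass (single loss only; stacked double losses are rare
enough in practice that emitting them would mostly add false matching
opportunities). Fragment charges run 1..min(max\_charge, precursor charge −
1), defaulting to 2 when the precursor charge is unknown.

## Glycan fragment enumeration

Y ions: the branch-stepping procedure starts at the reducing-end root,
walks each branch to its terminus emitting a fragment per step, returns to
the nearest junction, and when stepping a new branch also extends the
fragments accumulated on the previous branches. The closure of this
procedure is precisely the set of compositions of root-containing connected
subtrees, which is how it is implemented: a bottom-up product over children
with composition-level deduplication at every junction (the deduplication
also keeps the intermediate sets small, so typical N-glycans enumerate in
microseconds despite the worst-case exponential subtree count). Y0 (empty
composition, bare peptide) and the intact glycan are always included.

Under this subtree formalization a fragment can never lose the core HexNAc
while retaining a branch — a deliberate consequence of requiring
connectivity through the root.

B ions: the direction-reversed walk yields, for each node, the complete
subtree it roots — i.e. the products of exactly one glycosidic cleavage,
deduplicated by composition. Internal (doubly cleaved) fragments and
cross-ring (A/X) fragments are not generated. Fucose-migration artifacts
are not modelled.

Glycan Y/B/oxonium ions are attached only to spectra whose activation has a
collisional component (CID, HCD, EThcD, ETciD); ETD/ECD spectra get peptide
c/z ions only, since glycosidic bonds largely survive electron-driven
dissociation.

When an identification carries only a composition (most search-tool
exports), the Y ladder cannot be derived without a topology, so annotation
emits Y0, the intact-glycan Y ion and the oxonium set — deliberate
under-annotation rather than guessing a structure. Supplying GlycoCT or
WURCS in the glycan column unlocks the full ladder.

## Oxonium table

Entries are (name, required composition, neutral-loss formula); an entry
fires when its required counts are contained in the glycan composition.
Built-ins: the HexNAc ladder 204.087/186.076/168.066/138.055/126.055 (the
last two as −CH6O3 / −C2H6O3), Hex 163.060 and its water loss, NeuAc
292.103/274.092, NeuGc 308.098/290.087, HexHexNAc 366.139, NeuAcHexHexNAc
657.235. All values are computed from residue formulas; the table is
extensible via the same tab-separated config dialect as modifications.
Oxonium ions are emitted singly charged by default.

## Structure parsers

GlycoCT condensed: RES/LIN sections; substituent residues (n-acetyl,
n-glycolyl) are folded into their base residue to select the table symbol
(HEX→Hex/HexNAc/Fuc by substituent and 6-deoxy flag, NON+N-acyl→NeuAc/NeuGc,
PEN→Xyl). Repeat, undetermined and alternative sections raise an
unsupported-structure error, as do multiple parents, cycles and
disconnected residues.

WURCS 2.0: a deliberate subset — definite tree topologies over residues
classifiable by skeleton length (6 carbons → Hex/HexNAc/Fuc, 5 → Xyl,
9 + N-acyl → NeuAc/NeuGc). The first residue of the sequence section is
taken as the reducing end and edges are oriented away from it, so either
donor/acceptor order in the link section yields the same tree. Any
ambiguity marker (`?`, `|`, `{}`, `*`) in the link section raises rather
than guessing. Linkage positions and anomericity are parsed past but
ignored: only topology affects fragment masses.

## Matching

Peaks are kept sorted ascending; each ion binary-searches its nearest peak
and matches if the signed error (ppm: (obs−theo)/theo·1e6; Da: obs−theo) is
within tolerance. Default tolerance 20 ppm. Nearest peak wins; equidistant
straddles break to the lower index. Matching is per-ion, so one peak may
explain several ions; rendering then picks one label per peak by the fixed
priority peptide series > glycan Y > B > oxonium, lower charge first, then
smaller absolute error — making output independent of enumeration order.

## Rendering

Matplotlib object API (no pyplot global state). Figures embed no
timestamps in svg/pdf and pin `svg.hashsalt`, so re-rendering identical
inputs is byte-identical for those formats; eps is emitted through the ps
backend, which always writes a `%%CreationDate` comment, so eps files are
reproducible in content but not byte-identical. `svg.fonttype=none` keeps
labels as text elements. Mirrored mode negates the second spectrum's
intensities and formats the y-axis as magnitudes; the shared x-range is the
union of both spectra's ranges unless overridden. Relative-intensity mode
scales each pane's base peak to 100% independently. Label collisions are
resolved greedily in intensity-descending order by vertical tiering.

## Synthetic data

The generator emulates: fragment m/z accuracy (Gaussian jitter in ppm),
partial fragmentation coverage (each theoretical ion emitted independently
with probability `fraction`), chemical noise (uniform decoy peaks over the
observed range at low intensity), and a crudely decaying intensity profile
(exponential in the fragment's rank within its series, factor 0.92). It
does not emulate isotope envelopes, charge-state-dependent intensity
structure, co-isolation chimerism or retention time — so passing tests
demonstrate correctness of enumeration, serialization, matching and
rendering, not robustness to real instrument artifacts. Defaults: precursor
charge 3, HCD, fraction 1.0, no decoys, no jitter; one seed drives all
randomness in a spectrum.

mzML output is indexed, float32, zlib-compressed — the most common dialect
in the wild — with correct activation CV accessions (hybrids are written as
ETD plus the collisional term). The reader maps CV terms back, defaulting
to HCD with a warning when no term is recognizable.

## Problem sizes and numerics

The test suite verifies the Y/B enumerations against exhaustive
2^|V| subset oracles on 200 random trees of up to 12 nodes, fragment-mass
identities on 100 random peptides to 1e-6 Da, and end-to-end recovery on
a 19-residue glycopeptide with an 11-residue biantennary glycan (≈160
theoretical ions per spectrum) — sizes at which the exhaustive oracles are
exact and the whole suite runs in seconds. Float32 peak encoding bounds
round-trip m/z error near 0.06 ppm, far inside the 20 ppm default
tolerance.

## Known limitations

* No ion-mobility dimension: frame-based (TIMS-TOF) data are unsupported.
* Composition-only identifications annotate a reduced Y set (see above).
* a/x peptide series and internal fragments are not generated.
* The per-tool dialect column maps are best-effort reconstructions of each
  tool's export format; users should supply a dialect config when a tool's
  headers differ.
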