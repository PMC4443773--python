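# Methods

## Problem and approach

Public small-molecule collections distribute 2D connection tables; a 3D
database has to push each record through hydrogen addition, 2D→3D embedding
and force-field minimization. Every one of those steps can silently corrupt
stereochemistry: a tetrahedral center flips (R↔S), an annotation is lost, a
double bond crosses E↔Z, or the topology itself changes. `stereofid`
implements the line-notation comparison methodology for detecting this: the
structure is snapshotted at three checkpoints — the screened 2D input
(`cpd`), the hydrogen-added and optionally salt-stripped structure (`wash`),
and the embedded, energy-minimized 3D structure (`mm`) — and each checkpoint
pair (cpd–wash, wash–mm, cpd–mm) is classified by comparing identifiers
generated independently on both sides.

Two channels are used:

* **InChI**: the string is split into sublayers and correspondence is
  required for formula, `c` (connectivity), `h` (hydrogens), `b`
  (double-bond stereo) and `t` (tetrahedral stereo). An undefined
  stereocenter surfaces as a `?` entry in `t`.
* **Canonical SMILES**: one fixed canonicalizer (RDKit) produces both
  strings, so the comparison is a plain text comparison of the
  phosphate-normalized strings, backed by the descriptor inventory
  (`@`/`@@` groups, `/` and `\` directional characters).

Each pair lands in exactly one of six classes: *Same*, *Chiral inversion*,
*Chiral missing*, *Cis/trans inversion*, *Cis/trans missing*, *Else
unmatched*; pairs where either side defeats the canonicalizer form a
separate *Untranslatable* bucket so the frequency-table columns still
partition the input.

## Verdict precedence

The six classes are mutually exclusive, so coexisting differences need an
order. Constitution dominates: any formula/`c`/`h` mismatch is *Else
unmatched*. Chirality outranks cis/trans (chiral inversion is the dominant
corruption mode in practice). Within each stereo family, "missing" is
decided before "inverted": the `t`/`b` sublayer is parsed into
`{center-or-bond: sign}` entries; a `?` sign on either side **or** an entry
key present on one side only means the annotation was lost (*missing*),
while identical keys with flipped signs mean *inverted*. The key-set rule
matters because a standard InChI omits an undefined element from the layer
entirely when no defined sibling forces a `?` placeholder. All coexisting
differences are preserved in the verdict's evidence string.

Two comparison modes exist. `strict-paper` compares chirality on `t` only.
The default `extended` mode also consults the `m` parity sublayer, because a
whole-molecule mirror inversion (single-center molecules in particular)
leaves `t` unchanged and flips only `m` — in strict mode an enantiomer pair
reads as *Same*, which the test suite asserts as the documented blind spot
of the t-only rule.

## The phosphate rule

Tetrahedral descriptors on phosphorus are stripped from SMILES before
comparison (`[P@@](=O)(O)…` → `P(=O)(O)…`): the oxygens around a phosphate
center are rendered inequivalent only by the line notation's arbitrary
protonation/bond assignment, not by the chemistry, so a "flipped" P tag is
noise. The stripped bracket is dropped when nothing else needs it, matching
what the canonicalizer itself prints for untagged phosphorus. InChI needs no
such rule — a P(=O)(OH) center never reaches the `t` sublayer. The
consequence, asserted in the known-limits suite rather than hidden, is that
a genuine phosphorus inversion is invisible to both channels.

## Pipeline and the chirality constraint

The bundled backend embeds with RDKit ETKDGv3 (falling back to the plain
experimental-torsion parameter set for tiny cumulated systems such as
propadiene, which the v3 knowledge terms reject) and minimizes with MMFF94,
with a per-record UFF fallback when MMFF parameters are missing; the applied
force field and final energy (kcal/mol) are recorded in the record
properties. Absolute energies are force-field-specific and are reported for
conformer ordering only.

The chirality constraint is deliberately **not** a backend flag: after
minimization the stereo layers are re-perceived from the 3D coordinates and
verified against the wash snapshot via the InChI channel; on a mismatch the
embedding is retried with a derived seed (default 4 retries). Backends have
historically inverted centers silently, so verification is post-hoc by
construction. Under this policy the packaged fully annotated fixtures come
back *Same* at cpd–mm at 100%, which is the tool's own correctness bar for
its bundled backend (a proprietary modeling suite measured ~94% for the
equivalent step; that number depends on that vendor's code and dataset and
is not reproduced here).

Undefined centers follow one of two policies: `preserve_undefined` (default)
carries the `?` through the wash; `random_assign` draws a parity from the
seeded generator and logs the assignment, emulating converters that invent
tags. Note that embedding necessarily assigns *some* 3D configuration to an
undefined center, so under `preserve_undefined` the cpd–mm comparison of
such records correctly reads *Chiral missing* — the `?` exists only on the
2D side. Every API that touches randomness takes an explicit seed; there is
no hidden global state.

"Wash" optionally reduces multi-component records (salts) to their largest
fragment first — most heavy atoms, then total mass, then lowest original
atom index, a deterministic rendering of common wash semantics. Stripping
changes the formula, so salt records classify as *Else unmatched* at
cpd–wash under the stripping policy; with stripping off, the bundled
backend embeds the components together and the identity bar applies.

## Geometry QC

Three plausibility checks on coordinates, independent of the identifier
channels:

* **Conjugated planarity** — every non-ring single bond whose two end atoms
  each carry a double bond (pattern-based double–single–double detection;
  aromatic rings exempt) must have its C=C–C=C torsion within
  `planarity_tolerance_deg` (default 20°) of 0° or 180°.
* **Allene twist** — for each cumulated C=C=C unit, the torsion from one
  terminal substituent to the other across the axis must be within 20° of
  ±90°. Force fields frequently flatten allenes to ~180°, which this check
  flags; a mono-substituted terminus uses its lone substituent and a bare
  terminus is skipped.
* **Short bonds** — heavy-atom bonds below `short_bond_lower` (default
  1.05 Å) indicate an input drawn at the coordinate scale of optical
  structure recognition output (~0.90–0.98 Å per bond against ~1.5 Å for a
  clean layout), which derails embedding downstream. This check runs on 2D
  records too.

The 20° and 1.05 Å defaults are judgment calls (the phenomena they bound are
only exemplified, not specified, in the source workflow) and are exposed as
parameters; a nonzero flag count marks the record as needing curation.
Flag counts are monotone non-increasing in the tolerance.

## Synthetic fixtures

The packaged set (35 records) is compiled at build time from annotated
SMILES templates via 2D depiction at ideal 1.5 Å bond lengths — chiral
metabolites (single- and multi-center), E/Z acids and alcohols, conjugated
polyenes, allenes, chiral phosphates, salts, partially annotated centers and
placeholder (R/R#/X) entries; every tag class appears at least twice.
Placeholder records are compiled from a dummy-atom template and renamed,
since line notations cannot spell "R".

Undefined-center fixtures are deliberately *partial* (one defined plus one
undefined center): a standard InChI prints the `?` marker only when a
defined sibling forces the `t` sublayer to exist, so a fully unannotated
molecule would be invisible to the `?` census and the census/manifest
equality would be ill-defined.

The corruption oracle applies exactly one lesion per record —
identity, invert-one-stereocenter, remove-stereo-annotation, flip-E/Z,
remove-E/Z-annotation, delete-terminal-atom, add-methyl, drop-fragment —
with a known expected verdict. Over the full applicable (fixture × mode)
cross (~131 pairs per channel) the InChI channel recovers 100% of planted
verdicts. The SMILES channel recovers ≥95%: the documented residual is a
conjugated polyene whose middle double bond shares its directional
single-bond characters with the flanking defined bonds, so the string
cannot express "middle bond undefined" — the InChI `b` sublayer (`5-4?`)
catches what the SMILES grammar cannot. Phosphate fixtures are quarantined
in a known-limits suite whose asserted outcome is the divergence itself
(lesions on P read back as *Same*).

What the fixtures do not emulate: macrocycles, porphyrin-scale symmetric
systems (the classic canonicalization-failure cases), meso/pseudo-asymmetric
pathologies (excluded from the main oracle because they defeat
identifier-based detection by construction), tautomer drift, and real OCR
noise beyond the bond-length scaling symptom. A green suite therefore
demonstrates the detection machinery, not the error *rates* of any
particular converter on real collections — those depend on the converter
and the dataset.

## Problem sizes and numerics

The shipped suite runs the full pipeline on all 35 fixtures (~4 s on one
CPU) and the oracle cross on ~131 pairs per channel; geometry fixtures use a
C12 polyene backbone, a deliberately reduced carotenoid-like chain that
keeps the planarity sweep instantaneous. 2D records are recognized by
|z| < 1e-4 Å on every atom (flat files in the wild carry floating-point
dust). Coordinates are written with 4 decimals (MOL convention). Embedding
seeds are masked to positive 31-bit values. `report.json` is canonical
(sorted keys, no timestamps — those live in `run.log`), so identical
input + policy + seed reproduces it byte for byte.
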