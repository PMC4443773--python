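# stereofid

Stereochemistry-fidelity quality control for 2D→3D small-molecule structure
conversion.

Building a 3D structure database from the 2D connection tables that public
compound collections distribute means running every record through hydrogen
addition, 2D→3D embedding and force-field minimization — and each of those
steps can silently corrupt stereochemistry: a tetrahedral center inverts
(R↔S), a chiral annotation is lost, a double bond flips E↔Z, or the
topology itself changes. `stereofid` is for database curators and
cheminformatics pipeline authors who need to *detect and classify* that
corruption automatically, so that human curation effort goes only where the
machines failed.

## Method

Each record is snapshotted at three checkpoints — the screened 2D input
(`cpd`), the hydrogen-added/washed structure (`wash`), and the embedded,
energy-minimized 3D structure (`mm`) — and every checkpoint pair is
classified by comparing identifiers generated independently on both sides:

* **InChI sublayers** — correspondence of formula, `c` (connectivity), `h`
  (hydrogens), `b` (double-bond stereo) and `t` (tetrahedral stereo);
  undefined centers appear as `?` in `t`. The default *extended* mode also
  consults the `m` parity sublayer, which catches whole-molecule mirror
  inversions that leave `t` unchanged.
* **Canonical SMILES** — a text comparison of phosphate-normalized strings
  from a single fixed canonicalizer, backed by the stereo-descriptor
  inventory (`@`/`@@`, `/`, `\`). Tetrahedral tags on phosphorus are
  ignored: phosphate oxygens are chemically equivalent, so those tags are
  notation noise.

Verdicts: **Same**, **Chiral inversion**, **Chiral missing**, **Cis/trans
inversion**, **Cis/trans missing**, **Else unmatched** (+ a separate
*Untranslatable* bucket). Records with generic residues (R, R#, \*),
unspecified halogens (X) or repeat units are screened out first;
multi-component (salt) entries are detected and optionally reduced to their
largest fragment. Geometric sanity checks flag non-planar conjugated
polyenes, flattened allenes (the terminal planes of C=C=C belong at 90°),
and the suspiciously short bonds typical of optically scanned drawings.
See `docs/methods.md` for the full model.

## Worked example

```python
from stereofid.fixtures import build_fixture_set, corrupt
from stereofid.stereo_compare import classify_pair

fixtures = {spec.fixture_id: rec for rec, spec in build_fixture_set(0)}
record = fixtures["multi-l-threonine"]          # L-threonine, (2S,3R)
lesion = corrupt(record, "invert_one_stereocenter", seed=1).record

for channel in ("inchi", "smiles"):
    v = classify_pair(record, lesion, channel=channel)
    print(channel, "->", v.verdict.value, "|", v.evidence)
```

prints

```
inchi -> Chiral inversion | t: '2-,3+' != '2-,3-'; m: '1' != '0'
smiles -> Chiral inversion | 'C[C@@H](O)[C@H](N)C(=O)O' != 'C[C@H](O)[C@H](N)C(=O)O'
```

Both channels agree: one center flipped. The InChI evidence pinpoints it —
center 3 changed sign in the `t` sublayer (and the parity layer `m`
followed), while formula and connectivity are untouched, which is exactly
what separates *Chiral inversion* from *Else unmatched*.

The same machinery runs from the shell:

```
stereofid fixtures --out fx/ --seed 3           # packaged synthetic set + oracle
stereofid run --in fx/fixtures.sdf --seed 9 --out run/
# -> 35 records: 32 classified, 3 rejected, 0 untranslatable, 0 failed
stereofid compare --before run/checkpoint_cpd.sdf --after run/checkpoint_mm.sdf
stereofid census --in fx/fixtures.sdf
```

`run/` contains `report.json` (canonical, byte-reproducible per seed),
`frequency.csv` (verdict × checkpoint-pair counts), `census.csv`
(stereo-annotation presence at each stage), `layers.csv` (per-sublayer
correspondence), `geometry_flags.csv` and the three checkpoint SDF
snapshots.

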