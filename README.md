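# gts — design automation for the GT plasmid-assembly standard

`gts` is a toolkit for researchers who build plasmids from **reusable,
standard DNA parts** under the GT (Guanine/Thymine) assembly standard. Under
that standard any DNA sequence longer than 35 nt that starts with `G` and
ends with `T` is a **fragment** (the functional payload: promoter, gene,
origin, marker, homology arm, ...), and any 20–80 nt sequence with the
anatomy `L–SE–R` is a **barcode**, whose 15–20 nt SE (sticky-end) core is
shared by its two halves `L+SE` and `SE+R`. In a plasmid, fragments and
barcodes strictly alternate around the circle; neighbouring fragments each
carry one half of the barcode between them, and assembly is driven by the
re-pairing of those halves — as long chemically exposed sticky ends (CLIVA),
as homology regions (Gibson / In-fusion), or through restriction sites
embedded in the barcode.

The toolkit automates everything between a part list and a verified plasmid
map:

* **Grammar validation** of fragments, barcodes and whole designs
  (alternation, SE uniqueness, length bounds).
* **Oligo design** for all four families of the standard:
  - *Foligos* — PCR primers with a phosphorothioate (PS) bond after the
    first base (chemical route) or a Type IIS cassette `AS+RS+SS+binding`
    (enzymatic route); both yield a fragment flanked by 1-nt 3′ overhangs
    (`T` at the native 3′ end, `C` opposite the native 5′ `G`);
  - *Noligos* — two plain oligos annealed directly into short (36–59 nt)
    fragments;
  - *Boligos* — the four ≤90 nt, 5′-phosphorylated stem-loop oligos per
    barcode (`{L,R}` half × `{G,A}` 3′ base) whose sealed loop makes the
    barcoded fragment a closed dumbbell with no free ligatable ends;
  - *Aoligos* — the PS-modified ligation-PCR primers matching each Boligo.
* **Junction resolution**: any of the eight flip configurations of two
  fragments around a barcode resolves to a pair of the barcode's four stock
  Boligos — no custom oligo is ever needed, including for plasmid edits
  (replace / delete / insert) and second-tier RE or Golden-Gate subcloning.
* **Strand-level simulation** of the whole chemistry — PCR, PS cleavage,
  Type IIS digestion, hairpin folding, 1-nt sticky-end ligation,
  ligation-PCR, long-sticky-end assembly — which must reproduce, base for
  base, the product the design declares.
* **Combinatorial libraries**: choice slots and operon-shuffle slots
  (n! orderings with positional internal barcodes), screening-depth and
  assembly-accuracy bookkeeping, and colony-PCR QC prediction.

## Worked example

```python
from gts import (AssemblyDesign, simulate_design, design_boligos,
                 design_aoligos, resolve_junctions, FixtureSpec, generate_parts)

reg = generate_parts(FixtureSpec(seed=1, n_fragments=4, n_barcodes=4))
d = AssemblyDesign.from_strings(
    "demo", ["N01", "f001", "N02", "<f002", "N03", "f003"])   # "<" = flipped

for fj in resolve_junctions(d, reg):
    print(fj.fragment, fj.upstream.barcode_id, fj.upstream.boligo_role,
          "|", fj.downstream.barcode_id, fj.downstream.boligo_role)

product = simulate_design(d, reg)          # raises on any strand-level mismatch
print(len(product), "bp,", len(product.features), "features")
print(design_boligos(reg.barcode("N02"))["RG"].vendor_string())
print(design_aoligos(reg.barcode("N02"))["RG"].vendor_string())
```

prints

```
f001 N01 RG | N02 LA
<f002 N02 RA | N03 LG
f003 N03 RG | N01 LA
437 bp, 6 features
/5Phos/TTCATGAGGGACTGCTCGTACCTTTTTTGGTACGAGCAGTCCCTCATGAAG
GGTACGAG*CAGTCCC*TCATGAAG
```

Reading the output: the forward fragment `f001` takes the `RG` Boligo of its
upstream barcode and the `LA` Boligo of its downstream barcode; flipping
`f002` swaps it to the `RA`/`LG` pair — still stock oligos. The simulated
product is a 437-bp circle whose six features (3 barcodes + 3 fragments)
tile it exactly, i.e. every junction is scarless. The Boligo order string
shows the 5′-phosphate and the hairpin (arm – `TTTTTT` loop – complementary
arm – unpaired `G`); the Aoligo shows its two PS bonds (`*`), whose iodine
cleavage later exposes the full 16-nt SE as a sticky end.

The same pipeline runs headless:

```bash
gts --seed 3 fixtures --out work
gts --seed 3 simulate --registry work/registry.csv --design work/design.yaml --out work
```

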