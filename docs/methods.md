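# Methods

This note documents the models and numeric choices behind `gts`: how the
standard's chemistry is represented, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design was
genuinely open.

## The part grammar

Three rules define the standard. A *fragment* is any sequence of ≥36 nt
starting `G` and ending `T`; a *barcode* is any 20–80 nt sequence
decomposed as `L–SE–R` with a 15–20 nt SE; in a design, fragments and
barcodes strictly alternate around the circle. The two conserved terminal
bases of a fragment are the entire junction overhead: the 3′ `T` can open
any of the 16 T-leading codons (including all three stops) and the 5′ `G`
can close ATG or 15 other G-ending codons, which is why most joins are
scarless (`enumerate_junction_codons` enumerates these by brute force over
the 64 codons; the two sets intersect in the four `T·N·G` codons).

Beyond the published bounds we enforce one derived constraint at barcode
validation time: each half (`L+SE`, `SE+R`) may be at most 41 nt. A Boligo
hairpin for a half of length *h* is `2 h + 7` nt (two arms, 6-nt loop, one
unpaired base) and the standard caps Boligos at 90 nt, so `h ≤ 41`. The
published 80-nt barcode cap is therefore not reachable in full (max
`41 + 41 − 15 = 67` with a 15-nt SE); both caps are enforced and the
stricter one wins. Checking this early means oligo design can never fail
late.

## Melting temperature

SE acceptance and primer binding both use a duplex melting temperature under
the unified nearest-neighbor model (SantaLucia 2004 parameter set), two-state
approximation, entropic salt correction `ΔS + 0.368 (N−1) ln[Na⁺]`, at
50 mM monovalent salt and 500 nM per strand. Thresholds: 48 °C for SEs,
60 °C for primer binding sites; both configurable via YAML. The standard
names no model or thresholds; these are this package's defaults, chosen as
ordinary synthesis-oligo conditions. The implementation delegates to
Biopython's `Tm_NN`; the test suite re-derives the same quantity from an
independently coded parameter table and requires agreement to 0.1 °C over
1 000 random 15–20-mers.

## Oligo families and the strand model

The simulator's one data structure is `Duplex`: the top-strand sequence over
the union of both strands plus the half-open interval each strand covers.
Overhang type, length and polarity then fall out of interval arithmetic, and
flipping a molecule is a coordinate reflection. A prepared fragment is
always `extent = fragment`, `top = [1, n)`, `bottom = [0, n−1)` — i.e. 1-nt
3′ overhangs `T` (top, native 3′ end) and `C` (bottom, opposite the native
5′ `G`). All three preparation routes must produce exactly this object:

* *PS route*: primers are fragment prefixes with a PS bond after base 1;
  complete iodine cleavage removes the first base of each strand.
* *Type IIS route*: primers are `AS (6 random nt) + recognition + spacer +
  binding`; the spacer length is `top_cut_offset − 1` so the cut lands one
  base inside the fragment and leaves the same 1-nt 3′ overhang. Design
  retries random padding until the amplicon carries exactly the two intended
  sites. Requires a fragment free of internal sites for the chosen enzyme.
* *Noligo route* (36–59 nt): the two annealed oligos are the fragment minus
  its leading `G` and the reverse complement minus its leading `A`.

Equality of the three routes is asserted on sequence and end geometry.
5′-phosphate state deliberately does not enter that equality: RE digestion
leaves phosphates while chemical cleavage and plain synthesis oligos do not,
and a junction only needs one covalently sealed strand — which the Boligo's
mandatory 5′-phosphate always provides (polymerase extension through the
other strand then restores it during ligation-PCR).

Boligo layout: the L-half hairpin is `(L+SE) + loop + revcomp(L+SE) + b`,
the R-half hairpin `revcomp(SE+R) + loop + (SE+R) + b`, with `b ∈ {G, A}`
the single unpaired 3′ base. This arm order is derived, not free: it is the
unique choice for which the junction oligo required by *every* one of the
eight flip configurations is one of the four stock variants, and the
round-trip simulation verifies it. The default 6-nt loop is `TTTTTT`; a loop
whose two terminal bases are Watson–Crick complementary is rejected, since
that pair would extend the stem and shrink the loop. Each Aoligo is its
Boligo's post-loop arm plus the overhang base, with PS bonds at the SE/inner
boundary (bond |SE|, so complete cleavage exposes the full SE) and at the SE
center. The boundary-bond placement is a reasoned reconstruction (the
sources show the positions only graphically); it is pinned down here by the
requirement that activation exposes exactly the SE, which the round-trip
oracle checks.

## Junction resolution

With orientations `f` (fragment) and `B` (barcode), the stock role at a
fragment's junctions is:

| side       | half                    | base                     |
|------------|-------------------------|--------------------------|
| upstream   | R if B forward, else L  | G if f forward, else A   |
| downstream | L if B forward, else R  | A if f forward, else G   |

equivalently: the overhang base is `G` exactly when the fragment's native 5′
end faces the junction. The mapping from the 8 orientation assignments of
(f1, B, f2) to Boligo pairs is injective (tested by enumeration).

## Assembly

`assemble` builds a junction graph over piece ends. Sticky modes (chemical
long sticky ends, Golden Gate, conventional RE) join a top-strand 3′
overhang to a bottom-strand 3′ overhang with identical top-sense sequence
(and 5′/5′ likewise); overlap modes (Gibson / In-fusion) join on exact
terminal homology of ≥15 nt, the SE being the homology region — whether
those methods need more overlap than the SE is not settled by the sources,
and the simulator treats the SE as sufficient. Every closed path over all
pieces, deduplicated by canonical rotation/strand form (Booth's least
rotation over both strands), is a product. An end with more than one
distinct partner raises `ambiguous-assembly`; an end pairing with its own
mirror image (possible only for self-complementary overhangs, i.e.
dimerization of two copies) is not counted, since directional two-enzyme
cloning would otherwise always be flagged. Cleavage and digestion are
modelled as complete; partial products are out of scope.

The central invariant — the repository's primary acceptance property — is
the round trip: for seeded random valid designs of 2–7 fragments with
arbitrary flips, designing all oligos, preparing, barcoding, activating and
assembling yields exactly one circular product whose canonical sequence
equals the concatenation of the oriented parts. `simulate_design` recomputes
both sides and raises on any disagreement; the suite runs 100 such designs
in well under a minute.

`simulate_design` covers the chemistries where barcode halves drive assembly
directly (cliva/gibson/infusion). Designs using restriction enzymes are
second-tier operations on already-built plasmids and go through
`plan_re_subcloning`, which digests the inputs, keeps each plasmid's
marker-containing piece (the in-silico counterpart of gel purification) and
requires a unique circular ligation product. Reassembled junctions retain
their recognition sites — that is what keeps modules replaceable later.

## Edits

Edits are planned purely in stock oligos. *Replace* amplifies the backbone
with the outward Aoligos of the two barcodes flanking the target and
barcodes the new fragment with those same barcodes. *Delete* excises the
target together with one adjacent fragment (named in the request, upstream
by default) and the barcode between them, then re-barcodes that neighbor
with the outer barcodes — removing a lone fragment would leave two adjacent
barcodes and break alternation. *Insert* re-barcodes an anchor fragment
with (outer barcode, new barcode) and barcodes the new fragment with (new
barcode, other outer barcode). The insert scheme is this package's design
choice: a new barcode absent from the parent plasmid offers no primer
binding site, so the backbone must be opened at an existing fragment whose
re-barcoding introduces the new junction; this is the only insertion closed
under stock oligos. Every edit result is re-validated and its simulation
must match its declaration.

## Screens

The SE self-ligation screen rejects SEs containing a self-reverse-
complementary run of ≥8 nt (configurable; only even lengths can be
self-complementary, so scanning at the rounded-up bound suffices). The
barcode-set screen scores every pair by the longest perfect duplex formed
between overhang variants {SE, revcomp(SE)} — computed as longest common
substring against the reverse complement — flagging pairs at ≥10 nt and
treating duplicated SEs (identical or mutually reverse-complementary) as a
hard failure. Both cutoffs are package choices where the standard states
the requirement without a rule; they are deliberately conservative proxies,
not thermodynamic fidelity predictions.

Silent mutagenesis removes internal Type IIS sites from coding fragments by
the minimal synonymous edit (fewest changed nucleotides, then lowest
position; single-codon before two-codon substitutions) that destroys the
site on both strands, creates no new site for any panel enzyme anywhere in
the fragment, and leaves the fragment grammar-valid. Methionine/tryptophan-
only stretches correctly yield `no-synonymous-fix-exists`.

## Enzyme table

Enzyme geometry is data, not code: a bundled CSV of recognition sequence and
top/bottom cut offsets (top-strand coordinates from the recognition start;
sites found on the bottom strand are mirrored). The 1-nt 3′-overhang panel
is MboII, HphI, BmrI, BciVI, plus MnlI as a provisional fifth member; the
panel order is the documented deterministic tie-break for enzyme choice.
BciVI's offsets are set to the 1-nt overhang geometry; the I-CeuI entry uses
a 19-bp recognition core with approximate offsets (homing-endonuclease
geometry varies between sources) and is marked accordingly in the table.

## Synthetic data

`gts.fixtures` generates seeded registries: fragments spanning the Noligo
range through multi-hundred-nt amplicons at mid-band GC, only emitting
fragments whose termini admit primers at the configured threshold (as a
curated real registry would); barcodes built around SEs that pass the Tm and
self-ligation screens; optional implanted recognition sites and coding
fragments (frame 1, `ATG … stop`) with in-frame sites for mutagenesis
fixtures. The generator emulates the *grammar and screening* properties of
real part libraries, not their biology: no codon-usage realism, no repeats,
no secondary-structure pathologies, no polymerase errors (the dominant
error source in real workflows) and no ligation-fidelity thermodynamics.
Passing tests therefore certify the bookkeeping and chemistry logic, not
wet-lab success rates. Default problem sizes (14-part registries, 100
round-trip designs, 200-barcode oligo corpora) were chosen as comfortably
representative while keeping the whole suite around a second of runtime.

## Known limitations

* Folding checks are exact-complementarity checks, not free-energy models;
  primer–dimer scanning is out of scope.
* Gibson/In-fusion chew-back kinetics are abstracted to overlap identity.
* IUPAC ambiguity codes, RNA parts and methylation sensitivity are not
  supported.
* `assemble` enumerates products by DFS over piece orientations; it is meant
  for design verification (≤ tens of pieces), not for genome-scale digests.
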