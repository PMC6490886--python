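# Methods

This note documents the models, rules and numerical conventions behind
`pksdecode`, the choices made where the underlying biology leaves the design
open, and what the synthetic-data suites do and do not demonstrate.

## Domain model and fingerprint rules

A modular type I PKS multienzyme is treated as a string of catalytic
domains. Published sequence analyses define the *chemistry* of these domains
through a handful of active-site residues but not their boundaries, so the
package separates the two concerns:

* **Location.** Every domain type carries a constant *locator* block — a
  conserved stretch such as the KS N-terminal EPIAIVGxACRFPG region, the AT
  GQGSQ block, the KR Rossmann GGxGxxG motif or the ACP phosphopantetheine
  DSL serine block — at a fixed offset inside a fixed-length window. Hits
  are exact locator matches, reported N→C and non-overlapping; windows
  clipped by a protein end are flagged partial and excluded from
  classification. Externally derived intervals (e.g. from a profile-HMM
  scan) can be injected in place of locator scanning.
* **Classification.** Fingerprint *slots* sit at fixed offsets from the
  block start, and every call is a pure function of the slot residues:
  flanking sequence can never change a call (property-tested by mutating
  non-anchor positions). The rules are exactly the field's published ones —
  AT: GHSQ+HAFH malonyl, GHS(I/L/V)+YASH methylmalonyl, GHSx with a
  divergent small-residue second motif (SPGH/VASH) exotic alkylmalonyl,
  recognized-but-discordant pairs surface as `unknown` with a
  `discordant` flag rather than a guess; DH: active only with both the
  Hxxx(G/D)xxxxPG His and the Dxxx(Q/H) Asp, with the substitution named
  (His→Arg, His→Tyr, …); KR: activity from the catalytic Tyr (missing
  Lys/Ser degrade confidence only), B1 from the LDD Asp, A-type from the
  diagnostic Trp, A2 from the His-for-Gln substitution; ER: Tyr motif →
  (2S), otherwise (2R); KSQ: Gln at the KS catalytic-Cys slot.

All anchors, offsets and rule strings live in `data/domain_profiles.yaml`
and are user-editable; the packaged offsets are the generator's layout, not
empirical alignments, which is the honest statement of what this package
can claim: the classification logic is exact, the localization layer is a
well-specified stand-in for profile alignment on real sequences.

The KR stereo mapping is exposed as config. The source literature's table
assigns A1 → (2S,3R) and *both* B1 and A2 → (2R,3R) even though A2 is an
A-type subclass; this looks like a printed inconsistency, so the package
defaults to the as-printed mapping, flags every A2 call with
`A2-stereo-as-printed`, and lets the user override the table.

## Assembly line

Modules are parsed per protein by the grammar `KS (AT) (DH) (ER) (KR) ACP`,
with an N-terminal `KSQ AT ACP` loading didomain (KSQ decarboxylation of
the AT's substrate gives the starter: methylmalonyl → propionate, malonyl →
acetate) and a chain-terminating TE. A module's reduction level is the
maximal reduction its *active* domains support: no/inactive KR → ketone,
no/inactive DH → hydroxyl, no ER → enoyl, full complement → methylene.
Orphan or truncated modules are flagged malformed, reported, and excluded
from ordering.

**Ordering.** The loading-bearing protein is pinned first and the
TE-bearing protein last; the remaining proteins are permuted exhaustively
(practical to 8 proteins, the scale of these clusters) and each arrangement
is scored by per-cycle mismatch against the target backbone: 1 per
differing extender class, 1 per differing reduction level, 0.5 when only a
specified stereo label differs (weights are config). Without a loading
module *and* without a TE the orientation is declared ambiguous (error
with the candidate set) rather than guessed.

**Iteration.** With k more target cycles than physical modules, k stutter
events are enumerated: a module may serve r ≥ 1 *consecutive* cycles, and a
multi-cycle block is admissible only if its target cycles are chemically
identical (same extender, reduction and stereo labels). All admissible
placements are scored; ties break toward the earliest stuttered cycle and
are reported, never hidden. The mapping is monotone by construction
(stuttering, not revisiting), and cycles = modules + stutter events in
every returned assignment. More modules than cycles (module skipping) is
out of scope and raises. Both searches are validated against brute-force
composition/permutation oracles implemented independently in the test
suite.

## The ossamycin fixtures

The packaged fixtures transcribe the cluster table (27 ORFs), the
multienzyme domain calls, the 15-cycle target backbone and the tailoring
events. Backbone numbering follows the assembly arithmetic: C-1 at the
carboxy terminus, cycle i of 15 contributing C-(31−2i)/C-(32−2i), the
propionate starter C-31..C-33, and the isobutyl side chain of the unusual
extender numbered C-34..C-37 (which is where the side-chain hydroxylation
site C-35 falls). Anchored cells of the target are fixed by explicit
statements about the system: AT2 predicts methylmalonyl where malonyl is
installed at C-27/C-28 (kept as a reported discrepancy, with the target
extender used for the product); AT7 selects isobutyrylmalonyl via SPGH;
DH1/DH7 are dead via His→Arg/His→Tyr; modules 4 and 7 lack KR, leaving
ketones at C-25 (the spiroacetal carbonyl) and C-19; the cycle-11 module's
ER carries the Tyr motif ((2S) α-methyl at C-10); cycles 9/10 are malonyl
and fully reduced; the TE cyclizes onto the C-23 hydroxyl (24-ring).
Figure-resident cells (the remaining extender/reduction/stereo entries) are
transcribed at lower confidence and marked `figure` in the YAML; they were
chosen once to be chemically coherent with the anchors — in particular the
module complement sequence is non-degenerate, so the established protein
order OssA1→…→OssA8 and the 9/10 iteration are the unique best
reconciliation, matching the fact that the true order *was* established
for this system — and they are not revisited. Which monomodular protein
(OssA5 vs OssA6) houses the iterated module is not asserted a priori; the
call tables resolve it (the malonyl-specific monomodule serves 9/10) and
tests only pin the set.

## Product model

The chain is assembled unit-by-unit from the cycle→module assignment; each
unit's β-state comes from its module, with target-extender overrides only
for cycles the assignment flags as discrepant (the AT2 case — otherwise
the predicted product would carry a methyl the compound lacks).
Macrolactonization at carbon c requires a chain hydroxyl there and gives a
ring of c+1 atoms; rings below 12 atoms are flagged implausible but not
rejected. Tailoring events apply ordered formula deltas — hydroxylation
+O; glycosylation + (residue − H2O), with the ossamine residue formula
derived from the sugar-pathway engine rather than hard-coded; the single
ordering constraint is that glycosylation needs a hydroxyl already present
at its site. Spiroacetal closure is bookkept formula-neutral by default
(ketone + hydroxyls retained) because its timing and enzymology are open;
`acetal_convention="ketal"` switches to −H2O. The neutral convention is
validated by the only mass anchor available: the model minus one
hydroxylation reproduces the measured des-hydroxy ion [M+H]+ 896.5 within
0.18 Da (tolerance 0.3), and removing a hydroxylation shifts the
monoisotopic mass by exactly 15.9949 Da.

Formulas are computed by exact valence bookkeeping (atom counts plus
degrees of unsaturation, all known from the model), with monoisotopic
masses from an internal CHNOPS table; the emitted SMILES is
constitution-exact (stereo labels are reported per unit, not as chirality
marks) and round-trips to the same formula through RDKit in the tests.
Enoyl geometry (E/Z) is recorded as unassigned: no geometry rule is
modelled.

## Sugar pathway

A rule engine over role assignments: two recruited pre-steps
(dTDP-d-glucose synthase, 4,6-dehydratase; flagged external), then
2,3-dehydration, 3-ketoreduction, 3,4-dehydration (the undefined external
reductase is folded into this step's delta), epimerisation, 4-transamination
and N,N-dimethylation, each with a fixed formula delta from d-glucose;
glycosyl transfer terminates the graph. The early-epimerisation branch
moves epimerisation before 3,4-dehydration (dTDP-l-kedarosamine-type
intermediate); both branches yield the same residue formula (C8H17NO2) by
construction, and the engine verifies substrate/product chaining is
gap-free. Missing roles are data (listed), not errors; the epimerisation
transform tag is deliberately generic (5- vs 3,5-epimerisation is not
settled).

## Synthetic data

The generator emits multienzymes as domain blocks joined by random linkers
(12–30 aa), with background drawn from a fixed, actinobacteria-biased
amino-acid frequency profile (deliberately non-uniform, keeping accidental
motif matches rare) and a collision scrubber that redraws any window that
recreates a locator off-plan. One integer seed drives everything through
per-protein substreams (stable integer hashing), so output is
byte-identical per seed. A mutation rate applies only outside anchors and
slots. What this emulates: the motif grammar, module packing, loading/TE
placement, decoys, and planted iteration. What it does not: real domain
boundary variation, locator divergence, indels, or phylogenetic structure —
so passing round-trips demonstrate the correctness of the classification,
ordering and iteration logic, not the recall of the locator scanner on
natural sequences (for which the interval-injection hook exists).

Test problem sizes were chosen to keep the suites sharp and quick: the
randomized suites use 2–4 proteins with 1–3 modules each (distinct module
chemistries, so planted order and stutter are uniquely recoverable), 200
seeded configurations in the acceptance property, and exhaustive oracles on
every instance.

## Known limitations

* Locator-based domain location is exact only for sequences that carry the
  configured anchor blocks verbatim; real multienzymes need externally
  supplied intervals or retuned profiles.
* Stereo labels follow the as-printed KR/ER tables, including the flagged
  A2 oddity; no structure-based stereochemistry is attempted.
* The figure-derived cells of the target backbone are a coherent
  transcription, not measured data; the product formula (C51H93NO12) is
  anchored only through the des-hydroxy ion check and carries that cell
  uncertainty.
* Trans-AT systems, module skipping, non-TE release chemistry and enzyme
  kinetics are out of scope.
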