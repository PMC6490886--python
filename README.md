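# pksdecode

Bioinformatic decoding of modular type I polyketide synthase (PKS) gene
clusters, built around the ossamycin biosynthetic gene cluster of
*Streptomyces hygroscopicus* var. *ossamyceticus* as the worked system.

Ossamycin is a 24-membered macrocyclic polyketide bearing a 6,6-spiroacetal
and the rare deoxyaminosugar l-ossamine. Its gene cluster (27 ORFs, ~127
kbp) encodes eight giant multienzymes, OssA1–OssA8, that together contain
only **14 extension modules although 15 chain-extension cycles** are needed
for the product — a rare case of *programmed iteration*, where one module
"stutters" and performs two consecutive, chemically identical extensions.
`pksdecode` reproduces the reasoning that uncovers this: it classifies gene
roles, reads the active-site fingerprints of every catalytic domain, infers
the order of the multienzymes against the required backbone, finds the
iterated module, assembles the predicted product, and reconstructs the
sugar pathway.

## What it computes

* **Role classification** (`cluster_io`) — an ordered, first-match keyword
  rule table over the free-text annotations of a cluster table
  (TSV/GenBank/GFF3) with a closed role vocabulary.
* **Domain grammar** (`domain_grammar`) — anchored locator-block scanning of
  multienzyme sequences and rule-based fingerprint classification:
  * AT extender choice: GHSQ + HAFH → malonyl; GHS(I/L/V) + YASH →
    (2*S*)-methylmalonyl; a GHSx serine motif with a divergent
    small-residue second motif (SPGH, VASH) → exotic alkylmalonyl;
  * DH activity: essential His in Hxxx(G/D)xxxxPG *and* Asp in Dxxx(Q/H);
  * KR activity (Lys/Ser/Tyr triad, Tyr decisive) and stereotype: LDD Asp →
    B1; diagnostic Trp → A-type, His-for-Gln → A2 (Keatinge-Clay naming);
  * ER α-outcome: Tyr motif → (2*S*), else (2*R*);
  * KSQ loading domains: Gln replacing the KS catalytic Cys.
* **Assembly line** (`assembly_line`) — modules from the grammar
  KS·AT·(DH)·(ER)·(KR)·ACP; exhaustive protein-order search pinned by the
  loading module and the TE; iteration detection by scored enumeration of
  stutter placements over consecutive, chemically identical target cycles.
* **Product** (`product_builder`) — chain assembly (C-1 at the carboxy
  terminus; backbone carbons = starter + 2×cycles), TE macrolactonization
  (ring size = cyclization carbon + 1), post-PKS tailoring (P450
  hydroxylations, ossaminyl transfer, spiroacetal bookkeeping), exact
  monoisotopic mass/formula, SMILES export.
* **Sugar pathway** (`sugar_pathway`) — the six cluster-encoded steps from
  dTDP-4-keto-6-deoxy-d-glucose to dTDP-l-ossamine (plus two recruited
  pre-steps), with the alternative early-epimerisation branch, and the
  glycosyl residue formula derived by per-step deltas (C8H17NO2).
* **Synthetic data** (`synthetic_data`) — multienzyme sequences with
  planted motifs in profile-biased background, with complete ground truth,
  so the whole stack is testable without downloads.

## Worked example

Run the packaged fixtures (cluster table, transcribed domain calls, target
backbone, tailoring events) end to end:

```
$ pksdecode run --out run/
27 genes | 14 extension modules | 15 cycles | iterated: ['OssA5:m1'] | ring size 24 | [M+H]+ 912.6771
report: run/report.json
```

Reading the line: the cluster has 27 genes (8 modular PKS, 4 cytochrome
P450s, 6 ossamine-pathway genes); the eight multienzymes order as
OssA1→A2→A3→A4→A5→A6→A7→A8 with the monomodular OssA5 module serving
cycles 9 *and* 10 (both malonyl, fully reduced) — 14 modules, 15 cycles;
cyclization at the C-23 hydroxyl closes a 24-membered macrolactone, and the
fully tailored model (3 ring hydroxyls, a side-chain hydroxyl, ossamine at
C-8) has formula C51H93NO12, [M+H]+ 912.68. The report also records the
AT2 discrepancy (motifs predict methylmalonyl where the product requires
malonyl at C-27/C-28) and a 22-membered rebuild when the iteration is
suppressed — the structural relationship between the 22- and 24-membered
members of this compound family.

The sugar pathway:

```
$ pksdecode sugar
0. nucleotidylation     (unassigned)     alpha-d-glucose-1-phosphate -> dTDP-d-glucose [external]
1. 4,6-dehydration      (unassigned)     dTDP-d-glucose -> dTDP-4-keto-6-deoxy-d-glucose [external]
2. 2,3-dehydration      oss_s            dTDP-4-keto-6-deoxy-d-glucose -> dTDP-3,4-diketo-2,6-dideoxy-d-glucose
3. 3-ketoreduction      oss_t_sugar      dTDP-3,4-diketo-2,6-dideoxy-d-glucose -> dTDP-4-keto-2,6-dideoxy-d-glucose
4. 3,4-dehydration      oss_q            dTDP-4-keto-2,6-dideoxy-d-glucose -> dTDP-d-cinerulose
5. epimerisation        oss_z1           dTDP-d-cinerulose -> dTDP-l-cinerulose
6. transamination       oss_j            dTDP-l-cinerulose -> dTDP-4-amino-2,3,4,6-tetradeoxy-l-hexose
7. N,N-dimethylation    oss_i            dTDP-4-amino-2,3,4,6-tetradeoxy-l-hexose -> dTDP-l-ossamine
8. glycosyl transfer    oss_gt           dTDP-l-ossamine -> l-ossaminyl-aglycone
residue formula: C8H17NO2
```

Synthetic lines with planted ground truth:

```bash
pksdecode simulate --seed 7 --out sim/    # FASTA + ground truth + cluster TSV
pksdecode run --fasta sim/proteins.faa --out sim_run/
```

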