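# Post-PKS tailoring of the ossamycin macrolactone. Four stereospecific
# cytochrome-P450 hydroxylations decorate the macrocycle (C-4, C-8, C-10) and
# the side chain (C-35); l-ossamine is then transferred onto the C-8 hydroxyl
# (glycosyl transfer cannot occur without it). Site-to-enzyme assignment of
# the four P450s is left open by the deletion data (overlapping
# specificities), so agents are listed jointly. Spiroacetal closure at the
# C-25 ketone (with the C-21/C-29 hydroxyls) is bookkept formula-neutral by
# default; its timing and enzymology (putative spirocyclase OssO) are open.
events:
  - {kind: hydroxylation, site: 4,  agent: "cytochrome P450 (OssL/OssK/OssM/OssF; assignment open)"}
  - {kind: hydroxylation, site: 8,  agent: "cytochrome P450 (OssL/OssK/OssM/OssF; assignment open)"}
  - {kind: hydroxylation, site: 10, agent: "cytochrome P450 (OssL/OssK/OssM/OssF; assignment open)"}
  - {kind: hydroxylation, site: 35, agent: "cytochrome P450 (OssL/OssK/OssM/OssF; assignment open)"}
  - {kind: glycosylation, site: 8,  agent: "OssG(T) glycosyltransferase", sugar: l-ossamine}
  - {kind: spiroacetal, site: [25, 21, 29], agent: "OssO (putative spirocyclase)"}
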