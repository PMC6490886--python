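# Target backbone for ossamycin: the 15 chain-extension cycles required to
# elaborate the polyketide, transcribed from the published biosynthetic
# proposal. Backbone numbering: C-1 is the carboxy/thioester carbon; cycle i
# contributes carbons C-(31-2i) (carbonyl) and C-(32-2i) (alpha); the
# propionate starter contributes C-31..C-33. Each cycle's reduction level
# describes the fate of its beta carbon (= the carbonyl carbon delivered by
# the previous cycle / the starter).
#
# confidence: "anchored" cells are fixed by explicit statements about the
# system (AT2 malonyl-actual at C-27/C-28; AT7 isobutyrylmalonyl with SPGH;
# DH1/DH7 inactive; KR-less modules 4 and 7 leaving ketones at C-25 and C-19;
# iterated cycles 9/10 malonyl + fully reduced; cycle-11 module ER giving a
# 2S alpha-methyl; lactone hydroxyl at C-23). "figure" cells are transcribed
# from the pathway drawing and are lower-confidence.
starter:
  unit: propionate
  carbons: 3
  source: "loading KSQ + methylmalonyl-AT + ACP (decarboxylation)"
cyclization_carbon: 23
extensions:
  - {cycle: 1,  extender: methylmalonyl,         reduction: hydroxyl,  alpha_stereo: 2R,  beta_stereo: 3R,  confidence: figure}
  - {cycle: 2,  extender: malonyl,               reduction: hydroxyl,  alpha_stereo: null, beta_stereo: 3R, confidence: anchored}
  - {cycle: 3,  extender: malonyl,               reduction: methylene, alpha_stereo: null, beta_stereo: null, confidence: figure}
  - {cycle: 4,  extender: methylmalonyl,         reduction: ketone,    alpha_stereo: null, beta_stereo: null, confidence: anchored}
  - {cycle: 5,  extender: malonyl,               reduction: hydroxyl,  alpha_stereo: null, beta_stereo: 3R, confidence: anchored}
  - {cycle: 6,  extender: methylmalonyl,         reduction: hydroxyl,  alpha_stereo: 2S,  beta_stereo: 3R, confidence: figure}
  - {cycle: 7,  extender: unusual-alkylmalonyl,  reduction: ketone,    alpha_stereo: null, beta_stereo: null, confidence: anchored,
     sidechain: {carbons: 4, origin: isobutyrylmalonyl-CoA}}
  - {cycle: 8,  extender: methylmalonyl,         reduction: methylene, alpha_stereo: 2R,  beta_stereo: null, confidence: figure}
  - {cycle: 9,  extender: malonyl,               reduction: methylene, alpha_stereo: null, beta_stereo: null, confidence: anchored}
  - {cycle: 10, extender: malonyl,               reduction: methylene, alpha_stereo: null, beta_stereo: null, confidence: anchored}
  - {cycle: 11, extender: methylmalonyl,         reduction: methylene, alpha_stereo: 2S,  beta_stereo: null, confidence: anchored}
  - {cycle: 12, extender: malonyl,               reduction: methylene, alpha_stereo: null, beta_stereo: null, confidence: figure}
  - {cycle: 13, extender: methylmalonyl,         reduction: methylene, alpha_stereo: 2R,  beta_stereo: null, confidence: figure}
  - {cycle: 14, extender: malonyl,               reduction: methylene, alpha_stereo: null, beta_stereo: null, confidence: figure}
  - {cycle: 15, extender: malonyl,               reduction: enoyl,     alpha_stereo: null, beta_stereo: null, confidence: figure,
     geometry: unassigned}
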