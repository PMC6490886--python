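# Ordered keyword rules for functional role classification; first match wins.
# Patterns are case-insensitive regular expressions searched against the
# free-text "proposed function" of each gene. Override with --rules.
rules:
  - id: pks
    role: modular-PKS
    pattern: "polyketide synthase"
  - id: te2
    role: thioesterase-II
    pattern: "thioesterase"
  - id: regulator
    role: regulator
    pattern: "regulator|luxr"
  - id: ccr
    role: CCR
    pattern: "crotonyl-coa (carboxylase[ /]*)?reductase"
  - id: fabh
    role: FabH-like
    pattern: "ketoacyl-acp synthase iii|fabh"
  - id: p450
    role: cytochrome-P450
    pattern: "cytochrome p-?450"
  - id: spiro
    role: spirocyclase-like
    pattern: "spirocyclase"
  - id: sugar_23dh
    role: sugar-2,3-dehydratase
    pattern: "2,3-dehydratase"
  - id: sugar_3kr
    role: sugar-3-ketoreductase
    pattern: "3-ketoreductase"
  - id: sugar_34dh
    role: sugar-3,4-dehydratase
    pattern: "3,4-dehydratase"
  - id: sugar_epim
    role: sugar-epimerase
    pattern: "epimerase"
  - id: sugar_tam
    role: sugar-transaminase
    pattern: "transaminase"
  # "SAM-dependent" is required so that unrelated methyltransferases
  # (e.g. a serine hydroxymethyltransferase) fall through to "other".
  - id: sugar_nmt
    role: sugar-N-methyltransferase
    pattern: "sam-dependent methyltransferase|n,n-dimethyltransferase"
  - id: gt
    role: glycosyltransferase
    pattern: "glycosyl\\s?transferase"
  - id: transporter
    role: transporter
    pattern: "transporter|efflux"
  - id: hypothetical
    role: hypothetical
    pattern: "hypothetical"
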