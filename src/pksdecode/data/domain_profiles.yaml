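# Domain anchor profiles for modular type I PKS multienzymes.
#
# Published active-site fingerprints define catalytic residues, not domain
# boundaries, so each domain type is modelled as a fixed-length block carrying
# (a) a constant "locator" — a conserved block that identifies and anchors the
#     domain (e.g. the KS N-terminal EPIAIVGxACRFPG region, the AT GQGSQ
#     region, the KR Rossmann GGxGxxG motif) and is never mutated; and
# (b) fingerprint "slots" at fixed offsets from the block start, holding the
#     catalytic/specificity residues that the classifier interprets.
# Offsets are 0-based from block start; intervals reported to callers are
# 1-based inclusive. All offsets are editable here; externally supplied domain
# intervals (e.g. from profile HMM scans) can be injected via
# domain_grammar.scan_domains(..., intervals=...).
domains:
  KS:
    length: 220
    locator: "EPIAIVGMACRFPG"
    locator_offset: 12
    slots:
      KS_Q_substitution:
        offset: 80
        length: 8
        default: "VDTACSSS"   # catalytic Cys; Gln here marks a decarboxylative KSQ loading domain
        variant_index: 4
  AT:
    length: 170
    locator: "VFVFPGQGSQ"
    locator_offset: 10
    slots:
      AT_serine_motif:
        offset: 62
        length: 4
        default: "GHSQ"       # GHSQ=malonyl; GHS(I/L/V)=methylmalonyl serine motif
      AT_second_his_motif:
        offset: 120
        length: 4
        default: "HAFH"       # HAFH=malonyl; YASH=methylmalonyl; SPGH/VASH=divergent small-residue variants
  DH:
    length: 130
    locator: "GLDYGPAFRS"
    locator_offset: 8
    slots:
      DH_his_motif:
        offset: 30
        length: 11
        default: "HELLGGRSLPG"  # Hxxx(G/D)xxxxPG; His->Arg/Tyr at index 0 inactivates
        variant_index: 0
      DH_asp_motif:
        offset: 75
        length: 5
        default: "DAAFQ"        # Dxxx(Q/H)
        variant_index: 0
  ER:
    length: 140
    locator: "TLEPGGVGLA"
    locator_offset: 10
    slots:
      ER_tyr_motif:
        offset: 70
        length: 5
        default: "GYKAL"        # Tyr at index 1 -> (2S) alpha outcome; otherwise (2R)
        variant_index: 1
  KR:
    length: 150
    locator: "GTYLITGGLG"
    locator_offset: 8
    slots:
      KR_lys:
        offset: 40
        length: 1
        default: "K"
      KR_LDD_motif:
        offset: 60
        length: 3
        default: "LDD"          # Asp as 3rd residue -> B-type
      KR_A_trp:
        offset: 66
        length: 1
        default: "W"            # Trp -> A-type
      KR_A2_his_for_gln:
        offset: 75
        length: 1
        default: "Q"            # His here in an A-type KR -> A2
      KR_ser:
        offset: 95
        length: 1
        default: "S"
      KR_tyr:
        offset: 110
        length: 1
        default: "Y"            # catalytic Tyr, most important for activity
  ACP:
    length: 70
    locator: "NLGFDSLTAV"       # phosphopantetheine-attachment DSL serine block
    locator_offset: 25
    slots: {}
  TE:
    length: 110
    locator: "PLVLGGWSAG"       # GxSxG hydrolase block
    locator_offset: 15
    slots: {}

# Acyltransferase substrate rules: both fingerprints must agree.
at_rules:
  malonyl:
    serine: ["GHSQ"]
    second: ["HAFH"]
  methylmalonyl:
    serine: ["GHSI", "GHSL", "GHSV"]
    second: ["YASH"]
  # A GHS? serine motif combined with a divergent small-residue variant in the
  # second-His position marks selection of exotic alkylmalonyl extender units.
  unusual_second: ["SPGH", "VASH"]

# Ketoreductase type -> predicted product configuration labels (as printed in
# the motif literature this package follows; the A2 row repeats the B1 labels
# and is flagged as a printed inconsistency in reports — override here if a
# corrected mapping is preferred).
kr_stereochemistry:
  A1: {alpha: "2S", beta: "3R"}
  B1: {alpha: "2R", beta: "3R"}
  A2: {alpha: "2R", beta: "3R"}
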