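"""Domain location and active-site fingerprint classification."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pksdecode import domain_grammar as dg
from pksdecode import synthetic_data as sd


def _emit_single(spec, seed=1, loading=None, te=False, **kwargs):
    config = sd.GeneratorConfig(
        seed=seed, proteins=((spec,),), loading=loading, te=te, **kwargs
    )
    line = sd.emit_line(config)
    return line


def test_scan_recovers_planted_domains_in_order(profiles):
    spec = sd.ModuleSpec(at_substrate="malonyl", kr=sd.KRSpec("B1"))
    line = _emit_single(spec)
    pid, seq = line.sequences[0]
    hits = dg.scan_domains(seq, profiles, pid)
    assert [h.domain_type for h in hits] == ["KS", "AT", "KR", "ACP"]
    truth = line.ground_truth["proteins"][0]["domains"]
    assert [(h.domain_type, *h.interval) for h in hits] == [
        (d["type"], d["start"], d["end"]) for d in truth
    ]
    assert not any(h.partial for h in hits)


def test_decoy_sequence_yields_no_hits(profiles):
    config = sd.random_line_config(3, decoy_count=2)
    line = sd.emit_line(config)
    decoys = [seq for pid, seq in line.sequences if pid.startswith("decoy")]
    assert decoys
    for seq in decoys:
        assert dg.scan_domains(seq, profiles) == ()


def test_short_sequence_is_empty_not_error(profiles):
    assert dg.scan_domains("MKT", profiles) == ()


def test_illegal_characters_raise(profiles):
    with pytest.raises(dg.SequenceError, match="illegal"):
        dg.scan_domains("MKTA*JB", profiles)


def test_ksq_loading_didomain_recognized_as_ksq(profiles):
    spec = sd.ModuleSpec(at_substrate="malonyl", kr=sd.KRSpec("A1"))
    line = _emit_single(spec, loading=sd.LoadingSpec("methylmalonyl"))
    _, seq = line.sequences[0]
    hits = dg.scan_domains(seq, profiles)
    assert [h.domain_type for h in hits] == ["KSQ", "AT", "ACP", "KS", "AT", "KR", "ACP"]


@pytest.mark.parametrize(
    "serine, second, substrate",
    [
        ("GHSQ", "HAFH", "malonyl"),
        ("GHSI", "YASH", "methylmalonyl"),
        ("GHSL", "YASH", "methylmalonyl"),
        ("GHSV", "YASH", "methylmalonyl"),
        ("GHSV", "SPGH", "unusual-alkylmalonyl"),
        ("GHSV", "VASH", "unusual-alkylmalonyl"),
        ("GHSQ", "SPGH", "unusual-alkylmalonyl"),
        ("AHSQ", "HAFH", "unknown"),
    ],
)
def test_at_substrate_rules(profiles, serine, second, substrate):
    call = dg.at_call_from_motifs(serine, second, profiles)
    assert call.substrate == substrate


def test_at_discordant_motifs_surface_not_guess(profiles):
    call = dg.at_call_from_motifs("GHSQ", "YASH", profiles)
    assert call.substrate == "unknown"
    assert call.confidence.startswith("discordant")


@pytest.mark.parametrize(
    "ldd, trp, a2, tyr, active, kr_type, beta",
    [
        ("LDD", "F", "Q", "Y", True, "B1", "3R"),  # d-configured 3-hydroxy
        ("LNA", "W", "Q", "Y", True, "A1", "3R"),
        ("LNA", "W", "H", "Y", True, "A2", "3R"),
        ("LNA", "W", "Q", "F", False, "unknown", None),  # catalytic Tyr absent
        ("LNA", "F", "Q", "Y", True, "unknown", None),
    ],
)
def test_kr_typing(profiles, ldd, trp, a2, tyr, active, kr_type, beta):
    call = dg.kr_call_from_motifs("K", "S", tyr, ldd, trp, a2, profiles)
    assert call.active is active
    assert call.kr_type == kr_type
    assert call.beta_config == beta
    if kr_type == "A2":
        assert "A2-stereo-as-printed" in call.flags


def test_kr_missing_lys_downgrades_confidence_not_activity(profiles):
    call = dg.kr_call_from_motifs("R", "S", "Y", "LDD", "F", "Q", profiles)
    assert call.active
    assert call.confidence == "triad-degraded"


@pytest.mark.parametrize(
    "his, asp, active, reason",
    [
        ("HELLGGRSLPG", "DAAFQ", True, "intact"),
        ("RELLGGRSLPG", "DAAFQ", False, "His->Arg"),
        ("YELLGGRSLPG", "DAAFQ", False, "His->Tyr"),
        ("HELLGGRSLPG", "NAAFQ", False, "Asp->Asn"),
        ("HELLVGRSLPG", "DAAFQ", False, "degenerate-motif"),  # G/D position broken
    ],
)
def test_dh_activity_needs_both_motifs(his, asp, active, reason):
    call = dg.dh_call_from_motifs(his, asp)
    assert call.active is active
    assert call.reason == reason


def test_er_tyr_motif_controls_alpha_outcome(profiles):
    assert dg.er_call_from_motifs("GYKAL", profiles).alpha_outcome == "2S"
    assert dg.er_call_from_motifs("GVKAL", profiles).alpha_outcome == "2R"


def test_classify_contract_violation(profiles):
    spec = sd.ModuleSpec(at_substrate="malonyl", kr=sd.KRSpec("A1"))
    line = _emit_single(spec)
    _, seq = line.sequences[0]
    hits = dg.scan_domains(seq, profiles)
    kr_hit = next(h for h in hits if h.domain_type == "KR")
    with pytest.raises(ValueError, match="requires a AT hit"):
        dg.classify_at(kr_hit, profiles)


def test_truncated_domain_flagged_partial_and_unclassified(profiles):
    spec = sd.ModuleSpec(at_substrate="malonyl", kr=sd.KRSpec("A1"))
    line = _emit_single(spec)
    pid, seq = line.sequences[0]
    full_hits = dg.scan_domains(seq, profiles)
    acp = next(h for h in full_hits if h.domain_type == "ACP")
    # keep the ACP locator but truncate the block before its window ends
    cut = seq[: acp.interval[0] - 1 + 40]
    calls = dg.classify_protein(pid, cut, profiles)
    assert calls[-1].domain_type == "ACP"
    assert calls[-1].partial
    assert calls[-1].call is None and calls[-1].fingerprints == ()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), rate=st.floats(0.0, 0.25))
def test_classification_depends_only_on_fingerprints(seed, rate):
    """Mutating non-anchor flanking positions never changes any call."""
    profiles = dg.load_profiles()
    config = sd.random_line_config(seed)
    clean = sd.emit_line(dataclasses.replace(config, mutation_rate=0.0))
    noisy = sd.emit_line(dataclasses.replace(config, mutation_rate=rate))

    def summarize(line):
        out = []
        for pid, seq in line.sequences:
            for c in dg.classify_protein(pid, seq, profiles):
                key = (pid, c.domain_type)
                call = c.call
                if call is None:
                    out.append(key)
                elif isinstance(call, dg.ATCall):
                    out.append(key + (call.substrate,))
                elif isinstance(call, dg.KRCall):
                    out.append(key + (call.active, call.kr_type))
                elif isinstance(call, dg.DHCall):
                    out.append(key + (call.active, call.reason))
                elif isinstance(call, dg.ERCall):
                    out.append(key + (call.alpha_outcome,))
        return out

    assert summarize(clean) == summarize(noisy)


def test_injected_intervals_bypass_locator_scanning(profiles):
    spec = sd.ModuleSpec(at_substrate="methylmalonyl", kr=sd.KRSpec("A1"))
    line = _emit_single(spec)
    pid, seq = line.sequences[0]
    truth = line.ground_truth["proteins"][0]["domains"]
    intervals = [(d["type"], d["start"], d["end"]) for d in truth]
    hits = dg.scan_domains(seq, profiles, pid, intervals=intervals)
    assert [h.domain_type for h in hits] == [d["type"] for d in truth]
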