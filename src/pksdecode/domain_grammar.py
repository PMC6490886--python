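"""Locate PKS catalytic domains and classify their active-site fingerprints.

The grammar of a modular type I PKS multienzyme is a string of catalytic
domains (KS/KSQ, AT, DH, ER, KR, ACP, TE).  Published sequence analyses define
these domains by short conserved blocks and predict their chemistry from a
handful of active-site residues:

* AT extender-unit choice from the serine motif (GHSQ = malonyl,
  GHS(I/L/V) = methylmalonyl) together with the second-His motif (HAFH vs
  YASH; divergent small-residue variants such as SPGH or VASH mark exotic
  alkylmalonyl units);
* DH activity from an essential His in Hxxx(G/D)xxxxPG and an essential Asp
  in Dxxx(Q/H);
* KR activity from the Lys/Ser/Tyr catalytic triad (Tyr the most important),
  and stereotype from the LDD Asp motif (B-type) vs a diagnostic Trp (A-type),
  with a His-for-Gln substitution separating A2 from A1;
* ER alpha-stereochemistry ((2S) vs (2R)) from a Tyr-containing motif;
* a Gln in place of the KS catalytic Cys marking a decarboxylative loading
  (KSQ) domain.

Domain *boundaries* are not defined by those fingerprints, so location uses
anchored locator blocks with fixed-length windows and fingerprint slots at
fixed offsets (``data/domain_profiles.yaml``); every rule and offset is
config.  Classification is a pure function of the extracted fingerprint
residues — flanking sequence never changes a call.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

__all__ = [
    "DomainHit",
    "Fingerprint",
    "ATCall",
    "KRCall",
    "DHCall",
    "ERCall",
    "DomainCall",
    "Profiles",
    "load_profiles",
    "scan_domains",
    "extract_fingerprints",
    "classify_at",
    "classify_kr",
    "classify_dh",
    "classify_er",
    "classify_protein",
    "at_call_from_motifs",
    "kr_call_from_motifs",
    "dh_call_from_motifs",
    "er_call_from_motifs",
]

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")

DOMAIN_TYPES = ("KS", "KSQ", "AT", "DH", "ER", "KR", "ACP", "TE")

_AA3 = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr", "X": "Xaa",
}


class SequenceError(ValueError):
    """Raised on sequences outside the amino-acid alphabet."""


@dataclass(frozen=True)
class DomainHit:
    """A located catalytic domain on a multienzyme (1-based inclusive interval)."""

    protein_id: str
    domain_type: str
    interval: tuple[int, int]
    sequence: str
    partial: bool = False  # truncated at a protein end; excluded from classification

    def __post_init__(self) -> None:
        if self.domain_type not in DOMAIN_TYPES:
            raise ValueError(f"unknown domain type {self.domain_type!r}")
        if self.interval[0] < 1 or self.interval[1] < self.interval[0]:
            raise ValueError(f"bad interval {self.interval}")


@dataclass(frozen=True)
class Fingerprint:
    """An extracted active-site motif: observed residues + anchor position."""

    motif_name: str
    observed: str
    anchor_pos: int  # 1-based position in the parent protein

    def __post_init__(self) -> None:
        if not self.observed:
            raise ValueError(f"{self.motif_name}: empty observed string")


@dataclass(frozen=True)
class ATCall:
    substrate: str  # malonyl | methylmalonyl | unusual-alkylmalonyl | unknown
    fingerprints: tuple[Fingerprint, ...]
    confidence: str  # rule id that fired, or "discordant:..." / "no-rule"


@dataclass(frozen=True)
class KRCall:
    active: bool
    kr_type: str  # A1 | A2 | B1 | unknown
    beta_config: Optional[str]
    alpha_config: Optional[str]
    confidence: str = "full-triad"
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class DHCall:
    active: bool
    reason: str  # "intact" or the substitution, e.g. "His->Arg"


@dataclass(frozen=True)
class ERCall:
    present: bool
    alpha_outcome: str  # 2S | 2R | n/a


@dataclass(frozen=True)
class DomainCall:
    """A domain hit together with its fingerprints and classification."""

    protein_id: str
    domain_type: str
    interval: Optional[tuple[int, int]]
    fingerprints: tuple[Fingerprint, ...] = ()
    call: object = None  # ATCall/KRCall/DHCall/ERCall or None (KS/KSQ/ACP/TE)
    partial: bool = False


@dataclass(frozen=True)
class Profiles:
    """Parsed anchor/offset/rule configuration."""

    domains: dict
    at_rules: dict
    kr_stereochemistry: dict

    def block(self, domain_type: str) -> dict:
        key = "KS" if domain_type == "KSQ" else domain_type
        return self.domains[key]


def load_profiles(path: Optional[str | Path] = None) -> Profiles:
    """Load anchor profiles (packaged default when no path is given)."""
    if path is None:
        text = resources.files("pksdecode.data").joinpath("domain_profiles.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return Profiles(
        domains=raw["domains"],
        at_rules=raw["at_rules"],
        kr_stereochemistry=raw["kr_stereochemistry"],
    )


def _validate_sequence(seq: str) -> None:
    bad = set(seq.upper()) - VALID_AA
    if bad:
        raise SequenceError(f"illegal residue(s) {sorted(bad)} in protein sequence")


def scan_domains(
    protein: str,
    profiles: Optional[Profiles] = None,
    protein_id: str = "protein",
    intervals: Optional[Sequence[tuple[str, int, int]]] = None,
) -> tuple[DomainHit, ...]:
    """Locate domains in a multienzyme sequence, N->C, non-overlapping.

    ``intervals`` optionally injects externally determined domain intervals
    as ``(domain_type, start, end)`` 1-based tuples (e.g. from a profile-HMM
    scan); locator scanning is skipped for injected calls.  Sequences shorter
    than any locator window yield an empty result.
    """
    if profiles is None:
        profiles = load_profiles()
    seq = protein.upper()
    _validate_sequence(seq)

    raw_hits: list[tuple[int, int, str]] = []  # (start0, end0_exclusive, type)
    if intervals is not None:
        for dtype, start, end in intervals:
            raw_hits.append((start - 1, end, dtype))
    else:
        for dtype, spec in profiles.domains.items():
            locator = spec["locator"]
            offset = spec["locator_offset"]
            length = spec["length"]
            pos = seq.find(locator)
            while pos != -1:
                raw_hits.append((pos - offset, pos - offset + length, dtype))
                pos = seq.find(locator, pos + 1)

    raw_hits.sort(key=lambda h: (h[0], h[1]))
    hits: list[DomainHit] = []
    prev_end = -1
    for start0, end0, dtype in raw_hits:
        clipped_start = max(start0, 0)
        clipped_end = min(end0, len(seq))
        if clipped_start >= clipped_end:
            continue
        if clipped_start < prev_end:  # overlap: first hit wins
            continue
        partial = (clipped_start != start0) or (clipped_end != end0)
        subseq = seq[clipped_start:clipped_end]
        if dtype == "KS" and not partial:
            dtype = _ks_or_ksq(subseq, profiles)
        hits.append(
            DomainHit(
                protein_id=protein_id,
                domain_type=dtype,
                interval=(clipped_start + 1, clipped_end),
                sequence=subseq,
                partial=partial,
            )
        )
        prev_end = clipped_end
    return tuple(hits)


def _ks_or_ksq(block_seq: str, profiles: Profiles) -> str:
    slot = profiles.domains["KS"]["slots"]["KS_Q_substitution"]
    observed = block_seq[slot["offset"] : slot["offset"] + slot["length"]]
    if len(observed) == slot["length"] and observed[slot["variant_index"]] == "Q":
        return "KSQ"
    return "KS"


def extract_fingerprints(
    hit: DomainHit, profiles: Optional[Profiles] = None
) -> tuple[Fingerprint, ...]:
    """Pull fingerprint slot residues out of a full-length domain hit."""
    if profiles is None:
        profiles = load_profiles()
    if hit.partial:
        return ()
    spec = profiles.block(hit.domain_type)
    out = []
    for motif_name, slot in spec.get("slots", {}).items():
        observed = hit.sequence[slot["offset"] : slot["offset"] + slot["length"]]
        if observed:
            out.append(
                Fingerprint(
                    motif_name=motif_name,
                    observed=observed,
                    anchor_pos=hit.interval[0] + slot["offset"],
                )
            )
    return tuple(out)


def _require(hit: DomainHit, expected: str) -> None:
    if hit.domain_type != expected:
        raise ValueError(
            f"classify_{expected.lower()} requires a {expected} hit, got {hit.domain_type}"
        )


def _fp_map(fps: Iterable[Fingerprint]) -> dict[str, Fingerprint]:
    return {fp.motif_name: fp for fp in fps}


# ---------------------------------------------------------------- AT domains


def at_call_from_motifs(
    serine: str, second: str, profiles: Optional[Profiles] = None,
    fingerprints: tuple[Fingerprint, ...] = (),
) -> ATCall:
    """Classify AT substrate from the two fingerprint motifs.

    Both motifs must agree; recognized-but-discordant combinations surface as
    ``unknown`` with a "discordant" evidence flag rather than a guess.
    """
    if profiles is None:
        profiles = load_profiles()
    rules = profiles.at_rules
    serine_class = None
    for cls in ("malonyl", "methylmalonyl"):
        if serine in rules[cls]["serine"]:
            serine_class = cls
    second_class = None
    for cls in ("malonyl", "methylmalonyl"):
        if second in rules[cls]["second"]:
            second_class = cls
    serine_is_ghs = bool(re.fullmatch(r"GHS[A-Z]", serine))

    if serine_class and serine_class == second_class:
        return ATCall(serine_class, fingerprints, f"{serine}+{second}")
    if serine_is_ghs and second in rules["unusual_second"]:
        return ATCall("unusual-alkylmalonyl", fingerprints, f"{serine}+{second}")
    if serine_class and second_class and serine_class != second_class:
        return ATCall("unknown", fingerprints, f"discordant:{serine}+{second}")
    return ATCall("unknown", fingerprints, f"no-rule:{serine}+{second}")


def classify_at(hit: DomainHit, profiles: Optional[Profiles] = None) -> ATCall:
    _require(hit, "AT")
    if profiles is None:
        profiles = load_profiles()
    fps = extract_fingerprints(hit, profiles)
    m = _fp_map(fps)
    return at_call_from_motifs(
        m["AT_serine_motif"].observed, m["AT_second_his_motif"].observed, profiles, fps
    )


# ---------------------------------------------------------------- KR domains


def kr_call_from_motifs(
    lys: str, ser: str, tyr: str, ldd: str, trp: str, a2: str,
    profiles: Optional[Profiles] = None,
) -> KRCall:
    """Classify KR activity and stereotype from fingerprint residues.

    Activity hinges on the catalytic Tyr; missing Lys/Ser only degrade
    confidence.  The Asp of an LDD-like motif marks B-type; a diagnostic Trp
    marks A-type, subdivided into A2 by a His-for-Gln substitution.
    """
    if profiles is None:
        profiles = load_profiles()
    active = tyr == "Y"
    if not active:
        return KRCall(False, "unknown", None, None, f"catalytic-Tyr-absent({_AA3.get(tyr, tyr)})")
    confidence = "full-triad" if (lys == "K" and ser == "S") else "triad-degraded"
    flags: tuple[str, ...] = ()
    if len(ldd) == 3 and ldd[2] == "D":
        kr_type = "B1"
    elif trp == "W":
        kr_type = "A2" if a2 == "H" else "A1"
        if kr_type == "A2":
            flags = ("A2-stereo-as-printed",)
    else:
        kr_type = "unknown"
    stereo = profiles.kr_stereochemistry.get(kr_type)
    beta = stereo["beta"] if stereo else None
    alpha = stereo["alpha"] if stereo else None
    return KRCall(True, kr_type, beta, alpha, confidence, flags)


def classify_kr(hit: DomainHit, profiles: Optional[Profiles] = None) -> KRCall:
    _require(hit, "KR")
    if profiles is None:
        profiles = load_profiles()
    m = _fp_map(extract_fingerprints(hit, profiles))
    return kr_call_from_motifs(
        m["KR_lys"].observed,
        m["KR_ser"].observed,
        m["KR_tyr"].observed,
        m["KR_LDD_motif"].observed,
        m["KR_A_trp"].observed,
        m["KR_A2_his_for_gln"].observed,
        profiles,
    )


# ---------------------------------------------------------------- DH domains


_DH_HIS_RE = re.compile(r"H[A-Z]{3}[GD][A-Z]{4}PG")
_DH_ASP_RE = re.compile(r"D[A-Z]{3}[QH]")


def dh_call_from_motifs(his_motif: str, asp_motif: str) -> DHCall:
    """DH is active only with both the His box (Hxxx(G/D)xxxxPG) and Dxxx(Q/H)."""
    his_ok = bool(_DH_HIS_RE.fullmatch(his_motif))
    asp_ok = bool(_DH_ASP_RE.fullmatch(asp_motif))
    if his_ok and asp_ok:
        return DHCall(True, "intact")
    if his_motif and his_motif[0] != "H":
        return DHCall(False, f"His->{_AA3.get(his_motif[0], his_motif[0])}")
    if asp_motif and asp_motif[0] != "D":
        return DHCall(False, f"Asp->{_AA3.get(asp_motif[0], asp_motif[0])}")
    return DHCall(False, "degenerate-motif")


def classify_dh(hit: DomainHit, profiles: Optional[Profiles] = None) -> DHCall:
    _require(hit, "DH")
    if profiles is None:
        profiles = load_profiles()
    m = _fp_map(extract_fingerprints(hit, profiles))
    return dh_call_from_motifs(m["DH_his_motif"].observed, m["DH_asp_motif"].observed)


# ---------------------------------------------------------------- ER domains


def er_call_from_motifs(tyr_motif: str, profiles: Optional[Profiles] = None) -> ERCall:
    if profiles is None:
        profiles = load_profiles()
    idx = profiles.domains["ER"]["slots"]["ER_tyr_motif"].get("variant_index", 0)
    has_tyr = len(tyr_motif) > idx and tyr_motif[idx] == "Y"
    return ERCall(True, "2S" if has_tyr else "2R")


def classify_er(hit: DomainHit, profiles: Optional[Profiles] = None) -> ERCall:
    _require(hit, "ER")
    if profiles is None:
        profiles = load_profiles()
    m = _fp_map(extract_fingerprints(hit, profiles))
    return er_call_from_motifs(m["ER_tyr_motif"].observed, profiles)


# ------------------------------------------------------- whole-protein calls


def classify_protein(
    protein_id: str,
    sequence: str,
    profiles: Optional[Profiles] = None,
    intervals: Optional[Sequence[tuple[str, int, int]]] = None,
) -> tuple[DomainCall, ...]:
    """Scan one multienzyme and classify every full-length domain hit."""
    if profiles is None:
        profiles = load_profiles()
    calls = []
    for hit in scan_domains(sequence, profiles, protein_id, intervals):
        fps = extract_fingerprints(hit, profiles)
        call: object = None
        if not hit.partial:
            if hit.domain_type == "AT":
                call = classify_at(hit, profiles)
            elif hit.domain_type == "KR":
                call = classify_kr(hit, profiles)
            elif hit.domain_type == "DH":
                call = classify_dh(hit, profiles)
            elif hit.domain_type == "ER":
                call = classify_er(hit, profiles)
        calls.append(
            DomainCall(
                protein_id=protein_id,
                domain_type=hit.domain_type,
                interval=hit.interval,
                fingerprints=fps,
                call=call,
                partial=hit.partial,
            )
        )
    return tuple(calls)
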