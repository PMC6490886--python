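"""Synthetic PKS multienzymes with planted, fully known ground truth.

Each emitted protein is a concatenation of domain blocks — the constant
locator block plus fingerprint slots of ``data/domain_profiles.yaml`` planted
inside background sequence drawn from a fixed amino-acid frequency profile —
joined by random linkers.  Background is profile-biased (not uniform) and a
collision scrubber redraws any window that happens to recreate a locator, so
domain location is exact by construction.  The ground truth records every
planted interval, motif and call, which makes the scanner/classifier and the
downstream assembly logic testable end to end without any external sequence.

Determinism: one integer seed drives everything; per-protein substreams are
derived by stable integer hashing, so the same config + seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .domain_grammar import Profiles, at_call_from_motifs, load_profiles

__all__ = [
    "KRSpec",
    "DHSpec",
    "ERSpec",
    "ModuleSpec",
    "LoadingSpec",
    "GeneratorConfig",
    "EmittedLine",
    "UnrealizableSpecError",
    "emit_line",
    "emit_cluster_table",
    "write_fasta",
    "config_from_call_tables",
    "ossamycin_mimic_config",
    "random_line_config",
    "target_from_config",
]

# Amino-acid background profile, biased toward the composition of high-GC
# actinobacterial proteins (Ala/Gly/Arg/Pro/Val-rich) — deliberately not
# uniform, to keep accidental motif matches rare.
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array(
    [0.12, 0.008, 0.06, 0.055, 0.025, 0.10, 0.02, 0.03, 0.02, 0.09,
     0.015, 0.02, 0.06, 0.025, 0.075, 0.055, 0.065, 0.09, 0.012, 0.02]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

_SERINE_DEFAULT = {"malonyl": "GHSQ", "methylmalonyl": "GHSI", "unusual-alkylmalonyl": "GHSV"}
_SECOND_DEFAULT = {"malonyl": "HAFH", "methylmalonyl": "YASH", "unusual-alkylmalonyl": "SPGH"}

_DH_ACTIVE = "HELLGGRSLPG"
_DH_ASP = "DAAFQ"
_KR_TYPE_MOTIFS = {  # (LDD slot, Trp slot, His-for-Gln slot)
    "B1": ("LDD", "F", "Q"),
    "A1": ("LNA", "W", "Q"),
    "A2": ("LNA", "W", "H"),
}


class UnrealizableSpecError(ValueError):
    """A module spec contradicts the motif rules it would be planted with."""


@dataclass(frozen=True)
class KRSpec:
    kr_type: str = "A1"  # A1 | A2 | B1
    active: bool = True  # catalytic Tyr present

    def __post_init__(self) -> None:
        if self.kr_type not in _KR_TYPE_MOTIFS:
            raise UnrealizableSpecError(f"KR type {self.kr_type!r} has no motif template")


@dataclass(frozen=True)
class DHSpec:
    active: bool = True
    substitution: Optional[str] = None  # 'R' or 'Y' replacing the essential His

    def __post_init__(self) -> None:
        if self.active and self.substitution:
            raise UnrealizableSpecError("an active DH cannot carry a His substitution")
        if not self.active and self.substitution not in ("R", "Y"):
            raise UnrealizableSpecError("an inactive DH needs substitution 'R' or 'Y'")


@dataclass(frozen=True)
class ERSpec:
    tyr: bool = False  # Tyr motif -> (2S) alpha outcome


@dataclass(frozen=True)
class ModuleSpec:
    """Planted chemistry of one extension module (KS AT [DH] [ER] [KR] ACP)."""

    at_substrate: str = "malonyl"
    serine_motif: Optional[str] = None
    second_motif: Optional[str] = None
    dh: Optional[DHSpec] = None
    er: Optional[ERSpec] = None
    kr: Optional[KRSpec] = None

    def motifs(self) -> tuple[str, str]:
        ser = self.serine_motif or _SERINE_DEFAULT.get(self.at_substrate)
        sec = self.second_motif or _SECOND_DEFAULT.get(self.at_substrate)
        if ser is None or sec is None:
            raise UnrealizableSpecError(f"no AT motifs for substrate {self.at_substrate!r}")
        return ser, sec

    def validate(self, profiles: Profiles) -> None:
        ser, sec = self.motifs()
        call = at_call_from_motifs(ser, sec, profiles)
        if call.substrate != self.at_substrate:
            raise UnrealizableSpecError(
                f"AT motifs {ser}+{sec} classify as {call.substrate!r}, "
                f"not the requested {self.at_substrate!r}"
            )
        if self.er is not None and self.dh is None:
            raise UnrealizableSpecError("an ER without a DH is not a realizable module")

    @property
    def reduction_level(self) -> str:
        if self.kr is None or not self.kr.active:
            return "ketone"
        if self.dh is None or not self.dh.active:
            return "hydroxyl"
        if self.er is None:
            return "enoyl"
        return "methylene"


@dataclass(frozen=True)
class LoadingSpec:
    at_substrate: str = "methylmalonyl"  # KSQ decarboxylation -> propionate starter


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    proteins: tuple[tuple[ModuleSpec, ...], ...]
    loading: Optional[LoadingSpec] = field(default_factory=LoadingSpec)
    te: bool = True
    loading_index: int = 0  # which protein carries the loading didomain
    te_index: int = -1  # which protein carries the TE
    protein_ids: Optional[tuple[str, ...]] = None
    linker_length_range: tuple[int, int] = (12, 30)
    decoy_count: int = 0
    mutation_rate: float = 0.0
    accessory_genes: tuple[tuple[str, str, int], ...] = ()  # (name, function, length_aa)

    def __post_init__(self) -> None:
        if not self.proteins or not any(self.proteins):
            raise UnrealizableSpecError("config must pack at least one module")
        if not 0.0 <= self.mutation_rate <= 0.5:
            raise UnrealizableSpecError("mutation_rate must be in [0, 0.5]")
        if self.protein_ids is not None and len(self.protein_ids) != len(self.proteins):
            raise UnrealizableSpecError("protein_ids length must match proteins")


@dataclass(frozen=True)
class EmittedLine:
    """Generator output: sequences plus the complete planted ground truth."""

    sequences: tuple[tuple[str, str], ...]  # (protein_id, sequence), decoys included
    ground_truth: dict


def _substream(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng((seed * 1000003 + 7919 * (index + 1)) % 2**31)


def _background(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(_AA, size=length, p=_AA_FREQ))


def _plant(block: list[str], offset: int, text: str) -> None:
    block[offset : offset + len(text)] = list(text)


def _domain_block(
    dtype: str, motifs: dict[str, str], profiles: Profiles, rng: np.random.Generator
) -> tuple[list[str], dict[str, str], list[tuple[int, int]]]:
    """Build one domain block; returns (residues, motifs, protected ranges)."""
    spec = profiles.block(dtype)
    block = _background(rng, spec["length"])
    protected = []
    loc_off = spec["locator_offset"]
    _plant(block, loc_off, spec["locator"])
    protected.append((loc_off, loc_off + len(spec["locator"])))
    for motif_name, slot in spec.get("slots", {}).items():
        text = motifs.get(motif_name, slot["default"])
        if len(text) != slot["length"]:
            raise UnrealizableSpecError(
                f"{dtype}/{motif_name}: motif {text!r} does not fit slot length {slot['length']}"
            )
        _plant(block, slot["offset"], text)
        protected.append((slot["offset"], slot["offset"] + slot["length"]))
    return block, motifs, protected


def _module_domains(spec: ModuleSpec) -> list[tuple[str, dict[str, str]]]:
    ser, sec = spec.motifs()
    domains: list[tuple[str, dict[str, str]]] = [
        ("KS", {"KS_Q_substitution": "VDTACSSS"}),
        ("AT", {"AT_serine_motif": ser, "AT_second_his_motif": sec}),
    ]
    if spec.dh is not None:
        his = _DH_ACTIVE if spec.dh.active else spec.dh.substitution + _DH_ACTIVE[1:]
        domains.append(("DH", {"DH_his_motif": his, "DH_asp_motif": _DH_ASP}))
    if spec.er is not None:
        domains.append(("ER", {"ER_tyr_motif": "GYKAL" if spec.er.tyr else "GVKAL"}))
    if spec.kr is not None:
        ldd, trp, a2 = _KR_TYPE_MOTIFS[spec.kr.kr_type]
        domains.append(
            ("KR", {"KR_lys": "K", "KR_ser": "S", "KR_tyr": "Y" if spec.kr.active else "F",
                    "KR_LDD_motif": ldd, "KR_A_trp": trp, "KR_A2_his_for_gln": a2})
        )
    domains.append(("ACP", {}))
    return domains


def _scrub_collisions(
    seq: list[str],
    protected: list[tuple[int, int]],
    profiles: Profiles,
    rng: np.random.Generator,
    max_rounds: int = 100,
) -> None:
    """Redraw unprotected residues wherever a locator appears off-plan."""
    protected_positions = set()
    for a, b in protected:
        protected_positions.update(range(a, b))
    locators = [spec["locator"] for spec in profiles.domains.values()]
    for _ in range(max_rounds):
        text = "".join(seq)
        dirty = False
        for locator in locators:
            pos = text.find(locator)
            while pos != -1:
                window = range(pos, pos + len(locator))
                free = [i for i in window if i not in protected_positions]
                if free:
                    dirty = True
                    for i in free:
                        seq[i] = str(rng.choice(_AA, p=_AA_FREQ))
                pos = text.find(locator, pos + 1)
        if not dirty:
            return
    raise RuntimeError("collision scrubbing did not converge")


def emit_line(config: GeneratorConfig, profiles: Optional[Profiles] = None) -> EmittedLine:
    """Emit FASTA-ready proteins and the ground-truth table for one line."""
    if profiles is None:
        profiles = load_profiles()
    for prot in config.proteins:
        for spec in prot:
            spec.validate(profiles)

    ids = config.protein_ids or tuple(f"pks_{i + 1}" for i in range(len(config.proteins)))
    sequences: list[tuple[str, str]] = []
    truth_proteins = []
    lo, hi = config.linker_length_range

    for p_index, (pid, module_specs) in enumerate(zip(ids, config.proteins)):
        rng = _substream(config.seed, p_index)
        residues: list[str] = []
        protected: list[tuple[int, int]] = []
        planted_domains: list[dict] = []
        module_truth: list[dict] = []

        def _append_block(dtype: str, motifs: dict[str, str]) -> None:
            linker = _background(rng, int(rng.integers(lo, hi + 1)))
            residues.extend(linker)
            start = len(residues)
            block, _, block_protected = _domain_block(dtype, motifs, profiles, rng)
            residues.extend(block)
            protected.extend((start + a, start + b) for a, b in block_protected)
            planted_domains.append(
                {"type": dtype, "start": start + 1, "end": start + len(block),
                 "motifs": dict(motifs)}
            )

        is_first = p_index == config.loading_index % len(config.proteins)
        is_last = p_index == config.te_index % len(config.proteins)
        loading_truth = None
        if is_first and config.loading is not None:
            ser = _SERINE_DEFAULT[config.loading.at_substrate]
            sec = _SECOND_DEFAULT[config.loading.at_substrate]
            _append_block("KS", {"KS_Q_substitution": "VDTAQSSS"})
            planted_domains[-1]["type"] = "KSQ"
            _append_block("AT", {"AT_serine_motif": ser, "AT_second_his_motif": sec})
            _append_block("ACP", {})
            loading_truth = {"at_substrate": config.loading.at_substrate}
        for spec in module_specs:
            for dtype, motifs in _module_domains(spec):
                _append_block(dtype, motifs)
            module_truth.append(
                {"at_substrate": spec.at_substrate,
                 "reduction_level": spec.reduction_level,
                 "kr_type": spec.kr.kr_type if (spec.kr and spec.kr.active) else None,
                 "dh_active": bool(spec.dh and spec.dh.active),
                 "er_present": spec.er is not None,
                 "er_tyr": bool(spec.er and spec.er.tyr)}
            )
        if is_last and config.te:
            _append_block("TE", {})
        residues.extend(_background(rng, int(rng.integers(lo, hi + 1))))

        if config.mutation_rate > 0:
            protected_positions = set()
            for a, b in protected:
                protected_positions.update(range(a, b))
            mask = rng.random(len(residues)) < config.mutation_rate
            for i in np.nonzero(mask)[0]:
                if int(i) not in protected_positions:
                    residues[int(i)] = str(rng.choice(_AA, p=_AA_FREQ))

        _scrub_collisions(residues, protected, profiles, rng)
        sequences.append((pid, "".join(residues)))
        truth_proteins.append(
            {"protein_id": pid, "length": len(residues), "domains": planted_domains,
             "loading": loading_truth, "modules": module_truth,
             "te": is_last and config.te}
        )

    decoy_ids = []
    for d in range(config.decoy_count):
        rng = _substream(config.seed, len(config.proteins) + d)
        residues = _background(rng, int(rng.integers(250, 600)))
        _scrub_collisions(residues, [], profiles, rng)
        did = f"decoy_{d + 1}"
        decoy_ids.append(did)
        sequences.append((did, "".join(residues)))

    return EmittedLine(
        sequences=tuple(sequences),
        ground_truth={"proteins": truth_proteins, "decoys": decoy_ids,
                      "seed": config.seed},
    )


def write_fasta(line: EmittedLine, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=pid, description="synthetic PKS multienzyme")
               for pid, seq in line.sequences]
    SeqIO.write(records, str(path), "fasta")


def emit_cluster_table(config: GeneratorConfig, profiles: Optional[Profiles] = None):
    """Emit a ClusterAnnotation consistent with the emitted proteins.

    PKS rows use the emitted protein lengths; accessory genes (P450s, sugar
    genes, regulator, transporter, ...) come from the config.
    """
    from .cluster_io import ClusterAnnotation, GeneRecord, _assign_ids

    line = emit_line(config, profiles)
    pks_rows = [
        GeneRecord(gene_id=pid.lower(), name=pid, length_aa=len(seq),
                   proposed_function="Polyketide synthase")
        for pid, seq in line.sequences
        if not pid.startswith("decoy_")
    ]
    accessory = [
        GeneRecord(gene_id=name.lower(), name=name, length_aa=length,
                   proposed_function=function)
        for name, function, length in config.accessory_genes
    ]
    return ClusterAnnotation(genes=_assign_ids(pks_rows + accessory), source="fixture")


# --------------------------------------------------------- derived configs


def config_from_call_tables(tables, seed: int,
                            accessory_genes: tuple[tuple[str, str, int], ...] = (),
                            mutation_rate: float = 0.0,
                            decoy_count: int = 0) -> GeneratorConfig:
    """Translate per-protein domain-call tables into a generator config.

    Used to emit sequence-level mimics of a transcribed line (e.g. the
    packaged 14-module, 8-protein fixture) with identical planted chemistry.
    """
    proteins: list[tuple[ModuleSpec, ...]] = []
    ids: list[str] = []
    loading: Optional[LoadingSpec] = None
    loading_index = 0
    te = False
    te_index = -1
    for p_idx, (pid, calls) in enumerate(tables.items()):
        ids.append(pid)
        specs: list[ModuleSpec] = []
        i = 0
        calls = list(calls)
        while i < len(calls):
            c = calls[i]
            if c.domain_type == "KSQ":
                at = calls[i + 1].call
                loading = LoadingSpec(at_substrate=at.substrate)
                loading_index = p_idx
                i += 3
                continue
            if c.domain_type == "KS":
                j = i + 1
                at = dh = er = kr = None
                while j < len(calls) and calls[j].domain_type in ("AT", "DH", "ER", "KR"):
                    dc = calls[j]
                    if dc.domain_type == "AT":
                        at = dc
                    elif dc.domain_type == "DH":
                        dh = dc
                    elif dc.domain_type == "ER":
                        er = dc
                    else:
                        kr = dc
                    j += 1
                if j < len(calls) and calls[j].domain_type == "ACP":
                    j += 1
                fp = {f.motif_name: f.observed for f in at.fingerprints}
                dh_spec = None
                if dh is not None:
                    his = {f.motif_name: f.observed for f in dh.fingerprints}["DH_his_motif"]
                    dh_spec = DHSpec(active=dh.call.active,
                                     substitution=None if dh.call.active else his[0])
                er_spec = None
                if er is not None:
                    er_spec = ERSpec(tyr=er.call.alpha_outcome == "2S")
                kr_spec = None
                if kr is not None:
                    kr_spec = KRSpec(kr_type=kr.call.kr_type if kr.call.active else "A1",
                                     active=kr.call.active)
                specs.append(
                    ModuleSpec(
                        at_substrate=at.call.substrate,
                        serine_motif=fp.get("AT_serine_motif"),
                        second_motif=fp.get("AT_second_his_motif"),
                        dh=dh_spec, er=er_spec, kr=kr_spec,
                    )
                )
                i = j
                continue
            if c.domain_type == "TE":
                te = True
                te_index = p_idx
            i += 1
        proteins.append(tuple(specs))
    return GeneratorConfig(
        seed=seed, proteins=tuple(proteins), loading=loading, te=te,
        loading_index=loading_index, te_index=te_index,
        protein_ids=tuple(ids), accessory_genes=accessory_genes,
        mutation_rate=mutation_rate, decoy_count=decoy_count,
    )


def ossamycin_mimic_config(seed: int, **kwargs) -> GeneratorConfig:
    """A 14-extension-module, 8-protein line mirroring the packaged fixture."""
    from .assembly_line import ossamycin_call_tables

    return config_from_call_tables(ossamycin_call_tables(), seed, **kwargs)


def spec_chemistry(spec: ModuleSpec, profiles: Optional[Profiles] = None) -> tuple:
    """(extender, reduction, alpha, beta) labels a planted module installs."""
    if profiles is None:
        profiles = load_profiles()
    reduction = spec.reduction_level
    substituted = spec.at_substrate in ("methylmalonyl", "unusual-alkylmalonyl")
    alpha = beta = None
    if reduction == "hydroxyl" and spec.kr is not None and spec.kr.active:
        stereo = profiles.kr_stereochemistry[spec.kr.kr_type]
        beta = stereo["beta"]
        if substituted:
            alpha = stereo["alpha"]
    elif reduction == "methylene" and substituted and spec.er is not None:
        alpha = "2S" if spec.er.tyr else "2R"
    return (spec.at_substrate, reduction, alpha, beta)


_RANDOM_KR = (None, KRSpec("A1"), KRSpec("A2"), KRSpec("B1"), KRSpec("A1", active=False))
_RANDOM_DH = (None, DHSpec(True), DHSpec(False, "R"), DHSpec(False, "Y"))
_RANDOM_AT = ("malonyl", "methylmalonyl", "unusual-alkylmalonyl")


def _random_module(rng: np.random.Generator) -> ModuleSpec:
    at = _RANDOM_AT[int(rng.integers(len(_RANDOM_AT)))]
    kr = _RANDOM_KR[int(rng.integers(len(_RANDOM_KR)))]
    dh = _RANDOM_DH[int(rng.integers(len(_RANDOM_DH)))] if kr else None
    er = None
    if kr is not None and kr.active and dh is not None and dh.active and rng.random() < 0.5:
        er = ERSpec(tyr=bool(rng.random() < 0.5))
    return ModuleSpec(at_substrate=at, dh=dh, er=er, kr=kr)


def random_line_config(
    seed: int,
    max_proteins: int = 4,
    max_modules_per_protein: int = 3,
    mutation_rate: float = 0.0,
    decoy_count: int = 0,
) -> GeneratorConfig:
    """Random realizable line with pairwise-distinct module chemistries.

    Distinct chemistries make the planted protein order and stutter placement
    uniquely recoverable, which is what the round-trip suites assert.
    """
    rng = np.random.default_rng(seed % 2**31)
    profiles = load_profiles()
    n_proteins = int(rng.integers(2, max_proteins + 1))
    proteins: list[tuple[ModuleSpec, ...]] = []
    seen: set[tuple] = set()
    for _ in range(n_proteins):
        n_mod = int(rng.integers(1, max_modules_per_protein + 1))
        specs = []
        for _ in range(n_mod):
            for _attempt in range(200):
                spec = _random_module(rng)
                key = spec_chemistry(spec, profiles)
                if key not in seen:
                    seen.add(key)
                    specs.append(spec)
                    break
            else:  # chemistry space exhausted; accept a repeat
                specs.append(spec)
                break
        proteins.append(tuple(specs))
    return GeneratorConfig(
        seed=seed, proteins=tuple(proteins), loading=LoadingSpec(), te=True,
        mutation_rate=mutation_rate, decoy_count=decoy_count,
    )


def target_from_config(
    config: GeneratorConfig, stutter_module: Optional[int] = None
) -> "TargetBackbone":
    """Target backbone whose cycles mirror the planted modules in order.

    ``stutter_module`` (0-based index into the flattened module list) plants
    a programmed iteration: that module's cycle appears twice consecutively.
    """
    from .assembly_line import Extension, TargetBackbone

    profiles = load_profiles()
    flat: list[ModuleSpec] = [s for prot in config.proteins for s in prot]
    extensions: list[Extension] = []
    cycle = 1
    for idx, spec in enumerate(flat):
        reps = 2 if idx == stutter_module else 1
        extender, reduction, alpha, beta = spec_chemistry(spec, profiles)
        for _ in range(reps):
            extensions.append(
                Extension(
                    cycle=cycle,
                    extender=extender,
                    reduction=reduction,
                    alpha_stereo=alpha,
                    beta_stereo=beta,
                    sidechain_carbons=4 if extender == "unusual-alkylmalonyl" else 0,
                )
            )
            cycle += 1
    starter_unit, starter_carbons = ("propionate", 3)
    if config.loading is not None and config.loading.at_substrate == "malonyl":
        starter_unit, starter_carbons = ("acetate", 2)
    return TargetBackbone(starter_unit, starter_carbons, tuple(extensions), None)
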