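"""Assembly-line reconstruction: modules, multienzyme order, programmed iteration.

Domain calls are grouped into extension modules by the canonical grammar
``KS (AT) (DH) (ER) (KR) ACP`` with an optional N-terminal ``KSQ AT ACP``
loading module and a chain-terminating TE.  The order of multienzymes is then
inferred against a target backbone (the per-cycle extender / reduction /
stereochemistry the final product requires) by exhaustive search over
arrangements that keep the loading-module protein first and the TE protein
last, scoring each arrangement by per-cycle chemistry mismatches.

When the target demands more extension cycles than physical modules exist,
one or more modules must be used iteratively ("stuttering"): a module serves
two or more *consecutive* cycles of identical chemistry.  All admissible
stutter placements are enumerated and scored; ties are broken toward the
earliest cycle and reported.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .domain_grammar import (
    ATCall,
    DHCall,
    DomainCall,
    ERCall,
    Fingerprint,
    KRCall,
    Profiles,
    at_call_from_motifs,
    dh_call_from_motifs,
    er_call_from_motifs,
    kr_call_from_motifs,
    load_profiles,
)

__all__ = [
    "ExtensionModule",
    "LoadingModule",
    "ModuleTable",
    "Extension",
    "TargetBackbone",
    "IterationAssignment",
    "OrderingResult",
    "SurplusModulesError",
    "IterationError",
    "AmbiguousOrderError",
    "build_modules",
    "order_multienzymes",
    "detect_iteration",
    "module_chemistry",
    "load_call_tables",
    "load_target",
    "ossamycin_call_tables",
    "ossamycin_target",
    "suppress_iteration",
    "DEFAULT_WEIGHTS",
]

REDUCTION_LEVELS = ("ketone", "hydroxyl", "enoyl", "methylene")

#: Mismatch weights: 1 per differing extender class, 1 per differing reduction
#: level, 0.5 when only a specified stereo label differs.
DEFAULT_WEIGHTS: dict[str, float] = {"extender": 1.0, "reduction": 1.0, "stereo": 0.5}

#: Starter units furnished by a loading didomain after KSQ decarboxylation.
_STARTER_BY_AT = {
    "malonyl": ("acetate", 2),
    "methylmalonyl": ("propionate", 3),
}


class SurplusModulesError(ValueError):
    """More physical modules than target cycles (module skipping is out of scope)."""


class IterationError(ValueError):
    """No admissible stutter placement reconciles modules with target cycles."""


class AmbiguousOrderError(ValueError):
    """Neither a loading module nor a TE pins the line; ordering is ambiguous."""

    def __init__(self, candidates: Sequence[str]):
        self.candidates = tuple(candidates)
        super().__init__(
            f"cannot orient assembly line: no loading module and no TE found; "
            f"candidate proteins: {', '.join(candidates)}"
        )


@dataclass(frozen=True)
class ExtensionModule:
    """One chain-extension module and its classified catalytic complement."""

    module_id: str
    protein_id: str
    index_in_protein: int  # 0-based module ordinal on its protein, N->C
    at: ATCall
    kr: Optional[KRCall] = None
    dh: Optional[DHCall] = None
    er: Optional[ERCall] = None
    malformed: bool = False
    warnings: tuple[str, ...] = ()

    @property
    def reduction_level(self) -> str:
        """Maximal reduction supported by *active* domains.

        An inactive (or absent) KR caps processing at the ketone; an inactive
        DH caps at the hydroxyl; without ER the module stops at the enoyl.
        """
        if self.kr is None or not self.kr.active:
            return "ketone"
        if self.dh is None or not self.dh.active:
            return "hydroxyl"
        if self.er is None:
            return "enoyl"
        return "methylene"


@dataclass(frozen=True)
class LoadingModule:
    """N-terminal KSQ+AT+ACP didomain supplying the starter unit."""

    protein_id: str
    at: ATCall
    starter_unit: str
    starter_carbons: int


@dataclass(frozen=True)
class ModuleTable:
    """Result of grouping per-protein domain calls into modules."""

    loading: Optional[LoadingModule]
    modules_by_protein: dict[str, tuple[ExtensionModule, ...]]
    te_protein_id: Optional[str]
    warnings: tuple[str, ...] = ()

    @property
    def extension_modules(self) -> tuple[ExtensionModule, ...]:
        return tuple(
            m for mods in self.modules_by_protein.values() for m in mods if not m.malformed
        )

    @property
    def per_protein_counts(self) -> dict[str, int]:
        return {p: len([m for m in mods if not m.malformed])
                for p, mods in self.modules_by_protein.items()}


@dataclass(frozen=True)
class Extension:
    """One required chain-extension cycle of the target backbone."""

    cycle: int
    extender: str  # malonyl | methylmalonyl | unusual-alkylmalonyl
    reduction: str  # state of this cycle's beta carbon after processing
    alpha_stereo: Optional[str] = None
    beta_stereo: Optional[str] = None
    confidence: str = "anchored"
    sidechain_carbons: int = 0
    geometry: Optional[str] = None

    def chemistry(self) -> tuple:
        return (self.extender, self.reduction, self.alpha_stereo, self.beta_stereo)


@dataclass(frozen=True)
class TargetBackbone:
    """Required cycles plus carbon numbering for the finished chain.

    C-1 is the carboxy-terminal (thioester) carbon; with n cycles, cycle i
    contributes carbons C-(2(n-i)+1) and C-(2(n-i)+2) and its reduction acts
    on the beta carbon C-(2(n-i)+3); the starter occupies the highest numbers.
    """

    starter_unit: str
    starter_carbons: int
    extensions: tuple[Extension, ...]
    cyclization_carbon: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.extensions:
            raise ValueError("a target backbone needs at least one extension cycle")
        cycles = [e.cycle for e in self.extensions]
        if cycles != list(range(1, len(cycles) + 1)):
            raise ValueError("extension cycles must be contiguous from 1")

    @property
    def n_cycles(self) -> int:
        return len(self.extensions)

    @property
    def backbone_carbon_count(self) -> int:
        return self.starter_carbons + 2 * self.n_cycles

    def carbons_for_cycle(self, cycle: int) -> tuple[int, int]:
        n = self.n_cycles
        return (2 * (n - cycle) + 1, 2 * (n - cycle) + 2)

    def beta_carbon(self, cycle: int) -> int:
        return 2 * (self.n_cycles - cycle) + 3

    def producing_cycle_of_beta_carbon(self, carbon: int) -> int:
        """Inverse of :meth:`beta_carbon` (which cycle set this carbon's state)."""
        cycle = (2 * self.n_cycles + 3 - carbon) / 2
        if cycle != int(cycle) or not 1 <= cycle <= self.n_cycles:
            raise ValueError(f"carbon C-{carbon} is not a beta carbon of any cycle")
        return int(cycle)


@dataclass(frozen=True)
class IterationAssignment:
    """Mapping of target cycles onto physical modules."""

    cycle_to_module: dict[int, str]
    iterated_modules: tuple[str, ...]
    discrepancies: tuple[dict, ...]
    score: float
    stutter_cycles: tuple[int, ...]  # cycles served by an already-used module
    ties: tuple[tuple[int, ...], ...] = ()  # stutter_cycles of equally-scored placements


@dataclass(frozen=True)
class OrderingResult:
    order: tuple[str, ...]
    score: float
    assignment: IterationAssignment
    tied_orders: tuple[tuple[str, ...], ...] = ()


# ------------------------------------------------------------- module grammar


def _classify_fixture_domain(dtype: str, motifs: Mapping[str, str], profiles: Profiles):
    if dtype == "AT":
        return at_call_from_motifs(
            motifs["AT_serine_motif"], motifs["AT_second_his_motif"], profiles
        )
    if dtype == "KR":
        return kr_call_from_motifs(
            motifs.get("KR_lys", ""), motifs.get("KR_ser", ""), motifs.get("KR_tyr", ""),
            motifs.get("KR_LDD_motif", ""), motifs.get("KR_A_trp", ""),
            motifs.get("KR_A2_his_for_gln", ""), profiles,
        )
    if dtype == "DH":
        return dh_call_from_motifs(motifs.get("DH_his_motif", ""), motifs.get("DH_asp_motif", ""))
    if dtype == "ER":
        return er_call_from_motifs(motifs.get("ER_tyr_motif", ""), profiles)
    return None


def load_call_tables(
    path: Optional[str | Path] = None, profiles: Optional[Profiles] = None
) -> dict[str, tuple[DomainCall, ...]]:
    """Load per-protein domain-call tables from JSON.

    The JSON stores raw fingerprint motifs; every call is (re)computed here
    through the same classifiers used on scanned sequences.
    """
    if profiles is None:
        profiles = load_profiles()
    if path is None:
        text = resources.files("pksdecode.data").joinpath("ossamycin_calls.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    tables: dict[str, tuple[DomainCall, ...]] = {}
    ks_slot = profiles.domains["KS"]["slots"]["KS_Q_substitution"]
    for prot in raw["proteins"]:
        pid = prot["protein_id"]
        calls = []
        for entry in prot["domains"]:
            dtype = entry["type"]
            motifs = entry.get("motifs", {})
            if dtype == "KS":
                cat = motifs.get("KS_Q_substitution", "")
                if len(cat) > ks_slot["variant_index"] and cat[ks_slot["variant_index"]] == "Q":
                    dtype = "KSQ"
            fps = tuple(
                Fingerprint(motif_name=name, observed=obs, anchor_pos=0)
                for name, obs in motifs.items()
            )
            calls.append(
                DomainCall(
                    protein_id=pid,
                    domain_type=dtype,
                    interval=None,
                    fingerprints=fps,
                    call=_classify_fixture_domain(dtype, motifs, profiles),
                )
            )
        tables[pid] = tuple(calls)
    return tables


def ossamycin_call_tables() -> dict[str, tuple[DomainCall, ...]]:
    """The packaged ossamycin (OssA1-A8) domain-call fixture."""
    return load_call_tables(None)


def build_modules(calls_by_protein: Mapping[str, Sequence[DomainCall]]) -> ModuleTable:
    """Group N->C domain calls into loading/extension modules per protein.

    Orphan domains (e.g. an ACP with no KS upstream, or a module truncated
    before its ACP) produce structured warnings and a module flagged
    malformed; malformed modules are excluded from ordering but reported.
    """
    loading: Optional[LoadingModule] = None
    te_protein: Optional[str] = None
    warnings: list[str] = []
    by_protein: dict[str, tuple[ExtensionModule, ...]] = {}

    for pid, calls in calls_by_protein.items():
        usable = [c for c in calls if not c.partial]
        for c in calls:
            if c.partial:
                warnings.append(f"{pid}: partial {c.domain_type} hit excluded")
        modules: list[ExtensionModule] = []
        i = 0
        n = len(usable)
        while i < n:
            c = usable[i]
            if c.domain_type == "KSQ":
                if i != 0:
                    warnings.append(f"{pid}: internal KSQ at position {i}; treated as malformed")
                    i += 1
                    continue
                if (
                    i + 2 < n
                    and usable[i + 1].domain_type == "AT"
                    and usable[i + 2].domain_type == "ACP"
                ):
                    at = usable[i + 1].call
                    starter, carbons = _STARTER_BY_AT.get(at.substrate, ("unknown", 2))
                    if loading is not None:
                        warnings.append(f"{pid}: second loading module ignored")
                    else:
                        loading = LoadingModule(pid, at, starter, carbons)
                    i += 3
                    continue
                warnings.append(f"{pid}: KSQ without AT+ACP; loading module malformed")
                i += 1
                continue
            if c.domain_type == "KS":
                j = i + 1
                at = dh = er = kr = None
                mod_warnings: list[str] = []
                if j < n and usable[j].domain_type == "AT":
                    at = usable[j].call
                    j += 1
                else:
                    mod_warnings.append("KS without AT")
                while j < n and usable[j].domain_type in ("DH", "ER", "KR"):
                    dcall = usable[j]
                    if dcall.domain_type == "DH":
                        dh = dcall.call
                    elif dcall.domain_type == "ER":
                        er = dcall.call
                    else:
                        kr = dcall.call
                    j += 1
                closed = j < n and usable[j].domain_type == "ACP"
                if closed:
                    j += 1
                else:
                    mod_warnings.append("module not closed by ACP")
                malformed = (at is None) or not closed
                module = ExtensionModule(
                    module_id=f"{pid}:m{len(modules) + 1}",
                    protein_id=pid,
                    index_in_protein=len(modules),
                    at=at if at is not None else ATCall("unknown", (), "missing-AT"),
                    kr=kr,
                    dh=dh,
                    er=er,
                    malformed=malformed,
                    warnings=tuple(mod_warnings),
                )
                modules.append(module)
                warnings.extend(f"{pid}:{module.module_id}: {w}" for w in mod_warnings)
                i = j
                continue
            if c.domain_type == "TE":
                te_protein = pid
                i += 1
                continue
            warnings.append(f"{pid}: orphan {c.domain_type} at position {i}")
            i += 1
        by_protein[pid] = tuple(modules)
    return ModuleTable(loading, by_protein, te_protein, tuple(warnings))


# ----------------------------------------------------------- target backbone


def load_target(path: Optional[str | Path] = None) -> TargetBackbone:
    """Load a target backbone from YAML (packaged ossamycin fixture if None)."""
    if path is None:
        text = resources.files("pksdecode.data").joinpath("ossamycin_target.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    extensions = []
    for row in raw["extensions"]:
        side = row.get("sidechain") or {}
        extensions.append(
            Extension(
                cycle=int(row["cycle"]),
                extender=row["extender"],
                reduction=row["reduction"],
                alpha_stereo=row.get("alpha_stereo"),
                beta_stereo=row.get("beta_stereo"),
                confidence=row.get("confidence", "anchored"),
                sidechain_carbons=int(side.get("carbons", 0)),
                geometry=row.get("geometry"),
            )
        )
    return TargetBackbone(
        starter_unit=raw["starter"]["unit"],
        starter_carbons=int(raw["starter"]["carbons"]),
        extensions=tuple(extensions),
        cyclization_carbon=raw.get("cyclization_carbon"),
    )


def ossamycin_target() -> TargetBackbone:
    return load_target(None)


def suppress_iteration(
    target: TargetBackbone, assignment: IterationAssignment
) -> TargetBackbone:
    """Rebuild the target as if no module iterated (one cycle per module).

    Drops the stuttered (repeat) cycles and moves the cyclization carbon to
    the homologous position, i.e. the hydroxyl made by the same producing
    cycle in the shorter chain.
    """
    drop = set(assignment.stutter_cycles)
    kept = [e for e in target.extensions if e.cycle not in drop]
    renumbered = tuple(replace(e, cycle=i + 1) for i, e in enumerate(kept))
    new_site = None
    if target.cyclization_carbon is not None:
        producer = target.producing_cycle_of_beta_carbon(target.cyclization_carbon)
        if producer in drop:
            raise ValueError("cyclization hydroxyl is produced by a stuttered cycle")
        shift = sum(1 for c in drop if c > producer)
        new_producer = producer - sum(1 for c in drop if c < producer)
        shorter = TargetBackbone(
            target.starter_unit, target.starter_carbons, renumbered, None
        )
        new_site = shorter.beta_carbon(new_producer)
        del shift
    return TargetBackbone(target.starter_unit, target.starter_carbons, renumbered, new_site)


# ------------------------------------------------------ scoring & iteration


def module_chemistry(module: ExtensionModule) -> tuple:
    """(extender, reduction, alpha, beta) labels this module is predicted to install."""
    extender = module.at.substrate
    reduction = module.reduction_level
    substituted = extender in ("methylmalonyl", "unusual-alkylmalonyl")
    alpha = beta = None
    if reduction == "hydroxyl" and module.kr is not None and module.kr.active:
        beta = module.kr.beta_config
        if substituted:
            alpha = module.kr.alpha_config
    elif reduction == "methylene" and substituted and module.er is not None:
        alpha = module.er.alpha_outcome
    return (extender, reduction, alpha, beta)


def _cycle_mismatches(
    module: ExtensionModule, ext: Extension, weights: Mapping[str, float]
) -> tuple[float, list[dict]]:
    m_ext, m_red, m_alpha, m_beta = module_chemistry(module)
    score = 0.0
    details: list[dict] = []
    if m_ext != ext.extender:
        score += weights["extender"]
        details.append(
            {"cycle": ext.cycle, "field": "extender", "module": module.module_id,
             "predicted": m_ext, "target": ext.extender}
        )
    if m_red != ext.reduction:
        score += weights["reduction"]
        details.append(
            {"cycle": ext.cycle, "field": "reduction", "module": module.module_id,
             "predicted": m_red, "target": ext.reduction}
        )
    stereo_differs = (ext.alpha_stereo is not None and m_alpha != ext.alpha_stereo) or (
        ext.beta_stereo is not None and m_beta != ext.beta_stereo
    )
    if stereo_differs:
        score += weights["stereo"]
        details.append(
            {"cycle": ext.cycle, "field": "stereo", "module": module.module_id,
             "predicted": f"alpha={m_alpha},beta={m_beta}",
             "target": f"alpha={ext.alpha_stereo},beta={ext.beta_stereo}"}
        )
    return score, details


def _placements(n_modules: int, k: int) -> Iterable[tuple[int, ...]]:
    """All multisets of module indices receiving one extra consecutive cycle each."""
    if k == 0:
        yield ()
        return
    yield from itertools.combinations_with_replacement(range(n_modules), k)


def _evaluate_placement(
    modules: Sequence[ExtensionModule],
    target: TargetBackbone,
    extras: Mapping[int, int],
    weights: Mapping[str, float],
) -> Optional[tuple[float, IterationAssignment]]:
    """Score one stutter placement; None if a stutter block mixes chemistries."""
    cycle_to_module: dict[int, str] = {}
    iterated: list[str] = []
    stutter_cycles: list[int] = []
    score = 0.0
    details: list[dict] = []
    cycle = 1
    for j, module in enumerate(modules):
        uses = 1 + extras.get(j, 0)
        block = target.extensions[cycle - 1 : cycle - 1 + uses]
        if uses > 1:
            chems = {e.chemistry() for e in block}
            if len(chems) != 1:
                return None
            iterated.append(module.module_id)
            stutter_cycles.extend(e.cycle for e in block[1:])
        for ext in block:
            cycle_to_module[ext.cycle] = module.module_id
            s, d = _cycle_mismatches(module, ext, weights)
            score += s
            details.extend(d)
        cycle += uses
    assignment = IterationAssignment(
        cycle_to_module=cycle_to_module,
        iterated_modules=tuple(iterated),
        discrepancies=tuple(details),
        score=score,
        stutter_cycles=tuple(stutter_cycles),
    )
    return score, assignment


def _best_assignment(
    modules: Sequence[ExtensionModule],
    target: TargetBackbone,
    weights: Mapping[str, float],
) -> tuple[float, IterationAssignment, tuple[tuple[int, ...], ...]]:
    n_cycles = target.n_cycles
    n_modules = len(modules)
    if n_cycles < n_modules:
        raise SurplusModulesError(
            f"{n_modules} modules for {n_cycles} cycles: module skipping is not modelled"
        )
    k = n_cycles - n_modules
    best: Optional[tuple[float, IterationAssignment]] = None
    ties: list[IterationAssignment] = []
    for combo in _placements(n_modules, k):
        extras: dict[int, int] = {}
        for j in combo:
            extras[j] = extras.get(j, 0) + 1
        result = _evaluate_placement(modules, target, extras, weights)
        if result is None:
            continue
        score, assignment = result
        if best is None or score < best[0] - 1e-9:
            best = (score, assignment)
            ties = []
        elif abs(score - best[0]) <= 1e-9:
            ties.append(assignment)
    if best is None:
        raise IterationError(
            f"no admissible stutter placement: {n_modules} modules, {n_cycles} cycles, "
            f"no run of {k + 1} chemically identical consecutive target cycles "
            f"aligns with any module"
        )
    # deterministic tie-break toward the earliest stuttered cycle
    candidates = [best[1]] + ties
    candidates.sort(key=lambda a: (a.stutter_cycles, tuple(sorted(a.cycle_to_module.items()))))
    winner = candidates[0]
    tie_summaries = tuple(a.stutter_cycles for a in candidates[1:])
    winner = replace(winner, ties=tie_summaries)
    return best[0], winner, tie_summaries


def detect_iteration(
    ordered_modules: Sequence[ExtensionModule],
    target: TargetBackbone,
    weights: Optional[Mapping[str, float]] = None,
) -> IterationAssignment:
    """Map target cycles onto ordered physical modules, detecting stuttering.

    With equal counts the mapping is the identity.  With k more cycles than
    modules, k stutter events are placed on consecutive, chemically identical
    target cycles so as to minimise the total mismatch score; the mapping is
    monotone by construction (a module's cycles are consecutive, no back-jumps).
    """
    if weights is None:
        weights = DEFAULT_WEIGHTS
    _, assignment, _ = _best_assignment(list(ordered_modules), target, weights)
    return assignment


def order_multienzymes(
    table: ModuleTable,
    target: TargetBackbone,
    weights: Optional[Mapping[str, float]] = None,
) -> OrderingResult:
    """Infer assembly-line protein order by exhaustive mismatch minimisation.

    The loading-module protein is pinned first and the TE-bearing protein
    last; the remaining proteins are permuted exhaustively (practical for the
    <= 8-protein lines this models).  Each arrangement is scored through the
    same cycle-assignment search used by :func:`detect_iteration`.
    """
    if weights is None:
        weights = DEFAULT_WEIGHTS
    proteins = [p for p, mods in table.modules_by_protein.items()
                if mods or (table.loading and table.loading.protein_id == p)
                or table.te_protein_id == p]
    first = table.loading.protein_id if table.loading else None
    last = table.te_protein_id
    if first is None and last is None:
        raise AmbiguousOrderError(sorted(proteins))
    middle = sorted(p for p in proteins if p not in (first, last))

    best: Optional[tuple[float, tuple[str, ...], IterationAssignment]] = None
    tied: list[tuple[str, ...]] = []
    for perm in itertools.permutations(middle):
        order = tuple(p for p in ((first,) + perm + ((last,) if last != first else ())) if p)
        modules = [m for pid in order for m in table.modules_by_protein.get(pid, ())
                   if not m.malformed]
        try:
            score, assignment, _ = _best_assignment(modules, target, weights)
        except (IterationError, SurplusModulesError):
            continue
        if best is None or score < best[0] - 1e-9:
            best = (score, order, assignment)
            tied = []
        elif abs(score - best[0]) <= 1e-9:
            tied.append(order)
    if best is None:
        raise IterationError("no protein arrangement admits a consistent cycle assignment")
    score, order, assignment = best
    return OrderingResult(order=order, score=score, assignment=assignment,
                          tied_orders=tuple(tied))
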