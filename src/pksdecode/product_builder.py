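"""Predicted polyketide product: chain assembly, macrolactonization, tailoring, mass.

The linear chain is assembled unit-by-unit from the loading starter and the
cycle->module assignment, carbons numbered with C-1 at the carboxy/thioester
terminus (cycle i of n contributes C-(2(n-i)+1) and C-(2(n-i)+2); each
cycle's reduction state is carried by its beta carbon).  TE-mediated
macrolactonization onto the hydroxyl at carbon c gives a ring of c+1 atoms
(C-1..C-c plus the ester oxygen).  Post-PKS tailoring events (P450
hydroxylations, glycosyl transfer, spiro/hemiacetal closure) are applied as
ordered formula deltas; the single ordering constraint encoded is that
glycosylation requires a hydroxyl already present at its site.

Formulas are computed by exact valence bookkeeping (atom counts plus degrees
of unsaturation), with the spiroacetal kept formula-neutral by default
(ketone + hydroxyls retained) because its timing and enzymology are open;
``acetal_convention="ketal"`` switches to -H2O bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from . import formulas
from .assembly_line import (
    Extension,
    ExtensionModule,
    IterationAssignment,
    LoadingModule,
    TargetBackbone,
    module_chemistry,
)
from .sugar_pathway import ossamine_residue_formula

__all__ = [
    "ChainUnit",
    "PolyketideChain",
    "Macrolactone",
    "TailoringEvent",
    "MassResult",
    "ChemistryError",
    "assemble_chain",
    "macrolactonize",
    "apply_tailoring",
    "compute_mass",
    "export_structure",
    "formula_from_smiles",
    "chain_formula",
    "load_tailoring_events",
    "ossamycin_tailoring_events",
]

_SUBSTITUENT_BY_EXTENDER = {
    "malonyl": ("H", 0),
    "methylmalonyl": ("methyl", 1),
    "unusual-alkylmalonyl": ("isobutyl", 4),
}

#: minimum ring size considered chemically plausible for a TE macrolactone
_PLAUSIBLE_RING = 12


class ChemistryError(ValueError):
    """A requested transformation is inconsistent with the assembled chain."""


@dataclass(frozen=True)
class ChainUnit:
    """Product of one extension cycle."""

    cycle_index: int
    alpha_substituent: str  # H | methyl | isobutyl
    beta_state: str  # ketone | hydroxyl | enoyl | methylene
    alpha_stereo: Optional[str] = None
    beta_stereo: Optional[str] = None
    carbons: tuple[int, int] = (0, 0)  # (carbonyl, alpha) backbone numbers
    sidechain_carbons: tuple[int, ...] = ()
    geometry: Optional[str] = None
    module_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.beta_state == "enoyl" and self.alpha_stereo is not None:
            raise ValueError("an enoyl unit has no alpha stereocentre")
        if self.beta_state != "hydroxyl" and self.beta_stereo is not None:
            raise ValueError("beta_stereo is only meaningful for a hydroxyl unit")


@dataclass(frozen=True)
class PolyketideChain:
    starter_unit: str
    starter_carbons: int
    units: tuple[ChainUnit, ...]  # cycle order 1..n (unit n sits at the C-1 end)

    @property
    def n_cycles(self) -> int:
        return len(self.units)

    @property
    def backbone_carbon_count(self) -> int:
        return self.starter_carbons + 2 * self.n_cycles

    def beta_carbon(self, cycle: int) -> int:
        return 2 * (self.n_cycles - cycle) + 3

    def hydroxyl_carbons(self) -> dict[int, ChainUnit]:
        return {self.beta_carbon(u.cycle_index): u for u in self.units
                if u.beta_state == "hydroxyl"}

    def ketone_carbons(self) -> tuple[int, ...]:
        return tuple(sorted(self.beta_carbon(u.cycle_index) for u in self.units
                            if u.beta_state == "ketone"))

    def ene_bonds(self) -> tuple[tuple[int, int], ...]:
        out = []
        for u in self.units:
            if u.beta_state == "enoyl":
                b = self.beta_carbon(u.cycle_index)
                out.append((b - 1, b))  # alpha=beta-1 in backbone numbering
        return tuple(sorted(out))

    def carbon_state(self, carbon: int) -> str:
        """Human-readable state of a backbone carbon (for error messages)."""
        if carbon == 1:
            return "carboxyl"
        if carbon in self.hydroxyl_carbons():
            return "hydroxyl"
        if carbon in self.ketone_carbons():
            return "ketone"
        if any(carbon in bond for bond in self.ene_bonds()):
            return "enoyl"
        if carbon <= self.backbone_carbon_count:
            return "methylene/methyl"
        return "absent"


@dataclass(frozen=True)
class TailoringEvent:
    kind: str  # hydroxylation | glycosylation | spiroacetal | hemiacetal
    site: tuple[int, ...]  # carbon number(s); first is the principal site
    agent: str = ""
    formula_delta: dict[str, int] = field(default_factory=dict)
    sugar: Optional[str] = None


@dataclass(frozen=True)
class Macrolactone:
    chain: PolyketideChain
    lactone_oxygen_carbon: int
    ring_size: int
    tailoring: tuple[TailoringEvent, ...] = ()
    implausible: bool = False

    def __post_init__(self) -> None:
        if self.ring_size != self.lactone_oxygen_carbon + 1:
            raise ValueError("ring_size must equal lactone carbon + 1 (ester oxygen)")


@dataclass(frozen=True)
class MassResult:
    formula: dict[str, int]
    monoisotopic_mass: float
    mh_plus: float


# ------------------------------------------------------------ chain assembly


def assemble_chain(
    loading: LoadingModule,
    assignment: IterationAssignment,
    modules: Sequence[ExtensionModule],
    target: Optional[TargetBackbone] = None,
) -> PolyketideChain:
    """Build the linear polyketide from the cycle->module assignment.

    Each cycle takes its chemistry from the module that serves it.  For
    cycles the assignment flags as extender-discrepant (motif prediction
    contradicted by the required product, the AT2 situation) the target
    extender is installed and the motif call remains visible in the
    assignment's discrepancy list.
    """
    by_id = {m.module_id: m for m in modules}
    n = len(assignment.cycle_to_module)
    if target is not None and target.n_cycles != n:
        raise ValueError(
            f"assignment covers {n} cycles but target requires {target.n_cycles}"
        )
    overrides: dict[int, str] = {}
    for d in assignment.discrepancies:
        if d["field"] == "extender":
            overrides[d["cycle"]] = d["target"]

    units = []
    next_side = 0  # assigned after backbone length is known
    for cycle in range(1, n + 1):
        module_id = assignment.cycle_to_module.get(cycle)
        if module_id is None or module_id not in by_id:
            raise ValueError(f"cycle {cycle} is not mapped to a known module")
        module = by_id[module_id]
        extender, reduction, alpha, beta = module_chemistry(module)
        extender = overrides.get(cycle, extender)
        substituent, n_side = _SUBSTITUENT_BY_EXTENDER.get(extender, (None, 0))
        if substituent is None:
            raise ValueError(f"cycle {cycle}: unknown extender {extender!r}")
        if substituent == "H":
            alpha = None
        if reduction == "enoyl":
            alpha = None
        carbons = (2 * (n - cycle) + 1, 2 * (n - cycle) + 2)
        units.append(
            ChainUnit(
                cycle_index=cycle,
                alpha_substituent=substituent,
                beta_state=reduction,
                alpha_stereo=alpha,
                beta_stereo=beta if reduction == "hydroxyl" else None,
                carbons=carbons,
                sidechain_carbons=(),
                module_id=module_id,
            )
        )
    backbone = loading.starter_carbons + 2 * n
    next_side = backbone + 1
    numbered = []
    for u in units:
        n_side = _SUBSTITUENT_BY_EXTENDER[
            "unusual-alkylmalonyl" if u.alpha_substituent == "isobutyl" else
            ("methylmalonyl" if u.alpha_substituent == "methyl" else "malonyl")
        ][1]
        if u.alpha_substituent == "isobutyl":
            u = replace(u, sidechain_carbons=tuple(range(next_side, next_side + n_side)))
            next_side += n_side
        numbered.append(u)
    return PolyketideChain(loading.starter_unit, loading.starter_carbons, tuple(numbered))


def macrolactonize(chain: PolyketideChain, site: int) -> Macrolactone:
    """Close the macrocycle onto the hydroxyl at backbone carbon ``site``."""
    hydroxyls = chain.hydroxyl_carbons()
    if site not in hydroxyls:
        raise ChemistryError(
            f"cannot lactonize at C-{site}: carbon state is "
            f"{chain.carbon_state(site)!r}, not a hydroxyl"
        )
    ring = site + 1
    return Macrolactone(chain, site, ring, implausible=ring < _PLAUSIBLE_RING)


# ---------------------------------------------------------------- tailoring


def _known_carbons(chain: PolyketideChain) -> set[int]:
    carbons = set(range(1, chain.backbone_carbon_count + 1))
    for u in chain.units:
        carbons.update(u.sidechain_carbons)
    return carbons


def _available_hydroxyls(mac: Macrolactone) -> set[int]:
    """Hydroxyl-bearing carbons: chain hydroxyls (minus the lactone) + P450 sites."""
    free = set(mac.chain.hydroxyl_carbons()) - {mac.lactone_oxygen_carbon}
    for ev in mac.tailoring:
        if ev.kind == "hydroxylation":
            free.add(ev.site[0])
    return free


def apply_tailoring(mac: Macrolactone, events: Iterable[TailoringEvent],
                    acetal_convention: str = "neutral") -> Macrolactone:
    """Apply tailoring events in list order, validating chemistry dependencies.

    Formula deltas are additive and order-independent for independent events;
    the one ordering constraint is that glycosylation needs a hydroxyl
    already present at its site (hence hydroxylation-before-glycosylation at
    C-8 for the ossamine attachment).
    """
    if acetal_convention not in ("neutral", "ketal"):
        raise ValueError("acetal_convention must be 'neutral' or 'ketal'")
    current = mac
    known = _known_carbons(mac.chain)
    for ev in events:
        sites = ev.site
        missing = [c for c in sites if c not in known]
        if missing:
            raise ChemistryError(f"{ev.kind} at C-{missing[0]}: no such carbon in the chain")
        if ev.kind == "hydroxylation":
            delta = {"O": 1}
        elif ev.kind == "glycosylation":
            site = sites[0]
            if site not in _available_hydroxyls(current):
                raise ChemistryError(
                    f"glycosylation at C-{site} requires a hydroxyl at that carbon "
                    f"(state: {current.chain.carbon_state(site)!r}; no prior "
                    f"hydroxylation event); glycosyl transfer cannot occur"
                )
            residue = ossamine_residue_formula() if ev.sugar in (None, "l-ossamine") \
                else dict(ev.formula_delta)
            delta = formulas.subtract(residue, formulas.WATER)
        elif ev.kind in ("spiroacetal", "hemiacetal"):
            ketone_site = sites[0]
            if ketone_site not in current.chain.ketone_carbons():
                raise ChemistryError(
                    f"{ev.kind} at C-{ketone_site}: requires a ketone "
                    f"(state: {current.chain.carbon_state(ketone_site)!r})"
                )
            needed = 2 if ev.kind == "spiroacetal" else 1
            partners = [c for c in sites[1:] if c in _available_hydroxyls(current)]
            if len(sites) > 1 and len(partners) < min(needed, len(sites) - 1):
                raise ChemistryError(
                    f"{ev.kind} at C-{ketone_site}: partner hydroxyl(s) "
                    f"{list(sites[1:])} not available"
                )
            delta = formulas.subtract({}, formulas.WATER) \
                if (ev.kind == "spiroacetal" and acetal_convention == "ketal") else {}
        else:
            raise ChemistryError(f"unknown tailoring event kind {ev.kind!r}")
        applied = replace(ev, formula_delta=delta)
        current = replace(current, tailoring=current.tailoring + (applied,))
    return current


def load_tailoring_events(path: Optional[str | Path] = None) -> tuple[TailoringEvent, ...]:
    """Read a tailoring-event list from YAML (packaged ossamycin set if None)."""
    if path is None:
        text = resources.files("pksdecode.data").joinpath("ossamycin_tailoring.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    events = []
    for row in raw["events"]:
        site = row["site"]
        sites = tuple(site) if isinstance(site, (list, tuple)) else (int(site),)
        events.append(
            TailoringEvent(
                kind=row["kind"],
                site=sites,
                agent=row.get("agent", ""),
                sugar=row.get("sugar"),
            )
        )
    return tuple(events)


def ossamycin_tailoring_events() -> tuple[TailoringEvent, ...]:
    return load_tailoring_events(None)


# ------------------------------------------------------------------- masses


def _base_counts(chain: PolyketideChain) -> tuple[int, int, int]:
    """(carbons, oxygens-from-chain-states, unsaturations-from-chain) of the free acid."""
    carbons = chain.backbone_carbon_count
    for u in chain.units:
        if u.alpha_substituent == "methyl":
            carbons += 1
        elif u.alpha_substituent == "isobutyl":
            carbons += 4
    n_oh = len(chain.hydroxyl_carbons())
    n_ket = len(chain.ketone_carbons())
    n_ene = len(chain.ene_bonds())
    oxygens = 2 + n_oh + n_ket  # carboxyl 2 O + one O per OH/ketone
    unsat = 1 + n_ket + n_ene  # carboxyl C=O + each ketone + each C=C
    return carbons, oxygens, unsat


def chain_formula(chain: PolyketideChain) -> dict[str, int]:
    """Elemental formula of the linear chain as the free acid."""
    for u in chain.units:
        if u.beta_state not in ("ketone", "hydroxyl", "enoyl", "methylene"):
            raise ChemistryError(f"cycle {u.cycle_index}: unresolved beta state {u.beta_state!r}")
    c, o, unsat = _base_counts(chain)
    h = 2 * c + 2 - 2 * unsat
    return {"C": c, "H": h, "O": o}


def _macrolactone_formula(mac: Macrolactone) -> dict[str, int]:
    # lactonization: acid + internal OH -> ester + H2O (one ring, -H2O)
    base = chain_formula(mac.chain)
    base = formulas.subtract(base, formulas.WATER)
    for ev in mac.tailoring:
        base = formulas.add(base, ev.formula_delta)
    return base


def compute_mass(mac: Macrolactone) -> MassResult:
    """Monoisotopic mass and [M+H]+ of the (tailored) macrolactone."""
    formula = _macrolactone_formula(mac)
    mono = formulas.monoisotopic_mass(formula)
    return MassResult(formula=formula, monoisotopic_mass=round(mono, 4),
                      mh_plus=round(mono + formulas.PROTON_MASS, 4))


# --------------------------------------------------------- structure export


def export_structure(mac: Macrolactone) -> str:
    """Emit a SMILES string for the (tailored) product.

    Constitution (connectivity, unsaturation, substituents, sugar) is exact;
    configurational labels (2S/3R etc.) live in the per-unit report rather
    than as SMILES chirality marks, and the spiroacetal follows the same
    formula-neutral convention as the mass bookkeeping (ketone + hydroxyls).
    """
    chain = mac.chain
    site = mac.lactone_oxygen_carbon
    hydroxyls = set(chain.hydroxyl_carbons()) - {site}
    ketones = set(chain.ketone_carbons())
    enes = set(chain.ene_bonds())
    methyl_at = {u.carbons[1] for u in chain.units if u.alpha_substituent == "methyl"}
    side_at = {u.carbons[1]: u.sidechain_carbons for u in chain.units
               if u.alpha_substituent == "isobutyl"}
    extra_oh: set[int] = set()
    glyco_at: set[int] = set()
    for ev in mac.tailoring:
        if ev.kind == "hydroxylation":
            extra_oh.add(ev.site[0])
        elif ev.kind == "glycosylation":
            glyco_at.add(ev.site[0])

    sugar_smiles = "OC2CCC(N(C)C)C(C)O2"  # l-ossamine pyranoside, ring label 2

    def substituents(c: int) -> str:
        parts = []
        if c in ketones:
            parts.append("(=O)")
        if c in glyco_at:
            parts.append(f"({sugar_smiles})")
        elif c in hydroxyls or c in extra_oh:
            parts.append("(O)")
        if c in methyl_at:
            parts.append("(C)")
        if c in side_at:
            s = side_at[c]
            oh = ["(O)" if x in extra_oh else "" for x in s]
            parts.append(f"(C{oh[0]}C{oh[1]}(C{oh[2]})C{oh[3]})")
        return "".join(parts)

    tokens = ["O1C(=O)"]  # ester oxygen + C-1 carbonyl
    for c in range(2, chain.backbone_carbon_count + 1):
        bond = "=" if (c - 1, c) in enes else ""
        ring = "1" if c == site else ""
        tokens.append(f"{bond}C{ring}{substituents(c)}")
    return "".join(tokens)


def formula_from_smiles(smiles: str) -> dict[str, int]:
    """Parse a SMILES string back to an elemental formula (via RDKit)."""
    try:
        from rdkit import Chem
        from rdkit.Chem import rdMolDescriptors
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("formula_from_smiles requires rdkit") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError("SMILES does not parse")
    hill = rdMolDescriptors.CalcMolFormula(mol)
    import re as _re

    counts: dict[str, int] = {}
    for el, num in _re.findall(r"([A-Z][a-z]?)(\d*)", hill):
        if el:
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    return counts
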