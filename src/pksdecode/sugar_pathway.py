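"""Rule-based reconstruction of the dTDP-l-ossamine deoxyaminosugar pathway.

l-Ossamine (2,3,4,6-tetradeoxy-4-N,N-dimethylamino-hexose) is built on a
dTDP carrier from d-glucose-1-phosphate.  The two earliest enzymes
(dTDP-d-glucose synthase and 4,6-dehydratase) are recruited from elsewhere in
the genome; six cluster-encoded enzymes then act: 2,3-dehydratase (OssS) and
3-ketoreductase (the sugar OssT) accomplish 2-deoxygenation, the
3,4-dehydratase (OssQ, assisted by an undefined external reductase)
3-deoxygenation to dTDP-d-cinerulose, an epimerase (OssZ1), a 4-transaminase
(OssJ) and a SAM-dependent N,N-dimethyltransferase (OssI) complete the
glycosyl donor, which the glycosyltransferase OssG(T) transfers onto the C-8
hydroxyl of the aglycone.

Epimerisation timing is not settled biochemically: the alternative
"early-epimerisation" branch places it before 3,4-dehydration, passing
through a dTDP-l-kedarosamine-type intermediate.  Both branches apply the
same formula deltas, so the final residue formula is branch-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from . import formulas
from .cluster_io import RoleAssignment, SUGAR_ROLES

__all__ = [
    "SugarStep",
    "PathwayGraph",
    "reconstruct_pathway",
    "residue_formula",
    "glycosyl_transfer_delta",
    "ossamine_residue_formula",
    "to_dot",
    "BRANCHES",
]

BRANCHES = ("canonical", "early-epimerisation")

#: role -> transform tag for the six cluster-encoded biosynthetic steps.
_ROLE_TRANSFORM = {
    "sugar-2,3-dehydratase": "2,3-dehydration",
    "sugar-3-ketoreductase": "3-ketoreduction",
    "sugar-3,4-dehydratase": "3,4-dehydration",
    "sugar-epimerase": "epimerisation",
    "sugar-transaminase": "transamination",
    "sugar-N-methyltransferase": "N,N-dimethylation",
}

#: formula delta of each transform, applied to the free-sugar moiety.
_TRANSFORM_DELTA: dict[str, dict[str, int]] = {
    "nucleotidylation": {},
    "4,6-dehydration": {"H": -2, "O": -1},
    "2,3-dehydration": {"H": -2, "O": -1},
    "3-ketoreduction": {"H": 2},
    # the paired external reduction is folded into the dehydration step
    "3,4-dehydration": {"O": -1},
    "epimerisation": {},
    "transamination": {"N": 1, "H": 3, "O": -1},
    "N,N-dimethylation": {"C": 2, "H": 4},
}

_GLUCOSE = {"C": 6, "H": 12, "O": 6}

#: intermediate product names along the canonical branch, keyed by transform.
_CANONICAL_PRODUCTS = {
    "nucleotidylation": "dTDP-d-glucose",
    "4,6-dehydration": "dTDP-4-keto-6-deoxy-d-glucose",
    "2,3-dehydration": "dTDP-3,4-diketo-2,6-dideoxy-d-glucose",
    "3-ketoreduction": "dTDP-4-keto-2,6-dideoxy-d-glucose",
    "3,4-dehydration": "dTDP-d-cinerulose",
    "epimerisation": "dTDP-l-cinerulose",
    "transamination": "dTDP-4-amino-2,3,4,6-tetradeoxy-l-hexose",
    "N,N-dimethylation": "dTDP-l-ossamine",
    "glycosyl transfer": "l-ossaminyl-aglycone",
}

_EARLY_PRODUCTS = dict(
    _CANONICAL_PRODUCTS,
    **{
        "epimerisation": "dTDP-l-kedarosamine-type intermediate",
        "3,4-dehydration": "dTDP-l-cinerulose",
    },
)


@dataclass(frozen=True)
class SugarStep:
    order_index: int
    enzyme_role: str
    gene_id: Optional[str]
    substrate_name: str
    product_name: str
    transform: str
    external: bool = False  # recruited outside the cluster / external helper
    note: str = ""


@dataclass(frozen=True)
class PathwayGraph:
    steps: tuple[SugarStep, ...]
    branch: str
    missing_roles: tuple[str, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.steps, self.steps[1:]):
            if a.product_name != b.substrate_name:
                raise ValueError(
                    f"pathway gap: step {a.order_index} yields {a.product_name!r} "
                    f"but step {b.order_index} consumes {b.substrate_name!r}"
                )


def _biosynthetic_order(branch: str) -> list[str]:
    if branch == "canonical":
        return ["2,3-dehydration", "3-ketoreduction", "3,4-dehydration",
                "epimerisation", "transamination", "N,N-dimethylation"]
    if branch == "early-epimerisation":
        return ["2,3-dehydration", "3-ketoreduction", "epimerisation",
                "3,4-dehydration", "transamination", "N,N-dimethylation"]
    raise ValueError(f"branch must be one of {BRANCHES}, got {branch!r}")


def reconstruct_pathway(
    roles: Iterable[RoleAssignment], branch: str = "canonical"
) -> PathwayGraph:
    """Build the ordered pathway graph, binding cluster genes to steps.

    Missing roles are recorded in ``missing_roles`` (they are data, not an
    error); the two pre-pathway enzymes are always emitted as
    "recruited elsewhere" placeholders.
    """
    order = _biosynthetic_order(branch)
    products = _CANONICAL_PRODUCTS if branch == "canonical" else _EARLY_PRODUCTS
    transform_to_role = {v: k for k, v in _ROLE_TRANSFORM.items()}
    gene_by_role: dict[str, str] = {}
    for r in roles:
        if r.role in _ROLE_TRANSFORM or r.role == "glycosyltransferase":
            gene_by_role.setdefault(r.role, r.gene_id)

    steps: list[SugarStep] = []
    substrate = "alpha-d-glucose-1-phosphate"
    idx = 0
    for transform, role_label, note in (
        ("nucleotidylation", "dTDP-d-glucose synthase", "recruited elsewhere in the genome"),
        ("4,6-dehydration", "dTDP-d-glucose 4,6-dehydratase", "recruited elsewhere in the genome"),
    ):
        product = products[transform]
        steps.append(SugarStep(idx, role_label, None, substrate, product, transform,
                               external=True, note=note))
        substrate = product
        idx += 1

    missing: list[str] = []
    for transform in order:
        role = transform_to_role[transform]
        gene = gene_by_role.get(role)
        if gene is None:
            missing.append(role)
        note = ""
        if transform == "3,4-dehydration":
            note = "assisted by an undefined reductase encoded elsewhere"
        product = products[transform]
        steps.append(SugarStep(idx, role, gene, substrate, product, transform,
                               external=(transform == "3,4-dehydration" and not gene),
                               note=note))
        substrate = product
        idx += 1

    gt_gene = gene_by_role.get("glycosyltransferase")
    if gt_gene is None:
        missing.append("glycosyltransferase")
    steps.append(SugarStep(idx, "glycosyltransferase", gt_gene, substrate,
                           products["glycosyl transfer"], "glycosyl transfer"))
    return PathwayGraph(tuple(steps), branch, tuple(missing))


def residue_formula(graph: PathwayGraph) -> dict[str, int]:
    """Elemental formula of the free sugar after N,N-dimethylation.

    Derived by applying each transform's formula delta from d-glucose; raises
    if the graph is missing any biosynthetic transform (either absent from
    the step list or unassigned in the cluster).
    """
    required = set(_TRANSFORM_DELTA) - {"nucleotidylation"}
    seen = {s.transform for s in graph.steps}
    absent = sorted(required - seen)
    role_missing = sorted(set(graph.missing_roles) - {"glycosyltransferase"})
    if absent or role_missing:
        raise ValueError(
            "pathway incomplete: "
            + "; ".join(
                filter(None, [
                    f"missing transforms: {', '.join(absent)}" if absent else "",
                    f"unassigned roles: {', '.join(role_missing)}" if role_missing else "",
                ])
            )
        )
    formula = dict(_GLUCOSE)
    for step in graph.steps:
        if step.transform in _TRANSFORM_DELTA:
            formula = formulas.add(formula, _TRANSFORM_DELTA[step.transform])
    return formula


def glycosyl_transfer_delta(graph: PathwayGraph) -> dict[str, int]:
    """Formula change of the aglycone upon glycosyl transfer (residue - H2O)."""
    return formulas.subtract(residue_formula(graph), formulas.WATER)


def ossamine_residue_formula() -> dict[str, int]:
    """Free l-ossamine formula from a complete canonical pathway (C8H17NO2).

    Gene bindings do not change the arithmetic, so a fully-bound synthetic
    role set is used; the product module derives the glycosylation delta from
    this rather than hard-coding the residue.
    """
    roles = tuple(
        RoleAssignment(f"gene_{i}", role, "synthetic")
        for i, role in enumerate(SUGAR_ROLES + ("glycosyltransferase",))
    )
    return residue_formula(reconstruct_pathway(roles, "canonical"))


def to_dot(graph: PathwayGraph) -> str:
    """Graphviz DOT rendering of the pathway."""
    lines = ["digraph sugar_pathway {", "  rankdir=LR;", "  node [shape=box];"]
    for step in graph.steps:
        gene = step.gene_id or "unassigned"
        style = ' style=dashed' if step.external else ""
        label = f"{step.transform}\\n{step.enzyme_role}\\n[{gene}]"
        lines.append(
            f'  "{step.substrate_name}" -> "{step.product_name}" [label="{label}"{style}];'
        )
    lines.append("}")
    return "\n".join(lines)
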