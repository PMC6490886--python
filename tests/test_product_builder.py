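"""Chain assembly, macrolactonization, tailoring, mass and structure export."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pksdecode import assembly_line as al
from pksdecode import formulas
from pksdecode import product_builder as pb
from pksdecode import synthetic_data as sd
from pksdecode.domain_grammar import classify_protein, load_profiles

DES_HYDROXY_MH_PLUS = 896.5  # printed [M+H]+ of the mono-deshydroxy congener
O_MASS = 15.9949


@pytest.fixture(scope="module")
def oss_chain(oss_module_table_m, oss_ordering_m, oss_target_m):
    table, ordering, target = oss_module_table_m, oss_ordering_m, oss_target_m
    modules = [m for pid in ordering.order for m in table.modules_by_protein[pid]]
    return pb.assemble_chain(table.loading, ordering.assignment, modules, target)


# session fixtures re-exposed at module scope for clarity
@pytest.fixture(scope="module")
def oss_module_table_m(oss_tables):
    return al.build_modules(oss_tables)


@pytest.fixture(scope="module")
def oss_target_m():
    return al.ossamycin_target()


@pytest.fixture(scope="module")
def oss_ordering_m(oss_module_table_m, oss_target_m):
    return al.order_multienzymes(oss_module_table_m, oss_target_m)


@pytest.fixture(scope="module")
def oss_macrolactone(oss_chain, oss_target_m):
    return pb.macrolactonize(oss_chain, oss_target_m.cyclization_carbon)


@pytest.fixture(scope="module")
def oss_tailored(oss_macrolactone):
    return pb.apply_tailoring(oss_macrolactone, pb.ossamycin_tailoring_events())


def _minimal_chain(beta_state="ketone", starter=("acetate", 2), substituent="H"):
    unit = pb.ChainUnit(
        cycle_index=1, alpha_substituent=substituent, beta_state=beta_state,
        carbons=(1, 2),
    )
    return pb.PolyketideChain(starter[0], starter[1], (unit,))


# ------------------------------------------------------------ chain assembly


def test_ossamycin_chain_has_33_backbone_carbons(oss_chain):
    assert oss_chain.backbone_carbon_count == 33
    assert oss_chain.starter_unit == "propionate"


def test_unusual_extender_carries_c4_sidechain(oss_chain):
    unit7 = oss_chain.units[6]
    assert unit7.alpha_substituent == "isobutyl"
    assert unit7.sidechain_carbons == (34, 35, 36, 37)
    assert unit7.carbons == (17, 18)


def test_at2_override_installs_malonyl(oss_chain):
    unit2 = oss_chain.units[1]
    assert unit2.alpha_substituent == "H"  # motif said methylmalonyl; product needs malonyl


def test_spiroketal_ketone_sits_at_c25(oss_chain):
    assert 25 in oss_chain.ketone_carbons()
    assert 19 in oss_chain.ketone_carbons()


def test_trivial_single_malonyl_cycle_is_acetoacetate():
    chain = _minimal_chain("ketone")
    assert chain.backbone_carbon_count == 4
    assert pb.chain_formula(chain) == {"C": 4, "H": 6, "O": 3}  # 3-oxobutanoic acid


# --------------------------------------------------------- macrolactonization


def test_ring_size_is_site_plus_one(oss_macrolactone):
    assert oss_macrolactone.lactone_oxygen_carbon == 23
    assert oss_macrolactone.ring_size == 24
    assert not oss_macrolactone.implausible


def test_lactonization_requires_hydroxyl(oss_chain):
    with pytest.raises(pb.ChemistryError, match="C-25.*ketone"):
        pb.macrolactonize(oss_chain, 25)


def test_beta_lactone_flagged_implausible():
    chain = _minimal_chain("hydroxyl")
    mac = pb.macrolactonize(chain, 3)
    assert mac.ring_size == 4
    assert mac.implausible


def test_iteration_suppressed_rebuild_gives_ring_22(
    oss_module_table_m, oss_ordering_m, oss_target_m
):
    shorter = al.suppress_iteration(oss_target_m, oss_ordering_m.assignment)
    modules = [m for pid in oss_ordering_m.order
               for m in oss_module_table_m.modules_by_protein[pid]]
    identity = al.IterationAssignment(
        cycle_to_module={i + 1: m.module_id for i, m in enumerate(modules)},
        iterated_modules=(), discrepancies=oss_ordering_m.assignment.discrepancies,
        score=0.0, stutter_cycles=(),
    )
    chain = pb.assemble_chain(oss_module_table_m.loading, identity, modules, shorter)
    mac = pb.macrolactonize(chain, shorter.cyclization_carbon)
    assert mac.ring_size == 22


# ------------------------------------------------------------------ tailoring


def test_tailoring_fixture_applies_all_events(oss_tailored, oss_macrolactone):
    assert len(oss_tailored.tailoring) == 6
    before = pb.compute_mass(oss_macrolactone).formula
    after = pb.compute_mass(oss_tailored).formula
    delta = formulas.subtract(after, before)
    # net: 4 hydroxylations + ossaminyl residue (formula-neutral spiroacetal)
    assert delta == formulas.add({"O": 4}, formulas.subtract(
        {"C": 8, "H": 17, "N": 1, "O": 2}, formulas.WATER))


def test_empty_event_list_is_identity(oss_macrolactone):
    assert pb.apply_tailoring(oss_macrolactone, []) == oss_macrolactone


def test_glycosylation_requires_prior_hydroxyl(oss_macrolactone):
    events = [e for e in pb.ossamycin_tailoring_events() if e.kind == "glycosylation"]
    with pytest.raises(pb.ChemistryError, match="C-8.*cannot occur"):
        pb.apply_tailoring(oss_macrolactone, events)


def test_independent_events_commute(oss_macrolactone):
    events = pb.ossamycin_tailoring_events()
    hydroxylations = [e for e in events if e.kind == "hydroxylation"]
    a = pb.apply_tailoring(oss_macrolactone, hydroxylations)
    b = pb.apply_tailoring(oss_macrolactone, list(reversed(hydroxylations)))
    assert pb.compute_mass(a).formula == pb.compute_mass(b).formula


def test_unknown_event_kind_raises(oss_macrolactone):
    with pytest.raises(pb.ChemistryError, match="unknown tailoring"):
        pb.apply_tailoring(oss_macrolactone, [pb.TailoringEvent("oxidation", (4,))])


def test_ketal_convention_releases_water(oss_macrolactone):
    events = pb.ossamycin_tailoring_events()
    neutral = pb.apply_tailoring(oss_macrolactone, events, acetal_convention="neutral")
    ketal = pb.apply_tailoring(oss_macrolactone, events, acetal_convention="ketal")
    dm = pb.compute_mass(neutral).monoisotopic_mass - pb.compute_mass(ketal).monoisotopic_mass
    assert dm == pytest.approx(formulas.monoisotopic_mass(formulas.WATER), abs=1e-3)


# --------------------------------------------------------------------- mass


def test_water_monoisotopic_mass():
    assert formulas.monoisotopic_mass({"H": 2, "O": 1}) == pytest.approx(18.0106, abs=1e-4)


def test_des_hydroxy_ion_matches_printed_mz(oss_tailored):
    full = pb.compute_mass(oss_tailored)
    assert abs((full.mh_plus - O_MASS) - DES_HYDROXY_MH_PLUS) <= 0.3


def test_removing_one_hydroxylation_shifts_mass_by_one_oxygen(oss_macrolactone):
    events = list(pb.ossamycin_tailoring_events())
    full = pb.apply_tailoring(oss_macrolactone, events)
    minus = pb.apply_tailoring(
        oss_macrolactone,
        [e for i, e in enumerate(events) if not (e.kind == "hydroxylation" and i == 3)],
    )
    dm = pb.compute_mass(full).monoisotopic_mass - pb.compute_mass(minus).monoisotopic_mass
    assert dm == pytest.approx(O_MASS, abs=1e-4)


def test_mass_matches_per_element_summation_oracle(oss_tailored):
    result = pb.compute_mass(oss_tailored)
    # independent summation with independently stated isotope masses
    table = {"C": 12.0, "H": 1.00782503, "N": 14.00307401, "O": 15.99491462}
    expected = sum(table[el] * n for el, n in result.formula.items())
    assert result.monoisotopic_mass == pytest.approx(expected, abs=1e-4)
    assert result.mh_plus == pytest.approx(expected + 1.00727646, abs=1e-4)


def test_unresolved_beta_state_raises():
    unit = pb.ChainUnit(cycle_index=1, alpha_substituent="H", beta_state="unknown",
                        carbons=(1, 2))
    chain = pb.PolyketideChain("acetate", 2, (unit,))
    with pytest.raises(pb.ChemistryError, match="unresolved"):
        pb.chain_formula(chain)


# ------------------------------------------------------------------- export


def test_minimal_lactone_smiles_is_valid():
    chain = _minimal_chain("hydroxyl")
    mac = pb.macrolactonize(chain, 3)
    smiles = pb.export_structure(mac)
    assert pb.formula_from_smiles(smiles) == pb.compute_mass(mac).formula


def test_ossamycin_smiles_round_trips_formula(oss_tailored):
    smiles = pb.export_structure(oss_tailored)
    assert pb.formula_from_smiles(smiles) == pb.compute_mass(oss_tailored).formula


def test_untailored_smiles_counts_backbone_plus_substituents(oss_macrolactone, oss_chain):
    smiles = pb.export_structure(oss_macrolactone)
    counts = pb.formula_from_smiles(smiles)
    n_methyl = sum(1 for u in oss_chain.units if u.alpha_substituent == "methyl")
    assert counts["C"] == oss_chain.backbone_carbon_count + n_methyl + 4


def test_smiles_mass_agrees_with_rdkit(oss_tailored):
    rdkit = pytest.importorskip("rdkit")
    from rdkit import Chem
    from rdkit.Chem.Descriptors import ExactMolWt

    mol = Chem.MolFromSmiles(pb.export_structure(oss_tailored))
    assert ExactMolWt(mol) == pytest.approx(
        pb.compute_mass(oss_tailored).monoisotopic_mass, abs=1e-3
    )


# ------------------------------------------------------------- properties


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 5000))
def test_carbon_conservation_across_generated_lines(seed):
    """backbone carbons = starter + 2 x cycles for every generated line."""
    profiles = load_profiles()
    config = sd.random_line_config(seed)
    line = sd.emit_line(config)
    tables = {pid: classify_protein(pid, seq, profiles)
              for pid, seq in line.sequences if not pid.startswith("decoy")}
    table = al.build_modules(tables)
    target = sd.target_from_config(config)
    ordering = al.order_multienzymes(table, target)
    modules = [m for pid in ordering.order for m in table.modules_by_protein[pid]]
    chain = pb.assemble_chain(table.loading, ordering.assignment, modules, target)
    assert chain.backbone_carbon_count == target.starter_carbons + 2 * target.n_cycles
    pb.chain_formula(chain)  # formula is always resolvable for generated lines
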