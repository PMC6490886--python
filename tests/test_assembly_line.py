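"""Module grammar, multienzyme ordering and programmed-iteration detection."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from pksdecode import assembly_line as al
from pksdecode import synthetic_data as sd
from pksdecode.domain_grammar import classify_protein, load_profiles


def _tables_from_config(config, profiles):
    line = sd.emit_line(config)
    return {
        pid: classify_protein(pid, seq, profiles)
        for pid, seq in line.sequences
        if not pid.startswith("decoy")
    }


# ------------------------------------------------------------ build_modules


def test_fixture_yields_14_modules_loading_and_te(oss_module_table):
    assert len(oss_module_table.extension_modules) == 14
    assert oss_module_table.loading is not None
    assert oss_module_table.loading.protein_id == "OssA1"
    assert oss_module_table.loading.starter_unit == "propionate"
    assert oss_module_table.te_protein_id == "OssA8"


def test_first_four_multienzymes_house_eight_modules(oss_module_table):
    counts = oss_module_table.per_protein_counts
    assert sum(counts[p] for p in ("OssA1", "OssA2", "OssA3", "OssA4")) == 8
    assert counts["OssA5"] == counts["OssA6"] == 1


def test_ossa7_ossa8_house_four_modules(oss_tables):
    restricted = {p: oss_tables[p] for p in ("OssA7", "OssA8")}
    table = al.build_modules(restricted)
    assert len(table.extension_modules) == 4


def test_minimal_module_is_ketone_level(profiles):
    spec = sd.ModuleSpec(at_substrate="malonyl")  # KS-AT-ACP only
    config = sd.GeneratorConfig(seed=5, proteins=((spec,),), loading=None, te=False)
    table = al.build_modules(_tables_from_config(config, profiles))
    (module,) = table.extension_modules
    assert module.reduction_level == "ketone"
    assert table.loading is None


def test_inactive_dh_caps_reduction_at_hydroxyl(oss_module_table):
    m1 = oss_module_table.modules_by_protein["OssA1"][0]
    assert m1.dh is not None and not m1.dh.active
    assert m1.kr is not None and m1.kr.active
    assert m1.reduction_level == "hydroxyl"


def test_orphan_acp_flagged_malformed(profiles):
    # build a call table with a dangling ACP: drop the KS of a scanned module
    config = sd.GeneratorConfig(
        seed=9, proteins=((sd.ModuleSpec(at_substrate="malonyl"),),),
        loading=None, te=False,
    )
    calls = list(next(iter(_tables_from_config(config, profiles).values())))
    no_ks = [c for c in calls if c.domain_type != "KS"]
    table = al.build_modules({"p": no_ks})
    assert table.extension_modules == ()
    assert any("orphan" in w for w in table.warnings)


# -------------------------------------------------------------- ordering


def test_fixture_order_pins_loading_first_te_last(oss_ordering):
    order = oss_ordering.order
    assert order[:4] == ("OssA1", "OssA2", "OssA3", "OssA4")
    assert order[-2:] == ("OssA7", "OssA8")
    assert set(order[4:6]) == {"OssA5", "OssA6"}
    assert oss_ordering.tied_orders == ()


def test_fixture_order_agrees_with_bruteforce(oss_module_table, oss_target, oss_ordering):
    best, winners = oracles.best_order_bruteforce(oss_module_table, oss_target)
    assert oss_ordering.score == pytest.approx(best)
    assert oss_ordering.order in winners
    assert len(winners) == 1


def test_single_protein_line_is_trivial(profiles):
    spec = sd.ModuleSpec(at_substrate="methylmalonyl", kr=sd.KRSpec("B1"))
    config = sd.GeneratorConfig(seed=2, proteins=((spec,),))
    table = al.build_modules(_tables_from_config(config, profiles))
    target = sd.target_from_config(config)
    result = al.order_multienzymes(table, target)
    assert result.order == ("pks_1",)


def test_no_loading_no_te_is_ambiguous(profiles):
    spec = sd.ModuleSpec(at_substrate="malonyl", kr=sd.KRSpec("A1"))
    config = sd.GeneratorConfig(
        seed=3, proteins=((spec,), (sd.ModuleSpec(at_substrate="methylmalonyl"),)),
        loading=None, te=False,
    )
    table = al.build_modules(_tables_from_config(config, profiles))
    target = sd.target_from_config(config)
    with pytest.raises(al.AmbiguousOrderError) as err:
        al.order_multienzymes(table, target)
    assert set(err.value.candidates) == {"pks_1", "pks_2"}


def test_shuffled_four_protein_line_recovers_planted_order(profiles):
    config = sd.random_line_config(41, max_proteins=4)
    table = al.build_modules(_tables_from_config(config, profiles))
    target = sd.target_from_config(config)
    result = al.order_multienzymes(table, target)
    n = len(config.proteins)
    assert result.order == tuple(f"pks_{i + 1}" for i in range(n))
    assert result.score == 0.0


# -------------------------------------------------------------- iteration


def test_fixture_iteration_is_cycles_9_and_10(oss_ordering, oss_target, oss_modules_in_order):
    a = oss_ordering.assignment
    assert len(a.iterated_modules) == 1
    (iterated,) = a.iterated_modules
    assert a.cycle_to_module[9] == iterated
    assert a.cycle_to_module[10] == iterated
    assert a.stutter_cycles == (10,)
    assert a.ties == ()
    # the iterated module is one of the two monomodular middle proteins
    assert iterated.split(":")[0] in ("OssA5", "OssA6")
    for cycle in (9, 10):
        ext = oss_target.extensions[cycle - 1]
        assert ext.extender == "malonyl"
        assert ext.reduction == "methylene"


def test_fixture_discrepancy_list_contains_at2(oss_ordering, oss_target):
    d = [x for x in oss_ordering.assignment.discrepancies if x["field"] == "extender"]
    assert len(d) == 1
    assert d[0]["cycle"] == 2
    assert d[0]["predicted"] == "methylmalonyl"
    assert d[0]["target"] == "malonyl"
    # the discordant cycle builds the C-27/C-28 pair
    assert oss_target.carbons_for_cycle(2) == (27, 28)


def test_equal_counts_give_identity_mapping(profiles):
    config = sd.random_line_config(11)
    table = al.build_modules(_tables_from_config(config, profiles))
    target = sd.target_from_config(config)  # no stutter planted
    modules = [m for mods in table.modules_by_protein.values() for m in mods]
    assignment = al.detect_iteration(modules, target)
    assert assignment.iterated_modules == ()
    assert assignment.cycle_to_module == {
        i + 1: m.module_id for i, m in enumerate(modules)
    }


def test_surplus_modules_error(profiles):
    config = sd.random_line_config(12)
    table = al.build_modules(_tables_from_config(config, profiles))
    target = sd.target_from_config(config)
    modules = list(table.extension_modules)
    short = dataclasses.replace(
        target, extensions=target.extensions[: len(modules) - 1]
    )
    short = al.TargetBackbone(
        target.starter_unit, target.starter_carbons,
        target.extensions[: len(modules) - 1], None,
    )
    with pytest.raises(al.SurplusModulesError):
        al.detect_iteration(modules, short)


def test_no_consistent_stutter_raises_with_diagnostic(profiles):
    # all-distinct cycles but one cycle more than modules: no identical pair
    config = sd.random_line_config(13)
    table = al.build_modules(_tables_from_config(config, profiles))
    target = sd.target_from_config(config)
    modules = list(table.extension_modules)[:-1]  # one fewer module, no repeat cycle
    if len(modules) == 0:
        pytest.skip("degenerate draw")
    with pytest.raises(al.IterationError, match="stutter"):
        al.detect_iteration(modules, target)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 5000), data=st.data())
def test_iteration_agrees_with_bruteforce_enumeration(seed, data):
    """Planted stutters are recovered and match exhaustive placement search."""
    profiles = load_profiles()
    config = sd.random_line_config(seed)
    n_modules = sum(len(p) for p in config.proteins)
    stutter = data.draw(st.integers(0, n_modules - 1))
    target = sd.target_from_config(config, stutter_module=stutter)
    table = al.build_modules(_tables_from_config(config, profiles))
    modules = [m for mods in table.modules_by_protein.values() for m in mods]
    assignment = al.detect_iteration(modules, target)

    # conservation: cycles = modules + stutter events
    assert target.n_cycles == len(modules) + len(assignment.stutter_cycles)
    # monotone mapping, consecutive stutters
    order_ids = [m.module_id for m in modules]
    seq = [order_ids.index(assignment.cycle_to_module[c])
           for c in range(1, target.n_cycles + 1)]
    assert seq == sorted(seq)
    # the planted stutter module serves both of its cycles
    planted = modules[stutter].module_id
    assert assignment.iterated_modules == (planted,)
    assert assignment.cycle_to_module[stutter + 1] == planted
    assert assignment.cycle_to_module[stutter + 2] == planted

    best, winners = oracles.best_assignment_bruteforce(modules, target)
    assert assignment.score == pytest.approx(best)
    blocks = {}
    for c, mid in assignment.cycle_to_module.items():
        blocks.setdefault(order_ids.index(mid), []).append(c)
    impl_blocks = [sorted(blocks[i]) for i in range(len(modules))]
    assert impl_blocks in [b for _, b in winners]


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 5000))
def test_ordering_agrees_with_bruteforce_permutations(seed):
    profiles = load_profiles()
    config = sd.random_line_config(seed, max_proteins=4)
    table = al.build_modules(_tables_from_config(config, profiles))
    target = sd.target_from_config(config)
    result = al.order_multienzymes(table, target)
    best, winners = oracles.best_order_bruteforce(table, target)
    assert result.score == pytest.approx(best)
    assert result.order in winners


def test_suppress_iteration_gives_homologous_site(oss_target, oss_ordering):
    shorter = al.suppress_iteration(oss_target, oss_ordering.assignment)
    assert shorter.n_cycles == 14
    assert shorter.cyclization_carbon == 21
    assert shorter.backbone_carbon_count == 31
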