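"""Independent brute-force oracles for ordering and iteration placement.

Deliberately re-derived with different machinery from the library: cycle
blocks are enumerated as compositions (cut-point subsets) rather than
extra-use multisets, and scores are accumulated with plain loops, so
agreement is a meaningful cross-check rather than a tautology.
"""

import itertools

from pksdecode.assembly_line import DEFAULT_WEIGHTS, module_chemistry


def cycle_mismatch_score(module, ext, weights=DEFAULT_WEIGHTS):
    m_ext, m_red, m_alpha, m_beta = module_chemistry(module)
    score = 0.0
    if m_ext != ext.extender:
        score += weights["extender"]
    if m_red != ext.reduction:
        score += weights["reduction"]
    if (ext.alpha_stereo is not None and m_alpha != ext.alpha_stereo) or (
        ext.beta_stereo is not None and m_beta != ext.beta_stereo
    ):
        score += weights["stereo"]
    return score


def all_block_assignments(n_cycles, n_modules):
    """Every split of cycles 1..n into n_modules consecutive non-empty blocks."""
    for cuts in itertools.combinations(range(1, n_cycles), n_modules - 1):
        bounds = (0,) + cuts + (n_cycles,)
        yield [list(range(bounds[i] + 1, bounds[i + 1] + 1)) for i in range(n_modules)]


def best_assignment_bruteforce(modules, target, weights=DEFAULT_WEIGHTS):
    """(min score, list of (score, blocks)) over all chemistry-valid assignments."""
    results = []
    for blocks in all_block_assignments(target.n_cycles, len(modules)):
        valid = True
        for block in blocks:
            chems = {target.extensions[c - 1].chemistry() for c in block}
            if len(block) > 1 and len(chems) != 1:
                valid = False
                break
        if not valid:
            continue
        score = 0.0
        for module, block in zip(modules, blocks):
            for c in block:
                score += cycle_mismatch_score(module, target.extensions[c - 1], weights)
        results.append((score, blocks))
    if not results:
        return None, []
    best = min(s for s, _ in results)
    return best, [r for r in results if abs(r[0] - best) <= 1e-9]


def best_order_bruteforce(table, target, weights=DEFAULT_WEIGHTS):
    """(min score, set of orders achieving it) over all pinned permutations."""
    proteins = list(table.modules_by_protein)
    first = table.loading.protein_id if table.loading else None
    last = table.te_protein_id
    middle = [p for p in proteins if p not in (first, last)]
    results = {}
    for perm in itertools.permutations(middle):
        order = tuple(p for p in (first,) + perm + ((last,) if last != first else ()) if p)
        modules = [m for pid in order for m in table.modules_by_protein[pid]
                   if not m.malformed]
        score, _ = best_assignment_bruteforce(modules, target, weights)
        if score is not None:
            results[order] = score
    best = min(results.values())
    return best, {o for o, s in results.items() if abs(s - best) <= 1e-9}
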