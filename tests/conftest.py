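"""Shared fixtures and independent oracles for the test suite.

The oracles here (brute-force Mann–Whitney enumeration, exhaustive origin
enumeration, truth-vs-recovery comparison) are deliberately written without
reference to the implementation paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

import clonescope as cs


def mw_two_sided_enumeration(a, b) -> float:
    """Two-sided exact Mann–Whitney p by full enumeration of all labelings.

    For pooled values x (no ties) and group sizes (n1, n2): enumerate every
    choice of n1 positions as "group a", compute the U statistic for each,
    and report the probability of a U at least as extreme (as far from the
    null mean) as the observed one.
    """
    a, b = list(a), list(b)
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    n1, n2 = len(a), len(b)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    observed = u_stat(a, b)
    center = n1 * n2 / 2.0
    count = 0
    total = 0
    for idx in combinations(range(n1 + n2), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n1 + n2) if i not in idx]
        u = u_stat(ga, gb)
        if abs(u - center) >= abs(observed - center):
            count += 1
        total += 1
    return count / total


def brute_force_origin(populations) -> str:
    """Origin by direct subset containment, independent of classify_origin."""
    six = {"n", "m", "E", "M", "B", "T"}
    return "HSC" if six.issubset(set(populations)) else "HPC"


def truth_partition(bundle):
    """Ground-truth partition of mutant cells: set of frozensets of cell ids."""
    parts: dict[str, set] = {}
    for cell_id, clone_id in bundle.truth.cell_clone.items():
        if not clone_id.endswith(":WT"):
            parts.setdefault(clone_id, set()).add(cell_id)
    return {frozenset(v) for v in parts.values()}


def recovery_report(bundle) -> dict:
    """Run the pipeline on a bundle and compare against the ground truth.

    Returns booleans for partition equality, mutation-class recovery and
    per-clone origin recovery, plus the exclusion table.
    """
    gm = cs.build_genotype_matrix(bundle.read_counts, bundle.cells, bundle.sites)
    clones, classes, exclusions = cs.reconstruct_cohort(gm)
    recovered = {frozenset(c.member_cells) for c in clones}
    truth_by_id = {c.clone_id: c for c in bundle.truth.clones}
    intended = bundle.sites.set_index("site_id")["true_class"]
    classes_ok = all(classes.loc[s, "mut_class"] == intended[s] for s in classes.index) and set(
        classes.index
    ) == {s for c in bundle.truth.clones for s in c.signature}
    origins_ok = all(
        c.clone_id in truth_by_id and truth_by_id[c.clone_id].origin == c.origin for c in clones
    )
    return {
        "partition_equal": recovered == truth_partition(bundle),
        "classes_equal": classes_ok,
        "origins_equal": origins_ok,
        "exclusions": exclusions,
        "clones": clones,
        "gm": gm,
    }


@pytest.fixture(scope="session")
def noiseless_bundle():
    """A small noiseless two-group cohort with exactly recoverable truth."""
    cfg = cs.noiseless_config(
        n_donors_hd=2, n_donors_mds=3, cells_per_population=(8, 12), seed=7
    )
    return cs.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_bundle():
    """A default-noise cohort (dropout, false positives, coverage tail)."""
    cfg = cs.SimConfig(
        n_donors_hd=2, n_donors_mds=4, cells_per_population=(10, 16), seed=11
    )
    return cs.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
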