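"""Clone reconstruction, CH/MDS classification, origin inference and
cross-donor clone families."""

from itertools import chain, combinations

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clonescope as cs
from clonescope.clones import Clone

from conftest import brute_force_origin, recovery_report


def _gm_from_calls(call_rows, groups=None, populations=None):
    """Build a GenotypeMatrix directly from MUT/WT/NA call strings."""
    cells = sorted(call_rows)
    sites = sorted({s for row in call_rows.values() for s in row})
    groups = groups or {}
    populations = populations or {}
    reads = []
    for c in cells:
        for s in sites:
            v = call_rows[c].get(s, "WT")
            if v == "NA":
                ref, alt = 0, 0
            elif v == "MUT":
                ref, alt = 50, 50
            else:
                ref, alt = 100, 0
            reads.append({"cell_id": c, "site_id": s, "ref_reads": ref, "alt_reads": alt})
    cells_df = pd.DataFrame(
        {
            "cell_id": cells,
            "donor_id": [c.split("_")[0] for c in cells],
            "group": [groups.get(c, "MDS") for c in cells],
            "population": [populations.get(c, "n") for c in cells],
        }
    )
    sites_df = pd.DataFrame({"site_id": sites, "gene": sites, "variant": sites})
    return cs.build_genotype_matrix(pd.DataFrame(reads), cells_df, sites_df)


class TestClassifyMutations:
    def test_detection_dichotomy(self):
        gm = _gm_from_calls(
            {
                "d1_a": {"s1": "MUT", "s2": "WT"},
                "d2_a": {"s1": "MUT", "s2": "MUT"},
                "d2_b": {"s3": "WT"},
            },
            groups={"d1_a": "HD", "d2_a": "MDS", "d2_b": "MDS"},
        )
        classes = cs.classify_mutations(gm)
        assert classes.loc["s1", "mut_class"] == "CH"  # detected in both groups
        assert classes.loc["s2", "mut_class"] == "MDS"  # MDS-group only
        assert "s3" not in classes.index  # never MUT-called -> omitted
        assert not classes.loc["s1", "hd_only"]

    def test_hd_only_detection_is_ch_and_flagged(self):
        gm = _gm_from_calls({"d1_a": {"s1": "MUT"}}, groups={"d1_a": "HD"})
        classes = cs.classify_mutations(gm)
        assert classes.loc["s1", "mut_class"] == "CH"
        assert bool(classes.loc["s1", "hd_only"])

    def test_zero_mut_cohort_empty_classification(self):
        gm = _gm_from_calls({"d1_a": {"s1": "WT"}})
        assert len(cs.classify_mutations(gm)) == 0


class TestReconstructClones:
    def test_partition_and_exclusions(self):
        gm = _gm_from_calls(
            {
                "d1_a": {"s1": "MUT", "s2": "WT"},
                "d1_b": {"s1": "MUT", "s2": "WT"},
                "d1_c": {"s1": "MUT", "s2": "MUT"},
                "d1_d": {"s1": "WT", "s2": "WT"},  # WT clone
                "d1_e": {"s1": "NA", "s2": "MUT"},  # NA at a detected site
                "d1_f": {"s1": "WT", "s2": "WT", "s3": "NA"},  # NA only at undetected site
            }
        )
        clones, excl_wt, excl_na = cs.reconstruct_clones(gm, "d1")
        sigs = {c.signature: c for c in clones}
        assert set(sigs) == {frozenset({"s1"}), frozenset({"s1", "s2"})}
        assert sigs[frozenset({"s1"})].size == 2
        assert excl_wt == 2  # d1_d and d1_f (NA at s3 is ignored: s3 undetected)
        assert excl_na == 1
        assert sum(c.size for c in clones) + excl_wt + excl_na == 6

    def test_all_wt_donor(self):
        gm = _gm_from_calls({"d1_a": {"s1": "WT"}, "d1_b": {"s1": "WT"}})
        clones, excl_wt, excl_na = cs.reconstruct_clones(gm, "d1")
        assert clones == [] and excl_wt == 2 and excl_na == 0

    @given(
        st.lists(
            st.tuples(st.integers(0, 7), st.sampled_from(list(cs.POPULATIONS))),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_partition_property_random_genotypes(self, cells):
        """Sizes + WT-excluded + NA-excluded always sum to the qualified
        count, signatures are unique and nonempty, and the clone count obeys
        the 2^m - 1 bound for m detected mutations."""
        rows = {}
        for i, (mask, pop) in enumerate(cells):
            rows[f"d1_c{i:02d}"] = {f"s{j}": ("MUT" if mask >> j & 1 else "WT") for j in range(3)}
        pops = {f"d1_c{i:02d}": pop for i, (_, pop) in enumerate(cells)}
        gm = _gm_from_calls(rows, populations=pops)
        clones, excl_wt, excl_na = cs.reconstruct_clones(gm, "d1")
        n_q = len(gm.qualified_index("d1"))
        assert sum(c.size for c in clones) + excl_wt + excl_na == n_q
        sigs = [c.signature for c in clones]
        assert len(set(sigs)) == len(sigs)
        assert all(s for s in sigs)
        m = len(cs.detected_sites(gm, gm.qualified_index("d1")))
        assert len(clones) <= 2**m - 1 if m else len(clones) == 0


class TestClassifyClone:
    def _classes(self):
        return pd.DataFrame(
            {"mut_class": {"ch1": "CH", "ch2": "CH", "mds1": "MDS"}}
        ).rename_axis("site_id")

    def _clone(self, sig):
        return Clone("d1:x", "d1", frozenset(sig), ("c1",), frozenset({"n"}))

    def test_rules(self):
        classes = self._classes()
        assert cs.classify_clone(self._clone({"ch1"}), classes) == ("CH", False)
        assert cs.classify_clone(self._clone({"ch1", "ch2"}), classes) == ("CH", False)
        assert cs.classify_clone(self._clone({"mds1"}), classes) == ("MDS", False)
        # MDS wins regardless of coexisting CH mutations; flagged double-mutant
        assert cs.classify_clone(self._clone({"ch1", "mds1"}), classes) == ("MDS", True)

    def test_unclassified_site_is_inconsistent(self):
        with pytest.raises(cs.ConsistencyError, match="unknown_site"):
            cs.classify_clone(self._clone({"unknown_site"}), self._classes())


class TestClassifyOrigin:
    def test_examples(self):
        assert cs.classify_origin({"n", "m", "E", "M", "B", "T"}) == "HSC"
        assert cs.classify_origin({"H", "n", "m", "E", "M", "B", "T"}) == "HSC"
        assert cs.classify_origin({"n", "m", "E", "M", "B"}) == "HPC"
        assert cs.classify_origin({"H"}) == "HPC"  # H alone says nothing about lineages

    def test_exhaustive_subset_oracle(self):
        """All 127 nonempty population subsets agree with brute-force
        containment of the six-lineage set."""
        pops = list(cs.POPULATIONS)
        subsets = list(
            chain.from_iterable(combinations(pops, k) for k in range(1, 8))
        )
        assert len(subsets) == 127
        for sub in subsets:
            assert cs.classify_origin(set(sub)) == brute_force_origin(sub)

    def test_empty_population_set_is_inconsistent(self):
        with pytest.raises(cs.ConsistencyError):
            cs.classify_origin(frozenset())


class TestFamiliesAndBreakdown:
    def test_shared_family_across_donors(self):
        gm = _gm_from_calls(
            {"d1_a": {"s1": "MUT"}, "d2_a": {"s1": "MUT"}, "d2_b": {"s2": "MUT"}}
        )
        clones, _, _ = cs.reconstruct_cohort(gm)
        fams = {f.family_id: f for f in cs.match_clone_families(clones)}
        shared = [f for f in fams.values() if f.shared]
        assert len(shared) == 1
        assert set(shared[0].donor_ids) == {"d1", "d2"}
        solo = [f for f in fams.values() if not f.shared]
        assert len(solo) == 1

    def test_all_unique_signatures(self):
        gm = _gm_from_calls({"d1_a": {"s1": "MUT"}, "d2_a": {"s2": "MUT"}})
        clones, _, _ = cs.reconstruct_cohort(gm)
        fams = cs.match_clone_families(clones)
        assert len(fams) == len(clones)
        assert not any(f.shared for f in fams)

    def test_planted_shared_clone_in_three_donors(self):
        """One CH mutation planted in one HD and two MDS donors yields one
        shared three-donor family."""
        panel = (cs.SiteTemplate("DNMT3A", "p.R882H", "CH"),)
        cfg = cs.noiseless_config(
            n_donors_hd=1,
            n_donors_mds=2,
            sites=panel,
            clones_per_donor=(1, 1),
            hd_clones_per_donor=(1, 1),
            cells_per_population=(4, 6),
            seed=17,
        )
        b = cs.simulate_cohort(cfg)
        gm = cs.build_genotype_matrix(b.read_counts, b.cells, b.sites)
        clones, _, _ = cs.reconstruct_cohort(gm)
        fams = cs.match_clone_families(clones)
        assert len(fams) == 1 and fams[0].shared
        assert len(fams[0].clone_ids) == 3

    def test_origin_breakdown_fractions(self):
        def clone(cid, cls, origin):
            c = Clone(cid, "d1", frozenset({cid}), ("x",), frozenset({"n"}))
            c.clone_class, c.origin = cls, origin
            return c

        clones = [clone("a", "CH", "HSC"), clone("b", "CH", "HPC"), clone("c", "MDS", "HPC")]
        bd = cs.origin_breakdown(clones)
        assert bd.loc["CH", "fraction_hsc"] == pytest.approx(0.5)
        assert bd.loc["MDS", "fraction_hsc"] == 0.0
        empty = cs.origin_breakdown([])
        assert (empty["n_total"] == 0).all()
        assert empty["fraction_hsc"].isna().all()


def test_noiseless_recovery_matches_truth(noiseless_bundle):
    """Partition, mutation classes and origin calls all equal ground truth on
    a noiseless cohort, with zero exclusions."""
    rep = recovery_report(noiseless_bundle)
    assert rep["partition_equal"]
    assert rep["classes_equal"]
    assert rep["origins_equal"]
    assert (rep["exclusions"][["excluded_na"]] == 0).all().all()


def test_noisy_cohort_never_coclusters_conflicting_genotypes(noisy_bundle):
    """Under dropout, recovered clones may split or merge relative to truth,
    but cells in one clone never disagree at a definite (non-NA) call."""
    gm = cs.build_genotype_matrix(noisy_bundle.read_counts, noisy_bundle.cells, noisy_bundle.sites)
    clones, _, _ = cs.reconstruct_cohort(gm)
    assert clones
    for c in clones:
        sub = gm.calls.loc[list(c.member_cells)]
        for site in sub.columns:
            vals = set(sub[site]) - {"NA"}
            assert len(vals) <= 1, f"conflicting calls in {c.clone_id} at {site}"
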