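"""Clone reconstruction, CH/MDS classification and HSC/HPC origin inference.

Clones are defined as cells with identical combinations of called mutations,
evaluated per donor over the donor's *detected* sites (sites MUT-called in at
least one of that donor's qualified cells).  Cells with an NA call at any
donor-detected site have an uncertain combination and are excluded; cells
wild type at every detected site form the WT clone, which is excluded from
clonal analyses.

Mutation classes follow the cohort-level detection dichotomy: a site
MUT-called in at least one healthy-donor (HD-group) cell is a CH
(clonal-hematopoiesis) mutation; a site MUT-called only in MDS-group cells
is an MDS mutation.  A clone carrying any MDS mutation is an MDS clone
regardless of coexisting CH mutations; a clone carrying both classes is
additionally flagged as a double-mutant clone.

Origin is inferred from lineage spread: a clone observed in all six mature
lineage populations {n, m, E, M, B, T} — membership in the CD34+ ``H``
population is ignored — must derive from a multipotent HSC; any narrower
spread is called HPC-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConsistencyError
from .genotype import CALL_MUT, CALL_NA, GenotypeMatrix, detected_sites
from .simulate import LINEAGES, POPULATIONS

CLASS_CH = "CH"
CLASS_MDS = "MDS"
ORIGIN_HSC = "HSC"
ORIGIN_HPC = "HPC"


@dataclass
class Clone:
    clone_id: str
    donor_id: str
    signature: frozenset[str]
    member_cells: tuple[str, ...]
    populations: frozenset[str]
    clone_class: str | None = None
    double_mutant: bool | None = None
    origin: str | None = None
    family_id: str | None = None
    shared: bool | None = None

    @property
    def size(self) -> int:
        return len(self.member_cells)


@dataclass
class CloneFamily:
    """Clones with the same signature matched across donors."""

    family_id: str
    signature: frozenset[str]
    clone_ids: tuple[str, ...]
    donor_ids: tuple[str, ...]
    shared: bool = field(default=False)


def classify_mutations(gm: GenotypeMatrix) -> pd.DataFrame:
    """Classify every detected site as CH or MDS from qualified cells.

    Returns a DataFrame indexed by site_id with columns ``mut_class``,
    ``hd_only`` (detected in HD cells but never in MDS cells — classed CH by
    the detection rule, flagged for transparency), ``n_mut_hd`` and
    ``n_mut_mds``.  Sites never MUT-called are omitted.
    """
    idx = gm.qualified_index()
    mut = gm.calls.loc[idx] == CALL_MUT
    group = gm.cells.loc[idx, "group"]
    n_hd = mut[group == "HD"].sum(axis=0)
    n_mds = mut[group == "MDS"].sum(axis=0)
    rows = []
    for site in gm.site_ids:
        h, m = int(n_hd.get(site, 0)), int(n_mds.get(site, 0))
        if h + m == 0:
            continue
        rows.append(
            {
                "site_id": site,
                "mut_class": CLASS_CH if h > 0 else CLASS_MDS,
                "hd_only": h > 0 and m == 0,
                "n_mut_hd": h,
                "n_mut_mds": m,
            }
        )
    return pd.DataFrame(rows, columns=["site_id", "mut_class", "hd_only", "n_mut_hd", "n_mut_mds"]).set_index(
        "site_id"
    )


def reconstruct_clones(gm: GenotypeMatrix, donor_id: str) -> tuple[list[Clone], int, int]:
    """Partition one donor's qualified cells into clones.

    Returns ``(clones, excluded_wt, excluded_na)``.  The partition property
    holds by construction: the clone sizes plus the two exclusion counts sum
    to the donor's qualified-cell count.
    """
    idx = gm.qualified_index(donor_id)
    if len(idx) == 0:
        return [], 0, 0
    donor_detected = detected_sites(gm, idx)
    if not donor_detected:
        return [], len(idx), 0
    sub = gm.calls.loc[idx, donor_detected]
    na_mask = (sub == CALL_NA).any(axis=1)
    excluded_na = int(na_mask.sum())
    kept = sub.loc[~na_mask]
    mut = kept == CALL_MUT
    signatures: dict[frozenset[str], list[str]] = {}
    excluded_wt = 0
    for cell_id, row in zip(kept.index, mut.to_numpy()):
        sig = frozenset(s for s, m in zip(donor_detected, row) if m)
        if not sig:
            excluded_wt += 1
            continue
        signatures.setdefault(sig, []).append(cell_id)
    pops = gm.cells["population"]
    clones = []
    for sig in sorted(signatures, key=lambda s: tuple(sorted(s))):
        members = tuple(signatures[sig])
        clones.append(
            Clone(
                clone_id=f"{donor_id}:{'+'.join(sorted(sig))}",
                donor_id=donor_id,
                signature=sig,
                member_cells=members,
                populations=frozenset(pops.loc[list(members)]),
            )
        )
    return clones, excluded_wt, excluded_na


def classify_clone(clone: Clone, classes: pd.DataFrame) -> tuple[str, bool]:
    """(clone_class, double_mutant) for one clone.

    A signature containing any MDS-class site makes an MDS clone regardless
    of coexisting CH mutations; a pure-CH signature makes a CH clone; the
    double-mutant flag marks signatures carrying both classes.
    """
    missing = [s for s in clone.signature if s not in classes.index]
    if missing:
        raise ConsistencyError(
            f"clone {clone.clone_id}: unclassified signature sites {sorted(missing)}"
        )
    site_classes = {classes.loc[s, "mut_class"] for s in clone.signature}
    has_mds = CLASS_MDS in site_classes
    has_ch = CLASS_CH in site_classes
    return (CLASS_MDS if has_mds else CLASS_CH), (has_mds and has_ch)


def classify_origin(clone_or_populations) -> str:
    """HSC iff the clone is observed in all six mature lineages.

    Accepts a :class:`Clone` or a population set.  Membership in ``H`` is
    ignored; an empty population set is inconsistent.
    """
    pops = (
        clone_or_populations.populations
        if isinstance(clone_or_populations, Clone)
        else frozenset(clone_or_populations)
    )
    if not pops:
        raise ConsistencyError("clone with empty population set")
    unknown = pops - set(POPULATIONS)
    if unknown:
        raise ConsistencyError(f"unknown population labels {sorted(unknown)}")
    return ORIGIN_HSC if LINEAGES <= pops else ORIGIN_HPC


def annotate_clones(clones: list[Clone], classes: pd.DataFrame) -> list[Clone]:
    """Fill clone_class, double_mutant and origin in place; returns the list."""
    for c in clones:
        c.clone_class, c.double_mutant = classify_clone(c, classes)
        c.origin = classify_origin(c)
    return clones


def match_clone_families(clones: list[Clone]) -> list[CloneFamily]:
    """Group clones by exact signature across donors.

    A family is *shared* when its signature occurs in two or more distinct
    donors.  Family ids are assigned deterministically in signature order and
    stamped onto the clones.
    """
    by_sig: dict[frozenset[str], list[Clone]] = {}
    for c in clones:
        by_sig.setdefault(c.signature, []).append(c)
    families = []
    for k, sig in enumerate(sorted(by_sig, key=lambda s: tuple(sorted(s)))):
        members = by_sig[sig]
        donors = tuple(dict.fromkeys(c.donor_id for c in members))
        fam = CloneFamily(
            family_id=f"F{k + 1:03d}",
            signature=sig,
            clone_ids=tuple(c.clone_id for c in members),
            donor_ids=donors,
            shared=len(donors) >= 2,
        )
        for c in members:
            c.family_id = fam.family_id
            c.shared = fam.shared
        families.append(fam)
    return families


def origin_breakdown(clones: list[Clone]) -> pd.DataFrame:
    """Per clone-class counts of HSC- vs HPC-derived clones.

    Returns a DataFrame indexed by clone_class with n_hsc, n_hpc, n_total
    and fraction_hsc (NaN when the class has no clones).
    """
    rows = []
    for cls in (CLASS_CH, CLASS_MDS):
        sub = [c for c in clones if c.clone_class == cls]
        n_hsc = sum(1 for c in sub if c.origin == ORIGIN_HSC)
        n_hpc = sum(1 for c in sub if c.origin == ORIGIN_HPC)
        n = n_hsc + n_hpc
        rows.append(
            {
                "clone_class": cls,
                "n_hsc": n_hsc,
                "n_hpc": n_hpc,
                "n_total": n,
                "fraction_hsc": (n_hsc / n) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("clone_class")


def reconstruct_cohort(gm: GenotypeMatrix) -> tuple[list[Clone], pd.DataFrame, pd.DataFrame]:
    """Full clonal reconstruction over every donor.

    Returns ``(clones, classes, exclusions)`` where ``exclusions`` is a
    per-donor DataFrame of qualified / clone-assigned / WT-excluded /
    NA-excluded cell counts.  Clones are annotated with class, origin and
    family membership.
    """
    classes = classify_mutations(gm)
    all_clones: list[Clone] = []
    rows = []
    for donor_id in gm.donor_ids:
        clones, excl_wt, excl_na = reconstruct_clones(gm, donor_id)
        annotate_clones(clones, classes)
        all_clones.extend(clones)
        rows.append(
            {
                "donor_id": donor_id,
                "n_qualified": len(gm.qualified_index(donor_id)),
                "n_assigned": sum(c.size for c in clones),
                "excluded_wt": excl_wt,
                "excluded_na": excl_na,
            }
        )
    match_clone_families(all_clones)
    exclusions = pd.DataFrame(
        rows, columns=["donor_id", "n_qualified", "n_assigned", "excluded_wt", "excluded_na"]
    ).set_index("donor_id")
    bad = exclusions[
        exclusions["n_qualified"]
        != exclusions["n_assigned"] + exclusions["excluded_wt"] + exclusions["excluded_na"]
    ]
    if len(bad):
        raise ConsistencyError(f"partition property violated for donors {list(bad.index)}")
    return all_clones, classes, exclusions


def clone_table(clones: list[Clone]) -> pd.DataFrame:
    """Flatten clones to the tabular exchange format used by the statistics
    stage and the clones.tsv output."""
    if not clones:
        return pd.DataFrame(
            columns=[
                "clone_id",
                "donor_id",
                "signature",
                "size",
                "size_fraction",
                "populations",
                "n_populations",
                "clone_class",
                "double_mutant",
                "origin",
                "family_id",
                "shared",
            ]
        )
    per_donor_total: dict[str, int] = {}
    for c in clones:
        per_donor_total[c.donor_id] = per_donor_total.get(c.donor_id, 0) + c.size
    rows = []
    for c in clones:
        rows.append(
            {
                "clone_id": c.clone_id,
                "donor_id": c.donor_id,
                "signature": ";".join(sorted(c.signature)),
                "size": c.size,
                "size_fraction": c.size / per_donor_total[c.donor_id],
                "populations": "".join(p for p in POPULATIONS if p in c.populations),
                "n_populations": len(c.populations),
                "clone_class": c.clone_class,
                "double_mutant": c.double_mutant,
                "origin": c.origin,
                "family_id": c.family_id,
                "shared": c.shared,
            }
        )
    return pd.DataFrame(rows)
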