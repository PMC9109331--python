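"""Synthetic single-cell amplicon cohorts with known clonal structure.

The study design being emulated: bone-marrow cells from healthy donors (HD
group) and MDS patients are index-sorted into seven populations — CD34+ HPCs
(``H``) and six mature lineages: neutrophils (``n``), monocytes (``m``),
erythroblasts (``E``), megakaryocytes (``M``), B cells (``B``) and T cells
(``T``) — and genotyped by targeted amplicon sequencing over a small panel of
recurrently mutated myeloid genes (*U2AF1*, *SF3B1*, *TET2*, *ASXL1*, *TP53*,
*DNMT3A*).  Because the original per-patient tables are not public, this
module generates read-count tables of the same shape with a fully known
ground truth, so that every downstream stage (genotype calling, clone
reconstruction, classification, origin inference, statistics) can be tested
against the truth rather than against itself.

The generative model, per donor:

1.  A nested clonal hierarchy is drawn.  The root is the wild-type (WT)
    clone; each non-root clone adds exactly one new mutation to its parent's
    signature, so every child signature strictly contains its parent's.
    Clonal-hematopoiesis (CH) mutations are acquired before MDS mutations on
    any line of descent, reflecting their earlier acquisition.
2.  Each non-WT clone is assigned a true cell of origin.  An HSC-derived
    clone emits cells into all six mature lineages; an HPC-derived clone
    emits into a random proper subset of them (size 1–5).  Emission into the
    ``H`` population is drawn independently of origin, because the origin
    rule downstream deliberately ignores ``H``.
3.  Cells are sampled per population.  Every clone is guaranteed at least
    one cell in each population it emits in (so the realized population set
    equals the emission set and the true origin is recoverable from a
    noiseless table); the remaining cells are split between the WT clone
    (``wt_fraction``) and the non-WT clones by per-clone weights, with
    CH-only clones upweighted by ``ch_size_advantage`` to reproduce the
    larger observed size of CH clones.
4.  Read counts are drawn per (cell, site): coverage is negative binomial
    (``mean_coverage``, ``coverage_dispersion``); at a mutant, non-dropped
    site the variant reads are binomial with success probability
    ``expressed_vaf`` (jittered per cell-site); allelic dropout silences the
    variant allele entirely; wild-type or dropped sites emit variant reads
    only through rare false-positive events.

CH-class sites are planted in at least one HD donor *and* one MDS donor
(when both groups exist), and MDS-class sites only in MDS donors, so the
downstream detection-based classification can recover the intended classes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

POPULATIONS: tuple[str, ...] = ("H", "n", "m", "E", "M", "B", "T")
#: The six mature lineages used by the HSC/HPC origin rule (H excluded).
LINEAGES: frozenset[str] = frozenset({"n", "m", "E", "M", "B", "T"})
LINEAGE_ORDER: tuple[str, ...] = ("n", "m", "E", "M", "B", "T")


@dataclass(frozen=True)
class SiteTemplate:
    """A mutation site on the panel: gene, protein-level variant label and the
    class it is intended to represent (CH or MDS)."""

    gene: str
    variant: str
    intended_class: str  # "CH" | "MDS"

    @property
    def site_id(self) -> str:
        return f"{self.gene}:{self.variant}"


def default_site_panel() -> list[SiteTemplate]:
    """The default 18-variant panel: 3 CH-class and 15 MDS-class variants
    spread over the six recurrently mutated genes.

    Variant labels are synthetic but drawn from hotspots typical of each
    gene (e.g. *DNMT3A* R882, *SF3B1* K700E, *U2AF1* S34F).
    """
    ch = [
        SiteTemplate("DNMT3A", "p.R882H", "CH"),
        SiteTemplate("TET2", "p.Q810*", "CH"),
        SiteTemplate("ASXL1", "p.G646fs", "CH"),
    ]
    mds = [
        SiteTemplate("U2AF1", "p.S34F", "MDS"),
        SiteTemplate("U2AF1", "p.Q157P", "MDS"),
        SiteTemplate("SF3B1", "p.K700E", "MDS"),
        SiteTemplate("SF3B1", "p.H662Q", "MDS"),
        SiteTemplate("SF3B1", "p.R625C", "MDS"),
        SiteTemplate("TET2", "p.C1135Y", "MDS"),
        SiteTemplate("TET2", "p.R1516*", "MDS"),
        SiteTemplate("TET2", "p.S792*", "MDS"),
        SiteTemplate("ASXL1", "p.R693*", "MDS"),
        SiteTemplate("ASXL1", "p.E635fs", "MDS"),
        SiteTemplate("TP53", "p.R175H", "MDS"),
        SiteTemplate("TP53", "p.R273H", "MDS"),
        SiteTemplate("TP53", "p.Y220C", "MDS"),
        SiteTemplate("DNMT3A", "p.W860R", "MDS"),
        SiteTemplate("DNMT3A", "p.R736H", "MDS"),
    ]
    return ch + mds


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study's shape: 7 donors in the HD group (five
    healthy donors plus two AML patients in remission), 14 MDS patients,
    an 18-variant panel over 6 genes, 7 sorted populations with 18–26
    cells each, a long-tailed per-site coverage distribution against a
    10-read qualification threshold, heterozygous expressed VAF near 0.5
    with broad single-cell spread, and appreciable allelic dropout.

    Parameters
    ----------
    n_donors_hd, n_donors_mds
        Donors per group.  HD donors carry only CH mutations.
    sites
        Panel of :class:`SiteTemplate`.  Sites with ``intended_class="MDS"``
        are planted only in MDS donors; CH sites in both groups.
    clones_per_donor
        Inclusive range of non-WT clones per MDS donor.  The realized count
        is clipped into ``[s, 2**s - 1]`` for ``s`` distinct donor sites.
    hd_clones_per_donor
        Same, for HD donors (smaller by default; some HD donors carry no
        clone at all, as seen in real healthy marrow).
    cells_per_population
        Inclusive range of cells sorted per population per donor.
    mean_coverage, coverage_dispersion
        Negative-binomial coverage per (cell, site): mean ``m`` and size
        ``r`` (variance ``m + m**2/r``; small ``r`` = long tail).
    allelic_dropout_rate
        Probability that a mutant (cell, site) loses all variant-allele
        expression and reads like wild type.
    false_positive_rate
        Probability that a wild-type (or dropped) (cell, site) emits
        variant reads; the spurious variant fraction is Uniform(0.05, 0.5).
    expressed_vaf, vaf_jitter
        Expected variant-read fraction at an expressed mutant site, with
        Gaussian per-(cell, site) jitter (clipped to [0.05, 0.95]).
    wt_fraction
        Expected fraction of non-guaranteed cells drawn from the WT clone.
    hsc_origin_rate_ch, hsc_origin_rate_mds
        Probability that a CH-only / MDS clone is truly HSC-derived
        (defaults 0.27 and 0.10, the fractions observed in the study).
    ch_size_advantage
        Multiplier on the sampling weight of CH-only clones.
    seed
        Seed for all randomness; identical configs give identical tables.
    """

    n_donors_hd: int = 7
    n_donors_mds: int = 14
    sites: tuple[SiteTemplate, ...] = field(
        default_factory=lambda: tuple(default_site_panel())
    )
    clones_per_donor: tuple[int, int] = (2, 8)
    hd_clones_per_donor: tuple[int, int] = (0, 2)
    cells_per_population: tuple[int, int] = (18, 26)
    mean_coverage: float = 100.0
    coverage_dispersion: float = 2.0
    allelic_dropout_rate: float = 0.2
    false_positive_rate: float = 0.001
    expressed_vaf: float = 0.5
    vaf_jitter: float = 0.08
    wt_fraction: float = 0.4
    hsc_origin_rate_ch: float = 0.27
    hsc_origin_rate_mds: float = 0.10
    ch_size_advantage: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first invalid field."""
        for name in ("n_donors_hd", "n_donors_mds"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a nonnegative integer, got {v!r}")
        if not self.sites:
            raise ConfigurationError("sites must be a nonempty list of SiteTemplate")
        for s in self.sites:
            if s.intended_class not in ("CH", "MDS"):
                raise ConfigurationError(
                    f"sites: intended_class must be CH or MDS, got {s.intended_class!r}"
                )
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("sites: duplicate site ids in panel")
        for name in ("clones_per_donor", "hd_clones_per_donor", "cells_per_population"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"{name} must be a range 0 <= lo <= hi, got {(lo, hi)!r}")
        for name in ("mean_coverage", "coverage_dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in (
            "allelic_dropout_rate",
            "false_positive_rate",
            "expressed_vaf",
            "wt_fraction",
            "hsc_origin_rate_ch",
            "hsc_origin_rate_mds",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0, 1], got {v!r}")
        if self.vaf_jitter < 0:
            raise ConfigurationError(f"vaf_jitter must be >= 0, got {self.vaf_jitter!r}")
        if self.ch_size_advantage <= 0:
            raise ConfigurationError(
                f"ch_size_advantage must be > 0, got {self.ch_size_advantage!r}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sites"] = [dataclasses.asdict(s) for s in self.sites]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "sites" in d:
            d["sites"] = tuple(SiteTemplate(**s) for s in d["sites"])
        for name in ("clones_per_donor", "hd_clones_per_donor", "cells_per_population"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)


def noiseless_config(**overrides) -> SimConfig:
    """A config with all noise sources off and reliable deep coverage.

    Dropout, false positives and VAF jitter are zero and the coverage
    distribution is tight around 100x, so genotype calls reproduce the
    truth matrix exactly and no cell is lost to low coverage.
    """
    base = dict(
        allelic_dropout_rate=0.0,
        false_positive_rate=0.0,
        vaf_jitter=0.0,
        mean_coverage=100.0,
        coverage_dispersion=100.0,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class TrueClone:
    """Ground-truth clone: its mutation signature, parent, origin and the
    populations it emits cells into."""

    clone_id: str
    donor_id: str
    signature: frozenset[str]
    parent_id: str | None
    origin: str  # "HSC" | "HPC"
    lineages: frozenset[str]  # subset of the six mature lineages
    h_emission: bool

    @property
    def emits_in(self) -> frozenset[str]:
        return self.lineages | ({"H"} if self.h_emission else frozenset())


@dataclass
class CohortTruth:
    """Simulator ground truth: config, donors, clonal hierarchies and the
    true clone of every cell (WT cells map to ``<donor>:WT``)."""

    config: SimConfig
    donors: pd.DataFrame  # donor_id, group, blast_pct
    clones: list[TrueClone]
    cell_clone: dict[str, str]

    def clones_of(self, donor_id: str) -> list[TrueClone]:
        return [c for c in self.clones if c.donor_id == donor_id]

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "seed": self.config.seed,
            "donors": self.donors.to_dict(orient="records"),
            "clones": [
                {
                    "clone_id": c.clone_id,
                    "donor_id": c.donor_id,
                    "signature": sorted(c.signature),
                    "parent_id": c.parent_id,
                    "origin": c.origin,
                    "lineages": sorted(c.lineages),
                    "h_emission": c.h_emission,
                }
                for c in self.clones
            ],
            "cell_clone": self.cell_clone,
        }


@dataclass
class CohortBundle:
    """One simulated cohort: the three input tables plus the ground truth."""

    read_counts: pd.DataFrame  # cell_id, site_id, ref_reads, alt_reads
    cells: pd.DataFrame  # cell_id, donor_id, group, population
    sites: pd.DataFrame  # site_id, gene, variant, true_class
    truth: CohortTruth


def _has_mds(signature: frozenset[str], site_class: dict[str, str]) -> bool:
    return any(site_class[s] == "MDS" for s in signature)


def _donor_site_sets(
    rng: np.random.Generator, config: SimConfig, donors: pd.DataFrame, n_clones: dict[str, int]
) -> dict[str, list[str]]:
    """Choose which panel sites each donor's clones will use.

    MDS donors draw a mix of CH and MDS sites; HD donors draw CH sites only.
    A fix-up pass then guarantees every used CH site occurs in at least one
    donor of each group (when both groups exist), so the detection-based
    classifier downstream recovers the intended class of every planted site.
    """
    ch_sites = [s.site_id for s in config.sites if s.intended_class == "CH"]
    mds_sites = [s.site_id for s in config.sites if s.intended_class == "MDS"]
    hd_ids = list(donors.loc[donors["group"] == "HD", "donor_id"])
    mds_ids = list(donors.loc[donors["group"] == "MDS", "donor_id"])
    ch_prob = 0.4 if (hd_ids and ch_sites) else 0.0

    chosen: dict[str, list[str]] = {}
    for donor_id in donors["donor_id"]:
        n = n_clones[donor_id]
        if n == 0:
            chosen[donor_id] = []
            continue
        if donor_id in hd_ids:
            if not ch_sites:
                chosen[donor_id] = []
                continue
            s = min(n, 1 + int(rng.integers(0, 2)), len(ch_sites))
            idx = rng.choice(len(ch_sites), size=s, replace=False)
            chosen[donor_id] = [ch_sites[i] for i in sorted(idx)]
        else:
            s = 1 + int(rng.integers(0, min(n, 4)))
            k_ch = int(rng.binomial(s, ch_prob))
            k_ch = min(k_ch, len(ch_sites))
            k_mds = min(s - k_ch, len(mds_sites))
            if k_ch + k_mds == 0:
                # requested sites but the draw landed on an empty pool
                if mds_sites:
                    k_mds = min(s, len(mds_sites))
                elif ch_prob > 0:
                    k_ch = min(s, len(ch_sites))
            picked: list[str] = []
            if k_ch:
                idx = rng.choice(len(ch_sites), size=k_ch, replace=False)
                picked += [ch_sites[i] for i in sorted(idx)]
            if k_mds:
                idx = rng.choice(len(mds_sites), size=k_mds, replace=False)
                picked += [mds_sites[i] for i in sorted(idx)]
            chosen[donor_id] = picked

    # Cross-group guarantee for CH sites actually in use.
    used_ch = [s for s in ch_sites if any(s in chosen[d] for d in chosen)]
    for s in used_ch:
        in_hd = any(s in chosen[d] for d in hd_ids)
        in_mds = any(s in chosen[d] for d in mds_ids)
        if not in_hd and hd_ids:
            d = hd_ids[int(rng.integers(0, len(hd_ids)))]
            chosen[d].append(s)
        if not in_mds and mds_ids:
            d = mds_ids[int(rng.integers(0, len(mds_ids)))]
            chosen[d].append(s)
    return chosen


def _build_hierarchy(
    rng: np.random.Generator,
    donor_id: str,
    donor_sites: list[str],
    site_class: dict[str, str],
    n_clones: int,
) -> list[tuple[frozenset[str], int | None]]:
    """Grow the donor's nested clone hierarchy.

    Returns (signature, parent-index) pairs, parent index into the same list
    with ``None`` meaning the WT root.  Each clone adds one new site to its
    parent; a CH site is never added below an MDS-bearing clone, so CH
    mutations precede MDS mutations on every descent path.
    """
    if not donor_sites:
        return []
    ordered = sorted([s for s in donor_sites if site_class[s] == "CH"]) + sorted(
        [s for s in donor_sites if site_class[s] == "MDS"]
    )
    s = len(ordered)
    n_clones = int(np.clip(n_clones, s, 2**s - 1))

    nodes: list[frozenset[str]] = [frozenset()]  # index 0 = WT root
    parents: list[int | None] = [None]
    seen = {frozenset()}
    # First pass: introduce every donor site once.
    for site in ordered:
        if site_class[site] == "CH":
            cands = [i for i, sig in enumerate(nodes) if not _has_mds(sig, site_class)]
        else:
            cands = list(range(len(nodes)))
        pi = int(cands[rng.integers(0, len(cands))])
        sig = nodes[pi] | {site}
        nodes.append(sig)
        parents.append(pi)
        seen.add(sig)
    # Second pass: extra clones recombining existing sites.
    attempts = 0
    while len(nodes) - 1 < n_clones and attempts < 60 * n_clones:
        attempts += 1
        pi = int(rng.integers(0, len(nodes)))
        psig = nodes[pi]
        if _has_mds(psig, site_class):
            pool = [x for x in ordered if x not in psig and site_class[x] == "MDS"]
        else:
            pool = [x for x in ordered if x not in psig]
        if not pool:
            continue
        site = pool[int(rng.integers(0, len(pool)))]
        sig = psig | {site}
        if sig in seen:
            continue
        nodes.append(sig)
        parents.append(pi)
        seen.add(sig)
    out = []
    for i in range(1, len(nodes)):
        out.append((nodes[i], parents[i] if parents[i] != 0 else None))
    # parent index returned relative to this output list (None = WT root)
    return [(sig, (p - 1) if p is not None else None) for sig, p in out]


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Generate one cohort: read counts, cell and site metadata, and truth.

    Deterministic given ``config`` (including its seed): the same config
    yields byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    site_class = {s.site_id: s.intended_class for s in config.sites}
    site_ids = [s.site_id for s in config.sites]

    donor_rows = []
    for i in range(config.n_donors_hd):
        donor_rows.append({"donor_id": f"HD{i + 1}", "group": "HD", "blast_pct": float("nan")})
    for i in range(config.n_donors_mds):
        donor_rows.append(
            {"donor_id": f"PT{i + 1}", "group": "MDS", "blast_pct": round(float(rng.uniform(1, 20)), 1)}
        )
    donors = pd.DataFrame(donor_rows, columns=["donor_id", "group", "blast_pct"])

    lo, hi = config.clones_per_donor
    hlo, hhi = config.hd_clones_per_donor
    n_clones = {}
    for row in donor_rows:
        if row["group"] == "HD":
            n_clones[row["donor_id"]] = int(rng.integers(hlo, hhi + 1))
        else:
            n_clones[row["donor_id"]] = int(rng.integers(lo, hi + 1))

    chosen = _donor_site_sets(rng, config, donors, n_clones)

    clones: list[TrueClone] = []
    clone_index: dict[str, TrueClone] = {}
    for donor_id in donors["donor_id"]:
        n_req = max(n_clones[donor_id], len(chosen[donor_id]))
        hierarchy = _build_hierarchy(rng, donor_id, chosen[donor_id], site_class, n_req)
        donor_clones: list[TrueClone] = []
        for sig, parent_idx in hierarchy:
            clone_id = f"{donor_id}:{'+'.join(sorted(sig))}"
            is_ch_only = not _has_mds(sig, site_class)
            p_hsc = config.hsc_origin_rate_ch if is_ch_only else config.hsc_origin_rate_mds
            if rng.random() < p_hsc:
                origin, lineages = "HSC", LINEAGES
            else:
                origin = "HPC"
                k = int(rng.integers(1, 6))  # proper subset, size 1..5
                idx = rng.choice(6, size=k, replace=False)
                lineages = frozenset(LINEAGE_ORDER[i] for i in idx)
            parent_id = donor_clones[parent_idx].clone_id if parent_idx is not None else None
            clone = TrueClone(
                clone_id=clone_id,
                donor_id=donor_id,
                signature=sig,
                parent_id=parent_id,
                origin=origin,
                lineages=lineages,
                h_emission=bool(rng.random() < 0.5),
            )
            donor_clones.append(clone)
            clone_index[clone_id] = clone
        clones.extend(donor_clones)

    # --- cells ---------------------------------------------------------
    clo, chi = config.cells_per_population
    cell_rows = []
    cell_clone: dict[str, str] = {}
    for donor_id, group in zip(donors["donor_id"], donors["group"]):
        donor_clones = [c for c in clones if c.donor_id == donor_id]
        weights = {}
        for c in donor_clones:
            w = float(rng.gamma(2.0, 1.0))
            if not _has_mds(c.signature, site_class):
                w *= config.ch_size_advantage
            weights[c.clone_id] = w
        wt_id = f"{donor_id}:WT"
        for pop in POPULATIONS:
            emitting = [c for c in donor_clones if pop in c.emits_in]
            n_cells = int(rng.integers(clo, chi + 1))
            n_cells = max(n_cells, len(emitting))
            assignment = [c.clone_id for c in emitting]  # guarantee one cell each
            n_free = n_cells - len(assignment)
            if n_free > 0:
                if emitting:
                    w = np.array([weights[c.clone_id] for c in emitting])
                    w = w / w.sum()
                    for _ in range(n_free):
                        if rng.random() < config.wt_fraction:
                            assignment.append(wt_id)
                        else:
                            assignment.append(emitting[int(rng.choice(len(emitting), p=w))].clone_id)
                else:
                    assignment.extend([wt_id] * n_free)
            for j, clone_id in enumerate(assignment):
                cell_id = f"{donor_id}_{pop}_{j + 1:03d}"
                cell_rows.append(
                    {"cell_id": cell_id, "donor_id": donor_id, "group": group, "population": pop}
                )
                cell_clone[cell_id] = clone_id
    cells = pd.DataFrame(cell_rows, columns=["cell_id", "donor_id", "group", "population"])

    # --- read counts (vectorized over the cells x sites grid) ----------
    n_c, n_s = len(cells), len(site_ids)
    mut = np.zeros((n_c, n_s), dtype=bool)
    site_pos = {s: j for j, s in enumerate(site_ids)}
    for i, cid in enumerate(cells["cell_id"]):
        tc = cell_clone[cid]
        if not tc.endswith(":WT"):
            for s in clone_index[tc].signature:
                mut[i, site_pos[s]] = True

    r = config.coverage_dispersion
    p_nb = r / (r + config.mean_coverage)
    coverage = rng.negative_binomial(r, p_nb, size=(n_c, n_s))
    dropped = rng.random(size=(n_c, n_s)) < config.allelic_dropout_rate
    vaf_eff = np.clip(
        rng.normal(config.expressed_vaf, config.vaf_jitter or 1e-12, size=(n_c, n_s)), 0.05, 0.95
    )
    fp_event = rng.random(size=(n_c, n_s)) < config.false_positive_rate
    fp_frac = rng.uniform(0.05, 0.5, size=(n_c, n_s))
    expressed = mut & ~dropped
    p_alt = np.where(expressed, vaf_eff, np.where(fp_event, fp_frac, 0.0))
    alt = rng.binomial(coverage, p_alt)
    ref = coverage - alt

    read_counts = pd.DataFrame(
        {
            "cell_id": np.repeat(cells["cell_id"].to_numpy(), n_s),
            "site_id": np.tile(np.array(site_ids), n_c),
            "ref_reads": ref.ravel(),
            "alt_reads": alt.ravel(),
        }
    )

    sites = pd.DataFrame(
        [
            {"site_id": s.site_id, "gene": s.gene, "variant": s.variant, "true_class": s.intended_class}
            for s in config.sites
        ],
        columns=["site_id", "gene", "variant", "true_class"],
    )
    truth = CohortTruth(config=config, donors=donors, clones=clones, cell_clone=cell_clone)
    return CohortBundle(read_counts=read_counts, cells=cells, sites=sites, truth=truth)


def true_mut_matrix(bundle: CohortBundle) -> pd.DataFrame:
    """Boolean cells x sites matrix of true mutant status (truth oracle)."""
    site_ids = list(bundle.sites["site_id"])
    index = list(bundle.cells["cell_id"])
    clone_index = {c.clone_id: c for c in bundle.truth.clones}
    data = np.zeros((len(index), len(site_ids)), dtype=bool)
    pos = {s: j for j, s in enumerate(site_ids)}
    for i, cid in enumerate(index):
        tc = bundle.truth.cell_clone[cid]
        if not tc.endswith(":WT"):
            for s in clone_index[tc].signature:
                data[i, pos[s]] = True
    return pd.DataFrame(data, index=pd.Index(index, name="cell_id"), columns=site_ids)


def write_fixture(bundle: CohortBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as read_counts.tsv, cells.tsv, sites.tsv, truth.json.

    The tables round-trip losslessly through :func:`clonescope.io.read_table`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "read_counts": directory / "read_counts.tsv",
        "cells": directory / "cells.tsv",
        "sites": directory / "sites.tsv",
        "truth": directory / "truth.json",
    }
    bundle.read_counts.to_csv(paths["read_counts"], sep="\t", index=False)
    bundle.cells.to_csv(paths["cells"], sep="\t", index=False)
    bundle.sites.to_csv(paths["sites"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth.to_dict(), fh, indent=1, default=float)
    return paths
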