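"""Genotype calling: per-cell per-site read counts -> MUT / WT / NA calls.

The calling rule mirrors the study's filtration: a site covered by fewer
than ``min_coverage`` (default 10) total reads is uncallable and reported NA;
at covered sites the variant allele frequency ``vaf = alt / (ref + alt)`` is
computed and the site is called MUT when the variant evidence clears both an
absolute-read and a VAF threshold (defaults: ``alt >= 2`` and
``vaf >= 0.05``), otherwise WT.  Cells are *qualified* when they carry at
least ``min_informative_sites`` callable (non-NA) sites; unqualified cells
are retained, flagged, and excluded from every downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ReferentialIntegrityError, UndefinedStatisticError, ValidationError
from .simulate import POPULATIONS

CALL_MUT = "MUT"
CALL_WT = "WT"
CALL_NA = "NA"


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the genotype caller.

    ``min_coverage`` is the 10-read qualification threshold; ``min_alt_reads``
    and ``min_vaf`` guard against single-read PCR/sequencing errors at
    covered sites; ``min_informative_sites`` is the cell-qualification rule
    (a cell needs at least this many non-NA sites to be usable).
    All comparisons are inclusive (``>=``).
    """

    min_coverage: int = 10
    min_alt_reads: int = 2
    min_vaf: float = 0.05
    min_informative_sites: int = 1

    def validate(self) -> None:
        if self.min_coverage < 1:
            raise ValidationError(f"min_coverage must be >= 1, got {self.min_coverage}")
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValidationError(f"min_vaf must be in [0, 1], got {self.min_vaf}")
        if self.min_alt_reads < 0:
            raise ValidationError(f"min_alt_reads must be >= 0, got {self.min_alt_reads}")
        if self.min_informative_sites < 0:
            raise ValidationError(
                f"min_informative_sites must be >= 0, got {self.min_informative_sites}"
            )


@dataclass(frozen=True)
class ReadCountRecord:
    cell_id: str
    site_id: str
    ref_reads: int
    alt_reads: int


@dataclass(frozen=True)
class GenotypeCall:
    """One call: MUT/WT/NA, with the VAF defined iff the call is not NA."""

    value: str
    vaf: float | None

    def __post_init__(self):
        assert (self.value == CALL_NA) == (self.vaf is None)


def call_from_counts(ref_reads: int, alt_reads: int, params: CallerParams | None = None) -> GenotypeCall:
    """Apply the calling rule to one (ref, alt) pair."""
    params = params or CallerParams()
    params.validate()
    if ref_reads < 0 or alt_reads < 0:
        raise ValidationError(
            f"read counts must be nonnegative, got ref={ref_reads}, alt={alt_reads}"
        )
    total = ref_reads + alt_reads
    if total < params.min_coverage:
        return GenotypeCall(CALL_NA, None)
    vaf = alt_reads / total
    if alt_reads >= params.min_alt_reads and vaf >= params.min_vaf:
        return GenotypeCall(CALL_MUT, vaf)
    return GenotypeCall(CALL_WT, vaf)


def call_genotype(record: ReadCountRecord, params: CallerParams | None = None) -> GenotypeCall:
    """Call one :class:`ReadCountRecord`."""
    return call_from_counts(record.ref_reads, record.alt_reads, params)


@dataclass
class GenotypeMatrix:
    """Qualified-cell genotype matrix plus per-cell and per-site metadata.

    Attributes
    ----------
    calls : DataFrame, cells x sites, values in {MUT, WT, NA}
    vaf : DataFrame, cells x sites, NaN exactly where the call is NA
    cells : DataFrame indexed by cell_id with donor_id, group, population,
        n_informative and the ``qualified`` flag
    sites : DataFrame indexed by site_id with gene / variant (extra columns
        such as a simulator's true_class are passed through)
    """

    calls: pd.DataFrame
    vaf: pd.DataFrame
    cells: pd.DataFrame
    sites: pd.DataFrame
    params: CallerParams

    @property
    def site_ids(self) -> list[str]:
        return list(self.calls.columns)

    def qualified_index(self, donor_id: str | None = None) -> pd.Index:
        mask = self.cells["qualified"]
        if donor_id is not None:
            mask = mask & (self.cells["donor_id"] == donor_id)
        return self.cells.index[mask]

    @property
    def donor_ids(self) -> list[str]:
        return list(dict.fromkeys(self.cells["donor_id"]))


def _check_referential(read_counts: pd.DataFrame, cells: pd.DataFrame, sites: pd.DataFrame) -> None:
    known_cells = set(cells["cell_id"])
    known_sites = set(sites["site_id"])
    bad_cells = sorted(set(read_counts["cell_id"]) - known_cells)
    bad_sites = sorted(set(read_counts["site_id"]) - known_sites)
    if bad_cells or bad_sites:
        parts = []
        if bad_cells:
            parts.append(f"unknown cell ids: {bad_cells[:10]}")
        if bad_sites:
            parts.append(f"unknown site ids: {bad_sites[:10]}")
        raise ReferentialIntegrityError("; ".join(parts))


def build_genotype_matrix(
    read_counts: pd.DataFrame,
    cells: pd.DataFrame,
    sites: pd.DataFrame,
    params: CallerParams | None = None,
) -> GenotypeMatrix:
    """Build the cells x sites genotype matrix from long-format read counts.

    A (cell, site) pair with no read-count row is treated as zero coverage
    (NA).  Duplicate (cell, site) rows and references to unknown ids are
    rejected.
    """
    params = params or CallerParams()
    params.validate()
    for col in ("ref_reads", "alt_reads"):
        vals = read_counts[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValidationError(f"{col} must be integer, got dtype {vals.dtype}")
        if (vals < 0).any():
            rows = np.nonzero(vals < 0)[0][:10].tolist()
            raise ValidationError(f"negative {col} at rows {rows}")
    dup = read_counts.duplicated(subset=["cell_id", "site_id"])
    if dup.any():
        offenders = read_counts.loc[dup, ["cell_id", "site_id"]].head(10).to_records(index=False)
        raise ValidationError(f"duplicate (cell_id, site_id) rows: {list(offenders)}")
    if cells["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell_id in cell table")
    if sites["site_id"].duplicated().any():
        raise ValidationError("duplicate site_id in site table")
    bad_pop = sorted(set(cells["population"]) - set(POPULATIONS))
    if bad_pop:
        raise ValidationError(f"unknown population labels {bad_pop}; expected {POPULATIONS}")
    _check_referential(read_counts, cells, sites)

    cell_ids = list(cells["cell_id"])
    site_ids = list(sites["site_id"])
    alt = (
        read_counts.pivot(index="cell_id", columns="site_id", values="alt_reads")
        .reindex(index=cell_ids, columns=site_ids)
        .fillna(0)
        .to_numpy()
    )
    ref = (
        read_counts.pivot(index="cell_id", columns="site_id", values="ref_reads")
        .reindex(index=cell_ids, columns=site_ids)
        .fillna(0)
        .to_numpy()
    )
    total = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    covered = total >= params.min_coverage
    mut = covered & (alt >= params.min_alt_reads) & (vaf >= params.min_vaf)
    calls = np.where(~covered, CALL_NA, np.where(mut, CALL_MUT, CALL_WT))
    vaf = np.where(covered, vaf, np.nan)

    index = pd.Index(cell_ids, name="cell_id")
    calls_df = pd.DataFrame(calls, index=index, columns=site_ids)
    vaf_df = pd.DataFrame(vaf, index=index, columns=site_ids)
    cells_meta = cells.set_index("cell_id").copy()
    cells_meta["n_informative"] = covered.sum(axis=1)
    cells_meta["qualified"] = cells_meta["n_informative"] >= params.min_informative_sites
    sites_meta = sites.set_index("site_id").copy()
    return GenotypeMatrix(calls=calls_df, vaf=vaf_df, cells=cells_meta, sites=sites_meta, params=params)


def mutant_cell_fraction(gm: GenotypeMatrix, donor_id: str) -> float:
    """Percentage of the donor's qualified cells carrying >= 1 MUT call.

    Raises :class:`UndefinedStatisticError` for a donor with no qualified
    cells — an unmeasurable donor is not a donor measured at 0%.
    """
    idx = gm.qualified_index(donor_id)
    if len(idx) == 0:
        raise UndefinedStatisticError(f"donor {donor_id!r} has no qualified cells")
    any_mut = (gm.calls.loc[idx] == CALL_MUT).any(axis=1)
    return 100.0 * float(any_mut.mean())


def mutation_count(gm: GenotypeMatrix, donor_id: str) -> int:
    """Number of distinct sites MUT-called in >= 1 of the donor's qualified cells."""
    idx = gm.qualified_index(donor_id)
    if len(idx) == 0:
        raise UndefinedStatisticError(f"donor {donor_id!r} has no qualified cells")
    return int((gm.calls.loc[idx] == CALL_MUT).any(axis=0).sum())


def detected_sites(gm: GenotypeMatrix, cell_index: Iterable[str] | None = None) -> list[str]:
    """Sites MUT-called in at least one qualified cell (optionally restricted)."""
    idx = pd.Index(cell_index) if cell_index is not None else gm.qualified_index()
    mask = (gm.calls.loc[idx] == CALL_MUT).any(axis=0)
    return [s for s in gm.site_ids if mask[s]]
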