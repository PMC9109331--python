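"""Table readers/writers, run configuration and the pipeline orchestrator.

All tables are plain delimited text with a header row (tab for ``.tsv`` /
``.txt``, comma for ``.csv``); columns may appear in any order, required
columns are checked by name, and unknown extra columns are preserved.  The
pipeline runs simulate -> genotype -> clones -> stats and writes a JSON run
manifest with input checksums and per-stage counts so every exclusion the
analysis makes (unqualified cells, NA cells, WT clones) is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clones import clone_table, reconstruct_cohort
from .errors import ConfigurationError, SchemaError
from .genotype import CallerParams, GenotypeMatrix, build_genotype_matrix
from .simulate import CohortBundle, SimConfig, simulate_cohort, write_fixture
from .stats import (
    blast_stratified_comparison,
    compare_donor_groups,
    donor_summary_table,
)
from .errors import ClonescopeError

log = logging.getLogger("clonescope")

#: required column -> dtype kind ("str", "int", "float", "bool")
SCHEMAS: dict[str, dict[str, str]] = {
    "read_counts": {"cell_id": "str", "site_id": "str", "ref_reads": "int", "alt_reads": "int"},
    "cells": {"cell_id": "str", "donor_id": "str", "group": "str", "population": "str"},
    "sites": {"site_id": "str", "gene": "str", "variant": "str"},
    "donors": {"donor_id": "str", "group": "str", "blast_pct": "float"},
    "clones": {
        "clone_id": "str",
        "donor_id": "str",
        "signature": "str",
        "size": "int",
        "size_fraction": "float",
        "populations": "str",
        "n_populations": "int",
        "clone_class": "str",
        "double_mutant": "bool",
        "origin": "str",
        "family_id": "str",
        "shared": "bool",
    },
}


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a delimited table and validate it against a named schema.

    Raises :class:`SchemaError` naming any missing required column, or the
    first offending row when an integer column holds non-integer values.
    """
    path = Path(path)
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    if not path.exists():
        raise ConfigurationError(f"input file does not exist: {path}")
    df = pd.read_csv(path, sep=_delimiter(path), dtype=str, keep_default_na=False)
    required = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing} for schema {schema!r}")
    for col, kind in required.items():
        if kind == "int":
            num = pd.to_numeric(df[col], errors="coerce")
            bad = num.isna() | (num != num.round())
            if bad.any():
                row = int(np.nonzero(bad.to_numpy())[0][0])
                raise SchemaError(
                    f"{path.name}: column {col!r} must be integer; "
                    f"offending value {df[col].iloc[row]!r} at data row {row + 1}"
                )
            df[col] = num.astype(np.int64)
        elif kind == "float":
            blank = df[col] == ""
            num = pd.to_numeric(df[col].mask(blank), errors="coerce")
            bad = num.isna() & ~blank
            if bad.any():
                row = int(np.nonzero(bad.to_numpy())[0][0])
                raise SchemaError(
                    f"{path.name}: column {col!r} must be numeric; "
                    f"offending value {df[col].iloc[row]!r} at data row {row + 1}"
                )
            df[col] = num
        elif kind == "bool":
            df[col] = df[col].map({"True": True, "False": False, "true": True, "false": False})
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_delimiter(path), index=False)
    return path


# -- wide genotype table --------------------------------------------------

_GENO_META = ["cell_id", "donor_id", "group", "population", "qualified", "n_informative"]
_VAF_SUFFIX = "|vaf"


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> Path:
    """One row per cell: metadata, qualified flag, a MUT/WT/NA column per
    site and a matching ``<site>|vaf`` column (blank at NA)."""
    out = gm.cells.reset_index()[_GENO_META[:4]].copy()
    out["qualified"] = gm.cells["qualified"].to_numpy()
    out["n_informative"] = gm.cells["n_informative"].to_numpy()
    for site in gm.site_ids:
        out[site] = gm.calls[site].to_numpy()
        out[site + _VAF_SUFFIX] = gm.vaf[site].round(6).to_numpy()
    return write_table(out, path)


def read_genotypes(path: str | Path, params: CallerParams | None = None) -> GenotypeMatrix:
    """Read a wide genotype table back into a :class:`GenotypeMatrix`."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file does not exist: {path}")
    df = pd.read_csv(path, sep=_delimiter(path), dtype=str, keep_default_na=False)
    missing = [c for c in _GENO_META if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing} for genotypes")
    site_ids = [c for c in df.columns if c not in _GENO_META and not c.endswith(_VAF_SUFFIX)]
    index = pd.Index(df["cell_id"], name="cell_id")
    calls = pd.DataFrame({s: df[s].to_numpy() for s in site_ids}, index=index)
    vaf = pd.DataFrame(
        {s: pd.to_numeric(df[s + _VAF_SUFFIX].replace("", np.nan)).to_numpy() for s in site_ids},
        index=index,
    )
    cells = df[_GENO_META].set_index("cell_id")
    cells["qualified"] = cells["qualified"].map({"True": True, "False": False})
    cells["n_informative"] = cells["n_informative"].astype(int)
    sites = pd.DataFrame({"site_id": site_ids}).set_index("site_id")
    parts = pd.Series(site_ids).str.split(":", n=1, expand=True)
    sites["gene"] = parts[0].to_numpy()
    sites["variant"] = (parts[1] if parts.shape[1] > 1 else parts[0]).to_numpy()
    return GenotypeMatrix(calls=calls, vaf=vaf, cells=cells, sites=sites, params=params or CallerParams())


# -- run configuration and orchestration ----------------------------------


@dataclass
class RunConfig:
    """Configuration of one pipeline run: either the three input table paths
    or a simulation config, plus caller thresholds and output options."""

    out_dir: str | Path = "clonescope_out"
    reads_path: str | Path | None = None
    cells_path: str | Path | None = None
    sites_path: str | Path | None = None
    donors_path: str | Path | None = None
    sim_config: SimConfig | None = None
    caller: CallerParams = field(default_factory=CallerParams)
    shannon_base: float | None = None
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.sim_config is None:
            needed = {"reads_path": self.reads_path, "cells_path": self.cells_path, "sites_path": self.sites_path}
            missing = [k for k, v in needed.items() if v is None]
            if missing:
                raise ConfigurationError(
                    f"either sim_config or all of reads/cells/sites paths are required; missing {missing}"
                )
            for k, v in {**needed, "donors_path": self.donors_path}.items():
                if v is not None and not Path(v).exists():
                    raise ConfigurationError(f"{k}: file does not exist: {v}")
        self.caller.validate()


@dataclass
class RunManifest:
    version: str
    config: dict
    checksums: dict[str, str]
    counts: dict
    started: str
    finished: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run simulate (optional) -> genotype -> clones -> stats, writing
    genotypes.tsv, clones.tsv, summary.json and manifest.json to out_dir."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    started = datetime.now(timezone.utc).isoformat()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    checksums: dict[str, str] = {}
    blast: dict[str, float] = {}
    if config.sim_config is not None:
        sim = config.sim_config
        if config.seed is not None:
            sim = dataclasses.replace(sim, seed=config.seed)
        bundle: CohortBundle = simulate_cohort(sim)
        fixture_paths = write_fixture(bundle, out_dir / "simulated")
        checksums = {k: _sha256(p) for k, p in fixture_paths.items()}
        reads, cells, sites = bundle.read_counts, bundle.cells, bundle.sites
        blast = {
            r.donor_id: r.blast_pct
            for r in bundle.truth.donors.itertuples()
            if not (isinstance(r.blast_pct, float) and np.isnan(r.blast_pct))
        }
        log.info("simulated cohort: %d cells, %d sites", len(cells), len(sites))
    else:
        reads = read_table(config.reads_path, "read_counts")
        cells = read_table(config.cells_path, "cells")
        sites = read_table(config.sites_path, "sites")
        for name, p in (
            ("read_counts", config.reads_path),
            ("cells", config.cells_path),
            ("sites", config.sites_path),
        ):
            checksums[name] = _sha256(Path(p))
        if config.donors_path is not None:
            donors = read_table(config.donors_path, "donors")
            checksums["donors"] = _sha256(Path(config.donors_path))
            blast = {
                r.donor_id: r.blast_pct for r in donors.itertuples() if not np.isnan(r.blast_pct)
            }

    gm = build_genotype_matrix(reads, cells, sites, config.caller)
    n_cells = len(gm.cells)
    n_qualified = int(gm.cells["qualified"].sum())
    log.info("genotyped %d cells; %d qualified, %d unqualified", n_cells, n_qualified, n_cells - n_qualified)
    write_genotypes(gm, out_dir / "genotypes.tsv")

    clones, classes, exclusions = reconstruct_cohort(gm)
    cdf = clone_table(clones)
    write_table(cdf, out_dir / "clones.tsv")
    log.info(
        "reconstructed %d clones over %d donors; excluded %d WT cells, %d NA cells",
        len(clones), len(exclusions), int(exclusions["excluded_wt"].sum()), int(exclusions["excluded_na"].sum()),
    )

    summaries = donor_summary_table(gm, cdf, exclusions, blast_pct=blast, shannon_base=config.shannon_base)
    comparisons: dict[str, dict] = {}
    if {"HD", "MDS"} <= set(summaries["group"]):
        comparisons["hd_vs_mds"] = {k: v.to_dict() for k, v in compare_donor_groups(summaries).items()}
    try:
        comparisons["blast_strata"] = {
            k: v.to_dict() for k, v in blast_stratified_comparison(summaries, cdf).items()
        }
    except ClonescopeError as exc:
        log.info("blast-stratified comparison skipped: %s", exc)

    summary = {
        "donor_summaries": json.loads(summaries.to_json(orient="records")),
        "comparisons": comparisons,
        "parameters": {
            "caller": dataclasses.asdict(config.caller),
            "shannon_base": config.shannon_base or "e",
        },
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    counts = {
        "cells_in": n_cells,
        "cells_qualified": n_qualified,
        "cells_unqualified": n_cells - n_qualified,
        "mutations_detected": int(len(classes)),
        "clones": len(clones),
        "per_donor": json.loads(exclusions.reset_index().to_json(orient="records")),
    }
    manifest = RunManifest(
        version=__version__,
        config={
            "caller": dataclasses.asdict(config.caller),
            "shannon_base": config.shannon_base,
            "seed": config.seed,
            "simulated": config.sim_config is not None,
            **({"sim_config": config.sim_config.to_dict()} if config.sim_config else {}),
        },
        checksums=checksums,
        counts=counts,
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
    )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1, default=str)
    return manifest
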