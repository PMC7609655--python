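"""Table readers/writers, run configuration and the pipeline driver.

All tables are UTF-8 comma-separated text with a header row; reports are
JSON and run configuration is YAML.  The driver executes the full
analysis sequence — simulate (or load) → clone identification → ring
traits → detrending → heritability → model comparison — with every
source of randomness derived from the single top-level seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anatomy import TRAIT_COLUMNS, cells_to_traits
from .cloneid import (CloneAssignment, Genotype, cluster_clones,
                      filter_null_alleles, make_locus_call)
from .compare import compare_trait, comparison_table, format_comparison
from .detrend import detrend_traits
from .herit import heritability_suite, reports_to_frame
from .synthio import (PopulationConfig, TreeMeta, default_trait_panel,
                      simulate_cell_data, simulate_genotypes,
                      simulate_population)

logger = logging.getLogger(__name__)

CELL_COLUMNS = ["tree_id", "year", "radial_position_um", "radial_extent_um",
                "lumen_area_um2", "cwt_um"]


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, cols: list, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _first_bad_line(mask: pd.Series) -> int:
    # +2: header line plus 1-based numbering
    return int(mask.idxmax()) + 2


# ---------------------------------------------------------------------------
# cells

def read_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CELL_COLUMNS, path)
    bad = df["lumen_area_um2"] <= 0
    if bad.any():
        raise SchemaError(f"{path}: non-positive lumen_area_um2 on line "
                          f"{_first_bad_line(bad)}")
    bad = df["cwt_um"] <= 0
    if bad.any():
        raise SchemaError(f"{path}: non-positive cwt_um on line "
                          f"{_first_bad_line(bad)}")
    key = df[["tree_id", "year", "radial_position_um"]]
    dup = key.duplicated(keep=False)
    if dup.any():
        dupes = key.loc[dup].head(5).to_dict("records")
        raise SchemaError(f"{path}: duplicated tree-year-position keys: {dupes}")
    logger.info("read %d cells from %s", len(df), path)
    return df


def write_cells(df: pd.DataFrame, path) -> None:
    df[CELL_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotypes

def genotype_columns(n_loci: int) -> list:
    return ["tree_id"] + [f"L{l + 1:02d}_a{a}" for l in range(n_loci)
                          for a in (1, 2)]


def write_genotypes(genotypes: list[Genotype], path) -> None:
    """One row per tree; missing locus = empty cells, null allele = NULL."""
    n_loci = genotypes[0].n_loci if genotypes else 0
    rows = []
    for g in genotypes:
        row: dict = {"tree_id": g.tree_id}
        for l, call in enumerate(g.locus_calls):
            c1 = f"L{l + 1:02d}_a1"
            c2 = f"L{l + 1:02d}_a2"
            if call is None:
                row[c1] = row[c2] = ""
            else:
                alleles = sorted(call, key=str)
                if len(alleles) == 1:
                    alleles = alleles * 2
                row[c1], row[c2] = alleles
        rows.append(row)
    pd.DataFrame(rows, columns=genotype_columns(n_loci)).to_csv(path, index=False)


def read_genotypes(path) -> list[Genotype]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "tree_id" not in df.columns:
        raise SchemaError(f"{path}: missing column tree_id")
    allele_cols = [c for c in df.columns if c != "tree_id"]
    if len(allele_cols) % 2 != 0:
        raise SchemaError(f"{path}: odd number of allele columns")
    n_loci = len(allele_cols) // 2
    genotypes = []
    for i, row in df.iterrows():
        calls = []
        for l in range(n_loci):
            try:
                calls.append(make_locus_call(row[f"L{l + 1:02d}_a1"],
                                             row[f"L{l + 1:02d}_a2"]))
            except (ValueError, KeyError) as exc:
                raise SchemaError(
                    f"{path}: bad allele call at locus {l + 1}, line {i + 2}: "
                    f"{exc}") from exc
        genotypes.append(Genotype(tree_id=row["tree_id"], locus_calls=calls))
    logger.info("read %d genotypes (%d loci) from %s", len(genotypes),
                n_loci, path)
    return genotypes


# ---------------------------------------------------------------------------
# tree metadata

def write_metadata(trees: list[TreeMeta], path) -> None:
    years = sorted(next(iter(trees)).cdbh_by_year) if trees else []
    rows = []
    for t in trees:
        row = {"tree_id": t.tree_id, "spatial_group": t.spatial_group,
               "clonal_group": t.clonal_group or "", "x_m": t.x, "y_m": t.y}
        row.update({f"cdbh_{yr}": t.cdbh_by_year[yr] for yr in years})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata(path) -> list[TreeMeta]:
    df = pd.read_csv(path, dtype={"tree_id": str, "spatial_group": str,
                                  "clonal_group": str})
    _require_columns(df, ["tree_id", "spatial_group", "x_m", "y_m"], path)
    year_cols = sorted(c for c in df.columns if c.startswith("cdbh_"))
    if not year_cols:
        raise SchemaError(f"{path}: no cdbh_<year> columns")
    trees = []
    for i, row in df.iterrows():
        cdbh = {int(c.split("_")[1]): float(row[c]) for c in year_cols}
        vals = [cdbh[y] for y in sorted(cdbh)]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise SchemaError(f"{path}: decreasing cDBH on line {i + 2}")
        cg = row.get("clonal_group", "")
        trees.append(TreeMeta(
            tree_id=row["tree_id"], spatial_group=row["spatial_group"],
            clonal_group=cg if isinstance(cg, str) and cg else None,
            x=float(row["x_m"]), y=float(row["y_m"]), cdbh_by_year=cdbh,
        ))
    logger.info("read metadata for %d trees from %s", len(trees), path)
    return trees


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class Thresholds:
    max_mismatch: int = 2
    max_null: int = 2
    aicc_gap: float = 4.0
    alpha: float = 0.05


@dataclass
class RunConfig:
    """Pipeline configuration: either input paths or a simulate block."""

    out_dir: str = "results"
    seed: int = 0
    years: tuple = (2007, 2017)
    inputs: dict | None = None          # cells / genotypes / metadata paths
    simulate: dict | None = None        # population kwargs + generator knobs
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("exactly one of 'inputs' or 'simulate' required")
        if self.inputs is not None:
            for key in ("cells", "genotypes", "metadata"):
                if key not in self.inputs:
                    raise ValueError(f"inputs block missing {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise ValueError(f"input file not found: "
                                     f"{self.inputs[key]} ({key})")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    thr = Thresholds(**raw.pop("thresholds", {}))
    years = tuple(raw.pop("years", (2007, 2017)))
    return RunConfig(thresholds=thr, years=years, **raw)


# ---------------------------------------------------------------------------
# pipeline driver

def _simulate_inputs(cfg: RunConfig, out: Path):
    sim = dict(cfg.simulate or {})
    pop_kwargs = sim.get("population", {})
    pop = PopulationConfig(seed=cfg.seed, years=cfg.years, **pop_kwargs)
    trees = simulate_population(pop)
    genotypes = simulate_genotypes(
        trees, seed=cfg.seed + 1,
        error_rate=sim.get("error_rate", 0.02),
        null_rate=sim.get("null_rate", 0.02),
    )
    panel = default_trait_panel(trees, seed=cfg.seed + 2,
                                fractions=sim.get("variance_fractions"),
                                rho=sim.get("rho", 0.3))
    cells = simulate_cell_data(panel, seed=cfg.seed + 3,
                               cells_per_ring=sim.get("cells_per_ring", 30))
    inputs_dir = out / "inputs"
    inputs_dir.mkdir(parents=True, exist_ok=True)
    write_cells(cells, inputs_dir / "cells.csv")
    write_genotypes(genotypes, inputs_dir / "genotypes.csv")
    write_metadata(trees, inputs_dir / "metadata.csv")
    return trees, genotypes, cells


def assemble_panel(traits: pd.DataFrame, trees: list[TreeMeta],
                   assignment: CloneAssignment) -> pd.DataFrame:
    """Join ring traits with metadata and clone assignment.

    ``genetic_group`` comes from the clone assignment (clone label, or
    the tree's own id for singletons); trees without a genotype keep
    their own id and count as non-clonal.
    """
    meta = {t.tree_id: t for t in trees}
    panel = traits.copy()
    panel["spatial_group"] = panel["tree_id"].map(
        lambda t: meta[t].spatial_group)
    panel["cDBH"] = [meta[t].cdbh_by_year[y]
                     for t, y in zip(panel["tree_id"], panel["year"])]
    panel["genetic_group"] = panel["tree_id"].map(
        lambda t: assignment.group_of.get(t, t))
    panel["clonal"] = panel["tree_id"].map(
        lambda t: not assignment.singleton.get(t, True))
    return panel


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run report."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed,
                    "config": {"years": list(cfg.years),
                               "thresholds": asdict(cfg.thresholds),
                               "simulate": cfg.simulate,
                               "inputs": cfg.inputs},
                    "stages": {}, "warnings": []}

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            report["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3), **counts}
            logger.info("stage %s done: %s", name, counts)
        return done

    try:
        mark = stage("load")
        if cfg.simulate is not None:
            trees, genotypes, cells = _simulate_inputs(cfg, out)
        else:
            cells = read_cells(cfg.inputs["cells"])
            genotypes = read_genotypes(cfg.inputs["genotypes"])
            trees = read_metadata(cfg.inputs["metadata"])
        mark(trees=len(trees), genotypes=len(genotypes), cells=len(cells))

        mark = stage("clones")
        kept = filter_null_alleles(genotypes, cfg.thresholds.max_null)
        assignment = cluster_clones(kept, cfg.thresholds.max_mismatch)
        mark(genotypes_kept=len(kept),
             clone_groups=len(assignment.clone_groups),
             clonal_trees=assignment.n_clonal_trees,
             spatial_groups=len({t.spatial_group for t in trees}))

        mark = stage("traits")
        traits = cells_to_traits(cells)
        n_incomplete = int(traits["incomplete_ring"].sum())
        if n_incomplete:
            report["warnings"].append(
                f"{n_incomplete} rings with an empty zone")
        mark(rings=len(traits), incomplete=n_incomplete)

        mark = stage("detrend")
        traits = detrend_traits(traits)
        write_traits = traits.copy()
        write_traits.to_csv(out / "traits.csv", index=False)
        mark(rows=len(traits))

        panel = assemble_panel(traits, trees, assignment)
        # growth traits are analysed on the detrended widths
        analysis_cols = {}
        for trait in TRAIT_COLUMNS:
            col = f"{trait}_detrended" if trait in ("EWW", "LWW") else trait
            analysis_cols[trait] = col
            if col != trait:
                panel[trait + "_raw"] = panel[trait]
                panel[trait] = panel[col]

        mark = stage("heritability")
        reports = heritability_suite(panel, TRAIT_COLUMNS)
        herit_frame = reports_to_frame(reports)
        herit_frame.to_csv(out / "heritability.csv", index=False)
        clamped = herit_frame["flags"].astype(bool).sum()
        if clamped:
            report["warnings"].append(f"{clamped} flagged H2 estimates")
        mark(traits=len(reports))

        mark = stage("compare")
        verdicts = [compare_trait(panel, t, alpha=cfg.thresholds.alpha)
                    for t in TRAIT_COLUMNS]
        table = comparison_table(verdicts)
        table.to_csv(out / "comparison.csv", index=False)
        (out / "comparison.txt").write_text(format_comparison(table) + "\n")
        mark(traits=len(verdicts),
             failed=int(table["failed"].sum()))

        report["ok"] = True
    except Exception as exc:
        report["ok"] = False
        report["error"] = {"stage": _last_stage(report), "message": str(exc)}
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    default=_jsonable))
        raise

    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                default=_jsonable))
    return report


def _last_stage(report: dict) -> str:
    stages = list(report["stages"])
    return stages[-1] if stages else "load"


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
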