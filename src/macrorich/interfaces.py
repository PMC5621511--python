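"""Formats, configuration, and the umbrella pipeline/CLI.

File formats are plain text throughout: labelled CSV for matrices and site
tables, ESRI ASCII grids for rasters, newick for trees, two-column CSV for
tip-range codings, JSON for event logs and manifests.  The pipeline runs
the stages in the order of the analysis chain (assemble -> hotspot ->
nestedness -> cooccurrence -> environment models -> biogeography), writes
per-stage results plus a manifest with content hashes, and draws all
randomness from per-stage seeds declared in the configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import dendropy
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, InvalidArgumentError, ParseError
from .grid_assembly import (
    PresenceAbsenceMatrix,
    RichnessGrid,
    build_matrix,
    kappa_compare,
    regrid,
    stack_richness,
)
from .hotspot_detection import (
    build_weights,
    delineate_hotspots,
    getis_ord_gstar,
    morans_i,
)
from .historical_biogeography import RangeCoding, bsm, compare_models, fit_dec
from .nestedness import test as nestedness_test
from .cooccurrence import cooccurrence_test
from .environment_models import (
    assemble_sites,
    forward_stepwise,
    quantile_envelope,
    sar_fit,
)
from .synthetic_data import (
    EnvStack,
    RangeSet,
    make_environment,
    make_ranges,
    simulate_dec,
)

__all__ = [
    "read_matrix", "write_matrix", "read_grid", "write_grid",
    "read_tree", "write_tree", "read_coding", "write_coding",
    "read_ranges", "write_ranges",
    "PipelineConfig", "run_pipeline", "main", "ALGORITHM_REGISTRY",
]

# the pinned algorithm variants this package implements
ALGORITHM_REGISTRY = {
    "temperature": "isocline formulation (fill-dependent isocline, "
                   "normalized squared diagonal distances, scale 100/0.04145), "
                   "deterministic pack-by-totals",
    "nodf": "marginal-total paired overlap, order-invariant",
    "discrepancy": "column-packed leftmost-block count, stable ties",
    "null_model": "fixed rows / equiprobable columns",
    "gi_star": "self-inclusive Getis-Ord, population sd, normality Z",
    "sar": "spatial-error ML, eigenvalue log-determinant, pseudo-R2 = "
           "corr(trend, observed)^2",
    "dec_root_prior": "uniform over allowed non-empty ranges",
    "dec_cladogenesis": "equal weight per allowed event; j split equally "
                        "among jump destinations",
    "bsm_paths": "uniformization, retry cap 100",
}


# ---------------------------------------------------------------------------
# Matrix and grid IO
# ---------------------------------------------------------------------------

def write_matrix(matrix: PresenceAbsenceMatrix, path) -> None:
    matrix.to_frame().to_csv(path, index_label="species")


def read_matrix(path) -> PresenceAbsenceMatrix:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"{path}: cannot parse labelled CSV matrix: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: empty matrix")
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ParseError(f"{path}: matrix entries must be 0/1")
    return PresenceAbsenceMatrix(matrix=vals.astype(int),
                                 species=list(df.index.astype(str)),
                                 site_labels=list(df.columns.astype(str)),
                                 provenance={"path": str(path)})


def write_grid(grid, path, cell_size: float | None = None,
               nodata: float = -9999.0) -> None:
    """Write a 2-D array or RichnessGrid as an ESRI ASCII grid."""
    if isinstance(grid, RichnessGrid):
        arr, cs = grid.richness.astype(float), grid.cell_size
        arr = np.where(grid.valid, arr, nodata)
    else:
        arr = np.asarray(grid, dtype=float)
        cs = cell_size if cell_size is not None else 1.0
    rows, cols = arr.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\nnrows {rows}\nxllcorner 0\nyllcorner 0\n"
                 f"cellsize {cs!r}\nNODATA_value {nodata!r}\n")
        for row in arr:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_grid(path):
    """Read an ESRI ASCII grid -> (array with NaN at nodata, cell_size)."""
    header = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value"}:
                header[parts[0].lower()] = float(parts[1])
            else:
                try:
                    rows.append([float(v) for v in parts])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad grid value: {exc}") from exc
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ParseError(f"{path}: missing header field {key!r}")
    arr = np.asarray(rows, dtype=float)
    if arr.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ParseError(f"{path}: data shape {arr.shape} does not match header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        arr = np.where(arr == nodata, np.nan, arr)
    return arr, header["cellsize"]


def write_ranges(ranges: RangeSet, directory) -> None:
    """One CSV per species: row, col, presence (occupied cells only)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid, occ in zip(ranges.species_ids, ranges.occupancy):
        rr, cc = np.nonzero(occ)
        pd.DataFrame({"row": rr, "col": cc, "presence": 1}).to_csv(
            directory / f"{sid}.csv", index=False)
    meta = {"shape": list(ranges.shape), "cell_size": ranges.cell_size,
            "species": list(ranges.species_ids)}
    (directory / "rangeset.json").write_text(json.dumps(meta, indent=1))


def read_ranges(directory) -> RangeSet:
    directory = Path(directory)
    meta_path = directory / "rangeset.json"
    if not meta_path.exists():
        raise ParseError(f"{directory}: missing rangeset.json metadata")
    meta = json.loads(meta_path.read_text())
    shape = tuple(meta["shape"])
    occ = np.zeros((len(meta["species"]), *shape), dtype=bool)
    for s, sid in enumerate(meta["species"]):
        df = pd.read_csv(directory / f"{sid}.csv")
        occ[s, df["row"], df["col"]] = df["presence"].astype(bool)
    return RangeSet(species_ids=list(meta["species"]), occupancy=occ,
                    cell_size=meta["cell_size"])


# ---------------------------------------------------------------------------
# Trees and codings
# ---------------------------------------------------------------------------

def read_tree(path) -> dendropy.Tree:
    """Parse a newick tree; unnamed internal nodes get stable preorder ids."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: cannot parse newick: {exc}") from exc
    from .synthetic_data import _label_internal_nodes
    _label_internal_nodes(tree)
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, suppress_internal_node_labels=False)


def read_coding(path, tree: dendropy.Tree | None = None,
                areas=None) -> RangeCoding:
    """Two-column CSV (tip label, area string like "B" or "BC")."""
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: cannot parse coding CSV: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: coding file needs two columns (tip, range)")
    tips = df.iloc[:, 0].astype(str)
    rngs = df.iloc[:, 1].astype(str)
    ranges = dict(zip(tips, rngs))
    if areas is None:
        areas = tuple(sorted({a for r in rngs for a in r}))
    coding = RangeCoding(areas=tuple(areas), ranges=ranges)
    if tree is not None:
        tree_tips = {l.taxon.label for l in tree.leaf_node_iter() if l.taxon}
        extra = set(ranges) - tree_tips
        missing = tree_tips - set(ranges)
        if extra or missing:
            raise InvalidArgumentError(
                f"coding/tree mismatch: unknown tips {sorted(extra)}, "
                f"uncoded tips {sorted(missing)}")
    return coding


def write_coding(coding: RangeCoding, path) -> None:
    pd.DataFrame({"tip": list(coding.ranges),
                  "range": list(coding.ranges.values())}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

_STAGES = ("simulate", "richness", "hotspot", "nestedness", "cooccur",
           "envmodel", "biogeo")
_STOCHASTIC = {"simulate", "nestedness", "cooccur", "envmodel", "biogeo"}
_ALLOWED_KEYS = {
    "simulate": {"seed", "shape", "n_species", "placement", "cell_size",
                 "gradient", "size_distribution"},
    "richness": {"cell_sizes", "kappa_classes"},
    "hotspot": {"scheme", "alpha", "correction", "moran_inference",
                "n_perm", "seed"},
    "nestedness": {"seed", "n_iter", "indices", "order"},
    "cooccur": {"seed", "n_null"},
    "envmodel": {"seed", "candidates", "taus", "n_boot", "sar"},
    "biogeo": {"seed", "n_tips", "d", "e", "j", "areas", "root_range",
               "n_maps", "models"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``stages`` toggles which stages run (in canonical order); each stage's
    parameter dict may only use known keys, and every stochastic stage must
    declare an explicit integer ``seed``.
    """

    stages: list
    params: dict = field(default_factory=dict)
    out_dir: str = "macrorich_run"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        stages = raw.pop("stages", list(_STAGES))
        out_dir = raw.pop("out_dir", "macrorich_run")
        unknown_stages = set(stages) - set(_STAGES)
        if unknown_stages:
            raise ConfigError(f"unknown stages: {sorted(unknown_stages)}")
        params = {}
        for stage, spec in raw.items():
            if stage not in _STAGES:
                raise ConfigError(f"unknown config section {stage!r}")
            bad = set(spec) - _ALLOWED_KEYS[stage]
            if bad:
                raise ConfigError(f"unknown keys in {stage!r}: {sorted(bad)}")
            params[stage] = dict(spec)
        for stage in stages:
            if stage in _STOCHASTIC:
                seed = params.get(stage, {}).get("seed")
                if not isinstance(seed, int):
                    raise ConfigError(
                        f"stochastic stage {stage!r} needs an explicit integer seed")
        ordered = [s for s in _STAGES if s in stages]
        return cls(stages=ordered, params=params, out_dir=out_dir)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir=None) -> Path:
    """Execute the configured stages in order; returns the run directory.

    Every stage writes CSV/JSON results into the run directory; a manifest
    lists each output with its content hash, and the log records versions,
    seeds and runtimes.  Reruns with an identical config are bit-identical.
    """
    run_dir = Path(out_dir or config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"macrorich {__version__}",
                 f"numpy {np.__version__}, pandas {pd.__version__}",
                 f"stages: {config.stages}"]
    state: dict = {}
    for stage in config.stages:
        t0 = time.perf_counter()
        p = config.params.get(stage, {})
        try:
            _run_stage(stage, p, state, run_dir)
        except Exception as exc:
            log_lines.append(f"{stage}: FAILED: {exc}")
            (run_dir / "log.txt").write_text("\n".join(log_lines) + "\n")
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        log_lines.append(f"{stage}: ok ({dt:.2f}s, seed={p.get('seed')})")
    manifest = {f.name: _sha256(f)
                for f in sorted(run_dir.iterdir())
                if f.is_file() and f.name not in {"manifest.json", "log.txt"}}
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (run_dir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return run_dir


def _run_stage(stage: str, p: dict, state: dict, run_dir: Path) -> None:
    if stage == "simulate":
        shape = tuple(p.get("shape", (20, 20)))
        env = make_environment(shape, p.get("gradient"), seed=p["seed"],
                               cell_size=p.get("cell_size", 1.0))
        ranges = make_ranges(p.get("n_species", 40), env,
                             size_distribution=p.get("size_distribution"),
                             placement=p.get("placement", "peaked"),
                             seed=p["seed"] + 1)
        for name, layer in env.layers.items():
            write_grid(layer, run_dir / f"env_{name}.asc", env.cell_size)
        write_ranges(ranges, run_dir / "ranges")
        state["env"], state["ranges"] = env, ranges
    elif stage == "richness":
        ranges = state["ranges"]
        grid = stack_richness(ranges)
        write_grid(grid, run_dir / "richness.asc")
        matrix = build_matrix(ranges)
        write_matrix(matrix, run_dir / "matrix.csv")
        state["grid"], state["matrix"] = grid, matrix
        sizes = p.get("cell_sizes")
        if sizes:
            kap = []
            base = regrid(ranges, max(sizes))
            for cs in sizes:
                other = regrid(ranges, cs)
                if other.shape == base.shape:
                    kap.append({"cell_size": cs,
                                "kappa": kappa_compare(base, other,
                                                       p.get("kappa_classes", 10))})
            if kap:
                pd.DataFrame(kap).to_csv(run_dir / "kappa.csv", index=False)
    elif stage == "hotspot":
        grid = state["grid"]
        w = build_weights(grid, scheme=p.get("scheme", "queen"))
        mor = morans_i(grid.richness.astype(float), w,
                       inference=p.get("moran_inference", "normal"),
                       n_perm=p.get("n_perm", 999), seed=p.get("seed"))
        wstar = build_weights(grid, scheme=p.get("scheme", "queen"),
                              include_self=True)
        z = getis_ord_gstar(grid.richness.astype(float), wstar)
        res = delineate_hotspots(z, wstar, alpha=p.get("alpha", 0.05),
                                 correction=p.get("correction", "fdr"))
        (run_dir / "morans.json").write_text(json.dumps(
            {"I": mor.I, "expected": mor.expected, "z": mor.z, "p": mor.p,
             "inference": mor.inference}, indent=1))
        cells = pd.DataFrame({
            "cell": wstar.cell_ids,
            "z": res.z_grid.flat[wstar.cell_ids],
            "p": res.p_grid.flat[wstar.cell_ids],
            "hot_cluster": res.hot_labels.flat[wstar.cell_ids],
            "cold_cluster": res.cold_labels.flat[wstar.cell_ids]})
        cells.to_csv(run_dir / "hotspot_cells.csv", index=False)
        res.clusters.to_csv(run_dir / "hotspot_clusters.csv", index=False)
        state["hotspot"] = res
    elif stage == "nestedness":
        M = state["matrix"].matrix
        rows = []
        for idx in p.get("indices", ["T", "BR", "NODF", "NODFc", "NODFr"]):
            r = nestedness_test(M, idx, n_iter=p.get("n_iter", 1000),
                                seed=p["seed"])
            rows.append({"index": idx, "observed": r.observed,
                         "null_mean": r.null_mean, "ci_low": r.null_ci[0],
                         "ci_high": r.null_ci[1], "p": r.p,
                         "p_opposite": r.p_opposite})
        pd.DataFrame(rows).to_csv(run_dir / "nestedness.csv", index=False)
    elif stage == "cooccur":
        r = cooccurrence_test(state["matrix"].matrix,
                              n_null=p.get("n_null", 5000), seed=p["seed"])
        pd.DataFrame([{"observed": r.observed, "null_mean": r.null_mean,
                       "null_var": r.null_var, "ses": r.ses,
                       "p_upper": r.p_upper, "p_lower": r.p_lower,
                       "n_null": r.n_null}]).to_csv(
            run_dir / "cooccurrence.csv", index=False)
    elif stage == "envmodel":
        sites = assemble_sites(state["grid"], state["env"])
        candidates = p.get("candidates") or [c for c in sites.columns
                                             if c not in ("longitude", "latitude",
                                                          "richness")]
        ols = forward_stepwise(sites, candidates)
        rows = [{"term": t, "ols_coeff": ols.params[t], "std_error": ols.bse[t],
                 "p": ols.pvalues[t]} for t in ols.params.index]
        if p.get("sar", True) and ols.covariates:
            w = build_weights(state["grid"], row_standardize=True)
            sar = sar_fit(sites, ols.covariates, w)
            for row in rows:
                row["sar_coeff"] = sar.params.get(row["term"], np.nan)
            meta = {"ols_r2": ols.r2, "ols_aicc": ols.aicc, "sar_r2": sar.r2,
                    "sar_aicc": sar.aicc, "sar_lambda": sar.lambda_}
        else:
            meta = {"ols_r2": ols.r2, "ols_aicc": ols.aicc}
        pd.DataFrame(rows).to_csv(run_dir / "envmodel_terms.csv", index=False)
        (run_dir / "envmodel_fit.json").write_text(json.dumps(meta, indent=1))
        env_rows = []
        for cov in (ols.covariates or candidates[:1]):
            q = quantile_envelope(sites[cov].to_numpy(),
                                  sites["richness"].to_numpy(dtype=float),
                                  taus=tuple(p.get("taus", (0.01, 0.99))),
                                  n_boot=p.get("n_boot", 1000), seed=p["seed"])
            for tau in q.taus:
                env_rows.append({"covariate": cov, "tau": tau,
                                 "slope": q.slopes[tau],
                                 "intercept": q.intercepts[tau],
                                 "p": q.p_values[tau], "rho": q.pearson_rho})
        pd.DataFrame(env_rows).to_csv(run_dir / "envelopes.csv", index=False)
    elif stage == "biogeo":
        from .synthetic_data import simulate_tree
        seed = p["seed"]
        areas = tuple(p.get("areas", ("A", "B", "C", "D")))
        tree = simulate_tree(p.get("n_tips", 20), seed=seed)
        hist = simulate_dec(tree, p.get("d", 0.1), p.get("e", 0.02),
                            p.get("j", 0.0), areas,
                            p.get("root_range", areas[1]), seed=seed)
        write_tree(tree, run_dir / "tree.nwk")
        write_coding(hist.coding, run_dir / "coding.csv")
        (run_dir / "history.json").write_text(json.dumps(hist.events, indent=1))
        fits = [fit_dec(tree, hist.coding, m)
                for m in p.get("models", ("DEC", "DEC+j"))]
        compare_models(fits).to_csv(run_dir / "dec_models.csv", index=False)
        best = min(fits, key=lambda f: f.aic)
        summary = bsm(tree, hist.coding, best, n_maps=p.get("n_maps", 200),
                      seed=seed + 1)
        summary.dispersal.to_csv(run_dir / "bsm_dispersal.csv")
        (run_dir / "bsm_totals.json").write_text(
            json.dumps(summary.event_totals, indent=1))
    else:  # pragma: no cover
        raise ConfigError(f"unknown stage {stage!r}")


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.version_option(__version__, message="\n".join(
    ["macrorich %(version)s"] + [f"  {k}: {v}" for k, v in ALGORITHM_REGISTRY.items()]))
def main():
    """Species-richness macroecology & historical biogeography pipeline."""


@main.command()
@click.option("--config", "config_path", required=True,
              type=click.Path(exists=True))
@click.option("--out", "out_dir", default=None)
def run(config_path, out_dir):
    """Run the configured pipeline end to end."""
    cfg = PipelineConfig.from_yaml(config_path)
    run_dir = run_pipeline(cfg, out_dir)
    click.echo(f"run complete: {run_dir}")


@main.command()
@click.option("--ranges", "ranges_dir", required=True, type=click.Path(exists=True))
@click.option("--cell-size", type=float, default=None)
@click.option("--out", required=True)
def richness(ranges_dir, cell_size, out):
    """Stack a range-set directory into a richness ESRI ASCII grid."""
    rs = read_ranges(ranges_dir)
    grid = regrid(rs, cell_size) if cell_size else stack_richness(rs)
    write_grid(grid, out)
    click.echo(f"richness grid written to {out}")


@main.command()
@click.option("--map-a", required=True, type=click.Path(exists=True))
@click.option("--map-b", required=True, type=click.Path(exists=True))
@click.option("--classes", type=int, default=10)
def kappa(map_a, map_b, classes):
    """Kappa agreement between two richness grids."""
    a, cs_a = read_grid(map_a)
    b, cs_b = read_grid(map_b)
    ga = RichnessGrid(np.nan_to_num(a).astype(int), cs_a, ~np.isnan(a))
    gb = RichnessGrid(np.nan_to_num(b).astype(int), cs_b, ~np.isnan(b))
    click.echo(f"kappa = {kappa_compare(ga, gb, classes):.6f}")


@main.command()
@click.option("--grid", "grid_path", required=True, type=click.Path(exists=True))
@click.option("--weights", "scheme", type=click.Choice(["queen", "rook"]),
              default="queen")
@click.option("--alpha", type=float, default=0.05)
@click.option("--correction", type=click.Choice(["fdr", "none"]), default="fdr")
@click.option("--out", required=True)
def hotspot(grid_path, scheme, alpha, correction, out):
    """Gi* hotspot delineation on a richness grid."""
    arr, cs = read_grid(grid_path)
    grid = RichnessGrid(np.nan_to_num(arr).astype(int), cs, ~np.isnan(arr))
    w = build_weights(grid, scheme=scheme, include_self=True)
    res = delineate_hotspots(getis_ord_gstar(grid.richness.astype(float), w),
                             w, alpha=alpha, correction=correction)
    pd.DataFrame({"cell": w.cell_ids,
                  "z": res.z_grid.flat[w.cell_ids],
                  "p": res.p_grid.flat[w.cell_ids],
                  "hot_cluster": res.hot_labels.flat[w.cell_ids],
                  "cold_cluster": res.cold_labels.flat[w.cell_ids]}).to_csv(
        out, index=False)
    click.echo(res.clusters.to_string(index=False))


@main.command()
@click.option("--matrix", "matrix_path", required=True, type=click.Path(exists=True))
@click.option("--index", default="all")
@click.option("--iters", type=int, default=10000)
@click.option("--seed", type=int, required=True)
@click.option("--order", type=click.Choice(["totals", "energy"]), default="totals")
@click.option("--energy-file", type=click.Path(exists=True), default=None)
@click.option("--out", required=True)
def nestedness(matrix_path, index, iters, seed, order, energy_file, out):
    """Nestedness indices with the fixed-rows/equiprobable-columns null."""
    pam = read_matrix(matrix_path)
    M = pam.matrix
    if order == "energy":
        if energy_file is None:
            raise click.UsageError("--order energy requires --energy-file")
        scores = pd.read_csv(energy_file).iloc[:, -1].to_numpy(dtype=float)
        from .nestedness import pack
        M = pack(M, external_site_scores=scores).matrix
    indices = ["T", "BR", "NODF", "NODFc", "NODFr"] if index == "all" else [index]
    rows = []
    for idx in indices:
        r = nestedness_test(M, idx, n_iter=iters, seed=seed)
        rows.append({"index": idx, "observed": r.observed,
                     "null_mean": r.null_mean, "ci_low": r.null_ci[0],
                     "ci_high": r.null_ci[1], "p": r.p})
    pd.DataFrame(rows).to_csv(out, index=False)
    click.echo(pd.DataFrame(rows).to_string(index=False))


@main.command()
@click.option("--matrix", "matrix_path", required=True, type=click.Path(exists=True))
@click.option("--nulls", type=int, default=50000)
@click.option("--seed", type=int, required=True)
@click.option("--out", required=True)
def cooccur(matrix_path, nulls, seed, out):
    """Checkerboard C-score SES test."""
    pam = read_matrix(matrix_path)
    r = cooccurrence_test(pam.matrix, n_null=nulls, seed=seed)
    df = pd.DataFrame([{"observed": r.observed, "null_mean": r.null_mean,
                        "null_var": r.null_var, "ses": r.ses,
                        "p_upper": r.p_upper, "p_lower": r.p_lower,
                        "n_null": r.n_null, "seed": seed}])
    df.to_csv(out, index=False)
    click.echo(df.to_string(index=False))


@main.command()
@click.option("--tree", "tree_path", required=True, type=click.Path(exists=True))
@click.option("--coding", "coding_path", required=True, type=click.Path(exists=True))
@click.option("--model", type=click.Choice(["dec", "decj", "both"]), default="both")
@click.option("--maps", type=int, default=0)
@click.option("--seed", type=int, default=None)
@click.option("--out", required=True)
def biogeo(tree_path, coding_path, model, maps, seed, out):
    """Fit DEC/DEC+j and optionally run stochastic mapping."""
    tree = read_tree(tree_path)
    coding = read_coding(coding_path, tree=tree)
    models = {"dec": ["DEC"], "decj": ["DEC+j"],
              "both": ["DEC", "DEC+j"]}[model]
    fits = [fit_dec(tree, coding, m) for m in models]
    table = compare_models(fits)
    table.to_csv(out, index=False)
    click.echo(table.to_string(index=False))
    if maps:
        if seed is None:
            raise click.UsageError("--maps requires --seed")
        best = min(fits, key=lambda f: f.aic)
        summary = bsm(tree, coding, best, n_maps=maps, seed=seed)
        disp_path = str(out) + ".dispersal.csv"
        summary.dispersal.to_csv(disp_path)
        click.echo(summary.dispersal.to_string())
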