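"""End-to-end pipeline: simulate → normalize → profile → RCCA → group test.

The stages are thin compositions of the library modules; each run writes its
tables plus a JSON manifest recording inputs, parameters, seed, version and
per-stage table shapes, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .datamodel import (
    AbundanceMatrix,
    EnvTable,
    LineageTable,
    write_abundance_table,
    write_env_table,
    write_lineage_table,
    write_module_map,
)
from .diffabund import compare_groups, comparisons_frame, split_by_salinity
from .profiles import (
    GenomeEquivalents,
    normalize_by_genome_equivalents,
    relative_abundance,
    write_annotation_table,
    write_genome_equivalents,
)
from .rcca import CVGrid, RCCAResult, biplot_data, fit_env_features
from .synthetic import (
    GradientSpec,
    PlantedTruth,
    generate_community,
    generate_environment,
    generate_functional_profile,
)

__all__ = ["GradientRun", "run_gradient", "write_rcca_outputs", "write_simulation"]

log = logging.getLogger("halocca")


@dataclass
class GradientRun:
    """Everything one simulated-gradient analysis produced."""

    spec: GradientSpec
    seed: int
    env: EnvTable
    taxa: AbundanceMatrix
    lineage: LineageTable
    truth: PlantedTruth
    annotations: pd.DataFrame
    modules_raw: AbundanceMatrix
    genome_equivalents: GenomeEquivalents
    modules_normalized: AbundanceMatrix
    result: RCCAResult
    cv: CVGrid | None


def run_gradient(
    spec: GradientSpec,
    seed: int,
    cv: bool = True,
    lambda_x: float | None = None,
    lambda_y: float | None = None,
) -> GradientRun:
    """Simulate one gradient and run the functional RCCA on it.

    Module counts are genome-equivalent normalized before the fit; the ridge
    pair is chosen by leave-one-out cross-validation unless given explicitly.
    """
    t0 = time.perf_counter()
    env = generate_environment(spec, seed)
    taxa, lineage, truth = generate_community(spec, env, seed)
    annotations, modules_raw, ge = generate_functional_profile(spec, taxa, truth)
    modules_norm = normalize_by_genome_equivalents(modules_raw, ge)
    result, cvgrid = fit_env_features(
        env, modules_norm, lambda_x=lambda_x, lambda_y=lambda_y, cv=cv
    )
    log.debug("gradient run seed=%d took %.2fs", seed, time.perf_counter() - t0)
    return GradientRun(
        spec=spec,
        seed=seed,
        env=env,
        taxa=taxa,
        lineage=lineage,
        truth=truth,
        annotations=annotations,
        modules_raw=modules_raw,
        genome_equivalents=ge,
        modules_normalized=modules_norm,
        result=result,
        cv=cvgrid,
    )


def write_simulation(run: GradientRun, outdir: str | Path) -> dict[str, list[int]]:
    """Write the simulated tables; returns per-file (rows, cols) shapes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_env_table(run.env, outdir / "env.tsv")
    write_abundance_table(run.taxa, outdir / "taxa_counts.tsv")
    write_annotation_table(run.annotations, outdir / "annotations.tsv")
    write_abundance_table(run.modules_raw, outdir / "modules.tsv")
    write_genome_equivalents(run.genome_equivalents, outdir / "genome_equivalents.tsv")
    write_lineage_table(run.lineage, outdir / "lineage.tsv")
    write_module_map(run.spec.module_map(), outdir / "module_map.tsv")
    truth = {
        "carriage": {
            t: [m for m in run.truth.carriage.columns if run.truth.carriage.at[t, m]]
            for t in run.truth.carriage.index
        },
        "expected_sign": run.truth.expected_sign,
        "niches": {
            t.name: {"mean": t.niche_mean, "sd": t.niche_sd, "genome_size": t.genome_size}
            for t in run.truth.taxa
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {
        "env.tsv": list(run.env.frame.shape),
        "taxa_counts.tsv": list(run.taxa.frame.shape),
        "annotations.tsv": list(run.annotations.shape),
        "modules.tsv": list(run.modules_raw.frame.shape),
        "genome_equivalents.tsv": [len(run.genome_equivalents.values), 1],
        "lineage.tsv": list(run.lineage.frame.shape),
    }


def write_rcca_outputs(
    result: RCCAResult, cv: CVGrid | None, outdir: str | Path
) -> dict[str, list[int]]:
    """Write rho/weights/variates/structure/biplot (and CV grid) TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    shapes: dict[str, list[int]] = {}
    rho = pd.DataFrame(
        {"variate": [f"CV{k + 1}" for k in range(result.n_variates)], "rho": result.rho}
    )
    rho.to_csv(outdir / "rho.tsv", sep="\t", index=False)
    shapes["rho.tsv"] = list(rho.shape)
    for name, frame in (
        ("weights_x", result.x_weights),
        ("weights_y", result.y_weights),
        ("variates_x", result.x_variates),
        ("variates_y", result.y_variates),
        ("structure_x", result.x_structure),
        ("structure_y", result.y_structure),
    ):
        frame.sort_index().to_csv(outdir / f"{name}.tsv", sep="\t")
        shapes[f"{name}.tsv"] = list(frame.shape)
    bp = biplot_data(result) if result.n_variates >= 2 else None
    if bp is not None:
        bp.to_csv(outdir / "biplot.tsv", sep="\t", index=False)
        shapes["biplot.tsv"] = list(bp.shape)
    if cv is not None:
        cv.frame.to_csv(outdir / "cv_grid.tsv", sep="\t", index=False)
        shapes["cv_grid.tsv"] = list(cv.frame.shape)
    return shapes


def run_all(
    spec: GradientSpec, seed: int, outdir: str | Path, threshold_psu: float = 10.0
) -> dict:
    """Full chain on a simulated gradient; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    t0 = time.perf_counter()
    run = run_gradient(spec, seed, cv=True)
    stages["simulate"] = {"files": write_simulation(run, outdir)}
    write_abundance_table(run.modules_normalized, outdir / "modules_normalized.tsv")
    stages["normalize"] = {
        "files": {"modules_normalized.tsv": list(run.modules_normalized.frame.shape)}
    }
    stages["rcca"] = {
        "files": write_rcca_outputs(run.result, run.cv, outdir),
        "lambda_x": run.result.lambda_x,
        "lambda_y": run.result.lambda_y,
        "rho1": float(run.result.rho[0]),
    }
    groups = split_by_salinity(run.env, threshold_psu=threshold_psu)
    props = relative_abundance(run.modules_raw)
    comparisons = comparisons_frame(compare_groups(props, groups))
    comparisons.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)
    stages["diff"] = {
        "files": {"comparisons.tsv": list(comparisons.shape)},
        "threshold_psu": threshold_psu,
    }
    manifest = {
        "version": __version__,
        "seed": seed,
        "parameters": {
            "n_samples": spec.n_samples,
            "salinity_range": [spec.salinity_min, spec.salinity_max],
            "read_depth": spec.read_depth,
            "dirichlet_concentration": spec.dirichlet_concentration,
            "n_taxa": len(spec.taxa),
            "n_modules": len(spec.modules),
        },
        "stages": stages,
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
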