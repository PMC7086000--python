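"""End-to-end orchestration: simulate -> infer -> group.

Each stage reads/writes plain delimited text and JSON under an output
directory and echoes its fully resolved configuration beside its outputs, so
a run is reproducible from the directory alone. Stages are independently
re-runnable; ``infer`` consumes the file dialects that ``simulate`` emits
(or equivalently prepared real data), and ``group`` consumes ``infer``'s
results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atrophy import VolumeTable, compute_control_stats, zscore_atrophy
from .connectome import average_connectomes, graph_laplacian, read_connectome
from .group import (fit_vs_time_since_injury, pca_predicted_maps,
                    peaktime_vs_time_since_injury)
from .inference import optimize_seed_combination, screen_single_seeds
from .ndm import all_seed_profiles
from .parcellation import Parcellation
from .synthetic import SyntheticCohortSpec, generate_cohort, write_cohort

log = logging.getLogger("netspread")


@dataclass
class PipelineConfig:
    """Resolved settings for a pipeline run; defaults are the analysis grid
    alpha = 0.25 on time indices 0..19 with max-weight Laplacian scaling."""

    data_dir: str = "cohort"
    output_dir: str = "results"
    alpha: float = 0.25
    n_timepoints: int = 20
    normalization: str = "max-weight-scaled"
    backward_prune: bool = True
    pca_components: int = 5
    rng_seed: int = 0
    simulate: dict = field(default_factory=dict)   # SyntheticCohortSpec overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def echo(self, outdir) -> None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        Path(outdir, "config_resolved.yaml").write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def run_simulate(config: PipelineConfig) -> dict:
    """Generate a synthetic cohort and write it to ``data_dir``."""
    overrides = dict(config.simulate)
    overrides.setdefault("rng_seed", config.rng_seed)
    overrides.setdefault("alpha", config.alpha)
    overrides.setdefault("n_timepoints", config.n_timepoints)
    spec = SyntheticCohortSpec(**overrides)
    cohort = generate_cohort(spec)
    manifest = write_cohort(cohort, config.data_dir)
    config.echo(config.data_dir)
    log.info("simulated cohort: %d controls, %d patients, %d regions",
             spec.n_controls, spec.n_patients, spec.n_regions)
    return manifest


def _load_inputs(config: PipelineConfig):
    data = Path(config.data_dir)
    manifest_path = data / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing cohort manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    files = manifest["files"]
    parc = Parcellation.read(data / files["parcellation"])
    for key in ("control_volumes", "patient_volumes", "covariates"):
        if not (data / files[key]).exists():
            raise FileNotFoundError(f"missing input file: {data / files[key]}")
    conns = [read_connectome(data / f, parc) for f in files["control_connectomes"]]
    controls = VolumeTable.read(data / files["control_volumes"], parc)
    patients = VolumeTable.read(data / files["patient_volumes"], parc)
    from ._io import read_delimited
    covars = read_delimited(data / files["covariates"], index_col=0)
    return parc, conns, controls, patients, covars


def run_infer(config: PipelineConfig) -> pd.DataFrame:
    """Infer per-patient epicenters; write summary table and result records."""
    parc, conns, controls, patients, _ = _load_inputs(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timepoints = tuple(range(config.n_timepoints))

    lap = graph_laplacian(average_connectomes(conns), config.normalization)
    stats = compute_control_stats(controls)
    profiles = all_seed_profiles(lap, config.alpha, timepoints)

    rows, records, predicted = [], [], []
    for sid, volumes in zip(patients.subjects, patients.volumes):
        try:
            amap = zscore_atrophy(volumes, stats)
            screen = screen_single_seeds(profiles, amap)
            res = optimize_seed_combination(lap, screen, amap, config.alpha,
                                            timepoints,
                                            backward_prune=config.backward_prune)
        except Exception as exc:
            raise RuntimeError(f"inference failed for {sid}: {exc}") from exc
        names = [parc.region_names[i] for i in res.seed_indices]
        rows.append({"subject": sid, "n_seeds": len(names), "t_max": res.t_max,
                     "r_best": res.r_best, "r_squared": res.r_squared})
        records.append({"subject": sid, "epicenters": names,
                        "seed_indices": list(res.seed_indices),
                        "t_max": res.t_max, "r_best": res.r_best,
                        "r_squared": res.r_squared,
                        "search_trace": [[list(s), int(t), float(r)]
                                         for s, t, r in res.search_trace]})
        predicted.append(res.predicted)
        log.info("%s: %d seeds, t_max=%d, r=%.3f", sid, len(names), res.t_max, res.r_best)
        log.debug("%s search trace: %s", sid, res.search_trace)

    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "epicenters_summary.csv", index=False)
    (outdir / "epicenters.json").write_text(json.dumps(records, indent=2) + "\n")
    pd.DataFrame(np.array(predicted), index=list(patients.subjects),
                 columns=parc.region_names) \
        .to_csv(outdir / "predicted_atrophy.csv", index_label="subject")
    config.echo(outdir)
    return summary


def run_group(config: PipelineConfig) -> dict:
    """PCA of predicted maps plus fit/peak-time vs. time-since-injury."""
    parc, _, _, patients, covars = _load_inputs(config)
    outdir = Path(config.output_dir)
    pred_path = outdir / "predicted_atrophy.csv"
    summary_path = outdir / "epicenters_summary.csv"
    if not pred_path.exists() or not summary_path.exists():
        raise FileNotFoundError("inference results not found; run infer first")
    from ._io import read_delimited
    pred = read_delimited(pred_path, index_col=0)
    summary = pd.read_csv(summary_path, index_col=0)
    if len(summary) < 4:
        raise ValueError("need at least 4 patients for association analyses")

    k = min(config.pca_components, len(pred) - 1, pred.shape[1])
    pca = pca_predicted_maps(pred.to_numpy(), k=k)
    pd.DataFrame(pca.components, index=[f"PC{i+1}" for i in range(k)],
                 columns=parc.region_names) \
        .to_csv(outdir / "pca_loadings.csv", index_label="component")
    pd.DataFrame({"component": [f"PC{i+1}" for i in
                                range(len(pca.explained_variance_fraction))],
                  "explained_variance_fraction": pca.explained_variance_fraction}) \
        .to_csv(outdir / "pca_explained_variance.csv", index=False)

    tsi = covars.loc[list(summary.index), "tsi_years"].to_numpy()
    age = covars.loc[list(summary.index), "age_years"].to_numpy()

    class _Row:                      # adapt summary rows to result objects
        def __init__(self, r):
            self.r_squared = r.r_squared
            self.t_max = r.t_max

    results = [_Row(r) for r in summary.itertuples()]
    fit_assoc = fit_vs_time_since_injury(results, tsi, age)
    try:
        peak_assoc = peaktime_vs_time_since_injury(results, tsi)
        peak = {"r": peak_assoc.r, "p_value": peak_assoc.p_value, "n": peak_assoc.n}
    except ValueError as exc:
        peak = {"r": None, "p_value": None, "n": len(results),
                "undefined_reason": str(exc)}
    report = {
        "pca_explained_variance_fraction": [float(v) for v in
                                            pca.explained_variance_fraction],
        "pca_components_reported": k,
        "fit_vs_tsi": {"r": fit_assoc.r, "p_value": fit_assoc.p_value,
                       "n": fit_assoc.n, "covariates": list(fit_assoc.covariates)},
        "peaktime_vs_tsi": peak,
    }
    (outdir / "group_analysis.json").write_text(json.dumps(report, indent=2) + "\n")
    config.echo(outdir)
    return report
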