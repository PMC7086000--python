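"""Synthetic cohorts with known ground-truth injury epicenters.

The generator emulates the study design this pipeline targets: a modular
weighted connectome (stochastic block model with log-normal streamline-count
weights), a small healthy-control cohort defining per-region volume norms,
and patients whose regional volume deficits are produced by forward network
diffusion from known seed regions plus Gaussian noise. Because the
generating process is exactly the analysis model, noise-free cohorts give a
sharp oracle: inference must recover the true seeds, t_max must equal the
generating diffusion time and the fit correlation must reach 1.

Defaults mirror the target study conditions: 82 regions, 19 controls,
17 patients, one seed per patient spreading to time index 7 on the 0..19
grid with alpha = 0.25, patient volume noise of 0.1 control SDs. Control
volumes use multiplicative noise standardized to exact per-region sample
moments so that sigma_i is exactly proportional to mu_i — this keeps the
noise-free patient round-trip exact (measured atrophy a positive rescaling
of the generating diffusion pattern). Everything is reproducible from
``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import connected_components

from .atrophy import ControlStats, VolumeTable, compute_control_stats
from .connectome import Connectome, graph_laplacian, write_connectome
from .ndm import DEFAULT_ALPHA, simulate_diffusion
from .parcellation import Parcellation

_MAX_CONNECTIVITY_RETRIES = 50


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study-condition parameters for cohort generation.

    noise_sd is the per-region patient volume noise in control-SD units
    (z-score perturbation magnitude); control_noise_sd is the fractional
    between-subject spread of control volumes; atrophy_gain is the maximal
    fractional volume loss in the most affected region.
    """

    n_regions: int = 82
    n_modules: int = 4
    intra_module_density: float = 0.6
    inter_module_density: float = 0.1
    weight_scale: float = 50.0
    weight_sigma_log: float = 0.8
    n_controls: int = 19
    n_patients: int = 17
    true_seeds_per_patient: int = 1
    true_time: int = 7
    alpha: float = DEFAULT_ALPHA
    n_timepoints: int = 20
    atrophy_gain: float = 0.2
    noise_sd: float = 0.1
    control_noise_sd: float = 0.1
    connectome_jitter: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.intra_module_density <= 1 and 0 < self.inter_module_density <= 1):
            raise ValueError("densities must lie in (0, 1]")
        for name in ("n_regions", "n_modules", "n_controls", "n_patients",
                     "true_seeds_per_patient", "n_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.atrophy_gain >= 1:
            raise ValueError("atrophy_gain >= 1 would produce non-positive volumes")
        if not 0 < self.true_time < self.n_timepoints - 1:
            raise ValueError("true_time must be interior to the analysis time grid")
        if self.noise_sd < 0 or self.control_noise_sd < 0 or self.weight_sigma_log < 0:
            raise ValueError("noise levels invalid")


@dataclass(frozen=True)
class GroundTruth:
    """What was actually injected into one synthetic patient."""

    seeds: tuple               # true seed region indices
    true_time: int
    noise_seed: int
    generating_atrophy: np.ndarray   # noise-free measured-atrophy vector


@dataclass(frozen=True)
class SyntheticCohort:
    spec: SyntheticCohortSpec
    parcellation: Parcellation
    control_connectomes: list
    template_connectome: Connectome
    control_volumes: VolumeTable
    patient_volumes: VolumeTable
    truths: list
    tsi: np.ndarray            # years since injury per patient
    age: np.ndarray            # age at scan per patient

    @property
    def average_connectome(self) -> Connectome:
        from .connectome import average_connectomes
        return average_connectomes(self.control_connectomes)


def _standardized_noise(rng, shape) -> np.ndarray:
    """iid normal noise with exact per-column sample mean 0 and sample SD 1."""
    e = rng.standard_normal(shape)
    e = e - e.mean(axis=0)
    sd = e.std(axis=0, ddof=1)
    return e / sd


def generate_connectome(spec: SyntheticCohortSpec, rng=None) -> Connectome:
    """Weighted stochastic-block-model connectome, connected by construction.

    Edges are sampled per intra/inter-module density; weights are log-normal
    (right-skewed, like streamline counts) with mean ``weight_scale``.
    Regeneration is retried up to a bound if the realized graph is
    disconnected.
    """
    rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
    n = spec.n_regions
    modules = np.arange(n) % spec.n_modules
    sigma_log = spec.weight_sigma_log
    mu_log = np.log(spec.weight_scale) - sigma_log ** 2 / 2.0
    iu = np.triu_indices(n, k=1)
    same = modules[iu[0]] == modules[iu[1]]
    dens = np.where(same, spec.intra_module_density, spec.inter_module_density)
    for _ in range(_MAX_CONNECTIVITY_RETRIES):
        present = rng.random(len(dens)) < dens
        w = np.where(present, rng.lognormal(mu_log, sigma_log, len(dens)), 0.0)
        W = np.zeros((n, n))
        W[iu] = w
        W = W + W.T
        ncomp, _ = connected_components(W > 0, directed=False)
        if ncomp == 1:
            return Connectome(W, Parcellation.generic(n))
    raise RuntimeError("could not generate a connected graph within the retry bound")


def generate_controls(spec: SyntheticCohortSpec, connectome: Connectome,
                      rng=None) -> VolumeTable:
    """Control regional volumes: log-normal baselines, multiplicative noise.

    Noise columns are standardized so the realized per-region sample mean is
    exactly the baseline and the sample SD exactly control_noise_sd x
    baseline — the z-scoring reference is then analytically known.
    """
    rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
    n = connectome.n_regions
    baseline = rng.lognormal(np.log(6000.0), 0.5, n)   # mm^3-scale region volumes
    if spec.n_controls >= 2:
        eta = _standardized_noise(rng, (spec.n_controls, n))
    else:
        eta = np.zeros((1, n))
    V = baseline[None, :] * (1.0 + spec.control_noise_sd * eta)
    subjects = tuple(f"control_{i:02d}" for i in range(spec.n_controls))
    return VolumeTable(subjects, V, connectome.parcellation)


def generate_patient(spec: SyntheticCohortSpec, connectome: Connectome,
                     control_stats: ControlStats, seeds, noise_seed: int,
                     laplacian=None):
    """One patient volume vector plus its ground truth.

    Pathology g diffuses from the seed indicator to ``true_time``; regional
    volume is mu * (1 - atrophy_gain * g / max(g)) + sigma * eps with
    eps ~ N(0, noise_sd). With noise_sd = 0 the measured atrophy recovered
    by z-scoring equals the recorded generating pattern exactly.
    """
    seeds = tuple(int(s) for s in seeds)
    n = connectome.n_regions
    if not seeds or any(not 0 <= s < n for s in seeds):
        raise ValueError("true seeds must be a non-empty set of valid region indices")
    lap = laplacian if laplacian is not None else graph_laplacian(connectome)
    f0 = np.zeros(n)
    f0[list(seeds)] = 1.0
    g = simulate_diffusion(lap, f0, spec.alpha, (spec.true_time,)).values[:, 0]
    loss = spec.atrophy_gain * g / np.max(g)
    rng = np.random.default_rng(noise_seed)
    eps = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.zeros(n)
    volumes = control_stats.mu * (1.0 - loss) + control_stats.sigma * eps
    if np.any(volumes <= 0):
        raise ValueError("generated non-positive volume; reduce atrophy_gain or noise")
    generating_atrophy = control_stats.mu * loss / control_stats.sigma
    truth = GroundTruth(seeds, spec.true_time, noise_seed, generating_atrophy)
    return volumes, truth


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Full bundle: per-control connectomes, volume tables, truths, covariates.

    Per-control connectomes are small multiplicative jitters of one template
    so that control averaging is exercised; patient time-since-injury is
    uniform on [1, 5] years and age at scan uniform on [10, 17] years,
    independent of the injected pathology.
    """
    rng = np.random.default_rng(spec.rng_seed)
    template = generate_connectome(spec, rng)
    n = spec.n_regions

    control_connectomes = []
    iu = np.triu_indices(n, k=1)
    for _ in range(spec.n_controls):
        jit = np.zeros((n, n))
        jit[iu] = rng.normal(0.0, spec.connectome_jitter, len(iu[0]))
        jit = jit + jit.T
        W = template.weights * np.clip(1.0 + jit, 0.0, None)
        control_connectomes.append(Connectome(W, template.parcellation))

    controls = generate_controls(spec, template, rng)
    stats = compute_control_stats(controls)

    from .connectome import average_connectomes
    lap = graph_laplacian(average_connectomes(control_connectomes))

    truths, rows = [], []
    for p in range(spec.n_patients):
        seeds = rng.choice(n, size=spec.true_seeds_per_patient, replace=False)
        noise_seed = int(rng.integers(0, 2 ** 31 - 1))
        volumes, truth = generate_patient(spec, template, stats,
                                          tuple(int(s) for s in seeds),
                                          noise_seed, laplacian=lap)
        truths.append(truth)
        rows.append(volumes)
    patient_table = VolumeTable(tuple(f"patient_{i:02d}" for i in range(spec.n_patients)),
                                np.array(rows), template.parcellation)
    tsi = rng.uniform(1.0, 5.0, spec.n_patients)
    age = rng.uniform(10.0, 17.0, spec.n_patients)
    return SyntheticCohort(spec, template.parcellation, control_connectomes,
                           template, controls, patient_table, truths, tsi, age)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write the cohort in the exact file dialects the pipeline consumes.

    Returns the manifest (also written as ``manifest.json``), which records
    file paths, spec parameters and the per-patient ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.parcellation.write(outdir / "parcellation.tsv")
    conn_files = []
    for i, conn in enumerate(cohort.control_connectomes):
        f = f"connectome_control_{i:02d}.csv"
        write_connectome(conn, outdir / f)
        conn_files.append(f)
    cohort.control_volumes.write(outdir / "volumes_controls.csv")
    cohort.patient_volumes.write(outdir / "volumes_patients.csv")
    cov_lines = ["subject,tsi_years,age_years"]
    for sid, t, a in zip(cohort.patient_volumes.subjects, cohort.tsi, cohort.age):
        cov_lines.append(f"{sid},{t:.6f},{a:.6f}")
    (outdir / "covariates.csv").write_text("\n".join(cov_lines) + "\n")
    manifest = {
        "spec": asdict(cohort.spec),
        "files": {
            "parcellation": "parcellation.tsv",
            "control_connectomes": conn_files,
            "control_volumes": "volumes_controls.csv",
            "patient_volumes": "volumes_patients.csv",
            "covariates": "covariates.csv",
        },
        "ground_truth": [
            {"subject": sid,
             "seed_indices": list(tr.seeds),
             "seed_regions": [cohort.parcellation.region_names[s] for s in tr.seeds],
             "true_time": tr.true_time,
             "noise_seed": tr.noise_seed}
            for sid, tr in zip(cohort.patient_volumes.subjects, cohort.truths)
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
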