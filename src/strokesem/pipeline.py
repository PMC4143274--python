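"""End-to-end orchestration on synthetic subjects.

A run simulates a cohort table from a path model, renders each subject as a
multimodal phantom whose planted white-matter lesion load and white-matter
diffusivity follow that subject's simulated values, then recovers everything
through the measurement chain — tensor fit, diffusivity maps, tissue
segmentation, per-tissue summaries, the integrity factor — and finally fits
the competing path models to the measured cohort covariance.

Per-subject failures are isolated: a subject whose inputs cannot be processed
is excluded with a named reason and the run continues. All intermediates are
written as standard formats (uncompressed NIfTI, CSV, JSON) and every output
file is checksummed, so a rerun with the same config and seed is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import labels as L
from .cohort import CohortModelSpec, simulate_cohort
from .dti import diffusivity_maps, fit_tensor
from .integrity import integrity_scores
from .phantom import DEFAULT_TENSOR_PROFILES, Lesion, Phantom, PhantomSpec, make_phantom
from .segment import SegmentationConfig, segment_subject, summarize_tissues
from .sem import PathModelSpec, compare_models, fit_ml, model_with_ilv, model_without_ilv
from .stats import log_transform_volumes

__all__ = ["PipelineConfig", "run_pipeline", "default_cohort_spec", "render_subject"]

# Standardized path weights used for the default simulated cohort: age drives
# lesion load and (inverse) white-matter integrity, which with education
# drive the one-year cognitive score.
DEFAULT_PATHS = {
    ("age", "wml"): 0.306,
    ("age", "nawm_integrity"): 0.370,
    ("wml", "cognition"): -0.231,
    ("nawm_integrity", "cognition"): -0.176,
    ("education", "cognition"): 0.328,
}


def default_cohort_spec(n_subjects: int, seed: int) -> CohortModelSpec:
    return CohortModelSpec(
        n_subjects=n_subjects,
        variables=("age", "education", "wml", "nawm_integrity", "cognition"),
        path_coefficients=dict(DEFAULT_PATHS),
        exogenous_correlations={("age", "education"): -0.10},
        seed=seed,
    )


@dataclass
class PipelineConfig:
    out_dir: Path
    n_subjects: int = 12
    grid_shape: tuple[int, int, int] = (40, 40, 32)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    noise_sigma: float = 2.0
    noise_model: str = "gaussian"
    segmentation: SegmentationConfig = field(
        default_factory=lambda: SegmentationConfig(min_lesion_voxels=2)
    )
    cohort_spec: CohortModelSpec | None = None
    models: dict[str, PathModelSpec] | None = None
    infarct_fraction: float = 0.65
    save_volumes: bool = True
    seed: int = 0
    # fault-injection / override hook: subject index -> phantom transformer
    perturb: dict[int, Callable[[Phantom], Phantom]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)


def _lesion_set(
    spec_grid: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    wml_rel_pct: float,
    ischemic_rel_pct: float,
    icv_mm3: float,
) -> tuple[Lesion, ...]:
    """Spheres realizing the target relative lesion volumes.

    WML load is split across up to three fixed deep-white-matter sites along
    +x/-x/+y; the acute lesion sits on -y. Radii follow from the target
    volume; the largest per-site radius is capped so spheres stay inside the
    brain and never overlap.
    """
    shape = np.asarray(spec_grid, dtype=float)
    vox = np.asarray(voxel_size, dtype=float)
    center = (shape - 1) / 2.0
    axes_vox = 0.94 * (shape - 1) / 2.0  # voxel units, matches PhantomSpec default
    sites = [(0.5, 0, 0), (-0.5, 0, 0), (0, 0.5, 0)]
    max_r_mm = 0.30 * float(np.min(axes_vox * vox))

    lesions: list[Lesion] = []
    remaining = max(wml_rel_pct, 0.0) / 100.0 * icv_mm3
    for site in sites:
        if remaining <= 0:
            break
        vol = min(remaining, 4.0 / 3.0 * np.pi * max_r_mm**3)
        r = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        if r < float(np.max(vox)):  # sub-voxel leftovers are not plantable
            break
        c = center + np.asarray(site) * axes_vox
        lesions.append(Lesion("wml", tuple(int(round(x)) for x in c), float(r)))
        remaining -= vol
    if ischemic_rel_pct > 0:
        vol = ischemic_rel_pct / 100.0 * icv_mm3
        r = min((3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0), max_r_mm)
        if r >= float(np.max(vox)):
            c = center + np.asarray([0, -0.55, 0]) * axes_vox
            lesions.append(Lesion("ischemic", tuple(int(round(x)) for x in c), float(r)))
    return tuple(lesions)


def render_subject(
    cfg: PipelineConfig, row: pd.Series, subject_seed: int
) -> PhantomSpec:
    """Phantom spec for one simulated subject.

    The subject's standardized WML burden maps to a relative lesion volume
    around 1.3% of ICV; the integrity score scales the white-matter
    eigenvalues (worse integrity = higher diffusivity).
    """
    # ellipsoid ICV estimate for target volumes
    shape = np.asarray(cfg.grid_shape, dtype=float)
    vox = np.asarray(cfg.voxel_size, dtype=float)
    axes_mm = 0.94 * (shape - 1) / 2.0 * vox
    icv = 4.0 / 3.0 * np.pi * float(np.prod(axes_mm))

    wml_rel = float(np.clip(1.3 + 0.9 * row["wml"], 0.2, 3.0))
    isch_rel = float(np.clip(0.35 + 0.15 * row.get("ilv_latent", 0.0), 0.1, 1.2)) if row[
        "has_infarct"
    ] else 0.0
    profiles = dict(DEFAULT_TENSOR_PROFILES)
    base, sd = profiles[L.NAWM]
    scale = 1.0 + 0.06 * float(row["nawm_integrity"])
    profiles[L.NAWM] = (tuple(v * scale for v in base), sd)
    return PhantomSpec(
        grid_shape=cfg.grid_shape,
        voxel_size=cfg.voxel_size,
        lesions=_lesion_set(cfg.grid_shape, cfg.voxel_size, wml_rel, isch_rel, icv),
        tensor_profiles=profiles,
        noise_model=cfg.noise_model,
        noise_sigma=cfg.noise_sigma,
        seed=subject_seed,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full chain; returns (and writes) the run report."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    written: list[Path] = []

    cohort_spec = cfg.cohort_spec or default_cohort_spec(cfg.n_subjects, cfg.seed)
    table = simulate_cohort(cohort_spec)
    table["has_infarct"] = rng.random(len(table)) < cfg.infarct_fraction
    table["ilv_latent"] = rng.normal(size=len(table))
    locs = np.array(["cortical", "subcortical", "subtentorial"])
    table["infarct_location"] = np.where(
        table["has_infarct"], rng.choice(locs, size=len(table), p=[0.33, 0.52, 0.15]), "none"
    )
    subject_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=len(table))]

    rows, excluded = [], []
    for i in range(len(table)):
        sid = f"sub-{i:03d}"
        try:
            phantom = make_phantom(render_subject(cfg, table.iloc[i], subject_seeds[i]))
            if i in cfg.perturb:
                phantom = cfg.perturb[i](phantom)
            tensor = fit_tensor(phantom.dwi_series, phantom.brain_mask)
            maps = diffusivity_maps(tensor)
            seg = segment_subject(
                phantom.flair, phantom.dwi_b1000, maps, phantom.brain_mask, cfg.segmentation
            )
            summary = summarize_tissues(seg, maps)
            nawm = seg.mask(L.NAWM) & tensor.valid_mask
            lam = tensor.eigenvalues[nawm].mean(axis=0)
            rows.append(
                {
                    "subject": sid,
                    "age": table.iloc[i]["age"],
                    "education": table.iloc[i]["education"],
                    "cognition": table.iloc[i]["cognition"],
                    "has_infarct": bool(table.iloc[i]["has_infarct"]),
                    "infarct_location": table.iloc[i]["infarct_location"],
                    "icv_mm3": seg.icv_mm3,
                    "wml_volume_mm3": summary.loc["wml", "volume_mm3"],
                    "wml_relative_pct": summary.loc["wml", "relative_volume_pct"],
                    "ischemic_volume_mm3": summary.loc["ischemic", "volume_mm3"],
                    "ischemic_relative_pct": summary.loc["ischemic", "relative_volume_pct"],
                    "nawm_fa": summary.loc["nawm", "mean_fa"],
                    "nawm_md": summary.loc["nawm", "mean_md"],
                    "nawm_l1": lam[0],
                    "nawm_l2": lam[1],
                    "nawm_l3": lam[2],
                }
            )
            if cfg.save_volumes:
                sdir = out / sid
                written.append(phantom.flair.save(sdir / "flair.nii"))
                written.append(phantom.truth.save(sdir / "truth.nii"))
                written.append(seg.labels.save(sdir / "labels.nii"))
                summary.to_csv(sdir / "tissue_summary.csv")
                written.append(sdir / "tissue_summary.csv")
        except Exception as err:  # isolate per-subject failures
            excluded.append({"subject": sid, "reason": str(err)})

    measured = pd.DataFrame(rows).set_index("subject")
    report: dict = {
        "subjects_in": int(len(table)),
        "subjects_analyzed": int(len(measured)),
        "subjects_excluded": excluded,
        "seed": cfg.seed,
    }
    sem_results = {}
    if len(measured) >= 8:
        factor = integrity_scores(measured)
        measured["nawm_integrity"] = factor.scores
        measured = log_transform_volumes(
            measured,
            columns=("wml_volume_mm3", "ischemic_volume_mm3"),
            epsilon=float(np.prod(cfg.voxel_size)),
        )
        sem_table = pd.DataFrame(
            {
                "age": measured["age"],
                "education": measured["education"],
                "wml": measured["wml_volume_mm3_log10"],
                "nawm_integrity": measured["nawm_integrity"],
                "ilv": measured["ischemic_volume_mm3_log10"],
                "cognition": measured["cognition"],
            }
        )
        models = cfg.models or {"model_1": model_with_ilv(), "model_2": model_without_ilv()}
        fits = {}
        for name, spec in models.items():
            S = sem_table[list(spec.variables)].cov()
            fit = fit_ml(spec, S, n=len(sem_table))
            fits[name] = fit
            sem_results[name] = {
                "converged": fit.converged,
                "df": fit.df,
                "chi2": fit.chi2,
                "std_coefficients": {f"{a}->{b}": v for (a, b), v in fit.std_coefficients.items()},
                **{k: fit.indices[k] for k in ("cfi", "gfi", "agfi", "rmsea", "p_value")},
            }
        if len(fits) == 2:
            names = tuple(fits)
            sem_results["comparison"] = compare_models(fits[names[0]], fits[names[1]], names)
    report["sem"] = sem_results

    cohort_path = out / "cohort.csv"
    measured.to_csv(cohort_path)
    written.append(cohort_path)
    report["checksums"] = {str(p.relative_to(out)): _sha256(p) for p in sorted(written)}
    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    return report
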