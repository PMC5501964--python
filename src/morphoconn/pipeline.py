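"""End-to-end orchestration: volumes -> regional PDFs -> MC -> associations.

The pipeline consumes preprocessed gray-matter density volumes (one NIfTI
per subject), a shared-grid parcellation, and a behavioral table, and writes
a run directory containing the tidy MC table, the total-score association
scan, subscale scans for every connection passing FDR, mediation results,
a manifest with every parameter needed to re-run, and a log.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mc import MCParams, compute_mc_profile, profiles_to_frame
from .stats import (
    SUBSCALE_COLUMNS,
    associations_to_frame,
    mediate,
    run_association_scan,
)
from .volume_io import read_gm_volume, read_parcellation, smooth_gaussian

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run (YAML-serializable)."""

    volumes: str = ""                # glob for per-subject GM NIfTI files
    atlas: str = ""
    roi_table: str = ""
    behavior: str = ""
    out_dir: str = "morphoconn_run"
    grid_size: int = 256
    density_floor: float = 1e-10
    inclusion_threshold: float = 0.0
    fwhm_mm: float | None = None     # optional pre-smoothing, mm FWHM
    outcome: str = "bis_total"
    covariates: tuple[str, ...] = ("age", "sex")
    alpha: float = 0.05
    fdr_scope: str = "hemisphere"
    all_subscales: bool = False      # scan subscales for every connection
    n_boot: int = 5000
    rng_seed: int = 0
    skip_failed: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        self.covariates = tuple(self.covariates)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat: dict = {}
        for section in ("paths", "mc", "stats"):
            flat.update(raw.pop(section, {}) or {})
        flat.update(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def mc_params(self) -> MCParams:
        return MCParams(self.grid_size, self.density_floor, self.inclusion_threshold)


def _subject_id_from_path(path: str) -> str:
    stem = Path(path).name.split(".")[0]
    return stem[:-3] if stem.endswith("_gm") else stem


def validate_inputs(config: RunConfig) -> list[str]:
    """Itemized pre-flight checks; an empty list means the run can proceed."""
    issues: list[str] = []
    vol_paths = sorted(glob.glob(config.volumes)) if config.volumes else []
    if not vol_paths:
        issues.append(f"no volumes match glob {config.volumes!r}")
    for p in (config.atlas, config.roi_table, config.behavior):
        if not p or not Path(p).exists():
            issues.append(f"missing input file: {p!r}")
    if issues:
        return issues

    try:
        parc = read_parcellation(config.atlas, config.roi_table)
    except ValueError as exc:
        return [f"atlas/ROI-table inconsistency: {exc}"]
    behavior = pd.read_csv(config.behavior)
    needed = {"subject_id", config.outcome, *config.covariates, *SUBSCALE_COLUMNS}
    for col in sorted(needed):
        if col not in behavior.columns:
            issues.append(f"behavior table lacks column {col!r}")

    beh_ids = set(behavior["subject_id"].astype(str)) if "subject_id" in behavior else set()
    for p in vol_paths:
        vol = read_gm_volume(p, _subject_id_from_path(p))
        if vol.shape != parc.shape:
            issues.append(
                f"grid mismatch for {p}: volume {vol.shape} vs atlas {parc.shape}"
            )
        if beh_ids and vol.subject_id not in beh_ids:
            issues.append(f"volume subject {vol.subject_id!r} absent from behavior table")
    return issues


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Deterministic given ``config.rng_seed`` (the only stochastic stage is the
    mediation bootstrap).  A subject failing extraction aborts the run with a
    named error unless ``config.skip_failed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("morphoconn")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> Path:
    issues = validate_inputs(config)
    if issues:
        raise ValueError("input validation failed:\n  " + "\n  ".join(issues))

    parc = read_parcellation(config.atlas, config.roi_table)
    behavior = pd.read_csv(config.behavior)
    behavior["subject_id"] = behavior["subject_id"].astype(str)
    params = config.mc_params()

    profiles = []
    failed: list[str] = []
    for path in sorted(glob.glob(config.volumes)):
        vol = read_gm_volume(path, _subject_id_from_path(path))
        if config.fwhm_mm:
            vol = smooth_gaussian(vol, config.fwhm_mm)
        try:
            profiles.extend(compute_mc_profile(vol, parc, params))
        except ValueError as exc:
            if not config.skip_failed:
                raise
            logger.warning("skipping subject %s: %s", vol.subject_id, exc)
            failed.append(vol.subject_id)
    if failed:
        behavior = behavior[~behavior["subject_id"].isin(failed)]

    mc_frame = profiles_to_frame(profiles, parc)
    mc_frame.to_csv(out / "mc.csv", index=False)
    logger.info("computed MC for %d subject-hemispheres", len(profiles))

    roi_names = dict(zip(parc.roi_table["id"].astype(int), parc.roi_table["name"]))
    scan = run_association_scan(
        profiles, behavior,
        outcome=config.outcome,
        covariate_columns=config.covariates,
        alpha=config.alpha,
        fdr_scope=config.fdr_scope,
        roi_names=roi_names,
    )
    assoc_frame = associations_to_frame(scan)
    assoc_frame.to_csv(out / "associations.csv", index=False)

    significant = [res for res in scan if res.q < config.alpha]
    logger.info(
        "%d / %d connections pass FDR at alpha=%.3g", len(significant), len(scan), config.alpha
    )

    # subscale scans: by default only for connections surviving the
    # total-score FDR (two-stage logic); --all-subscales scans everything
    focus = scan if config.all_subscales else significant
    sub_rows = []
    for subscale in SUBSCALE_COLUMNS:
        sub_scan = run_association_scan(
            profiles, behavior,
            outcome=subscale,
            covariate_columns=config.covariates,
            alpha=config.alpha,
            fdr_scope=config.fdr_scope,
            roi_names=roi_names,
        )
        keep = {(res.hemisphere, res.target_roi) for res in focus}
        for res in sub_scan:
            if (res.hemisphere, res.target_roi) in keep:
                row = associations_to_frame([res]).iloc[0].to_dict()
                row["outcome"] = subscale
                sub_rows.append(row)
    if sub_rows:
        pd.DataFrame(sub_rows).to_csv(out / "associations_subscales.csv", index=False)

    # mediation: does a subscale carry the total-score association?
    subj_order = sorted({p.subject_id for p in profiles})
    beh = behavior.set_index("subject_id").loc[subj_order]
    cov = beh[list(config.covariates)].to_numpy(dtype=float) if config.covariates else None
    mediations = []
    for res in significant:
        prof_by_subj = {
            p.subject_id: p for p in profiles if p.hemisphere == res.hemisphere
        }
        mc_vec = np.array([prof_by_subj[s].entries[res.target_roi] for s in subj_order])
        for subscale in SUBSCALE_COLUMNS:
            med = mediate(
                x=beh[config.outcome].to_numpy(dtype=float),
                m=beh[subscale].to_numpy(dtype=float),
                y=mc_vec,
                covariates=cov,
                n_boot=config.n_boot,
                rng_seed=config.rng_seed,
                alpha=config.alpha,
            )
            med.mediator = subscale
            med.covariates = config.covariates
            entry = dataclasses.asdict(med)
            entry.update(
                hemisphere=res.hemisphere,
                target_roi=res.target_roi,
                target_name=res.target_name,
                outcome=config.outcome,
            )
            mediations.append(entry)
    (out / "mediation.json").write_text(json.dumps(mediations, indent=2, default=float))

    manifest = {
        "config": dataclasses.asdict(config),
        "n_subjects": len(subj_order),
        "n_connections": len(scan),
        "n_significant": len(significant),
        "python": platform.python_version(),
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _versions() -> dict[str, str]:
    import nibabel
    import scipy

    from . import __version__

    return {
        "morphoconn": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
    }
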