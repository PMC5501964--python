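"""Synthetic cohorts for exercising the full morphological-connectivity stack.

The generator emulates the statistical shape of a small VBM study: ~24
subjects, each a 3-D gray-matter density volume whose ROI-wise intensity
distributions are Beta distributions on [0, 1]; a bilateral cuboid atlas with
one seed ROI and ipsilateral target ROIs per hemisphere; and a BIS-like
behavioral table (total = sum of three correlated subscales, plus age, sex,
head size).

A single planted effect links brain to behavior: one seed-target pair in the
right hemisphere is coupled to a latent subject trait u_i ~ N(0, 1).  The
coupled ROI's Beta parameters interpolate between "identical to the seed
ROI" and "maximally distinct" with weight sigmoid(coupling_strength * u_i),
so the seed-coupled morphological connectivity is monotone in the trait by
construction and sign(corr(MC, trait)) = sign(coupling_strength).  The same
trait drives the behavioral subscales, giving the downstream association
scan a known ground truth.  The left hemisphere carries no coupling and acts
as a built-in negative control.

Beta distributions are used for ROI intensities because their support is
exactly the gray-matter intensity boundary [0, 1] that the density estimator
assumes.  Voxels are drawn i.i.d. within each ROI; spatial autocorrelation
can be added afterwards with ``volume_io.smooth_gaussian`` if wanted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import mc as mc_mod
from .volume_io import GMVolume, Parcellation, RegionalSample, write_gm_volume, write_parcellation

MIN_ROI_VOXELS = 50

# fixed offsets deriving independent RNG substreams from one cohort seed
_STREAM_TRAIT = 1
_STREAM_ROI_PARAMS = 2
_STREAM_VOXELS = 3
_STREAM_BEHAVIOR = 4


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one simulated cohort.

    ``n_rois`` counts ROIs per hemisphere (1 seed + n_rois-1 targets);
    ``seed_roi`` and ``coupled_roi`` are within-hemisphere indices (1-based).
    ``coupling_strength`` in [-1, 1] sets the sign and steepness of the
    planted MC-trait link; ``subscale_loadings`` are the loadings of the
    three BIS-like subscales on the latent trait; ``noise_sd`` is the sd of
    the independent noise added to each subscale (trait has unit sd).
    """

    n_subjects: int = 24
    grid_shape: tuple[int, int, int] = (24, 32, 32)
    voxel_size_mm: float = 2.0
    n_rois: int = 23
    seed_roi: int = 1
    coupled_roi: int = 4
    coupling_strength: float = 0.8
    subscale_loadings: tuple[float, float, float] = (0.7, 0.8, 0.6)
    noise_sd: float = 0.6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if any(g < 8 for g in self.grid_shape):
            raise ValueError("each grid dimension must be at least 8")
        if self.n_rois < 3:
            raise ValueError("n_rois must be at least 3 per hemisphere")
        if not 1 <= self.seed_roi <= self.n_rois or not 1 <= self.coupled_roi <= self.n_rois:
            raise ValueError("seed_roi and coupled_roi must be in 1..n_rois")
        if self.seed_roi == self.coupled_roi:
            raise ValueError("seed_roi and coupled_roi must differ")
        if not -1.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [-1, 1]")
        if len(self.subscale_loadings) != 3 or any(
            not 0.0 <= l <= 1.0 for l in self.subscale_loadings
        ):
            raise ValueError("subscale_loadings must be 3 reals in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """What was planted: the latent trait, the realized MC-trait correlation
    for the coupled pair, and every subject's per-ROI Beta parameters."""

    latent_trait: np.ndarray
    planted_mc_trait_corr: float
    coupled_pair: tuple[int, int]          # (seed label, coupled label), right hemi
    roi_params: dict[str, dict[int, tuple[float, float]]]  # subject -> label -> (a, b)
    seed_coupled_mc: np.ndarray            # realized MC per subject

    def to_json(self) -> str:
        payload = {
            "latent_trait": self.latent_trait.tolist(),
            "planted_mc_trait_corr": self.planted_mc_trait_corr,
            "coupled_pair": list(self.coupled_pair),
            "seed_coupled_mc": self.seed_coupled_mc.tolist(),
            "roi_params": {
                sid: {str(k): list(v) for k, v in params.items()}
                for sid, params in self.roi_params.items()
            },
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Atlas construction


def _pack_cuboids(
    region_shape: tuple[int, int, int], n: int, min_voxels: int = MIN_ROI_VOXELS, margin: int = 1
) -> list[tuple[slice, slice, slice]]:
    """Place n disjoint cuboids in a region by splitting it into a lattice of
    blocks and carving a margin-inset cuboid from each.  Raises when the
    packing is infeasible (blocks too small for ``min_voxels``)."""
    shape = np.asarray(region_shape, dtype=int)
    div = np.ones(3, dtype=int)
    while int(np.prod(div)) < n:
        block = shape / div
        axis = int(np.argmax(block))
        if div[axis] >= shape[axis]:
            raise ValueError(f"cannot pack {n} ROIs into region of shape {region_shape}")
        div[axis] += 1
    block = shape // div
    inner = block - 2 * margin
    if np.any(inner < 1) or int(np.prod(inner)) < min_voxels:
        raise ValueError(
            f"cannot pack {n} ROIs of >= {min_voxels} voxels into region "
            f"of shape {region_shape}"
        )
    cuboids = []
    for bx in range(div[0]):
        for by in range(div[1]):
            for bz in range(div[2]):
                if len(cuboids) == n:
                    return cuboids
                origin = np.array([bx, by, bz]) * block + margin
                cuboids.append(tuple(slice(int(o), int(o + s)) for o, s in zip(origin, inner)))
    return cuboids


def generate_toy_atlas(
    grid_shape: tuple[int, int, int], n_rois: int, rng_seed: int = 0
) -> Parcellation:
    """Non-overlapping cuboid ROIs tiling a grid; label 0 is background.

    Hemisphere is assigned from each cuboid's center along the first axis
    (left half = "L"); all ROIs get role "target" — callers promote a seed.
    ``rng_seed`` is accepted for interface stability; the packing itself is
    deterministic.
    """
    del rng_seed
    cuboids = _pack_cuboids(grid_shape, n_rois)
    labels = np.zeros(grid_shape, dtype=np.int16)
    rows = []
    for i, cub in enumerate(cuboids, start=1):
        labels[cub] = i
        cx = 0.5 * (cub[0].start + cub[0].stop)
        hemi = "L" if cx < grid_shape[0] / 2 else "R"
        rows.append({"id": i, "name": f"roi{i:02d}", "hemisphere": hemi, "role": "target"})
    return Parcellation(labels, pd.DataFrame(rows))


def generate_bilateral_atlas(
    grid_shape: tuple[int, int, int],
    n_rois_per_hemi: int,
    seed_roi: int = 1,
    voxel_size_mm: float = 2.0,
) -> Parcellation:
    """Mirrored two-hemisphere atlas: labels 1..n in the left half of axis 0,
    labels n+1..2n mirrored in the right half; ``seed_roi`` (1-based,
    within-hemisphere) gets role "seed" in both hemispheres."""
    nx = grid_shape[0]
    half = (nx // 2, grid_shape[1], grid_shape[2])
    cuboids = _pack_cuboids(half, n_rois_per_hemi)
    labels = np.zeros(grid_shape, dtype=np.int16)
    rows = []
    for i, cub in enumerate(cuboids, start=1):
        labels[cub] = i
        mirror_x = slice(nx - cub[0].stop, nx - cub[0].start)
        labels[(mirror_x, cub[1], cub[2])] = n_rois_per_hemi + i
        role = "seed" if i == seed_roi else "target"
        rows.append({"id": i, "name": f"roi{i:02d}_L", "hemisphere": "L", "role": role})
        rows.append(
            {"id": n_rois_per_hemi + i, "name": f"roi{i:02d}_R", "hemisphere": "R", "role": role}
        )
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    return Parcellation(labels, pd.DataFrame(rows).sort_values("id").reset_index(drop=True), affine)


# ---------------------------------------------------------------------------
# Cohort generation


def _sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=np.float64)))


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[GMVolume], Parcellation, pd.DataFrame, GroundTruth]:
    """Simulate a full cohort: GM volumes, bilateral atlas, behavior, truth.

    Deterministic given ``spec.rng_seed``; independent substreams are derived
    from the seed by fixed offsets so that, e.g., the behavioral noise does
    not shift when the grid changes.
    """
    parc = generate_bilateral_atlas(
        spec.grid_shape, spec.n_rois, spec.seed_roi, spec.voxel_size_mm
    )
    n = spec.n_subjects
    rng_trait = np.random.default_rng([spec.rng_seed, _STREAM_TRAIT])
    rng_roi = np.random.default_rng([spec.rng_seed, _STREAM_ROI_PARAMS])
    rng_vox = np.random.default_rng([spec.rng_seed, _STREAM_VOXELS])
    rng_beh = np.random.default_rng([spec.rng_seed, _STREAM_BEHAVIOR])

    u = rng_trait.standard_normal(n)

    # base Beta parameters, one pair per label; the seed is deliberately
    # asymmetric so its mirrored "maximally distinct" counterpart is far away
    labels_all = parc.roi_table["id"].to_numpy()
    seed_labels = {
        "L": int(spec.seed_roi),
        "R": int(spec.n_rois + spec.seed_roi),
    }
    coupled_label = int(spec.n_rois + spec.coupled_roi)  # right hemisphere only
    base: dict[int, tuple[float, float]] = {}
    for lab in labels_all:
        if int(lab) in seed_labels.values():
            base[int(lab)] = (rng_roi.uniform(2.0, 4.0), rng_roi.uniform(5.0, 8.0))
        else:
            base[int(lab)] = (rng_roi.uniform(2.0, 8.0), rng_roi.uniform(2.0, 8.0))
    far = tuple(reversed(base[seed_labels["R"]]))  # mirror of the seed's base

    masks = {int(lab): parc.labels == int(lab) for lab in labels_all}
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])

    volumes: list[GMVolume] = []
    roi_params: dict[str, dict[int, tuple[float, float]]] = {}
    mc_params = mc_mod.MCParams()
    seed_coupled_mc = np.empty(n)
    w = np.asarray(_sigmoid(spec.coupling_strength * u))

    for i in range(n):
        sid = f"sub-{i + 1:02d}"
        data = np.zeros(spec.grid_shape)
        params_i: dict[int, tuple[float, float]] = {}
        for lab in labels_all:
            lab = int(lab)
            a0, b0 = base[lab]
            jitter = rng_vox.normal(0.0, 0.2, size=2)
            params_i[lab] = (max(a0 + jitter[0], 0.5), max(b0 + jitter[1], 0.5))
        seed_r = params_i[seed_labels["R"]]
        params_i[coupled_label] = (
            w[i] * seed_r[0] + (1.0 - w[i]) * far[0],
            w[i] * seed_r[1] + (1.0 - w[i]) * far[1],
        )
        for lab, (a, b) in params_i.items():
            m = masks[lab]
            data[m] = rng_vox.beta(a, b, size=int(m.sum()))
        volumes.append(GMVolume(data, affine, sid))
        roi_params[sid] = params_i

        pdf_seed = mc_mod.estimate_pdf(
            RegionalSample(seed_labels["R"], data[masks[seed_labels["R"]]]), mc_params
        )
        pdf_coupled = mc_mod.estimate_pdf(
            RegionalSample(coupled_label, data[masks[coupled_label]]), mc_params
        )
        seed_coupled_mc[i] = mc_mod.mc_similarity(pdf_seed, pdf_coupled)

    behavior = _generate_behavior(spec, u, rng_beh)
    realized = (
        float(np.corrcoef(seed_coupled_mc, u)[0, 1]) if np.std(seed_coupled_mc) > 0 else 0.0
    )
    truth = GroundTruth(
        latent_trait=u,
        planted_mc_trait_corr=realized,
        coupled_pair=(seed_labels["R"], coupled_label),
        roi_params=roi_params,
        seed_coupled_mc=seed_coupled_mc,
    )
    return volumes, parc, behavior, truth


def _generate_behavior(spec: CohortSpec, u: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """BIS-like integer subscales driven by the latent trait.

    Each subscale is loading * u + N(0, noise_sd), mapped to an integer score
    clip(round(21 + 5 * raw), 10, 40) so subscale means sit near 21 and the
    total (the sum of the three) near 63, in the familiar BIS-11 range.
    """
    n = u.size
    subscales = {}
    for name, loading in zip(
        ("bis_attentional", "bis_motor", "bis_nonplanning"), spec.subscale_loadings
    ):
        raw = loading * u + rng.normal(0.0, spec.noise_sd, size=n)
        subscales[name] = np.clip(np.rint(21.0 + 5.0 * raw), 10, 40).astype(int)
    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:02d}" for i in range(n)],
            "bis_attentional": subscales["bis_attentional"],
            "bis_motor": subscales["bis_motor"],
            "bis_nonplanning": subscales["bis_nonplanning"],
            "age": rng.integers(18, 34, size=n),
            "sex": (rng.random(n) < 10.0 / 24.0).astype(int),
            "head_size": np.round(rng.normal(1400.0, 100.0, size=n), 1),
        }
    )
    table.insert(
        1,
        "bis_total",
        table["bis_attentional"] + table["bis_motor"] + table["bis_nonplanning"],
    )
    return table


def write_cohort(
    volumes: list[GMVolume],
    parc: Parcellation,
    behavior: pd.DataFrame,
    truth: GroundTruth,
    out_dir: str | Path,
) -> Path:
    """Write a generated cohort to disk: per-subject NIfTI volumes, the atlas
    label volume + ROI table CSV, the behavior CSV, and a ground-truth JSON
    sidecar.  Returns the output directory."""
    out = Path(out_dir)
    (out / "volumes").mkdir(parents=True, exist_ok=True)
    for vol in volumes:
        write_gm_volume(vol, out / "volumes" / f"{vol.subject_id}_gm.nii.gz")
    write_parcellation(parc, out / "atlas.nii.gz", out / "roi_table.csv")
    behavior.to_csv(out / "behavior.csv", index=False)
    (out / "ground_truth.json").write_text(truth.to_json())
    return out
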