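"""Morphological connectivity: regional PDF estimation and KL similarity.

The central statistic: for each region of interest (ROI) the distribution of
gray-matter density values is estimated with a Gaussian kernel density
estimate (Scott's-rule bandwidth) on a fixed grid spanning the gray-matter
intensity boundary [0, 1].  The morphological connectivity (MC) between two
regions is a similarity derived from the symmetrized Kullback-Leibler
divergence of their discretized densities,

    MC(p, q) = exp(-[KL(p||q) + KL(q||p)]),

which lies in (0, 1] and equals 1 exactly when the two discretized densities
coincide.  Densities are floored at a small epsilon and renormalized before
the divergence so that the KL terms are finite where an empirical density
would otherwise vanish.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .volume_io import GMVolume, Parcellation, RegionalSample, extract_regional_samples

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCParams:
    """Tunable parameters of the MC estimator.

    grid_size: number of uniform evaluation points on [0, 1].
    density_floor: epsilon added as a floor before renormalization, keeping
        every KL term finite.
    inclusion_threshold: minimum GM value for a voxel to enter its ROI sample
        (strict inequality).
    """

    grid_size: int = 256
    density_floor: float = 1e-10
    inclusion_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.grid_size < 8:
            raise ValueError("grid_size must be at least 8")
        if self.density_floor <= 0:
            raise ValueError("density_floor must be positive")


@dataclass
class RegionalPDF:
    """Discretized probability density of GM values in one ROI."""

    roi_id: int
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_voxels: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.grid.shape != self.density.shape:
            raise ValueError("grid and density must have the same length")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class MCProfile:
    """Per-subject vector of seed-to-target MC values for one hemisphere."""

    subject_id: str
    hemisphere: str
    seed_roi: int
    entries: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for roi, mc in self.entries.items():
            if not (0.0 < mc <= 1.0):
                raise ValueError(f"MC for target {roi} outside (0, 1]: {mc}")


def scott_bandwidth(values: np.ndarray) -> float:
    """Scott's-rule kernel bandwidth for a univariate sample.

    Returns ``n ** (-1/5) * sd(values)`` (sample sd, ddof=1) — the 1-D Scott
    factor times the data scale.  A constant sample has no scale and is
    rejected: a zero-spread ROI indicates broken inputs, not a valid density.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values for a bandwidth")
    sd = float(np.std(values, ddof=1))
    # guard against rounding residue in the mean of a constant sample
    if sd <= 1e-12 * max(1.0, float(np.abs(values).max())):
        raise ValueError("degenerate ROI distribution (zero variance sample)")
    return float(n ** (-0.2)) * sd


def estimate_pdf(sample: RegionalSample, params: MCParams = MCParams()) -> RegionalPDF:
    """Gaussian KDE of an ROI sample on a uniform grid over [0, 1].

    The kernel sum is evaluated directly at each grid point, then floored at
    ``params.density_floor`` and renormalized to unit trapezoidal integral.
    Kernel mass that leaks outside [0, 1] (including from data values above
    1) is absorbed by the renormalization.
    """
    h = scott_bandwidth(sample.values)
    grid = np.linspace(0.0, 1.0, params.grid_size)
    # direct kernel summation, chunked over grid to bound memory
    z = (grid[:, None] - sample.values[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (sample.n_voxels * h * np.sqrt(2.0 * np.pi))
    dens = np.maximum(dens, params.density_floor)
    area = np.trapezoid(dens, grid)
    dens /= area
    return RegionalPDF(sample.roi_id, grid, dens, h, sample.n_voxels)


def _check_same_grid(p: RegionalPDF, q: RegionalPDF) -> None:
    if p.grid.shape != q.grid.shape or not np.array_equal(p.grid, q.grid):
        raise ValueError("PDFs are defined on different grids")


def kl_divergence(p: RegionalPDF, q: RegionalPDF) -> float:
    """Symmetrized KL divergence KL(p||q) + KL(q||p) on a shared grid.

    Each directed term is the discrete sum of ``p_i * ln(p_i / q_i) * dx``
    over the grid with the floored, renormalized densities, so the result is
    finite, non-negative, and zero iff the discretized densities are equal.
    """
    _check_same_grid(p, q)
    dx = float(p.grid[1] - p.grid[0])
    if np.array_equal(p.density, q.density):
        return 0.0
    log_ratio = np.log(p.density) - np.log(q.density)
    forward = float(np.sum(p.density * log_ratio) * dx)
    backward = float(np.sum(q.density * -log_ratio) * dx)
    return max(forward + backward, 0.0)


def mc_similarity(p: RegionalPDF, q: RegionalPDF) -> float:
    """Morphological connectivity MC = exp(-KLsym); in (0, 1], 1 iff p == q.

    The exponential map is the default similarity; see ``mc_from_kl`` for the
    pluggable alternatives.
    """
    return mc_from_kl(kl_divergence(p, q))


def mc_from_kl(klsym: float, mapping: str = "exp") -> float:
    """Map a symmetrized KL divergence to a similarity in (0, 1].

    ``exp``:     MC = exp(-KLsym)   (default; strictly decreasing, MC(0)=1)
    ``inverse``: MC = 1 / (1 + KLsym)
    """
    if klsym < 0:
        raise ValueError("KL divergence cannot be negative")
    if mapping == "exp":
        return float(np.exp(-klsym))
    if mapping == "inverse":
        return float(1.0 / (1.0 + klsym))
    raise ValueError(f"unknown KL-to-similarity mapping: {mapping!r}")


def compute_mc_profile(
    vol: GMVolume,
    parc: Parcellation,
    params: MCParams = MCParams(),
) -> list[MCProfile]:
    """Seed-to-target MC profiles for one subject, one per hemisphere.

    The parcellation must designate exactly one seed ROI per hemisphere;
    targets are the ipsilateral ROIs with role ``target`` (contralateral
    relations are not computed).  Any empty or zero-variance ROI aborts the
    subject with an error naming the ROI.
    """
    samples = extract_regional_samples(vol, parc, params.inclusion_threshold)
    by_id = {s.roi_id: s for s in samples}

    pdfs: dict[int, RegionalPDF] = {}
    for roi_id, sample in by_id.items():
        try:
            pdfs[roi_id] = estimate_pdf(sample, params)
        except ValueError as exc:
            raise ValueError(
                f"subject {vol.subject_id}: ROI {roi_id} "
                f"({parc.roi_name(roi_id)}): {exc}"
            ) from exc

    profiles: list[MCProfile] = []
    hemispheres = sorted(set(parc.roi_table["hemisphere"]))
    for hemi in hemispheres:
        seeds = parc.rois(role="seed", hemisphere=hemi)
        if len(seeds) == 0:
            continue
        if len(seeds) > 1:
            raise ValueError(
                f"hemisphere {hemi!r} has {len(seeds)} seed ROIs; exactly one expected"
            )
        seed_id = int(seeds["id"].iloc[0])
        targets = parc.rois(role="target", hemisphere=hemi)
        entries = {
            int(t): mc_similarity(pdfs[seed_id], pdfs[int(t)])
            for t in targets["id"]
        }
        profiles.append(MCProfile(vol.subject_id, hemi, seed_id, entries))
    if not profiles:
        raise ValueError("parcellation designates no seed ROI in any hemisphere")
    return profiles


def compute_mc_matrix(
    vol: GMVolume, parc: Parcellation, params: MCParams = MCParams()
) -> tuple[np.ndarray, list[int]]:
    """Full ROI-by-ROI MC matrix (all non-ignored ROIs, both hemispheres)."""
    samples = extract_regional_samples(vol, parc, params.inclusion_threshold)
    pdfs = [estimate_pdf(s, params) for s in samples]
    ids = [s.roi_id for s in samples]
    n = len(pdfs)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = mc_similarity(pdfs[i], pdfs[j])
    return mat, ids


def profiles_to_frame(profiles: list[MCProfile], parc: Parcellation | None = None):
    """Tidy DataFrame (subject_id, hemisphere, seed, target, mc) from profiles."""
    import pandas as pd

    rows = []
    for prof in profiles:
        for target, mc in sorted(prof.entries.items()):
            rows.append(
                {
                    "subject_id": prof.subject_id,
                    "hemisphere": prof.hemisphere,
                    "seed": prof.seed_roi,
                    "target": target,
                    "target_name": parc.roi_name(target) if parc is not None else "",
                    "mc": mc,
                }
            )
    return pd.DataFrame(rows)
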