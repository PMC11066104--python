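"""Synthetic 3D phantom cohorts, atlases, reference maps and visit tables.

Everything downstream (classifier, relevance maps, validation battery,
longitudinal analyses) is exercised on these fixtures, so the generators are
first-class, seeded, and fully deterministic.  "Brains" are axis-aligned
ellipsoids at 80% of the grid extent; simulated atrophy is a multiplicative
intensity reduction inside known atlas regions, so ground-truth signal voxels
are exactly known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

SITES = ("siteA", "siteB")
SEXES = ("F", "M")
DIAGNOSES = ("CN", "MCI", "DEM")
TRAJECTORIES = ("improving", "stable", "progressive", "ambiguous")

_MIN_GRID = 8


@dataclass
class LesionSpec:
    """Which atlas regions carry the class signal, and how strong it is.

    ``effect`` is the fractional intensity reduction (0.3 => case voxels in the
    lesion regions are 30% dimmer than the control baseline).
    """

    regions: tuple[int, ...]
    effect: float


@dataclass
class SyntheticAtlas:
    """Integer-labelled region volume; 0 is background, k>=1 a region."""

    labels: np.ndarray
    names: dict[int, str]

    @property
    def region_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.names))

    def region_mask(self, region_ids) -> np.ndarray:
        ids = np.atleast_1d(np.asarray(region_ids, dtype=int))
        unknown = set(ids.tolist()) - set(self.names)
        if unknown:
            raise ValueError(f"unknown region id(s): {sorted(unknown)}")
        return np.isin(self.labels, ids)


@dataclass
class Phantom:
    volume: np.ndarray
    label: int
    lesion_mask: np.ndarray
    subject_id: str
    site: str
    age: float
    sex: str

    def metadata(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "site": self.site,
            "age": self.age,
            "sex": self.sex,
            "label": self.label,
        }


def brain_mask(grid: int) -> np.ndarray:
    """Axis-aligned ellipsoid mask at 80% of the grid extent."""
    if grid < _MIN_GRID:
        raise ValueError(f"grid {grid} too small to contain atlas (min {_MIN_GRID})")
    c = (grid - 1) / 2.0
    semi = 0.8 * grid / 2.0
    zz, yy, xx = np.meshgrid(*([np.arange(grid)] * 3), indexing="ij")
    rho2 = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) / semi**2
    return rho2 <= 1.0


def _ellipsoid_rho2(grid: int) -> np.ndarray:
    c = (grid - 1) / 2.0
    semi = 0.8 * grid / 2.0
    zz, yy, xx = np.meshgrid(*([np.arange(grid)] * 3), indexing="ij")
    return ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) / semi**2


def build_atlas(grid: int = 48, n_regions: int = 8, seed: int = 0) -> SyntheticAtlas:
    """Partition the brain mask into ``n_regions`` contiguous-id Voronoi cells.

    Centroids are drawn inside the mask from ``seed``; every in-mask voxel is
    assigned to its nearest centroid, so regions tile the mask exactly and every
    possible lesion voxel lies in exactly one region.
    """
    mask = brain_mask(grid)
    rng = np.random.default_rng(seed)
    coords = np.argwhere(mask)
    idx = rng.choice(len(coords), size=n_regions, replace=False)
    centroids = coords[idx].astype(float)
    labels = np.zeros((grid,) * 3, dtype=np.int32)
    d2 = np.stack(
        [((coords - cen) ** 2).sum(axis=1) for cen in centroids], axis=1
    )
    assign = d2.argmin(axis=1) + 1
    labels[tuple(coords.T)] = assign
    names = {k: f"region_{k:02d}" for k in range(1, n_regions + 1)}
    return SyntheticAtlas(labels=labels, names=names)


def _base_intensity(grid: int) -> np.ndarray:
    # Smooth radial profile, brighter centre (0.65) than rim (0.35); the
    # volume-weighted mean sits near 0.5 so a U(0,1) noise box is
    # intensity-neutral with respect to healthy tissue (occlusion removes
    # information instead of simulating atrophy).
    rho2 = np.clip(_ellipsoid_rho2(grid), 0.0, 1.0)
    return 0.65 - 0.3 * rho2


def generate_cohort(
    n_per_class: int,
    grid: int = 48,
    lesion_spec: LesionSpec | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    atlas: SyntheticAtlas | None = None,
    sex_regions: tuple[int, ...] = (),
    sex_effect: float = 0.0,
    intensity_jitter: float = 0.0,
) -> list[Phantom]:
    """Generate ``n_per_class`` cases (label 1) and controls (label 0).

    Cases differ from controls only by a multiplicative intensity reduction
    (factor ``1 - effect``) inside the lesion regions, plus i.i.d. Gaussian
    noise.  Optionally, subjects with sex "F" carry an analogous reduction of
    ``sex_effect`` inside ``sex_regions`` — an attribute orthogonal to the
    label, used by the alternative-task null pipeline.

    ``intensity_jitter`` applies a per-subject global brightness factor drawn
    uniformly from ``[1 - jitter, 1 + jitter]`` (both classes alike), emulating
    acquisition-scale variability: it makes overall brightness uninformative,
    so classifiers must rely on the spatial contrast of the lesion.
    """
    if n_per_class == 0:
        return []
    if atlas is None:
        atlas = build_atlas(grid)
    if atlas.labels.shape != (grid,) * 3:
        raise ValueError("grid does not match atlas grid")
    if lesion_spec is None:
        lesion_spec = LesionSpec(regions=(1,), effect=0.3)
    if lesion_spec.effect < 0:
        raise ValueError("effect size must be >= 0")
    lesion = atlas.region_mask(lesion_spec.regions)
    sexmask = atlas.region_mask(sex_regions) if sex_regions else None

    rng = np.random.default_rng(seed)
    mask = brain_mask(grid)
    base = _base_intensity(grid)
    n = 2 * n_per_class
    labels = np.array([1] * n_per_class + [0] * n_per_class)
    sexes = np.array((SEXES * ((n + 1) // 2))[:n])
    rng.shuffle(sexes)
    sites = rng.choice(SITES, size=n)
    ages = rng.uniform(55.0, 90.0, size=n)

    cohort: list[Phantom] = []
    for i in range(n):
        vol = base.copy()
        if labels[i] == 1:
            vol[lesion] *= 1.0 - lesion_spec.effect
        if sexmask is not None and sexes[i] == "F":
            vol[sexmask] *= 1.0 - sex_effect
        if intensity_jitter > 0:
            vol *= rng.uniform(1.0 - intensity_jitter, 1.0 + intensity_jitter)
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
        vol = np.clip(vol, 0.0, 1.0)
        vol[~mask] = 0.0
        # brain-masking stays testable: in-brain voxels strictly positive
        vol[mask] = np.maximum(vol[mask], 1e-4)
        cohort.append(
            Phantom(
                volume=vol.astype(np.float32),
                label=int(labels[i]),
                lesion_mask=(lesion & mask) if labels[i] == 1 else np.zeros_like(mask),
                subject_id=f"sub-{i:04d}",
                site=str(sites[i]),
                age=float(ages[i]),
                sex=str(sexes[i]),
            )
        )
    return cohort


def cohort_metadata(cohort: list[Phantom]) -> pd.DataFrame:
    return pd.DataFrame([p.metadata() for p in cohort])


def generate_reference_map(
    atlas: SyntheticAtlas, hot_regions, blur: float = 1.0
) -> np.ndarray:
    """Synthetic stand-in for an externally supplied consensus reference map.

    The indicator of ``hot_regions`` is Gaussian-blurred by ``blur`` voxels and
    re-masked to the brain; with ``blur=0`` the support is exactly the union of
    the hot regions.
    """
    ids = tuple(np.atleast_1d(hot_regions).tolist())
    if len(ids) == 0:
        raise ValueError("hot_regions must be nonempty")
    hot = atlas.region_mask(ids).astype(float)
    if blur > 0:
        g = ndimage.gaussian_filter(hot, sigma=blur)
        g[hot > 0] = np.maximum(g[hot > 0], 1e-12)
    else:
        g = hot
    g[atlas.labels == 0] = 0.0
    return g


def generate_visit_table(
    n_subjects: int,
    trajectory_mix: dict[str, float] | None = None,
    visit_gap: tuple[float, float] = (180.0, 60.0),
    seed: int = 0,
    n_visits_range: tuple[int, int] = (3, 7),
) -> pd.DataFrame:
    """Longitudinal visit table: (subject_id, visit_date, diagnosis).

    ``trajectory_mix`` gives proportions over {improving, stable, progressive,
    ambiguous}; each subject's diagnosis sequence follows its trajectory
    grammar.  ``visit_date`` is integer days since study start, strictly
    increasing per subject.
    """
    if trajectory_mix is None:
        trajectory_mix = {"stable": 0.5, "progressive": 0.3, "improving": 0.1, "ambiguous": 0.1}
    unknown = set(trajectory_mix) - set(TRAJECTORIES)
    if unknown:
        raise ValueError(f"unknown trajectory kind(s): {sorted(unknown)}")
    total = sum(trajectory_mix.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"trajectory proportions must sum to 1 (got {total})")

    rng = np.random.default_rng(seed)
    kinds = [k for k in TRAJECTORIES if trajectory_mix.get(k, 0) > 0]
    probs = np.array([trajectory_mix[k] for k in kinds])
    draw = rng.choice(len(kinds), size=n_subjects, p=probs / probs.sum())

    rows = []
    lo, hi = n_visits_range
    gap_mu, gap_sd = visit_gap
    for s in range(n_subjects):
        kind = kinds[draw[s]]
        nv = int(rng.integers(max(lo, 3 if kind == "ambiguous" else 2), hi + 1))
        gaps = np.maximum(30, rng.normal(gap_mu, gap_sd, size=nv - 1)).astype(int)
        dates = np.concatenate([[0], np.cumsum(gaps)])
        diags = _trajectory_sequence(kind, nv, rng)
        for d, dx in zip(dates, diags):
            rows.append({"subject_id": f"mci-{s:04d}", "visit_date": int(d), "diagnosis": dx})
    return pd.DataFrame(rows)


def _trajectory_sequence(kind: str, nv: int, rng: np.random.Generator) -> list[str]:
    if kind == "stable":
        return ["MCI"] * nv
    if kind == "improving":
        # MCI run followed by CN run; never DEM
        split = int(rng.integers(1, nv))
        return ["MCI"] * split + ["CN"] * (nv - split)
    if kind == "progressive":
        # >=1 MCI visit before the first DEM visit, DEM thereafter
        split = int(rng.integers(1, nv))
        return ["MCI"] * split + ["DEM"] * (nv - split)
    if kind == "ambiguous":
        # bounces through all three stages -> excluded downstream
        seq = ["MCI", "CN", "DEM"]
        extra = ["DEM"] * (nv - 3)
        return seq + extra
    raise ValueError(kind)


def trajectory_labels(visits: pd.DataFrame) -> pd.Series:
    """Classify each subject's diagnostic trajectory from raw visit rows.

    Returns one of {improving, stable, progressive, ambiguous} per subject;
    "ambiguous" covers every sequence outside the three clean grammars (e.g.
    not starting at MCI, or reversals after a dementia diagnosis).
    """
    out = {}
    for sid, grp in visits.sort_values("visit_date").groupby("subject_id"):
        seq = grp["diagnosis"].tolist()
        out[sid] = _classify_sequence(seq)
    return pd.Series(out, name="trajectory")


def _classify_sequence(seq: list[str]) -> str:
    if seq[0] != "MCI":
        return "ambiguous"
    if all(d == "MCI" for d in seq):
        return "stable"
    first_change = next(i for i, d in enumerate(seq) if d != "MCI")
    head, tail = seq[:first_change], seq[first_change:]
    if all(d == "MCI" for d in head) and all(d == "DEM" for d in tail):
        return "progressive"
    if all(d == "MCI" for d in head) and all(d == "CN" for d in tail):
        return "improving"
    return "ambiguous"
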