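"""Synthetic brain-like cohorts for exercising the dementia-detection pipeline.

Real voxel-based-morphometry cohorts (gray-matter density maps plus clinical
covariates) are access-restricted, so this module generates volumes with the
same statistical structure the pipeline assumes: control intensities follow a
linear covariate model (age, sex, total intracranial volume, scanner field
strength) plus Gaussian noise, and patients additionally show a multiplicative
intensity reduction ("atrophy") inside designated atlas regions, with mild
cognitive impairment (MCI) intermediate between controls and dementia (AD).

The phantom is deliberately simple -- a smoothed ellipsoidal "brain" with a few
ellipsoid/box regions, one of which is always named ``hippocampus`` -- but every
downstream stage (residualization, CNN training, relevance propagation, region
aggregation, occlusion) runs on it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_preproc import GrayMatterVolume, write_volume

DIAGNOSES = ("CN", "MCI", "AD")

COVARIATE_COLUMNS = ("age", "sex", "tiv", "field_strength")


@dataclass
class RegionAtlas:
    """Integer-labeled 3D grid naming regions (0 = background).

    A synthetic analogue of an anatomical parcellation: every nonzero label
    maps to a region name, and a ``hippocampus`` region is mandatory because
    the pipeline's validation analyses are anchored on it.
    """

    labels: np.ndarray
    region_names: dict[int, str]
    voxel_size_mm: float = 1.5

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"atlas labels must be 3D, got shape {self.labels.shape}")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.region_names)
        if missing:
            raise ValueError(f"labels without a name: {sorted(missing)}")
        if "hippocampus" not in self.region_names.values():
            raise ValueError("atlas must contain a region named 'hippocampus'")

    def mask(self, region: str) -> np.ndarray:
        """Boolean mask of the named region."""
        for label, name in self.region_names.items():
            if name == region:
                return self.labels == label
        raise KeyError(f"no region named {region!r}")

    def lookup(self, coordinate) -> str:
        """Region name at a voxel coordinate, or ``'background'``."""
        coordinate = tuple(int(c) for c in coordinate)
        if len(coordinate) != 3 or any(
            c < 0 or c >= s for c, s in zip(coordinate, self.labels.shape)
        ):
            raise IndexError(f"coordinate {coordinate} outside grid {self.labels.shape}")
        label = int(self.labels[coordinate])
        return self.region_names.get(label, "background") if label else "background"


@dataclass
class SubjectRecord:
    """One subject's identifier, covariates, and diagnosis."""

    subject_id: str
    age: float          # years
    sex: int            # 0/1
    tiv: float          # total intracranial volume, ml
    field_strength: int  # 0 = 1.5T, 1 = 3T
    diagnosis: str      # CN / MCI / AD

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.tiv <= 0:
            raise ValueError("TIV must be positive")
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}; expected one of {DIAGNOSES}")

    @property
    def covariate_vector(self) -> np.ndarray:
        return np.array([self.age, self.sex, self.tiv, self.field_strength], float)


def default_atrophy_regions() -> dict:
    # AD attenuation 0.4; MCI intermediate at half the AD value.
    return {"hippocampus": {"MCI": 0.2, "AD": 0.4}}


def default_covariate_slopes() -> dict:
    # Per-covariate intensity slopes in raw units (density per year, per ml, ...).
    return {"age": -0.003, "sex": -0.02, "tiv": 1e-4, "field_strength": 0.01}


def default_covariate_distributions() -> dict:
    return {
        "age": ("uniform", 60.0, 85.0),
        "sex": ("bernoulli", 0.5),
        "tiv": ("normal", 1450.0, 130.0),
        "field_strength": ("bernoulli", 0.7),
    }


@dataclass
class CohortSpec:
    """Ground-truth generative parameters of a synthetic cohort."""

    n_control: int = 100
    n_mci: int = 50
    n_ad: int = 50
    grid_shape: tuple = (40, 40, 48)
    voxel_size_mm: float = 1.5
    base_intensity: float = 0.8
    covariate_distributions: dict = field(default_factory=default_covariate_distributions)
    covariate_slopes: dict = field(default_factory=default_covariate_slopes)
    atrophy_regions: dict = field(default_factory=default_atrophy_regions)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_mci, self.n_ad) < 0:
            raise ValueError("group counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for region, frac in self.atrophy_regions.items():
            for dx, f in frac.items():
                if not 0 <= f < 1:
                    raise ValueError(f"attenuation for {region}/{dx} outside [0,1): {f}")
            if frac.get("MCI", 0.0) > frac.get("AD", 0.0):
                raise ValueError(f"MCI attenuation must not exceed AD attenuation ({region})")

    @property
    def n_total(self) -> int:
        return self.n_control + self.n_mci + self.n_ad

    def to_json(self, path) -> None:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        d = json.loads(Path(path).read_text())
        d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


# ---------------------------------------------------------------------------
# atlas construction
# ---------------------------------------------------------------------------

def _region_mask(grid_shape, spec: dict) -> np.ndarray:
    """Boolean mask for one ellipsoid/box region spec; errors if outside grid."""
    shape = spec.get("shape", "ellipsoid")
    center = np.asarray(spec["center"], float)
    if shape == "ellipsoid":
        semi = np.asarray(spec["semi_axes"], float)
        lo, hi = center - semi, center + semi
    elif shape == "box":
        half = np.asarray(spec["half_size"], float)
        lo, hi = center - half, center + half
    else:
        raise ValueError(f"unknown region shape {shape!r}")
    if (lo < -0.5).any() or (hi > np.asarray(grid_shape) - 0.5).any():
        raise ValueError(f"region {spec.get('name')!r} extends outside grid {grid_shape}")
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    if shape == "ellipsoid":
        d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
        return d2 <= 1.0
    inside = [(np.abs(g - c) <= h) for g, c, h in zip(grids, center, half)]
    return inside[0] & inside[1] & inside[2]


def make_atlas(grid_shape, region_specs, seed: int = 0, voxel_size_mm: float = 1.5) -> RegionAtlas:
    """Build a labeled atlas from non-overlapping ellipsoid/box region specs.

    ``region_specs`` is a sequence of dicts with keys ``name``, ``shape``
    (``"ellipsoid"`` or ``"box"``), ``center`` and ``semi_axes``/``half_size``
    in voxel units. Deterministic for a fixed seed (the seed is reserved for
    future jittered atlases; construction itself is exact).
    """
    labels = np.zeros(tuple(grid_shape), dtype=np.int32)
    names: dict[int, str] = {}
    for i, spec in enumerate(region_specs, start=1):
        mask = _region_mask(grid_shape, spec)
        if (labels[mask] != 0).any():
            other = names[int(labels[mask][labels[mask] != 0][0])]
            raise ValueError(f"region {spec['name']!r} overlaps region {other!r}")
        labels[mask] = i
        names[i] = spec["name"]
    if not region_specs:
        names = {}
        # an atlas with no regions is only useful internally; RegionAtlas
        # requires a hippocampus, so return the raw pieces via a permissive path
        atlas = RegionAtlas.__new__(RegionAtlas)
        atlas.labels = labels
        atlas.region_names = names
        atlas.voxel_size_mm = voxel_size_mm
        return atlas
    return RegionAtlas(labels=labels, region_names=names, voxel_size_mm=voxel_size_mm)


def default_region_specs(grid_shape) -> list[dict]:
    """Three regions scaled to the grid: hippocampus, temporal patch, parietal box."""
    g = np.asarray(grid_shape, float)
    c = (g - 1) / 2
    return [
        {
            "name": "hippocampus",
            "shape": "ellipsoid",
            "center": [c[0], c[1] - 0.12 * g[1], c[2] - 0.15 * g[2]],
            "semi_axes": list(0.09 * g),
        },
        {
            "name": "temporal",
            "shape": "ellipsoid",
            "center": [c[0] + 0.22 * g[0], c[1], c[2] - 0.10 * g[2]],
            "semi_axes": list(0.08 * g),
        },
        {
            "name": "parietal",
            "shape": "box",
            "center": [c[0] - 0.20 * g[0], c[1] + 0.15 * g[1], c[2] + 0.15 * g[2]],
            "half_size": list(0.07 * g),
        },
    ]


# ---------------------------------------------------------------------------
# volume generation
# ---------------------------------------------------------------------------

def base_template(grid_shape, base_intensity: float = 0.8, smooth_sigma: float = 1.5) -> np.ndarray:
    """Smooth radial 'brain': an ellipsoid at ``base_intensity``, 0 outside.

    Gaussian smoothing softens the boundary so the phantom resembles a
    modulated gray-matter density map rather than a binary mask.
    """
    grid_shape = tuple(grid_shape)
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    c = [(s - 1) / 2 for s in grid_shape]
    semi = [0.42 * s for s in grid_shape]
    d2 = sum(((g - ci) / a) ** 2 for g, ci, a in zip(grids, c, semi))
    vol = np.where(d2 <= 1.0, base_intensity, 0.0)
    return ndimage.gaussian_filter(vol, sigma=smooth_sigma)


def simulate_subject(
    atlas: RegionAtlas,
    record: SubjectRecord,
    spec: CohortSpec,
    seed: int,
    template: np.ndarray | None = None,
) -> GrayMatterVolume:
    """Generate one subject's gray-matter map from the cohort's generative model.

    Voxel value = template + Σ slope_c · covariate_c + Gaussian noise (covariate
    effects and noise applied on the brain support only), then multiplied by
    (1 − attenuation) inside each atrophy region for the subject's diagnosis,
    and clipped at 0.
    """
    if record.diagnosis not in DIAGNOSES:  # pragma: no cover - guarded in record
        raise ValueError(f"unknown diagnosis {record.diagnosis!r}")
    if template is None:
        template = base_template(spec.grid_shape, spec.base_intensity)
    rng = np.random.default_rng(seed)
    support = template > 1e-3
    shift = sum(
        spec.covariate_slopes.get(name, 0.0) * value
        for name, value in zip(COVARIATE_COLUMNS, record.covariate_vector)
    )
    values = template.copy()
    values[support] += shift
    if spec.noise_sd > 0:
        values[support] += rng.normal(0.0, spec.noise_sd, size=int(support.sum()))
    for region, fractions in spec.atrophy_regions.items():
        f = fractions.get(record.diagnosis, 0.0)
        if f > 0:
            values[atlas.mask(region)] *= 1.0 - f
    np.clip(values, 0.0, None, out=values)
    return GrayMatterVolume(
        values=values,
        voxel_size_mm=spec.voxel_size_mm,
        space_tag="synthetic-MNI-like",
        subject_id=record.subject_id,
    )


def _draw_covariate(dist, rng) -> float:
    kind = dist[0]
    if kind == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    if kind == "normal":
        return float(rng.normal(dist[1], dist[2]))
    if kind == "bernoulli":
        return float(rng.random() < dist[1])
    raise ValueError(f"unknown distribution kind {kind!r}")


def simulate_cohort(spec: CohortSpec, atlas: RegionAtlas | None = None):
    """Simulate a full cohort: volumes, subject records, and the atlas used.

    Reproducible for a fixed ``spec.seed``; group sizes are exactly as
    requested; covariates are drawn i.i.d. from the spec's distributions.
    """
    if spec.n_total == 0:
        raise ValueError("cohort must contain at least one subject")
    if atlas is None:
        atlas = make_atlas(spec.grid_shape, default_region_specs(spec.grid_shape),
                           seed=spec.seed, voxel_size_mm=spec.voxel_size_mm)
    if atlas.labels.shape != tuple(spec.grid_shape):
        raise ValueError("atlas grid does not match cohort grid")
    root = np.random.SeedSequence(spec.seed)
    cov_rng = np.random.default_rng(root.spawn(1)[0])
    subject_seeds = root.generate_state(spec.n_total) % (2**31)
    template = base_template(spec.grid_shape, spec.base_intensity)

    diagnoses = ["CN"] * spec.n_control + ["MCI"] * spec.n_mci + ["AD"] * spec.n_ad
    records, volumes = [], []
    for i, dx in enumerate(diagnoses):
        rec = SubjectRecord(
            subject_id=f"S{i + 1:04d}",
            age=_draw_covariate(spec.covariate_distributions["age"], cov_rng),
            sex=int(_draw_covariate(spec.covariate_distributions["sex"], cov_rng)),
            tiv=_draw_covariate(spec.covariate_distributions["tiv"], cov_rng),
            field_strength=int(
                _draw_covariate(spec.covariate_distributions["field_strength"], cov_rng)
            ),
            diagnosis=dx,
        )
        records.append(rec)
        volumes.append(
            simulate_subject(atlas, rec, spec, seed=int(subject_seeds[i]), template=template)
        )
    return volumes, records, atlas


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "tiv": [r.tiv for r in records],
            "field_strength": [r.field_strength for r in records],
            "diagnosis": [r.diagnosis for r in records],
        }
    )


def write_covariates(records, path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_covariates(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SubjectRecord(
            subject_id=str(r.subject_id),
            age=float(r.age),
            sex=int(r.sex),
            tiv=float(r.tiv),
            field_strength=int(r.field_strength),
            diagnosis=str(r.diagnosis),
        )
        for r in df.itertuples()
    ]


def write_atlas(atlas: RegionAtlas, nii_path, names_path=None) -> None:
    vol = GrayMatterVolume(atlas.labels.astype(np.float32), atlas.voxel_size_mm, "atlas")
    write_volume(vol, nii_path)
    if names_path is not None:
        Path(names_path).write_text(
            json.dumps({str(k): v for k, v in atlas.region_names.items()}, indent=2)
        )


def read_atlas(nii_path, names_path) -> RegionAtlas:
    from .io_preproc import read_volume

    vol = read_volume(nii_path)
    names = {int(k): v for k, v in json.loads(Path(names_path).read_text()).items()}
    return RegionAtlas(
        labels=np.rint(vol.values).astype(np.int32),
        region_names=names,
        voxel_size_mm=vol.voxel_size_mm,
    )
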