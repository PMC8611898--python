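"""Volume I/O and covariate residualization.

Gray-matter density maps carry strong nuisance signal from age, sex, head size
(total intracranial volume, TIV) and scanner field strength. Before
classification, a per-voxel linear model

    vx_i = b0 + b1*age + b2*sex + b3*TIV + b4*FS + e_i

is fitted by ordinary least squares on the healthy controls only, and the
model prediction is subtracted from every subject's map (fit on controls,
apply to all). The same machinery residualizes scalar features such as
hippocampus volume.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

COVARIATE_ORDER = ("intercept", "age", "sex", "tiv", "field_strength")


@dataclass
class GrayMatterVolume:
    """A 3D scalar grid (modulated gray-matter density) with grid metadata."""

    values: np.ndarray
    voxel_size_mm: float = 1.5
    space_tag: str = "MNI-like"
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("volume contains non-finite values")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class ResidualModel:
    """Per-feature OLS coefficients (intercept, age, sex, TIV, FS)."""

    coefficients: np.ndarray       # (5, n_features)
    feature_shape: tuple           # () for scalar features, else the grid shape
    fit_n: int

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, float)
        if self.coefficients.shape[0] != len(COVARIATE_ORDER):
            raise ValueError("expected one coefficient row per covariate (plus intercept)")
        if self.fit_n <= len(COVARIATE_ORDER):
            raise ValueError("need more fitting subjects than model coefficients")


@dataclass
class ResidualVolume:
    """Residual image of one subject after covariate correction."""

    values: np.ndarray
    source_subject_id: str | None = None
    voxel_size_mm: float = 1.5


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> GrayMatterVolume:
    """Read a single-frame NIfTI volume.

    Non-isotropic voxel sizes are accepted with a warning; the smallest
    dimension is kept as the nominal isotropic size.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape} in {path.name}")
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-5):
        warnings.warn(
            f"non-isotropic voxels {tuple(zooms)} in {path.name}; keeping smallest",
            stacklevel=2,
        )
    return GrayMatterVolume(
        values=np.asarray(data, np.float64),
        voxel_size_mm=float(min(zooms)),
        space_tag="from-file",
        subject_id=path.name.split(".")[0],
    )


def write_volume(volume: GrayMatterVolume, path) -> None:
    """Write a volume as NIfTI with an isotropic diagonal affine."""
    affine = np.diag([volume.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.values, np.float64), affine)
    img.header.set_zooms([volume.voxel_size_mm] * 3)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------

def design_matrix(covariates: np.ndarray) -> np.ndarray:
    """Prepend an intercept column to an (n, 4) covariate array."""
    covariates = np.asarray(covariates, float)
    if covariates.ndim != 2 or covariates.shape[1] != 4:
        raise ValueError(f"expected (n, 4) covariates, got {covariates.shape}")
    return np.column_stack([np.ones(len(covariates)), covariates])


def _check_design(X: np.ndarray) -> None:
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(
                f"rank-deficient design: covariate {COVARIATE_ORDER[j]!r} is constant"
            )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear covariates)")


def fit_residualizer(control_features: np.ndarray, control_covariates: np.ndarray) -> ResidualModel:
    """Fit per-feature OLS coefficients on control subjects.

    ``control_features`` is (n_controls, ...) -- trailing axes are flattened
    into features, so voxel grids and scalars share one code path. Solved with
    a pseudo-inverse (relative rank tolerance 1e-10) so zero-variance features
    get zero slopes instead of failing.
    """
    features = np.asarray(control_features, float)
    n = features.shape[0]
    feature_shape = features.shape[1:]
    flat = features.reshape(n, -1)
    X = design_matrix(control_covariates)
    if len(X) != n:
        raise ValueError("features and covariates disagree on subject count")
    if n < 6:
        raise ValueError("need at least 6 control subjects")
    _check_design(X)
    coef = np.linalg.pinv(X, rcond=1e-10) @ flat  # (5, n_features)
    return ResidualModel(coefficients=coef, feature_shape=feature_shape, fit_n=n)


def apply_residualizer(features: np.ndarray, covariates: np.ndarray, model: ResidualModel) -> np.ndarray:
    """Subtract the model prediction: residual = observed − X·beta.

    The model is fitted on controls but applicable to any subject.
    """
    features = np.asarray(features, float)
    if features.shape[1:] != tuple(model.feature_shape):
        raise ValueError(
            f"feature shape {features.shape[1:]} does not match model {model.feature_shape}"
        )
    X = design_matrix(covariates)
    if len(X) != features.shape[0]:
        raise ValueError("features and covariates disagree on subject count")
    flat = features.reshape(features.shape[0], -1)
    res = flat - X @ model.coefficients
    return res.reshape(features.shape)


def residualize_scalar(values, covariates, control_mask):
    """Fit on the control subset, apply to all; for scalar features.

    Returns (residuals, ResidualModel). Used for hippocampus volumes.
    """
    values = np.asarray(values, float).reshape(-1, 1)
    control_mask = np.asarray(control_mask, bool)
    covariates = np.asarray(covariates, float)
    model = fit_residualizer(values[control_mask], covariates[control_mask])
    res = apply_residualizer(values, covariates, model)
    return res.ravel(), model


def residualize_volumes(volumes, records, model: ResidualModel) -> list[ResidualVolume]:
    """Apply a fitted voxelwise model to a list of volumes."""
    feats = np.stack([v.values for v in volumes])
    covs = np.stack([r.covariate_vector for r in records])
    res = apply_residualizer(feats, covs, model)
    return [
        ResidualVolume(values=res[i], source_subject_id=volumes[i].subject_id,
                       voxel_size_mm=volumes[i].voxel_size_mm)
        for i in range(len(volumes))
    ]


def fit_residualizer_on_controls(volumes, records) -> ResidualModel:
    """Convenience wrapper: fit the voxelwise model on the CN subjects only."""
    controls = [(v, r) for v, r in zip(volumes, records) if r.diagnosis == "CN"]
    if not controls:
        raise ValueError("no control subjects to fit on")
    feats = np.stack([v.values for v, _ in controls])
    covs = np.stack([r.covariate_vector for _, r in controls])
    return fit_residualizer(feats, covs)


# ---------------------------------------------------------------------------
# model persistence: 5-frame NIfTI coefficient stack + JSON sidecar
# ---------------------------------------------------------------------------

def save_residual_model(model: ResidualModel, nii_path, sidecar_path) -> None:
    shape = tuple(model.feature_shape) if model.feature_shape else (1, 1, 1)
    stack = model.coefficients.reshape((len(COVARIATE_ORDER),) + shape)
    img = nib.Nifti1Image(np.moveaxis(stack, 0, -1), np.eye(4))
    nib.save(img, str(nii_path))
    Path(sidecar_path).write_text(
        json.dumps(
            {
                "covariate_order": list(COVARIATE_ORDER),
                "feature_shape": list(model.feature_shape),
                "fit_n": model.fit_n,
            },
            indent=2,
        )
    )


def load_residual_model(nii_path, sidecar_path) -> ResidualModel:
    meta = json.loads(Path(sidecar_path).read_text())
    stack = np.moveaxis(np.asarray(nib.load(str(nii_path)).dataobj), -1, 0)
    coef = stack.reshape(len(COVARIATE_ORDER), -1)
    return ResidualModel(
        coefficients=coef,
        feature_shape=tuple(meta["feature_shape"]),
        fit_n=int(meta["fit_n"]),
    )
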