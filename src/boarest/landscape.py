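"""Principal-component summary of landscape composition.

Land-use around each camera site (percentages of six classes within a 500 m
buffer) is collinear; the density model therefore uses the first four
principal components of the standardized site compositions as habitat
covariates.  Grid cells over the wider study area are projected onto the
*same* axes, standardized with the camera-site means and standard deviations,
so that habitat-preference coefficients estimated at camera sites apply
unchanged to cell-level density prediction.

The PCA itself is a fixed pre-processing step (not a node in the Bayesian
model) and is delegated to scikit-learn on the standardized matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["LANDSCAPE_CLASSES", "PcaBasis", "fit_pca", "project"]

#: the six land-use classes, as percentage columns
LANDSCAPE_CLASSES = [
    "broadleaf",
    "conifer",
    "farmland",
    "bamboo",
    "abandoned",
    "residential",
]


@dataclass
class PcaBasis:
    """Fitted PCA basis on standardized camera-site compositions."""

    classes: list[str]
    mean: np.ndarray  # per-class mean over camera sites
    sd: np.ndarray  # per-class s.d. (ddof=1) over camera sites
    loadings: np.ndarray  # (n_classes, n_classes); columns are axes
    explained_variance: np.ndarray  # eigenvalues of the correlation matrix
    explained_ratio: np.ndarray
    n_axes: int = 4
    site_scores: pd.DataFrame | None = field(default=None, repr=False)


def _validate_composition(df: pd.DataFrame, classes: list[str]) -> np.ndarray:
    missing = [c for c in classes if c not in df.columns]
    if missing:
        raise ValueError(f"composition table is missing classes: {missing}")
    x = df[classes].to_numpy(dtype=float)
    if np.any(x < 0) or np.any(x > 100):
        raise ValueError("landscape percentages must lie in [0, 100]")
    if np.any(x.sum(axis=1) > 100.0 + 1e-6):
        raise ValueError("landscape percentages of a row must sum to <= 100")
    return x


def fit_pca(site_compositions: pd.DataFrame, n_axes: int = 4) -> PcaBasis:
    """Fit the landscape PCA on camera-site compositions.

    Compositions are standardized (mean 0, s.d. 1 per class) before the
    decomposition, so the axes diagonalize the correlation matrix.  Sign
    convention: the largest-magnitude loading of each axis is positive.
    Classes with zero variance are dropped with a warning.
    """
    classes = list(LANDSCAPE_CLASSES)
    x = _validate_composition(site_compositions, classes)
    n = x.shape[0]
    if n <= len(classes):
        raise ValueError(
            f"need more sites ({n}) than landscape classes ({len(classes)}) to fit the PCA"
        )
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.all(keep):
        dropped = [c for c, k in zip(classes, keep) if not k]
        warnings.warn(
            f"landscape classes with zero variance dropped from PCA: {dropped}",
            stacklevel=2,
        )
        classes = [c for c, k in zip(classes, keep) if k]
        x = x[:, keep]
        sd = sd[keep]
    if n_axes > len(classes):
        raise ValueError("n_axes cannot exceed the number of varying classes")
    mean = x.mean(axis=0)
    z = (x - mean) / sd

    pca = PCA(n_components=len(classes), svd_solver="full")
    scores_full = pca.fit_transform(z)
    loadings = pca.components_.T  # columns = axes
    # deterministic signs: largest-|loading| entry of each axis is positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores_full[:, j] *= -1.0

    ids = (
        site_compositions["site_id"]
        if "site_id" in site_compositions.columns
        else site_compositions.index
    )
    site_scores = pd.DataFrame(
        scores_full[:, :n_axes],
        columns=[f"PC{j + 1}" for j in range(n_axes)],
        index=pd.Index(ids, name="site_id"),
    )
    return PcaBasis(
        classes=classes,
        mean=mean,
        sd=sd,
        loadings=loadings,
        explained_variance=pca.explained_variance_.copy(),
        explained_ratio=pca.explained_variance_ratio_.copy(),
        n_axes=n_axes,
        site_scores=site_scores,
    )


def project(basis: PcaBasis, compositions: pd.DataFrame, n_axes: int | None = None) -> pd.DataFrame:
    """Project compositions (sites or grid cells) onto the fitted axes.

    Standardization uses the *camera-site* means and s.d.s stored in the
    basis, which keeps cell-level covariates on the same scale as the ones
    the habitat coefficients were estimated on.
    """
    n_axes = basis.n_axes if n_axes is None else n_axes
    x = _validate_composition(compositions, basis.classes)
    z = (x - basis.mean) / basis.sd
    scores = z @ basis.loadings[:, :n_axes]
    id_col = next(
        (c for c in ("cell_id", "site_id", "camera_id") if c in compositions.columns),
        None,
    )
    ids = compositions[id_col] if id_col is not None else compositions.index
    return pd.DataFrame(
        scores,
        columns=[f"PC{j + 1}" for j in range(n_axes)],
        index=pd.Index(ids, name=id_col or "id"),
    )
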