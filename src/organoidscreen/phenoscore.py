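"""Discriminating-feature training and phenotypic distance scoring.

Training contrasts vehicle-control (DMSO) wells against high-dose wells of
one compound. Features are z-scored with training statistics (global mean,
pooled within-class SD) and ranked by absolute loading on a principal
component; the top k (default 10) features define the phenotypic
fingerprint space.

Three component strategies are available. The default, ``centroid``, fits
the PCA on the two class-centroid vectors, whose first component is
exactly the standardized class-mean-difference direction — so features
are ranked by how far the classes separate in within-class SD units.
``best_separating`` and ``pc1`` instead fit the PCA on the full
standardized well matrix and use the component whose scores best separate
the classes (or unconditionally the first). With tens of wells and
hundreds of features the full-matrix components are dominated by sampling
noise (the leading Wishart noise eigenvalue exceeds any realistic signal
eigenvalue), which makes ``centroid`` the reliable default for screens of
this size.

Every well is then scored by the Euclidean distance between its
standardized selected-feature vector and the control-well centroid:

    D = sqrt( sum_f ( (x_f - mu_f)/sigma_f - c_f )^2 )

A low distance means the well resembles untreated controls; distance
grows with dose for a responsive line, giving a dose-response readout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import ValidationError
from .morphometry import WellProfile


class TrainingError(RuntimeError):
    """Raised when the training classes are too small or empty."""


@dataclass
class FeatureSelection:
    """Trained standardization + ranked discriminating features."""

    selected_features: List[str]
    train_mean: Dict[str, float]
    train_sd: Dict[str, float]
    component_loadings: Dict[str, float]
    control_centroid: Dict[str, float]
    training_wells: Dict[str, List[str]]
    strategy: str = "best_separating"
    separation: float = 0.0
    component_index: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSelection":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class DistanceResult:
    well_id: str
    compound: str
    dose_nM: float
    distance: float


def _usable(profiles: Sequence[WellProfile]) -> List[WellProfile]:
    return [p for p in profiles if not p.degenerate]


def _feature_matrix(profiles: Sequence[WellProfile],
                    names: Sequence[str]) -> np.ndarray:
    return np.array([[p.features[n] for n in names] for p in profiles])


def train_feature_space(profiles: Sequence[WellProfile],
                        control_label: str = "DMSO",
                        compound: str | None = None,
                        k: int = 10,
                        strategy: str = "centroid",
                        ) -> FeatureSelection:
    """Select the top-k discriminating features between control and
    high-dose wells and fit the standardization used for scoring.

    The high-dose class is every treated well of ``compound`` (or of the
    single compound present) at its maximum dose. Zero-variance features
    are dropped before z-scoring; ties in |loading| break by feature name.
    """
    profiles = _usable(list(profiles))
    controls = [p for p in profiles
                if p.metadata.get("role") == "control"
                or p.metadata.get("compound") == control_label]
    control_ids = {id(p) for p in controls}
    treated = [p for p in profiles if id(p) not in control_ids]
    if compound is not None:
        treated = [p for p in treated
                   if p.metadata.get("compound") == compound]
    if not treated:
        raise TrainingError("no treated wells for the requested compound")
    top_dose = max(float(p.metadata.get("dose_nM", 0)) for p in treated)
    high = [p for p in treated
            if float(p.metadata.get("dose_nM", 0)) == top_dose]
    if len(controls) < 2 or len(high) < 2:
        raise TrainingError("need >= 2 wells in each training class")

    train = controls + high
    labels = np.array([0] * len(controls) + [1] * len(high))
    all_names = sorted(train[0].features)
    mat = _feature_matrix(train, all_names)

    keep = mat.std(axis=0, ddof=0) > 0
    names = [n for n, kf in zip(all_names, keep) if kf]
    if k > len(names):
        raise ValidationError(
            f"k={k} exceeds the {len(names)} non-constant features")
    mat = mat[:, keep]
    mean = mat.mean(axis=0)
    # pooled within-class SD: measures class separation in noise units and
    # keeps a shifted feature's own shift out of its scale
    var0 = mat[labels == 0].var(axis=0, ddof=0)
    var1 = mat[labels == 1].var(axis=0, ddof=0)
    n0, n1 = (labels == 0).sum(), (labels == 1).sum()
    sd = np.sqrt((n0 * var0 + n1 * var1) / (n0 + n1))
    combined_sd = mat.std(axis=0, ddof=0)
    sd = np.maximum(sd, 1e-8 * combined_sd)
    z = (mat - mean) / sd

    comp_idx = 0
    if strategy == "centroid":
        centroids = np.vstack([z[labels == 0].mean(axis=0),
                               z[labels == 1].mean(axis=0)])
        pca = PCA(n_components=1, svd_solver="full")
        pca.fit(centroids)
        loadings = pca.components_[0]
    elif strategy in ("pc1", "best_separating"):
        n_comp = min(len(train) - 1, z.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full")
        scores = pca.fit_transform(z)
        if strategy == "best_separating":
            seps = []
            for j in range(n_comp):
                s0, s1 = scores[labels == 0, j], scores[labels == 1, j]
                pooled = np.sqrt((s0.var(ddof=0) + s1.var(ddof=0)) / 2)
                seps.append(abs(s0.mean() - s1.mean())
                            / max(pooled, 1e-12))
            comp_idx = int(np.argmax(seps))
        loadings = pca.components_[comp_idx]
    else:
        raise ValidationError(f"unknown strategy {strategy!r}")

    # fix the sign so the largest-|loading| entry is positive
    if loadings[np.argmax(np.abs(loadings))] < 0:
        loadings = -loadings
    # rank by |loading| descending, ties by feature name order
    order = sorted(range(len(names)),
                   key=lambda i: (-abs(loadings[i]), names[i]))
    selected = [names[i] for i in order[:k]]

    # separation of the trained fingerprint: standardized class-mean
    # difference projected onto the selected-feature subspace
    sel_idx = [names.index(n) for n in selected]
    z_sel = z[:, sel_idx]
    diff = z_sel[labels == 1].mean(axis=0) - z_sel[labels == 0].mean(axis=0)
    direction_sel = diff / max(np.linalg.norm(diff), 1e-12)
    proj = z_sel @ direction_sel
    s0, s1 = proj[labels == 0], proj[labels == 1]
    pooled = np.sqrt((s0.var(ddof=0) + s1.var(ddof=0)) / 2)
    separation = float(abs(s0.mean() - s1.mean()) / max(pooled, 1e-12))

    mean_map = {n: float(mean[names.index(n)]) for n in selected}
    sd_map = {n: float(sd[names.index(n)]) for n in selected}
    centroid = {}
    for n in selected:
        vals = np.array([p.features[n] for p in controls])
        centroid[n] = float((vals.mean() - mean_map[n]) / sd_map[n])

    return FeatureSelection(
        selected_features=selected,
        train_mean=mean_map, train_sd=sd_map,
        component_loadings={n: float(loadings[names.index(n)])
                            for n in selected},
        control_centroid=centroid,
        training_wells={"control": [p.well_id for p in controls],
                        "high_dose": [p.well_id for p in high]},
        strategy=strategy, separation=separation,
        component_index=comp_idx)


def score_well(profile: WellProfile, selection: FeatureSelection,
               ) -> DistanceResult:
    """Euclidean distance of one well to the control centroid in the
    standardized selected-feature space."""
    missing = [n for n in selection.selected_features
               if n not in profile.features]
    if missing:
        raise ValidationError(f"profile lacks selected features: {missing}")
    sq = 0.0
    for n in selection.selected_features:
        z = ((profile.features[n] - selection.train_mean[n])
             / selection.train_sd[n])
        sq += (z - selection.control_centroid[n]) ** 2
    return DistanceResult(
        well_id=profile.well_id,
        compound=str(profile.metadata.get("compound", "")),
        dose_nM=float(profile.metadata.get("dose_nM", np.nan)),
        distance=float(np.sqrt(sq)))


def score_plate(profiles: Sequence[WellProfile],
                selection: FeatureSelection) -> pd.DataFrame:
    """Mean ± SD distance per (compound, dose) condition.

    Returns one row per condition with columns compound, dose_nM,
    mean_distance, sd_distance, n; degenerate wells are excluded.
    """
    results = [score_well(p, selection) for p in _usable(list(profiles))]
    df = pd.DataFrame([r.__dict__ for r in results])
    if df.empty:
        return pd.DataFrame(columns=["compound", "dose_nM", "mean_distance",
                                     "sd_distance", "n"])
    grouped = (df.groupby(["compound", "dose_nM"], as_index=False)
               .agg(mean_distance=("distance", "mean"),
                    sd_distance=("distance", lambda x: x.std(ddof=1)
                                 if len(x) > 1 else 0.0),
                    n=("distance", "size")))
    return grouped.sort_values(["compound", "dose_nM"]).reset_index(drop=True)


def score_wells(profiles: Sequence[WellProfile],
                selection: FeatureSelection) -> pd.DataFrame:
    """Per-well distance table (well, compound, dose_nM, distance)."""
    results = [score_well(p, selection) for p in _usable(list(profiles))]
    return pd.DataFrame([r.__dict__ for r in results])
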