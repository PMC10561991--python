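"""Phenotype classification from curated time-series features.

Each specimen's binned activity series is mapped to the 22 canonical
curated features (see :mod:`behavkit._catch22`), standardized, and fed
to a support-vector machine with stratified cross-validation.  A 2-D
decision surface over the first two principal axes of the standardized
features reproduces the field's usual visualization of how the
classifier separates phenotypes.  For massive-feature toolboxes that
run outside Python, :func:`export_timeseries_bundle` writes a plain-text
per-specimen series bundle plus a manifest.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from ._catch22 import FEATURE_NAMES, MIN_LENGTH, compute_features

__all__ = [
    "FEATURE_NAMES",
    "extract_curated_features",
    "zscore_features",
    "classify_phenotypes",
    "decision_surface",
    "export_timeseries_bundle",
]


def extract_curated_features(series_by_id: dict[str, np.ndarray] | pd.DataFrame,
                             value_column: str | None = None):
    """Extract the 22 curated features per specimen.

    Parameters
    ----------
    series_by_id
        Either ``{id: 1-D array}`` or a long frame with an ``id`` column
        and *value_column* (rows in time order).
    value_column
        Required for the frame form.

    Returns
    -------
    (features, excluded)
        *features*: frame indexed by specimen id with exactly the 22
        named feature columns, rows in input order.  Failed cells are
        NaN (the per-cell failure flag); constant series keep their row
        with every cell flagged.  *excluded*: ids of series too short to
        process (< 10 bins), excluded and reported rather than half
        computed.
    """
    if isinstance(series_by_id, pd.DataFrame):
        if value_column is None:
            raise ValueError("value_column required for frame input")
        series_by_id = {
            sid: grp[value_column].to_numpy(dtype=float)
            for sid, grp in series_by_id.groupby("id", sort=False)
        }
    rows, index, excluded = [], [], []
    for sid, series in series_by_id.items():
        series = np.asarray(series, dtype=float)
        if len(series) < MIN_LENGTH:
            excluded.append(sid)
            continue
        rows.append(compute_features(series))
        index.append(sid)
    fm = pd.DataFrame(rows, index=pd.Index(index, name="id"),
                      columns=list(FEATURE_NAMES))
    return fm, excluded


def zscore_features(fm: pd.DataFrame):
    """Standardize each feature column to mean 0, sd 1.

    Zero-variance (or all-NaN) columns are set to 0 and reported in the
    returned flag list instead of silently producing NaN.
    Returns ``(standardized, flagged_columns)``.
    """
    out = fm.copy()
    flagged = []
    for col in out.columns:
        vals = out[col].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        sd = vals[finite].std() if finite.any() else 0.0
        if not finite.any() or sd == 0:
            out[col] = 0.0
            flagged.append(col)
        else:
            out[col] = (vals - vals[finite].mean()) / sd
    return out, flagged


def classify_phenotypes(fm: pd.DataFrame, labels, kernel: str = "rbf",
                        k_folds: int = 5, seed: int | None = None):
    """Cross-validated SVM phenotype classification.

    Features are standardized internally (NaN cells imputed to the
    column mean, i.e. 0 after standardization).  Stratified k-fold with
    seeded fold assignment; accuracy is the fraction of correct held-out
    predictions.

    Returns ``(accuracy, predictions)`` where predictions is a frame
    ``(id, label, predicted)``.
    """
    labels = pd.Series(np.asarray(labels), index=fm.index)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < k_folds:
        raise ValueError(
            f"class {classes[int(np.argmin(counts))]!r} has only "
            f"{counts.min()} specimens; use k_folds <= {counts.min()}"
        )
    X, _ = zscore_features(fm)
    X = X.fillna(0.0).to_numpy()
    y = labels.to_numpy()
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    clf = SVC(kernel=kernel, gamma="scale")
    pred = cross_val_predict(clf, X, y, cv=cv)
    accuracy = float(np.mean(pred == y))
    predictions = pd.DataFrame({"id": fm.index, "label": y, "predicted": pred})
    return accuracy, predictions


def decision_surface(fm: pd.DataFrame, labels, kernel: str = "rbf",
                     grid_resolution: int = 100, seed: int | None = None):
    """Decision surface of an SVM in the plane of the first two
    principal axes of the standardized features.

    Returns a dict with the projected points (``points``: id, pc1, pc2,
    label), the fitted 2-D classifier, and the label grid (``xx``,
    ``yy``, ``grid_labels``) over the data's bounding box.
    """
    X, _ = zscore_features(fm)
    X = X.fillna(0.0).to_numpy()
    labels = np.asarray(labels)
    proj = PCA(n_components=2, random_state=seed).fit_transform(X)
    x0, x1 = proj[:, 0].min(), proj[:, 0].max()
    y0, y1 = proj[:, 1].min(), proj[:, 1].max()
    xx, yy = np.meshgrid(np.linspace(x0, x1, grid_resolution),
                         np.linspace(y0, y1, grid_resolution))
    if len(np.unique(labels)) == 1:
        clf = None  # nothing to separate: the surface is uniform
        grid_labels = np.full(xx.size, labels[0])
    else:
        clf = SVC(kernel=kernel, gamma="scale").fit(proj, labels)
        grid_labels = clf.predict(np.column_stack([xx.ravel(), yy.ravel()]))
    points = pd.DataFrame({"id": fm.index, "pc1": proj[:, 0],
                           "pc2": proj[:, 1], "label": labels})
    return {
        "points": points,
        "classifier": clf,
        "xx": xx,
        "yy": yy,
        "grid_labels": grid_labels.reshape(xx.shape),
    }


def export_timeseries_bundle(series_by_id, out_dir,
                             meta: pd.DataFrame | None = None,
                             value_column: str | None = None) -> pd.DataFrame:
    """Write one plain-text series file per specimen plus a manifest.

    The interchange shape expected by external massive-feature
    toolboxes: one value per line per file, and a ``manifest.csv``
    listing (id, file, metadata columns).  Returns the manifest.
    """
    if isinstance(series_by_id, pd.DataFrame):
        if value_column is None:
            raise ValueError("value_column required for frame input")
        series_by_id = {
            sid: grp[value_column].to_numpy(dtype=float)
            for sid, grp in series_by_id.groupby("id", sort=False)
        }
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, (sid, series) in enumerate(series_by_id.items()):
        fname = f"series_{i:04d}.txt"
        np.savetxt(os.path.join(out_dir, fname),
                   np.asarray(series, dtype=float), fmt="%.10g")
        row = {"id": sid, "file": fname}
        if meta is not None:
            mrow = meta[meta["id"] == sid]
            if len(mrow):
                row.update(mrow.iloc[0].drop("id").to_dict())
        rows.append(row)
    manifest = pd.DataFrame(rows, columns=None if rows else ["id", "file"])
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
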