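"""Compositing, denoising and forest-probability modelling.

Daily reflectance is reduced to annual medians, the annual series is
smoothed with a 3-year moving median, and a bagged-tree classifier
trained on labelled (bands + elevation) records yields annual
forest-probability maps.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, cross_val_predict


def annual_median_composite(values, dates, year: int):
    """Per pixel-band median over valid daily observations of one year.

    Parameters
    ----------
    values : (n_obs, ...) array; NaN marks invalid observations.
    dates : array-like of numpy datetime64 / pandas timestamps, one per
        observation.
    year : calendar year to composite.

    Returns the composite with NaN where no valid observation exists.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(dates, dtype="datetime64[Y]").astype(int) + 1970
    sel = years == year
    if not sel.any():
        raise ValueError(f"year {year} absent from input dates")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(values[sel], axis=0)


def moving_median3(values, years, alignment: str = "trailing"):
    """3-year moving median with a valid-window (full windows only) policy.

    ``alignment`` controls the output year labels: 'trailing' labels each
    window by its last year (input 2000-2017 -> output 2002-2017),
    'centered' by its middle year (-> 2001-2016).  Window content is the
    same either way; only the labelling differs.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=int)
    n = len(years)
    if values.shape[0] != n:
        raise ValueError("values and years length mismatch")
    if n < 3:
        raise ValueError(f"need >= 3 annual values, got {n}")
    if alignment not in ("trailing", "centered"):
        raise ValueError(f"unknown alignment {alignment!r}")
    windows = np.stack([values[i : i + 3] for i in range(n - 2)])
    smoothed = np.median(windows, axis=1)
    out_years = years[2:] if alignment == "trailing" else years[1:-1]
    return smoothed, out_years


def train_forest_classifier(
    X,
    y,
    seed: int = 0,
    n_estimators: int = 500,
    cv_folds: int = 3,
):
    """Fit a probabilistic forest/non-forest classifier.

    ``X`` holds one record per training point (bands + elevation); ``y``
    is binary (1 = forest).  Returns ``(classifier, cv_r)`` where cv_r is
    the k-fold cross-validation Pearson correlation between predicted
    forest probability and the labels.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != len(y):
        raise ValueError("X and y length mismatch")
    if X.shape[0] < 30:
        raise ValueError(f"need >= 30 training records, got {X.shape[0]}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("single-class training set; both classes required")
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    prob = cross_val_predict(clf, X, y, cv=cv, method="predict_proba")[:, 1]
    if np.std(prob) == 0:
        cv_r = 0.0
    else:
        cv_r = float(stats.pearsonr(prob, y)[0])
    clf.fit(X, y)
    return clf, cv_r


def average_band_features(reflectance: np.ndarray) -> np.ndarray:
    """Average bands across all years, per pixel, for stable-class
    training points: (year, band, row, col) -> (band, row, col)."""
    return np.asarray(reflectance, dtype=float).mean(axis=0)


def predict_probability(clf, reflectance: np.ndarray, elevation: np.ndarray):
    """Annual forest-probability stack from a fitted classifier.

    ``reflectance`` is (year, band, row, col), ``elevation`` (row, col).
    Pixels with any missing band (or missing elevation) in a given year
    are flagged missing (NaN), never coerced to non-forest.
    """
    reflectance = np.asarray(reflectance, dtype=float)
    if reflectance.ndim != 4:
        raise ValueError("reflectance must be (year, band, row, col)")
    ny, nb, nr, nc = reflectance.shape
    if nb != clf.n_features_in_ - 1:
        raise ValueError(
            f"band count {nb} does not match training ({clf.n_features_in_ - 1})"
        )
    elevation = np.asarray(elevation, dtype=float)
    prob = np.full((ny, nr, nc), np.nan)
    elev_flat = elevation.reshape(-1)
    for yi in range(ny):
        feats = reflectance[yi].reshape(nb, -1).T
        X = np.column_stack([feats, elev_flat])
        valid = np.all(np.isfinite(X), axis=1)
        if valid.any():
            p = clf.predict_proba(X[valid])[:, 1]
            flat = np.full(nr * nc, np.nan)
            flat[valid] = p
            prob[yi] = flat.reshape(nr, nc)
    return prob
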