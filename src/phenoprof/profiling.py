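"""Phenotypic profile construction: mean, PCA and SVM-based d-profiles.

A *profile* condenses the single-cell feature distribution of one treatment
into one vector so treatments can be compared and clustered:

- **mean** profiles are the arithmetic mean of each feature across all
  cells of the treatment;
- **PCA** profiles keep the principal-component scores of the
  treatment-by-feature matrix of mean profiles that explain 95% of its
  variance;
- **d-profiles** train a linear support-vector machine separating the
  treated cells from negative-control cells in feature space and use the
  unit normal of the separating hyperplane as the profile.  Features that
  vary strongly but identically in treated and control cells receive small
  weights, which is what makes d-profiles discriminative.

Features are standardized against the control population (z-scores by
control mean and population SD) before SVM or PCA fitting, so the SVM
weight magnitudes are comparable across features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import LinearSVC

from .containers import FeatureTable

logger = logging.getLogger(__name__)

PROFILE_METHODS = ("mean", "pca", "dprofile")


@dataclass
class Profile:
    """One treatment's profile vector with its method and group metadata."""

    values: np.ndarray
    treatment_id: str
    method: str
    group_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.method not in PROFILE_METHODS:
            raise ValueError(f"unknown profile method {self.method!r}")
        if self.method == "dprofile":
            nrm = np.linalg.norm(self.values)
            if abs(nrm - 1.0) > 1e-9:
                raise ValueError(f"d-profile must be unit-norm, |w|={nrm}")


@dataclass
class ProfileSet:
    """Profiles sharing one method and dimensionality, with group labels."""

    profiles: list[Profile]
    method: str = ""
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("empty profile set")
        if not self.method:
            self.method = self.profiles[0].method
        dims = {p.values.size for p in self.profiles}
        if len(dims) != 1:
            raise ValueError(f"profiles have mixed dimensionality: {dims}")
        for p in self.profiles:
            if p.method != self.method:
                raise ValueError("profiles mix methods")

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, treatment_id: str) -> Profile:
        for p in self.profiles:
            if p.treatment_id == treatment_id:
                return p
        raise KeyError(treatment_id)

    @property
    def group_map(self) -> dict[str, str | None]:
        return {p.treatment_id: p.group_id for p in self.profiles}

    def to_matrix(self) -> np.ndarray:
        return np.vstack([p.values for p in self.profiles])


@dataclass
class Standardizer:
    """Control-anchored z-score transform, reapplicable to treated cells."""

    feature_names: list[str]
    location: np.ndarray
    scale: np.ndarray

    def apply(self, table: FeatureTable) -> FeatureTable:
        sub = table.select_columns(self.feature_names)
        z = (sub.values - self.location) / self.scale
        return FeatureTable(z, list(self.feature_names), sub.cells.copy())


def standardize_features(
    table: FeatureTable, control_table: FeatureTable
) -> tuple[FeatureTable, Standardizer]:
    """Z-score ``table`` by the control population's mean and SD per feature.

    Features whose control SD is zero (no information) are dropped with a
    logged list.  The returned :class:`Standardizer` reapplies the same
    transform to any other table.
    """
    if control_table.n_cells < 2:
        raise ValueError("control table needs >= 2 cells")
    if control_table.feature_names != table.feature_names:
        raise ValueError("tables must share the feature-name list")
    loc = np.nanmean(control_table.values, axis=0)
    scale = np.nanstd(control_table.values, axis=0)
    keep = scale > 0
    if not keep.all():
        dropped = [n for n, k in zip(table.feature_names, keep) if not k]
        logger.info("dropping %d zero-variance features: %s",
                    len(dropped), dropped)
    names = [n for n, k in zip(table.feature_names, keep) if k]
    std = Standardizer(names, loc[keep], scale[keep])
    return std.apply(table), std


def clean_nan_features(
    tables: dict[str, FeatureTable],
    control: FeatureTable,
    max_nan_fraction: float = 0.10,
) -> tuple[dict[str, FeatureTable], FeatureTable]:
    """Drop mostly-undefined features; impute the rest with control medians.

    A feature undefined (NaN) in more than ``max_nan_fraction`` of all cells
    is removed everywhere; remaining NaNs are replaced by the control median
    of the feature, so downstream solvers see complete data.
    """
    all_values = np.vstack([control.values] + [t.values for t in tables.values()])
    nan_frac = np.isnan(all_values).mean(axis=0)
    keep = nan_frac <= max_nan_fraction
    names = [n for n, k in zip(control.feature_names, keep) if k]
    if len(names) < len(control.feature_names):
        logger.info("dropping %d features with > %.0f%% undefined values",
                    len(control.feature_names) - len(names),
                    100 * max_nan_fraction)

    med = np.nanmedian(control.values[:, keep], axis=0)
    med = np.where(np.isnan(med), 0.0, med)

    def fix(t: FeatureTable) -> FeatureTable:
        v = t.values[:, keep].copy()
        idx = np.where(np.isnan(v))
        v[idx] = med[idx[1]]
        return FeatureTable(v, list(names), t.cells.copy())

    return {k: fix(t) for k, t in tables.items()}, fix(control)


def mean_profile(
    table: FeatureTable, treatment_id: str, group_id: str | None = None
) -> Profile:
    """Arithmetic mean of each feature across the treatment's cells."""
    if table.n_cells == 0:
        raise ValueError("cannot average an empty table")
    with np.errstate(invalid="ignore"):
        vals = np.nanmean(table.values, axis=0)
    return Profile(vals, treatment_id, "mean", group_id)


def pca_profiles(
    mean_set: ProfileSet, variance_kept: float = 0.95
) -> ProfileSet:
    """PCA scores of the treatment x feature matrix of mean profiles.

    The matrix is column-centred; the smallest number of leading components
    whose cumulative explained variance reaches ``variance_kept`` is
    retained and each treatment's score vector becomes its profile.
    """
    if len(mean_set) < 2:
        raise ValueError("PCA profiles need >= 2 treatments")
    if not 0 < variance_kept <= 1:
        raise ValueError("variance_kept must be in (0, 1]")
    x = mean_set.to_matrix()
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
    k = min(k, scores.shape[1])
    profiles = [
        Profile(scores[i, :k], p.treatment_id, "pca", p.group_id)
        for i, p in enumerate(mean_set.profiles)
    ]
    return ProfileSet(profiles, "pca")


def d_profile(
    treated: FeatureTable,
    control: FeatureTable,
    treatment_id: str = "",
    group_id: str | None = None,
    C: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 20000,
) -> Profile:
    """Unit normal of a linear-SVM hyperplane separating treated from control.

    The SVM is L2-regularized with squared-hinge loss, solved in the primal
    (treated = +1, control = -1) with class-balanced weights; the intercept
    is excluded from the profile, which is normalized to unit length.
    Expects standardized, complete (non-NaN) features.
    """
    if treated.n_cells == 0 or control.n_cells == 0:
        raise ValueError("both classes must be nonempty")
    if treated.feature_names != control.feature_names:
        raise ValueError("tables must share the feature-name list")
    x = np.vstack([treated.values, control.values])
    if not np.isfinite(x).all():
        raise ValueError("non-finite feature values; standardize/impute first")
    y = np.concatenate([np.ones(treated.n_cells), -np.ones(control.n_cells)])
    svm = LinearSVC(
        C=C,
        loss="squared_hinge",
        penalty="l2",
        dual=False,
        tol=tol,
        class_weight="balanced",
        max_iter=max_iter,
    )
    svm.fit(x, y)
    w = svm.coef_.ravel().astype(float)
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("degenerate SVM solution (zero weight vector)")
    return Profile(w / nrm, treatment_id, "dprofile", group_id)


def build_profiles(
    tables: dict[str, FeatureTable],
    method: str,
    control_treatment: str | None = None,
    group_map: dict[str, str] | None = None,
    standardize: bool = True,
    variance_kept: float = 0.95,
    C: float = 1.0,
) -> ProfileSet:
    """One profile per non-control treatment by the chosen method.

    ``tables`` maps treatment id -> FeatureTable.  Mean profiles average the
    features as stored; PCA and d-profiles are fitted on control-anchored
    z-scores (``standardize=True``), so both need ``control_treatment`` to
    name the negative-control treatment, whose cells also form the SVM's
    negative class.  The control itself receives no profile.
    """
    if method not in PROFILE_METHODS:
        raise ValueError(f"unknown profile method {method!r}; "
                         f"choose from {PROFILE_METHODS}")
    group_map = group_map or {}
    needs_control = method == "dprofile" or (standardize and method == "pca")
    if needs_control and (control_treatment is None
                          or control_treatment not in tables):
        raise ValueError(
            f"method {method!r} requires a control treatment present in the "
            f"tables"
        )
    treated_ids = [t for t in tables if t != control_treatment]
    if not treated_ids:
        raise ValueError("no non-control treatments to profile")

    if method == "mean":
        means = [
            mean_profile(tables[t], t, group_map.get(t)) for t in treated_ids
        ]
        return ProfileSet(means, "mean", tables[treated_ids[0]].feature_names)

    work = {t: tables[t] for t in treated_ids}
    if needs_control:
        control = tables[control_treatment]
        work, control = clean_nan_features(work, control)
        if standardize:
            _, std = standardize_features(control, control)
            work = {t: std.apply(tab) for t, tab in work.items()}
            control = std.apply(control)
    else:
        control = None

    if method == "dprofile":
        profiles = [
            d_profile(work[t], control, t, group_map.get(t), C=C)
            for t in treated_ids
        ]
        return ProfileSet(profiles, "dprofile", control.feature_names)

    means = [
        mean_profile(work[t], t, group_map.get(t)) for t in treated_ids
    ]
    mean_set = ProfileSet(means, "mean", work[treated_ids[0]].feature_names)
    return pca_profiles(mean_set, variance_kept=variance_kept)
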