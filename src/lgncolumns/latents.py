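"""Latent-variable estimation across pooled depth profiles.

The four per-group metrics (cell counts, radial spread, topological order,
topographical order) are reduced to their shape by a zero-mean /
unit-variance standardization per profile, resampled onto the 21 depth
levels, and stacked into one matrix (rows = metric × group profiles,
columns = depth levels).  An autoassociative partial-least-squares
decomposition (X = Y = the profile matrix) then asks how many latent
factors are needed: cumulative % explained variance and a cross-validated
reconstruction error are reported per latent count.

Cross-validation uses an element-wise held-out reconstruction: for each
held-out profile, every depth level is predicted from the remaining levels
through the train-fold loadings.  Unlike a plain orthogonal projection of
the held-out row (whose error can only decrease with more latents), this
estimate rises again once components start fitting noise, so its minimum
estimates the effective rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold, LeaveOneOut

from .columns import DepthProfile
from .errors import ConfigError, DegenerateGeometryError, MissingMetricError
from .order import OrderResult

METRICS = ("count", "spread", "topology", "topography")


def standardize_profile(values) -> np.ndarray:
    """Shape-preserving normalization: zero mean, unit population variance."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise DegenerateGeometryError("profile must be a 1D array of length ≥ 2")
    sd = v.std()  # population (1/n) convention
    if sd < 1e-12:
        raise DegenerateGeometryError("constant profile cannot be standardized")
    return (v - v.mean()) / sd


@dataclass
class ProfileMatrix:
    """Standardized metric × group profiles on a common depth axis."""

    values: np.ndarray  # (n_rows, n_levels), each row mean 0 / variance 1
    metrics: list[str]
    groups: list[str]
    depths: np.ndarray  # (n_levels,)

    @property
    def n_rows(self) -> int:
        return len(self.values)

    @property
    def n_levels(self) -> int:
        return self.values.shape[1]

    def row_labels(self) -> list[str]:
        return [f"{m}:{g}" for m, g in zip(self.metrics, self.groups)]


def _resample_profile(profile: DepthProfile, depths: np.ndarray) -> np.ndarray:
    """Linear interpolation of bin-centre values onto the map depth levels."""
    centers = profile.centers
    mean = profile.mean
    ok = np.isfinite(mean)
    if ok.sum() < 2:
        raise MissingMetricError(f"profile {profile.kind!r} has < 2 finite bins")
    return np.interp(depths, centers[ok], mean[ok])


def _order_curve(results: list[OrderResult], depths: np.ndarray) -> np.ndarray:
    obs_depths = np.array([r.depth for r in results], dtype=float)
    values = np.array([r.normalized_pt for r in results], dtype=float)
    order = np.argsort(obs_depths)
    return np.interp(depths, obs_depths[order], values[order])


def assemble_profiles(
    counts: dict[str, DepthProfile],
    spreads: dict[str, DepthProfile],
    topology: dict[str, list[OrderResult]],
    topography: dict[str, list[OrderResult]],
    depths: np.ndarray | None = None,
) -> ProfileMatrix:
    """Stack the four standardized metrics for every group into one matrix.

    All four metrics must be present for every included group; count and
    spread bin centres and the topology step depths are linearly
    interpolated onto the 21 map levels so every row shares one depth axis.
    """
    if depths is None:
        depths = np.round(np.linspace(0.0, 1.0, 21), 10)
    groups = sorted(set(counts) | set(spreads) | set(topology) | set(topography))
    gaps = [
        f"{g}:{name}"
        for g in groups
        for name, d in zip(METRICS, (counts, spreads, topology, topography))
        if g not in d
    ]
    if gaps:
        raise MissingMetricError(f"missing metric(s) for group(s): {gaps}")
    rows, metrics, row_groups = [], [], []
    for g in groups:
        for name, curve in (
            ("count", _resample_profile(counts[g], depths)),
            ("spread", _resample_profile(spreads[g], depths)),
            ("topology", _order_curve(topology[g], depths)),
            ("topography", _order_curve(topography[g], depths)),
        ):
            rows.append(standardize_profile(curve))
            metrics.append(name)
            row_groups.append(g)
    return ProfileMatrix(
        values=np.array(rows), metrics=metrics, groups=row_groups, depths=depths
    )


# ---------------------------------------------------------------------------
# PLS latent scan


@dataclass
class LatentScan:
    """Explained variance and CV reconstruction error per latent count."""

    n_latents: np.ndarray  # 1 … max
    pct_var_explained: np.ndarray  # cumulative, non-decreasing
    cv_mse: np.ndarray
    fold_scheme: str
    seed: int | None

    @property
    def best_by_cv(self) -> int:
        """Smallest latent count whose CV error ties the minimum.

        Errors within a tiny tolerance of the minimum (relative 1e-9, plus
        an absolute floor of 1e-12 on unit-variance profiles) count as
        ties, so exact low-rank inputs resolve to the true rank instead of
        an arbitrary numerically-zero competitor.
        """
        minimum = float(self.cv_mse.min())
        threshold = minimum * (1 + 1e-9) + 1e-12
        return int(self.n_latents[np.argmax(self.cv_mse <= threshold)])


def _fit_pls(X: np.ndarray, n_components: int) -> PLSRegression:
    with warnings.catch_warnings():
        # exact low-rank input legitimately exhausts the residual early
        warnings.filterwarnings("ignore", message=".*residual is constant.*")
        return PLSRegression(n_components=n_components, scale=False).fit(X, X)


def _held_out_mse(X_test: np.ndarray, mean: np.ndarray, L: np.ndarray, m: int) -> float:
    """Element-wise reconstruction error of held-out rows.

    Each variable j of a held-out centred row y is predicted by solving
    the least-squares score fit on the remaining variables with the first
    m loading vectors, then evaluating loading row j at those scores.
    """
    Lm = L[:, :m]
    total, count = 0.0, 0
    for y in X_test - mean:
        for j in range(len(y)):
            keep = np.arange(len(y)) != j
            score, *_ = np.linalg.lstsq(Lm[keep], y[keep], rcond=None)
            pred = Lm[j] @ score
            total += (pred - y[j]) ** 2
            count += 1
    return total / count


def pls_latent_scan(
    matrix: ProfileMatrix | np.ndarray,
    max_latents: int,
    folds: str | int = "loo",
    seed: int | None = None,
    orientation: str = "rows",
) -> LatentScan:
    """Scan latent counts 1 … ``max_latents`` of an autoassociative PLS.

    ``orientation='rows'`` treats profiles as observations and depth levels
    as variables; ``'columns'`` transposes the matrix first.  ``folds`` is
    ``'loo'`` or an integer k ≥ 2 (shuffled k-fold, seeded).
    """
    X = matrix.values if isinstance(matrix, ProfileMatrix) else np.asarray(matrix, float)
    if orientation == "columns":
        X = X.T
    elif orientation != "rows":
        raise ConfigError(f"unknown orientation {orientation!r}")
    n_rows, n_cols = X.shape
    if not 1 <= max_latents < min(n_rows, n_cols):
        raise ConfigError(
            f"max_latents must be in [1, {min(n_rows, n_cols) - 1}], got {max_latents}"
        )
    # explained variance from one full-depth fit (components are nested)
    full = _fit_pls(X, max_latents)
    Yc = X - X.mean(axis=0)
    ss_tot = float((Yc**2).sum())
    pct = np.empty(max_latents)
    for m in range(1, max_latents + 1):
        fitted = full.x_scores_[:, :m] @ full.y_loadings_[:, :m].T
        pct[m - 1] = 100.0 * (1.0 - float(((Yc - fitted) ** 2).sum()) / ss_tot)

    if folds == "loo":
        splitter = LeaveOneOut()
        scheme = "leave-one-out"
    else:
        k = int(folds)
        if k < 2 or k > n_rows:
            raise ConfigError(f"k-fold needs 2 ≤ k ≤ {n_rows}, got {k}")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        scheme = f"{k}-fold"
    sse = np.zeros(max_latents)
    n_folds = 0
    for train, test in splitter.split(X):
        fit = _fit_pls(X[train], max_latents)
        L = fit.y_loadings_
        mean = X[train].mean(axis=0)
        for m in range(1, max_latents + 1):
            sse[m - 1] += _held_out_mse(X[test], mean, L, m)
        n_folds += 1
    return LatentScan(
        n_latents=np.arange(1, max_latents + 1),
        pct_var_explained=pct,
        cv_mse=sse / n_folds,
        fold_scheme=scheme,
        seed=seed,
    )
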