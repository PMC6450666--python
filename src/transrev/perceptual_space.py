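"""Perceptual odor spaces from pairwise similarity ratings.

Each subject rates the dissimilarity of all six unordered odor pairs on a
0 ("identical") to 1 ("completely different") scale. Metric MDS embeds the
resulting 4x4 dissimilarity matrix in the plane; individual spaces are
aligned to the group-average space by a full Procrustes transform
(translation, isotropic scaling, rotation/reflection), and the aligned
coordinates supply the expected-vs-received odor distance on each reversal
trial, used downstream as a parametric regressor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .task_design import OdorSet, TrialSchedule


@dataclass
class PerceptualSpace:
    """2-D odor configuration for one subject (or the group average)."""

    coords: np.ndarray  # (4, 2)
    stress: float
    aligned: bool = False
    disparity: float | None = None
    scale: float | None = None  # Procrustes scale applied to this space

    def distances(self) -> np.ndarray:
        return squareform(pdist(self.coords))


def ratings_to_dissimilarity(ratings: pd.DataFrame, n_odors: int = 4) -> np.ndarray:
    """Long-format ratings (odor_i, odor_j, rating) -> symmetric matrix.

    Repeated ratings of a pair are averaged; the rating scale maps linearly
    onto dissimilarity.
    """
    D = np.zeros((n_odors, n_odors))
    counts = np.zeros((n_odors, n_odors))
    for row in ratings.itertuples():
        i, j, r = int(row.odor_i), int(row.odor_j), float(row.rating)
        D[i, j] += r
        D[j, i] += r
        counts[i, j] += 1
        counts[j, i] += 1
    with np.errstate(invalid="ignore"):
        D = np.where(counts > 0, D / np.maximum(counts, 1), 0.0)
    np.fill_diagonal(D, 0.0)
    return D


def _check_dissimilarity(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("dissimilarities must be non-negative")
    return D


def classical_scaling(D: np.ndarray, dim: int = 2) -> np.ndarray:
    """Torgerson double-centering embedding; deterministic MDS initialization."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:dim]
    lam = np.clip(w[idx], 0.0, None)
    return V[:, idx] * np.sqrt(lam)


def mds_embed(D: np.ndarray, dim: int = 2) -> PerceptualSpace:
    """Stress-minimizing metric MDS, initialized from classical scaling.

    The deterministic initialization removes the need for random restarts,
    so identical ratings always yield identical (up to solver) coordinates.
    """
    D = _check_dissimilarity(D)
    if np.allclose(D, 0.0):
        return PerceptualSpace(coords=np.zeros((D.shape[0], dim)), stress=0.0)
    model = MDS(
        n_components=dim,
        metric_mds=True,
        metric="precomputed",
        n_init=1,
        init="classical_mds",
        max_iter=1000,
        eps=1e-12,
    )
    coords = model.fit_transform(D, init=classical_scaling(D, dim))
    return PerceptualSpace(coords=coords, stress=float(model.stress_))


def group_average_space(
    subject_dissimilarities: list[np.ndarray], dim: int = 2
) -> PerceptualSpace:
    """Embed the element-wise mean dissimilarity matrix."""
    if not subject_dissimilarities:
        raise ValueError("need at least one subject")
    mats = [_check_dissimilarity(D) for D in subject_dissimilarities]
    return mds_embed(np.mean(mats, axis=0), dim)


def procrustes_align(
    space: PerceptualSpace, reference: PerceptualSpace
) -> PerceptualSpace:
    """Full Procrustes superimposition of ``space`` onto ``reference``.

    Translation, isotropic scaling and rotation/reflection minimizing the
    summed squared point distances; relative distance ratios within the
    configuration are preserved. Disparity is the minimized sum of squared
    differences after both configurations are scaled to unit norm (the
    scipy convention), so 0 means an exact similarity transform.
    """
    X, Y = np.asarray(space.coords, float), np.asarray(reference.coords, float)
    if X.shape != Y.shape:
        raise ValueError("configurations must share point count and dimension")
    Xc, Yc = X - X.mean(0), Y - Y.mean(0)
    nX, nY = np.linalg.norm(Xc), np.linalg.norm(Yc)
    if nY == 0:
        raise ValueError("degenerate (all-coincident) reference")
    if nX == 0:
        raise ValueError("degenerate (all-coincident) input configuration")
    R, s = orthogonal_procrustes(Xc / nX, Yc / nY)
    # aligned coords in the reference frame
    aligned = (Xc / nX) @ R * s * nY + Y.mean(0)
    disparity = float(np.sum((Yc / nY - (Xc / nX) @ R * s) ** 2))
    return PerceptualSpace(
        coords=aligned,
        stress=space.stress,
        aligned=True,
        disparity=disparity,
        scale=float(s * nY / nX),
    )


def reversal_distances(
    space: PerceptualSpace, schedule: TrialSchedule
) -> np.ndarray:
    """Expected-vs-received odor distance on each trial.

    On a reversal trial the expected odor is the pre-reversal US of the
    presented CS; the distance is Euclidean in the (aligned) space. Zero on
    non-reversal trials.
    """
    coords = np.asarray(space.coords, float)
    if schedule.us.max() >= coords.shape[0]:
        raise ValueError("schedule contains odor ids outside the space")
    D = squareform(pdist(coords))
    out = np.zeros(schedule.n_trials)
    prev_us: dict[int, int] = {}
    for t in range(schedule.n_trials):
        c, u = int(schedule.cs[t]), int(schedule.us[t])
        if schedule.is_reversal[t] and c in prev_us:
            out[t] = D[prev_us[c], u]
        prev_us[c] = u
    return out


def within_between_summary(
    spaces: list[PerceptualSpace], odors: OdorSet
) -> pd.DataFrame:
    """Per-subject mean within- and between-category distances.

    Returns one row per subject (mean_within over the 2 same-category
    pairs, mean_between over the 4 cross-category pairs, and their
    difference); the paired t statistic across subjects is attached as
    DataFrame attrs ``t``/``p`` (NaN and ``degenerate=True`` when the
    differences have zero variance).
    """
    ids = list(odors.odor_ids)
    pairs = [(i, j) for a, i in enumerate(ids) for j in ids[a + 1:]]
    rows = []
    for s, space in enumerate(spaces):
        Dm = space.distances()
        within = [Dm[i, j] for i, j in pairs if odors.same_category(i, j)]
        between = [Dm[i, j] for i, j in pairs if not odors.same_category(i, j)]
        rows.append(
            {
                "subject_id": s,
                "mean_within": float(np.mean(within)),
                "mean_between": float(np.mean(between)),
            }
        )
    df = pd.DataFrame(rows)
    df["difference"] = df["mean_between"] - df["mean_within"]
    df.attrs["degenerate"] = False
    if len(df) >= 2:
        if np.isclose(df["difference"].std(ddof=1), 0.0):
            df.attrs.update(t=np.nan, p=np.nan, degenerate=True)
        else:
            t, p = stats.ttest_rel(df["mean_between"], df["mean_within"])
            df.attrs.update(t=float(t), p=float(p))
    else:
        df.attrs.update(t=np.nan, p=np.nan, degenerate=True)
    return df
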