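"""Feature screening and medioid/outlier exemplar selection.

Given per-recording feature vectors labelled by emission context, a
one-way ANOVA is run on each feature column independently; columns that
do not separate the contexts (p >= alpha) are discarded.  In the reduced
space, each context's centroid is the arithmetic mean of its members, the
medioid is the recording closest to its own centroid in Euclidean
distance (the most representative sound of that context), and the outlier
is the recording farthest from it (the least typical one).

Features mix units (Hz, roughness, dimensionless ratios), so by default
they are z-scored over all recordings before centroids and distances are
computed; pass ``standardize=False`` for raw-space behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

log = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """Per-feature ANOVA decisions at significance level ``alpha``."""

    table: pd.DataFrame  # feature, F, p, kept
    alpha: float

    @property
    def kept(self) -> list[str]:
        return list(self.table.loc[self.table["kept"], "feature"])

    def family_summary(self) -> dict[str, bool]:
        """Whether any column of each feature family survived the screen."""
        fams: dict[str, bool] = {}
        for _, row in self.table.iterrows():
            fam = row["feature"].rsplit("_", 1)[0]
            fams[fam] = fams.get(fam, False) or bool(row["kept"])
        return fams


@dataclass
class Exemplar:
    clip_id: str
    distance: float


@dataclass
class ExemplarSet:
    """Per-context centroid, medioid and outlier in the reduced space."""

    centroids: dict[str, np.ndarray]
    medioids: dict[str, Exemplar]
    outliers: dict[str, Exemplar]
    feature_cols: list[str]
    standardized: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ctx in sorted(self.centroids):
            for role, ex in (("medioid", self.medioids[ctx]),
                             ("outlier", self.outliers[ctx])):
                rows.append({"context": ctx, "role": role,
                             "clip_id": ex.clip_id,
                             "distance": ex.distance})
        return pd.DataFrame(rows)


def anova_screen(features: pd.DataFrame, alpha: float = 0.05,
                 feature_cols=FEATURE_NAMES,
                 label_col: str = "context") -> ScreenResult:
    """One-way ANOVA of every feature column across context labels.

    A column is kept iff p < alpha.  A column that is constant both
    within and between classes has an undefined F statistic and is
    dropped with a warning.
    """
    labels = features[label_col]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if features.groupby(label_col).size().min() < 2:
        raise ValueError("need at least two samples per class")
    rows = []
    for col in feature_cols:
        groups = [features.loc[labels == c, col].to_numpy(dtype=float)
                  for c in classes]
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            log.warning("feature %s constant everywhere; F undefined, dropped",
                        col)
            rows.append({"feature": col, "F": np.nan, "p": np.nan,
                         "kept": False})
            continue
        F, p = stats.f_oneway(*groups)
        rows.append({"feature": col, "F": float(F), "p": float(p),
                     "kept": bool(p < alpha)})
    table = pd.DataFrame(rows)
    if not table["kept"].any():
        log.warning("no feature passed the screen at alpha=%s", alpha)
    return ScreenResult(table=table, alpha=alpha)


def zscore_columns(features: pd.DataFrame, cols) -> pd.DataFrame:
    """Z-score the given columns over all recordings (population mean/SD)."""
    out = features.copy()
    for col in cols:
        v = out[col].to_numpy(dtype=float)
        sd = v.std()
        out[col] = (v - v.mean()) / sd if sd > 0 else 0.0
    return out


def class_centroids(features: pd.DataFrame, cols,
                    label_col: str = "context") -> dict[str, np.ndarray]:
    """Arithmetic mean vector of each class in the given feature columns."""
    centroids = {}
    for ctx, grp in features.groupby(label_col):
        if len(grp) == 0:
            raise ValueError(f"empty class {ctx}")
        centroids[ctx] = grp[list(cols)].to_numpy(dtype=float).mean(axis=0)
    return centroids


def select_exemplars(features: pd.DataFrame, cols,
                     centroids: dict[str, np.ndarray] | None = None,
                     standardize: bool = True,
                     label_col: str = "context") -> ExemplarSet:
    """Pick each context's medioid and outlier by distance to its centroid.

    Medioid = member with minimal Euclidean distance to the class
    centroid, outlier = maximal; distance ties break on the lowest
    clip_id.  Every class needs at least two members so the two roles are
    distinct recordings.
    """
    cols = list(cols)
    if not cols:
        raise ValueError("no features kept; cannot select exemplars")
    work = zscore_columns(features, cols) if standardize else features.copy()
    if centroids is None:
        centroids = class_centroids(work, cols, label_col)
    medioids, outliers = {}, {}
    for ctx, grp in work.groupby(label_col):
        if len(grp) < 2:
            raise ValueError(
                f"class {ctx!r} has {len(grp)} member(s); need >= 2 for a "
                "distinct medioid and outlier")
        pts = grp[cols].to_numpy(dtype=float)
        dist = np.linalg.norm(pts - centroids[ctx][None, :], axis=1)
        order = sorted(range(len(grp)),
                       key=lambda i: (dist[i], grp["clip_id"].iloc[i]))
        med_i = order[0]
        order_out = sorted(range(len(grp)),
                           key=lambda i: (-dist[i], grp["clip_id"].iloc[i]))
        out_i = order_out[0]
        medioids[ctx] = Exemplar(grp["clip_id"].iloc[med_i], float(dist[med_i]))
        outliers[ctx] = Exemplar(grp["clip_id"].iloc[out_i], float(dist[out_i]))
    return ExemplarSet(centroids=centroids, medioids=medioids,
                       outliers=outliers, feature_cols=cols,
                       standardized=standardize)
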