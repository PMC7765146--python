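"""Principal component analysis of emotion-descriptor ratings.

Each observation is one participant's rating of one meow: 11 descriptor
scores on 7-point scales.  PCA (correlation-matrix by default, i.e. on
standardized descriptors) extracts the dominant axes of the ratings; the
first component is read as a valence axis.  The sign of each component is
arbitrary, so PC1 is oriented such that the "calm_relaxed" descriptor
loads non-positively: negative PC1 scores then mean positive perceived
valence.  The analysis can be run on all responses or restricted to the
responses whose context was classified correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .survey import DESCRIPTORS

_DESC_COLS = [f"d_{d}" for d in DESCRIPTORS]


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # descriptors x components
    scores: pd.DataFrame  # observations x components (+ metadata)
    explained_variance_pct: np.ndarray
    mode: str  # "correlation" | "covariance"
    subset: str  # "all" | "correct_only"


def pca_descriptors(responses: pd.DataFrame, subset: str = "all",
                    mode: str = "correlation") -> PCAResult:
    """PCA of the 11 descriptor scores.

    ``subset="correct_only"`` keeps only responses whose chosen context
    matches the true one.  ``mode="correlation"`` standardizes each
    descriptor to unit variance first (the default; descriptors share a
    scale but not necessarily a variance), ``mode="covariance"`` only
    centers.  All 11 components are returned, ordered by decreasing
    explained variance, which sums to 100 percent.
    """
    if subset not in ("all", "correct_only"):
        raise ValueError(f"unknown subset {subset!r}")
    if mode not in ("correlation", "covariance"):
        raise ValueError(f"unknown mode {mode!r}")
    work = responses.copy()
    work["correct"] = work["chosen_context"] == work["true_context"]
    if subset == "correct_only":
        work = work[work["correct"]]
    if len(work) < 12:
        raise ValueError(f"need >= 12 observations, have {len(work)}")
    X = work[_DESC_COLS].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing descriptor scores in used rows")
    X = X - X.mean(axis=0)
    if mode == "correlation":
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            const = [d for d, s in zip(DESCRIPTORS, sd) if s == 0]
            raise ValueError(f"constant descriptor(s) in correlation mode: {const}")
        X = X / sd

    pca = PCA(n_components=len(_DESC_COLS), svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # descriptors x components

    # Deterministic sign convention: PC1 anchored on calm_relaxed <= 0,
    # the remaining components on their largest-magnitude loading >= 0.
    calm = DESCRIPTORS.index("calm_relaxed")
    for j in range(loadings.shape[1]):
        if j == 0:
            flip = loadings[calm, 0] > 0
        else:
            flip = loadings[np.argmax(np.abs(loadings[:, j])), j] < 0
        if flip:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    comp_names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    loadings_df = pd.DataFrame(loadings, index=list(DESCRIPTORS),
                               columns=comp_names)
    scores_df = pd.DataFrame(scores, columns=comp_names,
                             index=work.index)
    for meta in ("true_context", "variant", "correct", "participant_id"):
        if meta in work.columns:
            scores_df[meta] = work[meta].to_numpy()
    evp = 100.0 * pca.explained_variance_ratio_
    return PCAResult(loadings=loadings_df, scores=scores_df,
                     explained_variance_pct=evp, mode=mode, subset=subset)


def valence_summary(result: PCAResult) -> dict:
    """Per-context mean +/- SD of PC1/PC2 scores and the loading partition.

    Returns a dict with a ``context_scores`` table and the descriptor
    partition by PC1 loading sign (``negative_pc1`` descriptors mark the
    positive-valence side under the sign convention).
    """
    rows = []
    for ctx, grp in result.scores.groupby("true_context"):
        rows.append({
            "context": ctx,
            "n": len(grp),
            "pc1_mean": float(grp["PC1"].mean()),
            "pc1_sd": float(grp["PC1"].std(ddof=1)) if len(grp) > 1 else 0.0,
            "pc2_mean": float(grp["PC2"].mean()),
            "pc2_sd": float(grp["PC2"].std(ddof=1)) if len(grp) > 1 else 0.0,
        })
    pc1 = result.loadings["PC1"]
    return {
        "context_scores": pd.DataFrame(rows),
        "negative_pc1": sorted(pc1[pc1 <= 0].index),
        "positive_pc1": sorted(pc1[pc1 > 0].index),
        "explained_variance_pct": result.explained_variance_pct[:2].tolist(),
    }


def plot_pca(result: PCAResult, path) -> None:
    """Two-panel score/loading plot (use an .svg path for text output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 5))
    for ctx, grp in result.scores.groupby("true_context"):
        ax1.scatter(grp["PC1"], grp["PC2"], s=12, alpha=0.6, label=ctx)
    ax1.set_xlabel(f"PC1 ({result.explained_variance_pct[0]:.1f}%)")
    ax1.set_ylabel(f"PC2 ({result.explained_variance_pct[1]:.1f}%)")
    ax1.legend(fontsize=8)
    ax1.set_title(f"Scores ({result.subset})")
    for desc in result.loadings.index:
        x, y = result.loadings.loc[desc, ["PC1", "PC2"]]
        ax2.arrow(0, 0, x, y, head_width=0.01, color="gray", alpha=0.7)
        ax2.annotate(desc, (x, y), fontsize=7)
    ax2.set_xlabel("PC1 loading")
    ax2.set_ylabel("PC2 loading")
    ax2.set_title("Loadings")
    ax2.axhline(0, lw=0.5, color="k")
    ax2.axvline(0, lw=0.5, color="k")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
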