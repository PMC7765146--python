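"""Listener-survey scoring and statistics.

A survey cohort listens to six meows (one medioid and one outlier for each
of three emission contexts) and, per meow, picks the context, judges the
emotional valence, and rates 11 emotion descriptors.  Each participant also
fills in the 22-item Animal Empathy Scale (AES; 9-point items, half of them
reverse-scored) and a 3-item Cat Empathy Scale (CES).

This module scores the scales and runs the statistical battery: accuracy
contingency tables with chi-square comparisons, an exact binomial test
against the 1/3 chance level, Mann-Whitney group comparisons of empathy
scores, Spearman correlations of empathy with classification success, and
Cronbach's alpha for internal consistency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: Emission contexts, in canonical order.
CONTEXTS = ("waiting_for_food", "isolation", "brushing")

#: Exemplar variants presented to listeners.
VARIANTS = ("medioid", "outlier")

#: The 11 emotion descriptors rated on 7-point scales, canonical order.
DESCRIPTORS = (
    "agitated_anxious",
    "aggressive_angry",
    "frustrated",
    "restless_nervous",
    "frightened",
    "suffering",
    "friendly",
    "calm_relaxed",
    "happy",
    "curious",
    "playful",
)

#: Descriptors conveying positive valence; the remaining six are negative.
POSITIVE_DESCRIPTORS = frozenset(
    {"friendly", "calm_relaxed", "happy", "curious", "playful"}
)

N_AES_ITEMS = 22
N_CES_ITEMS = 3

#: Default AES polarity key: which of the 22 items are worded empathically
#: and which unempathically (reverse-scored).  The published instrument's
#: exact key is not part of this package; this synthetic default alternates
#: polarities, giving the required 11/11 split.  Pass your own key to
#: :func:`score_aes` when scoring real administrations.
DEFAULT_AES_POLARITY = tuple(
    "empathic" if i % 2 == 0 else "unempathic" for i in range(N_AES_ITEMS)
)


@dataclass
class MeowResponse:
    """One listener's answers for one presented meow."""

    true_context: str
    variant: str  # "medioid" | "outlier"
    chosen_context: str
    valence: str  # "positive" | "negative"
    descriptor_scores: dict[str, int]

    @property
    def correct(self) -> bool:
        return self.chosen_context == self.true_context


@dataclass
class ResponseRecord:
    """One participant: attributes, scale items and six meow responses."""

    participant_id: str
    gender: str  # "male" | "female"
    parent: bool
    cat_owner: bool
    grew_up_with_cats: bool
    aes_items: list[int]
    ces_items: list[int]
    responses: list[MeowResponse] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Scale scoring

def reverse_item(x: int) -> int:
    """Reverse a 9-point response (an involution: reversing twice is identity)."""
    return 10 - x


def score_aes(items, polarity=DEFAULT_AES_POLARITY) -> int:
    """Total AES score in [22, 198].

    Items marked ``unempathic`` in the polarity key are reverse-scored
    (10 - x) before summing, so agreement with empathic statements scores
    high and agreement with unempathic statements scores low.
    """
    items = list(items)
    if len(items) != N_AES_ITEMS or len(polarity) != N_AES_ITEMS:
        raise ValueError(f"AES requires {N_AES_ITEMS} items and polarities")
    n_unemp = sum(p == "unempathic" for p in polarity)
    if n_unemp != N_AES_ITEMS // 2:
        raise ValueError("AES polarity key must mark exactly 11 unempathic items")
    total = 0
    for x, pol in zip(items, polarity):
        if not (1 <= x <= 9):
            raise ValueError(f"AES item out of 1..9 range: {x}")
        total += reverse_item(x) if pol == "unempathic" else x
    return total


def score_ces(items) -> int:
    """Total CES score in [3, 27] (plain sum of three 9-point items)."""
    items = list(items)
    if len(items) != N_CES_ITEMS:
        raise ValueError(f"CES requires {N_CES_ITEMS} items")
    for x in items:
        if not (1 <= x <= 9):
            raise ValueError(f"CES item out of 1..9 range: {x}")
    return sum(items)


def n_correct_medioids(record: ResponseRecord) -> int:
    """Number of correctly classified medioid meows, 0..3.

    Only the three medioid presentations count; the 0-3 range of the
    correct-identification score fixes this reading.
    """
    return sum(r.correct for r in record.responses if r.variant == "medioid")


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha for a participants x items score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of totals),
    with sample variances (ddof=1).  Reverse-scoring must already have
    been applied to the items.
    """
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 3:
        raise ValueError("need >=3 participants and >=2 items")
    k = m.shape[1]
    item_var = m.var(axis=0, ddof=1).sum()
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero variance of total scores")
    return k / (k - 1) * (1.0 - item_var / total_var)


# ---------------------------------------------------------------------------
# Contingency statistics

@dataclass
class ContingencyResult:
    """Chi-square test on an observed count table."""

    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float
    correction: bool


def chisq_2x2(observed, correction: bool = False) -> ContingencyResult:
    """Pearson chi-square test of independence on a 2x2 (or 2xk) table.

    Continuity (Yates) correction is off by default; pass
    ``correction=True`` for the corrected statistic.  Expected counts are
    the classical row*column/total products.
    """
    obs = np.asarray(observed, dtype=float)
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("observed counts must be nonnegative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=correction)
    return ContingencyResult(observed=obs, expected=expected, chi2=float(chi2),
                             df=int(df), p=float(p), correction=correction)


@dataclass
class ChanceTestResult:
    """Exact binomial comparison of an accuracy count against chance."""

    correct: int
    n: int
    p0: float
    p_greater: float
    p_two_sided: float


def chance_test(correct: int, n: int, p0: float = 1.0 / 3.0) -> ChanceTestResult:
    """Exact binomial test of ``correct`` successes in ``n`` against ``p0``.

    With three answer options the chance level is 1/3.  Both the one-sided
    (greater-than-chance) and the two-sided p-value are reported.
    """
    if not 0 <= correct <= n:
        raise ValueError("need 0 <= correct <= n")
    greater = stats.binomtest(correct, n, p0, alternative="greater")
    two = stats.binomtest(correct, n, p0, alternative="two-sided")
    return ChanceTestResult(correct=correct, n=n, p0=p0,
                            p_greater=greater.pvalue, p_two_sided=two.pvalue)


def mann_whitney(scores_a, scores_b) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when both groups have at most 20
    untied observations, otherwise the tie-corrected normal approximation.
    Returns (U, p, method) with the method recorded in the output.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(a) <= 20 and len(b) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need equal-length inputs of length >= 5")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("zero variance in ranks")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Cohort data frames

def cohort_frames(records: list[ResponseRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into (participants, responses) data frames.

    The participants frame has one row per participant with attributes and
    raw scale items; the responses frame has one row per participant x meow
    with the context answer, valence and the 11 descriptor scores.
    """
    prows, rrows = [], []
    for rec in records:
        prow = {
            "participant_id": rec.participant_id,
            "gender": rec.gender,
            "parent": rec.parent,
            "cat_owner": rec.cat_owner,
            "grew_up_with_cats": rec.grew_up_with_cats,
        }
        prow.update({f"aes_{i + 1}": v for i, v in enumerate(rec.aes_items)})
        prow.update({f"ces_{i + 1}": v for i, v in enumerate(rec.ces_items)})
        prows.append(prow)
        for resp in rec.responses:
            rrow = {
                "participant_id": rec.participant_id,
                "true_context": resp.true_context,
                "variant": resp.variant,
                "chosen_context": resp.chosen_context,
                "valence": resp.valence,
            }
            rrow.update({f"d_{d}": resp.descriptor_scores[d] for d in DESCRIPTORS})
            rrows.append(rrow)
    return pd.DataFrame(prows), pd.DataFrame(rrows)


def accuracy_table(responses: pd.DataFrame, context: str, variant: str,
                   grouping: str | None = None,
                   participants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Correct/incorrect counts and percentages for one presented meow.

    With ``grouping`` (a participant attribute column), one row per group
    level; otherwise a single row.  Percentages are 100*correct/total
    rounded to two decimals.
    """
    sel = responses[(responses["true_context"] == context)
                    & (responses["variant"] == variant)].copy()
    sel["correct"] = sel["chosen_context"] == sel["true_context"]
    if grouping is not None:
        if participants is None:
            raise ValueError("grouping requires the participants frame")
        sel = sel.merge(participants[["participant_id", grouping]],
                        on="participant_id")
        keys = [grouping]
    else:
        sel["all"] = "all"
        keys = ["all"]
    rows = []
    for level, grp in sel.groupby(keys[0], sort=True):
        n_corr = int(grp["correct"].sum())
        n_tot = int(len(grp))
        rows.append({
            "group": level,
            "correct": n_corr,
            "incorrect": n_tot - n_corr,
            "pct_correct": round(100.0 * n_corr / n_tot, 2) if n_tot else np.nan,
            "pct_incorrect": round(100.0 * (n_tot - n_corr) / n_tot, 2) if n_tot else np.nan,
        })
    return pd.DataFrame(rows)


def participant_scores(participants: pd.DataFrame,
                       responses: pd.DataFrame,
                       aes_polarity=DEFAULT_AES_POLARITY) -> pd.DataFrame:
    """Per-participant AES/CES totals and medioid correct count (0..3)."""
    aes_cols = [f"aes_{i + 1}" for i in range(N_AES_ITEMS)]
    ces_cols = [f"ces_{i + 1}" for i in range(N_CES_ITEMS)]
    out = participants[["participant_id", "gender", "parent", "cat_owner",
                        "grew_up_with_cats"]].copy()
    out["aes_total"] = [
        score_aes(row, aes_polarity) for row in participants[aes_cols].to_numpy()
    ]
    out["ces_total"] = [score_ces(row) for row in participants[ces_cols].to_numpy()]
    med = responses[responses["variant"] == "medioid"].copy()
    med["correct"] = med["chosen_context"] == med["true_context"]
    ncorr = med.groupby("participant_id")["correct"].sum().astype(int)
    out = out.merge(ncorr.rename("n_correct_medioids"), on="participant_id",
                    how="left")
    out["n_correct_medioids"] = out["n_correct_medioids"].fillna(0).astype(int)
    return out


def reversed_item_matrix(participants: pd.DataFrame,
                         aes_polarity=DEFAULT_AES_POLARITY) -> np.ndarray:
    """AES item matrix with unempathic items reverse-scored (for alpha)."""
    aes_cols = [f"aes_{i + 1}" for i in range(N_AES_ITEMS)]
    m = participants[aes_cols].to_numpy(dtype=float)
    rev = np.array([p == "unempathic" for p in aes_polarity])
    m[:, rev] = 10 - m[:, rev]
    return m


_GROUPINGS = {
    "gender": ("female", "male"),
    "parent": (True, False),
    "cat_owner": (True, False),
    "grew_up_with_cats": (True, False),
}


def analyze(participants: pd.DataFrame, responses: pd.DataFrame,
            aes_polarity=DEFAULT_AES_POLARITY, alpha: float = 0.05) -> dict:
    """Run the full statistical battery on a survey cohort.

    Returns a nested dict with: per-context medioid/outlier accuracy tables
    and medioid-vs-outlier chi-square tests; chance-level binomial tests;
    accuracy-by-attribute chi-squares; Mann-Whitney comparisons of AES/CES
    by gender and ownership; Spearman correlations of AES/CES with the 0-3
    medioid correct count; and Cronbach's alpha of the reversed AES items.
    """
    scores = participant_scores(participants, responses, aes_polarity)
    report: dict = {"alpha": alpha, "contexts": {}, "group_effects": {},
                    "empathy": {}, "correlations": {}}

    for ctx in CONTEXTS:
        med = accuracy_table(responses, ctx, "medioid")
        out = accuracy_table(responses, ctx, "outlier")
        table = [[int(med.loc[0, "correct"]), int(med.loc[0, "incorrect"])],
                 [int(out.loc[0, "correct"]), int(out.loc[0, "incorrect"])]]
        chi = chisq_2x2(table)
        n_med = table[0][0] + table[0][1]
        chance = chance_test(table[0][0], n_med)
        report["contexts"][ctx] = {
            "medioid": med.loc[0].to_dict(),
            "outlier": out.loc[0].to_dict(),
            "medioid_vs_outlier": {"chi2": chi.chi2, "df": chi.df, "p": chi.p},
            "chance": {"p_greater": chance.p_greater,
                       "p_two_sided": chance.p_two_sided},
        }
        effects = {}
        for attr in _GROUPINGS:
            tab = accuracy_table(responses, ctx, "medioid", grouping=attr,
                                 participants=participants)
            if len(tab) == 2 and tab[["correct", "incorrect"]].to_numpy().min() >= 0:
                try:
                    chi_a = chisq_2x2(tab[["correct", "incorrect"]].to_numpy())
                    effects[attr] = {"table": tab.to_dict("records"),
                                     "chi2": chi_a.chi2, "p": chi_a.p}
                except ValueError:
                    pass
        report["group_effects"][ctx] = effects

    for scale in ("aes_total", "ces_total"):
        by = {}
        for attr, (lvl_a, lvl_b) in _GROUPINGS.items():
            a = scores.loc[scores[attr] == lvl_a, scale]
            b = scores.loc[scores[attr] == lvl_b, scale]
            if len(a) and len(b):
                u, p, method = mann_whitney(a, b)
                by[attr] = {
                    "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
                    "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
                    "U": u, "p": p, "method": method,
                }
        report["empathy"][scale] = by
        rho, p = spearman(scores[scale], scores["n_correct_medioids"])
        report["correlations"][scale] = {"rho": rho, "p": p}

    rho, p = spearman(scores["aes_total"], scores["ces_total"])
    report["correlations"]["aes_vs_ces"] = {"rho": rho, "p": p}
    report["cronbach_alpha_aes"] = float(
        cronbach_alpha(reversed_item_matrix(participants, aes_polarity)))
    report["scores"] = scores
    return report
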