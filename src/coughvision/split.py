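"""Subject-wise train/validation/test splitting under balancing rules.

All data from one subject land in exactly one split, preventing identity
leakage between training and evaluation. Within each diagnostic category,
subjects are apportioned 60/20/20 by largest-remainder rounding; every
category with at least three subjects is guaranteed presence in all three
splits. Among assignments satisfying those hard rules, a seeded
random-restart hill-climbing search minimises a balance score that sums,
over categories and splits, the deviation of the split's male fraction
from the category's cohort male fraction and the relative deviation of the
split's mean cough density (events per recorded hour) from the category
mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

SPLITS = ("train", "validation", "test")
DEFAULT_RATIOS = (0.6, 0.2, 0.2)


def cough_rate(cough_count: float, duration_s: float) -> float:
    """Cough density: events per recorded hour of (silence-removed) audio.

    This is the class-imbalance proxy of the dataset, not a clinical 24-hour
    cough frequency.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return cough_count / (duration_s / 3600.0)


def apportion_sizes(n: int, ratios=DEFAULT_RATIOS) -> tuple[int, ...]:
    """Largest-remainder apportionment of ``n`` subjects to the split ratios.

    Remainder ties are broken toward the later split (test before
    validation before train). Categories of three or more subjects are
    guaranteed at least one subject per split (a seat moves from the most
    oversubscribed split if rounding left one empty).
    """
    quotas = np.array([n * r for r in ratios])
    sizes = np.floor(quotas).astype(int)
    remainders = quotas - sizes
    # stable argsort on (-remainder, -index): ties -> later split first
    order = sorted(range(len(ratios)), key=lambda i: (-remainders[i], -i))
    for i in range(n - sizes.sum()):
        sizes[order[i % len(ratios)]] += 1
    if n >= len(ratios):
        # all-splits coverage: move a seat from the largest split to any
        # split left empty by rounding
        while (sizes == 0).any():
            donor = int(np.argmax(sizes))
            recipient = int(np.flatnonzero(sizes == 0)[0])
            sizes[donor] -= 1
            sizes[recipient] += 1
    return tuple(int(s) for s in sizes)


@dataclass
class BalanceScore:
    """Soft-balance objective; zero iff splits are perfectly balanced."""

    sex_ratio_deviation: float
    rate_deviation: float

    @property
    def total(self) -> float:
        return self.sex_ratio_deviation + self.rate_deviation


@dataclass
class SplitAssignment:
    """Subject -> split mapping plus the cohort table it was built from."""

    mapping: dict[str, str]
    subjects: pd.DataFrame  # subject_id, category, sex, cough_rate
    score: BalanceScore

    def split_of(self, subject_id: str) -> str:
        return self.mapping[subject_id]

    def subject_ids(self, split: str) -> list[str]:
        return sorted(s for s, sp in self.mapping.items() if sp == split)


def _score(df: pd.DataFrame, assignment: np.ndarray) -> BalanceScore:
    """Balance score of an assignment (array of split indices per row)."""
    sex_dev = 0.0
    rate_dev = 0.0
    male = (df["sex"].to_numpy() == "M").astype(float)
    rates = df["cough_rate"].to_numpy(dtype=float)
    for cat_idx in np.unique(df["_cat_idx"].to_numpy()):
        in_cat = df["_cat_idx"].to_numpy() == cat_idx
        cat_male_frac = male[in_cat].mean()
        cat_rate = rates[in_cat].mean()
        for s in range(3):
            sel = in_cat & (assignment == s)
            if not sel.any():
                continue
            sex_dev += abs(male[sel].mean() - cat_male_frac)
            rate_dev += abs(rates[sel].mean() - cat_rate) / max(cat_rate, 1.0)
    return BalanceScore(sex_dev, rate_dev)


def assign_splits(
    subjects: pd.DataFrame,
    ratios=DEFAULT_RATIOS,
    seed: int = 0,
    n_restarts: int = 8,
    max_hillclimb_iters: int = 200,
) -> SplitAssignment:
    """Assign whole subjects to train/validation/test.

    Parameters
    ----------
    subjects : DataFrame
        Columns ``subject_id``, ``category``, ``sex`` ("M"/"F"),
        ``cough_rate`` (events per hour).
    ratios : tuple of 3 floats
        Split proportions, default (0.6, 0.2, 0.2).
    seed : int
        Drives the restart initialisations; same cohort + seed gives the
        same assignment.
    n_restarts, max_hillclimb_iters : int
        Search effort: random valid initialisations, each refined by
        same-category pairwise-swap hill-climbing.

    Notes
    -----
    Categories with one or two subjects cannot appear in all three splits;
    a warning is emitted and their subjects are placed by the soft
    objective alone (sizes still by largest remainder).
    """
    df = subjects.copy().sort_values("subject_id").reset_index(drop=True)
    required = {"subject_id", "category", "sex", "cough_rate"}
    if not required.issubset(df.columns):
        raise ValueError(f"subjects must have columns {sorted(required)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in cohort")
    cats = sorted(df["category"].unique())
    df["_cat_idx"] = df["category"].map({c: i for i, c in enumerate(cats)})

    cat_rows: list[np.ndarray] = []
    cat_sizes: list[tuple[int, ...]] = []
    for i, cat in enumerate(cats):
        rows = np.flatnonzero(df["_cat_idx"].to_numpy() == i)
        sizes = apportion_sizes(len(rows), ratios)
        if len(rows) < 3:
            warnings.warn(
                f"category {cat!r} has {len(rows)} subject(s); cannot cover "
                "all three splits",
                stacklevel=2,
            )
        cat_rows.append(rows)
        cat_sizes.append(sizes)

    rng = np.random.default_rng(seed)
    best_assign: np.ndarray | None = None
    best_score = np.inf
    n = len(df)
    for _ in range(max(1, n_restarts)):
        assign = np.empty(n, dtype=int)
        for rows, sizes in zip(cat_rows, cat_sizes):
            perm = rng.permutation(rows)
            labels = np.repeat(np.arange(3), sizes)
            assign[perm] = labels
        score = _score(df, assign).total
        # pairwise swap hill-climbing within categories
        improved = True
        iters = 0
        while improved and iters < max_hillclimb_iters:
            improved = False
            iters += 1
            for rows in cat_rows:
                for ii in range(len(rows)):
                    for jj in range(ii + 1, len(rows)):
                        a, b = rows[ii], rows[jj]
                        if assign[a] == assign[b]:
                            continue
                        assign[a], assign[b] = assign[b], assign[a]
                        new = _score(df, assign).total
                        if new < score - 1e-12:
                            score = new
                            improved = True
                        else:
                            assign[a], assign[b] = assign[b], assign[a]
        if score < best_score - 1e-12:
            best_score = score
            best_assign = assign.copy()
    assert best_assign is not None
    mapping = {
        sid: SPLITS[s] for sid, s in zip(df["subject_id"], best_assign)
    }
    return SplitAssignment(
        mapping=mapping,
        subjects=df.drop(columns="_cat_idx"),
        score=_score(df, best_assign),
    )


def random_valid_assignment(
    subjects: pd.DataFrame, ratios=DEFAULT_RATIOS, seed: int = 0
) -> dict[str, str]:
    """A uniformly random assignment satisfying the hard size rules only.

    Used as the comparison population when checking search quality.
    """
    df = subjects.sort_values("subject_id").reset_index(drop=True)
    rng = np.random.default_rng(seed)
    mapping: dict[str, str] = {}
    for cat in sorted(df["category"].unique()):
        rows = df[df["category"] == cat]
        sizes = apportion_sizes(len(rows), ratios)
        perm = rng.permutation(rows["subject_id"].to_numpy())
        labels = np.repeat(SPLITS, sizes)
        mapping.update(dict(zip(perm, labels)))
    return mapping


def score_assignment(
    subjects: pd.DataFrame, mapping: dict[str, str]
) -> BalanceScore:
    """Balance score of an arbitrary subject -> split mapping."""
    df = subjects.copy().sort_values("subject_id").reset_index(drop=True)
    cats = sorted(df["category"].unique())
    df["_cat_idx"] = df["category"].map({c: i for i, c in enumerate(cats)})
    idx = {s: i for i, s in enumerate(SPLITS)}
    assign = df["subject_id"].map(lambda s: idx[mapping[s]]).to_numpy()
    return _score(df, assign)


def split_report(assignment: SplitAssignment) -> pd.DataFrame:
    """Per-category, per-split cough density and sex ratio table.

    Mirrors the cohort-statistics layout used to audit a split: one row per
    diagnostic category (plus Total), with mean cough count per hour and an
    ``M:F`` subject ratio for each split. Refuses an assignment with an
    empty split.
    """
    df = assignment.subjects.copy()
    df["split"] = df["subject_id"].map(assignment.mapping)
    for split in SPLITS:
        if (df["split"] == split).sum() == 0:
            raise ValueError(f"split {split!r} is empty; refusing to report")
    rows = []
    cats = sorted(df["category"].unique())
    for cat in cats + ["Total"]:
        sub = df if cat == "Total" else df[df["category"] == cat]
        row: dict[str, object] = {"category": cat}
        for split in SPLITS:
            cell = sub[sub["split"] == split]
            m = int((cell["sex"] == "M").sum())
            f = int((cell["sex"] == "F").sum())
            row[f"{split}_count_per_hour"] = (
                round(float(cell["cough_rate"].mean()), 1) if len(cell) else np.nan
            )
            row[f"{split}_sex_ratio"] = f"{m}:{f}"
        rows.append(row)
    return pd.DataFrame(rows)


class SubjectSplitter(BaseEstimator):
    """Estimator wrapper around the balanced subject-wise split search.

    After :meth:`fit`, ``assignment_`` holds the subject -> split mapping
    and ``report_`` the per-category audit table.
    """

    def __init__(self, ratios=DEFAULT_RATIOS, seed: int = 0, n_restarts: int = 8):
        self.ratios = ratios
        self.seed = seed
        self.n_restarts = n_restarts

    def fit(self, subjects: pd.DataFrame, y=None):
        self.assignment_ = assign_splits(
            subjects, ratios=self.ratios, seed=self.seed, n_restarts=self.n_restarts
        )
        self.report_ = split_report(self.assignment_)
        return self

    def split_of(self, subject_id: str) -> str:
        return self.assignment_.split_of(subject_id)
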