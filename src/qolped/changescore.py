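"""Mean-level pre/post comparison and change-score classification.

The pandemic's average effect on QoL is assessed with a paired t test on
a genetically unrelated subsample (family data violate the independence
assumption; spouses are genetically unrelated and may both be retained),
with Cohen's d for paired samples as the effect size.  Individual change
is classified by the sign of (pandemic - pre-pandemic), and decreasers
are additionally checked for crossing the "sufficient" threshold: a
score of 6 or higher counts as sufficient QoL, 5 or lower as
insufficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from qolped.pedigree import Pedigree, kinship_coefficient

SUFFICIENT_THRESHOLD = 6


class ChangeScoreError(ValueError):
    pass


@dataclass
class ChangeSummary:
    n_both: int
    n_decreased: int
    n_stable: int
    n_increased: int
    pct_decreased: float
    pct_stable: float
    pct_increased: float
    n_suff_to_insuff: int
    # filled when the paired test on the unrelated subsample is run
    t_stat: float | None = None
    t_df: int | None = None
    cohens_d: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def pool_scale_floor(values):
    """Recode scores of 0 to 1 (one pre-pandemic instrument ran 0-10;
    the bottom two categories are pooled so all data share the 1-10
    scale)."""
    v = np.asarray(values, dtype=float)
    return np.where(v == 0, 1.0, v)


def select_unrelated(ped: Pedigree, seed: int, max_exhaustive: int = 12) -> list[str]:
    """Seeded selection of a largest set of pairwise genetically
    unrelated individuals (kinship 0; spouses permitted).

    Individuals from different families are always unrelated, so the
    problem separates by family.  For families up to ``max_exhaustive``
    members the maximum kinship-zero subset is found exactly (ties
    broken by seeded-random preference, so e.g. "both parents" beats
    any single twin); larger families fall back to a seeded random
    greedy pass.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    kept: list[str] = []
    for fam_id, grp in ped.df.groupby("fam_id", sort=False):
        ids = list(grp["person_id"])
        rng.shuffle(ids)
        n = len(ids)
        related = np.zeros((n, n), dtype=bool)
        for a in range(n):
            for b in range(a + 1, n):
                related[a, b] = related[b, a] = (
                    kinship_coefficient(ped, ids[a], ids[b]) > 0.0
                )
        if n <= max_exhaustive:
            best: list[int] = []

            def grow(chosen: list[int], start: int):
                nonlocal best
                if len(chosen) > len(best):
                    best = list(chosen)
                for c in range(start, n):
                    if len(chosen) + (n - c) <= len(best):
                        break  # cannot beat the incumbent
                    if not any(related[c, q] for q in chosen):
                        chosen.append(c)
                        grow(chosen, c + 1)
                        chosen.pop()

            grow([], 0)
            kept.extend(ids[c] for c in best)
        else:
            fam_kept: list[int] = []
            for c in range(n):
                if not any(related[c, q] for q in fam_kept):
                    fam_kept.append(c)
            kept.extend(ids[c] for c in fam_kept)
    return kept


def paired_test(pre, pan) -> tuple[float, int, float, float]:
    """Paired t test of the pre-pandemic vs pandemic scores.

    The difference is taken pre - pan, so a drop in QoL gives a positive
    t.  Returns (t, df, p, d) with df = n - 1 and Cohen's d for paired
    samples d = mean(diff)/sd(diff) = t / sqrt(n).
    """
    pre = np.asarray(pre, dtype=float)
    pan = np.asarray(pan, dtype=float)
    ok = ~(np.isnan(pre) | np.isnan(pan))
    diff = pre[ok] - pan[ok]
    n = len(diff)
    if n < 2:
        raise ChangeScoreError("need at least 2 paired observations")
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ChangeScoreError("zero standard deviation of differences")
    t = float(diff.mean() / (sd / np.sqrt(n)))
    df = n - 1
    from scipy import stats

    p = float(2.0 * stats.t.sf(abs(t), df))
    d = t / np.sqrt(n)
    return t, df, p, float(d)


def classify_change(pre, pan, suff_threshold: int = SUFFICIENT_THRESHOLD) -> ChangeSummary:
    """Classify paired scores as decreased / stable / increased by the
    sign of (pan - pre), and count decreasers who crossed from
    sufficient (>= ``suff_threshold``) to insufficient (<= threshold-1)."""
    pre = np.asarray(pre, dtype=float)
    pan = np.asarray(pan, dtype=float)
    ok = ~(np.isnan(pre) | np.isnan(pan))
    pre, pan = pre[ok], pan[ok]
    if not (np.all(pre == np.round(pre)) and np.all(pan == np.round(pan))):
        warnings.warn("non-integer scores on the 1-10 ladder; classifying anyway")
    change = pan - pre
    n_both = len(change)
    n_dec = int((change < 0).sum())
    n_sta = int((change == 0).sum())
    n_inc = int((change > 0).sum())
    dec = change < 0
    n_cross = int(((pre >= suff_threshold) & (pan <= suff_threshold - 1) & dec).sum())
    pct = lambda k: round(100.0 * k / n_both, 2) if n_both else float("nan")
    return ChangeSummary(
        n_both=n_both,
        n_decreased=n_dec,
        n_stable=n_sta,
        n_increased=n_inc,
        pct_decreased=pct(n_dec),
        pct_stable=pct(n_sta),
        pct_increased=pct(n_inc),
        n_suff_to_insuff=n_cross,
    )


def change_by_baseline_score(pre, pan) -> pd.DataFrame:
    """Counts of decreased / stable / increased per pre-pandemic score
    1-10 (the table behind the per-score change bar charts)."""
    pre = np.asarray(pre, dtype=float)
    pan = np.asarray(pan, dtype=float)
    ok = ~(np.isnan(pre) | np.isnan(pan))
    pre, pan = pre[ok], pan[ok]
    rows = []
    for s in range(1, 11):
        sel = pre == s
        ch = pan[sel] - pre[sel]
        rows.append(
            {
                "pre_score": s,
                "n": int(sel.sum()),
                "n_decreased": int((ch < 0).sum()),
                "n_stable": int((ch == 0).sum()),
                "n_increased": int((ch > 0).sum()),
            }
        )
    return pd.DataFrame(rows)


def change_summary_for_pedigree(ped: Pedigree, seed: int) -> dict:
    """Full change-score analysis of a pedigree: paired t test on the
    unrelated subsample, change classification of everyone with both
    occasions, and the per-baseline-score breakdown."""
    df = ped.df
    pre = pool_scale_floor(df["qol_pre"].to_numpy(dtype=float))
    pan = df["qol_pan"].to_numpy(dtype=float)
    unrelated = set(select_unrelated(ped, seed))
    in_sub = df["person_id"].isin(unrelated).to_numpy()
    ok = ~(np.isnan(pre) | np.isnan(pan))
    t, tdf, p, d = paired_test(pre[in_sub & ok], pan[in_sub & ok])
    summary = classify_change(pre[ok], pan[ok])
    summary.t_stat, summary.t_df, summary.cohens_d = t, tdf, d
    return {
        "n_unrelated_subsample": int((in_sub & ok).sum()),
        "t": t,
        "df": tdf,
        "p": p,
        "cohens_d": d,
        "change": summary.to_dict(),
        "by_baseline_score": change_by_baseline_score(pre[ok], pan[ok]).to_dict("records"),
    }
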