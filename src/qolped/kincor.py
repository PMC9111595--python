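"""Weighted kinship correlations with standard errors and pooling.

Familial resemblance for the phenotype is summarized by Pearson
correlations over pairs of relatives of one type (MZ/DZ twins, spouses,
parent-offspring, siblings), computed within each occasion and across
occasions.  Because one individual can appear in several pairs of the
same type (a mother with three phenotyped children contributes three
mother-child pairs), pairs are down-weighted: pair (i, j) gets weight
1/sqrt(k_i * k_j), where k_x counts the pairs of this type containing x.
Disjoint pairs keep weight 1 and the weighted N equals the pair count.

Standard errors use the closed form se = sqrt((1 - r^2) / (n - 2)) with
the weighted N, and confidence intervals are r +/- 1.96 se.  The two
directional cross-time correlations (phenotype at occasion 1 in member 1
against occasion 2 in member 2, and vice versa) are pooled by
fixed-effect meta-analysis on the Fisher z scale with inverse-variance
weights n - 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from qolped.pedigree import Pedigree, SYMMETRIC_TYPES, classify_pairs

Z95 = 1.959963984540054  # normal 97.5% quantile


class KincorError(ValueError):
    pass


@dataclass
class CorrEstimate:
    """A weighted correlation for one relationship type and occasion pair."""

    relationship_type: str
    occasion_pair: str  # pre-pre | pan-pan | pre1-pan2 | pan1-pre2 | pooled-cross
    r: float
    se: float
    ci_low: float
    ci_high: float
    n_weighted: float

    def round_display(self) -> dict:
        """Table-style display values (r/se/CI to 2 dp, N to integer)."""
        return {
            "relationship_type": self.relationship_type,
            "occasion_pair": self.occasion_pair,
            "n_weighted": int(round(self.n_weighted)),
            "r": round(self.r, 2),
            "se": round(self.se, 2),
            "ci_low": round(self.ci_low, 2),
            "ci_high": round(self.ci_high, 2),
        }


def corr_se(r: float, n: float) -> float:
    """Closed-form standard error sqrt((1 - r^2) / (n - 2))."""
    if n <= 2:
        raise KincorError(f"need weighted n > 2 for a standard error, got {n}")
    return float(np.sqrt((1.0 - r * r) / (n - 2.0)))


def pair_weights(pairs: pd.DataFrame) -> np.ndarray:
    """Weights 1/sqrt(k_i * k_j) for pairs of one relationship type.

    ``pairs`` needs columns id1, id2.  k_x is the number of listed pairs
    containing x, so individuals used only once give weight 1.
    """
    if len(pairs) == 0:
        raise KincorError("no pairs to weight")
    counts: dict[str, int] = {}
    for i, j in zip(pairs["id1"], pairs["id2"]):
        counts[i] = counts.get(i, 0) + 1
        counts[j] = counts.get(j, 0) + 1
    k1 = np.array([counts[i] for i in pairs["id1"]], dtype=float)
    k2 = np.array([counts[j] for j in pairs["id2"]], dtype=float)
    return 1.0 / np.sqrt(k1 * k2)


def weighted_correlation(
    x, y, w, double_entry: bool, relationship_type: str = "", occasion_pair: str = ""
) -> CorrEstimate:
    """Weighted Pearson correlation with the closed-form se and 95% CI.

    For symmetric relationship types each pair enters in both orderings
    at half weight (``double_entry=True``); ``n_weighted`` counts each
    pair once either way.  With unit weights and single entry this is
    the ordinary Pearson estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise KincorError("x, y, w must have equal length")
    if len(x) < 3:
        raise KincorError("need at least 3 pairs")
    n_weighted = float(w.sum())
    if double_entry:
        x, y = np.concatenate([x, y]), np.concatenate([y, x])
        w = np.concatenate([w, w]) / 2.0
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    vx = (w * (x - mx) ** 2).sum() / sw
    vy = (w * (y - my) ** 2).sum() / sw
    if vx <= 0 or vy <= 0:
        raise KincorError("degenerate phenotype: zero weighted variance")
    cov = (w * (x - mx) * (y - my)).sum() / sw
    r = float(cov / np.sqrt(vx * vy))
    se = corr_se(r, n_weighted)
    return CorrEstimate(
        relationship_type, occasion_pair, r, se, r - Z95 * se, r + Z95 * se, n_weighted
    )


def _type_estimate(
    ped: Pedigree, pairs: pd.DataFrame, rtype: str, col1: str, col2: str, label: str
) -> CorrEstimate | None:
    """Correlation for one type between phenotype column col1 on member 1
    and col2 on member 2, over pairs complete for those cells.

    For symmetric types the pair is entered in both member orderings at
    half weight.  Within one occasion that is handled inside
    weighted_correlation; for cross-time estimates the member swap is
    done explicitly (swapping the *variables* instead would pool the two
    occasions' different means and variances and bias r toward 0).
    """
    pheno = ped.df.set_index("person_id")
    sub = pairs[pairs["relationship_type"] == rtype]
    if sub.empty:
        return None
    symmetric = rtype in SYMMETRIC_TYPES
    x1 = pheno.loc[sub["id1"], col1].to_numpy(dtype=float)
    y1 = pheno.loc[sub["id2"], col2].to_numpy(dtype=float)
    ok1 = ~(np.isnan(x1) | np.isnan(y1))
    try:
        if symmetric and col1 != col2:
            x2 = pheno.loc[sub["id2"], col1].to_numpy(dtype=float)
            y2 = pheno.loc[sub["id1"], col2].to_numpy(dtype=float)
            ok2 = ~(np.isnan(x2) | np.isnan(y2))
            keep = ok1 | ok2
            sub_k = sub[keep]
            if len(sub_k) < 3:
                return None
            w = pair_weights(sub_k)
            o1, o2 = ok1[keep], ok2[keep]
            share = np.where(o1 & o2, 0.5, 1.0) * w
            X = np.concatenate([x1[keep][o1], x2[keep][o2]])
            Y = np.concatenate([y1[keep][o1], y2[keep][o2]])
            W = np.concatenate([share[o1], share[o2]])
            return weighted_correlation(
                X, Y, W, double_entry=False,
                relationship_type=rtype, occasion_pair=label,
            )
        sub_k = sub[ok1]
        if len(sub_k) < 3:
            return None
        w = pair_weights(sub_k)
        return weighted_correlation(
            x1[ok1], y1[ok1], w, double_entry=symmetric,
            relationship_type=rtype, occasion_pair=label,
        )
    except KincorError:
        return None


def cross_correlations(ped: Pedigree, pairs: pd.DataFrame, rtype: str) -> list[CorrEstimate]:
    """The two directional cross-time correlations for one type:
    occasion 1 in member 1 vs occasion 2 in member 2, and the reverse."""
    out = []
    for col1, col2, label in (
        ("qol_pre", "qol_pan", "pre1-pan2"),
        ("qol_pan", "qol_pre", "pan1-pre2"),
    ):
        est = _type_estimate(ped, pairs, rtype, col1, col2, label)
        if est is not None:
            out.append(est)
    return out


def pool_fixed_effect(estimates: list[CorrEstimate]) -> CorrEstimate:
    """Fixed-effect pooling of correlations on the Fisher z scale.

    Each r is z-transformed, combined with inverse-variance weights
    n_weighted - 3, and back-transformed; the pooled se on the z scale
    is propagated to the r scale by the delta method.
    """
    if not estimates:
        raise KincorError("nothing to pool")
    for e in estimates:
        if e.n_weighted <= 3:
            raise KincorError(
                f"cannot pool estimate with n_weighted={e.n_weighted} (need > 3)"
            )
    z = np.array([np.arctanh(e.r) for e in estimates])
    w = np.array([e.n_weighted - 3.0 for e in estimates])
    zbar = (w * z).sum() / w.sum()
    se_z = 1.0 / np.sqrt(w.sum())
    r = float(np.tanh(zbar))
    se = float((1.0 - r * r) * se_z)
    n = float(sum(e.n_weighted for e in estimates))
    return CorrEstimate(
        estimates[0].relationship_type, "pooled-cross",
        r, se, r - Z95 * se, r + Z95 * se, n,
    )


def kinship_correlation_table(
    ped: Pedigree, types: list[str] | None = None
) -> pd.DataFrame:
    """Within-occasion, directional cross-time and pooled cross-time
    correlations for every relationship type present in the pedigree.

    Mirrors the familiar kinship-correlation table: one row per type and
    occasion pair with weighted N, r, se and the 95% CI.
    """
    pairs = classify_pairs(ped)
    if types is None:
        types = [t for t in pairs["relationship_type"].unique() if t != "other"]
    rows = []
    for rtype in types:
        for col, label in (("qol_pre", "pre-pre"), ("qol_pan", "pan-pan")):
            est = _type_estimate(ped, pairs, rtype, col, col, label)
            if est is not None:
                rows.append(est)
        crosses = cross_correlations(ped, pairs, rtype)
        rows.extend(crosses)
        if crosses:
            try:
                rows.append(pool_fixed_effect(crosses))
            except KincorError:
                pass
    return pd.DataFrame(
        [
            {
                "relationship_type": e.relationship_type,
                "occasion_pair": e.occasion_pair,
                "n_weighted": e.n_weighted,
                "r": e.r,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
            for e in rows
        ]
    )
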