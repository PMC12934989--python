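"""Routed two-group tests, BH correction, volcano tables and the FC–FC
eight-class directional classification.

Test routing follows standard practice for small-cohort metabolomics:
Shapiro–Wilk normality on each group; if both pass, Brown–Forsythe
(Levene with median centering) decides Student vs Welch t; any
non-normality routes to a two-sided Mann–Whitney U (exact when both
groups have n ≤ 8 and no ties, normal approximation with tie correction
otherwise).  Fold changes are computed on raw intensity means, so the
FC–FC axes stay interpretable as abundance ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .io import PathwayMap

FCFC_CLASSES = (
    "both_up",
    "both_down",
    "tissue_up_only",
    "tissue_down_only",
    "plasma_up_only",
    "plasma_down_only",
    "tissue_up_plasma_down",
    "tissue_down_plasma_up",
    "unchanged",
)


@dataclass
class TestResult:
    metabolite: str
    test_used: str  # student_t | welch_t | mann_whitney
    statistic: float
    p: float
    q: float = float("nan")
    log2fc: float = float("nan")
    degenerate: bool = False


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        return False  # constant data: Shapiro undefined, route nonparametric
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(x).pvalue > alpha


def route_and_test(
    x, y, alpha: float = 0.05, metabolite: str = "", routing_alpha: float = 0.05
) -> TestResult:
    """Two-sided two-group test with assumption-based routing.

    ``routing_alpha`` is the significance level for the Shapiro–Wilk and
    Brown–Forsythe gate tests (0.05 by default).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValidationError("each group needs n >= 3")
    if np.ptp(np.concatenate([x, y])) == 0:
        # all values identical in both groups: no evidence of a difference
        return TestResult(metabolite, "student_t", 0.0, 1.0, degenerate=True)

    if _is_normal(x, routing_alpha) and _is_normal(y, routing_alpha):
        lev = stats.levene(x, y, center="median")
        equal_var = lev.pvalue > routing_alpha
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        name = "student_t" if equal_var else "welch_t"
        return TestResult(metabolite, name, float(res.statistic), float(res.pvalue))

    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (max(x.size, y.size) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        metabolite, "mann_whitney", float(res.statistic), float(res.pvalue)
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def volcano(
    mgus: pd.DataFrame,
    mm: pd.DataFrame,
    alpha: float = 0.05,
    fc_threshold: float = 0.58,
) -> pd.DataFrame:
    """Per-metabolite MM-vs-MGUS differential table.

    ``mgus`` and ``mm`` are subjects × metabolites intensity tables sharing
    columns.  log2FC is log2(mean_MM / mean_MGUS) on raw intensities; a
    metabolite is flagged ``up_in_MM`` / ``up_in_MGUS`` when both q < alpha
    and |log2FC| ≥ fc_threshold.
    """
    common = [c for c in mgus.columns if c in set(mm.columns)]
    if len(common) < 2:
        raise ValidationError("need at least 2 shared metabolites")
    rows = []
    for met in common:
        a = mgus[met].to_numpy(dtype=float)
        b = mm[met].to_numpy(dtype=float)
        res = route_and_test(a, b, alpha=alpha, metabolite=met)
        ma, mb = a.mean(), b.mean()
        eps_flag = False
        if ma <= 0 or mb <= 0:
            pos = np.concatenate([a, b])
            pos = pos[pos > 0]
            eps = (pos.min() / 2) if pos.size else 1e-12
            ma, mb = ma + eps, mb + eps
            eps_flag = True
        log2fc = float(np.log2(mb / ma))
        rows.append(
            {
                "metabolite": met,
                "test_used": res.test_used,
                "statistic": res.statistic,
                "p": res.p,
                "log2fc": log2fc,
                "eps_offset": eps_flag,
                "degenerate": res.degenerate,
            }
        )
    out = pd.DataFrame(rows).set_index("metabolite")
    out["q"] = bh_adjust(out["p"].to_numpy())
    sig = (out["q"] < alpha) & (out["log2fc"].abs() >= fc_threshold)
    out["flag"] = np.where(
        sig & (out["log2fc"] > 0),
        "up_in_MM",
        np.where(sig & (out["log2fc"] < 0), "up_in_MGUS", "ns"),
    )
    return out


def fcfc_classify(
    log2fc_tissue: float, log2fc_plasma: float, threshold: float = 0.58
) -> str:
    """One of the eight directional classes (or ``unchanged``).

    Both axes beyond ±threshold with matching signs → concordant classes;
    exactly one axis beyond with the other inside → the four "only"
    classes; opposite signs both beyond → the two offset classes.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    t, p = float(log2fc_tissue), float(log2fc_plasma)
    if np.isnan(t) or np.isnan(p):
        raise ValidationError("NaN fold change cannot be classified")
    t_up, t_dn = t >= threshold, t <= -threshold
    p_up, p_dn = p >= threshold, p <= -threshold
    if t_up and p_up:
        return "both_up"
    if t_dn and p_dn:
        return "both_down"
    if t_up and p_dn:
        return "tissue_up_plasma_down"
    if t_dn and p_up:
        return "tissue_down_plasma_up"
    if t_up:
        return "tissue_up_only"
    if t_dn:
        return "tissue_down_only"
    if p_up:
        return "plasma_up_only"
    if p_dn:
        return "plasma_down_only"
    return "unchanged"


def fcfc_table(
    log2fc_tissue: pd.Series, log2fc_plasma: pd.Series, threshold: float = 0.58
) -> pd.DataFrame:
    """FC–FC classification over the shared metabolite panel.

    Metabolites with a NaN fold change on either axis are excluded with a
    warning.
    """
    shared = log2fc_tissue.index.intersection(log2fc_plasma.index)
    df = pd.DataFrame(
        {
            "log2fc_tissue": log2fc_tissue.loc[shared],
            "log2fc_plasma": log2fc_plasma.loc[shared],
        }
    )
    bad = df.isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} metabolites with NaN fold changes",
            stacklevel=2,
        )
        df = df[~bad]
    df["class"] = [
        fcfc_classify(t, p, threshold)
        for t, p in zip(df["log2fc_tissue"], df["log2fc_plasma"])
    ]
    return df


def pathway_tally(table: pd.DataFrame, pmap: PathwayMap) -> pd.DataFrame:
    """Counts per (class, super_pathway, sub_pathway) for Sankey-style
    summaries.  Empty combinations are absent (no zero rows)."""
    rows = []
    for met, cls in table["class"].items():
        sup, sub = pmap.lookup(str(met))
        rows.append({"class": cls, "super_pathway": sup, "sub_pathway": sub})
    if not rows:
        return pd.DataFrame(columns=["class", "super_pathway", "sub_pathway", "n"])
    return (
        pd.DataFrame(rows)
        .groupby(["class", "super_pathway", "sub_pathway"], as_index=False)
        .size()
        .rename(columns={"size": "n"})
    )
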