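"""Metabolite–proliferation coupling and 3-HK-style correlation context.

Covers: per-group correlations of niche-region metabolite means against
the S-phase proliferation score; the segmentation-gain statistic
Δ|ρ| = |ρ_niche| − |ρ_whole-marrow|; correlation-partner sets around an
anchor metabolite with hypergeometric pathway over-representation; the
pairwise pathway correlation network; and per-pathway regression-slope
summaries.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, ValidationError
from .io import PathwayMap


def proliferation_correlations(
    tissue_means: pd.DataFrame,
    sphase: pd.Series,
    groups: pd.Series,
) -> pd.DataFrame:
    """Per-group metabolite–proliferation correlations.

    ``tissue_means`` is a subjects × metabolites table of niche-region mean
    intensities; ``sphase`` and ``groups`` are aligned per-subject series.
    Each supplied group must contain ≥ 4 subjects.  Returns a long table
    with Pearson r/p, Spearman ρ/p and the simple-regression slope β1 of
    proliferation on the z-scored metabolite (β1 shares Pearson's sign and
    equals r·sd(sphase) exactly).  Zero-variance metabolites yield NaN and
    are flagged.
    """
    sphase = sphase.loc[tissue_means.index].astype(float)
    groups = groups.loc[tissue_means.index]
    rows = []
    for g in pd.unique(groups):
        idx = groups[groups == g].index
        if len(idx) < 4:
            raise ValidationError(f"group {g!r} has fewer than 4 subjects")
        y = sphase.loc[idx].to_numpy()
        for met in tissue_means.columns:
            x = tissue_means.loc[idx, met].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append(
                    {
                        "group": g,
                        "metabolite": met,
                        "pearson_r": np.nan,
                        "pearson_p": np.nan,
                        "spearman_rho": np.nan,
                        "spearman_p": np.nan,
                        "beta1": np.nan,
                        "degenerate": True,
                    }
                )
                continue
            pr = stats.pearsonr(x, y)
            sp = stats.spearmanr(x, y)
            z = (x - x.mean()) / x.std()
            beta1 = float(np.polyfit(z, y, 1)[0])
            rows.append(
                {
                    "group": g,
                    "metabolite": met,
                    "pearson_r": float(pr.statistic),
                    "pearson_p": float(pr.pvalue),
                    "spearman_rho": float(sp.statistic),
                    "spearman_p": float(sp.pvalue),
                    "beta1": beta1,
                    "degenerate": False,
                }
            )
    return pd.DataFrame(rows)


def segmentation_gain(
    rho_niche: pd.Series, rho_whole: pd.Series
) -> pd.DataFrame:
    """Δ|ρ| = |ρ_niche| − |ρ_whole| per metabolite, sorted descending."""
    if set(rho_niche.index) != set(rho_whole.index):
        raise ValidationError("metabolite lists of the two inputs differ")
    rho_whole = rho_whole.loc[rho_niche.index]
    out = pd.DataFrame(
        {
            "abs_rho_niche": rho_niche.abs(),
            "abs_rho_whole": rho_whole.abs(),
        }
    )
    out["delta_abs_rho"] = out["abs_rho_niche"] - out["abs_rho_whole"]
    return out.sort_values("delta_abs_rho", ascending=False)


def correlation_partner_sets(
    matrix: pd.DataFrame, anchor: str, r_threshold: float = 0.30
) -> tuple[list[str], list[str]]:
    """Metabolites positively (r > threshold) / negatively (r < −threshold)
    Pearson-correlated with the anchor across subjects.

    The anchor itself is excluded from both sets.  No p-value filter is
    applied — the sets are defined purely by the correlation magnitude.
    """
    if anchor not in matrix.columns:
        raise ValidationError(f"anchor {anchor!r} not in matrix")
    if matrix.shape[0] < 5:
        raise ValidationError("need >= 5 subjects")
    a = matrix[anchor].to_numpy(dtype=float)
    if np.std(a) == 0:
        raise DegenerateDataError("anchor metabolite is constant")
    pos, neg = [], []
    for met in matrix.columns:
        if met == anchor:
            continue
        x = matrix[met].to_numpy(dtype=float)
        if np.std(x) == 0:
            continue
        r = float(stats.pearsonr(a, x).statistic)
        if r > r_threshold:
            pos.append(met)
        elif r < -r_threshold:
            neg.append(met)
    return pos, neg


def pathway_overrepresentation(
    hit_set: list[str],
    background: list[str],
    pmap: PathwayMap,
    level: str = "sub",
    top_k: int = 5,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per pathway.

    The background is the set of metabolites detected in the same
    compartment (controls detection bias).  Returns the ``top_k`` pathways
    ranked by ascending p, with the overlap, pathway size and
    metabolite_ratio = overlap / |hit_set|.
    """
    if level not in ("sub", "super"):
        raise ValidationError("level must be 'sub' or 'super'")
    bg = list(dict.fromkeys(background))
    hits = [m for m in dict.fromkeys(hit_set)]
    if not set(hits) <= set(bg):
        raise ValidationError("hit set must be a subset of the background")
    if not hits:
        return pd.DataFrame(
            columns=["pathway", "overlap", "set_size", "pathway_size",
                     "background_size", "p", "metabolite_ratio"]
        )
    get = pmap.sub_pathway if level == "sub" else pmap.super_pathway
    by_pathway: dict[str, set[str]] = {}
    for m in bg:
        by_pathway.setdefault(get(m), set()).add(m)
    M, N = len(bg), len(hits)
    rows = []
    for pw, members in sorted(by_pathway.items()):
        k = len(set(hits) & members)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), N))
        rows.append(
            {
                "pathway": pw,
                "overlap": k,
                "set_size": N,
                "pathway_size": len(members),
                "background_size": M,
                "p": p,
                "metabolite_ratio": k / N,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["p", "pathway"])
        .head(top_k)
        .reset_index(drop=True)
    )


def pairwise_pathway_network(
    matrix: pd.DataFrame,
    members: list[str],
    alpha: float = 0.05,
    include_external: bool = True,
) -> pd.DataFrame:
    """Pairwise Pearson correlation edges around a pathway's metabolites.

    Edges cover all member–member pairs and (optionally) member–other
    pairs; each edge carries (r, p) and a significance flag at ``alpha``.
    Unequal member panels across groups are handled by simply passing the
    group-specific subject subset and member list.
    """
    members = [m for m in members if m in matrix.columns]
    if len(members) < 2:
        raise ValidationError("need >= 2 pathway members present in the matrix")
    others = [c for c in matrix.columns if c not in set(members)]
    pairs = list(combinations(members, 2))
    if include_external:
        pairs += [(m, o) for m in members for o in others]
    rows = []
    for a, b in pairs:
        x = matrix[a].to_numpy(dtype=float)
        y = matrix[b].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        res = stats.pearsonr(x, y)
        rows.append(
            {
                "a": a,
                "b": b,
                "r": float(res.statistic),
                "p": float(res.pvalue),
                "significant": bool(res.pvalue < alpha),
                "internal": b in set(members),
            }
        )
    return pd.DataFrame(rows)


def pathway_slope_summary(
    coupling: pd.DataFrame, pmap: PathwayMap
) -> pd.DataFrame:
    """Per (group, super-pathway) summary of regression slopes β1.

    Reports the slope distribution (median and IQR) and the counts of
    positively / negatively coupled metabolites.  Pathways with no scored
    metabolites are omitted.
    """
    df = coupling.dropna(subset=["beta1"]).copy()
    df["super_pathway"] = [pmap.super_pathway(m) for m in df["metabolite"]]
    rows = []
    for (g, pw), sub in df.groupby(["group", "super_pathway"]):
        b = sub["beta1"].to_numpy()
        rows.append(
            {
                "group": g,
                "super_pathway": pw,
                "n": len(b),
                "beta1_median": float(np.median(b)),
                "beta1_q1": float(np.quantile(b, 0.25)),
                "beta1_q3": float(np.quantile(b, 0.75)),
                "n_positive": int((b > 0).sum()),
                "n_negative": int((b < 0).sum()),
            }
        )
    return pd.DataFrame(rows)
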