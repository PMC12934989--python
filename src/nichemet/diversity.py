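"""Hill-number (q = 2) diversity framework for niche vs microenvironment.

For a relative-abundance profile p over the metabolite panel, the Hill
number of order 2 is ²D = 1/Σpᵢ² — the effective number of equally
abundant features (inverse Simpson concentration).  Three statistics build
on it:

* **evenness** E = ²D / K_eff, with K_eff the richness (count of features
  with strictly positive abundance); E = 1 iff the profile is uniform on
  its support — low E means a few metabolites dominate the compartment;
* **two-community β diversity** β = ²D_γ / ²D_α,w per subject, where the
  γ profile pools the plasma-cell-rich and microenvironment profiles with
  pixel-count weights, and ²D_α,w is a weighted mean of the two
  within-compartment ²D values.  The default α is the weighted arithmetic
  mean of the ²D values (the literal "pixel/count-weighted mean"); the
  ``"jost"`` option instead takes the weighted harmonic mean (equivalently
  the reciprocal of the weighted mean Simpson concentration), which
  guarantees β ≥ 1 by Jensen's inequality.  With the arithmetic option
  β < 1 can occur and is logged as a diagnostic;
* cohort inference: two-sided Mann–Whitney on evenness and β between
  groups, the Cliff's δ effect size (MGUS vs MM orientation: δ < 0 means
  higher values in MM), and an HC3-robust OLS of logit(evenness) on
  logit(plasma-cell fraction).

Profiles are built from raw TIC-normalized intensities (never from signed
z-scores) averaged over the compartment's pixels and renormalized to sum
to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._utils import logit
from .exceptions import DegenerateDataError, ValidationError
from .io import MSIDataset
from .segmentation import SegmentationResult, tic_normalize

logger = logging.getLogger(__name__)

_SUM_TOL = 1e-9


@dataclass
class AbundanceProfile:
    """Relative metabolite abundances of one compartment."""

    p: np.ndarray
    weight: float  # pixel count of the compartment

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0):
            raise ValidationError("abundances must be non-negative")
        if abs(self.p.sum() - 1.0) > _SUM_TOL:
            raise ValidationError("abundances must sum to 1")
        if self.weight <= 0:
            raise ValidationError("weight must be positive")

    @property
    def k_eff(self) -> int:
        return int((self.p > 0).sum())


def profile_from_intensities(values: np.ndarray, weight: float = 1.0) -> AbundanceProfile:
    """Normalize a non-negative intensity vector into an abundance profile."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValidationError("intensities must be non-negative")
    total = v.sum()
    if total <= 0:
        raise DegenerateDataError("cannot build a profile from an all-zero vector")
    return AbundanceProfile(p=v / total, weight=weight)


def _as_p(p) -> np.ndarray:
    if isinstance(p, AbundanceProfile):
        return p.p
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("abundances must be non-negative")
    if abs(arr.sum() - 1.0) > _SUM_TOL:
        raise ValidationError("abundance vector must sum to 1 (got %g)" % arr.sum())
    return arr


def hill_number(p, q: float = 2.0) -> float:
    """General Hill number ^qD = (Σ pᵢ^q)^{1/(1−q)} (q→1: exp Shannon)."""
    arr = _as_p(p)
    pos = arr[arr > 0]
    if pos.size == 0:
        raise DegenerateDataError("empty support")
    if q == 1.0:
        return float(np.exp(-np.sum(pos * np.log(pos))))
    return float(np.sum(pos**q) ** (1.0 / (1.0 - q)))


def hill_d2(p) -> float:
    """Hill number of order 2: ²D = 1 / Σ pᵢ²."""
    arr = _as_p(p)
    return float(1.0 / np.sum(arr**2))


def evenness(p) -> float:
    """E = ²D / K_eff, in (0, 1]; 1 iff uniform on the support."""
    arr = _as_p(p)
    k_eff = int((arr > 0).sum())
    if k_eff == 0:
        raise DegenerateDataError("empty support: K_eff = 0")
    return hill_d2(arr) / k_eff


def beta_two_community(
    p_a, p_b, w_a: float, w_b: float, alpha_mean: str = "arithmetic"
) -> float:
    """Two-community β = ²D_γ / ²D_α,w.

    ``alpha_mean='arithmetic'`` (default) takes the weighted arithmetic
    mean of the two ²D values; ``'jost'`` takes the weighted harmonic mean
    (β ≥ 1 guaranteed).
    """
    a, b = _as_p(p_a), _as_p(p_b)
    if a.shape != b.shape:
        raise ValidationError("profiles must share the feature universe")
    if w_a <= 0 or w_b <= 0:
        raise ValidationError("weights must be positive")
    wa = w_a / (w_a + w_b)
    wb = 1.0 - wa
    gamma = wa * a + wb * b
    d_gamma = hill_d2(gamma)
    d_a, d_b = hill_d2(a), hill_d2(b)
    if alpha_mean == "arithmetic":
        d_alpha = wa * d_a + wb * d_b
    elif alpha_mean == "jost":
        d_alpha = 1.0 / (wa / d_a + wb / d_b)
    else:
        raise ValidationError("alpha_mean must be 'arithmetic' or 'jost'")
    beta = d_gamma / d_alpha
    if alpha_mean == "arithmetic" and beta < 1.0:
        logger.info(
            "beta = %.4f < 1 under the arithmetic alpha mean (theoretical "
            "caveat of the literal weighted-mean definition)",
            beta,
        )
    return float(beta)


def cliffs_delta(x, y) -> float:
    """Cliff's δ = (#{xᵢ > yⱼ} − #{xᵢ < yⱼ}) / (n_x n_y); ties count 0.

    Orientation convention: x = MGUS, y = MM, so δ < 0 indicates higher
    values in MM.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    diff = x[:, None] - y[None, :]
    return float((np.sign(diff)).sum() / (x.size * y.size))


def evenness_vs_pc_regression(
    evenness_values, pc_percent
) -> tuple[float, float, object]:
    """HC3-robust OLS of logit(evenness) on logit(plasma-cell fraction).

    Returns (slope, two-sided HC3 p-value on the slope, fitted results).
    """
    e = np.asarray(evenness_values, dtype=float)
    pc = np.asarray(pc_percent, dtype=float)
    if e.size != pc.size or e.size < 4:
        raise ValidationError("need aligned vectors with n >= 4")
    x = logit(pc)
    y = logit(e)
    if np.std(x) == 0:
        raise DegenerateDataError("regressor has zero variance")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit(cov_type="HC3", use_t=True)
    return float(fit.params[1]), float(fit.pvalues[1]), fit


def subject_diversity(
    data: MSIDataset,
    seg: SegmentationResult,
    alpha_mean: str = "arithmetic",
) -> dict:
    """Per-subject diversity row from a segmented section.

    Builds niche and microenvironment abundance profiles from raw
    TIC-normalized intensities (compartment means, renormalized) and
    returns ²D, evenness and K_eff per compartment plus the paired β.
    """
    if not seg.niche_labels:
        raise DegenerateDataError(
            f"section {data.section_id!r} has no called niche clusters"
        )
    tic = tic_normalize(data)
    is_niche = np.isin(seg.labels, list(seg.niche_labels))
    if is_niche.all():
        raise DegenerateDataError("section has no microenvironment pixels")
    prof_n = profile_from_intensities(
        tic.intensities[is_niche].mean(axis=0), weight=float(is_niche.sum())
    )
    prof_m = profile_from_intensities(
        tic.intensities[~is_niche].mean(axis=0), weight=float((~is_niche).sum())
    )
    return {
        "subject_id": data.subject_id,
        "d2_niche": hill_d2(prof_n),
        "d2_micro": hill_d2(prof_m),
        "k_eff_niche": prof_n.k_eff,
        "k_eff_micro": prof_m.k_eff,
        "evenness_niche": evenness(prof_n),
        "evenness_micro": evenness(prof_m),
        "beta": beta_two_community(
            prof_n, prof_m, prof_n.weight, prof_m.weight, alpha_mean=alpha_mean
        ),
        "niche_pixels": int(is_niche.sum()),
        "micro_pixels": int((~is_niche).sum()),
    }


def cohort_diversity_tests(
    report: pd.DataFrame, groups: pd.Series, pc_percent: pd.Series | None = None
) -> dict:
    """Cohort-level inference on the per-subject diversity report.

    Two-sided Mann–Whitney on niche evenness and on β between MGUS and MM,
    Cliff's δ for both (MGUS vs MM orientation), and — when plasma-cell
    fractions are supplied — the HC3 evenness regression.
    """
    groups = groups.loc[report.index]
    mgus = report[groups == "MGUS"]
    mm = report[groups == "MM"]
    if len(mgus) < 3 or len(mm) < 3:
        raise ValidationError("need >= 3 subjects per group")
    out = {
        "mw_p_evenness": float(
            stats.mannwhitneyu(
                mgus["evenness_niche"], mm["evenness_niche"], alternative="two-sided"
            ).pvalue
        ),
        "mw_p_beta": float(
            stats.mannwhitneyu(
                mgus["beta"], mm["beta"], alternative="two-sided"
            ).pvalue
        ),
        "cliffs_delta_evenness": cliffs_delta(
            mgus["evenness_niche"], mm["evenness_niche"]
        ),
        "cliffs_delta_beta": cliffs_delta(mgus["beta"], mm["beta"]),
    }
    if pc_percent is not None:
        slope, p, _ = evenness_vs_pc_regression(
            report["evenness_niche"].to_numpy(),
            pc_percent.loc[report.index].to_numpy(),
        )
        out["ols_slope"] = slope
        out["ols_hc3_p"] = p
    return out
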