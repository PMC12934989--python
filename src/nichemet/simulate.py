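"""Synthetic MGUS→MM cohort generator.

Emulates the data structure of a paired spatial + systemic metabolomics
study of plasma-cell disorders:

* 10 MGUS-like and 10 newly diagnosed MM subjects, each contributing one
  MSI section on a regular pixel grid;
* each section contains a plasma-cell-rich *niche* compartment (a union of
  random discs, so niches are connected blobs) embedded in the bone-marrow
  *microenvironment*; the niche pixel fraction is drawn per subject from a
  stage-dependent range (MGUS 3–7%, MM 50–90%, mirroring typical marrow
  plasma-cell burdens);
* three of the MGUS subjects are "progressive" (plasmacytoma-like): their
  marrow looks MGUS-like (small niches) but their niche metabolome already
  carries MM-level effects;
* pixel intensities are log-normal: intensity = baseline × 2^(effect) ×
  noise, so the multiplicative effects planted per (feature, compartment,
  stage) compose additively in log2 space, matching the downstream log2FC
  analyses;
* a configurable set of features carries a monotone stage trend in the
  niche, another set couples (with stage-dependent sign) to the subject's
  S-phase proliferation score, a handful of "dominance" features are
  strongly boosted in MM niches (driving an evenness deficit), and niche
  *marker* features (3-HK-like) are elevated in niches of all subjects
  while a tryptophan-like feature is enriched in the microenvironment;
* each subject's bulk bone-marrow-plasma profile is a convex combination
  of the subject's tissue niche mean and independent log-normal noise,
  controlled by ``bulk_coupling`` (1 → bulk equals the niche mean exactly
  when noise is off).

Everything downstream is testable against the returned :class:`GroundTruth`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import MSIDataset, PathwayMap, SubjectRecord, STAGE_CODE
from ._utils import derive_seed

COMPARTMENTS = ("micro", "niche")
MICRO, NICHE = 0, 1


@dataclass
class SimulationParams:
    """All knobs of the synthetic cohort.

    Effects are stored as a dense ``(n_features, 2 compartments, 3 stages)``
    array of log2 multiplicative effects; ``coupling_sign`` holds the
    per-stage sign (−1/0/+1) of the proliferation coupling per feature.
    Use :func:`default_params` to obtain the study-default parameterization.
    """

    n_subjects_per_group: int = 10
    grid: tuple[int, int] = (64, 64)
    n_features: int = 60
    niche_fraction_mgus: tuple[float, float] = (0.03, 0.07)
    niche_fraction_mm: tuple[float, float] = (0.50, 0.90)
    n_progressive: int = 3
    noise_sigma: float = 0.5  # pixel-level log2 noise SD
    subject_sigma: float = 0.35  # subject-level log2 biological variability
    bulk_coupling: float = 0.8
    bulk_noise_sigma: float = 0.5
    prolif_coupling: float = 0.75  # log2 shift per SD of S-phase within stage
    seed: int = 0
    feature_ids: list[str] = field(default_factory=list)
    effects: np.ndarray | None = None
    coupling_sign: np.ndarray | None = None
    marker_features: list[str] = field(default_factory=list)
    trend_features: list[str] = field(default_factory=list)
    prolif_features: list[str] = field(default_factory=list)
    dominant_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.grid) < 16:
            raise ValidationError("grid dimensions must be >= 16")
        if self.n_features < 20:
            raise ValidationError("n_features must be >= 20")
        for lo, hi in (self.niche_fraction_mgus, self.niche_fraction_mm):
            if not (0 < lo <= hi < 1):
                raise ValidationError("niche fraction ranges must lie in (0, 1)")
        if self.niche_fraction_mm[0] <= self.niche_fraction_mgus[1]:
            raise ValidationError(
                "MM niche-fraction range must lie strictly above the MGUS range"
            )
        if not self.feature_ids:
            self.feature_ids = [f"feat_{i:03d}" for i in range(self.n_features)]
        if len(self.feature_ids) != self.n_features:
            raise ValidationError("feature_ids length != n_features")
        if self.effects is None:
            self.effects = np.zeros((self.n_features, 2, 3))
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (self.n_features, 2, 3):
            raise ValidationError("effects must have shape (n_features, 2, 3)")
        if self.coupling_sign is None:
            self.coupling_sign = np.zeros((self.n_features, 3))
        self.coupling_sign = np.asarray(self.coupling_sign, dtype=float)

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise ValidationError(f"feature {feature_id!r} not in panel") from None

    def copy(self) -> "SimulationParams":
        return dataclasses.replace(
            self,
            feature_ids=list(self.feature_ids),
            effects=self.effects.copy(),
            coupling_sign=self.coupling_sign.copy(),
            marker_features=list(self.marker_features),
            trend_features=list(self.trend_features),
            prolif_features=list(self.prolif_features),
            dominant_features=list(self.dominant_features),
        )


@dataclass
class GroundTruth:
    """What the generator planted, for downstream verification."""

    compartment: dict[str, np.ndarray]  # section_id -> per-pixel {0 micro, 1 niche}
    pc_percent: dict[str, float]  # subject_id -> realized niche pixel fraction
    marker_features: list[str]
    trend_features: list[str]
    prolif_features: list[str]
    dominant_features: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pc_percent": self.pc_percent,
            "marker_features": self.marker_features,
            "trend_features": self.trend_features,
            "prolif_features": self.prolif_features,
            "dominant_features": self.dominant_features,
            "compartment": {k: v.tolist() for k, v in self.compartment.items()},
        }
        Path(path).write_text(json.dumps(payload))


def default_params(seed: int = 0, **overrides) -> SimulationParams:
    """The default study conditions.

    60 features: 5 niche markers (+2 log2 in every niche), one 3-HK-like
    marker that additionally trends upward with stage, one tryptophan-like
    feature enriched in the microenvironment, 4 further stage-trend
    features (+1 log2 per stage step in the niche), 4 proliferation-coupled
    features (negative coupling in MGUS stages, positive in MM — the
    nucleotide-reversal motif), 4 MM-dominance features (+3 log2 in MM
    niches) and 41 null features.
    """
    n_features = int(overrides.pop("n_features", 60))
    if n_features < 20:
        raise ValidationError("n_features must be >= 20")
    ids = [f"feat_{i:03d}" for i in range(n_features)]
    markers = ["niche_marker_0", "niche_marker_1", "niche_marker_2",
               "niche_marker_3", "hk_like"]
    ids[0:4] = markers[:4]
    ids[4] = "hk_like"
    ids[5] = "trp_like"
    trend = ["hk_like", "trend_0", "trend_1", "trend_2", "trend_3"]
    ids[6:10] = trend[1:]
    prolif = ["prolif_0", "prolif_1", "prolif_2", "prolif_3"]
    ids[10:14] = prolif
    dominant = ["dominant_0", "dominant_1", "dominant_2", "dominant_3"]
    ids[14:18] = dominant

    effects = np.zeros((n_features, 2, 3))
    coupling_sign = np.zeros((n_features, 3))

    def idx(name: str) -> int:
        return ids.index(name)

    for m in markers:
        effects[idx(m), NICHE, :] += 2.0  # niche marker, all stages
    # tryptophan-like: enriched outside niches, fading with stage inside them
    effects[idx("trp_like"), MICRO, :] += 1.5
    effects[idx("trp_like"), NICHE, :] += np.array([0.5, 0.0, -0.5])
    for t in trend:
        effects[idx(t), NICHE, :] += np.array([0.0, 1.0, 2.0])  # +1 log2/stage
    for j, p in enumerate(prolif):
        # nucleotide-reversal motif: negative coupling in MGUS, positive in MM
        coupling_sign[idx(p), :] = [-1.0, -1.0, 1.0]
        effects[idx(p), NICHE, :] += 0.5
    # MM niche dominance: +4 log2 (16x) concentrates the MM niche profile on
    # a few features (the planted evenness deficit) while keeping the
    # TIC-relative marker contrast intact for niche calling.
    for d in dominant:
        effects[idx(d), NICHE, 2] += 4.0

    params = SimulationParams(
        seed=seed,
        n_features=n_features,
        feature_ids=ids,
        effects=effects,
        coupling_sign=coupling_sign,
        marker_features=markers,
        trend_features=trend,
        prolif_features=prolif,
        dominant_features=dominant,
        **overrides,
    )
    return params


def plant_stage_trend(
    params: SimulationParams, features: list[str], delta: float
) -> SimulationParams:
    """Return a copy of ``params`` with a +delta log2/stage niche trend added.

    ``delta = 0`` is a no-op (the features are not added to the planted
    trend list).  Unknown feature ids raise ``ValidationError``.
    """
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    out = params.copy()
    if delta == 0:
        return out
    for f in features:
        j = out.feature_index(f)
        out.effects[j, NICHE, :] += delta * np.arange(3)
        if f not in out.trend_features:
            out.trend_features.append(f)
    return out


def _disc_union_mask(
    H: int, W: int, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean niche mask as a union of random discs with exactly ``target``
    True pixels (the last disc is trimmed from its rim inward)."""
    if not 0 < target < H * W:
        raise ValidationError(
            f"infeasible niche size {target} for a {H}x{W} grid; "
            "use a smaller niche fraction"
        )
    mask = np.zeros((H, W), dtype=bool)
    yy, xx = np.mgrid[0:H, 0:W]
    max_r = max(3, min(H, W) // 8)
    for _ in range(10_000):
        count = int(mask.sum())
        if count >= target:
            break
        cy = int(rng.integers(0, H))
        cx = int(rng.integers(0, W))
        r = int(rng.integers(2, max_r + 1))
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        new = disc & ~mask
        n_new = int(new.sum())
        if count + n_new <= target:
            mask |= disc
        else:
            # trim: keep the pixels of the final disc closest to its center
            keep = target - count
            ny, nx = np.nonzero(new)
            d2 = (ny - cy) ** 2 + (nx - cx) ** 2
            order = np.lexsort((nx, ny, d2))[:keep]
            mask[ny[order], nx[order]] = True
    if int(mask.sum()) != target:
        raise ValidationError("could not reach the target niche fraction")
    return mask


def simulate_cohort(
    params: SimulationParams | None = None,
) -> tuple[list[MSIDataset], list[SubjectRecord], GroundTruth]:
    """Generate the full synthetic cohort.

    Returns one MSI section per subject, the matched subject records
    (including bulk plasma profiles) and the planted ground truth.
    Bit-identical for identical params (single seeded generator).
    """
    if params is None:
        params = default_params()
    rng = np.random.default_rng(params.seed)
    H, W = params.grid
    n_pix = H * W
    p = params.n_features

    # One decade of baseline spread: wide enough for realistic rank structure,
    # narrow enough that planted multiplicative effects (not baseline luck)
    # control profile concentration.
    baselines = 10.0 ** rng.uniform(3.5, 4.5, size=p)

    # -- subject roster ----------------------------------------------------
    n = params.n_subjects_per_group
    roster: list[tuple[str, str, str]] = []  # (subject_id, group, stage)
    for i in range(n):
        stage = "MGUS_prog" if i >= n - params.n_progressive else "MGUS_nonprog"
        roster.append((f"MGUS{i + 1:02d}", "MGUS", stage))
    for i in range(n):
        roster.append((f"MM{i + 1:02d}", "MM", "MM"))

    # S-phase proliferation scores (percent), log-normal around the typical
    # clinical medians (~0.5% MGUS, ~0.7% MM).
    sphase = np.empty(len(roster))
    for i, (_, group, _) in enumerate(roster):
        mu, sd = (np.log(0.5), 0.6) if group == "MGUS" else (np.log(0.7), 1.0)
        sphase[i] = float(np.clip(np.exp(rng.normal(mu, sd)), 0.05, 10.0))

    # Within-stage z-scores of S-phase drive the proliferation coupling.
    stage_codes = np.array([STAGE_CODE[s] for _, _, s in roster])
    z_sphase = np.zeros(len(roster))
    for s in np.unique(stage_codes):
        m = stage_codes == s
        vals = np.log(sphase[m])
        sd = vals.std()
        z_sphase[m] = (vals - vals.mean()) / sd if sd > 0 else 0.0

    frac_range = {
        "MGUS_nonprog": params.niche_fraction_mgus,
        "MGUS_prog": params.niche_fraction_mgus,
        "MM": params.niche_fraction_mm,
    }

    datasets: list[MSIDataset] = []
    records: list[SubjectRecord] = []
    compartments: dict[str, np.ndarray] = {}
    pc_truth: dict[str, float] = {}

    yy, xx = np.mgrid[0:H, 0:W]
    coords = np.column_stack([xx.ravel(), yy.ravel()])

    for i, (sid, group, stage) in enumerate(roster):
        lo, hi = frac_range[stage]
        target = int(round(rng.uniform(lo, hi) * n_pix))
        mask = _disc_union_mask(H, W, target, rng).ravel()
        comp = mask.astype(int)  # 1 = niche
        s = STAGE_CODE[stage]

        # per-subject log2 effect per (feature, compartment)
        u = rng.normal(0.0, params.subject_sigma, size=p)
        eff = params.effects[:, :, s].copy()  # (p, 2)
        eff += u[:, None]
        eff[:, NICHE] += params.prolif_coupling * params.coupling_sign[:, s] * z_sphase[i]

        log2_mean = np.log2(baselines)[:, None] + eff  # (p, 2)
        pixel_log2 = log2_mean.T[comp]  # (n_pix, p)
        noise = rng.normal(0.0, params.noise_sigma, size=(n_pix, p))
        intensities = 2.0 ** (pixel_log2 + noise)

        ds = MSIDataset(
            section_id=sid,
            subject_id=sid,
            coords=coords.copy(),
            intensities=intensities,
            feature_ids=list(params.feature_ids),
        )
        datasets.append(ds)
        compartments[sid] = comp
        frac = float(mask.sum()) / n_pix
        pc_truth[sid] = frac

        niche_mean = intensities[mask].mean(axis=0)
        bulk_noise = baselines * 2.0 ** rng.normal(0.0, params.bulk_noise_sigma, size=p)
        bulk = params.bulk_coupling * niche_mean + (1 - params.bulk_coupling) * bulk_noise
        records.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                stage=stage,
                pc_percent=frac,
                sphase=float(sphase[i]),
                plasma_profile=pd.Series(bulk, index=list(params.feature_ids)),
            )
        )

    truth = GroundTruth(
        compartment=compartments,
        pc_percent=pc_truth,
        marker_features=list(params.marker_features),
        trend_features=list(params.trend_features),
        prolif_features=list(params.prolif_features),
        dominant_features=list(params.dominant_features),
    )
    return datasets, records, truth


def simulate_subject_means(
    params: SimulationParams, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Light-weight subject-level draw from the same generative model.

    Returns (niche_means, micro_means, meta) where the mean matrices are
    subjects × features intensity tables and meta carries group/stage/
    sphase.  Used for replicated power analyses where generating full pixel
    grids would be wasteful: subject-level biological variability
    (``subject_sigma``) dominates the sampling noise of compartment means.
    """
    p = params.n_features
    baselines = 10.0 ** rng.uniform(3.5, 4.5, size=p)
    n = params.n_subjects_per_group
    roster = []
    for i in range(n):
        stage = "MGUS_prog" if i >= n - params.n_progressive else "MGUS_nonprog"
        roster.append((f"MGUS{i + 1:02d}", "MGUS", stage))
    for i in range(n):
        roster.append((f"MM{i + 1:02d}", "MM", "MM"))

    sphase = np.empty(len(roster))
    for i, (_, group, _) in enumerate(roster):
        mu, sd = (np.log(0.5), 0.6) if group == "MGUS" else (np.log(0.7), 1.0)
        sphase[i] = float(np.clip(np.exp(rng.normal(mu, sd)), 0.05, 10.0))
    stage_codes = np.array([STAGE_CODE[s] for _, _, s in roster])
    z = np.zeros(len(roster))
    for s in np.unique(stage_codes):
        m = stage_codes == s
        vals = np.log(sphase[m])
        sd = vals.std()
        z[m] = (vals - vals.mean()) / sd if sd > 0 else 0.0

    niche = np.empty((len(roster), p))
    micro = np.empty((len(roster), p))
    for i, (_, _, stage) in enumerate(roster):
        s = STAGE_CODE[stage]
        u = rng.normal(0.0, params.subject_sigma, size=p)
        eff = params.effects[:, :, s].copy()
        eff += u[:, None]
        eff[:, NICHE] += params.prolif_coupling * params.coupling_sign[:, s] * z[i]
        niche[i] = baselines * 2.0 ** eff[:, NICHE]
        micro[i] = baselines * 2.0 ** eff[:, MICRO]

    ids = [r[0] for r in roster]
    meta = pd.DataFrame(
        {
            "group": [r[1] for r in roster],
            "stage": [r[2] for r in roster],
            "stage_code": stage_codes,
            "sphase": sphase,
        },
        index=pd.Index(ids, name="subject_id"),
    )
    cols = list(params.feature_ids)
    return (
        pd.DataFrame(niche, index=ids, columns=cols),
        pd.DataFrame(micro, index=ids, columns=cols),
        meta,
    )


def synthetic_pathway_map(feature_ids: list[str]) -> PathwayMap:
    """A plausible pathway annotation for the synthetic panel.

    Planted feature families get coherent assignments (markers and the
    3-HK-like feature → amino-acid/tryptophan metabolism, trend and
    proliferation features → nucleotide metabolism, dominance features →
    lipid metabolism); null features cycle through the remaining
    super-pathways so tallies are non-degenerate.
    """
    supers = ["carbohydrate", "energy", "vitamin", "other", "lipid", "amino acid"]
    assignments: dict[str, tuple[str, str]] = {}
    k = 0
    for f in feature_ids:
        if f.startswith(("niche_marker", "hk_like", "trp_like")):
            assignments[f] = ("amino acid", "tryptophan metabolism")
        elif f.startswith("trend") or f.startswith("prolif"):
            assignments[f] = ("nucleotide", "pyrimidine metabolism")
        elif f.startswith("dominant"):
            assignments[f] = ("lipid", "sphingolipid metabolism")
        else:
            sup = supers[k % len(supers)]
            assignments[f] = (sup, f"{sup} subpathway {k % 3}")
            k += 1
    return PathwayMap(assignments)
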