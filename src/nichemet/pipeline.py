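"""End-to-end pipeline: simulate → segment → differential → coupling →
diversity → multivariate, with a machine-readable run manifest.

Per-stage seeds are derived from the master config seed by fixed offsets,
so any stage can be re-run in isolation and reproduce its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as cp
from . import diffstats as ds
from . import diversity as dv
from . import multivariate as mv
from . import segmentation as sg
from ._utils import derive_seed
from .exceptions import NicheMetError
from .io import (
    AnalysisConfig,
    MSIDataset,
    PathwayMap,
    SubjectRecord,
    plasma_frame,
    subject_frame,
    write_subject_table,
)
from .simulate import (
    SimulationParams,
    default_params,
    simulate_cohort,
    synthetic_pathway_map,
)

STAGE_OFFSETS = {
    "simulate": 1,
    "segment": 2,
    "diffexpr": 3,
    "coupling": 4,
    "diversity": 5,
    "multivariate": 6,
}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)  # name -> {status, seconds}
    outputs: dict = field(default_factory=dict)  # name -> path
    summary: dict = field(default_factory=dict)  # headline numbers

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _config_hash(config: AnalysisConfig) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16]


def compartment_means(
    data: MSIDataset, seg: sg.SegmentationResult
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(niche mean, microenvironment mean, whole-section mean) of raw
    intensities per feature."""
    is_niche = np.isin(seg.labels, list(seg.niche_labels))
    whole = data.intensities.mean(axis=0)
    niche = data.intensities[is_niche].mean(axis=0) if is_niche.any() else whole
    micro = data.intensities[~is_niche].mean(axis=0) if (~is_niche).any() else whole
    return niche, micro, whole


def run_all(
    config: AnalysisConfig,
    workdir: str | Path,
    sim_params: SimulationParams | None = None,
    datasets: list[MSIDataset] | None = None,
    records: list[SubjectRecord] | None = None,
    pathway_map: PathwayMap | None = None,
    markers: list[str] | None = None,
    write_pixel_tables: bool = False,
) -> RunManifest:
    """Execute all stages on simulated (default) or supplied data.

    Outputs TSV/JSON artifacts under ``workdir`` and returns the manifest.
    When no pathway map is supplied and the data are simulated, the
    synthetic pathway annotation is used; with external data and no map,
    all metabolites tally under "other".
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config), seed=config.seed)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
                manifest.stages[name] = {
                    "status": "ok",
                    "seconds": round(time.perf_counter() - t0, 3),
                }
            except NicheMetError as exc:
                manifest.stages[name] = {
                    "status": f"failed: {exc}",
                    "seconds": round(time.perf_counter() - t0, 3),
                }
                manifest.to_json(workdir / "manifest.json")
                raise

        return wrap

    state: dict = {}

    # ------------------------------------------------------------------ simulate
    @stage("simulate")
    def _simulate():
        nonlocal datasets, records, pathway_map, markers
        if datasets is None:
            params = sim_params or default_params(
                seed=derive_seed(config.seed, STAGE_OFFSETS["simulate"])
            )
            datasets, records, truth = simulate_cohort(params)
            state["truth"] = truth
            state["params"] = params
            if markers is None:
                markers = list(params.marker_features)
            if pathway_map is None:
                pathway_map = synthetic_pathway_map(list(params.feature_ids))
        if pathway_map is None:
            pathway_map = PathwayMap()
        if markers is None:
            raise NicheMetError("marker feature list required for external data")
        state["datasets"] = datasets
        state["records"] = records
        state["dataset_by_id"] = {d.section_id: d for d in datasets}
        write_subject_table(
            records, workdir / "subjects.tsv", workdir / "plasma.tsv"
        )
        if write_pixel_tables:
            from .io import write_pixel_table

            pix = workdir / "pixels"
            pix.mkdir(exist_ok=True)
            for d in datasets:
                write_pixel_table(d, pix / f"{d.section_id}.tsv")
        manifest.outputs["subjects"] = str(workdir / "subjects.tsv")

    # ------------------------------------------------------------------ segment
    @stage("segment")
    def _segment():
        seed = derive_seed(config.seed, STAGE_OFFSETS["segment"])
        segs = {}
        rows = []
        niche_means, micro_means, whole_means = {}, {}, {}
        for d in datasets:
            seg = sg.segment_section(
                d, K=config.k_sections, seed=seed, markers=markers
            )
            segs[d.section_id] = seg
            n_mean, m_mean, w_mean = compartment_means(d, seg)
            niche_means[d.subject_id] = n_mean
            micro_means[d.subject_id] = m_mean
            whole_means[d.subject_id] = w_mean
            rows.append(
                {
                    "subject_id": d.subject_id,
                    "niche_fraction": seg.niche_fraction,
                    "n_clusters": seg.n_clusters,
                    "flagged": seg.flagged,
                }
            )
        cols = list(datasets[0].feature_ids)
        state["segs"] = segs
        state["niche_means"] = pd.DataFrame(niche_means, index=cols).T
        state["micro_means"] = pd.DataFrame(micro_means, index=cols).T
        state["whole_means"] = pd.DataFrame(whole_means, index=cols).T
        frac = pd.DataFrame(rows).set_index("subject_id")
        state["fractions"] = frac
        frac.to_csv(workdir / "niche_fractions.tsv", sep="\t")
        manifest.outputs["niche_fractions"] = str(workdir / "niche_fractions.tsv")

        meta = subject_frame(records)
        conc = sg.concordance(
            frac.loc[meta.index, "niche_fraction"].to_numpy(),
            meta["pc_percent"].to_numpy(),
        )
        state["concordance"] = conc
        manifest.summary["concordance_pearson_r"] = conc.pearson_r
        manifest.summary["concordance_spearman_rho"] = conc.spearman_rho

    # ------------------------------------------------------------------ diffexpr
    @stage("diffexpr")
    def _diffexpr():
        meta = subject_frame(records)
        tissue = state["niche_means"]
        plasma = plasma_frame(records)
        mgus_ids = meta.index[meta["group"] == "MGUS"]
        mm_ids = meta.index[meta["group"] == "MM"]
        tissue_volc = ds.volcano(
            tissue.loc[mgus_ids], tissue.loc[mm_ids],
            alpha=config.alpha, fc_threshold=config.fc_threshold,
        )
        plasma_volc = ds.volcano(
            plasma.loc[plasma.index.intersection(mgus_ids)],
            plasma.loc[plasma.index.intersection(mm_ids)],
            alpha=config.alpha, fc_threshold=config.fc_threshold,
        )
        shared = tissue_volc.index.intersection(plasma_volc.index)
        fcfc = ds.fcfc_table(
            tissue_volc["log2fc"], plasma_volc["log2fc"], config.fc_threshold
        )
        tally = ds.pathway_tally(fcfc, pathway_map)
        tissue_volc.to_csv(workdir / "volcano_tissue.tsv", sep="\t")
        plasma_volc.to_csv(workdir / "volcano_plasma.tsv", sep="\t")
        fcfc.to_csv(workdir / "fcfc.tsv", sep="\t")
        tally.to_csv(workdir / "fcfc_pathway_tally.tsv", sep="\t", index=False)
        state["tissue_volcano"] = tissue_volc
        state["plasma_volcano"] = plasma_volc
        state["fcfc"] = fcfc
        manifest.summary["n_shared_metabolites"] = int(len(shared))
        manifest.summary["fcfc_class_counts"] = (
            fcfc["class"].value_counts().to_dict()
        )
        manifest.outputs["fcfc"] = str(workdir / "fcfc.tsv")

    # ------------------------------------------------------------------ coupling
    @stage("coupling")
    def _coupling():
        meta = subject_frame(records)
        tissue = state["niche_means"]
        whole = state["whole_means"]
        corr = cp.proliferation_correlations(
            tissue, meta["sphase"], meta["group"]
        )
        corr_whole = cp.proliferation_correlations(
            whole, meta["sphase"], meta["group"]
        )
        gains = {}
        for g in ("MGUS", "MM"):
            rn = corr[corr["group"] == g].set_index("metabolite")["spearman_rho"]
            rw = corr_whole[corr_whole["group"] == g].set_index("metabolite")[
                "spearman_rho"
            ]
            keep = rn.dropna().index.intersection(rw.dropna().index)
            gains[g] = cp.segmentation_gain(rn.loc[keep], rw.loc[keep])
        slopes = cp.pathway_slope_summary(corr, pathway_map)
        anchor = "hk_like" if "hk_like" in tissue.columns else tissue.columns[0]
        pos, neg = cp.correlation_partner_sets(
            tissue, anchor, r_threshold=config.corr_threshold
        )
        enrich = cp.pathway_overrepresentation(
            pos, [m for m in tissue.columns if m != anchor], pathway_map
        )
        corr.to_csv(workdir / "proliferation_correlations.tsv", sep="\t", index=False)
        slopes.to_csv(workdir / "pathway_slopes.tsv", sep="\t", index=False)
        enrich.to_csv(workdir / "anchor_enrichment.tsv", sep="\t", index=False)
        for g, gdf in gains.items():
            gdf.to_csv(workdir / f"segmentation_gain_{g}.tsv", sep="\t")
        state["coupling"] = corr
        state["gains"] = gains
        manifest.summary["median_delta_abs_rho_MM"] = float(
            gains["MM"]["delta_abs_rho"].median()
        )

    # ------------------------------------------------------------------ diversity
    @stage("diversity")
    def _diversity():
        meta = subject_frame(records)
        rows = []
        for d in datasets:
            seg = state["segs"][d.section_id]
            if not seg.niche_labels:
                continue
            rows.append(dv.subject_diversity(d, seg))
        report = pd.DataFrame(rows).set_index("subject_id")
        tests = dv.cohort_diversity_tests(
            report, meta["group"], meta["pc_percent"]
        )
        report.to_csv(workdir / "diversity_report.tsv", sep="\t")
        state["diversity_report"] = report
        state["diversity_tests"] = tests
        manifest.summary.update(
            {f"diversity_{k}": v for k, v in tests.items()}
        )
        manifest.outputs["diversity"] = str(workdir / "diversity_report.tsv")

    # ------------------------------------------------------------------ multivariate
    @stage("multivariate")
    def _multivariate():
        seed = derive_seed(config.seed, STAGE_OFFSETS["multivariate"])
        meta = subject_frame(records)
        # three region types: MGUS niche, MGUS whole marrow, MM niche
        mgus_ids = meta.index[meta["group"] == "MGUS"]
        mm_ids = meta.index[meta["group"] == "MM"]
        blocks = [
            np.log2(state["niche_means"].loc[mgus_ids].to_numpy() + 1),
            np.log2(state["whole_means"].loc[mgus_ids].to_numpy() + 1),
            np.log2(state["niche_means"].loc[mm_ids].to_numpy() + 1),
        ]
        X = np.vstack(blocks)
        sd = X.std(axis=0)
        Xz = (X - X.mean(axis=0)) / np.where(sd < 1e-12, 1.0, sd)
        region = np.array(
            ["MGUS_niche"] * len(mgus_ids)
            + ["MGUS_whole"] * len(mgus_ids)
            + ["MM_niche"] * len(mm_ids)
        )
        perm = mv.permanova(
            X=Xz, groups=region, n_perm=config.n_permutations, seed=seed
        )
        scores, evr, _ = mv.pca_scores(Xz, n_components=2)
        trend = mv.trend_volcano(
            np.log2(state["niche_means"] + 1),
            meta["stage_code"],
            alpha=config.alpha,
        )
        # spatial heterogeneity + per-cluster VIP on the first MGUS section
        het_rows = []
        for d in datasets:
            if meta.loc[d.subject_id, "group"] != "MGUS":
                continue
            _, props, simpson = sg.spatial_heterogeneity(
                d, K=config.k_spatial, seed=seed
            )
            het_rows.append(
                {"subject_id": d.subject_id, "simpson": simpson,
                 "proportions": ",".join(f"{p:.4f}" for p in props)}
            )
        het = pd.DataFrame(het_rows).set_index("subject_id")
        trend.to_csv(workdir / "trend_volcano.tsv", sep="\t")
        het.to_csv(workdir / "spatial_heterogeneity.tsv", sep="\t")
        pd.DataFrame(
            scores, columns=["PC1", "PC2"]
        ).assign(region=region).to_csv(workdir / "pca_scores.tsv", sep="\t", index=False)
        state["permanova"] = perm
        state["trend"] = trend
        state["heterogeneity"] = het
        manifest.summary["permanova_r2"] = perm.r2
        manifest.summary["permanova_p"] = perm.p
        manifest.summary["n_monotone_metabolites"] = int(trend["monotone"].sum())
        manifest.summary["simpson_range_mgus"] = [
            float(het["simpson"].min()),
            float(het["simpson"].max()),
        ]

    manifest.to_json(workdir / "manifest.json")
    manifest.outputs["manifest"] = str(workdir / "manifest.json")
    state["manifest"] = manifest
    run_all.last_state = state  # exposed for programmatic consumers
    return manifest
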