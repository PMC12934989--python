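"""Data model and file input/output.

The package works on three kinds of on-disk inputs, all plain delimited
text so that runs are reproducible and diffable:

* **pixel tables** — one row per MSI pixel, columns ``x``, ``y`` and one
  column per metabolite (intensities in arbitrary units, non-negative);
* **subject tables** — per-patient metadata (diagnosis group, progression
  stage, bone-marrow plasma-cell fraction, S-phase proliferation score)
  plus a wide companion table of bulk bone-marrow-plasma profiles;
* **pathway maps** — metabolite → (super-pathway, sub-pathway) annotations.

Physical pixel pitch (e.g. 50 μm for MALDI–FT-ICR imaging) is metadata
only; all computations use 0-based integer grid coordinates.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._utils import LOGIT_EPS
from .exceptions import FormatError, ValidationError

GROUPS = ("MGUS", "MM")
STAGES = ("MGUS_nonprog", "MGUS_prog", "MM")
#: Ordinal codes used by the monotone-trend analysis.
STAGE_CODE = {"MGUS_nonprog": 0, "MGUS_prog": 1, "MM": 2}

SUPER_PATHWAYS = (
    "nucleotide",
    "amino acid",
    "lipid",
    "carbohydrate",
    "energy",
    "vitamin",
    "other",
)


@dataclass
class MSIDataset:
    """One tissue section's pixel-level metabolite intensity grid.

    Parameters
    ----------
    section_id, subject_id:
        Identifiers; one section per subject in the default design.
    coords:
        ``(n_pixels, 2)`` integer array of (x, y) grid indices, 0-based,
        unique within the section.
    intensities:
        ``(n_pixels, n_features)`` array, arbitrary units.  Raw data must
        be non-negative and finite; derived (normalized) matrices carry
        ``normalized=True`` and may contain signed z-scores.
    feature_ids:
        Metabolite names, one per intensity column.
    feature_mz:
        Optional m/z values (Da), same length as ``feature_ids``.
    """

    section_id: str
    subject_id: str
    coords: np.ndarray
    intensities: np.ndarray
    feature_ids: list[str]
    feature_mz: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("coords must be an (n_pixels, 2) array")
        if self.intensities.shape[0] != self.coords.shape[0]:
            raise ValidationError("coords and intensities disagree on n_pixels")
        if self.intensities.shape[1] != len(self.feature_ids):
            raise ValidationError("n_features != len(feature_ids)")
        uniq = {tuple(c) for c in self.coords.tolist()}
        if len(uniq) != self.coords.shape[0]:
            seen: set[tuple[int, int]] = set()
            for c in map(tuple, self.coords.tolist()):
                if c in seen:
                    raise ValidationError(
                        f"duplicate pixel coordinate {c} in section "
                        f"{self.section_id!r}"
                    )
                seen.add(c)
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities contain non-finite values")
        if not self.normalized and np.any(self.intensities < 0):
            rows, cols = np.nonzero(self.intensities < 0)
            cells = [
                f"(pixel {tuple(self.coords[r])}, {self.feature_ids[c]})"
                for r, c in list(zip(rows, cols))[:5]
            ]
            raise ValidationError(
                "negative intensities at " + ", ".join(cells)
            )
        if self.feature_mz is not None:
            self.feature_mz = np.asarray(self.feature_mz, dtype=float)
            if self.feature_mz.shape[0] != len(self.feature_ids):
                raise ValidationError("feature_mz length != n_features")

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature {feature_id!r}") from None


@dataclass
class SubjectRecord:
    """One patient's metadata and (optional) bulk bone-marrow-plasma profile."""

    subject_id: str
    group: str
    stage: str
    pc_percent: float  # fraction of bone-marrow plasma cells, in (0, 1)
    sphase: float  # proliferative fraction, percent in [0, 100]
    plasma_profile: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if self.stage not in STAGES:
            raise ValidationError(
                f"unknown stage {self.stage!r}; expected one of {STAGES}"
            )
        if self.group == "MM" and self.stage != "MM":
            raise ValidationError("group MM requires stage MM")
        if self.group == "MGUS" and self.stage == "MM":
            raise ValidationError("group MGUS cannot have stage MM")
        # The logit transform used downstream is undefined at 0 and 1.
        self.pc_percent = float(np.clip(self.pc_percent, LOGIT_EPS, 1 - LOGIT_EPS))
        if not 0 <= self.sphase <= 100:
            raise ValidationError("sphase must be a percentage in [0, 100]")

    @property
    def stage_code(self) -> int:
        return STAGE_CODE[self.stage]


class PathwayMap:
    """Metabolite → (super-pathway, sub-pathway) annotation map.

    Unknown metabolites are lazily assigned to ``("other", "other")``; the
    first such lookup emits a single warning.
    """

    def __init__(self, assignments: Mapping[str, tuple[str, str]] | None = None):
        self.assignments: dict[str, tuple[str, str]] = dict(assignments or {})
        self._warned_unknown = False

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathwayMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        if "metabolite" not in cols or "super_pathway" not in cols:
            raise FormatError(
                "pathway map needs columns metabolite, super_pathway[, sub_pathway]"
            )
        if "sub_pathway" not in cols:
            df["sub_pathway"] = df["super_pathway"]
        assignments: dict[str, tuple[str, str]] = {}
        for met, sup, sub in df[["metabolite", "super_pathway", "sub_pathway"]].itertuples(
            index=False
        ):
            entry = (str(sup), str(sub))
            if met in assignments and assignments[met] != entry:
                raise ValidationError(
                    f"metabolite {met!r} mapped to conflicting pathways "
                    f"{assignments[met]} and {entry}"
                )
            assignments[met] = entry
        return cls(assignments)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"metabolite": m, "super_pathway": s, "sub_pathway": b}
            for m, (s, b) in sorted(self.assignments.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def lookup(self, metabolite: str) -> tuple[str, str]:
        try:
            return self.assignments[metabolite]
        except KeyError:
            if not self._warned_unknown:
                warnings.warn(
                    f"metabolite {metabolite!r} (and possibly others) not in "
                    "pathway map; assigning to 'other'",
                    stacklevel=2,
                )
                self._warned_unknown = True
            return ("other", "other")

    def super_pathway(self, metabolite: str) -> str:
        return self.lookup(metabolite)[0]

    def sub_pathway(self, metabolite: str) -> str:
        return self.lookup(metabolite)[1]

    def __contains__(self, metabolite: str) -> bool:
        return metabolite in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class AnalysisConfig:
    """Pipeline-wide knobs.

    ``fc_threshold`` defaults to log2(1.5) rounded to two decimals (0.58),
    the conventional 1.5-fold-change cut; ``corr_threshold`` is the Pearson
    cut used to define correlation-partner sets; ``k_sections`` is the
    number of clusters for per-section niche segmentation and ``k_spatial``
    the number used for the spatial-heterogeneity analysis.
    """

    seed: int = 0
    k_sections: int = 4
    k_spatial: int = 6
    fc_threshold: float = round(float(np.log2(1.5)), 2)
    corr_threshold: float = 0.30
    n_permutations: int = 999
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0:
            raise ValidationError("fc_threshold must be > 0")
        if not 0 < self.corr_threshold < 1:
            raise ValidationError("corr_threshold must be in (0, 1)")
        if self.n_permutations < 99:
            raise ValidationError("n_permutations must be >= 99")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Pixel tables
# ---------------------------------------------------------------------------

def read_pixel_table(
    path: str | Path,
    section_id: str | None = None,
    subject_id: str | None = None,
) -> MSIDataset:
    """Read a TSV pixel table (columns ``x``, ``y``, then metabolites)."""
    path = Path(path)
    # round_trip parsing: pandas' fast float reader can be 1 ulp off, which
    # would break byte-exact write/read identity
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("x", "y"):
        if col not in df.columns:
            raise FormatError(f"pixel table {path.name} is missing column {col!r}")
    feature_ids = [c for c in df.columns if c not in ("x", "y")]
    if not feature_ids:
        raise FormatError(f"pixel table {path.name} has no metabolite columns")
    sid = section_id if section_id is not None else path.stem
    return MSIDataset(
        section_id=sid,
        subject_id=subject_id if subject_id is not None else sid,
        coords=df[["x", "y"]].to_numpy(),
        intensities=df[feature_ids].to_numpy(dtype=float),
        feature_ids=feature_ids,
    )


def write_pixel_table(data: MSIDataset, path: str | Path) -> None:
    """Write a pixel table; numeric values keep full double precision."""
    df = pd.DataFrame(data.intensities, columns=data.feature_ids)
    df.insert(0, "y", data.coords[:, 1])
    df.insert(0, "x", data.coords[:, 0])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Subject tables
# ---------------------------------------------------------------------------

def read_subject_table(
    meta_path: str | Path,
    plasma_path: str | Path | None = None,
) -> list[SubjectRecord]:
    """Read subject metadata (+ optional wide plasma-profile table).

    Stage is inferred when absent: MM subjects get stage ``MM``; MGUS
    subjects default to ``MGUS_nonprog`` unless a truthy ``progression``
    column marks them as progressive.
    """
    meta = pd.read_csv(
        meta_path, sep="\t", dtype={"subject_id": str}, float_precision="round_trip"
    )
    required = {"subject_id", "group", "pc_percent", "sphase"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"subject table missing columns {sorted(missing)}")

    plasma = None
    if plasma_path is not None:
        plasma = pd.read_csv(
            plasma_path, sep="\t", index_col=0, float_precision="round_trip"
        )
        plasma.index = plasma.index.astype(str)

    records: list[SubjectRecord] = []
    for row in meta.itertuples(index=False):
        group = str(row.group)
        if hasattr(row, "stage") and isinstance(row.stage, str) and row.stage:
            stage = row.stage
        elif group == "MM":
            stage = "MM"
        else:
            progressed = bool(getattr(row, "progression", False))
            stage = "MGUS_prog" if progressed else "MGUS_nonprog"
        profile = None
        if plasma is not None:
            if str(row.subject_id) in plasma.index:
                profile = plasma.loc[str(row.subject_id)].astype(float)
            else:
                warnings.warn(
                    f"subject {row.subject_id!r} absent from plasma table; "
                    "profile marked missing",
                    stacklevel=2,
                )
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                group=group,
                stage=stage,
                pc_percent=float(row.pc_percent),
                sphase=float(row.sphase),
                plasma_profile=profile,
            )
        )
    return records


def write_subject_table(
    records: Sequence[SubjectRecord],
    meta_path: str | Path,
    plasma_path: str | Path | None = None,
) -> None:
    meta = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "stage": [r.stage for r in records],
            "pc_percent": [r.pc_percent for r in records],
            "sphase": [r.sphase for r in records],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False, float_format="%.17g")
    if plasma_path is not None:
        profiles = {
            r.subject_id: r.plasma_profile
            for r in records
            if r.plasma_profile is not None
        }
        if profiles:
            pd.DataFrame(profiles).T.rename_axis("subject_id").to_csv(
                plasma_path, sep="\t", float_format="%.17g"
            )


def read_imzml(
    path: str | Path,
    feature_mz: Sequence[float],
    tol: float = 0.005,
    section_id: str | None = None,
    subject_id: str | None = None,
) -> MSIDataset:
    """Optional imzML ingestion adapter (requires pyimzml).

    Converts a centroided imzML file into the pixel-table model by summing
    intensity within ±``tol`` Da of each requested m/z.  This is a
    convenience bridge for already-processed data, not a processing
    pipeline: no peak picking, normalization or annotation is performed.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    parser = ImzMLParser(str(path))
    mzs = np.asarray(feature_mz, dtype=float)
    coords = []
    rows = []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        spec_mz, spec_int = parser.getspectrum(i)
        spec_mz = np.asarray(spec_mz)
        spec_int = np.asarray(spec_int)
        row = [
            float(spec_int[np.abs(spec_mz - m) <= tol].sum()) for m in mzs
        ]
        coords.append((int(x), int(y)))
        rows.append(row)
    sid = section_id if section_id is not None else path.stem
    return MSIDataset(
        section_id=sid,
        subject_id=subject_id if subject_id is not None else sid,
        coords=np.asarray(coords, dtype=int),
        intensities=np.asarray(rows, dtype=float),
        feature_ids=[f"mz_{m:.5f}" for m in mzs],
        feature_mz=mzs,
    )


def load_pathway_map(path: str | Path) -> PathwayMap:
    """Convenience alias for :meth:`PathwayMap.from_tsv`."""
    return PathwayMap.from_tsv(path)


def subject_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by subject_id (no plasma profiles)."""
    return pd.DataFrame(
        {
            "group": [r.group for r in records],
            "stage": [r.stage for r in records],
            "stage_code": [r.stage_code for r in records],
            "pc_percent": [r.pc_percent for r in records],
            "sphase": [r.sphase for r in records],
        },
        index=pd.Index([r.subject_id for r in records], name="subject_id"),
    )


def plasma_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Bulk plasma profiles as a subjects × metabolites DataFrame."""
    profiles = {
        r.subject_id: r.plasma_profile
        for r in records
        if r.plasma_profile is not None
    }
    return pd.DataFrame(profiles).T.rename_axis("subject_id")
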