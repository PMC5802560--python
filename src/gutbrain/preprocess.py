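"""Feature-table containers, transforms, and the on-disk dialects.

Two feature tables drive the analysis: an OTU relative-abundance table
(samples x OTUs, rows closed to 1) and a brain table of per-ROI
diffusion-tensor summaries (fractional anisotropy ``fa``, radial
diffusivity ``rd``, axial diffusivity ``ad`` and trace ``tr`` = 3 x mean
diffusivity).  The prescribed preprocessing is a log2 transform of the OTU
abundances and a per-feature z-scaling of the brain values; both are gated
by explicit scale flags so they cannot be applied twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "BrainFeatureTable",
    "DietLabels",
    "AlignmentReport",
    "log2_transform",
    "zscale",
    "align_cohort",
    "read_otu_table",
    "read_brain_table",
    "read_labels",
    "read_taxonomy",
]

METRICS = ("fa", "rd", "ad", "tr")
BRAIN_FEATURE_SEP = ":"
_CLOSURE_TOL = 1e-6


def _check_unique(values, what: str) -> None:
    if pd.Index(values).has_duplicates:
        raise ValueError(f"duplicate {what} identifiers")


@dataclass(frozen=True)
class OtuTable:
    """Samples x OTUs abundance matrix.

    ``scale`` is ``"relative"`` (values in [0,1], rows sum to 1) or
    ``"log2"`` (after :func:`log2_transform`).  ``taxonomy`` optionally maps
    otu_id to a taxonomy string.
    """

    values: pd.DataFrame
    scale: str = "relative"
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("relative", "log2"):
            raise ValueError(f"unknown OTU table scale {self.scale!r}")
        self.values.index.name = "sample_id"
        self.values.columns.name = None
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "OTU")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("OTU table contains missing values")
        if self.scale == "relative":
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError("relative abundances must lie in [0, 1]")
            if arr.size:
                sums = arr.sum(axis=1)
                bad = np.flatnonzero(np.abs(sums - 1.0) > _CLOSURE_TOL)
                if len(bad):
                    sid = self.values.index[bad[0]]
                    raise ValueError(
                        f"sample {sid!r} abundances sum to {sums[bad[0]]:.8f}, not 1"
                    )

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def otu_ids(self) -> list:
        return list(self.values.columns)


@dataclass(frozen=True)
class BrainFeatureTable:
    """Samples x brain features; feature id is ``"<roi>:<metric>"``."""

    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "zscaled"):
            raise ValueError(f"unknown brain table scale {self.scale!r}")
        self.values.index.name = "sample_id"
        self.values.columns.name = None
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "brain feature")
        if np.isnan(self.values.to_numpy(dtype=float)).any():
            raise ValueError("brain table contains missing values")
        for fid in self.values.columns:
            roi, sep, metric = str(fid).rpartition(BRAIN_FEATURE_SEP)
            if not sep or metric not in METRICS:
                raise ValueError(
                    f"brain feature {fid!r} is not '<roi>{BRAIN_FEATURE_SEP}<metric>' "
                    f"with metric in {METRICS}"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    def roi_metric_pairs(self) -> list[tuple[str, str]]:
        return [tuple(str(f).rsplit(BRAIN_FEATURE_SEP, 1)) for f in self.values.columns]


@dataclass(frozen=True)
class DietLabels:
    """sample_id -> diet class, with a fixed ordered class universe."""

    labels: pd.Series
    classes: tuple = ()

    def __post_init__(self) -> None:
        self.labels.index.name = "sample_id"
        object.__setattr__(self, "labels", self.labels.rename("diet"))
        _check_unique(self.labels.index, "sample")
        observed = tuple(sorted(set(self.labels)))
        classes = self.classes or observed
        if not set(self.labels) <= set(classes):
            raise ValueError("labels contain classes outside the declared class set")
        object.__setattr__(self, "classes", tuple(classes))

    @property
    def sample_ids(self) -> list:
        return list(self.labels.index)

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(self.classes, fill_value=0)


@dataclass(frozen=True)
class AlignmentReport:
    kept: tuple
    dropped: dict = field(default_factory=dict)  # table name -> dropped sample ids


def log2_transform(table: OtuTable, pseudocount: float = 1e-6) -> OtuTable:
    """Entry-wise value' = log2(value + pseudocount).

    The pseudocount keeps zero abundances finite; the default 1e-6 is on the
    order of the smallest detectable relative abundance at typical 16S
    sequencing depth. Refuses to transform twice.
    """
    if table.scale != "relative":
        raise ValueError("table is already log2-transformed")
    if not np.isfinite(pseudocount) or pseudocount <= 0:
        raise ValueError(f"pseudocount must be a positive finite real, got {pseudocount}")
    out = np.log2(table.values.to_numpy(dtype=float) + pseudocount)
    return replace(
        table,
        values=pd.DataFrame(out, index=table.values.index, columns=table.values.columns),
        scale="log2",
    )


def zscale(table: BrainFeatureTable) -> BrainFeatureTable:
    """Center each feature and divide by its sample sd (n-1 denominator).

    Zero-variance features are mapped to all-zero with a warning: they are
    uninformative, not malformed.
    """
    if table.scale != "raw":
        raise ValueError("table is already z-scaled")
    if len(table.values) < 2:
        raise ValueError("z-scaling needs at least 2 samples")
    arr = table.values.to_numpy(dtype=float)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        names = [str(c) for c in table.values.columns[const]]
        warnings.warn(
            f"constant brain features set to zero: {', '.join(names)}",
            stacklevel=2,
        )
    safe_sd = np.where(const, 1.0, sd)
    out = (arr - mu) / safe_sd
    out[:, const] = 0.0
    return replace(
        table,
        values=pd.DataFrame(out, index=table.values.index, columns=table.values.columns),
        scale="zscaled",
    )


def align_cohort(
    otu: OtuTable, brain: BrainFeatureTable, labels: DietLabels
) -> tuple[OtuTable, BrainFeatureTable, DietLabels, AlignmentReport]:
    """Restrict all three tables to their common samples, sorted by sample_id."""
    sets = {
        "otu": set(otu.sample_ids),
        "brain": set(brain.sample_ids),
        "labels": set(labels.sample_ids),
    }
    common = sorted(sets["otu"] & sets["brain"] & sets["labels"], key=str)
    if not common:
        raise ValueError("no samples are shared by the OTU, brain and label tables")
    report = AlignmentReport(
        kept=tuple(common),
        dropped={
            name: tuple(sorted(ids - set(common), key=str))
            for name, ids in sets.items()
            if ids - set(common)
        },
    )
    return (
        replace(otu, values=otu.values.loc[common]),
        replace(brain, values=brain.values.loc[common]),
        replace(labels, labels=labels.labels.loc[common]),
        report,
    )


# ---------------------------------------------------------------------------
# on-disk dialects (shared with synthetic_cohort.write_cohort)
# ---------------------------------------------------------------------------

def read_otu_table(path, taxonomy_path=None, strict: bool = True) -> OtuTable:
    """Read a wide TSV: first column sample_id, remaining columns OTU ids."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path is not None else None
    if strict and df.isna().to_numpy().any():
        raise ValueError(f"{path}: OTU table contains NA values")
    return OtuTable(values=df.astype(float), scale="relative", taxonomy=taxonomy)


def read_taxonomy(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["otu_id", "taxonomy"]:
        raise ValueError(f"{path}: expected columns otu_id, taxonomy")
    return df.set_index("otu_id")["taxonomy"]


def read_brain_table(path, strict: bool = True) -> BrainFeatureTable:
    """Read long-form CSV with columns sample_id, roi, metric, value."""
    df = pd.read_csv(path, dtype={"sample_id": str, "roi": str, "metric": str})
    expected = ["sample_id", "roi", "metric", "value"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    if strict and df["value"].isna().any():
        raise ValueError(f"{path}: brain table contains NA values")
    bad = set(df["metric"]) - set(METRICS)
    if bad:
        raise ValueError(f"{path}: unknown diffusion metrics {sorted(bad)}")
    df = df.assign(feature=df["roi"] + BRAIN_FEATURE_SEP + df["metric"])
    wide = df.pivot(index="sample_id", columns="feature", values="value")
    if strict and wide.isna().to_numpy().any():
        raise ValueError(f"{path}: incomplete sample x feature grid")
    # preserve first-appearance feature order from the file
    order = df["feature"].drop_duplicates().tolist()
    return BrainFeatureTable(values=wide[order].astype(float), scale="raw")


def read_labels(path) -> DietLabels:
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != ["sample_id", "diet"]:
        raise ValueError(f"{path}: expected columns sample_id, diet")
    return DietLabels(labels=df.set_index("sample_id")["diet"])
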