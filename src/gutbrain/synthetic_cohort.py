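"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the study design the analysis was built for: a
balanced cohort (default 4 diets x 5 animals = 20 samples), an OTU
relative-abundance table in which a subset of *signal* OTUs shift their
mean log2 abundance between diets, and a brain feature table (ROI x
diffusion metric) in which *linked* features respond linearly to the
standardized abundance of a planted OTU on top of a diet-specific baseline
and Gaussian noise.  Ground truth (which OTUs are signal, which pairs are
linked) is returned alongside the tables so recovery can be measured.

Abundances are drawn as per-OTU log-normal intensities and closed to the
simplex; the diet shift for a signal OTU is applied symmetrically
(+effect/2 in its assigned diet, -effect/2 elsewhere, in units of the
within-diet sd on the log2 scale), so the between-diet contrast equals
``otu_effect_size * otu_within_sd`` and a zero-effect design makes signal
columns exchangeable with noise columns.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import BRAIN_FEATURE_SEP, METRICS, BrainFeatureTable, DietLabels, OtuTable

__all__ = ["CohortDesign", "GroundTruth", "Cohort", "generate_cohort", "write_cohort"]

_GENERA = (
    "Lactococcus", "Roseburia", "Barnesiella", "Prevotella", "Bacteroides",
    "Clostridium", "Ruminococcus", "Akkermansia", "Blautia", "Oscillospira",
)


@dataclass(frozen=True)
class CohortDesign:
    """Parameters of one synthetic cohort.

    Defaults follow the emulated study: 4 diet classes x 5 animals,
    100 OTUs of which 9 discriminate diet, diffusion features as ROI x
    {fa, rd, ad, tr}, and 9 planted OTU->brain links.  Effect sizes are in
    log2-abundance units relative to ``otu_within_sd``.
    """

    n_per_diet: int = 5
    diets: tuple = ("A", "B", "C", "D")
    n_otus: int = 100
    n_brain_features: int = 40
    n_signal_otus: int = 9
    otu_effect_size: float = 4.0
    otu_within_sd: float = 1.0
    n_linked_pairs: int = 9
    link_strength: float = 3.0
    noise_sd: float = 1.0
    brain_diet_sd: float = 0.5
    paired_sampling: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_per_diet", "n_otus", "n_brain_features", "n_signal_otus",
                     "n_linked_pairs"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        if len(self.diets) < 2 or len(set(self.diets)) != len(self.diets):
            raise ValueError("diets must be >= 2 distinct class labels")
        if self.n_signal_otus > self.n_otus:
            raise ValueError("n_signal_otus exceeds n_otus")
        if self.n_linked_pairs > self.n_signal_otus * self.n_brain_features:
            raise ValueError("n_linked_pairs exceeds n_signal_otus * n_brain_features")
        for name in ("otu_effect_size", "otu_within_sd", "link_strength",
                     "noise_sd", "brain_diet_sd"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.otu_within_sd == 0:
            raise ValueError("otu_within_sd must be > 0")

    @property
    def n_samples(self) -> int:
        return self.n_per_diet * len(self.diets)


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: signal OTUs, their assigned diets, linked pairs."""

    signal_otu_ids: tuple
    assigned_diet: dict  # signal otu_id -> diet with elevated abundance
    linked_pairs: tuple  # (otu_id, brain_feature_id, link_strength)
    per_diet_log2_means: dict  # signal otu_id -> {diet: mean log2 intensity}

    def to_dict(self) -> dict:
        return {
            "signal_otu_ids": list(self.signal_otu_ids),
            "assigned_diet": dict(self.assigned_diet),
            "linked_pairs": [list(p) for p in self.linked_pairs],
            "per_diet_log2_means": {
                k: dict(v) for k, v in self.per_diet_log2_means.items()
            },
        }


@dataclass(frozen=True)
class Cohort:
    """One generated cohort: the three analysis tables plus ground truth.

    ``otu_baseline`` holds the pre-diet (weaning) samples when the design
    requests paired sampling; its rows share sample ids with ``otu``.
    """

    otu: OtuTable
    brain: BrainFeatureTable
    labels: DietLabels
    truth: GroundTruth
    otu_baseline: OtuTable | None = None

    def otu_diff(self, pseudocount: float = 1e-6) -> OtuTable:
        """Post-minus-pre log2 abundance change table (paired designs only).

        Supports the reading of the analysis in which the OTU features are
        the log2 change between the two fecal samples rather than the
        post-diet abundances.
        """
        if self.otu_baseline is None:
            raise ValueError("cohort was generated without paired sampling")
        post = np.log2(self.otu.values.to_numpy() + pseudocount)
        pre = np.log2(self.otu_baseline.values.to_numpy() + pseudocount)
        return OtuTable(
            values=pd.DataFrame(
                post - pre, index=self.otu.values.index, columns=self.otu.values.columns
            ),
            scale="log2",
            taxonomy=self.otu.taxonomy,
        )


def _close_rows(log2_intensity: np.ndarray) -> np.ndarray:
    inten = np.exp2(log2_intensity)
    return inten / inten.sum(axis=1, keepdims=True)


def generate_cohort(design: CohortDesign) -> Cohort:
    """Draw one cohort. Identical designs (same seed) give identical tables."""
    ss = np.random.SeedSequence(design.seed)
    structure_rng, otu_rng, brain_rng, pre_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    n, p, q = design.n_samples, design.n_otus, design.n_brain_features
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    diet_of = np.repeat(np.arange(len(design.diets)), design.n_per_diet)
    otu_ids = [f"OTU{i + 1:03d}" for i in range(p)]
    rois = [f"roi{i // len(METRICS) + 1:02d}" for i in range(q)]
    feature_ids = [f"{rois[i]}{BRAIN_FEATURE_SEP}{METRICS[i % len(METRICS)]}" for i in range(q)]

    # planted structure
    signal_idx = np.sort(structure_rng.choice(p, size=design.n_signal_otus, replace=False))
    assigned = {
        int(i): d % len(design.diets) for d, i in enumerate(signal_idx)
    }  # round-robin diet assignment
    base_mean = structure_rng.normal(0.0, 2.0, size=p)
    # Each planted pair should carry the full marginal link_strength, so brain
    # features are used without replacement while capacity allows; only when
    # n_linked_pairs exceeds n_brain_features does a feature take several OTUs.
    otu_cycle = [int(signal_idx[k % design.n_signal_otus]) for k in range(design.n_linked_pairs)]
    feat_order = []
    while len(feat_order) < design.n_linked_pairs:
        feat_order.extend(structure_rng.permutation(q).tolist())
    linked = sorted(
        {(o, int(f)) for o, f in zip(otu_cycle, feat_order)}
    )
    while len(linked) < design.n_linked_pairs:  # collision repair for reuse case
        o = int(structure_rng.choice(signal_idx))
        f = int(structure_rng.integers(q))
        if (o, f) not in linked:
            linked.append((o, f))
    linked = sorted(linked)
    diet_baseline = structure_rng.normal(0.0, design.brain_diet_sd, size=(len(design.diets), q))

    # per-(diet, OTU) mean log2 intensities
    shift = design.otu_effect_size * design.otu_within_sd
    mu = np.tile(base_mean, (len(design.diets), 1))
    for i, d in assigned.items():
        mu[:, i] -= shift / 2.0
        mu[d, i] += shift

    z = otu_rng.normal(mu[diet_of, :], design.otu_within_sd)
    rel = _close_rows(z)
    otu_values = pd.DataFrame(rel, index=sample_ids, columns=otu_ids)

    taxonomy = pd.Series(
        [
            f"k__Bacteria;g__{_GENERA[i % len(_GENERA)]};s__sp{i + 1:03d}"
            for i in range(p)
        ],
        index=pd.Index(otu_ids, name="otu_id"),
        name="taxonomy",
    )

    # brain features: diet baseline + linear OTU linkage + noise
    log2_rel = np.log2(rel)
    brain = diet_baseline[diet_of, :].copy()
    for i, j in linked:
        x = log2_rel[:, i]
        xsd = x.std(ddof=1)
        xstd = (x - x.mean()) / xsd if xsd > 0 else np.zeros_like(x)
        brain[:, j] += design.link_strength * xstd
    brain += brain_rng.normal(0.0, design.noise_sd, size=(n, q))
    brain_values = pd.DataFrame(brain, index=sample_ids, columns=feature_ids)

    labels = DietLabels(
        labels=pd.Series(
            [design.diets[d] for d in diet_of], index=sample_ids, name="diet"
        ),
        classes=tuple(design.diets),
    )

    truth = GroundTruth(
        signal_otu_ids=tuple(otu_ids[i] for i in signal_idx),
        assigned_diet={otu_ids[i]: design.diets[d] for i, d in assigned.items()},
        linked_pairs=tuple(
            (otu_ids[i], feature_ids[j], float(design.link_strength)) for i, j in linked
        ),
        per_diet_log2_means={
            otu_ids[i]: {design.diets[d]: float(mu[d, i]) for d in range(len(design.diets))}
            for i in signal_idx
        },
    )

    baseline = None
    if design.paired_sampling:
        # weaning distribution: common means, no diet effect
        z0 = pre_rng.normal(np.tile(base_mean, (n, 1)), design.otu_within_sd)
        baseline = OtuTable(
            values=pd.DataFrame(_close_rows(z0), index=sample_ids, columns=otu_ids),
            scale="relative",
            taxonomy=taxonomy,
        )

    return Cohort(
        otu=OtuTable(values=otu_values, scale="relative", taxonomy=taxonomy),
        brain=BrainFeatureTable(values=brain_values, scale="raw"),
        labels=labels,
        truth=truth,
        otu_baseline=baseline,
    )


_FLOAT_FMT = "%.17g"  # lossless binary64 round-trip


def _check_taxonomy_writable(taxonomy: pd.Series) -> None:
    for otu, tax in taxonomy.items():
        if any(c in str(tax) for c in ("\t", "\n", "\r")):
            raise ValueError(
                f"taxonomy for {otu!r} contains a tab or newline, which the TSV "
                "dialect does not escape"
            )


def write_cohort(cohort: Cohort, directory) -> dict:
    """Write the cohort in the dialects `preprocess` reads back.

    Emits ``otu.tsv`` (wide TSV), ``brain.csv`` (long form
    sample_id,roi,metric,value), ``labels.csv``, ``truth.json`` and, when
    present, ``taxonomy.tsv`` and ``otu_baseline.tsv``. Returns the mapping
    of table name to file path. Same cohort -> byte-identical files.
    """
    if len(cohort.otu.sample_ids) == 0:
        raise ValueError("refusing to write a cohort with no samples")
    if set(cohort.otu.sample_ids) != set(cohort.brain.sample_ids) or set(
        cohort.otu.sample_ids
    ) != set(cohort.labels.sample_ids):
        raise ValueError("tables disagree on sample identifiers")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["otu"] = directory / "otu.tsv"
    cohort.otu.values.rename_axis("sample_id").to_csv(
        paths["otu"], sep="\t", float_format=_FLOAT_FMT
    )

    long = cohort.brain.values.rename_axis("sample_id").reset_index().melt(
        id_vars="sample_id", var_name="feature", value_name="value"
    )
    roi_metric = long["feature"].str.rsplit(BRAIN_FEATURE_SEP, n=1, expand=True)
    long = pd.DataFrame(
        {
            "sample_id": long["sample_id"],
            "roi": roi_metric[0],
            "metric": roi_metric[1],
            "value": long["value"],
        }
    ).sort_values(["sample_id", "roi", "metric"], kind="mergesort")
    paths["brain"] = directory / "brain.csv"
    long.to_csv(paths["brain"], index=False, float_format=_FLOAT_FMT)

    paths["labels"] = directory / "labels.csv"
    cohort.labels.labels.rename("diet").rename_axis("sample_id").to_csv(paths["labels"])

    paths["truth"] = directory / "truth.json"
    paths["truth"].write_text(json.dumps(cohort.truth.to_dict(), indent=1, sort_keys=True))

    if cohort.otu.taxonomy is not None:
        _check_taxonomy_writable(cohort.otu.taxonomy)
        paths["taxonomy"] = directory / "taxonomy.tsv"
        cohort.otu.taxonomy.rename("taxonomy").rename_axis("otu_id").to_csv(
            paths["taxonomy"], sep="\t"
        )
    if cohort.otu_baseline is not None:
        paths["otu_baseline"] = directory / "otu_baseline.tsv"
        cohort.otu_baseline.values.rename_axis("sample_id").to_csv(
            paths["otu_baseline"], sep="\t", float_format=_FLOAT_FMT
        )
    return paths


def null_design(design: CohortDesign) -> CohortDesign:
    """Same design with all planted effects removed (for null simulations)."""
    return dataclasses.replace(design, otu_effect_size=0.0, link_strength=0.0,
                               brain_diet_sd=0.0)
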