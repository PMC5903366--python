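"""Probabilistic label fusion and atlas-level operations.

A probabilistic label is the voxel-wise fraction of manual delineations
(observers x templates) that include the voxel: with three observers each
labeling eight validation templates, the fused probability at a voxel is
k/24 where k delineations contain it. Downstream this module also converts
a probabilistic atlas to deterministic (maximum-probability, strictly
P > threshold) labels and summarizes label uncertainty as the cumulative
relative frequency (CRF) of probabilities over non-zero voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volio import (
    AtlasForgeError,
    GeometryError,
    LabeledVolume,
    ValidationError,
    VoxelGrid,
)

logger = logging.getLogger("atlasforge")

#: the 16 subcortical regions of the CIT168 vocabulary, in canonical order
DEFAULT_VOCABULARY: tuple[tuple[str, str], ...] = (
    ("Pu", "Putamen"),
    ("Ca", "Caudate"),
    ("NAC", "Nucleus Accumbens"),
    ("EXA", "Extended Amygdala"),
    ("GPe", "Globus Pallidus (External)"),
    ("GPi", "Globus Pallidus (Internal)"),
    ("VeP", "Ventral Pallidum"),
    ("SNc", "Substantia Nigra (Compacta)"),
    ("SNr", "Substantia Nigra (Reticulata)"),
    ("PBP", "Parabrachial Pigmented Nucleus"),
    ("STH", "Subthalamic Nucleus"),
    ("VTA", "Ventral Tegmental Area"),
    ("HTH", "Hypothalamus"),
    ("RN", "Red Nucleus"),
    ("MN", "Mammillary Nucleus"),
    ("HN", "Habenular Nuclei"),
)


class EmptyLabelError(AtlasForgeError):
    """Operation undefined on an all-zero label."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ObserverLabelSet:
    """Per-(region, observer, template) binary labels on one common grid.

    Per (observer, template) the regions must be mutually exclusive: a voxel
    may belong to at most one region in any single manual delineation. That
    property is checked at construction and any violation is an error.
    """

    entries: dict[tuple[str, str, str], LabeledVolume]
    vocabulary: tuple[tuple[str, str], ...] = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("observer label set is empty")
        acronyms = {a for a, _ in self.vocabulary}
        grid = next(iter(self.entries.values())).grid
        for (region, obs, tpl), vol in self.entries.items():
            if region not in acronyms:
                raise ValidationError(f"region {region!r} not in vocabulary")
            if vol.kind != "binary":
                raise ValidationError(f"label ({region}, {obs}, {tpl}) is not binary")
            if not vol.grid.same_geometry(grid):
                raise GeometryError(
                    f"label ({region}, {obs}, {tpl}) is on a different grid"
                )
        for obs, tpl in {(o, t) for (_, o, t) in self.entries}:
            stack = [
                v.data for (r, o, t), v in self.entries.items()
                if (o, t) == (obs, tpl)
            ]
            overlap = np.sum(stack, axis=0) > 1
            if overlap.any():
                raise ValidationError(
                    f"observer {obs}, template {tpl}: {int(overlap.sum())} voxels "
                    "belong to more than one region"
                )

    @property
    def grid(self) -> VoxelGrid:
        return next(iter(self.entries.values())).grid

    @property
    def regions(self) -> list[str]:
        present = {r for (r, _, _) in self.entries}
        return [a for a, _ in self.vocabulary if a in present]

    @property
    def observers(self) -> list[str]:
        return sorted({o for (_, o, _) in self.entries})

    @property
    def templates(self) -> list[str]:
        return sorted({t for (_, _, t) in self.entries})

    def labels_for_region(self, region: str) -> dict[tuple[str, str], LabeledVolume]:
        return {
            (o, t): v for (r, o, t), v in self.entries.items() if r == region
        }

    def get(self, region: str, observer: str, template: str) -> LabeledVolume | None:
        return self.entries.get((region, observer, template))


@dataclass
class ProbAtlas:
    """One probabilistic label per region, plus fusion provenance."""

    labels: dict[str, LabeledVolume]
    vocabulary: tuple[tuple[str, str], ...] = DEFAULT_VOCABULARY
    provenance: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        acronyms = [a for a, _ in self.vocabulary]
        grid = next(iter(self.labels.values())).grid
        for region, vol in self.labels.items():
            if region not in acronyms:
                raise ValidationError(f"region {region!r} not in vocabulary")
            if vol.kind != "probability":
                raise ValidationError(f"label {region} is not a probability map")
            if not vol.grid.same_geometry(grid):
                raise GeometryError(f"label {region} is on a different grid")
        # keep canonical vocabulary order for deterministic downstream behaviour
        self.labels = {a: self.labels[a] for a in acronyms if a in self.labels}

    @property
    def grid(self) -> VoxelGrid:
        return next(iter(self.labels.values())).grid

    @property
    def regions(self) -> list[str]:
        return list(self.labels)

    def probability_sum(self) -> np.ndarray:
        return np.sum([v.data for v in self.labels.values()], axis=0)


def fuse_observer_set(label_set: ObserverLabelSet) -> ProbAtlas:
    """Fuse every region of an observer set by simple (unweighted) averaging.

    Because each single delineation is mutually exclusive across regions,
    the fused per-voxel probabilities sum to at most 1; that invariant is
    verified here (tolerance 1e-6).
    """
    labels = {}
    provenance = sorted({(o, t) for (_, o, t) in label_set.entries})
    for region in label_set.regions:
        vols = list(label_set.labels_for_region(region).values())
        labels[region] = build_prob_label(vols)
    atlas = ProbAtlas(labels, label_set.vocabulary, provenance)
    if float(atlas.probability_sum().max()) > 1.0 + 1e-6:
        raise ValidationError("fused probabilities sum to more than 1 at some voxel")
    return atlas


# ---------------------------------------------------------------------------
# Fusion and averaging
# ---------------------------------------------------------------------------

def build_prob_label(
    labels: list[LabeledVolume], weights: np.ndarray | None = None
) -> LabeledVolume:
    """Voxel-wise (weighted) mean of binary labels -> probabilistic label.

    With default equal weights the value at a voxel is exactly
    (number of labels containing it) / (number of labels).
    """
    if not labels:
        raise ValidationError("need at least one label to fuse")
    grid = labels[0].grid
    for lab in labels:
        if lab.kind != "binary":
            raise ValidationError("build_prob_label expects binary labels")
        if not lab.grid.same_geometry(grid):
            raise GeometryError("labels are on different grids")
    stack = np.stack([lab.data.astype(float) for lab in labels])
    if weights is None:
        prob = stack.mean(axis=0)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(labels),) or np.any(weights < 0) or weights.sum() == 0:
            raise ValidationError(
                "weights must be non-negative, one per label, not all zero"
            )
        prob = np.tensordot(weights / weights.sum(), stack, axes=1)
    return LabeledVolume(grid, prob, "probability")


def make_validation_split(
    n_total: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split 0..n_total-1 into two disjoint random halves (sample, complement).

    Deterministic given the seed; distinct seeds give the repeated-split
    design used for validation templates (e.g. 4 seeds -> 8 half-cohorts of
    84 from 168 subjects).
    """
    if n_total % 2 != 0:
        raise ValidationError("n_total must be even to split into equal halves")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_total)
    half = n_total // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


def average_volumes(vols: list[LabeledVolume]) -> LabeledVolume:
    """Voxel-wise arithmetic mean of intensity volumes (simple template averaging)."""
    if not vols:
        raise ValidationError("need at least one volume to average")
    grid = vols[0].grid
    for v in vols:
        if v.kind != "intensity":
            raise ValidationError("average_volumes expects intensity volumes")
        if not v.grid.same_geometry(grid):
            raise GeometryError("volumes are on different grids")
    mean = np.mean([v.data for v in vols], axis=0)
    return LabeledVolume(grid, mean, "intensity")


# ---------------------------------------------------------------------------
# Deterministic labels
# ---------------------------------------------------------------------------

def prob2det(atlas: ProbAtlas, threshold: float = 0.5) -> LabeledVolume:
    """Maximum-probability deterministic labels with strict P > threshold.

    Each voxel is assigned the region of maximal probability if that
    probability strictly exceeds ``threshold``, else background (0). Region
    ids are 1-based positions in the vocabulary order, which also breaks
    exact probability ties deterministically (ties are counted and logged).
    """
    if not 0.0 <= threshold < 1.0:
        raise ValidationError("threshold must lie in [0, 1)")
    regions = atlas.regions
    stack = np.stack([atlas.labels[r].data for r in regions])
    best = np.argmax(stack, axis=0)  # first maximum == vocabulary order
    pmax = np.take_along_axis(stack, best[None], axis=0)[0]
    n_ties = int(((stack == pmax).sum(axis=0) > 1)[pmax > threshold].sum())
    if n_ties:
        logger.info(
            "prob2det: %d voxels had tied maximal probabilities; "
            "broken by vocabulary order", n_ties,
        )
    vocab_ids = {r: i + 1 for i, (r, _) in enumerate(atlas.vocabulary)}
    ids = np.array([vocab_ids[r] for r in regions])
    out = np.where(pmax > threshold, ids[best], 0).astype(np.int32)
    return LabeledVolume(atlas.grid, out, "index")


def det_region_mask(det: LabeledVolume, atlas: ProbAtlas, region: str) -> LabeledVolume:
    """Binary mask of one region from a deterministic index map."""
    vocab_ids = {r: i + 1 for i, (r, _) in enumerate(atlas.vocabulary)}
    return LabeledVolume(
        det.grid, (det.data == vocab_ids[region]).astype(np.uint8), "binary"
    )


# ---------------------------------------------------------------------------
# Cumulative relative frequency of label probabilities
# ---------------------------------------------------------------------------

@dataclass
class CRFCurve:
    """CRF(t) = fraction of non-zero voxels with probability <= t."""

    thresholds: np.ndarray
    crf: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.crf = np.asarray(self.crf, dtype=float)
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValidationError("thresholds must be strictly ascending")
        if np.any(np.diff(self.crf) < 0):
            raise ValidationError("CRF must be non-decreasing")
        if abs(self.crf[-1] - 1.0) > 1e-12:
            raise ValidationError("CRF must end at 1")

    def __call__(self, t: float) -> float:
        i = np.searchsorted(self.thresholds, t)
        if i >= len(self.thresholds) or self.thresholds[i] != t:
            raise ValidationError(f"threshold {t} not on the curve")
        return float(self.crf[i])


def crf(prob: LabeledVolume, thresholds: int | np.ndarray = 100) -> CRFCurve:
    """Cumulative relative frequency of a probabilistic label.

    Only non-zero voxels enter the denominator; crf(t) = #{0 < p <= t} /
    #{p > 0}. An integer ``thresholds`` means that many evenly spaced values
    in (0, 1]; an explicit array must be ascending and reach the maximum
    observed probability so the curve ends at 1.
    """
    if prob.kind != "probability":
        raise ValidationError("crf expects a probability map")
    vals = prob.data[prob.data > 0]
    if vals.size == 0:
        raise EmptyLabelError("CRF is undefined for an all-zero label")
    if np.isscalar(thresholds):
        n = int(thresholds)
        ts = np.linspace(1.0 / n, 1.0, n)
    else:
        ts = np.asarray(thresholds, dtype=float)
        if ts.max() < vals.max():
            raise ValidationError(
                "thresholds must reach the maximum observed probability"
            )
    frac = np.searchsorted(np.sort(vals), ts, side="right") / vals.size
    return CRFCurve(ts, frac)


def crf_table(atlas: ProbAtlas, thresholds: int | np.ndarray = 100) -> pd.DataFrame:
    """Long-format CRF table (region, threshold, crf) over all atlas regions."""
    rows = []
    for region in atlas.regions:
        curve = crf(atlas.labels[region], thresholds)
        rows.append(
            pd.DataFrame(
                {"region": region, "threshold": curve.thresholds, "crf": curve.crf}
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Atlas directory I/O
# ---------------------------------------------------------------------------

def save_atlas(atlas: ProbAtlas, outdir: str | Path) -> Path:
    """Write one probability NIfTI per region plus a vocabulary TSV."""
    from .volio import write_volume

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for region, vol in atlas.labels.items():
        write_volume(vol, outdir / f"{region}.nii.gz")
    vocab = pd.DataFrame(atlas.vocabulary, columns=["acronym", "name"])
    vocab["present"] = vocab["acronym"].isin(atlas.regions)
    vocab.to_csv(outdir / "vocabulary.tsv", sep="\t", index=False)
    return outdir


def load_atlas(path: str | Path) -> ProbAtlas:
    """Load an atlas directory written by :func:`save_atlas`."""
    from .volio import read_volume

    path = Path(path)
    vocab_df = pd.read_csv(path / "vocabulary.tsv", sep="\t")
    vocabulary = tuple(zip(vocab_df["acronym"], vocab_df["name"]))
    present = vocab_df[vocab_df.get("present", True) == True]["acronym"]  # noqa: E712
    labels = {
        region: read_volume(path / f"{region}.nii.gz", expected_kind="probability")
        for region in present
    }
    return ProbAtlas(labels, vocabulary)


# ---------------------------------------------------------------------------
# Manifest I/O (region / observer / template / path)
# ---------------------------------------------------------------------------

def read_manifest(
    path: str | Path, vocabulary: tuple[tuple[str, str], ...] = DEFAULT_VOCABULARY
) -> ObserverLabelSet:
    """Load an observer label set from a TSV manifest.

    Columns: region, observer, template, path (paths relative to the
    manifest's directory).
    """
    from .volio import read_volume

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"region", "observer", "template", "path"}
    if not required.issubset(df.columns):
        raise ValidationError(f"manifest needs columns {sorted(required)}")
    entries = {}
    for row in df.itertuples(index=False):
        vol = read_volume(path.parent / row.path, expected_kind="binary")
        entries[(row.region, row.observer, row.template)] = vol
    return ObserverLabelSet(entries, vocabulary)
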