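"""Raw feature extraction over genomic intervals.

Two feature families:

* binned signal features — the interval is partitioned into consecutive
  ``bin_width``-bp windows (default 10 bp; a shorter remainder window is
  kept as its own bin), the per-base signal is summed within each bin, and
  the feature is the mean of the per-bin values;
* annotation overlap fractions — the fraction of the interval's bases
  covered by the union of an annotation interval set, each base counted
  once however many raw annotation intervals cover it.

SV length is deliberately *not* part of the raw vector: it is appended
unnormalized after Z-scoring (see :mod:`svpath.normalize`), so that
Z-normalization removes implicit length effects while length itself stays
available to the classifier as an explicit feature.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import GenomicIntervalSet, SignalTrack, SVRecord

__all__ = [
    "FeatureSpec",
    "FeatureConfig",
    "FeatureMatrix",
    "overlap_fraction",
    "binned_signal_feature",
    "extract_feature_vector",
    "build_feature_matrix",
    "DEFAULT_SIGNAL_FEATURES",
    "DEFAULT_ANNOTATION_FEATURES",
]

# Default 22-feature layout: 10 signal tracks + 12 annotation interval sets.
DEFAULT_SIGNAL_FEATURES = (
    "H3K27ac",
    "H3K4me1",
    "H3K4me3",
    "H3K36me3",
    "H3K27me3",
    "GC_content",
    "rep_timing",
    "CTCF",
    "WGBS",
    "PhyloP",
)
DEFAULT_ANNOTATION_FEATURES = (
    "coding",
    "utr5",
    "utr3",
    "splice_site",
    "promoter",
    "tad_boundary",
    "heterochromatin",
    "fragile_site",
    "sine",
    "ultraconserved",
    "sensitive",
    "cancer_gene",
)


@dataclass(frozen=True)
class FeatureSpec:
    """One named feature: a signal track or an annotation set.

    ``missing_for`` lists cohort labels (0 and/or 1) for which the
    underlying dataset is unavailable; cells of those cohorts are flagged
    missing rather than computed, and Z-normalization imputes them to 0.
    """

    name: str
    kind: str  # "signal" | "annotation"
    source: object
    missing_for: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("signal", "annotation"):
            raise ValueError(f"feature {self.name}: kind must be signal|annotation")
        if self.kind == "signal" and not isinstance(self.source, SignalTrack):
            raise TypeError(f"feature {self.name}: signal source must be a SignalTrack")
        if self.kind == "annotation" and not isinstance(self.source, GenomicIntervalSet):
            raise TypeError(
                f"feature {self.name}: annotation source must be a GenomicIntervalSet"
            )


@dataclass
class FeatureConfig:
    """Ordered feature layout shared by disease and control cohorts."""

    features: list[FeatureSpec]
    bin_width: int = 10
    bin_agg: str = "sum"  # per-bin total (default) or per-bin mean
    include_length: bool = True

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if "length" in names:
            raise ValueError("'length' is reserved for the appended length feature")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if self.bin_agg not in ("sum", "mean"):
            raise ValueError("bin_agg must be 'sum' or 'mean'")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def subset(self, drop: Iterable[str]) -> "FeatureConfig":
        """A copy without the named features (truncated-model experiments)."""
        drop = set(drop)
        return FeatureConfig(
            features=[f for f in self.features if f.name not in drop],
            bin_width=self.bin_width,
            bin_agg=self.bin_agg,
            include_length=self.include_length,
        )

    @classmethod
    def from_sources(
        cls,
        tracks: Mapping[str, SignalTrack],
        annotations: Mapping[str, GenomicIntervalSet],
        missing_for: Mapping[str, Iterable[int]] | None = None,
        **kwargs,
    ) -> "FeatureConfig":
        missing_for = missing_for or {}
        feats = [
            FeatureSpec(n, "signal", t, frozenset(missing_for.get(n, ())))
            for n, t in tracks.items()
        ] + [
            FeatureSpec(n, "annotation", a, frozenset(missing_for.get(n, ())))
            for n, a in annotations.items()
        ]
        return cls(features=feats, **kwargs)


# ---------------------------------------------------------------------------
# Interval-level primitives
# ---------------------------------------------------------------------------

def overlap_fraction(
    chrom: str, start: int, end: int, annotation: GenomicIntervalSet
) -> float:
    """Fraction of ``[start, end)`` bases covered by the annotation union.

    A chromosome absent from the annotation set simply yields 0.0.
    """
    if end <= start:
        raise ValueError("overlap_fraction requires end > start")
    covered = int(annotation.overlap_bases(chrom, start, end))
    return covered / (end - start)


def _bin_edges(length: int, bin_width: int) -> np.ndarray:
    edges = np.arange(0, length, bin_width, dtype=np.int64)
    return np.append(edges, length)


def _binned_batch(
    track: SignalTrack,
    chrom: str,
    starts: np.ndarray,
    length: int,
    bin_width: int,
    bin_agg: str,
) -> np.ndarray:
    """Binned feature for many same-length intervals at once (one prefix pass)."""
    rel = _bin_edges(length, bin_width)
    edges = np.asarray(starts, dtype=np.int64)[:, None] + rel[None, :]
    pref = track.prefix(chrom, edges.ravel()).reshape(edges.shape)
    sums = np.diff(pref, axis=1)
    if bin_agg == "mean":
        sums = sums / np.diff(rel)[None, :]
    return sums.mean(axis=1)


def binned_signal_feature(
    chrom: str,
    start: int,
    end: int,
    track: SignalTrack,
    bin_width: int = 10,
    bin_agg: str = "sum",
) -> float:
    """Mean of per-bin signal totals over ``[start, end)``.

    The interval is split into ``ceil((end-start)/bin_width)`` consecutive
    bins (the last possibly shorter); each bin contributes the sum of its
    per-base values (or, with ``bin_agg="mean"``, its per-base mean), and
    the feature is the arithmetic mean over bins.
    """
    if end <= start:
        raise ValueError("binned_signal_feature requires end > start")
    return float(
        _binned_batch(track, chrom, np.array([start]), end - start, bin_width, bin_agg)[0]
    )


def _overlap_batch(
    annotation: GenomicIntervalSet, chrom: str, starts: np.ndarray, length: int
) -> np.ndarray:
    starts = np.asarray(starts, dtype=np.int64)
    return annotation.overlap_bases(chrom, starts, starts + length) / float(length)


def _feature_batch(
    spec: FeatureSpec, config: FeatureConfig, chrom: str, starts: np.ndarray, length: int
) -> np.ndarray:
    if spec.kind == "signal":
        return _binned_batch(
            spec.source, chrom, starts, length, config.bin_width, config.bin_agg
        )
    return _overlap_batch(spec.source, chrom, starts, length)


# ---------------------------------------------------------------------------
# Per-SV vectors and the feature matrix
# ---------------------------------------------------------------------------

def extract_feature_vector(
    sv: SVRecord, config: FeatureConfig
) -> tuple[pd.Series, pd.Series]:
    """Raw feature values (and missing flags) for one SV, in config order.

    Features whose dataset is marked absent for the SV's cohort are flagged
    missing and carry NaN. The length feature is not included here.
    """
    values = np.empty(len(config.features))
    missing = np.zeros(len(config.features), dtype=bool)
    starts = np.array([sv.start])
    for j, spec in enumerate(config.features):
        if sv.label in spec.missing_for:
            values[j] = np.nan
            missing[j] = True
            continue
        try:
            values[j] = _feature_batch(spec, config, sv.chrom, starts, sv.length)[0]
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"feature {spec.name} failed on SV {sv.id}") from exc
    names = config.names
    return pd.Series(values, index=names), pd.Series(missing, index=names)


class FeatureMatrix:
    """Rows = SVs, columns = named features, plus labels and missing flags."""

    def __init__(
        self,
        values: pd.DataFrame,
        labels: pd.Series,
        missing: pd.DataFrame | None = None,
        state: str = "raw",
    ):
        if state not in ("raw", "z_normalized"):
            raise ValueError("state must be 'raw' or 'z_normalized'")
        if not values.index.is_unique:
            raise ValueError("row ids must be unique")
        if missing is None:
            missing = pd.DataFrame(
                False, index=values.index, columns=values.columns
            )
        if not values.index.equals(labels.index) or not values.index.equals(missing.index):
            raise ValueError("values/labels/missing row ids must align")
        if list(values.columns) != list(missing.columns):
            raise ValueError("values/missing columns must align")
        if state == "z_normalized" and values.isna().any().any():
            raise ValueError("z_normalized matrix may not contain NaN cells")
        self.values = values
        self.labels = labels.astype(int)
        self.missing = missing.astype(bool)
        self.state = state

    # sklearn-friendly views -------------------------------------------------
    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=np.int64)

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(), self.labels.copy(), self.missing.copy(), self.state
        )

    def subset_rows(self, ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.loc[ids],
            self.labels.loc[ids],
            self.missing.loc[ids],
            self.state,
        )

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "label", self.labels)
        out.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path, state: str) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        labels = df.pop("label")
        return cls(df, labels, state=state)


def build_feature_matrix(
    svs: Sequence[SVRecord], config: FeatureConfig
) -> FeatureMatrix:
    """Raw feature matrix for a cohort; row order follows input order."""
    ids = [sv.id for sv in svs]
    if len(set(ids)) != len(ids) or "" in ids:
        raise ValueError("SVs must carry unique non-empty ids")
    vals = np.empty((len(svs), len(config.features)))
    miss = np.zeros_like(vals, dtype=bool)
    for i, sv in enumerate(svs):
        starts = np.array([sv.start])
        for j, spec in enumerate(config.features):
            if sv.label in spec.missing_for:
                vals[i, j] = np.nan
                miss[i, j] = True
            else:
                try:
                    vals[i, j] = _feature_batch(
                        spec, config, sv.chrom, starts, sv.length
                    )[0]
                except Exception as exc:  # noqa: BLE001
                    raise RuntimeError(
                        f"feature {spec.name} failed on SV {sv.id}"
                    ) from exc
    names = config.names
    values = pd.DataFrame(vals, index=ids, columns=names)
    missing = pd.DataFrame(miss, index=ids, columns=names)
    labels = pd.Series([sv.label for sv in svs], index=ids)
    return FeatureMatrix(values, labels, missing, state="raw")
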