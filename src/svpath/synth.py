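"""Synthetic genomes, tracks, annotations, and SV cohorts for testing.

The generator emits a small multi-chromosome genome with run-length signal
tracks (Gaussian segment values, truncated at 0), random annotation
interval sets, and disease/control SV cohorts with configurable length
distributions. Planted structure is recoverable by construction:

* ``planted_signal_shift`` adds a fixed elevation (in units of the segment
  noise sd) to designated tracks under every disease-SV footprint;
* ``planted_annotation_bias`` makes designated annotation sets overlap
  disease SVs with elevated probability.

SV placement itself is always uniform per chromosome, so the shuffle null
used for Z-normalization matches the placement process exactly and planted
effects are the only disease/control differences beyond the chosen length
distributions.
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import (
    DEFAULT_ANNOTATION_FEATURES,
    DEFAULT_SIGNAL_FEATURES,
    FeatureConfig,
)
from .genomic_io import ChromSizes, GenomicIntervalSet, SignalTrack, SVRecord, read_sv_bed

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "write_fixture", "read_fixture", "worked_example_fixture"]

DEFAULT_CHROM_SIZES = {"chr1": 2_000_000, "chr2": 1_500_000, "chr3": 1_000_000}
DEFAULT_PLANTED_TRACKS = ("H3K27ac", "H3K4me3", "CTCF", "WGBS", "PhyloP")
DEFAULT_PLANTED_ANNOTATIONS = ("tad_boundary", "ultraconserved")


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic cohort pair.

    Lengths are drawn log-uniformly from the given (lo, hi) ranges in bp;
    the minimum of 51 bp keeps every SV past the >50 bp cohort filter.
    """

    chrom_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    n_disease: int = 500
    n_control: int = 500
    length_range_disease: tuple[int, int] = (100, 5000)
    length_range_control: tuple[int, int] = (100, 5000)
    planted_signal_shift: float = 0.0
    planted_tracks: tuple[str, ...] = DEFAULT_PLANTED_TRACKS
    planted_annotation_bias: float = 0.0
    planted_annotations: tuple[str, ...] = DEFAULT_PLANTED_ANNOTATIONS
    sv_type: str = "DEL"
    segment_bp: int = 200
    signal_sd: float = 0.5
    signal_mean_range: tuple[float, float] = (1.5, 3.0)
    annotation_spacing: int = 25_000
    annotation_length_range: tuple[int, int] = (500, 3000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_disease < 20 or self.n_control < 20:
            raise ValueError("cohort sizes must be >= 20")
        for rng_ in (self.length_range_disease, self.length_range_control):
            if rng_[0] < 51 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid length range {rng_} (min 51 bp)")
            if rng_[1] > min(self.chrom_sizes.values()):
                raise ValueError("SV length range exceeds the shortest chromosome")
        if self.planted_signal_shift < 0 or self.planted_annotation_bias < 0:
            raise ValueError("planted effects must be >= 0")
        unknown = set(self.planted_tracks) - set(DEFAULT_SIGNAL_FEATURES)
        unknown |= set(self.planted_annotations) - set(DEFAULT_ANNOTATION_FEATURES)
        if unknown:
            raise ValueError(f"unknown planted feature names: {sorted(unknown)}")


@dataclass
class Fixture:
    spec: FixtureSpec
    chrom_sizes: ChromSizes
    disease: list[SVRecord]
    control: list[SVRecord]
    tracks: dict[str, SignalTrack]
    annotations: dict[str, GenomicIntervalSet]

    def feature_config(
        self,
        include_length: bool = True,
        bin_width: int = 10,
        missing_for: Mapping | None = None,
    ) -> FeatureConfig:
        """The default 22-feature layout over this fixture's datasets."""
        return FeatureConfig.from_sources(
            self.tracks,
            self.annotations,
            missing_for=missing_for,
            bin_width=bin_width,
            include_length=include_length,
        )


def _draw_svs(rng, spec, n, length_range, label, prefix) -> list[SVRecord]:
    chroms = list(spec.chrom_sizes)
    sizes = np.array([spec.chrom_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    out = []
    for i in range(n):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        L = spec.chrom_sizes[chrom]
        length = int(round(np.exp(rng.uniform(np.log(length_range[0]), np.log(length_range[1])))))
        length = int(np.clip(length, 51, L))
        start = int(rng.integers(0, L - length + 1))
        out.append(
            SVRecord(chrom, start, start + length, spec.sv_type, label, id=f"{prefix}{i:05d}")
        )
    return out


def _overlay(bounds, values, intervals, delta):
    """Add ``delta`` per covering interval to a run-length (bounds, values)."""
    if not len(intervals):
        return bounds, values
    iv = np.asarray(intervals, dtype=np.int64)
    pts = np.unique(np.concatenate([bounds, iv.ravel()]))
    base_idx = np.searchsorted(bounds, pts[:-1], side="right") - 1
    new_vals = values[np.clip(base_idx, 0, len(values) - 1)].copy()
    events = np.zeros(len(pts), dtype=np.int64)
    np.add.at(events, np.searchsorted(pts, iv[:, 0]), 1)
    np.add.at(events, np.searchsorted(pts, iv[:, 1]), -1)
    depth = np.cumsum(events)[:-1]
    return pts, new_vals + delta * depth


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Deterministically generate one fixture from its spec (seed included)."""
    rng = np.random.default_rng(spec.seed)
    chrom_sizes = ChromSizes(spec.chrom_sizes)

    disease = _draw_svs(rng, spec, spec.n_disease, spec.length_range_disease, 1, "d")
    control = _draw_svs(rng, spec, spec.n_control, spec.length_range_control, 0, "c")
    disease_by_chrom: dict[str, list] = {}
    for sv in disease:
        disease_by_chrom.setdefault(sv.chrom, []).append((sv.start, sv.end))

    tracks: dict[str, SignalTrack] = {}
    for name in DEFAULT_SIGNAL_FEATURES:
        mean = rng.uniform(*spec.signal_mean_range)
        segs = {}
        for chrom, L in spec.chrom_sizes.items():
            n_seg = int(np.ceil(L / spec.segment_bp))
            bounds = np.minimum(np.arange(n_seg + 1, dtype=np.int64) * spec.segment_bp, L)
            vals = np.clip(rng.normal(mean, spec.signal_sd, size=n_seg), 0.0, None)
            if spec.planted_signal_shift > 0 and name in spec.planted_tracks:
                bounds, vals = _overlay(
                    bounds,
                    vals,
                    disease_by_chrom.get(chrom, []),
                    spec.planted_signal_shift * spec.signal_sd,
                )
            segs[chrom] = (bounds, vals)
        tracks[name] = SignalTrack(name, segs)

    annotations: dict[str, GenomicIntervalSet] = {}
    for name in DEFAULT_ANNOTATION_FEATURES:
        rows = []
        for chrom, L in spec.chrom_sizes.items():
            n_iv = max(1, L // spec.annotation_spacing)
            lens = rng.integers(*spec.annotation_length_range, size=n_iv, endpoint=True)
            starts = rng.integers(0, L - lens + 1)
            rows.extend((chrom, int(s), int(s + l)) for s, l in zip(starts, lens))
        if spec.planted_annotation_bias > 0 and name in spec.planted_annotations:
            for sv in disease:
                if rng.random() < spec.planted_annotation_bias:
                    # cover a random half of the SV footprint
                    half = max(1, sv.length // 2)
                    s = int(rng.integers(sv.start, sv.end - half + 1))
                    rows.append((sv.chrom, s, s + half))
        annotations[name] = GenomicIntervalSet(rows)

    return Fixture(spec, chrom_sizes, disease, control, tracks, annotations)


def write_fixture(fixture: Fixture, outdir) -> dict:
    """Write BED/bedGraph/chrom.sizes files plus a manifest; returns the manifest."""
    outdir = Path(outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    (outdir / "annotations").mkdir(parents=True, exist_ok=True)
    fixture.chrom_sizes.to_file(outdir / "chrom.sizes")
    for fname, svs in (("disease.bed", fixture.disease), ("control.bed", fixture.control)):
        with open(outdir / fname, "w") as fh:
            for sv in svs:
                fh.write(f"{sv.chrom}\t{sv.start}\t{sv.end}\t{sv.sv_type}\n")
    track_files, annot_files = {}, {}
    for name, track in fixture.tracks.items():
        path = outdir / "tracks" / f"{name}.bedGraph"
        track.to_bedgraph(path)
        track_files[name] = str(path.relative_to(outdir))
    for name, annot in fixture.annotations.items():
        path = outdir / "annotations" / f"{name}.bed"
        annot.to_bed(path, merged=True)
        annot_files[name] = str(path.relative_to(outdir))
    manifest = {
        "chrom_sizes": "chrom.sizes",
        "disease": "disease.bed",
        "control": "control.bed",
        "tracks": track_files,
        "annotations": annot_files,
        "seed": fixture.spec.seed,
        "n_disease": fixture.spec.n_disease,
        "n_control": fixture.spec.n_control,
        "planted_signal_shift": fixture.spec.planted_signal_shift,
        "planted_tracks": list(fixture.spec.planted_tracks),
        "planted_annotation_bias": fixture.spec.planted_annotation_bias,
        "planted_annotations": list(fixture.spec.planted_annotations),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def read_fixture(outdir) -> tuple[list[SVRecord], list[SVRecord], dict, dict, ChromSizes]:
    """Read a written fixture back through the standard readers."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    chrom_sizes = ChromSizes.from_file(outdir / manifest["chrom_sizes"])
    disease = read_sv_bed(outdir / manifest["disease"], label=1, id_prefix="d")
    control = read_sv_bed(outdir / manifest["control"], label=0, id_prefix="c")
    tracks = {
        name: SignalTrack.from_bedgraph(outdir / rel, chrom_sizes, name=name)
        for name, rel in manifest["tracks"].items()
    }
    annotations = {
        name: GenomicIntervalSet.from_bed(outdir / rel, chrom_sizes)
        for name, rel in manifest["annotations"].items()
    }
    return disease, control, tracks, annotations, chrom_sizes


def worked_example_fixture() -> tuple[SVRecord, GenomicIntervalSet]:
    """A 10,000 bp variant with exactly 5,000 bases inside TAD intervals.

    The TAD set covers the variant's first half (plus an unrelated distal
    interval), so the overlap-fraction feature must equal exactly 0.5.
    """
    sv = SVRecord("chr1", 100_000, 110_000, "DEL", 1, id="worked_example")
    tads = GenomicIntervalSet(
        [("chr1", 95_000, 105_000), ("chr1", 400_000, 450_000)]
    )
    return sv, tads
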