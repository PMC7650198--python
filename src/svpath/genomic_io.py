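"""Core genomic data types and flat-file I/O.

All coordinates inside the package are 0-based half-open ``[start, end)``
(BED convention). VCF input (1-based inclusive POS) is converted at the
boundary and never leaks through.

The two queryable containers defined here back every downstream feature:

``GenomicIntervalSet``
    a per-chromosome union of intervals with O(log k) per-base overlap
    counting against arbitrary query windows, built on prefix sums of the
    merged intervals.

``SignalTrack``
    a per-chromosome piecewise-constant (run-length) real-valued function of
    genomic position, with a vectorized prefix-sum query ``prefix(x)`` =
    integral of the signal over ``[0, x)``. Bases with no reported signal
    have value 0, so queries are total functions over the chromosome.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SV_TYPES = ("DEL", "DUP")

__all__ = [
    "SV_TYPES",
    "ParseError",
    "SVRecord",
    "ChromSizes",
    "GenomicIntervalSet",
    "SignalTrack",
    "read_sv_bed",
    "read_sv_vcf",
    "filter_svs",
    "write_score_table",
    "read_score_table",
]


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


@dataclass(frozen=True)
class SVRecord:
    """One structural-variant interval.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open coordinates; ``end > start``.
    sv_type : str
        ``"DEL"`` or ``"DUP"``.
    label : int
        1 for disease-cohort variants, 0 for benign/control variants.
    allele_freq : float, optional
        Population allele frequency in [0, 1], when known.
    id : str
        Opaque unique identifier; assigned by the readers.
    """

    chrom: str
    start: int
    end: int
    sv_type: str
    label: int
    allele_freq: float | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"SV {self.id or self.chrom}: end ({self.end}) must exceed "
                f"start ({self.start})"
            )
        if self.start < 0:
            raise ValueError(f"SV {self.id}: negative start {self.start}")
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"SV {self.id}: sv_type must be one of {SV_TYPES}")
        if self.label not in (0, 1):
            raise ValueError(f"SV {self.id}: label must be 0 or 1")
        if self.allele_freq is not None and not 0.0 <= self.allele_freq <= 1.0:
            raise ValueError(f"SV {self.id}: allele_freq outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class ChromSizes(Mapping):
    """Mapping chromosome name -> length in bp; all lengths positive."""

    def __init__(self, sizes: Mapping[str, int]):
        clean = {}
        for chrom, size in sizes.items():
            size = int(size)
            if size <= 0:
                raise ValueError(f"chromosome {chrom}: non-positive length {size}")
            clean[str(chrom)] = size
        self._sizes = clean

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __repr__(self) -> str:
        return f"ChromSizes({self._sizes!r})"

    def check_svs(self, svs: Iterable[SVRecord]) -> None:
        """Raise if any SV falls on an unknown chromosome or beyond its end."""
        for sv in svs:
            if sv.chrom not in self._sizes:
                raise ValueError(f"SV {sv.id}: unknown chromosome {sv.chrom}")
            if sv.end > self._sizes[sv.chrom]:
                raise ValueError(
                    f"SV {sv.id}: end {sv.end} exceeds {sv.chrom} length "
                    f"{self._sizes[sv.chrom]}"
                )

    @classmethod
    def from_file(cls, path) -> "ChromSizes":
        sizes = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ParseError(f"{path} line {lineno}: expected 'chrom\\tsize'")
                try:
                    sizes[fields[0]] = int(fields[1])
                except ValueError as exc:
                    raise ParseError(f"{path} line {lineno}: non-integer size") from exc
        return cls(sizes)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, size in self._sizes.items():
                fh.write(f"{chrom}\t{size}\n")


class GenomicIntervalSet:
    """Per-chromosome union of half-open intervals with fast overlap counts.

    Overlapping input intervals are merged ("collapsed") at construction, so
    each covered base counts once regardless of how many raw intervals cover
    it. The raw (unmerged, optionally named) records are retained for
    gene-level queries.
    """

    def __init__(self, intervals: Iterable[tuple], names: Iterable[str] | None = None):
        rows = []
        names = list(names) if names is not None else None
        for i, item in enumerate(intervals):
            if len(item) == 4:
                chrom, start, end, name = item
            else:
                chrom, start, end = item
                name = names[i] if names is not None else ""
            start, end = int(start), int(end)
            if end <= start or start < 0:
                raise ValueError(f"interval {chrom}:{start}-{end} is not half-open")
            rows.append((str(chrom), start, end, str(name)))
        self._records = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        self._merged: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in self._records.groupby("chrom", sort=True):
            starts = grp["start"].to_numpy(np.int64)
            ends = grp["end"].to_numpy(np.int64)
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            cummax = np.maximum.accumulate(ends)
            new_block = np.ones(len(starts), dtype=bool)
            new_block[1:] = starts[1:] > cummax[:-1]
            mstarts = starts[new_block]
            block_id = np.cumsum(new_block) - 1
            mends = np.zeros(len(mstarts), dtype=np.int64)
            np.maximum.at(mends, block_id, ends)
            cum = np.concatenate(([0], np.cumsum(mends - mstarts)))
            self._merged[chrom] = (mstarts, mends, cum)

    # -- introspection -----------------------------------------------------
    @property
    def records(self) -> pd.DataFrame:
        """Raw (unmerged) intervals as a DataFrame copy."""
        return self._records.copy()

    @property
    def chroms(self) -> list[str]:
        return sorted(self._merged)

    def __len__(self) -> int:
        return len(self._records)

    def merged_intervals(self, chrom: str) -> np.ndarray:
        """Merged ``(k, 2)`` start/end array for one chromosome."""
        if chrom not in self._merged:
            return np.empty((0, 2), dtype=np.int64)
        s, e, _ = self._merged[chrom]
        return np.column_stack([s, e])

    def total_covered(self, chrom: str) -> int:
        if chrom not in self._merged:
            return 0
        return int(self._merged[chrom][2][-1])

    # -- queries -----------------------------------------------------------
    def covered_before(self, chrom: str, pos) -> np.ndarray:
        """Number of covered bases in ``[0, pos)``; vectorized over ``pos``."""
        pos = np.asarray(pos, dtype=np.int64)
        if chrom not in self._merged:
            return np.zeros(pos.shape, dtype=np.int64)
        starts, ends, cum = self._merged[chrom]
        i = np.searchsorted(starts, pos, side="right")
        base = cum[i]
        prev_end = np.where(i > 0, ends[np.maximum(i - 1, 0)], 0)
        overshoot = np.clip(prev_end - pos, 0, None)
        overshoot = np.where(i > 0, overshoot, 0)
        return base - overshoot

    def overlap_bases(self, chrom: str, start, end) -> np.ndarray:
        """Covered bases of ``[start, end)``; vectorized over start/end."""
        return self.covered_before(chrom, end) - self.covered_before(chrom, start)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_bed(cls, path, chrom_sizes: ChromSizes | None = None) -> "GenomicIntervalSet":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 3:
                    raise ParseError(f"{path} line {lineno}: fewer than 3 BED fields")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path} line {lineno}: non-integer coordinates"
                    ) from exc
                if end <= start:
                    raise ParseError(f"{path} line {lineno}: end <= start")
                name = fields[3] if len(fields) > 3 else ""
                if chrom_sizes is not None:
                    if fields[0] not in chrom_sizes:
                        raise ParseError(
                            f"{path} line {lineno}: unknown chromosome {fields[0]}"
                        )
                    if end > chrom_sizes[fields[0]]:
                        raise ParseError(
                            f"{path} line {lineno}: interval beyond chromosome end"
                        )
                rows.append((fields[0], start, end, name))
        return cls(rows)

    def to_bed(self, path, merged: bool = False) -> None:
        with open(path, "w") as fh:
            if merged:
                for chrom in self.chroms:
                    for s, e in self.merged_intervals(chrom):
                        fh.write(f"{chrom}\t{s}\t{e}\n")
            else:
                for row in self._records.itertuples(index=False):
                    name = f"\t{row.name}" if row.name else ""
                    fh.write(f"{row.chrom}\t{row.start}\t{row.end}{name}\n")


class SignalTrack:
    """Run-length encoded per-base signal over a genome.

    Each chromosome is stored as segment boundaries ``[0, b1, ..., L]`` and
    one value per segment; ``prefix(chrom, x)`` returns the integral of the
    per-base signal over ``[0, x)`` so that any window sum is a difference of
    two prefix evaluations.
    """

    def __init__(self, name: str, segments: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        self.name = name
        self._bounds: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, (bounds, values) in segments.items():
            bounds = np.asarray(bounds, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if bounds.ndim != 1 or values.ndim != 1 or len(bounds) != len(values) + 1:
                raise ValueError(f"{name}/{chrom}: need k+1 bounds for k values")
            if bounds[0] != 0:
                raise ValueError(f"{name}/{chrom}: bounds must start at 0")
            if np.any(np.diff(bounds) <= 0):
                raise ValueError(f"{name}/{chrom}: bounds must be strictly increasing")
            self._bounds[chrom] = bounds
            self._values[chrom] = values
            widths = np.diff(bounds).astype(np.float64)
            self._cum[chrom] = np.concatenate(([0.0], np.cumsum(values * widths)))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._bounds)

    def chrom_length(self, chrom: str) -> int:
        return int(self._bounds[chrom][-1])

    def segments(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._bounds[chrom].copy(), self._values[chrom].copy()

    def _check_range(self, chrom: str, lo, hi) -> None:
        if chrom not in self._bounds:
            raise KeyError(f"track {self.name}: unknown chromosome {chrom}")
        L = self._bounds[chrom][-1]
        if np.any(np.asarray(lo) < 0) or np.any(np.asarray(hi) > L):
            raise ValueError(f"track {self.name}: query outside [0, {L}] on {chrom}")

    def prefix(self, chrom: str, pos) -> np.ndarray:
        """Integral of the signal over ``[0, pos)``; vectorized over ``pos``."""
        pos_arr = np.asarray(pos, dtype=np.int64)
        self._check_range(chrom, pos_arr, pos_arr)
        bounds = self._bounds[chrom]
        values = self._values[chrom]
        idx = np.searchsorted(bounds, pos_arr, side="right") - 1
        idx = np.clip(idx, 0, len(values) - 1)
        return self._cum[chrom][idx] + values[idx] * (pos_arr - bounds[idx])

    def range_sum(self, chrom: str, start, end) -> np.ndarray:
        """Sum of per-base values over ``[start, end)``."""
        return self.prefix(chrom, end) - self.prefix(chrom, start)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base values over ``[start, end)`` (exactly end-start)."""
        start, end = int(start), int(end)
        if end <= start:
            raise ValueError("values() requires end > start")
        self._check_range(chrom, start, end)
        bounds = self._bounds[chrom]
        values = self._values[chrom]
        i0 = np.searchsorted(bounds, start, side="right") - 1
        i1 = np.searchsorted(bounds, end, side="left")
        seg_bounds = bounds[i0 : i1 + 1].copy()
        seg_bounds[0] = start
        seg_bounds[-1] = end
        lengths = np.diff(seg_bounds)
        return np.repeat(values[i0:i1], lengths)

    @classmethod
    def constant(cls, value: float, chrom_sizes: ChromSizes, name: str = "constant"):
        segs = {
            c: (np.array([0, L]), np.array([float(value)])) for c, L in chrom_sizes.items()
        }
        return cls(name, segs)

    @classmethod
    def from_bedgraph(cls, path, chrom_sizes: ChromSizes, name: str | None = None):
        """Read a bedGraph file; unreported bases get value 0.

        Intervals must be sorted and non-overlapping within each chromosome
        (the format bedtools and UCSC tools emit).
        """
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 4:
                    raise ParseError(f"{path} line {lineno}: need 4 bedGraph fields")
                chrom = fields[0]
                try:
                    start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
                except ValueError as exc:
                    raise ParseError(f"{path} line {lineno}: malformed fields") from exc
                if end <= start:
                    raise ParseError(f"{path} line {lineno}: end <= start")
                if chrom not in chrom_sizes:
                    raise ParseError(f"{path} line {lineno}: unknown chromosome {chrom}")
                if end > chrom_sizes[chrom]:
                    raise ParseError(f"{path} line {lineno}: beyond chromosome end")
                per_chrom.setdefault(chrom, []).append((start, end, value))
        segments = {}
        for chrom, L in chrom_sizes.items():
            entries = sorted(per_chrom.get(chrom, []))
            bounds = [0]
            values = []
            cursor = 0
            for start, end, value in entries:
                if start < cursor:
                    raise ParseError(f"{path}: overlapping bedGraph intervals on {chrom}")
                if start > cursor:
                    bounds.append(start)
                    values.append(0.0)
                bounds.append(end)
                values.append(value)
                cursor = end
            if cursor < L:
                bounds.append(L)
                values.append(0.0)
            segments[chrom] = (np.array(bounds), np.array(values))
        return cls(name or str(path), segments)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                bounds = self._bounds[chrom]
                values = self._values[chrom]
                for i, v in enumerate(values):
                    if v != 0.0:
                        fh.write(f"{chrom}\t{bounds[i]}\t{bounds[i + 1]}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# SV readers / writers
# ---------------------------------------------------------------------------

def read_sv_bed(
    path,
    label: int,
    sv_type_column: int | None = 3,
    af_column: int | None = None,
    id_prefix: str = "sv",
) -> list[SVRecord]:
    """Read SVs from a BED3+ file (tab-separated, 0-based half-open).

    ``sv_type_column``/``af_column`` are 0-based column indices; when the
    type column is absent from a line the record defaults to ``DEL``. No
    length or type filtering happens here (see :func:`filter_svs`).
    """
    records: list[SVRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path} line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ParseError(f"{path} line {lineno}: end <= start")
            sv_type = "DEL"
            if sv_type_column is not None and len(fields) > sv_type_column:
                raw = fields[sv_type_column].upper()
                if raw not in SV_TYPES:
                    raise ParseError(
                        f"{path} line {lineno}: sv_type {raw!r} not in {SV_TYPES}"
                    )
                sv_type = raw
            af = None
            if af_column is not None and len(fields) > af_column and fields[af_column] not in ("", "."):
                try:
                    af = float(fields[af_column])
                except ValueError as exc:
                    raise ParseError(f"{path} line {lineno}: non-numeric AF") from exc
            records.append(
                SVRecord(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    sv_type=sv_type,
                    label=label,
                    allele_freq=af,
                    id=f"{id_prefix}{len(records):06d}",
                )
            )
    return records


def read_sv_vcf(path, label: int, id_prefix: str = "sv") -> list[SVRecord]:
    """Read DEL/DUP structural variants from a VCF with SVTYPE/END INFO keys.

    1-based inclusive POS/END become 0-based half-open ``[POS-1, END)``.
    Other SVTYPEs are dropped silently; SV lines without a usable END are
    skipped with a warning.
    """
    import pysam

    records: list[SVRecord] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            sv_type = rec.info.get("SVTYPE")
            if sv_type not in SV_TYPES:
                continue
            start = rec.start  # pysam: already 0-based
            end = rec.stop  # pysam: END when present, else inferred from REF
            # without an END key pysam falls back to POS + len(REF) - 1,
            # i.e. a <= 1 bp "SV" for symbolic alleles: treat as missing END
            if end is None or end <= start + 1:
                warnings.warn(
                    f"{path}: skipping SV at {rec.chrom}:{rec.pos} with no usable END",
                    stacklevel=2,
                )
                continue
            af = rec.info.get("AF")
            if isinstance(af, tuple):
                af = af[0] if af else None
            records.append(
                SVRecord(
                    chrom=rec.chrom,
                    start=start,
                    end=end,
                    sv_type=sv_type,
                    label=label,
                    allele_freq=float(af) if af is not None else None,
                    id=f"{id_prefix}{len(records):06d}",
                )
            )
    return records


def filter_svs(
    svs: Iterable[SVRecord],
    min_length: int = 50,
    sv_type: str | None = None,
    max_af: float | None = None,
    min_af: float | None = None,
) -> list[SVRecord]:
    """Apply the cohort-assembly filters: length strictly > ``min_length``,
    matching SV type, and (strict) allele-frequency bounds.

    AF bounds only apply to records that carry an allele frequency; records
    without one pass the AF filters unchanged. Idempotent; output is always
    a subset of the input in input order.
    """
    if min_af is not None and max_af is not None and min_af > max_af:
        raise ValueError(f"min_af ({min_af}) > max_af ({max_af})")
    out = []
    for sv in svs:
        if sv.length <= min_length:
            continue
        if sv_type is not None and sv.sv_type != sv_type:
            continue
        if sv.allele_freq is not None:
            if min_af is not None and not sv.allele_freq > min_af:
                continue
            if max_af is not None and not sv.allele_freq < max_af:
                continue
        out.append(sv)
    return out


SCORE_TABLE_COLUMNS = ["id", "chrom", "start", "end", "sv_type", "label", "score", "group"]


def write_score_table(table: pd.DataFrame, path) -> None:
    """Write a per-SV score table as TSV (header + one line per SV)."""
    missing = [c for c in SCORE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    table.loc[:, SCORE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_score_table(path) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"id": str, "chrom": str, "sv_type": str, "group": str},
    )
    missing = [c for c in SCORE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: score table missing columns {missing}")
    return table
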