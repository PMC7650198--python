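"""Length- and chromosome-matched shuffle nulls for structural variants.

Every SV gets a null set of randomized intervals that keep its chromosome
and its exact length, with start positions drawn uniformly (independently,
with replacement) from the integers ``[0, chrom_length - sv_length]``.
Feature values computed over these intervals form the per-SV null
distribution used for Z-score normalization: because the null matches the
SV's length, any systematic length effect on a feature cancels out.
"""

from __future__ import annotations

from collections.abc import Callable
from dataclasses import dataclass

import numpy as np

from .genomic_io import ChromSizes, SVRecord

__all__ = ["NullSet", "shuffle_sv", "build_null_feature_values"]

DEFAULT_N_SHUFFLES = 1000


@dataclass(frozen=True)
class NullSet:
    """Randomized intervals matched to one parent SV."""

    parent_id: str
    chrom: str
    length: int
    starts: np.ndarray  # shape (n,), int64

    @property
    def n(self) -> int:
        return len(self.starts)

    def intervals(self) -> list[tuple[str, int, int]]:
        return [(self.chrom, int(s), int(s) + self.length) for s in self.starts]


def shuffle_sv(
    sv: SVRecord,
    chrom_sizes: ChromSizes,
    n: int = DEFAULT_N_SHUFFLES,
    rng: np.random.Generator | None = None,
) -> NullSet:
    """Draw ``n`` uniform same-length, same-chromosome placements for ``sv``.

    Starts are uniform over ``[0, L - length]`` inclusive, so an SV as long
    as its chromosome has the single forced placement at 0. No exclusion
    zones are applied: null intervals may overlap each other and the
    original SV.
    """
    if rng is None:
        rng = np.random.default_rng()
    if sv.chrom not in chrom_sizes:
        raise ValueError(f"SV {sv.id}: chromosome {sv.chrom} not in chrom sizes")
    L = chrom_sizes[sv.chrom]
    if sv.length > L:
        raise ValueError(
            f"SV {sv.id}: length {sv.length} exceeds {sv.chrom} length {L}; "
            "cannot place shuffled instances"
        )
    starts = rng.integers(0, L - sv.length + 1, size=int(n), dtype=np.int64)
    return NullSet(parent_id=sv.id, chrom=sv.chrom, length=sv.length, starts=starts)


def build_null_feature_values(
    null_set: NullSet,
    feature_extractor: Callable[[str, int, int], float],
) -> np.ndarray:
    """Evaluate a scalar interval feature on every null interval, in order."""
    out = np.empty(null_set.n, dtype=np.float64)
    for i, (chrom, start, end) in enumerate(null_set.intervals()):
        try:
            out[i] = feature_extractor(chrom, start, end)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise RuntimeError(
                f"feature extractor failed on null interval "
                f"{chrom}:{start}-{end} (parent {null_set.parent_id})"
            ) from exc
    return out
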