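"""Orthogonal validation analyses on scored SV groups.

Conservation: the per-SV mean of a nucleotide-level conservation track
(PhyloP-style) compared between high- and low-scoring groups with a
one-sided rank-sum test.

Gene enrichment: for each gene, the fraction of its nucleotides covered by
the SV group, compared against a null built by re-placing every SV in the
group uniformly on its own chromosome (length preserved) ``n_perm`` times;
the enrichment is the Z-score of the observed fraction under the
permutation moments.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import ChromSizes, GenomicIntervalSet, SignalTrack, SVRecord

__all__ = [
    "mean_conservation",
    "compare_score_groups",
    "overlapping_genes",
    "permutation_gene_enrichment",
]


def mean_conservation(
    svs: Sequence[SVRecord], track: SignalTrack
) -> tuple[pd.Series, float]:
    """Per-SV per-base mean of the conservation track, plus the group mean."""
    vals = {
        sv.id: float(track.range_sum(sv.chrom, sv.start, sv.end)) / sv.length
        for sv in svs
    }
    series = pd.Series(vals, name="mean_conservation")
    return series, float(series.mean()) if len(series) else float("nan")


def compare_score_groups(high, low) -> tuple[float, float]:
    """One-sided Mann-Whitney rank-sum test of high > low.

    Returns (U statistic, p-value). Identical groups give p near 0.5;
    clearly separated groups give vanishing p.
    """
    high = np.asarray(high, dtype=float)
    low = np.asarray(low, dtype=float)
    if len(high) == 0 or len(low) == 0:
        raise ValueError("both score groups must be non-empty")
    res = stats.mannwhitneyu(high, low, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def overlapping_genes(
    sv_group: Sequence[SVRecord], genes: GenomicIntervalSet
) -> list[str]:
    """Sorted unique names of genes overlapping (>= 1 bp) any SV in the group."""
    cover = GenomicIntervalSet([sv.interval() for sv in sv_group])
    hits = set()
    for row in genes.records.itertuples(index=False):
        if cover.overlap_bases(row.chrom, row.start, row.end) > 0:
            hits.add(row.name)
    return sorted(hits)


def _union_coverage(starts: np.ndarray, length_or_lengths, q_starts, q_ends) -> np.ndarray:
    """Covered bases of each query under the union of the given intervals."""
    ends = starts + length_or_lengths
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    cummax = np.maximum.accumulate(e)
    new = np.ones(len(s), dtype=bool)
    new[1:] = s[1:] > cummax[:-1]
    ms = s[new]
    block = np.cumsum(new) - 1
    me = np.zeros(len(ms), dtype=np.int64)
    np.maximum.at(me, block, e)
    cum = np.concatenate(([0], np.cumsum(me - ms)))

    def C(x):
        i = np.searchsorted(ms, x, side="right")
        base = cum[i]
        prev = np.where(i > 0, me[np.maximum(i - 1, 0)], 0)
        return base - np.where(i > 0, np.clip(prev - x, 0, None), 0)

    return C(np.asarray(q_ends)) - C(np.asarray(q_starts))


def permutation_gene_enrichment(
    sv_group: Sequence[SVRecord],
    genes: GenomicIntervalSet,
    chrom_sizes: ChromSizes,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Permutation Z-score enrichment of the SV group over each gene.

    For every permutation each SV is re-placed uniformly on its own
    chromosome with its own length (the same placement process as the
    feature-normalization nulls). Per gene the statistic is the fraction of
    gene nucleotides covered by the union of the group; the Z-score uses the
    permutation mean and sd. Genes whose chromosome carries no SVs, or whose
    permutation sd is 0, get an undefined (NaN) Z, reported but not fatal.

    Lengths are sorted within each chromosome before placement, so the
    result is exactly invariant to the ordering of the input group.
    """
    if rng is None:
        rng = np.random.default_rng()
    chrom_sizes.check_svs(sv_group)
    gene_df = genes.records.sort_values(["chrom", "start", "end", "name"]).reset_index(
        drop=True
    )
    lengths_by_chrom: dict[str, np.ndarray] = {}
    starts_by_chrom: dict[str, np.ndarray] = {}
    for chrom in sorted({sv.chrom for sv in sv_group}):
        members = [sv for sv in sv_group if sv.chrom == chrom]
        order = np.argsort([sv.length for sv in members], kind="stable")
        lengths_by_chrom[chrom] = np.array([members[i].length for i in order], dtype=np.int64)
        starts_by_chrom[chrom] = np.array([members[i].start for i in order], dtype=np.int64)

    gene_lengths = (gene_df["end"] - gene_df["start"]).to_numpy()
    observed = np.zeros(len(gene_df))
    null = np.zeros((n_perm, len(gene_df)))
    for chrom, grp in gene_df.groupby("chrom", sort=True):
        idx = grp.index.to_numpy()
        qs = grp["start"].to_numpy()
        qe = grp["end"].to_numpy()
        if chrom not in lengths_by_chrom:
            observed[idx] = np.nan
            null[:, idx] = np.nan
            continue
        lens = lengths_by_chrom[chrom]
        L = chrom_sizes[chrom]
        observed[idx] = _union_coverage(starts_by_chrom[chrom], lens, qs, qe) / gene_lengths[idx]
        highs = L - lens + 1
        for p in range(n_perm):
            starts = (rng.random(len(lens)) * highs).astype(np.int64)
            null[p, idx] = _union_coverage(starts, lens, qs, qe) / gene_lengths[idx]

    import warnings as _warnings

    with _warnings.catch_warnings():
        # genes on SV-free chromosomes have all-NaN null columns by design
        _warnings.simplefilter("ignore", RuntimeWarning)
        null_mean = np.nanmean(null, axis=0) if n_perm else np.full(len(gene_df), np.nan)
        null_sd = np.nanstd(null, axis=0) if n_perm else np.full(len(gene_df), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (observed - null_mean) / null_sd
    z[~np.isfinite(z)] = np.nan
    return pd.DataFrame(
        {
            "gene": gene_df["name"],
            "chrom": gene_df["chrom"],
            "observed": observed,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "n_perm": n_perm,
        }
    )
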