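"""Per-SV null Z-normalization, length appending, and class balancing.

Each cell of the raw feature matrix is standardized against the feature's
null distribution over that SV's shuffled intervals:

    z = (raw - mu_null) / sd_null        (z := 0 when sd_null = 0)

Because the null intervals share the SV's length and chromosome, the
transformation removes systematic length (and chromosome composition)
effects from every feature, which matters when disease and control cohorts
have very different SV length distributions. Cohort-absent ("missing")
features are imputed to 0 in the Z matrix — i.e. treated as showing no
difference from the null. SV length in bp is then appended as an extra,
deliberately unnormalized column.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureConfig, FeatureMatrix, _feature_batch
from .genomic_io import ChromSizes, SVRecord
from .shuffle import DEFAULT_N_SHUFFLES, shuffle_sv

__all__ = [
    "NullSummary",
    "compute_null_summary",
    "z_normalize_cell",
    "z_normalize_matrix",
    "append_length_feature",
    "balance_classes",
]


@dataclass
class NullSummary:
    """Null mean/sd per (SV id, feature), from n shuffled instances each.

    ``ddof=0`` (population sd) by convention; at n=1000 shuffles the
    distinction from the sample sd is negligible.
    """

    mu: pd.DataFrame
    sd: pd.DataFrame
    n: int
    ddof: int = 0

    def __post_init__(self) -> None:
        if not self.mu.index.equals(self.sd.index) or list(self.mu.columns) != list(
            self.sd.columns
        ):
            raise ValueError("mu and sd must share index and columns")
        if (self.sd.to_numpy() < 0).any():
            raise ValueError("null sd must be non-negative")

    def entry(self, sv_id: str, feature: str) -> tuple[float, float]:
        return float(self.mu.at[sv_id, feature]), float(self.sd.at[sv_id, feature])

    def to_tsv(self, path) -> None:
        long = self.mu.stack().rename("mu").to_frame()
        long["sd"] = self.sd.stack()
        long.index.names = ["id", "feature"]
        with open(path, "w") as fh:
            fh.write(f"# n={self.n} ddof={self.ddof}\n")
            long.reset_index().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "NullSummary":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ")
            meta = dict(kv.split("=") for kv in header.split())
            long = pd.read_csv(fh, sep="\t", dtype={"id": str, "feature": str})
        mu = long.pivot(index="id", columns="feature", values="mu")
        sd = long.pivot(index="id", columns="feature", values="sd")
        # pivot sorts; restore first-seen order
        ids = long["id"].drop_duplicates()
        feats = long["feature"].drop_duplicates()
        mu = mu.loc[ids, feats].rename_axis(index=None, columns=None)
        sd = sd.loc[ids, feats].rename_axis(index=None, columns=None)
        return cls(mu, sd, int(meta["n"]), int(meta["ddof"]))


def compute_null_summary(
    svs: Sequence[SVRecord],
    config: FeatureConfig,
    chrom_sizes: ChromSizes,
    n: int = DEFAULT_N_SHUFFLES,
    rng: np.random.Generator | None = None,
    ddof: int = 0,
) -> NullSummary:
    """Shuffle every SV ``n`` times and summarize each feature's null.

    Features marked cohort-absent for an SV's label get NaN moments (their
    matrix cells are flagged missing and imputed downstream). Evaluation is
    vectorized over the n null intervals of each SV, which all share one
    length and chromosome.
    """
    if rng is None:
        rng = np.random.default_rng()
    ids = [sv.id for sv in svs]
    mu = np.full((len(svs), len(config.features)), np.nan)
    sd = np.full_like(mu, np.nan)
    for i, sv in enumerate(svs):
        null = shuffle_sv(sv, chrom_sizes, n=n, rng=rng)
        for j, spec in enumerate(config.features):
            if sv.label in spec.missing_for:
                continue
            vals = _feature_batch(spec, config, null.chrom, null.starts, null.length)
            mu[i, j] = vals.mean()
            sd[i, j] = vals.std(ddof=ddof)
    names = config.names
    return NullSummary(
        mu=pd.DataFrame(mu, index=ids, columns=names),
        sd=pd.DataFrame(sd, index=ids, columns=names),
        n=int(n),
        ddof=ddof,
    )


def z_normalize_cell(raw_value: float, mu: float, sd: float) -> float:
    """Standardize one cell; a degenerate (sd = 0) null maps to 0."""
    if sd == 0:
        return 0.0
    return (raw_value - mu) / sd


def z_normalize_matrix(raw: FeatureMatrix, nulls: NullSummary) -> FeatureMatrix:
    """Z-score every non-missing cell against its per-SV null; impute 0.

    Raises if a non-missing cell lacks a finite null entry, naming the
    (SV, feature) pair.
    """
    if raw.state != "raw":
        raise ValueError("z_normalize_matrix expects a raw-state matrix")
    mu = nulls.mu.reindex(index=raw.values.index, columns=raw.values.columns)
    sd = nulls.sd.reindex(index=raw.values.index, columns=raw.values.columns)
    miss = raw.missing.to_numpy()
    bad = ~miss & ~(np.isfinite(mu.to_numpy()) & np.isfinite(sd.to_numpy()))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"no null summary for non-missing cell "
            f"(SV {raw.values.index[i]}, feature {raw.values.columns[j]})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (raw.values.to_numpy() - mu.to_numpy()) / sd.to_numpy()
    z[sd.to_numpy() == 0] = 0.0
    z[miss] = 0.0
    values = pd.DataFrame(z, index=raw.values.index, columns=raw.values.columns)
    missing = pd.DataFrame(False, index=raw.values.index, columns=raw.values.columns)
    return FeatureMatrix(values, raw.labels.copy(), missing, state="z_normalized")


def append_length_feature(
    matrix: FeatureMatrix, svs: Sequence[SVRecord], include_length: bool = True
) -> FeatureMatrix:
    """Append raw SV length (bp) as a final, unnormalized ``length`` column.

    With ``include_length=False`` the matrix is returned unchanged (the
    truncated-model configuration used to probe length's contribution).
    """
    if matrix.state != "z_normalized":
        raise ValueError("length is appended after Z-normalization")
    if not include_length:
        return matrix
    by_id = {sv.id: sv for sv in svs}
    try:
        lengths = [by_id[i].length for i in matrix.ids]
    except KeyError as exc:
        raise ValueError(f"matrix row {exc.args[0]!r} has no matching SV record") from exc
    values = matrix.values.copy()
    values["length"] = np.asarray(lengths, dtype=np.float64)
    missing = matrix.missing.copy()
    missing["length"] = False
    return FeatureMatrix(values, matrix.labels.copy(), missing, state="z_normalized")


def balance_classes(
    disease: Sequence[SVRecord],
    controls: Sequence[SVRecord],
    rng: np.random.Generator | None = None,
) -> tuple[list[SVRecord], list[SVRecord]]:
    """Subsample controls without replacement to the disease cohort's size.

    The disease cohort is returned unchanged; the control subsample keeps
    the original relative order. Requires at least as many controls as
    disease SVs.
    """
    if len(controls) < len(disease):
        raise ValueError(
            f"insufficient controls: {len(controls)} controls for "
            f"{len(disease)} disease SVs"
        )
    if rng is None:
        rng = np.random.default_rng()
    keep = np.sort(rng.choice(len(controls), size=len(disease), replace=False))
    return list(disease), [controls[i] for i in keep]
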