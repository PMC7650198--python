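"""End-to-end orchestration: extract -> shuffle -> normalize -> balance ->
train -> score -> evaluate -> enrich, driven by one config and one seed.

The master seed fans out to fixed per-stage seeds through
``numpy.random.SeedSequence``, so a single integer reproduces the whole
run bit-for-bit; every artifact records the config hash and the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .downstream import permutation_gene_enrichment
from .ensemble import (
    Hyperparams,
    auroc,
    aupr,
    classify_by_score,
    config_fingerprint,
    evaluate_cv,
    save_ensemble,
    score_in_corpus,
    train_ensemble,
    tune_hyperparameters,
)
from .features import FeatureConfig, build_feature_matrix
from .genomic_io import (
    ChromSizes,
    GenomicIntervalSet,
    SignalTrack,
    read_sv_bed,
    read_sv_vcf,
    filter_svs,
    write_score_table,
)
from .normalize import (
    append_length_feature,
    balance_classes,
    compute_null_summary,
    z_normalize_matrix,
)

logger = logging.getLogger("svpath")

__all__ = ["RunConfig", "run_pipeline", "fixture_run_config"]

_STAGE_NAMES = ("balance", "nulls", "tune", "train", "cv", "holdout", "enrich")


@dataclass
class RunConfig:
    """All inputs and constants for one pipeline run."""

    chrom_sizes: str
    disease_sv: str
    control_sv: str
    tracks: dict = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)
    genes: str | None = None
    sv_type: str = "DEL"
    min_length: int = 50
    min_af: float | None = None
    max_af: float | None = None
    balance: bool = True
    n_shuffles: int = 1000
    bin_width: int = 10
    bin_agg: str = "sum"
    include_length: bool = True
    drop_features: list = field(default_factory=list)
    n_slices: int = 10
    max_depth: int = 8
    n_trees: int = 300
    min_samples_split: int = 10
    tune_budget: int = 0
    cv_folds: int = 10
    holdout_fraction: float = 0.3
    high_threshold: float = 0.9
    low_threshold: float = 0.2
    n_permutations: int = 1000
    seed: int = 0
    out_dir: str = "svpath_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hyperparams(self) -> Hyperparams:
        return Hyperparams(
            max_depth=self.max_depth,
            n_trees=self.n_trees,
            min_samples_split=self.min_samples_split,
        )

    def fingerprint(self) -> str:
        data = asdict(self)
        data.pop("out_dir")
        return config_fingerprint(data)


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    return {
        name: int(c.generate_state(1)[0] % (2**31))
        for name, c in zip(_STAGE_NAMES, children)
    }


def _read_svs(path, label, id_prefix):
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return read_sv_vcf(path, label=label, id_prefix=id_prefix)
    return read_sv_bed(path, label=label, id_prefix=id_prefix)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns a summary dict (also written
    to ``run.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    fingerprint = config.fingerprint()
    logging.basicConfig(level=logging.INFO, format="%(name)s %(levelname)s %(message)s")
    logger.info("run %s seed=%d", fingerprint, config.seed)

    base = Path(config.chrom_sizes).parent
    chrom_sizes = ChromSizes.from_file(config.chrom_sizes)
    disease = _read_svs(config.disease_sv, 1, "d")
    control = _read_svs(config.control_sv, 0, "c")
    logger.info("loaded %d disease / %d control SVs", len(disease), len(control))

    disease = filter_svs(
        disease, config.min_length, config.sv_type, min_af=None, max_af=None
    )
    control = filter_svs(
        control, config.min_length, config.sv_type,
        min_af=config.min_af, max_af=config.max_af,
    )
    logger.info("after filters: %d disease / %d control", len(disease), len(control))

    if config.balance:
        disease, control = balance_classes(
            disease, control, np.random.default_rng(seeds["balance"])
        )
        logger.info("balanced to %d per class", len(disease))

    tracks = {
        name: SignalTrack.from_bedgraph(path, chrom_sizes, name=name)
        for name, path in config.tracks.items()
    }
    annotations = {
        name: GenomicIntervalSet.from_bed(path, chrom_sizes)
        for name, path in config.annotations.items()
    }
    feat_config = FeatureConfig.from_sources(
        tracks,
        annotations,
        bin_width=config.bin_width,
        bin_agg=config.bin_agg,
        include_length=config.include_length,
    )
    if config.drop_features:
        feat_config = feat_config.subset(config.drop_features)

    svs = disease + control
    chrom_sizes.check_svs(svs)
    raw = build_feature_matrix(svs, feat_config)
    raw.to_tsv(out / "raw_matrix.tsv")
    nulls = compute_null_summary(
        svs, feat_config, chrom_sizes,
        n=config.n_shuffles, rng=np.random.default_rng(seeds["nulls"]),
    )
    z = z_normalize_matrix(raw, nulls)
    z = append_length_feature(z, svs, include_length=feat_config.include_length)
    z.to_tsv(out / "z_matrix.tsv")
    logger.info("feature matrix: %d rows x %d columns", len(z), len(z.feature_names))

    if config.tune_budget > 0:
        hp = tune_hyperparameters(
            z, config.tune_budget, seed=seeds["tune"], n_slices=config.n_slices
        )
        logger.info("tuned hyperparams: %s", hp)
    else:
        hp = config.hyperparams()

    ensemble = train_ensemble(z, hp, seed=seeds["train"], n_slices=config.n_slices)
    save_ensemble(ensemble, out / "model.svpath.joblib", config_hash=fingerprint)
    table = score_in_corpus(ensemble, z, svs)
    table = classify_by_score(table, config.high_threshold, config.low_threshold)
    write_score_table(table, out / "scores.tsv")

    evaluation = {
        "oof_auroc": auroc(z.y, ensemble.oof_scores_),
        "oof_aupr": aupr(z.y, ensemble.oof_scores_),
    }
    cv = evaluate_cv(z, hp, folds=config.cv_folds, seed=seeds["cv"], n_slices=config.n_slices)
    evaluation.update({"cv_" + k: v for k, v in cv.items()})
    evaluation.update(_holdout_eval(z, hp, config, seeds["holdout"]))
    with open(out / "evaluation.json", "w") as fh:
        json.dump(evaluation, fh, indent=2, sort_keys=True)
    logger.info(
        "cv auROC %.3f / holdout auROC %.3f",
        evaluation["cv_mean_auroc"], evaluation["holdout_auroc"],
    )

    enrichment_path = None
    if config.genes:
        genes = GenomicIntervalSet.from_bed(config.genes, chrom_sizes)
        pathogenic = [
            sv for sv, grp in zip(svs, table["group"]) if grp == "pathogenic"
        ]
        if pathogenic:
            enr = permutation_gene_enrichment(
                pathogenic, genes, chrom_sizes,
                n_perm=config.n_permutations,
                rng=np.random.default_rng(seeds["enrich"]),
            )
            enrichment_path = out / "enrichment.tsv"
            enr.to_csv(enrichment_path, sep="\t", index=False)
            logger.info("enrichment over %d genes written", len(enr))
        else:
            logger.info("no pathogenic-group SVs; enrichment skipped")

    summary = {
        "version": __version__,
        "config_hash": fingerprint,
        "seed": config.seed,
        "n_disease": int(sum(table["label"] == 1)),
        "n_control": int(sum(table["label"] == 0)),
        "n_features": len(z.feature_names),
        "hyperparams": asdict(hp),
        "evaluation": evaluation,
        "group_counts": table["group"].value_counts().to_dict(),
        "artifacts": {
            "raw_matrix": "raw_matrix.tsv",
            "z_matrix": "z_matrix.tsv",
            "scores": "scores.tsv",
            "model": "model.svpath.joblib",
            "evaluation": "evaluation.json",
            **({"enrichment": "enrichment.tsv"} if enrichment_path else {}),
        },
    }
    with open(out / "run.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _holdout_eval(z, hp, config, seed: int) -> dict:
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(z))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=config.holdout_fraction,
        stratify=z.y,
        random_state=seed % (2**31),
    )
    ids = z.ids
    train_m = z.subset_rows([ids[i] for i in np.sort(train_idx)])
    test_m = z.subset_rows([ids[i] for i in np.sort(test_idx)])
    est = train_ensemble(train_m, hp, seed=seed, n_slices=config.n_slices)
    scores = est.predict_proba(test_m.values.to_numpy())[:, 1]
    return {
        "holdout_auroc": auroc(test_m.y, scores),
        "holdout_aupr": aupr(test_m.y, scores),
        "holdout_fraction": config.holdout_fraction,
    }


def fixture_run_config(fixture_dir, out_dir, **overrides) -> RunConfig:
    """Build a RunConfig pointing at a written synthetic fixture directory."""
    fixture_dir = Path(fixture_dir)
    with open(fixture_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = RunConfig(
        chrom_sizes=str(fixture_dir / manifest["chrom_sizes"]),
        disease_sv=str(fixture_dir / manifest["disease"]),
        control_sv=str(fixture_dir / manifest["control"]),
        tracks={n: str(fixture_dir / p) for n, p in manifest["tracks"].items()},
        annotations={n: str(fixture_dir / p) for n, p in manifest["annotations"].items()},
        out_dir=str(out_dir),
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown RunConfig field {key!r}")
        setattr(cfg, key, value)
    return cfg
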