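"""End-to-end orchestration: read -> preprocess -> (morphology) ->
graph & composite weights -> augmentation -> PCA -> network fit -> Leiden ->
metrics, plus the ablation harness.

A single global seed fans out to per-stage seeds derived by hashing the
stage name, so toggling one stage never shifts another stage's randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (SpatialDataset, pca_reduce, preprocess, read_labels_tsv,
                   read_visium, write_labels_tsv)
from .domains import (DomainResult, adjusted_rand_index, internal_indices,
                      leiden_domains, normalized_mutual_information,
                      write_metrics_json)
from .errors import ParameterError, StageError
from .graph import (build_adjacency, composite_weights,
                    expression_dissimilarity, morphology_dissimilarity,
                    augment_expression)
from .morphology import (HistogramProjectionEmbedder, embed_patches,
                         extract_spot_patches, read_features_tsv,
                         reduce_features)
from .network import FitResult, VarggConfig, fit

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_ablation", "stage_seed",
           "ABLATION_VARIANTS"]

ABLATION_VARIANTS = ("NG", "NM", "NGM", "NV")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Everything a run needs; YAML-serializable."""

    dataset_path: str | None = None
    image_path: str | None = None
    morphology_path: str | None = None
    labels_path: str | None = None
    # preprocessing
    target_sum: float | None = 1e4
    log_transform: bool = True
    n_hvg: int | None = 3000
    # spatial graph & augmentation
    k_neighbors: int = 6
    graph_method: str = "kdtree"
    alpha: float = 0.5
    expression_weight_mode: str = "dissimilarity"
    # morphology branch
    use_morphology: bool = False
    patch_side: int = 64
    morph_reduced_dim: int = 100
    # dimensionality & network
    pca_dim: int = 200
    vargg: VarggConfig = field(default_factory=VarggConfig)
    # clustering
    target_domains: int | None = None
    resolution: float | None = 1.0
    leiden_knn: int = 15
    # bookkeeping
    out_dir: str | None = None
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.vargg, dict):
            self.vargg = VarggConfig(**self.vargg)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage(name: str, code: str):
    """Decorator-free stage wrapper: run fn, re-raise as StageError."""
    class _ctx:
        def __init__(self):
            self.t0 = 0.0

        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, code, str(exc)) from exc
            logger.info("stage %-12s %.2fs", name, time.perf_counter() - self.t0)
            return False
    return _ctx()


def _load_dataset(cfg: PipelineConfig, dataset: SpatialDataset | None
                  ) -> SpatialDataset:
    if dataset is None:
        if cfg.dataset_path is None:
            raise ParameterError("no dataset given (set dataset_path)")
        dataset = read_visium(cfg.dataset_path)
    if cfg.labels_path is not None:
        lab = read_labels_tsv(cfg.labels_path)
        dataset.labels = np.array([lab[s] for s in dataset.spot_ids], dtype=int)
    return dataset


def _morphology_features(cfg: PipelineConfig, ds: SpatialDataset
                         ) -> np.ndarray | None:
    if not cfg.use_morphology:
        return None
    if ds.morphology is not None:
        values = ds.morphology
    elif cfg.morphology_path is not None:
        ids, values = read_features_tsv(cfg.morphology_path)
        order = {s: i for i, s in enumerate(ids)}
        values = values[[order[s] for s in ds.spot_ids]]
    elif cfg.image_path is not None:
        from PIL import Image
        img = np.asarray(Image.open(cfg.image_path))
        patches = extract_spot_patches(img, ds.coords, cfg.patch_side)
        values = embed_patches(patches, HistogramProjectionEmbedder()).values
    else:
        raise ParameterError(
            "use_morphology=True but no morphology source available")
    n_comp = min(cfg.morph_reduced_dim, values.shape[0], values.shape[1])
    from .morphology import MorphologyFeatures
    return reduce_features(MorphologyFeatures(values, "pipeline"), n_comp).reduced


def run_pipeline(cfg: PipelineConfig,
                 dataset: SpatialDataset | None = None
                 ) -> tuple[DomainResult, FitResult]:
    """Execute the full run and persist outputs when ``out_dir`` is set.

    Returns the domain calls with their metric bundle (ARI/NMI when ground
    truth labels are available; SC/DBI/CH always) and the fitted network
    state. Identical config and seed give byte-identical outputs.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    with _stage("load", "E_LOAD"):
        ds = _load_dataset(cfg, dataset)
    with _stage("preprocess", "E_PREP"):
        ds_p = preprocess(ds, cfg.target_sum, cfg.log_transform, cfg.n_hvg)
    with _stage("morphology", "E_MORPH"):
        morph = _morphology_features(cfg, ds_p)
        logger.info("morphology: %s", "on" if morph is not None else "off")
    with _stage("graph", "E_GRAPH"):
        adj = build_adjacency(ds_p.coords, cfg.k_neighbors, cfg.graph_method)
    with _stage("weights", "E_WEIGHTS"):
        wg = expression_dissimilarity(ds_p.expression, adj.edges,
                                      mode=cfg.expression_weight_mode)
        wm = (morphology_dissimilarity(morph, adj.edges)
              if morph is not None else None)
        wall = composite_weights(adj, wg, wm)
    with _stage("augment", "E_AUG"):
        X_aug = augment_expression(ds_p.expression, wall, cfg.alpha)
    with _stage("pca", "E_PCA"):
        n_comp = min(cfg.pca_dim, *X_aug.shape)
        X_red = pca_reduce(X_aug, n_comp).values
    with _stage("fit", "E_FIT"):
        vcfg = dataclasses.replace(cfg.vargg, input_dim=n_comp,
                                   seed=stage_seed(cfg.seed, "fit"))
        result = fit(X_red, adj.symmetrize(), vcfg)
    with _stage("cluster", "E_CLUSTER"):
        domains = leiden_domains(result.latent, knn=cfg.leiden_knn,
                                 resolution=cfg.resolution
                                 if cfg.target_domains is None else None,
                                 target_domains=cfg.target_domains,
                                 seed=stage_seed(cfg.seed, "cluster"))
    with _stage("metrics", "E_METRICS"):
        metrics = internal_indices(result.latent, domains.labels)
        if ds.labels is not None:
            metrics["ARI"] = adjusted_rand_index(ds.labels, domains.labels)
            metrics["NMI"] = normalized_mutual_information(ds.labels,
                                                           domains.labels)
        domains.metrics = metrics

    if cfg.out_dir is not None:
        with _stage("persist", "E_WRITE"):
            root = Path(cfg.out_dir)
            root.mkdir(parents=True, exist_ok=True)
            write_labels_tsv(root / "domains.tsv", ds.spot_ids, domains.labels)
            result.to_dir(root, spot_ids=ds.spot_ids)
            write_metrics_json(root / "metrics.json", metrics)
            provenance = {
                "config": asdict(cfg),
                "vargg_version": __version__,
                "seed": cfg.seed,
                "morphology": "on" if morph is not None else "off",
                "n_spots": int(ds.n_spots),
                "n_genes_used": int(ds_p.n_genes),
                "pca_dim": int(n_comp),
                "resolution_used": float(domains.resolution_used),
            }
            with open(root / "provenance.yaml", "w") as fh:
                yaml.safe_dump(provenance, fh, sort_keys=True)
    return domains, result


def _variant_config(cfg: PipelineConfig, variant: str) -> PipelineConfig:
    out = dataclasses.replace(cfg)
    out.vargg = dataclasses.replace(cfg.vargg)
    if variant == "full":
        return out
    if variant not in ABLATION_VARIANTS:
        raise ParameterError(f"unknown ablation variant {variant!r}")
    if variant in ("NG", "NGM"):
        out.vargg.noise_sigma = 0.0
    if variant in ("NM", "NGM"):
        out.vargg.use_attention = False
    if variant == "NV":
        out.use_morphology = False
    return out


def run_ablation(cfg: PipelineConfig,
                 variants: tuple[str, ...] = ABLATION_VARIANTS,
                 dataset: SpatialDataset | None = None,
                 include_full: bool = True) -> pd.DataFrame:
    """Run the pipeline once per variant with shared seeds.

    NG drops the Gaussian corruption, NM bypasses all attention stages, NGM
    both, NV disables the morphology branch. Returns a variant x metrics
    table (also written as ``ablation.csv`` under ``out_dir`` if set).
    """
    names = (("full",) if include_full else ()) + tuple(variants)
    rows = []
    base_out = cfg.out_dir
    for name in names:
        vcfg = _variant_config(cfg, name)
        vcfg.out_dir = (str(Path(base_out) / name)
                        if base_out is not None else None)
        domains, _ = run_pipeline(vcfg, dataset=dataset)
        rows.append({"variant": name, "n_domains": domains.n_domains,
                     **(domains.metrics or {})})
    table = pd.DataFrame(rows).set_index("variant")
    if base_out is not None:
        table.to_csv(Path(base_out) / "ablation.csv")
    return table
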