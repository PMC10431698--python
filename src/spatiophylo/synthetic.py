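"""Synthetic data with the statistical structure the analysis assumes.

Generates pure-birth trees, clustered coordinates, sociodemographic
covariates, traits composed of fixed effects plus Brownian (tree),
Matern (spatial) and iid noise components, and Bernoulli feature
matrices whose per-taxon success probability targets a raw score —
the generative mirror of the fitted model, so every pipeline stage is
testable without external downloads.

Defaults define the reference simulation conditions: 300 taxa, a unit
phylogenetic SD against spatial and residual SDs of 0.3, the "local"
Matern field (phi = 1.25, kappa = 1) over 2-degree coordinate clusters,
and 10% missingness in feature tables.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .covariance import CovarianceStructure
from .features import FeatureMatrix
from .phylo import Phylogeny, brownian_vcv
from .spatial import (
    SpatialParams,
    area_effect_structure,
    greatcircle_distances,
    matern_covariance,
)


@dataclass
class SimulationConfig:
    """Generating parameters for a full synthetic dataset."""

    n_taxa: int = 300
    birth_rate: float = 1.0
    n_clusters: int = 8
    cluster_sd: float = 2.0  # degrees
    lat_range: tuple = (-40.0, 60.0)
    lon_range: tuple = (-160.0, 160.0)
    beta: dict = field(default_factory=dict)  # covariate -> coefficient
    intercept: float = 0.0
    sigma_phylo: float = 1.0
    sigma_spatial: float = 0.3
    sigma_resid: float = 0.3
    matern: SpatialParams = field(default_factory=lambda: SpatialParams(1.25, 1.0))
    n_features: int = 100
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_phylo, self.sigma_spatial, self.sigma_resid) < 0:
            raise ValueError("SDs must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["matern"] = {"phi": self.matern.phi, "kappa": self.matern.kappa}
        return json.dumps(d, indent=2, sort_keys=True)


def _subseeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2^31) derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def simulate_tree(n: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Ultrametric pure-birth tree with ``n`` extant tips, seeded."""
    if n < 2:
        raise ValueError("need at least 2 tips")
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n,
        rng=random.Random(seed),
    )
    # stable taxon labels shared with the tabular outputs
    taxa = dendropy.TaxonNamespace()
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"lang{i:04d}")
    tree.taxon_namespace = taxa
    return Phylogeny(tree)


def simulate_coordinates(
    taxa: list[str],
    seed: int = 0,
    n_clusters: int = 8,
    cluster_sd: float = 2.0,
    lat_range: tuple = (-40.0, 60.0),
    lon_range: tuple = (-160.0, 160.0),
) -> pd.DataFrame:
    """Clustered coordinates: a mixture of 2-D Gaussians on the map.

    Clusters (rather than uniform scatter) give the Matern field
    detectable structure at moderate sample sizes.
    """
    rng = np.random.default_rng(seed)
    centers_lat = rng.uniform(*lat_range, size=n_clusters)
    centers_lon = rng.uniform(*lon_range, size=n_clusters)
    assign = rng.integers(0, n_clusters, size=len(taxa))
    lat = np.clip(centers_lat[assign] + cluster_sd * rng.standard_normal(len(taxa)),
                  -89.9, 89.9)
    lon = centers_lon[assign] + cluster_sd * rng.standard_normal(len(taxa))
    lon = ((lon + 180.0) % 360.0) - 180.0
    lon[lon <= -180.0] = 180.0
    return pd.DataFrame({"taxon": taxa, "latitude": lat, "longitude": lon,
                         "cluster": assign})


def simulate_covariates(taxa, seed: int = 0) -> pd.DataFrame:
    """Sociodemographic covariates with realistic dependence.

    log10 speaker counts ~ Normal(4, 1.5) floored at 0; vehicularity is
    Bernoulli with a logistic link on the speaker scale (big languages
    are more often vehicular); neighbor counts are Poisson(6); official
    status and use in education are more likely for vehicular languages.
    """
    if isinstance(taxa, int):
        taxa = [f"lang{i:04d}" for i in range(taxa)]
    n = len(taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    l1_log10 = np.clip(rng.normal(4.0, 1.5, size=n), 0.0, None)
    p_veh = 1.0 / (1.0 + np.exp(-(l1_log10 - 5.0)))
    vehicular = (rng.uniform(size=n) < p_veh).astype(int)
    neighbors = rng.poisson(6.0, size=n)
    official = (rng.uniform(size=n) < np.where(vehicular == 1, 0.6, 0.05)).astype(int)
    education = (rng.uniform(size=n) < np.where(vehicular == 1, 0.7, 0.15)).astype(int)

    def z(x):
        x = np.asarray(x, float)
        return (x - x.mean()) / x.std(ddof=1)

    return pd.DataFrame(
        {
            "taxon": taxa,
            "L1_log10": l1_log10,
            "L1_z": z(l1_log10),
            "vehicular": vehicular,
            "neighbors": neighbors,
            "neighbors_z": z(neighbors),
            "official": official,
            "education": education,
        }
    )


def _psd_factor(C: np.ndarray) -> np.ndarray:
    """Symmetric square root via eigendecomposition (tolerates singular C)."""
    w, U = np.linalg.eigh((C + C.T) / 2.0)
    return U * np.sqrt(np.clip(w, 0.0, None))


def simulate_trait(
    tree: Phylogeny,
    coords: pd.DataFrame,
    X: pd.DataFrame | None,
    cfg: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Trait = intercept + X beta + Brownian effect + Matern effect + noise.

    Both structured covariances are standardized to unit mean variance
    before scaling by their SDs, matching the fitted model's
    parameterization.  Returns a score table with the raw latent trait
    (``latent``), a clamped raw score in [0, 1] (``raw_score``) and the
    standardized score (``z_score``).
    """
    seed = cfg.seed if seed is None else seed
    taxa = tree.tip_labels
    cp = brownian_vcv(tree).standardize_and_invert(invert=False)
    coords = coords.set_index("taxon").loc[taxa].reset_index()
    D = greatcircle_distances(coords)
    cs = matern_covariance(D, cfg.matern).standardize_and_invert(invert=False)
    n = len(taxa)
    mu = np.full(n, cfg.intercept)
    if cfg.beta:
        if X is None:
            raise ValueError("beta given but no covariate table")
        Xi = X.set_index("taxon").loc[taxa]
        for name, b in cfg.beta.items():
            mu = mu + b * Xi[name].to_numpy(float)
    rng = np.random.default_rng(seed)
    y = mu.copy()
    if cfg.sigma_phylo > 0:
        y = y + cfg.sigma_phylo * (_psd_factor(cp.matrix) @ rng.standard_normal(n))
    if cfg.sigma_spatial > 0:
        y = y + cfg.sigma_spatial * (_psd_factor(cs.matrix) @ rng.standard_normal(n))
    if cfg.sigma_resid > 0:
        y = y + cfg.sigma_resid * rng.standard_normal(n)
    raw = np.clip(0.5 + 0.15 * y, 0.0, 1.0)
    sd = y.std(ddof=1)
    zsc = (y - y.mean()) / sd if sd > 0 else np.zeros(n)
    return pd.DataFrame(
        {"taxon": taxa, "latent": y, "raw_score": raw, "z_score": zsc}
    )


def simulate_feature_matrix(
    scores: pd.DataFrame,
    n_features: int = 100,
    missing_rate: float = 0.1,
    seed: int = 0,
) -> FeatureMatrix:
    """Bernoulli features targeting each taxon's raw score, then MCAR gaps."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    p = np.clip(scores["raw_score"].to_numpy(float), 0.0, 1.0)
    n = len(p)
    rng = np.random.default_rng(seed)
    mat = (rng.uniform(size=(n, n_features)) < p[:, None]).astype(float)
    if missing_rate > 0:
        mask = rng.uniform(size=mat.shape) < missing_rate
        mat[mask] = np.nan
    df = pd.DataFrame(
        mat,
        index=pd.Index(scores["taxon"], name="taxon"),
        columns=[f"F{j:03d}" for j in range(n_features)],
    )
    return FeatureMatrix(df)


@dataclass
class SimulatedDataset:
    """A full synthetic study bundle plus its generating truth."""

    config: SimulationConfig
    tree: Phylogeny
    coords: pd.DataFrame
    covariates: pd.DataFrame
    scores: pd.DataFrame
    features: FeatureMatrix
    structures: dict[str, CovarianceStructure]

    def write_fixture(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.tree.write(out / "tree.nwk")
        self.coords.to_csv(out / "coords.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        self.scores.to_csv(out / "scores.csv", index=False)
        self.features.data.to_csv(out / "features.csv")
        truth = {
            "config": json.loads(self.config.to_json()),
            "seed": self.config.seed,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))


def simulate_dataset(cfg: SimulationConfig | None = None, **overrides) -> SimulatedDataset:
    """Generate the complete bundle: tree, coordinates, covariates, trait,
    features, and the standardized covariance structures used to generate."""
    if cfg is None:
        cfg = SimulationConfig(**overrides)
    s_tree, s_coord, s_cov, s_trait, s_feat = _subseeds(cfg.seed, 5)
    tree = simulate_tree(cfg.n_taxa, cfg.birth_rate, seed=s_tree)
    taxa = tree.tip_labels
    coords = simulate_coordinates(
        taxa, seed=s_coord, n_clusters=cfg.n_clusters,
        cluster_sd=cfg.cluster_sd, lat_range=cfg.lat_range,
        lon_range=cfg.lon_range,
    )
    covariates = simulate_covariates(taxa, seed=s_cov)
    scores = simulate_trait(tree, coords, covariates, cfg, seed=s_trait)
    features = simulate_feature_matrix(
        scores, cfg.n_features, cfg.missing_rate, seed=s_feat
    )
    D = greatcircle_distances(coords)
    structures = {
        "phylo": brownian_vcv(tree).standardize_and_invert(invert=False),
        "spatial_local": matern_covariance(
            D, SpatialParams(1.25, 1.0), name="spatial_local"
        ).standardize_and_invert(invert=False),
        "spatial_regional": matern_covariance(
            D, SpatialParams(17.0, 1.0), name="spatial_regional"
        ).standardize_and_invert(invert=False),
        # coordinate clusters double as area labels for the block structure
        "areas": area_effect_structure(
            coords.rename(columns={"cluster": "area"})[["taxon", "area"]]
        ).standardize_and_invert(invert=False),
    }
    return SimulatedDataset(
        config=cfg, tree=tree, coords=coords, covariates=covariates,
        scores=scores, features=features, structures=structures,
    )
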