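"""Pipeline orchestration: configuration, feature extraction, reports.

``PipelineConfig`` defaults reproduce the study-scale parameter
grids: co-occurrence distances and LBP radii
{1, 5, 10, 15, 25, 50, 100, 150, 250} px, eight co-occurrence
angles, N = 8 neighbors, the 6 x 6 Gabor bank with gamma = eta =
0.5.  ``PipelineConfig.desk_scale()`` trims the sweeps for small
synthetic images.

``run_pipeline`` executes the full analysis — features, visual rank
scores, correlation sweep, PCA, the weighted-sum complexity model,
single-factor analysis — and writes tidy CSV reports plus a manifest
(config hash, seed, versions) sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, colorspaces, firstorder, gabor, glcm, lbp, psychophysics, statmodels
from .io import write_feature_csv
from .psychophysics import RankMatrix, VRSVector

logger = logging.getLogger("texcomplex")

#: the four headline texture measures entering the joint model
HEADLINE_MEASURES = ("sigma", "entp_com", "lbp_uniform", "gabor_sigma")


@dataclass
class PipelineConfig:
    spaces: list[str] = field(
        default_factory=lambda: ["sRGB", "intensity", "HSV", "YCbCr", "I1I2I3", "CIELAB"]
    )
    firstorder_enabled: bool = True
    histogram_bins: int = 256
    glcm_distances: list[int] = field(default_factory=lambda: list(glcm.DISTANCE_SWEEP))
    glcm_angles: list[int] = field(default_factory=lambda: list(glcm.ANGLES_8))
    glcm_levels: int = 256
    lbp_radii: list[int] = field(default_factory=lambda: list(lbp.RADIUS_SWEEP))
    lbp_neighbors: int = 8
    gabor_frequencies: list[float] = field(default_factory=lambda: list(gabor.DEFAULT_FREQUENCIES))
    gabor_orientations: list[float] = field(default_factory=lambda: list(gabor.DEFAULT_ORIENTATIONS))
    gabor_gamma: float = 0.5
    gabor_eta: float = 0.5
    rescale_range: tuple[float, float] = (0.0, 10.0)
    vtc_distance: int = 100  # co-occurrence distance of the headline CoM entropy
    vtc_radius: int = 10  # LBP radius of the headline uniform feature
    vtc_frequency: float = 0.18  # Gabor frequency of the headline sigma
    seed: int = 0

    @classmethod
    def desk_scale(cls, image_px: int = 128) -> "PipelineConfig":
        """Sweeps trimmed to what a small synthetic image supports."""
        keep = [d for d in glcm.DISTANCE_SWEEP if d < image_px // 2]
        return cls(
            glcm_distances=keep,
            glcm_levels=64,
            lbp_radii=[r for r in lbp.RADIUS_SWEEP if r < image_px // 4],
            histogram_bins=64,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "rescale_range" in raw:
            raw["rescale_range"] = tuple(raw["rescale_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["rescale_range"] = list(d["rescale_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def extract_channel_features(ch: colorspaces.ChannelImage, config: PipelineConfig) -> list[dict]:
    """All configured features of one channel, as tidy rows."""
    rows: list[dict] = []

    def add(feature: str, params: str, value: float) -> None:
        rows.append(
            {
                "space": ch.space,
                "channel": ch.name,
                "feature": feature,
                "params": params,
                "value": value,
            }
        )

    if config.firstorder_enabled:
        for name, value in firstorder.descriptors(ch, config.histogram_bins).as_dict().items():
            add(name, "", value)
    size = min(ch.shape)
    indexed = glcm.quantize(ch, config.glcm_levels)
    for d in config.glcm_distances:
        if d >= size:
            logger.warning("skipping CoM distance %d >= image size %d", d, size)
            continue
        feats = {k: [] for k in glcm.FEATURE_NAMES}
        for theta in config.glcm_angles:
            C = glcm.compute_com(indexed, d, theta, config.glcm_levels)
            for k, v in glcm.com_features(C).as_dict().items():
                feats[k].append(v)
        for k, vals in feats.items():
            add(k, f"d={d}", float(np.mean(vals)))
    for R in config.lbp_radii:
        if 2 * R + 1 > size:
            logger.warning("skipping LBP radius %d on image of size %d", R, size)
            continue
        feats = lbp.lbp_features(lbp.lbp_histogram(ch, R, config.lbp_neighbors))
        add("lbp_uniform", f"R={R}", feats.uniform)
        add("lbp_nonuniform", f"R={R}", feats.nonuniform)
    for F in config.gabor_frequencies:
        gf = gabor.rotation_invariant_gabor_features(
            ch,
            F,
            orientations=tuple(config.gabor_orientations),
            gamma=config.gabor_gamma,
            eta=config.gabor_eta,
        )
        add("gabor_mu", f"F={F}", gf.mu)
        add("gabor_sigma", f"F={F}", gf.sigma)
    return rows


def extract_features(images: dict[str, np.ndarray], config: PipelineConfig) -> pd.DataFrame:
    """Tidy feature table for a set of sRGB images."""
    rows: list[dict] = []
    for sample_id, img in images.items():
        t0 = time.perf_counter()
        for ch in colorspaces.decompose(img, config.spaces):
            for row in extract_channel_features(ch, config):
                rows.append({"sample_id": sample_id} | row)
        logger.info("features(%s): %.2f s", sample_id, time.perf_counter() - t0)
    return pd.DataFrame(rows)


def headline_measures(features: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """The four joint-model measures of the intensity channel, per sample.

    Global sigma, CoM entropy at the configured distance, uniform LBP
    at the configured radius, Gabor sigma at the configured frequency.
    Falls back to the largest available distance/radius when the
    configured one was skipped (small images).
    """
    sel = features[features["channel"] == "Int"]

    def pick(feature: str, params: str | None) -> pd.Series:
        cell = sel[sel["feature"] == feature]
        if params is not None and params in set(cell["params"]):
            cell = cell[cell["params"] == params]
        else:
            last = sorted(cell["params"].unique())[-1] if len(cell) else None
            cell = cell[cell["params"] == last]
        return cell.set_index("sample_id")["value"]

    cols = {
        "sigma": pick("sigma", ""),
        "entp_com": pick("entp_com", f"d={config.vtc_distance}"),
        "lbp_uniform": pick("lbp_uniform", f"R={config.vtc_radius}"),
        "gabor_sigma": pick("gabor_sigma", f"F={config.vtc_frequency}"),
    }
    return pd.DataFrame(cols).sort_index()


def run_pipeline(
    config: PipelineConfig,
    images: dict[str, np.ndarray],
    ranks: dict[str, RankMatrix],
    out_dir: str | Path,
) -> dict:
    """Full analysis run; returns the report objects and writes CSVs.

    ``ranks`` maps attribute labels (at least ``Cpx``) to rank
    matrices whose sample ids must match the image set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "Cpx" not in ranks:
        raise ValueError("ranks must include the complexity attribute 'Cpx'")
    image_ids = sorted(images)
    for att, rm in ranks.items():
        missing = sorted(set(rm.sample_ids) ^ set(image_ids))
        if missing:
            raise ValueError(
                f"sample reconciliation failed for attribute {att!r}: mismatched ids {missing}"
            )

    t0 = time.perf_counter()
    features = extract_features(images, config)
    features["sample_id"] = features["sample_id"].astype(str)
    write_feature_csv(features, out / "features.csv")
    logger.info("stage features: %.2f s", time.perf_counter() - t0)

    vrs_by_att: dict[str, VRSVector] = {a: psychophysics.vrs(rm) for a, rm in ranks.items()}
    vrs_df = pd.DataFrame(
        {a: pd.Series(v.rescaled, index=v.sample_ids) for a, v in vrs_by_att.items()}
    ).loc[image_ids]
    vrs_df.rename_axis("sample_id").to_csv(out / "vrs.csv")

    reports: dict = {"features": features, "vrs": vrs_df}

    corr = statmodels.correlation_sweep(features, vrs_by_att["Cpx"])
    corr.to_csv(out / "correlations.csv", index=False)
    reports["correlations"] = corr

    if set(statmodels.ATTRIBUTES) <= set(vrs_df.columns):
        pca = statmodels.pca_vrs(vrs_df[list(statmodels.ATTRIBUTES)])
        pca_out = pca.coefficients.copy()
        pca_out.loc["eigenvalue"] = pca.eigenvalues
        pca_out.loc["variance_share"] = pca.explained_variance_ratio
        pca_out.to_csv(out / "pca.csv")
        reports["pca"] = pca

    measures = headline_measures(features, config).loc[image_ids]
    lo, hi = config.rescale_range
    scaled = measures.apply(
        lambda c: lo + (hi - lo) * (c - c.min()) / (c.max() - c.min()) if c.max() > c.min() else c * 0
    )
    target = vrs_df["Cpx"].to_numpy()
    vtc = statmodels.VTCModel(target, scaled.to_numpy(), labels=list(scaled.columns)).fit()
    vtc.coefficients.to_frame().to_csv(out / "vtc.csv")
    reports["vtc"] = vtc

    factor = statmodels.SingleFactorModel(measures.to_numpy(), labels=list(measures.columns)).fit()
    factor.table.to_csv(out / "factor.csv")
    reports["factor"] = factor

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config) | {"rescale_range": list(config.rescale_range)},
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_images": len(images),
        "attributes": sorted(ranks),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    reports["manifest"] = manifest
    logger.info("pipeline complete: %.2f s", time.perf_counter() - t0)
    return reports
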