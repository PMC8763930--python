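"""End-to-end orchestration: simulate -> segment -> features -> select -> risk model.

A single flat key=value configuration file drives the whole run so every
radiomics setting is archivable with its results.  All randomness derives
from the one seed in the config; reruns with the same config are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import riskmodel as rm
from .features import PreprocessSpec, extract_all_features
from .segmentation import (
    apply_volume_exclusion,
    contralateral_suvmean,
    segment_lesion,
)
from .selection import build_signature
from .synthetic import CohortSpec, PhantomSpec, generate_cohort, generate_phantom

__all__ = ["PipelineConfig", "run_pipeline", "make_demo_data", "imaging_cohort_features"]

logger = logging.getLogger("thyropet")


@dataclass
class PipelineConfig:
    """Flat, serialisable configuration of a full pipeline run.

    Every default is the package's documented standard setting; the
    round-trip write -> read -> write is byte-identical.
    """

    # synthetic cohort
    n_patients: int = 20
    prevalence_malignant: float = 23.0 / 78.0
    # segmentation
    min_ml: float = 3.0
    # preprocessing / features
    resample_spacing: float = 2.0
    discretization: str = "fixed_bin_width"
    bin_parameter: float = 0.25
    glcm_distance: int = 1
    # selection
    rho_threshold: float = 0.7
    alpha: float = 0.05
    folds: int = 10
    per_center: bool = True
    lasso_rule: str = "lambda-min"
    # risk model
    n_boot: int = 1000
    # randomness
    seed: int = 0

    def preprocess_spec(self) -> PreprocessSpec:
        return PreprocessSpec(
            resample_spacing=self.resample_spacing,
            discretization=self.discretization,
            bin_parameter=self.bin_parameter,
            glcm_distance=self.glcm_distance,
        )

    def write(self, path: str | Path) -> None:
        lines = [
            f"{f.name}={getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "PipelineConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            t = types[key]
            if t in ("int", int):
                kwargs[key] = int(raw)
            elif t in ("float", float):
                kwargs[key] = float(raw)
            elif t in ("bool", bool):
                kwargs[key] = raw in ("True", "true", "1")
            else:
                kwargs[key] = raw
        return cls(**kwargs)


def _phantom_plan(n: int, prevalence: float, seed: int) -> pd.DataFrame:
    """Per-patient phantom parameters conditioned on malignancy.

    Malignant lesions get higher shape irregularity (lower sphericity) and
    finer texture (lower GLCM autocorrelation), matching the direction of
    the reference signature's negative coefficients.
    """
    rng = np.random.default_rng(seed)
    n_mal = max(2, int(round(prevalence * n)))
    malignant = np.zeros(n, dtype=int)
    malignant[rng.choice(n, size=n_mal, replace=False)] = 1
    irregularity = np.clip(
        rng.normal(0.25 + 0.4 * malignant, 0.12), 0.0, 1.0
    )
    coarseness = np.clip(rng.normal(0.65 - 0.35 * malignant, 0.1), 0.0, 1.0)
    p_iv = np.where(malignant == 1, 18 / 23, 25 / 55)
    return pd.DataFrame({
        "patient_id": [f"P{i:03d}" for i in range(n)],
        "malignant": malignant,
        "bethesda_iv": (rng.random(n) < p_iv).astype(int),
        "center_id": np.where(rng.random(n) < 0.85, "A", "B"),
        "shape_irregularity": irregularity,
        "texture_coarseness": coarseness,
        "lesion_volume_ml": 3.0 + rng.gamma(2.0, 4.0, size=n),
        "lesion_mean_suv": rng.uniform(3.5, 7.0, size=n),
        "TSH": np.exp(rng.normal(np.log(1.7), 0.5, size=n)),
        "phantom_seed": rng.integers(0, 2**31 - 1, size=n),
    })


def imaging_cohort_features(
    plan: pd.DataFrame,
    preprocess: PreprocessSpec,
    min_ml: float = 3.0,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
) -> pd.DataFrame:
    """Run the imaging stages (phantom -> segment -> features) over a plan.

    For each planned patient: build the phantom, estimate the threshold as
    the contralateral-lobe SUVmean, grow the lesion from the truth-mask
    centroid, apply the minimum-volume exclusion, and extract the full
    feature vector.  Excluded patients are logged and absent from the
    returned table.
    """
    rows = []
    for rec in plan.to_dict("records"):
        spec = PhantomSpec(
            grid_shape=grid_shape,
            lesion_volume_ml=float(rec["lesion_volume_ml"]),
            shape_irregularity=float(rec["shape_irregularity"]),
            texture_coarseness=float(rec["texture_coarseness"]),
            lesion_mean_suv=float(rec["lesion_mean_suv"]),
            center_id=str(rec["center_id"]),
            seed=int(rec["phantom_seed"]),
        )
        phantom = generate_phantom(spec)
        threshold = contralateral_suvmean(phantom.volume, phantom.contralateral_mask)
        centroid = tuple(
            int(round(v)) for v in np.argwhere(phantom.truth_mask.mask).mean(axis=0)
        )
        if phantom.volume.data[centroid] <= threshold:  # centroid off-lesion
            inside = np.argwhere(phantom.truth_mask.mask)
            suvs = phantom.volume.data[tuple(inside.T)]
            centroid = tuple(inside[int(np.argmax(suvs))])
        mask = segment_lesion(phantom.volume, centroid, threshold)
        if apply_volume_exclusion(mask, min_ml) == "excluded":
            logger.info(
                "patient %s excluded: lesion %.2f mL < %.1f mL",
                rec["patient_id"], mask.volume_ml, min_ml,
            )
            continue
        feats = extract_all_features(phantom.volume, mask, preprocess)
        feats.update(
            patient_id=rec["patient_id"],
            center_id=rec["center_id"],
            TSH=rec["TSH"],
            bethesda_iv=int(rec["bethesda_iv"]),
            malignant=int(rec["malignant"]),
        )
        rows.append(feats)
    return pd.DataFrame(rows)


def make_demo_data(seed: int = 0, directory: str | Path | None = None,
                   n_phantoms: int = 4) -> dict:
    """Small demonstration fixtures: a few phantoms plus a 78-row cohort.

    Returns ``{"plan": ..., "cohort": ..., "phantoms": [...]}``; if
    ``directory`` is given the cohort is written as CSV and the phantoms
    as NIfTI files.
    """
    plan = _phantom_plan(n_phantoms, 0.5, seed)
    phantoms = []
    for rec in plan.to_dict("records"):
        spec = PhantomSpec(
            lesion_volume_ml=float(rec["lesion_volume_ml"]),
            shape_irregularity=float(rec["shape_irregularity"]),
            texture_coarseness=float(rec["texture_coarseness"]),
            lesion_mean_suv=float(rec["lesion_mean_suv"]),
            center_id=str(rec["center_id"]),
            seed=int(rec["phantom_seed"]),
        )
        phantoms.append(generate_phantom(spec))
    cohort = generate_cohort(CohortSpec(seed=seed))
    if directory is not None:
        from .synthetic import write_phantom

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(directory / "cohort.csv", index=False)
        for k, phantom in enumerate(phantoms):
            write_phantom(phantom, directory, f"phantom_{k:02d}")
    return {"plan": plan, "cohort": cohort, "phantoms": phantoms}


def _degenerate_features(table: pd.DataFrame) -> list[str]:
    """Feature columns constant within any per-centre stratum (cannot be
    Z-scored; e.g. saturated texture features on small lesions)."""
    from .selection import META_COLUMNS

    degenerate = []
    for col in table.columns:
        if col in META_COLUMNS:
            continue
        for _, g in table.groupby("center_id", sort=False):
            if g[col].nunique() <= 1:
                degenerate.append(col)
                break
    return degenerate


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the five stages end to end into a run directory.

    Writes ``features.csv`` (per-lesion feature vectors extracted from the
    phantom images), ``signature.json`` (the fitted radiomics signature),
    ``riskmodel.json`` (score-model and test results), ``config.cfg`` and
    ``run.log``.  Deterministic given the config.  Completed-stage outputs
    survive a later-stage failure.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("config: %s", config)
        logger.info("seed: %d", config.seed)
        config.write(out_dir / "config.cfg")

        plan = _phantom_plan(config.n_patients, config.prevalence_malignant,
                             config.seed)
        logger.info("stage simulate: %d phantoms planned", len(plan))
        table = imaging_cohort_features(
            plan, config.preprocess_spec(), min_ml=config.min_ml
        )
        table.to_csv(out_dir / "features.csv", index=False)
        logger.info("stage features: %d lesions extracted", len(table))

        candidates = table.drop(columns=["TLG"])  # TLG = SUVmean x MTV exactly
        degenerate = _degenerate_features(candidates)
        if degenerate:
            logger.info("dropping zero-variance features: %s", degenerate)
            candidates = candidates.drop(columns=degenerate)
        model, scored = build_signature(
            candidates,
            per_center=config.per_center,
            rho_threshold=config.rho_threshold,
            alpha=config.alpha,
            folds=config.folds,
            seed=config.seed,
            rule=config.lasso_rule,
        )
        model.to_json(out_dir / "signature.json")
        logger.info("stage select: signature %s", model.selected_features)

        report: dict = {"n_patients": len(scored)}
        t_rs = rm.ContingencyTable2x2.from_flags(
            scored["rs_positive"].to_numpy(bool), scored["malignant"].to_numpy(bool)
        )
        report["rs_performance"] = dataclasses.asdict(rm.diagnostic_performance(t_rs))
        try:
            report["score_model"] = rm.combined_score_model(scored)
        except ValueError as err:
            report["score_model"] = {"error": str(err)}
        boot = rm.bootstrap_optimism_auc(
            scored, ["rs_positive", "bethesda_iv"],
            n_boot=config.n_boot, seed=config.seed,
        )
        report["bootstrap"] = boot
        (out_dir / "riskmodel.json").write_text(json.dumps(report, indent=2, default=float))
        logger.info("stage riskmodel: corrected AUC %.3f", boot["corrected_auc"])
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
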