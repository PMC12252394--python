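"""End-to-end orchestration: indices → labels → bands → model → evaluation.

``run_pipeline`` executes the whole classification workflow on a spectra +
phenotype pair (from CSV files or freshly simulated), writing every stage's
artifacts plus a manifest (config hash, seed, stage outputs) to an output
directory. Each artifact embeds the seed so a rerun with the same
configuration reproduces the numeric tables byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import canopy_io, evaluation, indices, labeling, selection, simulate
from .containers import SpectraMatrix

__all__ = ["PipelineConfig", "run_pipeline", "condition_dataset"]

log = logging.getLogger("nefwheat")

#: stress condition -> (contrast, reference cultivar, stress level kg/ha)
CONDITIONS = {
    "low_N": ("N0_vs_N1", simulate.LOW_N_REFERENCE, 0.0),
    "high_N": ("N2_vs_N1", simulate.HIGH_N_REFERENCE, 450.0),
}


@dataclass
class PipelineConfig:
    """Paths plus per-stage knobs; ``None`` paths trigger simulation."""

    spectra_path: str | None = None
    phenotype_path: str | None = None
    output_dir: str = "nefwheat_out"
    seed: int = 0
    skip_tsne: bool = False
    nfue_mode: str = "centered"
    cv_folds: int = 10
    models: tuple = ("svm_xgboost", "svm")
    lasso: dict = field(default_factory=dict)
    cars: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def condition_dataset(spectra: SpectraMatrix, labels: labeling.EfficiencyLabels, level):
    """Samples at one stress level with binary efficient/inefficient targets."""
    meta = spectra.meta
    mask = (meta["n_level"] == level).to_numpy() & meta["variety"].isin(
        sorted(labels.varieties)
    ).to_numpy()
    sub = spectra.select_samples(mask)
    y = np.array(
        [
            "efficient" if v in labels.efficient else "inefficient"
            for v in sub.meta["variety"]
        ]
    )
    return sub, y


def _load_or_simulate(cfg: PipelineConfig):
    if cfg.spectra_path is not None:
        spectra = canopy_io.read_spectra_csv(cfg.spectra_path)
        pheno_path = Path(cfg.phenotype_path or "")
        if not pheno_path.exists():
            raise FileNotFoundError(f"phenotype file not found: {pheno_path}")
        pheno = pd.read_csv(pheno_path)
        design = None
    else:
        design = simulate.SyntheticDesign(seed=cfg.seed, **cfg.design)
        spectra = simulate.generate_spectra(design)
        pheno = simulate.generate_phenotypes(design)
    return spectra, pheno, design


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage; returns the artifacts directory."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
    }
    t0 = time.time()

    def stage(name):
        log.info("stage %s (seed %d)", name, cfg.seed)
        manifest["stages"][name] = {"t": round(time.time() - t0, 2), "outputs": []}
        return manifest["stages"][name]["outputs"]

    try:
        outputs = stage("data")
        spectra, pheno, design = _load_or_simulate(cfg)
        canopy_io.write_spectra_csv(spectra, out / "spectra.csv")
        pheno.to_csv(out / "phenotypes.csv", index=False)
        outputs += ["spectra.csv", "phenotypes.csv"]

        outputs = stage("indices")
        tables = {}
        for cond, (contrast, ref, level) in CONDITIONS.items():
            tab = indices.index_table(pheno, contrast, nfue_mode=cfg.nfue_mode)
            tab.to_csv(out / f"indices_{cond}.csv")
            indices.summarize(tab).to_csv(out / f"index_summary_{cond}.csv")
            tables[cond] = tab
            outputs += [f"indices_{cond}.csv", f"index_summary_{cond}.csv"]

        outputs = stage("labeling")
        labels = {}
        emb = labeling.EmbeddingConfig(seed=cfg.seed)
        for cond, (contrast, ref, level) in CONDITIONS.items():
            labels[cond] = labeling.label_varieties(
                tables[cond], ref, emb, condition=cond, skip_tsne=cfg.skip_tsne
            )
            labels[cond].to_frame().assign(seed=cfg.seed).to_csv(
                out / f"labels_{cond}.csv", index=False
            )
            outputs.append(f"labels_{cond}.csv")
        groups = labeling.combine_conditions(labels["low_N"], labels["high_N"])
        pd.DataFrame(
            {
                "variety": list(groups),
                "group": list(groups.values()),
                "strategy": [labeling.strategy_for(g) for g in groups.values()],
                "seed": cfg.seed,
            }
        ).to_csv(out / "groups.csv", index=False)
        outputs.append("groups.csv")

        outputs = stage("band_selection")
        lasso_cfg = selection.LassoConfig(seed=cfg.seed, **cfg.lasso)
        cars_cfg = selection.CarsConfig(seed=cfg.seed, **cfg.cars)
        subsets, datasets = {}, {}
        for cond, (contrast, ref, level) in CONDITIONS.items():
            sub, y = condition_dataset(spectra, labels[cond], level)
            datasets[cond] = (sub, y)
            chosen = selection.lasso_cars(sub, y, lasso_cfg, cars_cfg)
            subsets[cond] = chosen
            chosen.to_frame().assign(seed=cfg.seed).to_csv(
                out / f"bands_{cond}.csv", index=False
            )
            if chosen.trace is not None:
                chosen.trace.to_frame().to_csv(out / f"cars_trace_{cond}.csv", index=False)
                outputs.append(f"cars_trace_{cond}.csv")
            outputs.append(f"bands_{cond}.csv")

        outputs = stage("evaluation")
        for cond in CONDITIONS:
            sub, y = datasets[cond]
            X = sub.reflectance[:, subsets[cond].indices]
            table = evaluation.compare_models(
                X,
                y,
                groups=sub.meta["n_level"].to_numpy(),
                names=cfg.models,
                k=cfg.cv_folds,
                seed=cfg.seed,
            )
            table.assign(condition=cond, seed=cfg.seed).to_csv(
                out / f"model_comparison_{cond}.csv", index=False
            )
            outputs.append(f"model_comparison_{cond}.csv")
    except Exception as err:  # partial artifacts stay on disk
        failing = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {failing!r}: {err}") from err

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(cfg)))
    return out
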