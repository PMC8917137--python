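"""End-to-end orchestration: simulate -> preprocess -> quantify -> train -> predict -> report.

A single top-level seed is fanned out to per-stage seeds through a stable
hash derivation, so each stage is independently reproducible.  Every output
table starts with a ``# phospec config=<hash> stage=<name>`` comment line
carrying the run's configuration hash; the run log records per-stage timing
and record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, replace
from typing import Any

import pandas as pd
import yaml

from . import bands, pcr, preprocess, season, synthetic
from .io import read_spectra, write_spectra

__all__ = [
    "RunConfig",
    "PipelineError",
    "derive_seed",
    "run_lab_training",
    "run_field_analysis",
    "run_all",
]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage, partial outputs remain on disk."""


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived from the top-level seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Validated top-level run configuration (one YAML file)."""

    seed: int = 0
    outdir: str = "phospec_run"
    lab_spectra_path: str | None = None     # ingest instead of simulating
    field_spectra_path: str | None = None
    field_plants_path: str | None = None
    n_resamples: int = 6000
    max_components: int = 41
    folds: int = 10
    target_transform: str = "log10"
    generator: synthetic.GeneratorConfig = field(default_factory=synthetic.GeneratorConfig)
    field_params: synthetic.FieldParams = field(default_factory=synthetic.FieldParams)
    preprocess: preprocess.PreprocessConfig = field(
        default_factory=preprocess.PreprocessConfig
    )
    fit: bands.FitConfig = field(default_factory=bands.FitConfig)
    stats_variant: str = "welch"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        nested = {
            "generator": synthetic.GeneratorConfig,
            "field_params": synthetic.FieldParams,
            "preprocess": preprocess.PreprocessConfig,
            "fit": bands.FitConfig,
        }
        for key, val in raw.items():
            if key in nested:
                sub = dict(val)
                if key == "generator" and "dose" in sub:
                    sub["dose"] = synthetic.DoseResponseParams(**sub["dose"])
                if key == "preprocess":
                    for tkey in ("region", "normalization_region"):
                        if tkey in sub:
                            sub[tkey] = tuple(sub[tkey])
                kwargs[key] = nested[key](**sub)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return obj
        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: str, cfg_hash: str, stage: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# phospec config={cfg_hash} stage={stage}\n")
        df.to_csv(fh, index=index)


class _RunLog:
    def __init__(self, path: str, cfg_hash: str) -> None:
        self.path = path
        self.entries: list[dict] = []
        self.cfg_hash = cfg_hash

    def stage(self, name: str):
        return _StageTimer(self, name)

    def write(self) -> None:
        with open(self.path, "w") as fh:
            json.dump({"config": self.cfg_hash, "stages": self.entries}, fh, indent=2)


class _StageTimer:
    def __init__(self, runlog: _RunLog, name: str) -> None:
        self.runlog, self.name = runlog, name
        self.records = None

    def __enter__(self):
        self.t0 = time.monotonic()
        return self

    def __exit__(self, exc_type, exc, tb):
        entry = {
            "stage": self.name,
            "seconds": round(time.monotonic() - self.t0, 3),
            "records": self.records,
            "ok": exc is None,
        }
        self.runlog.entries.append(entry)
        self.runlog.write()
        if exc is not None and not isinstance(exc, PipelineError):
            raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def run_lab_training(config: RunConfig) -> dict[str, str]:
    """Simulate/ingest the lab design, preprocess, bootstrap-train the P model.

    Writes the raw and processed spectra, the ground-truth/targets table, the
    serialized model, the CV learning curve and a structured run log; returns
    the artifact paths.
    """
    os.makedirs(config.outdir, exist_ok=True)
    h = config.config_hash()
    runlog = _RunLog(os.path.join(config.outdir, "run_log.json"), h)
    paths = {"run_log": runlog.path}

    with runlog.stage("simulate") as st:
        if config.lab_spectra_path is not None:
            if not os.path.exists(config.lab_spectra_path):
                raise FileNotFoundError(config.lab_spectra_path)
            sset = read_spectra(config.lab_spectra_path)
            truth = sset.metadata.reset_index()
        else:
            sset, truth = synthetic.simulate_lab_dataset(
                derive_seed(config.seed, "simulate-lab"), config.generator
            )
        st.records = len(sset)
        paths["lab_spectra"] = os.path.join(config.outdir, "lab_spectra.csv")
        write_spectra(sset, paths["lab_spectra"])
        paths["lab_truth"] = os.path.join(config.outdir, "lab_truth.csv")
        _write_table(truth, paths["lab_truth"], h, "simulate")

    with runlog.stage("preprocess") as st:
        # the regression trains on baseline-corrected spectra; max-normalization
        # is reserved for the relative band-quantification outputs
        train_cfg = replace(config.preprocess, normalization_scope="none")
        processed, dispersion = preprocess.run_preprocess(sset, train_cfg)
        st.records = len(processed)
        paths["processed"] = os.path.join(config.outdir, "lab_processed.csv")
        write_spectra(processed, paths["processed"])
        paths["dispersion"] = os.path.join(config.outdir, "lab_dispersion.csv")
        _write_table(dispersion, paths["dispersion"], h, "preprocess", index=True)

    with runlog.stage("train") as st:
        if "p_conc_uM" not in processed.metadata.columns:
            raise PipelineError("stage 'train' failed: no p_conc_uM targets in metadata")
        targets = processed.metadata["p_conc_uM"].astype(float)
        bcfg = pcr.BootstrapConfig(
            n_resamples=config.n_resamples,
            seed=derive_seed(config.seed, "bootstrap"),
        )
        model, cv = pcr.bootstrap_train(
            processed,
            targets,
            bcfg,
            folds=config.folds,
            max_components=config.max_components,
            target_transform=config.target_transform,
        )
        st.records = config.n_resamples
        paths["model"] = os.path.join(config.outdir, "pcr_model.json")
        pcr.save_model(model, paths["model"])
        curve = pd.DataFrame(
            {
                "n_components": range(1, len(cv.msep_by_components) + 1),
                "msep": cv.msep_by_components,
                "selected": [
                    k == cv.selected_components
                    for k in range(1, len(cv.msep_by_components) + 1)
                ],
            }
        )
        paths["learning_curve"] = os.path.join(config.outdir, "learning_curve.csv")
        _write_table(curve, paths["learning_curve"], h, "train")
        summary = pd.DataFrame(
            [
                {
                    "selected_components": cv.selected_components,
                    "msep": cv.msep,
                    "folds": cv.fold_count,
                    "n_resamples": config.n_resamples,
                    "target_transform": config.target_transform,
                }
            ]
        )
        paths["cv_summary"] = os.path.join(config.outdir, "cv_summary.csv")
        _write_table(summary, paths["cv_summary"], h, "train")
    return paths


def run_field_analysis(config: RunConfig, model_file: str) -> dict[str, str]:
    """Quantify field spectra, predict available P, and emit the season report."""
    if not os.path.exists(model_file):
        raise PipelineError(f"stage 'load-model' failed: model file {model_file!r} missing")
    model = pcr.load_model(model_file)
    os.makedirs(config.outdir, exist_ok=True)
    h = config.config_hash()
    runlog = _RunLog(os.path.join(config.outdir, "field_run_log.json"), h)
    paths = {"run_log": runlog.path}

    with runlog.stage("simulate-field") as st:
        if config.field_spectra_path is not None:
            sset = read_spectra(config.field_spectra_path)
            plants = pd.read_csv(config.field_plants_path, comment="#")
        else:
            sset, plants = synthetic.simulate_field_dataset(
                derive_seed(config.seed, "simulate-field"),
                config.field_params,
                config.generator,
            )
        st.records = len(sset)
        paths["field_spectra"] = os.path.join(config.outdir, "field_spectra.csv")
        write_spectra(sset, paths["field_spectra"])
        paths["field_plants"] = os.path.join(config.outdir, "field_plants.csv")
        _write_table(plants, paths["field_plants"], h, "simulate-field")

    with runlog.stage("preprocess-field") as st:
        # one spectrum per plant-timepoint: nothing to aggregate; the model
        # input skips normalization to match the training matrix
        pp_cfg = replace(config.preprocess, replicate_policy="keep-all")
        processed, _ = preprocess.run_preprocess(sset, pp_cfg)
        model_input, _ = preprocess.run_preprocess(
            sset, replace(pp_cfg, normalization_scope="none")
        )
        st.records = len(processed)

    with runlog.stage("quantify") as st:
        profiles = bands.quantify_set(processed, fit_config=config.fit)
        st.records = len(profiles)
        paths["profiles"] = os.path.join(config.outdir, "field_profiles.csv")
        _write_table(profiles, paths["profiles"], h, "quantify")

    with runlog.stage("predict") as st:
        predictions = pcr.predict_available(model, model_input)
        st.records = len(predictions)
        paths["predictions"] = os.path.join(config.outdir, "field_predictions.csv")
        _write_table(
            predictions.rename("predicted_available_P_uM").reset_index(),
            paths["predictions"], h, "predict",
        )

    with runlog.stage("report") as st:
        table = season.season_table(profiles, predictions)
        paths["season_table"] = os.path.join(config.outdir, "season_table.csv")
        _write_table(table, paths["season_table"], h, "report")

        lines = []
        pairwise_rows = []
        for site in sorted(profiles["site"].unique()):
            for sig in ("Pi", "Po", "cl_ratio"):
                comps = season.pairwise_timepoints(
                    profiles, sig, site=site, variant=config.stats_variant
                )
                for c in comps:
                    pairwise_rows.append(
                        {
                            "site": site, "signature": sig,
                            "pair": f"{c.group_a}-{c.group_b}",
                            "statistic": c.statistic, "p_value": c.p_value,
                            "p_adjusted": c.p_adjusted,
                            "mean_a": c.mean_a, "mean_b": c.mean_b,
                        }
                    )
        paths["pairwise"] = os.path.join(config.outdir, "pairwise_tests.csv")
        _write_table(pd.DataFrame(pairwise_rows), paths["pairwise"], h, "report")

        merged = profiles.merge(
            plants[["sample_id", "second_year_biomass_g"]], on="sample_id"
        )
        t5 = merged[merged["timepoint"] == "T5"].copy()
        t5["pi_po"] = t5["Pi"] / t5["Po"]
        assoc_rows = []
        for scope, dfv in [("all", t5)] + [
            (s, t5[t5["site"] == s]) for s in sorted(t5["site"].unique())
        ]:
            res = season.ratio_biomass_association(
                dfv["pi_po"], dfv["second_year_biomass_g"]
            )
            assoc_rows.append(
                {
                    "scope": scope, "coefficient": res.coefficient,
                    "p_value": res.p_value, "n": res.n, "method": res.method,
                }
            )
            lines.append(
                f"Pi/Po(T5) vs second-year biomass [{scope}]: "
                f"rho={res.coefficient:.3f}, p={res.p_value:.2e}, n={res.n}"
            )
        paths["association"] = os.path.join(config.outdir, "association.csv")
        _write_table(pd.DataFrame(assoc_rows), paths["association"], h, "report")
        paths["analysis_log"] = os.path.join(config.outdir, "analysis_log.txt")
        with open(paths["analysis_log"], "w") as fh:
            fh.write(f"# phospec config={h} stage=report\n")
            fh.write("\n".join(lines) + "\n")
        st.records = len(pairwise_rows) + len(assoc_rows)
    return paths


def run_all(config: RunConfig) -> dict[str, str]:
    """Lab training followed by field analysis with the freshly trained model."""
    paths = run_lab_training(config)
    paths.update(run_field_analysis(config, paths["model"]))
    return paths
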