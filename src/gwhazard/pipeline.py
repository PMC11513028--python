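"""End-to-end analysis pipeline with a reproducible run manifest.

Chains the stages simulate/load -> summaries -> pollution indices -> risk
chain -> surrogate training -> validation reports, writing every module's
delimited-text output plus ``manifest.json`` into one output directory.
One global seed fans out to per-stage seeds through a documented
derivation (``stage_seed``), so stages are independently reproducible and
running them separately with shared seeds equals running ``all``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .hhra import risk_table, risk_summary
from .indices import index_table
from .metrics import fit_report
from .registry import ELEMENTS, Registry, load_registry
from .samples import (classify_water_suitability, load_samples, summary_table,
                      write_samples)
from .surrogate import (MLPConfig, RBFConfig, SurrogateModel, importance,
                        partition, train_mlp, train_rbf)
from .synth import default_config, generate, ground_truth

log = logging.getLogger("gwhazard")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "TARGET_FAMILIES"]

#: surrogate target families: name -> (target columns, input columns,
#: RBF train fraction, MLP train fraction)
TARGET_FAMILIES: dict[str, tuple[tuple[str, ...], tuple[str, ...], float, float]] = {
    "indices": (("hpi", "hei", "ci", "mhpi_ni"), ELEMENTS, 0.75, 0.70),
    "hi": (("hi_ing_adult", "hi_ing_child"), ELEMENTS, 0.75, 0.85),
    "cr": (("cr_ing_adult", "cr_ing_child"), ("Cr", "As", "Cd", "Pb"), 0.80, 0.70),
}

_STAGE_CODES = {"simulate": 1, "partition": 2, "rbf": 3, "mlp": 4, "importance": 5}


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the global seed."""
    ss = np.random.SeedSequence([int(seed), _STAGE_CODES[stage]])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class PipelineConfig:
    seed: int
    out: Path
    input: Path | None = None           # None -> simulate
    n_samples: int = 40
    cohorts: tuple[str, ...] = ("adult", "child")
    bdl_policy: str = "half_dl"
    dermal_slope_policy: str = "as_printed"
    mac_source: str = "backcalc"
    model: str = "both"                 # rbf | mlp | both
    families: tuple[str, ...] = ("indices", "hi", "cr")
    multi_output: bool = False
    registry_path: str | None = None
    importance_repeats: int = 10

    def as_dict(self) -> dict:
        d = {k: (str(v) if isinstance(v, Path) else v)
             for k, v in self.__dict__.items()}
        d["families"] = list(self.families)
        d["cohorts"] = list(self.cohorts)
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _train_one(family: str, kind: str, X: pd.DataFrame, Y: pd.DataFrame,
               frac: float, seed: int) -> SurrogateModel:
    part = partition(list(X.index), frac, stage_seed(seed, "partition"))
    if kind == "rbf":
        return train_rbf(X, Y, part, RBFConfig(), seed=stage_seed(seed, "rbf"))
    return train_mlp(X, Y, part, MLPConfig(), seed=stage_seed(seed, "mlp"))


def train_family(truth: pd.DataFrame, family: str, kind: str, seed: int,
                 multi_output: bool = False) -> list[SurrogateModel]:
    """Train surrogate(s) for one target family on a ground-truth table."""
    targets, inputs, frac_rbf, frac_mlp = TARGET_FAMILIES[family]
    frac = frac_rbf if kind == "rbf" else frac_mlp
    X = truth.set_index("sample_id")[list(inputs)]
    Yall = truth.set_index("sample_id")[list(targets)]
    if multi_output:
        return [_train_one(family, kind, X, Yall, frac, seed)]
    return [_train_one(family, kind, X, Yall[[t]], frac, seed) for t in targets]


def reports_for(models: Sequence[SurrogateModel], truth: pd.DataFrame,
                seed: int, importance_repeats: int = 10
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(metric summary, tidy parity/residual data, importance scores)."""
    rows, parity_frames, imp_rows = [], [], []
    for model in models:
        X = truth.set_index("sample_id")[model.input_names]
        Y = truth.set_index("sample_id")[model.output_names]
        pred = model.predict(X)
        part_seed = model.metadata["partition_seed"]
        frac = model.metadata["train_fraction"]
        part = partition(list(X.index), frac, part_seed)
        labels = part.labels(list(X.index))
        for col in model.output_names:
            rep = fit_report(col, list(X.index), Y[col].to_numpy(),
                             pred[col].to_numpy(), labels)
            row = rep.summary_row()
            row["family"] = model.family
            rows.append(row)
            frame = rep.parity.copy()
            frame.insert(0, "model", model.family)
            frame.insert(1, "target", col)
            parity_frames.append(frame)
        imp = importance(model, X, Y, n_repeats=importance_repeats,
                         seed=stage_seed(seed, "importance"))
        for feat, score in imp.items():
            imp_rows.append({"model": model.family,
                             "target": "+".join(model.output_names),
                             "input": feat, "importance": score})
    summary = pd.DataFrame(rows)
    parity = pd.concat(parity_frames, ignore_index=True) if parity_frames \
        else pd.DataFrame()
    return summary, parity, pd.DataFrame(imp_rows)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full analysis and return the output directory."""
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    registry = load_registry(cfg.registry_path, mac_source=cfg.mac_source)
    log.info("pipeline start: seed=%d bdl_policy=%s registry=%s",
             cfg.seed, cfg.bdl_policy, registry.version)

    # -- samples ------------------------------------------------------------
    if cfg.input is None:
        samples = generate(default_config(stage_seed(cfg.seed, "simulate"),
                                          cfg.n_samples))
    else:
        samples = load_samples(cfg.input, registry)
    write_samples(samples, out / "samples.csv")

    # -- descriptive summaries and suitability ------------------------------
    variables = [v for v in ("ph", "ec", "tds") if getattr(samples[0], v) is not None]
    variables += [el for el in registry.elements if el in samples[0].concentrations]
    summary_table(samples, variables, policy=cfg.bdl_policy).to_csv(
        out / "summary.csv", index=False)
    suit_rows = []
    for s in samples:
        row = {"sample_id": s.sample_id}
        if s.ec is not None:
            row["ec_class"] = classify_water_suitability(s.ec, "ec", registry)
        if s.tds is not None:
            row["tds_drinking_class"] = classify_water_suitability(
                s.tds, "tds_drinking", registry)
            row["tds_salinity_class"] = classify_water_suitability(
                s.tds, "tds_salinity", registry)
        suit_rows.append(row)
    pd.DataFrame(suit_rows).to_csv(out / "suitability.csv", index=False)

    # -- indices and risk ----------------------------------------------------
    indices = index_table(samples, registry, policy=cfg.bdl_policy)
    indices.to_csv(out / "indices.csv", index=False)
    risks = risk_table(samples, registry, cohorts=cfg.cohorts,
                       policy=cfg.bdl_policy,
                       dermal_slope_policy=cfg.dermal_slope_policy)
    risks.to_csv(out / "risk.csv", index=False)
    risk_summary(risks).to_csv(out / "risk_summary.csv", index=False)

    truth = ground_truth(samples, registry, cohorts=cfg.cohorts,
                         policy=cfg.bdl_policy,
                         dermal_slope_policy=cfg.dermal_slope_policy)
    truth.to_csv(out / "truth.csv", index=False)

    # -- surrogates ----------------------------------------------------------
    kinds = ("rbf", "mlp") if cfg.model == "both" else (cfg.model,)
    models: list[SurrogateModel] = []
    model_dir = out / "models"
    model_dir.mkdir(exist_ok=True)
    for kind in kinds:
        for family in cfg.families:
            trained = train_family(truth, family, kind, cfg.seed,
                                   cfg.multi_output)
            for m in trained:
                name = f"{kind}_{family}_{'_'.join(m.output_names)}.json"
                m.save(model_dir / name)
            models.extend(trained)
    summary, parity, imp = reports_for(models, truth, cfg.seed,
                                       cfg.importance_repeats)
    summary.to_csv(out / "fit_report.csv", index=False)
    parity.to_csv(out / "parity.csv", index=False)
    imp.to_csv(out / "importance.csv", index=False)

    manifest = {
        "subcommand": "all",
        "config": cfg.as_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGE_CODES},
        "registry_version": registry.version,
        "bdl_policy": cfg.bdl_policy,
        "dermal_slope_policy": cfg.dermal_slope_policy,
        "package_version": __version__,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("pipeline done: %s", out)
    return out
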