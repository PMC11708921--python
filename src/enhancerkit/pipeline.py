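"""End-to-end reproducible pipeline: scan -> gradients -> profiles ->
model-space sweep -> reports, driven by a single config with recorded
seeds and an output manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gradients import (TranslationConfig, load_gradient_table,
                        translate_mrna_to_protein, write_gradient_table)
from .model_space import (FitConfig, parameter_landscape, sweep_model_space)
from .motif import (find_sites, read_fasta, read_pwms, select_strongest,
                    write_sites_tsv)
from .thermo import ExpressionProfile, GradientSet, NO_SWITCH
from .utils import derived_seed

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    sequences: str = ""
    pwms: str = ""
    gradients: str = ""
    profiles: Dict[str, str] = field(default_factory=dict)
    output_dir: str = "out"
    ln_p_cutoff: float = -8.0
    k_per_tf: int = 2
    translate_tfs: List[str] = field(default_factory=lambda: ["CAD", "KNI"])
    translation: Dict = field(default_factory=dict)
    switch_directions: List[str] = field(
        default_factory=lambda: ["activator_to_repressor"])
    fit: Dict = field(default_factory=dict)
    seed: int = 0
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_profile_table(path) -> ExpressionProfile:
    """Read a profile TSV with columns ap_percent (or position), mean and
    optional se, n."""
    df = pd.read_csv(path, sep="\t")
    col = "ap_percent" if "ap_percent" in df.columns else "position"
    se = df["se"].to_numpy() if "se" in df.columns else None
    n = int(df["n"].iloc[0]) if "n" in df.columns else None
    return ExpressionProfile(df[col].to_numpy(dtype=float),
                             df["mean"].to_numpy(dtype=float), se, n)


def write_profile_table(profile: ExpressionProfile, path) -> None:
    data = {"ap_percent": profile.ap_grid, "mean": profile.mean}
    if profile.se is not None:
        data["se"] = profile.se
    if profile.n_embryos is not None:
        data["n"] = profile.n_embryos
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Dict:
    """Execute scan -> annotate -> load gradients/profiles -> sweep ->
    reports; returns (and writes) the output manifest."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: List[str] = []

    # --- scan ---------------------------------------------------------
    sequences = read_fasta(config.sequences)
    pwms = read_pwms(config.pwms)
    annotations = {}
    for enh_id, seq in sequences.items():
        sites_by_tf = {}
        for tf, pwm in pwms.items():
            cutoff = pwm.ln_p_cutoff if pwm.ln_p_cutoff is not None \
                else config.ln_p_cutoff
            sites_by_tf[tf] = find_sites(pwm, seq, cutoff)
        ann = select_strongest(sites_by_tf, config.k_per_tf,
                               enhancer_id=enh_id,
                               sequence_length=len(seq))
        annotations[enh_id] = ann
        site_path = out / f"sites_{enh_id}.tsv"
        write_sites_tsv(ann, site_path)
        artifacts.append(str(site_path))
        logger.info("scan: %s -> %d sites", enh_id, len(ann.sites))

    # --- gradients ----------------------------------------------------
    gradients = load_gradient_table(config.gradients)
    if config.translate_tfs:
        tcfg = TranslationConfig(**config.translation)
        conc = dict(gradients.concentrations)
        for tf in config.translate_tfs:
            if tf in conc:
                conc[tf] = translate_mrna_to_protein(conc[tf], tcfg)
        gradients = GradientSet(gradients.ap_grid, conc)
    grad_path = out / "gradients_used.tsv"
    write_gradient_table(gradients, grad_path)
    artifacts.append(str(grad_path))

    needed = {s.tf_name for ann in annotations.values() for s in ann.sites}
    missing = needed - set(gradients.tfs)
    if missing:
        raise ValueError(f"missing gradient: {', '.join(sorted(missing))}")

    # --- profiles -----------------------------------------------------
    profiles = {enh_id: load_profile_table(p)
                for enh_id, p in config.profiles.items()}

    # --- sweep --------------------------------------------------------
    results = {}
    for enh_id, ann in annotations.items():
        if enh_id not in profiles:
            logger.warning("no observed profile for %s; skipping sweep",
                           enh_id)
            continue
        for direction in (config.switch_directions or [NO_SWITCH]):
            fit_cfg = FitConfig(**{**config.fit,
                                   "switching": direction,
                                   "seed": derived_seed(
                                       config.seed,
                                       zlib.crc32(enh_id.encode()))})
            res = sweep_model_space(ann, profiles[enh_id], gradients,
                                    fit_cfg)
            tag = f"{enh_id}_{direction}"
            results[tag] = res
            sweep_path = out / f"sweep_{tag}.tsv"
            res.summary_table().to_csv(sweep_path, sep="\t", index=False)
            artifacts.append(str(sweep_path))
            best = res.best_fit
            params_path = out / f"best_params_{tag}.json"
            params_path.write_text(json.dumps({
                "subset": list(best.subset),
                "rmse": best.rmse,
                "aic": best.aic,
                "n_params": best.n_params,
                "k": best.params.k,
                "k_hb_repressor": best.params.k_hb_repressor,
                "c": {"|".join(k): v for k, v in best.params.c.items()},
                "q": {"|".join(k): v for k, v in best.params.q.items()},
                "hb_threshold": best.params.hb_threshold,
                "hb_switch_direction": best.params.hb_switch_direction,
            }, indent=2))
            artifacts.append(str(params_path))
            if config.make_plots:
                from . import viz
                for name, fn in [
                        (f"rmse_aic_{tag}.png",
                         lambda p: viz.plot_rmse_aic(res, p)),
                        (f"thresholds_{tag}.png",
                         lambda p: viz.plot_threshold_histogram(
                             res.threshold_histogram, p)),
                        (f"k_heatmap_{tag}.png",
                         lambda p: viz.plot_k_heatmap(
                             parameter_landscape(res), p)),
                        (f"best_fit_{tag}.png",
                         lambda p: viz.plot_fit(profiles[enh_id],
                                                best.predictions, p, tag))]:
                    path = out / name
                    fn(path)
                    artifacts.append(str(path))

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "elapsed_s": round(time.time() - t0, 2),
        "artifacts": [{"path": p, "sha256": _sha256(Path(p))}
                      for p in artifacts],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
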