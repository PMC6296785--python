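"""End-to-end orchestration: generate -> process -> analyze -> decode ->
fit -> report.

A :class:`RunConfig` (YAML-friendly dict of stage settings plus one master
seed) drives the full analysis; every stage's randomness is derived
deterministically from the master seed, so identical configs produce
byte-identical outputs (verified by the manifest checksums the run emits).
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

from . import decoding, processing, selectivity, stimuli, synth
from .data import write_dataset
from .fitting import build_fit_target, compare_models
from .models import ModelSpec

log = logging.getLogger("facedyn")

DEFAULT_MODEL_LIST = [
    {"architecture": "feedforward", "n_stages": 3},
    {"architecture": "lateral_inhibition", "n_stages": 3},
    {"architecture": "normalization_linear", "n_stages": 3},
    {"architecture": "normalization_nonlinear", "n_stages": 3},
    {"architecture": "feedback_linear_reconstruction", "n_stages": 3},
    {"architecture": "feedback_linear_reconstruction", "n_stages": 3,
     "readout": "state_and_error"},
]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str = "facedyn_run"
    seed: int = 0
    synth: dict = field(default_factory=dict)       # overrides of the default world
    alpha_change: float = 0.01
    n_boot: int = 1000
    decoder: dict = field(default_factory=lambda: {"n_sites": 30, "n_resamples": 100})
    models: list = field(default_factory=lambda: [dict(m) for m in DEFAULT_MODEL_LIST])
    fitting: dict = field(default_factory=lambda: {"n_starts": 12, "n_refine": 6,
                                                   "dt": 1.0})
    write_hdf5: bool = True

    def __post_init__(self):
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")
        for m in self.models:
            ModelSpec(**m)  # validates architecture/readout/n_stages

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also written to
    ``out_dir/report.json`` along with all tables and a checksum manifest).
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    outputs: list[Path] = []

    def save_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        outputs.append(path)

    # --- stimuli -------------------------------------------------------------
    log.info("stage: stimuli")
    manifest = stimuli.build_screen_image_set()
    stimuli.manifest_to_json(manifest, out / "stimulus_manifest.json")
    stimuli.manifest_to_csv(manifest, out / "stimulus_manifest.csv")
    outputs += [out / "stimulus_manifest.json", out / "stimulus_manifest.csv"]
    by_tag: dict = {}
    for img in manifest:
        tag = sorted(img.subset_tags)[0]
        by_tag[tag] = by_tag.get(tag, 0) + 1
    report["stimuli"] = {"n_images": len(manifest), "subsets": by_tag}

    # --- synthesis -----------------------------------------------------------
    log.info("stage: synthesis")
    seed = _stage_seed(config.seed, "synth")
    dataset = synth.generate_population(config.synth, seed=seed)
    screen = synth.generate_screen_responses(config.synth, seed=seed)
    if config.write_hdf5:
        write_dataset(dataset, out / "population.h5")
        outputs.append(out / "population.h5")
    report["synthesis"] = {"n_sites": len(dataset.sites),
                           "n_images": len(dataset.manifest),
                           "generator_seed": seed}

    # --- processing ----------------------------------------------------------
    log.info("stage: processing")
    dataset = processing.latency_correct(dataset)
    dataset = processing.baseline_subtract_dataset(dataset)
    screen = processing.latency_correct(screen)
    screen = processing.baseline_subtract_dataset(screen)
    screen_sites = {s.site_id: s for s in screen.sites}
    screen_pass = {
        sid: processing.visual_drive_screen(site, screen.manifest)
        for sid, site in screen_sites.items()
    }
    dataset.sites = [s for s in dataset.sites if screen_pass.get(s.site_id, False)]

    reference = dataset.meta["reference_image"]
    pit_sites = dataset.region_sites("pIT")
    matched = processing.select_matched_images(pit_sites, reference)
    typicality = {img.image_id: img.typicality for img in dataset.manifest}
    typical = [i for i in matched if typicality[i] == "typical"]
    atypical = [i for i in matched if typicality[i] == "atypical"]
    per_site = {
        s.site_id: processing.per_site_matched_images(s, dataset.manifest, reference)
        for s in dataset.sites
    }
    save_df(processing.qc_table(dataset, screen_pass, per_site), "qc_sites.csv")
    report["processing"] = {
        "n_pass_screen": sum(screen_pass.values()),
        "n_matched": len(matched),
        "n_matched_typical": len(typical),
        "n_matched_atypical": len(atypical),
    }

    # --- selectivity ---------------------------------------------------------
    log.info("stage: selectivity")
    sel_seed = _stage_seed(config.seed, "selectivity")
    results = []
    for k, site in enumerate(dataset.sites):
        results.append(
            selectivity.classify_change(
                site, typical, atypical, alpha=config.alpha_change,
                n_boot=config.n_boot, seed=sel_seed + k,
            )
        )
    save_df(selectivity.results_table(results), "selectivity_sites.csv")
    summaries = {}
    for region in ("pIT", "cIT", "aIT"):
        rres = [r for r in results if r.region == region]
        if not rres:
            continue
        changing = [r for r in rres if r.change_class != "no_change"]
        decreasing = [r for r in changing if r.change_class == "decreased"]
        summaries[region] = {}
        for window in ("early", "late"):
            s = selectivity.population_summary(rres, window, n_boot=config.n_boot,
                                               seed=sel_seed)
            summaries[region][window] = {
                "median_dprime": s.median_dprime,
                "median_se": s.median_se,
                "fraction_prefer_typical": s.fraction_prefer_typical,
            }
        summaries[region]["n_changing"] = len(changing)
        summaries[region]["n_decreasing"] = len(decreasing)
        if changing:
            summaries[region]["binomial_p"] = selectivity.binomial_sign_test(
                len(decreasing), len(changing))
    report["selectivity"] = summaries

    non_ref = [i for i in matched if i != reference]
    correlations = {}
    for region in ("pIT", "cIT", "aIT"):
        cc = selectivity.cross_area_correlation(
            dataset.region_sites(region), processing.EARLY_WINDOW,
            pit_sites, processing.LATE_WINDOW, non_ref,
            n_boot=config.n_boot, seed=sel_seed,
        )
        correlations[f"{region}_early_vs_pIT_late"] = {
            "rho": cc.rho, "se": cc.se, "p": cc.p_value}
    report["correlations"] = correlations
    (out / "selectivity_summary.json").write_text(
        json.dumps({"summaries": summaries, "correlations": correlations}, indent=1))
    outputs.append(out / "selectivity_summary.json")

    # --- decoding ------------------------------------------------------------
    log.info("stage: decoding")
    dec_seed = _stage_seed(config.seed, "decoding")
    labels = {i: typicality[i] for i in matched}
    rows = []
    for region in ("pIT", "cIT", "aIT"):
        res = decoding.decode_population(
            dataset, region, labels, seed=dec_seed, **config.decoder)
        rows.append(res.__dict__)
    decode_df = pd.DataFrame(rows)
    save_df(decode_df, "decoding.csv")
    report["decoding"] = {r["region"]: r["accuracy_mean"] for r in rows}

    # --- model fitting -------------------------------------------------------
    if config.models:
        log.info("stage: fitting (%d models)", len(config.models))
        fit_seed = _stage_seed(config.seed, "fitting")
        specs = [ModelSpec(**m) for m in config.models]
        regions = ("pIT", "cIT", "aIT") if any(s.n_stages == 3 for s in specs) \
            else ("pIT", "aIT")
        target = build_fit_target(dataset, typical, atypical, reference,
                                  regions=regions)
        table, fits = compare_models(specs, target, seed=fit_seed,
                                     **config.fitting)
        save_df(table, "model_comparison.csv")
        report["model_ranking"] = table["model"].tolist()
        report["model_losses"] = dict(zip(table["model"], table["loss"]))
    else:
        report["model_ranking"] = []
        report["fitting_skipped"] = "empty model list"

    # --- manifest ------------------------------------------------------------
    report["runtime_s"] = round(time.time() - t_start, 1)
    report["outputs"] = {p.name: _checksum(p) for p in outputs}
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
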