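"""Synthetic multi-site recordings with the statistical structure the
analysis assumes.

Each site's firing-rate template is

    r(t) = b0 + A * g_i * alpha(t) + E * psi_e(t) * f_early(i)
              + L * psi_l(t) * f_late(i)

where ``alpha`` is the common visual transient (sigmoidal rise, mild
adaptation, off-response decay after the 100 ms presentation), ``psi_e`` and
``psi_l`` are early- and late-phase selectivity kernels, ``g_i`` the
per-image drive, and ``f_early``/``f_late`` per-image selectivity factors
built from the image class (typical = 1, atypical = 0) plus image-level
jitter.  Trials are inhomogeneous Poisson counts per 1 ms bin multiplied by
a slow per-presentation excitability gain — multi-unit-like rates where the
gain noise, not Poisson noise, limits long-window decoding.

Site amplitudes ``E`` and ``L`` are calibrated analytically from this noise
model so each site's early/late d' (typical vs atypical, pooled-trial
variance) matches per-class targets drawn from the region's configuration;
a correction term absorbs the common-mode response difference introduced by
the per-class drive bands.  The jitters of the selectivity factors are
centred within the matched image classes, so the realized class contrast is
exact, while their image-level structure (a "face evidence" component shared
across regions) makes early responses in higher regions predict late pIT
responses negatively, as the error-coding account requires.  Monkey M2
sites are generated 13 ms slower throughout.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .data import PopulationDataset, SiteRecording
from .fitting import FitTarget, target_from_signals
from .models import ModelParams, ModelSpec, readout, simulate
from .stimuli import build_screen_image_set, build_screen_set

__all__ = [
    "DEFAULT_SYNTH_CONFIG",
    "generate_population",
    "generate_screen_responses",
    "generate_from_model",
]

#: Defaults emulate the study's structure: 115/70/40 sites across pIT/cIT/aIT,
#: 10 trials per image, monkey 2 running 13 ms slow, and per-class d'
#: dynamics calibrated to the reported population statistics (early/late
#: medians +0.11/-0.12 in pIT, +0.13/+0.17 in aIT, 43/8 changing pIT sites,
#: 21 response-matched images of which 13 are atypical).
DEFAULT_SYNTH_CONFIG: dict = {
    "n_trials": 10,
    "baseline_rate": 40.0,
    "time_ms": (-50, 250),
    "m2_latency_ms": 13,
    "amp_lognorm_sd": 0.25,
    "gain_noise_sd": 0.35,       # slow per-presentation excitability gain
    "fraction_nonvisual": 0.0,
    "template": {
        "rise_delay_ms": 3.0,     # sigmoid centre after response onset
        "rise_sd_ms": 3.0,
        "plateau": 0.80,          # sustained fraction of the peak transient
        "adapt_tau_ms": 120.0,
        "late_onset_delay_ms": 35.0,
        "late_rise_sd_ms": 6.0,
        "late_decay_tau_ms": 200.0,
        "off_delay_ms": 105.0,    # response offset after the 100 ms image
        "off_sd_ms": 10.0,
    },
    # duration of the late (error-like) selectivity transient; None keeps it
    # sustained until the response offset (the aIT preference persists)
    "late_duration_ms": {"pIT": 43.0, "cIT": 43.0, "aIT": None},
    # fraction of the 60-200 ms integrated class signal cancelled by the
    # post-error rebound in transient regions (1 = fully nulled)
    "decode_null_fraction": 0.75,
    "regions": {
        "pIT": {
            "n_sites": 115,
            "onset_ms": 57.0,
            "peak_rate": 320.0,
            "frac_m2": 72 / 115,
            "early_jitter": 0.6,
            "late_jitter": 1.2,
            "site_classes": {
                "decreasing": {"n": 43, "d_early": (0.22, 0.08), "d_late": (-0.55, 0.12)},
                "increasing": {"n": 8, "d_early": (-0.15, 0.08), "d_late": (0.55, 0.10)},
                "stable": {"n": 64, "d_early": (0.04, 0.12), "d_late_delta": (-0.08, 0.10)},
            },
        },
        "cIT": {
            "n_sites": 70,
            "onset_ms": 60.0,
            "peak_rate": 300.0,
            "frac_m2": 0.5,
            "early_jitter": 0.35,
            "late_jitter": 0.5,
            "site_classes": {
                "decreasing": {"n": 18, "d_early": (0.18, 0.08), "d_late": (-0.40, 0.12)},
                "increasing": {"n": 4, "d_early": (-0.08, 0.08), "d_late": (0.35, 0.10)},
                "stable": {"n": 48, "d_early": (0.06, 0.12), "d_late_delta": (-0.06, 0.10)},
            },
        },
        "aIT": {
            "n_sites": 40,
            "onset_ms": 63.0,
            "peak_rate": 280.0,
            "frac_m2": 0.5,
            "early_jitter": 0.7,
            "late_jitter": 0.6,
            "site_classes": {
                "stable": {"n": 40, "d_early": (0.13, 0.10), "d_late_delta": (0.04, 0.04)},
            },
        },
    },
    # shared image-level "face evidence" jitter (the prediction signal)
    "shared_evidence_jitter": 0.5,
    "matched": {
        "n_typical": 8,
        "n_atypical": 13,
        # early-response drive bands relative to the whole face (the
        # realized typical-atypical drive difference is absorbed into the
        # selectivity calibration)
        "typical_band": (1.02, 1.10),
        "atypical_band": (1.02, 1.10),
        "unmatched_range": (0.45, 0.70),
        "photo_drive_ratio": 0.5,
        "outline_drive_ratio": 0.1,
    },
    "screen": {
        "n_per_category": 10,
        "n_trials": 5,
        "category_drive": {
            "faces": (0.7, 1.3),
            "bodies": (0.35, 0.85),
            "objects": (0.35, 0.85),
            "places": (0.35, 0.85),
        },
    },
    # documentation of the population statistics the defaults are
    # calibrated to (checked by the test suite at Monte-Carlo tolerance)
    "calibration_targets": {
        "pIT": {"median_d_early": 0.11, "median_d_late": -0.12,
                "frac_typical_early": 0.66, "frac_typical_late": 0.34},
        "aIT": {"median_d_early": 0.13, "median_d_late": 0.17,
                "frac_typical_early": 0.78, "frac_typical_late": 0.78},
        "frac_decreasing_of_changing_pIT": 0.84,
        "rho_cIT_early_pIT_late": -0.52,
        "rho_aIT_early_pIT_late": -0.36,
        "delta_rate_typical_pct": -18.0,
        "delta_rate_atypical_pct": 2.0,
        "screen_median_dprime": 0.96,
        "n_matched": 21,
    },
}

EARLY = (60, 90)
LATE = (100, 130)
SELECT_WINDOW = (60, 100)
_WINDOW_S = 0.030


def _merge(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


# ---------------------------------------------------------------------------
# temporal kernels
# ---------------------------------------------------------------------------

def _off_gate(t: np.ndarray, onset: float, tpl: dict) -> np.ndarray:
    return 1.0 - ndtr((t - onset - tpl["off_delay_ms"]) / tpl["off_sd_ms"])


def _common_kernel(t: np.ndarray, onset: float, tpl: dict) -> np.ndarray:
    """Sigmoidal rise to an adapting plateau, off-gated, peak-normalized."""
    centre = onset + tpl["rise_delay_ms"]
    ramp = ndtr((t - centre) / tpl["rise_sd_ms"])
    adapt = tpl["plateau"] + (1 - tpl["plateau"]) * np.exp(
        -np.clip(t - centre, 0, None) / tpl["adapt_tau_ms"])
    kern = ramp * adapt * _off_gate(t, onset, tpl)
    peak = kern.max()
    return kern / peak if peak > 0 else kern


def _early_kernel(t: np.ndarray, onset: float, tpl: dict) -> np.ndarray:
    """Early-phase selectivity: rides the transient, gated off before the
    late window."""
    off = onset + tpl["late_onset_delay_ms"]
    return _common_kernel(t, onset, tpl) * (1.0 - ndtr((t - off) / tpl["late_rise_sd_ms"]))


def _late_kernel(t: np.ndarray, onset: float, tpl: dict,
                 duration: float | None = None) -> np.ndarray:
    """Late-phase selectivity: ramps in ~35 ms after response onset; a
    finite ``duration`` makes it a transient, otherwise it persists until
    the response offset."""
    on = onset + tpl["late_onset_delay_ms"]
    gate = ndtr((t - on) / tpl["late_rise_sd_ms"])
    decay = np.exp(-np.clip(t - on, 0, None) / tpl["late_decay_tau_ms"])
    if duration is not None:
        gate = gate * (1.0 - ndtr((t - on - duration) / 5.0))
    return gate * decay * _off_gate(t, onset, tpl)


def _rebound_kernel(t: np.ndarray, onset: float, tpl: dict,
                    duration: float) -> np.ndarray:
    """Recovery phase following a transient late error signal: the
    selectivity rebounds toward its pre-error sign before the response
    ends (only used for regions with a finite late duration)."""
    on = onset + tpl["late_onset_delay_ms"] + duration
    return ndtr((t - on) / 6.0) * _off_gate(t, onset, tpl)


def _window_mean(kern: np.ndarray, t: np.ndarray, window) -> float:
    mask = (t >= window[0]) & (t < window[1])
    return float(kern[mask].mean())


# ---------------------------------------------------------------------------
# site construction
# ---------------------------------------------------------------------------

@dataclass
class _SiteTemplate:
    site_id: str
    region: str
    animal: str
    amp: float
    d_early: float
    d_late: float
    site_class: str
    visual: bool


def _class_counts(classes: dict, n_sites: int) -> dict:
    counts = {name: spec["n"] for name, spec in classes.items()}
    total = sum(counts.values())
    if total == n_sites:
        return counts
    scaled = {k: int(round(v * n_sites / total)) for k, v in counts.items()}
    drift = n_sites - sum(scaled.values())
    largest = max(scaled, key=scaled.get)
    scaled[largest] += drift
    return scaled


def _draw_sites(config: dict, seed_seq: np.random.SeedSequence) -> list[_SiteTemplate]:
    rng = np.random.default_rng(seed_seq)
    sites: list[_SiteTemplate] = []
    for region, rc in config["regions"].items():
        n = rc["n_sites"]
        counts = _class_counts(rc["site_classes"], n)
        labels = [name for name, k in counts.items() for _ in range(k)]
        rng.shuffle(labels)
        n_m2 = int(round(rc["frac_m2"] * n))
        animals = np.array(["M2"] * n_m2 + ["M1"] * (n - n_m2))
        rng.shuffle(animals)
        nonvis = rng.random(n) < config["fraction_nonvisual"]
        for i in range(n):
            cls = rc["site_classes"][labels[i]]
            de = rng.normal(*cls["d_early"])
            if "d_late" in cls:
                dl = rng.normal(*cls["d_late"])
            else:
                dl = de + rng.normal(*cls["d_late_delta"])
            amp = rc["peak_rate"] * math.exp(rng.normal(0.0, config["amp_lognorm_sd"]))
            sites.append(
                _SiteTemplate(
                    site_id=f"{region}_{i:03d}",
                    region=region,
                    animal=str(animals[i]),
                    amp=amp,
                    d_early=de,
                    d_late=dl,
                    site_class=labels[i],
                    visual=not nonvis[i],
                )
            )
    return sites


def _trial_sigma(rate: float, gain_sd: float) -> float:
    """Trial s.d. of a 30 ms window mean: Poisson counting noise plus the
    slow multiplicative gain."""
    return math.sqrt(max(rate, 1.0) / _WINDOW_S + (gain_sd * rate) ** 2)


DECODE_WINDOW = (60, 200)


def _selectivity_amplitudes(site: _SiteTemplate, config: dict, t: np.ndarray,
                            onset: float, g_mean: float, dg_classes: float
                            ) -> tuple[float, float, float]:
    """Solve the kernel mix so the site's pooled-trial d' hits its targets
    under the noise model.

    ``dg_classes`` is the realized mean drive difference (typical minus
    atypical) of the matched images, whose common-mode contribution to the
    class contrast is absorbed here.  For regions whose late selectivity is
    a transient (pIT, cIT) a rebound kernel adds a third constraint: the
    class signal integrated over the 60-200 ms decode window is nulled, so
    the transient reversal carries no net long-window class information
    (which is what keeps linear decoding near chance there).
    """
    tpl = config["template"]
    b0 = config["baseline_rate"]
    gain_sd = config["gain_noise_sd"]
    duration = config["late_duration_ms"][site.region]
    alpha = _common_kernel(t, onset, tpl)
    psi_e = _early_kernel(t, onset, tpl)
    psi_l = _late_kernel(t, onset, tpl, duration)

    def drive_term(window):
        return site.amp * dg_classes * _window_mean(alpha, t, window)

    rc = config["regions"][site.region]
    # image-level variance of the selectivity factors within a class
    eta2 = config["shared_evidence_jitter"] ** 2
    var_f_early = rc["early_jitter"] ** 2 + (0.0 if site.region == "pIT" else eta2)
    var_f_late = rc["late_jitter"] ** 2 + eta2
    band = config["matched"]["typical_band"]
    sd_g = (band[1] - band[0]) / math.sqrt(12.0)

    psi_r = (_rebound_kernel(t, onset, tpl, duration)
             if duration is not None else np.zeros_like(alpha))
    M = np.array([[_window_mean(k, t, w) for k in (psi_e, psi_l)]
                  for w in (EARLY, LATE)])

    # class factors are 1 vs 0, so the required selectivity step per window
    # is d * sigma minus the drive common-mode difference; sigma includes the
    # between-image variance implied by the current solution, so iterate
    E = L = R = 0.0
    for _ in range(3):
        targets = []
        for w, d in zip((EARLY, LATE), (site.d_early, site.d_late)):
            abar = _window_mean(alpha, t, w)
            rate = b0 + site.amp * g_mean * abar
            e_term = E * _window_mean(psi_e, t, w)
            l_term = L * _window_mean(psi_l, t, w) + R * _window_mean(psi_r, t, w)
            var_images = (site.amp * sd_g * abar) ** 2 \
                + var_f_early * e_term ** 2 + var_f_late * l_term ** 2
            sigma = math.sqrt(_trial_sigma(rate, gain_sd) ** 2 + var_images)
            targets.append(d * sigma - drive_term(w))
        E, L = np.linalg.solve(M, np.array(targets))
        if duration is not None:
            # a post-error rebound cancels part of the long-window class
            # signal, keeping linear decoding near chance in this region
            net = (E * _window_mean(psi_e, t, DECODE_WINDOW)
                   + L * _window_mean(psi_l, t, DECODE_WINDOW)
                   + drive_term(DECODE_WINDOW))
            R = -config["decode_null_fraction"] * net \
                / _window_mean(psi_r, t, DECODE_WINDOW)
    return float(E), float(L), float(R)


# ---------------------------------------------------------------------------
# population generator
# ---------------------------------------------------------------------------

def generate_population(config: dict | None = None, seed: int = 0) -> PopulationDataset:
    """Generate the main 82-image population dataset (see module docstring).

    Identical ``config`` and ``seed`` give a byte-identical dataset.
    """
    cfg = _merge(DEFAULT_SYNTH_CONFIG, config)
    _validate(cfg)
    root = np.random.SeedSequence(seed)
    site_seq, image_seq, trial_seq = root.spawn(3)

    manifest = build_screen_image_set()
    sites = _draw_sites(cfg, site_seq)
    t0, t1 = cfg["time_ms"]
    t = np.arange(t0, t1)

    # --- matched set --------------------------------------------------------
    mc = cfg["matched"]
    reference = next(i.image_id for i in manifest if "whole_face_synth" in i.subset_tags)
    typical_ids = [i.image_id for i in manifest if i.typicality == "typical"]
    atypical_ids = [i.image_id for i in manifest if i.typicality == "atypical"]
    matched_typ = [reference] + [i for i in typical_ids if i != reference][: mc["n_typical"] - 1]
    matched_atyp = atypical_ids[: mc["n_atypical"]]

    # --- image-level selectivity factors, centred within matched classes ----
    img_rng = np.random.default_rng(image_seq)
    ids = [img.image_id for img in manifest]
    cls01 = {i.image_id: 1.0 if i.typicality == "typical" else 0.0 for i in manifest}
    eta = {i: img_rng.normal(0.0, cfg["shared_evidence_jitter"]) for i in ids}

    def centred(raw: dict) -> dict:
        out = dict(raw)
        for group in (matched_typ, matched_atyp):
            mean = np.mean([raw[i] for i in group])
            for i in group:
                out[i] = raw[i] - mean
        return out

    eta_c = centred(eta)
    f_early, f_late = {}, {}
    for region, rc in cfg["regions"].items():
        zeta = centred({i: img_rng.normal(0.0, rc["early_jitter"]) for i in ids})
        xi = centred({i: img_rng.normal(0.0, rc["late_jitter"]) for i in ids})
        if region == "pIT":
            f_early[region] = {i: cls01[i] + zeta[i] for i in ids}
        else:
            f_early[region] = {i: cls01[i] + eta_c[i] + zeta[i] for i in ids}
        f_late[region] = {i: cls01[i] + eta_c[i] + xi[i] for i in ids}

    # --- per-image drives ----------------------------------------------------
    drives = {}
    for img in manifest:
        i = img.image_id
        if i == reference:
            drives[i] = 1.0
        elif i in matched_typ:
            drives[i] = img_rng.uniform(*mc["typical_band"])
        elif i in matched_atyp:
            drives[i] = img_rng.uniform(*mc["atypical_band"])
        elif "whole_face_original" in img.subset_tags:
            drives[i] = mc["photo_drive_ratio"]
        elif "outline_only" in img.subset_tags:
            drives[i] = mc["outline_drive_ratio"]
        else:
            drives[i] = img_rng.uniform(*mc["unmatched_range"])
    g_typ = float(np.mean([drives[i] for i in matched_typ]))
    g_atyp = float(np.mean([drives[i] for i in matched_atyp]))
    g_mean = 0.5 * (g_typ + g_atyp)
    dg_classes = g_typ - g_atyp

    # --- per-site trials ------------------------------------------------------
    n_trials = cfg["n_trials"]
    b0 = cfg["baseline_rate"]
    gain_sd = cfg["gain_noise_sd"]
    tpl = cfg["template"]
    out_sites = []
    trial_children = trial_seq.spawn(len(sites))
    for site, child in zip(sites, trial_children):
        rc = cfg["regions"][site.region]
        onset = rc["onset_ms"] + (cfg["m2_latency_ms"] if site.animal == "M2" else 0)
        duration = cfg["late_duration_ms"][site.region]
        alpha = _common_kernel(t, onset, tpl)
        psi_e = _early_kernel(t, onset, tpl)
        psi_l = _late_kernel(t, onset, tpl, duration)
        psi_r = (_rebound_kernel(t, onset, tpl, duration)
                 if duration is not None else np.zeros_like(alpha))
        # d' calibration uses latency-corrected (M1-aligned) window positions
        E, L, R = _selectivity_amplitudes(site, cfg, t, rc["onset_ms"], g_mean, dg_classes)
        if not site.visual:
            amp, E_s, L_s, R_s = 0.0, 0.0, 0.0, 0.0
        else:
            amp, E_s, L_s, R_s = site.amp, E, L, R
        rng = np.random.default_rng(child)
        trials = {}
        for i in ids:
            template = (
                b0
                + amp * drives[i] * alpha
                + E_s * psi_e * f_early[site.region][i]
                + (L_s * psi_l + R_s * psi_r) * f_late[site.region][i]
            )
            gains = np.clip(rng.normal(1.0, gain_sd, size=(n_trials, 1)), 0.05, None)
            lam = np.clip(template[None, :] * gains, 0.0, None) * 1e-3
            counts = rng.poisson(lam)
            trials[i] = (counts * 1e3).astype(np.float32)
        out_sites.append(
            SiteRecording(
                site_id=site.site_id,
                region=site.region,
                animal=site.animal,
                time_ms=t.copy(),
                trials=trials,
                meta={
                    "site_class": site.site_class,
                    "d_early_target": site.d_early,
                    "d_late_target": site.d_late,
                    "amp": site.amp,
                    "E": E_s,
                    "L": L_s,
                    "visual": site.visual,
                },
            )
        )

    return PopulationDataset(
        sites=out_sites,
        manifest=manifest,
        generator_seed=seed,
        meta={
            "reference_image": reference,
            "matched_typical": matched_typ,
            "matched_atypical": matched_atyp,
            "drives": drives,
            "calibration_targets": cfg["calibration_targets"],
        },
    )


def generate_screen_responses(config: dict | None = None, seed: int = 0) -> PopulationDataset:
    """Responses of the same sites to the 40-image general screen set
    (default 5 repetitions), used for the visual-drive and face-selectivity
    screens.  Site identities and amplitudes match ``generate_population``
    for the same config and seed."""
    cfg = _merge(DEFAULT_SYNTH_CONFIG, config)
    _validate(cfg)
    root = np.random.SeedSequence(seed)
    site_seq = root.spawn(3)[0]

    sc = cfg["screen"]
    manifest = build_screen_set(sc["n_per_category"])
    sites = _draw_sites(cfg, site_seq)
    t0, t1 = cfg["time_ms"]
    t = np.arange(t0, t1)
    tpl = cfg["template"]
    b0 = cfg["baseline_rate"]
    gain_sd = cfg["gain_noise_sd"]

    screen_root = np.random.SeedSequence((seed, 1))
    exemplar_seq, *children = screen_root.spawn(len(sites) + 1)
    rng = np.random.default_rng(exemplar_seq)
    exemplar = {
        img.image_id: rng.uniform(*sc["category_drive"][img.category]) for img in manifest
    }
    out_sites = []
    for site, child in zip(sites, children):
        rc = cfg["regions"][site.region]
        onset = rc["onset_ms"] + (cfg["m2_latency_ms"] if site.animal == "M2" else 0)
        alpha = _common_kernel(t, onset, tpl)
        amp = site.amp if site.visual else 0.0
        srng = np.random.default_rng(child)
        trials = {}
        for img in manifest:
            template = b0 + amp * exemplar[img.image_id] * alpha
            gains = np.clip(srng.normal(1.0, gain_sd, size=(sc["n_trials"], 1)), 0.05, None)
            counts = srng.poisson(np.clip(template[None, :] * gains, 0.0, None) * 1e-3)
            trials[img.image_id] = (counts * 1e3).astype(np.float32)
        out_sites.append(
            SiteRecording(
                site_id=site.site_id,
                region=site.region,
                animal=site.animal,
                time_ms=t.copy(),
                trials=trials,
                meta={"visual": site.visual},
            )
        )
    return PopulationDataset(sites=out_sites, manifest=manifest, generator_seed=seed)


def generate_from_model(
    model_spec: ModelSpec,
    model_params: ModelParams,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid=(50.0, 200.0),
    dt: float = 0.5,
) -> FitTarget:
    """Region common/differential profiles simulated from a model, plus
    additive Gaussian noise — the parameter-recovery harness.  The ground
    truth is stored in the target's ``meta``."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    trace = simulate(model_spec, model_params, dt=dt)
    time = np.arange(grid[0], grid[1] + 0.5, 1.0)
    idx = np.rint((time - trace.time[0]) / dt).astype(int)
    signals = {r: s[:, idx] for r, s in readout(trace).items()}
    rng = np.random.default_rng(seed)
    noisy = {r: s + rng.normal(0.0, noise_sd, size=s.shape) if noise_sd else s
             for r, s in signals.items()}
    target = target_from_signals(time, noisy)
    target.meta = {
        "true_params": {n: v for n, v in zip(model_spec.param_names(),
                                             model_params.to_vector(model_spec))},
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return target


def _validate(cfg: dict) -> None:
    if cfg["n_trials"] < 1:
        raise ValueError("n_trials must be >= 1")
    if cfg["gain_noise_sd"] < 0:
        raise ValueError("gain_noise_sd must be nonnegative")
    for region, rc in cfg["regions"].items():
        if region not in ("pIT", "cIT", "aIT"):
            raise ValueError(f"unknown region {region!r}")
        if rc["n_sites"] < 1:
            raise ValueError(f"{region}: n_sites must be positive")
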