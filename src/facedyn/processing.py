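"""Raw traces -> analysis-ready windowed rates.

Order of operations in the pipeline: latency correction (single global 13 ms
shift aligning monkey M2 to M1) first, then per-image baseline subtraction
(25-50 ms post-onset window, averaged across repetitions), then windowing,
screening and image matching.  All analysis windows are half-open
``[start, end)`` in milliseconds relative to image onset.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PopulationDataset, SiteRecording
from .stimuli import ScreenImage, SCREEN_CATEGORIES

BASELINE_WINDOW = (25, 50)
EARLY_WINDOW = (60, 90)
LATE_WINDOW = (100, 130)
DRIVE_WINDOW = (60, 160)
MATCH_WINDOW = (60, 100)

#: monkey 2's visual latencies run 13 ms slower than monkey 1's
M2_LATENCY_MS = 13


class DataError(ValueError):
    """Input data does not satisfy an operation's requirements."""


# ---------------------------------------------------------------------------
# baseline subtraction and latency correction
# ---------------------------------------------------------------------------

def baseline_subtract(site: SiteRecording) -> SiteRecording:
    """Subtract each image's across-repetition mean rate in the 25-50 ms
    post-onset window from all that image's trials.  Output may be negative.
    """
    try:
        sl = site.bin_slice(BASELINE_WINDOW)
    except ValueError as err:
        raise DataError(f"site {site.site_id}: {err}") from None
    trials = {}
    for image_id, arr in site.trials.items():
        baseline = arr[:, sl].mean()
        trials[image_id] = arr - baseline
    return SiteRecording(
        site_id=site.site_id,
        region=site.region,
        animal=site.animal,
        time_ms=site.time_ms.copy(),
        trials=trials,
        meta=dict(site.meta),
    )


def baseline_subtract_dataset(dataset: PopulationDataset) -> PopulationDataset:
    out = copy.copy(dataset)
    out.sites = [baseline_subtract(s) for s in dataset.sites]
    out.baseline_subtracted = True
    return out


def latency_correct(dataset: PopulationDataset, shift_ms: int = M2_LATENCY_MS) -> PopulationDataset:
    """Shift all monkey-M2 traces earlier by ``shift_ms`` (default 13 ms) so
    both animals share a common latency axis; M1 traces are unchanged.

    The returned dataset is flagged ``latency_corrected``; correcting twice
    raises, as the shift is a single absolute adjustment.
    """
    if dataset.latency_corrected:
        raise ValueError("dataset is already latency corrected")
    shift = int(shift_ms)
    sites = []
    for site in dataset.sites:
        if site.animal != "M2" or shift == 0:
            sites.append(site)
            continue
        trials = {}
        for image_id, arr in site.trials.items():
            shifted = np.empty_like(arr)
            shifted[:, :-shift] = arr[:, shift:]
            # pad the vacated tail with the final sample (edge hold)
            shifted[:, -shift:] = arr[:, -1:]
            trials[image_id] = shifted
        sites.append(
            SiteRecording(
                site_id=site.site_id,
                region=site.region,
                animal=site.animal,
                time_ms=site.time_ms.copy(),
                trials=trials,
                meta=dict(site.meta),
            )
        )
    out = copy.copy(dataset)
    out.sites = sites
    out.latency_corrected = True
    return out


# ---------------------------------------------------------------------------
# windowed rates
# ---------------------------------------------------------------------------

def windowed_rate(site: SiteRecording, image_id: str, window) -> tuple[float, np.ndarray]:
    """Mean rate of one image in a half-open window.

    Returns ``(across-trial mean, per-trial means)`` in spikes/s.
    """
    sl = site.bin_slice(window)
    per_trial = site.trials[image_id][:, sl].mean(axis=1)
    return float(per_trial.mean()), per_trial


def class_trial_rates(site: SiteRecording, image_ids, window) -> np.ndarray:
    """Per-trial window-mean rates pooled over all presentations of all
    images in a class (the pooling used by the d' statistic)."""
    sl = site.bin_slice(window)
    return np.concatenate([site.trials[i][:, sl].mean(axis=1) for i in image_ids])


# ---------------------------------------------------------------------------
# screens and image matching
# ---------------------------------------------------------------------------

def visual_drive_screen(site: SiteRecording, screen_manifest, window=DRIVE_WINDOW) -> bool:
    """True iff any screen category's mean baseline-subtracted response in
    the 60-160 ms window exceeds 2x the SEM over that category's trials.

    ``screen_manifest`` must be the 40-image screen set with category labels;
    the site is expected to be baseline subtracted already.
    """
    by_cat: dict[str, list] = {}
    for img in screen_manifest:
        if not isinstance(img, ScreenImage):
            raise DataError("visual-drive screen needs a category-labelled screen manifest")
        if img.image_id in site.trials:
            by_cat.setdefault(img.category, []).append(img.image_id)
    if set(by_cat) != set(SCREEN_CATEGORIES):
        raise DataError(
            f"site {site.site_id}: screen responses missing categories "
            f"{sorted(set(SCREEN_CATEGORIES) - set(by_cat))}"
        )
    for ids in by_cat.values():
        rates = class_trial_rates(site, ids, window)
        sem = rates.std(ddof=1) / np.sqrt(rates.size)
        if rates.mean() > 2.0 * sem:
            return True
    return False


def population_mean_rate(sites, image_id: str, window) -> float:
    """Across-site mean of per-site mean windowed rates for one image."""
    return float(np.mean([windowed_rate(s, image_id, window)[0] for s in sites]))


def select_matched_images(
    population,
    reference_image: str,
    threshold: float = 0.9,
    window=MATCH_WINDOW,
) -> list[str]:
    """Images whose early population response reaches ``threshold`` x the
    response to the reference (whole-face) image.

    ``population`` is a list of sites (typically the pIT sample).  The
    reference image always qualifies.
    """
    sites = list(population)
    if not sites or reference_image not in sites[0].trials:
        raise DataError(f"reference image {reference_image!r} absent from population")
    ref = population_mean_rate(sites, reference_image, window)
    out = []
    for image_id in sites[0].image_ids:
        if population_mean_rate(sites, image_id, window) >= threshold * ref:
            out.append(image_id)
    return out


@dataclass
class MatchedImages:
    """Per-site response-matched image lists, or a rejection."""

    site_id: str
    typical: list
    atypical: list
    accepted: bool


def per_site_matched_images(
    site: SiteRecording,
    manifest,
    reference_image: str,
    band=(0.75, 1.25),
    min_per_class: int = 5,
    window=MATCH_WINDOW,
) -> MatchedImages:
    """Per-site selection: images whose early response lies within ``band``
    (default 0.75x-1.25x) of the site's response to the complete face.

    The site is rejected when fewer than ``min_per_class`` typical or
    atypical images fall inside the band.
    """
    typicality = {img.image_id: img.typicality for img in manifest}
    ref, _ = windowed_rate(site, reference_image, window)
    lo, hi = band
    typical, atypical = [], []
    for image_id in site.image_ids:
        cls = typicality.get(image_id)
        if cls not in ("typical", "atypical"):
            continue
        rate, _ = windowed_rate(site, image_id, window)
        if lo * ref <= rate <= hi * ref:
            (typical if cls == "typical" else atypical).append(image_id)
    accepted = len(typical) >= min_per_class and len(atypical) >= min_per_class
    return MatchedImages(site.site_id, typical, atypical, accepted)


def qc_table(dataset: PopulationDataset, screen_pass: dict, matched: dict) -> pd.DataFrame:
    """Per-site QC table: screen outcome and matched-image counts."""
    rows = []
    for site in dataset.sites:
        m = matched.get(site.site_id)
        rows.append(
            {
                "site_id": site.site_id,
                "region": site.region,
                "passed_screen": bool(screen_pass.get(site.site_id, False)),
                "n_matched_typical": len(m.typical) if m else 0,
                "n_matched_atypical": len(m.atypical) if m else 0,
            }
        )
    return pd.DataFrame(rows)
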