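"""d' selectivity dynamics: the core results machinery.

The discriminability index

    d' = (mean_1 - mean_2) / sqrt((var_1 + var_2) / 2)

is computed over *all* trials of all images in each class (so the variance
includes between-image as well as trial-to-trial variability).  Positive d'
means a preference for the first class; by convention the typical face-part
configurations are passed first.

Early/late dynamics use 30 ms half-open windows at 60-90 and 100-130 ms
post-onset.  A site's change in selectivity is assessed by a trial-level
bootstrap of d'_late - d'_early (resampling trials with replacement within
each image), with a two-sided p-value at resolution 1/n_boot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .processing import EARLY_WINDOW, LATE_WINDOW, class_trial_rates, windowed_rate

ALPHA_CHANGE = 0.01
N_BOOT = 1000


class DegenerateVarianceError(ValueError):
    """Zero pooled variance: d' is undefined."""


def dprime(group_a, group_b) -> float:
    """d' between two pools of per-trial rates (group A minus group B)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 trials per group")
    pooled = 0.5 * (a.var(ddof=1) + b.var(ddof=1))
    if pooled <= 0:
        raise DegenerateVarianceError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


@dataclass
class SelectivityResult:
    site_id: str
    region: str
    d_early: float
    d_late: float
    change_class: str = "no_change"          # increased / decreased / no_change
    p_change: float = float("nan")
    class_labels: tuple = ("typical", "atypical")
    degenerate: bool = False
    meta: dict = field(default_factory=dict)


def early_late_selectivity(
    site,
    typical_images,
    atypical_images,
    early=EARLY_WINDOW,
    late=LATE_WINDOW,
) -> SelectivityResult:
    """d' (typical vs atypical) in the early and late analysis windows,
    pooling every presentation of every image in each class."""
    if not typical_images or not atypical_images:
        raise ValueError("both image lists must be nonempty")
    d_early = dprime(
        class_trial_rates(site, typical_images, early),
        class_trial_rates(site, atypical_images, early),
    )
    d_late = dprime(
        class_trial_rates(site, typical_images, late),
        class_trial_rates(site, atypical_images, late),
    )
    return SelectivityResult(site.site_id, site.region, d_early, d_late)


def _window_rates_per_image(site, image_ids, window):
    sl = site.bin_slice(window)
    return [site.trials[i][:, sl].mean(axis=1) for i in image_ids]


def _pooled_dprime(rates_t, rates_a):
    t = np.concatenate(rates_t, axis=-1)
    a = np.concatenate(rates_a, axis=-1)
    mt, ma = t.mean(axis=-1), a.mean(axis=-1)
    vt, va = t.var(axis=-1, ddof=1), a.var(axis=-1, ddof=1)
    pooled = 0.5 * (vt + va)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (mt - ma) / np.sqrt(pooled)


def classify_change(
    site,
    typical_images,
    atypical_images,
    alpha: float = ALPHA_CHANGE,
    n_boot: int = N_BOOT,
    seed: int = 0,
    early=EARLY_WINDOW,
    late=LATE_WINDOW,
) -> SelectivityResult:
    """Classify a site's early-to-late change in d' by trial bootstrap.

    Trials are resampled with replacement within each image (jointly for the
    two windows, so within-trial structure is preserved), the difference
    d'_late - d'_early is recomputed ``n_boot`` times, and the two-sided
    bootstrap p-value is taken from the distribution's tail at zero.  The
    change class is the sign of the observed difference when p < alpha.
    """
    rng = np.random.default_rng(seed)
    res = early_late_selectivity(site, typical_images, atypical_images, early, late)
    if not (np.isfinite(res.d_early) and np.isfinite(res.d_late)):
        res.degenerate = True
        return res

    boot = {"early": {"t": [], "a": []}, "late": {"t": [], "a": []}}
    for cls, images in (("t", typical_images), ("a", atypical_images)):
        early_rates = _window_rates_per_image(site, images, early)
        late_rates = _window_rates_per_image(site, images, late)
        for e_r, l_r in zip(early_rates, late_rates):
            n = e_r.size
            idx = rng.integers(0, n, size=(n_boot, n))
            boot["early"][cls].append(e_r[idx])
            boot["late"][cls].append(l_r[idx])

    d_early_b = _pooled_dprime(boot["early"]["t"], boot["early"]["a"])
    d_late_b = _pooled_dprime(boot["late"]["t"], boot["late"]["a"])
    delta = d_late_b - d_early_b
    finite = delta[np.isfinite(delta)]
    if finite.size < n_boot // 2:
        res.degenerate = True
        return res
    p_hi = np.mean(finite >= 0)
    p_lo = np.mean(finite <= 0)
    # two-sided bootstrap p at resolution 1/n_boot; the floor reports 0.0
    p = float(min(1.0, 2.0 * min(p_hi, p_lo)))
    res.p_change = p
    observed = res.d_late - res.d_early
    if p < alpha and observed != 0:
        res.change_class = "decreased" if observed < 0 else "increased"
    return res


@dataclass
class PopulationSummary:
    region: str
    window_name: str
    n_sites: int
    fraction_prefer_typical: float
    fraction_se: float
    median_dprime: float
    median_se: float


def population_summary(
    results,
    window: str,
    n_boot: int = N_BOOT,
    seed: int = 0,
) -> PopulationSummary:
    """Fraction of sites preferring the typical class and the median d' in
    one window ('early' or 'late'), with site-level bootstrap SEs."""
    results = list(results)
    if not results:
        raise ValueError("need at least one selectivity result")
    if window not in ("early", "late"):
        raise ValueError("window must be 'early' or 'late'")
    d = np.array([r.d_early if window == "early" else r.d_late for r in results])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    boots = d[idx]
    region = results[0].region if len({r.region for r in results}) == 1 else "mixed"
    return PopulationSummary(
        region=region,
        window_name=window,
        n_sites=d.size,
        fraction_prefer_typical=float(np.mean(d > 0)),
        fraction_se=float(np.mean(boots > 0, axis=1).std(ddof=1)),
        median_dprime=float(np.median(d)),
        median_se=float(np.median(boots, axis=1).std(ddof=1)),
    )


def binomial_sign_test(k_decreasing: int, n_changing: int) -> float:
    """Exact one-sided binomial tail P(X >= k | n, p = 1/2)."""
    if not 0 <= k_decreasing <= n_changing:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binom.sf(k_decreasing - 1, n_changing, 0.5))


@dataclass
class CrossAreaCorrelation:
    rho: float
    se: float
    p_value: float
    n_images: int


def cross_area_correlation(
    pop_a,
    window_a,
    pop_b,
    window_b,
    image_ids,
    n_boot: int = N_BOOT,
    seed: int = 0,
) -> CrossAreaCorrelation:
    """Spearman rank correlation, across images, between two populations'
    mean windowed rates (e.g. cIT early vs pIT late).

    SE and the two-sided p-value come from a joint bootstrap over images and
    sites (resolution 1/n_boot).
    """
    image_ids = list(image_ids)
    if len(image_ids) < 5:
        raise ValueError("need at least 5 images")
    rng = np.random.default_rng(seed)

    def site_by_image(pop, window):
        return np.array([
            [windowed_rate(s, i, window)[0] for i in image_ids] for s in pop
        ])

    mat_a = site_by_image(pop_a, window_a)
    mat_b = site_by_image(pop_b, window_b)
    rho = float(stats.spearmanr(mat_a.mean(axis=0), mat_b.mean(axis=0)).statistic)

    n_img = len(image_ids)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        img_idx = rng.integers(0, n_img, size=n_img)
        a = mat_a[rng.integers(0, mat_a.shape[0], size=mat_a.shape[0])][:, img_idx]
        bb = mat_b[rng.integers(0, mat_b.shape[0], size=mat_b.shape[0])][:, img_idx]
        boots[b] = stats.spearmanr(a.mean(axis=0), bb.mean(axis=0)).statistic
    boots = boots[np.isfinite(boots)]
    # two-sided bootstrap p for rho != 0
    p = float(min(1.0, 2.0 * min(np.mean(boots <= 0), np.mean(boots >= 0))))
    return CrossAreaCorrelation(rho=rho, se=float(boots.std(ddof=1)), p_value=p,
                                n_images=n_img)


def results_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "region": r.region,
                "d_early": r.d_early,
                "d_late": r.d_late,
                "change_class": r.change_class,
                "p_change": r.p_change,
            }
            for r in results
        ]
    )
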