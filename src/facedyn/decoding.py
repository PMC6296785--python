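"""Linear population decoding of image classes from windowed rates.

Serially recorded sites are combined into pseudo-populations: for each
resample a random subset of sites is drawn, each site's trials are shuffled
within image, and pseudo-trials are formed by aligning trial positions.
Trials are split 90/10 within each image so every image appears in both
training and test sets but on held-out trials.  The decoder is a linear
maximum-margin classifier (linear SVM) with features z-scored using
training-fold statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .processing import DataError

DECODE_WINDOW = (60, 200)


@dataclass
class DecodeResult:
    region: str
    n_sites: int
    accuracy_mean: float
    accuracy_se: float
    n_resamples: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _rate_tensor(sites, image_ids, window):
    """(n_sites, n_images, n_trials) window-mean rates."""
    sl = sites[0].bin_slice(window)
    out = np.empty((len(sites), len(image_ids), sites[0].trials[image_ids[0]].shape[0]))
    for s_idx, site in enumerate(sites):
        for i_idx, image_id in enumerate(image_ids):
            out[s_idx, i_idx] = site.trials[image_id][:, sl].mean(axis=1)
    return out


def decode_population(
    dataset_or_sites,
    region: str | None,
    labels: dict,
    n_sites: int = 30,
    window=DECODE_WINDOW,
    train_frac: float = 0.9,
    n_resamples: int = 100,
    seed: int = 0,
    C: float = 1.0,
) -> DecodeResult:
    """Resampled linear-SVM decoding accuracy for a two-class image labelling.

    ``labels`` maps image_id -> class label (exactly two distinct labels).
    ``region`` selects sites when a dataset is passed; pass ``None`` with a
    plain site list.
    """
    if region is not None:
        sites = dataset_or_sites.region_sites(region)
    else:
        sites = list(dataset_or_sites)
        region = sites[0].region if sites else "NA"
    # canonical site order: results do not depend on input ordering
    sites = sorted(sites, key=lambda s: s.site_id)
    if len(sites) < n_sites:
        raise DataError(f"region {region}: {len(sites)} sites < n_sites={n_sites}")

    image_ids = [i for i in sites[0].image_ids if i in labels]
    classes = sorted({labels[i] for i in image_ids})
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    y_img = np.array([classes.index(labels[i]) for i in image_ids])

    tensor = _rate_tensor(sites, image_ids, window)
    n_total_sites, n_images, n_trials = tensor.shape
    if n_trials < 2:
        raise DataError("every image needs at least 2 trials")
    n_test = max(1, int(round((1.0 - train_frac) * n_trials)))

    rng = np.random.default_rng(seed)
    accs = np.empty(n_resamples)
    for r in range(n_resamples):
        site_idx = rng.choice(n_total_sites, size=n_sites, replace=False)
        sub = tensor[site_idx]
        # pseudo-trials: shuffle each site's trial order within every image
        shuffled = np.empty_like(sub)
        for s in range(n_sites):
            for i in range(n_images):
                shuffled[s, i] = sub[s, i, rng.permutation(n_trials)]
        # features (image, trial) x sites; stratified split by trial position
        X = shuffled.transpose(1, 2, 0)
        test_pos = rng.permutation(n_trials)[:n_test]
        test_mask = np.zeros(n_trials, dtype=bool)
        test_mask[test_pos] = True
        X_train = X[:, ~test_mask].reshape(-1, n_sites)
        X_test = X[:, test_mask].reshape(-1, n_sites)
        y_train = np.repeat(y_img, n_trials - n_test)
        y_test = np.repeat(y_img, n_test)
        clf = make_pipeline(StandardScaler(), LinearSVC(C=C))
        clf.fit(X_train, y_train)
        accs[r] = clf.score(X_test, y_test)

    return DecodeResult(
        region=region,
        n_sites=n_sites,
        accuracy_mean=float(accs.mean()),
        accuracy_se=float(accs.std(ddof=1) / np.sqrt(n_resamples)),
        n_resamples=n_resamples,
        seed=seed,
    )
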