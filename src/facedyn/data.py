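"""In-memory containers for multi-site recordings and HDF5 serialization.

A :class:`SiteRecording` holds one multi-unit site's per-trial firing-rate
traces (1 ms bins, spikes/s, aligned to image onset at t = 0).  A
:class:`PopulationDataset` bundles the sites with the stimulus manifest they
were tested on.  Datasets round-trip through HDF5 (one 3-D array per site)
plus a JSON-embedded manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from . import stimuli
from .stimuli import PartConfigImage, ScreenImage

REGIONS = ("pIT", "cIT", "aIT")
ANIMALS = ("M1", "M2")


@dataclass
class SiteRecording:
    site_id: str
    region: str
    animal: str
    time_ms: np.ndarray                      # (n_bins,), 1 ms spacing
    trials: dict                             # image_id -> (n_trials, n_bins) spikes/s
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.animal not in ANIMALS:
            raise ValueError(f"unknown animal {self.animal!r}")
        self.time_ms = np.asarray(self.time_ms)

    @property
    def image_ids(self) -> list:
        return list(self.trials)

    def bin_slice(self, window) -> slice:
        """Half-open [start, end) ms window -> slice into the time axis."""
        start, end = window
        if end <= start:
            raise ValueError("empty analysis window")
        t0 = int(self.time_ms[0])
        lo, hi = int(start) - t0, int(end) - t0
        if lo < 0 or hi > self.time_ms.size:
            raise ValueError(f"window {window} outside trace span")
        return slice(lo, hi)


@dataclass
class PopulationDataset:
    sites: list
    manifest: list
    generator_seed: int | None = None
    latency_corrected: bool = False
    baseline_subtracted: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = {img.image_id for img in self.manifest}
        for site in self.sites:
            missing = set(site.trials) - ids
            if missing:
                raise ValueError(
                    f"site {site.site_id} references images absent from the "
                    f"manifest: {sorted(missing)[:3]}..."
                )

    def region_sites(self, region: str) -> list:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return [s for s in self.sites if s.region == region]

    def image(self, image_id: str):
        for img in self.manifest:
            if img.image_id == image_id:
                return img
        raise KeyError(image_id)


# ---------------------------------------------------------------------------
# HDF5 serialization
# ---------------------------------------------------------------------------

def write_dataset(dataset: PopulationDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["generator_seed"] = -1 if dataset.generator_seed is None else dataset.generator_seed
        f.attrs["latency_corrected"] = dataset.latency_corrected
        f.attrs["baseline_subtracted"] = dataset.baseline_subtracted
        f.attrs["meta_json"] = json.dumps(dataset.meta, default=float)
        if dataset.manifest and isinstance(dataset.manifest[0], ScreenImage):
            f.attrs["manifest_kind"] = "screen"
            f.attrs["manifest_json"] = json.dumps(
                [{"image_id": i.image_id, "category": i.category} for i in dataset.manifest]
            )
        else:
            f.attrs["manifest_kind"] = "part_config"
            f.attrs["manifest_json"] = json.dumps(
                [stimuli._to_record(i) for i in dataset.manifest]
            )
        grp = f.create_group("sites")
        for site in dataset.sites:
            g = grp.create_group(site.site_id)
            image_ids = site.image_ids
            data = np.stack([site.trials[i] for i in image_ids]).astype(np.float32)
            g.create_dataset("trials", data=data, compression="gzip", compression_opts=1)
            g.create_dataset("time_ms", data=site.time_ms)
            g.attrs["region"] = site.region
            g.attrs["animal"] = site.animal
            g.attrs["image_ids"] = json.dumps(image_ids)
            g.attrs["meta"] = json.dumps(site.meta, default=float)


def read_dataset(path) -> PopulationDataset:
    with h5py.File(path, "r") as f:
        kind = f.attrs["manifest_kind"]
        records = json.loads(f.attrs["manifest_json"])
        if kind == "screen":
            manifest = [ScreenImage(**r) for r in records]
        else:
            manifest = [stimuli._from_record(r) for r in records]
        sites = []
        for sid in sorted(f["sites"], key=lambda s: (len(s), s)):
            g = f["sites"][sid]
            image_ids = json.loads(g.attrs["image_ids"])
            data = np.asarray(g["trials"])
            sites.append(
                SiteRecording(
                    site_id=sid,
                    region=str(g.attrs["region"]),
                    animal=str(g.attrs["animal"]),
                    time_ms=np.asarray(g["time_ms"]),
                    trials={img: data[k] for k, img in enumerate(image_ids)},
                    meta=json.loads(g.attrs["meta"]),
                )
            )
        seed = int(f.attrs["generator_seed"])
        return PopulationDataset(
            sites=sites,
            manifest=manifest,
            generator_seed=None if seed < 0 else seed,
            latency_corrected=bool(f.attrs["latency_corrected"]),
            baseline_subtracted=bool(f.attrs["baseline_subtracted"]),
            meta=json.loads(f.attrs.get("meta_json", "{}")),
        )


def site_table(dataset: PopulationDataset) -> pd.DataFrame:
    """Per-site summary table (CSV-friendly)."""
    rows = [
        {
            "site_id": s.site_id,
            "region": s.region,
            "animal": s.animal,
            "n_images": len(s.trials),
            "n_trials": next(iter(s.trials.values())).shape[0] if s.trials else 0,
        }
        for s in dataset.sites
    ]
    return pd.DataFrame(rows)
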