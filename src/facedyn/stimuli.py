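"""Combinatorial face-part stimulus design.

Stimuli are abstract descriptors: a face outline containing up to four face
parts (eyes, nose, mouth) placed on an evenly spaced 3x3 grid of positions
(cells 0-8, row-major).  An image is *typical* when every part it contains
sits at its canonical frontal-face position, *atypical* otherwise; the
original face photograph and the empty noise-filled outline are not
part-configuration images and are labelled ``non_config``.

Canonical frontal-face cells (row-major 3x3):

* left eye  -> cell 0
* right eye -> cell 2
* nose      -> cell 4 (centre)
* mouth     -> cell 7 (bottom centre)

The screening set of 82 images is built from the enumeration rules of the
experiment (single parts at all positions, a roving eye against each anchored
part, a roving nose/mouth against the contralateral eye, and faces with one
or two parts missing), deduplicating against previously enumerated images as
the rules are applied in order.
"""

from __future__ import annotations

import csv
import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "PartConfigImage",
    "ScreenImage",
    "CANONICAL_CELLS",
    "EYE_PARTS",
    "DEFAULT_RULES",
    "enumerate_candidate_space",
    "build_screen_image_set",
    "classify_typicality",
    "part_count_subset",
    "manifest_to_json",
    "manifest_from_json",
    "manifest_to_csv",
    "manifest_from_csv",
]

#: part identities; "eye" is the generic roving eye, side-specific identities
#: exist because the left and right eye of the source face are distinct parts.
PARTS = ("left_eye", "right_eye", "eye", "nose", "mouth")
EYE_PARTS = frozenset({"left_eye", "right_eye", "eye"})

#: canonical frontal-face cell(s) per part class
CANONICAL_CELLS = {"eye": frozenset({0, 2}), "nose": frozenset({4}), "mouth": frozenset({7})}

TYPICAL = "typical"
ATYPICAL = "atypical"
NON_CONFIG = "non_config"

SUBSET_TAGS = (
    "whole_face_original",
    "outline_only",
    "whole_face_synth",
    "one_part",
    "two_part_eye_roving",
    "two_part_nose_mouth_roving",
    "missing_parts",
    "permuted_T",
)


def _part_class(part: str) -> str:
    return "eye" if part in EYE_PARTS else part


@dataclass(frozen=True)
class PartConfigImage:
    """One abstract stimulus: parts on the 3x3 grid inside the face outline."""

    image_id: str
    grid_assignment: Mapping[int, str] = field(default_factory=dict)
    has_outline: bool = True
    size_deg: int = 6
    typicality: str = NON_CONFIG
    subset_tags: frozenset = frozenset()

    def __post_init__(self):
        grid = dict(self.grid_assignment)
        for cell, part in grid.items():
            if not (0 <= cell <= 8):
                raise ValueError(f"grid cell {cell} outside 0-8")
            if part not in PARTS:
                raise ValueError(f"unknown part {part!r}")
        if len(grid) > 4:
            raise ValueError("at most 4 parts per image")
        object.__setattr__(self, "grid_assignment", grid)
        object.__setattr__(self, "subset_tags", frozenset(self.subset_tags))

    @property
    def n_parts(self) -> int:
        return len(self.grid_assignment)

    def collapse_key(self):
        """Appearance key used for deduplication: eye identity is collapsed to
        a generic eye class, so e.g. ``left_eye@0 + eye@2`` and
        ``right_eye@2 + eye@0`` are the same two-eye image."""
        return (
            frozenset((c, _part_class(p)) for c, p in self.grid_assignment.items()),
            self.size_deg,
            self.has_outline,
            self.image_id if not self.grid_assignment else None,
        )


@dataclass(frozen=True)
class ScreenImage:
    """One image of the 40-image general screen set (faces / bodies / objects
    / places), used for the face-selectivity and visual-drive screens."""

    image_id: str
    category: str

    def __post_init__(self):
        if self.category not in SCREEN_CATEGORIES:
            raise ValueError(f"unknown screen category {self.category!r}")


SCREEN_CATEGORIES = ("faces", "bodies", "objects", "places")


def build_screen_set(n_per_category: int = 10) -> list[ScreenImage]:
    """The general screen set: ``n_per_category`` exemplars of each of the
    four categories (default 10, i.e. 40 images)."""
    return [
        ScreenImage(image_id=f"screen_{cat}_{i:02d}", category=cat)
        for cat in SCREEN_CATEGORIES
        for i in range(n_per_category)
    ]


# ---------------------------------------------------------------------------
# candidate space
# ---------------------------------------------------------------------------

#: per-cell alternatives in the full candidate space
_CELL_CHOICES = (None, "eye", "nose", "mouth")


def enumerate_candidate_space(n_cells: int = 9) -> tuple[int, Iterator[tuple]]:
    """Enumerate every assignment of {empty, eye, nose, mouth} to the grid.

    Returns ``(count, iterator)`` where ``count == 4 ** n_cells`` (262,144 for
    the full 9-cell grid) and the iterator yields each assignment as a tuple
    of per-cell entries (``None`` for empty).
    """
    if not 1 <= n_cells <= 9:
        raise ValueError("n_cells must be in 1..9")
    count = len(_CELL_CHOICES) ** n_cells
    return count, itertools.product(_CELL_CHOICES, repeat=n_cells)


# ---------------------------------------------------------------------------
# typicality
# ---------------------------------------------------------------------------

def classify_typicality(image: PartConfigImage) -> str:
    """Classify a part-configuration image as typical or atypical.

    Typical iff every present part occupies a canonical frontal-face cell
    (an eye at either eye cell counts).  Images without parts (photograph,
    empty outline) are not part configurations and return ``non_config``.
    """
    if image.n_parts == 0 or not image.has_outline:
        return NON_CONFIG
    for cell, part in image.grid_assignment.items():
        if cell not in CANONICAL_CELLS[_part_class(part)]:
            return ATYPICAL
    return TYPICAL


# ---------------------------------------------------------------------------
# screening-set construction
# ---------------------------------------------------------------------------

_CANONICAL_FACE = {0: "left_eye", 2: "right_eye", 4: "nose", 7: "mouth"}

#: The composition of the "one or two parts missing" subset is supplied
#: explicitly: the four 3-part faces (each canonical face part removed in
#: turn) and three 2-part canonical faces.  The paper's own counting of which
#: two-part faces were "already counted above" is not mechanically
#: recoverable, so the default manifest fixes the composition.
_DEFAULT_MISSING_PARTS = tuple(
    [
        {c: p for c, p in _CANONICAL_FACE.items() if c != drop}
        for drop in (0, 2, 4, 7)
    ]
    + [
        {0: "left_eye", 4: "nose"},
        {0: "left_eye", 7: "mouth"},
        {4: "nose", 7: "mouth"},
    ]
)

DEFAULT_RULES: dict = {
    "size_deg": 6,
    # anchors for the roving-eye two-part images: each part at its canonical
    # outline-centred position
    "eye_roving_anchors": (("left_eye", 0), ("right_eye", 2), ("nose", 4), ("mouth", 7)),
    # recordings were made in left hemispheres: the contralateral eye is the
    # right eye (configurable)
    "contralateral_eye": ("right_eye", 2),
    "missing_parts_manifest": _DEFAULT_MISSING_PARTS,
}

_KNOWN_RULES = {
    "whole_face_original",
    "outline_only",
    "whole_face_synth",
    "one_part",
    "two_part_eye_roving",
    "two_part_nose_mouth_roving",
    "missing_parts",
}


def _grid_id(grid: Mapping[int, str], size_deg: int) -> str:
    body = "-".join(f"{c}{_PART_CODES[grid[c]]}" for c in sorted(grid))
    return f"cfg{size_deg}:{body}"


_PART_CODES = {"left_eye": "le", "right_eye": "re", "eye": "ey", "nose": "no", "mouth": "mo"}
_CODE_PARTS = {v: k for k, v in _PART_CODES.items()}


def _make(grid: Mapping[int, str], tag: str, size_deg: int) -> PartConfigImage:
    img = PartConfigImage(
        image_id=_grid_id(grid, size_deg),
        grid_assignment=dict(grid),
        size_deg=size_deg,
        subset_tags=frozenset({tag}),
    )
    return replace(img, typicality=classify_typicality(img))


def build_screen_image_set(rules_config: Mapping | None = None) -> list[PartConfigImage]:
    """Build the 82-image screening set from the enumeration rules.

    Rules are applied in the experiment's order; an image whose appearance
    (collapsed eye identity) was already emitted by an earlier rule is
    dropped, which mechanically reproduces the printed subset counts
    27 / 31 / 14.  The missing-parts subset comes from an explicit manifest
    in the config (side-specific eye identities, so its entries are distinct
    grid assignments from the roving generic-eye images).
    """
    cfg = dict(DEFAULT_RULES)
    if rules_config:
        unknown = set(rules_config) - set(DEFAULT_RULES) - {"rules"}
        if unknown:
            raise ValueError(f"unknown rules-config keys: {sorted(unknown)}")
        cfg.update(rules_config)
        if "rules" in rules_config:
            bad = set(rules_config["rules"]) - _KNOWN_RULES
            if bad:
                raise ValueError(f"unknown enumeration rule(s): {sorted(bad)}")
    size = cfg["size_deg"]

    images: list[PartConfigImage] = []
    seen: set = set()

    def emit(img: PartConfigImage, *, dedup: bool = True) -> None:
        key = img.collapse_key()
        if dedup and key in seen:
            return
        seen.add(key)
        images.append(img)

    # 1-2. photograph of the original whole face and the noise-filled outline
    emit(PartConfigImage(image_id=f"whole_face_original_sz{size}", size_deg=size,
                         subset_tags={"whole_face_original"}))
    emit(PartConfigImage(image_id=f"outline_only_sz{size}", size_deg=size,
                         subset_tags={"outline_only"}))

    # 3. whole face synthesized from the four parts at canonical positions
    emit(_make(_CANONICAL_FACE, "whole_face_synth", size))

    # 4. all single-part images: eye, nose or mouth at each of the 9 cells
    for part in ("eye", "nose", "mouth"):
        for cell in range(9):
            emit(_make({cell: part}, "one_part", size))

    # 5. anchored part at its canonical position plus a roving eye at each of
    #    the remaining 8 cells (4*8 - 1 after dedup)
    for part, anchor in cfg["eye_roving_anchors"]:
        for cell in range(9):
            if cell == anchor:
                continue
            emit(_make({anchor: part, cell: "eye"}, "two_part_eye_roving", size))

    # 6. contralateral eye at its canonical position plus a roving nose or
    #    mouth at the remaining cells (2*8 - 2 after dedup)
    eye_part, eye_cell = cfg["contralateral_eye"]
    for part in ("nose", "mouth"):
        for cell in range(9):
            if cell == eye_cell:
                continue
            emit(_make({eye_cell: eye_part, cell: part}, "two_part_nose_mouth_roving", size))

    # 7. correctly configured faces with one or two parts missing (explicit
    #    manifest; distinct grid assignments from the generic-eye images)
    manifest_seen: set = set()
    for grid in cfg["missing_parts_manifest"]:
        img = _make(grid, "missing_parts", size)
        if img.collapse_key() in manifest_seen:
            continue
        manifest_seen.add(img.collapse_key())
        if img.image_id in {i.image_id for i in images}:
            continue
        emit(img, dedup=False)

    ids = [img.image_id for img in images]
    if len(set(ids)) != len(ids):  # pragma: no cover - construction guarantee
        raise RuntimeError("duplicate image ids in screening set")
    return images


def part_count_subset(images: Sequence[PartConfigImage], n_parts: int) -> list[PartConfigImage]:
    """Images whose part count equals ``n_parts`` (outline-only and the
    whole-face photograph are never part-count images)."""
    if not 0 <= n_parts <= 4:
        raise ValueError("n_parts must be in 0..4")
    return [img for img in images if img.grid_assignment and img.n_parts == n_parts]


# ---------------------------------------------------------------------------
# manifest serialization
# ---------------------------------------------------------------------------

def _to_record(img: PartConfigImage) -> dict:
    rec = {
        "image_id": img.image_id,
        "size_deg": img.size_deg,
        "typicality": img.typicality,
        "subset_tag": sorted(img.subset_tags)[0] if img.subset_tags else "",
        "has_outline": img.has_outline,
    }
    for c in range(9):
        rec[f"cell_{c}"] = img.grid_assignment.get(c, "")
    return rec


def _from_record(rec: Mapping) -> PartConfigImage:
    grid = {c: rec[f"cell_{c}"] for c in range(9) if rec.get(f"cell_{c}")}
    return PartConfigImage(
        image_id=rec["image_id"],
        grid_assignment=grid,
        has_outline=bool(rec.get("has_outline", True)),
        size_deg=int(rec["size_deg"]),
        typicality=rec["typicality"],
        subset_tags=frozenset({rec["subset_tag"]} if rec.get("subset_tag") else set()),
    )


def manifest_to_json(images: Iterable[PartConfigImage], path) -> None:
    with open(path, "w") as fh:
        json.dump([_to_record(i) for i in images], fh, indent=1)


def manifest_from_json(path) -> list[PartConfigImage]:
    with open(path) as fh:
        return [_from_record(rec) for rec in json.load(fh)]


def manifest_to_csv(images: Iterable[PartConfigImage], path) -> None:
    images = list(images)
    fields = list(_to_record(images[0]))
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for img in images:
            writer.writerow(_to_record(img))


def manifest_from_csv(path) -> list[PartConfigImage]:
    out = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rec = dict(rec)
            rec["has_outline"] = rec.get("has_outline", "True") in ("True", "true", "1")
            out.append(_from_record(rec))
    return out
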