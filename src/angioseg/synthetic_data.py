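"""Synthetic coronary angiogram-like image generator.

Real angiographic datasets of labelled coronary pathology are rarely public,
so this module synthesizes the study material: bright, tree-like vessel
structures on a darker noisy background, in four diagnostic classes —

* ``normal``        – an unmodified vessel tree,
* ``block``         – a contiguous occlusion gap rendered at background
                      intensity (total interruption of a segment),
* ``narrow``        – a local stenosis, i.e. the vessel radius inside a
                      short window is multiplied by ``stenosis_fraction``,
* ``flow_reduced``  – globally lowered vessel intensity, emulating reduced
                      contrast-agent inflow.

The tree is a recursive binary branching of straight segments with
per-generation radius decay.  Rasterization is a hard (non-anti-aliased)
per-pixel distance-to-segment test, so the ground-truth mask is unambiguous;
Gaussian blur and additive Gaussian noise are applied afterwards.  Every
generated byte is a deterministic function of the spec and its seed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi

__all__ = [
    "ClassLabel",
    "VesselTreeSpec",
    "Branch",
    "PathologyInfo",
    "GroundTruth",
    "ManifestRecord",
    "DatasetManifest",
    "build_tree",
    "apply_pathology",
    "render",
    "generate_vessel_tree",
    "generate_dataset",
]


class ClassLabel(enum.Enum):
    """The four diagnostic vessel classes, with a stable 0–3 encoding."""

    NORMAL = "normal"
    BLOCK = "block"
    NARROW = "narrow"
    FLOW_REDUCED = "flow_reduced"

    @property
    def code(self) -> int:
        return _LABEL_CODES[self]

    @classmethod
    def from_code(cls, code: int) -> "ClassLabel":
        for label, c in _LABEL_CODES.items():
            if c == int(code):
                return label
        raise ValueError(f"unknown class code {code!r}")

    @classmethod
    def coerce(cls, value) -> "ClassLabel":
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            try:
                return cls(value)
            except ValueError:
                raise ValueError(f"unknown class label {value!r}") from None
        if isinstance(value, (int, np.integer)):
            return cls.from_code(int(value))
        raise ValueError(f"unknown class label {value!r}")


_LABEL_CODES = {
    ClassLabel.NORMAL: 0,
    ClassLabel.BLOCK: 1,
    ClassLabel.NARROW: 2,
    ClassLabel.FLOW_REDUCED: 3,
}


@dataclass(frozen=True)
class VesselTreeSpec:
    """Parameters of one synthetic angiogram.

    Intensities live in [0, 1]; lengths and radii are in pixels.  The
    defaults describe a thin-vessel tree typical of an angiogram resized to
    128×128, with mild acquisition noise.
    """

    image_size: int = 128
    n_branches: int = 7
    branch_angle_spread: float = 35.0
    root_radius: float = 2.5
    radius_decay: float = 0.8
    vessel_intensity: float = 0.85
    background_intensity: float = 0.25
    noise_sigma: float = 0.02
    blur_sigma: float = 0.0
    pathology: ClassLabel = ClassLabel.NORMAL
    stenosis_fraction: float = 0.35
    stenosis_length: float = 24.0
    occlusion_gap: int = 12
    flow_intensity_factor: float = 0.5
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "pathology", ClassLabel.coerce(self.pathology))
        checks = [
            (self.image_size >= 8, "image_size", "must be >= 8"),
            (self.n_branches >= 0, "n_branches", "must be >= 0"),
            (self.root_radius >= 1, "root_radius", "must be >= 1"),
            (0 < self.radius_decay <= 1, "radius_decay", "must be in (0, 1]"),
            (0 <= self.background_intensity < self.vessel_intensity <= 1,
             "vessel_intensity", "must exceed background_intensity, both in [0, 1]"),
            (self.noise_sigma >= 0, "noise_sigma", "must be >= 0"),
            (self.blur_sigma >= 0, "blur_sigma", "must be >= 0"),
            (0 < self.stenosis_fraction < 1, "stenosis_fraction", "must be in (0, 1)"),
            (self.stenosis_length > 0, "stenosis_length", "must be > 0"),
            (self.occlusion_gap >= 1, "occlusion_gap", "must be >= 1"),
            (0 < self.flow_intensity_factor <= 1,
             "flow_intensity_factor", "must be in (0, 1]"),
        ]
        for ok, name, msg in checks:
            if not ok:
                raise ValueError(f"invalid VesselTreeSpec field {name!r}: {msg}")


@dataclass
class Branch:
    """One straight vessel segment, sampled at ~1 px spacing.

    ``points`` is an (N, 2) array of (row, col) centerline coordinates;
    ``radii`` and ``intensities`` carry per-point rendering parameters so
    pathologies can act on sub-windows.  ``parent`` is the index of the
    branch this one forks from (None for the root).
    """

    points: np.ndarray
    radii: np.ndarray
    intensities: np.ndarray
    generation: int = 0
    parent: int | None = None

    def copy(self) -> "Branch":
        return Branch(self.points.copy(), self.radii.copy(),
                      self.intensities.copy(), self.generation, self.parent)


@dataclass
class PathologyInfo:
    kind: ClassLabel
    branch_index: int | None = None
    start: int = 0
    stop: int = 0


@dataclass
class GroundTruth:
    """Mask, label and centerlines accompanying a generated image."""

    mask: np.ndarray
    label: ClassLabel
    centerlines: list = field(default_factory=list)
    pathology: PathologyInfo | None = None


@dataclass
class ManifestRecord:
    path: str
    label: ClassLabel
    split: str = ""


@dataclass
class DatasetManifest:
    records: list
    seed: int = 0

    def __post_init__(self):
        paths = [r.path for r in self.records]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest paths must be unique")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {"path": [r.path for r in self.records],
             "label": [r.label.value for r in self.records],
             "split": [r.split for r in self.records]}
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, seed: int = 0) -> "DatasetManifest":
        df = pd.read_csv(path, keep_default_na=False)
        records = [
            ManifestRecord(str(p), ClassLabel.coerce(l), str(s))
            for p, l, s in zip(df["path"], df["label"], df["split"])
        ]
        return cls(records=records, seed=seed)

    def by_split(self, split: str) -> list:
        return [r for r in self.records if r.split == split]


# ---------------------------------------------------------------------------
# tree construction


def build_tree(spec: VesselTreeSpec, rng: np.random.Generator) -> list:
    """Grow a binary branching tree of straight segments, breadth-first.

    The root enters from the left border; children fork at
    ``±branch_angle_spread`` (with mild jitter) and shrink by
    ``radius_decay`` per generation.  Jitter amplitudes are small on
    purpose: angiographic studies acquire standardized projections, so the
    same artery keeps a broadly consistent layout across patients while
    individual anatomy varies.  Polylines are truncated at the image
    border; branches fully outside the frame are dropped.
    """
    if spec.n_branches == 0:
        return []
    s = spec.image_size
    length0 = 0.30 * s
    root_start = np.array([0.50 * s, 0.06 * s])
    root_angle = rng.uniform(-4.0, 4.0)  # degrees, 0 = +col direction
    queue = [(root_start, root_angle, float(spec.root_radius), 0, length0,
              None)]
    branches: list = []
    while queue and len(branches) < spec.n_branches:
        start, angle, radius, gen, length, parent = queue.pop(0)
        length = length * rng.uniform(0.95, 1.05)
        n_pts = max(2, int(round(length)) + 1)
        theta = math.radians(angle)
        direction = np.array([math.sin(theta), math.cos(theta)])
        t = np.arange(n_pts, dtype=float)
        pts = start[None, :] + t[:, None] * direction[None, :]
        inside = ((pts[:, 0] >= 1.0) & (pts[:, 0] <= s - 2.0)
                  & (pts[:, 1] >= 1.0) & (pts[:, 1] <= s - 2.0))
        # keep the leading run of in-frame points
        stop = int(np.argmin(inside)) if not inside.all() else n_pts
        spread_a = spec.branch_angle_spread * rng.uniform(0.85, 1.15)
        spread_b = spec.branch_angle_spread * rng.uniform(0.85, 1.15)
        if stop >= 2:
            pts = pts[:stop]
            idx = len(branches)
            branches.append(Branch(
                points=pts,
                radii=np.full(len(pts), radius),
                intensities=np.full(len(pts), spec.vessel_intensity),
                generation=gen,
                parent=parent,
            ))
            end = pts[-1]
            child_r = radius * spec.radius_decay
            child_len = length * 0.75
            queue.append((end, angle - spread_a, child_r, gen + 1, child_len,
                          idx))
            queue.append((end, angle + spread_b, child_r, gen + 1, child_len,
                          idx))
    return branches


# ---------------------------------------------------------------------------
# pathology


def apply_pathology(branches: list, label, spec: VesselTreeSpec,
                    rng: np.random.Generator | None = None):
    """Modify a tree's rendering parameters according to the class label.

    Returns ``(branches, PathologyInfo)``; the input list is never mutated.

    ``block``: a contiguous centerline window of ``occlusion_gap`` points is
    rendered at background intensity, and — because an occlusion stops the
    contrast agent — the branch beyond the gap and its whole downstream
    subtree are not opacified (they are removed from both image and mask;
    the gap itself stays in the mask).  ``narrow``: the radius inside a
    ``stenosis_length`` window is multiplied by ``stenosis_fraction``.
    ``flow_reduced``: all vessel intensities are multiplied by
    ``flow_intensity_factor``.

    Occlusions and stenoses are placed on proximal branches (generation
    ≤ 1, the thick epicardial segments where such lesions are diagnosed),
    at a uniform-random eligible branch/position under ``rng``; the window
    is recorded so tests can locate it.
    """
    label = ClassLabel.coerce(label)
    if label is ClassLabel.NORMAL:
        return branches, PathologyInfo(kind=label)
    if not branches:
        raise ValueError("pathology requires a tree with at least one branch")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    out = [b.copy() for b in branches]
    if label is ClassLabel.FLOW_REDUCED:
        for b in out:
            b.intensities *= spec.flow_intensity_factor
        return out, PathologyInfo(kind=label)

    window = (spec.occlusion_gap if label is ClassLabel.BLOCK
              else int(round(spec.stenosis_length)))
    window = max(1, int(window))
    eligible = [i for i, b in enumerate(out)
                if b.generation <= 1 and len(b.points) >= window + 4]
    if not eligible:
        eligible = [i for i, b in enumerate(out)
                    if len(b.points) >= window + 4]
    if not eligible:  # fall back to the longest branch, shrink the window
        eligible = [int(np.argmax([len(b.points) for b in out]))]
        window = max(1, len(out[eligible[0]].points) - 4)
    idx = int(rng.choice(eligible))
    b = out[idx]
    start = int(rng.integers(2, len(b.points) - window - 1))
    stop = start + window
    if label is ClassLabel.NARROW:
        b.radii[start:stop] *= spec.stenosis_fraction
        return out, PathologyInfo(kind=label, branch_index=idx,
                                  start=start, stop=stop)

    # BLOCK: gap at background intensity, downstream not opacified
    b.points = b.points[:stop]
    b.radii = b.radii[:stop]
    b.intensities = b.intensities[:stop]
    b.intensities[start:stop] = spec.background_intensity
    drop: set = set()
    for j, br in enumerate(out):  # parents precede children (BFS order)
        if br.parent is not None and (br.parent == idx or br.parent in drop):
            drop.add(j)
    remap = {}
    kept = []
    for j, br in enumerate(out):
        if j in drop:
            continue
        remap[j] = len(kept)
        br.parent = remap.get(br.parent) if br.parent is not None else None
        kept.append(br)
    return kept, PathologyInfo(kind=label, branch_index=remap[idx],
                               start=start, stop=stop)


# ---------------------------------------------------------------------------
# rasterization


def _stamp_capsule(image, mask, p0, p1, radius, value):
    """Set pixels within ``radius`` of segment p0–p1 (exact distance test)."""
    h, w = image.shape
    r0 = max(0, int(math.floor(min(p0[0], p1[0]) - radius)) - 1)
    r1 = min(h - 1, int(math.ceil(max(p0[0], p1[0]) + radius)) + 1)
    c0 = max(0, int(math.floor(min(p0[1], p1[1]) - radius)) - 1)
    c1 = min(w - 1, int(math.ceil(max(p0[1], p1[1]) + radius)) + 1)
    if r1 < r0 or c1 < c0:
        return
    rows = np.arange(r0, r1 + 1, dtype=float)
    cols = np.arange(c0, c1 + 1, dtype=float)
    dr = rows[:, None] - p0[0]
    dc = cols[None, :] - p0[1]
    v = np.asarray(p1, dtype=float) - np.asarray(p0, dtype=float)
    vv = float(v @ v)
    if vv == 0.0:
        dist = np.hypot(dr, dc)
    else:
        t = np.clip((dr * v[0] + dc * v[1]) / vv, 0.0, 1.0)
        dist = np.hypot(dr - t * v[0], dc - t * v[1])
    sel = dist <= radius
    sub = image[r0:r1 + 1, c0:c1 + 1]
    np.maximum(sub, value, out=sub, where=sel)
    mask[r0:r1 + 1, c0:c1 + 1] |= sel


def render(branches: list, image_size: int,
           background_intensity: float = 0.0):
    """Rasterize a tree onto a flat background.

    Returns ``(image, mask)`` where the mask marks exactly the pixels whose
    center lies within the local radius of any centerline segment (including
    an occlusion gap, whose *intensity* alone is suppressed).  Overlapping
    branches combine by maximum intensity.
    """
    image = np.full((image_size, image_size), float(background_intensity))
    mask = np.zeros((image_size, image_size), dtype=bool)
    for b in branches:
        pts, radii, vals = b.points, b.radii, b.intensities
        for i in range(len(pts) - 1):
            r = max(float(radii[i]), float(radii[i + 1]))
            _stamp_capsule(image, mask, pts[i], pts[i + 1], r,
                           float(vals[i]))
    return image, mask


def generate_vessel_tree(spec: VesselTreeSpec):
    """Generate one synthetic angiogram and its ground truth.

    Deterministic: identical ``spec`` (including ``seed``) gives bitwise
    identical output.  Returns ``(image, GroundTruth)`` with the image in
    [0, 1] floats.
    """
    rng = np.random.default_rng(spec.seed)
    branches = build_tree(spec, rng)
    branches, patho = apply_pathology(branches, spec.pathology, spec, rng)
    image, mask = render(branches, spec.image_size, spec.background_intensity)
    if spec.blur_sigma > 0:
        image = ndi.gaussian_filter(image, spec.blur_sigma, mode="nearest")
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
    image = np.clip(image, 0.0, 1.0)
    truth = GroundTruth(
        mask=mask.astype(np.uint8),
        label=spec.pathology,
        centerlines=[b.points for b in branches],
        pathology=patho,
    )
    return image, truth


# ---------------------------------------------------------------------------
# dataset writer


def _write_png(path: Path, image: np.ndarray) -> None:
    arr = np.round(255.0 * np.clip(image, 0.0, 1.0)).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def generate_dataset(out_dir, n_per_class: int = 100, seed: int = 0,
                     image_size: int = 128,
                     base_spec: VesselTreeSpec | None = None) -> DatasetManifest:
    """Write a balanced four-class dataset of PNGs plus masks and a manifest.

    Layout: ``images/<label>/<label>_<i>.png``, ``masks/<label>/...`` and a
    ``manifest.csv`` with header ``path,label,split`` (splits left empty; see
    :func:`angioseg.classifier.split_dataset`).  The default ``n_per_class``
    of 100 yields 400 images.  Per-image seeds are derived from ``seed``
    via ``numpy.random.SeedSequence`` so the whole dataset is reproducible
    byte for byte.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    base = base_spec if base_spec is not None else VesselTreeSpec(image_size=image_size)
    records = []
    for label in ClassLabel:
        (out_dir / "images" / label.value).mkdir(parents=True, exist_ok=True)
        (out_dir / "masks" / label.value).mkdir(parents=True, exist_ok=True)
        for i in range(n_per_class):
            child = np.random.SeedSequence(
                entropy=seed, spawn_key=(label.code, i))
            img_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
            spec = replace(base, image_size=image_size, pathology=label,
                           seed=img_seed)
            image, truth = generate_vessel_tree(spec)
            rel = Path("images") / label.value / f"{label.value}_{i:03d}.png"
            _write_png(out_dir / rel, image)
            _write_png(out_dir / "masks" / label.value
                       / f"{label.value}_{i:03d}.png",
                       truth.mask.astype(float))
            records.append(ManifestRecord(path=str(rel), label=label))
    manifest = DatasetManifest(records=records, seed=seed)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest
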