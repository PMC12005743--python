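"""Procedural generation of face-like grayscale stimuli.

Real face-recognition psychophysics for prosthetic vision uses photographic
datasets (identity x viewpoint x expression).  This module emulates that
structure with layered 2-D primitives — a head ellipse with a chin-sharpness
warp, a hair cap, two eyes, a nose and a mouth on a plain white field —
so that every downstream stage (phosphene rendering, model training,
psychophysics, extrapolation) is testable without photographs.  The
primitives deliberately realize the cues human observers report relying on
at low resolution: the facial contour line and the hair mass.

Identity is a parameter vector drawn per class from continuous ranges
(two classes differ almost surely); each identity is rendered under 9
conditions (viewpoints -45/0/+45 degrees x expressions neutral/joy/anger),
with viewpoint realized as a horizontal shear/shift of the frontal face.
Within-class training variation comes from jitter: small translation,
intensity gain, and feature-size noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

CANVAS = 128
BACKGROUND = 255

VIEWPOINTS = (-45, 0, 45)
EXPRESSIONS = ("neutral", "joy", "anger")


@dataclass(frozen=True, order=True)
class Condition:
    """A (viewpoint angle, facial expression) rendering variant."""

    viewpoint_deg: int
    expression: str

    def __post_init__(self) -> None:
        if self.viewpoint_deg not in VIEWPOINTS:
            raise ValueError(f"viewpoint must be one of {VIEWPOINTS}")
        if self.expression not in EXPRESSIONS:
            raise ValueError(f"expression must be one of {EXPRESSIONS}")

    @property
    def label(self) -> str:
        return f"{self.viewpoint_deg:+d}_{self.expression}"


def all_conditions() -> list[Condition]:
    """The 9 model-test conditions: 3 viewpoints x 3 expressions."""
    return [Condition(v, e) for v in VIEWPOINTS for e in EXPRESSIONS]


def human_conditions() -> list[Condition]:
    """The 5 conditions shown to human observers.

    All three expressions frontally, plus neutral at both side viewpoints.
    """
    return [
        Condition(0, "neutral"),
        Condition(0, "joy"),
        Condition(0, "anger"),
        Condition(-45, "neutral"),
        Condition(45, "neutral"),
    ]


@dataclass(frozen=True)
class FaceClassParams:
    """Identity-defining geometry and tones of one synthetic facial class.

    Lengths are in pixels on the 128 x 128 canvas; tones are fractions of
    full intensity in [0, 1].  Ranges are chosen so every feature stays
    inside the canvas under the +/-45-degree shear and training jitter.
    """

    class_id: int
    face_a: float  # head semi-axis, horizontal
    face_b: float  # head semi-axis, vertical
    chin_sharpness: float  # [0, 1]; narrows the lower head
    skin_tone: float
    hair_coverage: float  # fraction of the upper head covered by hair
    hair_tone: float
    eye_dx: float  # eye center offset from midline
    eye_dy: float  # eye center offset above face center
    eye_rx: float
    eye_ry: float
    eye_tone: float
    nose_len: float
    nose_w: float
    mouth_dy: float  # mouth center below face center
    mouth_w: float
    mouth_h: float
    mouth_tone: float
    rng_seed: int

    def vector(self) -> np.ndarray:
        """Numeric parameter vector (excludes class_id and rng_seed)."""
        d = asdict(self)
        d.pop("class_id")
        d.pop("rng_seed")
        return np.array(list(d.values()), dtype=float)


def sample_class_params(seed: int, class_id: int) -> FaceClassParams:
    """Draw the identity parameters of one facial class.

    Deterministic function of (seed, class_id); all values come from
    continuous uniform ranges, so distinct classes differ almost surely.
    For a guaranteed between-class pixel-distance margin use
    :func:`sample_distinct_classes`.
    """
    rng = np.random.default_rng([seed, class_id])
    u = rng.uniform

    return FaceClassParams(
        class_id=class_id,
        face_a=u(33, 45),
        face_b=u(47, 59),
        chin_sharpness=u(0.0, 1.0),
        skin_tone=u(0.5, 0.88),
        hair_coverage=u(0.1, 0.55),
        hair_tone=u(0.03, 0.47),
        eye_dx=u(13, 19),
        eye_dy=u(8, 16),
        eye_rx=u(4, 7),
        eye_ry=u(2.5, 4.5),
        eye_tone=u(0.05, 0.3),
        nose_len=u(10, 18),
        nose_w=u(3, 6),
        mouth_dy=u(20, 30),
        mouth_w=u(10, 18),
        mouth_h=u(2.5, 5),
        mouth_tone=u(0.2, 0.45),
        rng_seed=seed,
    )


def _tone(t: float) -> float:
    return 255.0 * t


def _draw_frontal(p: FaceClassParams, expression: str, fscale: float) -> np.ndarray:
    """Draw the frontal face as a float image (before smoothing/shear)."""
    cx = (CANVAS - 1) / 2.0  # 63.5 — exact mirror axis
    cy = 66.0
    yy, xx = np.mgrid[0:CANVAS, 0:CANVAS].astype(float)

    img = np.full((CANVAS, CANVAS), float(BACKGROUND))

    a = p.face_a * fscale
    b = p.face_b * fscale

    # head ellipse with chin-sharpness warp: the lower head narrows
    dy_n = (yy - cy) / b
    narrowing = 1.0 - 0.45 * p.chin_sharpness * np.clip(dy_n, 0, None) ** 2
    e = ((xx - cx) / (a * narrowing)) ** 2 + dy_n**2
    head = e <= 1.0
    img[head] = _tone(p.skin_tone)

    # darker contour ring along the head boundary (key low-res cue)
    ring = (e <= 1.0) & (e >= 0.86)
    img[ring] = _tone(p.skin_tone * 0.55)

    # hair cap over the upper head
    y_hair = cy - b * (1.0 - 2.0 * p.hair_coverage)
    img[head & (yy < y_hair)] = _tone(p.hair_tone)

    # expression modulation
    eye_ry = p.eye_ry * fscale * (0.75 if expression == "joy" else 1.0)
    mouth_w = p.mouth_w * fscale * (1.25 if expression == "joy" else 0.9 if expression == "anger" else 1.0)
    curve = {"neutral": 0.0, "joy": 1.0, "anger": -1.0}[expression]

    # eyes, mirrored pair
    for sx in (-1.0, 1.0):
        ex = cx + sx * p.eye_dx * fscale
        ey = cy - p.eye_dy * fscale
        eye = ((xx - ex) / (p.eye_rx * fscale)) ** 2 + ((yy - ey) / eye_ry) ** 2 <= 1.0
        img[eye] = _tone(p.eye_tone)

    # nose: narrow vertical wedge from between the eyes downward
    ny0 = cy - p.eye_dy * fscale * 0.3
    nlen = p.nose_len * fscale
    frac = np.clip((yy - ny0) / nlen, 0, 1)
    nose = (yy >= ny0) & (yy <= ny0 + nlen) & (np.abs(xx - cx) <= p.nose_w * fscale * frac)
    img[nose] = _tone(max(p.skin_tone - 0.2, 0.05))

    # mouth: horizontal band with expression-dependent curvature
    my = cy + p.mouth_dy * fscale
    rel = (xx - cx) / mouth_w
    band_y = my + curve * 3.0 * (rel**2)  # joy: corners up; anger: corners down
    mouth = (np.abs(rel) <= 1.0) & (np.abs(yy - band_y) <= p.mouth_h * fscale / 2.0)
    img[mouth & head] = _tone(p.mouth_tone)

    return img


def render_face(
    params: FaceClassParams,
    condition: Condition,
    jitter_seed: int | None = None,
) -> np.ndarray:
    """Render one 128 x 128 uint8 stimulus.

    ``jitter_seed=None`` yields the canonical (test) image of the
    (identity, condition) pair.  An integer seed adds training jitter:
    integer translation up to +/-3 px, intensity gain +/-10% (measured
    from the white background), and a global feature-size factor +/-5%.
    Deterministic in all arguments.
    """
    fscale, dx, dy, gain = 1.0, 0, 0, 1.0
    if jitter_seed is not None:
        rng = np.random.default_rng(jitter_seed)
        fscale = 1.0 + rng.uniform(-0.05, 0.05)
        dx = int(rng.integers(-3, 4))
        dy = int(rng.integers(-3, 4))
        gain = 1.0 + rng.uniform(-0.1, 0.1)

    img = _draw_frontal(params, condition.expression, fscale)
    img = gaussian_filter(img, sigma=1.5, mode="nearest")

    # viewpoint: per-row integer shear + constant shift (exact mirror pairs)
    if condition.viewpoint_deg != 0:
        s = condition.viewpoint_deg / 45.0
        rows = np.arange(CANVAS)
        shift = np.rint(0.15 * s * (rows - 66.0)).astype(int) + int(round(5 * s))
        out = np.full_like(img, float(BACKGROUND))
        for y in range(CANVAS):
            src = np.arange(CANVAS) - shift[y]
            ok = (src >= 0) & (src < CANVAS)
            out[y, ok] = img[y, src[ok]]
        img = out

    if dx or dy:
        out = np.full_like(img, float(BACKGROUND))
        ys = slice(max(dy, 0), CANVAS + min(dy, 0))
        xs = slice(max(dx, 0), CANVAS + min(dx, 0))
        ys_src = slice(max(-dy, 0), CANVAS + min(-dy, 0))
        xs_src = slice(max(-dx, 0), CANVAS + min(-dx, 0))
        out[ys, xs] = img[ys_src, xs_src]
        img = out

    # gain measured from white keeps the background exactly 255
    img = BACKGROUND - gain * (BACKGROUND - img)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass
class FaceDataset:
    """Images with class labels, conditions and train/val/test split tags."""

    images: np.ndarray  # (N, 128, 128) uint8
    labels: np.ndarray  # (N,) int
    conditions: list[Condition]
    split: np.ndarray  # (N,) str in {"train", "val", "test"}
    class_params: list[FaceClassParams] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))

    def subset(self, split: str) -> "FaceDataset":
        m = self.split == split
        return FaceDataset(
            self.images[m],
            self.labels[m],
            [c for c, keep in zip(self.conditions, m) if keep],
            self.split[m],
            self.class_params,
        )

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_id": np.arange(len(self)),
                "class_id": self.labels,
                "viewpoint_deg": [c.viewpoint_deg for c in self.conditions],
                "expression": [c.expression for c in self.conditions],
                "split": self.split,
            }
        )

    def save(self, outdir: str | Path) -> pd.DataFrame:
        """Write 8-bit grayscale PNGs plus a manifest CSV; returns the manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        man = self.manifest()
        paths = []
        for i, row in man.iterrows():
            name = (
                f"c{row.class_id:02d}_{row.viewpoint_deg:+03d}_{row.expression}"
                f"_{row.split}_{i:05d}.png"
            )
            Image.fromarray(self.images[i], mode="L").save(outdir / name)
            paths.append(name)
        man.insert(0, "image_path", paths)
        man.to_csv(outdir / "manifest.csv", index=False)
        return man


# identity dimensions that dominate pixel distance, with their ranges;
# used to keep sampled classes separated
_KEY_DIMS = {
    "skin_tone": (0.5, 0.88),
    "hair_coverage": (0.1, 0.55),
    "hair_tone": (0.03, 0.47),
    "face_a": (33, 45),
    "face_b": (47, 59),
}


def _scaled_key(p: FaceClassParams) -> np.ndarray:
    return np.array(
        [(getattr(p, k) - lo) / (hi - lo) for k, (lo, hi) in _KEY_DIMS.items()]
    )


def _canonical_probe(p: FaceClassParams) -> np.ndarray:
    """Two canonical renderings (frontal and -45 neutral) as row vectors."""
    a = render_face(p, Condition(0, "neutral"), None).astype(np.float32)
    b = render_face(p, Condition(-45, "neutral"), None).astype(np.float32)
    return np.stack([a, b]).reshape(2, -1)


def sample_distinct_classes(
    seed: int,
    n_classes: int,
    min_sep: float = 0.35,
    min_pixel_dist: float = 30.0,
) -> list[FaceClassParams]:
    """Sample ``n_classes`` identities with a guaranteed separation margin.

    Each class is drawn with :func:`sample_class_params` and accepted only
    if (a) its key-dimension vector is at least ``min_sep`` away
    (L-infinity, on ranges scaled to [0, 1]) from every accepted class, and
    (b) its canonical renderings keep a per-row root-sum-square pixel
    distance (scaled by the canvas side) of at least ``min_pixel_dist``
    from every accepted class's matching renderings.  Rejected draws are
    deterministically redrawn with a perturbed seed.  The pixel margin
    comfortably exceeds the distance training jitter moves an image from
    its canonical form, keeping identities separable by raw pixel distance
    (and hence learnable) for any seed.
    """
    params: list[FaceClassParams] = []
    probes: list[np.ndarray] = []
    for c in range(n_classes):
        for attempt in range(100):
            p = sample_class_params(seed + 7919 * attempt, c)
            if not all(
                np.max(np.abs(_scaled_key(p) - _scaled_key(q))) >= min_sep
                for q in params
            ):
                continue
            probe = _canonical_probe(p)
            if probes and min(
                np.sqrt(((probe - q) ** 2).sum(-1)).min() / CANVAS for q in probes
            ) < min_pixel_dist:
                continue
            break
        else:
            raise RuntimeError(
                f"could not separate {n_classes} identities at margin {min_sep}"
            )
        params.append(p)
        probes.append(probe)
    return params


def plan_split(n_classes: int, train_per_class: int, val_frac: float = 0.15) -> dict[str, int]:
    """Design arithmetic of a dataset build (no rendering).

    The training pool of ``n_classes * train_per_class`` images is divided
    (1 - val_frac):val_frac into train and validation; the test split holds
    one canonical image per (class, condition) pair.
    """
    pool = n_classes * train_per_class
    n_val = round(pool * val_frac)
    return {
        "train": pool - n_val,
        "val": n_val,
        "test": n_classes * len(all_conditions()),
    }


def generate_dataset(
    n_classes: int = 16,
    train_per_class: int = 1000,
    seed: int = 0,
    val_frac: float = 0.15,
) -> FaceDataset:
    """Build a complete synthetic dataset.

    Test split: the canonical (jitter-free) image of every class under all
    9 conditions, exactly once.  Training pool: ``train_per_class`` jittered
    images per class, cycling through the 9 conditions so each is evenly
    represented, divided 85:15 into train and validation.  The whole dataset is a pure function of
    (seed, configuration).
    """
    if n_classes < 2:
        raise ValueError("a recognition design needs at least 2 classes")
    params = sample_distinct_classes(seed, n_classes)
    conds = all_conditions()
    rng = np.random.default_rng([seed, 10**6])

    images, labels, conditions, split = [], [], [], []
    for p in params:
        for cond in conds:
            images.append(render_face(p, cond, jitter_seed=None))
            labels.append(p.class_id)
            conditions.append(cond)
            split.append("test")

    pool_idx = []
    for p in params:
        for i in range(train_per_class):
            # cycle conditions so every condition is evenly represented
            cond = conds[i % len(conds)]
            jit = int(rng.integers(2**31))
            images.append(render_face(p, cond, jitter_seed=jit))
            labels.append(p.class_id)
            conditions.append(cond)
            pool_idx.append(len(images) - 1)
            split.append("train")

    split = np.array(split, dtype=object)
    n_val = round(len(pool_idx) * val_frac)
    val_pick = rng.permutation(pool_idx)[:n_val]
    split[val_pick] = "val"

    return FaceDataset(
        images=np.stack(images) if images else np.empty((0, CANVAS, CANVAS), np.uint8),
        labels=np.array(labels, dtype=int),
        conditions=conditions,
        split=split.astype(str),
        class_params=params,
    )


SOURCE_IDENTITIES = 400  # identities in the emulated photo database
SOURCE_VARIANTS_PER_IDENTITY = 27  # lighting/viewpoint/expression variants


def source_image_count(
    n_identities: int = SOURCE_IDENTITIES,
    variants_per_identity: int = SOURCE_VARIANTS_PER_IDENTITY,
) -> int:
    """Size of the photo database the generator emulates (identities x
    per-identity variants before curation)."""
    return n_identities * variants_per_identity


def visual_angle_deg(width_cm: float = 7.33, distance_cm: float = 60.0) -> float:
    """Visual angle subtended by a stimulus of the given width at the given
    viewing distance (the study geometry: 7.33 cm at 60 cm ~= 7 degrees)."""
    return math.degrees(2.0 * math.atan(width_cm / 2.0 / distance_cm))
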