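"""Procedural synthetic H&E-like biopsy slides with known ground truth.

Real large-bowel biopsy whole-slide images cannot be redistributed, so the
pipeline is exercised on procedurally generated stand-ins.  A synthetic
slide is a near-white background (Gaussian pixel noise, sigma 3/255, so
tissue detection is non-trivial) carrying a small number of wobbly-edged
tissue sections — usually three, mimicking the three levels cut from a
paraffin block and mounted on one slide.  Each section is rendered with a
class-distinctive procedural texture (regular circular crypts for normal
large-bowel mucosa, crowded elongated dark glands for adenoma, fragmented
irregular glands for adenocarcinoma, dense basophilic stippling for
inflammation, serrated star-shaped lumens for HP/SSL, villous fringes for
small bowel, and so on).  The textures are not photorealistic; they are
designed so that simple texture statistics separate the classes by a wide
margin, guaranteeing that both the mock classifier and the trainable
classifier have signal.

Common slide artifacts (coverslip edges, air bubbles, printed text, tissue
folds, dust, diathermy smears) can be overlaid; they perturb pixels only,
never the ground-truth label map.

Images are generated directly at a x5-equivalent scale (about 2 um/pixel),
default 3072 x 3072, sized so a typical slide yields 10-50 tiles of
512 x 512 after tissue detection.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Iterator, Mapping

import numpy as np
from scipy import ndimage

from .hierarchy import DiagnosticClass, class_from_code, hierarchy_max
from .triage import CaseRecord, allocate_pathway

ARTIFACT_TYPES = frozenset(
    {"coverslip_edge", "bubble", "printing", "fold", "dust", "diathermy"}
)

#: Dominant stain colour per class (RGB).  Spread widely enough that mean
#: tissue colour alone separates classes; structure adds texture contrast.
CLASS_BASE_COLOR: dict[DiagnosticClass, tuple[int, int, int]] = {
    DiagnosticClass.adenocarcinoma: (135, 70, 150),
    DiagnosticClass.adenoma: (185, 105, 185),
    DiagnosticClass.anal_mucosa: (235, 190, 170),
    DiagnosticClass.hp_ssl: (205, 145, 210),
    DiagnosticClass.inflammation: (150, 130, 205),
    DiagnosticClass.normal_small_bowel: (240, 160, 210),
    DiagnosticClass.artifact: (175, 175, 175),
    DiagnosticClass.immunohistochemistry: (150, 160, 210),
    DiagnosticClass.connective_tissue: (245, 185, 205),
    DiagnosticClass.normal_large_bowel: (220, 140, 185),
}

BACKGROUND_LEVEL = 246.0
BACKGROUND_NOISE_SIGMA = 3.0


class SlidePlacementError(ValueError):
    """Image too small to place the requested tissue sections."""


@dataclass
class SlideImage:
    """A raster slide image plus identifier and magnification metadata."""

    pixels: np.ndarray  # uint8, H x W x 3
    slide_id: str
    magnification: float = 5.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class GroundTruthMap:
    """Pixel-level truth for a synthetic slide.

    ``label_image`` holds 0 for background and the class rank code for
    tissue; ``slide_truth`` is the hierarchy maximum of the codes present.
    """

    label_image: np.ndarray  # uint8, H x W
    slide_truth: DiagnosticClass

    @classmethod
    def from_label_image(cls, label_image: np.ndarray) -> "GroundTruthMap":
        codes = np.unique(label_image)
        codes = codes[codes > 0]
        if codes.size == 0:
            raise ValueError("label image contains no tissue")
        truth = hierarchy_max(class_from_code(int(c)) for c in codes)
        return cls(label_image=label_image, slide_truth=truth)

    def classes_present(self) -> set[DiagnosticClass]:
        codes = np.unique(self.label_image)
        return {class_from_code(int(c)) for c in codes if c > 0}


@dataclass
class SyntheticSlideSpec:
    """Recipe for one synthetic slide."""

    slide_id: str
    true_classes: list[DiagnosticClass]
    n_sections: int = 3
    image_size: tuple[int, int] = (3072, 3072)
    artifact_types: frozenset[str] = frozenset()
    seed: int = 0
    section_radius: int | None = None  # default: min(image_size)//7

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if min(self.image_size) < 512:
            raise ValueError("image_size must be at least 512 in each dimension")
        if not self.true_classes:
            raise ValueError("true_classes must be non-empty")
        unknown = set(self.artifact_types) - ARTIFACT_TYPES
        if unknown:
            raise ValueError(f"unknown artifact types: {sorted(unknown)}")


@dataclass
class CohortSpec:
    """Recipe for a cohort of cases with known case-level diagnoses.

    ``class_mix`` gives the probability of each case-level diagnosis; the
    defaults for specimens per case (one to five) follow typical endoscopy
    practice.  Scan-completion timestamps are drawn uniformly over the
    accrual window.
    """

    n_cases: int
    class_mix: Mapping[DiagnosticClass, float]
    specimens_per_case: tuple[int, int] = (1, 5)
    slides_per_specimen: tuple[int, int] = (1, 2)
    start_number: int = 2312345
    seed: int = 0
    image_size: tuple[int, int] = (3072, 3072)
    n_sections: int = 3
    section_radius: int | None = None
    accrual_start: datetime = field(
        default_factory=lambda: datetime(2022, 5, 1, 8, 0, tzinfo=timezone.utc)
    )
    accrual_hours: float = 336.0  # two weeks

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        total = float(sum(self.class_mix.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1 (got {total})")
        for lo, hi in (self.specimens_per_case, self.slides_per_specimen):
            if lo < 1 or hi < lo:
                raise ValueError("count ranges must be positive and ordered")


# ---------------------------------------------------------------------------
# Procedural textures
# ---------------------------------------------------------------------------

def _base(shape: tuple[int, int], color, rng: np.random.Generator) -> np.ndarray:
    out = np.empty(shape + (3,), dtype=np.float64)
    out[:] = color
    out += rng.normal(0.0, 5.0, size=out.shape)
    return out


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    return np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")


def _lattice_polar(shape, spacing, rng):
    """Distance/angle to the nearest point of a jittered square lattice."""
    yy, xx = _grid(shape)
    oy = rng.uniform(0, spacing)
    ox = rng.uniform(0, spacing)
    dy = (yy - oy) % spacing - spacing / 2
    dx = (xx - ox) % spacing - spacing / 2
    return np.hypot(dy, dx), np.arctan2(dy, dx)


def _smooth_field(shape, sigma, rng):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return (f - f.mean()) / (f.std() + 1e-12)


def _tex_normal_large_bowel(shape, rng):
    img = _base(shape, CLASS_BASE_COLOR[DiagnosticClass.normal_large_bowel], rng)
    r, _ = _lattice_polar(shape, 40.0, rng)
    img[(r >= 8) & (r < 14)] = (160, 90, 150)  # crypt epithelium ring
    img[r < 8] = (243, 230, 240)  # lumen
    return img


def _tex_adenoma(shape, rng):
    img = _base(shape, CLASS_BASE_COLOR[DiagnosticClass.adenoma], rng)
    yy, xx = _grid(shape)
    phase = _smooth_field(shape, 30, rng) * 2.0
    v = np.sin(2 * np.pi * xx / 18.0 + phase)
    img[v > 0.25] = (120, 60, 130)  # crowded elongated dark glands
    return img


def _tex_adenocarcinoma(shape, rng):
    img = _base(shape, CLASS_BASE_COLOR[DiagnosticClass.adenocarcinoma], rng)
    f = _smooth_field(shape, 7, rng)
    img[f > 0.55] = (80, 40, 95)  # fragmented irregular gland clusters
    img[f < -1.1] = (205, 175, 195)  # pale stromal pockets
    return img


def _tex_inflammation(shape, rng):
    img = _base(shape, CLASS_BASE_COLOR[DiagnosticClass.inflammation], rng)
    dots = rng.random(shape) > 0.97
    dots = ndimage.maximum_filter(dots, size=3)  # 3-px inflammatory cells
    img[dots] = (70, 60, 140)
    return img


def _tex_hp_ssl(shape, rng):
    img = _base(shape, CLASS_BASE_COLOR[DiagnosticClass.hp_ssl], rng)
    r, theta = _lattice_polar(shape, 52.0, rng)
    rim = 15.0 + 4.0 * np.sin(6 * theta)  # serrated (star-shaped) lumen
    img[np.abs(r - rim) < 3.0] = (140, 85, 150)
    img[r < rim - 3.0] = (246, 238, 246)
    return img


def _tex_normal_small_bowel(shape, rng):
    img = _base(shape, CLASS_BASE_COLOR[DiagnosticClass.normal_small_bowel], rng)
    yy, xx = _grid(shape)
    phase = _smooth_field(shape, 40, rng)
    fingers = np.sin(2 * np.pi * xx / 32.0 + 3.0 * phase)
    img[np.abs(fingers) > 0.75] = (200, 115, 175)  # villous fringe walls
    return img


def _tex_artifact(shape, rng):
    img = _base(shape, CLASS_BASE_COLOR[DiagnosticClass.artifact], rng)
    yy, xx = _grid(shape)
    n_folds = max(1, int(round(3 * shape[0] / 600)))  # fold density per area
    for _ in range(n_folds):
        a = rng.uniform(0.1, 0.9) * shape[0]
        b = rng.uniform(10, 40)
        path = a + b * np.sin(xx / rng.uniform(40, 90))
        img[np.abs(yy - path) < 4] = (90, 90, 90)
    return img


def _tex_immunohistochemistry(shape, rng):
    img = _base(shape, CLASS_BASE_COLOR[DiagnosticClass.immunohistochemistry], rng)
    f = _smooth_field(shape, 6, rng)
    img[f > 0.65] = (130, 85, 45)  # DAB-brown positive blobs on blue counterstain
    return img


def _tex_connective_tissue(shape, rng):
    img = _base(shape, CLASS_BASE_COLOR[DiagnosticClass.connective_tissue], rng)
    yy, xx = _grid(shape)
    fibres = 8.0 * np.sin(2 * np.pi * (xx + yy) / 55.0 + _smooth_field(shape, 50, rng))
    img += fibres[..., None]
    return img


def _tex_anal_mucosa(shape, rng):
    img = _base(shape, CLASS_BASE_COLOR[DiagnosticClass.anal_mucosa], rng)
    yy, _ = _grid(shape)
    shades = np.array([(225, 170, 150), (240, 200, 180), (210, 150, 135)], float)
    band = ((yy // 24) % 3).astype(int)
    img = shades[band] + rng.normal(0.0, 5.0, size=img.shape)
    return img


_TEXTURES = {
    DiagnosticClass.normal_large_bowel: _tex_normal_large_bowel,
    DiagnosticClass.adenoma: _tex_adenoma,
    DiagnosticClass.adenocarcinoma: _tex_adenocarcinoma,
    DiagnosticClass.inflammation: _tex_inflammation,
    DiagnosticClass.hp_ssl: _tex_hp_ssl,
    DiagnosticClass.normal_small_bowel: _tex_normal_small_bowel,
    DiagnosticClass.artifact: _tex_artifact,
    DiagnosticClass.immunohistochemistry: _tex_immunohistochemistry,
    DiagnosticClass.connective_tissue: _tex_connective_tissue,
    DiagnosticClass.anal_mucosa: _tex_anal_mucosa,
}


def render_texture(
    diagnosis: DiagnosticClass, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Render the class-distinctive texture as a float RGB array."""
    return _TEXTURES[diagnosis](shape, rng)


def generate_class_tile(
    diagnosis: DiagnosticClass, size: int = 512, seed: int = 0
) -> np.ndarray:
    """A uint8 tile fully covered by one class texture (for training sets)."""
    rng = np.random.default_rng(seed)
    return np.clip(render_texture(diagnosis, (size, size), rng), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Slide assembly
# ---------------------------------------------------------------------------

def _section_centers(
    shape: tuple[int, int], n: int, radius: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Non-overlapping section centres on a cell grid; error if they don't fit."""
    h, w = shape
    pad = 24.0
    cell = 2 * radius + pad
    rows = int((h - pad) // cell)
    cols = int((w - pad) // cell)
    if rows * cols < n:
        raise SlidePlacementError(
            f"cannot place {n} sections of radius {radius:.0f} on a {h}x{w} image"
        )
    cells = [(i, j) for i in range(rows) for j in range(cols)]
    order = rng.permutation(len(cells))[:n]
    centers = []
    for k in order:
        i, j = cells[int(k)]
        cy = pad / 2 + (i + 0.5) * cell + rng.uniform(-pad / 2, pad / 2)
        cx = pad / 2 + (j + 0.5) * cell + rng.uniform(-pad / 2, pad / 2)
        centers.append((cy, cx))
    return centers


def _section_mask_window(
    shape, cy, cx, radius, rng
) -> tuple[slice, slice, np.ndarray]:
    """Wobbly-edged elliptical section mask within a bounding window."""
    ry = radius * rng.uniform(0.80, 1.0)
    rx = radius * rng.uniform(0.80, 1.0)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    pad = 1.35
    r0 = max(int(cy - pad * ry), 0)
    r1 = min(int(cy + pad * ry) + 1, shape[0])
    c0 = max(int(cx - pad * rx), 0)
    c1 = min(int(cx + pad * rx) + 1, shape[1])
    yy, xx = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dn = np.hypot((yy - cy) / ry, (xx - cx) / rx)
    theta = np.arctan2(yy - cy, xx - cx)
    wobble = 1.0 + 0.10 * np.sin(3 * theta + p1) + 0.06 * np.sin(5 * theta + p2)
    return slice(r0, r1), slice(c0, c1), dn < wobble


def generate_slide(spec: SyntheticSlideSpec) -> tuple[SlideImage, GroundTruthMap]:
    """Render one synthetic slide and its pixel-level ground truth.

    Sections cycle through ``spec.true_classes`` so every listed class is
    present when ``n_sections >= len(true_classes)``.  Byte-identical output
    for identical spec and seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    radius = spec.section_radius or min(h, w) // 7

    img = np.clip(
        BACKGROUND_LEVEL
        + BACKGROUND_NOISE_SIGMA * rng.standard_normal((h, w, 3), dtype=np.float32),
        0,
        255,
    )
    label = np.zeros((h, w), dtype=np.uint8)

    centers = _section_centers((h, w), spec.n_sections, radius, rng)
    for i, (cy, cx) in enumerate(centers):
        diagnosis = spec.true_classes[i % len(spec.true_classes)]
        rs, cs, mask = _section_mask_window((h, w), cy, cx, radius, rng)
        texture = render_texture(diagnosis, mask.shape, rng)
        window = img[rs, cs]
        window[mask] = texture[mask]
        label[rs, cs][mask] = diagnosis.rank

    pixels = np.clip(img, 0, 255).astype(np.uint8)
    if spec.artifact_types:
        pixels = add_artifacts(pixels, spec.artifact_types, seed=spec.seed + 1)
    slide = SlideImage(pixels=pixels, slide_id=spec.slide_id)
    return slide, GroundTruthMap.from_label_image(label)


# ---------------------------------------------------------------------------
# Slide artifacts
# ---------------------------------------------------------------------------

def _art_coverslip_edge(img, rng):
    h, w = img.shape[:2]
    side = rng.integers(0, 4)
    offset = int(rng.uniform(0.01, 0.05) * (h if side < 2 else w))
    if side == 0:
        img[offset : offset + 3, :] = (60, 60, 60)
    elif side == 1:
        img[h - offset - 3 : h - offset, :] = (60, 60, 60)
    elif side == 2:
        img[:, offset : offset + 3] = (60, 60, 60)
    else:
        img[:, w - offset - 3 : w - offset] = (60, 60, 60)


def _art_bubble(img, rng):
    h, w = img.shape[:2]
    cy, cx = rng.uniform(0.15, 0.85) * h, rng.uniform(0.15, 0.85) * w
    r = rng.uniform(0.02, 0.05) * min(h, w)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d = np.hypot(yy - cy, xx - cx)
    img[np.abs(d - r) < 2.5] = (110, 110, 110)
    inner = d < r - 2.5
    img[inner] = np.minimum(img[inner].astype(int) + 6, 255).astype(np.uint8)


def _art_printing(img, rng):
    h, w = img.shape[:2]
    y0 = int(rng.uniform(0.02, 0.08) * h)
    x0 = int(rng.uniform(0.02, 0.3) * w)
    glyph_h, glyph_w, gap = max(10, h // 150), max(6, w // 250), max(3, w // 500)
    for k in range(8):  # blocky text-like glyphs
        x = x0 + k * (glyph_w + gap)
        if x + glyph_w >= w:
            break
        if rng.random() < 0.85:
            img[y0 : y0 + glyph_h, x : x + glyph_w] = (40, 40, 40)


def _art_fold(img, rng):
    h, w = img.shape[:2]
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    a = rng.uniform(0.2, 0.8) * h
    path = a + rng.uniform(20, 60) * np.sin(xx / rng.uniform(80, 160))
    band = np.abs(yy - path) < rng.uniform(3, 7)
    img[band] = (img[band].astype(int) * 0.45).astype(np.uint8)


def _art_dust(img, rng):
    h, w = img.shape[:2]
    n = int(rng.integers(30, 80))
    ys = rng.integers(1, h - 1, size=n)
    xs = rng.integers(1, w - 1, size=n)
    for y, x in zip(ys, xs):
        img[y - 1 : y + 2, x - 1 : x + 2] = (70, 65, 60)


def _art_diathermy(img, rng):
    h, w = img.shape[:2]
    cy, cx = rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w
    r = rng.uniform(0.03, 0.06) * min(h, w)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d = np.hypot(yy - cy, xx - cx)
    smear = np.clip(1.0 - d / r, 0, 1)[..., None]
    brown = np.array([120, 85, 55], float)
    img[:] = np.clip(img * (1 - 0.6 * smear) + brown * 0.6 * smear, 0, 255).astype(
        np.uint8
    )


_ARTIFACT_RENDERERS = {
    "coverslip_edge": _art_coverslip_edge,
    "bubble": _art_bubble,
    "printing": _art_printing,
    "fold": _art_fold,
    "dust": _art_dust,
    "diathermy": _art_diathermy,
}


def add_artifacts(image: np.ndarray, artifact_types, seed: int = 0) -> np.ndarray:
    """Overlay the named slide artifacts on a copy of an RGB image.

    The ground-truth label map is untouched by design: artifacts are
    optical, not tissue.  Unknown artifact names raise ValueError.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image")
    unknown = set(artifact_types) - ARTIFACT_TYPES
    if unknown:
        raise ValueError(f"unknown artifact types: {sorted(unknown)}")
    out = image.copy()
    rng = np.random.default_rng(seed)
    for name in sorted(artifact_types):  # sorted for determinism
        _ARTIFACT_RENDERERS[name](out, rng)
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _sample_counts(rng, lo_hi: tuple[int, int]) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


def iter_cohort(spec: CohortSpec, render: bool = True) -> Iterator[CaseRecord]:
    """Yield cases one at a time (images attached) to bound peak memory.

    With ``render=False`` the slide images are skipped (slide entries are
    ``(None, GroundTruthMap)`` with an empty label raster); the identifier
    scheme, class sampling, structure and timestamps are identical, which
    makes cohort-level statistics cheap to study.
    """
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.class_mix.keys())
    probs = np.array([spec.class_mix[c] for c in classes], dtype=float)
    probs /= probs.sum()
    nlb = DiagnosticClass.normal_large_bowel

    for i in range(spec.n_cases):
        number = spec.start_number + i
        case_id = f"SP{number}"
        case_class = classes[int(rng.choice(len(classes), p=probs))]
        n_spec = _sample_counts(rng, spec.specimens_per_case)
        scan_complete = spec.accrual_start + timedelta(
            hours=float(rng.uniform(0, spec.accrual_hours))
        )

        specimens: dict[str, list[str]] = {}
        slide_specs: list[SyntheticSlideSpec] = []
        for s in range(n_spec):
            letter = string.ascii_uppercase[s]
            n_slides = _sample_counts(rng, spec.slides_per_specimen)
            specimens[letter] = []
            for k in range(1, n_slides + 1):
                slide_id = f"{case_id}-{letter}-{k}"
                specimens[letter].append(slide_id)
                slide_specs.append(
                    SyntheticSlideSpec(
                        slide_id=slide_id,
                        true_classes=[nlb],  # provisional; fixed below
                        n_sections=spec.n_sections,
                        image_size=spec.image_size,
                        section_radius=spec.section_radius,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                )

        # One slide always carries the case class; others carry either the
        # case class or background-normal mucosa.  Normal large bowel is the
        # hierarchy minimum, so the case-level truth is exactly case_class.
        carrier = int(rng.integers(0, len(slide_specs)))
        for j, sspec in enumerate(slide_specs):
            if j == carrier or case_class is nlb or rng.random() < 0.5:
                sspec.true_classes = [case_class]
            else:
                sspec.true_classes = [nlb]

        slide_data = {}
        for sspec in slide_specs:
            if render:
                slide, truth = generate_slide(sspec)
            else:
                slide = None
                truth = GroundTruthMap(
                    label_image=np.zeros((0, 0), dtype=np.uint8),
                    slide_truth=hierarchy_max(sspec.true_classes),
                )
            slide_data[sspec.slide_id] = (slide, truth)

        truth_case = hierarchy_max(t.slide_truth for _, t in slide_data.values())
        yield CaseRecord(
            case_id=case_id,
            case_number=number,
            specimens=specimens,
            scan_complete=scan_complete,
            pathway=allocate_pathway(number),
            truth_diagnosis=truth_case,
            slide_data=slide_data,
        )


def generate_cohort(spec: CohortSpec, render: bool = True) -> list[CaseRecord]:
    """Materialize a full cohort; see :func:`iter_cohort` for streaming."""
    return list(iter_cohort(spec, render=render))


def write_cohort(cases: list[CaseRecord], out_dir) -> str:
    """Write slide PNGs and a manifest CSV; returns the manifest path.

    Manifest columns: case_id, specimen_id, slide_id, image_path,
    truth_class, scan_complete_timestamp (ISO-8601).
    """
    import pandas as pd
    from PIL import Image
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        if case.slide_data is None:
            raise ValueError(f"{case.case_id}: no slide images attached")
        for letter, slide_ids in sorted(case.specimens.items()):
            for slide_id in slide_ids:
                slide, truth = case.slide_data[slide_id]
                path = out / f"{slide_id}.png"
                Image.fromarray(slide.pixels).save(path)
                rows.append(
                    {
                        "case_id": case.case_id,
                        "specimen_id": f"{case.case_id}-{letter}",
                        "slide_id": slide_id,
                        "image_path": path.name,
                        "truth_class": truth.slide_truth.name,
                        "scan_complete_timestamp": case.scan_complete.isoformat(),
                    }
                )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return str(manifest)
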