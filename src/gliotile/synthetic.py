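"""Seeded synthetic H&E-like slide cohort.

Stands in for an annotated glioma WSI archive: each synthetic slide is a
patchwork of vertical class strips rendered as a marked Poisson blob process
(purple nucleus-like disks over a pink eosin-like background), with
rectangular ROI annotations over part of each strip and a slide-level
diagnosis.  The generator reproduces the statistical structure the pipeline
assumes rather than histological appearance:

* five classes whose textures are distinguishable from local color statistics
  alone, with a ``difficulty`` dial that linearly collapses the per-class
  texture parameters onto their common mean (difficulty 1 = indistinguishable);
* severe class imbalance (roughly 18:1 normal:necrosis at the default tile
  shares);
* the slide-consistency rule: a slide with diagnosis ``d`` contains only
  strips of class ``d``, normal tissue or necrosis (normal-control slides:
  normal tissue only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import disk as _disk

from .scheme import DEFAULT_SCHEME, ClassScheme
from .tiling import count_tiles


@dataclass
class ROIAnnotation:
    """Rectangular annotation: 0-based top-left corner, half-open extent."""

    x: int
    y: int
    width: int
    height: int
    label: str

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI width and height must be positive")


@dataclass
class SlideRecord:
    """One slide: image (array or file reference), diagnosis and ROIs."""

    slide_id: str
    width: int
    height: int
    diagnosis: str
    rois: list[ROIAnnotation] = field(default_factory=list)
    image: np.ndarray | None = None
    image_path: str | None = None

    def load_image(self) -> np.ndarray:
        if self.image is None:
            if self.image_path is None:
                raise ValueError(f"slide {self.slide_id!r} has no image or path")
            import imageio.v3 as iio

            self.image = np.asarray(iio.imread(self.image_path))
        return self.image


@dataclass
class TextureParams:
    """Marked-point texture parameters for one class.

    ``density`` is the expected blob count per pixel of area; ``radius`` the
    blob radius in pixels; colors are RGB in [0, 255]; ``noise_scale`` the
    standard deviation of the additive Gaussian pixel noise.
    """

    density: float
    radius: float
    fg_color: tuple[float, float, float]
    bg_color: tuple[float, float, float]
    noise_scale: float = 8.0

    def __post_init__(self):
        if self.density < 0:
            raise ValueError("blob density must be non-negative")
        if self.radius <= 0:
            raise ValueError("blob radius must be positive")


#: Default per-class textures.  Densities/radii sketch the morphology
#: (glioblastoma hypercellular, oligodendroglioma sparse large cells with
#: halos, necrosis acellular and dull); background colors emulate differing
#: eosin intensity so classes are separable from local color statistics.
DEFAULT_TEXTURES: dict[str, TextureParams] = {
    "ac": TextureParams(4e-4, 3.0, (90, 60, 140), (232, 170, 200)),
    "odg": TextureParams(1.5e-4, 5.0, (70, 50, 120), (244, 210, 226)),
    "gbm": TextureParams(9e-4, 3.0, (60, 40, 110), (216, 148, 188)),
    "normal": TextureParams(1e-4, 2.0, (120, 90, 160), (250, 226, 236)),
    "necrosis": TextureParams(0.5e-4, 4.0, (150, 130, 130), (205, 186, 176)),
}

#: Default per-class expected ground-truth tile shares for the cohort,
#: mirroring the tile-level imbalance of the emulated archive's training set
#: (normal:necrosis roughly 18:1).
DEFAULT_IMBALANCE_TARGETS: dict[str, float] = {
    "ac": 30040 / 129579,
    "odg": 27072 / 129579,
    "gbm": 13064 / 129579,
    "normal": 56295 / 129579,
    "necrosis": 3108 / 129579,
}

#: Default cohort shape: 8 astrocytoma, 8 oligodendroglioma, 12 glioblastoma
#: and 1 normal-control slide.
DEFAULT_DIAGNOSIS_PROPORTIONS: dict[str, float] = {
    "ac": 8 / 29,
    "odg": 8 / 29,
    "gbm": 12 / 29,
    "normal": 1 / 29,
}


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic cohort generator.

    Slides measure ``block_grid`` blocks of ``tile_size`` pixels each, so a
    block holds exactly one non-overlapping tile and a strip of ``k`` columns
    yields ``(2k-1)(2*ny-1)`` half-overlapping tiles.
    """

    n_slides: int = 29
    block_grid: tuple[int, int] = (8, 6)
    tile_size: int = 512
    class_textures: dict[str, TextureParams] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURES)
    )
    imbalance_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IMBALANCE_TARGETS)
    )
    diagnoses: list[str] | None = None
    roi_plan: list[list[tuple[str, int]]] | None = None
    annotated_fraction: float = 1.0
    difficulty: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_slides < 1:
            raise ValueError("n_slides must be >= 1")
        nx, ny = self.block_grid
        if nx < 1 or ny < 1:
            raise ValueError("block_grid dimensions must be >= 1")
        if self.tile_size < 1:
            raise ValueError("tile_size must be >= 1")
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValueError("difficulty must lie in [0, 1]")
        if not 0.0 < self.annotated_fraction <= 1.0:
            raise ValueError("annotated_fraction must lie in (0, 1]")
        total = sum(self.imbalance_targets.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"imbalance_targets must sum to 1, got {total}")
        if self.diagnoses is not None and len(self.diagnoses) != self.n_slides:
            raise ValueError("diagnoses must have one entry per slide")

    @property
    def slide_size(self) -> tuple[int, int]:
        """Slide (width, height) in pixels."""
        nx, ny = self.block_grid
        return nx * self.tile_size, ny * self.tile_size


@dataclass
class Cohort:
    """Generated slides plus the realized tile-share bookkeeping."""

    slides: list[SlideRecord]
    scheme: ClassScheme
    config: SyntheticConfig
    realized_tile_shares: dict[str, float]
    max_relative_share_deviation: float


def interpolated_textures(
    textures: dict[str, TextureParams], difficulty: float
) -> dict[str, TextureParams]:
    """Shrink inter-class texture separation by ``difficulty`` in [0, 1].

    Every numeric parameter is moved linearly toward the across-class mean;
    at difficulty 1 all classes share identical parameters.
    """
    labels = list(textures)
    mean = {
        "density": float(np.mean([textures[c].density for c in labels])),
        "radius": float(np.mean([textures[c].radius for c in labels])),
        "fg": np.mean([textures[c].fg_color for c in labels], axis=0),
        "bg": np.mean([textures[c].bg_color for c in labels], axis=0),
        "noise": float(np.mean([textures[c].noise_scale for c in labels])),
    }
    d = difficulty
    out = {}
    for c in labels:
        p = textures[c]
        out[c] = TextureParams(
            density=(1 - d) * p.density + d * mean["density"],
            radius=(1 - d) * p.radius + d * mean["radius"],
            fg_color=tuple((1 - d) * np.asarray(p.fg_color) + d * mean["fg"]),
            bg_color=tuple((1 - d) * np.asarray(p.bg_color) + d * mean["bg"]),
            noise_scale=(1 - d) * p.noise_scale + d * mean["noise"],
        )
    return out


def sample_blob_centers(
    rng: np.random.Generator, density: float, width: int, height: int
) -> np.ndarray:
    """Poisson number (mean = density * area) of uniform blob centers."""
    n = rng.poisson(density * width * height)
    if n == 0:
        return np.empty((0, 2))
    xs = rng.uniform(0, width, size=n)
    ys = rng.uniform(0, height, size=n)
    return np.column_stack([ys, xs])


def render_class_texture(
    label: str,
    size: tuple[int, int],
    params: dict[str, TextureParams] | TextureParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render a ``(height, width, 3)`` uint8 marked-Poisson texture patch."""
    if isinstance(params, TextureParams):
        p = params
    else:
        try:
            p = params[label]
        except KeyError:
            raise KeyError(f"no texture parameters for class {label!r}") from None
    width, height = size
    img = np.empty((height, width, 3), dtype=np.float64)
    img[:] = np.asarray(p.bg_color, dtype=np.float64)
    centers = sample_blob_centers(rng, p.density, width, height)
    fg = np.asarray(p.fg_color, dtype=np.float64)
    for cy, cx in centers:
        rr, cc = _disk((cy, cx), p.radius, shape=(height, width))
        img[rr, cc] = fg
    img += rng.normal(0.0, p.noise_scale, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _apportion(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n units to the given shares."""
    quotas = {k: n * v for k, v in proportions.items()}
    counts = {k: int(math.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    by_rem = sorted(quotas, key=lambda k: (-(quotas[k] - counts[k]), list(quotas).index(k)))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def default_diagnoses(n_slides: int, scheme: ClassScheme = DEFAULT_SCHEME) -> list[str]:
    """Diagnosis list following the default cohort proportions."""
    props = {d: DEFAULT_DIAGNOSIS_PROPORTIONS.get(d, 0.0) for d in scheme.diagnoses}
    counts = _apportion(props, n_slides)
    out: list[str] = []
    for d in scheme.diagnoses:
        out.extend([d] * counts.get(d, 0))
    return out


def _strip_tiles(k_cols: int, ny: int) -> int:
    """Half-overlap tile count of a strip of k block columns, full height."""
    return (2 * k_cols - 1) * (2 * ny - 1)


def _allocate_columns(
    diagnoses: list[str],
    scheme: ClassScheme,
    targets: dict[str, float],
    nx: int,
    ny: int,
) -> list[dict[str, int]]:
    """Greedy quota allocation of block columns to classes, per slide.

    Columns are handed out one at a time; each goes to the eligible class
    whose assignment minimizes the total absolute deviation between realized
    and target tile shares, measured in overlap-tile counts so narrow strips
    are not under-weighted.  Tiny classes (necrosis) thus stop receiving
    columns as soon as the next increment would overshoot more than the
    alternatives undershoot.
    """
    per_slide: list[dict[str, int]] = [dict() for _ in diagnoses]
    tiles = {c: 0 for c in scheme.labels}

    def delta(i: int, c: str) -> int:
        k = per_slide[i].get(c, 0)
        return _strip_tiles(k + 1, ny) - (_strip_tiles(k, ny) if k else 0)

    def add(i: int, c: str):
        tiles[c] += delta(i, c)
        per_slide[i][c] = per_slide[i].get(c, 0) + 1

    def deviation_after(i: int, c: str) -> float:
        d = delta(i, c)
        total = sum(tiles.values()) + d
        return sum(
            abs((tiles[cc] + (d if cc == c else 0)) / total - targets.get(cc, 0.0))
            / max(targets.get(cc, 0.0), 1e-9)
            for cc in scheme.labels
        )

    # every slide opens with one column of its diagnosis class
    free = []
    for i, d in enumerate(diagnoses):
        add(i, d)
        free.append(nx - 1)
    # remaining columns round-robin (fullest-free slide first), each to the
    # eligible class minimizing the post-assignment share deviation
    for _ in range(sum(free)):
        slide_idx = max(range(len(free)), key=lambda i: free[i])
        allowed = [
            c
            for c in scheme.labels
            if c in scheme.allowed_classes(diagnoses[slide_idx])
        ]
        best = min(allowed, key=lambda c: deviation_after(slide_idx, c))
        add(slide_idx, best)
        free[slide_idx] -= 1
    _improve_allocation(per_slide, diagnoses, scheme, targets, ny)
    return per_slide


def _improve_allocation(per_slide, diagnoses, scheme, targets, ny, max_iter=500):
    """Hill-climb single-column moves to shrink the total share deviation.

    Each move shifts one block column on one slide from class ``a`` to an
    eligible class ``b``; the slide's diagnosis class always keeps at least
    one column.  Stops at a local optimum of sum_c |share_c - target_c|.
    """

    def tiles_of(alloc: dict[str, int]) -> dict[str, int]:
        return {c: _strip_tiles(k, ny) for c, k in alloc.items() if k > 0}

    def total_deviation() -> float:
        tiles = {c: 0 for c in scheme.labels}
        for alloc in per_slide:
            for c, t in tiles_of(alloc).items():
                tiles[c] += t
        total = sum(tiles.values())
        return sum(
            abs(tiles[c] / total - targets.get(c, 0.0))
            / max(targets.get(c, 0.0), 1e-9)
            for c in tiles
        )

    for _ in range(max_iter):
        base = total_deviation()
        best_move, best_dev = None, base - 1e-12
        for i, diag in enumerate(diagnoses):
            allowed = scheme.allowed_classes(diag)
            for a, k in list(per_slide[i].items()):
                min_keep = 1 if a == diag else 0
                if k - 1 < min_keep:
                    continue
                for b in scheme.labels:
                    if b == a or b not in allowed:
                        continue
                    per_slide[i][a] -= 1
                    if per_slide[i][a] == 0:
                        del per_slide[i][a]
                    per_slide[i][b] = per_slide[i].get(b, 0) + 1
                    dev = total_deviation()
                    per_slide[i][b] -= 1
                    if per_slide[i][b] == 0:
                        del per_slide[i][b]
                    per_slide[i][a] = per_slide[i].get(a, 0) + 1
                    if dev < best_dev:
                        best_move, best_dev = (i, a, b), dev
        if best_move is None:
            return
        i, a, b = best_move
        per_slide[i][a] -= 1
        if per_slide[i][a] == 0:
            del per_slide[i][a]
        per_slide[i][b] = per_slide[i].get(b, 0) + 1


def generate_cohort(
    config: SyntheticConfig, scheme: ClassScheme = DEFAULT_SCHEME
) -> Cohort:
    """Generate a seeded cohort of synthetic slides with ROI annotations.

    Deterministic given ``(config, seed)``: the root seed spawns one child
    stream per slide, so cohorts are reproducible slide by slide.  Every
    slide satisfies the diagnosis-consistency rule by construction, and the
    realized ground-truth tile shares (reported on the returned ``Cohort``)
    track ``config.imbalance_targets``.
    """
    nx, ny = config.block_grid
    T = config.tile_size
    diagnoses = (
        list(config.diagnoses)
        if config.diagnoses is not None
        else default_diagnoses(config.n_slides, scheme)
    )
    for d in diagnoses:
        scheme.allowed_classes(d)  # raises on unknown diagnosis

    if config.roi_plan is not None:
        if len(config.roi_plan) != config.n_slides:
            raise ValueError("roi_plan must have one entry per slide")
        per_slide = []
        for i, plan in enumerate(config.roi_plan):
            used = sum(k for _, k in plan)
            if used > nx:
                raise ValueError(
                    f"roi_plan for slide {i} needs {used} block columns but the "
                    f"slide has only {nx}: plan does not fit inside the slide"
                )
            if used < nx:
                raise ValueError(
                    f"roi_plan for slide {i} covers {used}/{nx} block columns; "
                    "plans must tile the whole slide"
                )
            allowed = scheme.allowed_classes(diagnoses[i])
            cols: dict[str, int] = {}
            for label, k in plan:
                if label not in allowed:
                    raise ValueError(
                        f"roi_plan slide {i}: class {label!r} not permitted "
                        f"under diagnosis {diagnoses[i]!r}"
                    )
                if k < 1:
                    raise ValueError("roi_plan column counts must be >= 1")
                cols[label] = cols.get(label, 0) + k
            per_slide.append(cols)
    else:
        per_slide = _allocate_columns(
            diagnoses, scheme, config.imbalance_targets, nx, ny
        )

    textures = interpolated_textures(config.class_textures, config.difficulty)
    for c in scheme.labels:
        if c not in textures:
            raise KeyError(f"no texture parameters for class {c!r}")

    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_slides)
    slides: list[SlideRecord] = []
    gt_tiles = {c: 0 for c in scheme.labels}
    stride = T // 2
    f = math.sqrt(config.annotated_fraction)
    for i, diag in enumerate(diagnoses):
        rng = np.random.default_rng(children[i])
        runs = [(c, k) for c, k in per_slide[i].items()]
        order = rng.permutation(len(runs))
        runs = [runs[j] for j in order]
        width, height = nx * T, ny * T
        image = np.empty((height, width, 3), dtype=np.uint8)
        rois: list[ROIAnnotation] = []
        x0 = 0
        for label, k in runs:
            w = k * T
            image[:, x0 : x0 + w] = render_class_texture(
                label, (w, height), textures[label], rng
            )
            m_cols = max(1, round(f * k))
            m_rows = max(1, round(f * ny))
            col_off = int(rng.integers(0, k - m_cols + 1))
            row_off = int(rng.integers(0, ny - m_rows + 1))
            roi = ROIAnnotation(
                x=x0 + col_off * T,
                y=row_off * T,
                width=m_cols * T,
                height=m_rows * T,
                label=label,
            )
            rois.append(roi)
            gt_tiles[label] += count_tiles(roi.width, roi.height, T, stride)
            x0 += w
        slides.append(
            SlideRecord(
                slide_id=f"slide_{i:03d}",
                width=width,
                height=height,
                diagnosis=diag,
                rois=rois,
                image=image,
            )
        )

    total = sum(gt_tiles.values())
    shares = {c: gt_tiles[c] / total for c in scheme.labels if gt_tiles[c]}
    devs = [
        abs(shares.get(c, 0.0) - t) / t
        for c, t in config.imbalance_targets.items()
        if t > 0
    ]
    return Cohort(
        slides=slides,
        scheme=scheme,
        config=config,
        realized_tile_shares=shares,
        max_relative_share_deviation=max(devs) if devs else 0.0,
    )


def split_cohort(
    slides: list[SlideRecord], test_fraction: float = 0.25, seed: int = 0
) -> tuple[list[SlideRecord], list[SlideRecord]]:
    """Slide-level train/test split, stratified by diagnosis.

    Within each diagnosis the slides are shuffled with the given seed and
    ``round(test_fraction * n)`` of them go to the test side; a diagnosis
    with a single slide stays in the training set.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    by_diag: dict[str, list[SlideRecord]] = {}
    for s in slides:
        by_diag.setdefault(s.diagnosis, []).append(s)
    train, test = [], []
    for d in sorted(by_diag):
        group = by_diag[d]
        if len(group) < 2:
            train.extend(group)
            continue
        idx = rng.permutation(len(group))
        n_test = min(len(group) - 1, max(1, round(test_fraction * len(group))))
        test_ids = {group[j].slide_id for j in idx[:n_test]}
        for s in group:
            (test if s.slide_id in test_ids else train).append(s)
    train.sort(key=lambda s: s.slide_id)
    test.sort(key=lambda s: s.slide_id)
    return train, test
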