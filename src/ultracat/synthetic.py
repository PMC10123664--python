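"""Procedural stand-in for a photographic image database.

The pipeline's scientific claims are about *relationships* — transfer
learning beats training from scratch, augmentation buys rotation robustness,
patch scrambling below the cue scale destroys categorization, dataset
composition induces cross-task bias.  To exercise those relationships
without any download, this module generates a toy hyperonym hierarchy
(root → {animal, artifact, neutral} → leaves) and renders images whose
class-discriminative content is a low-level texture statistic:

* **animal-like** leaves carry curved, orientation-isotropic structure
  (soft rings/arcs at a characteristic radius);
* **artifact-like** leaves carry rectilinear structure (an oriented grating
  patch at a characteristic wavelength, vertical by default and therefore
  rotation-*sensitive* unless ``rotation_invariant_cues`` is set);
* **neutral** leaves carry background clutter only.

Nuisance variation (position, scale, per-image color tint, clutter) is
class-independent.  ``cross_category_exclusion`` controls the anti-
correlation between the two superordinate cues within one image: with that
probability an image carries only its own branch's cue, otherwise the
opposite cue is superimposed as well.  With ``signal=False`` every leaf
renders pure clutter, making labels statistically independent of pixels —
the 'random' control condition.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import MissingNodeError, TaskUndefinedError
from .hierarchy import SynsetGraph

__all__ = [
    "SyntheticSpec",
    "generate_hierarchy",
    "render_image",
    "make_source",
    "SyntheticImageSource",
    "orientation_features",
    "fit_orientation_probe",
    "probe_accuracy",
]

BRANCHES = ("animal", "artifact", "neutral")
ROOT = "entity"


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for the toy hierarchy and its images.

    Lengths are fractions of the image side so the same spec renders at any
    resolution; the side must be divisible by 32 so every default patch size
    of the shuffle battery tiles the image exactly.
    """

    n_animal: int = 8
    n_artifact: int = 8
    n_neutral: int = 4
    side: int = 256
    #: amplitude of the class cue relative to the [0, 1] intensity range
    cue_contrast: float = 0.55
    #: amplitude factor of the opposite-branch cue when superimposed; < 1
    #: because the intruding category is a minor element of the scene
    cross_cue_attenuation: float = 0.6
    #: sd of the smoothed background clutter
    clutter: float = 0.10
    #: grating wavelength (fraction of side); 0.1875 → 48 px at 256
    wavelength_frac: float = 0.1875
    #: Gaussian envelope sd of the grating patch (fraction of side)
    envelope_frac: float = 0.2
    ring_radius_frac: float = 0.11
    ring_width_frac: float = 0.04
    n_rings: int = 4
    #: nuisances: max centre offset (fraction of side), object scale range
    offset_frac: float = 0.12
    scale_range: tuple[float, float] = (0.85, 1.2)
    tint: float = 0.04
    #: P(an image carries only its own branch's cue)
    cross_category_exclusion: float = 0.9
    #: if True, grating orientation is uniform per image instead of vertical
    rotation_invariant_cues: bool = False
    #: if False, labels are independent of pixels (pure clutter everywhere)
    signal: bool = True

    def __post_init__(self) -> None:
        if self.side % 32 != 0:
            raise ValueError("image side must be divisible by 32")
        if not 0.0 <= self.cross_category_exclusion <= 1.0:
            raise ValueError("cross_category_exclusion must lie in [0, 1]")
        if self.n_animal < 0 or self.n_artifact < 0 or self.n_neutral < 0:
            raise ValueError("leaf counts must be nonnegative")

    @property
    def branch_counts(self) -> dict[str, int]:
        return {"animal": self.n_animal, "artifact": self.n_artifact, "neutral": self.n_neutral}

    def with_(self, **kwargs) -> "SyntheticSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def leaf_name(branch: str, i: int) -> str:
    return f"{branch}_{i:03d}"


def _leaf_branch(spec: SyntheticSpec, label: str) -> str:
    parts = label.rsplit("_", 1)
    if len(parts) == 2 and parts[0] in BRANCHES and parts[1].isdigit():
        branch, idx = parts[0], int(parts[1])
        if idx < spec.branch_counts[branch]:
            return branch
    raise MissingNodeError(f"label {label!r} does not belong to this synthetic hierarchy")


def generate_hierarchy(spec: SyntheticSpec, seed: int = 0) -> SynsetGraph:
    """Build the toy DAG root → {animal, artifact, neutral} → leaves.

    The structure and leaf order are functions of the spec alone, so class
    indices are stable across seeds; ``seed`` is accepted for API symmetry
    with the renderer.
    """
    counts = spec.branch_counts
    if sum(counts.values()) == 0:
        raise TaskUndefinedError("no leaves in any branch: the hierarchy is empty")
    edges = []
    leaves: list[str] = []
    for branch in BRANCHES:
        if counts[branch] == 0:
            continue
        edges.append((branch, ROOT))
        for i in range(counts[branch]):
            name = leaf_name(branch, i)
            edges.append((name, branch))
            leaves.append(name)
    return SynsetGraph.from_edges(edges, leaves)


def _leaf_params(label: str) -> np.random.Generator:
    """Leaf-identity RNG: stable per-leaf style parameters (CRC-seeded)."""
    return np.random.default_rng(zlib.crc32(label.encode("utf-8")))


def _clutter(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    noise = rng.standard_normal((spec.side, spec.side))
    smooth = gaussian_filter(noise, sigma=spec.side / 32.0, mode="wrap")
    sd = smooth.std()
    if sd > 0:
        smooth /= sd
    return spec.clutter * smooth


def _grid(side: int) -> tuple[np.ndarray, np.ndarray]:
    c = (side - 1) / 2.0
    y, x = np.mgrid[0:side, 0:side]
    return y - c, x - c


def _ring_cue(rng: np.random.Generator, spec: SyntheticSpec, leaf_rng: np.random.Generator,
              scale: float, dy: float, dx: float) -> np.ndarray:
    """Orientation-isotropic curved structure: a few soft annuli."""
    side = spec.side
    y, x = _grid(side)
    n = int(np.clip(spec.n_rings + leaf_rng.integers(-1, 2), 1, None))
    # leaf identity = characteristic ring radius (wide spread across leaves)
    radius0 = spec.ring_radius_frac * side * scale * (0.7 + 0.8 * leaf_rng.random())
    cue = np.zeros((side, side))
    for _ in range(n):
        cy = dy + rng.uniform(-0.15, 0.15) * side
        cx = dx + rng.uniform(-0.15, 0.15) * side
        r = radius0 * rng.uniform(0.7, 1.3)
        w = max(spec.ring_width_frac * side * scale, 1.0)
        d = np.hypot(y - cy, x - cx)
        sign = rng.choice((-1.0, 1.0))
        cue += sign * np.exp(-0.5 * ((d - r) / w) ** 2)
    peak = np.abs(cue).max()
    return cue / peak if peak > 0 else cue


def _grating_cue(rng: np.random.Generator, spec: SyntheticSpec, leaf_rng: np.random.Generator,
                 scale: float, dy: float, dx: float) -> np.ndarray:
    """Rectilinear oriented structure: a Gabor-like grating patch."""
    side = spec.side
    y, x = _grid(side)
    if spec.rotation_invariant_cues:
        theta = rng.uniform(0.0, np.pi)
    else:
        theta = np.deg2rad(rng.uniform(-5.0, 5.0))  # near-vertical stripes
    # leaf identity = characteristic wavelength (wide spread across leaves)
    lam = spec.wavelength_frac * side * scale * (0.7 + 0.8 * leaf_rng.random())
    phase = leaf_rng.uniform(0, 2 * np.pi) + rng.uniform(-0.5, 0.5)
    u = (x - dx) * np.cos(theta) + (y - dy) * np.sin(theta)
    carrier = np.sin(2 * np.pi * u / lam + phase)
    sigma = spec.envelope_frac * side * scale
    envelope = np.exp(-0.5 * (((x - dx) ** 2 + (y - dy) ** 2) / sigma**2))
    return carrier * envelope


def render_image(label: str, spec: SyntheticSpec, seed) -> np.ndarray:
    """Render one ``side × side`` RGB image (uint8) for a leaf label.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; identical
    (label, spec, seed) triples give identical bytes.
    """
    branch = _leaf_branch(spec, label)
    rng = np.random.default_rng(seed)
    leaf_rng = _leaf_params(label)

    base = 0.5 + _clutter(rng, spec)
    scale = rng.uniform(*spec.scale_range)
    dy = rng.uniform(-spec.offset_frac, spec.offset_frac) * spec.side
    dx = rng.uniform(-spec.offset_frac, spec.offset_frac) * spec.side

    if spec.signal and branch != "neutral":
        own = _ring_cue if branch == "animal" else _grating_cue
        base = base + spec.cue_contrast * own(rng, spec, leaf_rng, scale, dy, dx)
        if rng.random() > spec.cross_category_exclusion:
            other = _grating_cue if branch == "animal" else _ring_cue
            dy2 = rng.uniform(-spec.offset_frac, spec.offset_frac) * spec.side
            dx2 = rng.uniform(-spec.offset_frac, spec.offset_frac) * spec.side
            amp = spec.cue_contrast * spec.cross_cue_attenuation
            base = base + amp * other(rng, spec, leaf_rng, scale, dy2, dx2)

    tint = rng.uniform(-spec.tint, spec.tint, size=3)
    img = base[:, :, None] + tint[None, None, :]
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


class SyntheticImageSource:
    """Lazily rendering, caching image source over a synthetic hierarchy.

    Satisfies the dataset builder's contract: an ordered label set, a count
    per label, and deterministic addressing by ``(label, index)``.  Per-image
    seeds are derived from ``(master seed, crc32(label), index)`` so the
    content of an address never depends on rendering order.
    """

    def __init__(self, spec: SyntheticSpec, seed: int, images_per_label: int):
        if images_per_label < 1:
            raise ValueError("images_per_label must be >= 1")
        self.spec = spec
        self.seed = int(seed)
        self.images_per_label = int(images_per_label)
        self.graph = generate_hierarchy(spec)
        self._cache: dict[tuple[str, int], np.ndarray] = {}

    @property
    def labels(self) -> tuple[str, ...]:
        return self.graph.leaf_labels

    def count(self, label: str) -> int:
        _leaf_branch(self.spec, label)
        return self.images_per_label

    def get(self, label: str, index: int) -> np.ndarray:
        if not 0 <= index < self.count(label):
            raise IndexError(f"image index {index} out of range for label {label!r}")
        key = (label, index)
        if key not in self._cache:
            ss = np.random.SeedSequence(
                [self.seed, zlib.crc32(label.encode("utf-8")), index]
            )
            self._cache[key] = render_image(label, self.spec, ss)
        return self._cache[key]

    def __len__(self) -> int:
        return self.images_per_label * len(self.labels)


def make_source(spec: SyntheticSpec, seed: int, images_per_label: int) -> SyntheticImageSource:
    """Create a lazily rendering :class:`SyntheticImageSource`."""
    return SyntheticImageSource(spec, seed, images_per_label)


# ---------------------------------------------------------------------------
# Hand-crafted orientation statistics + linear probe.
#
# These ground the discriminability the learning experiments assume: the two
# branch cues separate in oriented-gradient-energy space, and the artifact
# cue (fixed near-vertical) is rotation-sensitive in the raw orientation
# histogram while the animal cue is not.
# ---------------------------------------------------------------------------

N_ORIENTATION_BINS = 8


def orientation_features(image: np.ndarray, include_invariants: bool = True) -> np.ndarray:
    """Gradient-orientation energy histogram of one RGB image.

    Returns the energy-normalized histogram of gradient orientations folded
    to [0, π) (``N_ORIENTATION_BINS`` bins), optionally followed by two
    rotation-invariant summaries: log total gradient energy and the circular
    resultant length of the doubled orientations (anisotropy; ~0 for
    isotropic curved structure, →1 for a single oriented grating).
    """
    gray = image.astype(np.float64).mean(axis=2) / 255.0
    gy, gx = np.gradient(gray)
    energy = gx * gx + gy * gy
    angle = np.mod(np.arctan2(gy, gx), np.pi)
    total = energy.sum()
    if total <= 0:
        hist = np.zeros(N_ORIENTATION_BINS)
        aniso = 0.0
    else:
        hist, _ = np.histogram(
            angle, bins=N_ORIENTATION_BINS, range=(0.0, np.pi), weights=energy
        )
        hist = hist / total
        aniso = np.abs((energy * np.exp(2j * angle)).sum()) / total
    if not include_invariants:
        return hist
    return np.concatenate([hist, [np.log1p(total), aniso]])


def _probe_dataset(
    spec: SyntheticSpec,
    seed: int,
    n_per_class: int,
    include_invariants: bool,
    rotate_deg: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    if spec.n_animal == 0 or spec.n_artifact == 0:
        raise TaskUndefinedError("probe needs both an animal and an artifact branch")
    rng = np.random.default_rng(seed)
    X, y = [], []
    for cls, branch in enumerate(("animal", "artifact")):
        n_leaves = spec.branch_counts[branch]
        for i in range(n_per_class):
            label = leaf_name(branch, int(rng.integers(n_leaves)))
            img = render_image(label, spec, np.random.SeedSequence([seed, cls, i]))
            if rotate_deg:
                from .transforms import TransformSpec, apply_transform

                img = apply_transform(img, TransformSpec(kind="rotation", angle=rotate_deg))
            X.append(orientation_features(img, include_invariants))
            y.append(cls)
    return np.asarray(X), np.asarray(y)


def fit_orientation_probe(
    spec: SyntheticSpec,
    seed: int = 0,
    n_train: int = 100,
    include_invariants: bool = True,
):
    """Fit a logistic-regression probe on orientation features (animal vs artifact)."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    X, y = _probe_dataset(spec, seed, n_train, include_invariants)
    probe = make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
    probe.fit(X, y)
    return probe


def probe_accuracy(
    probe,
    spec: SyntheticSpec,
    seed: int = 1,
    n_test: int = 100,
    include_invariants: bool = True,
    rotate_deg: float = 0.0,
) -> float:
    """Held-out accuracy of a fitted probe, optionally on rotated renders."""
    X, y = _probe_dataset(spec, seed, n_test, include_invariants, rotate_deg)
    return float((probe.predict(X) == y).mean())
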