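"""Seeded synthetic RCM-like stacks with known labels and boundary depths.

Real confocal stacks show three ordered strata whose reflectance textures
differ: the epidermis presents rounded cellular blobs, the dermis fibrous
collagen streaks, and the junction zone (DEJ) a patchy mixture of both.
Deeper slices progressively lose contrast as scattering attenuates the
signal.  The generator emulates exactly these properties — blob texture
above the first boundary, an increasing patchy dermal fraction across the
DEJ, anisotropic streak texture below, multiplicative contrast decay with
depth and additive sensor noise — so that every downstream stage (encoder,
sequence models, post-processing, metrics) can be exercised against known
per-slice labels and boundary depths.  It makes no attempt at photorealism:
no speckle statistics, no undulating 3-D junction surface, no optical
aberration model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stack_io import RCMStack, StrataLabelSequence

__all__ = [
    "TextureParams", "SyntheticStackSpec", "SyntheticDatasetConfig",
    "sample_spec", "generate_stack", "generate_dataset", "corrupt_labels",
    "SyntheticDataset",
]


@dataclass
class TextureParams:
    """Per-stratum texture knobs.

    ``epi_scale_px`` is the isotropic blob radius of the epidermal texture;
    ``derm_scales_px`` the (long, short) axes of the elongated dermal
    streaks; ``*_contrast`` the RMS amplitude of each texture around the
    mid-gray background.
    """

    epi_scale_px: float = 3.0
    epi_contrast: float = 0.22
    derm_scales_px: tuple = (5.0, 0.8)
    derm_contrast: float = 0.30
    dej_patch_scale_px: float = 6.0


@dataclass
class SyntheticStackSpec:
    """Everything needed to render one stack deterministically."""

    n_slices: int
    image_size: tuple = (64, 64)
    axial_step_um: float = 3.0
    b1: int = 0                      # first DEJ slice index
    b2: int = 0                      # first dermis slice index
    texture: TextureParams = field(default_factory=TextureParams)
    contrast_decay_rate: float = 0.03   # per-slice decay below the first boundary
    noise_sigma: float = 0.04
    depth_origin_um: float = 0.0
    seed: int = 0
    stack_id: str = "stack"
    subject_id: str = "subject"

    def __post_init__(self):
        if not (10 <= self.n_slices <= 101):
            raise ValueError("n_slices must be in [10, 101]")
        if not (0 < self.b1 < self.b2 < self.n_slices):
            raise ValueError("need 0 < b1 < b2 < n_slices")
        if self.contrast_decay_rate < 0 or self.noise_sigma < 0:
            raise ValueError("decay rate and noise sigma must be >= 0")


@dataclass
class SyntheticDatasetConfig:
    """Study-level knobs for a whole synthetic dataset.

    ``class_fraction_targets`` are the expected per-stack fractions of
    epidermis / DEJ / dermis slices; the defaults mirror the class balance
    of clinical stack collections, where the shallow epidermis dominates.
    Splits are subject-wise: all stacks of one subject land in one split.
    """

    n_stacks: int = 60
    class_fraction_targets: tuple = (0.44, 0.34, 0.22)
    subjects: int = 20
    split_fractions: tuple = (0.5, 0.2, 0.3)
    n_slices_range: tuple = (20, 46)
    image_size: tuple = (64, 64)
    axial_step_um: float = 3.0
    boundary_jitter_slices: float = 1.5
    contrast_decay_rate: float = 0.03
    noise_sigma: float = 0.04
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.class_fraction_targets, dtype=float)
        if (f <= 0).any() or (f >= 1).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("class fractions must lie in (0,1) and sum to 1")
        s = np.asarray(self.split_fractions, dtype=float)
        if (s < 0).any() or abs(s.sum() - 1.0) > 1e-9:
            raise ValueError("split fractions must be >= 0 and sum to 1")


def sample_spec(config: SyntheticDatasetConfig, rng: np.random.Generator,
                stack_id: str = "stack", subject_id: str = "subject",
                ) -> SyntheticStackSpec:
    """Draw one stack spec whose expected class fractions match the config.

    Boundary indices are placed at the target fractions of the stack depth
    plus symmetric integer-rounded Gaussian jitter, so E[b1] ~ f_epi * n and
    E[b2] ~ (f_epi + f_dej) * n.
    """
    f_epi, f_dej, _ = config.class_fraction_targets
    n = int(rng.integers(config.n_slices_range[0], config.n_slices_range[1] + 1))
    jit = config.boundary_jitter_slices
    b1 = int(np.rint(f_epi * n + rng.normal(0.0, jit)))
    b2 = int(np.rint((f_epi + f_dej) * n + rng.normal(0.0, jit)))
    b1 = int(np.clip(b1, 1, n - 3))
    b2 = int(np.clip(b2, b1 + 1, n - 1))
    if not (0 < b1 < b2 < n):
        raise ValueError("class fraction targets leave no room for b1 < b2")
    return SyntheticStackSpec(
        n_slices=n, image_size=tuple(config.image_size),
        axial_step_um=config.axial_step_um, b1=b1, b2=b2,
        contrast_decay_rate=config.contrast_decay_rate,
        noise_sigma=config.noise_sigma,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
        stack_id=stack_id, subject_id=subject_id)


def _blob_texture(rng, shape, scale, contrast):
    """White noise smoothed by an isotropic Gaussian, RMS-normalized."""
    noise = rng.standard_normal(shape)
    tex = ndimage.gaussian_filter(noise, scale, mode="wrap")
    return contrast * tex / max(tex.std(), 1e-12)

def _streak_texture(rng, shape, scales, contrast):
    """White noise smoothed by an elongated, randomly oriented Gaussian."""
    pad = int(4 * max(scales)) + 8
    big = (shape[0] + 2 * pad, shape[1] + 2 * pad)
    noise = rng.standard_normal(big)
    tex = ndimage.gaussian_filter(noise, scales, mode="wrap")
    angle = float(rng.uniform(0.0, 180.0))
    tex = ndimage.rotate(tex, angle, reshape=False, order=1, mode="wrap")
    tex = tex[pad:pad + shape[0], pad:pad + shape[1]]
    return contrast * tex / max(tex.std(), 1e-12)

def _patch_mask(rng, shape, scale, fraction):
    """Smooth random field thresholded so ~``fraction`` of pixels are on."""
    if fraction <= 0.0:
        return np.zeros(shape, dtype=bool)
    if fraction >= 1.0:
        return np.ones(shape, dtype=bool)
    fieldv = ndimage.gaussian_filter(rng.standard_normal(shape), scale,
                                     mode="wrap")
    thresh = np.quantile(fieldv, 1.0 - fraction)
    return fieldv >= thresh


def generate_stack(spec: SyntheticStackSpec):
    """Render one stack; returns (RCMStack, StrataLabelSequence, boundaries).

    Slice ``i`` is epidermis for i < b1, DEJ for b1 <= i < b2, dermis
    otherwise.  DEJ slices mix the two textures spatially with a dermal
    pixel fraction ramping linearly from 0 at b1 to 1 at b2 - 1.  Slices at
    or below b1 are attenuated by ``exp(-rate * (i - b1))`` before additive
    Gaussian noise.  True boundary depths are the depths of the first slice
    of each deeper stratum.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    tp = spec.texture
    slices = np.empty((spec.n_slices, h, w))
    labels = np.empty(spec.n_slices, dtype=np.int64)
    for i in range(spec.n_slices):
        if i < spec.b1:
            tex = _blob_texture(rng, (h, w), tp.epi_scale_px, tp.epi_contrast)
            labels[i] = 0
        elif i < spec.b2:
            epi = _blob_texture(rng, (h, w), tp.epi_scale_px, tp.epi_contrast)
            derm = _streak_texture(rng, (h, w), tp.derm_scales_px,
                                   tp.derm_contrast)
            span = max(spec.b2 - 1 - spec.b1, 1)
            frac = (i - spec.b1) / span
            mask = _patch_mask(rng, (h, w), tp.dej_patch_scale_px, frac)
            tex = np.where(mask, derm, epi)
            labels[i] = 1
        else:
            tex = _streak_texture(rng, (h, w), tp.derm_scales_px,
                                  tp.derm_contrast)
            labels[i] = 2
        img = 0.5 + tex
        if i >= spec.b1 and spec.contrast_decay_rate > 0:
            img = img * np.exp(-spec.contrast_decay_rate * (i - spec.b1))
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=(h, w))
        slices[i] = np.clip(img, 0.0, 1.0)
    stack = RCMStack(slices, axial_step_um=spec.axial_step_um,
                     depth_origin_um=spec.depth_origin_um,
                     stack_id=spec.stack_id, subject_id=spec.subject_id)
    seq = StrataLabelSequence(labels, stack_id=spec.stack_id)
    boundaries = (spec.depth_origin_um + spec.b1 * spec.axial_step_um,
                  spec.depth_origin_um + spec.b2 * spec.axial_step_um)
    return stack, seq, boundaries


@dataclass
class SyntheticDataset:
    stacks: list
    labels: list
    boundaries: list                 # (epi_dej_um, dej_derm_um) per stack
    manifest: "object"               # pandas DataFrame

    def split(self, name: str):
        """Indices of stacks in the given split (train/val/test)."""
        return [i for i, s in enumerate(self.manifest["split"]) if s == name]


def generate_dataset(config: SyntheticDatasetConfig) -> SyntheticDataset:
    """Generate ``n_stacks`` stacks with a subject-wise train/val/test split.

    Subjects are partitioned first (no subject crosses splits, mirroring
    patient-wise stratification of clinical data), then stacks are dealt to
    subjects round-robin.
    """
    import pandas as pd

    if config.n_stacks < config.subjects:
        raise ValueError("need n_stacks >= subjects")
    rng = np.random.default_rng(config.seed)
    subjects = [f"subj{j:03d}" for j in range(config.subjects)]
    perm = rng.permutation(config.subjects)
    n_train = int(round(config.split_fractions[0] * config.subjects))
    n_val = int(round(config.split_fractions[1] * config.subjects))
    n_train = min(n_train, config.subjects)
    n_val = min(n_val, config.subjects - n_train)
    split_of = {}
    for rank, j in enumerate(perm):
        split_of[subjects[j]] = ("train" if rank < n_train else
                                 "val" if rank < n_train + n_val else "test")
    if config.subjects == 1:
        warnings.warn("single subject: all stacks land in one split")
    stacks, labels, boundaries, rows = [], [], [], []
    for k in range(config.n_stacks):
        subj = subjects[k % config.subjects]
        spec = sample_spec(config, rng, stack_id=f"stack{k:03d}",
                           subject_id=subj)
        st, lab, bnd = generate_stack(spec)
        stacks.append(st)
        labels.append(lab)
        boundaries.append(bnd)
        rows.append({"stack_id": spec.stack_id, "subject_id": subj,
                     "split": split_of[subj], "n_slices": spec.n_slices,
                     "b1": spec.b1, "b2": spec.b2,
                     "axial_step_um": spec.axial_step_um,
                     "depth_origin_um": spec.depth_origin_um,
                     "epi_dej_um": bnd[0], "dej_derm_um": bnd[1]})
    return SyntheticDataset(stacks, labels, boundaries, pd.DataFrame(rows))


def corrupt_labels(labels: StrataLabelSequence, flip_prob: float,
                   window: int, rng: np.random.Generator) -> StrataLabelSequence:
    """Flip labels near the true boundaries to emulate boundary ambiguity.

    Slices within ``window`` of a boundary index (the first slice of the
    deeper stratum) are independently swapped across that boundary with
    probability ``flip_prob``; slices far from any boundary are untouched.
    This mimics the real failure mode of slice classifiers: transitional
    slices contain features of both strata.
    """
    if not (0.0 <= flip_prob <= 1.0):
        raise ValueError("flip_prob must lie in [0, 1]")
    lab = labels.labels.copy()
    bounds = []
    ge1 = np.nonzero(labels.labels >= 1)[0]
    eq2 = np.nonzero(labels.labels == 2)[0]
    if len(ge1):
        bounds.append(int(ge1[0]))
    if len(eq2):
        bounds.append(int(eq2[0]))
    for i in range(len(lab)):
        dists = [abs(i - b) for b in bounds]
        if not dists or min(dists) > window:
            continue
        if rng.random() >= flip_prob:
            continue
        b = bounds[int(np.argmin(dists))]
        # swap across the nearest boundary: shallow side takes the deeper
        # class and vice versa
        shallow = labels.labels[b - 1] if b > 0 else labels.labels[b]
        deep = labels.labels[b]
        lab[i] = int(deep) if labels.labels[i] == shallow else int(shallow)
    return StrataLabelSequence(lab, stack_id=labels.stack_id)
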