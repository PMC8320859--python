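"""Synthetic hierarchical face/mouth/texture data with known planted structure.

Every generator here emulates one of the two study designs the package
targets — static frontal faces with sex, subject, and expression effects, and
dynamic 3D mouth outlines through a full smile cycle — plus face-like
grayscale images for appearance models.  All planted effects (directions,
per-subject coefficients, phase boundaries) are returned as ground truth so
model recovery can be scored exactly.

Randomness is fully reproducible: every effect family draws from its own
named substream derived from the seed via ``SeedSequence`` spawn keys, and
per-subject streams are keyed by subject index, so enlarging a design leaves
already-generated subjects bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LandmarkShape, ShapeDataset
from .smile import PhaseSegmentation, Trajectory

# ---------------------------------------------------------------------------
# built-in templates

#: 21 facial landmarks (mm, x to subject's right, y up), frontal view
FACE_LANDMARK_NAMES = (
    "g", "n", "enl", "enr", "exl", "exr", "psl", "psr", "pil", "pir",
    "prn", "sn", "all", "alr", "ls", "cphl", "cphr", "li", "chl", "chr", "pg",
)

FACE_TEMPLATE_2D = np.array([
    [0.0, 70.0],    # glabella
    [0.0, 55.0],    # nasion
    [-12.0, 42.0],  # endocanthion L
    [12.0, 42.0],   # endocanthion R
    [-32.0, 43.0],  # exocanthion L
    [32.0, 43.0],   # exocanthion R
    [-22.0, 47.0],  # palpebrale superius L
    [22.0, 47.0],   # palpebrale superius R
    [-22.0, 39.0],  # palpebrale inferius L
    [22.0, 39.0],   # palpebrale inferius R
    [0.0, 20.0],    # pronasale
    [0.0, 10.0],    # subnasale
    [-12.0, 13.0],  # alare L
    [12.0, 13.0],   # alare R
    [0.0, -2.0],    # labiale superius
    [-5.0, 1.0],    # crista philtri L
    [5.0, 1.0],     # crista philtri R
    [0.0, -18.0],   # labiale inferius
    [-24.0, -9.0],  # chelion L
    [24.0, -9.0],   # chelion R
    [0.0, -45.0],   # pogonion
])

#: 13 points along the outer mouth boundary (mm; x right, y up, z forward)
MOUTH_TEMPLATE_3D = np.array([
    [-25.0, 0.0, 0.0],   # chelion L
    [-18.0, 6.0, 2.0],
    [-9.0, 9.0, 3.0],
    [0.0, 10.0, 3.5],
    [9.0, 9.0, 3.0],
    [18.0, 6.0, 2.0],
    [25.0, 0.0, 0.0],    # chelion R
    [20.0, -5.0, 1.5],
    [12.0, -8.0, 2.5],
    [4.0, -10.0, 3.0],
    [-4.0, -10.0, 3.0],
    [-12.0, -8.0, 2.5],
    [-20.0, -5.0, 1.5],
])

MOUTH_CHELION_LEFT = 0
MOUTH_CHELION_RIGHT = 6


def _field(k: int, d: int, entries: dict[int, tuple]) -> np.ndarray:
    f = np.zeros((k, d))
    for i, v in entries.items():
        f[i] = v
    return f


def face_smile_field() -> np.ndarray:
    """Smile displacement for the 21-point face: mouth widens, corners rise,
    lips part slightly, eyes narrow, nose base widens a touch."""
    return _field(21, 2, {
        18: (-6.0, 4.0), 19: (6.0, 4.0),       # chelions widen and rise
        14: (0.0, 1.0), 17: (0.0, -2.0),       # lips part
        15: (-1.0, 1.0), 16: (1.0, 1.0),       # philtrum follows
        6: (0.0, -1.5), 7: (0.0, -1.5),        # upper lids drop
        8: (0.0, 1.5), 9: (0.0, 1.5),          # lower lids rise
        12: (-1.5, 0.0), 13: (1.5, 0.0),       # nose base widens
    })


def face_group_field() -> np.ndarray:
    """Sex-like contrast: eye spacing and mouth width vs face length."""
    return _field(21, 2, {
        2: (-2.0, 0.0), 3: (2.0, 0.0),
        4: (-3.0, 0.0), 5: (3.0, 0.0),
        6: (-2.0, 0.0), 7: (2.0, 0.0),
        8: (-2.0, 0.0), 9: (2.0, 0.0),
        18: (-2.5, 0.0), 19: (2.5, 0.0),
        0: (0.0, -3.0), 20: (0.0, 3.0),        # shorter face
    })


def face_subject_field() -> np.ndarray:
    """Between-subject contrast: overall face elongation."""
    t = FACE_TEMPLATE_2D.copy()
    f = np.zeros_like(t)
    f[:, 1] = (t[:, 1] - t[:, 1].mean()) / 40.0 * 3.0
    return f


def mouth_smile_field() -> np.ndarray:
    """Smile displacement for the mouth outline: corners draw wide and up,
    lips flatten and draw back.  Chelion y/z components are mirror-symmetric
    so the inter-chelion distance stays exactly linear in the amplitude."""
    f = np.zeros((13, 3))
    x = MOUTH_TEMPLATE_3D[:, 0]
    y = MOUTH_TEMPLATE_3D[:, 1]
    f[:, 0] = x / 25.0 * 6.0            # widen proportionally to x
    f[:, 1] = -y / 10.0 * 2.0           # lips flatten
    f[:, 2] = -1.0                      # drawn back
    f[MOUTH_CHELION_LEFT] = (-6.0, 2.0, -1.5)
    f[MOUTH_CHELION_RIGHT] = (6.0, 2.0, -1.5)
    return f


def mouth_subject_field() -> np.ndarray:
    """Between-subject contrast: upturned vs downturned corners, lip
    prominence.  Chelion displacements are equal on both sides, leaving the
    rest inter-chelion distance untouched."""
    f = np.zeros((13, 3))
    y = MOUTH_TEMPLATE_3D[:, 1]
    f[:, 1] = -y / 10.0 * 1.0           # thinner/thicker lips
    f[:, 2] = y / 10.0 * 0.8            # lip prominence
    f[MOUTH_CHELION_LEFT] = (0.0, 1.5, 0.0)
    f[MOUTH_CHELION_RIGHT] = (0.0, 1.5, 0.0)
    return f


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _orthogonalize(fields: list[np.ndarray]) -> list[np.ndarray]:
    """Gram-Schmidt on flattened fields, keeping the first field pure."""
    out: list[np.ndarray] = []
    for f in fields:
        v = f.reshape(-1).astype(float)
        for u in out:
            v = v - (v @ u) * u
        out.append(_unit(v))
    return out


def _stream(seed: int, family: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(family, index)))


# ---------------------------------------------------------------------------
# hierarchical shape data

@dataclass
class ShapeSimConfig:
    """Design of the hierarchical shape simulation.

    Sigmas are in template coordinate units (mm).  The three planted effect
    fields default to the built-in face fields and are orthogonalized
    (condition kept pure, then group, then subject) so each level carries an
    independent planted direction.
    """

    template: np.ndarray = field(default_factory=lambda: FACE_TEMPLATE_2D.copy())
    landmark_names: tuple = FACE_LANDMARK_NAMES
    n_groups: int = 2
    n_subjects_per_group: int = 10
    conditions: tuple = ("neutral", "smile")
    sigma_group: float = 5.0
    sigma_subject: float = 5.0
    sigma_condition: float = 5.0
    sigma_noise: float = 0.5
    group_field: np.ndarray | None = None
    subject_field: np.ndarray | None = None
    condition_field: np.ndarray | None = None
    orthogonalize: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("sigma_group", "sigma_subject", "sigma_condition", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_groups < 1 or self.n_subjects_per_group < 1 or not self.conditions:
            raise ValueError("design sizes must be positive")


def generate_hierarchical_shapes(config: ShapeSimConfig) -> tuple[ShapeDataset, dict]:
    """Template + group + subject + condition effects + i.i.d. point noise.

    Group effects alternate ``+/- sigma_group`` along the group direction
    (for more than two groups, evenly spaced centered weights are used);
    subject coefficients are drawn once per subject with SD ``sigma_subject``;
    the condition field is added (scaled by ``sigma_condition``) for every
    non-baseline condition; point noise is isotropic Gaussian with SD
    ``sigma_noise`` per coordinate.  Returns the dataset and a ground-truth
    record with the (unit, flattened) planted directions and all drawn
    coefficients.
    """
    cfg = config
    template = np.asarray(cfg.template, float)
    k, d = template.shape
    fields = [
        cfg.condition_field if cfg.condition_field is not None else face_smile_field(),
        cfg.group_field if cfg.group_field is not None else face_group_field(),
        cfg.subject_field if cfg.subject_field is not None else face_subject_field(),
    ]
    if cfg.orthogonalize:
        cond_dir, group_dir, subj_dir = _orthogonalize(fields)
    else:
        cond_dir, group_dir, subj_dir = (_unit(f.reshape(-1)) for f in fields)

    # evenly spaced, centered group weights; two groups give +1 / -1
    gw = np.linspace(1.0, -1.0, cfg.n_groups) if cfg.n_groups > 1 else np.zeros(1)

    vectors, rows = [], []
    subj_coefs = {}
    flat_template = template.reshape(-1)
    n_subj_total = 0
    for g in range(cfg.n_groups):
        for s in range(cfg.n_subjects_per_group):
            sid = f"g{g + 1}s{s + 1}"
            subj_rng = _stream(cfg.seed, family=0, index=n_subj_total)
            coef = subj_rng.normal(0.0, 1.0)
            subj_coefs[sid] = coef
            for c, cond in enumerate(cfg.conditions):
                noise_rng = _stream(cfg.seed, family=1,
                                    index=n_subj_total * len(cfg.conditions) + c)
                z = (flat_template
                     + cfg.sigma_group * gw[g] * group_dir
                     + cfg.sigma_subject * coef * subj_dir
                     + cfg.sigma_condition * float(c > 0) * cond_dir
                     + noise_rng.normal(0.0, cfg.sigma_noise, k * d))
                vectors.append(z)
                rows.append({"dataset_id": "sim", "group_id": f"g{g + 1}",
                             "subject_id": sid, "condition_id": cond,
                             "frame_index": ""})
            n_subj_total += 1

    dataset = ShapeDataset(np.vstack(vectors), pd.DataFrame(rows), d,
                           cfg.landmark_names if k == len(cfg.landmark_names) else None)
    truth = {
        "group_direction": group_dir,
        "subject_direction": subj_dir,
        "condition_direction": cond_dir,
        "group_weights": {f"g{g + 1}": gw[g] for g in range(cfg.n_groups)},
        "subject_coefficients": subj_coefs,
        "template": template,
    }
    return dataset, truth


# ---------------------------------------------------------------------------
# smile trajectories

@dataclass
class SmileSimConfig:
    """Design of the dynamic-smile simulation.

    ``phase_fractions`` are the durations of the seven phases as fractions of
    the trajectory (must sum to 1).  The amplitude follows the 0.5 baseline,
    a rescaled-logistic rise through onset with its inflexion at the
    acceleration/deceleration boundary, a plateau at ``peak`` through apex,
    and a mirrored fall through offset.  ``steepness`` is the logistic rate
    per frame.  ``noise_sd`` is Gaussian landmark noise in mm; ``subject_sd``
    scales the per-subject mouth-shape effect.
    """

    n_subjects: int = 5
    n_frames: int = 150
    phase_fractions: tuple = (0.24, 0.033, 0.033, 0.22, 0.033, 0.033, 0.408)
    peak: float = 0.75
    steepness: float = 0.8
    noise_sd: float = 0.0
    subject_sd: float = 2.0
    frame_rate: float | None = 24.0
    seed: int = 0

    def __post_init__(self):
        fr = np.asarray(self.phase_fractions, float)
        if fr.size != 7 or np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("phase_fractions must be 7 positive values summing to 1")
        if self.peak <= 0.5:
            raise ValueError("peak amplitude must exceed the 0.5 baseline (no smile)")
        if not 20 <= self.n_frames:
            raise ValueError("need at least 20 frames")


def smile_profile(config: SmileSimConfig) -> tuple[np.ndarray, tuple[int, ...]]:
    """Ground-truth amplitude profile and the six phase-boundary frames."""
    n = config.n_frames
    edges = np.rint(np.cumsum(config.phase_fractions)[:6] * n).astype(int)
    e1, e2, e3, e4, e5, e6 = (int(e) for e in edges)
    t = np.arange(n, dtype=float)
    amp = np.full(n, 0.5)
    A = config.peak - 0.5
    s = config.steepness

    def rescaled_logistic(tt, mid, lo, hi):
        L = 1.0 / (1.0 + np.exp(-s * (tt - mid)))
        L0 = 1.0 / (1.0 + np.exp(-s * (lo - mid)))
        L1 = 1.0 / (1.0 + np.exp(-s * (hi - mid)))
        return (L - L0) / (L1 - L0)

    rise = slice(e1, e3)
    amp[rise] = 0.5 + A * rescaled_logistic(t[rise], e2, e1, e3)
    amp[e3:e4] = config.peak
    fall = slice(e4, e6)
    amp[fall] = 0.5 + A * (1.0 - rescaled_logistic(t[fall], e5, e4, e6))
    return amp, (e1, e2, e3, e4, e5, e6)


def smile_displacement_scale(config: SmileSimConfig) -> float:
    """Mean per-landmark displacement (mm) of the full smile, the natural
    scale against which landmark noise is expressed."""
    f = mouth_smile_field()
    d0 = float(np.linalg.norm(MOUTH_TEMPLATE_3D[MOUTH_CHELION_RIGHT]
                              - MOUTH_TEMPLATE_3D[MOUTH_CHELION_LEFT]))
    dx = f[MOUTH_CHELION_RIGHT, 0] - f[MOUTH_CHELION_LEFT, 0]
    f = f * (2.0 * d0 * (config.peak - 0.5) / dx)
    return float(np.linalg.norm(f, axis=1).mean())


def generate_smile_trajectories(
    config: SmileSimConfig,
    shape_config: ShapeSimConfig | None = None,
) -> tuple[list[Trajectory], list[PhaseSegmentation], dict]:
    """Mouth trajectories following the ground-truth amplitude profile.

    Each subject's rest mouth is the 13-point template plus a per-subject
    shape effect; every frame adds the smile displacement scaled by
    ``(a(t) - 0.5) / (peak - 0.5)`` plus optional landmark noise.  The smile
    field is normalized so the inter-chelion distance reproduces the profile
    exactly; with zero noise ``smile_amplitude`` returns the profile to
    machine precision.  An optional ``shape_config`` overrides the
    subject-effect and noise SDs (``sigma_subject``, ``sigma_noise``).
    """
    cfg = config
    subject_sd = shape_config.sigma_subject if shape_config else cfg.subject_sd
    noise_sd = shape_config.sigma_noise if shape_config else cfg.noise_sd
    profile, bounds = smile_profile(cfg)

    template = MOUTH_TEMPLATE_3D
    smile_f = mouth_smile_field()
    subj_f = mouth_subject_field()
    # scale the smile field so full activation moves the chelion distance
    # from d0 to 2*d0*peak
    d0 = float(np.linalg.norm(template[MOUTH_CHELION_RIGHT]
                              - template[MOUTH_CHELION_LEFT]))
    dx = smile_f[MOUTH_CHELION_RIGHT, 0] - smile_f[MOUTH_CHELION_LEFT, 0]
    smile_f = smile_f * (2.0 * d0 * (cfg.peak - 0.5) / dx)

    activation = (profile - 0.5) / (cfg.peak - 0.5)
    trajectories, segmentations = [], []
    subj_coefs = {}
    for i in range(cfg.n_subjects):
        sid = f"s{i + 1}"
        coef = _stream(cfg.seed, family=2, index=i).normal(0.0, 1.0)
        subj_coefs[sid] = coef
        rest = template + subject_sd * coef * subj_f
        frames = rest[None] + activation[:, None, None] * smile_f[None]
        if noise_sd > 0:
            noise_rng = _stream(cfg.seed, family=3, index=i)
            frames = frames + noise_rng.normal(0.0, noise_sd, frames.shape)
        trajectories.append(Trajectory(frames, subject_id=sid,
                                       frame_rate=cfg.frame_rate))
        segmentations.append(PhaseSegmentation(bounds, cfg.n_frames))

    truth = {
        "profile": profile,
        "boundaries": bounds,
        "chelion_left": MOUTH_CHELION_LEFT,
        "chelion_right": MOUTH_CHELION_RIGHT,
        "smile_field": smile_f,
        "subject_field": subj_f,
        "subject_coefficients": subj_coefs,
    }
    return trajectories, segmentations, truth


# ---------------------------------------------------------------------------
# texture images

@dataclass
class TextureSimConfig:
    """Design of the face-like grayscale image simulation (intensities in
    [0, 1] before illumination jitter)."""

    height: int = 48
    width: int = 48
    n_groups: int = 2
    n_subjects_per_group: int = 8
    conditions: tuple = ("neutral", "smile")
    group_contrast: float = 0.08
    condition_contrast: float = 0.12
    subject_sd: float = 0.03
    illum_gain_sd: float = 0.0
    illum_offset_sd: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[:h, :w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_texture_images(config: TextureSimConfig):
    """Face-like rasters with planted group/condition patches.

    Returns ``(images, roi_mask, labels, truth)`` where ``images`` is an
    ``(n, H, W)`` float stack, ``roi_mask`` a :class:`~mpcaface.texture.RoiMask`
    over the face ellipse, ``labels`` the hierarchical label frame, and
    ``truth`` carries the patch masks and effect images.  The group effect
    brightens the cheek patches (sign alternating by group), the condition
    effect brightens the mouth patch for the non-baseline condition, subjects
    get a smooth random field, and each image draws its own illumination
    gain/offset jitter.
    """
    from scipy.ndimage import gaussian_filter

    from .texture import RoiMask

    cfg = config
    h, w = cfg.height, cfg.width
    face = _ellipse_mask(h, w, h * 0.52, w * 0.5, h * 0.42, w * 0.36)
    base = np.full((h, w), 0.25)
    base[face] = 0.65
    for cx in (w * 0.36, w * 0.64):                       # eyes
        base[_ellipse_mask(h, w, h * 0.40, cx, h * 0.045, w * 0.07)] = 0.30
    mouth = _ellipse_mask(h, w, h * 0.72, w * 0.5, h * 0.05, w * 0.14)
    base[mouth] = 0.35
    cheeks = (_ellipse_mask(h, w, h * 0.58, w * 0.30, h * 0.09, w * 0.09)
              | _ellipse_mask(h, w, h * 0.58, w * 0.70, h * 0.09, w * 0.09))

    gw = np.linspace(1.0, -1.0, cfg.n_groups) if cfg.n_groups > 1 else np.zeros(1)
    images, rows = [], []
    n_subj_total = 0
    n_img = 0
    for g in range(cfg.n_groups):
        for s in range(cfg.n_subjects_per_group):
            sid = f"g{g + 1}s{s + 1}"
            srng = _stream(cfg.seed, family=10, index=n_subj_total)
            subj_field = gaussian_filter(srng.normal(0.0, 1.0, (h, w)), sigma=4.0)
            subj_field *= cfg.subject_sd / max(subj_field.std(), 1e-12)
            for c, cond in enumerate(cfg.conditions):
                irng = _stream(cfg.seed, family=11, index=n_img)
                img = base.copy()
                img[cheeks] += cfg.group_contrast * gw[g]
                if c > 0:
                    img[mouth] += cfg.condition_contrast
                img = img + subj_field
                if cfg.noise_sd > 0:
                    img = img + irng.normal(0.0, cfg.noise_sd, (h, w))
                gain = 1.0 + irng.normal(0.0, cfg.illum_gain_sd) if cfg.illum_gain_sd else 1.0
                offset = irng.normal(0.0, cfg.illum_offset_sd) if cfg.illum_offset_sd else 0.0
                images.append(gain * img + offset)
                rows.append({"dataset_id": "simtex", "group_id": f"g{g + 1}",
                             "subject_id": sid, "condition_id": cond,
                             "frame_index": ""})
                n_img += 1
            n_subj_total += 1

    roi = RoiMask(face)
    truth = {
        "base": base,
        "roi": roi,
        "cheek_patch": cheeks,
        "mouth_patch": mouth,
        "group_weights": {f"g{g + 1}": gw[g] for g in range(cfg.n_groups)},
    }
    return np.stack(images), roi, pd.DataFrame(rows), truth
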