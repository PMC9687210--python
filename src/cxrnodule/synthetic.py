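"""Synthetic phantoms, detection sets, and longitudinal cohorts.

Real chest radiographs and trained detector weights live outside this
package; every downstream stage is instead exercised on controlled
synthetic data:

* **Phantoms** — radiograph-like rasters with a bright soft-tissue
  background, two dark elliptical lung fields, a central mediastinal band,
  optional rib-like sinusoidal texture, and 0–2 nodules inserted as 2-D
  Gaussian bumps of controlled physical diameter and contrast. A stated
  fraction is emitted with inverted polarity and jittered brightness to
  exercise Stage-I normalization.
* **Detection sets** — pseudo-model outputs derived directly from ground
  truth with controlled per-stratum miss rates and Poisson false positives,
  so ensembling and FROC evaluation can be tested without any detector.
* **Timelines** — longitudinal cohorts where a nodule appears, grows with a
  volume-doubling-time law (diameter doubles every ``3 * DT`` days), and is
  detected at each visit with per-size-stratum probabilities per source.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .detection import Detection, DetectionSet
from .evaluation import DEFAULT_STRATA, GroundTruthNodule, SizeStratum
from .images import GrayImage
from .lung_roi import RoiBox
from .temporal import CxrRecord, PatientTimeline

__all__ = [
    "PhantomConfig",
    "TimelineConfig",
    "ScoreModel",
    "generate_phantoms",
    "generate_detection_sets",
    "generate_timelines",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Controls for the lung-field phantom generator.

    ``mm_per_pixel`` = 0.35 maps the clinical size strata onto sensible
    pixel diameters (6 mm ≈ 17 px, 30 mm ≈ 86 px) at the default 512-pixel
    raster.
    """

    image_size: int = 512
    mm_per_pixel: float = 0.35
    n_images: int = 20
    nodules_per_image: tuple[int, int] = (0, 2)  # inclusive range
    nodule_diameter_mm_range: tuple[float, float] = (6.0, 30.0)
    nodule_contrast_range: tuple[float, float] = (0.2, 0.45)
    inverse_polarity_fraction: float = 0.0
    brightness_jitter: float = 0.0
    rib_amplitude: float = 0.015
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        if not 0.0 <= self.inverse_polarity_fraction <= 1.0:
            raise ValueError("inverse_polarity_fraction must be in [0, 1]")


def _lung_ellipses(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of the left and right lung fields for an n x n raster."""
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    cy = 0.48 * n
    ry, rx = 0.295 * n, 0.13 * n
    left = ((xx - 0.32 * n) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    right = ((xx - 0.68 * n) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    return left, right


def _base_phantom(n: int, rib_amplitude: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Nodule-free phantom raster plus the combined lung mask.

    Geometry mimics a frontal CXR: dark air outside the patient (image
    corners), a bright soft-tissue disc, a brighter central mediastinal
    band, and two dark lung fields the dark-region segmenter can find
    without touching the border.
    """
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    body = (xx - 0.5 * n) ** 2 + (yy - 0.5 * n) ** 2 <= (0.56 * n) ** 2
    left, right = _lung_ellipses(n)
    lungs = left | right
    px = np.full((n, n), 0.08)  # air
    band = np.exp(-((np.arange(n) - 0.5 * n) / (0.09 * n)) ** 2)
    px[body] = (np.full((n, n), 0.80) + 0.10 * band[None, :])[body]
    px[lungs] = 0.30
    if rib_amplitude > 0:
        y1 = np.arange(n, dtype=np.float64)
        phase = rng.uniform(0, 2 * np.pi)
        ribs = rib_amplitude * np.sin(2 * np.pi * y1 / (0.09 * n) + phase)
        px[lungs] += np.broadcast_to(ribs[:, None], (n, n))[lungs]
    return np.clip(px, 0.0, 1.0), lungs


_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # sigma -> full width at half maximum


def _insert_nodule(
    px: np.ndarray, cy: float, cx: float, diameter_px: float, contrast: float
) -> None:
    """Add a bright Gaussian bump whose FWHM equals the nodule diameter."""
    sigma = diameter_px / _FWHM
    n = px.shape[0]
    r = int(np.ceil(3 * sigma))
    y0, y1 = max(0, int(cy) - r), min(n, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(n, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    bump = contrast * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    px[y0:y1, x0:x1] = np.clip(px[y0:y1, x0:x1] + bump, 0.0, 1.0)


def generate_phantoms(
    cfg: PhantomConfig,
) -> tuple[list[GrayImage], list[GroundTruthNodule], dict[str, dict]]:
    """Generate phantom images with inserted nodules and ground truth.

    Returns ``(images, truths, meta)`` where ``meta`` records, per image id,
    whether polarity was inverted and the brightness offset applied —
    the generator's own labels, usable as an oracle for Stage-I tests.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.image_size
    images: list[GrayImage] = []
    truths: list[GroundTruthNodule] = []
    meta: dict[str, dict] = {}
    d_lo, d_hi = cfg.nodule_diameter_mm_range
    c_lo, c_hi = cfg.nodule_contrast_range
    lo_k, hi_k = cfg.nodules_per_image

    for i in range(cfg.n_images):
        image_id = f"phantom_{i:04d}"
        px, lungs = _base_phantom(n, cfg.rib_amplitude, rng)
        k = int(rng.integers(lo_k, hi_k + 1))
        placed: list[tuple[float, float, float]] = []
        for _ in range(k):
            diameter_mm = float(rng.uniform(d_lo, d_hi))
            contrast = float(rng.uniform(c_lo, c_hi))
            diameter_px = diameter_mm / cfg.mm_per_pixel
            ok = False
            for _attempt in range(200):  # resample until inside a lung field
                cy = float(rng.uniform(0.15 * n, 0.85 * n))
                cx = float(rng.uniform(0.10 * n, 0.90 * n))
                r = diameter_px / 2.0
                ys = np.clip(
                    np.round([cy - r, cy + r, cy, cy]).astype(int), 0, n - 1
                )
                xs = np.clip(
                    np.round([cx, cx, cx - r, cx + r]).astype(int), 0, n - 1
                )
                inside = lungs[ys, xs].all() and lungs[int(round(cy)), int(round(cx))]
                far = all((cy - py) ** 2 + (cx - px_) ** 2 > (r + pr) ** 2
                          for py, px_, pr in placed)
                if inside and far:
                    ok = True
                    break
            if not ok:
                continue  # nodule larger than the lung field: rejected
            _insert_nodule(px, cy, cx, diameter_px, contrast)
            placed.append((cy, cx, diameter_px / 2.0))
            half = diameter_px / 2.0
            box = RoiBox(
                x0=max(0, int(np.floor(cx - half))),
                y0=max(0, int(np.floor(cy - half))),
                x1=min(n, int(np.ceil(cx + half)) + 1),
                y1=min(n, int(np.ceil(cy + half)) + 1),
            )
            truths.append(
                GroundTruthNodule(
                    image_id=image_id,
                    center_x=cx,
                    center_y=cy,
                    diameter_mm=diameter_mm,
                    box=box,
                )
            )
        if cfg.noise_sigma > 0:
            px = px + rng.normal(0.0, cfg.noise_sigma, size=px.shape)
        inverted = bool(rng.random() < cfg.inverse_polarity_fraction)
        offset = float(rng.uniform(-cfg.brightness_jitter, cfg.brightness_jitter))
        px = np.clip(px + offset, 0.0, 1.0)
        if inverted:
            px = 1.0 - px
        images.append(GrayImage(np.clip(px, 0.0, 1.0), id=image_id))
        meta[image_id] = {"inverted": inverted, "brightness_offset": offset}
    return images, truths, meta


@dataclass(frozen=True)
class ScoreModel:
    """Log-uniform score distributions for hits and false positives.

    Scores are drawn as ``10**U(log10_lo, log10_hi)`` so the standard
    threshold ladder (1e-4 … 1e-1) sweeps out an informative curve: hits
    concentrate high, false positives low, with controllable overlap.
    """

    hit_log10_range: tuple[float, float] = (-2.0, 0.0)
    fp_log10_range: tuple[float, float] = (-4.0, -1.0)

    def draw_hit(self, rng: np.random.Generator) -> float:
        return float(10.0 ** rng.uniform(*self.hit_log10_range))

    def draw_fp(self, rng: np.random.Generator) -> float:
        return float(10.0 ** rng.uniform(*self.fp_log10_range))


def _stratum_of(diameter_mm: float, strata: Sequence[SizeStratum]) -> str:
    for s in strata:
        if s.contains(diameter_mm):
            return s.label
    raise ValueError(f"no stratum for diameter {diameter_mm}")


def generate_detection_sets(
    truths: Sequence[GroundTruthNodule],
    image_ids: Sequence[str],
    image_size: int,
    miss_rate_by_stratum: Mapping[str, float],
    fp_rate_per_image: float,
    seed: int,
    score_model: ScoreModel = ScoreModel(),
    model_tag: str = "toy",
    strata: Sequence[SizeStratum] = DEFAULT_STRATA,
) -> tuple[list[DetectionSet], dict[int, bool]]:
    """Pseudo-detector outputs derived from ground truth.

    Each truth is emitted as a hitting box (the truth's own box) with
    probability ``1 - miss_rate(stratum)``; ``Poisson(fp_rate_per_image)``
    false boxes are placed away from every truth center. Returns the sets
    and the per-truth-index emission mask (the generator's own miss oracle).
    """
    if any(not 0.0 <= m <= 1.0 for m in miss_rate_by_stratum.values()):
        raise ValueError("miss rates must be in [0, 1]")
    if fp_rate_per_image < 0:
        raise ValueError("fp_rate_per_image must be >= 0")
    rng = np.random.default_rng(seed)
    truths_by_image: dict[str, list[tuple[int, GroundTruthNodule]]] = {
        iid: [] for iid in image_ids
    }
    for j, t in enumerate(truths):
        if t.image_id not in truths_by_image:
            raise ValueError(f"truth for unknown image {t.image_id!r}")
        truths_by_image[t.image_id].append((j, t))

    emitted: dict[int, bool] = {}
    sets: list[DetectionSet] = []
    fp_side = 24
    for iid in image_ids:
        dets: list[Detection] = []
        for j, t in truths_by_image[iid]:
            miss = miss_rate_by_stratum.get(_stratum_of(t.diameter_mm, strata), 0.0)
            hit = bool(rng.random() >= miss)
            emitted[j] = hit
            if hit:
                dets.append(
                    Detection(box=t.box, score=score_model.draw_hit(rng), model_tag=model_tag)
                )
        n_fp = int(rng.poisson(fp_rate_per_image))
        centers = [(t.center_x, t.center_y) for _, t in truths_by_image[iid]]
        for _ in range(n_fp):
            for _attempt in range(100):
                x0 = int(rng.integers(0, image_size - fp_side))
                y0 = int(rng.integers(0, image_size - fp_side))
                box = RoiBox(x0, y0, x0 + fp_side, y0 + fp_side)
                if not any(box.contains_point(cx, cy) for cx, cy in centers):
                    dets.append(
                        Detection(box=box, score=score_model.draw_fp(rng), model_tag=model_tag)
                    )
                    break
        sets.append(DetectionSet(image_id=iid, detections=tuple(dets)))
    return sets, emitted


#: Per-visit detection probabilities by size stratum. The reader is weaker
#: than the AI on small nodules and both improve with size, the pattern
#: expected of human readers versus a screening model.
_DEFAULT_READER_PROBS = {
    "<6 mm": 0.02, "6–10 mm": 0.10, "10–20 mm": 0.30, "20–30 mm": 0.60, ">30 mm": 0.85,
}
_DEFAULT_AI_PROBS = {
    "<6 mm": 0.05, "6–10 mm": 0.20, "10–20 mm": 0.45, "20–30 mm": 0.75, ">30 mm": 0.90,
}


@dataclass(frozen=True)
class TimelineConfig:
    """Controls for the longitudinal cohort generator.

    Follow-up spans 5 years (1825 days) before diagnosis; nodules grow by
    volume doubling (diameter doubles every ``3 * doubling_time_days``).
    """

    n_patients: int = 383
    followup_days: int = 1825
    visit_interval_days: int = 120
    initial_diameter_mm: tuple[float, float] = (3.0, 8.0)
    doubling_time_days: tuple[float, float] = (60.0, 400.0)
    reader_detect_prob_by_stratum: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_READER_PROBS)
    )
    ai_detect_prob_by_stratum: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AI_PROBS)
    )
    diagnosis_delay_days: int = 30
    start_date: dt.date = dt.date(2011, 1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        for m in (self.reader_detect_prob_by_stratum, self.ai_detect_prob_by_stratum):
            if any(not 0.0 <= p <= 1.0 for p in m.values()):
                raise ValueError("detection probabilities must be in [0, 1]")
        if self.doubling_time_days[0] <= 0:
            raise ValueError("doubling_time_days must be positive")


def diameter_at(initial_mm: float, days_since_onset: float, doubling_time_days: float) -> float:
    """Nodule diameter under volume doubling: d(t) = d0 * 2^(t / (3 DT))."""
    return initial_mm * 2.0 ** (days_since_onset / (3.0 * doubling_time_days))


def generate_timelines(
    cfg: TimelineConfig, strata: Sequence[SizeStratum] = DEFAULT_STRATA
) -> list[PatientTimeline]:
    """Generate a longitudinal cohort of pre-diagnosis CXR series.

    Per patient: a nodule appears at a random day within follow-up and
    grows with its doubling time; radiographs are taken every
    ``visit_interval_days``; at each visit each source flags the nodule
    independently with its size-stratum probability. Diagnosis falls an
    administrative delay after the first reader detection, or at the end of
    follow-up; records after diagnosis are discarded.
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[PatientTimeline] = []
    for i in range(cfg.n_patients):
        pid = f"patient_{i:04d}"
        onset = float(rng.uniform(0, cfg.followup_days * 0.8))
        d0 = float(rng.uniform(*cfg.initial_diameter_mm))
        dt_days = float(rng.uniform(*cfg.doubling_time_days))
        visit_days = np.arange(0, cfg.followup_days + 1, cfg.visit_interval_days)

        flags: list[tuple[int, bool, bool]] = []
        diagnosis_day = cfg.followup_days
        for day in visit_days:
            if day < onset:
                flags.append((int(day), False, False))
                continue
            diam = diameter_at(d0, day - onset, dt_days)
            lbl = _stratum_of(min(diam, 1e6), strata)
            p_reader = cfg.reader_detect_prob_by_stratum.get(lbl, 0.0)
            p_ai = cfg.ai_detect_prob_by_stratum.get(lbl, 0.0)
            by_reader = bool(rng.random() < p_reader)
            by_ai = bool(rng.random() < p_ai)
            flags.append((int(day), by_reader, by_ai))
            if by_reader and diagnosis_day == cfg.followup_days:
                diagnosis_day = min(cfg.followup_days, int(day) + cfg.diagnosis_delay_days)
        kept = [f for f in flags if f[0] <= diagnosis_day]
        base = cfg.start_date + dt.timedelta(days=int(rng.integers(0, 365)))
        records = tuple(
            CxrRecord(
                date=base + dt.timedelta(days=day),
                detected_by_reader=r,
                detected_by_ai=a,
            )
            for day, r, a in kept
        )
        out.append(
            PatientTimeline(
                patient_id=pid,
                diagnosis_date=base + dt.timedelta(days=diagnosis_day),
                records=records,
            )
        )
    return out
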