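"""Reproducible synthetic benchmarks for the pipeline.

Three experiment families, each fully determined by a base seed:

* **phantom suite** — full-pipeline segmentation accuracy on the default
  multi-vessel fundus phantoms;
* **scale recovery** — whether the optimal-scale map tracks vessel width
  (wide vessels should peak at larger Hessian scales than narrow ones);
* **distractor suppression** — whether the symmetry-transform stage keeps
  a larger fraction of vessel pixels than of optic-disk-analogue pixels.

The disk analogue in the suppression trials is deliberately sized like a
real optic disc relative to the vessels (radius 16 px against a vote reach
of 2 s_max = 12 px): the transform suppresses blobs whose radius exceeds
the voting range, which is the geometry of actual fundus images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.morphology import skeletonize

from .evaluate import confusion, metrics
from .graphcut_seg import PipelineConfig, segment
from .hessian_enhance import multiscale_enhance
from .io_fixtures import (
    DiskDistractor,
    PhantomSpec,
    VesselPath,
    fundus_phantom_spec,
    generate_phantom,
)
from .nlm_filter import NlmParams, estimate_noise_sigma, nlm_denoise
from .radial_symmetry import extract_coarse, radial_symmetry_transform


def _trial_seed(base_seed: int, stream: int, trial: int) -> int:
    """A stable, well-mixed 31-bit seed per (base, stream, trial)."""
    ss = np.random.SeedSequence([int(base_seed), int(stream), int(trial)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SuiteResult:
    sensitivities: list
    specificities: list
    accuracies: list

    @property
    def mean_se(self) -> float:
        return float(np.mean(self.sensitivities))

    @property
    def mean_sp(self) -> float:
        return float(np.mean(self.specificities))

    @property
    def mean_ac(self) -> float:
        return float(np.mean(self.accuracies))


def phantom_suite_accuracy(n_phantoms: int = 10,
                           image_size: tuple[int, int] = (200, 200),
                           noise_sigma: float = 0.03,
                           base_seed: int = 0,
                           config: Optional[PipelineConfig] = None
                           ) -> SuiteResult:
    """Segment ``n_phantoms`` default fundus phantoms end to end and score
    each against its exact ground truth."""
    ses, sps, acs = [], [], []
    for i in range(n_phantoms):
        seed = _trial_seed(base_seed, 0, i)
        phantom = generate_phantom(
            fundus_phantom_spec(image_size, noise_sigma, rng_seed=seed))
        result = segment(phantom.image, config)
        se, sp, ac = metrics(confusion(result.mask, phantom.truth_mask))
        ses.append(se)
        sps.append(sp)
        acs.append(ac)
    return SuiteResult(ses, sps, acs)


def _two_vessel_spec(seed: int, size: int = 128,
                     half_widths: tuple[float, float] = (2.0, 6.0),
                     noise_sigma: float = 0.03) -> PhantomSpec:
    """Two well-separated near-horizontal vessels of the given half-widths."""
    rng = np.random.default_rng(seed)
    margin = max(half_widths) + 2
    r1 = size * 0.25 + rng.uniform(-5, 5)
    r2 = size * 0.72 + rng.uniform(-5, 5)
    return PhantomSpec(
        (size, size),
        vessel_paths=(
            VesselPath(((r1, margin), (r1 + rng.uniform(-6, 6), size - margin)),
                       half_widths[0], 0.25),
            VesselPath(((r2, margin), (r2 + rng.uniform(-6, 6), size - margin)),
                       half_widths[1], 0.25),
        ),
        noise_sigma=noise_sigma,
        rng_seed=seed,
    )


def scale_recovery_trial(seed: int,
                         scales: tuple = (1, 2, 3, 4, 5, 6)) -> bool:
    """One trial: does the wide vessel's centerline carry a strictly larger
    median optimal scale than the narrow vessel's?"""
    spec = _two_vessel_spec(seed)
    phantom = generate_phantom(spec)
    ss = multiscale_enhance(phantom.image.pixels, scales=scales)
    narrow = skeletonize(phantom.width_map == spec.vessel_paths[0].half_width)
    wide = skeletonize(phantom.width_map == spec.vessel_paths[1].half_width)
    med_narrow = float(np.median(ss.opt_scale[narrow]))
    med_wide = float(np.median(ss.opt_scale[wide]))
    return med_wide > med_narrow


def scale_recovery_trials(n_trials: int = 100, base_seed: int = 0) -> int:
    """Number of trials (out of ``n_trials``) where width→scale ordering
    is recovered."""
    return sum(scale_recovery_trial(_trial_seed(base_seed, 1, i))
               for i in range(n_trials))


def _vessel_disk_spec(seed: int, size: int = 128, half_width: float = 5.0,
                      disk_radius: float = 16.0, contrast: float = 0.25,
                      noise_sigma: float = 0.03) -> PhantomSpec:
    """One primary vessel plus an equal-contrast disk distractor; the disk
    polarity alternates with the seed (dark/bright)."""
    rng = np.random.default_rng(seed)
    r = size * 0.27 + rng.uniform(-6, 6)
    center = (size * 0.67 + rng.uniform(-5, 5), size * 0.5 + rng.uniform(-10, 10))
    polarity = 1.0 if seed % 2 == 0 else -1.0
    return PhantomSpec(
        (size, size),
        vessel_paths=(
            VesselPath(((r, half_width + 3), (r + rng.uniform(-8, 8),
                                              size - half_width - 4)),
                       half_width, contrast),
        ),
        disk_distractor=DiskDistractor(center, disk_radius,
                                       polarity * contrast),
        noise_sigma=noise_sigma,
        rng_seed=seed,
    )


def suppression_trial(seed: int) -> bool:
    """One trial: after enhancement, filtering, symmetry transform and
    coarse extraction, does a larger fraction of vessel pixels survive than
    of disk pixels?"""
    spec = _vessel_disk_spec(seed)
    phantom = generate_phantom(spec)
    ss = multiscale_enhance(phantom.image.pixels)
    vl = ss.vl / ss.vl.max() if ss.vl.max() > 0 else ss.vl
    h = max(10.0 * estimate_noise_sigma(vl), 1e-6)
    nl = nlm_denoise(vl, NlmParams(7, 2, h))
    sym = radial_symmetry_transform(nl, ss.opt_scale)
    coarse = extract_coarse(sym.vl_sym)

    size = spec.image_size[0]
    rows, cols = np.mgrid[0:size, 0:size]
    disk = spec.disk_distractor
    disk_px = (np.hypot(rows - disk.center[0], cols - disk.center[1])
               <= disk.radius) & ~phantom.truth_mask
    frac_vessel = float(coarse.mask[phantom.truth_mask].mean())
    frac_disk = float(coarse.mask[disk_px].mean())
    return frac_vessel > frac_disk


def suppression_trials(n_trials: int = 100, base_seed: int = 0) -> int:
    """Number of trials (out of ``n_trials``) where vessel pixels outlive
    disk-distractor pixels in the coarse vasculature."""
    return sum(suppression_trial(_trial_seed(base_seed, 2, i))
               for i in range(n_trials))


def determinism_check(seed: int = 0,
                      image_size: tuple[int, int] = (200, 200)) -> bool:
    """Segment the same phantom twice; bit-identical masks expected."""
    spec = fundus_phantom_spec(image_size, 0.03, rng_seed=seed)
    a = segment(generate_phantom(spec).image)
    b = segment(generate_phantom(spec).image)
    return bool(np.array_equal(a.mask, b.mask))
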