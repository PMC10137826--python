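"""Two-platform synthetic cohorts with planted rank-reversal signal.

The generator emulates the study design the pipeline targets: two
cohorts measured on different platforms (e.g. a microarray and a qPCR
card) that share a latent per-sample expression state. Disease signal is
planted as *within-sample ordering* — for each planted pair (A, B),
healthy samples show A below B and COPD samples show A above B, each
with probability 1 - p_flip — because orderings, not abundances, are the
pipeline's feature space. A mean-shift option exists for testing
expression-level baselines.

Each platform rendering applies a strictly increasing distortion
(affine, log-affine or a random monotone spline), adds independent
technical noise, censors the lowest-abundance fraction of measurements
(detection limit -> missing), and optionally flips to Ct orientation
(larger value = less abundant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import COPD, HEALTHY, ExpressionCohort, SCALE_CT, SCALE_EXPRESSION
from .errors import ValidationError
from .pairs import pair_id

TRANSFORMS = ("affine", "log_affine", "spline")


@dataclass
class PlatformSpec:
    """How one platform distorts the latent abundance state.

    ``slope``/``intercept`` parameterize the affine and log-affine maps
    (the spline draws its own monotone shape from ``seed``); ``noise_sd``
    is independent technical noise on the transformed scale;
    ``detection_limit_quantile`` censors that fraction of the
    lowest-abundance rendered measurements to missing; for a ``ct``
    scale the rendering is ``ct_offset - transformed`` so larger values
    mean fewer copies.
    """

    name: str
    scale: str = SCALE_EXPRESSION
    transform: str = "affine"
    slope: float = 1.0
    intercept: float = 0.0
    noise_sd: float = 0.0
    detection_limit_quantile: float = 0.0
    ct_offset: float = 40.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_EXPRESSION, SCALE_CT):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.transform not in TRANSFORMS:
            raise ValidationError(
                f"unknown transform {self.transform!r}; expected one of {TRANSFORMS}"
            )
        if self.slope <= 0:
            raise ValidationError("transform slope must be > 0 (strictly increasing)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0.0 <= self.detection_limit_quantile < 1.0:
            raise ValidationError("detection_limit_quantile must be in [0, 1)")


@dataclass
class LatentCohort:
    """Shared latent log-abundance state with labels and planted truth."""

    values: pd.DataFrame  # features x samples, latent log2-like abundance
    labels: pd.Series
    planted_pairs: list[str]
    p_flip: float
    seed: int | None = None

    def to_cohort(self, cohort_id: str = "latent") -> ExpressionCohort:
        """View the latent state itself as an (undistorted) expression cohort."""
        return ExpressionCohort(
            cohort_id=cohort_id,
            values=self.values.copy(),
            labels=self.labels.copy(),
            scale=SCALE_EXPRESSION,
        )


def generate_latent(
    n_copd: int = 60,
    n_healthy: int = 60,
    n_features: int = 40,
    n_planted: int = 5,
    p_flip: float = 0.1,
    seed: int | None = None,
    mean_shift: float = 0.0,
    n_shifted: int = 0,
) -> LatentCohort:
    """Draw a latent cohort with planted case/control rank reversals.

    Per-feature baselines are log-normal-like: feature means are
    N(6, 1.5^2) on a log2-like scale with N(0, 1) per-sample variation.
    The two members of a planted pair share one baseline mean, so their
    ordering is sample-specific; the ordering is then enforced by
    swapping the two values within a sample — healthy: A < B, COPD:
    A > B, each with probability ``1 - p_flip`` (A is the
    lexicographically first member of the canonical pair). Non-planted
    features are label-independent unless ``mean_shift`` adds a COPD
    mean offset to ``n_shifted`` of them (for expression-level baseline
    tests). Deterministic given ``seed``.
    """
    if n_copd < 1 or n_healthy < 1:
        raise ValidationError("need at least one sample per class")
    if n_features < 2:
        raise ValidationError("need at least two features")
    if n_planted < 0 or 2 * n_planted > n_features:
        raise ValidationError(
            f"n_planted={n_planted} needs 2*n_planted <= n_features={n_features}"
        )
    if not 0.0 <= p_flip <= 0.5:
        raise ValidationError(f"p_flip must be in [0, 0.5], got {p_flip}")
    if n_shifted < 0 or mean_shift < 0:
        raise ValidationError("n_shifted and mean_shift must be >= 0")

    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_features)))
    features = [f"miR-{i + 1:0{width}d}" for i in range(n_features)]
    samples = [f"COPD-{i + 1:03d}" for i in range(n_copd)] + [
        f"HC-{i + 1:03d}" for i in range(n_healthy)
    ]
    labels = pd.Series([COPD] * n_copd + [HEALTHY] * n_healthy, index=samples)
    is_copd = labels.to_numpy() == COPD

    mu = rng.normal(6.0, 1.5, size=n_features)
    planted_idx = rng.choice(n_features, size=2 * n_planted, replace=False)
    planted: list[str] = []
    values = mu[:, None] + rng.normal(0.0, 1.0, size=(n_features, n_copd + n_healthy))

    for j in range(n_planted):
        ia, ib = planted_idx[2 * j], planted_idx[2 * j + 1]
        # canonical orientation: A = lexicographically first member
        if features[ib] < features[ia]:
            ia, ib = ib, ia
        planted.append(pair_id(features[ia], features[ib]))
        # shared baseline so the ordering is noise-scale, then enforce it
        shared = rng.normal(6.0, 1.5)
        values[ia] = shared + rng.normal(0.0, 1.0, size=values.shape[1])
        values[ib] = shared + rng.normal(0.0, 1.0, size=values.shape[1])
        flip = rng.random(values.shape[1]) < p_flip
        want_a_above = is_copd ^ flip  # COPD: A > B unless flipped
        a_above = values[ia] > values[ib]
        swap = a_above != want_a_above
        va = values[ia].copy()
        values[ia][swap] = values[ib][swap]
        values[ib][swap] = va[swap]

    if n_shifted and mean_shift:
        free = [i for i in range(n_features) if i not in set(planted_idx)]
        if n_shifted > len(free):
            raise ValidationError(
                f"n_shifted={n_shifted} exceeds the {len(free)} non-planted features"
            )
        shifted = rng.choice(np.array(free), size=n_shifted, replace=False)
        values[np.ix_(shifted, np.flatnonzero(is_copd))] += mean_shift

    frame = pd.DataFrame(values, index=features, columns=samples)
    return LatentCohort(
        values=frame, labels=labels, planted_pairs=sorted(planted), p_flip=p_flip, seed=seed
    )


def _monotone_map(x: np.ndarray, spec: PlatformSpec, rng: np.random.Generator) -> np.ndarray:
    lo = float(x.min())
    if spec.transform == "affine":
        return spec.slope * x + spec.intercept
    if spec.transform == "log_affine":
        return spec.slope * np.log(x - lo + 1.0) + spec.intercept
    # random rank-preserving spline: piecewise linear with positive slopes
    hi = float(x.max())
    knots = np.linspace(lo, hi, 9)
    slopes = rng.uniform(0.25, 2.0, size=8)
    heights = np.concatenate([[0.0], np.cumsum(slopes * np.diff(knots))])
    return spec.slope * np.interp(x, knots, heights) + spec.intercept


def render_platform(latent: LatentCohort, spec: PlatformSpec) -> ExpressionCohort:
    """Render the latent state through one platform's distortion.

    Applies the monotone transform, adds technical noise, censors the
    ``detection_limit_quantile`` lowest-abundance fraction to missing,
    and negates for Ct orientation. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    x = latent.values.to_numpy()
    t = _monotone_map(x, spec, rng)
    if spec.noise_sd > 0:
        t = t + rng.normal(0.0, spec.noise_sd, size=t.shape)
    missing = np.zeros(t.shape, dtype=bool)
    if spec.detection_limit_quantile > 0:
        thr = np.quantile(t, spec.detection_limit_quantile)
        missing = t < thr  # low abundance on the pre-negation scale
    rendered = spec.ct_offset - t if spec.scale == SCALE_CT else t
    rendered = np.where(missing, np.nan, rendered)
    values = pd.DataFrame(rendered, index=latent.values.index, columns=latent.values.columns)
    labels = latent.labels.copy()
    labels.index = values.columns
    return ExpressionCohort(
        cohort_id=spec.name, values=values, labels=labels, scale=spec.scale
    )


def default_platform_specs(seed: int | None = None) -> tuple[PlatformSpec, PlatformSpec]:
    """The standard pair of study platforms: an array-like and a qPCR-like one.

    The array platform compresses the high end (log-affine) on an
    expression scale; the qPCR platform reports Ct values (affine then
    negated around ``ct_offset``). Both carry technical noise of 0.15 on
    the transformed scale and censor their lowest 2% of measurements.
    """
    s = np.random.default_rng(seed).integers(0, 2**31 - 1, size=2)
    array = PlatformSpec(
        name="sim-array",
        scale=SCALE_EXPRESSION,
        transform="log_affine",
        slope=3.0,
        intercept=1.0,
        noise_sd=0.15,
        detection_limit_quantile=0.02,
        seed=int(s[0]),
    )
    qpcr = PlatformSpec(
        name="sim-qpcr",
        scale=SCALE_CT,
        transform="affine",
        slope=1.0,
        intercept=4.0,
        noise_sd=0.15,
        detection_limit_quantile=0.02,
        ct_offset=40.0,
        seed=int(s[1]),
    )
    return array, qpcr


def simulate_two_platform(
    n_copd: int = 60,
    n_healthy: int = 60,
    n_features: int = 40,
    n_planted: int = 5,
    p_flip: float = 0.1,
    seed: int | None = None,
) -> tuple[LatentCohort, ExpressionCohort, ExpressionCohort]:
    """A two-cohort study: one latent population split across two platforms.

    Draws ``n_copd + n_healthy`` latent samples, assigns half of each
    class to the array-like platform and the other half to the qPCR-like
    platform, and renders each subset through its platform. The two
    cohorts therefore contain *independent* samples (as two real study
    cohorts would) but share the feature set and the planted pairs.
    """
    rng = np.random.default_rng(seed)
    latent = generate_latent(
        n_copd=n_copd,
        n_healthy=n_healthy,
        n_features=n_features,
        n_planted=n_planted,
        p_flip=p_flip,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    spec_a, spec_b = default_platform_specs(int(rng.integers(0, 2**31 - 1)))

    copd_ids = list(latent.labels.index[latent.labels == COPD])
    hc_ids = list(latent.labels.index[latent.labels == HEALTHY])
    to_a = set(copd_ids[: len(copd_ids) // 2]) | set(hc_ids[: len(hc_ids) // 2])
    cols = list(latent.values.columns)
    cols_a = [c for c in cols if c in to_a]
    cols_b = [c for c in cols if c not in to_a]

    cohorts = []
    for spec, subset in ((spec_a, cols_a), (spec_b, cols_b)):
        sub_latent = LatentCohort(
            values=latent.values[subset],
            labels=latent.labels.loc[subset],
            planted_pairs=latent.planted_pairs,
            p_flip=latent.p_flip,
            seed=latent.seed,
        )
        cohorts.append(render_platform(sub_latent, spec))
    return latent, cohorts[0], cohorts[1]
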