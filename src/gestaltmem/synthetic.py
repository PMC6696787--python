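"""Synthetic trial-level data for the three behavioral paradigms.

The generator instantiates the causal picture motivating the whole
analysis: each image carries two independent latent traits, *goodness of
organization* (g) and *contextual distinctiveness* (d), both standard
normal. Goodness speeds processing, so it raises rapid-categorization
accuracy and shortens thumbnail search times; distinctiveness makes an
image atypical of its category, so it lowers rapid-categorization accuracy
while making the image easier to spot among same-category distractors —
and both traits raise memorability. With those default signs the raw
image-level correlation between categorizability and memorability is near
zero or negative while the partial correlation controlling distinctiveness
is positive: the qualitative signature the analysis pipeline is built to
detect.

Three paradigms are simulated at the original design sizes: a rapid-scene
categorization study (147 participants x 616 trials, half congruent), a
thumbnail search study (75 participants, a random 30 of 44 images per
category, 6-s response limit, log-normal RTs censored into timeouts), and
an online distinctiveness-rating study (7-point scale from -3
representative to +3 distinctive, variable block completion averaging
about 44 ratings per image). Memorability plays the role of an externally
supplied per-image score and is generated directly from the traits.

All simulators are pure functions of (params, seed): a single global seed
feeds a per-stage :class:`numpy.random.SeedSequence` spawn-key scheme, so
each stage is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .core import ImageRef, ParameterError, make_score_table
from .masks import RasterImage

__all__ = [
    "GenerativeParams",
    "generate_image_population",
    "simulate_categorization_study",
    "simulate_search_study",
    "simulate_rating_study",
    "generate_feature_vectors",
    "generate_test_images",
]

# Spawn keys for per-stage random streams derived from the global seed.
_STAGE_POPULATION = 0
_STAGE_STUDY1 = 1
_STAGE_STUDY2 = 2
_STAGE_STUDY3 = 3
_STAGE_FEATURES = 4
_STAGE_IMAGES = 5

_DEFAULT_CATEGORIES: Tuple[Tuple[str, str], ...] = (
    ("bathroom", "indoor"),
    ("cockpit", "indoor"),
    ("airport_terminal", "indoor"),
    ("bedroom", "indoor"),
    ("kitchen", "indoor"),
    ("living_room", "indoor"),
    ("conference_room", "indoor"),
    ("mountain", "outdoor"),
    ("bridge", "outdoor"),
    ("playground", "outdoor"),
    ("pasture", "outdoor"),
    ("house", "outdoor"),
    ("amusement_park", "outdoor"),
    ("skyscraper", "outdoor"),
)


@dataclass
class GenerativeParams:
    """Ground-truth parameters of the synthetic cohorts.

    Latent traits are N(0, trait_sd) per image. Memorability is a logistic
    squashing of ``mem_offset + w_good_mem*g + w_dist_mem*d + noise``.
    Categorization difficulty is ``-(w_good_cat*g + w_dist_cat*d) + noise``
    plus a per-category offset with dispersion ``category_difficulty_sd``
    (categories genuinely differ in how easy they are, which produces the
    ceiling effects seen in the per-category descriptives). Search log-RT
    image effects are ``w_good_rt*g + w_dist_rt*d``.

    Default effect sizes are chosen so that, at the original sample sizes,
    the observed image-level correlations fall in the regime of interest:
    raw categorizability-memorability near zero/negative, distinctiveness
    correlating negatively with categorizability and positively with
    memorability, and a positive categorizability-memorability partial
    correlation once distinctiveness is controlled.

    When ``timeout_rate_target`` is set (default 2%), the log-RT location
    is solved from the marginal log-normal so that the expected timeout
    fraction matches it; an explicit ``rt_location`` overrides this.
    """

    n_categories: int = 14
    n_images_per_category: int = 44
    n_participants_study1: int = 147
    n_participants_study2: int = 75
    n_participants_study3: int = 137
    images_per_participant_study2: int = 30

    w_good_mem: float = 0.35
    w_dist_mem: float = 0.55
    w_good_cat: float = 0.35
    w_dist_cat: float = -0.40
    w_good_rt: float = -0.12
    w_dist_rt: float = -0.08

    trait_sd: float = 1.0
    participant_sd: float = 0.35
    noise_sd: float = 0.5
    category_difficulty_sd: float = 0.8

    mem_offset: float = 1.0
    accuracy_offset: float = 1.3
    no_bias: float = 0.9
    lapse_rate: float = 0.02
    nonresponse_rate: float = 0.005

    rt_location: Optional[float] = None
    rt_scale: float = 0.45
    rt_participant_sd: float = 0.15
    timeout_rate_target: Optional[float] = 0.02
    wrong_click_rate: float = 0.03

    rating_thresholds: Tuple[float, ...] = (-1.35, -0.35, 0.45, 1.25, 2.05, 2.85)
    rating_noise_sd: float = 0.8
    mean_blocks_completed: float = 4.5

    feature_center_sd: float = 5.0
    feature_sd: float = 1.0
    w_dist_feat: float = 0.4

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_categories",
            "n_images_per_category",
            "n_participants_study1",
            "n_participants_study2",
            "n_participants_study3",
            "images_per_participant_study2",
        ):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        for name in ("trait_sd", "rt_scale"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in (
            "participant_sd",
            "noise_sd",
            "category_difficulty_sd",
            "rt_participant_sd",
            "rating_noise_sd",
            "feature_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("lapse_rate", "nonresponse_rate", "wrong_click_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.timeout_rate_target is not None and not (
            0 < self.timeout_rate_target < 1
        ):
            raise ParameterError("timeout_rate_target must lie in (0, 1)")
        if self.images_per_participant_study2 > self.n_images_per_category:
            raise ParameterError(
                "images_per_participant_study2 cannot exceed n_images_per_category"
            )
        thr = np.asarray(self.rating_thresholds, dtype=float)
        if thr.ndim != 1 or len(thr) < 1 or not np.all(np.diff(thr) > 0):
            raise ParameterError("rating_thresholds must be strictly increasing")
        if self.mean_blocks_completed <= 0:
            raise ParameterError("mean_blocks_completed must be > 0")

    @property
    def n_images(self) -> int:
        return self.n_categories * self.n_images_per_category

    @property
    def rating_scale(self) -> Tuple[int, int]:
        """Integer rating bounds implied by the thresholds (k -> [-ceil(k/2), k-ceil(k/2)])."""
        k = len(self.rating_thresholds)
        lo = -((k + 1) // 2)
        return (lo, lo + k)


def _rng(params: GenerativeParams, stage: int) -> np.random.Generator:
    """Per-stage generator derived from the single global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(stage,))
    )


def _category_names(params: GenerativeParams) -> List[Tuple[str, Optional[str]]]:
    if params.n_categories <= len(_DEFAULT_CATEGORIES):
        return [list(_DEFAULT_CATEGORIES)[i] for i in range(params.n_categories)]
    names = list(_DEFAULT_CATEGORIES) + [
        (f"category_{i:02d}", None)
        for i in range(len(_DEFAULT_CATEGORIES), params.n_categories)
    ]
    return names[: params.n_categories]


def generate_image_population(
    params: GenerativeParams,
) -> Tuple[List[ImageRef], pd.DataFrame, pd.DataFrame]:
    """Draw the image population: refs, latent traits, memorability scores.

    Returns
    -------
    refs
        One :class:`ImageRef` per image.
    traits
        DataFrame indexed by ``image_id`` with columns ``category``,
        ``goodness``, ``distinctiveness``, ``memorability``,
        ``difficulty`` (rapid-categorization difficulty, higher = harder)
        and ``log_rt_location`` (image effect on search log-RT).
    memorability
        A memorability score table, standing in for the external
        FIGRIM-derived scores (nominal 80 responses per image).
    """
    rng = _rng(params, _STAGE_POPULATION)
    n = params.n_images
    cats = _category_names(params)

    image_ids, categories, superordinates = [], [], []
    for ci, (cname, sup) in enumerate(cats):
        for k in range(params.n_images_per_category):
            image_ids.append(f"{cname}_{k:03d}")
            categories.append(cname)
            superordinates.append(sup)

    g = rng.normal(0.0, params.trait_sd, size=n)
    d = rng.normal(0.0, params.trait_sd, size=n)
    mem_noise = rng.normal(0.0, params.noise_sd, size=n)
    diff_noise = rng.normal(0.0, params.noise_sd, size=n)
    cat_offsets = rng.normal(0.0, params.category_difficulty_sd, size=len(cats))
    cat_offset_per_image = np.repeat(cat_offsets, params.n_images_per_category)

    m = expit(params.mem_offset + params.w_good_mem * g + params.w_dist_mem * d + mem_noise)
    difficulty = (
        cat_offset_per_image
        - (params.w_good_cat * g + params.w_dist_cat * d)
        + diff_noise
    )
    log_rt_loc = params.w_good_rt * g + params.w_dist_rt * d

    refs = [
        ImageRef(image_id=i, category=c, superordinate=s)
        for i, c, s in zip(image_ids, categories, superordinates)
    ]
    traits = pd.DataFrame(
        {
            "category": categories,
            "goodness": g,
            "distinctiveness": d,
            "memorability": m,
            "difficulty": difficulty,
            "log_rt_location": log_rt_loc,
        },
        index=pd.Index(image_ids, name="image_id"),
    )
    mem_table = make_score_table(
        image_ids, categories, m, np.full(n, 80), "memorability"
    )
    return refs, traits, mem_table


def _congruent_assignment(
    rng: np.random.Generator, n_participants: int, n_categories: int, n_per_cat: int
) -> np.ndarray:
    """Boolean (participants x images) congruency matrix.

    Within each category and participant, a random half of the images is
    congruent; with an odd per-category count the extra image goes to the
    congruent half.
    """
    n_congruent = (n_per_cat + 1) // 2
    u = rng.random((n_participants, n_categories, n_per_cat))
    ranks = np.argsort(np.argsort(u, axis=2), axis=2)
    congruent = ranks < n_congruent
    return congruent.reshape(n_participants, n_categories * n_per_cat)


def simulate_categorization_study(
    traits: pd.DataFrame, params: GenerativeParams
) -> pd.DataFrame:
    """Simulate the rapid-scene categorization study (one trial per image).

    Each participant sees every image once; per participant and category a
    random half of the images carries the congruent label. Correctness on
    congruent trials follows a lapse-floored logistic in (participant
    ability - image difficulty); incongruent trials add a 'no' bias, which
    reproduces the overall conservative criterion (beta > 1). A small
    fraction of trials times out; a non-response is recorded as incorrect.
    """
    rng = _rng(params, _STAGE_STUDY1)
    n_p = params.n_participants_study1
    n_img = len(traits)
    if n_img != params.n_images:
        raise ParameterError("traits do not match params (image count mismatch)")

    congruent = _congruent_assignment(
        rng, n_p, params.n_categories, params.n_images_per_category
    )
    ability = rng.normal(0.0, params.participant_sd, size=n_p)[:, None]
    difficulty = traits["difficulty"].to_numpy()[None, :]
    drive = params.accuracy_offset + ability - difficulty
    p_correct_cong = params.lapse_rate / 2 + (1 - params.lapse_rate) * expit(drive)
    p_correct_incong = params.lapse_rate / 2 + (1 - params.lapse_rate) * expit(
        drive + params.no_bias
    )
    p_correct = np.where(congruent, p_correct_cong, p_correct_incong)

    responded = rng.random((n_p, n_img)) >= params.nonresponse_rate
    correct = (rng.random((n_p, n_img)) < p_correct) & responded

    participant_ids = np.repeat([f"s1_p{i:03d}" for i in range(n_p)], n_img)
    image_ids = np.tile(traits.index.to_numpy(), n_p)
    categories = np.tile(traits["category"].to_numpy(), n_p)
    return pd.DataFrame(
        {
            "participant_id": participant_ids,
            "image_id": image_ids,
            "category": categories,
            "congruent": congruent.ravel(),
            "responded": responded.ravel(),
            "correct": correct.ravel(),
        }
    )


def _marginal_log_rt_sd(params: GenerativeParams) -> float:
    image_var = (params.w_good_rt**2 + params.w_dist_rt**2) * params.trait_sd**2
    return math.sqrt(params.rt_scale**2 + params.rt_participant_sd**2 + image_var)


def resolve_rt_location(params: GenerativeParams, rt_limit: float = 6.0) -> float:
    """Log-RT location: explicit value, or solved from the timeout target."""
    if params.rt_location is not None:
        return params.rt_location
    if params.timeout_rate_target is None:
        raise ParameterError("either rt_location or timeout_rate_target must be set")
    z = norm.ppf(1.0 - params.timeout_rate_target)
    return math.log(rt_limit) - z * _marginal_log_rt_sd(params)


def simulate_search_study(
    traits: pd.DataFrame, params: GenerativeParams, rt_limit: float = 6.0
) -> pd.DataFrame:
    """Simulate the thumbnail search study.

    Each participant searches for a random ``images_per_participant_study2``
    of the images in every category. RTs are log-normal with additive image
    and participant effects on the log scale; raw RTs beyond the response
    limit become timeouts with the RT fixed at the limit, and a small
    fraction of the remaining trials are wrong clicks (the distractor was
    clicked), whose RTs are drawn from the same distribution.
    """
    rng = _rng(params, _STAGE_STUDY2)
    n_p = params.n_participants_study2
    n_cat = params.n_categories
    n_per = params.n_images_per_category
    n_sel = params.images_per_participant_study2
    if len(traits) != params.n_images:
        raise ParameterError("traits do not match params (image count mismatch)")

    # Random 30-of-44 subset per participant and category.
    u = rng.random((n_p, n_cat, n_per))
    ranks = np.argsort(np.argsort(u, axis=2), axis=2)
    selected = (ranks < n_sel).reshape(n_p, n_cat * n_per)

    loc = resolve_rt_location(params, rt_limit)
    part_eff = rng.normal(0.0, params.rt_participant_sd, size=n_p)[:, None]
    image_eff = traits["log_rt_location"].to_numpy()[None, :]
    log_rt = loc + part_eff + image_eff + rng.normal(
        0.0, params.rt_scale, size=(n_p, params.n_images)
    )
    rt = np.exp(log_rt)
    timeout = rt > rt_limit
    wrong = (~timeout) & (rng.random((n_p, params.n_images)) < params.wrong_click_rate)
    rt = np.where(timeout, rt_limit, rt)
    outcome = np.where(timeout, "timeout", np.where(wrong, "wrong_click", "correct"))

    mask = selected.ravel()
    participant_ids = np.repeat(
        [f"s2_p{i:03d}" for i in range(n_p)], params.n_images
    )[mask]
    image_ids = np.tile(traits.index.to_numpy(), n_p)[mask]
    categories = np.tile(traits["category"].to_numpy(), n_p)[mask]
    return pd.DataFrame(
        {
            "participant_id": participant_ids,
            "image_id": image_ids,
            "category": categories,
            "rt": rt.ravel()[mask],
            "outcome": outcome.ravel()[mask],
        }
    )


def simulate_rating_study(
    traits: pd.DataFrame, params: GenerativeParams
) -> pd.DataFrame:
    """Simulate the online distinctiveness-rating study.

    Participants complete a variable number of category blocks (1 plus a
    truncated Poisson, averaging ``mean_blocks_completed``), rating all
    images of each completed block once. A trial's latent judgment is the
    image's latent distinctiveness plus a participant bias and trial noise,
    discretized through the fixed ordered thresholds onto the integer
    scale (e.g. 6 thresholds -> ratings -3..3).
    """
    rng = _rng(params, _STAGE_STUDY3)
    n_p = params.n_participants_study3
    n_cat = params.n_categories
    if len(traits) != params.n_images:
        raise ParameterError("traits do not match params (image count mismatch)")
    thresholds = np.asarray(params.rating_thresholds, dtype=float)
    k = len(thresholds)
    rating_min = -((k + 1) // 2)

    extra = min(params.mean_blocks_completed, n_cat) - 1.0
    n_blocks = 1 + rng.poisson(max(extra, 0.0), size=n_p)
    n_blocks = np.minimum(n_blocks, n_cat)

    cat_names = [c for c, _ in _category_names(params)]
    cat_index = {c: i for i, c in enumerate(cat_names)}
    img_by_cat = [
        traits.index.to_numpy()[traits["category"].to_numpy() == c] for c in cat_names
    ]
    d_by_cat = [
        traits["distinctiveness"].to_numpy()[traits["category"].to_numpy() == c]
        for c in cat_names
    ]

    rows_pid, rows_img, rows_cat, rows_rating = [], [], [], []
    bias = rng.normal(0.0, params.participant_sd, size=n_p)
    for p in range(n_p):
        blocks = rng.choice(n_cat, size=n_blocks[p], replace=False)
        for b in blocks:
            imgs = img_by_cat[b]
            latent = d_by_cat[b] + bias[p] + rng.normal(
                0.0, params.rating_noise_sd, size=len(imgs)
            )
            ratings = rating_min + np.searchsorted(thresholds, latent, side="right")
            rows_pid.append(np.full(len(imgs), f"s3_p{p:03d}", dtype=object))
            rows_img.append(imgs)
            rows_cat.append(np.full(len(imgs), cat_names[b], dtype=object))
            rows_rating.append(ratings)

    return pd.DataFrame(
        {
            "participant_id": np.concatenate(rows_pid),
            "image_id": np.concatenate(rows_img),
            "category": np.concatenate(rows_cat),
            "rating": np.concatenate(rows_rating).astype(int),
        }
    )


def generate_feature_vectors(
    traits: pd.DataFrame, dim: int, params: GenerativeParams
) -> pd.DataFrame:
    """Category-structured feature vectors standing in for CNN embeddings.

    Each category has a Gaussian center; an image's displacement from its
    center has magnitude scaled by ``max(0, 1 + w_dist_feat * d)``, so
    within-category distance to the centroid grows with latent
    distinctiveness. Returns a DataFrame indexed by ``image_id`` with a
    ``category`` column and feature columns ``f0..f{dim-1}``.
    """
    if dim < 2:
        raise ParameterError("dim must be >= 2")
    rng = _rng(params, _STAGE_FEATURES)
    cats = traits["category"].to_numpy()
    cat_names = list(dict.fromkeys(cats))
    centers = {
        c: rng.normal(0.0, params.feature_center_sd, size=dim) for c in cat_names
    }
    d = traits["distinctiveness"].to_numpy()
    scale = np.maximum(0.0, 1.0 + params.w_dist_feat * d)
    disp = rng.normal(0.0, params.feature_sd, size=(len(traits), dim))
    vectors = np.stack([centers[c] for c in cats]) + scale[:, None] * disp
    out = pd.DataFrame(
        vectors, index=traits.index.copy(), columns=[f"f{i}" for i in range(dim)]
    )
    out.insert(0, "category", cats)
    return out


def _band_limited_noise(rng: np.random.Generator, size: int, cutoff: float) -> np.ndarray:
    """Low-pass filtered white noise, normalized to [0, 1]."""
    white = rng.normal(size=(size, size))
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    keep = np.sqrt(fy**2 + fx**2) <= cutoff
    img = np.fft.ifft2(np.fft.fft2(white) * keep).real
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo) if hi > lo else np.full_like(img, 0.5)


def generate_test_images(
    n: int, size: int = 512, seed: int = 0
) -> List[RasterImage]:
    """Procedural RGB fixture images with diverse amplitude spectra.

    Cycles through four recipes — linear gradients, band-limited noise,
    geometric shapes on plain grounds, and oriented sinusoidal gratings —
    so the set spans DC-dominated, low-pass and narrow-band spectra.
    Deterministic under the seed; pixels lie in [0, 1].
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if size < 8:
        raise ParameterError("size must be >= 8")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_IMAGES,)))
    yy, xx = np.meshgrid(
        np.linspace(0, 1, size), np.linspace(0, 1, size), indexing="ij"
    )
    images: List[RasterImage] = []
    for i in range(n):
        kind = i % 4
        channels = []
        if kind == 0:  # oriented linear gradient per channel
            for _ in range(3):
                theta = rng.uniform(0, 2 * np.pi)
                ramp = np.cos(theta) * xx + np.sin(theta) * yy
                lo, hi = ramp.min(), ramp.max()
                channels.append((ramp - lo) / (hi - lo))
        elif kind == 1:  # shared band-limited noise, per-channel gain
            base = _band_limited_noise(rng, size, cutoff=rng.uniform(0.05, 0.3))
            gains = rng.uniform(0.5, 1.0, size=3)
            channels = [np.clip(base * gn, 0, 1) for gn in gains]
        elif kind == 2:  # geometric shapes: disk and rectangle
            bg = rng.uniform(0.1, 0.9, size=3)
            fg = rng.uniform(0.0, 1.0, size=3)
            cy, cx = rng.uniform(0.25, 0.75, size=2)
            r = rng.uniform(0.1, 0.3)
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            x0, y0 = rng.uniform(0.0, 0.5, size=2)
            rect = (xx >= x0) & (xx <= x0 + 0.3) & (yy >= y0) & (yy <= y0 + 0.2)
            for c in range(3):
                ch = np.full((size, size), bg[c])
                ch[rect] = 1.0 - bg[c]
                ch[disk] = fg[c]
                channels.append(ch)
        else:  # sinusoidal grating
            freq = rng.uniform(2, size / 8)
            theta = rng.uniform(0, np.pi)
            phase = rng.uniform(0, 2 * np.pi)
            wave = np.sin(
                2 * np.pi * freq * (np.cos(theta) * xx + np.sin(theta) * yy) + phase
            )
            base = (wave + 1) / 2
            gains = rng.uniform(0.6, 1.0, size=3)
            channels = [base * gn for gn in gains]
        pixels = np.stack(channels, axis=-1)
        images.append(
            RasterImage(pixels=pixels, value_range=(0.0, 1.0), provenance=f"synthetic_{i}")
        )
    return images
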