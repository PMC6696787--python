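"""Published reference values for the FIGRIM 14-category scene set.

These are the category-level descriptive statistics and image-level
zero-order correlations reported for the original three-study dataset
(rapid-scene categorization, thumbnail search, and distinctiveness
ratings on 616 FIGRIM scene images, 44 per category). They serve as
inputs for reanalyses that start from published summary statistics — for
example recomputing the ceiling correlation between per-category means
and SDs, or deriving the distinctiveness-controlled partial correlations
from the published zero-order values.
"""

from __future__ import annotations

#: Number of scored images (14 categories x 44 images).
N_IMAGES = 616

#: Per-category descriptives of the categorizability scores
#: (proportion correct on congruent trials): mean, median, SD, min, max.
CATEGORIZABILITY_DESCRIPTIVES = {
    "living_room":      (0.55, 0.56, 0.17, 0.22, 0.87),
    "bridge":           (0.60, 0.64, 0.21, 0.17, 0.97),
    "kitchen":          (0.63, 0.65, 0.15, 0.20, 0.95),
    "bathroom":         (0.64, 0.69, 0.19, 0.27, 0.92),
    "conference_room":  (0.65, 0.64, 0.18, 0.30, 0.92),
    "bedroom":          (0.66, 0.69, 0.16, 0.28, 0.94),
    "airport_terminal": (0.67, 0.69, 0.14, 0.27, 0.90),
    "amusement_park":   (0.70, 0.76, 0.23, 0.15, 0.96),
    "playground":       (0.73, 0.79, 0.19, 0.23, 0.94),
    "mountain":         (0.82, 0.85, 0.09, 0.61, 0.97),
    "cockpit":          (0.85, 0.88, 0.10, 0.43, 0.97),
    "house":            (0.87, 0.89, 0.08, 0.61, 0.98),
    "pasture":          (0.88, 0.90, 0.10, 0.40, 0.99),
    "skyscraper":       (0.89, 0.90, 0.06, 0.77, 0.97),
}

#: Per-category descriptives of the shrinkability scores (mean search RT, s).
SHRINKABILITY_DESCRIPTIVES = {
    "skyscraper":       (2.03, 2.03, 0.52, 0.88, 3.37),
    "bridge":           (2.11, 2.05, 0.56, 1.00, 3.69),
    "bedroom":          (2.12, 2.05, 0.40, 1.47, 3.06),
    "mountain":         (2.21, 2.10, 0.47, 1.18, 3.08),
    "conference_room":  (2.23, 2.25, 0.45, 1.30, 3.20),
    "amusement_park":   (2.30, 2.20, 0.71, 1.12, 4.82),
    "pasture":          (2.30, 2.17, 0.55, 1.46, 3.61),
    "house":            (2.34, 2.29, 0.45, 1.35, 3.38),
    "bathroom":         (2.38, 2.33, 0.47, 1.48, 3.35),
    "cockpit":          (2.45, 2.59, 0.56, 1.05, 3.35),
    "living_room":      (2.45, 2.49, 0.50, 1.41, 3.39),
    "kitchen":          (2.48, 2.46, 0.44, 1.56, 3.44),
    "airport_terminal": (2.50, 2.39, 0.63, 0.89, 4.06),
    "playground":       (2.59, 2.59, 0.65, 1.37, 4.14),
}

#: Per-category descriptives of the perceived distinctiveness scores
#: (mean 7-point rating, -3 representative .. +3 distinctive).
DISTINCTIVENESS_DESCRIPTIVES = {
    "kitchen":          (-1.10, -1.15, 0.69, -2.09, 1.95),
    "conference_room":  (-1.08, -1.22, 0.83, -2.24, 1.22),
    "bathroom":         (-0.96, -1.18, 0.94, -2.24, 1.20),
    "cockpit":          (-0.96, -1.05, 0.94, -2.17, 2.05),
    "bedroom":          (-0.93, -1.01, 0.82, -2.12, 0.86),
    "pasture":          (-0.93, -1.18, 1.00, -2.36, 1.13),
    "living_room":      (-0.87, -1.06, 0.85, -2.05, 1.20),
    "playground":       (-0.87, -1.09, 0.90, -2.05, 1.28),
    "airport_terminal": (-0.79, -0.99, 0.71, -1.93, 1.09),
    "house":            (-0.78, -1.13, 1.09, -2.24, 1.91),
    "mountain":         (-0.78, -1.01, 0.84, -1.84, 1.23),
    "skyscraper":       (-0.72, -0.80, 0.74, -1.81, 1.19),
    "amusement_park":   (-0.69, -0.75, 0.89, -2.00, 1.26),
    "bridge":           (-0.67, -0.62, 0.67, -1.96, 0.88),
}

#: Published image-level zero-order Pearson correlations (within-category
#: z-scored variables, n = 616, df = 614).
R_CATEGORIZABILITY_MEMORABILITY = -0.07
R_SHRINKABILITY_MEMORABILITY = -0.23
R_DISTINCTIVENESS_MEMORABILITY = 0.49
R_DISTINCTIVENESS_CATEGORIZABILITY = -0.31
R_DISTINCTIVENESS_SHRINKABILITY = -0.15
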