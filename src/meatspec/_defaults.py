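"""Default statistical targets for the synthetic sheep-meat dataset.

Per-cut distributional targets (mean, SD, min, max) for the six
physicochemical properties, and the pooled pairwise correlation targets
between them.  These are literature-informed reference values for the six
commercial sheep-meat cuts; all of them are overridable through
:class:`meatspec.generate.GeneratorConfig`.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

#: Canonical cut-type labels, in design order.
CUT_TYPES: tuple[str, ...] = (
    "silverside",
    "back_strap",
    "oyster",
    "fillet",
    "thick_flank",
    "tenderloin",
)

#: Canonical property labels, in reference-table column order.
PROPERTIES: tuple[str, ...] = (
    "pH",
    "L_star",
    "a_star",
    "b_star",
    "cooking_loss",
    "shear_force",
)


class PropertyStats(NamedTuple):
    """Distributional target for one property within one cut."""

    mean: float
    sd: float
    minimum: float
    maximum: float


# cut -> property -> (mean, sd, min, max)
DEFAULT_PROPERTY_DISTRIBUTIONS: dict[str, dict[str, PropertyStats]] = {
    "tenderloin": {
        "pH": PropertyStats(5.86, 0.09, 5.74, 6.10),
        "L_star": PropertyStats(43.19, 2.46, 38.45, 47.64),
        "a_star": PropertyStats(11.39, 1.36, 8.95, 14.48),
        "b_star": PropertyStats(10.90, 1.17, 8.07, 13.54),
        "cooking_loss": PropertyStats(22.63, 3.29, 15.87, 29.46),
        "shear_force": PropertyStats(38.80, 4.80, 29.41, 49.55),
    },
    "thick_flank": {
        "pH": PropertyStats(5.94, 0.14, 5.75, 6.34),
        "L_star": PropertyStats(42.76, 2.05, 39.87, 48.80),
        "a_star": PropertyStats(11.97, 1.06, 10.36, 14.15),
        "b_star": PropertyStats(12.40, 1.00, 10.05, 14.53),
        "cooking_loss": PropertyStats(18.99, 4.81, 11.84, 30.67),
        "shear_force": PropertyStats(44.49, 5.19, 37.56, 57.67),
    },
    "oyster": {
        "pH": PropertyStats(5.94, 0.08, 5.81, 6.09),
        "L_star": PropertyStats(43.19, 1.90, 39.26, 47.44),
        "a_star": PropertyStats(12.49, 1.17, 10.36, 14.91),
        "b_star": PropertyStats(12.82, 1.11, 9.79, 15.09),
        "cooking_loss": PropertyStats(17.67, 4.42, 9.81, 28.07),
        "shear_force": PropertyStats(42.31, 4.27, 34.53, 50.26),
    },
    "fillet": {
        "pH": PropertyStats(6.04, 0.08, 5.90, 6.18),
        "L_star": PropertyStats(47.43, 2.30, 42.21, 51.03),
        "a_star": PropertyStats(12.39, 1.53, 9.59, 15.86),
        "b_star": PropertyStats(13.95, 1.58, 10.67, 16.39),
        "cooking_loss": PropertyStats(19.93, 5.27, 12.31, 32.20),
        "shear_force": PropertyStats(49.87, 4.98, 44.25, 62.59),
    },
    "silverside": {
        "pH": PropertyStats(5.79, 0.08, 5.69, 6.04),
        "L_star": PropertyStats(39.00, 1.72, 36.61, 42.73),
        "a_star": PropertyStats(13.06, 0.90, 11.27, 15.03),
        "b_star": PropertyStats(11.79, 0.96, 10.51, 14.04),
        "cooking_loss": PropertyStats(18.46, 4.59, 12.04, 28.80),
        "shear_force": PropertyStats(44.30, 4.92, 35.85, 54.05),
    },
    "back_strap": {
        "pH": PropertyStats(5.82, 0.09, 5.70, 6.08),
        "L_star": PropertyStats(41.55, 2.44, 32.21, 44.70),
        "a_star": PropertyStats(11.91, 1.43, 8.74, 14.66),
        "b_star": PropertyStats(12.09, 1.34, 7.07, 14.74),
        "cooking_loss": PropertyStats(23.18, 4.12, 16.83, 31.87),
        "shear_force": PropertyStats(42.95, 9.97, 25.46, 62.26),
    },
}

#: Pooled pairwise Pearson correlation targets between the six properties,
#: in :data:`PROPERTIES` order.
DEFAULT_PROPERTY_CORRELATIONS: np.ndarray = np.array(
    [
        #  pH      L*      a*      b*      CL      SF
        [1.000, 0.406, -0.188, 0.224, -0.224, 0.266],
        [0.406, 1.000, -0.074, 0.654, -0.169, 0.139],
        [-0.188, -0.074, 1.000, 0.567, 0.017, -0.052],
        [0.224, 0.654, 0.567, 1.000, -0.245, 0.152],
        [-0.224, -0.169, 0.017, -0.245, 1.000, -0.127],
        [0.266, 0.139, -0.052, 0.152, -0.127, 1.000],
    ]
)
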