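"""Medaka <-> human age conversion from life-history hallmarks.

A through-origin quadratic maps human years x to medaka months y:

    y = a * x + b * x**2

fitted by least squares through hallmark pairs (sexual maturation, median
life expectancy per sex, maximum recorded lifespan per sex).  The inverse
map takes the positive root of b x^2 + a x - y = 0.

The widely quoted reference coefficients for this model are a = 0.0954
with a quadratic coefficient printed as 0.0171; that printed value is
inconsistent both with the hallmark data and with the published 8 -> 46.0
and 12 -> 60.4 month->year interpolations, all of which are reproduced by
0.00171.  The corrected value is therefore the default; models built from
the as-printed value carry a discrepancy note in their metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidModelError, TelovitaError

#: (label, human years, medaka months) hallmark pairs.  Human sexual
#: maturation spans 12-15 y; the midpoint is used by default (the choice
#: is exposed via ``maturation_age_human``).
HALLMARKS = (
    ("maturation", 13.5, 3.0),
    ("median_lifespan_M", 65.7, 13.7),
    ("median_lifespan_F", 70.1, 14.6),
    ("max_lifespan_M", 116.1, 32.0),
    ("max_lifespan_F", 122.4, 39.5),
)

REFERENCE_LINEAR_COEF = 0.0954
REFERENCE_QUADRATIC_COEF = 0.00171  # decimal-corrected (see module docstring)
REFERENCE_QUADRATIC_COEF_AS_PRINTED = 0.0171


@dataclass
class AgeConversionModel:
    a: float  # medaka-months per human-year
    b: float  # medaka-months per human-year^2 (>= 0 for invertibility)
    r_squared: float = np.nan  # about zero (no-intercept convention)
    r_squared_mean: float = np.nan  # about the mean, for reference
    hallmark_pairs: tuple = ()
    notes: tuple = ()

    def __post_init__(self):
        if self.a < 0 or self.b < 0 or (self.a == 0 and self.b == 0):
            raise InvalidModelError("need a, b >= 0 and (a, b) != (0, 0)")


def fit_model(pairs=None, maturation_age_human=13.5):
    """Least squares of medaka months on (x, x^2) with no intercept.

    ``pairs`` is an iterable of (human_years, medaka_months); defaults to
    the five hallmark pairs with the requested human maturation age.
    R^2 about zero (the no-intercept convention) is the primary figure;
    R^2 about the mean is reported alongside.
    """
    if pairs is None:
        pairs = [(h if label != "maturation" else maturation_age_human, m)
                 for label, h, m in HALLMARKS]
    pairs = [(float(x), float(y)) for x, y in pairs]
    if len(pairs) < 3:
        raise TelovitaError("need >= 3 hallmark pairs")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.any(x <= 0) or np.any(y <= 0):
        raise TelovitaError("hallmark ages must be positive")
    X = np.column_stack([x, x**2])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred = X @ coef
    sse = float(np.sum((y - pred) ** 2))
    r2_zero = 1.0 - sse / float(np.sum(y**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2_mean = 1.0 - sse / sst if sst > 0 else np.nan
    a, b = (float(v) for v in coef)
    # round-off can leave a vanishing negative coefficient on exact data
    a = 0.0 if -1e-9 < a < 0 else a
    b = 0.0 if -1e-9 < b < 1e-12 else b
    return AgeConversionModel(a=a, b=b, r_squared=r2_zero,
                              r_squared_mean=r2_mean,
                              hallmark_pairs=tuple(pairs))


def reference_model(corrected=True):
    """The published-coefficient model (decimal-corrected by default)."""
    if corrected:
        return AgeConversionModel(
            a=REFERENCE_LINEAR_COEF, b=REFERENCE_QUADRATIC_COEF,
            notes=("quadratic coefficient decimal-corrected from the printed "
                   "0.0171 to 0.00171 (the printed value reproduces neither "
                   "the hallmark data nor the published interpolations)",))
    return AgeConversionModel(
        a=REFERENCE_LINEAR_COEF, b=REFERENCE_QUADRATIC_COEF_AS_PRINTED,
        notes=("as-printed quadratic coefficient; inconsistent with the "
               "hallmark data (kept for comparison only)",))


def human_to_medaka(model, age_human):
    """Forward map, human years -> medaka months."""
    age_human = np.asarray(age_human, dtype=float)
    if np.any(age_human < 0):
        raise TelovitaError("age must be non-negative")
    out = model.a * age_human + model.b * age_human**2
    return out if out.ndim else float(out)


def medaka_to_human(model, age_medaka):
    """Inverse map, medaka months -> human years (positive quadratic root)."""
    y = np.asarray(age_medaka, dtype=float)
    if np.any(y < 0):
        raise TelovitaError("age must be non-negative")
    if model.b == 0:
        out = y / model.a
    else:
        out = (-model.a + np.sqrt(model.a**2 + 4.0 * model.b * y)) / (2.0 * model.b)
    return out if out.ndim else float(out)
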