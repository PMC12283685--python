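"""Shared domain types, constants and exceptions.

Salinity classes follow the conventional topsoil (0-10 cm) electrical
conductivity (EC, dS/m) scheme: non-saline (< 2), slightly saline [2, 4),
moderately saline [4, 8), highly saline [8, 16) and extremely saline
(>= 16).  "Salt-affected" soil is class slightly-saline or worse
(EC >= 2 dS/m); "saline" soil is moderately-saline or worse (EC >= 4 dS/m).
Classes are encoded as integers 0..4 throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Salinity classification constants
# ---------------------------------------------------------------------------

CLASS_NAMES: tuple[str, ...] = (
    "non", "slightly", "moderately", "highly", "extremely"
)
N_CLASSES = 5

#: EC (dS/m) breakpoints between consecutive classes; intervals are
#: half-open [lower, upper), the last class is unbounded above.
EC_BREAKS: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0)

#: Lowest class index counted as salt-affected (EC >= 2 dS/m).
SALT_AFFECTED_MIN_CLASS = 1
#: Lowest class index counted as saline (EC >= 4 dS/m).
SALINE_MIN_CLASS = 2

#: Raster nodata code for class maps.
NODATA = 255

#: Mean Earth radius (km) used for spherical pixel areas.
EARTH_RADIUS_KM = 6371.0088

# ---------------------------------------------------------------------------
# Land-cover ids (GLC_FCS30D-style 30 m product, collapsed to coarse groups)
# ---------------------------------------------------------------------------

LC_GROUPS: dict[int, str] = {
    10: "rainfed_cropland",
    11: "herbaceous_cover",
    20: "irrigated_cropland",
    51: "forest", 52: "forest", 61: "forest", 62: "forest",
    71: "forest", 72: "forest", 81: "forest", 82: "forest",
    91: "forest", 92: "forest",
    120: "shrubland", 121: "shrubland", 122: "shrubland",
    130: "grassland",
    150: "sparse_vegetation", 152: "sparse_vegetation",
    153: "sparse_vegetation",
    181: "wetland", 182: "wetland", 183: "wetland", 184: "wetland",
    185: "wetland", 186: "wetland", 187: "wetland",
}

LC_IDS: frozenset[int] = frozenset(LC_GROUPS)


# ---------------------------------------------------------------------------
# Exceptions
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    """Invalid configuration (degenerate ranges, out-of-bound fractions...)."""


class InputError(ValueError):
    """Invalid input data for an operation."""


class InsufficientDataError(InputError):
    """Sample too small for the requested fit or test."""


class DegenerateFitError(InputError):
    """Distribution fit impossible (e.g. zero-variance sample)."""


# ---------------------------------------------------------------------------
# Fitted-parameter and result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaParams:
    """Maximum-likelihood Gamma parameters (shape ``alpha``, scale ``beta``)
    together with the sample size ``n`` they were fitted on.  ``n`` drives
    the quantile clamp used by the standardization transform."""

    alpha: float
    beta: float
    n: int

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise DegenerateFitError(
                f"gamma parameters must be positive, got alpha={self.alpha}, "
                f"beta={self.beta}"
            )


@dataclass
class SensitivityResult:
    """Outcome of one multi-group salinity-vs-fluorescence test.

    ``significant`` is defined as omnibus ``p_value < alpha``; when the
    stratum is untestable (< 2 eligible groups) ``testable`` is False and
    ``p_value`` is NaN.
    """

    stratum: Any
    statistic: float
    p_value: float
    significant: bool
    alpha: float
    group_sizes: dict[int, int]
    testable: bool = True
    pairwise: pd.DataFrame | None = None


@dataclass(frozen=True)
class FeatureSet:
    """A subset of the 12 SIFI time scales used as classifier inputs."""

    scales: tuple[int, ...]
    anchor_month: int = 12

    def __post_init__(self) -> None:
        if not all(1 <= s <= 12 for s in self.scales):
            raise InputError(f"scales must lie in 1..12, got {self.scales}")
        if len(set(self.scales)) != len(self.scales):
            raise InputError("duplicate scales in feature set")

    @property
    def columns(self) -> list[str]:
        return [f"sifi_{s}" for s in self.scales]


@dataclass
class RegionModel:
    """A fitted per-cell salinity classifier with its provenance.

    ``provenance`` is ``"native"`` for models trained on their own (typical)
    cell and ``"transferred"`` for models copied or adapted from the best
    typical-cell model.  ``degenerate`` marks single-class cells whose
    "model" is a constant predictor; such models are never transfer sources.
    """

    cell_id: tuple[int, int] | str
    feature_set: FeatureSet
    hyperparameters: dict[str, Any]
    cv_accuracy: float
    provenance: str  # "native" | "transferred"
    seed: int
    estimator: Any = None
    degenerate: bool = False
    constant_class: int | None = None
    adapted: bool | None = None  # transferred models only
    train_X: np.ndarray | None = field(default=None, repr=False)
    train_y: np.ndarray | None = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.degenerate:
            return np.full(len(X), self.constant_class, dtype=int)
        if self.estimator is None:
            raise InputError("model has no fitted estimator")
        return self.estimator.predict(X).astype(int)


@dataclass
class ClassificationReport:
    """Five-class confusion matrix (rows = true, cols = predicted) and the
    derived per-class precision/recall/F1 plus overall accuracy."""

    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    n: int
    #: classes with no true and no predicted members (metrics forced to 0)
    empty_classes: tuple[int, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": CLASS_NAMES,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.confusion.sum(axis=1),
            }
        )
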