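"""Linear scoring models and their JSON serialization.

A model is a sparse linear combination of named descriptors,
``score = c_1 * v_1 + ... + c_k * v_k``, with no intercept (an additive
constant cannot change a ranking).  By convention the leading coefficient is
normalized to +1 or -1, mirroring the way such equations are conventionally
printed; normalization divides by a positive constant and therefore never
changes a ranking or a thresholded class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["LinearModel", "ProbabilityProfile", "read_model", "write_model"]


@dataclass
class ProbabilityProfile:
    """Score-based probability estimates from the training ranking.

    The training ranking is cut into consecutive percentile bins (default
    width 2% of the instances); each bin records its positive fraction, which
    becomes the predicted probability for any new score falling in that bin.
    ``lower_bounds[i]`` is the smallest training score inside bin *i* (bins
    ordered best-first, bounds non-increasing); scores outside the training
    range clamp to the extreme bins.
    """

    lower_bounds: np.ndarray  # non-increasing, one per bin
    bin_positive_fraction: np.ndarray
    bin_fraction: float

    def __post_init__(self) -> None:
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.bin_positive_fraction = np.asarray(self.bin_positive_fraction, float)
        if self.lower_bounds.shape != self.bin_positive_fraction.shape:
            raise ValueError("bounds and fractions must align")
        if ((self.bin_positive_fraction < 0) | (self.bin_positive_fraction > 1)).any():
            raise ValueError("bin positive fractions must lie in [0, 1]")

    @property
    def bin_edges(self) -> np.ndarray:
        """Score values delimiting the bins (len = n_bins + 1, descending)."""
        return np.concatenate(([np.inf], self.lower_bounds))

    def probability(self, scores) -> np.ndarray:
        """Per-score positive probability: the fraction of the containing bin."""
        s = np.atleast_1d(np.asarray(scores, dtype=float))
        # first bin whose lower bound is <= score; below-range clamps to last
        idx = np.searchsorted(-self.lower_bounds, -s, side="left")
        idx = np.minimum(idx, len(self.lower_bounds) - 1)
        return self.bin_positive_fraction[idx]

    def to_dict(self) -> dict:
        return {
            "lower_bounds": self.lower_bounds.tolist(),
            "bin_positive_fraction": self.bin_positive_fraction.tolist(),
            "bin_fraction": self.bin_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProbabilityProfile":
        return cls(
            lower_bounds=np.asarray(d["lower_bounds"], float),
            bin_positive_fraction=np.asarray(d["bin_positive_fraction"], float),
            bin_fraction=float(d["bin_fraction"]),
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ProbabilityProfile)
            and np.array_equal(self.lower_bounds, other.lower_bounds)
            and np.array_equal(self.bin_positive_fraction, other.bin_positive_fraction)
            and self.bin_fraction == other.bin_fraction
        )


@dataclass
class LinearModel:
    """An ordered set of descriptor names with coefficients and a threshold.

    ``threshold`` separates predicted positives (score >= threshold) from
    negatives; it is derived from the training ranking, not fitted jointly.
    ``train_quality`` is the ranking-quality objective value on the training
    table.  ``provenance`` carries the config snapshot and RNG seed of the
    fit that produced the model.
    """

    variables: list[str]
    coefficients: np.ndarray
    threshold: float | None = None
    train_quality: float | None = None
    cluster_size: int | None = None
    seed: int | None = None
    provenance: dict = field(default_factory=dict)
    probability_profile: ProbabilityProfile | None = None

    def __post_init__(self) -> None:
        self.variables = [str(v) for v in self.variables]
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 1 or len(self.variables) != len(self.coefficients):
            raise ValueError("variables and coefficients must have equal length")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names in model")

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def score(self, table) -> np.ndarray:
        """Scores for each instance of a DescriptorTable or DataFrame.

        Variables are matched by name, so the model transfers across tables
        whose columns are ordered differently.
        """
        if hasattr(table, "columns") and callable(table.columns):  # DescriptorTable
            X = table.columns(self.variables)
        else:  # pandas DataFrame
            missing = [v for v in self.variables if v not in table.columns]
            if missing:
                raise KeyError(f"unknown descriptor(s) {missing}")
            X = table[self.variables].to_numpy(dtype=float)
        return X @ self.coefficients

    def normalized(self) -> "LinearModel":
        """Divide all coefficients (and the threshold) by |c0| so c0 = ±1.

        The divisor is positive, so every ranking and thresholded class is
        unchanged.
        """
        c0 = abs(self.coefficients[0])
        if c0 < 1e-12:
            raise ValueError("leading coefficient is ~0; rotate variables first")
        profile = self.probability_profile
        if profile is not None and c0 != 1.0:
            profile = ProbabilityProfile(
                lower_bounds=profile.lower_bounds / c0,
                bin_positive_fraction=profile.bin_positive_fraction,
                bin_fraction=profile.bin_fraction,
            )
        return LinearModel(
            variables=list(self.variables),
            coefficients=self.coefficients / c0,
            threshold=None if self.threshold is None else self.threshold / c0,
            train_quality=self.train_quality,
            cluster_size=self.cluster_size,
            seed=self.seed,
            provenance=dict(self.provenance),
            probability_profile=profile,
        )

    def equation(self) -> str:
        """Human-readable form, e.g. ``+1 HBT + 2.47 Lipole - ...``."""
        parts = []
        for name, c in zip(self.variables, self.coefficients):
            sign = "-" if c < 0 else "+"
            parts.append(f"{sign} {abs(c):g} {name}")
        return " ".join(parts).lstrip("+ ")

    def to_dict(self) -> dict:
        d = {
            "variables": list(self.variables),
            "coefficients": self.coefficients.tolist(),
            "threshold": self.threshold,
            "cluster_size": self.cluster_size,
            "train_quality": self.train_quality,
            "seed": self.seed,
        }
        if self.provenance:
            d["provenance"] = self.provenance
        if self.probability_profile is not None:
            d["probability_profile"] = self.probability_profile.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        try:
            model = cls(
                variables=d["variables"],
                coefficients=np.asarray(d["coefficients"], float),
                threshold=d.get("threshold"),
                train_quality=d.get("train_quality"),
                cluster_size=d.get("cluster_size"),
                seed=d.get("seed"),
                provenance=d.get("provenance", {}),
                probability_profile=(
                    ProbabilityProfile.from_dict(d["probability_profile"])
                    if d.get("probability_profile")
                    else None
                ),
            )
        except KeyError as e:
            raise ValueError(f"malformed model file: missing key {e}") from None
        return model

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LinearModel)
            and self.variables == other.variables
            and np.array_equal(self.coefficients, other.coefficients)
            and self.threshold == other.threshold
            and self.train_quality == other.train_quality
            and self.cluster_size == other.cluster_size
            and self.seed == other.seed
            and self.provenance == other.provenance
            and self.probability_profile == other.probability_profile
        )


def write_model(model: LinearModel, path) -> None:
    """Serialize a model to JSON (exact float round-trip via repr)."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def read_model(path) -> LinearModel:
    """Load a model from JSON, renormalizing the leading coefficient if needed.

    A file whose first coefficient is not ±1 is accepted: all coefficients
    and the threshold are divided by |c0| (a warning is emitted).  Scores
    scale by the same positive factor, so rankings and classes are unchanged.
    """
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed model file {path}: {e}") from None
    if not isinstance(d, dict):
        raise ValueError(f"malformed model file {path}: expected a JSON object")
    model = LinearModel.from_dict(d)
    if model.n_variables and abs(abs(model.coefficients[0]) - 1.0) > 1e-12:
        warnings.warn(
            f"leading coefficient {model.coefficients[0]:g} is not ±1; "
            "renormalizing (ranking unchanged)",
            stacklevel=2,
        )
        model = model.normalized()
    return model
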