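"""Run configuration for the EFO learner.

Defaults follow the method's published operating point: cluster size equal to
the number of training positives, 12 random-sampling cycles per included
variable, a top-5% enrichment-factor filter cut-off of 2.0, six variables per
model, pattern-search budget of 5000 iterations with an RMS step tolerance of
0.001, 20 models kept, and a 70/30 split repeated 5 times.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class EFOConfig:
    cluster_size: int | None = None  # None -> n_positive of the training table
    n_variables: int = 6
    ef_filter_cutoff: float = 2.0
    sampling_cycles_per_variable: int = 12
    hj_iterations: int = 5000
    hj_rms_tol: float = 0.001
    hj_starts: int = 3
    n_models_kept: int = 20
    split_fraction: float = 0.70
    split_repeats: int = 5
    max_combinations: int = 20000
    bin_fraction: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cluster_size is not None and self.cluster_size < 1:
            raise ValueError("cluster_size must be >= 1")
        if self.n_variables < 1:
            raise ValueError("n_variables must be >= 1")
        if self.ef_filter_cutoff < 0:
            raise ValueError("ef_filter_cutoff must be >= 0")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.sampling_cycles_per_variable < 1:
            raise ValueError("sampling_cycles_per_variable must be >= 1")
        if self.hj_starts < 1:
            raise ValueError("hj_starts must be >= 1")
        if not 0 < self.bin_fraction <= 0.5:
            raise ValueError("bin_fraction must lie in (0, 0.5]")

    def replace(self, **changes) -> "EFOConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EFOConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
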