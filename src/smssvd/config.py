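"""Run configuration for the decomposition pipeline."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class SMSSVDConfig:
    """Settings shared by the decomposition loop and the score optimizer.

    Parameters
    ----------
    target_dim
        Total number of dimensions to extract.  ``None`` means run in
        open-ended mode: iterate until the best projection score is no
        longer positive (no subset beats the randomization null) or the
        residual is numerically zero.
    n_randomizations
        Number of randomized (within-variable permuted) copies used to
        estimate the null informativeness.
    seed
        Master seed; every random draw in a run is derived from it.
    disable_selection
        Skip variable selection entirely.  The decomposition then equals
        the truncated SVD of the input.
    center_variables
        Subtract each variable's mean across samples before decomposing.
    threshold_grid_size
        Number of quantile-based standard-deviation thresholds scanned.
    d_max
        Upper bound for the per-signal dimension search.
    """

    target_dim: int | None = None
    n_randomizations: int = 10
    seed: int = 0
    disable_selection: bool = False
    center_variables: bool = False
    threshold_grid_size: int = 32
    d_max: int = 20

    def __post_init__(self) -> None:
        if self.target_dim is not None and self.target_dim < 1:
            raise ValueError("target_dim must be >= 1")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if self.threshold_grid_size < 2:
            raise ValueError("threshold_grid_size must be >= 2")
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")
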