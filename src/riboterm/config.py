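"""Pipeline configuration.

Every tunable of the termination-detection method lives here with its
published default, so a run is fully described by one object and can be
serialized alongside the outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunables for the termination-detection pipeline.

    Parameters
    ----------
    flank : int
        Reference-window flank on each side of a riboswitch locus, nt.
    min_cov_depth : float
        Minimum mean total coverage across the riboswitch for a
        locus x readset to enter analysis.
    sigma : float
        Standard deviation (nt) of the discretized-Gaussian convolution
        kernel.
    kernel_half_width : int
        Kernel half width; the kernel has ``2 * half_width + 1`` elements.
    zero_band : float
        Half width of the open zero region ``(-zero_band, zero_band)`` in
        convolution-amplitude units; values inside it are treated as noise
        floor during peak detection.
    ext_prop : tuple of float
        Noise-set region extensions, as proportions of riboswitch size:
        ``(a, b)`` places the region from ``start - a*size`` to
        ``end + b*size``. The default ``(-0.3, 1.0)`` drops the first 30%
        of the riboswitch and continues one riboswitch length past its
        3' end.
    roi_half_width_prop : float
        Region-of-interest half width around the riboswitch 3' end, as a
        proportion of riboswitch size.
    min_drop : float
        Minimum fractional coverage drop (as a positive fraction of mean
        riboswitch coverage) for a termination call.
    alpha_peak, alpha_mean, alpha_variance : float
        Significance thresholds for the per-peak pseudo p-value, the
        cluster Mann-Whitney mean test and the resampled Levene variance
        test.
    cophenetic_threshold : float
        Complete-linkage flat-cut distance for cross-condition peak
        clustering (relative-position units).
    n_levene_comparisons : int
        Minimum number of resampled Levene comparisons per cluster.
    min_noise_set : int
        Minimum number of other peaks required to fit the per-locus 2-D
        noise model.
    allow_single_reads : bool
        Count reads whose mate is unmapped toward read/clipped coverage.
    allow_soft_clips : bool
        Let soft-clipped pairs contribute fragment termini.
    seed : int
        Seed for every stochastic step (Levene resampling).
    """

    flank: int = 1000
    min_cov_depth: float = 15.0
    sigma: float = 1.5
    kernel_half_width: int = 25
    zero_band: float = 0.1
    ext_prop: tuple[float, float] = (-0.3, 1.0)
    roi_half_width_prop: float = 0.5
    min_drop: float = 0.20
    alpha_peak: float = 0.05
    alpha_mean: float = 0.05
    alpha_variance: float = 0.05
    cophenetic_threshold: float = 0.04
    n_levene_comparisons: int = 60
    min_noise_set: int = 3
    allow_single_reads: bool = False
    allow_soft_clips: bool = False
    seed: int = 1729

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kernel_half_width < 1:
            raise ValueError("kernel_half_width must be >= 1")
        if self.zero_band < 0:
            raise ValueError("zero_band must be non-negative")
        self.ext_prop = tuple(self.ext_prop)  # YAML round-trips lists

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["ext_prop"] = list(data["ext_prop"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
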