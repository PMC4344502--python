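"""Configuration objects shared across the pipeline.

Two dataclasses carry essentially all tunable knobs:

* :class:`SimConfig` — parameters of the synthetic small-RNA time-course
  generator (hairpin reference, decay kinetics, noise model, planted
  sequence biases).
* :class:`ThresholdConfig` — the analysis thresholds: read-length and
  detection filters, the fast/slow turnover class boundaries, the t-test
  alpha, permutation iterations, and the kinetic-shape gates.

Both validate themselves eagerly; invalid settings raise
:class:`ConfigError` before any data is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

NTS = ("A", "C", "G", "T")


class ConfigError(ValueError):
    """A configuration value is out of bounds or internally inconsistent."""


def _check_dist(name: str, dist: dict) -> None:
    if set(dist) != set(NTS):
        raise ConfigError(f"{name}: keys must be exactly {NTS}, got {sorted(dist)}")
    if any(p < 0 for p in dist.values()):
        raise ConfigError(f"{name}: negative probability")
    if abs(sum(dist.values()) - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities must sum to 1 (got {sum(dist.values())})")


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class SeqBias:
    """Planted positional composition differences between fast- and
    slow-turnover species.

    Fast species are biased the way the real unstable isoforms are:
    first base enriched for G/C and depleted for U, last base enriched
    for C and depleted for G, and positions 13-16 depleted of A.
    ``a_window_*`` is the per-position probability of drawing an A inside
    the 13-16 window. The slow distributions double as the background
    composition.
    """

    first_base_fast: dict = field(
        default_factory=lambda: {"A": 0.20, "C": 0.30, "G": 0.35, "T": 0.15})
    first_base_slow: dict = field(
        default_factory=lambda: {"A": 0.25, "C": 0.20, "G": 0.15, "T": 0.40})
    last_base_fast: dict = field(
        default_factory=lambda: {"A": 0.25, "C": 0.40, "G": 0.10, "T": 0.25})
    last_base_slow: dict = field(
        default_factory=lambda: {"A": 0.25, "C": 0.20, "G": 0.30, "T": 0.25})
    a_window_fast: float = 0.12
    a_window_slow: float = 0.35

    def validate(self) -> None:
        for name in ("first_base_fast", "first_base_slow",
                     "last_base_fast", "last_base_slow"):
            _check_dist(name, getattr(self, name))
        _check_prob("a_window_fast", self.a_window_fast)
        _check_prob("a_window_slow", self.a_window_slow)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the sequencing experiment the pipeline was designed
    around: an actinomycin-D time course at 0/1/4/12 h with biological
    triplicate, ~2e6 mature-mapped reads per library, a small minority
    (~8%) of fast-turnover species (mostly star strands) whose fast pool
    has a ~1 h half-life on top of a stable residual pool, ultrafast
    hairpin-loop byproducts, one dominant (~90%) isoform per mature
    species, and negative-binomial replicate noise in the CV regime of
    good biological triplicates.
    """

    n_hairpins: int = 300
    timepoints_h: tuple = (0.0, 1.0, 4.0, 12.0)
    n_replicates: int = 3
    depth: float = 2e6
    frac_fast: float = 0.08
    frac_fast_star_bias: float = 0.8
    h_fast: float = 1.0
    stable_fraction_range: tuple = (0.05, 0.4)
    h_slow: float = math.inf
    nb_dispersion: float = 0.05
    dominant_isoform_frac: float = 0.9
    seq_bias: SeqBias = field(default_factory=SeqBias)
    loop_halflife_h: float = 0.3
    seed: int = 0
    # secondary knobs (not part of the headline regime)
    abundance_sigma: float = 1.0       # log-normal sigma of per-species abundance
    star_ratio_min: float = 4.0        # non-star:star abundance ratio floor
    loop_frac: float = 0.05            # loop abundance relative to hairpin matures at 0 h
    spikein_frac: float = 0.005        # expected spike-in reads / depth, each of 3
    # profiling-platform simulation
    profiling_timepoints_h: tuple = (0.0, 2.0, 4.0, 6.0, 12.0, 24.0)
    profiling_replicates: int = 2
    profiling_noise_sigma: float = 0.1  # log-normal intensity noise; 0 = noiseless
    profiling_scale_sigma: float = 0.3  # log-normal per-sample scale factors

    def validate(self) -> None:
        if self.n_hairpins < 0:
            raise ConfigError("n_hairpins must be >= 0")
        if len(self.timepoints_h) < 1 or any(t < 0 for t in self.timepoints_h):
            raise ConfigError("timepoints_h must be non-negative hours")
        if 0.0 not in self.timepoints_h:
            raise ConfigError("timepoints_h must include 0")
        if len(set(self.timepoints_h)) != len(self.timepoints_h):
            raise ConfigError("timepoints_h must be distinct")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if not 0.0 < self.frac_fast < 1.0:
            raise ConfigError(f"frac_fast must be in (0, 1), got {self.frac_fast}")
        _check_prob("frac_fast_star_bias", self.frac_fast_star_bias)
        if self.h_fast <= 0:
            raise ConfigError("h_fast must be > 0")
        lo, hi = self.stable_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("stable_fraction_range must be within [0, 1] with lo <= hi")
        if self.h_slow <= 0:
            raise ConfigError("h_slow must be > 0 (math.inf for a pure plateau)")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        _check_prob("dominant_isoform_frac", self.dominant_isoform_frac)
        self.seq_bias.validate()
        if self.loop_halflife_h <= 0:
            raise ConfigError("loop_halflife_h must be > 0")
        if self.star_ratio_min < 1:
            raise ConfigError("star_ratio_min must be >= 1")
        if self.profiling_replicates < 1:
            raise ConfigError("profiling_replicates must be >= 1")


@dataclass(frozen=True)
class ThresholdConfig:
    """Analysis thresholds.

    ``detect_threshold`` is the "reliably quantifiable" floor: mean 0-h
    frequency >= 5e-6 of mature-mapped reads. ``fast50``/``fast25`` and
    ``slow`` are the remaining-fraction class boundaries at the endpoint
    (12 h by default); ``alpha`` the nominal t-test level. The mature
    assignment window and overlap fraction control how a read's footprint
    on the hairpin is attributed to a mature arm.
    """

    min_read_len: int = 15
    detect_threshold: float = 5e-6
    max_nta: int = 2
    fast50: float = 0.50
    fast25: float = 0.25
    slow: float = 0.75
    alpha: float = 0.05
    permutation_iters: int = 10000
    mature_window: int = 2
    mature_overlap: float = 0.75
    endpoint_h: float = 12.0
    mid_h: float = 4.0
    # kinetic-shape gates
    ultrafast_r1: float = 0.10
    twostep_aic_margin: float = 2.0
    twostep_max_h_fast: float = 2.0
    twostep_min_f_slow: float = 0.10
    # A-rich motif indicator
    min_a_count: int = 3

    def validate(self) -> None:
        if self.min_read_len < 1:
            raise ConfigError("min_read_len must be >= 1")
        if not 0.0 < self.detect_threshold < 1.0:
            raise ConfigError("detect_threshold must be in (0, 1)")
        if self.max_nta < 0:
            raise ConfigError("max_nta must be >= 0")
        if not self.fast25 < self.fast50 < self.slow:
            raise ConfigError("class boundaries must satisfy fast25 < fast50 < slow")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.permutation_iters <= 0:
            raise ConfigError("permutation_iters must be > 0")
        if self.mature_window < 0:
            raise ConfigError("mature_window must be >= 0")
        if not 0.0 < self.mature_overlap <= 1.0:
            raise ConfigError("mature_overlap must be in (0, 1]")


def _coerce(value, default):
    """Coerce a YAML scalar toward the type of the dataclass default."""
    if isinstance(default, float) and isinstance(value, str):
        if value.lower() in ("inf", "infinite", "infinity"):
            return math.inf
        return float(value)
    if isinstance(default, tuple) and isinstance(value, (list, tuple)):
        return tuple(value)
    return value


def dataclass_from_mapping(cls, mapping: dict):
    """Build ``cls`` from a plain mapping (e.g. a YAML section)."""
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in mapping.items():
        if key not in known:
            raise ConfigError(f"unknown {cls.__name__} field: {key!r}")
        if key == "seq_bias" and isinstance(value, dict):
            value = SeqBias(**value)
        else:
            defaults = cls()
            value = _coerce(value, getattr(defaults, key))
        kwargs[key] = value
    obj = cls(**kwargs)
    obj.validate()
    return obj
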