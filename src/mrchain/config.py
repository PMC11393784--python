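"""Shared analysis configuration for the MR pipeline."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

from .errors import ConfigurationError


@dataclass
class AnalysisConfig:
    """Parameters of the end-to-end MR workflow.

    ``p_threshold`` is the forward instrument threshold (genome-wide
    significance, 5e-8); ``reverse_p_threshold`` (5e-6) applies to
    reverse-direction analyses; per-trait overrides (e.g. 5e-7 for a
    trait with few genome-wide hits) go in ``p_threshold_overrides``.
    Clumping defaults are r2 <= 0.001 within 10,000 kb; weak instruments
    are excluded below F = 10.  ``screen_alpha`` is the significance
    level for mediator screening (mediator -> outcome IVW p); ``alpha``
    the level used to call a causal direction supported.
    """

    p_threshold: float = 5e-8
    reverse_p_threshold: float = 5e-6
    p_threshold_overrides: dict = field(default_factory=dict)
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    f_min: float = 10.0
    palindrome_band: tuple[float, float] = (0.42, 0.58)
    effects_model: str = "auto"
    n_boot: int = 1000
    n_sim: int = 1000
    presso_alpha: float = 0.05
    screen_alpha: float = 0.05
    alpha: float = 0.05
    bonferroni: bool = False
    second_order_se: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_threshold", "reverse_p_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name} must lie in (0, 1], got {v}")
        if self.clump_kb <= 0:
            raise ConfigurationError("clump_kb must be > 0")
        if not 0 <= self.clump_r2 <= 1:
            raise ConfigurationError("clump_r2 must lie in [0, 1]")
        if self.f_min < 0:
            raise ConfigurationError("f_min must be >= 0")
        if self.effects_model not in ("fixed", "random", "auto"):
            raise ConfigurationError(f"unknown effects model {self.effects_model!r}")

    def threshold_for(self, trait_label: str, reverse: bool = False) -> float:
        if trait_label in self.p_threshold_overrides:
            return self.p_threshold_overrides[trait_label]
        return self.reverse_p_threshold if reverse else self.p_threshold

    def derive_seed(self, tag: str) -> int:
        """Deterministic per-task seed below 2**31 (stable across runs)."""
        return (self.seed * 1_000_003 + zlib.crc32(tag.encode())) % 2**31
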