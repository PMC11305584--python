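"""Synthetic study-pair generator and CI-overlap calibration experiments.

The generator emulates the statistical structure the pair analyses assume:

* ratio pairs — a true log effect theta ~ N(mu, tau^2); the original
  estimate is drawn with sampling error se, the replication with a smaller
  error f*se (replications are larger studies); 95% CIs are built as
  estimate +/- 1.96*se on the log scale and exponentiated;
* ORR pairs — a true response rate with binomial counts on both sides and
  exact Clopper-Pearson intervals, standing in for uncontrolled phase-1
  trials and their larger follow-ups;
* optional selection of originals on p < alpha, which induces the winner's
  curse: conditioning on significance makes underpowered original estimates
  systematically overshoot the true effect.

Everything is driven by one explicit NumPy generator seeded from the config,
so fixtures are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

from .core_data import (
    Design,
    Direction,
    EffectEstimate,
    EffectMeasure,
    InterventionType,
    PairTable,
    Significance,
    StudyPair,
)
from .interval_stats import CI_Z_WIDTH, orr_from_counts

__all__ = [
    "SimulationConfig",
    "GenerationExhaustedError",
    "simulate_pairs",
    "overlap_false_failure_rate",
]

_Z95 = 1.96


class GenerationExhaustedError(RuntimeError):
    """The significance filter rejected every draw within the retry budget."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic pair generator.

    Defaults emulate the analysed literature: mostly null-to-moderate
    protective log effects with standard errors typical of published ratio
    CIs (median ~0.15 on the log scale, i.e. 95% CI width around 1.8-fold),
    replications with half the original's standard error, and no selection.

    ``orr_fraction`` of pairs are generated as phase-1 ORR pairs (favorable
    direction, no significance flag); the rest are ratio pairs whose
    direction follows ``direction_rule`` ("unfavorable", "favorable" or
    "random").
    """

    n_pairs: int
    orr_fraction: float = 0.0
    mu: float = 0.0
    tau: float = 0.2
    se_median: float = 0.15
    se_sigma: float = 0.4
    rep_se_factor: float = 0.5
    select_original_significant: bool = False
    alpha: float = 0.05
    direction_rule: str = "unfavorable"
    orr_n: int = 150
    orr_p_range: tuple[float, float] = (0.1, 0.6)
    seed: int = 0
    retry_factor: int = 100

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if not (0.0 <= self.orr_fraction <= 1.0):
            raise ValueError("orr_fraction must lie in [0, 1]")
        if self.tau < 0 or self.se_median <= 0 or self.se_sigma < 0:
            raise ValueError("scale parameters must be positive")
        if self.rep_se_factor <= 0:
            raise ValueError("rep_se_factor must be > 0")
        if self.direction_rule not in {"unfavorable", "favorable", "random"}:
            raise ValueError(f"unknown direction_rule {self.direction_rule!r}")

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "orr_p_range":
                v = f"{v[0]},{v[1]}"
            lines.append(f"{f.name}={v}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        kwargs = {}
        casts = {f.name: f for f in fields(cls)}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in casts:
                raise ValueError(f"unknown config key {key!r}")
            if key in {"n_pairs", "orr_n", "seed", "retry_factor"}:
                kwargs[key] = int(raw)
            elif key == "select_original_significant":
                kwargs[key] = raw.lower() in {"true", "1", "yes"}
            elif key == "direction_rule":
                kwargs[key] = raw
            elif key == "orr_p_range":
                lo, hi = raw.split(",")
                kwargs[key] = (float(lo), float(hi))
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)


def _ratio_estimate(log_point: float, se: float) -> EffectEstimate:
    return EffectEstimate(
        measure=EffectMeasure.RR,
        point=math.exp(log_point),
        lo=math.exp(log_point - _Z95 * se),
        hi=math.exp(log_point + _Z95 * se),
        level=0.95,
    )


def _draw_ratio_pair(cfg: SimulationConfig, rng: np.random.Generator, pair_id: str):
    """One ratio pair, or None if it fails the configured significance filter."""
    theta = rng.normal(cfg.mu, cfg.tau)
    se_o = float(rng.lognormal(math.log(cfg.se_median), cfg.se_sigma))
    y_o = rng.normal(theta, se_o)
    z = abs(y_o) / se_o
    # Normal two-sided p of the original, as the downstream analysis would
    # reconstruct it from the printed CI.
    p_o = 2.0 * 0.5 * math.erfc(z / math.sqrt(2.0))
    significant = p_o < cfg.alpha
    if cfg.select_original_significant and not significant:
        return None
    se_r = cfg.rep_se_factor * se_o
    y_r = rng.normal(theta, se_r)
    if cfg.direction_rule == "random":
        direction = Direction.UNFAVORABLE if rng.random() < 0.5 else Direction.FAVORABLE
    else:
        direction = Direction(cfg.direction_rule)
    return StudyPair(
        pair_id=pair_id,
        original=_ratio_estimate(y_o, se_o),
        replication=_ratio_estimate(y_r, se_r),
        direction=direction,
        original_significant=Significance.SIGNIFICANT if significant else Significance.NONSIGNIFICANT,
        order_inverted=False,
        original_design=Design.RCT,
        intervention_type=InterventionType.PHARMACOLOGICAL,
        original_p=p_o,
    )


def _draw_orr_pair(cfg: SimulationConfig, rng: np.random.Generator, pair_id: str) -> StudyPair:
    lo, hi = cfg.orr_p_range
    true_p = float(rng.uniform(lo, hi))
    n_rep = max(1, round(cfg.orr_n / cfg.rep_se_factor**2))
    # A trial with zero responders carries no usable response-rate ratio
    # (and would not be published as an efficacy claim); redraw those.
    x_o = int(rng.binomial(cfg.orr_n, true_p))
    while x_o == 0:
        x_o = int(rng.binomial(cfg.orr_n, true_p))
    x_r = int(rng.binomial(n_rep, true_p))
    while x_r == 0:
        x_r = int(rng.binomial(n_rep, true_p))
    return StudyPair(
        pair_id=pair_id,
        original=orr_from_counts(x_o, cfg.orr_n),
        replication=orr_from_counts(x_r, n_rep),
        direction=Direction.FAVORABLE,
        original_significant=Significance.NOT_APPLICABLE,
        order_inverted=False,
        original_design=Design.PHASE1,
        intervention_type=InterventionType.PHARMACOLOGICAL,
        original_n=cfg.orr_n,
    )


def simulate_pairs(config: SimulationConfig) -> PairTable:
    """Generate a synthetic pair table, reproducible from ``config.seed``.

    Raises :class:`GenerationExhaustedError` if the significance filter
    rejects every candidate within ``retry_factor * n_pairs`` draws.
    """
    rng = np.random.default_rng(config.seed)
    budget = max(1, config.retry_factor * max(1, config.n_pairs))
    pairs = []
    draws = 0
    while len(pairs) < config.n_pairs:
        pair_id = f"sim-{len(pairs):05d}"
        if rng.random() < config.orr_fraction:
            pairs.append(_draw_orr_pair(config, rng, pair_id))
            continue
        candidate = _draw_ratio_pair(config, rng, pair_id)
        draws += 1
        if candidate is not None:
            pairs.append(candidate)
        elif draws >= budget:
            raise GenerationExhaustedError(
                f"significance filter rejected all candidates in {budget} draws; "
                "increase power (mu/se) or the retry budget"
            )
    return PairTable.from_pairs(pairs)


def overlap_false_failure_rate(se_ratio: float, n_sims: int, seed: int = 0) -> float:
    """Monte-Carlo rate of disjoint 95% CIs for two estimates of one effect.

    Both estimates target the same true value; the second has standard error
    ``se_ratio`` times the first's. The CIs are disjoint iff
    ``|x1 - x2| > 1.96 * (1 + se_ratio)`` (in units of the first SE), so for
    equal errors the rate converges to 2*(1 - Phi(2*1.96/sqrt(2))), about
    0.56% — the chance the overlap criterion rejects a perfect replication.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if se_ratio <= 0:
        raise ValueError("se_ratio must be > 0")
    rng = np.random.default_rng(seed)
    # Difference of the two estimates ~ N(0, 1 + r^2); disjointness threshold
    # is z * (1 + r) on the same scale.
    diff = rng.standard_normal(n_sims) * math.sqrt(1.0 + se_ratio**2)
    return float(np.mean(np.abs(diff) > _Z95 * (1.0 + se_ratio)))
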