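"""Synthetic expression series with a planted critical transition.

A single latent factor per (timepoint, replicate) induces correlation. At
each timepoint ``t``, a planted group of ``dnb_size`` genes loads on the
factor with weight ``sqrt(rho_in(t))``, so the within-group correlation is
``rho_in(t)``; background ("coupled") genes load with weight
``rho_out(t)/sqrt(rho_in(t))``, which makes the realized group<->background
correlation exactly ``rho_out(t)``. The planted group's per-gene standard
deviation is ``baseline_sd * sd_boost`` at the transition timepoint and
``baseline_sd`` elsewhere. These analytically known moments give the
closed-form criticality-index limit implemented in :func:`expected_ci`.

All randomness is drawn from counter-based substreams keyed by
``(seed, stream, gene, timepoint)``, so generation is reproducible and
independent of evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from dnbkit.io_expr import ExpressionSeries

_STREAMS = {"factor": 1, "noise": 2, "de": 3}


def _rng(seed: int, stream: str, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, _STREAMS[stream], *key)))


@dataclass
class SimulationConfig:
    """Generative knobs for a planted-transition expression series.

    ``rho_in`` / ``rho_out`` are per-timepoint schedules (length
    ``n_timepoints``): the within-group correlation and the target realized
    group<->background correlation. ``t_star`` is the 1-based index of the
    planted transition. ``de_fraction`` of genes receive a mean shift
    ``de_shift`` at timepoints >= ``t_star`` so a differential screen has
    signal; when ``de_includes_dnb`` the planted group is shifted too (and
    counts toward the fraction), so the screen can pass it through as
    candidates.
    """

    n_genes: int = 100
    dnb_size: int = 20
    n_timepoints: int = 5
    n_replicates: int = 3
    t_star: int = 4
    baseline_sd: float = 1.0
    sd_boost: float = 1.0
    rho_in: Sequence[float] = (0.1, 0.1, 0.1, 0.1, 0.1)
    rho_out: Sequence[float] = (0.1, 0.1, 0.1, 0.1, 0.1)
    coupled_fraction: float = 1.0
    de_fraction: float = 0.0
    de_shift: float = 0.0
    de_includes_dnb: bool = True
    base_mean: float = 0.0
    timepoint_prefix: str = "T"
    scale: str = "log"
    seed: int = 0

    def __post_init__(self) -> None:
        self.rho_in = tuple(float(r) for r in self.rho_in)
        self.rho_out = tuple(float(r) for r in self.rho_out)

    def validate(self) -> None:
        if not 2 <= self.dnb_size < self.n_genes:
            raise ValueError("require 2 <= dnb_size < n_genes")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if self.n_replicates < 3:
            raise ValueError("n_replicates must be >= 3")
        if not 1 <= self.t_star <= self.n_timepoints:
            raise ValueError("require 1 <= t_star <= n_timepoints")
        if len(self.rho_in) != self.n_timepoints or len(self.rho_out) != self.n_timepoints:
            raise ValueError("rho_in and rho_out must have one value per timepoint")
        for t, (rin, rout) in enumerate(zip(self.rho_in, self.rho_out), 1):
            if not (0 <= rin < 1 and 0 <= rout < 1):
                raise ValueError(f"timepoint {t}: require 0 <= rho_in, rho_out < 1")
            if rin == 0 and rout > 0:
                raise ValueError(
                    f"timepoint {t}: rho_out > 0 requires rho_in > 0 (one-factor model)"
                )
            if rin > 0 and rout > math.sqrt(rin):
                raise ValueError(
                    f"timepoint {t}: rho_out must be <= sqrt(rho_in) "
                    f"({rout} > sqrt({rin}))"
                )
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")
        if self.sd_boost < 1:
            raise ValueError("sd_boost must be >= 1")
        if not 0 <= self.coupled_fraction <= 1:
            raise ValueError("coupled_fraction must be in [0, 1]")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")

    # convenience presets ----------------------------------------------------

    @classmethod
    def strong_effect(cls, **overrides) -> "SimulationConfig":
        """Settings with a clearly detectable planted transition.

        SD boost 3x, within-group correlation 0.1 -> 0.8 at the transition,
        group<->background correlation 0.3 -> 0.05, 10 replicates.
        """
        defaults = dict(
            n_genes=60,
            dnb_size=20,
            n_timepoints=5,
            n_replicates=10,
            t_star=4,
            baseline_sd=1.0,
            sd_boost=3.0,
            rho_in=(0.1, 0.1, 0.1, 0.8, 0.1),
            rho_out=(0.3, 0.3, 0.3, 0.05, 0.3),
            coupled_fraction=0.3,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def null_effect(cls, **overrides) -> "SimulationConfig":
        """No planted effect: independent genes, flat unit variance."""
        defaults = dict(
            n_genes=60,
            dnb_size=20,
            n_timepoints=5,
            n_replicates=10,
            t_star=4,
            baseline_sd=1.0,
            sd_boost=1.0,
            rho_in=(0.0,) * 5,
            rho_out=(0.0,) * 5,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def timepoint_labels(self) -> list[str]:
        return [f"{self.timepoint_prefix}{t}" for t in range(1, self.n_timepoints + 1)]

    def group_sd(self, t: int) -> float:
        """Planted-group per-gene SD at 1-based timepoint ``t``."""
        return self.baseline_sd * (self.sd_boost if t == self.t_star else 1.0)


@dataclass
class GroundTruth:
    """Planted structure of a simulated series."""

    dnb_genes: set[str]
    t_star: str
    t_star_index: int  # 1-based
    de_genes: set[str]
    config: SimulationConfig

    def as_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["rho_in"] = list(cfg["rho_in"])
        cfg["rho_out"] = list(cfg["rho_out"])
        return {
            "dnb_genes": sorted(self.dnb_genes),
            "t_star": self.t_star,
            "t_star_index": self.t_star_index,
            "de_genes": sorted(self.de_genes),
            "config": cfg,
        }


def simulate_series(config: SimulationConfig) -> tuple[ExpressionSeries, GroundTruth]:
    """Generate an expression series with a planted transition.

    Gene layout: the first ``dnb_size`` genes are the planted group, the
    next ``round(coupled_fraction * n_background)`` genes are factor-coupled
    background, the remainder are pure noise. Identical configs (same seed)
    produce identical matrices.
    """
    config.validate()
    n, k, T, n_rep = config.n_genes, config.dnb_size, config.n_timepoints, config.n_replicates
    genes = [f"g{i + 1:05d}" for i in range(n)]
    labels = config.timepoint_labels()
    samples, timepoint_of, replicate_of = [], {}, {}
    for tp in labels:
        for r in range(1, n_rep + 1):
            s = f"{tp}_r{r}"
            samples.append(s)
            timepoint_of[s] = tp
            replicate_of[s] = r

    n_coupled = int(round(config.coupled_fraction * (n - k)))

    # planted differential genes, drawn deterministically from the seed
    n_de = int(round(config.de_fraction * n))
    de_idx: set[int] = set()
    if n_de > 0:
        if config.de_includes_dnb:
            de_idx.update(range(min(k, n_de)))
        remaining = n_de - len(de_idx)
        if remaining > 0:
            pool = np.array(sorted(set(range(n)) - de_idx))
            picked = _rng(config.seed, "de").choice(pool, size=remaining, replace=False)
            de_idx.update(int(i) for i in picked)

    values = np.empty((n, T * n_rep))
    for ti in range(T):
        t1 = ti + 1
        rin, rout = config.rho_in[ti], config.rho_out[ti]
        s_t = config.group_sd(t1)
        a_bg = rout / math.sqrt(rin) if rin > 0 else 0.0
        z = _rng(config.seed, "factor", ti).standard_normal(n_rep)
        cols = slice(ti * n_rep, (ti + 1) * n_rep)
        w_in, w_in_eps = math.sqrt(rin), math.sqrt(1.0 - rin)
        w_bg_eps = math.sqrt(1.0 - a_bg * a_bg)
        for gi in range(n):
            eps = _rng(config.seed, "noise", gi, ti).standard_normal(n_rep)
            if gi < k:
                x = config.base_mean + s_t * (w_in * z + w_in_eps * eps)
            elif gi < k + n_coupled:
                x = config.base_mean + config.baseline_sd * (a_bg * z + w_bg_eps * eps)
            else:
                x = config.base_mean + config.baseline_sd * eps
            if gi in de_idx and t1 >= config.t_star:
                x = x + config.de_shift
            values[gi, cols] = x

    series = ExpressionSeries(
        genes=genes,
        samples=samples,
        values=values,
        timepoint_of=timepoint_of,
        replicate_of=replicate_of,
        timepoint_order=labels,
        scale=config.scale,
    )
    truth = GroundTruth(
        dnb_genes=set(genes[:k]),
        t_star=labels[config.t_star - 1],
        t_star_index=config.t_star,
        de_genes={genes[i] for i in sorted(de_idx)},
        config=config,
    )
    return series, truth


def expected_ci(config: SimulationConfig, t: int, pcc_out_floor: float = 1e-6) -> float:
    """Closed-form large-replicate limit of the planted group's CI at timepoint ``t``.

    ``sqrt(dnb_size) * rho_in(t) / max(coupled_fraction * rho_out(t), floor)
    * group_sd(t)``: the generator realizes the group<->background
    correlation as exactly ``rho_out(t)`` for the coupled background genes
    and 0 for the rest, so in the large-replicate limit PCC_out averages to
    ``coupled_fraction * rho_out(t)``. With a fully coupled background the
    expression reduces to ``sqrt(k) * rho_in / rho_out * s(t)``.
    """
    config.validate()
    if not 1 <= t <= config.n_timepoints:
        raise ValueError(f"timepoint index {t} out of range")
    rin = config.rho_in[t - 1]
    n_bg = config.n_genes - config.dnb_size
    realized_frac = int(round(config.coupled_fraction * n_bg)) / n_bg
    rout = max(realized_frac * config.rho_out[t - 1], pcc_out_floor)
    return math.sqrt(config.dnb_size) * (rin / rout) * config.group_sd(t)
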