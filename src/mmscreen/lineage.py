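"""Mother-machine lineage simulator.

Emulates the measurement stream of a microfluidic mother machine: thousands
of dead-end trenches, each retaining its oldest ("mother") cell, imaged at a
fixed cadence (default every 10 min for 10 h).  Single cells elongate
exponentially, divide under adder control (a constant length increment is
added between birth and division, with lognormal increment noise), and place
the septum near midcell with Gaussian noise.  After CRISPRi induction
(default at 2 h) every phenotype parameter relaxes exponentially from its
baseline toward a knockdown target, with depth and speed graded by the
guide's mismatch count.

Output is a tidy per-frame table (one row per trench per frame) shared with
the phenotyping statistics module, plus a ground-truth table of effective
targets for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "StrainEffect",
    "BASELINE",
    "knockdown_strength",
    "make_strain_effects",
    "make_control_strains",
    "simulate_experiment",
]

#: Default unperturbed physiology: growth rate (doublings/h), width (um),
#: adder increment (um), septum-placement SD (fraction of length), reporter
#: intensity (a.u.).
BASELINE: dict[str, float] = {
    "growth_rate": 1.5,
    "width": 1.0,
    "added_length": 3.0,
    "septum_sd": 0.04,
    "intensity": 1000.0,
}


@dataclass
class SimConfig:
    """Acquisition schedule and layout for one simulated experiment."""

    frame_interval_min: float = 10.0
    duration_h: float = 10.0
    induction_time_h: float = 2.0
    n_trenches_per_sgrna: int = 20
    trenches_per_fov: int = 50
    division_cv: float = 0.10       # CV of the adder increment per cycle
    measurement_cv: float = 0.03    # multiplicative noise on L, W, I
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.induction_time_h < self.duration_h:
            raise ValueError("induction must precede the end of the experiment")
        if self.frame_interval_min <= 0 or self.n_trenches_per_sgrna < 1:
            raise ValueError("positive frame interval and trench counts required")

    @property
    def frame_times_min(self) -> np.ndarray:
        return np.arange(0.0, self.duration_h * 60.0, self.frame_interval_min)


def knockdown_strength(n_mismatches: int, midpoint: float = 5.0, scale: float = 1.5) -> float:
    """Logistic map from guide complementarity to repression strength in [0, 1].

    Strength rises with (10 - n_mismatches): the perfect-match guide is the
    strongest, ten mismatches the weakest.
    """
    x = 10 - n_mismatches
    return 1.0 / (1.0 + math.exp(-(x - midpoint) / scale))


@dataclass
class StrainEffect:
    """Per-sgRNA knockdown response.

    ``targets`` are the full-knockdown endpoints of each parameter; the
    effective target actually approached is baseline + strength * (target -
    baseline), and the relaxation timescale is ``response_h / strength`` so
    stronger guides act deeper *and* faster.  ``strength == 0`` leaves the
    strain at baseline (a control).
    """

    sgrna_id: str
    gene: str = "control"
    n_mismatches: int = 10
    strength: float = 0.0
    baseline: dict[str, float] = field(default_factory=lambda: dict(BASELINE))
    targets: dict[str, float] = field(default_factory=dict)
    response_h: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")
        # growth rate may be 0 (arrest) and septum noise may be 0 (perfect midcell)
        for key, value in self.baseline.items():
            if key not in ("growth_rate", "septum_sd") and value <= 0:
                raise ValueError(f"baseline {key} must be positive")
            if value < 0:
                raise ValueError(f"baseline {key} must be non-negative")
        for key in self.targets:
            if key not in self.baseline:
                raise ValueError(f"unknown target parameter {key!r}")
        if self.targets.get("growth_rate", 0.0) < 0.0:
            raise ValueError("growth-rate target below zero is not meaningful")

    def effective_target(self, param: str) -> float:
        base = self.baseline[param]
        full = self.targets.get(param, base)
        return base + self.strength * (full - base)

    def value_at(self, param: str, t_h: float, induction_h: float) -> float:
        """Parameter value at absolute time ``t_h`` (exponential relaxation)."""
        base = self.baseline[param]
        if t_h <= induction_h or self.strength == 0.0 or param not in self.targets:
            return base
        tau = self.response_h / self.strength
        eff = self.effective_target(param)
        return eff + (base - eff) * math.exp(-(t_h - induction_h) / tau)


def make_strain_effects(
    genes: dict[str, dict[str, float]],
    n_mismatch_levels: list[int] | None = None,
    response_h: float = 1.0,
) -> list[StrainEffect]:
    """Build a mismatch series of strains for each gene.

    ``genes`` maps gene name -> full-knockdown targets (subset of BASELINE
    keys).  One strain is created per (gene, mismatch count).
    """
    if n_mismatch_levels is None:
        n_mismatch_levels = list(range(11))
    strains = []
    for gene, targets in genes.items():
        for mm in n_mismatch_levels:
            strains.append(
                StrainEffect(
                    sgrna_id=f"{gene}_mm{mm}",
                    gene=gene,
                    n_mismatches=mm,
                    strength=knockdown_strength(mm),
                    targets=dict(targets),
                    response_h=response_h,
                )
            )
    return strains


def make_control_strains(n: int) -> list[StrainEffect]:
    """Strains whose targets equal their baselines (zero knockdown strength)."""
    if n < 1:
        raise ValueError("need at least one control strain")
    return [
        StrainEffect(sgrna_id=f"control_{i}", gene="control", strength=0.0)
        for i in range(n)
    ]


def _simulate_trench(
    strain: StrainEffect,
    cfg: SimConfig,
    rng: np.random.Generator,
    trench_id: int,
    fov_id: int,
) -> list[dict]:
    """Continuous-time growth/division of one mother cell, sampled on the frame grid.

    Within a frame interval the growth rate is held at its value at the
    interval start; division-threshold crossings are solved exactly so that
    at zero noise interdivision times are analytic.
    """
    dt_h = cfg.frame_interval_min / 60.0
    induction = cfg.induction_time_h
    delta0 = strain.baseline["added_length"]
    length = delta0  # adder fixed point as initial birth length
    birth_length = length
    width = strain.baseline["width"]

    def draw_increment(t_h: float) -> float:
        delta = strain.value_at("added_length", t_h, induction)
        if cfg.division_cv > 0:
            delta *= max(1.0 + cfg.division_cv * rng.standard_normal(), 0.05)
        return delta

    increment = draw_increment(0.0)
    rows: list[dict] = []
    divided = False
    div_mother = div_daughter = div_time = np.nan
    for t_min in cfg.frame_times_min:
        t_h = t_min / 60.0
        intensity = strain.value_at("intensity", t_h, induction)
        noise = (
            1.0 + cfg.measurement_cv * rng.standard_normal(3)
            if cfg.measurement_cv > 0
            else np.ones(3)
        )
        # state AT the frame time; division flag covers the preceding interval
        rows.append(
            {
                "trench_id": trench_id,
                "fov_id": fov_id,
                "sgrna_id": strain.sgrna_id,
                "gene": strain.gene,
                "time_min": t_min,
                "length": length * noise[0],
                "width": width * noise[1],
                "intensity": intensity * noise[2],
                "division_flag": int(divided),
                "div_mother_length": div_mother,
                "div_daughter_length": div_daughter,
                "div_time_min": div_time,
            }
        )
        divided = False
        div_mother = div_daughter = div_time = np.nan

        # evolve through [t_h, t_h + dt_h): rates held at interval-start values,
        # division-threshold crossings solved exactly
        lam = strain.value_at("growth_rate", t_h, induction)
        sigma_s = strain.value_at("septum_sd", t_h, induction)
        target_w = strain.value_at("width", t_h, induction)
        width += (target_w - width) * min(dt_h / 0.5, 1.0)
        remaining = dt_h
        while remaining > 0:
            threshold = birth_length + increment
            if length >= threshold:
                t_cross = 0.0
            elif lam > 0:
                t_cross = math.log2(threshold / length) / lam
            else:
                t_cross = math.inf
            if t_cross > remaining + 1e-12:
                length *= 2.0 ** (lam * remaining)
                break
            t_cross = min(t_cross, remaining)
            length = max(length, threshold)
            frac = 0.5 if sigma_s == 0 else float(
                np.clip(rng.normal(0.5, sigma_s), 0.2001, 0.7999)
            )
            div_mother = length
            div_daughter = length * frac
            div_time = (t_h + (dt_h - remaining) + t_cross) * 60.0
            length = div_daughter
            birth_length = length
            increment = draw_increment(t_h)
            divided = True
            remaining -= t_cross
    return rows


def simulate_experiment(
    cfg: SimConfig,
    strains: list[StrainEffect],
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate all trenches of all strains.

    Returns (cells, truth): ``cells`` has one row per trench per frame with
    measured length/width/intensity, division flags and the true (pre-noise)
    mother and daughter lengths at divisions; ``truth`` echoes each strain's
    baseline, effective targets and strength.
    """
    if not strains:
        raise ValueError("no strains supplied")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    all_rows: list[dict] = []
    trench_id = 0
    for strain in strains:
        for _ in range(cfg.n_trenches_per_sgrna):
            fov_id = trench_id // cfg.trenches_per_fov
            all_rows.extend(_simulate_trench(strain, cfg, rng, trench_id, fov_id))
            trench_id += 1
    cells = pd.DataFrame(all_rows)

    truth_rows = []
    for s in strains:
        row = {
            "sgrna_id": s.sgrna_id,
            "gene": s.gene,
            "n_mismatches": s.n_mismatches,
            "strength": s.strength,
            "response_h": s.response_h,
        }
        for p in BASELINE:
            row[f"baseline_{p}"] = s.baseline[p]
            row[f"target_{p}"] = s.effective_target(p)
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    return cells, truth
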