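"""Synthetic longitudinal EAE cohorts with known ground truth.

The generator emulates a six-phase relapsing-remitting disease course
(baseline, pre-onset, onset, peak, remission, relapse) in which regional
stiffness follows per-region multiplicative trajectories — cortex-dominant
transient softening by default — and each animal carries a disability score
drawn around phase-level means on the 0-5 ascending-paralysis scale.

Generative model per (subject i, phase t, region r):

    SWS_itr = alpha_r * factor_r(t) + b_i + beta * score_it + eps_itr

with b_i ~ N(0, tau^2) a subject random intercept and eps ~ N(0, sigma^2).
The default beta is 0, so phase means are fixed by the trajectory factors
alone; score-coupled cohorts (beta != 0) are used to study the mixed model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .params import ParamMap
from .phantom import (MaterialProps, Phantom, WaveSimConfig,
                      simulate_multifrequency, MOUSE_FREQUENCIES)
from .regions import AtlasLabels, mouse_atlas

EAE_PHASES = ("baseline", "pre-onset", "onset", "peak", "remission", "relapse")

#: default phase-level disability-score means on the 0-5 EAE scale
DEFAULT_SCORE_MEANS = (0.0, 0.0, 1.5, 3.0, 0.5, 2.5)

#: default cortical trajectory: 25 % softening at peak, partial remission
DEFAULT_CORTEX_FACTORS = (1.00, 0.95, 0.85, 0.75, 0.92, 0.80)

#: milder deep-tissue softening (peak factor 0.90)
DEFAULT_DEEP_FACTORS = (1.00, 0.98, 0.95, 0.90, 0.97, 0.93)


@dataclass
class ScoreModel:
    """Coupling of stiffness to the disability score."""

    alpha: float = 2.0          # baseline SWS, m/s (single-region studies)
    beta: float = 0.0           # m/s per score unit
    random_intercept_sd: float = 0.05  # tau, m/s
    residual_sd: float = 0.05   # sigma, m/s


@dataclass
class CohortSpec:
    """Design of a synthetic longitudinal cohort."""

    n_subjects: int = 10
    timepoints: Tuple[str, ...] = EAE_PHASES
    region_trajectories: Optional[Dict[str, Sequence[float]]] = None
    region_baseline_sws: Optional[Dict[str, float]] = None
    score_model: ScoreModel = field(default_factory=ScoreModel)
    score_means: Sequence[float] = DEFAULT_SCORE_MEANS
    score_sd: float = 0.5
    voxel_noise_sd: float = 0.05  # m/s, independent per voxel
    mode: str = "map-level"       # or "wave-level"
    seed: Optional[int] = None

    def __post_init__(self):
        if "baseline" not in self.timepoints:
            raise ValueError("cohort must include a baseline phase")
        order = [p for p in EAE_PHASES if p in self.timepoints]
        if tuple(self.timepoints) != tuple(order):
            raise ValueError("timepoints must follow the EAE phase order")
        if self.mode not in ("map-level", "wave-level"):
            raise ValueError("mode must be 'map-level' or 'wave-level'")
        if self.region_trajectories is None:
            self.region_trajectories = {
                "cortex": DEFAULT_CORTEX_FACTORS,
                "deep": DEFAULT_DEEP_FACTORS,
            }
        for name, fac in self.region_trajectories.items():
            fac = tuple(float(x) for x in fac)
            if len(fac) != len(EAE_PHASES):
                raise ValueError(f"trajectory for {name!r} must give one factor "
                                 "per EAE phase")
            if any(f <= 0 for f in fac):
                raise ValueError("trajectory factors must be positive")
            if fac[0] != 1.0:
                raise ValueError("the baseline factor must equal 1")
            self.region_trajectories[name] = fac
        if self.region_baseline_sws is None:
            self.region_baseline_sws = {"cortex": 2.0, "deep": 2.1}
        if len(self.score_means) != len(EAE_PHASES):
            raise ValueError("need one score mean per EAE phase")

    def factor(self, region: str, phase: str) -> float:
        return self.region_trajectories[region][EAE_PHASES.index(phase)]


@dataclass
class SyntheticCohort:
    """Maps (and optionally wave fields) per (subject, phase) plus scores."""

    spec: CohortSpec
    atlas: AtlasLabels
    maps: Dict[Tuple[int, str], ParamMap]
    scores: pd.DataFrame  # columns: subject, timepoint, score
    region_values: pd.DataFrame  # subject, timepoint, region, value (truth + noise)
    wavefields: Optional[Dict[Tuple[int, str], list]] = None
    random_intercepts: Optional[np.ndarray] = None

    def maps_at(self, phase: str) -> List[ParamMap]:
        return [self.maps[(i, phase)] for i in range(self.spec.n_subjects)]


def _region_label_groups(atlas: AtlasLabels) -> Dict[str, np.ndarray]:
    """Voxel masks for the two modelled compartments."""
    cortex = atlas.mask_of("cortex")
    deep = atlas.mask_of("deep gray matter")
    return {"cortex": cortex, "deep": deep}


def simulate_cohort(spec: CohortSpec,
                    atlas: Optional[AtlasLabels] = None) -> SyntheticCohort:
    """Generate a reproducible synthetic cohort from its spec.

    Map-level mode paints per-(subject, phase) SWS maps onto the atlas;
    wave-level mode additionally materialises multifrequency wave fields
    from a matching two-compartment phantom so the full inversion chain can
    be exercised.
    """
    rng = np.random.default_rng(spec.seed)
    if atlas is None:
        atlas = mouse_atlas()
    groups = _region_label_groups(atlas)
    sm = spec.score_model
    b = rng.normal(0.0, sm.random_intercept_sd, spec.n_subjects)

    maps: Dict[Tuple[int, str], ParamMap] = {}
    waves: Dict[Tuple[int, str], list] = {}
    score_rows = []
    value_rows = []
    brain = atlas.mask_of("whole brain")
    for i in range(spec.n_subjects):
        for phase in spec.timepoints:
            mean_score = spec.score_means[EAE_PHASES.index(phase)]
            if mean_score == 0.0:
                score = 0.0
            else:
                score = float(np.clip(
                    np.round(rng.normal(mean_score, spec.score_sd) * 2) / 2,
                    0.0, 5.0))
            score_rows.append({"subject": i, "timepoint": phase, "score": score})

            values = np.full(atlas.labels.shape, np.nan)
            region_sws = {}
            for name, gmask in groups.items():
                alpha = spec.region_baseline_sws[name]
                sws = (alpha * spec.factor(name, phase) + b[i]
                       + sm.beta * score + rng.normal(0.0, sm.residual_sd))
                region_sws[name] = sws
                values[gmask] = sws
                value_rows.append({"subject": i, "timepoint": phase,
                                   "region": name, "value": sws})
            if spec.voxel_noise_sd > 0:
                values = values + rng.normal(0.0, spec.voxel_noise_sd,
                                             values.shape)
            mask = brain & np.isfinite(values)
            maps[(i, phase)] = ParamMap(np.where(mask, values, np.nan), "m/s",
                                        atlas.spacing, mask=mask)
            if spec.mode == "wave-level":
                phantom = _cohort_phantom(atlas, region_sws)
                cfg = WaveSimConfig(
                    frequencies=MOUSE_FREQUENCIES,
                    directions=[(np.cos(a), np.sin(a)) for a in
                                np.deg2rad((10.0, 100.0, 205.0, 295.0))],
                    snr=None,
                    seed=None,
                )
                waves[(i, phase)] = simulate_multifrequency(phantom, cfg)

    return SyntheticCohort(
        spec=spec, atlas=atlas, maps=maps,
        scores=pd.DataFrame(score_rows),
        region_values=pd.DataFrame(value_rows),
        wavefields=waves if spec.mode == "wave-level" else None,
        random_intercepts=b,
    )


def _cohort_phantom(atlas: AtlasLabels, region_sws: Dict[str, float]) -> Phantom:
    """Two-compartment phantom matching the atlas cortex/deep split."""
    from .phantom import cortex_shell_phantom

    cortex = MaterialProps.from_sws(max(region_sws["cortex"], 0.2))
    deep = MaterialProps.from_sws(max(region_sws["deep"], 0.2))
    return cortex_shell_phantom(cortex, deep,
                                grid_shape=atlas.labels.shape,
                                voxel_spacing=atlas.spacing)


def simulate_score_observations(n_subjects: int, alpha: float, beta: float,
                                random_intercept_sd: float, residual_sd: float,
                                phases: Sequence[str] = EAE_PHASES,
                                score_means: Sequence[float] = DEFAULT_SCORE_MEANS,
                                score_sd: float = 0.5,
                                seed: Optional[int] = None) -> pd.DataFrame:
    """Tabular score-coupled observations for mixed-model studies.

    value_it = alpha + beta * score_it + b_i + eps_it, returned as a tidy
    (subject, timepoint, score, value) frame; the trajectory is carried
    entirely by the score coupling, so the mixed model's slope is exactly
    ``beta`` by construction.
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, random_intercept_sd, n_subjects)
    rows = []
    for i in range(n_subjects):
        for phase in phases:
            mu = score_means[EAE_PHASES.index(phase)]
            score = float(np.clip(np.round(rng.normal(mu, score_sd) * 2) / 2,
                                  0.0, 5.0)) if mu > 0 else 0.0
            value = alpha + beta * score + b[i] + rng.normal(0.0, residual_sd)
            rows.append({"subject": i, "timepoint": phase,
                         "score": score, "value": value})
    return pd.DataFrame(rows)
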