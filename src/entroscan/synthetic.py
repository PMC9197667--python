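"""Synthetic two-group cohorts with planted, scale-localized complexity
differences.

Each regional series is a stationary AR(1) process

    x_t = phi * x_{t-1} + eps_t,   eps_t ~ N(0, noise_sd^2)

with phi = phi_base everywhere except the planted regions of group 0
("poor"), where phi = phi_base + delta_phi: a larger autoregressive
coefficient makes the series more regular and hence lowers its sample
entropy, emulating the complexity-loss direction (poorer cognition, lower
BOLD complexity).  A burn-in stretch is generated and discarded so
initial-condition transients do not bias entropy estimates.

The default configuration emulates the study conditions this package is
exercised under: two groups of 30 subjects, 90 regions (AAL-90 labels) by
175 time points, and 9 planted regions — by default the nine AAL regions
that make up the biomarker set the optimization stage is meant to recover
(CAL.R, SFGmed.L, PCG.L, ITG.L, STG.R, CUN.R, PUT.R, HIP.R, TPOmid.R).

AR(1) was chosen over fractional Gaussian noise as the complexity knob: one
parameter, closed-form lag-1 autocorrelation (= phi) for cheap validation,
and a monotone effect on entropy.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .io import StudyDataset, SubjectRecord, write_cohort

__all__ = ["AAL90_LABELS", "SynthConfig", "generate_cohort"]

# AAL-90 region abbreviations in atlas order (odd indices left, even right).
_AAL_STEMS = [
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "PCG", "HIP", "PHG", "AMYG", "CAL", "CUN", "LING", "SOG",
    "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG", "PCUN", "PCL",
    "CAU", "PUT", "PAL", "THA", "HES", "STG", "TPOsup", "MTG", "TPOmid",
    "ITG",
]
AAL90_LABELS: tuple[str, ...] = tuple(
    f"{stem}.{side}" for stem in _AAL_STEMS for side in ("L", "R")
)

#: The nine biomarker regions (0-based indices into AAL90_LABELS):
#: CAL.R, SFGmed.L, PCG.L, ITG.L, STG.R, CUN.R, PUT.R, HIP.R, TPOmid.R
BIOMARKER_REGION_INDICES: tuple[int, ...] = (43, 22, 34, 88, 81, 45, 73, 37, 87)


@dataclass
class SynthConfig:
    """Configuration of a synthetic cohort.

    ``planted_regions`` may be None, in which case the nine biomarker AAL
    indices are planted when n_regions == 90, otherwise 9 (or fewer) evenly
    spaced regions.
    """

    n_per_group: tuple[int, int] = (30, 30)
    n_regions: int = 90
    n_timepoints: int = 175
    planted_regions: tuple[int, ...] | None = None
    phi_base: float = 0.2
    delta_phi: float = 0.5
    noise_sd: float = 1.0
    burn_in: int = 500
    seed: int = 17

    def __post_init__(self) -> None:
        if abs(self.phi_base) >= 1 or abs(self.phi_base + self.delta_phi) >= 1:
            raise ValueError(
                f"non-stationary AR(1): need |phi| < 1, got phi_base = {self.phi_base}, "
                f"phi_base + delta_phi = {self.phi_base + self.delta_phi}"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if min(self.n_per_group) < 1 or self.n_regions < 1 or self.n_timepoints < 10:
            raise ValueError("cohort dimensions too small")
        planted = self.resolved_planted()
        if any(i < 0 or i >= self.n_regions for i in planted):
            raise ValueError(
                f"planted regions {planted} outside [0, {self.n_regions})"
            )

    def resolved_planted(self) -> tuple[int, ...]:
        if self.planted_regions is not None:
            return tuple(int(i) for i in self.planted_regions)
        if self.n_regions >= 90:
            return BIOMARKER_REGION_INDICES
        k = min(9, self.n_regions)
        return tuple(int(i) for i in np.linspace(0, self.n_regions - 1, k).round())

    def region_labels(self) -> list[str]:
        if self.n_regions == 90:
            return list(AAL90_LABELS)
        return [f"ROI_{i + 1:03d}" for i in range(self.n_regions)]


def _ar1(phi: float, eps: np.ndarray) -> np.ndarray:
    """AR(1) filter along the last axis, zero initial state."""
    return lfilter([1.0], [1.0, -phi], eps, axis=-1)


def generate_cohort(
    config: SynthConfig, out_dir: str | os.PathLike | None = None
) -> StudyDataset:
    """Generate a two-group cohort; optionally write manifest + matrices.

    Deterministic (byte-identical files) for a fixed config.  Group 0
    subjects come first (ids poor_NN), then group 1 (excellent_NN).
    """
    n0, n1 = config.n_per_group
    n_subj = n0 + n1
    total_len = config.burn_in + config.n_timepoints
    planted = set(config.resolved_planted())
    rng = np.random.default_rng(config.seed)
    eps = rng.standard_normal((n_subj, config.n_regions, total_len)) * config.noise_sd

    x = _ar1(config.phi_base, eps)
    if planted and config.delta_phi != 0:
        p_idx = sorted(planted)
        x[:n0, p_idx, :] = _ar1(config.phi_base + config.delta_phi, eps[:n0, p_idx, :])
    x = x[:, :, config.burn_in :]

    subjects = [
        SubjectRecord(
            subject_id=(f"poor_{i + 1:02d}" if i < n0 else f"excellent_{i - n0 + 1:02d}"),
            group=0 if i < n0 else 1,
            matrix=x[i],
        )
        for i in range(n_subj)
    ]
    dataset = StudyDataset(
        subjects=subjects,
        region_labels=config.region_labels(),
        n_timepoints=config.n_timepoints,
    )
    if out_dir is not None:
        write_cohort(dataset, out_dir)
    return dataset
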