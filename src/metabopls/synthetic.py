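"""Synthetic two-group, three-block metabolite cohorts with known ground truth.

The generator emulates the design of a targeted NMR metabolomics case/control
study: two diagnostic groups (default 18 COPD vs 28 OSAS) profiled in three
biofluid blocks (default 16 EBC, 31 serum and 27 urine metabolites).
Concentrations are log-normal — metabolite levels are positive and
right-skewed — with within-block equicorrelation induced by one shared latent
factor per biofluid.  Discriminative metabolites are planted as group shifts
on the log scale, expressed in pooled-SD units, so downstream selection
procedures can be scored against an exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .table import ConfigurationError, MetaboliteTable, SpectrumSet

__all__ = [
    "SyntheticSpec",
    "generate_cohort",
    "generate_spectra",
    "planted_truth",
    "DEFAULT_BLOCK_SIZES",
]

DEFAULT_BLOCK_SIZES = {"ebc": 16, "serum": 31, "urine": 27}


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    ``planted`` maps block-qualified variable names (e.g. ``"serum__v3"``) to
    standardized effect sizes: the second group's log-concentration is shifted
    by ``effect * noise_sd`` for that variable.  ``correlation`` is the
    within-block equicorrelation of log-concentrations; ``noise_sd`` their
    common log-scale standard deviation.  ``dilution_range`` only affects
    spectrum fixtures, not the concentration table.
    """

    n_group_a: int = 18
    n_group_b: int = 28
    group_a_label: str = "COPD"
    group_b_label: str = "OSAS"
    block_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BLOCK_SIZES)
    )
    planted: dict[str, float] = field(default_factory=dict)
    correlation: float = 0.3
    noise_sd: float = 0.5
    dilution_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ConfigurationError("each group needs at least 2 samples")
        if any(k < 2 for k in self.block_sizes.values()):
            raise ConfigurationError("each block needs at least 2 variables")
        if not 0.0 <= self.correlation < 1.0:
            raise ConfigurationError("correlation must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not all(math.isfinite(e) for e in self.planted.values()):
            raise ConfigurationError("planted effect sizes must be finite")
        layout = set(self.variable_names())
        unknown = sorted(set(self.planted) - layout)
        if unknown:
            raise ConfigurationError(
                f"planted variables not in block layout: {unknown}"
            )

    def variable_names(self) -> list[str]:
        return [
            f"{block}__v{j + 1}"
            for block, size in self.block_sizes.items()
            for j in range(size)
        ]

    @property
    def n_samples(self) -> int:
        return self.n_group_a + self.n_group_b

    @property
    def n_variables(self) -> int:
        return sum(self.block_sizes.values())


def planted_truth(spec: SyntheticSpec) -> set[str]:
    """The names of the variables carrying a planted group difference."""
    return set(spec.planted)


def generate_cohort(spec: SyntheticSpec) -> MetaboliteTable:
    """Draw one cohort table from ``spec``; bitwise deterministic given the seed.

    Log-concentration of variable j in sample i:

        z_ij = mu_j + noise_sd * (sqrt(rho) g_i(block) + sqrt(1-rho) e_ij)
               + [i in group B] * effect_j * noise_sd

    with g a per-sample, per-block latent factor and e iid standard normal, so
    every variable has log-scale SD ``noise_sd`` and within-block pairwise
    correlation ``rho``.  Concentrations are exp(z).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    is_b = np.zeros(n, dtype=bool)
    is_b[spec.n_group_a :] = True

    cols: list[np.ndarray] = []
    names: list[str] = []
    rho = spec.correlation
    for block, size in spec.block_sizes.items():
        mu = rng.uniform(np.log(0.1), np.log(10.0), size=size)
        latent = rng.standard_normal(n)
        eps = rng.standard_normal((n, size))
        z = mu[None, :] + spec.noise_sd * (
            math.sqrt(rho) * latent[:, None] + math.sqrt(1.0 - rho) * eps
        )
        for j in range(size):
            name = f"{block}__v{j + 1}"
            effect = spec.planted.get(name, 0.0)
            if effect:
                z[is_b, j] += effect * spec.noise_sd
            names.append(name)
        cols.append(np.exp(z))

    values = np.concatenate(cols, axis=1)
    labels = np.where(is_b, spec.group_b_label, spec.group_a_label).astype(object)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    return MetaboliteTable(sample_ids, labels, values, names)


def generate_spectra(
    n: int,
    points: int,
    dilution_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
    noise_sd: float = 0.0,
    n_peaks: int = 12,
    ppm_max: float = 10.0,
    ppm_min: float = 0.2,
) -> SpectrumSet:
    """Template-times-dilution spectrum fixtures for the PQN/binning stage.

    A common non-negative template (a sum of Gaussian peaks on a strictly
    decreasing ppm grid plus a small baseline) is scaled per sample by a
    dilution factor drawn uniformly from ``dilution_range`` and, optionally,
    perturbed by multiplicative log-normal point noise of log-SD ``noise_sd``.
    True dilutions are recorded so normalization can be scored exactly.
    """
    if n < 2:
        raise ValueError("need at least 2 spectra")
    if points < 10:
        raise ValueError("need at least 10 points per spectrum")
    lo, hi = float(dilution_range[0]), float(dilution_range[1])
    if lo <= 0 or hi < lo:
        raise ValueError("dilution range must satisfy 0 < lo <= hi")

    rng = np.random.default_rng(seed)
    ppm = np.linspace(ppm_max, ppm_min, points)
    centers = rng.uniform(ppm_min, ppm_max, size=n_peaks)
    widths = rng.uniform(0.02, 0.15, size=n_peaks)
    heights = rng.uniform(0.2, 1.0, size=n_peaks)
    template = np.full(points, 1e-3)
    for c, w, h in zip(centers, widths, heights):
        template += h * np.exp(-0.5 * ((ppm - c) / w) ** 2)

    dilutions = rng.uniform(lo, hi, size=n)
    intensities = dilutions[:, None] * template[None, :]
    if noise_sd > 0:
        intensities = intensities * np.exp(
            noise_sd * rng.standard_normal((n, points))
        )
    return SpectrumSet(ppm=ppm, intensities=intensities, true_dilutions=dilutions)
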