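"""Normalization, binning, autoscaling and multiblock fusion.

Probabilistic quotient normalization (PQN) corrects per-sample dilution:
after an initial total-integral normalization, each spectrum is divided by
the median of its pointwise quotients against a reference spectrum (median
or mean of the set).  Equal-width binning integrates spectra over contiguous
ppm windows.  Autoscaling centers every variable to mean 0 / SD 1 using
statistics estimated on the model set only, so test and bootstrap
out-of-bag samples are projected without information leakage.  Fusion is
low-level: blocks are concatenated column-wise and the fused matrix is
autoscaled as one.
"""

from __future__ import annotations

import numpy as np

from .table import MetaboliteTable, ScalingParams, SpectrumSet

__all__ = [
    "pqn_normalize",
    "bin_spectrum",
    "bin_spectra",
    "autoscale",
    "fit_scaling",
    "apply_scaling",
    "invert_scaling",
    "fuse_blocks",
    "read_spectra_csv",
    "write_spectra_csv",
]


# ---------------------------------------------------------------------------
# PQN
# ---------------------------------------------------------------------------

def pqn_normalize(
    spectra: SpectrumSet, reference: str = "median"
) -> tuple[SpectrumSet, np.ndarray]:
    """Probabilistic quotient normalization of a spectrum set.

    Each spectrum is first scaled to the median total integral of the set,
    the reference is the pointwise ``median`` (default) or ``mean`` of the
    integral-normalized spectra, and each spectrum is then divided by the
    median of its quotients against the reference (taken where the reference
    is positive).

    Returns the normalized set and the per-sample overall quotient factors f
    such that ``output = input / f``.
    """
    if reference not in ("median", "mean"):
        raise ValueError("reference must be 'median' or 'mean'")
    X = spectra.intensities
    if X.shape[0] < 2:
        raise ValueError("PQN needs at least 2 spectra")
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        bad = np.flatnonzero(totals <= 0).tolist()
        raise ValueError(f"all-zero spectra (quotients undefined): rows {bad}")

    integral_factors = totals / np.median(totals)
    Xn = X / integral_factors[:, None]

    ref = np.median(Xn, axis=0) if reference == "median" else Xn.mean(axis=0)
    mask = ref > 0
    if not mask.any():
        raise ValueError("reference spectrum has no positive entries")
    quotients = Xn[:, mask] / ref[None, mask]
    q_factors = np.median(quotients, axis=1)
    if np.any(q_factors <= 0):
        bad = np.flatnonzero(q_factors <= 0).tolist()
        raise ValueError(f"non-positive quotient factors for rows {bad}")

    out = Xn / q_factors[:, None]
    factors = integral_factors * q_factors
    return (
        SpectrumSet(
            ppm=spectra.ppm.copy(),
            intensities=out,
            true_dilutions=spectra.true_dilutions,
        ),
        factors,
    )


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def bin_spectrum(
    ppm: np.ndarray, intensity: np.ndarray, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width binning of one spectrum; bin value = sum of member points.

    Bins are anchored at the maximum ppm and laid out downward; the last,
    possibly partial, bin is kept, so the number of bins is
    ``ceil(range / bin_width)`` and the total integral is conserved exactly.

    Returns ``(bin_centers, bin_values)`` with centers in decreasing ppm order.
    """
    ppm = np.asarray(ppm, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if ppm.ndim != 1 or intensity.ndim != 1 or intensity.size != ppm.size:
        raise ValueError("intensity must be one spectrum aligned with the ppm axis")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    span = ppm.max() - ppm.min()
    if bin_width > span:
        raise ValueError("bin_width exceeds the ppm range of the axis")

    n_bins = int(np.ceil(span / bin_width))
    # nudge by 1e-9 bin widths so points sitting on an edge (up to float
    # error) land in the bin whose upper edge they are
    idx = np.floor((ppm.max() - ppm) / bin_width + 1e-9).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # point at the minimum falls in the last bin
    values = np.zeros(n_bins)
    np.add.at(values, idx, intensity)
    edges_hi = ppm.max() - bin_width * np.arange(n_bins)
    edges_lo = np.maximum(edges_hi - bin_width, ppm.min())
    centers = (edges_hi + edges_lo) / 2.0
    return centers, values


def bin_spectra(spectra: SpectrumSet, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Bin every spectrum of a set; returns (bin_centers, samples x bins matrix)."""
    centers, first = bin_spectrum(spectra.ppm, spectra.intensities[0], bin_width)
    out = np.empty((spectra.n_spectra, centers.size))
    out[0] = first
    for i in range(1, spectra.n_spectra):
        out[i] = bin_spectrum(spectra.ppm, spectra.intensities[i], bin_width)[1]
    return centers, out


def write_spectra_csv(spectra: SpectrumSet, path) -> None:
    """Samples x points matrix CSV whose header row is the ppm axis."""
    import pandas as pd

    pd.DataFrame(
        spectra.intensities, columns=[f"{v:.6f}" for v in spectra.ppm]
    ).to_csv(path, index=False)


def read_spectra_csv(path) -> SpectrumSet:
    """Read a matrix CSV written by :func:`write_spectra_csv`."""
    import pandas as pd

    df = pd.read_csv(path)
    ppm = np.array([float(c) for c in df.columns])
    return SpectrumSet(ppm=ppm, intensities=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Autoscaling
# ---------------------------------------------------------------------------

def fit_scaling(
    X: np.ndarray, variable_names: list[str], on_zero_variance: str = "error"
) -> ScalingParams:
    """Estimate per-variable mean and SD (ddof=1) on the given rows.

    ``on_zero_variance`` is ``"error"`` (default) or ``"unit"`` — the latter
    substitutes SD 1 for degenerate columns, used deep inside resampling loops
    where a duplicated-row fold could otherwise abort a long run.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    # relative threshold: a constant column's sd is ~1e-15 x its magnitude
    zero = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if zero.any():
        if on_zero_variance == "unit":
            sd = np.where(zero, 1.0, sd)
        else:
            bad = [variable_names[j] for j in np.flatnonzero(zero)]
            raise ValueError(f"zero-variance variables cannot be autoscaled: {bad}")
    return ScalingParams(list(variable_names), mean, sd)


def apply_scaling(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    return (np.asarray(X, dtype=float) - params.mean) / params.sd


def invert_scaling(Xs: np.ndarray, params: ScalingParams) -> np.ndarray:
    return np.asarray(Xs, dtype=float) * params.sd + params.mean


def autoscale(
    table: MetaboliteTable, params: ScalingParams | None = None
) -> tuple[MetaboliteTable, ScalingParams]:
    """Autoscale a table; fit on its rows, or apply previously fitted params.

    With ``params`` given (test-set projection) the variable sets must match.
    """
    if params is None:
        params = fit_scaling(table.values, table.variable_names)
    elif params.variable_names != table.variable_names:
        raise ValueError("scaling params do not match the table's variables")
    scaled = MetaboliteTable(
        sample_ids=list(table.sample_ids),
        group_labels=table.group_labels.copy(),
        values=apply_scaling(table.values, params),
        variable_names=list(table.variable_names),
        block_of_variable=dict(table.block_of_variable),
    )
    return scaled, params


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def fuse_blocks(tables: list[MetaboliteTable]) -> MetaboliteTable:
    """Column-wise concatenation of blocks, rows aligned by sample id.

    Every table must cover exactly the same samples (the study design keeps
    only individuals with all biofluids collected); sample order follows the
    first table.
    """
    if not tables:
        raise ValueError("no tables to fuse")
    first = tables[0]
    ref_ids = set(first.sample_ids)
    for t in tables[1:]:
        missing = sorted(ref_ids.symmetric_difference(t.sample_ids))
        if missing:
            raise ValueError(
                f"samples present in one block only (all biofluids required): {missing}"
            )
    aligned = [first] + [t.select_samples(first.sample_ids) for t in tables[1:]]
    for t in aligned[1:]:
        if not np.array_equal(t.group_labels, first.group_labels):
            raise ValueError("group labels disagree between blocks")
    names: list[str] = []
    block_map: dict[str, str] = {}
    for t in aligned:
        for v in t.variable_names:
            if v in block_map:
                raise ValueError(f"duplicate variable name across blocks: {v}")
            block_map[v] = t.block_of_variable[v]
        names.extend(t.variable_names)
    return MetaboliteTable(
        sample_ids=list(first.sample_ids),
        group_labels=first.group_labels.copy(),
        values=np.concatenate([t.values for t in aligned], axis=1),
        variable_names=names,
        block_of_variable=block_map,
    )
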