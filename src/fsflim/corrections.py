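"""Signal-correction chain: chained-bin decoding, dark subtraction, flat-fielding.

The pipeline order is fixed: decode chained bins (if acquired raw), subtract
the expected dark-count contribution, then flat-field the spectral detection
efficiency.  Dark counts are an additive rate and must come off before the
multiplicative efficiency correction — the two operations only commute when
the efficiency curve is flat.  Each correction records a tag in
``corrections_applied`` and refuses to run twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import CHAINED_BIT_DEPTH, FlimCube, SensorConfig, SpectralAxis, TimeAxis

__all__ = [
    "CorrectedCube",
    "DuplicateCorrectionError",
    "decode_chained",
    "subtract_dark",
    "flatfield_spectral",
]


class DuplicateCorrectionError(ValueError):
    """A correction was applied twice to the same cube."""


@dataclass
class CorrectedCube:
    """Real-valued cube after one or more corrections.

    ``values`` stays non-negative (negative intermediates are clipped to 0);
    ``corrections_applied`` is the ordered, duplicate-free list of tags.
    """

    values: np.ndarray
    spectral_axis: SpectralAxis
    time_axis: TimeAxis
    dwell_time: float
    corrections_applied: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    allow_negative: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.allow_negative and np.any(self.values < 0):
            raise ValueError("corrected values must be >= 0")
        if len(set(self.corrections_applied)) != len(self.corrections_applied):
            raise ValueError("duplicate correction tags")


def _as_corrected(cube: FlimCube | CorrectedCube) -> CorrectedCube:
    if isinstance(cube, CorrectedCube):
        return cube
    return CorrectedCube(
        values=cube.counts.astype(float),
        spectral_axis=cube.spectral_axis,
        time_axis=cube.time_axis,
        dwell_time=cube.dwell_time,
        corrections_applied=[],
        provenance=dict(cube.provenance),
    )


def decode_chained(raw: FlimCube) -> FlimCube:
    """Merge adjacent time-bin pairs (2j, 2j+1) into single bins.

    Doubles the per-bin dynamic range from the 10-bit counter bound to the
    20-bit chained bound; counts are conserved exactly.  The output bin j
    covers the union interval of its source pair, so the output axis has half
    the bins at twice the width.
    """
    if raw.chained:
        raise ValueError("cube is already chained")
    n = raw.time_axis.n_bins
    if n % 2 != 0:
        raise ValueError(f"chained decoding needs an even bin count, got {n}")
    merged = raw.counts.reshape(*raw.counts.shape[:3], n // 2, 2).sum(axis=-1)
    axis = TimeAxis(
        n_bins=n // 2,
        bin_width=2 * raw.time_axis.bin_width,
        t0_offset=raw.time_axis.t0_offset,
        laser_period=raw.time_axis.laser_period,
    )
    if merged.size and int(merged.max()) > 2**CHAINED_BIT_DEPTH - 1:
        raise ValueError("merged counts exceed the 20-bit chained capacity")
    return FlimCube(
        counts=merged.astype(np.uint32),
        spectral_axis=raw.spectral_axis,
        time_axis=axis,
        chained=True,
        dwell_time=raw.dwell_time,
        provenance={**raw.provenance, "chained_decoded": "true"},
    )


def subtract_dark(
    cube: FlimCube | CorrectedCube,
    sensor: SensorConfig,
    dwell: float | None = None,
    *,
    clip: bool = True,
) -> CorrectedCube:
    """Subtract the expected dark-count contribution from every bin.

    Dark counts are uncorrelated with the laser, so the expectation
    ``dark_rate(k) * dwell_s / n_bins`` is uniform over time bins; results are
    clipped at 0 (counts are Poisson, so individual bins can undershoot).
    ``clip=False`` keeps the signed residuals — a diagnostic mode in which the
    subtraction is exactly mean-zero on dark-only data, useful for verifying
    the dark model (the zero-floor clipping otherwise adds a small positive
    bias of order ``0.4 * sqrt(rate)`` per bin).

    ``dwell`` (µs) defaults to the cube's own metadata and must match it when
    given.
    """
    corr = _as_corrected(cube)
    if "dark" in corr.corrections_applied:
        raise DuplicateCorrectionError("dark subtraction already applied")
    if dwell is None:
        dwell = corr.dwell_time
    elif not np.isclose(dwell, corr.dwell_time):
        raise ValueError(
            f"dwell {dwell} µs does not match cube metadata {corr.dwell_time} µs"
        )
    k = corr.spectral_axis.n_channels
    expected = sensor.dark_rate_at(k) * (dwell * 1e-6) / corr.time_axis.n_bins
    values = corr.values - expected[None, None, :, None]
    if clip:
        values = np.clip(values, 0.0, None)
    return CorrectedCube(
        values=values,
        spectral_axis=corr.spectral_axis,
        time_axis=corr.time_axis,
        dwell_time=corr.dwell_time,
        corrections_applied=[*corr.corrections_applied, "dark"],
        provenance=corr.provenance,
        allow_negative=not clip,
    )


def flatfield_spectral(
    cube: FlimCube | CorrectedCube, sensor: SensorConfig
) -> CorrectedCube:
    """Divide out the relative spectral detection efficiency ``pde(k)/pde_peak``.

    Channels with zero efficiency cannot be corrected by division; they are
    masked (set to 0) and listed under ``masked_channels`` in provenance.
    """
    corr = _as_corrected(cube)
    if "flatfield" in corr.corrections_applied:
        raise DuplicateCorrectionError("spectral flat-field already applied")
    pde_rel = sensor.pde_at(corr.spectral_axis.n_channels) / sensor.pde_peak
    dead = pde_rel <= 0
    safe = np.where(dead, 1.0, pde_rel)
    values = corr.values / safe[None, None, :, None]
    values[:, :, dead, :] = 0.0
    prov = dict(corr.provenance)
    if dead.any():
        prov["masked_channels"] = ",".join(map(str, np.flatnonzero(dead)))
    return CorrectedCube(
        values=values,
        spectral_axis=corr.spectral_axis,
        time_axis=corr.time_axis,
        dwell_time=corr.dwell_time,
        corrections_applied=[*corr.corrections_applied, "flatfield"],
        provenance=prov,
    )
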