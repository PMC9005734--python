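"""Speckle-variance angiography from repeated B-scan series.

Flowing blood decorrelates the OCT speckle pattern between sequentially
acquired same-position B-scans, while static tissue speckle is frozen;
the inter-frame intensity variance therefore lights up vessels.  The
variance is taken with the 1/M (population) normalization over the M
repeated frames:

    sv(z, x) = (1/M) Σ_t ( Ī(z, x) − I_t(z, x) )²
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .volume import BScanSeries, Volume

__all__ = ["speckle_variance", "assemble_angio_volume", "speckle_variance_volume"]


def speckle_variance(series: BScanSeries) -> np.ndarray:
    """Per-pixel inter-frame variance of a repeated B-scan series.

    Uses the population (divide-by-M) convention.  The result is
    invariant to adding a constant to a pixel's time series and scales
    quadratically with intensity scaling.

    Raises
    ------
    ValueError
        If the input contains NaN (the first offending (z, x, t) index
        is named).
    """
    frames = series.intensities
    nan_mask = np.isnan(frames)
    if nan_mask.any():
        first = tuple(int(i) for i in np.argwhere(nan_mask)[0])
        raise ValueError(f"NaN in B-scan series at (z, x, t) = {first}")
    # np.var uses ddof=0, i.e. the divide-by-M population variance
    return np.var(frames, axis=2)


def assemble_angio_volume(
    series_list: Sequence[BScanSeries], slice_spacing: float = 15.0
) -> Volume:
    """Stack per-position speckle-variance frames into a 3D angiographic
    volume ``(z, x, y)``, y ordered by acquisition.

    All series must share shape and spacing.  ``slice_spacing`` is the
    lateral step between B-scan positions in μm.
    """
    if not series_list:
        raise ValueError("empty series list")
    ref = series_list[0]
    for i, s in enumerate(series_list[1:], start=1):
        if s.intensities.shape != ref.intensities.shape:
            raise ValueError(
                f"series {i} shape {s.intensities.shape} does not match "
                f"series 0 shape {ref.intensities.shape}"
            )
        if (s.axial_spacing, s.lateral_spacing) != (
            ref.axial_spacing,
            ref.lateral_spacing,
        ):
            raise ValueError(f"series {i} spacing does not match series 0")
    sv = np.stack([speckle_variance(s) for s in series_list], axis=2)
    return Volume(
        data=sv,
        spacing=(ref.axial_spacing, ref.lateral_spacing, float(slice_spacing)),
        meta={"kind": "speckle_variance", "n_frames": ref.n_frames,
              "intensity_scale": "linear"},
    )


def speckle_variance_volume(stack) -> Volume:
    """Convenience: speckle-variance volume straight from a simulated
    :class:`~svoct.synthetic.BScanStack` (or any object with a 4D
    ``intensities`` array and ``spacing``)."""
    frames = np.asarray(stack.intensities)
    if frames.ndim != 4:
        raise ValueError(f"expected (z, x, y, frames), got shape {frames.shape}")
    if np.isnan(frames).any():
        first = tuple(int(i) for i in np.argwhere(np.isnan(frames))[0])
        raise ValueError(f"NaN in B-scan stack at (z, x, y, t) = {first}")
    sv = np.var(frames, axis=3)
    return Volume(
        data=sv,
        spacing=tuple(stack.spacing),
        meta={"kind": "speckle_variance", "n_frames": frames.shape[3],
              "intensity_scale": "linear"},
    )
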