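"""Bark critical-band psychoacoustics and tone-set construction.

The tone-perception stimuli are pure tones placed on the centres of integer
Bark critical bands, so that each tone falls inside a single auditory filter.
This module provides the continuous Hz <-> Bark conversion (Traunmueller 1990),
the canonical Zwicker table of critical-band centre frequencies, the vowel
formant table the tones were derived from, and the tone-set selection
strategies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "hz_to_bark",
    "bark_to_hz",
    "bark_band_center",
    "vowel_formant_table",
    "select_tone_set",
    "BARK_BAND_CENTERS_HZ",
]

# Zwicker's canonical critical-band centre frequencies (Hz), bands 1..24.
BARK_BAND_CENTERS_HZ: tuple[float, ...] = (
    50.0, 150.0, 250.0, 350.0, 450.0, 570.0, 700.0, 840.0, 1000.0, 1170.0,
    1370.0, 1600.0, 1850.0, 2150.0, 2500.0, 2900.0, 3400.0, 4000.0, 4800.0,
    5800.0, 7000.0, 8500.0, 10500.0, 13500.0,
)

# Mean formant frequencies (Hz) of the seven Italian vowels across the three
# recordings of each, with standard deviations, and the integer Bark band each
# vowel was assigned to when the pure-tone set was built.
_VOWEL_ROWS = [
    # vowel, F1 mean, F1 sd, F2 mean, F2 sd, bark band
    ("i", 305.0, 21.1, 2702.0, 5.75, 5),
    ("e", 303.0, 35.9, 1736.0, 30.7, 8),
    ("ɛ", 400.0, 27.1, 1428.0, 47.4, 11),
    ("a", 525.0, 28.9, 1139.0, 7.1, 13),
    ("ɔ", 455.0, 68.1, 836.0, 34.9, 14),
    ("o", 338.0, 23.4, 637.0, 71.6, 15),
    ("u", 278.0, 16.2, 604.0, 27.0, 16),
]


def hz_to_bark(f_hz):
    """Convert frequency in Hz to the continuous Bark scale.

    Uses the Traunmueller (1990) approximation

        z = 26.81 * f / (1960 + f) - 0.53

    which is strictly increasing in ``f``.

    Parameters
    ----------
    f_hz : float or array_like
        Frequency in Hz, must be > 0.

    Returns
    -------
    float or ndarray
        Critical-band rate in Bark.
    """
    f = np.asarray(f_hz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    z = 26.81 * f / (1960.0 + f) - 0.53
    return float(z) if np.isscalar(f_hz) else z


def bark_to_hz(z_bark):
    """Inverse of :func:`hz_to_bark` (algebraic inverse of the Traunmueller map)."""
    z = np.asarray(z_bark, dtype=float)
    if np.any(z >= 26.28):
        raise ValueError("Bark value outside the invertible range (z < 26.28)")
    f = 1960.0 * (z + 0.53) / (26.28 - z)
    if np.any(f <= 0):
        raise ValueError("Bark value maps to a non-positive frequency")
    return float(f) if np.isscalar(z_bark) else f


def bark_band_center(band: int) -> float:
    """Canonical centre frequency (Hz) of integer critical band 1..24."""
    band = int(band)
    if not 1 <= band <= 24:
        raise ValueError(f"Bark band must be in 1..24, got {band}")
    return BARK_BAND_CENTERS_HZ[band - 1]


def vowel_formant_table() -> pd.DataFrame:
    """Formant table of the seven Italian vowel stimuli.

    Columns: vowel, f1_hz, f1_sd, f2_hz, f2_sd, bark_band. One row per vowel,
    ordered by decreasing F2 (front to back vowels).
    """
    df = pd.DataFrame(
        _VOWEL_ROWS, columns=["vowel", "f1_hz", "f1_sd", "f2_hz", "f2_sd", "bark_band"]
    )
    if not (df["f2_hz"] > df["f1_hz"]).all():
        raise AssertionError("F2 must exceed F1 for every vowel")
    return df


def select_tone_set(
    formants: pd.DataFrame | None = None,
    n: int = 7,
    strategy: str = "published",
    freq_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Build the pure-tone stimulus set.

    Parameters
    ----------
    formants : DataFrame, optional
        Vowel formant table (default: :func:`vowel_formant_table`).
    n : int
        Number of tones (>= 2) for the ``"f1_bins"`` strategy.
    strategy : {"published", "f1_bins"}
        ``"published"`` returns the Bark bands recorded in the formant table
        directly.  ``"f1_bins"`` divides ``freq_range`` into ``n`` equally
        spaced values, rounds each to the nearest integer Bark band via the
        continuous conversion, and maps bands to their canonical centres,
        deduplicating while preserving order.
    freq_range : (low_hz, high_hz), required for ``"f1_bins"``
        Frequency range to bin.  Taken as an explicit parameter because the
        literal min/max of the mean-F1 column does not span the published
        band set; callers decide which acoustic range to bin.

    Returns
    -------
    DataFrame with columns ``bark_band`` and ``center_hz``, centres strictly
    increasing.
    """
    if formants is None:
        formants = vowel_formant_table()
    if strategy == "published":
        bands = sorted(int(b) for b in formants["bark_band"])
    elif strategy == "f1_bins":
        if n < 2:
            raise ValueError("need n >= 2 tones")
        if freq_range is None:
            raise ValueError("freq_range is required for strategy 'f1_bins'")
        lo, hi = map(float, freq_range)
        if not (0 < lo < hi):
            raise ValueError("degenerate frequency range")
        values = np.linspace(lo, hi, n)
        bands_raw = [int(np.round(hz_to_bark(v))) for v in values]
        bands_raw = [min(max(b, 1), 24) for b in bands_raw]
        bands, seen = [], set()
        for b in bands_raw:
            if b not in seen:
                bands.append(b)
                seen.add(b)
        if len(bands) < len(bands_raw):
            import warnings

            warnings.warn(
                f"{len(bands_raw) - len(bands)} duplicate Bark bands dropped "
                "after rounding",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    centers = [bark_band_center(b) for b in bands]
    out = pd.DataFrame({"bark_band": bands, "center_hz": centers})
    if not np.all(np.diff(out["center_hz"]) > 0):
        raise AssertionError("tone centres must be strictly increasing")
    return out
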