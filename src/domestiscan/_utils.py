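"""Shared numeric helpers: presentation rounding, seeds, windowed reductions."""
from __future__ import annotations

import hashlib
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__all__ = [
    "ratio_2dp",
    "percent_2dp",
    "round2_half_up",
    "derive_seed",
    "window_reduce",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round2_half_up(x) -> float:
    """Round to 2 decimals with ties away from zero (table presentation)."""
    return float(Decimal(x).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def ratio_2dp(numerator, denominator):
    """numerator/denominator rounded half-up to 2 decimals.

    Returns ``None`` when the denominator is zero (the caller prints an
    "undefined" marker rather than raising).  Integer inputs are divided
    exactly before rounding so printed-table ratios are reproduced without
    binary-float artefacts.
    """
    if denominator == 0:
        return None
    return float(
        (Decimal(numerator) / Decimal(denominator)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def percent_2dp(part, total):
    """100*part/total rounded half-up to 2 decimals; None if total == 0."""
    if total == 0:
        return None
    return float(
        (Decimal(100) * Decimal(part) / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def derive_seed(seed: int, label: str) -> int:
    """Stable per-stage seed below 2**31 derived from a top-level seed.

    Uses SHA-256 of ``"{seed}:{label}"`` so every stage gets an independent
    stream while the whole run remains reproducible from one integer.
    """
    digest = hashlib.sha256(f"{int(seed)}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def window_reduce(
    site_chrom: np.ndarray,
    site_pos0: np.ndarray,
    windows,
    values: dict[str, np.ndarray] | None = None,
):
    """Count sites and sum per-site values over half-open genomic windows.

    Parameters
    ----------
    site_chrom, site_pos0
        Per-site chromosome labels and 0-based positions, sorted by
        (chrom, pos).
    windows
        Sequence of ``(chrom, start, end)`` with 0-based half-open bounds.
    values
        Optional named per-site arrays to sum within each window.

    Returns
    -------
    counts : int array aligned with ``windows``
    sums : dict of float arrays aligned with ``windows``
    """
    values = values or {}
    n_win = len(windows)
    counts = np.zeros(n_win, dtype=np.int64)
    sums = {k: np.zeros(n_win, dtype=float) for k in values}

    # contiguous per-chromosome slices (input sorted by chrom, pos)
    site_chrom = np.asarray(site_chrom)
    site_pos0 = np.asarray(site_pos0)
    chrom_slices = {}
    if len(site_chrom):
        change = np.flatnonzero(site_chrom[1:] != site_chrom[:-1]) + 1
        bounds = np.concatenate(([0], change, [len(site_chrom)]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            chrom_slices[site_chrom[a]] = (a, b)

    win_chrom = np.asarray([w[0] for w in windows])
    win_start = np.asarray([w[1] for w in windows], dtype=np.int64)
    win_end = np.asarray([w[2] for w in windows], dtype=np.int64)

    for chrom in np.unique(win_chrom):
        sel = np.flatnonzero(win_chrom == chrom)
        if chrom not in chrom_slices:
            continue
        a, b = chrom_slices[chrom]
        pos = site_pos0[a:b]
        lo = np.searchsorted(pos, win_start[sel], side="left")
        hi = np.searchsorted(pos, win_end[sel], side="left")
        counts[sel] = hi - lo
        for k, v in values.items():
            cs = np.concatenate(([0.0], np.cumsum(v[a:b], dtype=float)))
            sums[k][sel] = cs[hi] - cs[lo]
    return counts, sums
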