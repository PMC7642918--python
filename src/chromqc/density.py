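"""Fixed-window feature densities along scaffolds (1 Mb windows by default).

Used for karyotype-style density panels: per-window covered base pairs for
interval tracks (genes, repeats) and per-window counts for point tracks
(e.g. consensus NLR loci). Windows tile each scaffold at a fixed width with
the last window truncated, so window widths sum exactly to the scaffold
length; interval features spanning a window boundary are apportioned by
overlap, conserving total covered bases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["windowed_density"]


def windowed_density(
    features,
    scaffold_lengths: dict[str, int],
    window: int = 1_000_000,
    point: bool = False,
) -> pd.DataFrame:
    """Tabulate per-window feature density over every scaffold.

    ``features`` is an iterable of ``(seqid, start, end)`` triples
    (0-based half-open) or objects with those attributes. Interval mode
    sums covered bp per window, apportioned by overlap; point mode counts
    features in the window containing their start. Features outside
    scaffold bounds are an error naming the feature.

    Returns a DataFrame with columns (seqid, window_start, window_end,
    value), one row per window for every scaffold — including empty ones.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")

    values: dict[str, np.ndarray] = {}
    bounds: dict[str, np.ndarray] = {}
    for seqid, length in scaffold_lengths.items():
        n_win = max(1, int(np.ceil(length / window)))
        values[seqid] = np.zeros(n_win, dtype=float)
        edges = np.minimum(np.arange(n_win + 1, dtype=np.int64) * window, length)
        bounds[seqid] = edges

    for feat in features:
        if hasattr(feat, "seqid"):
            seqid, start, end = feat.seqid, feat.start, feat.end
        else:
            seqid, start, end = feat[0], int(feat[1]), int(feat[2])
        if seqid not in values:
            raise ValidationError(f"feature on unknown scaffold: ({seqid}, {start}, {end})")
        length = scaffold_lengths[seqid]
        if start < 0 or end > length or end < start:
            raise ValidationError(
                f"feature out of bounds for {seqid} (length {length}): [{start}, {end})"
            )
        if point:
            values[seqid][min(start // window, len(values[seqid]) - 1)] += 1
            continue
        first = start // window
        last = max(first, (end - 1) // window) if end > start else first
        for w in range(first, last + 1):
            w_start, w_end = w * window, min((w + 1) * window, length)
            values[seqid][w] += max(0, min(end, w_end) - max(start, w_start))

    rows = []
    for seqid in scaffold_lengths:
        edges = bounds[seqid]
        for w, value in enumerate(values[seqid]):
            rows.append(
                {
                    "seqid": seqid,
                    "window_start": int(edges[w]),
                    "window_end": int(edges[w + 1]),
                    "value": float(value),
                }
            )
    return pd.DataFrame(rows, columns=["seqid", "window_start", "window_end", "value"])
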