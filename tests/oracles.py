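"""Independent brute-force reference implementations used by the tests.

These are deliberately plain-Python, loop-based scans kept separate from the
package's vectorized code paths, so agreement between the two is meaningful.
"""

from __future__ import annotations

import math
import statistics


def brute_turning_amplitudes(values) -> list[float]:
    """Signed amplitudes between consecutive alternating extrema.

    Plateaus are represented by their first value; the first and last
    samples count as extrema.
    """
    vals = [float(v) for v in values]
    comp = [vals[0]]
    for v in vals[1:]:
        if v != comp[-1]:
            comp.append(v)
    if len(comp) < 2:
        return []
    extrema = [comp[0]]
    for i in range(1, len(comp) - 1):
        if (comp[i] - comp[i - 1]) * (comp[i + 1] - comp[i]) < 0:
            extrema.append(comp[i])
    extrema.append(comp[-1])
    return [b - a for a, b in zip(extrema, extrema[1:])]


def brute_mage(values) -> float:
    """Pooled MAGE: mean |amplitude| over swings exceeding one sample SD."""
    vals = [float(v) for v in values]
    if len(vals) < 3:
        return math.nan
    sd = statistics.stdev(vals)
    qualifying = [abs(a) for a in brute_turning_amplitudes(vals) if abs(a) > sd]
    if not qualifying:
        return math.nan
    return sum(qualifying) / len(qualifying)


def brute_excursions(values, minutes, lower, upper):
    """Scan sample-by-sample for runs outside [lower, upper].

    Returns a list of dicts with kind, start/end minutes, extremum and the
    trapezoidal AUC of the excess beyond the crossed edge.
    """
    out = []
    run = []  # list of (minute, value)
    kind = None

    def flush():
        if not run:
            return
        edge = upper if kind == "peak" else lower
        auc = 0.0
        for (m0, v0), (m1, v1) in zip(run, run[1:]):
            auc += (abs(v0 - edge) + abs(v1 - edge)) / 2.0 * (m1 - m0)
        ext = max(v for _, v in run) if kind == "peak" else min(v for _, v in run)
        out.append(
            {
                "kind": kind,
                "start_min": run[0][0],
                "end_min": run[-1][0],
                "duration": run[-1][0] - run[0][0],
                "extremum": ext,
                "auc": auc,
            }
        )

    for m, v in zip(minutes, values):
        state = "peak" if v > upper else ("nadir" if v < lower else None)
        if state != kind:
            flush()
            run, kind = [], state
        if state is not None:
            run.append((float(m), float(v)))
    flush()
    out.sort(key=lambda e: e["start_min"])
    return out
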