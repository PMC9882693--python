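"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's code paths (and lifelines): the
product-limit curve is a hand loop, neighbor queries are exhaustive scans,
and the survival annotation recomputes the whole procedure from first
principles so the pipeline can be checked sample-for-sample.
"""

from __future__ import annotations

import math

import numpy as np


def km_hand(times, events) -> list[tuple[float, float]]:
    """Product-limit estimate by direct looping: [(event time, S)]."""
    pairs = sorted(zip(times, events))
    distinct = sorted({t for t, _ in pairs})
    s = 1.0
    curve = []
    for t in distinct:
        n_at_risk = sum(1 for ti, _ in pairs if ti >= t)
        deaths = sum(1 for ti, ei in pairs if ti == t and ei == 1)
        if deaths > 0:
            s *= 1.0 - deaths / n_at_risk
            curve.append((t, s))
    return curve


def km_median_hand(times, events):
    for t, s in km_hand(times, events):
        if s <= 0.5 + 1e-12:
            return t
    return None


def neighbors_brute(coords: dict[str, np.ndarray], query: str, radius: float,
                    eligible=None) -> list[tuple[str, float]]:
    out = []
    q = coords[query]
    for sid, c in coords.items():
        if sid == query:
            continue
        if eligible is not None and not eligible(sid):
            continue
        d = float(np.sqrt(((c - q) ** 2).sum()))
        if d <= radius:
            out.append((sid, d))
    return sorted(out, key=lambda t: (t[1], t[0]))


def knearest_brute(coords, query, k, pool=None):
    scored = []
    q = coords[query]
    for sid in (pool if pool is not None else coords):
        if sid == query:
            continue
        scored.append((sid, float(np.sqrt(((coords[sid] - q) ** 2).sum()))))
    return sorted(scored, key=lambda t: (t[1], t[0]))[:k]


def annotate_brute(coords, meta_table, records, radius=2.0, fraction=0.25,
                   min_neighbors=10, stratify=("subtype", "dataset")):
    """Full reimplementation of the neighbor-median survival annotation."""
    results = {}
    ids = list(coords)
    strata = {}
    for sid in ids:
        key = tuple(str(meta_table.loc[sid, f]) for f in stratify)
        strata.setdefault(key, []).append(sid)
    for sid in ids:
        key = tuple(str(meta_table.loc[sid, f]) for f in stratify)
        stratum = strata[key]
        members = set(stratum)
        cands = neighbors_brute(coords, sid, radius, eligible=lambda s: s in members)
        k = math.floor(fraction * len(stratum))
        nbrs = cands[: min(k, len(cands))]
        if len(nbrs) < min_neighbors:
            results[sid] = (None, len(nbrs))
            continue
        times = [records.loc[n, "time"] for n, _ in nbrs]
        events = [records.loc[n, "event"] for n, _ in nbrs]
        results[sid] = (km_median_hand(times, events), len(nbrs))
    return results
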