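"""Sample filtering, Kaplan-Meier estimation, and survival annotation of landscapes.

The survival annotation colors each tumor sample with the Kaplan-Meier
median survival of a cohort of its nearest neighbors on the landscape,
where neighbors must share the sample's stratum (by default subtype and
dataset), lie within a fixed radius, and number at most a fixed fraction of
the stratum.  Samples with too few neighbors, or whose neighbor cohort has
an undefined KM median, stay unannotated.

Kaplan-Meier estimation is backed by lifelines; the module exposes the
product-limit curve as a plain step-function table (time, at-risk, deaths,
censored, survival, Greenwood variance) so downstream code and tests can
read values off it directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .landscape import Landscape, neighbors_within_radius
from .matrix import SampleMetadata

#: sample types removed before any survival analysis
NON_PRIMARY = ("recurrent", "secondary", "normal")

UNDEFINED = None  # KM median when the curve never reaches 0.5


class SurvivalRecord(NamedTuple):
    sample_id: str
    time: float
    event: int  # 1 = death observed, 0 = censored


@dataclass(frozen=True)
class AnnotationConfig:
    """Neighborhood rules for the survival annotation.

    radius
        Maximum embedding-space distance to a neighbor (inclusive).
    neighbor_fraction
        The neighbor cohort is the nearest floor(fraction * stratum size)
        candidates; the stratum count includes the sample itself.
    min_neighbors
        Samples with fewer neighbors than this stay unannotated.
    stratify_by
        Metadata fields neighbors must match exactly.
    """

    radius: float = 2.0
    neighbor_fraction: float = 0.25
    min_neighbors: int = 10
    stratify_by: tuple[str, ...] = ("subtype", "dataset")

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0 < self.neighbor_fraction <= 1:
            raise ValueError("neighbor_fraction must lie in (0, 1]")
        if self.min_neighbors < 1:
            raise ValueError("min_neighbors must be positive")


def filter_primary_unique(meta: SampleMetadata) -> tuple[list[str], pd.DataFrame]:
    """Keep primary samples, one per patient.

    Removes every sample typed recurrent, secondary or normal, then keeps
    the lexicographically smallest sample id among each patient's surviving
    samples.  Returns the kept ids (input order) and an exclusion log with
    one row per removed sample and the rule that removed it.
    """
    t = meta.table
    log_rows = []
    survivors = []
    for sid, row in t.iterrows():
        if row["sample_type"] in NON_PRIMARY:
            log_rows.append((sid, f"non_primary:{row['sample_type']}"))
        else:
            survivors.append(sid)
    by_patient: dict[str, list[str]] = {}
    for sid in survivors:
        by_patient.setdefault(t.at[sid, "patient_id"], []).append(sid)
    keep = set()
    for patient, sids in by_patient.items():
        chosen = min(sids)
        keep.add(chosen)
        for sid in sids:
            if sid != chosen:
                log_rows.append((sid, f"duplicate_patient:{patient}"))
    kept = [sid for sid in t.index if sid in keep]
    log = pd.DataFrame(log_rows, columns=["sample_id", "rule"])
    return kept, log


@dataclass
class KMCurve:
    """Product-limit estimate as a step-function table.

    ``table`` has one row per distinct observed time with columns
    ``at_risk``, ``deaths``, ``censored``, ``survival``, ``greenwood_var``;
    S(0) = 1 and the curve is non-increasing.
    """

    table: pd.DataFrame
    n: int

    def survival_at(self, t: float) -> float:
        prior = self.table.index[self.table.index <= t]
        if len(prior) == 0:
            return 1.0
        return float(self.table.loc[prior[-1], "survival"])


def _coerce_records(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records[["time", "event"]].copy()
    else:
        df = pd.DataFrame(records, columns=["sample_id", "time", "event"]).set_index(
            "sample_id"
        )
    if len(df) == 0:
        raise ValueError("need at least one survival record")
    if (df["time"] < 0).any():
        bad = df.index[df["time"] < 0].tolist()
        raise ValueError(f"negative survival time for: {bad[:5]}")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return df


def km_estimate(records) -> KMCurve:
    """Kaplan-Meier product-limit curve with at-risk/death counts.

    ``records`` is a list of :class:`SurvivalRecord` or a DataFrame with
    ``time`` and ``event`` columns.
    """
    df = _coerce_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"])
    tbl = kmf.event_table
    sf = kmf.survival_function_.iloc[:, 0]
    out = pd.DataFrame(
        {
            "at_risk": tbl["at_risk"],
            "deaths": tbl["observed"],
            "censored": tbl["censored"],
            "survival": sf.reindex(tbl.index).to_numpy(),
        }
    )
    if 0.0 in out.index and out.loc[0.0, ["deaths", "censored"]].sum() == 0:
        out = out.drop(index=0.0)
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i<=t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = out["deaths"] / (out["at_risk"] * (out["at_risk"] - out["deaths"]))
    terms = terms.replace([np.inf, -np.inf], 0.0).fillna(0.0)
    out["greenwood_var"] = out["survival"] ** 2 * terms.cumsum()
    out.index.name = "time"
    return KMCurve(table=out, n=len(df))


def km_median(curve: KMCurve):
    """Smallest event time with S(t) <= 0.5; ``None`` when never reached."""
    tbl = curve.table
    event_rows = tbl[tbl["deaths"] > 0]
    hit = event_rows[event_rows["survival"] <= 0.5 + 1e-12]
    if len(hit) == 0:
        return UNDEFINED
    return float(hit.index[0])


def km_by_group(records, groups) -> dict[str, tuple[KMCurve, float | None]]:
    """Per-group KM curve and median; each curve equals km_estimate on its subset."""
    df = _coerce_records(records)
    g = pd.Series(list(groups), index=df.index)
    out: dict[str, tuple[KMCurve, float | None]] = {}
    for level in sorted(g.unique()):
        sub = df[g == level]
        if len(sub) == 0:
            raise ValueError(f"empty group {level!r}")
        curve = km_estimate(sub)
        out[level] = (curve, km_median(curve))
    return out


def annotate_survival(
    L: Landscape,
    records: pd.DataFrame,
    meta: SampleMetadata,
    cfg: AnnotationConfig = AnnotationConfig(),
) -> pd.DataFrame:
    """Predict each sample's survival as the KM median of its neighbor cohort.

    For sample ``s``: the stratum is every landscape sample sharing s's
    ``stratify_by`` values (including s); candidates are stratum members
    other than s within ``cfg.radius``; the neighbor cohort is the
    ``floor(cfg.neighbor_fraction * stratum size)`` nearest candidates.
    Samples with fewer than ``cfg.min_neighbors`` neighbors, or whose
    cohort KM median is undefined, come back UNANNOTATED.  A sample's own
    survival time never enters its own prediction.

    Returns a frame indexed by sample_id with ``predicted_median`` (NaN if
    unannotated), ``n_neighbors``, ``cohort_size`` and ``status``.
    """
    t = meta.table
    for f in cfg.stratify_by:
        if f not in t.columns:
            raise ValueError(f"unknown stratify field {f!r}")
    missing = [s for s in L.sample_ids if s not in records.index or s not in t.index]
    if missing:
        raise ValueError(f"samples missing survival or metadata: {missing[:5]}")
    diam = L.diameter()
    if diam > 0 and cfg.radius > 0.25 * diam:
        warnings.warn(
            f"radius {cfg.radius} exceeds 25% of the embedding diameter {diam:.3g}; "
            "neighborhoods may span unrelated clusters",
            stacklevel=2,
        )

    key = t.loc[L.sample_ids, list(cfg.stratify_by)].astype(str).agg("\x1f".join, axis=1)
    strata: dict[str, list[str]] = {}
    for sid, k in key.items():
        strata.setdefault(k, []).append(sid)

    rows = {}
    for sid in L.sample_ids:
        stratum = strata[key[sid]]
        members = set(stratum)
        candidates = neighbors_within_radius(
            L, sid, cfg.radius, eligibility=lambda other: other in members
        )
        k = math.floor(cfg.neighbor_fraction * len(stratum))
        neighbors = candidates[: min(k, len(candidates))]
        row = {
            "n_neighbors": len(neighbors),
            "cohort_size": len(stratum),
            "predicted_median": np.nan,
            "status": "unannotated",
        }
        if len(neighbors) >= cfg.min_neighbors:
            ids = [n for n, _ in neighbors]
            med = km_median(km_estimate(records.loc[ids]))
            if med is not UNDEFINED:
                row["predicted_median"] = med
                row["status"] = "annotated"
        rows[sid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out[["predicted_median", "n_neighbors", "cohort_size", "status"]]
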