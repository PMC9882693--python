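"""Single-sample pathway scoring and moderated-t differential testing.

Each sample is scored against every gene set with a rank-only two-sided
Kolmogorov-Smirnov running-sum statistic: genes are ranked by expression
within the sample (average ranks for ties), the ranked list is walked from
highest to lowest expression, in-set genes step the running sum up by their
normalized rank weight |r_i - (N+1)/2| and out-of-set genes step it down
uniformly; the score is the maximum positive excursion plus the minimum
negative excursion, which is guaranteed to lie in [-1, 1].  A score near 1
means the set sits at the top of the sample's expression ranking
(up-regulated), near -1 at the bottom.

Group differences in pathway scores are tested per set with a two-group
linear model whose residual variance is shrunk toward a common prior by
empirical Bayes: the prior (d0, s0^2) is obtained by moment-matching the
scaled-F distribution of the log sample variances across sets, the
posterior variance is s~^2 = (d0 s0^2 + d s^2)/(d0 + d), and the moderated
t uses d0 + d degrees of freedom.  P-values are Benjamini-Hochberg adjusted
across sets within one contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix


@dataclass
class GeneSetCollection:
    """Named gene sets with a source tag."""

    sets: dict[str, tuple[str, ...]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, genes) -> "GeneSetCollection":
        """Drop genes outside ``genes``; sets left empty are removed."""
        universe = set(genes)
        kept = {}
        for name, members in self.sets.items():
            m = tuple(g for g in members if g in universe)
            if m:
                kept[name] = m
        return GeneSetCollection(kept, self.source)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: tab-separated name, description, member genes.

    Duplicate genes within a set are collapsed (first occurrence wins);
    empty lines are skipped; a duplicated set name or a line with fewer
    than three fields is an error naming the line.
    """
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ValueError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets, source=str(path))


@dataclass
class PathwayScoreMatrix:
    """Set x sample scores in [-1, 1] with the scoring method recorded."""

    scores: pd.DataFrame
    method: str
    dropped_sets: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.scores.to_numpy()
        if v.size and (np.nanmin(v) < -1 - 1e-9 or np.nanmax(v) > 1 + 1e-9):
            raise ValueError("pathway scores must lie in [-1, 1]")


def _ks_scores_one_sample(expr: np.ndarray, set_masks: list[np.ndarray]) -> np.ndarray:
    n = expr.size
    ranks = stats.rankdata(expr, method="average")  # 1 = lowest expression
    order = np.lexsort((np.arange(n), -ranks))  # walk highest expression first
    weights = np.abs(ranks - (n + 1) / 2.0)
    out = np.empty(len(set_masks))
    for i, mask in enumerate(set_masks):
        m = int(mask.sum())
        in_walk = mask[order]
        w_walk = np.where(in_walk, weights[order], 0.0)
        w_total = w_walk.sum()
        if w_total == 0:  # set sits exactly at the rank midpoint
            out[i] = 0.0
            continue
        steps = np.where(in_walk, w_walk / w_total, -1.0 / (n - m))
        rs = np.cumsum(steps)
        # the statistic lies in [-1, 1] exactly; clamp accumulated float error
        out[i] = np.clip(max(rs.max(), 0.0) + min(rs.min(), 0.0), -1.0, 1.0)
    return out


def score_samples(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 500,
) -> PathwayScoreMatrix:
    """Score every sample against every gene set on a [-1, 1] scale.

    Sets are restricted to the matrix's genes first; sets that end up
    outside [min_size, max_size] are dropped and logged.  Scores depend on
    within-sample ranks only, so they are invariant to any strictly
    monotone transform of a sample's expression values.
    """
    restricted = sets.restrict(m.gene_ids)
    dropped: dict[str, str] = {}
    for name in sets.sets:
        if name not in restricted.sets:
            dropped[name] = "no genes in matrix"
    usable: dict[str, tuple[str, ...]] = {}
    for name, genes in restricted.sets.items():
        if len(genes) < 2:
            raise ValueError(f"set {name!r} has < 2 genes in the matrix")
        if not (min_size <= len(genes) <= max_size):
            dropped[name] = f"size {len(genes)} outside [{min_size}, {max_size}]"
            continue
        usable[name] = genes
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    masks = []
    for genes in usable.values():
        mask = np.zeros(m.n_genes, dtype=bool)
        mask[[gene_pos[g] for g in genes]] = True
        masks.append(mask)
    x = m.values.to_numpy(dtype=float)
    cols = {}
    for j, sid in enumerate(m.sample_ids):
        cols[sid] = _ks_scores_one_sample(x[:, j], masks)
    scores = pd.DataFrame(cols, index=list(usable))
    scores.index.name = "set"
    return PathwayScoreMatrix(scores=scores, method="rank_ks", dropped_sets=dropped)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, as used for F moment matching)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-8:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to sample variances.

    Returns (d0, s0^2): the prior degrees of freedom and prior variance such
    that s^2 ~ s0^2 F(df, d0) matches the observed spread of log variances.
    d0 = inf when the variances are less dispersed than chi^2 sampling alone
    would produce.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = np.exp(e_mean)
    return float(d0), float(s0_2)


def moderated_t_test(
    scores: PathwayScoreMatrix,
    groups: pd.Series,
    d0: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated t test per gene set.

    ``groups`` maps sample id to one of exactly two levels; the contrast is
    mean(second level) - mean(first level) with levels in sorted order, and
    ``direction`` is "up" when that difference is positive.  ``d0``
    overrides the moment-matched prior degrees of freedom (0 recovers the
    ordinary pooled two-sample t).
    """
    g = pd.Series(groups)
    g = g[g.index.isin(scores.scores.columns)].dropna()
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    a = scores.scores[g.index[g == levels[0]]].to_numpy(dtype=float)
    b = scores.scores[g.index[g == levels[1]]].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    df_resid = n1 + n2 - 2
    diff = b.mean(axis=1) - a.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid

    d0_fit, s0_2 = fit_f_dist(s2, df_resid)
    if d0 is not None:
        d0_fit = float(d0)
    if np.isinf(d0_fit):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0_fit == 0:
        s2_post = s2
        df_total = df_resid
    else:
        s2_post = (d0_fit * s0_2 + df_resid * s2) / (d0_fit + df_resid)
        df_total = d0_fit + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "mean_diff": diff,
            "moderated_t": t,
            "p_value": p,
            "adj_p_value": adj,
            "direction": np.where(diff > 0, "up", "down"),
        },
        index=scores.scores.index,
    )
    out.attrs["d0"] = d0_fit
    out.attrs["s0_2"] = s0_2
    out.attrs["contrast"] = f"{levels[1]} - {levels[0]}"
    return out


def shared_regulated(
    results: list[pd.DataFrame],
    adj_p_threshold: float = 0.05,
    direction: str = "up",
) -> tuple[set[str], dict[str, int]]:
    """Sets significant with the given direction in every contrast table.

    Returns the exact intersection of significant set names plus per-table
    significant counts (keys ``table_0`` ... and ``intersection``).
    """
    if len(results) < 2:
        raise ValueError("need at least two result tables")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    base = set(results[0].index)
    for r in results[1:]:
        if set(r.index) != base:
            raise ValueError("result tables cover different collections")
    counts: dict[str, int] = {}
    shared: set[str] | None = None
    for i, r in enumerate(results):
        sig = set(
            r.index[(r["adj_p_value"] <= adj_p_threshold) & (r["direction"] == direction)]
        )
        counts[f"table_{i}"] = len(sig)
        shared = sig if shared is None else (shared & sig)
    counts["intersection"] = len(shared)
    return shared, counts
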