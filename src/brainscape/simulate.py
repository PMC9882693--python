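"""Multi-cohort RNA-seq simulator with planted batch effects and survival truth.

The generator emulates the statistical structure a multi-cohort integration
assumes: several cohorts measuring the same tumor subtypes, each cohort
adding its own per-gene location/scale distortion, subtypes distinguished by
disjoint signature gene sets, and per-sample right-censored survival times
whose distribution depends on subtype only.

The expression model, on log2 scale, is

    y_gsc = baseline_g + effect_k * 1[g in signature(k)] + gamma_gc + delta_gc * eps_gs

where ``k`` is the sample's subtype, ``gamma_gc ~ Normal(0, batch_location_sd)``
is the additive cohort offset, ``delta_gc`` is a positive multiplicative
cohort factor drawn from an inverse-gamma (mean approximately 1) that scales
the Normal(0, noise_sd) residual, mirroring the location/scale model the
empirical-Bayes correction stage assumes.  FPKM-scale values are ``2**y``.

Survival times are Weibull per subtype, parameterized by the subtype's
median and shape (scale = median / ln(2)^(1/shape)).  Censoring is an
independent exponential clock whose rate is calibrated by root-finding so
the expected censored fraction equals ``censoring_rate``.

Genomic overlay events (mutations, fusions, copy-number gains/losses) are
Bernoulli per (sample, gene), with elevated probabilities on the sample's
subtype signature genes so that overlay frequencies are subtype-enriched
with known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .matrix import ExpressionMatrix, SampleMetadata

VARIANT_CLASSES = ("missense", "nonsense", "frameshift", "splice_site")
FUSION_CONFIDENCES = ("high", "medium", "low")


@dataclass(frozen=True)
class SubtypeSpec:
    """One tumor subtype: signature geometry and survival distribution."""

    name: str
    n_signature_genes: int
    signature_effect: float  # log2 units added on signature genes
    survival_median: float  # time units (years in the default scenario)
    survival_shape: float = 1.0  # Weibull shape; 1.0 = exponential

    def __post_init__(self) -> None:
        if self.survival_median <= 0:
            raise ValueError(f"survival_median must be > 0 for {self.name!r}")
        if self.survival_shape <= 0:
            raise ValueError(f"survival_shape must be > 0 for {self.name!r}")

    @property
    def weibull_scale(self) -> float:
        return self.survival_median / np.log(2.0) ** (1.0 / self.survival_shape)


@dataclass(frozen=True)
class OverlaySpec:
    """Per-subtype Bernoulli event probabilities for the genomic overlays.

    ``*_background`` applies to every gene; ``*_signature`` replaces it on
    the subtype's own signature genes, producing subtype-enriched events.
    """

    mutation_background: float = 0.002
    mutation_signature: float = 0.15
    fusion_background: float = 0.0005
    fusion_signature: float = 0.05
    gain_background: float = 0.01
    gain_signature: float = 0.20
    loss_background: float = 0.01
    loss_signature: float = 0.20


@dataclass
class SimulationConfig:
    """Full description of one synthetic multi-cohort scenario."""

    n_cohorts: int = 2
    samples_per_cohort_per_subtype: int = 100
    n_genes: int = 2000
    subtype_specs: tuple[SubtypeSpec, ...] = (
        SubtypeSpec("idh_wildtype", 50, 2.0, 1.0, 1.0),
        SubtypeSpec("astrocytoma", 50, 2.0, 3.0, 1.0),
        SubtypeSpec("oligodendroglioma", 50, 2.0, 8.0, 1.0),
    )
    batch_location_sd: float = 1.8
    batch_scale_shape: float = 20.0
    batch_scale_scale: float = 19.0
    noise_sd: float = 1.0
    censoring_rate: float = 0.2
    overlay_specs: dict[str, OverlaySpec] | None = None
    baseline_mean: float = 4.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohorts < 1 or self.samples_per_cohort_per_subtype < 1:
            raise ValueError("cohort and sample counts must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not self.subtype_specs:
            raise ValueError("at least one subtype is required")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must lie in [0, 1]")
        total_sig = sum(s.n_signature_genes for s in self.subtype_specs)
        if total_sig > self.n_genes:
            raise ValueError("signature genes exceed n_genes; sets must be disjoint")
        names = [s.name for s in self.subtype_specs]
        if len(set(names)) != len(names):
            raise ValueError("subtype names must be unique")
        if self.overlay_specs is None:
            self.overlay_specs = {s.name: OverlaySpec() for s in self.subtype_specs}

    @property
    def cohort_names(self) -> list[str]:
        return [f"cohort{i + 1:02d}" for i in range(self.n_cohorts)]

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]


@dataclass
class SyntheticTruth:
    """Planted parameters, reproducible from (config, seed)."""

    baseline: pd.Series  # per-gene baseline log2 expression
    batch_offsets: pd.DataFrame  # genes x cohorts additive gamma
    batch_scales: pd.DataFrame  # genes x cohorts multiplicative delta
    signature_genes: dict[str, list[str]]
    signature_effects: dict[str, float]
    survival_params: dict[str, dict[str, float]]  # shape, scale, median
    event_times: pd.Series  # per-sample true (uncensored) event time
    censor_rate: float  # solved exponential censor rate

    def to_json(self) -> str:
        payload = {
            "baseline": self.baseline.to_dict(),
            "batch_offsets": {c: self.batch_offsets[c].to_dict() for c in self.batch_offsets},
            "batch_scales": {c: self.batch_scales[c].to_dict() for c in self.batch_scales},
            "signature_genes": self.signature_genes,
            "signature_effects": self.signature_effects,
            "survival_params": self.survival_params,
            "event_times": self.event_times.to_dict(),
            "censor_rate": self.censor_rate,
        }
        return json.dumps(payload, sort_keys=True, indent=1)


@dataclass
class OverlayTables:
    """Simulated genomic overlays in the pipeline's interchange shapes."""

    mutations: pd.DataFrame  # columns sample_id, gene_id, variant_class
    fusions: pd.DataFrame  # columns sample_id, gene_5prime, gene_3prime, confidence
    copy_number: pd.DataFrame  # genes x samples integers in {-2..2}


def _censor_probability(rate: float, specs) -> float:
    """Mixture-averaged P(C < T) for an exponential censor clock at ``rate``."""
    probs = []
    for s in specs:
        lam = s.weibull_scale
        k = s.survival_shape
        # P(C < T) = 1 - E[exp(-rate * T)], T ~ Weibull(k, lam)
        def integrand(t, lam=lam, k=k):
            pdf = (k / lam) * (t / lam) ** (k - 1.0) * np.exp(-((t / lam) ** k))
            return np.exp(-rate * t) * pdf

        val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
        probs.append(1.0 - val)
    return float(np.mean(probs))


def solve_censor_rate(specs, target: float) -> float:
    """Exponential censor rate giving an expected censored fraction ``target``."""
    if target <= 0:
        return 0.0
    if target >= 1:
        raise ValueError("censoring_rate must be < 1 for a finite censor clock")
    lo, hi = 1e-9, 1.0
    while _censor_probability(hi, specs) < target:
        hi *= 10.0
        if hi > 1e9:  # pragma: no cover - unreachable for sane medians
            raise RuntimeError("censor-rate bracketing failed")
    return float(optimize.brentq(lambda c: _censor_probability(c, specs) - target, lo, hi))


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[list[ExpressionMatrix], SampleMetadata, OverlayTables, SyntheticTruth]:
    """Draw one full synthetic scenario.

    Returns one FPKM-scale :class:`ExpressionMatrix` per cohort, a combined
    :class:`SampleMetadata`, the genomic :class:`OverlayTables`, and the
    :class:`SyntheticTruth` ledger of every planted parameter.
    """
    ss = np.random.SeedSequence(config.seed)
    # fixed per-stage seed order: changing one stage's draws cannot shift another's
    seeds = ss.spawn(6)
    rng_base = np.random.default_rng(seeds[0])
    rng_batch = np.random.default_rng(seeds[1])
    rng_noise = np.random.default_rng(seeds[2])
    rng_surv = np.random.default_rng(seeds[3])
    rng_cens = np.random.default_rng(seeds[4])
    rng_ovl = np.random.default_rng(seeds[5])

    genes = config.gene_names
    cohorts = config.cohort_names
    specs = config.subtype_specs

    baseline = pd.Series(
        rng_base.normal(config.baseline_mean, config.baseline_sd, config.n_genes),
        index=genes,
        name="baseline",
    )

    # disjoint signature blocks, assigned in declared subtype order
    signature_genes: dict[str, list[str]] = {}
    cursor = 0
    for s in specs:
        signature_genes[s.name] = genes[cursor : cursor + s.n_signature_genes]
        cursor += s.n_signature_genes
    signature_effects = {s.name: s.signature_effect for s in specs}

    gamma = pd.DataFrame(
        rng_batch.normal(0.0, config.batch_location_sd, (config.n_genes, config.n_cohorts)),
        index=genes,
        columns=cohorts,
    )
    # inverse-gamma multiplicative factors; defaults give mean ~= 1
    delta = pd.DataFrame(
        config.batch_scale_scale
        / rng_batch.gamma(config.batch_scale_shape, 1.0, (config.n_genes, config.n_cohorts)),
        index=genes,
        columns=cohorts,
    )

    # sample bookkeeping: one primary sample per patient
    sample_ids: list[str] = []
    sample_cohort: list[str] = []
    sample_subtype: list[str] = []
    for c in cohorts:
        for s in specs:
            for i in range(config.samples_per_cohort_per_subtype):
                sample_ids.append(f"{c}-{s.name}-{i + 1:03d}")
                sample_cohort.append(c)
                sample_subtype.append(s.name)

    sig_effect_col = np.zeros(config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    effect_by_subtype = {}
    for s in specs:
        v = np.zeros(config.n_genes)
        for g in signature_genes[s.name]:
            v[gene_index[g]] = s.signature_effect
        effect_by_subtype[s.name] = v

    matrices: list[ExpressionMatrix] = []
    for c in cohorts:
        cols = [i for i, cc in enumerate(sample_cohort) if cc == c]
        ids = [sample_ids[i] for i in cols]
        mean = (
            baseline.to_numpy()[:, None]
            + np.column_stack([effect_by_subtype[sample_subtype[i]] for i in cols])
            + gamma[c].to_numpy()[:, None]
        )
        eps = rng_noise.normal(0.0, 1.0, mean.shape) * config.noise_sd
        log2x = mean + delta[c].to_numpy()[:, None] * eps
        fpkm = pd.DataFrame(np.exp2(log2x), index=genes, columns=ids)
        matrices.append(ExpressionMatrix(fpkm, "FPKM"))

    # survival: Weibull per subtype, then an independent exponential censor clock
    event_time = np.empty(len(sample_ids))
    for s in specs:
        idx = [i for i, st in enumerate(sample_subtype) if st == s.name]
        event_time[idx] = s.weibull_scale * rng_surv.weibull(s.survival_shape, len(idx))
    censor_rate = solve_censor_rate(specs, config.censoring_rate)
    if censor_rate > 0:
        censor_time = rng_cens.exponential(1.0 / censor_rate, len(sample_ids))
    else:
        censor_time = np.full(len(sample_ids), np.inf)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    meta = pd.DataFrame(
        {
            "patient_id": [f"pt-{sid}" for sid in sample_ids],
            "dataset": sample_cohort,
            "disease": ["glioma"] * len(sample_ids),
            "subtype": sample_subtype,
            "sample_type": ["primary"] * len(sample_ids),
            "age": np.clip(rng_surv.normal(50, 15, len(sample_ids)).round(1), 1, 95),
            "sex": rng_surv.choice(["female", "male"], len(sample_ids)),
            "time": observed,
            "event": event,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    metadata = SampleMetadata(meta)

    overlays = _simulate_overlays(config, sample_ids, sample_subtype, signature_genes, rng_ovl)

    truth = SyntheticTruth(
        baseline=baseline,
        batch_offsets=gamma,
        batch_scales=delta,
        signature_genes=signature_genes,
        signature_effects=signature_effects,
        survival_params={
            s.name: {
                "shape": s.survival_shape,
                "scale": s.weibull_scale,
                "median": s.survival_median,
            }
            for s in specs
        },
        event_times=pd.Series(event_time, index=sample_ids, name="event_time"),
        censor_rate=censor_rate,
    )
    return matrices, metadata, overlays, truth


def _simulate_overlays(config, sample_ids, sample_subtype, signature_genes, rng):
    genes = config.gene_names
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    mut_rows = []
    fus_rows = []
    cn = np.zeros((n_genes, len(sample_ids)), dtype=int)

    prob_cache: dict[str, dict[str, np.ndarray]] = {}
    for name, spec in config.overlay_specs.items():
        sig_idx = [gene_index[g] for g in signature_genes.get(name, [])]
        probs = {}
        for kind in ("mutation", "fusion", "gain", "loss"):
            p = np.full(n_genes, getattr(spec, f"{kind}_background"))
            p[sig_idx] = getattr(spec, f"{kind}_signature")
            probs[kind] = p
        prob_cache[name] = probs

    for j, (sid, st) in enumerate(zip(sample_ids, sample_subtype)):
        probs = prob_cache[st]
        u = rng.random((4, n_genes))
        mut_hits = np.flatnonzero(u[0] < probs["mutation"])
        for gi in mut_hits:
            vc = VARIANT_CLASSES[rng.integers(len(VARIANT_CLASSES))]
            mut_rows.append((sid, genes[gi], vc))
        fus_hits = np.flatnonzero(u[1] < probs["fusion"])
        for gi in fus_hits:
            partner = genes[int(rng.integers(n_genes - 1))]
            if partner == genes[gi]:
                partner = genes[-1]
            conf = FUSION_CONFIDENCES[
                int(rng.choice(len(FUSION_CONFIDENCES), p=[0.7, 0.15, 0.15]))
            ]
            if rng.random() < 0.5:
                fus_rows.append((sid, genes[gi], partner, conf))
            else:
                fus_rows.append((sid, partner, genes[gi], conf))
        gains = u[2] < probs["gain"]
        losses = (u[3] < probs["loss"]) & ~gains  # a gene is gained or lost, not both
        amp = rng.random(n_genes) < 0.3  # fraction of events at the extreme level
        cn[gains & amp, j] = 2
        cn[gains & ~amp, j] = 1
        cn[losses & amp, j] = -2
        cn[losses & ~amp, j] = -1

    mutations = pd.DataFrame(mut_rows, columns=["sample_id", "gene_id", "variant_class"])
    fusions = pd.DataFrame(
        fus_rows, columns=["sample_id", "gene_5prime", "gene_3prime", "confidence"]
    )
    copy_number = pd.DataFrame(cn, index=genes, columns=sample_ids)
    return OverlayTables(mutations=mutations, fusions=fusions, copy_number=copy_number)


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """Flatten the truth ledger into one row per planted parameter.

    Columns: kind, subject, context, parameter, value — deterministic row
    order so repeated reports of the same truth are byte-identical.
    """
    rows = []
    for c in truth.batch_offsets.columns:
        for g in truth.batch_offsets.index:
            rows.append(("batch_offset", g, c, "gamma", truth.batch_offsets.at[g, c]))
    for c in truth.batch_scales.columns:
        for g in truth.batch_scales.index:
            rows.append(("batch_scale", g, c, "delta", truth.batch_scales.at[g, c]))
    for name in sorted(truth.signature_genes):
        for g in truth.signature_genes[name]:
            rows.append(("signature", g, name, "effect", truth.signature_effects[name]))
    for name in sorted(truth.survival_params):
        for param, value in sorted(truth.survival_params[name].items()):
            rows.append(("survival", name, "", param, value))
    rows.append(("censoring", "", "", "censor_rate", truth.censor_rate))
    return pd.DataFrame(rows, columns=["kind", "subject", "context", "parameter", "value"])
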