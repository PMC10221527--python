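"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a slaughter cohort measured at up to three gut
locations (ileum, cecum, faeces) together with one serum LC-MS feature
matrix per animal:

* taxa are zero-inflated log-normal — per-taxon Bernoulli presence at a
  prevalence drawn from a location-specific range, log-normal abundance
  given presence, rows renormalized to relative abundance (optionally
  realized as sequencing counts at a per-sample depth);
* metabolite log-intensities are a per-feature baseline plus sex and
  slaughter-batch shifts, implanted taxon effects, a log-linear
  injection-order drift and Gaussian noise; pooled-QC injections are
  replicate draws of the feature baseline subject only to drift and a
  small analytical noise;
* implanted taxon->metabolite effects act through presence (mean shift in
  units of the residual sd) and/or through standardized log-abundance
  among present animals, mirroring the binary/quantitative decomposition
  of the downstream two-part test;
* a binary fatness label is driven by a logistic score on four designated
  metabolites and median-split so the two groups are exactly balanced.

Everything is drawn from one seeded generator; per-stage substreams are
spawned deterministically, so a fixed seed yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import LOCATIONS, MetaboFeatureMatrix, TaxaTable

DEFAULT_PREVALENCE_RANGES = {
    # the small intestine carries fewer, sparser taxa than the hindgut
    "ileum": (0.10, 0.60),
    "cecum": (0.20, 0.90),
    "faeces": (0.20, 0.90),
}
# tag-count range observed per sample in typical 16S runs of this design
DEFAULT_COUNT_DEPTH_RANGE = (30_001, 44_994)


@dataclass(frozen=True)
class ImplantedEffect:
    """One true taxon -> metabolite effect.

    ``binary_effect`` is the mean shift of the standardized log-intensity
    when the taxon is present; ``quant_effect`` is the slope on the
    standardized log-abundance among present animals. ``locations`` lists
    the gut locations whose community carries the effect.
    """

    taxon: int
    metabolite: int
    binary_effect: float = 0.0
    quant_effect: float = 0.0
    locations: tuple[str, ...] = LOCATIONS

    def __post_init__(self) -> None:
        if self.binary_effect == 0.0 and self.quant_effect == 0.0:
            raise ValueError("an implanted effect needs a nonzero binary or quant component")
        bad = set(self.locations) - set(LOCATIONS)
        if bad:
            raise ValueError(f"unknown effect locations: {sorted(bad)}")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 300
    n_taxa: int = 50
    n_metabolites: int = 20
    locations: tuple[str, ...] = LOCATIONS
    prevalence_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE_RANGES))
    taxon_logmean_sd: float = 1.0
    effect_table: list[ImplantedEffect] = field(default_factory=list)
    sex_effect_sd: float = 0.3
    batch_effect_sd: float = 0.3
    n_batches: int = 5
    qc_every: int = 12
    qc_noise_sd: float = 0.05
    drift_slope: float = 0.0
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    annotated_fraction: float = 0.5
    fatness_effects: dict[int, float] = field(default_factory=dict)
    emit_counts: bool = False
    count_depth_range: tuple[int, int] = DEFAULT_COUNT_DEPTH_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_taxa", "n_metabolites", "n_batches"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.qc_every < 2:
            raise ValueError("qc_every must be >= 2")
        for loc in self.locations:
            if loc not in LOCATIONS:
                raise ValueError(f"unknown location {loc!r}")
            lo, hi = self.prevalence_ranges[loc]
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError(f"prevalence bounds for {loc} must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for eff in self.effect_table:
            if not 0 <= eff.taxon < self.n_taxa:
                raise ValueError(f"effect refers to out-of-range taxon index {eff.taxon}")
            if not 0 <= eff.metabolite < self.n_metabolites:
                raise ValueError(
                    f"effect refers to out-of-range metabolite index {eff.metabolite}")
        for idx in self.fatness_effects:
            if not 0 <= idx < self.n_metabolites:
                raise ValueError(f"fatness effect refers to out-of-range metabolite {idx}")


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _simulate_location(cfg: SimConfig, location: str,
                       rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (relative abundance, raw log-abundance-given-presence) frames."""
    n, t = cfg.n_samples, cfg.n_taxa
    lo, hi = cfg.prevalence_ranges[location]
    prevalence = rng.uniform(lo, hi, size=t)
    logmean = rng.normal(0.0, 2.0, size=t)
    present = rng.random((n, t)) < prevalence
    logabund = rng.normal(logmean, cfg.taxon_logmean_sd, size=(n, t))
    abund = np.where(present, np.exp(logabund), 0.0)
    # guard: a sample with nothing detected gets its most prevalent taxon back
    empty = ~present.any(axis=1)
    if empty.any():
        j = int(np.argmax(prevalence))
        abund[empty, j] = np.exp(logabund[empty, j])
    rel = abund / abund.sum(axis=1, keepdims=True)
    samples = [f"pig{i:04d}" for i in range(n)]
    taxa = [f"taxon{j:03d}" for j in range(t)]
    return (pd.DataFrame(rel, index=samples, columns=taxa),
            pd.DataFrame(np.where(abund > 0, logabund, np.nan),
                         index=samples, columns=taxa))


def _counts_from_relabund(rel: pd.DataFrame, depth_range: tuple[int, int],
                          rng: np.random.Generator) -> pd.DataFrame:
    depths = rng.integers(depth_range[0], depth_range[1] + 1, size=rel.shape[0])
    counts = np.vstack([rng.multinomial(d, p) for d, p in zip(depths, rel.to_numpy())])
    return pd.DataFrame(counts, index=rel.index, columns=rel.columns)


def _standardized_quant(logabund: pd.DataFrame) -> np.ndarray:
    """Zero-filled standardized log abundance among present samples.

    Effects act through the taxon's own latent log abundance (NaN where
    absent), not the renormalized community share: implanting on the share
    would smear the effect over every other taxon through the compositional
    constraint and leave the implanted truth ill-defined.
    """
    arr = logabund.to_numpy()
    out = np.zeros_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        mask = ~np.isnan(col)
        if mask.sum() >= 2 and col[mask].std() > 0:
            out[mask, j] = (col[mask] - col[mask].mean()) / col[mask].std()
    return out


def simulate_cohort(cfg: SimConfig):
    """Generate one synthetic cohort.

    Returns
    -------
    taxa : dict[str, TaxaTable]
        One table per configured location (relative abundance, or counts if
        ``cfg.emit_counts``).
    metabolites : MetaboFeatureMatrix
        Serum features for all animals plus interleaved pooled-QC injections.
    metadata : DataFrame
        sample_id-indexed sex, batch, backfat score and fatness group.
    truth : list[ImplantedEffect]
        The implanted effect table, verbatim.
    """
    rngs = _spawn(cfg.seed, 5 + len(cfg.locations))
    loc_rngs = dict(zip(cfg.locations, rngs[: len(cfg.locations)]))
    rng_meta, rng_metab, rng_run, rng_fat, rng_counts = rngs[len(cfg.locations):]

    n, m = cfg.n_samples, cfg.n_metabolites
    samples = [f"pig{i:04d}" for i in range(n)]

    rel_tables: dict[str, pd.DataFrame] = {}
    logabund_tables: dict[str, pd.DataFrame] = {}
    for loc in cfg.locations:
        rel_tables[loc], logabund_tables[loc] = _simulate_location(cfg, loc, loc_rngs[loc])

    # covariates
    sex = rng_meta.integers(0, 2, size=n)  # 0 = female, 1 = male
    batch = rng_meta.integers(0, cfg.n_batches, size=n)

    # metabolite structural part (before drift / noise), in units of noise_sd
    baseline = rng_metab.uniform(np.log(1e5), np.log(1e7), size=m)
    sex_shift = rng_metab.normal(0.0, cfg.sex_effect_sd, size=m)
    batch_shift = rng_metab.normal(0.0, cfg.batch_effect_sd, size=(cfg.n_batches, m))
    signal = np.zeros((n, m))
    quant_std = {loc: _standardized_quant(logabund_tables[loc]) for loc in cfg.locations}
    for eff in cfg.effect_table:
        for loc in eff.locations:
            if loc not in cfg.locations:
                continue
            presence = (rel_tables[loc].to_numpy()[:, eff.taxon] > 0).astype(float)
            signal[:, eff.metabolite] += eff.binary_effect * presence
            signal[:, eff.metabolite] += eff.quant_effect * quant_std[loc][:, eff.taxon]

    noise = rng_metab.normal(0.0, 1.0, size=(n, m))
    log_int = (baseline
               + sex_shift * sex[:, None]
               + batch_shift[batch]
               + cfg.noise_sd * (signal + noise))

    # run order: a QC injection opens the run and recurs every qc_every samples
    run_order = rng_run.permutation(n)
    inj_sample = np.empty(n, dtype=int)
    order, n_qc, pos = 1, 0, 0
    qc_orders = []
    while pos < n:
        qc_orders.append(order)
        n_qc += 1
        order += 1
        take = min(cfg.qc_every, n - pos)
        inj_sample[run_order[pos:pos + take]] = np.arange(order, order + take)
        order += take
        pos += take
    qc_orders.append(order)  # closing QC
    n_qc += 1

    drift_rate = np.log1p(cfg.drift_slope)
    log_int += drift_rate * inj_sample[:, None]
    intensity = np.exp(log_int)
    if cfg.missing_rate > 0:
        intensity[rng_metab.random((n, m)) < cfg.missing_rate] = 0.0

    qc_log = (baseline
              + drift_rate * np.asarray(qc_orders)[:, None]
              + rng_metab.normal(0.0, cfg.qc_noise_sd, size=(n_qc, m)))
    qc_int = np.exp(qc_log)

    features = [f"feat{j:04d}" for j in range(m)]
    qc_ids = [f"QC{k:03d}" for k in range(n_qc)]
    data = pd.DataFrame(np.vstack([intensity, qc_int]),
                        index=samples + qc_ids, columns=features)
    inj = pd.Series(np.concatenate([inj_sample, qc_orders]), index=data.index)
    is_qc = pd.Series([False] * n + [True] * n_qc, index=data.index)

    n_annotated = int(round(cfg.annotated_fraction * m))
    msi = np.full(m, np.nan)
    msi[:n_annotated] = np.where(np.arange(n_annotated) % 2 == 0, 1, 2)
    annotation = pd.DataFrame(
        {"compound": [f"cpd_{j:04d}" if j < n_annotated else "" for j in range(m)],
         "msi_level": msi,
         "ion_mode": np.where(np.arange(m) % 2 == 0, "positive", "negative")},
        index=features)
    metabolites = MetaboFeatureMatrix(data=data, injection_order=inj,
                                      is_qc=is_qc, annotation=annotation)

    # fatness label from a logistic score on the designated markers
    if cfg.fatness_effects:
        z = np.zeros((n, m))
        for j in range(m):
            col = log_int[:, j]
            z[:, j] = (col - col.mean()) / col.std() if col.std() > 0 else 0.0
        eta = sum(beta * z[:, j] for j, beta in cfg.fatness_effects.items())
        score = eta + rng_fat.logistic(0.0, 1.0, size=n)
    else:
        score = rng_fat.logistic(0.0, 1.0, size=n)
    fat_group = (pd.Series(score).rank(method="first").to_numpy() > n / 2).astype(int)

    metadata = pd.DataFrame(
        {"sex": np.where(sex == 1, "M", "F"),
         "batch": [f"batch{b}" for b in batch],
         "backfat_score": score,
         "fatness_group": np.where(fat_group == 1, "HFG", "LFG")},
        index=pd.Index(samples, name="sample_id"))

    taxa_tables: dict[str, TaxaTable] = {}
    for loc in cfg.locations:
        tab = rel_tables[loc]
        if cfg.emit_counts:
            tab = _counts_from_relabund(tab, cfg.count_depth_range, rng_counts)
        taxa_tables[loc] = TaxaTable(
            data=tab, location=loc, level="ASV",
            taxonomy={t: f"Bacteria;g__genus{int(t[5:]) % max(1, cfg.n_taxa // 3):02d}"
                      for t in tab.columns})

    return taxa_tables, metabolites, metadata, list(cfg.effect_table)


def simulate_null_pvalues(cfg: SimConfig, n_reps: int,
                          alphas: tuple[float, ...] = (0.01, 0.05, 0.10)) -> dict:
    """Empirical p-value calibration of the two-part scan under the null.

    Simulates ``n_reps`` effect-free cohorts, runs the association scan on
    each configured location and pools the per-pair meta p-values. Returns
    the fraction of p-values below each alpha plus the pool size.
    """
    from .association import run_association_scan

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if cfg.effect_table:
        raise ValueError("null calibration requires an empty effect_table")
    seeds = np.random.SeedSequence(cfg.seed).generate_state(n_reps) % (2**31)
    pooled: list[np.ndarray] = []
    for rep in range(n_reps):
        rep_cfg = SimConfig(**{**cfg.__dict__, "seed": int(seeds[rep])})
        taxa, metab, meta, _ = simulate_cohort(rep_cfg)
        for loc in rep_cfg.locations:
            res = run_association_scan(taxa[loc], metab, meta)
            pooled.append(res["p_value"].to_numpy())
    p = np.concatenate(pooled)
    return {"fractions": {alpha: float(np.mean(p < alpha)) for alpha in alphas},
            "n_pvalues": int(p.size),
            "n_reps": n_reps}
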