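"""Linked synthetic multi-cohort scRNA-seq / proteome / clinical generator.

Emulates the statistical structure of a multi-cohort lung-fibrosis study so
that every downstream stage has a parameter-recovery test without patient
data:

* UMI counts are negative-binomial with per-cell library-size factors,
  per-cohort depth multipliers, and cell-type marker effects on the mean.
* Disease effects are planted directly on the *detection-probability* scale:
  for disease-responsive genes in ILD cells of the target type, the
  probability that a cell shows a nonzero count is shifted by ``δ`` relative
  to the negative-binomial baseline (a zero-inflation / de-inflation step),
  so the detection-regression stage's target quantity is known exactly.
* Cell-type proportions are Dirichlet; ILD samples carry a latent fibrosis
  burden that depletes an AT2-like type and introduces a disease-only state
  (aberrant-basaloid analog) absent from controls.
* Body-fluid protein log-intensities are linear in the source cell type's
  proportion plus noise, with intensity-dependent (MNAR, logistic) dropout.
* Lung function declines linearly in fibrosis burden.

Generation is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CountMatrix, ProteinTable, validate_sample_table

_DEFAULT_TYPES = (
    "AT2",
    "AT1",
    "Macrophage",
    "Fibroblast",
    "Aberrant_basaloid",  # disease-only state, must stay last
)


@dataclass
class SimulationConfig:
    """All knobs of the linked generator; defaults define the study conditions."""

    # cohort layout
    n_cohorts: int = 3
    samples_per_cohort_per_arm: int = 5
    cells_per_sample: tuple[int, int] = (80, 120)
    # transcriptome
    n_genes: int = 1000
    cell_type_names: tuple[str, ...] = _DEFAULT_TYPES
    markers_per_cell_type: int = 20
    marker_fold: float = 8.0  # fold elevation of a marker in its own type
    nb_dispersion: float = 1.5  # NB size r (var = mu + mu^2 / r)
    baseline_mean: float = 0.3  # per-cell per-gene mean before effects
    baseline_log_sd: float = 0.6
    disease_gene_baseline_mean: float = 0.5  # mid-range detection for clean δ
    cohort_depth: tuple[float, ...] = (1.0, 0.6, 1.5)
    library_log_sd: float = 0.3
    # disease architecture
    n_disease_genes_per_type: int = 20
    detection_shift: float = 0.2  # δ, on the detection-probability scale
    disease_target_types: tuple[str, ...] = ("AT2",)
    n_sex_genes: int = 10
    sex_fold: float = 20.0  # male/female mean ratio for male-linked genes
    # proportions
    base_proportions: tuple[float, ...] = (0.30, 0.15, 0.35, 0.20, 0.0)
    dirichlet_concentration: float = 60.0
    disease_state_proportion: float = 0.06  # mean in ILD at mean burden
    at2_depletion: float = 0.5  # fractional AT2 loss at burden 1
    burden_range: tuple[float, float] = (0.4, 1.0)  # ILD fibrosis burden
    # proteome
    n_proteins: int = 300
    mapped_fraction: float = 0.6
    protein_beta: float = 3.0  # log2-intensity per SD of source-type proportion
    protein_gamma: float = 1.0
    protein_noise_sd: float = 0.8
    protein_alpha_mean: float = 22.0
    protein_alpha_sd: float = 2.0
    missing_midpoint_quantile: float = 0.08  # intensity quantile with 50% dropout
    missing_steepness: float = 1.2
    # clinical
    lungfn_columns: tuple[str, ...] = (
        "DLCO_SB_percent",
        "FVC_percent",
        "FEV1_percent",
        "TLC_percent",
    )
    lungfn_intercepts: tuple[float, ...] = (90.0, 95.0, 92.0, 94.0)
    lungfn_slopes: tuple[float, ...] = (45.0, 35.0, 25.0, 30.0)
    lungfn_noise_sd: tuple[float, ...] = (5.0, 6.0, 7.0, 6.0)
    clinical_missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        n_types = len(self.cell_type_names)
        if len(self.base_proportions) != n_types:
            raise ValueError("base_proportions length must match cell_type_names")
        needed = n_types * self.markers_per_cell_type + self.n_sex_genes
        needed += len(self.disease_target_types) * self.n_disease_genes_per_type
        if needed > self.n_genes:
            raise ValueError(
                f"gene architecture needs {needed} genes but n_genes={self.n_genes}"
            )
        if len(self.cohort_depth) < self.n_cohorts:
            raise ValueError("cohort_depth shorter than n_cohorts")
        if not 0 <= self.disease_state_proportion < 1:
            raise ValueError("disease_state_proportion must be in [0, 1)")
        return self


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would have to infer."""

    gene_roles: pd.DataFrame  # gene, marker_of, disease_target, delta, sex_linked
    sample_truth: pd.DataFrame  # sample_id, burden, disease_status, ...
    true_proportions: pd.DataFrame  # samples × cell types
    config: SimulationConfig
    protein_map: pd.DataFrame | None = None  # protein, source_type, source_gene, beta
    lungfn_latent: pd.Series | None = None
    extras: dict = field(default_factory=dict)


def nb_detection_probability(mu: np.ndarray, dispersion: float) -> np.ndarray:
    """P(count > 0) for NB with mean ``mu`` and size ``dispersion``."""
    mu = np.asarray(mu, dtype=float)
    return 1.0 - (dispersion / (dispersion + mu)) ** dispersion


@dataclass
class _GeneArchitecture:
    gene_ids: np.ndarray
    baseline: np.ndarray  # per-gene base mean
    type_mult: np.ndarray  # n_types × n_genes marker multipliers
    delta: np.ndarray  # n_types × n_genes detection shifts in ILD
    male_mult: np.ndarray  # per-gene multiplier applied in male samples
    roles: pd.DataFrame


def _build_gene_architecture(config: SimulationConfig, rng: np.random.Generator) -> _GeneArchitecture:
    n_types = len(config.cell_type_names)
    g = config.n_genes
    gene_ids = np.array([f"G{i:04d}" for i in range(g)], dtype=object)
    baseline = config.baseline_mean * rng.lognormal(
        -config.baseline_log_sd**2 / 2, config.baseline_log_sd, g
    )
    type_mult = np.ones((n_types, g))
    delta = np.zeros((n_types, g))
    male_mult = np.ones(g)
    marker_of = np.array([""] * g, dtype=object)
    disease_target = np.array([""] * g, dtype=object)
    sex_linked = np.zeros(g, dtype=bool)

    pos = 0
    for t in range(n_types):
        block = slice(pos, pos + config.markers_per_cell_type)
        type_mult[t, block] = config.marker_fold
        marker_of[block] = config.cell_type_names[t]
        pos += config.markers_per_cell_type
    for tname in config.disease_target_types:
        t = config.cell_type_names.index(tname)
        block = slice(pos, pos + config.n_disease_genes_per_type)
        baseline[block] = config.disease_gene_baseline_mean
        signs = np.where(np.arange(config.n_disease_genes_per_type) % 2 == 0, 1.0, -1.0)
        delta[t, block] = signs * config.detection_shift
        disease_target[block] = tname
        pos += config.n_disease_genes_per_type
    # half the sex-linked genes are male-specific (Y-like), half female-specific
    # (XIST-like), keeping total depth balanced between genders
    sex_idx = np.arange(pos, pos + config.n_sex_genes)
    baseline[sex_idx] = config.disease_gene_baseline_mean
    male_mult[sex_idx] = np.where(
        np.arange(config.n_sex_genes) % 2 == 0, config.sex_fold, 1.0 / config.sex_fold
    )
    sex_linked[sex_idx] = True

    roles = pd.DataFrame(
        {
            "gene": gene_ids,
            "marker_of": marker_of,
            "disease_target": disease_target,
            "delta": [
                delta[config.cell_type_names.index(dt), i] if dt else 0.0
                for i, dt in enumerate(disease_target)
            ],
            "sex_linked": sex_linked,
        }
    )
    return _GeneArchitecture(gene_ids, baseline, type_mult, delta, male_mult, roles)


def _draw_proportions(
    config: SimulationConfig, burden: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample cell-type proportions given fibrosis burdens (0 = healthy)."""
    n_types = len(config.cell_type_names)
    base = np.asarray(config.base_proportions[: n_types - 1], dtype=float)
    base = base / base.sum()
    mean_burden = np.mean(config.burden_range)
    props = np.zeros((len(burden), n_types))
    for i, b in enumerate(burden):
        alpha = base.copy()
        alpha[0] *= max(1.0 - config.at2_depletion * b, 0.05)  # AT2-like depletion
        alpha = alpha / alpha.sum() * config.dirichlet_concentration
        q = rng.dirichlet(alpha)
        if b > 0 and config.disease_state_proportion > 0:
            m = np.clip(config.disease_state_proportion * b / mean_burden, 1e-4, 0.5)
            c = 150.0
            p_d = rng.beta(m * c, (1 - m) * c)
        else:
            p_d = 0.0
        props[i, : n_types - 1] = q * (1 - p_d)
        props[i, n_types - 1] = p_d
    return props


def _make_sample_frame(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    k = 0
    for c in range(config.n_cohorts):
        for status in ("control", "ILD"):
            for _ in range(config.samples_per_cohort_per_arm):
                rows.append(
                    {
                        "sample_id": f"S{k:03d}",
                        "cohort_id": f"cohort{c}",
                        "disease_status": status,
                        "gender": "F" if k % 2 == 0 else "M",
                        "age": float(rng.integers(40, 76)),
                    }
                )
                k += 1
    return pd.DataFrame(rows)


def _simulate_counts(
    arch: _GeneArchitecture,
    samples: pd.DataFrame,
    burden: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw NB counts sample by sample and plant the detection shifts."""
    n_types = len(config.cell_type_names)
    r = config.nb_dispersion
    props = _draw_proportions(config, burden, rng)
    blocks, metas = [], []
    for i, row in samples.reset_index(drop=True).iterrows():
        n_cells = int(rng.integers(config.cells_per_sample[0], config.cells_per_sample[1] + 1))
        type_idx = rng.choice(n_types, size=n_cells, p=props[i])
        lib = rng.lognormal(-config.library_log_sd**2 / 2, config.library_log_sd, n_cells)
        depth = config.cohort_depth[int(row["cohort_id"].removeprefix("cohort"))]
        gene_mult = arch.baseline * (arch.male_mult if row["gender"] == "M" else 1.0)
        mu = (lib[:, None] * depth) * (gene_mult[None, :] * arch.type_mult[type_idx, :])
        lam = rng.gamma(r, mu / r)
        counts = rng.poisson(lam)
        if row["disease_status"] == "ILD":
            for t in range(n_types):
                genes = np.flatnonzero(arch.delta[t] != 0)
                if genes.size == 0:
                    continue
                cells = np.flatnonzero(type_idx == t)
                if cells.size == 0:
                    continue
                sub_mu = mu[np.ix_(cells, genes)]
                p0 = nb_detection_probability(sub_mu, r)
                p1 = np.clip(p0 + arch.delta[t][genes][None, :], 0.005, 0.995)
                u = rng.random(sub_mu.shape)
                sub = counts[np.ix_(cells, genes)]
                up = (p1 > p0) & (sub == 0) & (u < (p1 - p0) / np.maximum(1 - p0, 1e-12))
                down = (p1 < p0) & (sub > 0) & (u < (p0 - p1) / np.maximum(p0, 1e-12))
                sub[up] = 1
                sub[down] = 0
                counts[np.ix_(cells, genes)] = sub
        blocks.append(sp.csr_matrix(counts))
        metas.append(
            pd.DataFrame(
                {
                    "sample_id": row["sample_id"],
                    "cohort_id": row["cohort_id"],
                    "disease_status": row["disease_status"],
                    "cell_type": np.asarray(config.cell_type_names, dtype=object)[type_idx],
                }
            )
        )
    counts_all = sp.vstack(blocks, format="csr")
    cell_meta = pd.concat(metas, ignore_index=True)
    cell_ids = np.array([f"cell{i:06d}" for i in range(counts_all.shape[0])], dtype=object)
    cm = CountMatrix(counts_all, cell_ids, arch.gene_ids, cell_meta)
    cm.recompute_derived()
    prop_df = pd.DataFrame(
        props, index=samples["sample_id"].to_numpy(), columns=list(config.cell_type_names)
    )
    return cm, prop_df


def simulate_cohorts(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Generate the full multi-cohort single-cell dataset.

    Returns the cell × gene :class:`CountMatrix`, the per-sample covariate
    table, and a :class:`GroundTruth` with planted gene roles, per-sample
    fibrosis burdens and true cell-type proportions.
    """
    config = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    arch = _build_gene_architecture(config, rng)
    samples = _make_sample_frame(config, rng)
    burden = np.where(
        samples["disease_status"].to_numpy() == "ILD",
        rng.uniform(*config.burden_range, size=len(samples)),
        0.0,
    )
    cm, prop_df = _simulate_counts(arch, samples, burden, config, rng)
    per_sample = cm.cell_meta.groupby("sample_id")
    samples = samples.merge(
        per_sample.agg(n_cells=("sample_id", "size"), total_umi=("total_umi", "sum")),
        left_on="sample_id",
        right_index=True,
        how="left",
    )
    samples["n_cells"] = samples["n_cells"].fillna(0).astype(int)
    samples["total_umi"] = samples["total_umi"].fillna(0).astype(int)
    validate_sample_table(samples)
    sample_truth = samples[["sample_id", "disease_status"]].copy()
    sample_truth["burden"] = burden
    truth = GroundTruth(
        gene_roles=arch.roles,
        sample_truth=sample_truth,
        true_proportions=prop_df,
        config=config,
    )
    return cm, samples, truth


def simulate_proportions(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    n_per_arm: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Draw per-sample cell-type proportions only (no counts).

    Returns (proportions samples × types, disease labels, fibrosis burdens).
    With ``disease_state_proportion = 0`` and ``at2_depletion = 0`` the two
    arms are exchangeable.
    """
    config = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = n_per_arm or config.n_cohorts * config.samples_per_cohort_per_arm
    labels = pd.Series(
        ["control"] * n + ["ILD"] * n,
        index=[f"S{i:03d}" for i in range(2 * n)],
        name="disease_status",
    )
    burden = np.concatenate(
        [np.zeros(n), rng.uniform(*config.burden_range, size=n)]
    )
    props = _draw_proportions(config, burden, rng)
    prop_df = pd.DataFrame(props, index=labels.index, columns=list(config.cell_type_names))
    return prop_df, labels, pd.Series(burden, index=labels.index, name="burden")


def expression_profiles(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Per-cell-type mean expression profiles (genes × cell types).

    Deterministically reproduces the gene architecture drawn by
    :func:`simulate_cohorts` for the same (config, seed).
    """
    config = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    arch = _build_gene_architecture(config, rng)
    prof = arch.baseline[None, :] * arch.type_mult
    return pd.DataFrame(prof.T, index=arch.gene_ids, columns=list(config.cell_type_names))


def simulate_bulk_mixture(
    profiles: pd.DataFrame,
    proportions: pd.DataFrame,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Proportion-weighted bulk mixtures: genes × samples.

    ``bulk[:, s] = profiles @ proportions[s]`` with multiplicative lognormal
    noise — the idealized bulk a deconvolution stage should unmix.
    """
    rng = np.random.default_rng(seed)
    mix = profiles.to_numpy() @ proportions.to_numpy().T
    noise = rng.lognormal(-noise_sd**2 / 2, noise_sd, mix.shape)
    return pd.DataFrame(mix * noise, index=profiles.index, columns=proportions.index)


def simulate_staged_cohort(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    stage_burdens: tuple[float, ...] = (0.25, 0.55, 0.85),
    samples_per_stage: int = 4,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Single-cohort dataset with fibrosis burden increasing over stages.

    Emulates bulk samples from histopathological stages of increasing
    fibrotic remodeling; the sample table carries a ``stage`` column.
    """
    config = (config or SimulationConfig()).validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    arch = _build_gene_architecture(config, rng)
    rows = []
    burden = []
    k = 0
    for s, b in enumerate(stage_burdens, start=1):
        for _ in range(samples_per_stage):
            rows.append(
                {
                    "sample_id": f"T{k:03d}",
                    "cohort_id": "cohort0",
                    "disease_status": "ILD",
                    "gender": "F" if k % 2 == 0 else "M",
                    "age": float(rng.integers(40, 76)),
                    "stage": s,
                }
            )
            burden.append(b)
            k += 1
    samples = pd.DataFrame(rows)
    cm, prop_df = _simulate_counts(arch, samples, np.asarray(burden), config, rng)
    sample_truth = samples[["sample_id", "stage"]].copy()
    sample_truth["burden"] = burden
    truth = GroundTruth(
        gene_roles=arch.roles,
        sample_truth=sample_truth,
        true_proportions=prop_df,
        config=config,
    )
    return cm, samples, truth


def _lung_function(
    config: SimulationConfig, burden: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    cols = {}
    for name, a, b, s in zip(
        config.lungfn_columns,
        config.lungfn_intercepts,
        config.lungfn_slopes,
        config.lungfn_noise_sd,
    ):
        cols[name] = a - b * burden + rng.normal(0, s, len(burden))
    return pd.DataFrame(cols)


def simulate_balf_proteome(
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[ProteinTable, pd.DataFrame, GroundTruth]:
    """Body-fluid proteome + clinical table linked to an existing cohort.

    Mapped proteins carry the id of a marker gene of their source cell type
    (so the protein and transcriptome vocabularies overlap) and their log2
    intensity is ``α + β·z(proportion of source type) + γ·δ·burden + ε``.
    Dropout probability falls logistically with intensity (MNAR).  Lung
    function declines linearly in fibrosis burden.
    """
    config = (config or truth.config).validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    samples = truth.sample_truth["sample_id"].to_numpy()
    burden = truth.sample_truth["burden"].to_numpy(dtype=float)
    props = truth.true_proportions.loc[samples]
    roles = truth.gene_roles

    n_mapped = int(round(config.n_proteins * config.mapped_fraction))
    mappable = roles[roles["marker_of"] != ""][["gene", "marker_of", "delta"]]
    mappable = mappable.iloc[np.arange(min(n_mapped, len(mappable)))]
    records = []
    intens = np.empty((config.n_proteins, len(samples)))
    alphas = rng.normal(config.protein_alpha_mean, config.protein_alpha_sd, config.n_proteins)
    mean_burden = np.mean(config.burden_range)
    for p in range(config.n_proteins):
        if p < len(mappable):
            gene, src, delta = mappable.iloc[p]
            pr = props[src].to_numpy(dtype=float)
            z = (pr - pr.mean()) / max(pr.std(), 1e-12)
            signal = config.protein_beta * z
            signal = signal + config.protein_gamma * delta * burden / mean_burden
            pid = str(gene)
        else:
            signal = np.zeros(len(samples))
            src, pid = "", f"PROT{p:04d}"
        intens[p] = alphas[p] + signal + rng.normal(0, config.protein_noise_sd, len(samples))
        records.append({"protein": pid, "source_type": src})
    protein_ids = [r["protein"] for r in records]

    # MNAR dropout: 50% at the low-intensity midpoint quantile, →0 at high intensity
    mid = np.quantile(intens, config.missing_midpoint_quantile)
    p_missing = 1.0 / (1.0 + np.exp((intens - mid) / config.missing_steepness))
    observed = rng.random(intens.shape) >= p_missing
    values = np.where(observed, intens, np.nan)
    ptable = ProteinTable(
        intensities=pd.DataFrame(values, index=protein_ids, columns=samples),
        scale_tag="log2",
    ).validate()

    lungfn = _lung_function(config, burden, rng)
    # column-wise MCAR missingness on lung function
    mask = rng.random(lungfn.shape) < config.clinical_missing_rate
    lungfn = lungfn.mask(mask)
    status = truth.sample_truth["disease_status"] if "disease_status" in truth.sample_truth else pd.Series(["ILD"] * len(samples))
    diagnosis = [
        rng.choice(["IPF", "NSIP", "HP", "Sarcoidosis"]) if s == "ILD" else "non-ILD"
        for s in status
    ]
    clinical = pd.DataFrame({"sample_id": samples, "diagnosis": diagnosis})
    clinical["age"] = rng.integers(40, 76, len(samples)).astype(float)
    clinical["gender"] = np.where(np.arange(len(samples)) % 2 == 0, "F", "M")
    clinical = pd.concat([clinical, lungfn], axis=1)
    clinical["pLDH"] = 200.0 + 150.0 * burden + rng.normal(0, 30, len(samples))

    out_truth = replace(
        truth,
        protein_map=pd.DataFrame(records),
        lungfn_latent=pd.Series(burden, index=samples, name="burden"),
    )
    return ptable, clinical, out_truth
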