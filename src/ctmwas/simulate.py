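"""Synthetic neonatal-blood methylation datasets with planted cell-type effects.

The generator emulates the data structure the deconvolution MWAS assumes:
per-sample methylation scores are proportion-weighted mixtures of cell-type
baseline profiles, treatment effects act multiplicatively inside the mixture
(on specific cell types only), measured covariates add linear signal, and
noise is optionally AR(1)-autocorrelated along genomic position so that test
statistics of adjacent CpGs correlate.

For sample i and CpG j::

    m_ij = sum_k p_ik * mu_kj  +  x_i * sum_k p_ik * beta_kj
           + sum_c gamma_cj * z_ic + eps_ij

with cell proportions ``p_i ~ Dirichlet(concentration * means)``, binary
treatment ``x``, standardized covariates ``z`` and ``eps`` of marginal
standard deviation ``noise_sd``.  Planted effects ``beta_kj`` are nonzero on
runs of adjacent CpGs (loci) that share one affected cell type; their size is
calibrated against the realized regression design so the planted partial
correlation matches ``effect_partial_r``.

All randomness flows from integer seeds through a fixed generator-splitting
scheme (``numpy.random.SeedSequence(seed, spawn_key=...)``) with three
scopes: *genome* quantities (CpG positions, baseline profiles, annotation,
gene sets, covariate loadings) derive from ``genome_seed`` so several
studies can share one genome; *study* quantities (planted loci and their
cell types) derive from ``seed``; *sample* quantities (proportions,
covariates, noise) additionally key on ``replicate_id`` so a replication
dataset shares its genome and planted loci with the primary dataset while
drawing independent samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .go import GeneSet, GeneSetCollection

#: The six most common cell types in neonatal blood, in the conventional order.
CELL_TYPES = ("B", "granulocyte", "monocyte", "NK", "Tc", "Th")

#: Mean cell-type proportions of neonatal whole blood (B cells, granulocytes,
#: monocytes, NK cells, cytotoxic T, T-helper).
DIRICHLET_MEANS = (0.08, 0.39, 0.18, 0.05, 0.15, 0.15)

# spawn_key channels of the generator-splitting scheme
_CH_BASELINE = 0       # genome scope
_CH_POSITIONS = 1      # genome scope
_CH_PROPORTIONS = 2    # sample scope
_CH_COVARIATES = 3     # sample scope
_CH_NOISE = 4          # sample scope
_CH_LOCI = 5           # study scope
_CH_ANNOTATION = 6     # genome scope
_CH_GENESETS = 7       # genome scope
_CH_LOADINGS = 8       # genome scope


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class CovariateSpec:
    """Distributions of the sample-level covariates.

    Gestational age is in days; batches are labelled ``batch1..batchN``.
    Assay covariates (enrichment efficiency, percent reads aligned) mimic
    sequencing-level nuisance variables.
    """

    sex_prevalence: float = 0.5
    gestational_age_mean: float = 277.0
    gestational_age_sd: float = 15.0
    birth_year_range: tuple[int, int] = (1975, 1989)
    n_batches: int = 3
    enrichment_efficiency_mean: float = 0.70
    enrichment_efficiency_sd: float = 0.05
    pct_aligned_mean: float = 95.0
    pct_aligned_sd: float = 2.0


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic study.

    Defaults reproduce the primary laughing-gas design: 35 treated vs 77
    untreated newborns, six blood cell types with Dirichlet proportions whose
    means and spread match neonatal whole blood (concentration 35 gives
    per-type SDs of roughly 0.03-0.08).
    """

    n_treated: int = 35
    n_untreated: int = 77
    n_cpgs: int = 20_000
    n_chromosomes: int = 22
    cell_types: tuple[str, ...] = CELL_TYPES
    dirichlet_means: tuple[float, ...] = DIRICHLET_MEANS
    dirichlet_concentration: float = 35.0
    n_signal_loci: int = 0
    locus_size_range: tuple[int, int] = (2, 10)
    effect_partial_r: float = 0.5
    signal_cell_types: tuple[str, ...] | None = None
    noise_sd: float = 1.0
    ar1_phi: float = 0.3
    covariate_effect_sd: float = 0.3
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    chromosome_length: int = 2_000_000
    seed: int = 0
    #: seed of genome-scope quantities; defaults to ``seed``.  Give two
    #: studies the same genome_seed (and different seeds) to share CpG
    #: positions and baselines while planting different loci.
    genome_seed: int | None = None
    #: distinguishes independent sample draws (e.g. primary vs replication)
    #: of the same study; loci and genome are unaffected.
    replicate_id: int = 0

    def __post_init__(self) -> None:
        means = np.asarray(self.dirichlet_means, dtype=float)
        if len(means) != len(self.cell_types):
            raise ConfigurationError(
                f"dirichlet_means has {len(means)} entries for "
                f"{len(self.cell_types)} cell types"
            )
        if abs(means.sum() - 1.0) > 1e-9 or (means <= 0).any():
            raise ConfigurationError("dirichlet_means must be a positive simplex vector")
        for name, val in [
            ("n_treated", self.n_treated),
            ("n_untreated", self.n_untreated),
            ("n_cpgs", self.n_cpgs),
            ("n_chromosomes", self.n_chromosomes),
        ]:
            if val <= 0:
                raise ConfigurationError(f"{name} must be positive, got {val}")
        if not -1.0 < self.effect_partial_r < 1.0:
            raise ConfigurationError(
                f"effect_partial_r must be in (-1, 1), got {self.effect_partial_r}"
            )
        lo, hi = self.locus_size_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("locus_size_range must satisfy 1 <= min <= max")
        if self.n_signal_loci * hi > self.n_cpgs:
            raise ConfigurationError(
                "n_signal_loci * max locus size exceeds n_cpgs"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.signal_cell_types is not None:
            unknown = set(self.signal_cell_types) - set(self.cell_types)
            if unknown:
                raise ConfigurationError(f"unknown signal cell types: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return self.n_treated + self.n_untreated

    def rng(self, channel: int, scope: str = "study") -> np.random.Generator:
        """Child generator for one named component of the simulation."""
        if scope == "genome":
            root = self.seed if self.genome_seed is None else self.genome_seed
            key: tuple[int, ...] = (channel,)
        elif scope == "study":
            root, key = self.seed, (channel,)
        elif scope == "sample":
            root, key = self.seed, (channel, self.replicate_id)
        else:
            raise ValueError(f"unknown scope {scope!r}")
        return np.random.default_rng(np.random.SeedSequence(root, spawn_key=key))


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset, for parameter-recovery checks."""

    #: cell type -> list of (chrom, pos) carrying a planted effect
    planted_cpg_keys: dict[str, list[tuple[str, int]]]
    #: (chrom, pos, cell_type) -> planted coefficient
    planted_effects: dict[tuple[str, int, str], float]
    #: baseline mean-methylation profiles, (chrom, pos) x cell type
    baseline_profiles: pd.DataFrame

    def planted_keys_all(self) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for keys in self.planted_cpg_keys.values():
            out.update(keys)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "pos": p, "cell_type": k, "beta": b}
            for (c, p, k), b in sorted(self.planted_effects.items())
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "cell_type", "beta"])


# ---------------------------------------------------------------------------
# deterministic sub-components (shared between operations)
# ---------------------------------------------------------------------------

def _cpg_positions(config: SimulationConfig) -> pd.MultiIndex:
    """Sorted 1-based CpG coordinates, near-equal split over chromosomes.

    Positions are strictly increasing with at least 2 bp spacing.
    """
    rng = config.rng(_CH_POSITIONS, "genome")
    counts = np.full(config.n_chromosomes, config.n_cpgs // config.n_chromosomes)
    counts[: config.n_cpgs % config.n_chromosomes] += 1
    chroms: list[str] = []
    positions: list[int] = []
    for c, n_c in enumerate(counts, start=1):
        if n_c == 0:
            continue
        span = config.chromosome_length - 2 * n_c
        if span < n_c:
            raise ConfigurationError("chromosome_length too small for n_cpgs")
        base = np.sort(rng.choice(span, size=n_c, replace=False)) + 1
        pos = base + 2 * np.arange(n_c)
        chroms.extend([str(c)] * n_c)
        positions.extend(pos.tolist())
    return pd.MultiIndex.from_arrays(
        [np.array(chroms), np.array(positions, dtype=np.int64)], names=["chrom", "pos"]
    )


def _baseline_profiles(config: SimulationConfig, index: pd.MultiIndex) -> pd.DataFrame:
    """Cell-type baseline means: shared per-CpG level plus per-type deviation."""
    rng = config.rng(_CH_BASELINE, "genome")
    j = len(index)
    k = len(config.cell_types)
    base = rng.normal(0.0, 1.0, size=j)
    dev = rng.normal(0.0, 0.5, size=(j, k))
    mu = base[:, None] + dev
    return pd.DataFrame(mu, index=index, columns=list(config.cell_types))


def _plant_loci(
    config: SimulationConfig, index: pd.MultiIndex
) -> list[tuple[np.ndarray, str]]:
    """Choose non-overlapping runs of adjacent CpGs and one affected cell type each.

    Returns (global row indices of the locus, cell type) per locus.  Runs never
    cross a chromosome boundary.
    """
    if config.n_signal_loci == 0:
        return []
    rng = config.rng(_CH_LOCI)
    signal_types = config.signal_cell_types or config.cell_types
    chrom_codes = index.get_level_values("chrom").to_numpy()
    used = np.zeros(len(index), dtype=bool)
    loci: list[tuple[np.ndarray, str]] = []
    lo, hi = config.locus_size_range
    max_tries = 200 * config.n_signal_loci + 1000
    tries = 0
    while len(loci) < config.n_signal_loci:
        tries += 1
        if tries > max_tries:
            raise ConfigurationError(
                "could not place the requested signal loci without overlap"
            )
        size = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(index) - size + 1))
        rows = np.arange(start, start + size)
        if used[rows].any():
            continue
        if chrom_codes[rows[0]] != chrom_codes[rows[-1]]:
            continue
        used[rows] = True
        cell = str(rng.choice(signal_types))
        loci.append((rows, cell))
    return loci


def _simulate_metadata(config: SimulationConfig) -> pd.DataFrame:
    rng = config.rng(_CH_COVARIATES, "sample")
    cov = config.covariates
    n = config.n_samples
    x = np.concatenate(
        [np.ones(config.n_treated, dtype=int), np.zeros(config.n_untreated, dtype=int)]
    )
    meta = pd.DataFrame(
        {
            "treatment": x,
            "sex": rng.binomial(1, cov.sex_prevalence, size=n),
            "birth_year": rng.integers(
                cov.birth_year_range[0], cov.birth_year_range[1] + 1, size=n
            ),
            "gestational_age": np.round(
                rng.normal(cov.gestational_age_mean, cov.gestational_age_sd, size=n)
            ).astype(int),
            "batch": [f"batch{1 + i % cov.n_batches}" for i in rng.permutation(n)],
            "enrichment_efficiency": rng.normal(
                cov.enrichment_efficiency_mean, cov.enrichment_efficiency_sd, size=n
            ),
            "pct_aligned": rng.normal(cov.pct_aligned_mean, cov.pct_aligned_sd, size=n),
        },
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id"),
    )
    return meta


def _covariate_design_numeric(meta: pd.DataFrame) -> np.ndarray:
    """Standardized numeric covariate columns (batch dummy-coded, first level ref)."""
    from .mwas import build_covariate_design

    z = build_covariate_design(meta)
    return z.to_numpy()


def _calibrate_beta(
    design: np.ndarray, interaction_col: int, target_r: float, noise_sd: float
) -> float:
    """Coefficient whose expected partial correlation in `design` is `target_r`.

    With t = beta / SE(beta_hat) and r = t / sqrt(t^2 + df), the target t is
    r * sqrt(df / (1 - r^2)); SE(beta_hat) = noise_sd * sqrt([(X'X)^-1]_kk).
    """
    if target_r == 0.0:
        return 0.0
    n, p = design.shape
    df = n - np.linalg.matrix_rank(design)
    t_target = target_r * np.sqrt(df / (1.0 - target_r**2))
    xtx_inv = np.linalg.pinv(design.T @ design)
    se_unit = noise_sd * np.sqrt(xtx_inv[interaction_col, interaction_col])
    return float(t_target * se_unit)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate one study: methylation scores, metadata, true proportions, truth.

    Returns
    -------
    meth : DataFrame, (chrom, pos) x sample_id
        Continuous CpG methylation scores.
    metadata : DataFrame, sample_id x covariates
        Treatment 0/1, sex, birth year, gestational age (days), batch and
        assay covariates.
    proportions : DataFrame, sample_id x cell type
        The true (generating) cell proportions; rows on the simplex.
    truth : SimulationTruth
        Planted keys, coefficients and baseline profiles.
    """
    index = _cpg_positions(config)
    mu = _baseline_profiles(config, index)
    meta = _simulate_metadata(config)
    n, j, k = config.n_samples, config.n_cpgs, len(config.cell_types)

    rng_p = config.rng(_CH_PROPORTIONS, "sample")
    alpha = config.dirichlet_concentration * np.asarray(config.dirichlet_means)
    props = rng_p.dirichlet(alpha, size=n)
    proportions = pd.DataFrame(
        props, index=meta.index, columns=list(config.cell_types)
    )

    # planted cell-type x treatment effects, calibrated on the realized design
    loci = _plant_loci(config, index)
    beta = np.zeros((k, j))
    planted_keys: dict[str, list[tuple[str, int]]] = {c: [] for c in config.cell_types}
    planted_effects: dict[tuple[str, int, str], float] = {}
    if loci:
        x = meta["treatment"].to_numpy(float)
        z = _covariate_design_numeric(meta)
        design = np.column_stack([props, props * x[:, None], z])
        for rows, cell in loci:
            ki = config.cell_types.index(cell)
            b = _calibrate_beta(design, k + ki, config.effect_partial_r, config.noise_sd)
            for r_idx in rows:
                key = index[r_idx]
                beta[ki, r_idx] = b
                planted_keys[cell].append((key[0], int(key[1])))
                planted_effects[(key[0], int(key[1]), cell)] = b

    rng_e = config.rng(_CH_NOISE, "sample")
    eps = rng_e.normal(0.0, 1.0, size=(n, j))
    if config.ar1_phi:
        # AR(1) along position within each chromosome; marginal SD kept at 1
        phi = config.ar1_phi
        chrom_codes = index.get_level_values("chrom").to_numpy()
        starts = np.flatnonzero(np.r_[True, chrom_codes[1:] != chrom_codes[:-1]])
        scale = np.sqrt(1.0 - phi**2)
        out = np.empty_like(eps)
        bounds = np.r_[starts, j]
        for s, e in zip(bounds[:-1], bounds[1:]):
            out[:, s] = eps[:, s]
            for jj in range(s + 1, e):
                out[:, jj] = phi * out[:, jj - 1] + scale * eps[:, jj]
        eps = out
    eps *= config.noise_sd

    x = meta["treatment"].to_numpy(float)
    z = _covariate_design_numeric(meta)
    rng_g = config.rng(_CH_LOADINGS, "genome")  # per-CpG covariate loadings
    gamma = rng_g.normal(0.0, config.covariate_effect_sd, size=(z.shape[1], j))
    m = (
        props @ mu.to_numpy().T
        + (props * x[:, None]) @ beta
        + z @ gamma
        + eps
    )
    meth = pd.DataFrame(m.T, index=index, columns=meta.index)

    truth = SimulationTruth(
        planted_cpg_keys=planted_keys,
        planted_effects=planted_effects,
        baseline_profiles=mu,
    )
    return meth, meta, proportions, truth


def simulate_reference_panel(
    config: SimulationConfig, n_marker_cpgs_per_type: int = 50
) -> pd.DataFrame:
    """Reference panel of cell-type methylation profiles at marker CpGs.

    For each cell type the ``n_marker_cpgs_per_type`` CpGs with the largest
    contrast between that type and the closest other type are selected from
    the same baseline profiles that generate the mixtures, so panel keys are a
    subset of the dataset's CpG keys.  Rows are (chrom, pos), columns the cell
    types of ``config``.
    """
    if n_marker_cpgs_per_type < 1:
        raise ConfigurationError("need at least one marker CpG per cell type")
    index = _cpg_positions(config)
    mu = _baseline_profiles(config, index).to_numpy()
    k = len(config.cell_types)
    if n_marker_cpgs_per_type * k > len(index):
        raise ConfigurationError("not enough CpGs for the requested marker count")
    used = np.zeros(len(index), dtype=bool)
    chosen: list[np.ndarray] = []
    for ki in range(k):
        others = np.delete(mu, ki, axis=1)
        contrast = np.abs(mu[:, ki] - others[np.arange(len(mu)), np.abs(others - mu[:, [ki]]).argmin(axis=1)])
        # distance to the nearest other cell type: large => informative marker
        order = np.argsort(-contrast)
        picked = [i for i in order if not used[i]][:n_marker_cpgs_per_type]
        used[picked] = True
        chosen.append(np.asarray(picked))
    rows = np.sort(np.concatenate(chosen))
    panel = pd.DataFrame(
        mu[rows], index=index[rows], columns=list(config.cell_types)
    )
    return panel


def simulate_annotation_and_genesets(
    config: SimulationConfig,
    n_genes: int = 200,
    genes_per_term: tuple[int, int] = (5, 30),
    n_terms: int = 20,
    frac_loci_in_genes: float = 0.8,
    disjoint_terms: bool = False,
) -> tuple[pd.DataFrame, GeneSetCollection]:
    """Gene annotation and a GMT-style term collection over the simulated genome.

    A fraction ``frac_loci_in_genes`` of the planted signal loci is covered by
    a gene body, so CpG-to-gene linking downstream recovers them; remaining
    genes are placed uniformly without overlap (the fixture convention).
    Coordinates are 1-based inclusive; strands are random and define the TSS
    (start on '+', end on '-').
    """
    if not 0.0 <= frac_loci_in_genes <= 1.0:
        raise ConfigurationError("frac_loci_in_genes must be in [0, 1]")
    index = _cpg_positions(config)
    loci = _plant_loci(config, index)
    rng = config.rng(_CH_ANNOTATION, "genome")
    chrom_names = [str(c) for c in range(1, config.n_chromosomes + 1)]
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    records: list[dict] = []

    def _free(chrom: str, start: int, end: int) -> bool:
        return all(e < start or s > end for s, e in occupied[chrom])

    def _add_gene(chrom: str, start: int, end: int) -> None:
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{len(records):04d}"
        occupied[chrom].append((start, end))
        records.append(
            {"gene_id": gid, "chrom": chrom, "start": start, "end": end, "strand": strand}
        )

    # genes covering planted loci
    n_covered = int(round(frac_loci_in_genes * len(loci)))
    for rows, _cell in loci[:n_covered]:
        chrom = index[rows[0]][0]
        lo = int(index[rows[0]][1])
        hi = int(index[rows[-1]][1])
        start = max(1, lo - int(rng.integers(100, 2000)))
        end = min(config.chromosome_length, hi + int(rng.integers(100, 2000)))
        if _free(chrom, start, end):
            _add_gene(chrom, start, end)

    # remaining genes at random free positions
    tries = 0
    while len(records) < n_genes:
        tries += 1
        if tries > 200 * n_genes:
            raise ConfigurationError("could not place n_genes without overlap")
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        length = int(rng.integers(2_000, 20_001))
        start = int(rng.integers(1, config.chromosome_length - length))
        end = start + length
        if _free(chrom, start, end):
            _add_gene(chrom, start, end)

    annotation = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "strand"])
    annotation = annotation.sort_values(["chrom", "start"], key=_natural_sort_key).reset_index(drop=True)

    # gene sets
    rng_t = config.rng(_CH_GENESETS, "genome")
    gene_ids = annotation["gene_id"].tolist()
    lo, hi = genes_per_term
    if disjoint_terms and n_terms * hi > len(gene_ids):
        raise ConfigurationError("not enough genes for disjoint terms")
    categories = ("biological_process", "molecular_function", "cellular_component")
    pool = list(gene_ids)
    terms: list[GeneSet] = []
    for t in range(n_terms):
        size = int(rng_t.integers(lo, hi + 1))
        if disjoint_terms:
            members = [pool.pop(int(rng_t.integers(0, len(pool)))) for _ in range(size)]
        else:
            members = list(rng_t.choice(gene_ids, size=size, replace=False))
        terms.append(
            GeneSet(
                term_id=f"T{t:04d}",
                name=f"synthetic term {t}",
                category=categories[t % len(categories)],
                genes=tuple(sorted(members)),
            )
        )
    return annotation, GeneSetCollection(terms)


def _natural_sort_key(col: pd.Series) -> pd.Series:
    if col.name == "chrom":
        return col.map(lambda c: (0, int(c)) if str(c).isdigit() else (1, str(c)))
    return col
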