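"""Readers, writers, pipeline configuration and orchestration.

All tables travel as TSV; gene annotation as BED6 (0-based half-open on
disk, 1-based inclusive in memory) or GFF3; gene sets as GMT.  Internal
genomic coordinates are always 1-based inclusive; the chromosome order used
for circular permutation is the natural order 1..22, X, Y unless configured
otherwise.  ``run_pipeline`` orchestrates the full analysis — proportions,
MWAS, replication, cross-treatment overlap, GO — and writes a manifest
(effective config, seed, versions, output checksums) sufficient to
reproduce every table bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import (
    DEFAULT_CHROM_ORDER,
    chromosome_sort_key,
    circular_permutation_enrichment,
    cross_treatment_overlap,
    lookup_replication,
    results_to_frame,
)
from .go import (
    GeneSet,
    GeneSetCollection,
    assign_defining_genes,
    cluster_terms,
    filter_significant_terms,
    go_term_enrichment,
    select_go_input,
)
from .mwas import (
    build_covariate_design,
    residualize_covariates,
    run_bulk_mwas,
    run_celltype_mwas,
    select_principal_components,
)
from .proportions import estimate_proportions
from .simulate import (
    SimulationConfig,
    simulate_annotation_and_genesets,
    simulate_dataset,
    simulate_reference_panel,
)

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Raised when input files are malformed or inconsistent."""


# ---------------------------------------------------------------------------
# matrix-shaped tables keyed by (chrom, pos)
# ---------------------------------------------------------------------------

def write_methylation(meth: pd.DataFrame, path: str | Path) -> None:
    out = meth.reset_index()
    out.to_csv(path, sep="\t", index=False)


def read_methylation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "chrom" not in df.columns or "pos" not in df.columns:
        raise InputError(f"{path}: expected 'chrom' and 'pos' columns")
    df = df.set_index(["chrom", "pos"])
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()[:5]
        raise InputError(f"{path}: duplicate CpG keys, e.g. {dups}")
    return df


write_panel = write_methylation
read_panel = read_methylation


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=True)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.duplicated().any():
        raise InputError(f"{path}: duplicate sample IDs")
    return meta


write_proportions = write_metadata
read_proportions = read_metadata


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str}, keep_default_na=True
    )
    if "reason_code" in df.columns:
        df["reason_code"] = df["reason_code"].fillna("")
    return df


def write_results_bed(results: pd.DataFrame, path: str | Path) -> None:
    """Export result rows as BED6 (0-based half-open) for genome browsers."""
    bed = pd.DataFrame(
        {
            "chrom": results["chrom"],
            "start": results["pos"].astype(int) - 1,
            "end": results["pos"].astype(int),
            "name": results["analysis_unit"],
            "score": np.minimum(
                1000, np.nan_to_num(-10 * np.log10(results["p"].astype(float)), nan=0)
            ).astype(int),
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# gene annotation: BED6 and GFF3
# ---------------------------------------------------------------------------

def write_annotation_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write gene annotation as BED6; internal 1-based inclusive -> 0-based half-open."""
    bed = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["start"].astype(int) - 1,
            "end": annotation["end"].astype(int),
            "name": annotation["gene_id"],
            "score": 0,
            "strand": annotation["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_annotation_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int) + 1,  # back to 1-based inclusive
            "end": bed["end"].astype(int),
            "strand": bed["strand"],
        }
    )


def read_annotation_gff3(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    names = [
        "chrom", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
    ]
    gff = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=names, dtype={"chrom": str}
    )
    gff = gff[gff["type"] == feature]

    def _gene_id(attrs: str) -> str:
        for part in str(attrs).split(";"):
            k, _, v = part.strip().partition("=")
            if k in ("ID", "gene_id", "Name"):
                return v
        raise InputError(f"GFF3 attribute lacks ID/gene_id: {attrs!r}")

    return pd.DataFrame(
        {
            "gene_id": gff["attributes"].map(_gene_id),
            "chrom": gff["chrom"],
            "start": gff["start"].astype(int),  # GFF3 is already 1-based inclusive
            "end": gff["end"].astype(int),
            "strand": gff["strand"],
        }
    ).reset_index(drop=True)


def read_annotation(path: str | Path) -> pd.DataFrame:
    p = Path(path)
    if p.suffix.lower() in (".gff", ".gff3"):
        return read_annotation_gff3(p)
    return read_annotation_bed(p)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Standard GMT lines: term id, description ('name|category'), genes."""
    with open(path, "w") as fh:
        for t in collection:
            desc = f"{t.name}|{t.category}"
            fh.write("\t".join([t.term_id, desc, *t.genes]) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    terms: list[GeneSet] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{line_no}: GMT line needs >= 3 fields")
            term_id, desc, *genes = parts
            name, _, category = desc.partition("|")
            terms.append(
                GeneSet(
                    term_id=term_id,
                    name=name,
                    category=category or "biological_process",
                    genes=tuple(genes),
                )
            )
    return GeneSetCollection(terms)


def write_truth(truth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Effective settings of one pipeline run; defaults are the study's.

    File paths may be left unset, in which case the pipeline simulates its
    inputs from ``simulation`` (two treatments on a shared genome, each with
    a primary and a replication dataset).
    """

    output_dir: str = "ctmwas_output"
    methylation: str | None = None
    metadata: str | None = None
    methylation_replication: str | None = None
    metadata_replication: str | None = None
    panel: str | None = None
    annotation: str | None = None
    gmt: str | None = None

    q_significant: float = 0.1
    p_suggestive: float = 1e-6
    p_nominal: float = 0.05
    go_p: float = 0.05
    go_min_overlap: int = 3
    upstream_bp: int = 10_000
    n_permutations: int = 10_000
    n_pcs: int = 2
    #: simulation mode: marker CpGs per cell type in the generated reference
    #: panel.  Proportion-estimation error scales like 1/sqrt(panel size) and
    #: attenuates the interaction tests (errors-in-variables), so the panel
    #: is kept large relative to the simulated genome.
    panel_markers_per_type: int = 500
    seed: int = 0
    chrom_order: tuple[str, ...] = DEFAULT_CHROM_ORDER
    analysis_units: tuple[str, ...] | None = None
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("q_significant", "p_suggestive", "p_nominal", "go_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InputError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "chrom_order" in raw:
            raw["chrom_order"] = tuple(str(c) for c in raw["chrom_order"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["chrom_order"] = list(self.chrom_order)
        if self.analysis_units is not None:
            d["analysis_units"] = list(self.analysis_units)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class InputBundle:
    """Validated, mutually aligned inputs of one treatment contrast."""

    meth: pd.DataFrame
    metadata: pd.DataFrame
    panel: pd.DataFrame | None
    annotation: pd.DataFrame | None
    collection: GeneSetCollection | None
    meth_replication: pd.DataFrame | None = None
    metadata_replication: pd.DataFrame | None = None


def _check_alignment(meth: pd.DataFrame, meta: pd.DataFrame, label: str) -> None:
    missing = [s for s in meth.columns if s not in meta.index]
    extra = [s for s in meta.index if s not in meth.columns]
    if missing or extra:
        raise InputError(
            f"{label}: sample IDs misaligned; missing from metadata: {missing[:5]}, "
            f"absent from matrix: {extra[:5]}"
        )


def load_inputs(config: PipelineConfig) -> InputBundle:
    """Load and cross-validate all configured input files."""
    if config.methylation is None or config.metadata is None:
        raise InputError("methylation and metadata paths are required to load inputs")
    meth = read_methylation(config.methylation)
    meta = read_metadata(config.metadata)
    _check_alignment(meth, meta, "primary")
    if "treatment" not in meta.columns or meta["treatment"].isna().any():
        raise InputError("metadata must contain a complete 'treatment' column")
    panel = read_panel(config.panel) if config.panel else None
    annotation = read_annotation(config.annotation) if config.annotation else None
    collection = read_gmt(config.gmt) if config.gmt else None
    meth_rep = meta_rep = None
    if config.methylation_replication and config.metadata_replication:
        meth_rep = read_methylation(config.methylation_replication)
        meta_rep = read_metadata(config.metadata_replication)
        _check_alignment(meth_rep, meta_rep, "replication")
    logger.info(
        "loaded %d samples x %d CpGs; panel=%s, genes=%s, terms=%s",
        meth.shape[1],
        meth.shape[0],
        None if panel is None else panel.shape,
        None if annotation is None else len(annotation),
        None if collection is None else len(collection),
    )
    return InputBundle(meth, meta, panel, annotation, collection, meth_rep, meta_rep)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_mwas_stage(
    meth: pd.DataFrame,
    metadata: pd.DataFrame,
    proportions: pd.DataFrame,
    n_pcs: int,
    q_threshold: float,
    suggestive_threshold: float,
) -> pd.DataFrame:
    """Covariates -> PCs -> bulk + cell-type MWAS, concatenated."""
    z = build_covariate_design(metadata.loc[meth.columns])
    resid = residualize_covariates(meth, z)
    _, pcs = select_principal_components(resid, mode="fixed", n_fixed=n_pcs)
    bulk = run_bulk_mwas(
        meth, metadata, proportions, pcs,
        q_threshold=q_threshold, suggestive_threshold=suggestive_threshold,
    )
    ct = run_celltype_mwas(
        meth, metadata, proportions, pcs,
        q_threshold=q_threshold, suggestive_threshold=suggestive_threshold,
    )
    return pd.concat([bulk, ct], ignore_index=True)


def _simulated_inputs(config: PipelineConfig) -> dict:
    """Two treatments on one shared genome, each with primary + replication."""
    sim_kwargs = dict(config.simulation)
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=2)
    genome_seed = int(rng.integers(0, 2**31 - 1))
    out: dict = {"treatments": {}}
    base = SimulationConfig(
        seed=int(seeds[0]), genome_seed=genome_seed, **sim_kwargs
    )
    k = len(base.cell_types)
    n_markers = max(10, min(config.panel_markers_per_type, base.n_cpgs // (2 * k)))
    panel = simulate_reference_panel(base, n_marker_cpgs_per_type=n_markers)
    annotation, collection = simulate_annotation_and_genesets(base)
    out["panel"] = panel
    out["annotation"] = annotation
    out["collection"] = collection
    for name, s in zip(("treatmentA", "treatmentB"), seeds):
        primary_cfg = dataclasses.replace(base, seed=int(s), replicate_id=0)
        rep_kwargs = {"n_treated": 31, "replicate_id": 1}
        replication_cfg = dataclasses.replace(primary_cfg, **rep_kwargs)
        meth_p, meta_p, props_p, truth = simulate_dataset(primary_cfg)
        meth_r, meta_r, props_r, _ = simulate_dataset(replication_cfg)
        out["treatments"][name] = {
            "primary": (meth_p, meta_p),
            "replication": (meth_r, meta_r),
            "truth": truth,
        }
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis and write all result tables plus a manifest.

    In simulation mode (no input paths) two treatments are generated on a
    shared genome and the complete analysis — proportion estimation, bulk
    and cell-type MWAS for primary and replication datasets, look-up
    replication, circular-permutation replication enrichment,
    cross-treatment overlap, and GO enrichment with term clustering — runs
    for each.  With input paths set, the same stages run on the supplied
    single treatment contrast (cross-treatment overlap is skipped).
    Reruns with the same config and seed produce byte-identical tables.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, rel: str) -> None:
        path = outdir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        write_results(df, path)
        written.append(path)

    if config.methylation is None:
        sim = _simulated_inputs(config)
        panel, annotation, collection = (
            sim["panel"], sim["annotation"], sim["collection"],
        )
        treatments = sim["treatments"]
    else:
        bundle = load_inputs(config)
        if bundle.panel is None:
            raise InputError("a reference panel is required to run the pipeline")
        treatments = {
            "treatment": {
                "primary": (bundle.meth, bundle.metadata),
                "replication": (
                    (bundle.meth_replication, bundle.metadata_replication)
                    if bundle.meth_replication is not None
                    else None
                ),
            }
        }
        panel, annotation, collection = (
            bundle.panel, bundle.annotation, bundle.collection,
        )

    units = list(config.analysis_units) if config.analysis_units else None
    primary_results: dict[str, pd.DataFrame] = {}
    for tname, data in treatments.items():
        try:
            meth_p, meta_p = data["primary"]
            props_p = estimate_proportions(meth_p, panel)
            _write(props_p.reset_index(), f"{tname}/proportions_primary.tsv")
            res_p = run_mwas_stage(
                meth_p, meta_p, props_p, config.n_pcs,
                config.q_significant, config.p_suggestive,
            )
            _write(res_p, f"{tname}/mwas_primary.tsv")
            primary_results[tname] = res_p

            if data.get("replication") is not None:
                meth_r, meta_r = data["replication"]
                props_r = estimate_proportions(meth_r, panel)
                _write(props_r.reset_index(), f"{tname}/proportions_replication.tsv")
                res_r = run_mwas_stage(
                    meth_r, meta_r, props_r, config.n_pcs,
                    config.q_significant, config.p_suggestive,
                )
                _write(res_r, f"{tname}/mwas_replication.tsv")

                lookup = lookup_replication(res_p, res_r, alpha=0.05)
                _write(lookup, f"{tname}/replication_lookup.tsv")

                enr = circular_permutation_enrichment(
                    res_p, res_r,
                    thr_primary=config.p_suggestive,
                    thr_secondary=config.p_nominal,
                    n_permutations=config.n_permutations,
                    seed=config.seed,
                    analysis_units=units,
                    chrom_order=config.chrom_order,
                )
                _write(results_to_frame(enr), f"{tname}/replication_enrichment.tsv")

                if annotation is not None and collection is not None:
                    selected = select_go_input(
                        res_p, res_r, config.p_suggestive, config.p_nominal
                    )
                    universe = sorted(
                        {
                            (str(c), int(p))
                            for c, p in zip(res_p["chrom"], res_p["pos"])
                        },
                        key=lambda k: (
                            chromosome_sort_key(k[0], config.chrom_order), k[1],
                        ),
                    )
                    go_table = go_term_enrichment(
                        selected, universe, annotation, collection,
                        n_permutations=config.n_permutations,
                        seed=config.seed,
                        upstream=config.upstream_bp,
                    )
                    flat = go_table.assign(
                        genes=[";".join(g) for g in go_table["genes"]]
                    )
                    _write(flat, f"{tname}/go_enrichment.tsv")
                    sig = filter_significant_terms(
                        go_table, config.go_p, config.go_min_overlap
                    )
                    if len(sig):
                        tcg = cluster_terms(sig, seed=config.seed)
                        cl = pd.DataFrame(
                            {
                                "term_id": list(tcg.clusters),
                                "cluster": list(tcg.clusters.values()),
                            }
                        )
                        _write(cl, f"{tname}/go_clusters.tsv")
                        _write(
                            assign_defining_genes(tcg),
                            f"{tname}/go_defining_genes.tsv",
                        )
        except Exception as exc:
            raise RuntimeError(f"pipeline failed for {tname}: {exc}") from exc

    if len(primary_results) == 2:
        (na, ra), (nb, rb) = primary_results.items()
        a_to_b, b_to_a = cross_treatment_overlap(
            ra, rb,
            thr=config.p_suggestive,
            n_permutations=config.n_permutations,
            seed=config.seed,
            analysis_units=units,
        )
        frame = pd.concat(
            [
                results_to_frame(a_to_b).assign(direction=f"{na}->{nb}"),
                results_to_frame(b_to_a).assign(direction=f"{nb}->{na}"),
            ],
            ignore_index=True,
        )
        _write(frame, "cross_treatment_overlap.tsv")

    config.to_yaml(outdir / "effective_config.yaml")
    manifest = {
        "package": "ctmwas",
        "version": __version__,
        "seed": config.seed,
        "config": yaml.safe_load((outdir / "effective_config.yaml").read_text()),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(written)
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
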