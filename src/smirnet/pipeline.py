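"""End-to-end orchestration: normalization through target triage.

The full chain mirrors a regulator-discovery study on bulk RNA-seq of
multiple tissues: RPKM + log2 + mixed-model library correction, expression
filtering, per-comparison moderated-t differential expression, RIF scoring
of DE small RNAs, a PCIT co-expression network over the union of DE
transcripts (all samples), hub/centrality annotation, and a per-regulator
triage that narrows negative extreme-correlation mRNA neighbors first by
seed-site presence and then by duplex hybridization energy. Every stage
writes its table under the output directory and the run is reproducible
byte-for-byte from the same inputs.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diffexpr, enrich, io_formats, mirtarget, netgraph, normalize, pcit, rif
from .matrix import ExpressionMatrix

DEFAULT_COMPARISONS = ("HE/TE", "HE/TP", "TE/TP")


@dataclass
class PipelineParams:
    comparisons: Sequence[str] = DEFAULT_COMPARISONS
    min_rpkm: float = 2.0
    min_samples: int = 3
    log2_offset: float = 1.0
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    rif_z_threshold: float = 1.96
    correlation_cutoff: float = 0.95
    require_pcit: bool = True
    mfe_threshold: float = -20.0
    drop_animal_interaction: bool = False
    seed: int = 0


@dataclass
class PipelineConfig:
    counts: str
    samples: str
    annotation: str
    outdir: str
    mirna_fasta: Optional[str] = None
    target_fasta: Optional[str] = None
    gene_sets: Optional[str] = None
    tf_list: Optional[str] = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = PipelineParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["params"]["comparisons"] = list(raw["params"]["comparisons"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class PipelineResult:
    normalized: ExpressionMatrix
    kept_ids: List[str]
    de_table: pd.DataFrame
    de_summary: pd.DataFrame
    biotype_summary: pd.DataFrame
    rif_table: pd.DataFrame
    edges: pd.DataFrame
    network: nx.Graph
    components: List[List[str]]
    triage: pd.DataFrame
    triage_pairs: List[Tuple[str, str]]
    enrichment: Dict[str, pd.DataFrame]
    model_fit: normalize.MixedModelFit
    notices: List[str]


# ---------------------------------------------------------------------------
# reporting tables
# ---------------------------------------------------------------------------


def biotype_summary(
    annotation: pd.DataFrame, expressed_ids: Sequence[str]
) -> pd.DataFrame:
    """Counts and percentages of expressed transcripts per biotype."""
    ids = list(expressed_ids)
    missing = set(ids) - set(annotation.index)
    if missing:
        raise KeyError(f"unannotated ids: {sorted(missing)[:5]}")
    if not ids:
        return pd.DataFrame(columns=["biotype", "count", "percent"])
    counts = annotation.loc[ids, "biotype"].value_counts()
    total = counts.sum()
    return pd.DataFrame(
        {
            "biotype": counts.index,
            "count": counts.to_numpy(),
            "percent": np.round(100.0 * counts.to_numpy() / total, 1),
        }
    ).reset_index(drop=True)


def de_summary(de_table: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Biotype x comparison DE counts; the Total column is the size of the
    union of DE transcripts across comparisons (not a row sum)."""
    comparisons = sorted(de_table["comparison"].unique())
    flagged = de_table[de_table["is_de"]]
    biotypes = [b for b in io_formats.BIOTYPES]
    rows = []
    for bio in biotypes + ["Total"]:
        if bio == "Total":
            sub = flagged
        else:
            ids = set(annotation.index[annotation["biotype"] == bio])
            sub = flagged[flagged["transcript_id"].isin(ids)]
        row = {"biotype": bio}
        for comp in comparisons:
            row[comp] = int((sub["comparison"] == comp).sum())
        row["Total"] = int(sub["transcript_id"].nunique())
        rows.append(row)
    return pd.DataFrame(rows, columns=["biotype"] + comparisons + ["Total"])


# ---------------------------------------------------------------------------
# triage
# ---------------------------------------------------------------------------


def triage_regulators(
    network: nx.Graph,
    rif_table: pd.DataFrame,
    annotation: pd.DataFrame,
    mirnas: Optional[Dict[str, str]],
    targets: Optional[Dict[str, str]],
    mfe_threshold: float = -20.0,
) -> Tuple[pd.DataFrame, List[Tuple[str, str]], List[str]]:
    """Down-regulation triage for each RIF-significant small RNA in the net.

    Chain per regulator: negative extreme-correlation mRNA first neighbors
    -> those with a seed site for the regulator -> those whose duplex mfe
    falls below the threshold (the candidate target list; the chain is a
    subset chain by construction). Without sequences the triage stops after
    the correlation stage and says so in the notices.
    """
    notices: List[str] = []
    regulators = [
        r for r in rif.significant_regulators(rif_table) if r in network
    ]
    have_seqs = bool(mirnas) and bool(targets)
    if not have_seqs:
        notices.append(
            "no sequences supplied; triage stops at the negative-correlation stage"
        )

    rows = []
    pairs: List[Tuple[str, str]] = []
    for reg in regulators:
        summary = netgraph.neighborhood_summary(network, reg)
        neg_mrna = [
            n
            for n in summary["negative_neighbors"]
            if n in annotation.index and annotation.loc[n, "biotype"] == "mRNA"
        ]
        seed_confirmed: List[str] = []
        mfe_confirmed: List[str] = []
        if have_seqs and reg in mirnas:
            candidate_targets = {
                t: targets[t] for t in neg_mrna if t in targets
            }
            if candidate_targets:
                sites = mirtarget.scan_seed_sites(
                    {reg: mirnas[reg]}, candidate_targets
                )
                seed_confirmed = sorted({s.target_id for s in sites})
                duplexes = [
                    mirtarget.duplex_mfe(
                        mirnas[reg], candidate_targets[t], mirna_id=reg, target_id=t
                    )
                    for t in seed_confirmed
                ]
                confirmed = mirtarget.call_targets(sites, duplexes, mfe_threshold)
                mfe_confirmed = sorted(t for _, t in confirmed)
                pairs.extend((reg, t) for t in mfe_confirmed)
        elif have_seqs:
            notices.append(f"no mature sequence for regulator {reg}; skipped")
        rows.append(
            {
                "regulator_id": reg,
                "degree": summary["degree"],
                "n_positive": summary["n_positive"],
                "n_negative": summary["n_negative"],
                "negative_mrna_neighbors": ",".join(neg_mrna),
                "seed_confirmed": ",".join(seed_confirmed),
                "mfe_confirmed": ",".join(mfe_confirmed),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "regulator_id",
            "degree",
            "n_positive",
            "n_negative",
            "negative_mrna_neighbors",
            "seed_confirmed",
            "mfe_confirmed",
        ],
    )
    return frame, sorted(set(pairs)), notices


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def run_pipeline(
    counts: ExpressionMatrix,
    samples: pd.DataFrame,
    annotation: pd.DataFrame,
    params: Optional[PipelineParams] = None,
    mirnas: Optional[Dict[str, str]] = None,
    target_seqs: Optional[Dict[str, str]] = None,
    gene_sets: Optional[Dict[str, Dict]] = None,
) -> PipelineResult:
    """Run the full in-memory analysis chain (see module docstring)."""
    params = params or PipelineParams()
    notices: List[str] = []

    present = set(samples.loc[list(counts.sample_ids), "tissue"])
    comparisons = []
    for comp in params.comparisons:
        t1, t2 = diffexpr.comparison_tissues(comp)
        if t1 in present and t2 in present:
            comparisons.append(comp)
        else:
            notices.append(f"comparison {comp} skipped: tissue missing from data")
    if not comparisons:
        raise ValueError("no computable comparisons for the supplied tissues")

    # normalization chain; true mapped-read depths from the sample sheet
    # take precedence over column totals when available
    depth = None
    if "mapped_reads" in samples.columns:
        depth = (
            samples.loc[list(counts.sample_ids), "mapped_reads"].astype(float) / 1e6
        )
    rpkm_m = normalize.rpkm(counts, annotation, mapped_reads_millions=depth)
    kept, removed = diffexpr.filter_low_expression(
        rpkm_m, params.min_rpkm, params.min_samples
    )
    if not kept:
        raise ValueError("expression filter removed every transcript")
    rpkm_kept = rpkm_m.subset_transcripts(kept)
    log2_m = normalize.log2_transform(rpkm_kept, params.log2_offset)
    fit, normalized = normalize.fit_mixed_model(
        log2_m, samples, drop_animal_interaction=params.drop_animal_interaction
    )

    # differential expression
    de_table = diffexpr.run_differential_expression(
        normalized, samples, comparisons, params.alpha, params.lfc_threshold
    )
    summary = de_summary(de_table, annotation)
    bio_summary = biotype_summary(annotation, kept)

    # RIF
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rif_table = rif.run_rif(
            normalized, samples, de_table, annotation, comparisons,
            params.rif_z_threshold,
        )
    notices.extend(str(w.message) for w in caught)

    # PCIT network over the union of DE transcripts, all samples
    union_de = diffexpr.de_ids(de_table)
    if len(union_de) >= 3:
        corr = pcit.correlation_matrix(normalized, union_de)
        sig = pcit.pcit_significant(corr)
        if params.require_pcit:
            edges = pcit.extreme_edges(corr, sig, params.correlation_cutoff)
        else:
            table = pcit.edge_table(corr, sig, params.correlation_cutoff)
            edges = table.loc[
                table["r"].abs() > params.correlation_cutoff,
                ["node_a", "node_b", "r"],
            ].reset_index(drop=True)
    else:
        notices.append("fewer than 3 DE transcripts; network skipped")
        edges = pd.DataFrame(columns=["node_a", "node_b", "r"])

    network = netgraph.build_network(edges, de_table, annotation, rif_table)
    if network.number_of_nodes() >= 2:
        netgraph.classify_hubs(network)
    comps = netgraph.components(network)

    # triage
    triage, pairs, triage_notices = triage_regulators(
        network, rif_table, annotation, mirnas, target_seqs, params.mfe_threshold
    )
    notices.extend(triage_notices)

    # enrichment (universe = transcripts passing the expression filter)
    enrichment: Dict[str, pd.DataFrame] = {}
    if gene_sets:
        universe = kept
        for comp in comparisons:
            query = diffexpr.de_ids(de_table, comp)
            if query:
                enrichment[comp.replace("/", "_")] = enrich.enrich(
                    query, gene_sets, universe
                )
        if comps and len(comps[0]) > 1:
            query = [t for t in comps[0] if t in set(universe)]
            if query:
                enrichment["largest_component"] = enrich.enrich(
                    query, gene_sets, universe
                )

    return PipelineResult(
        normalized=normalized,
        kept_ids=kept,
        de_table=de_table,
        de_summary=summary,
        biotype_summary=bio_summary,
        rif_table=rif_table,
        edges=edges,
        network=network,
        components=comps,
        triage=triage,
        triage_pairs=pairs,
        enrichment=enrichment,
        model_fit=fit,
        notices=notices,
    )


def run_all(config: PipelineConfig) -> Path:
    """File-based entry point: load inputs, run, write every intermediate."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts_df = io_formats.read_counts(config.counts)
    samples = io_formats.read_sample_sheet(config.samples)
    annotation = io_formats.read_annotation(config.annotation)
    missing = set(counts_df.columns) - set(samples.index)
    if missing:
        raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
    counts = ExpressionMatrix(counts_df, "counts")

    mirnas = io_formats.read_fasta(config.mirna_fasta) if config.mirna_fasta else None
    target_seqs = (
        io_formats.read_fasta(config.target_fasta) if config.target_fasta else None
    )
    gene_sets = io_formats.read_gmt(config.gene_sets) if config.gene_sets else None
    if config.tf_list:
        tf_ids = set(Path(config.tf_list).read_text().split())
        annotation["is_tf"] = annotation["transcript_id"].isin(tf_ids)

    result = run_pipeline(
        counts,
        samples,
        annotation,
        config.params,
        mirnas,
        target_seqs,
        gene_sets,
    )

    io_formats.write_matrix(result.normalized.values, outdir / "normalized.tsv")
    result.de_table.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
    result.de_summary.to_csv(outdir / "de_summary.tsv", sep="\t", index=False)
    result.biotype_summary.to_csv(
        outdir / "biotype_summary.tsv", sep="\t", index=False
    )
    result.rif_table.to_csv(outdir / "rif_table.tsv", sep="\t", index=False)
    result.edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    io_formats.write_network(result.network, outdir / "network.graphml", "graphml")
    io_formats.write_network(result.network, outdir / "network.sif", "sif")
    result.triage.to_csv(outdir / "triage.tsv", sep="\t", index=False)
    for name, table in result.enrichment.items():
        table.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False)

    pca_coords, pca_var = normalize.pca_qc(result.normalized)
    pca_coords.to_csv(outdir / "pca_coordinates.tsv", sep="\t", index_label="sample_id")

    io_formats.write_json(
        {
            "version": __version__,
            "seed": config.params.seed,
            "params": {
                k: (list(v) if isinstance(v, (tuple, list)) else v)
                for k, v in dataclasses.asdict(config.params).items()
            },
            "n_transcripts_in": counts.shape[0],
            "n_kept": len(result.kept_ids),
            "network": netgraph.network_summary(result.network),
            "variance_components": result.model_fit.variance_components,
            "library_effects": result.model_fit.library_effects.to_dict(),
            "candidate_pairs": [list(p) for p in result.triage_pairs],
            "notices": result.notices,
        },
        outdir / "run_report.json",
    )
    return outdir
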