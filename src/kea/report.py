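"""Waterfall output, annotation, network export and the pipeline driver."""

from __future__ import annotations

import json
import logging
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexp, enrich, ksdb, preprocess
from .config import ConfigError, dump_config, load_config
from .io import FormatError, assemble_matrix, parse_phosphosty, read_design

log = logging.getLogger(__name__)


def waterfall_data(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Signed -log10(primary p) bar heights for the reported kinases.

    Over-active kinases get positive heights, under-active negative; rows
    are ordered over-active descending by height, then under-active
    descending by |height| — red and blue halves of the waterfall.
    """
    reported = enrich.reported_kinases(results)
    if reported.empty:
        warnings.warn("no kinases to report; waterfall is empty")
        return pd.DataFrame(
            columns=["kinase", "direction", "signed_height", "primary_p"]
        )
    heights = -np.log10(reported["primary_p"].to_numpy())
    signs = np.where(reported["direction"].to_numpy() == "over", 1.0, -1.0)
    table = pd.DataFrame(
        {
            "kinase": reported.index,
            "direction": reported["direction"].to_numpy(),
            "signed_height": signs * heights,
            "primary_p": reported["primary_p"].to_numpy(),
        }
    )
    over = table[table["direction"] == "over"].sort_values(
        "signed_height", ascending=False, kind="mergesort"
    )
    under = table[table["direction"] == "under"].sort_values(
        "signed_height", ascending=True, kind="mergesort"
    )
    under = under.iloc[::-1]  # descending by |height|
    return pd.concat([over, under]).reset_index(drop=True)


def plot_waterfall(table: pd.DataFrame, path: str | Path) -> None:
    """Render the waterfall bar chart (red = over-active, blue = under-active)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(table) + 1), 4))
    colors = ["#c0392b" if d == "over" else "#2980b9" for d in table["direction"]]
    labels = [
        f"{k} ({r})" if isinstance(r, str) and r else k
        for k, r in zip(table["kinase"], table.get("role", [""] * len(table)))
    ]
    ax.bar(range(len(table)), table["signed_height"], color=colors)
    ax.set_xticks(range(len(table)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel(r"signed $-\log_{10}$ p")
    ax.set_title("Kinase activity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def annotate_ts(table: pd.DataFrame, annotation_path: str | Path) -> pd.DataFrame:
    """Left-join tumor-suppressor/oncogene roles onto kinase rows.

    The annotation TSV needs ``gene`` and ``role`` columns (e.g. from a
    literature-mined cancer-gene resource); unmatched kinases stay
    unlabeled.
    """
    ann = pd.read_csv(annotation_path, sep=None, engine="python")
    for col in ("gene", "role"):
        if col not in ann.columns:
            raise FormatError(f"{annotation_path}: annotation needs column {col!r}")
    roles = ann.drop_duplicates("gene").set_index("gene")["role"]
    out = table.copy()
    key = out["kinase"] if "kinase" in out.columns else out.index
    out["role"] = [roles.get(k, "") for k in key]
    return out


_COMPOSITE_RE = re.compile(r"^[A-Za-z0-9-]+(/[A-Za-z0-9-]+)+$")


def decouple_name(name: str) -> list[str]:
    """Split composite kinase labels into individual gene symbols.

    ``MEK1/2`` becomes ``MEK1, MEK2`` (a short alternative replaces the
    trailing characters of the first symbol); ``ABL1/BCR`` stays two full
    names.
    """
    if not _COMPOSITE_RE.match(name):
        return [name]
    parts = name.split("/")
    head = parts[0]
    out = [head]
    for alt in parts[1:]:
        if len(alt) < len(head):
            out.append(head[: len(head) - len(alt)] + alt)
        else:
            out.append(alt)
    return out


def export_network_table(
    results: dict[str, pd.DataFrame],
    min_confidence: float = 0.8,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node table plus edge-request manifest for external network import.

    Composite names are decoupled into individual gene symbols so the rows
    can be fed directly to STRING/Cytoscape; no network API is called.  The
    manifest records the minimum overall edge confidence to request.
    """
    reported = enrich.reported_kinases(results)
    rows = []
    for kinase, row in reported.iterrows():
        for gene in decouple_name(str(kinase)):
            rows.append(
                {
                    "gene": gene,
                    "direction": row["direction"],
                    "primary_p": row["primary_p"],
                    "rank_score": row["rank_score"],
                }
            )
    nodes = pd.DataFrame(rows, columns=["gene", "direction", "primary_p", "rank_score"])
    manifest = pd.DataFrame(
        [
            {"parameter": "min_confidence", "value": min_confidence},
            {"parameter": "species", "value": 9606},
            {"parameter": "n_nodes", "value": len(nodes)},
        ]
    )
    if outdir is not None:
        outdir = Path(outdir)
        nodes.to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)
        manifest.to_csv(outdir / "network_edge_request.tsv", sep="\t", index=False)
    return nodes, manifest


def run_pipeline(config: str | Path | dict) -> dict:
    """Execute the full pipeline from a YAML configuration.

    Parsing -> preprocessing -> differential testing -> database assembly
    -> two-directional enrichment -> reports, with every stage output, the
    resolved configuration and a machine-readable summary written to the
    output directory.  A fixed seed makes the run directory reproducible.
    """
    cfg = load_config(config)
    outdir = Path(cfg["output"])
    outdir.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, outdir / "resolved_config.yaml")
    seed = int(cfg["seed"])
    summary: dict = {"seed": seed}

    # --- input --------------------------------------------------------------
    if cfg["input"]["simulate"] is not None:
        from .simulate import SimulationConfig, simulate_dataset

        sim_kwargs = dict(cfg["input"]["simulate"])
        sim_kwargs.setdefault("seed", seed)
        if "conditions" in sim_kwargs:
            sim_kwargs["conditions"] = tuple(sim_kwargs["conditions"])
        sim_cfg = SimulationConfig(**sim_kwargs)
        simdir = outdir / "simulated_input"
        _, design, db, truth = simulate_dataset(sim_cfg, outdir=simdir)
        phospho_paths = [simdir / "phospho_sty.txt"]
        design_map = design
    else:
        phospho = cfg["input"]["phospho"]
        phospho_paths = phospho if isinstance(phospho, list) else [phospho]
        for p in phospho_paths:
            if not Path(p).exists():
                raise ConfigError(f"input.phospho: file not found: {p}")
        design_map = read_design(cfg["input"]["design"])
        db = None

    records = parse_phosphosty([Path(p) for p in phospho_paths], design_map)
    summary["n_records"] = len(records)
    m = assemble_matrix(
        records, design_map,
        merge_multiplicity=cfg["preprocess"]["merge_multiplicity"],
    )
    summary["n_sites_raw"] = int(m.data.shape[0])
    m.to_tsv(outdir / "matrix_raw.tsv")

    # --- preprocessing ------------------------------------------------------
    m = preprocess.preprocess_matrix(
        m,
        loc_prob_min=cfg["preprocess"]["loc_prob_min"],
        impute_mode="impute" if cfg["preprocess"]["impute"] else "zero",
        seed=seed,
        minprob_q=cfg["preprocess"]["minprob_q"],
        minprob_sigma_scale=cfg["preprocess"]["minprob_sigma_scale"],
    )
    summary["n_sites_processed"] = int(m.data.shape[0])
    m.to_tsv(outdir / "matrix_processed.tsv")

    # --- database -----------------------------------------------------------
    if db is None:
        if cfg["database"]["load"]:
            db = ksdb.KinaseSubstrateDB.load(cfg["database"]["load"])
        else:
            synonyms = ksdb.load_synonyms(cfg["database"]["synonyms"])
            lists = []
            for name, path in cfg["database"]["sources"].items():
                assocs = ksdb.parse_source(name, path)
                lists.append(ksdb.unify_kinase_names(assocs, synonyms))
            db = ksdb.build_metadb(lists, synonyms=synonyms)
    if cfg["database"]["networkin"]:
        from .io import base_site_key

        universe = {base_site_key(k) for k in m.data.index}
        predictions = ksdb.load_networkin(
            cfg["database"]["networkin"],
            score_min=cfg["database"]["networkin_score_min"],
            universe=universe,
        )
        db = ksdb.merge_db(db, predictions)
    db.save(outdir / "ksdb")
    coverage, per_kinase = ksdb.coverage_report(db, m)
    per_kinase.rename("n_measured_substrates").to_csv(
        outdir / "kinase_coverage.tsv", sep="\t"
    )
    summary["db_n_kinases"] = len(db.associations)
    summary["db_n_associations"] = db.n_associations
    summary["coverage_fraction"] = round(float(coverage), 6)

    # --- differential testing ----------------------------------------------
    comp = cfg["comparison"]
    if comp["mode"] == "two_group":
        diff = diffexp.welch_test(m, comp["test"], comp["reference"])
        comparison_name = f"{comp['test']}_vs_{comp['reference']}"
    else:
        diff = diffexp.one_vs_rest(m, comp["test"], reference=comp["reference_style"])
        comparison_name = f"{comp['test']}_vs_rest"
    summary["comparison"] = comparison_name
    summary["n_sites_tested"] = int(diff.shape[0])
    volcano = diff.assign(neg_log10_p=-np.log10(diff["p_value"].clip(lower=1e-300)))
    volcano.to_csv(outdir / f"diff_{comparison_name}.tsv", sep="\t")

    # --- enrichment ---------------------------------------------------------
    results = enrich.enrich_kinases(
        diff, db,
        min_set_size=cfg["enrichment"]["min_set_size"],
        set_p_cutoff=cfg["enrichment"]["set_p_cutoff"],
        fdr_cutoff=cfg["enrichment"]["fdr_cutoff"],
        b_null=cfg["enrichment"]["b_null"],
        seed=seed,
    )
    for direction, table in results.items():
        table.to_csv(outdir / f"enrichment_{direction}.tsv", sep="\t")
        summary[f"n_significant_{direction}"] = int(
            (table["significant"] & table["retained"]).sum()
        )
    summary["n_sets_tested"] = int(results["over"].shape[0])

    # --- reports ------------------------------------------------------------
    wf = waterfall_data(results)
    if cfg["report"]["cancermine"]:
        wf = annotate_ts(wf, cfg["report"]["cancermine"])
    wf.to_csv(outdir / "waterfall.tsv", sep="\t", index=False)
    if cfg["report"]["waterfall_plot"] and not wf.empty:
        plot_waterfall(wf, outdir / "waterfall.png")
    export_network_table(
        results, min_confidence=cfg["report"]["min_confidence"], outdir=outdir
    )

    summary["reported_kinases"] = sorted(wf["kinase"]) if not wf.empty else []
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    log.info("pipeline finished: %s", outdir)
    return summary
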