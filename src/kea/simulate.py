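"""Synthetic phosphoproteomics datasets with planted kinase activities.

The generator emulates the data model the pipeline consumes: a MaxQuant
phosphosite table (localization probabilities, contaminant/reverse rows,
multiplicity-split intensity columns), log-normal intensities with
condition effects planted on the substrate sites of chosen "active"
kinases, sporadic missing-at-random dropout, intensity-dependent
missing-not-at-random dropout (logistic in log2 intensity, the
left-censoring picture that motivates MinProb imputation), and a matching
kinase-substrate database written both as a native bundle and in the
per-source dialects the parsers expect.  Every simulation ships a ground
truth object for parameter-recovery evaluation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import PhosphoSiteRecord, make_site_key
from .ksdb import Association, KinaseSubstrateDB, build_metadb


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults describe a small two-condition triplicate experiment: 2,000
    phosphosites, 50 kinases with 15 substrates each, 3 over-active kinases
    shifted by +1.5 log2 units in the test condition, replicate noise 0.5
    log2 units, and realistic MAR/MNAR missingness.
    """

    n_sites: int = 2000
    conditions: tuple[str, ...] = ("control", "treat")
    n_replicates: int = 3
    n_kinases: int = 50
    substrates_per_kinase: int = 15
    n_active: int = 3
    active_direction: str = "over"  # "over", "under" or "mixed"
    effect_size: float = 1.5  # log2 units, applied in the last condition
    noise_sd: float = 0.5  # replicate noise, log2 units
    baseline_mean: float = 23.0  # log2 intensity
    baseline_sd: float = 2.0
    mar_rate: float = 0.05  # per-cell sporadic dropout
    mnar_midpoint_quantile: float = 0.005  # of the baseline distribution
    mnar_steepness: float = 6.0  # logistic slope per log2 unit
    contaminant_frac: float = 0.02
    reverse_frac: float = 0.02
    low_locprob_frac: float = 0.1
    multiplicity2_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mar_rate", "contaminant_frac", "reverse_frac",
                     "low_locprob_frac", "multiplicity2_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if self.n_kinases * self.substrates_per_kinase > self.n_sites:
            raise ValueError(
                "infeasible config: kinases x substrates exceeds n_sites"
            )
        if self.n_active > self.n_kinases:
            raise ValueError("more active kinases than kinases")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery evaluation."""

    active_kinases: dict[str, str]  # kinase -> direction
    site_kinase: dict[str, str]  # base site key -> kinase (planted membership)
    true_means: dict[str, dict[str, float]]  # base site key -> condition -> mean
    mechanism: dict[str, dict[str, str]]  # site key -> sample -> observed|MAR|MNAR
    records: list[PhosphoSiteRecord] = field(default_factory=list, repr=False)
    matrix: pd.DataFrame | None = field(default=None, repr=False)

    def pair_labels(self, conditions, samples_of) -> pd.DataFrame:
        """Mechanism-aware (site, condition) labels comparable to the
        pipeline's count-based classification: complete when nothing is
        missing, MNAR when >=2 replicates are missing, and for a single
        missing replicate the label of that cell's mechanism."""
        rows = {}
        for key, per_sample in self.mechanism.items():
            rows[key] = {}
            for cond in conditions:
                mechs = [per_sample[s] for s in samples_of[cond]]
                n_missing = sum(mech != "observed" for mech in mechs)
                if n_missing == 0:
                    rows[key][cond] = "complete"
                elif n_missing >= 2:
                    rows[key][cond] = "MNAR"
                else:
                    rows[key][cond] = next(m for m in mechs if m != "observed")
        return pd.DataFrame(rows).T

    def to_json(self, path: str | Path) -> None:
        payload = {
            "active_kinases": self.active_kinases,
            "site_kinase": self.site_kinase,
            "true_means": self.true_means,
            "mechanism": self.mechanism,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def simulate_dataset(
    cfg: SimulationConfig,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, KinaseSubstrateDB, GroundTruth]:
    """Generate one synthetic experiment.

    Returns the MaxQuant-style table, the design table, the matching
    kinase-substrate database and the ground truth.  When ``outdir`` is
    given, the table (``phospho_sty.txt``), design (``design.csv``),
    database bundle and ground-truth JSON are also written, byte-identically
    for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    samples = [
        f"{cond}_{r + 1}" for cond in cfg.conditions for r in range(cfg.n_replicates)
    ]
    design = pd.DataFrame(
        {
            "sample": samples,
            "condition": [s.rsplit("_", 1)[0] for s in samples],
            "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
        }
    ).set_index("sample")
    test_cond = cfg.conditions[-1]

    # --- site identities ---------------------------------------------------
    genes = np.array([f"GENE{i + 1:05d}" for i in range(n)])
    residues = rng.choice(np.array(["S", "T", "Y"]), size=n, p=[0.84, 0.14, 0.02])
    positions = rng.integers(1, 1000, size=n)
    multiplicities = np.where(rng.random(n) < cfg.multiplicity2_frac, 2, 1)

    # --- kinase membership (disjoint substrate blocks) ---------------------
    kinases = [f"KIN{i + 1:03d}" for i in range(cfg.n_kinases)]
    site_kinase: dict[str, str] = {}
    assigned = rng.permutation(n)[: cfg.n_kinases * cfg.substrates_per_kinase]
    base_keys = np.array(
        [make_site_key(g, r, p) for g, r, p in zip(genes, residues, positions)]
    )
    for ki, kinase in enumerate(kinases):
        block = assigned[ki * cfg.substrates_per_kinase:(ki + 1) * cfg.substrates_per_kinase]
        for idx in block:
            site_kinase[base_keys[idx]] = kinase

    if cfg.active_direction == "mixed":
        dirs = ["over" if i % 2 == 0 else "under" for i in range(cfg.n_active)]
    else:
        dirs = [cfg.active_direction] * cfg.n_active
    active = {kinases[i]: dirs[i] for i in range(cfg.n_active)}

    # --- true means and noisy intensities ----------------------------------
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    effect = np.zeros(n)
    for idx in range(n):
        kinase = site_kinase.get(base_keys[idx])
        if kinase in active:
            effect[idx] = cfg.effect_size if active[kinase] == "over" else -cfg.effect_size
    true_means = {
        base_keys[i]: {
            cond: float(baseline[i] + (effect[i] if cond == test_cond else 0.0))
            for cond in cfg.conditions
        }
        for i in range(n)
    }
    X = np.empty((n, len(samples)))
    for j, s in enumerate(samples):
        cond = design.loc[s, "condition"]
        mean = baseline + (effect if cond == test_cond else 0.0)
        X[:, j] = mean + rng.normal(0.0, cfg.noise_sd, size=n)

    # --- missingness --------------------------------------------------------
    from scipy.stats import norm

    x0 = cfg.baseline_mean + norm.ppf(cfg.mnar_midpoint_quantile) * cfg.baseline_sd
    p_mnar = 1.0 / (1.0 + np.exp(cfg.mnar_steepness * (X - x0)))
    drop_mnar = rng.random(X.shape) < p_mnar
    drop_mar = (rng.random(X.shape) < cfg.mar_rate) & ~drop_mnar
    mechanism_arr = np.where(drop_mnar, "MNAR", np.where(drop_mar, "MAR", "observed"))
    observed = ~(drop_mnar | drop_mar)

    # --- quality flags ------------------------------------------------------
    u = rng.random(n)
    is_contaminant = u < cfg.contaminant_frac
    is_reverse = (u >= cfg.contaminant_frac) & (u < cfg.contaminant_frac + cfg.reverse_frac)
    low_loc = rng.random(n) < cfg.low_locprob_frac
    loc_prob = np.where(low_loc, rng.uniform(0.1, 0.7, size=n),
                        rng.uniform(0.75, 1.0, size=n)).round(3)

    # --- records and table --------------------------------------------------
    records: list[PhosphoSiteRecord] = []
    mechanism: dict[str, dict[str, str]] = {}
    rows = []
    for i in range(n):
        intens = {
            s: float(2.0 ** X[i, j]) if observed[i, j] else np.nan
            for j, s in enumerate(samples)
        }
        rec = PhosphoSiteRecord(
            protein_id=f"P{i + 1:05d}",
            gene_symbol=genes[i],
            residue=str(residues[i]),
            position=int(positions[i]),
            localization_prob=float(loc_prob[i]),
            multiplicity=int(multiplicities[i]),
            is_reverse=bool(is_reverse[i]),
            is_contaminant=bool(is_contaminant[i]),
            intensities=intens,
        )
        if any(np.isfinite(v) for v in intens.values()):
            records.append(rec)
        key = rec.site_key
        mechanism[key] = {s: str(mechanism_arr[i, j]) for j, s in enumerate(samples)}
        row = {
            "Proteins": rec.protein_id,
            "Gene names": rec.gene_symbol,
            "Amino acid": rec.residue,
            "Position": rec.position,
            "Localization prob": rec.localization_prob,
            "Reverse": "+" if rec.is_reverse else "",
            "Potential contaminant": "+" if rec.is_contaminant else "",
        }
        for mult in (1, 2):
            for s in samples:
                v = intens[s] if rec.multiplicity == mult else np.nan
                row[f"Intensity {s}___{mult}"] = 0.0 if not np.isfinite(v) else v
        rows.append(row)
    table = pd.DataFrame(rows)

    matrix = pd.DataFrame(
        {s: [rec.intensities[s] for rec in records] for s in samples},
        index=pd.Index([rec.site_key for rec in records], name="site"),
    )

    db = _build_sim_db(kinases, site_kinase)
    truth = GroundTruth(
        active_kinases=active,
        site_kinase=site_kinase,
        true_means=true_means,
        mechanism=mechanism,
        records=records,
        matrix=matrix,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_maxquant(table, outdir / "phospho_sty.txt")
        design.to_csv(outdir / "design.csv")
        db.save(outdir / "ksdb")
        truth.to_json(outdir / "ground_truth.json")
        with open(outdir / "sim_config.json", "w") as fh:
            json.dump(asdict(cfg), fh, indent=1)
    return table, design, db, truth


def _write_maxquant(table: pd.DataFrame, path: Path) -> None:
    out = table.copy()
    for col in out.columns:
        if col.startswith("Intensity "):
            # repr round-trips floats exactly, so parsing the written file
            # reproduces the in-memory truth bit for bit
            out[col] = out[col].map(lambda v: "0" if v == 0 else repr(float(v)))
    out.to_csv(path, sep="\t", index=False)


def _build_sim_db(kinases: list[str], site_kinase: dict[str, str]) -> KinaseSubstrateDB:
    assocs = [
        Association(kinase=k, substrate=s, evidence="experimental",
                    sources=frozenset({"PSP"}))
        for s, k in site_kinase.items()
    ]
    return build_metadb([assocs])


# -- per-source fixture writers ---------------------------------------------


def write_source_fixture(
    assocs: list[Association], source: str, path: str | Path
) -> None:
    """Write associations in one source's column dialect for parser tests."""
    rows = []
    for a in assocs:
        gene, site = a.substrate.rsplit("_", 1)
        residue, position = site[0], site[1:]
        if source == "PSP":
            rows.append({"GENE": a.kinase, "KIN_ORGANISM": "human",
                         "SUB_GENE": gene, "SUB_ORGANISM": "human",
                         "SUB_MOD_RSD": f"{residue}{position}"})
        elif source == "HPRD":
            rows.append({"ENZYME_GENE": a.kinase, "SUBSTRATE_GENE": gene,
                         "RESIDUE": residue, "POSITION": position})
        elif source == "RegPhos":
            rows.append({"catalytic_kinase": a.kinase, "GENE": gene,
                         "code": residue, "position": position,
                         "species": "human"})
        elif source == "Signor":
            long = {"S": "Ser", "T": "Thr", "Y": "Tyr"}[residue]
            rows.append({"ENTITYA": a.kinase, "ENTITYB": gene,
                         "MECHANISM": "phosphorylation",
                         "RESIDUE": f"{long}{position}", "TAX_ID": "9606"})
        elif source == "ELM":
            rows.append({"kinases": a.kinase, "gene": gene, "code": residue,
                         "position": position, "species": "Homo sapiens"})
        else:
            raise ValueError(f"unknown source {source!r}")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_networkin_fixture(
    predictions: list[tuple[str, str, float]], path: str | Path
) -> None:
    """Write (kinase, base site key, score) triples as a NetworKIN-style TSV."""
    rows = []
    for kinase, substrate, score in predictions:
        gene, site = substrate.rsplit("_", 1)
        rows.append({"substrate_name": gene, "residue": site[0],
                     "position": site[1:], "id": kinase,
                     "networkin_score": score})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def evaluate_recovery(
    results: dict[str, pd.DataFrame],
    truth: GroundTruth,
    all_kinases: list[str] | None = None,
) -> dict[str, float]:
    """Sensitivity, specificity and direction accuracy against the truth.

    A kinase counts as recovered when it is significant and retained in
    either direction; direction accuracy is scored among the recovered
    planted kinases.
    """
    reported: dict[str, str] = {}
    for direction, table in results.items():
        for kinase in table.index[table["significant"] & table["retained"]]:
            reported.setdefault(kinase, direction)
    truth_universe = set(truth.site_kinase.values())
    unknown = set(reported) - truth_universe
    if unknown:
        raise ValueError(f"reported kinases absent from ground truth: {sorted(unknown)}")
    planted = truth.active_kinases
    decoys = truth_universe - set(planted)
    recovered = [k for k in planted if k in reported]
    sensitivity = len(recovered) / len(planted) if planted else 1.0
    false_pos = [k for k in reported if k not in planted]
    specificity = 1.0 - (len(false_pos) / len(decoys) if decoys else 0.0)
    if recovered:
        direction_acc = float(
            np.mean([reported[k] == planted[k] for k in recovered])
        )
    else:
        direction_acc = 1.0 if not planted else 0.0
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "direction_accuracy": direction_acc,
        "n_reported": float(len(reported)),
        "n_false_positive": float(len(false_pos)),
    }
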