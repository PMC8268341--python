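"""Kinase-substrate meta-database: parsing, merging and coverage.

Experimentally observed kinase-substrate associations from five public
resources (PhosphoSitePlus, HPRD, RegPhos, Signor, phospho.ELM) are merged
into one meta-database keyed by (canonical kinase name, substrate site).
Kinase name redundancy across resources is resolved through a curated
synonym table.  Motif-based NetworKIN predictions, restricted to the sites
actually measured in a given experiment, can be layered on top with
``evidence='predicted'``; experimental evidence always takes precedence.
Kinases left with a single association carry no enrichment signal and are
removed.

No third-party database content ships with the package; parsers expect the
user-downloaded snapshots, with column dialects described in
``resources/source_columns.yaml``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources as importlib_resources
from pathlib import Path

import pandas as pd
import yaml

from .io import FormatError, base_site_key, make_site_key

log = logging.getLogger(__name__)

SOURCES = ("PSP", "HPRD", "RegPhos", "Signor", "ELM")

_SITE_RE = re.compile(r"^(?:p)?(Ser|Thr|Tyr|S|T|Y)[-]?(\d+)$", re.IGNORECASE)
_RESIDUE_MAP = {"SER": "S", "THR": "T", "TYR": "Y", "S": "S", "T": "T", "Y": "Y"}


@dataclass(frozen=True)
class Association:
    """One (kinase, substrate site) link with provenance."""

    kinase: str
    substrate: str  # base site key GENE_Y207, no multiplicity
    evidence: str  # "experimental" | "predicted"
    sources: frozenset[str]
    score: float | None = None  # prediction score, NetworKIN only


@dataclass
class KinaseSubstrateDB:
    """kinase -> {substrate -> Association}, with the synonym map used."""

    associations: dict[str, dict[str, Association]] = field(default_factory=dict)
    synonyms: dict[str, str] = field(default_factory=dict)

    @property
    def kinases(self) -> list[str]:
        return sorted(self.associations)

    def substrates(self, kinase: str) -> set[str]:
        return set(self.associations.get(kinase, {}))

    @property
    def n_associations(self) -> int:
        return sum(len(v) for v in self.associations.values())

    @property
    def n_substrates(self) -> int:
        return len({s for v in self.associations.values() for s in v})

    def iter_associations(self):
        for kinase in self.kinases:
            for sub in sorted(self.associations[kinase]):
                yield self.associations[kinase][sub]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "kinase": a.kinase,
                "substrate": a.substrate,
                "evidence": a.evidence,
                "sources": ";".join(sorted(a.sources)),
                "score": a.score,
            }
            for a in self.iter_associations()
        ]
        return pd.DataFrame(rows, columns=["kinase", "substrate", "evidence", "sources", "score"])

    def save(self, directory: str | Path) -> None:
        """Write the two-file TSV bundle (associations + synonyms)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        assoc_path = directory / "associations.tsv"
        with open(assoc_path, "w") as fh:
            fh.write("# kea kinase-substrate bundle v1\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)
        syn = pd.DataFrame(
            sorted(self.synonyms.items()), columns=["raw", "canonical"]
        )
        syn.to_csv(directory / "synonyms.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "KinaseSubstrateDB":
        directory = Path(directory)
        frame = pd.read_csv(directory / "associations.tsv", sep="\t", comment="#")
        syn_path = directory / "synonyms.tsv"
        synonyms: dict[str, str] = {}
        if syn_path.exists():
            syn = pd.read_csv(syn_path, sep="\t")
            synonyms = dict(zip(syn["raw"], syn["canonical"]))
        db = cls(synonyms=synonyms)
        for row in frame.itertuples(index=False):
            a = Association(
                kinase=row.kinase,
                substrate=row.substrate,
                evidence=row.evidence,
                sources=frozenset(str(row.sources).split(";")),
                score=None if pd.isna(row.score) else float(row.score),
            )
            db.associations.setdefault(a.kinase, {})[a.substrate] = a
        return db

    def to_gmt(self, path: str | Path) -> None:
        """Export kinase -> substrate-site sets in GMT format."""
        with open(path, "w") as fh:
            for kinase in self.kinases:
                subs = sorted(self.associations[kinase])
                fh.write("\t".join([kinase, "kea_meta_db"] + subs) + "\n")


# -- source parsing ---------------------------------------------------------


def _load_source_config(config: dict | None = None) -> dict:
    if config is not None:
        return config
    ref = importlib_resources.files("kea.resources").joinpath("source_columns.yaml")
    return yaml.safe_load(ref.read_text())


def _parse_site_token(token: str) -> tuple[str, int] | None:
    m = _SITE_RE.match(str(token).strip())
    if not m:
        return None
    return _RESIDUE_MAP[m.group(1).upper()], int(m.group(2))


def parse_source(
    name: str,
    path: str | Path,
    config: dict | None = None,
) -> list[Association]:
    """Parse one experimental source's snapshot into associations.

    Rows failing the configured species/mechanism filters or with malformed
    site annotations are skipped (counts logged).  All returned
    associations carry ``evidence='experimental'``.
    """
    cfg_all = _load_source_config(config)
    if name not in cfg_all or name == "NetworKIN":
        raise ValueError(f"unknown source {name!r}; expected one of {SOURCES}")
    cfg = cfg_all[name]
    table = pd.read_csv(path, sep=cfg.get("sep", "\t"), dtype=str, keep_default_na=False)

    for key in ("kinase", "substrate_gene"):
        if cfg[key] not in table.columns:
            raise FormatError(f"{path}: missing column {cfg[key]!r} for source {name}")

    n_filtered = 0
    for col, allowed in (cfg.get("filters") or {}).items():
        if col not in table.columns:
            continue
        allowed_lc = {str(v).lower() for v in allowed}
        keep = table[col].str.strip().str.lower().isin(allowed_lc)
        n_filtered += int((~keep).sum())
        table = table[keep]

    out: list[Association] = []
    n_malformed = 0
    for row in table.itertuples(index=False):
        rowd = dict(zip(table.columns, row))
        kinase = str(rowd[cfg["kinase"]]).strip().upper()
        gene = str(rowd[cfg["substrate_gene"]]).strip()
        parsed = None
        if "site" in cfg:
            parsed = _parse_site_token(rowd.get(cfg["site"], ""))
        else:
            res = str(rowd.get(cfg["residue"], "")).strip()
            pos = str(rowd.get(cfg["position"], "")).strip()
            if res and pos:
                parsed = _parse_site_token(res + pos)
        if not kinase or not gene or parsed is None:
            n_malformed += 1
            continue
        residue, position = parsed
        try:
            substrate = make_site_key(gene, residue, position)
        except ValueError:
            n_malformed += 1
            continue
        out.append(
            Association(
                kinase=kinase,
                substrate=substrate,
                evidence="experimental",
                sources=frozenset({name}),
            )
        )
    if n_filtered or n_malformed:
        log.info(
            "%s: kept %d associations (%d filtered, %d malformed)",
            name, len(out), n_filtered, n_malformed,
        )
    return out


def load_synonyms(path: str | Path | None = None) -> dict[str, str]:
    """Load the kinase synonym table (shipped curated TSV by default)."""
    if path is None:
        ref = importlib_resources.files("kea.resources").joinpath("kinase_synonyms.tsv")
        with importlib_resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    return {
        str(r).strip().upper(): str(c).strip().upper()
        for r, c in zip(table["raw"], table["canonical"])
    }


def unify_kinase_names(
    assocs: list[Association], synonyms: dict[str, str]
) -> list[Association]:
    """Replace raw kinase names with canonical ones; unmapped names pass through."""
    unmapped: set[str] = set()
    out = []
    for a in assocs:
        canonical = synonyms.get(a.kinase.upper())
        if canonical is None:
            unmapped.add(a.kinase)
            out.append(a)
        else:
            out.append(replace(a, kinase=canonical))
    if unmapped:
        log.warning("unify_kinase_names: %d names not in synonym table", len(unmapped))
    return out


def build_metadb(
    assoc_lists: list[list[Association]],
    synonyms: dict[str, str] | None = None,
) -> KinaseSubstrateDB:
    """Merge per-source association lists into the meta-database.

    Duplicate (kinase, substrate) pairs merge with a source-set union;
    kinases with a single association are removed.
    """
    merged: dict[tuple[str, str], Association] = {}
    for assocs in assoc_lists:
        for a in assocs:
            key = (a.kinase, a.substrate)
            prev = merged.get(key)
            if prev is None:
                merged[key] = a
            else:
                evidence = (
                    "experimental"
                    if "experimental" in (prev.evidence, a.evidence)
                    else "predicted"
                )
                score = prev.score if prev.score is not None else a.score
                merged[key] = replace(
                    prev,
                    evidence=evidence,
                    sources=prev.sources | a.sources,
                    score=score,
                )
    db = KinaseSubstrateDB(synonyms=synonyms or {})
    for a in merged.values():
        db.associations.setdefault(a.kinase, {})[a.substrate] = a
    _remove_single_entry_kinases(db)
    if not db.associations:
        raise ValueError("meta-database is empty after merging and filtering")
    log.info(
        "meta-database: %d associations, %d kinases, %d unique substrates",
        db.n_associations, len(db.associations), db.n_substrates,
    )
    return db


def _remove_single_entry_kinases(db: KinaseSubstrateDB) -> None:
    singletons = [k for k, v in db.associations.items() if len(v) < 2]
    for k in singletons:
        del db.associations[k]
    if singletons:
        log.info("removed %d single-entry kinases", len(singletons))


def load_networkin(
    path: str | Path,
    score_min: float = 2.0,
    universe: set[str] | None = None,
    config: dict | None = None,
) -> list[Association]:
    """Load NetworKIN predictions restricted to the measured site universe.

    ``universe`` holds base site keys (no multiplicity); predictions for
    sites outside it, or scoring below ``score_min``, are dropped.
    """
    cfg = _load_source_config(config)["NetworKIN"]
    table = pd.read_csv(path, sep=cfg.get("sep", "\t"), dtype=str, keep_default_na=False)
    if cfg["score"] not in table.columns:
        raise FormatError(f"{path}: missing NetworKIN score column {cfg['score']!r}")
    for key in ("kinase", "substrate_gene", "residue", "position"):
        if cfg[key] not in table.columns:
            raise FormatError(f"{path}: missing column {cfg[key]!r}")
    out: list[Association] = []
    n_skipped = 0
    for row in table.itertuples(index=False):
        rowd = dict(zip(table.columns, row))
        try:
            score = float(rowd[cfg["score"]])
        except ValueError:
            n_skipped += 1
            continue
        parsed = _parse_site_token(
            str(rowd[cfg["residue"]]).strip() + str(rowd[cfg["position"]]).strip()
        )
        gene = str(rowd[cfg["substrate_gene"]]).strip()
        kinase = str(rowd[cfg["kinase"]]).strip().upper()
        if parsed is None or not gene or not kinase:
            n_skipped += 1
            continue
        substrate = make_site_key(gene, *parsed)
        if score < score_min:
            continue
        if universe is not None and substrate not in universe:
            continue
        out.append(
            Association(
                kinase=kinase,
                substrate=substrate,
                evidence="predicted",
                sources=frozenset({"NetworKIN"}),
                score=score,
            )
        )
    if n_skipped:
        log.info("NetworKIN: skipped %d malformed rows", n_skipped)
    return out


def merge_db(
    experimental: KinaseSubstrateDB, predicted: list[Association]
) -> KinaseSubstrateDB:
    """Union the experimental meta-database with dataset-specific predictions.

    Experimental evidence takes precedence on conflicts (the source set
    still gains NetworKIN); the single-entry-kinase rule is re-applied.
    """
    merged = KinaseSubstrateDB(synonyms=dict(experimental.synonyms))
    for a in experimental.iter_associations():
        merged.associations.setdefault(a.kinase, {})[a.substrate] = a
    for a in predicted:
        slot = merged.associations.setdefault(a.kinase, {})
        prev = slot.get(a.substrate)
        if prev is None:
            slot[a.substrate] = a
        else:
            slot[a.substrate] = replace(
                prev, sources=prev.sources | a.sources,
                score=prev.score if prev.score is not None else a.score,
            )
    _remove_single_entry_kinases(merged)
    return merged


def coverage_report(db: KinaseSubstrateDB, m) -> tuple[float, pd.Series]:
    """Fraction of measured sites with >=1 kinase, and per-kinase substrate counts.

    Matrix site keys carry multiplicity suffixes; matching is on the base
    (gene, residue, position) key.
    """
    measured = list(m.data.index)
    if not measured:
        raise ValueError("empty matrix")
    measured_base = {base_site_key(k) for k in measured}
    covered_sites = {s for k in db.associations for s in db.associations[k]}
    n_covered = sum(1 for b in measured_base if b in covered_sites)
    fraction = n_covered / len(measured_base)
    per_kinase = pd.Series(
        {
            k: sum(1 for s in db.associations[k] if s in measured_base)
            for k in db.kinases
        },
        dtype=int,
    ).sort_values(ascending=False)
    return fraction, per_kinase
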