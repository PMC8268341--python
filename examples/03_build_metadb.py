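"""Build a kinase-substrate meta-database from per-source snapshot files.

Writes tiny synthetic snapshots in each supported source dialect, parses
them, unifies kinase names, merges into the meta-database and layers
NetworKIN-style predictions on top.
"""

import tempfile
from pathlib import Path

from kea import (Association, build_metadb, load_networkin, load_synonyms,
                 merge_db, parse_source, unify_kinase_names)
from kea.simulate import write_networkin_fixture, write_source_fixture


def assoc(k, s):
    return Association(kinase=k, substrate=s, evidence="experimental",
                       sources=frozenset({"PSP"}))


workdir = Path(tempfile.mkdtemp())
truth = {
    "PSP": [assoc("ABL1", "CRKL_Y207"), assoc("CK2A1", "TP53_S20"),
            assoc("CK2A1", "MYC_S62")],
    "Signor": [assoc("ABL1", "CRKL_Y207"), assoc("ABL1", "CRKL_Y251"),
               assoc("CSNK2A1", "TP53_S20")],
    "HPRD": [assoc("ATM", "TP53_S15"), assoc("ATM", "CHEK2_T68")],
}
synonyms = load_synonyms()  # shipped curated table: CK2A1 -> CSNK2A1, ...

lists = []
for source, assocs in truth.items():
    path = workdir / f"{source.lower()}.tsv"
    write_source_fixture(assocs, source, path)
    parsed = parse_source(source, path)
    lists.append(unify_kinase_names(parsed, synonyms))

db = build_metadb(lists, synonyms=synonyms)
print(f"experimental meta-database: {db.n_associations} associations, "
      f"{len(db.associations)} kinases, {db.n_substrates} substrates")
print(db.to_frame().to_string(index=False))
# note CK2A1 and CSNK2A1 merged into one kinase; duplicate (ABL1, CRKL_Y207)
# rows collapsed with a source-set union

nk_path = workdir / "networkin.tsv"
write_networkin_fixture([("ABL1", "CBL_Y700", 3.2), ("LYN", "CBL_Y700", 1.1)],
                        nk_path)
predictions = load_networkin(nk_path, score_min=2.0,
                             universe={"CBL_Y700", "CRKL_Y207"})
merged = merge_db(db, predictions)
print(f"\nafter predictions: {merged.n_associations} associations "
      f"(score >= 2.0, restricted to measured sites)")
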