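# Column mappings for the supported kinase-substrate source dialects.
# Each entry names the columns holding the kinase, the substrate gene and
# the modified site (either a combined residue+position column via `site`,
# or separate `residue` / `position` columns), plus row filters as
# column -> list of accepted values (case-insensitive).  Snapshot format
# drift is absorbed here without code changes.
PSP:
  sep: "\t"
  kinase: GENE
  substrate_gene: SUB_GENE
  site: SUB_MOD_RSD
  filters:
    KIN_ORGANISM: [human]
    SUB_ORGANISM: [human]
HPRD:
  sep: "\t"
  kinase: ENZYME_GENE
  substrate_gene: SUBSTRATE_GENE
  residue: RESIDUE
  position: POSITION
RegPhos:
  sep: "\t"
  kinase: catalytic_kinase
  substrate_gene: GENE
  residue: code
  position: position
  filters:
    species: [human]
Signor:
  sep: "\t"
  kinase: ENTITYA
  substrate_gene: ENTITYB
  site: RESIDUE
  filters:
    MECHANISM: [phosphorylation]
    TAX_ID: ["9606"]
ELM:
  sep: "\t"
  kinase: kinases
  substrate_gene: gene
  residue: code
  position: position
  filters:
    species: [Homo sapiens]
NetworKIN:
  sep: "\t"
  kinase: id
  substrate_gene: substrate_name
  residue: residue
  position: position
  score: networkin_score
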